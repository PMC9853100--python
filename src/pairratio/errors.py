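"""Exception hierarchy for pairratio."""


class PairRatioError(Exception):
    """Base class for all pairratio errors."""


class DomainError(PairRatioError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DesignError(PairRatioError, ValueError):
    """The design matrix is rank deficient or otherwise unusable."""


class NoInformationError(PairRatioError, ValueError):
    """No sample carries information (e.g. all pairwise totals are zero)."""


class NoDataError(PairRatioError, ValueError):
    """A zero policy or filter removed every sample."""
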