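"""All-pairs ratio analysis of a taxa-by-samples count table.

For k retained taxa there are k(k-1)/2 unordered pairs; each pair is fitted
once with the first taxon (in table order) as the numerator, and the
Benjamini-Hochberg step-up procedure controls the FDR across all tested
ratios of one treatment comparison. Results are summarized as a symmetric
significance grid and two taxon rankings ("unwrapping" and plain incident
counts). A taxon-versus-rest mode (the relative-abundance comparator,
"MWW") reuses the same beta-binomial machinery with the library total as
the denominator.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .betabin import PairData, fit_betabin, lrt_group_effect, wald_ci
from .errors import DesignError, DomainError
from . import logratio

__all__ = [
    "CountTable",
    "SignificanceGrid",
    "TaxonRanking",
    "enumerate_pairs",
    "prevalence_filter",
    "amalgamate",
    "bh_adjust",
    "run_all_pairs",
    "run_mww_mode",
    "build_grid",
    "unwrap_taxa",
    "count_taxa",
]

logger = logging.getLogger("pairratio")

RESULT_COLUMNS = [
    "taxon_a", "taxon_b", "estimate", "se", "ci_low", "ci_high",
    "p_value", "q_value", "n_informative", "status", "method_tag",
]


@dataclass
class CountTable:
    """A taxa-by-samples count matrix with per-sample metadata.

    ``counts`` has taxa as rows and samples as columns; ``metadata`` is
    indexed by sample id and must cover every sample column, with a
    ``group`` column and an optional ``study`` column.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DomainError("duplicate taxon ids")
        if self.counts.columns.has_duplicates:
            raise DomainError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise DomainError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise DomainError(f"metadata missing for samples: {missing}")
        # align metadata to column order; extra metadata rows are tolerated
        self.metadata = self.metadata.loc[self.counts.columns]
        self.metadata.index.name = "sample_id"

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def has_study(self) -> bool:
        return "study" in self.metadata.columns and self.metadata["study"].nunique() > 1

    def design(self, group_col: str = "group", include_study: bool | None = None) -> pd.DataFrame:
        """0/1 design columns from the metadata.

        The first group level in sorted order is the reference; the study
        indicator is added when two studies are present (or on request).
        """
        levels = sorted(self.metadata[group_col].unique())
        if len(levels) != 2:
            raise DesignError(f"need exactly 2 levels in {group_col!r}, found {levels}")
        design = pd.DataFrame(index=self.counts.columns)
        design["treatment"] = (self.metadata[group_col] == levels[1]).astype(int)
        if include_study is None:
            include_study = self.has_study()
        if include_study:
            if not self.has_study():
                logger.warning("study column absent or single-level; dropping study term")
            else:
                slevels = sorted(self.metadata["study"].unique())
                if len(slevels) != 2:
                    raise DesignError("only two-study designs are supported")
                design["study"] = (self.metadata["study"] == slevels[1]).astype(int)
        return design

    def pair_data(self, taxon_a, taxon_b, design: pd.DataFrame | None = None) -> PairData:
        """Counts of one pair; numerator is ``taxon_a``."""
        ya = self.counts.loc[taxon_a].to_numpy()
        yb = self.counts.loc[taxon_b].to_numpy()
        return PairData(
            numerator_counts=ya,
            pair_totals=ya + yb,
            design=self.design() if design is None else design,
            sample_ids=np.asarray(self.sample_ids),
        )


@dataclass
class SignificanceGrid:
    """Symmetric boolean matrix marking significant ratios at a threshold."""

    matrix: pd.DataFrame
    threshold: float

    @property
    def taxa(self) -> list:
        return list(self.matrix.index)

    def degree(self) -> pd.Series:
        return self.matrix.sum(axis=1).astype(int)

    def n_significant_ratios(self) -> int:
        return int(self.matrix.to_numpy().sum() // 2)


@dataclass
class TaxonRanking:
    """Ordered taxa with their significant-ratio counts."""

    taxa: list
    counts: list
    method: str  # "unwrap" | "count"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"taxon": self.taxa, "n_significant_ratios": self.counts,
                             "rank": range(1, len(self.taxa) + 1)})


def enumerate_pairs(table: CountTable) -> list[tuple]:
    """All k(k-1)/2 unordered taxon pairs in table order."""
    taxa = table.taxon_ids
    if len(taxa) < 2:
        raise DomainError("need at least 2 taxa to form a pair")
    return [(taxa[i], taxa[j]) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]


def prevalence_filter(table: CountTable, min_prevalence: float = 0.2) -> CountTable:
    """Keep taxa with nonzero counts in at least ceil(min_prevalence * n) samples."""
    if not (0.0 < min_prevalence <= 1.0):
        raise DomainError("min_prevalence must lie in (0, 1]")
    need = math.ceil(min_prevalence * table.n_samples)
    keep = (table.counts > 0).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    return CountTable(counts=table.counts.loc[keep].copy(), metadata=table.metadata.copy())


def amalgamate(table: CountTable, taxon_set: Sequence, new_id: str = "amalgamated") -> CountTable:
    """Sum the counts of ``taxon_set`` into one composite taxon."""
    taxon_set = list(taxon_set)
    missing = [t for t in taxon_set if t not in table.counts.index]
    if missing:
        raise DomainError(f"taxa not in table: {missing}")
    rest = table.counts.drop(index=taxon_set)
    summed = table.counts.loc[taxon_set].sum(axis=0).to_frame(new_id).T
    return CountTable(counts=pd.concat([rest, summed]), metadata=table.metadata.copy())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (tests that produced no valid p-value) are excluded from the
    family size m and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if valid.sum() > 0:
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def _pair_result_bbglm(data: PairData, covariates: list[str]) -> dict:
    res = lrt_group_effect(data, full=covariates, null=[c for c in covariates if c != "treatment"],
                           compute_se=True)
    status = "ok" if res.valid else "nonconverged"
    if res.valid and res.message == "boundary":
        status = "boundary"
    return {
        "estimate": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "p_value": res.p_value if res.valid else np.nan,
        "se": (res.ci_high - res.estimate) / 1.96 if np.isfinite(res.ci_high) else np.nan,
        "status": status, "method_tag": "bbglm",
    }


def _pair_result_logratio(data: PairData, method: str, covariates: list[str],
                          zero_policy: str, pseudocount: float,
                          n_perm: int, rng: np.random.Generator) -> dict:
    policy = "drop_double" if method == "lrlm_2" else zero_policy
    sample = logratio.log_ratio_transform(data, zero_policy=policy, pseudocount=pseudocount)
    if method in ("lrlm", "lrlm_2"):
        res = logratio.lrlm_test(sample, covariates=covariates, method_tag=method)
    elif method == "lrw":
        res = logratio.lrw_test(sample, method_tag=method)
    elif method == "lrp":
        res = logratio.lrp_test(sample, n_perm=n_perm, seed=rng, method_tag=method)
    else:
        raise DomainError(f"unknown method {method!r}")
    se = np.nan
    if np.isfinite(res.ci_high) and np.isfinite(res.ci_low) and np.isfinite(res.statistic):
        if res.statistic != 0:
            se = abs(res.estimate / res.statistic)
    return {
        "estimate": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "p_value": res.p_value, "se": se, "status": "ok", "method_tag": method,
    }


def run_all_pairs(
    table: CountTable,
    method: str = "bbglm",
    group_col: str = "group",
    include_study: bool | None = None,
    min_informative: int = 5,
    q_threshold: float = 0.05,
    zero_policy: str = "impute",
    pseudocount: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every unordered taxon pair and control the FDR across ratios.

    One row per pair, numerator = first taxon in table order; the reversed
    orientation is the sign flip of ``estimate`` (never refitted). A pair is
    skipped (status ``skipped``, excluded from the BH family) unless each
    group has at least ``min_informative`` samples with a positive pairwise
    total; ``min_informative=0`` fits everything. Non-converged fits are
    likewise excluded from the BH family m.
    """
    pairs = enumerate_pairs(table)
    design = table.design(group_col=group_col, include_study=include_study)
    covariates = list(design.columns)
    counts = table.counts.to_numpy()
    taxa = table.taxon_ids
    idx = {t: i for i, t in enumerate(taxa)}
    treatment = design["treatment"].to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    n_skipped = 0
    for a, b in pairs:
        ya = counts[idx[a]]
        yb = counts[idx[b]]
        tt = ya + yb
        n_info = int((tt > 0).sum())
        per_group = [int(((tt > 0) & (treatment == gval)).sum()) for gval in (0, 1)]
        base = {"taxon_a": a, "taxon_b": b, "n_informative": n_info}
        if min(per_group) < min_informative:
            rows.append({**base, "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "status": "skipped",
                         "method_tag": method})
            n_skipped += 1
            continue
        data = PairData(numerator_counts=ya, pair_totals=tt, design=design)
        try:
            if method == "bbglm":
                rows.append({**base, **_pair_result_bbglm(data, covariates)})
            else:
                rows.append({**base, **_pair_result_logratio(
                    data, method, covariates, zero_policy, pseudocount, n_perm, rng)})
        except Exception as exc:  # per-pair failures are recorded, not raised
            logger.warning("pair (%s, %s) failed: %s", a, b, exc)
            rows.append({**base, "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "status": "failed",
                         "method_tag": method})
    if n_skipped:
        logger.info("skipped %d of %d pairs below the minimum-information threshold",
                    n_skipped, len(pairs))
    results = pd.DataFrame(rows)
    results["q_value"] = bh_adjust(results["p_value"].to_numpy())
    results = results[RESULT_COLUMNS]
    results.attrs["q_threshold"] = q_threshold
    results.attrs["method"] = method
    return results


def run_mww_mode(
    table: CountTable,
    group_col: str = "group",
    include_study: bool | None = None,
    min_informative: int = 5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Taxon-versus-rest (relative abundance) comparison mode.

    Each taxon is modelled against the library total of the sample with the
    same beta-binomial machinery; BH is applied across taxa. Subject to
    closure bias: a genuine shift in one dominant taxon can flag unshifted
    taxa.
    """
    design = table.design(group_col=group_col, include_study=include_study)
    covariates = list(design.columns)
    lib = table.counts.sum(axis=0).to_numpy()
    treatment = design["treatment"].to_numpy()
    rows = []
    for taxon in table.taxon_ids:
        y = table.counts.loc[taxon].to_numpy()
        base = {"taxon_a": taxon, "taxon_b": "<rest>",
                "n_informative": int((lib > 0).sum())}
        per_group = [int(((lib > 0) & (treatment == gval)).sum()) for gval in (0, 1)]
        if min(per_group) < min_informative:
            rows.append({**base, "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "status": "skipped",
                         "method_tag": "mww"})
            continue
        data = PairData(numerator_counts=y, pair_totals=lib, design=design)
        try:
            out = _pair_result_bbglm(data, covariates)
            out["method_tag"] = "mww"
            rows.append({**base, **out})
        except Exception as exc:
            logger.warning("taxon %s failed: %s", taxon, exc)
            rows.append({**base, "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "status": "failed",
                         "method_tag": "mww"})
    results = pd.DataFrame(rows)
    results["q_value"] = bh_adjust(results["p_value"].to_numpy())
    results = results[RESULT_COLUMNS]
    results.attrs["q_threshold"] = q_threshold
    return results


def build_grid(results: pd.DataFrame, q_threshold: float = 0.05,
               restrict: bool = True) -> SignificanceGrid:
    """Symmetric significance grid (q < threshold) over the analyzed taxa.

    With ``restrict=True`` only taxa involved in at least one significant
    ratio are kept, mirroring the usual presentation of the grid.
    """
    taxa: list = []
    for t in pd.concat([results["taxon_a"], results["taxon_b"]]):
        if t not in taxa:
            taxa.append(t)
    # preserve first-appearance (table) order
    mat = pd.DataFrame(False, index=taxa, columns=taxa)
    sig = results[(results["q_value"] < q_threshold) & results["q_value"].notna()]
    for a, b in zip(sig["taxon_a"], sig["taxon_b"]):
        mat.loc[a, b] = True
        mat.loc[b, a] = True
    if restrict:
        keep = mat.any(axis=1)
        mat = mat.loc[keep, keep]
    return SignificanceGrid(matrix=mat, threshold=q_threshold)


def unwrap_taxa(grid: SignificanceGrid) -> TaxonRanking:
    """Greedy "unwrapping" ranking.

    Repeatedly select the taxon with the most remaining significant ratios,
    remove all ratios it is involved in, and continue until no significant
    ratio remains. Ties break by table order. The selected set accounts for
    every significant ratio.
    """
    mat = grid.matrix.to_numpy().copy()
    taxa = grid.taxa
    order, counts = [], []
    while mat.any():
        deg = mat.sum(axis=1)
        best = int(np.argmax(deg))  # argmax takes the first maximum: table-order tie-break
        order.append(taxa[best])
        counts.append(int(deg[best]))
        mat[best, :] = False
        mat[:, best] = False
    return TaxonRanking(taxa=order, counts=counts, method="unwrap")


def count_taxa(grid: SignificanceGrid) -> TaxonRanking:
    """Rank taxa by their number of incident significant ratios.

    Every significant ratio is counted for both of its taxa; ties break by
    table order (stable sort).
    """
    deg = grid.degree()
    order = deg.sort_values(ascending=False, kind="stable")
    return TaxonRanking(taxa=list(order.index), counts=[int(c) for c in order], method="count")
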