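"""Cohort-level statistics.

Group contrasts of repertoire metrics use the Wilcoxon rank-sum
(Mann-Whitney U) test, exact by null enumeration for small tie-free
samples and mid-rank normal approximation with tie correction otherwise.
Distribution contrasts use a pooled-resampling bootstrap Kolmogorov-
Smirnov test. Multiplicity control offers Bonferroni and Benjamini-
Hochberg adjustment. A six-variable PCA summarizes per-sample metric
vectors, with silhouette-based group separation in the (PC1, PC2) plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .types import ClinicalRecord

EXACT_WILCOXON_MAX_N = 20

#: the six metric columns entering the PCA, in canonical order
PCA_COLUMNS = (
    "pielou_tcr",
    "gini_tcr",
    "gini_vj",
    "pct_inframe",
    "mean_cdr3_len_oof",
    "y_index_unique",
)

_SIDEDNESS = {"two-sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    sidedness: str
    adjusted_p: Optional[float] = None
    adjustment: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def exact_wilcoxon(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two-sided",
    metric: str = "",
    group_a: str = "x",
    group_b: str = "y",
) -> ComparisonResult:
    """Wilcoxon rank-sum test of two independent samples.

    Exact null enumeration (no asymptotics) when the combined size is at
    most 20 and the pooled data carry no ties; otherwise mid-ranks with
    tie-corrected normal approximation and continuity correction.
    ``sidedness="greater"`` tests whether x tends larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= EXACT_WILCOXON_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_SIDEDNESS[sidedness], method=method)
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test=f"wilcoxon_ranksum_{method}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=sidedness,
    )


def _ks_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(two-sided sup|Fx-Fy|, one-sided sup(Fx-Fy)) at pooled jump points."""
    pooled = np.concatenate([x, y])
    pts = np.sort(np.unique(pooled))
    fx = np.searchsorted(np.sort(x), pts, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pts, side="right") / y.size
    diff = fx - fy
    return float(np.abs(diff).max()), float(diff.max())


def _bootstrap_ks_null(
    pooled: np.ndarray, nx: int, ny: int, n_boot: int, two_sided: bool, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized pooled-resampling null distribution of the KS statistic."""
    n = nx + ny
    idx = rng.integers(0, n, size=(n_boot, n))
    z = pooled[idx]
    order = np.argsort(z, axis=1, kind="stable")
    zs = np.take_along_axis(z, order, axis=1)
    # +1/nx steps for x-positions, -1/ny for y-positions, cumulated in sorted order
    labels = np.where(order < nx, 1.0 / nx, -1.0 / ny)
    cum = np.cumsum(labels, axis=1)
    # the ECDF difference is only defined at the last element of each tie run
    run_end = np.ones_like(zs, dtype=bool)
    run_end[:, :-1] = zs[:, :-1] != zs[:, 1:]
    masked = np.where(run_end, cum, -np.inf)
    d_plus = masked.max(axis=1)
    if not two_sided:
        return d_plus
    masked_neg = np.where(run_end, -cum, -np.inf)
    return np.maximum(d_plus, masked_neg.max(axis=1))


def bootstrap_ks(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two-sided",
    n_boot: int = 1000,
    seed: int = 0,
    metric: str = "",
    group_a: str = "x",
    group_b: str = "y",
) -> ComparisonResult:
    """Bootstrap Kolmogorov-Smirnov test with a pooled-resampling null.

    The observed statistic is sup|Fx - Fy| (two-sided) or sup(Fx - Fy)
    (one-sided). The null resamples both groups with replacement from the
    pooled data at their original sizes; the p-value uses the
    (1 + #exceedances) / (1 + n_boot) correction. Reproducible given seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    two_sided = sidedness == "two-sided"
    d_two, d_plus = _ks_statistics(x, y)
    observed = d_two if two_sided else d_plus
    rng = np.random.default_rng(seed)
    null = _bootstrap_ks_null(np.concatenate([x, y]), x.size, y.size, n_boot, two_sided, rng)
    exceed = int((null >= observed - 1e-12).sum())
    p = (1 + exceed) / (1 + n_boot)
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test="bootstrap_ks",
        statistic=observed,
        p_value=p,
        sidedness=sidedness,
    )


def adjust_pvalues(p_values: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment (Bonferroni or Benjamini-Hochberg)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return list(multipletests(p, method=key)[1])


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation coefficient and p-value (Spearman default, Pearson option)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class PcaSummary:
    projections: pd.DataFrame  # sample x PC scores, PC1.. columns
    variance_fractions: np.ndarray
    silhouette: Optional[float]  # group separation in (PC1, PC2); None if <2 groups


def pca_summary(metric_table: pd.DataFrame, groups: Optional[Sequence[str]] = None) -> PcaSummary:
    """PCA of the standardized six-variable metric table.

    ``metric_table`` must contain exactly the six canonical columns (extra
    columns are an error so silent mis-specification cannot slip through);
    rows are samples. Columns are standardized to zero mean and unit
    variance; a zero-variance column is refused by name. When group labels
    are given and at least two groups are present, the silhouette score of
    the labels in the (PC1, PC2) plane is reported.
    """
    if set(metric_table.columns) != set(PCA_COLUMNS):
        raise ValueError(f"metric table must have exactly the columns {PCA_COLUMNS}")
    if len(metric_table) < 3:
        raise ValueError("need at least 3 samples")
    table = metric_table.loc[:, list(PCA_COLUMNS)]
    for col in PCA_COLUMNS:
        if np.isclose(table[col].std(ddof=0), 0.0):
            raise ValueError(f"zero-variance column: {col}")
    z = StandardScaler().fit_transform(table.to_numpy(dtype=float))
    pca = PCA()
    scores = pca.fit_transform(z)
    proj = pd.DataFrame(
        scores,
        index=metric_table.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    sil = None
    if groups is not None:
        labels = np.asarray(list(groups))
        if np.unique(labels).size >= 2:
            sil = float(silhouette_score(scores[:, :2], labels))
    return PcaSummary(proj, pca.explained_variance_ratio_, sil)


def group_mean_table(records: Sequence[ClinicalRecord], group: str) -> dict[str, int]:
    """Nearest-integer mean cell counts for one clinical group."""
    rows = [r for r in records if r.group == group]
    if not rows:
        raise ValueError(f"unknown group {group!r}")
    cols = ("lymphocytes", "t_cells", "cd4", "cd8", "b_cells")
    return {c: round(float(np.mean([getattr(r, c) for r in rows]))) for c in cols}


__all__ = [
    "EXACT_WILCOXON_MAX_N",
    "PCA_COLUMNS",
    "ComparisonResult",
    "PcaSummary",
    "adjust_pvalues",
    "bootstrap_ks",
    "correlate",
    "exact_wilcoxon",
    "group_mean_table",
    "pca_summary",
]
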