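"""Per-sample scalar repertoire metrics.

Diversity, clonality, and evenness are summarized by three classical
indices over the clone-size distribution:

* Shannon's H = -sum p_i ln p_i (natural log, nats),
* the Gini inequality coefficient G = sum_ij |x_i - x_j| / (2 n^2 mu)
  (population form; 0 = perfectly even, 1 = maximally skewed),
* Pielou's evenness J = H / ln n (defined as 0 for a single clone).

Samples are normalized to a common read depth by seeded downsampling
without replacement before any metric is computed, so that depth-dependent
quantities (unique clone counts, top-100 fraction) are comparable across
samples sequenced to different depths.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .composition import mean_cdr3_length, y_index
from .types import (
    IN_FRAME,
    OOF_FRAMESHIFT,
    OOF_STOP,
    ClonotypeRecord,
    RepertoireSample,
    SampleMetrics,
)

DEFAULT_TARGET_READS = 1_000_000


def _counts_array(counts: Iterable[float]) -> np.ndarray:
    x = np.asarray(list(counts), dtype=float)
    if x.size == 0:
        raise ValueError("empty count multiset")
    return x


def shannon_index(counts: Iterable[float]) -> float:
    """Shannon entropy (nats) of a positive count multiset."""
    x = _counts_array(counts)
    if np.any(x <= 0):
        raise ValueError("counts must be positive")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def gini_coefficient(counts: Iterable[float]) -> float:
    """Population Gini inequality coefficient of a non-negative multiset.

    Computed with the sorted O(n log n) identity
    ``G = 2 sum_i i x_(i) / (n sum x) - (n + 1)/n`` (1-based ranks), which
    equals the pairwise-difference form sum_ij |x_i - x_j| / (2 n^2 mu).
    """
    x = _counts_array(counts)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("counts must not all be zero")
    n = x.size
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * xs).sum() / (n * total) - (n + 1.0) / n)


def pielou_evenness(counts: Iterable[float]) -> float:
    """Pielou's evenness H / ln n; 0 for the degenerate single-clone case."""
    x = _counts_array(counts)
    if x.size == 1:
        return 0.0
    return shannon_index(x) / float(np.log(x.size))


def vj_pairing_gini(sample: RepertoireSample, cell_weighting: str = "reads") -> float:
    """Gini coefficient over observed V-J pairing cells.

    Each observed (V, J) pair contributes its summed read count
    (``cell_weighting="reads"``, default) or its unique clonotype count
    (``"unique"``); unobserved pairs are excluded.
    """
    if not sample.clonotypes:
        raise ValueError("sample has no clonotypes")
    cells: dict[tuple[str, str], float] = {}
    for c in sample.clonotypes:
        w = c.read_count if cell_weighting == "reads" else 1
        cells[(c.v_call, c.j_call)] = cells.get((c.v_call, c.j_call), 0) + w
    return gini_coefficient(cells.values())


def downsample(sample: RepertoireSample, target_reads: int, seed: int = 0) -> RepertoireSample:
    """Draw ``target_reads`` reads without replacement from the read multiset.

    Clonotypes drawn to zero are dropped. Deterministic given the seed.
    Upsampling is refused.
    """
    total = sample.total_reads
    if target_reads > total:
        raise ValueError(f"target_reads {target_reads} exceeds total_reads {total}")
    if target_reads == total:
        return sample
    rng = np.random.default_rng(seed)
    counts = np.array([c.read_count for c in sample.clonotypes], dtype=np.int64)
    kept = rng.multivariate_hypergeometric(counts, target_reads, method="marginals")
    new_records = []
    for rec, k in zip(sample.clonotypes, kept):
        if k > 0:
            new_records.append(
                ClonotypeRecord(
                    cdr3_nt=rec.cdr3_nt,
                    cdr3_aa=rec.cdr3_aa,
                    v_call=rec.v_call,
                    j_call=rec.j_call,
                    d_call=rec.d_call,
                    read_count=int(k),
                    frame_class=rec.frame_class,
                    junction=rec.junction,
                )
            )
    return sample.replace_clonotypes(new_records)


def top_fraction(sample: RepertoireSample, k: int = 100) -> float:
    """Read fraction of the k largest clones (ties at the boundary broken by
    lexicographic junction sequence for determinism)."""
    ordered = sorted(sample.clonotypes, key=lambda c: (-c.read_count, c.cdr3_nt))
    top = ordered[:k]
    return sum(c.read_count for c in top) / sample.total_reads


def frame_percentages(sample: RepertoireSample) -> tuple[float, float, float]:
    """(in-frame, stop-containing, frameshifted) percentages, read-weighted."""
    total = sample.total_reads
    masses = {IN_FRAME: 0, OOF_STOP: 0, OOF_FRAMESHIFT: 0}
    for c in sample.clonotypes:
        masses[c.frame_class] += c.read_count
    return tuple(100.0 * masses[k] / total for k in (IN_FRAME, OOF_STOP, OOF_FRAMESHIFT))


def compute_sample_metrics(
    sample: RepertoireSample,
    target_reads: int = DEFAULT_TARGET_READS,
    seed: int = 0,
    vj_cell_weighting: str = "reads",
) -> SampleMetrics:
    """Downsample to a common depth, then fill every scalar metric."""
    norm = downsample(sample, target_reads, seed)
    diversity_counts = [c.read_count for c in norm.clonotypes]
    pct_if, pct_stop, pct_fs = frame_percentages(norm)
    try:
        y_u = y_index(norm, weighting="unique")
        y_t = y_index(norm, weighting="total")
    except ValueError:
        y_u = y_t = float("nan")
    return SampleMetrics(
        sample_id=norm.sample_id,
        group=norm.group,
        normalized_reads=target_reads,
        unique_clones=norm.unique_clones,
        shannon_h=shannon_index(diversity_counts),
        gini_tcr=gini_coefficient(diversity_counts),
        pielou_tcr=pielou_evenness(diversity_counts),
        gini_vj=vj_pairing_gini(norm, vj_cell_weighting),
        top100_fraction=top_fraction(norm, 100),
        pct_inframe=pct_if,
        pct_oof_stop=pct_stop,
        pct_oof_frameshift=pct_fs,
        mean_cdr3_len_inframe=mean_cdr3_length(norm, "in_frame"),
        mean_cdr3_len_oof=mean_cdr3_length(norm, "out_of_frame"),
        y_index_unique=y_u,
        y_index_total=y_t,
    )


__all__ = [
    "DEFAULT_TARGET_READS",
    "compute_sample_metrics",
    "downsample",
    "frame_percentages",
    "gini_coefficient",
    "pielou_evenness",
    "shannon_index",
    "top_fraction",
    "vj_pairing_gini",
]
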