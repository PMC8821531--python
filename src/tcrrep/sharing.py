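"""Clonotype sharing, common-clonotype calls, and paTCR enrichment.

Sharing identity is the amino-acid CDR3 string (pathology databases and
the public-clone literature are amino-acid level); a nucleotide-level mode
is available. Frameshifted clonotypes have no amino-acid sequence and are
excluded from amino-acid-level sharing. Database matching is exact string
identity ("absolutely aligned"); CDR3s containing a stop symbol never
match.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import PatcrRecord, RepertoireSample, PATCR_CATEGORIES

logger = logging.getLogger(__name__)


def _clone_ids(sample: RepertoireSample, level: str) -> dict[str, int]:
    """Map clonotype identity string -> summed read count."""
    out: dict[str, int] = defaultdict(int)
    for c in sample.clonotypes:
        ident = c.cdr3_aa if level == "aa" else c.cdr3_nt
        if ident is None:
            continue
        out[ident] += c.read_count
    return out


def sharing_fraction(
    sample_a: RepertoireSample,
    sample_b: RepertoireSample,
    weighting: str = "unique",
    level: str = "aa",
) -> float:
    """Fraction of clonotypes shared between two samples.

    unique: |shared identity set| / mean(unique counts of the two samples).
    total: read mass on shared identities / combined read mass.
    """
    a = _clone_ids(sample_a, level)
    b = _clone_ids(sample_b, level)
    if not a or not b:
        raise ValueError("empty sample in sharing computation")
    shared = a.keys() & b.keys()
    if weighting == "unique":
        return len(shared) / ((len(a) + len(b)) / 2.0)
    if weighting == "total":
        mass = sum(a[s] + b[s] for s in shared)
        return mass / (sum(a.values()) + sum(b.values()))
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class SharingMatrix:
    """Symmetric pairwise sharing fractions with unit self-sharing diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray
    weighting: str


def sharing_matrix(
    samples: Sequence[RepertoireSample], weighting: str = "unique", level: str = "aa"
) -> SharingMatrix:
    n = len(samples)
    m = np.eye(n)
    for i in range(n):
        for k in range(i + 1, n):
            f = sharing_fraction(samples[i], samples[k], weighting, level)
            m[i, k] = m[k, i] = f
    return SharingMatrix([s.sample_id for s in samples], m, weighting)


def common_clonotypes(
    control_samples: Sequence[RepertoireSample], min_samples: int = 5, level: str = "aa"
) -> set[str]:
    """Clonotypes present (any read count) in at least ``min_samples`` controls."""
    if len(control_samples) < min_samples:
        raise ValueError(
            f"need at least {min_samples} control samples, got {len(control_samples)}"
        )
    presence: dict[str, int] = defaultdict(int)
    for s in control_samples:
        for ident in _clone_ids(s, level):
            presence[ident] += 1
    return {ident for ident, k in presence.items() if k >= min_samples}


def common_fraction(sample: RepertoireSample, common_set: set[str], level: str = "aa") -> float:
    """Fraction of the sample's unique clonotypes that are common clonotypes."""
    ids = _clone_ids(sample, level)
    if not ids:
        raise ValueError("sample has no identifiable clonotypes")
    return len(ids.keys() & common_set) / len(ids)


def patcr_proportions(
    sample: RepertoireSample,
    patcr_db: Iterable[PatcrRecord],
    weighting: str = "unique",
) -> tuple[dict[str, float], dict[str, float]]:
    """Proportion of pathology-associated clonotypes per category and disease.

    Matching is exact amino-acid identity. The unique weighting divides
    matched unique clonotypes by all unique clonotypes of the sample (a
    clonotype without an amino-acid sequence can never match); the total
    weighting divides matched read mass by total read mass. Each category
    is computed independently (a CDR3 curated under several categories
    counts toward each), so the per-category fractions need not sum to the
    overall matched fraction.
    """
    db = list(patcr_db)
    by_cat: dict[str, set[str]] = {c: set() for c in PATCR_CATEGORIES}
    by_disease: dict[str, set[str]] = defaultdict(set)
    for rec in db:
        by_cat[rec.category].add(rec.cdr3_aa)
        by_disease[rec.disease].add(rec.cdr3_aa)

    n_unique = sample.unique_clones
    total_reads = sample.total_reads
    if n_unique == 0:
        raise ValueError("empty sample")
    if not db:
        logger.warning("empty paTCR database: all proportions are 0")

    def _prop(targets: set[str]) -> float:
        num_u = 0
        num_t = 0
        for c in sample.clonotypes:
            aa = c.cdr3_aa
            if aa is None or "*" in aa or aa not in targets:
                continue
            num_u += 1
            num_t += c.read_count
        return num_u / n_unique if weighting == "unique" else num_t / total_reads

    if weighting not in ("unique", "total"):
        raise ValueError(f"unknown weighting {weighting!r}")
    cat_props = {cat: _prop(ids) for cat, ids in by_cat.items()}
    disease_props = {d: _prop(ids) for d, ids in sorted(by_disease.items())}
    return cat_props, disease_props


__all__ = [
    "SharingMatrix",
    "common_clonotypes",
    "common_fraction",
    "patcr_proportions",
    "sharing_fraction",
    "sharing_matrix",
]
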