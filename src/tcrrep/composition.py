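"""Distributional junction metrics.

Length spectra of the CDR3 and of its six constituent pieces (3'V, 5'D,
3'D, 5'J deletions; V-D and D-J insertions), amino-acid composition
statistics (tyrosine index, fixed-position residue usage in 13-residue
CDR3s), and the nucleotide composition of inserted bases.

Weighting conventions: ``"unique"`` counts each clonotype once,
``"total"`` weights clonotypes by read count. Frame subsets are
``"in_frame"``, ``"out_of_frame"`` (stop-containing plus frameshifted), or
``"all"``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional

from .types import IN_FRAME, OOF_FRAMESHIFT, RepertoireSample

#: residues with positive Kyte-Doolittle hydropathy
HYDROPHOBIC_AA = frozenset("AILMFWVC")

INDEL_VARIABLES = ("del_v3", "del_d5", "del_d3", "del_j5", "ins_vd", "ins_dj")


@dataclass
class LengthDistribution:
    """Normalized histogram of an integer length variable."""

    name: str
    weighting: str
    histogram: dict[int, float]
    n: int
    mean: float

    @classmethod
    def from_weighted_lengths(cls, name: str, weighting: str, pairs) -> "LengthDistribution":
        mass: dict[int, float] = defaultdict(float)
        total = 0.0
        for length, w in pairs:
            mass[length] += w
            total += w
        if total <= 0:
            raise ValueError(f"{name}: empty length distribution")
        hist = {k: v / total for k, v in sorted(mass.items())}
        mean = sum(k * v for k, v in hist.items())
        return cls(name=name, weighting=weighting, histogram=hist, n=len(hist), mean=mean)


def _frame_filter(sample: RepertoireSample, frame_subset: str):
    if frame_subset == "all":
        return list(sample.clonotypes)
    if frame_subset == "in_frame":
        return [c for c in sample.clonotypes if c.frame_class == IN_FRAME]
    if frame_subset == "out_of_frame":
        return [c for c in sample.clonotypes if c.frame_class != IN_FRAME]
    raise ValueError(f"unknown frame_subset {frame_subset!r}")


def _weight(clone, weighting: str) -> float:
    if weighting == "unique":
        return 1.0
    if weighting == "total":
        return float(clone.read_count)
    raise ValueError(f"unknown weighting {weighting!r}")


def cdr3_length_distribution(
    sample: RepertoireSample, frame_subset: str = "all", weighting: str = "unique"
) -> LengthDistribution:
    """Histogram of junction nucleotide lengths over a frame subset."""
    clones = _frame_filter(sample, frame_subset)
    if not clones:
        raise ValueError(f"no clonotypes in frame subset {frame_subset!r}")
    return LengthDistribution.from_weighted_lengths(
        f"cdr3_len_{frame_subset}", weighting,
        ((len(c.cdr3_nt), _weight(c, weighting)) for c in clones),
    )


def mean_cdr3_length(sample: RepertoireSample, frame_subset: str, weighting: str = "unique") -> float:
    """Mean junction length; NaN when the subset is empty."""
    try:
        return cdr3_length_distribution(sample, frame_subset, weighting).mean
    except ValueError:
        return float("nan")


def indel_length_distributions(
    sample: RepertoireSample, frame_subset: str = "all", weighting: str = "unique"
) -> dict[str, Optional[LengthDistribution]]:
    """The six per-segment length histograms plus total non-templated length.

    The six per-segment distributions are computed over D-identified
    clonotypes only (no D boundary is fabricated for ambiguous junctions);
    ``total_n_length`` additionally includes the merged insertion of
    D-ambiguous clonotypes. Clonotypes without a decomposition are skipped.
    """
    clones = [c for c in _frame_filter(sample, frame_subset) if c.junction is not None]
    d_clones = [c for c in clones if c.junction.d_identified]
    out: dict[str, Optional[LengthDistribution]] = {}
    getters = {
        "del_v3": lambda j: j.del_v3,
        "del_d5": lambda j: j.del_d5,
        "del_d3": lambda j: j.del_d3,
        "del_j5": lambda j: j.del_j5,
        "ins_vd": lambda j: len(j.ins_vd_seq),
        "ins_dj": lambda j: len(j.ins_dj_seq),
    }
    for name, get in getters.items():
        if d_clones:
            out[name] = LengthDistribution.from_weighted_lengths(
                name, weighting,
                ((get(c.junction), _weight(c, weighting)) for c in d_clones),
            )
        else:
            out[name] = None
    if clones:
        out["total_n_length"] = LengthDistribution.from_weighted_lengths(
            "total_n_length", weighting,
            ((c.junction.total_n_length, _weight(c, weighting)) for c in clones),
        )
    else:
        out["total_n_length"] = None
    return out


def y_index(
    sample: RepertoireSample, weighting: str = "unique", include_stop_clones: bool = True
) -> float:
    """Fraction of tyrosine among CDR3 amino-acid residues.

    Frameshifted clonotypes are untranslatable and always excluded.
    Stop-containing clonotypes are included by default; their ``*`` symbol
    never counts as tyrosine and is excluded from the denominator.
    """
    num = 0.0
    den = 0.0
    for c in sample.clonotypes:
        if c.cdr3_aa is None:
            continue
        if not include_stop_clones and "*" in c.cdr3_aa:
            continue
        w = _weight(c, weighting)
        residues = c.cdr3_aa.replace("*", "")
        num += w * residues.count("Y")
        den += w * len(residues)
    if den == 0:
        raise ValueError("no translatable clonotypes")
    return num / den


def position_aa_composition(
    sample: RepertoireSample, position: int, weighting: str = "unique"
) -> tuple[dict[str, float], float]:
    """Residue usage at a 1-based position of 13-residue in-frame CDR3s.

    Returns the residue distribution and the mass on the hydrophobic set
    {A, I, L, M, F, W, V, C} (positive Kyte-Doolittle hydropathy).
    """
    if not 1 <= position <= 13:
        raise ValueError("position must be in 1..13")
    mass: Counter = Counter()
    total = 0.0
    for c in sample.clonotypes:
        if c.frame_class != IN_FRAME or c.cdr3_aa is None or len(c.cdr3_aa) != 13:
            continue
        w = _weight(c, weighting)
        mass[c.cdr3_aa[position - 1]] += w
        total += w
    if total == 0:
        raise ValueError("no 13-residue in-frame clonotypes")
    dist = {aa: m / total for aa, m in sorted(mass.items())}
    hydrophobic = sum(m for aa, m in dist.items() if aa in HYDROPHOBIC_AA)
    return dist, hydrophobic


def insertion_gc_content(sample: RepertoireSample) -> tuple[Optional[float], dict[str, float]]:
    """GC fraction and per-base composition of all inserted nucleotides.

    Merged insertions of D-ambiguous clonotypes are included. Returns
    ``(None, {})`` when the sample carries no inserted bases.
    """
    counts = Counter()
    for c in sample.clonotypes:
        j = c.junction
        if j is None:
            continue
        for seq in (j.ins_vd_seq, j.ins_dj_seq, j.merged_ins_seq):
            if seq:
                counts.update(seq)
    total = sum(counts.values())
    if total == 0:
        return None, {}
    comp = {b: counts.get(b, 0) / total for b in "ACGT"}
    return comp["G"] + comp["C"], comp


__all__ = [
    "HYDROPHOBIC_AA",
    "INDEL_VARIABLES",
    "LengthDistribution",
    "cdr3_length_distribution",
    "indel_length_distributions",
    "insertion_gc_content",
    "mean_cdr3_length",
    "position_aa_composition",
    "y_index",
]
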