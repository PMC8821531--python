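"""Core domain types for TCRbeta CDR3 repertoire analysis.

Conventions used throughout the package:

* The CDR3 "junction" runs from the conserved V-segment cysteine codon
  through the conserved J-segment phenylalanine/tryptophan codon, both
  inclusive. Every length reported anywhere in the package is a junction
  length under this convention.
* All coordinates are 0-based, half-open. 1-based coordinates appear only
  in human-readable report text.
* The reading frame of a junction is anchored at position 0 (the first base
  of the cysteine codon), including for out-of-frame junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

DNA_ALPHABET = frozenset("ACGT")

#: closed set of frame classes
IN_FRAME = "in_frame"
OOF_STOP = "oof_stop"
OOF_FRAMESHIFT = "oof_frameshift"
FRAME_CLASSES = (IN_FRAME, OOF_STOP, OOF_FRAMESHIFT)

#: closed set of study groups (free labels are also accepted where noted)
GROUPS = ("control", "atypical_SCID", "AT", "ICF1", "ICF2")

#: closed set of pathology categories for paTCR records
PATCR_CATEGORIES = ("pathogen", "autoimmune_allergy", "cancer", "other")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D, or J reference sequence.

    Parameters
    ----------
    name
        Unique gene/allele label.
    segment_class
        One of ``"V"``, ``"D"``, ``"J"``.
    sequence
        Uppercase DNA over {A, C, G, T}.
    anchor_offset
        0-based position of the first base of the conserved Cys codon (V)
        or Phe/Trp codon (J). ``None`` for D segments. Must be a
        multiple-of-3 distance from the segment's reading-frame start
        (position 0 by construction of the packaged reference) and lie
        inside the sequence.
    """

    name: str
    segment_class: str
    sequence: str
    anchor_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"segment {self.name!r}: empty sequence")
        if set(self.sequence) - DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise FormatError(f"segment {self.name!r}: non-ACGT characters {bad}")
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"segment {self.name!r}: bad class {self.segment_class!r}")
        if self.segment_class in ("V", "J"):
            if self.anchor_offset is None:
                raise FormatError(f"segment {self.name!r}: {self.segment_class} record lacks anchor_offset")
            if not 0 <= self.anchor_offset < len(self.sequence):
                raise FormatError(f"segment {self.name!r}: anchor_offset outside sequence")
            if self.anchor_offset % 3:
                raise FormatError(f"segment {self.name!r}: anchor_offset not in frame")
        elif self.anchor_offset is not None:
            raise FormatError(f"segment {self.name!r}: D record must not carry anchor_offset")

    @property
    def junction_region(self) -> str:
        """The part of the segment that can appear inside a junction.

        V: anchor (Cys codon) to the 3' end. J: 5' end through the anchor
        codon inclusive. D: the whole sequence.
        """
        if self.segment_class == "V":
            return self.sequence[self.anchor_offset :]
        if self.segment_class == "J":
            return self.sequence[: self.anchor_offset + 3]
        return self.sequence


@dataclass(frozen=True)
class JunctionDecomposition:
    """Decomposition of a junction into the six measured segments.

    ``del_*`` are exonucleolytic deletion lengths (nt) at the four
    recombining edges; ``ins_vd_seq``/``ins_dj_seq`` are the non-templated
    insertion sequences. When no D segment could be identified the whole
    inter-segment region is reported as ``merged_ins_seq`` and the four
    D-related fields are ``None``.
    """

    del_v3: int
    del_j5: int
    del_d5: Optional[int] = None
    del_d3: Optional[int] = None
    ins_vd_seq: Optional[str] = None
    ins_dj_seq: Optional[str] = None
    d_identified: bool = False
    merged_ins_seq: Optional[str] = None

    @property
    def total_n_length(self) -> int:
        """Total non-templated length regardless of D identification."""
        if self.d_identified:
            return len(self.ins_vd_seq or "") + len(self.ins_dj_seq or "")
        return len(self.merged_ins_seq or "")


@dataclass
class ClonotypeRecord:
    """One CDR3 clonotype.

    ``cdr3_nt`` spans the conserved Cys codon through the conserved Phe/Trp
    codon inclusive. ``cdr3_aa`` is present iff the junction length is a
    multiple of three (stop codons render as ``*``).
    """

    cdr3_nt: str
    v_call: str
    j_call: str
    read_count: int
    frame_class: str
    cdr3_aa: Optional[str] = None
    d_call: Optional[str] = None
    junction: Optional[JunctionDecomposition] = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.frame_class not in FRAME_CLASSES:
            raise ValueError(f"unknown frame_class {self.frame_class!r}")
        if (self.cdr3_aa is None) != (self.frame_class == OOF_FRAMESHIFT):
            raise ValueError("cdr3_aa must be present iff the junction is translatable")
        if self.frame_class == IN_FRAME:
            if len(self.cdr3_nt) % 3:
                raise ValueError("in_frame junction length must be a multiple of 3")
            if "*" in (self.cdr3_aa or ""):
                raise ValueError("in_frame junction must not contain a stop")

    @property
    def key(self) -> tuple[str, str, str]:
        """Clonotype identity used for merging: (cdr3_nt, v_call, j_call).

        The D call is excluded because D assignment is frequently ambiguous.
        """
        return (self.cdr3_nt, self.v_call, self.j_call)


@dataclass
class RepertoireSample:
    """One subject's clonotype collection with a group label."""

    sample_id: str
    group: str
    clonotypes: list[ClonotypeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        keys = [c.key for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            raise ValueError(f"sample {self.sample_id!r}: duplicate clonotype keys")

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clonotypes)

    @property
    def unique_clones(self) -> int:
        return len(self.clonotypes)

    def replace_clonotypes(self, clonotypes: Iterable[ClonotypeRecord]) -> "RepertoireSample":
        return RepertoireSample(self.sample_id, self.group, list(clonotypes))


@dataclass(frozen=True)
class PatcrRecord:
    """One pathology-associated CDR3 amino-acid record."""

    cdr3_aa: str
    category: str
    disease: str

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if not self.cdr3_aa.isupper():
            raise ValueError("cdr3_aa must be uppercase")
        if self.category not in PATCR_CATEGORIES:
            raise ValueError(f"unknown paTCR category {self.category!r}")


@dataclass(frozen=True)
class ClinicalRecord:
    """One row of the packaged clinical-characteristics table."""

    patient_id: str
    group: str
    clinical_diagnosis: str
    age_of_onset: float
    lymphocytes: float
    t_cells: float
    cd4: float
    cd8: float
    b_cells: float

    def __post_init__(self) -> None:
        for name in ("lymphocytes", "t_cells", "cd4", "cd8", "b_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SampleMetrics:
    """Per-sample scalar repertoire metrics (computed after downsampling)."""

    sample_id: str
    group: str
    normalized_reads: int
    unique_clones: int
    shannon_h: float
    gini_tcr: float
    pielou_tcr: float
    gini_vj: float
    top100_fraction: float
    pct_inframe: float
    pct_oof_stop: float
    pct_oof_frameshift: float
    mean_cdr3_len_inframe: float
    mean_cdr3_len_oof: float
    y_index_unique: float
    y_index_total: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


__all__ = [
    "DNA_ALPHABET",
    "IN_FRAME",
    "OOF_STOP",
    "OOF_FRAMESHIFT",
    "FRAME_CLASSES",
    "GROUPS",
    "PATCR_CATEGORIES",
    "FormatError",
    "GermlineSegment",
    "JunctionDecomposition",
    "ClonotypeRecord",
    "RepertoireSample",
    "PatcrRecord",
    "ClinicalRecord",
    "SampleMetrics",
]
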