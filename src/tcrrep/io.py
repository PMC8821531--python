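"""Readers and writers for all external formats.

Formats handled here:

* clonotype tables — AIRR-Rearrangement-style TSV (tab-separated, header
  row). The canonical dialect uses columns ``junction``, ``junction_aa``,
  ``v_call``, ``d_call``, ``j_call``, ``duplicate_count``; other dialects
  declare a column mapping onto those names.
* germline segment references — FASTA whose headers follow the grammar
  ``>NAME|CLASS[|anchor=N]`` with CLASS one of V/D/J; V and J records must
  carry the 0-based anchor offset of their conserved codon.
* pathology-associated CDR3 tables — CSV with ``cdr3_aa``, ``category``,
  ``disease`` columns (the column structure of TBAdb / McPAS-TCR exports).
* the packaged clinical-characteristics table — CSV fixture with one row
  per patient.

Frame classes are always recomputed from the junction sequence, never
trusted from the file.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .annotate import classify_frame, translate_junction
from .types import (
    DNA_ALPHABET,
    ClinicalRecord,
    ClonotypeRecord,
    FormatError,
    GermlineSegment,
    JunctionDecomposition,
    PatcrRecord,
    RepertoireSample,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: column mappings: canonical field -> column name in the file
DIALECTS: dict[str, dict[str, str]] = {
    "airr": {
        "junction": "junction",
        "junction_aa": "junction_aa",
        "v_call": "v_call",
        "d_call": "d_call",
        "j_call": "j_call",
        "duplicate_count": "duplicate_count",
    },
}

#: canonical column order of the decomposition block in annotated TSVs
DECOMPOSITION_COLUMNS = (
    "frame_class",
    "del_v3",
    "del_d5",
    "del_d3",
    "del_j5",
    "ins_vd",
    "ins_dj",
    "merged_ins",
)


class EmptySampleError(FormatError):
    """The clonotype file contains no usable rows."""


def _fixture(name: str) -> Path:
    return Path(resources.files("tcrrep").joinpath("data", name))


def default_germline_path() -> Path:
    """Packaged synthetic germline reference (12 V, 2 D, 13 J segments)."""
    return _fixture("germline_trb_synthetic.fasta")


def default_patcr_path() -> Path:
    """Packaged synthetic pathology-associated CDR3 table."""
    return _fixture("patcr_synthetic.csv")


def default_clinical_path() -> Path:
    """Packaged clinical-characteristics fixture (19 patients)."""
    return _fixture("clinical_table2.csv")


# ---------------------------------------------------------------------------
# clonotype tables
# ---------------------------------------------------------------------------


def _record_from_row(junction: str, v_call: str, j_call: str, d_call, count: int) -> ClonotypeRecord:
    frame = classify_frame(junction)
    return ClonotypeRecord(
        cdr3_nt=junction,
        cdr3_aa=translate_junction(junction),
        v_call=v_call,
        j_call=j_call,
        d_call=d_call if isinstance(d_call, str) and d_call else None,
        read_count=count,
        frame_class=frame,
    )


def read_repertoire(
    path: PathLike,
    dialect: str = "airr",
    sample_id: Optional[str] = None,
    group: str = "unknown",
    strict: bool = True,
) -> RepertoireSample:
    """Read one clonotype table into a :class:`RepertoireSample`.

    Rows with identical (junction, v_call, j_call) are merged with read
    counts summed. The frame class is recomputed from the junction. A
    missing ``duplicate_count`` column defaults every row to count 1 (with
    a warning). In lenient mode rows with malformed junctions are skipped
    with a warning instead of raising.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = DIALECTS[dialect]
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptySampleError(f"{path}: empty clonotype file") from None

    for field in ("junction", "v_call", "j_call"):
        if cols[field] not in df.columns:
            raise FormatError(f"{path}: missing required column {cols[field]!r}")
    if cols["duplicate_count"] in df.columns:
        counts = pd.to_numeric(df[cols["duplicate_count"]], errors="raise").astype(int)
    else:
        logger.warning("%s: no %r column; defaulting read counts to 1", path, cols["duplicate_count"])
        counts = pd.Series(1, index=df.index)

    merged: dict[tuple[str, str, str], int] = {}
    order: list[tuple[str, str, str]] = []
    dcalls: dict[tuple[str, str, str], Optional[str]] = {}
    for i in df.index:
        junction = str(df.at[i, cols["junction"]]).upper()
        if not junction or set(junction) - DNA_ALPHABET:
            msg = f"{path}: row {i}: malformed junction {junction!r}"
            if strict:
                raise FormatError(msg)
            logger.warning("%s (skipped)", msg)
            continue
        count = int(counts.at[i])
        if count < 1:
            msg = f"{path}: row {i}: non-positive duplicate_count {count}"
            if strict:
                raise FormatError(msg)
            logger.warning("%s (skipped)", msg)
            continue
        key = (junction, str(df.at[i, cols["v_call"]]), str(df.at[i, cols["j_call"]]))
        if key not in merged:
            merged[key] = 0
            order.append(key)
            d = df.at[i, cols["d_call"]] if cols["d_call"] in df.columns else None
            dcalls[key] = d if isinstance(d, str) and d and d.lower() != "nan" else None
        merged[key] += count

    if not merged:
        raise EmptySampleError(f"{path}: no usable clonotype rows")
    records = [_record_from_row(k[0], k[1], k[2], dcalls[k], merged[k]) for k in order]
    return RepertoireSample(sample_id or path.stem, group, records)


def write_repertoire(sample: RepertoireSample, path: PathLike, annotated: bool = False) -> None:
    """Write a sample as canonical AIRR-style TSV.

    With ``annotated=True`` the frame class and the six junction
    decomposition columns are appended.
    """
    rows = []
    for c in sample.clonotypes:
        row = {
            "junction": c.cdr3_nt,
            "junction_aa": c.cdr3_aa or "",
            "v_call": c.v_call,
            "d_call": c.d_call or "",
            "j_call": c.j_call,
            "duplicate_count": c.read_count,
        }
        if annotated:
            j = c.junction
            row["frame_class"] = c.frame_class
            if j is None:
                row.update({k: "" for k in DECOMPOSITION_COLUMNS[1:]})
            else:
                row.update(
                    del_v3=j.del_v3,
                    del_d5="" if j.del_d5 is None else j.del_d5,
                    del_d3="" if j.del_d3 is None else j.del_d3,
                    del_j5=j.del_j5,
                    ins_vd="" if j.ins_vd_seq is None else j.ins_vd_seq,
                    ins_dj="" if j.ins_dj_seq is None else j.ins_dj_seq,
                    merged_ins="" if j.merged_ins_seq is None else j.merged_ins_seq,
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotated(
    path: PathLike, sample_id: Optional[str] = None, group: str = "unknown"
) -> RepertoireSample:
    """Read an annotated TSV (as written by ``write_repertoire(annotated=True)``).

    Junction decompositions are reconstructed from the decomposition
    columns; rows with an empty ``del_v3`` carry no decomposition
    (unassignable clonotypes). No merging is performed: annotated files are
    already merged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"junction", "v_call", "j_call", "duplicate_count", "del_v3"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: not an annotated clonotype table (missing {sorted(missing)})")
    records = []
    for _, row in df.iterrows():
        junction = None
        if row["del_v3"] != "":
            if row.get("del_d5", "") != "":
                junction = JunctionDecomposition(
                    del_v3=int(row["del_v3"]),
                    del_j5=int(row["del_j5"]),
                    del_d5=int(row["del_d5"]),
                    del_d3=int(row["del_d3"]),
                    ins_vd_seq=row["ins_vd"],
                    ins_dj_seq=row["ins_dj"],
                    d_identified=True,
                )
            else:
                junction = JunctionDecomposition(
                    del_v3=int(row["del_v3"]),
                    del_j5=int(row["del_j5"]),
                    d_identified=False,
                    merged_ins_seq=row["merged_ins"],
                )
        nt = row["junction"].upper()
        records.append(
            ClonotypeRecord(
                cdr3_nt=nt,
                cdr3_aa=translate_junction(nt),
                v_call=row["v_call"],
                j_call=row["j_call"],
                d_call=row["d_call"] or None,
                read_count=int(row["duplicate_count"]),
                frame_class=classify_frame(nt),
                junction=junction,
            )
        )
    if not records:
        raise EmptySampleError(f"{path}: no clonotype rows")
    return RepertoireSample(sample_id or path.stem, group, records)


# ---------------------------------------------------------------------------
# germline reference
# ---------------------------------------------------------------------------


def read_germline(path: PathLike) -> list[GermlineSegment]:
    """Read a germline segment FASTA (header grammar ``>NAME|CLASS[|anchor=N]``)."""
    segments = []
    names = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise FormatError(f"{path}: bad header {rec.id!r}")
        name, seg_class = parts[0], parts[1]
        anchor = None
        for extra in parts[2:]:
            if extra.startswith("anchor="):
                anchor = int(extra.split("=", 1)[1])
        if name in names:
            raise FormatError(f"{path}: duplicate segment name {name!r}")
        names.add(name)
        segments.append(GermlineSegment(name, seg_class, str(rec.seq).upper(), anchor))
    if not segments:
        raise FormatError(f"{path}: no FASTA records")
    return segments


def write_germline(segments: Sequence[GermlineSegment], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in segments:
            header = f">{s.name}|{s.segment_class}"
            if s.anchor_offset is not None:
                header += f"|anchor={s.anchor_offset}"
            fh.write(header + "\n" + s.sequence + "\n")


# ---------------------------------------------------------------------------
# pathology-associated CDR3 table
# ---------------------------------------------------------------------------

_CATEGORY_ALIASES = {
    "pathogen": "pathogen",
    "pathogens": "pathogen",
    "autoimmune_allergy": "autoimmune_allergy",
    "autoimmune": "autoimmune_allergy",
    "allergy": "autoimmune_allergy",
    "autoimmune and allergy": "autoimmune_allergy",
    "cancer": "cancer",
    "tumor": "cancer",
    "other": "other",
}


def read_patcr_db(path: PathLike) -> list[PatcrRecord]:
    """Read a pathology-associated CDR3 CSV.

    Exact duplicate rows are removed; unknown category strings map to
    ``other`` with a warning; rows with an empty CDR3 are rejected with a
    warning.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("cdr3_aa", "category", "disease"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        cdr3 = (row["cdr3_aa"] or "").strip() if isinstance(row["cdr3_aa"], str) else ""
        if not cdr3:
            logger.warning("%s: row with empty cdr3_aa rejected", path)
            continue
        raw = (row["category"] or "").strip().lower() if isinstance(row["category"], str) else ""
        category = _CATEGORY_ALIASES.get(raw)
        if category is None:
            logger.warning("%s: unknown category %r mapped to 'other'", path, row["category"])
            category = "other"
        disease = row["disease"] if isinstance(row["disease"], str) else ""
        key = (cdr3.upper(), category, disease)
        if key in seen:
            continue
        seen.add(key)
        records.append(PatcrRecord(cdr3_aa=cdr3.upper(), category=category, disease=disease))
    if not records:
        raise FormatError(f"{path}: no valid paTCR rows")
    return records


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

EXPECTED_CLINICAL_ROWS = 19
EXPECTED_GROUP_SIZES = {"atypical_SCID": 3, "AT": 6, "ICF1": 6, "ICF2": 4}


def read_clinical_table(path: Optional[PathLike] = None, strict: bool = True) -> list[ClinicalRecord]:
    """Read the clinical-characteristics CSV (packaged fixture by default).

    In strict mode the table must contain exactly 19 patients with group
    sizes 3/6/6/4 for atypical_SCID/AT/ICF1/ICF2.
    """
    path = Path(path) if path is not None else default_clinical_path()
    df = pd.read_csv(path)
    records = [
        ClinicalRecord(
            patient_id=str(r.patient_id),
            group=str(r.group),
            clinical_diagnosis=str(r.clinical_diagnosis),
            age_of_onset=float(r.age_of_onset),
            lymphocytes=float(r.lymphocytes),
            t_cells=float(r.t_cells),
            cd4=float(r.cd4),
            cd8=float(r.cd8),
            b_cells=float(r.b_cells),
        )
        for r in df.itertuples()
    ]
    if strict:
        if len(records) != EXPECTED_CLINICAL_ROWS:
            raise FormatError(
                f"{path}: expected {EXPECTED_CLINICAL_ROWS} patients, found {len(records)}"
            )
        sizes = {g: sum(1 for r in records if r.group == g) for g in EXPECTED_GROUP_SIZES}
        if sizes != EXPECTED_GROUP_SIZES:
            raise FormatError(f"{path}: unexpected group sizes {sizes}")
    return records


__all__ = [
    "DIALECTS",
    "EmptySampleError",
    "default_clinical_path",
    "default_germline_path",
    "default_patcr_path",
    "read_annotated",
    "read_clinical_table",
    "read_germline",
    "read_patcr_db",
    "read_repertoire",
    "write_germline",
    "write_repertoire",
]
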