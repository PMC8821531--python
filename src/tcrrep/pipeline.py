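"""End-to-end orchestration: simulate -> annotate -> metrics -> composition
-> sharing/paTCR -> group comparison, with a JSON report.

The pipeline is deterministic: all randomness flows from the configured
seed through named per-stage child seeds, and no output file contains
timestamps, so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import composition as comp
from . import io as rio
from . import metrics as rmetrics
from . import sharing as rsharing
from . import stats as rstats
from .annotate import AlignParams, annotate_sample
from .simulate import preset_config, simulate_repertoire, spike_patcr, write_truth

logger = logging.getLogger(__name__)

METRIC_FIELDS = (
    "shannon_h",
    "gini_tcr",
    "pielou_tcr",
    "gini_vj",
    "top100_fraction",
    "pct_inframe",
    "pct_oof_stop",
    "pct_oof_frameshift",
    "unique_clones",
    "mean_cdr3_len_inframe",
    "mean_cdr3_len_oof",
    "y_index_unique",
    "y_index_total",
)


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    germline_path: Optional[Path] = None  # None -> packaged reference
    patcr_path: Optional[Path] = None  # None -> packaged table
    groups: dict = field(default_factory=lambda: {"control": 5, "AT": 3})
    n_clones: int = 2000
    n_reads: int = 20000
    target_reads: int = 10000
    seed: int = 0
    min_d_match: int = 3
    min_terminal_match: int = 5
    min_common_samples: int = 5
    n_boot: int = 1000
    boundary_mode: str = "posterior"
    spike_fraction: float = 0.0  # applied to non-control samples

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["outdir"] = Path(raw["outdir"])
        for key in ("germline_path", "patcr_path"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("germline_path", "patcr_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        if self.target_reads > self.n_reads:
            raise ValueError("target_reads exceeds n_reads")
        if not self.groups:
            raise ValueError("no groups configured")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; writes per-stage outputs plus report.json.

    Returns the report dict. Raises :class:`StageError` on stage failure.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    germline = rio.read_germline(config.germline_path or rio.default_germline_path())
    patcr_db = rio.read_patcr_db(config.patcr_path or rio.default_patcr_path())
    align = AlignParams(
        min_terminal_match=config.min_terminal_match, min_d_match=config.min_d_match
    )

    # ---- simulate ----
    samples = []
    try:
        k = 0
        for group, n_samples in sorted(config.groups.items()):
            for i in range(n_samples):
                sim_seed = config.seed * 10007 + k
                cfg = preset_config(
                    group, germline, seed=sim_seed,
                    n_clones=config.n_clones, n_reads=config.n_reads,
                )
                sid = f"{group}_{i + 1}"
                sample, truth = simulate_repertoire(cfg, sample_id=sid, group=group)
                if config.spike_fraction > 0 and group != "control":
                    sample, truth = spike_patcr(
                        sample, patcr_db, config.spike_fraction, seed=sim_seed + 1, truth=truth
                    )
                rio.write_repertoire(sample, out / f"{sid}.clones.tsv")
                write_truth(truth, out / f"{sid}.truth.tsv")
                samples.append(sample)
                k += 1
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    # ---- annotate ----
    annotated = []
    summaries = {}
    try:
        for i, s in enumerate(samples):
            ann, summary = annotate_sample(
                s, germline, align, boundary_mode=config.boundary_mode,
                seed=config.seed * 10007 + 5000 + i,
            )
            rio.write_repertoire(ann, out / f"{s.sample_id}.annotated.tsv", annotated=True)
            annotated.append(ann)
            summaries[s.sample_id] = {
                "assigned": summary.n_assigned,
                "unassignable": summary.n_unassignable,
                "d_identified": summary.n_d_identified,
            }
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # ---- metrics ----
    try:
        rows = []
        for i, s in enumerate(annotated):
            m = rmetrics.compute_sample_metrics(
                s, target_reads=config.target_reads, seed=config.seed * 10007 + 9000 + i
            )
            rows.append(m.as_dict())
        metrics_df = pd.DataFrame(rows)
        metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    # ---- composition ----
    try:
        comp_report = {}
        for s in annotated:
            gc, base_comp = comp.insertion_gc_content(s)
            indel = comp.indel_length_distributions(s)
            comp_report[s.sample_id] = {
                "insertion_gc": gc,
                "insertion_base_composition": base_comp,
                "indel_means": {
                    k: (None if v is None else v.mean) for k, v in indel.items()
                },
                "mean_cdr3_len_inframe": comp.mean_cdr3_length(s, "in_frame"),
                "mean_cdr3_len_oof": comp.mean_cdr3_length(s, "out_of_frame"),
            }
        (out / "composition.json").write_text(json.dumps(comp_report, indent=2, sort_keys=True))
    except Exception as exc:
        raise StageError("composition", exc) from exc

    # ---- sharing & paTCR ----
    try:
        share_u = rsharing.sharing_matrix(annotated, "unique")
        share_t = rsharing.sharing_matrix(annotated, "total")
        for mat, name in ((share_u, "sharing_unique.tsv"), (share_t, "sharing_total.tsv")):
            pd.DataFrame(mat.matrix, index=mat.sample_ids, columns=mat.sample_ids).to_csv(
                out / name, sep="\t"
            )
        controls = [s for s in annotated if s.group == "control"]
        common_report = None
        if len(controls) >= config.min_common_samples:
            common = rsharing.common_clonotypes(controls, config.min_common_samples)
            common_report = {
                s.sample_id: rsharing.common_fraction(s, common) for s in annotated
            }
        patcr_report = {}
        for s in annotated:
            cats, diseases = rsharing.patcr_proportions(s, patcr_db, "unique")
            patcr_report[s.sample_id] = {"categories": cats, "diseases": diseases}
        (out / "patcr.json").write_text(json.dumps(patcr_report, indent=2, sort_keys=True))
    except Exception as exc:
        raise StageError("sharing", exc) from exc

    # ---- group comparison ----
    try:
        comparisons = compare_metric_table(metrics_df, reference_group="control")
        comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("compare", exc) from exc

    report = {
        "config": {
            "groups": config.groups,
            "n_clones": config.n_clones,
            "n_reads": config.n_reads,
            "target_reads": config.target_reads,
            "seed": config.seed,
            "boundary_mode": config.boundary_mode,
            "min_d_match": config.min_d_match,
            "min_terminal_match": config.min_terminal_match,
            "spike_fraction": config.spike_fraction,
        },
        "annotation": summaries,
        "samples": {r["sample_id"]: {k: r[k] for k in METRIC_FIELDS} for r in rows},
        "common_clonotype_fraction": common_report,
        "n_comparisons": int(len(comparisons)),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def compare_metric_table(
    metrics_df: pd.DataFrame,
    reference_group: str = "control",
    method: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Wilcoxon contrasts of every metric, each group vs the reference.

    Adjusted p-values control multiplicity within each metric family (one
    family = one metric across all group contrasts).
    """
    if "group" not in metrics_df.columns:
        raise ValueError("metrics table lacks a 'group' column")
    groups = [g for g in sorted(metrics_df["group"].unique()) if g != reference_group]
    ref = metrics_df[metrics_df["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} absent")
    rows = []
    for metric in METRIC_FIELDS:
        if metric not in metrics_df.columns:
            continue
        family = []
        for g in groups:
            sub = metrics_df[metrics_df["group"] == g]
            res = rstats.exact_wilcoxon(
                sub[metric].to_numpy(), ref[metric].to_numpy(),
                metric=metric, group_a=g, group_b=reference_group,
            )
            family.append(res)
        adjusted = rstats.adjust_pvalues([r.p_value for r in family], method)
        for res, adj in zip(family, adjusted):
            rows.append(
                {
                    "metric": res.metric,
                    "group_a": res.group_a,
                    "group_b": res.group_b,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "p_adj": adj,
                    "method": method,
                    "sidedness": res.sidedness,
                }
            )
    return pd.DataFrame(rows)


__all__ = ["PipelineConfig", "StageError", "compare_metric_table", "run_pipeline"]
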