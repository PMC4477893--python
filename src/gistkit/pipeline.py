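"""End-to-end orchestration of the analysis stages.

A single declarative configuration names the input files and the model
parameters; every stage runs only when its inputs are configured, so any
subset of the pipeline can be executed.  Stage order follows the analysis
narrative: variant filtering -> founder classification -> arm-level
LOH/purity -> screen enrichment -> zinc-finger mapping -> methylome
clustering.  The run produces a JSON-serializable report echoing the
configuration, so a report plus the input files reproduces the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .filters import FilterConfig, records_to_frame, run_cascade
from .founder import FounderModelParams, classify_founder, count_founder_snvs
from .loh import arm_summaries
from .methylome import cluster_samples, normalize_matrix, variance_filter
from .screen import screen_panel, sites_from_frame
from .zinc_finger import map_variants_to_fingers, scan_c2h2

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("gistkit")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name in the message."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Paths left ``None`` skip the corresponding stage.  Parameter defaults
    are the study profile: purity 0.6, inclusion 0.95, minimum depth 10,
    test level 0.05, variance cutoff 0.1.
    """

    # model parameters
    purity: float = 0.6
    het_factor: float = 0.5
    inclusion: float = 0.95
    min_depth: int = 10
    max_control_alt: int = 0
    alpha: float = 0.05
    alleles_per_carrier: int = 1
    bonferroni: bool = False
    variance_threshold: float = 0.1
    cluster_cut: int = 2
    seed: int = 0
    # stage inputs
    variants: str | None = None
    variants_format: str = "tsv"  # or "vcf"
    snps: str | None = None
    arms: str | None = None
    screen_table: str | None = None
    protein_fasta: str | None = None
    protein_variants: str | None = None
    methylation_matrix: str | None = None
    methylation_reference: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def founder_params(self) -> FounderModelParams:
        return FounderModelParams(
            purity=self.purity, het_factor=self.het_factor, inclusion=self.inclusion
        )

    def input_paths(self) -> list[str]:
        return [
            p
            for p in (
                self.variants,
                self.snps,
                self.arms,
                self.screen_table,
                self.protein_fasta,
                self.protein_variants,
                self.methylation_matrix,
                self.methylation_reference,
            )
            if p is not None
        ]


def _check_inputs(config: PipelineConfig) -> None:
    for path in config.input_paths():
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")


def _stage_variants(config: PipelineConfig, out_dir: Path | None) -> dict:
    if config.variants_format == "vcf":
        records = gio.read_variant_vcf(config.variants)
    else:
        records = gio.read_variant_tsv(config.variants)
    survivors, report = run_cascade(
        records,
        FilterConfig(min_depth=config.min_depth, max_control_alt=config.max_control_alt),
    )
    params = config.founder_params()
    frame = records_to_frame(survivors)
    founder_flags = [
        classify_founder(r.tumour_alt_count, r.tumour_depth, params)
        for r in survivors
    ]
    frame["pass_founder"] = founder_flags
    counting = frame.rename(columns={"tumour_depth": "coverage"}).assign(
        alt_count=[r.tumour_alt_count for r in survivors]
    )
    n_founder_snvs = (
        count_founder_snvs(counting, params) if len(survivors) else 0
    )
    if out_dir is not None:
        frame.to_csv(out_dir / "variants_filtered.tsv", sep="\t", index=False)
    return {
        "filter_report": report.to_dict(),
        "n_survivors": len(survivors),
        "n_founder": int(sum(founder_flags)),
        "n_founder_snvs": int(n_founder_snvs),
    }


def _stage_loh(config: PipelineConfig, out_dir: Path | None) -> dict:
    snps = gio.read_snp_tsv(config.snps)
    if config.arms is not None:
        snps = gio.assign_arms(snps, gio.read_arm_bed(config.arms))
    summaries = arm_summaries(
        snps, purity=config.purity, min_depth=config.min_depth
    )
    if out_dir is not None:
        summaries.to_csv(out_dir / "arm_summaries.tsv", sep="\t", index=False)
    called = summaries[summaries["loh_call"] == True]  # noqa: E712
    return {
        "n_arms": len(summaries),
        "loh_arms": [f"{r.chrom}{r.arm}" for r in called.itertuples()],
        "purity_estimates": {
            f"{r.chrom}{r.arm}": None if pd.isna(r.purity_estimate) else float(r.purity_estimate)
            for r in called.itertuples()
        },
    }


def _stage_screen(config: PipelineConfig, out_dir: Path | None) -> dict:
    sites = sites_from_frame(gio.read_screen_tsv(config.screen_table))
    results, summary = screen_panel(
        sites,
        alpha=config.alpha,
        alleles_per_carrier=config.alleles_per_carrier,
        bonferroni=config.bonferroni,
    )
    if out_dir is not None:
        results.to_csv(out_dir / "screen_enrichment.tsv", sep="\t", index=False)
    summary["significant_sites"] = results.loc[
        results["significant"] == True, "site_id"  # noqa: E712
    ].tolist()
    return summary


def _stage_zf(config: PipelineConfig, out_dir: Path | None) -> dict:
    sequences = gio.read_fasta(config.protein_fasta)
    variants_by_seq: dict[str, list] = {}
    if config.protein_variants is not None:
        vtab = gio.read_protein_variants_tsv(config.protein_variants)
        for _, row in vtab.iterrows():
            if "hgvs" in vtab.columns and pd.notna(row.get("hgvs")):
                variant = row["hgvs"]
            else:
                variant = (int(row["position"]), row["ref_aa"], row["alt_aa"])
            variants_by_seq.setdefault(row["seq_id"], []).append(variant)
    finger_rows = []
    annotation_rows = []
    for seq_id, seq in sequences.items():
        fingers = scan_c2h2(seq)
        for f in fingers:
            finger_rows.append(
                dict(
                    seq_id=seq_id,
                    start=f.start,
                    end=f.end,
                    c1=f.c1,
                    c2=f.c2,
                    h1=f.h1,
                    h2=f.h2,
                    motif_seq=f.motif_seq,
                )
            )
        for ann in map_variants_to_fingers(seq, variants_by_seq.get(seq_id, [])):
            sub = ann.substitution
            annotation_rows.append(
                dict(
                    seq_id=seq_id,
                    position=ann.position,
                    ref_aa=ann.ref_aa,
                    alt_aa=ann.alt_aa,
                    in_finger=ann.in_finger,
                    role=sub.role if sub else None,
                    dist_upstream_of_terminal_H=(
                        sub.dist_upstream_of_terminal_H if sub else None
                    ),
                )
            )
    if out_dir is not None:
        pd.DataFrame(finger_rows).to_csv(
            out_dir / "zinc_fingers.tsv", sep="\t", index=False
        )
        pd.DataFrame(annotation_rows).to_csv(
            out_dir / "zf_variants.tsv", sep="\t", index=False
        )
    return {
        "n_sequences": len(sequences),
        "n_fingers": len(finger_rows),
        "n_variants_in_fingers": sum(1 for a in annotation_rows if a["in_finger"]),
        "n_variants_outside": sum(1 for a in annotation_rows if not a["in_finger"]),
    }


def _stage_methylome(config: PipelineConfig, out_dir: Path | None) -> dict:
    matrix = gio.read_matrix_tsv(config.methylation_matrix)
    if config.methylation_reference is not None:
        refs = gio.read_reference_tsv(config.methylation_reference)
        matrix = normalize_matrix(matrix, refs)
    kept = variance_filter(matrix, threshold=config.variance_threshold)
    if len(kept) < 2:
        raise PipelineError(
            f"methylome: only {len(kept)} probes pass the variance filter"
        )
    result = cluster_samples(matrix.loc[kept])
    labels = result.cut(config.cluster_cut)
    if out_dir is not None:
        labels.rename_axis("sample_id").reset_index().to_csv(
            out_dir / "cluster_labels.tsv", sep="\t", index=False
        )
        (out_dir / "dendrogram.nwk").write_text(result.to_newick())
    return {
        "n_probes_kept": int(len(kept)),
        "n_samples": result.n_samples,
        "cluster_sizes": labels.value_counts().sort_index().tolist(),
    }


_STAGES = [
    ("variants", lambda c: c.variants, _stage_variants),
    ("loh", lambda c: c.snps, _stage_loh),
    ("screen", lambda c: c.screen_table, _stage_screen),
    ("zinc_finger", lambda c: c.protein_fasta, _stage_zf),
    ("methylome", lambda c: c.methylation_matrix, _stage_methylome),
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages and return the report.

    A stage failure raises :class:`PipelineError` naming the stage; the
    report is deterministic for fixed inputs and configuration apart from
    its timestamp.
    """
    _check_inputs(config)
    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "gistkit",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": asdict(config),
        "stages": {},
    }
    for name, selector, runner in _STAGES:
        if selector(config) is None:
            logger.info("stage %s: skipped (no input configured)", name)
            continue
        logger.info("stage %s: running", name)
        try:
            report["stages"][name] = runner(config, out_dir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
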