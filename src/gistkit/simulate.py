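"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised on generated data carrying
ground-truth labels:

* tumour/normal variant tables — founder mutations draw mutant reads as
  ``Binomial(n, purity/2)`` (the Bernoulli sequencing model), subclonal
  mutations at a diluted clone fraction, germline heterozygotes at 0.5 in
  both samples; mutant reads split evenly between strands;
* a genome of germline-het SNPs with one chromosome arm under monoallelic
  loss — tumour BAF drawn from the purity mixture bands and arm depth
  scaled by ``(2 - t)/2``;
* a diploid screening panel with carrier counts drawn per sample from the
  population MAF, optionally with one enriched site;
* a methylation matrix with two sample groups separated on informative
  probes over a low-variance background;
* a protein with C2H2 fingers planted at known coordinates.

Identical seeds give identical outputs; all randomness flows through one
``numpy`` generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import VariantRecord

__all__ = [
    "SimulationConfig",
    "ZfProteinSim",
    "simulate_variant_table",
    "simulate_loh_genome",
    "simulate_screen_panel",
    "simulate_methylation",
    "simulate_zf_protein",
    "cascade_fixture",
]

#: published C2H2 motifs of ZNF407 (anchors upper-case); also shipped as FASTA
ZNF407_FINGER_MOTIFS = (
    "CkkCfyktrsstvltrHiklrH",
    "ClhCefsahssaslelHvkrkH",
)

#: known minor allele frequencies of the packaged ZNF407 screen panel
PANEL_KNOWN_MAFS = (
    0.0115, 0.0744, 0.0078, 0.0096, 0.2020, 0.079, 0.0032, 0.0032,
    0.079, 0.0794, 0.0014, 0.2025, 0.0023, 0.4096, 0.0078,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for all generators.

    Defaults mirror the sequenced case: purity 0.6, mean depth 45
    (bracketing the tumour/control averages of 42 and 50), loss of the
    long arm of chromosome 14, a 52-sample diploid screen panel, and a
    two-group methylation design (hypermethylated vs normal-like block).
    """

    seed: int = 0
    purity: float = 0.6
    n_founder: int = 200
    n_subclonal: int = 100
    n_germline_het: int = 100
    depth_mean: float = 45.0
    depth_model: str = "poisson"  # or "negative-binomial"
    depth_dispersion: float = 10.0
    clone_fraction_range: tuple[float, float] = (0.05, 0.3)
    control_error_rate: float = 0.0
    # LOH genome
    arms: tuple[str, ...] = ("1p", "1q", "2p", "2q", "14p", "14q")
    loh_arm: str | None = "14q"
    snps_per_arm: int = 500
    # screening panel: (maf, enriched) per site; None -> the known panel
    # MAFs with the first site enriched
    panel: tuple[tuple[float, bool], ...] | None = None
    panel_size: int = 52
    enrich_multiplier: float = 8.0
    # methylation design
    meth_group_sizes: tuple[int, int] = (10, 10)
    meth_informative: int = 200
    meth_background: int = 2000
    meth_group_means: tuple[float, float] = (0.8, 0.2)
    meth_noise_sd: float = 0.05
    meth_background_sd: float = 0.02
    # zinc-finger protein
    zf_n_fingers: int = 2
    zf_linker: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity!r}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if min(self.n_founder, self.n_subclonal, self.n_germline_het) < 0:
            raise ValueError("variant counts must be >= 0")
        if self.depth_model not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        if self.zf_linker < 10:
            raise ValueError("zf_linker must be >= 10")

    def resolved_panel(self) -> tuple[tuple[float, bool], ...]:
        if self.panel is not None:
            return self.panel
        return tuple(
            (maf, i == 0) for i, maf in enumerate(PANEL_KNOWN_MAFS)
        )


def _draw_depth(
    rng: np.random.Generator,
    size: int,
    mean: float,
    model: str = "poisson",
    dispersion: float = 10.0,
) -> np.ndarray:
    if model == "poisson":
        d = rng.poisson(mean, size)
    else:
        p = dispersion / (dispersion + mean)
        d = rng.negative_binomial(dispersion, p, size)
    return np.maximum(d, 1)


def simulate_variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Tumour/normal variant table with truth labels.

    Returns a frame with the full variant-record column set plus a
    ``truth`` column in {``founder``, ``subclonal``, ``germline``}.
    Somatic records have zero control support (unless
    ``control_error_rate`` > 0); germline records are heterozygous in both
    samples.
    """
    rng = np.random.default_rng(config.seed)
    blocks = []
    specs = [
        ("founder", config.n_founder),
        ("subclonal", config.n_subclonal),
        ("germline", config.n_germline_het),
    ]
    pos = 1
    for label, count in specs:
        if count == 0:
            continue
        n_t = _draw_depth(
            rng, count, config.depth_mean, config.depth_model, config.depth_dispersion
        )
        n_c = _draw_depth(
            rng, count, config.depth_mean, config.depth_model, config.depth_dispersion
        )
        if label == "founder":
            p_alt = np.full(count, config.purity / 2.0)
        elif label == "subclonal":
            lo, hi = config.clone_fraction_range
            clone = rng.uniform(lo, hi, count)
            p_alt = config.purity * clone / 2.0
        else:
            p_alt = np.full(count, 0.5)
        alt = rng.binomial(n_t, p_alt)
        fwd = rng.binomial(alt, 0.5)
        if label == "germline":
            control_alt = rng.binomial(n_c, 0.5)
        elif config.control_error_rate > 0:
            control_alt = rng.binomial(n_c, config.control_error_rate)
        else:
            control_alt = np.zeros(count, dtype=int)
        blocks.append(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "pos": np.arange(pos, pos + count),
                    "ref_allele": "A",
                    "alt_allele": "T",
                    "tumour_alt_fwd": fwd,
                    "tumour_alt_rev": alt - fwd,
                    "tumour_depth": n_t,
                    "control_alt_count": control_alt,
                    "control_depth": n_c,
                    "variant_class": "SNV",
                    "region_class": "exonic-coding",
                    "effect_class": "nonsynonymous",
                    "known_snp_id": [
                        f"rs9{pos + i}" if label == "germline" else None
                        for i in range(count)
                    ],
                    "truth": label,
                }
            )
        )
        pos += count
    if not blocks:
        cols = [
            "chrom", "pos", "ref_allele", "alt_allele", "tumour_alt_fwd",
            "tumour_alt_rev", "tumour_depth", "control_alt_count",
            "control_depth", "variant_class", "region_class", "effect_class",
            "known_snp_id", "truth",
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(blocks, ignore_index=True)


def simulate_loh_genome(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Germline-het SNPs across arms, one arm under monoallelic loss.

    On the lost arm the tumour BAF is drawn from the purity mixture bands
    ``(1 - t)/(2 - t)`` or ``1/(2 - t)`` (random phase per site), and the
    tumour depth mean is scaled by ``(2 - t)/2``.  Returns the SNP table
    and an arm-level truth table with the planted ``loh`` flag.
    """
    rng = np.random.default_rng(config.seed)
    t = config.purity
    low, high = (1.0 - t) / (2.0 - t), 1.0 / (2.0 - t)
    rows = []
    truth = []
    for arm_name in config.arms:
        chrom, arm = arm_name[:-1], arm_name[-1]
        is_loh = config.loh_arm is not None and arm_name == config.loh_arm and t > 0
        m = config.snps_per_arm
        n_c = _draw_depth(
            rng, m, config.depth_mean, config.depth_model, config.depth_dispersion
        )
        if is_loh:
            n_t = _draw_depth(
                rng,
                m,
                config.depth_mean * (2.0 - t) / 2.0,
                config.depth_model,
                config.depth_dispersion,
            )
            phase = rng.random(m) < 0.5
            p_alt = np.where(phase, low, high)
        else:
            n_t = _draw_depth(
                rng, m, config.depth_mean, config.depth_model, config.depth_dispersion
            )
            p_alt = np.full(m, 0.5)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "arm": arm,
                    "pos": np.arange(1, m + 1),
                    "tumour_alt": rng.binomial(n_t, p_alt),
                    "tumour_depth": n_t,
                    "control_alt": rng.binomial(n_c, 0.5),
                    "control_depth": n_c,
                }
            )
        )
        truth.append(dict(chrom=chrom, arm=arm, loh=bool(is_loh)))
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth)


def simulate_screen_panel(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carrier counts for a diploid screening panel.

    Each sample carries the variant when at least one of its two alleles
    mutates under ``Binomial(2, maf)``; enriched sites use
    ``maf * enrich_multiplier`` (capped at 0.5) as the generating
    frequency while the reported MAF stays at the population value.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.resolved_panel()
    rows = []
    truth = []
    for i, (maf, enriched) in enumerate(panel):
        gen_maf = min(maf * config.enrich_multiplier, 0.5) if enriched else maf
        genotypes = rng.binomial(2, gen_maf, config.panel_size)
        carriers = int((genotypes > 0).sum())
        rows.append(
            dict(
                site_id=f"site{i + 1:02d}",
                maf=maf,
                carriers=carriers,
                panel_size=config.panel_size,
            )
        )
        truth.append(dict(site_id=f"site{i + 1:02d}", enriched=bool(enriched)))
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_methylation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Probes × samples beta-value matrix with two planted sample groups.

    Informative probes are differentially methylated between the groups:
    alternating probes are hypermethylated in group A and hypomethylated
    in group B or vice versa (real differential methylation runs in both
    directions, and a one-sided block would carry no between-group signal
    under a correlation distance, which centres each sample).  Background
    probes sit at a probe-specific baseline with low-variance noise.
    Values are clipped to [0, 1].  Returns the matrix and a truth series
    of group labels per sample.
    """
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.meth_group_sizes
    samples = [f"A{i + 1:02d}" for i in range(n_a)] + [
        f"B{i + 1:02d}" for i in range(n_b)
    ]
    mean_a, mean_b = config.meth_group_means
    up_in_a = (np.arange(config.meth_informative) % 2 == 0)[:, None]
    means = np.concatenate(
        [
            np.where(up_in_a, mean_a, mean_b).repeat(n_a, axis=1),
            np.where(up_in_a, mean_b, mean_a).repeat(n_b, axis=1),
        ],
        axis=1,
    )
    informative = means + rng.normal(
        0.0, config.meth_noise_sd, (config.meth_informative, n_a + n_b)
    )
    baseline = rng.uniform(0.1, 0.9, config.meth_background)[:, None]
    background = baseline + rng.normal(
        0.0, config.meth_background_sd, (config.meth_background, n_a + n_b)
    )
    values = np.clip(np.concatenate([informative, background]), 0.0, 1.0)
    probes = [f"inf{i + 1:05d}" for i in range(config.meth_informative)] + [
        f"bg{i + 1:05d}" for i in range(config.meth_background)
    ]
    matrix = pd.DataFrame(values, index=probes, columns=samples)
    truth = pd.Series(
        ["A"] * n_a + ["B"] * n_b, index=samples, name="group"
    )
    return matrix, truth


@dataclass(frozen=True)
class ZfProteinSim:
    """A synthetic protein with planted C2H2 fingers and test variants."""

    sequence: str
    fingers: tuple[tuple[int, int], ...]  # 1-based (start, end) per finger
    variants: tuple[tuple[int, str, str], ...]  # (pos, ref, alt)


# background alphabet excludes C and H so no spurious fingers can arise
_ZF_BACKGROUND = "ADEFGIKLMNPQRSTVWY"


def simulate_zf_protein(config: SimulationConfig) -> ZfProteinSim:
    """Random protein with fingers planted at known coordinates.

    The planted motifs cycle through the two published ZNF407 finger
    strings, separated by linkers free of C and H.  One variant is placed
    two residues upstream of each finger's terminal histidine and one in
    the linker upstream of the first finger.
    """
    rng = np.random.default_rng(config.seed)
    motifs = [m.upper() for m in ZNF407_FINGER_MOTIFS]

    def linker(length: int) -> str:
        return "".join(rng.choice(list(_ZF_BACKGROUND), length))

    parts = [linker(config.zf_linker)]
    fingers = []
    pos = config.zf_linker
    for i in range(config.zf_n_fingers):
        motif = motifs[i % len(motifs)]
        fingers.append((pos + 1, pos + len(motif)))
        parts.append(motif)
        pos += len(motif)
        parts.append(linker(config.zf_linker))
        pos += config.zf_linker
    seq = "".join(parts)
    variants = []
    if config.zf_linker >= 5:
        ref = seq[4]
        variants.append((5, ref, "W" if ref != "W" else "A"))
    for start, end in fingers:
        p = end - 2  # two residues upstream of the terminal histidine
        ref = seq[p - 1]
        variants.append((p, ref, "W" if ref != "W" else "A"))
    return ZfProteinSim(
        sequence=seq, fingers=tuple(fingers), variants=tuple(variants)
    )


def cascade_fixture(
    n_germline: int = 10,
    n_single_strand: int = 10,
    n_low_depth: int = 10,
    n_non_transcribed: int = 40,
    n_silent: int = 15,
    n_known_snp: int = 5,
    n_clean: int = 10,
) -> tuple[list[VariantRecord], list[int]]:
    """Deterministic variant set with one planted failure mode per block.

    Each block passes every cascade stage before its own, so the expected
    per-stage survivor counts are forced by construction; they are
    returned alongside the records.
    """
    records: list[VariantRecord] = []
    pos = 1

    def add(count: int, **overrides) -> None:
        nonlocal pos
        base = dict(
            chrom="1",
            ref_allele="A",
            alt_allele="T",
            tumour_alt_fwd=7,
            tumour_alt_rev=7,
            tumour_depth=30,
            control_alt_count=0,
            control_depth=30,
            variant_class="SNV",
            region_class="exonic-coding",
            effect_class="nonsynonymous",
            known_snp_id=None,
        )
        base.update(overrides)
        for _ in range(count):
            records.append(VariantRecord(pos=pos, **base))
            pos += 1

    add(n_germline, control_alt_count=5)
    add(n_single_strand, tumour_alt_fwd=14, tumour_alt_rev=0)
    add(n_low_depth, tumour_depth=9, tumour_alt_fwd=4, tumour_alt_rev=4)
    half = n_non_transcribed // 2
    add(half, region_class="intronic")
    add(n_non_transcribed - half, region_class="intergenic")
    add(n_silent, effect_class="silent")
    add(n_known_snp, known_snp_id="rs1000")
    add(n_clean)

    total = len(records)
    expected = [
        total,
        total - n_germline,
        total - n_germline - n_single_strand,
        total - n_germline - n_single_strand - n_low_depth,
        n_silent + n_known_snp + n_clean,
        n_known_snp + n_clean,
        n_clean,
    ]
    return records, expected
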