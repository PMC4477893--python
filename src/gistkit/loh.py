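"""Arm-level loss-of-heterozygosity detection and purity estimation.

At a germline-heterozygous SNP the control shows a B-allele frequency (BAF)
near 0.5.  If one allele is lost in every tumour cell of a sample with
purity ``t``, reads at the site come from a mixture of one tumour allele
and two normal alleles, so the observed BAF shifts to

    (1 - t) / (2 - t)   (lost allele)   or   1 / (2 - t)   (retained allele),

which sum to 1.  Folding the BAF (``min(f, 1 - f)``) removes the phase and
leaves a single expected band ``b = (1 - t)/(2 - t)``; inverting gives the
purity estimate ``t = (1 - 2b)/(1 - b)``.

Monoallelic loss also halves the tumour copy number on the arm, so after
normalizing each sample by its genome-wide median depth the tumour/control
depth ratio on a lost arm is ``(2 - t)/2``.

The module summarises whole chromosome arms only — the working assumption
is clonal monoallelic loss of an entire arm, not segmental events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InsufficientDataError",
    "SNP_COLUMNS",
    "expected_baf_under_loh",
    "estimate_purity_from_baf",
    "select_control_hets",
    "arm_summaries",
]

SNP_COLUMNS = [
    "chrom",
    "arm",
    "pos",
    "tumour_alt",
    "tumour_depth",
    "control_alt",
    "control_depth",
]


class InsufficientDataError(ValueError):
    """Too few usable sites for a reliable estimate."""


def expected_baf_under_loh(purity: float) -> tuple[float, float]:
    """Expected (lower, upper) BAF of a germline het under monoallelic loss.

    Returns ``((1 - t)/(2 - t), 1/(2 - t))`` for purity ``t``; the two
    components sum to 1 and collapse to (0.5, 0.5) in a pure-normal sample.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity!r}")
    lower = (1.0 - purity) / (2.0 - purity)
    return lower, 1.0 - lower


def estimate_purity_from_baf(folded_baf, min_sites: int = 20) -> float:
    """Purity from the median folded BAF of het SNPs in an LOH region.

    Inverts the mixture relation ``b = (1 - t)/(2 - t)``:
    ``t = (1 - 2b)/(1 - b)``, clipped to [0, 1].

    Raises
    ------
    InsufficientDataError
        With fewer than ``min_sites`` values the median is too noisy for a
        meaningful estimate.
    """
    values = np.asarray(folded_baf, dtype=float)
    if values.size < min_sites:
        raise InsufficientDataError(
            f"need >= {min_sites} folded BAF values, got {values.size}"
        )
    if values.min() < 0.0 or values.max() > 0.5 + 1e-12:
        raise ValueError("folded BAF values must lie in [0, 0.5]")
    b = float(np.median(values))
    if b >= 1.0:
        return 0.0
    return float(np.clip((1.0 - 2.0 * b) / (1.0 - b), 0.0, 1.0))


def select_control_hets(
    snps: pd.DataFrame,
    baf_range: tuple[float, float] = (0.4, 0.6),
    min_depth: int = 10,
) -> pd.DataFrame:
    """Restrict a SNP table to sites heterozygous in the control.

    Keeps sites with control BAF inside ``baf_range`` and depth of at least
    ``min_depth`` in both samples — the mixture algebra above only holds at
    genuinely heterozygous sites.
    """
    cb = snps["control_alt"] / snps["control_depth"]
    keep = (
        (snps["control_depth"] >= min_depth)
        & (snps["tumour_depth"] >= min_depth)
        & (cb >= baf_range[0])
        & (cb <= baf_range[1])
    )
    return snps.loc[keep]


def _loh_cutoff(purity: float | None, fixed_cutoff: float) -> float:
    if purity is None:
        return fixed_cutoff
    lower, _ = expected_baf_under_loh(purity)
    return 0.5 * (0.5 + lower)  # midpoint between diploid and LOH bands


def arm_summaries(
    snps: pd.DataFrame,
    purity: float | None = None,
    fixed_cutoff: float = 0.4,
    baf_range: tuple[float, float] = (0.4, 0.6),
    min_depth: int = 10,
    min_sites_for_purity: int = 20,
) -> pd.DataFrame:
    """Per-arm folded-BAF and depth-ratio statistics with an LOH call.

    The SNP table needs columns ``chrom, arm, pos, tumour_alt,
    tumour_depth, control_alt, control_depth``.  Sites are first reduced to
    control heterozygotes; depths are normalized per sample by the
    genome-wide median before forming the arm-level tumour/control ratio
    (``depth_ratio``); the raw unnormalized ratio is also reported
    (``depth_ratio_raw``).

    An arm is called LOH when its median folded tumour BAF falls below the
    decision cutoff: the midpoint between 0.5 and the purity-expected LOH
    band when ``purity`` is given, else ``fixed_cutoff``.  Arms with no
    usable SNPs get ``n_snps = 0`` and a null call.  For called arms with
    enough sites a per-arm purity estimate is added.
    """
    missing = set(SNP_COLUMNS) - set(snps.columns)
    if missing:
        raise ValueError(f"SNP table lacks columns: {sorted(missing)}")
    usable = select_control_hets(snps, baf_range=baf_range, min_depth=min_depth)
    cutoff = _loh_cutoff(purity, fixed_cutoff)

    if len(usable):
        med_t = float(usable["tumour_depth"].median())
        med_c = float(usable["control_depth"].median())
    else:
        med_t = med_c = np.nan

    rows = []
    all_arms = snps[["chrom", "arm"]].drop_duplicates()
    for chrom, arm in all_arms.itertuples(index=False):
        sub = usable[(usable["chrom"] == chrom) & (usable["arm"] == arm)]
        n = len(sub)
        if n == 0:
            rows.append(
                dict(
                    chrom=chrom,
                    arm=arm,
                    n_snps=0,
                    median_folded_baf=np.nan,
                    depth_ratio=np.nan,
                    depth_ratio_raw=np.nan,
                    loh_call=None,
                    purity_estimate=np.nan,
                )
            )
            continue
        baf = sub["tumour_alt"] / sub["tumour_depth"]
        folded = np.minimum(baf, 1.0 - baf)
        med_folded = float(np.median(folded))
        arm_t = float(sub["tumour_depth"].median())
        arm_c = float(sub["control_depth"].median())
        ratio_raw = arm_t / arm_c
        ratio = (arm_t / med_t) / (arm_c / med_c)
        call = bool(med_folded < cutoff)
        purity_est = np.nan
        if call and n >= min_sites_for_purity:
            purity_est = estimate_purity_from_baf(
                folded, min_sites=min_sites_for_purity
            )
        rows.append(
            dict(
                chrom=chrom,
                arm=arm,
                n_snps=n,
                median_folded_baf=med_folded,
                depth_ratio=ratio,
                depth_ratio_raw=ratio_raw,
                loh_call=call,
                purity_estimate=purity_est,
            )
        )
    return pd.DataFrame(rows)
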