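"""Allele-frequency enrichment test for a prevalence-screen panel.

A panel of tumour samples is screened for point mutations at known
polymorphic sites.  For each site with a known population minor allele
frequency (MAF), the number of carrier samples observed in the panel is
compared with the count expected in a diploid panel drawn from the
population: under the null, the number of mutant alleles among
``2 * panel_size`` chromosomes is ``Binomial(2 * panel_size, maf)``.

Each carrier sample is counted as exactly one mutant allele (zygosity is
typically unreported in a screen), a conservative lower bound on the true
allele count; ``alleles_per_carrier=2`` switches to the upper bound.  The
test is the one-sided upper-tail exact binomial test; sites with unknown
MAF are reported as not-applicable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "ScreenSite",
    "EnrichmentResult",
    "expected_allele_count",
    "enrichment_test",
    "screen_panel",
]


@dataclass(frozen=True)
class ScreenSite:
    """One screened polymorphism.

    ``maf`` is the population minor allele frequency in [0, 0.5], or
    ``None`` when unknown; ``carriers`` counts panel samples carrying the
    variant at least once.
    """

    site_id: str
    maf: float | None
    carriers: int
    panel_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.panel_size:
            raise ValueError(
                f"{self.site_id}: carriers must be in [0, panel_size], "
                f"got {self.carriers} of {self.panel_size}"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.site_id}: maf must be in [0, 0.5] or None")


@dataclass(frozen=True)
class EnrichmentResult:
    site_id: str
    expected_alleles: float | None
    observed_alleles: int
    p_value: float | None
    significant: bool | None


def expected_allele_count(maf: float | None, panel_size: int) -> float | None:
    """Expected mutant alleles in a diploid panel: ``2 * panel_size * maf``.

    Returns ``None`` when the MAF is unknown.
    """
    if panel_size < 1:
        raise ValueError(f"panel_size must be >= 1, got {panel_size!r}")
    if maf is None:
        return None
    return 2.0 * panel_size * maf


def enrichment_test(
    site: ScreenSite, alpha: float = 0.05, alleles_per_carrier: int = 1
) -> EnrichmentResult:
    """One-sided upper-tail exact binomial test of carrier excess.

    Observed mutant alleles = ``carriers * alleles_per_carrier``;
    p = P(X >= observed), X ~ Binomial(2 * panel_size, maf).  Sites with
    unknown MAF get ``p_value = significant = None``.
    """
    if alleles_per_carrier not in (1, 2):
        raise ValueError("alleles_per_carrier must be 1 or 2")
    observed = site.carriers * alleles_per_carrier
    if site.maf is None:
        return EnrichmentResult(site.site_id, None, observed, None, None)
    n_alleles = 2 * site.panel_size
    p_value = float(stats.binom.sf(observed - 1, n_alleles, site.maf))
    return EnrichmentResult(
        site_id=site.site_id,
        expected_alleles=expected_allele_count(site.maf, site.panel_size),
        observed_alleles=observed,
        p_value=p_value,
        significant=bool(p_value < alpha),
    )


def screen_panel(
    sites: Iterable[ScreenSite],
    alpha: float = 0.05,
    alleles_per_carrier: int = 1,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Test every site of a panel; return per-site results and a summary.

    All sites must share one ``panel_size``.  With ``bonferroni=True`` the
    per-site level is ``alpha / n_testable``.  The summary reports the
    number of sites, the total carrier observations, how many sites were
    testable (known MAF) and how many were significant.
    """
    sites = list(sites)
    panel_sizes = {s.panel_size for s in sites}
    if len(panel_sizes) > 1:
        raise ValueError(f"inconsistent panel sizes: {sorted(panel_sizes)}")
    n_testable = sum(1 for s in sites if s.maf is not None)
    level = alpha / n_testable if (bonferroni and n_testable) else alpha
    results = [
        enrichment_test(s, alpha=level, alleles_per_carrier=alleles_per_carrier)
        for s in sites
    ]
    frame = pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "maf": [s.maf for s in sites],
            "carriers": [s.carriers for s in sites],
            "expected_alleles": [r.expected_alleles for r in results],
            "observed_alleles": [r.observed_alleles for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
    summary = {
        "n_sites": len(sites),
        "total_observations": int(sum(s.carriers for s in sites)),
        "n_testable": n_testable,
        "n_significant": int(sum(1 for r in results if r.significant)),
        "alpha": alpha,
        "per_site_alpha": level,
        "alleles_per_carrier": alleles_per_carrier,
    }
    return frame, summary


def sites_from_frame(frame: pd.DataFrame) -> list[ScreenSite]:
    """Build :class:`ScreenSite` rows from a table with columns
    ``site_id, maf, carriers, panel_size`` (MAF ``"?"``/empty -> unknown)."""
    out = []
    for _, row in frame.iterrows():
        maf = row["maf"]
        if pd.isna(maf) or str(maf).strip() in ("?", ""):
            maf_val = None
        else:
            maf_val = float(maf)
        out.append(
            ScreenSite(
                site_id=str(row["site_id"]),
                maf=maf_val,
                carriers=int(row["carriers"]),
                panel_size=int(row["panel_size"]),
            )
        )
    return out
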