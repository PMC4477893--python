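"""Somatic-variant filtering cascade for a tumour/normal pair.

Raw variant tables (already annotated for region, effect and known-SNP
status by an upstream caller) are reduced to novel, non-silent,
well-supported coding candidates by six predicates applied in a fixed
order:

1. somatic        — absent from the matched control (alt reads <= tolerance)
2. strand         — mutant reads on both strands
3. depth          — coverage >= min_depth in tumour and control
4. transcribed    — exonic region (coding or non-coding exon)
5. non-silent     — effect is not silent
6. novel          — no known-SNP identifier

The stages are independent predicates, so the final survivor set does not
depend on the order; a fixed order is needed only so per-stage attrition
counts are well defined.  A record failing several stages is charged to the
first failing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "FilterReport",
    "VARIANT_CLASSES",
    "REGION_CLASSES",
    "EFFECT_CLASSES",
    "TRANSCRIBED_REGIONS",
    "is_somatic",
    "strand_filter",
    "depth_filter",
    "is_transcribed",
    "is_non_silent",
    "is_novel",
    "run_cascade",
    "records_to_frame",
    "records_from_frame",
]

VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})
REGION_CLASSES = frozenset(
    {"exonic-coding", "exonic-noncoding", "intronic", "intergenic"}
)
EFFECT_CLASSES = frozenset(
    {"silent", "nonsynonymous", "frameshift", "noncoding", "unknown"}
)
TRANSCRIBED_REGIONS = frozenset({"exonic-coding", "exonic-noncoding"})


@dataclass
class VariantRecord:
    """One tumour/normal variant site with per-strand allele depths."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    tumour_alt_fwd: int
    tumour_alt_rev: int
    tumour_depth: int
    control_alt_count: int
    control_depth: int
    variant_class: str = "SNV"
    region_class: str = "exonic-coding"
    effect_class: str = "nonsynonymous"
    known_snp_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self._ident()}: pos must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"{self._ident()}: alleles must be non-empty")
        if self.tumour_alt_fwd + self.tumour_alt_rev > self.tumour_depth:
            raise ValueError(
                f"{self._ident()}: tumour alt reads exceed tumour depth"
            )
        if self.control_alt_count > self.control_depth:
            raise ValueError(
                f"{self._ident()}: control alt reads exceed control depth"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"{self._ident()}: unknown variant_class {self.variant_class!r}"
            )
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"{self._ident()}: unknown region_class {self.region_class!r}"
            )
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"{self._ident()}: unknown effect_class {self.effect_class!r}"
            )

    def _ident(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def tumour_alt_count(self) -> int:
        return self.tumour_alt_fwd + self.tumour_alt_rev


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 10
    max_control_alt: int = 0


# stage names in cascade order; FilterReport mirrors this order
_STAGES = ("somatic", "strand_ok", "depth_ok", "transcribed", "non_silent", "novel")


@dataclass
class FilterReport:
    """Counts of records surviving each cascade stage, in order."""

    input: int = 0
    somatic: int = 0
    strand_ok: int = 0
    depth_ok: int = 0
    transcribed: int = 0
    non_silent: int = 0
    novel: int = 0

    def counts(self) -> list[int]:
        return [self.input, *(getattr(self, s) for s in _STAGES)]

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def is_somatic(record: VariantRecord, max_control_alt: int = 0) -> bool:
    """True iff the variant is absent from the control (within tolerance)."""
    return record.control_alt_count <= max_control_alt


def strand_filter(record: VariantRecord) -> bool:
    """True iff mutant reads are seen on both strands."""
    return record.tumour_alt_fwd >= 1 and record.tumour_alt_rev >= 1


def depth_filter(record: VariantRecord, min_depth: int = 10) -> bool:
    """True iff both samples reach ``min_depth`` coverage at the site."""
    return record.tumour_depth >= min_depth and record.control_depth >= min_depth


def is_transcribed(record: VariantRecord) -> bool:
    return record.region_class in TRANSCRIBED_REGIONS


def is_non_silent(record: VariantRecord) -> bool:
    return record.effect_class != "silent"


def is_novel(record: VariantRecord) -> bool:
    return not record.known_snp_id


def run_cascade(
    records: Iterable[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the six-stage filter cascade; return survivors and attrition.

    Survivors preserve input order.  The report counts records surviving
    each successive stage, so its entries are non-increasing.
    """
    if config is None:
        config = FilterConfig()
    records = list(records)
    report = FilterReport(input=len(records))
    stages = [
        ("somatic", lambda r: is_somatic(r, config.max_control_alt)),
        ("strand_ok", strand_filter),
        ("depth_ok", lambda r: depth_filter(r, config.min_depth)),
        ("transcribed", is_transcribed),
        ("non_silent", is_non_silent),
        ("novel", is_novel),
    ]
    alive = records
    for name, predicate in stages:
        alive = [r for r in alive if predicate(r)]
        setattr(report, name, len(alive))
    return alive, report


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    cols = [f.name for f in VariantRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


def records_from_frame(frame: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for _, row in frame.iterrows():
        d = row.to_dict()
        snp = d.get("known_snp_id")
        if pd.isna(snp) or snp == "":
            d["known_snp_id"] = None
        out.append(
            VariantRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref_allele=str(d["ref_allele"]),
                alt_allele=str(d["alt_allele"]),
                tumour_alt_fwd=int(d["tumour_alt_fwd"]),
                tumour_alt_rev=int(d["tumour_alt_rev"]),
                tumour_depth=int(d["tumour_depth"]),
                control_alt_count=int(d["control_alt_count"]),
                control_depth=int(d["control_depth"]),
                variant_class=str(d["variant_class"]),
                region_class=str(d["region_class"]),
                effect_class=str(d["effect_class"]),
                known_snp_id=d["known_snp_id"],
            )
        )
    return out
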