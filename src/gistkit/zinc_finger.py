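"""C2H2 zinc-finger motif scanning and substitution mapping.

A C2H2 (Krüppel-type) zinc finger coordinates a zinc ion with two
cysteines and two histidines; the residues between the second cysteine and
the first histidine form the recognition helix that contacts DNA.  The
scanner matches the spacing pattern

    C - x(1,5) - C - x(10,14) - H - x(3,5) - H

left-to-right and non-overlapping, preferring the canonical
``C-x(2)-C-x(12)-H-x(3)-H`` spacing when several anchor assignments are
possible (this keeps a stray histidine inside the recognition helix from
being mistaken for a coordinating one).  Spacer bounds are configurable —
zinc-finger databases disagree on stringency, and predicted finger counts
vary accordingly.

Amino-acid substitutions are mapped into a matched finger by their offset,
classified as zinc-coordinating, recognition-helix or spacer, and reported
with their distance upstream of the terminal histidine — a position whose
residue preferences are sharply constrained in functional fingers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.IUPACData import protein_letters_3to1

__all__ = [
    "ZincFinger",
    "SubstitutionInFinger",
    "VariantAnnotation",
    "scan_c2h2",
    "locate_substitution",
    "map_variants_to_fingers",
    "parse_protein_variant",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: (min, max) lengths of the three spacers C..C, C..H, H..H
DEFAULT_SPACER_BOUNDS = ((1, 5), (10, 14), (3, 5))
#: canonical spacer lengths, preferred on ambiguous matches
CANONICAL_SPACERS = (2, 12, 3)


@dataclass(frozen=True)
class ZincFinger:
    """One matched C2H2 motif; all positions 1-based in the parent sequence."""

    start: int
    end: int
    c1: int
    c2: int
    h1: int
    h2: int
    motif_seq: str

    def __post_init__(self) -> None:
        if not self.c1 < self.c2 < self.h1 < self.h2:
            raise ValueError("anchors must satisfy c1 < c2 < h1 < h2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def anchor_offsets(self) -> tuple[int, int, int, int]:
        """Anchor positions relative to the motif, 1-based."""
        s = self.start - 1
        return (self.c1 - s, self.c2 - s, self.h1 - s, self.h2 - s)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class SubstitutionInFinger:
    """A substitution located inside a zinc finger."""

    finger: ZincFinger
    offset_in_motif: int
    role: str  # zinc-coordinating | recognition-helix | spacer
    dist_upstream_of_terminal_H: int
    helix_adjacent: bool = False


@dataclass(frozen=True)
class VariantAnnotation:
    position: int
    ref_aa: str
    alt_aa: str
    in_finger: bool
    substitution: SubstitutionInFinger | None


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in AA_ALPHABET:
            raise ValueError(
                f"non-amino-acid character {aa!r} at position {i}"
            )
    return seq


def scan_c2h2(
    sequence: str,
    spacer_bounds: Sequence[tuple[int, int]] = DEFAULT_SPACER_BOUNDS,
    canonical: Sequence[int] = CANONICAL_SPACERS,
) -> list[ZincFinger]:
    """Find non-overlapping C2H2 fingers, left to right.

    At each candidate first cysteine, every anchor assignment allowed by
    ``spacer_bounds`` is enumerated and the one closest to the
    ``canonical`` spacing (lexicographic distance over the three spacers,
    then leftmost anchors) is taken; scanning resumes after the terminal
    histidine.  Case-insensitive; coordinates 1-based.
    """
    seq = _validate_sequence(sequence)
    (lo1, hi1), (lo2, hi2), (lo3, hi3) = spacer_bounds
    n = len(seq)
    fingers: list[ZincFinger] = []
    i = 0  # 0-based index of candidate c1
    while i < n:
        if seq[i] != "C":
            i += 1
            continue
        best = None
        best_key = None
        for j in range(i + lo1 + 1, min(i + hi1 + 2, n)):
            if seq[j] != "C":
                continue
            for m in range(j + lo2 + 1, min(j + hi2 + 2, n)):
                if seq[m] != "H":
                    continue
                for p in range(m + lo3 + 1, min(m + hi3 + 2, n)):
                    if seq[p] != "H":
                        continue
                    spacers = (j - i - 1, m - j - 1, p - m - 1)
                    key = (
                        abs(spacers[0] - canonical[0]),
                        abs(spacers[1] - canonical[1]),
                        abs(spacers[2] - canonical[2]),
                        j,
                        m,
                        p,
                    )
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (j, m, p)
        if best is None:
            i += 1
            continue
        j, m, p = best
        fingers.append(
            ZincFinger(
                start=i + 1,
                end=p + 1,
                c1=i + 1,
                c2=j + 1,
                h1=m + 1,
                h2=p + 1,
                motif_seq=seq[i : p + 1],
            )
        )
        i = p + 1
    return fingers


def locate_substitution(finger: ZincFinger, offset_in_motif: int) -> SubstitutionInFinger:
    """Classify a position inside a finger by structural role.

    Roles: the four anchors are ``zinc-coordinating``; residues strictly
    between the second cysteine and the first histidine are
    ``recognition-helix``; the rest are ``spacer``, with positions between
    the two histidines flagged ``helix_adjacent`` (the recognition helix
    extends through the histidines, but no finer partition is attempted).
    """
    if not 1 <= offset_in_motif <= finger.length:
        raise ValueError(
            f"offset {offset_in_motif} outside finger of length {finger.length}"
        )
    c1, c2, h1, h2 = finger.anchor_offsets
    off = offset_in_motif
    helix_adjacent = False
    if off in (c1, c2, h1, h2):
        role = "zinc-coordinating"
    elif c2 < off < h1:
        role = "recognition-helix"
    else:
        role = "spacer"
        if h1 < off < h2:
            helix_adjacent = True
    return SubstitutionInFinger(
        finger=finger,
        offset_in_motif=off,
        role=role,
        dist_upstream_of_terminal_H=h2 - off,
        helix_adjacent=helix_adjacent,
    )


_HGVS_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_protein_variant(variant) -> tuple[int, str, str]:
    """Normalize a variant to ``(position, ref_aa, alt_aa)`` one-letter form.

    Accepts a ``(pos, ref, alt)`` tuple with one-letter codes or an
    ``"Arg1038Trp"``-style string with three-letter codes.
    """
    if isinstance(variant, str):
        m = _HGVS_RE.match(variant.strip())
        if not m:
            raise ValueError(f"cannot parse protein variant {variant!r}")
        ref3, pos, alt3 = m.groups()
        try:
            ref = protein_letters_3to1[ref3]
            alt = protein_letters_3to1[alt3]
        except KeyError as exc:
            raise ValueError(f"unknown amino-acid code in {variant!r}") from exc
        return int(pos), ref, alt
    pos, ref, alt = variant
    return int(pos), str(ref).upper(), str(alt).upper()


def map_variants_to_fingers(
    sequence: str,
    variants: Iterable,
    spacer_bounds: Sequence[tuple[int, int]] = DEFAULT_SPACER_BOUNDS,
) -> list[VariantAnnotation]:
    """Annotate substitutions with their position inside scanned fingers.

    Each variant's reference amino acid is checked against the sequence; a
    mismatch raises a ``ValueError`` naming position, expected and found
    residues.  Variants outside every finger are annotated
    ``in_finger=False``.
    """
    seq = _validate_sequence(sequence)
    fingers = scan_c2h2(seq, spacer_bounds=spacer_bounds)
    out: list[VariantAnnotation] = []
    for variant in variants:
        pos, ref, alt = parse_protein_variant(variant)
        if not 1 <= pos <= len(seq):
            raise ValueError(f"variant position {pos} outside sequence of length {len(seq)}")
        found = seq[pos - 1]
        if found != ref:
            raise ValueError(
                f"reference mismatch at position {pos}: expected {ref}, found {found}"
            )
        hit = next((f for f in fingers if f.contains(pos)), None)
        sub = None
        if hit is not None:
            sub = locate_substitution(hit, pos - hit.start + 1)
        out.append(
            VariantAnnotation(
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                in_finger=hit is not None,
                substitution=sub,
            )
        )
    return out
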