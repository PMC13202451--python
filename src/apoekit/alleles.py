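"""APOE epsilon haplotypes and diplotypes.

The common APOE protein isoforms are encoded by two coding SNPs on
chromosome 19 (GRCh38): rs429358 (chr19:44908684, T/C) and rs7412
(chr19:44908822, C/T).  The phased allele pair on one chromosome defines
the epsilon haplotype:

    rs429358=T, rs7412=T  ->  e2
    rs429358=T, rs7412=C  ->  e3   (most common)
    rs429358=C, rs7412=C  ->  e4   (dementia risk allele)
    rs429358=C, rs7412=T  ->  e1   (rare; the fourth combination)

A person's unordered pair of haplotypes is their diplotype (for example
"e3/e4"); e1 is called but flagged, since the standard three-haplotype
classification has no category for it.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass

RS429358 = ("chr19", 44908684, "T", "C")
RS7412 = ("chr19", 44908822, "C", "T")

VALID_BASES = frozenset({"T", "C"})


class ApoeAllele(enum.Enum):
    """One epsilon haplotype; ordering follows the numeric label."""

    E1 = "e1"
    E2 = "e2"
    E3 = "e3"
    E4 = "e4"

    @property
    def greek(self) -> str:
        return "ε" + self.value[1]

    def __lt__(self, other: "ApoeAllele") -> bool:
        return self.value < other.value

    def __str__(self) -> str:
        return self.value


#: allele pair at (rs429358, rs7412) -> epsilon haplotype; bijective on {T,C}^2
ALLELE_MAP: dict[tuple[str, str], ApoeAllele] = {
    ("T", "T"): ApoeAllele.E2,
    ("T", "C"): ApoeAllele.E3,
    ("C", "C"): ApoeAllele.E4,
    ("C", "T"): ApoeAllele.E1,
}

#: inverse of ALLELE_MAP: haplotype -> (rs429358 base, rs7412 base)
HAPLOTYPE_BASES: dict[ApoeAllele, tuple[str, str]] = {
    v: k for k, v in ALLELE_MAP.items()
}


class InvalidAlleleError(ValueError):
    """A base outside {T, C} was supplied at an APOE site."""


def allele_from_variants(rs429358_base: str, rs7412_base: str) -> ApoeAllele:
    """Map the phased bases at the two APOE sites to an epsilon haplotype.

    Returns e1 for the (C, T) combination, which is not part of the
    standard three-haplotype system; callers should treat it as a
    warning condition (see :meth:`Diplotype.has_e1`).

    Raises
    ------
    InvalidAlleleError
        If either base is not T or C.
    """
    key = (rs429358_base.upper(), rs7412_base.upper())
    if key[0] not in VALID_BASES or key[1] not in VALID_BASES:
        raise InvalidAlleleError(
            f"bases must be T or C at rs429358/rs7412, got {key}"
        )
    return ALLELE_MAP[key]


@functools.total_ordering
@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of epsilon haplotypes, stored in canonical order.

    ``Diplotype(e4, e3)`` and ``Diplotype(e3, e4)`` compare equal and
    render identically ("e3/e4"), so category counts never split an
    unordered genotype across two labels.
    """

    a: ApoeAllele
    b: ApoeAllele

    def __post_init__(self) -> None:
        lo, hi = sorted((self.a, self.b))
        object.__setattr__(self, "a", lo)
        object.__setattr__(self, "b", hi)

    @classmethod
    def from_string(cls, text: str) -> "Diplotype":
        """Parse "e3/e4" (ASCII) or the Greek rendering."""
        norm = text.replace("ε", "e").strip()
        left, _, right = norm.partition("/")
        return cls(ApoeAllele(left), ApoeAllele(right))

    @property
    def key(self) -> str:
        """Canonical ASCII label, e.g. ``"e3/e4"``."""
        return f"{self.a.value}/{self.b.value}"

    @property
    def greek(self) -> str:
        return f"{self.a.greek}/{self.b.greek}"

    @property
    def has_e1(self) -> bool:
        return ApoeAllele.E1 in (self.a, self.b)

    def count(self, allele: ApoeAllele) -> int:
        """Copies (0, 1 or 2) of ``allele`` carried."""
        return int(self.a is allele) + int(self.b is allele)

    def __str__(self) -> str:
        return self.key

    def __lt__(self, other: "Diplotype") -> bool:
        return (self.a, self.b) < (other.a, other.b)


#: the six diplotypes of the three-haplotype system, canonical order
STANDARD_DIPLOTYPES: tuple[Diplotype, ...] = tuple(
    Diplotype(a, b)
    for i, a in enumerate([ApoeAllele.E2, ApoeAllele.E3, ApoeAllele.E4])
    for b in [ApoeAllele.E2, ApoeAllele.E3, ApoeAllele.E4][i:]
)

E3E3 = Diplotype(ApoeAllele.E3, ApoeAllele.E3)
E2E2 = Diplotype(ApoeAllele.E2, ApoeAllele.E2)
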