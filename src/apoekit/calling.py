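"""Call APOE epsilon diplotypes from phased genotypes.

Samples are called from the two coding variants rs429358
(chr19:44908684 T/C) and rs7412 (chr19:44908822 C/T).  Sites are
located by chromosome and position, with the rs identifier as a
fallback, and the file's REF/ALT orientation is validated against the
expected alleles — a swapped orientation is a fatal error, never a
silent allele flip.

Phase matters: an individual heterozygous at both sites is e2/e4 if T-T
and C-C lie on opposite chromosomes but e1/e3 if T-C and C-T do.  Only
phased ("|") genotypes are accepted by default; unphased double
heterozygotes can optionally be resolved as e2/e4, which under a
near-zero e1 frequency is the only configuration not requiring an e1
haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .alleles import (
    ApoeAllele,
    Diplotype,
    RS429358,
    RS7412,
    allele_from_variants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedCallSet",
    "CallingResult",
    "SiteError",
    "AmbiguousPhaseError",
    "diplotype_from_calls",
    "read_phased_genotypes",
    "call_diplotypes",
    "write_diplotype_table",
]


class SiteError(RuntimeError):
    """An APOE site is absent or its REF/ALT orientation is wrong."""


class AmbiguousPhaseError(ValueError):
    """Unphased double heterozygote with no resolution policy enabled."""


@dataclass(frozen=True)
class PhasedCallSet:
    """Genotype calls for one sample at the two APOE sites.

    ``hap1``/``hap2`` hold the (rs429358 base, rs7412 base) pair on each
    chromosome; ``phased`` records whether both sites carried the "|"
    separator; ``missing`` flags any no-call.
    """

    sample_id: str
    hap1: tuple[str, str]
    hap2: tuple[str, str]
    phased: bool = True
    missing: bool = False

    @property
    def usable(self) -> bool:
        return not self.missing

    @property
    def het_both_sites(self) -> bool:
        return self.hap1[0] != self.hap2[0] and self.hap1[1] != self.hap2[1]


def diplotype_from_calls(
    calls: PhasedCallSet, resolve_unphased: bool = False
) -> Diplotype:
    """Call the epsilon diplotype for one sample.

    Raises
    ------
    ValueError
        If the call has missing sites.
    AmbiguousPhaseError
        If the sample is unphased and heterozygous at both sites and
        ``resolve_unphased`` is off.  With the policy on, such samples
        are called e2/e4 (with a warning), the configuration that does
        not posit an e1 haplotype.
    """
    if calls.missing:
        raise ValueError(f"sample {calls.sample_id}: missing genotype call")
    if not calls.phased and calls.het_both_sites:
        if not resolve_unphased:
            raise AmbiguousPhaseError(
                f"sample {calls.sample_id}: unphased and heterozygous at "
                "both sites; phase is required to distinguish e2/e4 from e1/e3"
            )
        logger.warning(
            "sample %s: unphased double heterozygote resolved as e2/e4",
            calls.sample_id,
        )
        return Diplotype(ApoeAllele.E2, ApoeAllele.E4)
    a = allele_from_variants(*calls.hap1)
    b = allele_from_variants(*calls.hap2)
    dip = Diplotype(a, b)
    if dip.has_e1:
        logger.warning(
            "sample %s: e1 haplotype called (%s); not part of the "
            "three-haplotype system",
            calls.sample_id,
            dip.key,
        )
    return dip


def _locate_site(vcf_path: str, chrom: str, pos: int, ref: str, alt: str,
                 rsid: str):
    """Find one site by position (identifier fallback) and validate REF/ALT."""
    found = None
    for variant in VCF(str(vcf_path)):
        by_pos = (
            variant.CHROM.removeprefix("chr") == chrom.removeprefix("chr")
            and variant.POS == pos
        )
        if by_pos or variant.ID == rsid:
            found = variant
            break
    if found is None:
        raise SiteError(f"site {rsid} ({chrom}:{pos}) absent from {vcf_path}")
    if found.REF != ref or list(found.ALT) != [alt]:
        raise SiteError(
            f"site {rsid}: expected REF={ref} ALT={alt}, found "
            f"REF={found.REF} ALT={found.ALT}; refusing to flip alleles"
        )
    return found


def read_phased_genotypes(path: str | Path) -> list[PhasedCallSet]:
    """Read the two APOE sites from a VCF and return per-sample calls.

    Raises :class:`SiteError` if either site is absent or its REF/ALT
    orientation does not match the expected alleles.
    """
    path = str(path)
    samples = VCF(path).samples
    sites = []
    for (chrom, pos, ref, alt), rsid in ((RS429358, "rs429358"),
                                         (RS7412, "rs7412")):
        sites.append((_locate_site(path, chrom, pos, ref, alt, rsid),
                      ref, alt))

    calls: list[PhasedCallSet] = []
    (v1, ref1, alt1), (v2, ref2, alt2) = sites
    gt1, gt2 = v1.genotypes, v2.genotypes
    for i, sample in enumerate(samples):
        a1, b1, ph1 = gt1[i][0], gt1[i][1], bool(gt1[i][2])
        a2, b2, ph2 = gt2[i][0], gt2[i][1], bool(gt2[i][2])
        missing = min(a1, b1, a2, b2) < 0
        if missing:
            calls.append(
                PhasedCallSet(sample, ("N", "N"), ("N", "N"),
                              phased=False, missing=True)
            )
            continue
        base = lambda idx, ref, alt: alt if idx == 1 else ref
        hap1 = (base(a1, ref1, alt1), base(a2, ref2, alt2))
        hap2 = (base(b1, ref1, alt1), base(b2, ref2, alt2))
        # homozygous sites carry no phase information, so only sites that
        # are actually heterozygous need the "|" separator
        phased = (ph1 or a1 == b1) and (ph2 or a2 == b2)
        calls.append(PhasedCallSet(sample, hap1, hap2, phased=phased))
    return calls


@dataclass
class CallingResult:
    """Diplotype calls plus the per-sample exclusion log."""

    diplotypes: pd.Series  # sample_id -> diplotype key
    excluded: dict[str, str] = field(default_factory=dict)
    n_e1: int = 0

    @property
    def n_called(self) -> int:
        return len(self.diplotypes)


def call_diplotypes(
    callsets: list[PhasedCallSet],
    resolve_unphased: bool = False,
) -> CallingResult:
    """Call every usable sample; log and exclude the rest.

    Missing calls and (without the policy) ambiguous unphased calls are
    excluded listwise with a reason, mirroring complete-case analysis.
    """
    keys: dict[str, str] = {}
    excluded: dict[str, str] = {}
    n_e1 = 0
    for cs in callsets:
        if cs.missing:
            excluded[cs.sample_id] = "missing genotype"
            continue
        try:
            dip = diplotype_from_calls(cs, resolve_unphased=resolve_unphased)
        except AmbiguousPhaseError:
            excluded[cs.sample_id] = "unphased double heterozygote"
            continue
        if dip.has_e1:
            n_e1 += 1
        keys[cs.sample_id] = dip.key
    if excluded:
        logger.info("excluded %d of %d samples during diplotype calling",
                    len(excluded), len(callsets))
    series = pd.Series(keys, name="diplotype", dtype=object)
    series.index.name = "sample_id"
    return CallingResult(series, excluded, n_e1)


def write_diplotype_table(result: CallingResult, path: str | Path) -> None:
    """Write the sample -> diplotype table as TSV."""
    result.diplotypes.to_frame().to_csv(path, sep="\t")
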