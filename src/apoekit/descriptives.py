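"""Genotype count tables, carrier proportions and allele frequencies.

Summarises called diplotypes by case/control status: per-diplotype
counts and proportions, e4 dose (0/1/2) counts, per-allele carrier
statistics, and allele frequencies computed from genotype counts
(2*hom + het over 2N).  Also provides the exact two-sided binomial test
used to compare a cohort's carrier proportion against an external
reference proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .alleles import ApoeAllele, Diplotype

__all__ = [
    "GenotypeCountTable",
    "summarize_genotypes",
    "carrier_stats",
    "carrier_enrichment_test",
]

GROUPS = ("cases", "controls", "overall")


@dataclass
class GenotypeCountTable:
    """Counts and derived proportions per group (cases/controls/overall).

    ``diplotype_counts[group]`` maps diplotype key -> integer count;
    ``n[group]`` is the group size.  Proportions and allele frequencies
    are computed on demand at full precision; rendering rounds to one
    decimal percentage.
    """

    diplotype_counts: dict[str, dict[str, int]]
    n: dict[str, int]

    def proportions(self, group: str) -> dict[str, float]:
        if self.n[group] == 0:
            raise ZeroDivisionError(f"group {group!r} is empty")
        return {
            k: c / self.n[group]
            for k, c in self.diplotype_counts[group].items()
        }

    def dose_counts(self, group: str, allele: ApoeAllele = ApoeAllele.E4
                    ) -> dict[int, int]:
        """Counts of samples carrying 0/1/2 copies of ``allele``."""
        out = {0: 0, 1: 0, 2: 0}
        for key, count in self.diplotype_counts[group].items():
            out[Diplotype.from_string(key).count(allele)] += count
        return out

    def allele_frequencies(self, group: str) -> dict[str, float]:
        """Allele frequencies from genotype counts: (2*hom + het)/(2N)."""
        if self.n[group] == 0:
            raise ZeroDivisionError(f"group {group!r} is empty")
        copies: dict[str, int] = {}
        for key, count in self.diplotype_counts[group].items():
            dip = Diplotype.from_string(key)
            for allele in (dip.a, dip.b):
                copies[allele.value] = copies.get(allele.value, 0) + count
        total = 2 * self.n[group]
        return {k: v / total for k, v in sorted(copies.items())}

    # --- reporting ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Table 1-shaped frame: one row per diplotype/dose/frequency."""
        rows = []
        for group in GROUPS:
            for key, count in sorted(self.diplotype_counts[group].items()):
                rows.append(
                    ("genotype", key, group, count,
                     round(100 * count / self.n[group], 1)
                     if self.n[group] else float("nan"))
                )
            for dose, count in self.dose_counts(group).items():
                rows.append(
                    ("e4_dose", str(dose), group, count,
                     round(100 * count / self.n[group], 1)
                     if self.n[group] else float("nan"))
                )
            if self.n[group]:
                for allele, freq in self.allele_frequencies(group).items():
                    rows.append(
                        ("allele_frequency", allele, group,
                         pd.NA, round(100 * freq, 1))
                    )
        return pd.DataFrame(
            rows, columns=["section", "category", "group", "n", "percent"]
        )

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None
              ) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            payload = {
                "n": self.n,
                "diplotype_counts": self.diplotype_counts,
                "allele_frequencies": {
                    g: self.allele_frequencies(g)
                    for g in GROUPS if self.n[g]
                },
                "e4_dose_counts": {
                    g: self.dose_counts(g) for g in GROUPS
                },
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def summarize_genotypes(
    diplotypes: Iterable[str | Diplotype],
    statuses: Iterable[bool],
) -> GenotypeCountTable:
    """Tabulate diplotypes by dementia status.

    ``statuses`` marks cases (True) and controls (False); the overall
    group is their union.  Counts are exact integers.
    """
    keys = [
        d.key if isinstance(d, Diplotype) else Diplotype.from_string(d).key
        for d in diplotypes
    ]
    status = [bool(s) for s in statuses]
    if len(keys) != len(status):
        raise ValueError("diplotypes and statuses differ in length")
    counts = {g: {} for g in GROUPS}
    for key, is_case in zip(keys, status):
        for group in ("cases" if is_case else "controls", "overall"):
            counts[group][key] = counts[group].get(key, 0) + 1
    n = {
        "cases": sum(status),
        "controls": len(status) - sum(status),
        "overall": len(status),
    }
    return GenotypeCountTable(counts, n)


def carrier_stats(
    table: GenotypeCountTable, allele: ApoeAllele, group: str = "overall"
) -> dict[str, float]:
    """Carrier counts/proportions for one allele within one group.

    Returns any-carrier, heterozygous (exactly one copy) and homozygous
    (two copies) counts with their proportions of the group N.
    """
    dose = table.dose_counts(group, allele)
    n = table.n[group]
    het, hom = dose[1], dose[2]
    carriers = het + hom
    prop = lambda c: c / n if n else 0.0
    return {
        "carriers": carriers,
        "het": het,
        "hom": hom,
        "prop_carriers": prop(carriers),
        "prop_het": prop(het),
        "prop_hom": prop(hom),
    }


def carrier_enrichment_test(
    carriers: int, n: int, reference_proportion: float
) -> float:
    """Exact two-sided binomial p-value for carrier enrichment/depletion.

    Compares the observed carrier count against an external reference
    carrier proportion using the minimum-likelihood two-sided convention
    (sum of all outcome probabilities no larger than the observed one).
    """
    if not 0 <= carriers <= n:
        raise ValueError("carriers must lie in [0, n]")
    if not 0.0 < reference_proportion < 1.0:
        raise ValueError("reference proportion must be strictly in (0, 1)")
    return float(
        stats.binomtest(carriers, n, reference_proportion,
                        alternative="two-sided").pvalue
    )


def table1_report(
    table: GenotypeCountTable,
    reference_e4_carrier_proportion: float | None = None,
) -> Mapping[str, object]:
    """Assemble the descriptive summary used by the pipeline report."""
    out: dict[str, object] = {
        "n": dict(table.n),
        "e4_carriers": {
            g: carrier_stats(table, ApoeAllele.E4, g)
            for g in GROUPS if table.n[g]
        },
        "e3_carriers": {
            g: carrier_stats(table, ApoeAllele.E3, g)
            for g in GROUPS if table.n[g]
        },
        "allele_frequencies": {
            g: table.allele_frequencies(g) for g in GROUPS if table.n[g]
        },
    }
    if reference_e4_carrier_proportion is not None and table.n["overall"]:
        cs = carrier_stats(table, ApoeAllele.E4, "overall")
        out["e4_enrichment_p"] = carrier_enrichment_test(
            int(cs["carriers"]), table.n["overall"],
            reference_e4_carrier_proportion,
        )
    return out
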