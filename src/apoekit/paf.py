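"""Stratified-exposure population attributable fractions for APOE.

The attributable fraction is computed by the case-load method: with the
low-risk e2/e2 genotype as the unexposed reference, each exposed
genotype stratum contributes

    PAF_g = CF_g * (OR_g - 1) / OR_g

where CF_g is the stratum's case fraction (cases with genotype g over
all cases) and OR_g its odds ratio versus e2/e2, treated as a risk
ratio under the rare-outcome approximation.  The joint PAF for carrying
any e3 or e4 allele sums the five strata e3/e3, e3/e4, e2/e3, e2/e4,
e4/e4.

Because the e3/e4 stratum mixes both risk alleles, its PAF is split
between e4 and e3 with the weight w = R/(R+1), R = OR(e2/e4)/OR(e2/e3):
the allele-level PAFs are

    PAF_e4 = PAF(e4/e4) + PAF(e2/e4) + w * PAF(e3/e4)
    PAF_e3 = PAF(e3/e3) + PAF(e2/e3) + (1-w) * PAF(e3/e4)

and conserve the joint PAF exactly.  Confidence bounds recompute every
stratum PAF at OR*exp(+/-1.96 SE(log OR)) and sum; decomposition bounds
use the ratio R at its own upper/lower bounds.  The bounds are a
propagation of per-stratum Wald limits treating strata as independent,
not a delta-method interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PafStratum",
    "PafDecomposition",
    "PafResult",
    "stratum_paf",
    "joint_paf",
    "allele_weight",
    "allele_paf",
    "paf_bounds",
    "paf_from_fits",
]

Z95 = 1.96

#: the five exposed strata of the e3-or-e4 joint PAF, e2/e2 reference
EXPOSED_STRATA = ("e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")

E4_ONLY = ("e4/e4", "e2/e4")
E3_ONLY = ("e3/e3", "e2/e3")
SHARED = "e3/e4"


def stratum_paf(
    odds_ratio: float, case_fraction: float, literal_formula: bool = False
) -> float:
    """Case-load attributable fraction of one exposed genotype stratum.

    The default is the Miettinen/Hanley arrangement
    ``case_fraction * (OR - 1)/OR``.  ``literal_formula`` switches to the
    arrangement ``(OR - 1)/(OR * case_fraction)`` for auditability; that
    variant is not a fraction of cases (it exceeds 1 for small case
    fractions) and is provided only so both readings can be compared.
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if not 0.0 <= case_fraction <= 1.0:
        raise ValueError("case fraction must lie in [0, 1]")
    if literal_formula:
        if case_fraction == 0:
            return math.inf if odds_ratio != 1.0 else 0.0
        return (odds_ratio - 1.0) / (odds_ratio * case_fraction)
    return case_fraction * (odds_ratio - 1.0) / odds_ratio


@dataclass
class PafStratum:
    """One exposed genotype stratum with its point and bound PAFs."""

    genotype: str
    odds_ratio: float
    se_log_or: float
    case_fraction: float
    paf: float = field(init=False)
    paf_lower: float = field(init=False)
    paf_upper: float = field(init=False)

    def __post_init__(self) -> None:
        self.paf = stratum_paf(self.odds_ratio, self.case_fraction)
        lo, hi = self.or_bounds()
        self.paf_lower = stratum_paf(lo, self.case_fraction)
        self.paf_upper = stratum_paf(hi, self.case_fraction)

    def or_bounds(self) -> tuple[float, float]:
        log_or = math.log(self.odds_ratio)
        return (
            math.exp(log_or - Z95 * self.se_log_or),
            math.exp(log_or + Z95 * self.se_log_or),
        )


def joint_paf(strata: Mapping[str, PafStratum]) -> tuple[float, float, float]:
    """Sum the five exposed strata: (point, lower, upper).

    Raises ``KeyError`` naming the first missing stratum.
    """
    for g in EXPOSED_STRATA:
        if g not in strata:
            raise KeyError(f"missing stratum {g!r}")
    point = sum(strata[g].paf for g in EXPOSED_STRATA)
    lower = sum(strata[g].paf_lower for g in EXPOSED_STRATA)
    upper = sum(strata[g].paf_upper for g in EXPOSED_STRATA)
    return point, lower, upper


def allele_weight(or_e4e2: float, or_e3e2: float) -> float:
    """Weight w = R/(R+1) with R = OR(e2/e4)/OR(e2/e3).

    Splits the e3/e4 stratum's PAF between the e4 (weight w) and e3
    (weight 1-w) alleles in proportion to their effect-size ratio.
    """
    if or_e4e2 <= 0 or or_e3e2 <= 0:
        raise ValueError("odds ratios must be positive")
    ratio = or_e4e2 / or_e3e2
    return ratio / (ratio + 1.0)


@dataclass
class PafDecomposition:
    """Allele-level split of the joint PAF between e4 and e3."""

    ratio: float
    weight_e4: float
    weight_e3: float
    paf_e4: float
    paf_e3: float
    paf_joint: float
    paf_e4_bounds: tuple[float, float]
    paf_e3_bounds: tuple[float, float]
    paf_joint_bounds: tuple[float, float]


def allele_paf(
    strata: Mapping[str, PafStratum], weight_e4: float
) -> tuple[float, float]:
    """Point allele-level PAFs (e4, e3) under a given e3/e4 split weight.

    The e2/e4 stratum is attributed wholly to e4 and e2/e3 wholly to
    e3; only the mixed e3/e4 stratum is weight-split, so the two
    allele PAFs sum to the joint PAF exactly.
    """
    if not 0.0 < weight_e4 < 1.0:
        raise ValueError("weight must lie strictly in (0, 1)")
    shared = strata[SHARED].paf
    paf_e4 = sum(strata[g].paf for g in E4_ONLY) + weight_e4 * shared
    paf_e3 = sum(strata[g].paf for g in E3_ONLY) + (1.0 - weight_e4) * shared
    return paf_e4, paf_e3


def paf_bounds(
    strata: Mapping[str, PafStratum],
    ratio_bounds: tuple[float, float] | None = None,
) -> PafDecomposition:
    """Full decomposition with propagated bounds.

    Stratum bounds come from each stratum's Wald OR limits; the
    decomposition's bounds additionally move the split weight to the
    ratio's lower/upper limit (``ratio_bounds``), pairing the weight
    bound with the matching stratum bounds.
    """
    w = allele_weight(strata["e2/e4"].odds_ratio, strata["e2/e3"].odds_ratio)
    ratio = strata["e2/e4"].odds_ratio / strata["e2/e3"].odds_ratio
    if ratio_bounds is None:
        ratio_bounds = _default_ratio_bounds(strata)
    w_lo = ratio_bounds[0] / (ratio_bounds[0] + 1.0)
    w_hi = ratio_bounds[1] / (ratio_bounds[1] + 1.0)

    point, joint_lo, joint_hi = joint_paf(strata)
    paf_e4, paf_e3 = allele_paf(strata, w)

    def bound(which: str, weight: float) -> tuple[float, float]:
        attr = "paf_lower" if which == "lower" else "paf_upper"
        shared = getattr(strata[SHARED], attr)
        e4 = sum(getattr(strata[g], attr) for g in E4_ONLY) + weight * shared
        e3 = (
            sum(getattr(strata[g], attr) for g in E3_ONLY)
            + (1.0 - weight) * shared
        )
        return e4, e3

    e4_bounds = (bound("lower", w_lo)[0], bound("upper", w_hi)[0])
    e3_bounds = (bound("lower", w_hi)[1], bound("upper", w_lo)[1])

    return PafDecomposition(
        ratio=ratio,
        weight_e4=w,
        weight_e3=1.0 - w,
        paf_e4=paf_e4,
        paf_e3=paf_e3,
        paf_joint=point,
        paf_e4_bounds=e4_bounds,
        paf_e3_bounds=e3_bounds,
        paf_joint_bounds=(joint_lo, joint_hi),
    )


def _default_ratio_bounds(
    strata: Mapping[str, PafStratum]
) -> tuple[float, float]:
    """Wald bounds for R = OR(e2/e4)/OR(e2/e3) treating the ORs as
    independent: SE(log R) = sqrt(SE4^2 + SE3^2)."""
    s4, s3 = strata["e2/e4"], strata["e2/e3"]
    log_r = math.log(s4.odds_ratio) - math.log(s3.odds_ratio)
    se = math.hypot(s4.se_log_or, s3.se_log_or)
    return (math.exp(log_r - Z95 * se), math.exp(log_r + Z95 * se))


@dataclass
class PafResult:
    """Strata plus joint and allele-decomposed PAFs with bounds."""

    strata: dict[str, PafStratum]
    decomposition: PafDecomposition
    n_cases: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genotype": s.genotype,
                "odds_ratio": s.odds_ratio,
                "se_log_or": s.se_log_or,
                "case_fraction": s.case_fraction,
                "paf": s.paf,
                "paf_lower": s.paf_lower,
                "paf_upper": s.paf_upper,
            }
            for s in self.strata.values()
        ]
        d = self.decomposition
        for name, paf, bounds in (
            ("e4_alleles", d.paf_e4, d.paf_e4_bounds),
            ("e3_alleles", d.paf_e3, d.paf_e3_bounds),
            ("e3_or_e4_joint", d.paf_joint, d.paf_joint_bounds),
        ):
            rows.append(
                {"genotype": name, "odds_ratio": float("nan"),
                 "se_log_or": float("nan"), "case_fraction": float("nan"),
                 "paf": paf, "paf_lower": bounds[0], "paf_upper": bounds[1]}
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = self.decomposition
        return {
            "n_cases": self.n_cases,
            "strata": {
                k: {
                    "odds_ratio": s.odds_ratio,
                    "se_log_or": s.se_log_or,
                    "case_fraction": s.case_fraction,
                    "paf": s.paf,
                    "bounds": [s.paf_lower, s.paf_upper],
                }
                for k, s in self.strata.items()
            },
            "weight_e4": d.weight_e4,
            "ratio": d.ratio,
            "paf_e4": d.paf_e4,
            "paf_e4_bounds": list(d.paf_e4_bounds),
            "paf_e3": d.paf_e3,
            "paf_e3_bounds": list(d.paf_e3_bounds),
            "paf_joint": d.paf_joint,
            "paf_joint_bounds": list(d.paf_joint_bounds),
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None
              ) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_dict(), indent=2))


def paf_from_fits(
    results: Iterable, case_counts: Mapping[str, int]
) -> PafResult:
    """Assemble the full PAF report from logistic fits vs e2/e2.

    ``results`` are association results (term = diplotype key, estimate
    = log OR versus e2/e2); ``case_counts`` maps every genotype,
    including the reference, to its case count.  Wraps
    :func:`stratum_paf`, :func:`joint_paf`, :func:`allele_weight` and
    :func:`paf_bounds` end to end.
    """
    total_cases = sum(case_counts.values())
    if total_cases == 0:
        raise ValueError("no cases supplied")
    by_term = {r.term: r for r in results}
    strata: dict[str, PafStratum] = {}
    for g in EXPOSED_STRATA:
        if g not in by_term:
            raise KeyError(f"no fitted odds ratio for stratum {g!r}")
        r = by_term[g]
        if not math.isfinite(r.estimate):
            raise ValueError(f"stratum {g!r} is non-estimable")
        if "reference_no_events" in getattr(r, "flags", ()):
            raise ValueError(
                "reference genotype has no cases; odds ratios versus it "
                "are non-identifiable, so the attributable fractions "
                "cannot be computed from this cohort"
            )
        strata[g] = PafStratum(
            genotype=g,
            odds_ratio=math.exp(r.estimate),
            se_log_or=r.se,
            case_fraction=case_counts.get(g, 0) / total_cases,
        )
    decomposition = paf_bounds(strata)
    return PafResult(strata, decomposition, total_cases)
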