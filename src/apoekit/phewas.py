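"""Phenome-wide association screen for APOE genotypes.

Every eligible trait — binary traits with at least 500 cases,
quantitative traits observed in more than 1000 samples — is tested for
association with each non-reference APOE diplotype (reference e3/e3),
using logistic regression for binary traits and linear regression for
quantitative ones, adjusted for the same covariates as the primary
survival models.

Multiplicity is controlled two ways: a study-wide Bonferroni threshold
alpha/m, where m is the number of eligible traits fixed *before* any
fitting (a trait's genotype terms share its test slot, and failed fits
keep their slot), and Benjamini-Hochberg FDR flags at the same alpha.
A config switch counts trait-genotype pairs instead of traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import SurvivalConfig, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "TraitSpec",
    "PhewasResult",
    "eligible_traits",
    "bonferroni_threshold",
    "bh_fdr",
    "run_phewas",
]

MIN_BINARY_CASES = 500
MIN_QUANTITATIVE_N = 1000  # strict: eligibility requires n > 1000


@dataclass(frozen=True)
class TraitSpec:
    """One candidate trait with its eligibility status."""

    name: str
    kind: Literal["binary", "quantitative"]
    n: int  # cases for binary, non-missing observations for quantitative

    @property
    def eligible(self) -> bool:
        if self.kind == "binary":
            return self.n >= MIN_BINARY_CASES
        return self.n > MIN_QUANTITATIVE_N


@dataclass
class PhewasResult:
    """One genotype-trait association."""

    trait: str
    kind: str
    term: str
    estimate: float
    se: float
    p: float
    passes_bonferroni: bool = False
    passes_fdr: bool = False
    failed: bool = False

    @property
    def effect_direction(self) -> int:
        if not np.isfinite(self.estimate) or self.estimate == 0:
            return 0
        return 1 if self.estimate > 0 else -1


def infer_trait_specs(
    cohort: pd.DataFrame, trait_columns: Sequence[str]
) -> list[TraitSpec]:
    """Classify trait columns as binary or quantitative and count them."""
    specs = []
    for name in trait_columns:
        col = cohort[name]
        non_missing = col.notna()
        if col.dtype == bool or set(col.dropna().unique()) <= {0, 1, True,
                                                               False}:
            n = int(col.fillna(False).astype(bool).sum())
            specs.append(TraitSpec(name, "binary", n))
        else:
            specs.append(TraitSpec(name, "quantitative",
                                   int(non_missing.sum())))
    return specs


def eligible_traits(traits: Sequence[TraitSpec]) -> list[TraitSpec]:
    """Apply the eligibility filters and log the fixed test count m."""
    kept = [t for t in traits if t.eligible]
    logger.info("PheWAS eligibility: %d of %d traits eligible",
                len(kept), len(traits))
    return kept


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Study-wide significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = q * (np.arange(1, m + 1) / m)
    below = p[order] <= thresholds
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


def run_phewas(
    cohort: pd.DataFrame,
    trait_columns: Sequence[str],
    config: SurvivalConfig | None = None,
    alpha: float = 0.05,
    multiplicity: Literal["traits", "pairs"] = "traits",
) -> tuple[list[PhewasResult], int]:
    """Screen all eligible traits against APOE genotypes.

    Returns the per genotype-trait results and the multiplicity count m
    (eligible traits, or trait-genotype pairs under
    ``multiplicity="pairs"``).  Bonferroni and BH flags are both set at
    ``alpha``; failed fits are reported with NaN estimates and excluded
    from BH input but keep their Bonferroni slot in m.
    """
    config = config or SurvivalConfig()
    specs = infer_trait_specs(cohort, trait_columns)
    kept = eligible_traits(specs)
    if not kept:
        logger.info("no eligible traits; screen skipped")
        return [], 0

    df = cohort
    if config.exclude_e1 and "diplotype" in df:
        df = df[~df["diplotype"].str.contains("e1")]
    X, genotype_terms, _ = build_design(df, config)
    Xc = sm.add_constant(X.astype(float), has_constant="add")

    results: list[PhewasResult] = []
    for spec in kept:
        y_full = df[spec.name]
        mask = y_full.notna().to_numpy()
        y = y_full[mask]
        Xs = Xc.loc[mask]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if spec.kind == "binary":
                    fit = sm.Logit(y.astype(int).to_numpy(), Xs).fit(
                        disp=0, maxiter=200
                    )
                else:
                    fit = sm.OLS(y.astype(float).to_numpy(), Xs).fit()
            for term in genotype_terms:
                est, se = float(fit.params[term]), float(fit.bse[term])
                if spec.kind == "binary":
                    p = float(2 * stats.norm.sf(abs(est / se)))
                else:
                    p = float(fit.pvalues[term])
                results.append(
                    PhewasResult(spec.name, spec.kind, term, est, se, p)
                )
        except Exception as exc:
            logger.warning("trait %s: fit failed (%s)", spec.name, exc)
            for term in genotype_terms:
                results.append(
                    PhewasResult(spec.name, spec.kind, term,
                                 float("nan"), float("nan"), float("nan"),
                                 failed=True)
                )

    m = len(kept) if multiplicity == "traits" else len(kept) * len(
        genotype_terms
    )
    threshold = bonferroni_threshold(alpha, m)
    ok = [r for r in results if not r.failed and np.isfinite(r.p)]
    flags = bh_fdr([r.p for r in ok], alpha)
    for r, fdr_flag in zip(ok, flags):
        r.passes_bonferroni = r.p <= threshold
        # Bonferroni is never less stringent than the BH step-up at the
        # same alpha, so significance implies an FDR flag
        r.passes_fdr = bool(fdr_flag) or r.passes_bonferroni
    return results, m


def results_frame(results: Sequence[PhewasResult], m: int) -> pd.DataFrame:
    """Plot-ready table: one row per genotype-trait pair with -log10 p."""
    frame = pd.DataFrame(
        [
            {
                "trait": r.trait,
                "kind": r.kind,
                "term": r.term,
                "estimate": r.estimate,
                "se": r.se,
                "p": r.p,
                "neg_log10_p": -np.log10(r.p) if r.p > 0 else np.inf,
                "direction": r.effect_direction,
                "passes_bonferroni": r.passes_bonferroni,
                "passes_fdr": r.passes_fdr,
                "failed": r.failed,
            }
            for r in results
        ]
    )
    frame.attrs["m"] = m
    return frame
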