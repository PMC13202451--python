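"""Genotype-dementia association models.

Implements the survival and logistic models used for the APOE-dementia
analysis: Cox proportional-hazards fits on an age time scale with the
origin at 16 (or 60 for the late-life sensitivity analysis), logistic
sensitivity fits with a configurable reference genotype, Kaplan-Meier
curves by e4 allele dose, and Schoenfeld-residual diagnostics for the
proportional-hazards assumption.

Genotype codings
----------------
genotypic
    One indicator per non-reference diplotype (reference e3/e3 by
    default, e2/e2 for the attributable-fraction inputs).
additive
    The e4 allele count (0/1/2) as a single linear term.
dominant
    An any-e4 carrier indicator.

Covariates default to age at recruitment, gender, the first ten genetic
principal components and binary genetic ancestry.  Time-to-event is age
at diagnosis minus the origin age for cases and administrative censoring
age (censor date minus birth year) minus the origin for controls; left
truncation at recruitment is available but off by default, matching the
replicated construction (see the methods note for the immortal
person-time caveat).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalConfig",
    "AssociationResult",
    "ModelFit",
    "build_survival_times",
    "fit_cox",
    "fit_logistic",
    "km_by_dose",
    "schoenfeld_diagnostics",
]

DEFAULT_COVARIATES = (
    "age_at_recruitment",
    "gender",
    *[f"pc{i}" for i in range(1, 11)],
    "ancestry",
)

Z95 = 1.96


@dataclass
class SurvivalConfig:
    """Model construction options shared by the Cox and logistic stages."""

    origin_age: float = 16.0
    censor_date: float = 2024.92
    covariates: Sequence[str] = DEFAULT_COVARIATES
    coding: Literal["genotypic", "additive", "dominant"] = "genotypic"
    reference: str = "e3/e3"
    stratify_gender: bool = False
    left_truncation: bool = False
    restrict_to_recruited_after_origin: bool = False
    exclude_e1: bool = True


@dataclass
class AssociationResult:
    """One fitted model term on the log-hazard or log-odds scale."""

    term: str
    estimate: float
    se: float
    p: float
    n_samples: int
    n_events: int
    model: str
    flags: tuple[str, ...] = ()

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else float("nan")

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    @property
    def ratio(self) -> float:
        """exp(estimate): hazard ratio or odds ratio."""
        return float(np.exp(self.estimate))

    @property
    def ratio_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "ci95_low": lo,
            "ci95_high": hi,
            "ratio": self.ratio,
            "p": self.p,
            "z": self.z,
            "n_samples": self.n_samples,
            "n_events": self.n_events,
            "model": self.model,
            "flags": list(self.flags),
        }


@dataclass
class ModelFit:
    """Results of one fitted model, plus the fitter for diagnostics."""

    results: list[AssociationResult]
    model: str
    fitter: object | None = None
    data: pd.DataFrame | None = None
    dropped_terms: dict[str, str] = field(default_factory=dict)

    def result(self, term: str) -> AssociationResult:
        for r in self.results:
            if r.term == term:
                return r
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])


# --- survival-time construction -------------------------------------------


def build_survival_times(
    cohort: pd.DataFrame, config: SurvivalConfig
) -> pd.DataFrame:
    """Attach duration/event columns and apply the exclusion rules.

    Cases contribute ``age_at_diagnosis - origin``; controls contribute
    ``(censor_date - birth_year) - origin``.  Samples with non-positive
    time are excluded with a logged reason, as are e1 carriers (by
    default) and, in late-origin sensitivity mode, participants
    recruited before the origin age.
    """
    df = cohort.copy()
    n0 = len(df)

    if config.exclude_e1 and "diplotype" in df:
        mask = df["diplotype"].str.contains("e1")
        if mask.any():
            logger.info("excluding %d e1 carriers", int(mask.sum()))
            df = df[~mask]

    if config.restrict_to_recruited_after_origin:
        mask = df["age_at_recruitment"] >= config.origin_age
        logger.info(
            "restricting to recruited at/after age %.0f: %d of %d kept",
            config.origin_age, int(mask.sum()), len(df),
        )
        df = df[mask]

    event = df["dementia_status"].astype(bool).to_numpy()
    censor_age = config.censor_date - df["birth_year"].to_numpy(float)
    end_age = np.where(
        event, df["age_at_diagnosis"].to_numpy(float), censor_age
    )
    duration = end_age - config.origin_age

    keep = duration > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "excluding %d samples with non-positive follow-up "
            "(event before origin age %.0f or censored before it)",
            n_dropped, config.origin_age,
        )
    df = df[keep].copy()
    df["duration"] = duration[keep]
    df["event"] = event[keep]
    if config.left_truncation:
        entry = (
            df["age_at_recruitment"].to_numpy(float) - config.origin_age
        ).clip(min=0.0)
        # entry must precede exit strictly for the risk-set construction
        df["entry"] = np.minimum(entry, df["duration"].to_numpy() * (1 - 1e-9))
    logger.info("survival table: %d of %d samples, %d events",
                len(df), n0, int(df["event"].sum()))
    return df


# --- design matrix ---------------------------------------------------------


def _e4_dose(df: pd.DataFrame) -> np.ndarray:
    return df["diplotype"].map(
        lambda k: k.count("e4") if isinstance(k, str) else 0
    ).to_numpy()


def build_design(
    df: pd.DataFrame, config: SurvivalConfig
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """Numeric design: genotype terms plus encoded covariates.

    Returns (design frame, genotype term names, flags for dropped
    columns).  Gender becomes a male indicator, ancestry an indicator
    of each non-first label; constant columns are dropped with a flag.
    """
    X = pd.DataFrame(index=df.index)
    genotype_terms: list[str] = []
    dropped: dict[str, str] = {}

    if config.coding == "genotypic":
        categories = sorted(df["diplotype"].unique())
        if config.reference not in categories:
            raise ValueError(
                f"reference diplotype {config.reference!r} absent from data"
            )
        for cat in categories:
            if cat == config.reference:
                continue
            X[cat] = (df["diplotype"] == cat).astype(float)
            genotype_terms.append(cat)
    elif config.coding == "additive":
        X["e4_dose"] = _e4_dose(df).astype(float)
        genotype_terms.append("e4_dose")
    elif config.coding == "dominant":
        X["e4_carrier"] = (_e4_dose(df) > 0).astype(float)
        genotype_terms.append("e4_carrier")
    else:
        raise ValueError(f"unknown coding {config.coding!r}")

    for cov in config.covariates:
        if cov == "gender":
            X["male"] = (df["gender"] == "male").astype(float)
        elif cov == "ancestry":
            labels = sorted(df["ancestry"].unique())
            for lab in labels[1:]:
                X[f"ancestry_{lab}"] = (df["ancestry"] == lab).astype(float)
        else:
            X[cov] = df[cov].astype(float)

    for col in list(X.columns):
        if X[col].nunique() <= 1 and col not in genotype_terms:
            dropped[col] = "constant column"
            X = X.drop(columns=col)
    return X, genotype_terms, dropped


def _drop_eventless_genotype_terms(
    X: pd.DataFrame, terms: list[str], event: np.ndarray
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """Indicator categories with zero events are non-estimable; drop them."""
    dropped = {}
    kept = []
    for t in terms:
        if t in ("e4_dose", "e4_carrier"):
            kept.append(t)
            continue
        if event[X[t].to_numpy() > 0].sum() == 0:
            dropped[t] = "no events in category"
            X = X.drop(columns=t)
        else:
            kept.append(t)
    return X, kept, dropped


# --- model fits ------------------------------------------------------------


def _fit_cox_single(
    surv: pd.DataFrame, config: SurvivalConfig, label: str
) -> ModelFit:
    X, terms, dropped = build_design(surv, config)
    event = surv["event"].to_numpy(bool)
    X, terms, d2 = _drop_eventless_genotype_terms(X, terms, event)
    dropped.update(d2)

    data = X.copy()
    data["duration"] = surv["duration"].to_numpy()
    data["event"] = event.astype(int)
    fit_kwargs = {"duration_col": "duration", "event_col": "event"}
    if config.left_truncation:
        data["entry"] = surv["entry"].to_numpy()
        fit_kwargs["entry_col"] = "entry"

    cph = CoxPHFitter()
    flags: tuple[str, ...] = ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, **fit_kwargs)
        except Exception as exc:  # separation / collinearity
            logger.warning("%s: Cox fit failed (%s)", label, exc)
            results = [
                AssociationResult(t, float("nan"), float("nan"), float("nan"),
                                  len(data), int(event.sum()), label,
                                  ("fit_failed",))
                for t in terms
            ]
            return ModelFit(results, label, None, data, dropped)

    results = []
    n, n_events = len(data), int(event.sum())
    for term in list(X.columns):
        est = float(cph.params_[term])
        se = float(cph.standard_errors_[term])
        term_flags = list(flags)
        if term in terms and se > 2.5:
            term_flags.append("imprecise")
        p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else float("nan")
        results.append(
            AssociationResult(term, est, se, p, n, n_events, label,
                              tuple(term_flags))
        )
    for term, reason in dropped.items():
        results.append(
            AssociationResult(term, float("nan"), float("nan"), float("nan"),
                              n, n_events, label, ("non_estimable", reason))
        )
    return ModelFit(results, label, cph, data, dropped)


def fit_cox(cohort: pd.DataFrame, config: SurvivalConfig) -> ModelFit | dict:
    """Fit the Cox model (Efron ties) with the configured coding.

    Returns a :class:`ModelFit`; in gender-stratified mode, a dict of
    per-stratum fits (separate models per gender, each without the
    gender covariate, matching a fully interacted stratified analysis).
    """
    surv = build_survival_times(cohort, config)
    label = f"cox_{config.coding}"
    if not config.stratify_gender:
        return _fit_cox_single(surv, config, label)
    fits = {}
    covs = tuple(c for c in config.covariates if c != "gender")
    for gender, sub in surv.groupby("gender"):
        sub_config = SurvivalConfig(
            **{**config.__dict__, "covariates": covs,
               "stratify_gender": False}
        )
        fits[gender] = _fit_cox_single(sub, sub_config, f"{label}_{gender}")
    return fits


def fit_logistic(cohort: pd.DataFrame, config: SurvivalConfig) -> ModelFit:
    """Logistic sensitivity model on dementia status (no time axis).

    The reference diplotype is configurable; with the rare e2/e2
    reference the non-reference effects are estimable but imprecise,
    and such terms are flagged rather than suppressed.
    """
    import statsmodels.api as sm

    df = cohort.copy()
    if config.exclude_e1 and "diplotype" in df:
        df = df[~df["diplotype"].str.contains("e1")]
    y = df["dementia_status"].astype(int).to_numpy()
    reference_no_events = (
        config.coding == "genotypic"
        and y[(df["diplotype"] == config.reference).to_numpy()].sum() == 0
    )
    X, terms, dropped = build_design(df, config)
    X, terms, d2 = _drop_eventless_genotype_terms(X, terms, y.astype(bool))
    dropped.update(d2)
    Xc = sm.add_constant(X.astype(float), has_constant="add")

    label = f"logistic_{config.coding}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:
            logger.warning("%s: logistic fit failed (%s)", label, exc)
            results = [
                AssociationResult(t, float("nan"), float("nan"), float("nan"),
                                  len(y), int(y.sum()), label,
                                  ("fit_failed",))
                for t in terms
            ]
            return ModelFit(results, label, None, Xc, dropped)

    results = []
    for term in X.columns:
        est = float(res.params[term])
        se = float(res.bse[term])
        flags = []
        if term in terms and se > 2.5:
            flags.append("imprecise")
        if term in terms and reference_no_events:
            # no events in the reference category: the MLE for every
            # genotype contrast diverges (complete separation)
            flags.append("reference_no_events")
        if not res.mle_retvals.get("converged", True):
            flags.append("not_converged")
        p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else float("nan")
        results.append(
            AssociationResult(term, est, se, p, len(y), int(y.sum()),
                              label, tuple(flags))
        )
    for term, reason in dropped.items():
        results.append(
            AssociationResult(term, float("nan"), float("nan"), float("nan"),
                              len(y), int(y.sum()), label,
                              ("non_estimable", reason))
        )
    return ModelFit(results, label, res, Xc, dropped)


# --- Kaplan-Meier and diagnostics ------------------------------------------


def km_by_dose(
    cohort: pd.DataFrame, config: SurvivalConfig
) -> dict[int, pd.DataFrame]:
    """Product-limit dementia-free survival curves by e4 dose (0/1/2).

    Each curve is a frame indexed by time with the survival estimate
    and Greenwood 95% band; empty dose groups are omitted with a
    warning.
    """
    surv = build_survival_times(cohort, config)
    dose = _e4_dose(surv)
    curves: dict[int, pd.DataFrame] = {}
    for d in (0, 1, 2):
        sub = surv[dose == d]
        if len(sub) == 0:
            logger.warning("e4 dose %d: no samples, curve omitted", d)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["duration"], sub["event"], label=f"dose_{d}")
        frame = kmf.survival_function_.copy()
        frame.columns = ["survival"]
        ci = kmf.confidence_interval_
        frame["lower"] = ci.iloc[:, 0].to_numpy()
        frame["upper"] = ci.iloc[:, 1].to_numpy()
        curves[d] = frame
    return curves


def schoenfeld_diagnostics(
    fit: ModelFit, time_transform: str = "rank"
) -> pd.DataFrame | None:
    """Scaled-Schoenfeld proportional-hazards tests, per covariate + global.

    Per-covariate tests follow the Grambsch-Therneau score test of a
    linear association between scaled Schoenfeld residuals and
    (transformed) event time; the global row tests all covariates
    jointly with a chi-square on p degrees of freedom.  Returns None
    (with a warning) for fits with fewer than 10 events.
    """
    if fit.fitter is None or fit.data is None:
        raise ValueError("diagnostics require a converged Cox fit")
    cph: CoxPHFitter = fit.fitter
    n_events = int(fit.data["event"].sum())
    if n_events < 10:
        logger.warning("only %d events; Schoenfeld diagnostics skipped",
                       n_events)
        return None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ph = proportional_hazard_test(cph, fit.data,
                                      time_transform=time_transform)
    rows = [
        {"covariate": var, "chi2": float(ph.summary.loc[idx, "test_statistic"]),
         "df": 1.0, "p": float(ph.summary.loc[idx, "p"])}
        for idx, var in zip(ph.summary.index,
                            ph.summary.index.get_level_values(0))
    ]

    # global Grambsch-Therneau test from raw Schoenfeld residuals
    resid = cph.compute_residuals(fit.data, "schoenfeld")
    times = fit.data.loc[resid.index, "duration"].to_numpy(float)
    if time_transform == "rank":
        g = stats.rankdata(times).astype(float)
    else:
        g = times.copy()
    g -= g.mean()
    S = resid.to_numpy(float)
    d = S.shape[0]
    u = S.T @ g
    vbar = np.linalg.inv(np.asarray(cph.variance_matrix_, float)) / d
    denom = float(g @ g)
    cov = denom * vbar
    chi2 = float(u @ np.linalg.solve(cov, u))
    p = float(stats.chi2.sf(chi2, S.shape[1]))
    rows.append({"covariate": "GLOBAL", "chi2": chi2,
                 "df": float(S.shape[1]), "p": p})
    return pd.DataFrame(rows).set_index("covariate")
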