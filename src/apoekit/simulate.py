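"""Synthetic cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume: phased APOE haplotypes drawn i.i.d. from configured frequencies
(so genotypes follow Hardy-Weinberg proportions), a two-population
ancestry mix with deliberate ancestry/PC confounding, dementia onset
under exact proportional hazards from an age-16 time origin with
administrative censoring at a fixed calendar date, and lipid-like traits
with per-e4-allele effects.

All randomness flows from a single integer seed through per-stage
substreams (haplotypes, covariates, onset, traits), so re-running with
the same configuration is byte-identical and disabling one stage does
not shift another stage's draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .alleles import ApoeAllele, Diplotype, HAPLOTYPE_BASES, RS429358, RS7412

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "draw_haplotypes",
    "simulate_covariates",
    "simulate_onset",
    "simulate_traits",
    "simulate_cohort",
    "write_cohort",
    "read_phenotypes",
]

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]


class ConfigurationError(ValueError):
    """Invalid generative parameters."""


# Haplotype frequencies, ancestry mix and genotype hazard ratios default to
# the British South Asian cohort this generator emulates; the baseline
# hazard is calibrated so a 51 104-sample cohort yields roughly 600
# dementia events under those hazard ratios.
_DEFAULT_HAP_FREQS = {"e2": 0.044, "e3": 0.852, "e4": 0.104}
_DEFAULT_ANCESTRY = {"Bangladeshi": 0.587, "Pakistani": 0.413}
_DEFAULT_LOG_HR = {
    "e2/e2": float(np.log(0.8)),
    "e2/e3": float(np.log(0.8)),
    "e2/e4": float(np.log(1.6)),
    "e3/e3": 0.0,
    "e3/e4": float(np.log(1.5)),
    "e4/e4": float(np.log(2.7)),
}
_DEFAULT_TRAIT_EFFECTS = {
    "ldl": (0.12, 1.0),
    "triglycerides": (0.10, 1.0),
    "total_cholesterol": (0.12, 1.0),
    "hdl": (-0.05, 1.0),
    "crp": (-0.08, 1.0),
}
_DEFAULT_BINARY_PREVALENCES = {"hypertension": 0.25, "type_2_diabetes": 0.20}


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Parameters
    ----------
    n_samples
        Cohort size.
    hap_freqs
        Haplotype frequencies for e2/e3/e4 (optionally e1); must sum to 1.
    ancestry_props
        Population label -> proportion; must sum to 1.
    true_log_hr
        Diplotype key ("e3/e4") -> true log hazard ratio versus e3/e3,
        which must be present with value exactly 0.
    baseline_hazard
        Constant dementia hazard (events per person-year) from age 16
        for the e3/e3 reference genotype.
    weibull_shape
        Shape of the baseline cumulative hazard ``H0(t) = lambda * t**k``;
        1 (default) gives the constant-hazard exponential model.
    recruitment_age_median, recruitment_age_iqr
        Targets for the log-normal age-at-recruitment distribution (years).
    recruitment_period
        Calendar window (decimal years) over which recruitment dates are
        drawn uniformly.
    birth_year_range
        Admissible birth years; draws outside are clipped.
    censor_date
        Administrative censoring date as a decimal year.
    male_prop
        P(male).
    pc1_ancestry_shift
        Mean shift of PC1 for the second-listed ancestry, creating the
        ancestry/PC confounding the covariate adjustment must handle.
    trait_effects
        Quantitative trait -> (per-e4-allele effect, residual SD), on a
        standardised scale.
    binary_trait_prevalences
        Binary trait -> baseline prevalence.
    binary_trait_effects
        Binary trait -> per-e4-allele log-odds effect (default 0).
    seed
        Root seed for all substreams.
    """

    n_samples: int = 51_104
    hap_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HAP_FREQS)
    )
    ancestry_props: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ANCESTRY)
    )
    true_log_hr: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_HR)
    )
    baseline_hazard: float = 3.6e-4
    weibull_shape: float = 1.0
    recruitment_age_median: float = 39.0
    recruitment_age_iqr: float = 17.5
    recruitment_period: tuple[float, float] = (2015.0, 2024.0)
    birth_year_range: tuple[int, int] = (1920, 2008)
    censor_date: float = 2024.92
    male_prop: float = 0.446
    pc1_ancestry_shift: float = 1.0
    trait_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TRAIT_EFFECTS)
    )
    binary_trait_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BINARY_PREVALENCES)
    )
    binary_trait_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be non-negative")
        freqs = dict(self.hap_freqs)
        if any(f < 0 for f in freqs.values()):
            raise ConfigurationError("haplotype frequencies must be non-negative")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"haplotype frequencies must sum to 1, got {total!r}"
            )
        unknown = set(freqs) - {"e1", "e2", "e3", "e4"}
        if unknown:
            raise ConfigurationError(f"unknown haplotypes: {sorted(unknown)}")
        if abs(sum(self.ancestry_props.values()) - 1.0) > 1e-12:
            raise ConfigurationError("ancestry proportions must sum to 1")
        if self.true_log_hr.get("e3/e3") != 0.0:
            raise ConfigurationError("true_log_hr must map 'e3/e3' to exactly 0")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        for name in self.binary_trait_effects:
            if name not in self.binary_trait_prevalences:
                raise ConfigurationError(
                    f"binary trait effect for unknown trait {name!r}"
                )

    # --- (de)serialisation -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["recruitment_period"] = list(self.recruitment_period)
        data["birth_year_range"] = list(self.birth_year_range)
        data["trait_effects"] = {
            k: list(v) for k, v in self.trait_effects.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("recruitment_period", "birth_year_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "trait_effects" in data:
            data["trait_effects"] = {
                k: tuple(v) for k, v in data["trait_effects"].items()
            }
        return cls(**data)

    def _substreams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        names = ("haplotypes", "covariates", "onset", "traits")
        return {
            name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(names, root.spawn(len(names)))
        }


# --- stages ----------------------------------------------------------------


def draw_haplotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw two phased haplotypes per sample, i.i.d. from ``hap_freqs``.

    Returns a frame with columns ``hap1``/``hap2`` (epsilon labels) and
    the defining bases at each site on each chromosome.  Independence of
    the two draws means diplotype proportions follow Hardy-Weinberg
    expectations exactly in distribution.
    """
    if rng is None:
        rng = config._substreams()["haplotypes"]
    labels = sorted(config.hap_freqs)
    probs = np.array([config.hap_freqs[k] for k in labels])
    draws = rng.choice(len(labels), size=(config.n_samples, 2), p=probs)
    hap1 = np.array(labels, dtype=object)[draws[:, 0]]
    hap2 = np.array(labels, dtype=object)[draws[:, 1]]
    bases = {
        lab: HAPLOTYPE_BASES[ApoeAllele(lab)] for lab in labels
    }
    frame = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(config.n_samples)],
            "hap1": hap1,
            "hap2": hap2,
        }
    )
    for h in ("hap1", "hap2"):
        frame[f"{h}_rs429358"] = [bases[lab][0] for lab in frame[h]]
        frame[f"{h}_rs7412"] = [bases[lab][1] for lab in frame[h]]
    frame["diplotype"] = [
        Diplotype(ApoeAllele(a), ApoeAllele(b)).key
        for a, b in zip(frame["hap1"], frame["hap2"])
    ]
    return frame


def simulate_covariates(
    config: SimulationConfig,
    haplotypes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach ancestry, gender, PCs, birth year and recruitment age.

    PC1 is mean-shifted by ancestry so that ancestry and PCs are
    confounded, as in real genotype data; the remaining PCs are
    independent standard normals.
    """
    if rng is None:
        rng = config._substreams()["covariates"]
    n = len(haplotypes)
    cohort = haplotypes.copy()

    labels = list(config.ancestry_props)
    probs = np.array([config.ancestry_props[k] for k in labels])
    anc_idx = rng.choice(len(labels), size=n, p=probs)
    cohort["ancestry"] = np.array(labels, dtype=object)[anc_idx]

    cohort["gender"] = np.where(
        rng.random(n) < config.male_prop, "male", "female"
    )

    pcs = rng.standard_normal((n, 10))
    # shift applies to every non-first population (two-population default)
    pcs[:, 0] += config.pc1_ancestry_shift * (anc_idx > 0)
    for j, col in enumerate(PC_COLUMNS):
        cohort[col] = pcs[:, j]

    # log-normal recruitment age hitting the configured median and IQR
    z75 = 0.6744897501960817
    mu = np.log(config.recruitment_age_median)
    sigma = np.arcsinh(
        config.recruitment_age_iqr / (2.0 * config.recruitment_age_median)
    ) / z75
    age = np.exp(mu + sigma * rng.standard_normal(n))
    age = np.clip(age, 16.0, 100.0)

    lo, hi = config.recruitment_period
    rec_date = rng.uniform(lo, hi, size=n)
    birth_year = rec_date - age
    birth_year = np.clip(birth_year, *config.birth_year_range)
    birth_year = np.minimum(birth_year, rec_date - 16.0)

    cohort["birth_year"] = birth_year
    cohort["age_at_recruitment"] = rec_date - birth_year
    return cohort


def simulate_onset(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw dementia onset under proportional hazards from age 16.

    Latent onset age is ``16 + T`` where T has cumulative hazard
    ``baseline_hazard * t**k * exp(log HR of the diplotype)``; the event
    is observed iff onset precedes the administrative censoring age
    (censor_date minus birth year).
    """
    if rng is None:
        rng = config._substreams()["onset"]
    cohort = cohort.copy()
    n = len(cohort)

    log_hr = cohort["diplotype"].map(
        lambda k: config.true_log_hr.get(k, 0.0)
    ).to_numpy(float)
    rate = config.baseline_hazard * np.exp(log_hr)
    u = rng.random(n)
    latent = (-np.log(u) / rate) ** (1.0 / config.weibull_shape)
    onset_age = 16.0 + latent

    censor_age = config.censor_date - cohort["birth_year"].to_numpy(float)
    if np.any(censor_age < 0):
        raise ConfigurationError("censor_date precedes some birth years")

    status = onset_age <= censor_age
    cohort["dementia_status"] = status
    cohort["age_at_diagnosis"] = np.where(status, onset_age, np.nan)
    return cohort


def simulate_traits(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach quantitative and binary traits with per-e4-allele effects.

    Quantitative traits are ``effect * e4_count + N(0, sd)`` on a
    standardised scale; binary traits are Bernoulli with a logit-linear
    e4 dose effect (zero unless configured).
    """
    if rng is None:
        rng = config._substreams()["traits"]
    cohort = cohort.copy()
    n = len(cohort)
    dose = (
        (cohort["hap1"] == "e4").astype(int)
        + (cohort["hap2"] == "e4").astype(int)
    ).to_numpy()

    for name, (effect, sd) in config.trait_effects.items():
        cohort[name] = effect * dose + sd * rng.standard_normal(n)

    for name, prev in config.binary_trait_prevalences.items():
        beta = config.binary_trait_effects.get(name, 0.0)
        logit = np.log(prev / (1.0 - prev)) + beta * dose
        p = 1.0 / (1.0 + np.exp(-logit))
        cohort[name] = rng.random(n) < p
    return cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Run all four stages and return the complete cohort table."""
    rngs = config._substreams()
    cohort = draw_haplotypes(config, rngs["haplotypes"])
    cohort = simulate_covariates(config, cohort, rngs["covariates"])
    cohort = simulate_onset(config, cohort, rngs["onset"])
    cohort = simulate_traits(config, cohort, rngs["traits"])
    return cohort


# --- output ----------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr19,length=58617616>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_cohort(
    cohort: pd.DataFrame,
    genotypes_path: str | Path,
    phenotypes_path: str | Path,
) -> None:
    """Write phased genotypes (VCF v4.2) and the phenotype table (TSV).

    The VCF carries the two APOE-defining records — chr19:44908684
    REF=T ALT=C (rs429358) and chr19:44908822 REF=C ALT=T (rs7412) —
    with phased "|" genotypes, one column per sample.  Reading the pair
    back reproduces every diplotype exactly.
    """
    samples = cohort["sample_id"].tolist()
    sites = [("rs429358", RS429358, "rs429358"), ("rs7412", RS7412, "rs7412")]
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for rsid, (chrom, pos, ref, alt), col in sites:
        gts = []
        for a1, a2 in zip(cohort[f"hap1_{col}"], cohort[f"hap2_{col}"]):
            gts.append(f"{int(a1 == alt)}|{int(a2 == alt)}")
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(genotypes_path).write_text("\n".join(lines) + "\n")

    pheno_cols = [
        c
        for c in cohort.columns
        if c
        not in {
            "hap1", "hap2",
            "hap1_rs429358", "hap1_rs7412",
            "hap2_rs429358", "hap2_rs7412",
        }
    ]
    cohort[pheno_cols].to_csv(
        phenotypes_path, sep="\t", index=False, na_rep=""
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV written by :func:`write_cohort`."""
    frame = pd.read_csv(path, sep="\t")
    if "dementia_status" in frame:
        frame["dementia_status"] = frame["dementia_status"].astype(bool)
    return frame
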