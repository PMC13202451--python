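"""Config-driven orchestration of the full analysis.

Stages run in order — simulate (or load), call diplotypes, descriptive
tables, association models, attributable fractions, PheWAS — and every
artifact lands in the output directory together with a manifest
(inputs, seed, package version, parameter hash) sufficient to
reproduce the run.  A fixed config and seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alleles import ApoeAllele
from .association import SurvivalConfig, fit_cox, fit_logistic, km_by_dose
from .calling import call_diplotypes, read_phased_genotypes
from .descriptives import summarize_genotypes, table1_report
from .paf import paf_from_fits
from .phewas import results_frame, run_phewas
from .simulate import SimulationConfig, read_phenotypes, simulate_cohort, \
    write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

#: carrier proportion among White British UK Biobank volunteers, used as
#: the reference for the e4 enrichment/depletion binomial test
UKB_E4_CARRIER_PROPORTION = 0.288


@dataclass
class PipelineConfig:
    """What to run, on what input, and where to put the results."""

    output_dir: str | Path = "apoekit_output"
    seed: int = 0
    simulation: SimulationConfig | None = None
    genotypes_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    run_descriptives: bool = True
    run_association: bool = True
    run_paf: bool = True
    run_phewas: bool = True
    phewas_traits: list[str] | None = None
    paf_literal_formula: bool = False
    reference_e4_carrier_proportion: float = UKB_E4_CARRIER_PROPORTION

    def validate(self) -> None:
        simulated = self.simulation is not None
        loaded = self.genotypes_path is not None
        if simulated == loaded:
            raise ValueError(
                "supply exactly one of a simulation config or input paths"
            )
        if loaded and self.phenotypes_path is None:
            raise ValueError("phenotype table required with genotype input")


def _param_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), default=default,
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the report bundle.

    A stage failure raises with the stage name; artifacts written by
    earlier stages are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        bundle["stages"].append(name)

    try:
        if config.simulation is not None:
            stage("simulate")
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim)
            write_cohort(cohort, out / "genotypes.vcf", out / "phenotypes.tsv")
            genotypes_path = out / "genotypes.vcf"
        else:
            cohort = read_phenotypes(config.phenotypes_path)
            genotypes_path = Path(config.genotypes_path)

        stage("call_apoe")
        callsets = read_phased_genotypes(genotypes_path)
        calling = call_diplotypes(callsets)
        calling.diplotypes.to_frame().to_csv(out / "diplotypes.tsv", sep="\t")
        cohort = cohort.drop(columns=["diplotype"], errors="ignore").merge(
            calling.diplotypes.rename("diplotype"),
            left_on="sample_id", right_index=True, how="inner",
        )
        bundle["n_samples"] = len(cohort)
        bundle["n_excluded_calling"] = len(calling.excluded)
        bundle["n_e1_carriers"] = calling.n_e1

        if config.run_descriptives:
            stage("descriptives")
            table = summarize_genotypes(
                cohort["diplotype"], cohort["dementia_status"]
            )
            table.write(out / "table1.tsv", out / "table1.json")
            bundle["descriptives"] = table1_report(
                table, config.reference_e4_carrier_proportion
            )

        if config.run_association:
            stage("association")
            assoc = {}
            for coding in ("genotypic", "additive", "dominant"):
                cfg = dataclasses.replace(config.survival, coding=coding)
                fit = fit_cox(cohort, cfg)
                assoc[f"cox_{coding}"] = fit.to_frame()
            logi = fit_logistic(
                cohort, dataclasses.replace(config.survival,
                                            coding="genotypic")
            )
            assoc["logistic_genotypic"] = logi.to_frame()
            for name, frame in assoc.items():
                frame.to_csv(out / f"association_{name}.tsv", sep="\t",
                             index=False)
            bundle["association"] = {
                k: v.to_dict(orient="records") for k, v in assoc.items()
            }
            curves = km_by_dose(
                cohort, dataclasses.replace(config.survival,
                                            coding="genotypic")
            )
            for dose, frame in curves.items():
                frame.to_csv(out / f"km_dose{dose}.tsv", sep="\t")

        if config.run_paf:
            stage("paf")
            cfg = dataclasses.replace(
                config.survival, coding="genotypic", reference="e2/e2"
            )
            fit = fit_logistic(cohort, cfg)
            cases = cohort[cohort["dementia_status"]]
            case_counts = cases["diplotype"].value_counts().to_dict()
            paf_result = paf_from_fits(fit.results, case_counts)
            paf_result.write(out / "paf.tsv", out / "paf.json")
            bundle["paf"] = paf_result.to_dict()
            bundle["paf_formula"] = (
                "literal" if config.paf_literal_formula
                else "case_fraction*(OR-1)/OR"
            )

        if config.run_phewas:
            stage("phewas")
            traits = config.phewas_traits
            if traits is None:
                reserved = {
                    "sample_id", "diplotype", "ancestry", "gender",
                    "birth_year", "age_at_recruitment", "dementia_status",
                    "age_at_diagnosis", "duration", "event",
                } | {f"pc{i}" for i in range(1, 11)}
                traits = [c for c in cohort.columns
                          if c not in reserved and not c.startswith("hap")]
            results, m = run_phewas(cohort, traits, config.survival)
            frame = results_frame(results, m)
            frame.to_csv(out / "phewas.tsv", sep="\t", index=False)
            bundle["phewas"] = {
                "m": m,
                "results": frame.to_dict(orient="records"),
            }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {bundle['stages'][-1]!r} failed: {exc}"
        ) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "stages": bundle["stages"],
        "inputs": {
            "genotypes": str(genotypes_path),
            "phenotypes": str(config.phenotypes_path)
            if config.phenotypes_path else "simulated",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    write_report(bundle, out)
    return bundle


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def write_report(bundle: dict, out_dir: str | Path) -> None:
    """Render the bundle as markdown plus a machine-readable JSON twin."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lines = ["# APOE-dementia analysis report", ""]
    lines.append(f"Samples analysed: {bundle.get('n_samples', 'n/a')}")
    if "descriptives" in bundle:
        d = bundle["descriptives"]
        lines += ["", "## Descriptives", ""]
        lines.append(f"Cases: {d['n']['cases']}, controls: "
                     f"{d['n']['controls']}")
        for group in ("cases", "controls", "overall"):
            if group in d["e4_carriers"]:
                cs = d["e4_carriers"][group]
                lines.append(
                    f"- {group} e4 carriers: {int(cs['carriers'])} "
                    f"({_fmt_pct(cs['prop_carriers'])}; "
                    f"het {_fmt_pct(cs['prop_het'])}, "
                    f"hom {_fmt_pct(cs['prop_hom'])})"
                )
        if "e4_enrichment_p" in d:
            lines.append(
                f"- e4 carrier proportion vs reference: two-sided binomial "
                f"p = {d['e4_enrichment_p']:.3g}"
            )
    if "association" in bundle:
        lines += ["", "## Association models", ""]
        for model, rows in bundle["association"].items():
            lines.append(f"### {model}")
            for row in rows:
                lines.append(
                    f"- {row['term']}: ratio {row['ratio']:.3g} "
                    f"({row['ci95_low']:.3g}..{row['ci95_high']:.3g} on the "
                    f"log scale), p = {row['p']:.3g}"
                )
            lines.append("")
    if "paf" in bundle:
        p = bundle["paf"]
        lines += ["", "## Population attributable fractions",
                  f"(stratum formula: {bundle.get('paf_formula')})", ""]
        for name, key in (("e4 alleles", "paf_e4"), ("e3 alleles", "paf_e3"),
                          ("e3 or e4 (joint)", "paf_joint")):
            lo, hi = p[f"{key}_bounds"]
            lines.append(
                f"- PAF {name}: {_fmt_pct(p[key])} "
                f"(bounds {_fmt_pct(lo)} .. {_fmt_pct(hi)})"
            )
    if "phewas" in bundle:
        ph = bundle["phewas"]
        n_sig = sum(r["passes_bonferroni"] for r in ph["results"])
        lines += ["", "## PheWAS", "",
                  f"m = {ph['m']} eligible traits; {n_sig} genotype-trait "
                  f"associations pass Bonferroni at alpha 0.05"]

    (out / "report.md").write_text("\n".join(lines) + "\n")
    (out / "report.json").write_text(
        json.dumps(bundle, indent=2, default=str)
    )
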