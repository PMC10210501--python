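"""End-to-end two-cohort comparison pipeline.

Orchestrates: simulate panel + two cohorts -> harmonize and score ->
eGFR + phenotype QC -> adjustment-model ladder -> univariable covariate
screen and stepwise variance profile -> Mann-Whitney comparison of the
PGS distributions -> cross-cohort allele-frequency tests with Bonferroni
tiers and binomial enrichment/direction summaries -> sensitivity rerun
excluding the planted APOE-like variant (and any configured ids).

The report is a plain nested dict (JSON-serializable) and is
byte-identical across reruns with the same config and seed; wall-clock
timings go to the log file only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import (compare_distributions, covariate_screen,
                          run_model_ladder, stepwise_variance_profile)
from .freqcompare import (best_guess_genotypes, binom_enrichment,
                          bonferroni_threshold, freq_diff_test,
                          per_variant_assoc, qq_points)
from .harmonize import harmonize_and_filter
from .pgs import compute_pgs, summarize_pgs
from .phenotypes import phenotype_qc
from .scoring import TRAIT_CREA, exclude_variants
from .simulate import get_preset, simulate_cohort, simulate_genotypes, \
    simulate_panel

logger = logging.getLogger("egfr_pgs")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration for a full two-cohort comparison run."""

    cohorts: tuple[str, ...] = ("general_adults", "elderly")
    traits: tuple[str, ...] = ("eGFRcrea", "eGFRcys")
    r2_threshold: float = 0.8            # frequency-analysis filter
    n_boot: int = 200                    # bootstrap reps for R² CIs
    seed: int = 0
    out_dir: str | None = None
    exclude_variant_ids: tuple[str, ...] = ()
    #: effect-allele frequency of the planted APOE-like variant in the
    #: (general-adult, elderly) cohort; None disables planting
    apoe_like_gap: tuple[float, float] | None = (0.87, 0.89)
    #: overrides applied to every preset (e.g. {"n": 200, "m_variants": 50}
    #: for a toy-scale run)
    preset_overrides: dict = field(default_factory=dict)
    run_per_variant_assoc: bool = False

    def __post_init__(self) -> None:
        if not self.cohorts or not self.traits:
            raise PipelineError("need at least one cohort and one trait")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cohorts", "traits", "exclude_variant_ids"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("apoe_like_gap") is not None:
            raw["apoe_like_gap"] = tuple(raw["apoe_like_gap"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _trait_key(trait: str) -> str:
    return "crea" if trait == TRAIT_CREA else "cys"


def _cohort_summary(pheno: pd.DataFrame, pgs_summary: pd.DataFrame) -> dict:
    female = pheno["sex"].isin(["F", "female"])
    out = {
        "n": len(pheno),
        "age_mean": float(pheno["age"].mean()),
        "age_sd": float(pheno["age"].std(ddof=1)),
        "female_fraction": float(female.mean()),
        "bmi_mean": float(pheno["bmi"].mean()),
        "egfr_crea_mean": float(pheno["egfr_crea"].mean()),
        "egfr_crea_sd": float(pheno["egfr_crea"].std(ddof=1)),
        "egfr_cys_mean": float(pheno["egfr_cys"].mean()),
        "egfr_cys_sd": float(pheno["egfr_cys"].std(ddof=1)),
        "ckd_fraction": float(pheno["ckd"].mean()),
    }
    for flag in ("diabetes", "hypertension", "cad", "high_ceiling_diuretics"):
        out[f"{flag}_prevalence"] = float(pheno[flag].mean())
    for kind in ("weighted", "unweighted"):
        out[f"pgs_{kind}_mean"] = float(pgs_summary.loc[kind, "mean"])
        out[f"pgs_{kind}_sd"] = float(pgs_summary.loc[kind, "sd"])
    return out


def run_comparison(config: RunConfig) -> dict:
    """Execute the full comparison for every configured trait.

    Returns the nested report dict; identical config + seed give an
    identical report.
    """
    master = np.random.default_rng(config.seed)

    def next_seed() -> int:
        return int(master.integers(0, 2 ** 31 - 1))

    report: dict = {"config": config.to_dict(), "traits": {}}

    for trait in config.traits:
        t0 = time.perf_counter()
        key = _trait_key(trait)
        presets = {c: get_preset(f"{c}_{key}", **config.preset_overrides)
                   for c in config.cohorts}

        # one shared panel per trait, calibrated to the mid-point of the
        # per-cohort PGS-SD targets
        sd_target = float(np.mean([p.target_pgs_sd
                                   for p in presets.values()]))
        panel_preset = next(iter(presets.values())).replace(
            target_pgs_sd=sd_target)
        panel = simulate_panel(panel_preset, next_seed())
        planted = None
        if config.apoe_like_gap:
            # plant the gap on the variant whose panel frequency is
            # closest to it, so the override barely perturbs the
            # variance calibration (mirrors a common APOE-like variant)
            gap_mean = float(np.mean(config.apoe_like_gap))
            freqs = np.array([v.effect_allele_freq
                              for v in panel.variants])
            planted = panel.variant_ids[int(np.argmin(
                np.abs(freqs - gap_mean)))]

        cohort_data: dict[str, dict] = {}
        for cohort in config.cohorts:
            preset = presets[cohort]
            overrides = None
            if planted is not None:
                gap = config.apoe_like_gap
                overrides = {planted: gap[1] if preset.study == "elderly"
                             else gap[0]}
            geno = simulate_genotypes(panel, preset.n, seed=next_seed(),
                                      freq_overrides=overrides)
            raw = simulate_cohort(preset, panel, geno, seed=next_seed())
            pheno, qc_report = phenotype_qc(raw, study_rules=preset.study)
            score_h, geno_h, harm_report = harmonize_and_filter(
                panel, geno, r2_threshold=None)
            pgs = compute_pgs(score_h, geno_h)
            summary = summarize_pgs(pgs)
            ladder = run_model_ladder(pheno, pgs, trait,
                                      n_boot=config.n_boot,
                                      seed=next_seed())
            screen = covariate_screen(pheno, trait)
            profile = stepwise_variance_profile(pheno, pgs, trait)

            # sensitivity: rescore without the planted / configured ids
            sens = None
            drop_ids = [v for v in
                        {planted, *config.exclude_variant_ids}
                        if v in set(score_h.variant_ids)]
            if drop_ids:
                score_s = exclude_variants(score_h, drop_ids)
                pgs_s = compute_pgs(score_s, geno_h)
                ladder_s = run_model_ladder(pheno, pgs_s, trait, n_boot=0)
                sens = {
                    "excluded_variants": sorted(drop_ids),
                    "models": [f.to_dict() for f in ladder_s],
                    "r2_delta_pct": [
                        100.0 * (s.r2 - f.r2)
                        for s, f in zip(ladder_s, ladder)],
                }

            model1 = ladder[0]
            cohort_data[cohort] = {
                "preset": preset.name,
                "qc": qc_report,
                "summary": _cohort_summary(pheno, summary),
                "harmonization_dropped": int(
                    (harm_report["action"] == "dropped").sum()),
                "ladder": [f.to_dict() for f in ladder],
                "screen": screen,
                "variance_profile": profile,
                "decomposition": {
                    "beta": model1.beta1,
                    "var_pgs": model1.pgs_variance,
                    "var_outcome": model1.outcome_variance,
                    "r2": model1.r2,
                },
                "sensitivity": sens,
                # private (non-serialized) carriers for cross-cohort stages
                "_pgs": pgs, "_geno": geno, "_pheno": pheno,
                "_panel": score_h,
            }

        trait_report: dict = {"cohorts": {
            c: {k: v for k, v in d.items() if not k.startswith("_")}
            for c, d in cohort_data.items()}}

        if len(config.cohorts) == 2:
            c1, c2 = config.cohorts
            d1, d2 = cohort_data[c1], cohort_data[c2]
            mw = {}
            for kind in ("weighted", "unweighted"):
                u, p = compare_distributions(
                    getattr(d1["_pgs"], kind).dropna(),
                    getattr(d2["_pgs"], kind).dropna())
                mw[kind] = {"U": u, "pvalue": p}
            trait_report["mann_whitney"] = mw

            # frequency comparison on the imputation-quality-filtered set
            filt = [harmonize_and_filter(panel, d["_geno"],
                                         r2_threshold=config.r2_threshold)
                    for d in (d1, d2)]
            bg1 = best_guess_genotypes(filt[0][1])
            bg2 = best_guess_genotypes(filt[1][1])
            freq = freq_diff_test(bg1, bg2)
            tested = freq.dropna(subset=["p_diff"])
            m_tested = len(tested)
            n_nominal = int((tested["p_diff"] < 0.05).sum())
            enrich = binom_enrichment(n_nominal, m_tested, 0.05, "greater")
            nominal = tested[tested["p_diff"] < 0.05]
            # success = eGFR-lowering allele rarer in the elderly cohort
            elderly_col = "eaf_study2" if presets[c2].study == "elderly" \
                else "eaf_study1"
            other_col = "eaf_study1" if elderly_col == "eaf_study2" \
                else "eaf_study2"
            k_dir = int((nominal[elderly_col] < nominal[other_col]).sum())
            direction = binom_enrichment(k_dir, max(len(nominal), 1), 0.5,
                                         "two_sided") \
                if len(nominal) else None
            qq, _ = qq_points(tested["p_diff"].to_numpy())
            trait_report["frequency_comparison"] = {
                "n_variants_tested": m_tested,
                "bonferroni_threshold": bonferroni_threshold(m_tested),
                "n_nominal": n_nominal,
                "n_bonferroni": int((tested["tier"] == "bonferroni").sum()),
                "planted_variant": planted,
                "table": freq,
                "qq": qq,
                "enrichment": enrich.to_dict(),
                "direction": None if direction is None
                else direction.to_dict(),
            }

            if config.run_per_variant_assoc:
                pooled = pd.concat([d1["_geno"].dosages, d2["_geno"].dosages])
                labels = np.concatenate([
                    np.zeros(len(d1["_geno"].dosages)),
                    np.ones(len(d2["_geno"].dosages))])
                ages = np.concatenate([d1["_pheno"]["age"].to_numpy(),
                                       d2["_pheno"]["age"].to_numpy()])
                trait_report["per_variant_assoc"] = per_variant_assoc(
                    pooled, labels, ages)

        report["traits"][trait] = trait_report
        logger.info("trait %s finished in %.1f s", trait,
                    time.perf_counter() - t0)

    return _jsonable(report)


def write_report(report: dict, out_dir) -> dict[str, str]:
    """Write the JSON master report plus the TSV tables and a log file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": str(out / "report.json")}
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    ladder_rows, screen_rows, profile_rows, freq_frames = [], [], [], []
    for trait, tr in report.get("traits", {}).items():
        for cohort, cd in tr.get("cohorts", {}).items():
            for row in cd["ladder"]:
                ladder_rows.append({"trait": trait, "cohort": cohort, **row})
            for row in cd["screen"]:
                screen_rows.append({"trait": trait, "cohort": cohort, **row})
            for row in cd["variance_profile"]:
                profile_rows.append({"trait": trait, "cohort": cohort, **row})
        fc = tr.get("frequency_comparison")
        if fc:
            df = pd.DataFrame(fc["table"])
            df.insert(0, "trait", trait)
            freq_frames.append(df)

    if ladder_rows:
        paths["table2"] = str(out / "table2_ladder.tsv")
        pd.DataFrame(ladder_rows).to_csv(paths["table2"], sep="\t",
                                         index=False)
    if screen_rows:
        paths["screen"] = str(out / "covariate_screen.tsv")
        pd.DataFrame(screen_rows).to_csv(paths["screen"], sep="\t",
                                         index=False)
    if profile_rows:
        paths["profile"] = str(out / "variance_profile.tsv")
        pd.DataFrame(profile_rows).to_csv(paths["profile"], sep="\t",
                                          index=False)
    if freq_frames:
        paths["freqdiff"] = str(out / "freqdiff.tsv")
        pd.concat(freq_frames).to_csv(paths["freqdiff"], sep="\t",
                                      index=False)

    paths["log"] = str(out / "run.log")
    with open(paths["log"], "w") as fh:
        fh.write(f"seed: {report.get('config', {}).get('seed')}\n")
        fh.write(f"written: {sorted(paths)}\n")
    return paths
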