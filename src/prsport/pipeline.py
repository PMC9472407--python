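"""End-to-end orchestration: simulate -> QC -> structure -> score ->
divergence/selection -> evaluate, from a single validated config.

Every stage is a pure function of (inputs, config, seed); running the same
config twice produces byte-identical tables.  The selection scan is
optional: its failure is recorded in the manifest without aborting the
case/control evaluation.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, divergence_stats, evaluation, selection_scan
from ._util import ValidationError, stage_rng
from .io_formats import ScoreDefinition
from .prs_engine import ProxyMap, resolve_variants, score_cohort
from .structure_qc import (filter_sample_missingness, genotype_pca,
                           pca_outlier_filter)
from .synthetic_data import (GeneticArchitecture, PopulationSpec, SiteSpec,
                             make_score_table, simulate_cohort,
                             simulate_sweep_haplotypes)

DEFAULT_POPULATIONS = (
    {"name": "popA", "fst": 0.01,
     "sites": [["siteA1", 300], ["siteA2", 300]], "case_fraction": 0.5},
    {"name": "popB", "fst": 0.12,
     "sites": [["siteB1", 300], ["siteB2", 300]], "case_fraction": 0.5},
)


@dataclass
class RunConfig:
    seed: int = 0
    populations: tuple = DEFAULT_POPULATIONS
    n_variants: int = 100
    prevalence: float = 0.25
    prs_liability_variance: float = 0.3
    effect_divergence: float = 0.5   # cross-population effect decorrelation
    missing_rate: float = 0.0067
    age_missing_rate: float = 0.02
    clinical_missing_rate: float = 0.1
    r2_threshold: float = 0.4
    missingness_max: float = 0.05
    outlier_sd: float = 2.0
    maf_threshold: float = 0.05
    n_pcs: int = 10
    group_high: float = 0.90
    group_mid: tuple = (0.40, 0.60)
    classifiers: tuple = ("stage", "gleason")
    run_selection_scan: bool = True
    out_dir: str = "prs_run"


_BOUNDS = {
    "prevalence": (0.0, 1.0, True, True),
    "prs_liability_variance": (0.0, 1.0, False, False),
    "missing_rate": (0.0, 1.0, False, True),
    "r2_threshold": (0.0, 1.0, True, False),
    "missingness_max": (0.0, 1.0, True, True),
    "maf_threshold": (0.0, 0.5, False, True),
    "group_high": (0.5, 1.0, True, True),
}


def validate_config(raw: dict | RunConfig | None):
    """Fill defaults and check every threshold; returns (config, errors).

    Errors are returned as a list of human-readable strings naming the field
    and the violated constraint — never raised.
    """
    errors: list[str] = []
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - known
        for key in sorted(unknown):
            errors.append(f"{key}: unknown config field")
        try:
            cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
        except TypeError as exc:
            return None, errors + [str(exc)]
    for name, (lo, hi, open_lo, open_hi) in _BOUNDS.items():
        v = getattr(cfg, name)
        lo_ok = v > lo if open_lo else v >= lo
        hi_ok = v < hi if open_hi else v <= hi
        if not (lo_ok and hi_ok):
            lo_b = "(" if open_lo else "["
            hi_b = ")" if open_hi else "]"
            errors.append(f"{name}: must lie in {lo_b}{lo}, {hi}{hi_b}, got {v}")
    if cfg.n_variants <= 0:
        errors.append("n_variants: must be positive")
    if cfg.outlier_sd <= 0:
        errors.append("outlier_sd: must be positive")
    lo, hi = cfg.group_mid
    if not 0.0 <= lo < hi <= cfg.group_high:
        errors.append("group_mid: need 0 <= low < high <= group_high")
    for c in cfg.classifiers:
        if c not in ("stage", "gleason"):
            errors.append(f"classifiers: unknown classifier {c!r}")
    try:
        _population_specs(cfg)
    except ValidationError as exc:
        errors.append(f"populations: {exc}")
    return (cfg if not errors else None), errors


def _population_specs(cfg: RunConfig) -> list[PopulationSpec]:
    specs = []
    for p in cfg.populations:
        sites = tuple(
            SiteSpec(name=s[0], n_samples=int(s[1]),
                     case_fraction=float(p["case_fraction"]))
            for s in p["sites"]
        )
        specs.append(PopulationSpec(name=p["name"], fst=float(p["fst"]),
                                    sites=sites))
    return specs


def _build_architecture(cfg: RunConfig, pop_names) -> GeneticArchitecture:
    """Shared ancestral frequencies; per-population effects sharing a common
    backbone with ``effect_divergence`` controlling the decorrelation."""
    rng = stage_rng(cfg.seed, "frequencies", index=1)
    freqs = rng.uniform(0.05, 0.95, cfg.n_variants)
    base = rng.normal(0.0, 0.1, cfg.n_variants)
    effects = {}
    rho = float(np.clip(1.0 - cfg.effect_divergence, 0.0, 1.0))
    for name in pop_names:
        noise = rng.normal(0.0, 0.1, cfg.n_variants)
        effects[name] = rho * base + np.sqrt(1.0 - rho * rho) * noise
    return GeneticArchitecture(
        n_variants=cfg.n_variants, ancestral_freqs=freqs,
        true_log_or=effects, prevalence=cfg.prevalence,
        prs_liability_variance=cfg.prs_liability_variance,
    )


def run_pipeline(config, out_dir: str | Path | None = None,
                 log=sys.stderr) -> dict:
    """Run the whole analysis; returns the result bundle and writes tables.

    Bundle keys: ``report`` (evaluation table), ``bowtie``, ``mann_whitney``,
    ``medians``, ``selection`` (or None), ``manifest``.
    """
    cfg, errors = validate_config(config)
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def say(msg):
        print(f"[prs] {msg}", file=log)

    pops = _population_specs(cfg)
    arch = _build_architecture(cfg, [p.name for p in pops])
    score_table = make_score_table(arch)
    score = ScoreDefinition(
        score_name="synthetic",
        variants=score_table[
            ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
        ],
        log_weights={p.name: arch.true_log_or[p.name].copy() for p in pops},
    )

    manifest = {"version": __version__, "config": asdict(cfg),
                "stages": {}, "selection_error": None}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()

    cohorts, eval_entries, freq_est = {}, {}, {}
    for i, pop in enumerate(pops):
        say(f"simulating cohort {pop.name}")
        cohort = simulate_cohort(
            pop, arch, cfg.seed + 1000 * (i + 1),
            effect_label=pop.name,
            missing_rate=cfg.missing_rate,
            age_missing_rate=cfg.age_missing_rate,
            clinical_missing_rate=cfg.clinical_missing_rate,
        )
        keep = filter_sample_missingness(cohort.dosages, cfg.missingness_max)
        doses = cohort.dosages[keep]
        meta = cohort.metadata.loc[keep].reset_index(drop=True)

        from .prs_engine import impute_missing_doses
        filled, _, _ = impute_missing_doses(doses, meta["site"].to_numpy())
        pca = genotype_pca(filled, k=cfg.n_pcs)
        inliers = pca_outlier_filter(pca.coordinates, cfg.outlier_sd)
        doses, filled = doses[inliers], filled[inliers]
        meta = meta.loc[inliers].reset_index(drop=True)
        pcs = pca.coordinates[inliers]
        manifest["stages"][f"qc_{pop.name}"] = {
            "n_input": len(keep), "n_after_missingness": int(keep.sum()),
            "n_after_pca": int(inliers.sum()),
        }

        from .io_formats import CohortData
        cohort_qc = CohortData(
            sample_ids=meta["sample"].tolist(),
            variants=pd.DataFrame({
                "variant_id": cohort.variant_ids,
                "chrom": score_table["chrom"],
                "pos": score_table["pos"],
                "ref": score_table["other_allele"],
                "alt": score_table["effect_allele"],
            }),
            dosages=doses, metadata=meta,
        )
        resolved = resolve_variants(score, cohort.variant_ids, ProxyMap(),
                                    cfg.r2_threshold)
        scores = {}
        for ancestry in score.ancestries:
            tab = score_cohort(cohort_qc, resolved, ancestry)
            scores[ancestry] = tab["standardized"].to_numpy()
        cohorts[pop.name] = {"cohort": cohort_qc, "meta": meta, "pcs": pcs,
                             "scores": scores}
        covs = pd.DataFrame(
            pcs[:, : cfg.n_pcs],
            columns=[f"PC{j + 1}" for j in range(pcs.shape[1])][: cfg.n_pcs],
        )
        covs.insert(0, "age", meta["age"].to_numpy())
        eval_entries[pop.name] = {
            "scores": scores,
            "status": (meta["status"] == "case").to_numpy(),
            "covariates": covs,
            "metadata": meta,
        }
        freq_est[pop.name] = np.nanmean(
            np.where(np.isfinite(doses), doses, np.nan), axis=0
        ) / 2.0

    say("divergence tests")
    names = [p.name for p in pops]
    bowtie = divergence_stats.bowtie_test_from_frequencies(
        freq_est[names[0]], freq_est[names[1]]
    )
    own_scores = {
        name: cohorts[name]["scores"][name] for name in names
    }
    mw = divergence_stats.mann_whitney_shift(own_scores[names[0]],
                                             own_scores[names[1]])
    medians = divergence_stats.population_medians(own_scores)

    selection = None
    if cfg.run_selection_scan:
        try:
            say("selection scan")
            selection = _selection_stage(cfg)
        except Exception as exc:  # optional stage: log, keep going
            manifest["selection_error"] = str(exc)
            say(f"selection scan failed (continuing): {exc}")

    say("evaluation")
    report = evaluation.build_evaluation_report(
        eval_entries, classifiers=cfg.classifiers, score_name=score.score_name
    )
    delong = None
    if len(names) == 2:
        r1 = evaluation.roc_auc(own_scores[names[0]],
                                eval_entries[names[0]]["status"])
        r2 = evaluation.roc_auc(own_scores[names[1]],
                                eval_entries[names[1]]["status"])
        delong = evaluation.delong_test(r1, r2, paired=False)

    for name in names:
        manifest["stages"][f"report_rows_{name}"] = int(
            (report["cohort"] == name).sum()
        )
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    medians.to_csv(out / "medians.tsv", sep="\t", index=False)
    results = {
        "report": report, "bowtie": bowtie, "mann_whitney": mw,
        "medians": medians, "selection": selection, "delong_cross": delong,
        "manifest": manifest,
    }
    with open(out / "results.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    say(f"done; outputs in {out}")
    return results


def _selection_stage(cfg: RunConfig) -> dict:
    """Small planted-sweep demonstration: iHS at neutral cores vs one swept
    core, percentile placement and the KS uniformity test."""
    rng_seed = cfg.seed + 77
    values, freqs = [], []
    n_panels = 40
    for i in range(n_panels):
        hap, pos, _ = simulate_sweep_haplotypes(
            60, 101, 50, 0.0, stage_rng(rng_seed, "haplotypes", index=i)
        )
        panel = selection_scan.HaplotypePanel(hap, pos, core_index=50)
        res = selection_scan.compute_ihs_unstandardized(panel)
        values.append(res["ihs"])
        freqs.append(res["derived_freq"])
    std, _ = selection_scan.standardize_ihs(values, freqs, n_bins=5)
    targets = std[: max(5, n_panels // 5)]
    pct = selection_scan.percentile_against_reference(targets, std)
    ks = selection_scan.ks_uniform_test(pct["percentile"].to_numpy())
    return {"n_panels": n_panels, "ks": ks,
            "percentiles": pct["percentile"].tolist()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
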