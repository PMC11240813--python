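"""End-to-end orchestration: simulate -> rank -> classify -> feeding
metrics -> statistics -> microbiome biomarkers, with every intermediate
table persisted and a machine-readable JSON report.

Reproducibility: each stage derives its randomness from the single run
seed combined with a fixed per-stage tag (the generators namespace their
own seed sequences), so any stage can be re-run in isolation and a fixed
seed yields a bit-identical report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from herdrank import io as hio
from herdrank import __version__
from herdrank.config import MicrobiomeConfig, RunConfig
from herdrank.dominance import (
    change_labels,
    classify_hierarchy,
    ranking_scores,
    transition_table,
)
from herdrank.feeding import daily_summaries, normalize_by_pen, phase_aggregate
from herdrank.microbiome import (
    build_network,
    bray_curtis,
    cv_auc,
    detect_modules,
    differential_biomarkers,
    netmoss_scores,
    rarefy,
    shannon_alpha,
    sparcc_correlations,
)
from herdrank.simulate import (
    BASE_DATE,
    Cohort,
    generate_abundances,
    generate_bouts,
    generate_cohort,
    generate_feeding_events,
    generate_weights,
    true_hierarchy,
)
from herdrank.stats import ModelSpec, chi_square_counts, fit_linear_model, fit_random_intercept_model

logger = logging.getLogger(__name__)

PHASES = (1, 2, 3)


def measured_hierarchy(cohort: Cohort, seed: int) -> pd.DataFrame:
    """Tournament-derived hierarchy for all three phases."""
    frames = []
    for phase in PHASES:
        bouts = generate_bouts(cohort, phase, seed=seed)
        table = ranking_scores(bouts, phase)
        assign = classify_hierarchy(table, cohort.pens_in_phase(phase))
        assign["phase"] = phase
        frames.append(assign)
    return pd.concat(frames, ignore_index=True)


def biomarker_chain(
    matrix: pd.DataFrame,
    classes: pd.Series,
    config: MicrobiomeConfig | None = None,
    seed: int = 0,
) -> dict:
    """Genus table + binary classes -> networks, scores, biomarkers, AUC."""
    cfg = config or MicrobiomeConfig()
    dom_cols = classes.index[classes == "dominant"]
    sub_cols = classes.index[classes == "submissive"]
    # ensemble over correlation-resampling replicates: network inference
    # from few samples is unstable, so normalized transition scores are
    # averaged across replicates (the last replicate's networks are kept
    # for inspection/export)
    nets = {}
    parts = {}
    score_acc = None
    n_rep = max(cfg.score_ensemble, 1)
    for rep in range(n_rep):
        for name, cols in (
            ("dominant", dom_cols),
            ("submissive", sub_cols),
            ("combined", list(dom_cols) + list(sub_cols)),
        ):
            corr = sparcc_correlations(
                matrix[cols],
                n_iter=cfg.sparcc_iterations,
                exclusion_threshold=cfg.sparcc_exclusion_threshold,
                n_resamples=cfg.sparcc_resamples,
                pseudocount=cfg.pseudocount,
                seed=(seed * 1000 + rep) & 0x7FFFFFFF,
            )
            nets[name] = build_network(corr, cfg.edge_threshold)
            parts[name] = detect_modules(nets[name], cfg.module_cut_height)
        rep_scores = netmoss_scores(
            nets["dominant"], nets["submissive"], nets["combined"],
            parts["dominant"], parts["submissive"],
        )
        score_acc = rep_scores if score_acc is None else score_acc + rep_scores
    scores = score_acc / n_rep
    biomarkers = differential_biomarkers(
        matrix, classes, scores,
        score_threshold=cfg.score_threshold,
        fdr_threshold=cfg.fdr_threshold,
    )
    panel = list(biomarkers.index[biomarkers["biomarker"]])
    auc = cv_auc(matrix, classes, panel, k=cfg.cv_folds, seed=seed) if panel else float("nan")
    return {
        "networks": nets,
        "partitions": parts,
        "scores": scores,
        "biomarkers": biomarkers,
        "panel": panel,
        "auc": auc,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages, writing artifacts under ``config.outdir``.

    Returns the report dict (also written as ``report.json``).
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    report: dict = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
    }

    # --- cohort & dominance --------------------------------------------
    # single-seed determinism: the cohort inherits the run seed
    import dataclasses as _dc

    cohort = generate_cohort(_dc.replace(config.cohort, seed=seed))
    hio.write_animals(cohort.animals, outdir / "animals.csv")
    cohort.mixing_plan.to_csv(outdir / "mixing_plan.csv", index=False)

    planted = pd.concat([true_hierarchy(cohort, p) for p in PHASES], ignore_index=True)

    all_bouts = []
    assigns = {}
    for phase in PHASES:
        bouts = generate_bouts(cohort, phase, seed=seed)
        all_bouts.append(bouts)
        table = ranking_scores(bouts, phase)
        assign = classify_hierarchy(table, cohort.pens_in_phase(phase))
        assign["phase"] = phase
        assigns[phase] = assign
    bouts_df = pd.concat(all_bouts, ignore_index=True)
    hio.write_bouts(bouts_df, outdir / "bouts.csv")
    hierarchy = pd.concat(assigns.values(), ignore_index=True)
    hio.write_hierarchy(hierarchy, outdir / "hierarchy.csv")
    report["hierarchy_counts"] = {
        str(phase): assigns[phase]["class"].value_counts().to_dict() for phase in PHASES
    }

    transitions = {}
    for a, b in ((1, 2), (2, 3), (1, 3)):
        mat = transition_table(assigns[a], assigns[b])
        mat.to_csv(outdir / f"transitions_{a}_{b}.csv")
        transitions[f"{a}->{b}"] = mat.to_numpy().tolist()
        labels = change_labels(assigns[a], assigns[b])
        labels.to_csv(outdir / f"changes_{a}_{b}.csv", index=False)
    report["transitions"] = transitions

    # chi-square: change category (Better/Worse/Same) vs treatment, 1->3
    labels13 = change_labels(assigns[1], assigns[3])
    labels13 = labels13.merge(
        cohort.animals[["animal_id", "treatment"]], on="animal_id"
    )
    ct = pd.crosstab(labels13["treatment"], labels13["change"])
    stat, dof, p = chi_square_counts(ct.to_numpy())
    report["change_vs_treatment_chi2"] = {"statistic": stat, "df": dof, "p": p}

    # --- feeding --------------------------------------------------------
    if config.run_feeding:
        days = range(0, config.cohort.end_day)
        if config.feeding_days_per_phase:
            kept = []
            for phase in PHASES:
                kept.extend(list(config.cohort.phase_days(phase))[: config.feeding_days_per_phase])
            days = kept
        events = generate_feeding_events(cohort, planted, days, seed=seed)
        hio.write_feeding_events(events, outdir / "feeding_events.csv")
        daily = daily_summaries(events)
        pens_by_day = _pen_membership_table(cohort, daily)
        daily = normalize_by_pen(daily, pens_by_day)
        daily.to_csv(outdir / "daily_summaries.csv", index=False)
        study_day = (daily["day"] - BASE_DATE).dt.days
        phase_map = dict(zip(daily["day"], study_day.map(config.cohort.phase_of_day)))
        phase_metrics = phase_aggregate(daily, phase_map)
        phase_metrics.to_csv(outdir / "phase_metrics.csv", index=False)

        contrasts = {}
        p3 = phase_metrics[phase_metrics["phase"] == 3].merge(
            hierarchy[hierarchy["phase"] == 3][["animal_id", "pen_id", "class"]],
            on="animal_id",
        ).merge(cohort.animals[["animal_id", "treatment"]], on="animal_id")
        # pen nests treatment (treatment is constant within pen), so the
        # absolute-metric models carry pen alone and the pen-relative
        # models carry treatment alone to keep the design full-rank
        for metric, use_pen in (
            ("intake_g", True),
            ("rel_intake_g", False),
            ("rel_n_visits", False),
            ("slot_pct_10_14", True),
        ):
            if use_pen:
                factors = {"class": "dominant", "pen_id": sorted(p3["pen_id"].unique())[0]}
            else:
                factors = {"class": "dominant", "treatment": "control"}
            fit = fit_linear_model(p3, ModelSpec(response=metric, factors=factors))
            contrasts[metric] = {
                "submissive_vs_dominant": fit.coef("class[submissive]"),
                "p": fit.pvalue("class[submissive]"),
            }
        report["feeding_contrasts"] = contrasts
        p3.to_csv(outdir / "phase3_feeding.csv", index=False)

    # --- weights --------------------------------------------------------
    if config.run_weights:
        weights = generate_weights(cohort, planted, seed=seed)
        hio.write_weights(weights, outdir / "weights.csv")
        w3 = weights[weights["day"] >= config.cohort.phase_boundaries[1]].merge(
            hierarchy[hierarchy["phase"] == 3][["animal_id", "class"]], on="animal_id"
        ).merge(cohort.animals[["animal_id", "treatment"]], on="animal_id")
        spec = ModelSpec(
            response="weight_kg",
            factors={"class": "dominant", "treatment": "control"},
            covariates=["day"],
            random_intercept="animal_id",
        )
        fit = fit_random_intercept_model(w3, spec)
        fit.table.to_csv(outdir / "weight_model_phase3.csv", index=False)
        report["weight_contrast_phase3"] = {
            "submissive_vs_dominant": fit.coef("class[submissive]"),
            "p": fit.pvalue("class[submissive]"),
            "var_random_intercept": fit.extra["var_random_intercept"],
        }
        p3_means = w3.groupby("class")["weight_kg"].mean()
        report["weight_phase3_means"] = p3_means.to_dict()

    # --- microbiome -----------------------------------------------------
    if config.run_microbiome:
        mcfg = config.microbiome
        extremes = hierarchy[
            (hierarchy["phase"] == 3) & (hierarchy["class"].isin(["dominant", "submissive"]))
        ]
        classes = pd.Series(
            extremes["class"].to_numpy(),
            index=pd.Index("S_" + extremes["animal_id"], name="sample_id"),
        )
        matrix = generate_abundances(
            classes,
            n_genera=mcfg.n_genera,
            planted=config.cohort.effects.planted_log2fc,
            depth_range=mcfg.depth_range,
            seed=seed,
            config=mcfg,
        )
        hio.write_abundance(matrix, outdir / "abundance.tsv")
        meta = pd.DataFrame(
            {
                "sample_id": classes.index,
                "animal_id": extremes["animal_id"].to_numpy(),
                "phase": 3,
                "class": classes.to_numpy(),
            }
        )
        hio.write_metadata(meta, outdir / "metadata.csv")

        rare = rarefy(matrix, mcfg.rarefaction_depth, seed=seed)
        shannon = shannon_alpha(rare)
        report["alpha_diversity"] = {
            cls: float(shannon[classes.index[classes == cls]].mean())
            for cls in ("dominant", "submissive")
        }
        bc = bray_curtis(rare)
        report["beta_diversity_mean_bray_curtis"] = float(
            bc.to_numpy()[np.triu_indices(bc.shape[0], 1)].mean()
        )

        chain = biomarker_chain(matrix, classes, mcfg, seed=seed)
        chain["biomarkers"].to_csv(outdir / "biomarkers.csv")
        for name, net in chain["networks"].items():
            net.edge_list().to_csv(outdir / f"network_{name}_edges.tsv", sep="\t", index=False)
        report["biomarkers"] = {
            "panel": chain["panel"],
            "n_called": len(chain["panel"]),
            "auc": chain["auc"],
        }

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _pen_membership_table(cohort: Cohort, daily: pd.DataFrame) -> pd.DataFrame:
    """animal_id, day (timestamp), pen_id rows covering all pen-days in
    ``daily`` (mixing-aware)."""
    rows = []
    for day in daily["day"].unique():
        study_day = int((day - BASE_DATE).days)
        pens = cohort.pens_on_day(study_day)
        for animal, pen in pens.items():
            rows.append({"animal_id": animal, "day": day, "pen_id": pen})
    return pd.DataFrame(rows)


def replicate_study(
    config: RunConfig, n_replicates: int, seed: int = 0, outdir: str | None = None
) -> pd.DataFrame:
    """Repeat a reduced pipeline across deterministic per-replicate seeds
    and aggregate directional findings.

    Per replicate: phase-3 intake contrast sign and p, phase-3 weight gap
    sign, number of biomarkers called and panel AUC.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    import dataclasses

    rows = []
    for r in range(n_replicates):
        rep_seed = seed + 1000 * r
        rep_cfg = dataclasses.replace(
            config,
            seed=rep_seed,
            cohort=dataclasses.replace(config.cohort, seed=rep_seed),
            outdir=f"{outdir or config.outdir}/rep{r:03d}",
        )
        report = run_pipeline(rep_cfg)
        row = {"replicate": r, "seed": rep_cfg.seed}
        if "feeding_contrasts" in report:
            c = report["feeding_contrasts"]["intake_g"]
            row["intake_contrast"] = c["submissive_vs_dominant"]
            row["intake_p"] = c["p"]
            row["dominant_eats_more"] = c["submissive_vs_dominant"] < 0
        if "weight_contrast_phase3" in report:
            row["weight_contrast"] = report["weight_contrast_phase3"]["submissive_vs_dominant"]
        if "biomarkers" in report:
            row["n_biomarkers"] = report["biomarkers"]["n_called"]
            row["auc"] = report["biomarkers"]["auc"]
        rows.append(row)
    return pd.DataFrame(rows)
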