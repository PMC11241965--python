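"""Configuration-driven end-to-end runner.

Chains simulate -> batch-correct -> filter -> differential abundance ->
drug effect sizes -> trajectory clustering -> set similarity -> progression
modelling -> biomarker ranking -> diagnostic classifiers, writing one TSV
per stage plus a JSON manifest (seeds, counts, file list).  Outputs are pure
functions of (inputs, config): re-running with the same config is
bit-identical.

The single top-level seed fans out to per-stage seeds by fixed offsets, so
one knob reproduces the whole run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch import correct_batches
from .differential import compare_and_intersect, differential_table
from .effects import es_dap_table, per_patient_log2fc
from .filters import FilterSpec, complete_proteins, sals_specific
from .io import AbundanceTable, to_log10, write_abundance
from .mldiag import MLExperimentConfig, run_experiment
from .progression import adj_a, aalsfrs, fit_all, fixed_point_rate, rank_biomarkers
from .similarity import (
    divergence_trajectory,
    paired_profile_correlation,
    signed_vector,
    similarity_heatmap,
)
from .simulate import SimulationConfig, bridge_pairs, simulate_cohort, write_cohort
from .trajectory import fit_trajectory_clusters, fold_change_cube, transfer_and_test

logger = logging.getLogger(__name__)

SEED_OFFSETS = {"simulate": 0, "ml": 1, "dunnett": 2}


def _naive_week0_ids(info: pd.DataFrame, table: AbundanceTable) -> dict:
    ids = set(table.sample_ids)
    meta = info[info["sample_id"].isin(ids)]
    meta = meta[meta["bridge_of"].fillna("") == ""] if "bridge_of" in meta.columns else meta
    ctrl = meta.loc[meta["cohort"] == "control", "sample_id"].tolist()
    naive0 = meta.loc[(meta["cohort"] == "SALS") & (~meta["ropi_exposed"])
                      & (meta["week"] == 0), "sample_id"].tolist()
    naive_all = meta.loc[(meta["cohort"] == "SALS")
                         & (~meta["ropi_exposed"]), "sample_id"].tolist()
    return {"control": ctrl, "naive_week0": naive0, "naive_all": naive_all}


def run_pipeline(config: dict | None = None, outdir="pipeline_out") -> dict:
    """Run every stage on a simulated cohort; return the manifest."""
    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    def _record(stage: str, filename: str, n_rows: int) -> None:
        manifest["stages"].setdefault(stage, []).append(
            {"file": filename, "rows": int(n_rows)})

    # --- simulate ---------------------------------------------------------
    sim_kwargs = dict(cfg.get("simulation", {}))
    sim_kwargs["seed"] = seed + SEED_OFFSETS["simulate"]
    sim_cfg = SimulationConfig(**sim_kwargs)
    cohort = simulate_cohort(sim_cfg)
    write_cohort(cohort, outdir / "cohort")
    for fluid, table in cohort.tables.items():
        _record("simulate", f"cohort/abundance_{fluid}.tsv", table.shape[0])
    manifest["simulation_config"] = asdict(sim_cfg)

    corrected: dict = {}
    logged: dict = {}
    dap: dict = {}
    esdap: dict = {}
    models: dict = {}
    cubes: dict = {}
    fluid_weeks = {"serum": sim_cfg.serum_weeks, "csf": sim_cfg.csf_weeks}

    for fluid, table in cohort.tables.items():
        # --- batch correction --------------------------------------------
        pairs = bridge_pairs(cohort.info, fluid)
        corr = correct_batches(table, cohort.info, pairs)
        corrected[fluid] = corr
        logged[fluid] = to_log10(corr)
        write_abundance(corr, outdir / f"corrected_{fluid}.tsv")
        _record("batch_correction", f"corrected_{fluid}.tsv", corr.shape[0])

        # --- filters ------------------------------------------------------
        subsets = _naive_week0_ids(cohort.info, corr)
        universe = complete_proteins(
            corr, subsets["control"] + subsets["naive_week0"])
        spec = FilterSpec(**cfg.get("sals_specific", {}))
        specific = sals_specific(corr, subsets["naive_all"],
                                 subsets["control"], spec)
        pd.Series(sorted(universe), name="protein_id").to_csv(
            outdir / f"universe_{fluid}.tsv", sep="\t", index=False)
        pd.Series(sorted(specific), name="protein_id").to_csv(
            outdir / f"sals_specific_{fluid}.tsv", sep="\t", index=False)
        _record("filter", f"universe_{fluid}.tsv", len(universe))
        _record("filter", f"sals_specific_{fluid}.tsv", len(specific))

        # --- differential abundance --------------------------------------
        dap[fluid] = differential_table(logged[fluid], cohort.info,
                                        protein_universe=universe)
        dap[fluid].to_csv(outdir / f"dap_{fluid}.tsv", sep="\t")
        _record("dap", f"dap_{fluid}.tsv", len(dap[fluid]))

        # --- effect sizes -------------------------------------------------
        fc24 = per_patient_log2fc(corr, cohort.info,
                                  int(cfg.get("es_dap_week", 24)))
        esdap[fluid] = es_dap_table(fc24.loc[sorted(universe)], cohort.info)
        esdap[fluid].to_csv(outdir / f"es_dap_{fluid}.tsv", sep="\t")
        _record("es_dap", f"es_dap_{fluid}.tsv", len(esdap[fluid]))

        # --- trajectory clustering ---------------------------------------
        post_weeks = [w for w in fluid_weeks[fluid] if w > 0]
        cube = fold_change_cube(corr.subset_proteins(sorted(universe)),
                                cohort.info, post_weeks)
        cubes[fluid] = cube
        arm = cohort.info.drop_duplicates("subject_id").set_index(
            "subject_id")["arm"]
        placebo = [s for s in cube[post_weeks[-1]].columns
                   if arm.get(s) == "placebo"]
        ropi = [s for s in cube[post_weeks[-1]].columns
                if arm.get(s) == "ROPI"]
        model = fit_trajectory_clusters(cube, placebo,
                                        k=int(cfg.get("k_clusters", 3)))
        models[fluid] = model
        model.labels_.rename_axis("protein_id").to_frame().to_csv(
            outdir / f"clusters_{fluid}.tsv", sep="\t")
        _record("trajectory", f"clusters_{fluid}.tsv", len(model.labels_))
        reports = transfer_and_test(model, cube, ropi, placebo)
        anova_rows = []
        for label, rep in reports.items():
            if rep is None:
                continue
            for term in rep["anova"].index:
                if term in ("Intercept", "Residual"):
                    continue
                anova_rows.append({
                    "cluster": label, "term": term,
                    "F": rep["anova"].loc[term, "F"],
                    "p": rep["anova"].loc[term, "PR(>F)"],
                })
        pd.DataFrame(anova_rows).to_csv(outdir / f"anova_{fluid}.tsv",
                                        sep="\t", index=False)
        _record("trajectory", f"anova_{fluid}.tsv", len(anova_rows))

    # --- set similarity ---------------------------------------------------
    shared = sorted(set(dap["serum"].index) | set(dap["csf"].index))
    vectors = {}
    for fluid in ("serum", "csf"):
        d = dap[fluid]
        vectors[f"dap_{fluid}"] = signed_vector(
            shared,
            up=d.index[d["is_dap"] & (d["direction"] == "up_in_case")],
            down=d.index[d["is_dap"] & (d["direction"] == "down_in_case")])
        e = esdap[fluid]
        vectors[f"esdap_{fluid}"] = signed_vector(
            shared,
            up=e.index[e["is_es_dap"] & (e["direction"] == "increased_by_ropi")],
            down=e.index[e["is_es_dap"] & (e["direction"] == "decreased_by_ropi")])
        lab = models[fluid].labels_
        vectors[f"time_{fluid}"] = signed_vector(
            shared,
            up=lab.index[lab == "increased"],
            down=lab.index[lab == "decreased"])
    sim_mat, order = similarity_heatmap(vectors)
    sim_mat.loc[order, order].to_csv(outdir / "cosine_similarity.tsv", sep="\t")
    _record("similarity", "cosine_similarity.tsv", len(sim_mat))

    profile = paired_profile_correlation(
        logged["serum"], logged["csf"], cohort.info,
        seed=seed + SEED_OFFSETS["dunnett"])
    profile["per_draw"].to_csv(outdir / "paired_profile_r.tsv", sep="\t",
                               index=False)
    _record("similarity", "paired_profile_r.tsv", len(profile["per_draw"]))

    d_ser = dap["serum"]
    lab_ser = models["serum"].labels_
    up_set = set(d_ser.index[d_ser["is_dap"] & (d_ser["direction"] == "up_in_case")]) \
        | set(lab_ser.index[lab_ser == "increased"])
    down_set = set(d_ser.index[d_ser["is_dap"] & (d_ser["direction"] == "down_in_case")]) \
        | set(lab_ser.index[lab_ser == "decreased"])
    div = divergence_trajectory(logged["serum"], cohort.info, up_set, down_set)
    div.to_csv(outdir / "divergence_serum.tsv", sep="\t", index=False)
    _record("similarity", "divergence_serum.tsv", len(div))

    # --- progression + biomarkers ----------------------------------------
    fits = fit_all(cohort.alsfrs)
    arm_map = cohort.truth.subjects["arm"].to_dict()
    fits = adj_a(fits, arm_map)
    fit_frame = pd.DataFrame(
        [{"subject_id": f.subject_id, "a": f.a, "b": f.b, "rss": f.rss,
          "converged": f.converged, "adj_a": f.adj_a,
          "aalsfrs_w24": aalsfrs(f, 24), "rate_w24": fixed_point_rate(f, 24)}
         for f in fits]).set_index("subject_id")
    fit_frame.to_csv(outdir / "progression_fits.tsv", sep="\t")
    _record("progression", "progression_fits.tsv", len(fit_frame))
    targets = {f.subject_id: f.adj_a for f in fits}
    ranking = rank_biomarkers(logged["serum"], cohort.info, targets)
    ranking.to_csv(outdir / "biomarkers_serum.tsv", sep="\t")
    _record("progression", "biomarkers_serum.tsv", len(ranking))

    # --- diagnostic classifiers ------------------------------------------
    if cfg.get("run_ml", True):
        ml_kwargs = dict(cfg.get("ml", {}))
        ml_kwargs.setdefault("seed", 111)
        ml_cfg = MLExperimentConfig(**ml_kwargs)
        X, y, validations = build_ml_matrices(logged["serum"], cohort.info,
                                              cohort.truth.bridge_subjects)
        results = run_experiment(X, y, validations, ml_cfg)
        results.to_csv(outdir / "ml_serum.tsv", sep="\t")
        _record("ml", "ml_serum.tsv", len(results))

    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
    return manifest


def build_ml_matrices(table: AbundanceTable, info: pd.DataFrame,
                      training_sals_subjects: list) -> tuple:
    """Assemble classifier matrices from one fluid's log10 table.

    Training base = all controls plus the week-0 samples of the designated
    patient subjects (the bridge subjects, echoing a second-batch training
    set); validation sets = the remaining patient samples split into
    drug-naive and drug-exposed.  The feature universe is the proteins
    detected in every training sample; validation gaps are filled with the
    training median of the feature.
    """
    if table.scale != "log10":
        raise ValueError("classifier matrices are built from log10 intensities")
    ids = set(table.sample_ids)
    meta = info[info["sample_id"].isin(ids)]
    meta = meta[meta["bridge_of"].fillna("") == ""] if "bridge_of" in meta.columns else meta
    ctrl = meta[meta["cohort"] == "control"]
    train_sals = meta[(meta["cohort"] == "SALS") & (meta["week"] == 0)
                      & (meta["subject_id"].isin(training_sals_subjects))]
    rest = meta[(meta["cohort"] == "SALS")
                & ~meta["sample_id"].isin(train_sals["sample_id"])]
    train_ids = ctrl["sample_id"].tolist() + train_sals["sample_id"].tolist()
    y = np.array([0] * len(ctrl) + [1] * len(train_sals))

    features = complete_proteins(table, train_ids)
    feats = sorted(features)
    if not feats:
        raise ValueError("no protein is complete across the training samples")
    X = table.data.loc[feats, train_ids].to_numpy().T
    med = np.nanmedian(X, axis=0)

    def _matrix(sample_ids):
        M = table.data.loc[feats, sample_ids].to_numpy().T
        gaps = np.isnan(M)
        M[gaps] = np.broadcast_to(med, M.shape)[gaps]
        return M

    naive_ids = rest.loc[~rest["ropi_exposed"], "sample_id"].tolist()
    exposed_ids = rest.loc[rest["ropi_exposed"], "sample_id"].tolist()
    validations = {}
    if naive_ids:
        validations["naive"] = (_matrix(naive_ids), np.ones(len(naive_ids), int))
    if exposed_ids:
        validations["exposed"] = (_matrix(exposed_ids),
                                  np.ones(len(exposed_ids), int))
    return X, y, validations
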