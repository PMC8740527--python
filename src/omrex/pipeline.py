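"""End-to-end orchestration: load a bundle of input tables, run every
analysis stage, and write a deterministic report bundle.

Inputs follow the schemas produced by :func:`omrex.simulate.Bundle.write`
(cells.csv, abundance.csv, oc.csv, experiments.csv, thaa.csv,
ms_features.csv, blanks.csv, asv_counts.tsv, samples.csv).  Outputs:
table2.csv (rates and gated growth efficiencies per experiment),
thaa_indicators.csv, class_changes.csv, correlations.csv, diversity.csv,
responders.csv, indicators.csv and run_log.json (seed + config hash).  All
results are computed before anything is written, so a failure never leaves
a partial bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomass, community, config as config_mod, ms, rates, thaa

log = logging.getLogger("omrex")

_FLOAT_FMT = "%.10g"


def load_bundle_tables(in_dir: str | Path) -> dict:
    """Read every input table of a bundle directory into DataFrames."""
    d = Path(in_dir)
    tables = {
        "experiments": pd.read_csv(d / "experiments.csv"),
        "abundance": pd.read_csv(d / "abundance.csv"),
        "cells": pd.read_csv(d / "cells.csv"),
        "oc": pd.read_csv(d / "oc.csv"),
        "thaa": pd.read_csv(d / "thaa.csv"),
        "samples": pd.read_csv(d / "samples.csv"),
    }
    ms_long = pd.read_csv(d / "ms_features.csv")
    tables["ms_areas"] = ms_long.pivot(
        index="feature_id", columns="sample_id", values="peak_area"
    )
    tables["ms_classes"] = (
        ms_long.drop_duplicates("feature_id")
        .set_index("feature_id")["compound_class"]
        .reindex(tables["ms_areas"].index)
    )
    tables["ms_blank"] = (
        pd.read_csv(d / "blanks.csv").set_index("feature_id")["blank_area"]
    )
    asv = pd.read_csv(d / "asv_counts.tsv", sep="\t", index_col=0)
    tables["asv_taxonomy"] = asv["taxonomy"]
    tables["asv_counts"] = asv.drop(columns=["taxonomy"])
    return tables


def rates_stage(tables: dict, cfg: dict) -> pd.DataFrame:
    """Per-experiment rates and gated growth efficiencies (table2-style)."""
    gates = config_mod.gates_from_config(cfg)
    conv_name = cfg["default_conversion"]
    bb = biomass.biomass_from_tables(
        tables["cells"], tables["abundance"], conversion=conv_name
    )
    rows = []
    for _, exp in tables["experiments"].iterrows():
        eid = exp["experiment_id"]
        bb_e = bb[bb["experiment_id"] == eid].sort_values("time_days")
        oc_e = tables["oc"][tables["oc"]["experiment_id"] == eid]
        bb_interp = np.interp(
            oc_e["time_days"], bb_e["time_days"], bb_e["bb_umol_c_per_l"]
        )
        doc = rates.doc_star(oc_e["oc_umol_l"].to_numpy(), bb_interp)
        t_stat = exp.get("days_to_stationary", np.nan)
        res = rates.analyze_experiment(
            bb_e["time_days"].to_numpy(),
            bb_e["bb_umol_c_per_l"].to_numpy(),
            oc_e["time_days"].to_numpy(),
            doc,
            t_stationary=None if pd.isna(t_stat) else float(t_stat),
            t_final=exp.get("days_to_final"),
            gates=gates,
            conversion_name=conv_name,
        )
        short = res["doc_fit_short"]
        long_ = res["doc_fit_long"]
        t0_sel = oc_e["time_days"] == oc_e["time_days"].min()
        row = {
            "experiment_id": eid,
            "depth_m": exp["depth_m"],
            "treatment": exp["treatment"],
            "days_to_stationary": res["t_stationary"],
            "doc0": float(doc[t0_sel.to_numpy()].mean()),
            "delta_doc": res["delta_doc"],
            "short_rate": short.magnitude,
            "short_rate_se": short.slope_se,
            "short_n": short.n,
            "short_p": short.p_two_tailed,
            "long_rate": long_.magnitude if long_ is not None else np.nan,
            "long_p": long_.p_two_tailed if long_ is not None else np.nan,
            "bp": res["bp_fit"].slope,
            "bp_se": res["bp_fit"].slope_se,
            "bp_p": res["bp_fit"].p_two_tailed,
            "resolvable": res["gates"].overall,
            "bge": res["bge"].bge if res["bge"].bge is not None else np.nan,
            "bge_err": res["bge"].bge_error
            if res["bge"].bge_error is not None
            else np.nan,
            "conversion_name": conv_name,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def thaa_stage(tables: dict, cfg: dict) -> pd.DataFrame:
    """Indicator values per replicate plus initial→stationary shift tests."""
    coeffs = config_mod.di_coefficients_from_config(cfg)
    atoms = cfg["amino_acids"]
    alpha = cfg["thresholds"]["alpha"]
    ind = thaa.indicator_table(tables["thaa"], coeffs, atoms)
    shift_rows = []
    for eid, grp in ind.groupby("experiment_id"):
        init = grp[grp["phase"] == "initial"]
        stat = grp[grp["phase"] == "stationary"]
        if len(init) < 2 or len(stat) < 2:
            continue
        di_cmp = thaa.compare_phases(
            init["di_score"], stat["di_score"], higher_is_degraded=False, alpha=alpha
        )
        gb_cmp = thaa.compare_phases(
            init["gaba_bala_molpct"],
            stat["gaba_bala_molpct"],
            higher_is_degraded=True,
            alpha=alpha,
        )
        shift_rows.append(
            {
                "experiment_id": eid,
                "di_delta": di_cmp.delta,
                "di_p": di_cmp.p,
                "di_direction": di_cmp.direction,
                "gaba_bala_delta": gb_cmp.delta,
                "gaba_bala_p": gb_cmp.p,
                "gaba_bala_direction": gb_cmp.direction,
            }
        )
    shifts = pd.DataFrame(shift_rows)
    if not shifts.empty:
        ind = ind.merge(shifts, on="experiment_id", how="left")
    return ind


def ms_stage(tables: dict, cfg: dict, covariate: pd.Series | None = None):
    """Blank filter, z-scores, class change summary and optional screen.

    ``covariate`` (indexed by experiment_id, e.g. initial DI score) enables
    the per-feature correlation screen across experiments.
    """
    thresholds = cfg["thresholds"]
    filtered = ms.blank_filter(
        tables["ms_areas"], tables["ms_blank"], factor=thresholds["blank_factor"]
    )
    z = ms.zscore_matrix(filtered)
    meta = tables["samples"].set_index("sample_id")
    phases = meta["phase"].reindex(z.columns)
    dz = ms.delta_z(z, phases)
    class_changes = ms.class_change_summary(dz, tables["ms_classes"])

    correlations = counts = None
    if covariate is not None:
        exp_of = meta["experiment_id"].reindex(z.columns)
        dz_by_exp = {}
        for eid in exp_of.unique():
            cols = z.columns[exp_of == eid]
            sub_phase = phases[cols]
            init = cols[sub_phase == "initial"]
            stat = cols[sub_phase == "stationary"]
            if len(init) and len(stat):
                dz_by_exp[eid] = z[stat].mean(axis=1) - z[init].mean(axis=1)
        dz_by_exp = pd.DataFrame(dz_by_exp)
        correlations, counts = ms.correlate_feature_changes(
            dz_by_exp,
            covariate,
            classes=tables["ms_classes"],
            alpha=thresholds["alpha"],
        )
    return {
        "class_changes": class_changes,
        "delta_z": dz,
        "correlations": correlations,
        "correlation_counts": counts,
    }


def community_stage(tables: dict, cfg: dict, seed: int) -> dict:
    """Diversity, responders and indicator taxa from the ASV table."""
    thresholds = cfg["thresholds"]
    counts = tables["asv_counts"]
    meta = tables["samples"].set_index("sample_id")
    meta = meta.loc[meta.index.intersection(counts.columns)]
    ra = community.relative_abundance(counts)
    top, coverage = community.top_n_asvs(ra, n=thresholds["top_n"])

    div_rows = []
    for sid in counts.columns:
        d = community.shannon(counts[sid])
        lo, hi = d.ci95
        div_rows.append(
            {
                "sample_id": sid,
                "experiment_id": meta.loc[sid, "experiment_id"],
                "phase": meta.loc[sid, "phase"],
                "H": d.H,
                "variance": d.variance,
                "ci95_low": lo,
                "ci95_high": hi,
                "n_reads": d.n_reads,
                "n_asvs": d.n_asvs,
                "top_coverage": float(coverage[sid]),
            }
        )
    diversity = pd.DataFrame(div_rows)

    resp_rows = []
    hut_rows = []
    for eid, grp in meta.groupby("experiment_id"):
        init_ids = grp.index[grp["phase"] == "initial"]
        stat_ids = grp.index[grp["phase"] == "stationary"]
        if len(init_ids) == 0 or len(stat_ids) == 0:
            continue
        ra_i = ra.loc[top, init_ids].mean(axis=1)
        ra_s = ra.loc[top, stat_ids].mean(axis=1)
        eps_i = 1.0 / counts[init_ids].sum().mean()
        eps_s = 1.0 / counts[stat_ids].sum().mean()
        lfc = community.log2_fold_change(
            ra_i, ra_s, eps_i, eps_s, threshold=thresholds["log2fc"]
        )
        lfc.insert(0, "experiment_id", eid)
        resp_rows.append(lfc.reset_index(names="asv_id"))
        d_i = community.shannon(counts[init_ids].sum(axis=1))
        d_s = community.shannon(counts[stat_ids].sum(axis=1))
        hut = community.hutcheson_t(d_s, d_i)
        hut_rows.append(
            {
                "experiment_id": eid,
                "H_initial": d_i.H,
                "H_stationary": d_s.H,
                "t": hut["t"],
                "df": hut["df"],
                "p": hut["p"],
            }
        )
    responders = pd.concat(resp_rows, ignore_index=True)

    indicators = community.indicator_rg(
        ra.loc[top],
        meta["phase"].reindex(ra.columns).to_list(),
        group="stationary",
        n_permutations=thresholds["n_permutations"],
        seed=seed,
        method="permutation",
    )
    return {
        "diversity": diversity,
        "diversity_shifts": pd.DataFrame(hut_rows),
        "responders": responders,
        "indicators": indicators,
    }


def run_pipeline(cfg: dict, in_dir: str | Path, out_dir: str | Path) -> dict:
    """Run every stage on a bundle directory and write the report bundle."""
    seed = int(cfg.get("seed", 0))
    tables = load_bundle_tables(in_dir)
    log.info("loaded bundle from %s (%d experiments)", in_dir, len(tables["experiments"]))

    table2 = rates_stage(tables, cfg)
    thaa_ind = thaa_stage(tables, cfg)

    initial_di = (
        thaa_ind[thaa_ind["phase"] == "initial"]
        .groupby("experiment_id")["di_score"]
        .mean()
    )
    ms_out = ms_stage(tables, cfg, covariate=initial_di)
    comm = community_stage(tables, cfg, seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = {
        "seed": seed,
        "config_hash": config_mod.config_hash(cfg),
        "n_experiments": int(len(tables["experiments"])),
        "outputs": [
            "table2.csv", "thaa_indicators.csv", "class_changes.csv",
            "correlations.csv", "diversity.csv", "diversity_shifts.csv",
            "responders.csv", "indicators.csv",
        ],
    }
    table2.to_csv(out / "table2.csv", index=False, float_format=_FLOAT_FMT)
    thaa_ind.to_csv(out / "thaa_indicators.csv", index=False, float_format=_FLOAT_FMT)
    ms_out["class_changes"].to_csv(
        out / "class_changes.csv", index=False, float_format=_FLOAT_FMT
    )
    if ms_out["correlations"] is not None:
        corr = ms_out["correlations"].copy()
        corr.to_csv(out / "correlations.csv", float_format=_FLOAT_FMT)
        ms_out["correlation_counts"].to_csv(
            out / "correlation_counts.csv", index=False, float_format=_FLOAT_FMT
        )
    comm["diversity"].to_csv(out / "diversity.csv", index=False, float_format=_FLOAT_FMT)
    comm["diversity_shifts"].to_csv(
        out / "diversity_shifts.csv", index=False, float_format=_FLOAT_FMT
    )
    comm["responders"].to_csv(out / "responders.csv", index=False, float_format=_FLOAT_FMT)
    comm["indicators"].to_csv(out / "indicators.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return {
        "table2": table2,
        "thaa_indicators": thaa_ind,
        "ms": ms_out,
        "community": comm,
        "run_log": run_log,
    }
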