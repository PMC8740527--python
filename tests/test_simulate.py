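"""Round-trip properties of the synthetic experiment generator."""

import numpy as np
import pandas as pd
import pytest

from omrex import community, ms, rates, thaa
from omrex.simulate import (
    SimulationParams,
    bge_recovery_trial,
    simulate_asv,
    simulate_bundle,
    simulate_doc,
    simulate_growth,
    simulate_ms,
    simulate_thaa,
)


def test_generators_are_pure_functions_of_params_and_seed():
    p = SimulationParams()
    a = simulate_bundle(p, seed=11)
    b = simulate_bundle(p, seed=11)
    pd.testing.assert_frame_equal(a.growth.abundance, b.growth.abundance)
    pd.testing.assert_frame_equal(a.oc, b.oc)
    pd.testing.assert_frame_equal(a.thaa, b.thaa)
    pd.testing.assert_frame_equal(a.ms_areas, b.ms_areas)
    pd.testing.assert_frame_equal(a.asv_counts, b.asv_counts)
    c = simulate_bundle(p, seed=12)
    assert not a.oc["oc_umol_l"].equals(c.oc["oc_umol_l"])


def test_detect_stationary_recovers_planted_day(bundle):
    for _, exp in bundle.growth.experiments.iterrows():
        ab = bundle.growth.abundance[
            bundle.growth.abundance["experiment_id"] == exp["experiment_id"]
        ]
        detected = rates.detect_stationary(
            ab["time_days"].to_numpy(), ab["cells_per_ml"].to_numpy()
        )
        assert abs(detected - exp["days_to_stationary"]) <= 1.0


def test_undiluted_treatments_decline_after_stationary(bundle):
    ab = bundle.growth.abundance
    for _, exp in bundle.growth.experiments.iterrows():
        series = ab[ab["experiment_id"] == exp["experiment_id"]]
        post = series[series["time_days"] > exp["days_to_stationary"] + 1]
        peak = series["cells_per_ml"].max()
        if exp["treatment"] == "undiluted":
            assert post["cells_per_ml"].iloc[-1] < 0.8 * peak
        else:
            assert post["cells_per_ml"].iloc[-1] > 0.8 * peak


def test_cell_dimensions_span_target_biovolumes(bundle):
    from omrex.biomass import cell_biovolume

    cells = bundle.growth.cells
    bv = cell_biovolume(cells["max_dim_um"].to_numpy(), cells["min_dim_um"].to_numpy())
    assert bv.min() >= 0.03 - 1e-9
    assert bv.max() <= 0.09 + 1e-9


def test_noise_free_closed_loop_recovers_bge_exactly():
    """With zero noise, the slope quotient returns the generative BGE."""
    p = SimulationParams(
        doc_noise_sd=0.0, abundance_noise_cv=0.0, bge_true=0.3, bp_true=0.1
    )
    growth = simulate_growth(p, seed=5)
    oc = simulate_doc(p, growth, seed=6)
    for _, exp in growth.experiments.iterrows():
        sub = oc[
            (oc["experiment_id"] == exp["experiment_id"])
            & (oc["time_days"] <= exp["days_to_stationary"])
        ]
        doc = rates.doc_star(sub["oc_umol_l"], sub["bb_true_umol_l"])
        doc_fit = rates.fit_rate(sub["time_days"], doc)
        bp_fit = rates.fit_rate(sub["time_days"], sub["bb_true_umol_l"])
        assert rates.bge(bp_fit.slope, doc_fit.magnitude) == pytest.approx(
            0.3, abs=1e-9
        )


def test_unit_bge_conserves_bulk_organic_carbon():
    """At BGE = 1 every removed dissolved carbon atom reappears as biomass,
    so the measured bulk OC is flat while DOC* declines at the production
    rate."""
    p = SimulationParams(doc_noise_sd=0.0, abundance_noise_cv=0.0, bge_true=1.0)
    growth = simulate_growth(p, seed=5)
    oc = simulate_doc(p, growth, seed=6)
    exp = growth.experiments.iloc[0]
    sub = oc[
        (oc["experiment_id"] == exp["experiment_id"])
        & (oc["time_days"] <= exp["days_to_stationary"])
    ]
    assert np.ptp(sub["oc_umol_l"].to_numpy()) == pytest.approx(0.0, abs=1e-9)
    doc = rates.doc_star(sub["oc_umol_l"], sub["bb_true_umol_l"])
    doc_fit = rates.fit_rate(sub["time_days"], doc)
    bp_fit = rates.fit_rate(sub["time_days"], sub["bb_true_umol_l"])
    assert doc_fit.magnitude == pytest.approx(bp_fit.slope, rel=1e-9)


def test_bge_recovery_with_analytical_noise():
    ests = [bge_recovery_trial(0.3, seed=i)["bge_est"] for i in range(100)]
    assert abs(np.nanmean(ests) - 0.3) < 0.03


class TestTHAAGenerator:
    def test_gaba_bala_strictly_increases_across_phases(self, bundle):
        table = thaa.indicator_table(bundle.thaa)
        means = table.groupby(["experiment_id", "phase"])["gaba_bala_molpct"].mean()
        for eid in bundle.growth.experiments["experiment_id"]:
            assert (
                means[eid]["initial"]
                < means[eid]["stationary"]
                < means[eid]["final"]
            )

    def test_di_decreases_with_degradation(self, bundle):
        table = thaa.indicator_table(bundle.thaa)
        means = table.groupby(["experiment_id", "phase"])["di_score"].mean()
        for eid in bundle.growth.experiments["experiment_id"]:
            assert means[eid]["initial"] > means[eid]["final"]

    def test_endmember_mixing_limits(self):
        from omrex.simulate import DEGRADED_MOLPCT, FRESH_MOLPCT

        fresh = pd.Series(FRESH_MOLPCT)
        degraded = pd.Series(DEGRADED_MOLPCT)
        assert fresh.sum() == pytest.approx(100.0)
        assert degraded.sum() == pytest.approx(100.0)
        for m in (0.0, 1.0):
            mix = (1 - m) * fresh + m * degraded
            target = fresh if m == 0.0 else degraded
            assert np.allclose(mix, target)


class TestMSGenerator:
    def test_planted_decay_detected(self, bundle):
        filtered = ms.blank_filter(bundle.ms_areas, bundle.ms_blank)
        z = ms.zscore_matrix(filtered)
        phases = bundle.ms_samples.set_index("sample_id")["phase"]
        dz = ms.delta_z(z, phases)
        out = ms.class_change_summary(dz, bundle.ms_classes).set_index("compound_class")
        assert out.loc["amino acid-like", "mean_delta_z"] < -0.3
        assert out.loc["amino acid-like", "p"] < 0.05

    def test_contaminants_removed_by_blank_filter(self, bundle):
        filtered = ms.blank_filter(bundle.ms_areas, bundle.ms_blank)
        contaminants = set(bundle.ms_classes.attrs["contaminant_features"])
        assert contaminants.isdisjoint(filtered.index)

    def test_no_decay_means_no_signal_beyond_type_i(self):
        p = SimulationParams(decay_multiplier=1.0)
        growth = simulate_growth(p, seed=21)
        areas, blank, classes, samples = simulate_ms(p, growth, seed=22)
        z = ms.zscore_matrix(ms.blank_filter(areas, blank))
        dz = ms.delta_z(z, samples.set_index("sample_id")["phase"])
        out = ms.class_change_summary(dz, classes)
        # with nothing planted, strong class shifts should be absent
        assert (out["mean_delta_z"].abs() < 0.5).all()


class TestASVGenerator:
    def test_planted_responders_are_flagged(self, bundle):
        counts = bundle.asv_counts
        meta = bundle.asv_samples.set_index("sample_id")
        ra = community.relative_abundance(counts)
        top, coverage = community.top_n_asvs(ra, 100)
        assert coverage.mean() == pytest.approx(0.96, abs=0.02)
        eid = bundle.growth.experiments["experiment_id"].iloc[0]
        grp = meta[meta["experiment_id"] == eid]
        init = grp.index[grp["phase"] == "initial"]
        stat = grp.index[grp["phase"] == "stationary"]
        lfc = community.log2_fold_change(
            ra.loc[top, init].mean(axis=1),
            ra.loc[top, stat].mean(axis=1),
            1.0 / counts[init].sum().mean(),
            1.0 / counts[stat].sum().mean(),
        )
        called = set(lfc.index[lfc["responder"]])
        planted = set(bundle.planted_responders)
        assert len(called & planted) / len(planted) >= 0.9

    def test_read_depths_in_configured_range(self, bundle):
        depths = bundle.asv_counts.sum(axis=0)
        assert depths.between(10951, 44686).all()

    def test_no_planted_responders_gives_near_empty_calls(self):
        p = SimulationParams(n_responders=0)
        growth = simulate_growth(p, seed=31)
        counts, _, meta, planted = simulate_asv(p, growth, seed=32)
        assert planted == []
        meta = meta.set_index("sample_id")
        ra = community.relative_abundance(counts)
        top, _ = community.top_n_asvs(ra, 100)
        eid = growth.experiments["experiment_id"].iloc[0]
        grp = meta[meta["experiment_id"] == eid]
        init = grp.index[grp["phase"] == "initial"]
        stat = grp.index[grp["phase"] == "stationary"]
        lfc = community.log2_fold_change(
            ra.loc[top, init].mean(axis=1),
            ra.loc[top, stat].mean(axis=1),
            1.0 / counts[init].sum().mean(),
            1.0 / counts[stat].sum().mean(),
        )
        assert lfc["responder"].sum() <= 2  # pseudocount-noise floor

    def test_planted_evenness_shift_raises_diversity(self):
        p = SimulationParams(evenness_power=0.9, n_responders=0)
        growth = simulate_growth(p, seed=41)
        counts, _, meta, _ = simulate_asv(p, growth, seed=42)
        meta = meta.set_index("sample_id")
        eid = growth.experiments["experiment_id"].iloc[0]
        grp = meta[meta["experiment_id"] == eid]
        init = counts[grp.index[grp["phase"] == "initial"]].sum(axis=1)
        stat = counts[grp.index[grp["phase"] == "stationary"]].sum(axis=1)
        d_i, d_s = community.shannon(init), community.shannon(stat)
        assert d_s.H > d_i.H
        assert community.hutcheson_t(d_s, d_i)["p"] < 0.05
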