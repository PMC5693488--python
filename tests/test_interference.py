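"""Interferent studies: marker arithmetic, gDNA spikes, input-mass robustness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelcheck.interference import (
    blood_titration, gdna_spike_test, implied_pure_blood_fraction, input_mass_test,
    marker_proportion,
)
from panelcheck.syndata import ExpressionProfile, SampleAnnotation, simulate_counts


class TestMarkerProportion:
    def test_plain_arithmetic(self, panel):
        counts = np.ones(panel.n_genes)
        counts[panel.marker_index] = 70.0
        counts[counts == 1.0] = (1000.0 - 70.0) / (panel.n_genes - 1)
        assert marker_proportion(counts, panel) == pytest.approx(0.07)

    def test_pure_blood_sample_near_configured_fraction(self, panel, profiles, config):
        ann = SampleAnnotation(sample_id="b", tissue_role="blood")
        c = simulate_counts(profiles["blood"], ann, config, seed=0)
        assert marker_proportion(c, panel) == pytest.approx(0.3075, abs=0.02)

    def test_tbb_sample_near_baseline(self, panel, profiles, config):
        ann = SampleAnnotation(sample_id="t", class_label="non-UIP")
        c = simulate_counts(profiles["nonuip_tbb"], ann, config, seed=1)
        assert marker_proportion(c, panel) == pytest.approx(0.003, abs=0.002)

    def test_zero_total_rejected(self, panel):
        with pytest.raises(ValueError):
            marker_proportion(np.zeros(panel.n_genes), panel)


class TestImpliedPureBloodFraction:
    def test_printed_quantities_imply_pure_blood_marker_share(self):
        assert implied_pure_blood_fraction(0.003, 0.07, 0.22) == pytest.approx(
            0.30754545, abs=1e-6
        )

    def test_no_enrichment_returns_baseline(self):
        assert implied_pure_blood_fraction(0.01, 0.01, 0.3) == pytest.approx(0.01)

    def test_pure_diluent_returns_mixture(self):
        assert implied_pure_blood_fraction(0.02, 0.31, 1.0) == pytest.approx(0.31)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            implied_pure_blood_fraction(0.5, 0.01, 0.1)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        st.floats(0.0, 0.2),
        st.floats(0.0, 1.0),
        st.floats(0.01, 1.0),
    )
    def test_inverts_forward_mixing(self, b, x, f):
        mixture = f * x + (1 - f) * b
        assert implied_pure_blood_fraction(b, mixture, f) == pytest.approx(x, abs=1e-9)


@pytest.fixture(scope="module")
def titration(panel, profiles, config, model):
    rng = np.random.default_rng(12)
    lib = pd.DataFrame(
        {
            "uip": simulate_counts(
                profiles["uip_tbb"],
                SampleAnnotation(sample_id="uip", class_label="UIP",
                                 tissue_role="uip_tbb"), config, rng),
            "blood": simulate_counts(
                profiles["blood"],
                SampleAnnotation(sample_id="blood", tissue_role="blood"),
                config, rng),
        },
        index=list(panel.gene_ids),
    )
    return blood_titration(lib, "uip", "blood", panel, model, config,
                           fractions=np.round(np.arange(0, 1.001, 0.05), 4),
                           n_simulations=100, n_bootstrap=200, seed=0)


class TestBloodTitration:
    def test_undiluted_level_keeps_parent_call(self, titration):
        result, _ = titration
        assert result.extra["reference_call"] == "UIP"
        assert result.level_summaries[0]["concordant"] == 1.0

    def test_marker_share_at_22_percent_blood_is_about_7_percent(self, titration):
        result, _ = titration
        # the 0.20 and 0.25 grid points bracket the 22% condition
        by_level = {s["level"]: s["marker_proportion"] for s in result.level_summaries}
        lo, hi = by_level[0.2], by_level[0.25]
        assert lo < 0.07 < hi or abs(lo - 0.07) < 0.01 or abs(hi - 0.07) < 0.01

    def test_lod_is_positive_and_bracketed(self, titration):
        _, lod = titration
        assert lod.detected and 0.0 < lod.point < 1.0
        assert lod.lower <= lod.point <= lod.upper


def test_blood_lod_shrinks_with_weaker_class_separation(panel, config):
    """Cutting the discriminating fold change 4x moves the blood LOD down."""
    from panelcheck.classifier import train_pipeline
    from panelcheck.syndata import make_profiles

    lods = {}
    for tag, lfc in (("strong", config.log2_fold_change),
                     ("weak", config.log2_fold_change / 4)):
        cfg = dataclasses.replace(config, log2_fold_change=lfc)
        profiles = make_profiles(panel, cfg)
        rng = np.random.default_rng(3)
        cols, labels = {}, []
        for cls, role in (("UIP", "uip_tbb"), ("non-UIP", "nonuip_tbb")):
            for i in range(15):
                ann = SampleAnnotation(sample_id=f"{role}{i}", class_label=cls,
                                       tissue_role=role)
                cols[f"{role}{i}"] = simulate_counts(profiles[role], ann, cfg, rng)
                labels.append(cls)
        m = train_pipeline(pd.DataFrame(cols, index=list(panel.gene_ids)),
                           np.array(labels))
        lib = pd.DataFrame(
            {
                "uip": simulate_counts(profiles["uip_tbb"],
                                       SampleAnnotation(sample_id="u", class_label="UIP",
                                                        tissue_role="uip_tbb"), cfg, rng),
                "blood": simulate_counts(profiles["blood"],
                                         SampleAnnotation(sample_id="b",
                                                          tissue_role="blood"), cfg, rng),
            },
            index=list(panel.gene_ids),
        )
        _, lod = blood_titration(lib, "uip", "blood", panel, m, cfg,
                                 n_simulations=100, n_bootstrap=200, seed=0)
        lods[tag] = lod.point
    assert lods["weak"] <= lods["strong"]


class TestGdnaSpike:
    def test_zero_fraction_arms_are_exchangeable(self, profiles, config, model):
        samples = {"a": (profiles["uip_tbb"].abundance * 1e5).round(),
                   "b": (profiles["nonuip_tbb"].abundance * 1e5).round()}
        r = gdna_spike_test(samples, profiles["gdna"], model, fraction=0.0,
                            replicate_sd=config.replicate_sd, seed=0)
        assert abs(r.effect_estimate) < 3 * config.replicate_sd
        assert r.p_value > 0.01

    def test_panel_average_gdna_profile_cannot_confound(self, profiles, config, model):
        """If the gDNA background equals the sample composition, spiking is a no-op."""
        sample = (profiles["uip_tbb"].abundance * 1e6).round()
        lookalike = ExpressionProfile("gdna", profiles["uip_tbb"].abundance,
                                      profiles["gdna"].dispersion)
        r = gdna_spike_test({"a": sample, "b": sample * 2}, lookalike, model,
                            fraction=0.30, n_replicates=5, depth=1_000_000,
                            replicate_sd=0.0, seed=1)
        assert abs(r.effect_estimate) < 0.05
        assert r.p_value > 0.01

    def test_paper_layout_emits_eighteen_scores(self, profiles, config, model):
        samples = {r: (profiles[r].abundance * 1e5).round()
                   for r in ("uip_tbb", "nonuip_tbb", "nonuip_slb")}
        r = gdna_spike_test(samples, profiles["gdna"], model, fraction=0.30,
                            n_replicates=3, replicate_sd=config.replicate_sd, seed=2)
        assert len(r.scores) == 18
        assert r.p_value is not None

    def test_single_replicate_rejected(self, profiles, model):
        with pytest.raises(ValueError):
            gdna_spike_test({"a": np.ones(190)}, profiles["gdna"], model,
                            n_replicates=1)


class TestInputMass:
    def test_high_depth_no_noise_is_mass_invariant(self, profiles, config, model):
        quiet = dataclasses.replace(config, depth=2e7, depth_jitter_sd=0.0,
                                    dispersion=0.0, mass_depth_exponent=0.0)
        r = input_mass_test({"u": profiles["uip_tbb"]}, model, quiet,
                            n_replicates=4, inject_replicate_noise=False, seed=0)
        spread = max(s["mean_score"] for s in r.level_summaries) - min(
            s["mean_score"] for s in r.level_summaries)
        assert spread < 0.02
        assert abs(r.effect_estimate) < 0.01

    def test_low_mass_has_larger_pooled_sd(self, profiles, config, model):
        cfg = dataclasses.replace(config, depth=1e5)
        r = input_mass_test(
            {n: profiles[n] for n in ("uip_tbb", "nonuip_tbb")}, model, cfg,
            n_replicates=12, inject_replicate_noise=False, seed=3)
        by_level = {s["level"]: s["sd_score"] for s in r.level_summaries}
        assert by_level[5.0] >= by_level[30.0]

    def test_masses_must_be_positive(self, profiles, config, model):
        with pytest.raises(ValueError):
            input_mass_test({"u": profiles["uip_tbb"]}, model, config,
                            masses=(0.0, 15.0))
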