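"""Generator behavior: panels, profiles, count moments, study layouts."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from panelcheck.classifier import score_counts
from panelcheck.io import write_counts
from panelcheck.syndata import (
    ExpressionProfile, GeneratorConfig, SampleAnnotation, StudyLayout,
    make_panel, make_profiles, simulate_counts, simulate_study,
)


class TestMakePanel:
    def test_default_panel_has_unique_ids_and_one_marker(self):
        panel = make_panel(190, seed=3)
        assert panel.n_genes == 190
        assert len(set(panel.gene_ids)) == 190
        assert panel.gene_ids.count("HBB") == 1
        assert np.all(panel.exonic_length > 0)

    def test_minimal_panel(self):
        assert make_panel(2, seed=0).n_genes == 2

    def test_too_small_panel_rejected(self):
        with pytest.raises(ValueError):
            make_panel(1, seed=0)

    def test_same_seed_same_panel(self):
        a, b = make_panel(50, seed=9), make_panel(50, seed=9)
        assert a.gene_ids == b.gene_ids
        assert np.array_equal(a.exonic_length, b.exonic_length)


class TestMakeProfiles:
    def test_all_roles_present_and_on_simplex(self, panel, config):
        profiles = make_profiles(panel, config)
        for name, p in profiles.items():
            assert p.name == name
            assert p.abundance.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p.abundance >= 0)

    def test_zero_class_separation_collapses_uip_and_nonuip(self, panel, config):
        null = dataclasses.replace(config, log2_fold_change=0.0)
        profiles = make_profiles(panel, null)
        np.testing.assert_allclose(
            profiles["uip_tbb"].abundance, profiles["nonuip_tbb"].abundance
        )

    def test_class_profiles_differ_on_configured_gene_count(self, panel, config):
        profiles = make_profiles(panel, config)
        ratio = profiles["uip_tbb"].abundance / profiles["nonuip_tbb"].abundance
        # renormalization shifts all genes by a common factor; the tilted genes
        # stand apart from that factor by 2**±lfc
        changed = np.abs(np.log2(ratio) - np.median(np.log2(ratio))) > 1.0
        assert changed.sum() == config.n_discriminating

    def test_blood_profile_marker_abundance_matches_config(self, panel, config):
        profiles = make_profiles(panel, config)
        assert profiles["blood"].abundance[panel.marker_index] == pytest.approx(
            0.3075, abs=1e-12
        )

    def test_gdna_abundance_proportional_to_exonic_length(self, panel, config):
        profiles = make_profiles(panel, config)
        lengths = panel.exonic_length
        expected = lengths / lengths.sum()
        np.testing.assert_allclose(profiles["gdna"].abundance, expected)
        # doubling one gene's length doubles its relative share
        i, j = 0, 1
        assert profiles["gdna"].abundance[i] / profiles["gdna"].abundance[j] == (
            pytest.approx(lengths[i] / lengths[j])
        )

    def test_too_many_discriminating_genes_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_genes=10, n_discriminating=10)


class TestSimulateCounts:
    def test_poisson_limit_recovers_abundance(self, panel, config):
        profile = make_profiles(panel, config)["nonuip_tbb"]
        noiseless = ExpressionProfile("x", profile.abundance, 0.0)
        cfg = dataclasses.replace(config, depth=5e6, depth_jitter_sd=0.0)
        ann = SampleAnnotation(sample_id="s")
        counts = simulate_counts(noiseless, ann, cfg, seed=0)
        np.testing.assert_allclose(
            counts / counts.sum(), profile.abundance, atol=5e-4
        )

    def test_marginal_variance_matches_nb_dispersion(self, panel, config):
        """Per-gene var/mean over replicates follows 1 + alpha * mean."""
        profile = make_profiles(panel, config)["nonuip_tbb"]
        cfg = dataclasses.replace(config, depth=1e5, depth_jitter_sd=0.0, dispersion=0.05)
        ann = SampleAnnotation(sample_id="s")
        rng = np.random.default_rng(11)
        reps = np.array([simulate_counts(profile, ann, cfg, rng) for _ in range(500)])
        mean = reps.mean(axis=0)
        var = reps.var(axis=0, ddof=1)
        big = mean > 500  # keep genes where the moment ratio is well estimated
        ratio = var[big] / mean[big]
        expected = 1 + 0.05 * mean[big]
        assert np.median(np.abs(ratio / expected - 1)) < 0.15

    def test_same_seed_identical_counts(self, profiles, config):
        ann = SampleAnnotation(sample_id="s")
        a = simulate_counts(profiles["uip_tbb"], ann, config, seed=5)
        b = simulate_counts(profiles["uip_tbb"], ann, config, seed=5)
        assert np.array_equal(a, b)

    def test_marker_calibration_of_pure_blood(self, panel, profiles, config):
        """Empirical marker share of pure blood stays within ±0.02 of 0.3075."""
        ann = SampleAnnotation(sample_id="b", tissue_role="blood")
        rng = np.random.default_rng(42)
        fracs = []
        for _ in range(40):
            c = simulate_counts(profiles["blood"], ann, config, rng)
            fracs.append(c[panel.marker_index] / c.sum())
        assert np.all(np.abs(np.array(fracs) - 0.3075) < 0.02)

    def test_low_input_mass_inflates_score_noise(self, profiles, config, model):
        """Replicate score SD at 5 ng is at least that at 30 ng."""
        rng = np.random.default_rng(17)
        cfg = dataclasses.replace(config, depth=1e5)
        sds = {}
        for mass in (5.0, 30.0):
            ann = SampleAnnotation(sample_id="s", input_mass_ng=mass)
            scores = [
                score_counts(model, simulate_counts(profiles["uip_tbb"], ann, cfg, rng))
                ["score"].iloc[0]
                for _ in range(30)
            ]
            sds[mass] = np.std(scores, ddof=1)
        assert sds[5.0] >= sds[30.0]


class TestSimulateStudy:
    def test_layout_shape_nine_by_three_by_three(self, panel, profiles, config, model):
        layout = StudyLayout(
            subjects={f"P{i}": "uip_tbb" if i % 2 else "nonuip_tbb" for i in range(9)},
            n_runs=3, n_replicates=3,
        )
        counts, ann, truth = simulate_study(panel, profiles, layout, config,
                                            seed=1, model=model)
        assert counts.shape == (panel.n_genes, 81)
        assert len(ann) == 81
        assert len(truth["replicate_effects"]) == 81

    def test_zero_noise_runs_without_model(self, panel, profiles, config):
        quiet = dataclasses.replace(
            config, run_effect_sd=0.0, lab_effect_sd=0.0, replicate_sd=0.0
        )
        layout = StudyLayout(subjects={"P1": "uip_tbb"}, n_runs=2, n_replicates=2)
        counts, _, truth = simulate_study(panel, profiles, layout, quiet, seed=0)
        assert counts.shape[1] == 4
        assert all(v == 0.0 for v in truth["replicate_effects"].values())
        assert all(v == 0.0 for v in truth["run_effects"].values())

    def test_noise_without_model_rejected(self, panel, profiles, config):
        layout = StudyLayout(subjects={"P1": "uip_tbb"})
        with pytest.raises(ValueError, match="model"):
            simulate_study(panel, profiles, layout, config, seed=0, model=None)

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError):
            StudyLayout(subjects={})

    def test_truth_record_roundtrips_through_json(self, panel, profiles, config, model):
        layout = StudyLayout(subjects={"P1": "uip_tbb"}, n_runs=2, n_replicates=2)
        _, _, truth = simulate_study(panel, profiles, layout, config, seed=3, model=model)
        assert json.loads(json.dumps(truth)) == truth

    def test_emitted_tsv_bytes_deterministic(self, panel, profiles, config, model, tmp_path):
        layout = StudyLayout(subjects={"P1": "nonuip_tbb"}, n_runs=2, n_replicates=2)
        paths = []
        for tag in ("a", "b"):
            counts, _, _ = simulate_study(panel, profiles, layout, config,
                                          seed=7, model=model)
            p = tmp_path / f"{tag}.tsv"
            write_counts(counts, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


def test_annotation_validation():
    with pytest.raises(ValueError):
        SampleAnnotation(sample_id="s", input_mass_ng=0.0)
    with pytest.raises(ValueError):
        SampleAnnotation(sample_id="s", class_label="UIP", tissue_role="nonuip_tbb")
    with pytest.raises(ValueError):
        SampleAnnotation(sample_id="s", dv200=120.0)
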