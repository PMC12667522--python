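"""Synthetic experiment generator: determinism, planted truth, marginals."""

import numpy as np
import pandas as pd
import pytest

from phosphodyn import (ConfigurationError, SyntheticConfig, calibrate,
                        generate_ko_experiment, generate_stage_experiment,
                        screen_multigroup)

NOISELESS = dict(noise_sd=0.0, protein_cv=0.0, protein_stage_sd=0.0,
                 zero_rate=0.0, missing_protein_rate=0.0)


def small_config(**overrides):
    base = dict(n_proteins=120, n_sites=200, n_kinases=4,
                substrates_per_kinase=10, seed=7)
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_fractions_summing_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(module_site_fractions=(0.6, 0.6, 0.1, 0.1))

    def test_trajectory_length_must_match_stages(self):
        with pytest.raises(ConfigurationError):
            small_config(module_trajectories=((1, 0),) * 4)

    def test_single_stage_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(n_stages=1, stage_labels=("only",),
                         module_trajectories=(), module_site_fractions=())

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(n_sites=0)

    def test_roundtrips_through_dict(self):
        cfg = small_config()
        assert SyntheticConfig.from_dict(cfg.to_dict()) == cfg


class TestDeterminism:
    def test_stage_experiment_identical_for_same_seed(self):
        a = generate_stage_experiment(small_config())
        b = generate_stage_experiment(small_config())
        pd.testing.assert_frame_equal(a.proteins.values, b.proteins.values)
        pd.testing.assert_frame_equal(a.sites.records, b.sites.records)
        pd.testing.assert_frame_equal(a.ksr.edges, b.ksr.edges)
        assert a.sequences == b.sequences

    def test_different_seeds_differ(self):
        a = generate_stage_experiment(small_config(seed=1))
        b = generate_stage_experiment(small_config(seed=2))
        assert not a.proteins.values.equals(b.proteins.values)

    def test_ko_experiment_identical_for_same_seed(self):
        a = generate_ko_experiment(small_config(), frac_down=0.2, effect=2.0)
        b = generate_ko_experiment(small_config(), frac_down=0.2, effect=2.0)
        pd.testing.assert_frame_equal(a.sites.records, b.sites.records)
        pd.testing.assert_series_equal(a.truth.ko_label, b.truth.ko_label)


class TestZeroNoiseFaithfulness:
    def test_flat_trajectory_gives_unit_relative_abundance(self):
        cfg = small_config(module_trajectories=((1.0, 1.0, 1.0, 1.0),),
                           module_site_fractions=(1.0,), **NOISELESS)
        exp = generate_stage_experiment(cfg)
        rel = calibrate(exp.sites, exp.proteins, localization_threshold=0.0)
        np.testing.assert_allclose(rel.r.to_numpy(), 1.0, atol=1e-12)

    def test_planted_fold_change_exact_through_normalization(self):
        cfg = small_config(module_trajectories=((2.0, 1.0, 1.0, 1.0),),
                           module_site_fractions=(1.0,), **NOISELESS)
        exp = generate_stage_experiment(cfg)
        rel = calibrate(exp.sites, exp.proteins, localization_threshold=0.0)
        diff = screen_multigroup(rel)
        np.testing.assert_allclose(diff["fc"], 2.0, atol=1e-12)
        # expected stage means from the planted truth are recovered exactly
        expected = exp.truth.expected_stage_means.loc[rel.r.index]
        for stage in rel.design.stages:
            observed = rel.r[rel.design.samples_in(stage)].mean(axis=1)
            np.testing.assert_allclose(observed, expected[stage], atol=1e-12)

    def test_ko_planted_effect_exact(self):
        cfg = small_config(**NOISELESS)
        exp = generate_ko_experiment(cfg, frac_down=0.25, effect=2.0)
        rel = calibrate(exp.sites, exp.proteins, localization_threshold=0.0)
        down = exp.truth.ko_label.reindex(rel.r.index) == "down"
        ctrl = rel.r[rel.design.samples_in("control")].mean(axis=1)
        ko = rel.r[rel.design.samples_in("ko")].mean(axis=1)
        ratio = ko / ctrl
        np.testing.assert_allclose(ratio[down], 0.5, atol=1e-12)
        np.testing.assert_allclose(ratio[~down], 1.0, atol=1e-12)

    def test_frac_down_zero_labels_all_null(self):
        exp = generate_ko_experiment(small_config(**NOISELESS),
                                     frac_down=0.0, effect=3.0)
        assert (exp.truth.ko_label == "null").all()

    def test_invalid_ko_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_ko_experiment(small_config(), frac_down=1.5, effect=2.0)
        with pytest.raises(ConfigurationError):
            generate_ko_experiment(small_config(), frac_down=0.1, effect=1.0)


class TestMarginalControl:
    def test_zero_and_missing_rates_within_binomial_error(self):
        cfg = SyntheticConfig(n_proteins=3000, n_sites=5000, zero_rate=0.05,
                              missing_protein_rate=0.10, seed=21)
        exp = generate_stage_experiment(cfg)
        cells = exp.sites.intensities.to_numpy()
        emp_zero = (cells == 0).mean()
        se_zero = np.sqrt(0.05 * 0.95 / cells.size)
        assert abs(emp_zero - 0.05) < 3 * se_zero
        emp_missing = 1 - len(exp.proteins.values) / cfg.n_proteins
        se_missing = np.sqrt(0.1 * 0.9 / cfg.n_proteins)
        assert abs(emp_missing - 0.10) < 3 * se_missing

    def test_localization_mixture_straddles_threshold(self):
        exp = generate_stage_experiment(SyntheticConfig(
            n_proteins=600, n_sites=1000, seed=3))
        probs = exp.sites.records["loc_prob"]
        assert ((probs > 0.75).mean() > 0.5) and ((probs <= 0.75).any())
        assert probs.between(0, 1).all()


class TestPlantedStructure:
    def test_module_counts_follow_fractions(self):
        exp = generate_stage_experiment(small_config())
        counts = exp.truth.site_module.value_counts()
        assert counts.get(1, 0) == round(0.15 * 200)

    def test_every_planted_edge_is_emitted_and_resolvable(self):
        exp = generate_stage_experiment(small_config())
        keys = set(exp.sites.site_keys)
        assert set(exp.ksr.site_keys).issubset(keys)
        planted = [k for k, (m, c) in exp.truth.kinase_module.items()
                   if m > 0]
        assert set(planted).issubset(set(exp.ksr.edges["kinase"]))

    def test_planted_kinase_substrates_concentrate_in_module(self):
        cfg = small_config(n_sites=400, n_proteins=240,
                           substrates_per_kinase=40)
        exp = generate_stage_experiment(cfg)
        kin, (mod, _) = next((k, v) for k, v in
                             exp.truth.kinase_module.items() if v[0] > 0)
        edges = exp.ksr.edges[exp.ksr.edges["kinase"] == kin]
        keys = (edges["protein_id"] + "_" + edges["residue"]
                + edges["position"].astype(str))
        in_module = exp.truth.site_module.reindex(keys.values) == mod
        # expected in-module probability = min(1, 5 * 0.15) = 0.75
        assert in_module.mean() > 0.5
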