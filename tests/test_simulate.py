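import dataclasses

import numpy as np
import pandas as pd
import pytest

from cnvdosage.io import GENOTYPES
from cnvdosage.simulate import (
    REARRANGED,
    GeneratorConfig,
    generate_dataset,
    generate_strain_reference,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_config):
        a = generate_dataset(dataclasses.replace(small_config, seed=7))
        b = generate_dataset(dataclasses.replace(small_config, seed=7))
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self, small_config):
        a = generate_dataset(dataclasses.replace(small_config, seed=7))
        b = generate_dataset(dataclasses.replace(small_config, seed=8))
        assert not a.matrix.equals(b.matrix)


class TestNoiselessMeans:
    def test_matrix_matches_expected_mean(self, noiseless_dataset):
        """With zero noise every measurement equals the deterministic model mean."""
        ds = noiseless_dataset
        rng = np.random.default_rng(0)
        probes = rng.choice(ds.matrix.index, size=25, replace=False)
        for probe in probes:
            for _, s in ds.samples.sample(6, random_state=1).iterrows():
                expected = ds.expected_log2_mean(probe, s["genotype"], s["tissue"])
                assert abs(ds.matrix.at[probe, s["sample_id"]] - expected) < 1e-9

    def test_wildtype_is_reference(self, noiseless_dataset):
        ds = noiseless_dataset
        interval = ds.annot.index[ds.annot["region_class"] == "interval"]
        probe = interval[5]  # past the two anchor probes
        t = ds.config.tissues[0]
        base = ds.truth.at[probe, "baseline"]
        assert ds.expected_log2_mean(probe, "2n_trans", t) == pytest.approx(base)
        assert ds.expected_log2_mean(probe, "1n", t) == pytest.approx(base + np.log2(0.66))

    def test_anchor_active_copies_drive_dosage(self, noiseless_dataset):
        """An anchor with two active copies in 3n sits at baseline there."""
        ds = noiseless_dataset
        cops3 = ds.annot.index[ds.annot["gene_id"] == "cops3_like"][0]
        t = ds.config.tissues[0]
        base = ds.truth.at[cops3, "baseline"]
        assert ds.expected_log2_mean(cops3, "3n", t) == pytest.approx(base)  # 2 copies
        assert ds.expected_log2_mean(cops3, "2n_cis", t) == pytest.approx(
            base + np.log2(0.66)
        )  # single active copy

    def test_zero_noise_linear_ratios_exact(self, noiseless_dataset):
        ds = noiseless_dataset
        interval = ds.annot[(ds.annot["region_class"] == "interval")]
        plain = interval.index[(interval["copies_2n_cis"] == 2) & (interval["copies_3n"] == 3)]
        t = ds.config.tissues[0]
        wt = ds.matrix.loc[plain, f"2n_trans_{t}_r1"]
        for g, ratio in (("1n", 0.66), ("2n_cis", 1.02), ("3n", 1.38)):
            obs = np.exp2(ds.matrix.loc[plain, f"{g}_{t}_r1"] - wt)
            assert np.allclose(obs, ratio, atol=1e-12)

    def test_unknown_genotype_errors(self, noiseless_dataset):
        with pytest.raises(ValueError, match="genotype"):
            noiseless_dataset.expected_log2_mean(
                noiseless_dataset.matrix.index[0], "4n", "heart"
            )


class TestTruthInvariants:
    def test_non_interval_probes_have_unit_dosage(self, small_dataset):
        truth, annot = small_dataset.truth, small_dataset.annot
        outside = annot["region_class"] != "interval"
        for g in GENOTYPES:
            assert (truth.loc[outside, f"dosage_mult_{g}"] == 1.0).all()

    def test_strain_artifacts_confined_to_block(self, small_dataset):
        truth, annot, cfg = small_dataset.truth, small_dataset.annot, small_dataset.config
        lo, hi = cfg.strain_block
        in_block = (annot["chromosome"] == cfg.cnv_chromosome) & annot["midpoint"].between(lo, hi)
        assert (truth.loc[~in_block, "strain_effect"] == 0).all()
        nonzero = truth["strain_effect"].abs() > 0
        assert (truth.loc[nonzero, "strain_effect"].abs() >= cfg.strain_effect_min).all()

    def test_flank_shifts_only_on_flank_carriers(self, small_dataset):
        truth, annot = small_dataset.truth, small_dataset.annot
        shifts = truth[[f"flank_shift_{g}" for g in REARRANGED]].abs().sum(axis=1)
        assert (shifts[~truth["flank_carrier"]] == 0).all()
        assert truth.loc[truth["flank_carrier"], "flank_carrier"].index.isin(
            annot.index[annot["region_class"] == "flank_cnv_chr"]
        ).all()

    def test_interval_probes_expressed_everywhere(self, small_dataset):
        truth, annot, cfg = small_dataset.truth, small_dataset.annot, small_dataset.config
        interval = annot["region_class"] == "interval"
        for t in cfg.tissues:
            assert truth.loc[interval, f"expressed_{t}"].all()

    def test_shared_direction_fraction_matches_config(self):
        """The injected three-way sign agreement converges to the configured probability."""
        cfg = GeneratorConfig(
            n_probes=6000, n_cnv_chr_probes=4000, flank_fraction=0.5, seed=21
        )
        truth = generate_dataset(cfg).truth
        carriers = truth[truth["flank_carrier"]]
        signs = np.sign(carriers[[f"flank_shift_{g}" for g in REARRANGED]].to_numpy())
        same = (signs == signs[:, [0]]).all(axis=1)
        n = len(carriers)
        tol = 3 * np.sqrt(0.8 * 0.2 / n)
        assert abs(same.mean() - cfg.flank_shared_direction_prob) < tol


class TestMonteCarloRatios:
    def test_mean_1n_ratio_recovers_config(self, small_dataset):
        """Empirical 1n/wild-type linear ratio over interval probes ~= 0.66."""
        ds = small_dataset
        interval = ds.annot[(ds.annot["region_class"] == "interval")]
        plain = interval.index[(interval["copies_2n_cis"] == 2) & (interval["copies_3n"] == 3)]
        samples = ds.samples
        per_probe = []
        for t in ds.config.tissues:
            wt = ds.matrix[samples.index[(samples.genotype == "2n_trans") & (samples.tissue == t)]]
            g1 = ds.matrix[samples.index[(samples.genotype == "1n") & (samples.tissue == t)]]
            per_probe.append(np.exp2(g1.loc[plain].mean(1) - wt.loc[plain].mean(1)))
        ratios = np.concatenate(per_probe)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.66) < 3 * se + 0.01  # +bias allowance for exp of noise


class TestStrainReference:
    def test_design_arithmetic(self, small_reference):
        # six tissues x 3 replicates x 2 strains
        assert small_reference.matrix.shape[1] == 36
        assert set(small_reference.samples["strain_label"]) == {"129S2", "C57BL6J"}

    def test_no_artifacts_means_noise_only_differences(self, small_config):
        cfg = dataclasses.replace(small_config, strain_affected_fraction=0.0, seed=3)
        ref = generate_strain_reference(cfg)
        s = ref.samples
        a = ref.matrix[s.index[s["strain_label"] == "129S2"]].mean(axis=1)
        b = ref.matrix[s.index[s["strain_label"] == "C57BL6J"]].mean(axis=1)
        # 18 samples per strain: mean differences are pure noise, O(noise_sd/3)
        assert (a - b).abs().max() < 6 * cfg.noise_sd / np.sqrt(18)

    def test_shares_probe_universe(self, small_dataset, small_reference):
        assert small_reference.matrix.index.equals(small_dataset.matrix.index)

    def test_artifact_probes_shift_one_strain(self, small_reference, small_dataset):
        truth = small_dataset.truth
        hit = truth.index[truth["strain_effect"].abs() > 0]
        s = small_reference.samples
        a = small_reference.matrix[s.index[s["strain_label"] == "129S2"]].mean(axis=1)
        b = small_reference.matrix[s.index[s["strain_label"] == "C57BL6J"]].mean(axis=1)
        observed = (a - b).loc[hit]
        expected = truth.loc[hit, "strain_effect"]
        assert np.corrcoef(observed, expected)[0, 1] > 0.9


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"flank_fraction": 1.5},
            {"dosage_ratio": {"1n": -0.5, "2n_trans": 1.0, "2n_cis": 1.0, "3n": 1.0}},
            {"replicates": 1},
            {"n_cnv_chr_probes": 50_000},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)
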