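"""Synthetic cohort generator: marginals, stability, determinism, closure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmod import synthetic
from mirmod.data_io import cpm_log_normalize
from mirmod.errors import ValidationError
from mirmod.synthetic import (
    EffectSpec,
    SimulationConfig,
    gen_adversities,
    gen_dataset,
    gen_expression,
    gen_ptss,
)


class TestAdversities:
    def test_prevalence_matches_config(self):
        cfg = SimulationConfig(n_participants=10000, n_mirnas=1, seed=1)
        adv = gen_adversities(cfg)
        assert adv["financial_lifetime"].mean() == pytest.approx(0.625, abs=0.02)
        assert adv["emotional_lifetime"].mean() == pytest.approx(0.316, abs=0.02)

    def test_count_and_scale_moments(self):
        cfg = SimulationConfig(n_participants=10000, n_mirnas=1, seed=2)
        adv = gen_adversities(cfg)
        p = cfg.adversity
        # NB trauma: mean and variance mu + mu^2/theta, within 3 SE-ish bands
        assert adv["trauma_lifetime"].mean() == pytest.approx(p.trauma_mean, rel=0.05)
        expected_var = p.trauma_mean + p.trauma_mean**2 / p.trauma_theta
        assert adv["trauma_lifetime"].var() == pytest.approx(expected_var, rel=0.1)
        assert adv["discrimination"].mean() == pytest.approx(p.discrimination_mean, abs=0.05)
        assert (adv["discrimination"] >= 0).all() and (adv["loneliness"] >= 0).all()

    def test_zero_copula_correlation_decorrelates(self):
        cfg = SimulationConfig(n_participants=10000, n_mirnas=1, seed=3)
        cfg.adversity.copula_correlation = 0.0
        adv = gen_adversities(cfg)
        corr = adv.corr().to_numpy()
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)

    def test_positive_copula_correlation_induces_association(self):
        cfg = SimulationConfig(n_participants=10000, n_mirnas=1, seed=4)
        adv = gen_adversities(cfg)
        r = stats.spearmanr(adv["trauma_lifetime"], adv["discrimination"]).statistic
        assert r > 0.1

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_participants=200, n_mirnas=1, seed=5)
        pd.testing.assert_frame_equal(gen_adversities(cfg), gen_adversities(cfg))

    def test_invalid_prevalence_rejected(self):
        cfg = SimulationConfig(n_participants=10, n_mirnas=1, seed=0)
        cfg.adversity.financial_prevalence = 1.5
        with pytest.raises(ValidationError):
            gen_adversities(cfg)


class TestExpression:
    def test_cross_wave_stability(self):
        cfg = SimulationConfig(n_participants=40, n_mirnas=300, seed=6)
        mats = gen_expression(cfg)
        norm2 = cpm_log_normalize(mats[2]).values
        norm4 = cpm_log_normalize(mats[4]).values
        rhos = [
            stats.spearmanr(norm2[:, i], norm4[:, i]).statistic
            for i in range(cfg.n_participants)
        ]
        assert np.median(rhos) > 0.75

    def test_poisson_limit_variance(self):
        cfg = SimulationConfig(n_participants=500, n_mirnas=200, seed=7)
        cfg.expression.count_dispersion = 1e8
        cfg.expression.biological_sd = 0.0
        cfg.expression.wave_sd = 0.0
        cfg.expression.library_size_range = (1e6, 1e6)
        counts = gen_expression(cfg, waves=(2,))[2].counts
        # constant mean per row: variance/mean ratio near 1 in the Poisson limit
        ratios = counts.var(axis=1) / np.maximum(counts.mean(axis=1), 1e-9)
        keep = counts.mean(axis=1) > 50
        assert np.median(ratios[keep]) == pytest.approx(1.0, abs=0.15)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_participants=30, n_mirnas=20, seed=8)
        a = gen_expression(cfg)[2].counts
        b = gen_expression(cfg)[2].counts
        np.testing.assert_array_equal(a, b)


class TestPTSS:
    def _null_setup(self, n, seed):
        cfg = SimulationConfig(n_participants=n, n_mirnas=5, seed=seed, n_modifiers=0)
        adv = gen_adversities(cfg)
        expr = gen_expression(cfg, waves=(2,))[2]
        return cfg, adv, expr

    def test_null_moments_match_nb(self):
        cfg, adv, expr = self._null_setup(20000, 9)
        effects = EffectSpec(intercept=float(np.log(35.0)), a={})
        y, _ = gen_ptss(adv, expr, effects, theta=5.0, seed=1)
        assert y.mean() == pytest.approx(35.0, abs=1.0)
        assert y.var() == pytest.approx(35 + 35**2 / 5, rel=0.1)

    def test_dispersion_cap_poisson_limit(self):
        cfg, adv, expr = self._null_setup(20000, 10)
        effects = EffectSpec(intercept=float(np.log(35.0)), a={})
        y, _ = gen_ptss(adv, expr, effects, theta=1e9, seed=2)
        assert y.var() / y.mean() == pytest.approx(1.0, abs=0.05)

    def test_seed_determinism_and_truth(self):
        cfg, adv, expr = self._null_setup(200, 11)
        effects = EffectSpec(c={("sim-mir-0001", "trauma"): 0.3})
        y1, t1 = gen_ptss(adv, expr, effects, theta=6.5, seed=3)
        y2, t2 = gen_ptss(adv, expr, effects, theta=6.5, seed=3)
        np.testing.assert_array_equal(y1, y2)
        assert t1.modifier_ids == ["sim-mir-0001"]
        assert t1.c["sim-mir-0001"]["trauma"] == 0.3


class TestDataset:
    def test_bundle_round_trips_and_feeds_pipeline(self, small_bundle, tmp_path):
        from mirmod.data_io import ExpressionMatrix, PhenotypeTable, align_samples
        from mirmod.screen import interaction_screen

        bundle = small_bundle
        assert set(bundle.expr) == {2, 4}
        assert sorted(bundle.pheno.df["wave"].unique()) == [2, 3, 4]
        # end-to-end: align and screen without error
        aligned = align_samples(
            cpm_log_normalize(bundle.expr[2]), bundle.pheno, 2, 3
        )
        recs = interaction_screen(aligned, adversity_j="trauma")
        assert len(recs) == bundle.config.n_mirnas

    def test_written_files_readable(self, small_cfg, tmp_path):
        from mirmod.data_io import ExpressionMatrix, PhenotypeTable

        synthetic.gen_dataset(small_cfg, outdir=tmp_path)
        pheno = PhenotypeTable.from_csv(tmp_path / "phenotypes.csv")
        expr = ExpressionMatrix.from_tsv(tmp_path / "counts_wave2.tsv")
        assert len(pheno.for_wave(3)) == small_cfg.n_participants
        assert expr.counts.shape == (small_cfg.n_mirnas, small_cfg.n_participants)

    def test_full_determinism(self, small_cfg):
        a = gen_dataset(small_cfg)
        b = gen_dataset(small_cfg)
        pd.testing.assert_frame_equal(a.pheno.df, b.pheno.df)
        np.testing.assert_array_equal(a.expr[4].counts, b.expr[4].counts)
        assert a.truth.modifier_ids == b.truth.modifier_ids

    def test_spread_modifiers_cycle_adversities(self):
        cfg = SimulationConfig(
            n_participants=60, n_mirnas=30, seed=12, n_modifiers=5,
            modifier_adversity="spread",
        )
        bundle = gen_dataset(cfg)
        planted_advs = {
            adv for per_mirna in bundle.truth.c.values() for adv in per_mirna
        }
        assert planted_advs == {
            "trauma", "financial", "emotional", "discrimination", "loneliness"
        }

    def test_zero_mirnas_rejected(self):
        with pytest.raises(ValidationError):
            gen_dataset(SimulationConfig(n_participants=10, n_mirnas=0, seed=0))

    def test_targets_and_pathways_plant_enrichment(self, small_cfg, small_bundle):
        table, pathways = synthetic.gen_targets_and_pathways(
            small_cfg, small_bundle.truth
        )
        assert set(table.columns) == {"mirna", "gene", "score"}
        planted = set(pathways["SIMPATH001"])
        mods = set(small_bundle.truth.modifier_ids)
        mod_targets = set(table.loc[table["mirna"].isin(mods), "gene"])
        other_targets = set(table.loc[~table["mirna"].isin(mods), "gene"])
        frac_mod = len(mod_targets & planted) / len(mod_targets)
        frac_other = len(other_targets & planted) / len(other_targets)
        assert frac_mod > 3 * frac_other
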