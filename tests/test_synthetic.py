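"""Generator determinism, rate laws and planted-truth properties."""

import numpy as np
import pandas as pd
import pytest

from gisnet.synthetic import (
    CancerConfig,
    ScreenConfig,
    _papillae_counts,
    simulate_cancer,
    simulate_screen,
)


class TestScreenGenerator:
    def test_same_seed_bit_identical(self):
        cfg = ScreenConfig(n_baits=20, n_queries=3, seed=42)
        p1, t1 = simulate_screen(cfg)
        p2, t2 = simulate_screen(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1.gene_folds, t2.gene_folds)
        assert t1.synergy_pairs == t2.synergy_pairs

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(assays=(("x", 0.0),))
        with pytest.raises(ValueError):
            ScreenConfig(fraction_gis=1.5)
        with pytest.raises(ValueError):
            ScreenConfig(patches_per_strain=0)
        with pytest.raises(ValueError):
            ScreenConfig(model="magic")

    def test_zero_rate_yields_zero_counts(self):
        cfg = ScreenConfig()
        rng = np.random.default_rng(0)
        for model in ("poisson", "luria_delbruck"):
            c = _papillae_counts(
                np.zeros(500), ScreenConfig(model=model), rng
            )
            assert (c == 0).all()

    @pytest.mark.parametrize("model", ["poisson", "luria_delbruck"])
    def test_expected_count_monotone_in_rate(self, model):
        cfg = ScreenConfig(model=model)
        rng = np.random.default_rng(1)
        means = [
            _papillae_counts(np.full(2000, m), cfg, rng).mean()
            for m in (0.5, 2.0, 10.0, 50.0)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_control_strain_median_in_band(self):
        """At m ~ 2 events per patch the control scores like the real
        control strain: median papillae count in the 1-5 band."""
        cfg = ScreenConfig(assays=(("dGCR", 1e-9),), cells_per_patch=2e9,
                           n_baits=5, n_queries=2, seed=3)
        patches, _ = simulate_screen(cfg)
        ctrl = patches[
            (patches["query_gene"] == "WT") & (patches["bait_gene"] == "leu2")
        ]
        med = ctrl["papillae_count"].median()
        assert 1 <= med <= 5

    def test_multiplicative_null_and_synergy_excess(self):
        cfg = ScreenConfig(n_baits=30, n_queries=4, fraction_gis=0.4,
                           fraction_gis_queries=0.4, fraction_synergy=0.3,
                           synergy_fold=8.0, seed=6)
        _, truth = simulate_screen(cfg)
        assert truth.synergy_pairs
        folds = dict(zip(truth.gene_folds["gene"], truth.gene_folds["rate_fold"]))
        doubles = truth.strain_folds[
            (truth.strain_folds["query"] != "WT")
            & (truth.strain_folds["bait"] != "leu2")
        ]
        for r in doubles.itertuples(index=False):
            null = folds[r.query] * folds[r.bait]
            if (r.query, r.bait) in truth.synergy_pairs:
                assert r.rate_fold == pytest.approx(null * cfg.synergy_fold)
                assert r.rate_fold > null
            else:
                assert r.rate_fold == pytest.approx(null, rel=1e-12)

    def test_no_growth_strains_flagged(self):
        cfg = ScreenConfig(n_baits=40, n_queries=2, no_growth_prob=0.5, seed=7)
        patches, _ = simulate_screen(cfg)
        failed = patches[~patches["grew"]]
        assert len(failed) > 0
        # failure is strain-level: all patches of a failed strain fail
        per_strain = patches.groupby(["query_gene", "bait_gene", "assay"])["grew"]
        assert set(per_strain.nunique()) == {1}


class TestCancerGenerator:
    def test_same_seed_bit_identical(self):
        cfg = CancerConfig(n_samples=30, n_genes=40, planted_ts_genes=4, seed=9)
        t1, truth1 = simulate_cancer(cfg)
        t2, truth2 = simulate_cancer(cfg)
        for key in t1:
            pd.testing.assert_frame_equal(t1[key], t2[key])
        assert truth1.planted_genes == truth2.planted_genes

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CancerConfig(planted_ts_genes=50, n_genes=10)
        with pytest.raises(ValueError):
            CancerConfig(cnv_loss_prob=1.5)

    def test_no_mutation_sources_empty_table(self):
        cfg = CancerConfig(n_samples=20, n_genes=30, planted_ts_genes=2,
                           background_mut_rate=0.0, planted_lof_rate=0.0, seed=1)
        tables, _ = simulate_cancer(cfg)
        assert tables["mutations"].empty

    def test_background_mutations_scale_with_length(self):
        """Per-gene Monte-Carlo mean matches length x rate within 5%."""
        cfg = CancerConfig(
            n_samples=20000, n_genes=8, planted_ts_genes=0,
            background_mut_rate=2e-3, planted_lof_rate=0.0,
            availability_probs={"mutation": 1.0, "cnv": 1.0,
                                "expression": 1.0, "methylation": 1.0},
            seed=13,
        )
        tables, _ = simulate_cancer(cfg)
        ann = tables["annotations"].set_index("gene")
        counts = tables["mutations"].groupby("gene").size()
        for gene, row in ann.iterrows():
            expected = row["length_aa"] * cfg.background_mut_rate * cfg.n_samples
            observed = counts.get(gene, 0)
            assert observed == pytest.approx(expected, rel=0.05)

    def test_planted_expression_shift_below_minus_two(self, small_cohort):
        cfg, tables, truth = small_cohort
        cnv, z = tables["cnv"], tables["expression_z"]
        planted = sorted(truth.planted_genes)
        reduced = (cnv[planted] < 0) & cnv[planted].notna() & z[planted].notna()
        vals = z[planted].to_numpy()[reduced.to_numpy()]
        assert len(vals) > 10
        assert vals.mean() < -2

    def test_planted_s_scores_below_minus_two(self, small_cohort):
        _, tables, truth = small_cohort
        ann = tables["annotations"].set_index("gene")
        assert (ann.loc[sorted(truth.planted_genes), "s_score"] <= -2).all()

    def test_availability_honoured(self, small_cohort):
        _, tables, _ = small_cohort
        avail = tables["availability"]
        off = avail.index[~avail["expression"]]
        assert tables["expression_z"].loc[off].isna().all().all()
        assert not set(tables["mutations"]["sample"]) & set(
            avail.index[~avail["mutation"]]
        )
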