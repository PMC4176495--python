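import numpy as np
import pytest
from scipy import stats as sps

from compscan.config import ConfigError, KnockdownModel, SimulationConfig
from compscan.simulate import (
    choose_bound_genes,
    simulate_annotation,
    simulate_chip_tracks,
    simulate_expression,
    simulate_has_and_labels,
    simulate_knockdown,
    simulate_study,
)


def small_cfg(**kw):
    base = dict(seed=1, arms=[("X", 300_000), ("3L", 300_000)], genes_per_arm=10)
    base.update(kw)
    return SimulationConfig(**base)


class TestAnnotation:
    def test_counts_and_exon_containment(self):
        ann = simulate_annotation(small_cfg())
        assert len(ann) == 20
        for g in ann:
            assert all(g.start <= a < b <= g.end for a, b in g.exons)

    def test_genes_do_not_overlap(self):
        ann = simulate_annotation(small_cfg(genes_per_arm=50, seed=3))
        for arm in ("X", "3L"):
            spans = sorted((g.start, g.end) for g in ann.on_arm(arm))
            assert all(b1 <= a2 for (_, b1), (a2, _) in zip(spans, spans[1:]))

    def test_both_strands_represented(self):
        ann = simulate_annotation(small_cfg())
        assert {g.strand for g in ann} == {"+", "-"}

    def test_deterministic(self):
        a1 = simulate_annotation(small_cfg(seed=7))
        a2 = simulate_annotation(small_cfg(seed=7))
        assert [(g.gene_id, g.start, g.end, g.exons) for g in a1] == [
            (g.gene_id, g.start, g.end, g.exons) for g in a2
        ]

    def test_zero_genes_allowed(self):
        assert len(simulate_annotation(small_cfg(genes_per_arm=0))) == 0

    def test_arm_too_short_names_arm(self):
        with pytest.raises(ConfigError, match="'X'"):
            simulate_annotation(small_cfg(arms=[("X", 5_000), ("3L", 300_000)]))

    def test_per_arm_gene_counts(self):
        ann = simulate_annotation(small_cfg(genes_per_arm={"X": 8, "3L": 3}))
        assert len(ann.on_arm("X")) == 8 and len(ann.on_arm("3L")) == 3


class TestExpression:
    def test_zero_noise_compensated_ratio_exactly_zero(self):
        cfg = small_cfg(ratio_noise_sd=0.0, compensated_fraction_X=1.0,
                        unexpressed_fraction=0.0)
        ann = simulate_annotation(cfg)
        table, truth = simulate_expression(cfg, ann)
        x = truth.index[(truth["arm"] == "X")]
        diff = table.data.loc[x, "male"] - table.data.loc[x, "female"]
        assert (diff == 0.0).all()

    def test_zero_noise_uncompensated_shift_exact(self):
        cfg = small_cfg(ratio_noise_sd=0.0, compensated_fraction_X=0.0,
                        unexpressed_fraction=0.0, uncompensated_shift=-1.0)
        ann = simulate_annotation(cfg)
        table, truth = simulate_expression(cfg, ann)
        x = truth.index[truth["arm"] == "X"]
        diff = table.data.loc[x, "male"] - table.data.loc[x, "female"]
        assert (diff == -1.0).all()

    def test_compensated_count_within_binomial_support(self):
        cfg = small_cfg(
            arms=[("X", 8_000_000), ("3L", 300_000)],
            genes_per_arm={"X": 1000, "3L": 10},
            unexpressed_fraction=0.0,
            compensated_fraction_X=0.9,
            seed=13,
        )
        ann = simulate_annotation(cfg)
        _, truth = simulate_expression(cfg, ann)
        n_comp = int(truth.loc[truth["arm"] == "X", "compensated"].sum())
        lo = sps.binom.ppf(1e-6, 1000, 0.9)
        hi = sps.binom.ppf(1 - 1e-6, 1000, 0.9)
        assert lo <= n_comp <= hi

    def test_unexpressed_fraction_sits_below_floor(self):
        cfg = small_cfg(unexpressed_fraction=0.5, seed=2)
        ann = simulate_annotation(cfg)
        table, truth = simulate_expression(cfg, ann)
        un = truth.index[~truth["expressed"]]
        assert (table.data.loc[un, ["male", "female"]] < cfg.detection_floor).all().all()

    def test_all_values_finite(self, small_study):
        assert np.isfinite(small_study.expression.data.to_numpy()).all()


class TestChipTracks:
    def test_counts_are_nonnegative_integers(self, small_study):
        for tr in (small_study.ip, small_study.input_male, small_study.input_female):
            for arr in tr.data.values():
                assert (arr >= 0).all()
                assert np.array_equal(arr, np.rint(arr))

    def test_copy_ratio_halves_male_input_on_x(self):
        cfg = small_cfg(copy_ratio_X=0.5, seed=4)
        ann = simulate_annotation(cfg)
        ip, im, iff, _ = simulate_chip_tracks(cfg, ann, set())
        m_x = im.values("X").mean()
        f_x = iff.values("X").mean()
        m_a = im.values("3L").mean()
        assert m_x == pytest.approx(0.5 * f_x, rel=0.03)
        assert m_a == pytest.approx(f_x, rel=0.03)

    def test_bound_gene_exons_enriched_by_true_fold(self):
        cfg = small_cfg(
            seed=6, enrichment_range=(4.0, 4.0), genes_per_arm=5,
            gene_length_median=30_000, gene_length_sigma=0.3,
        )
        ann = simulate_annotation(cfg)
        # pick an X gene with a large exonic footprint
        gid = max(ann.on_arm("X"), key=lambda g: g.exonic_length).gene_id
        ip, im, _, folds = simulate_chip_tracks(cfg, ann, {gid})
        g = ann[gid]
        exonic = np.concatenate([ip.values("X")[a:b] for a, b in g.exons])
        assert len(exonic) >= 10_000
        expected = 4.0 * cfg.read_depth_ip
        assert exonic.mean() == pytest.approx(expected, rel=0.05)
        assert folds[gid] == 4.0

    def test_deterministic(self):
        cfg = small_cfg(seed=8)
        ann = simulate_annotation(cfg)
        t1 = simulate_chip_tracks(cfg, ann, set())
        t2 = simulate_chip_tracks(cfg, ann, set())
        np.testing.assert_array_equal(t1[0].values("X"), t2[0].values("X"))


class TestKnockdown:
    def test_unbound_gene_drops_zero(self):
        km = KnockdownModel(noise_sd=0.0)
        assert km.drop(1.0, 5000) == 0.0

    def test_effect_decreases_with_length(self):
        km = KnockdownModel()
        assert km.drop(8.0, 1_000) >= km.drop(8.0, 100_000)

    def test_strongly_bound_short_gene_residual_near_80pct(self):
        km = KnockdownModel()
        drop = float(km.drop(64.0, 1_000))
        residual = 2.0 ** (-drop)
        assert residual == pytest.approx(0.80, abs=0.05)

    def test_residual_floor_clamps_drop(self):
        km = KnockdownModel(max_drop=3.0, residual_floor=0.5)
        assert float(km.drop(10_000.0, 100)) == pytest.approx(1.0)

    def test_noise_free_columns_reflect_model(self):
        cfg = small_cfg(seed=9, knockdown=KnockdownModel(noise_sd=0.0))
        ann = simulate_annotation(cfg)
        table, truth = simulate_expression(cfg, ann)
        import pandas as pd

        folds = pd.Series(1.0, index=table.gene_ids)
        out = simulate_knockdown(cfg, table, folds, ann)
        np.testing.assert_allclose(out.data["knockdown"], out.data["control"])


class TestHasAndLabels:
    def test_zero_sites_gives_empty_set_and_undefined_distances(self, small_study):
        cfg = small_cfg(has_count=0)
        ann = simulate_annotation(cfg)
        has, _, _ = simulate_has_and_labels(cfg, ann, set())
        assert len(has) == 0
        from compscan.compare import has_distances

        d = has_distances(ann, has)
        assert d.isna().all()

    def test_all_bound_flagged_when_fraction_one(self):
        cfg = small_cfg(housekeeping_fraction_bound=1.0)
        ann = simulate_annotation(cfg)
        bound = {g.gene_id for g in ann.on_arm("X")[:5]}
        _, hk, _ = simulate_has_and_labels(cfg, ann, bound)
        assert all(hk[g] for g in bound)

    def test_seed_changes_placements(self):
        ann = simulate_annotation(small_cfg(seed=1))
        h1, _, _ = simulate_has_and_labels(small_cfg(seed=1), ann, set())
        h2, _, _ = simulate_has_and_labels(small_cfg(seed=2), ann, set())
        assert h1.regions != h2.regions


class TestStudyDeterminism:
    def test_identical_seed_reproduces_everything(self):
        cfg = small_cfg(seed=21)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        assert s1.expression.data.equals(s2.expression.data)
        assert s1.bound_genes == s2.bound_genes
        np.testing.assert_array_equal(s1.ip.values("X"), s2.ip.values("X"))
        assert s1.has.regions == s2.has.regions
        assert s1.housekeeping == s2.housekeeping
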