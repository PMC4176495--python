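import numpy as np
import pandas as pd
import pytest

from compscan.annotation import GeneModel, GenomeAnnotation
from compscan.chip import (
    BindingReference,
    assign_bin,
    classify_binding,
    enrichment_pipeline,
    enrichment_ratio,
    gene_binding_value,
    gene_binding_values,
    input_floor,
    median_center,
    smooth_ratio,
)
from compscan.config import EnrichmentParams, SimulationConfig
from compscan.simulate import (
    choose_bound_genes,
    simulate_annotation,
    simulate_chip_tracks,
    simulate_expression,
)
from compscan.tracks import SignalTrack

from conftest import make_track

PARAMS = EnrichmentParams()


class TestInputFlooring:
    """The four flooring cases of the ratio rule, on 10-point tracks."""

    def test_input_above_mean_used_directly(self):
        # input mean 4; where input is 6 (>= mean) the raw value divides
        ip = make_track([8.0] * 10)
        inp = make_track([2.0, 6.0] * 5)
        r = enrichment_ratio(ip, inp, PARAMS).values("X")
        assert r[1] == pytest.approx(np.log2(8 / 6))

    def test_input_below_mean_floored_to_mean(self):
        ip = make_track([8.0] * 10)
        inp = make_track([2.0, 6.0] * 5)  # mean 4
        r = enrichment_ratio(ip, inp, PARAMS).values("X")
        assert r[0] == pytest.approx(np.log2(8 / 4))  # 2 -> floored to mean 4

    def test_mean_below_four_floor_is_four(self):
        ip = make_track([4.0] * 10)
        inp = make_track([2.0, 4.0] * 5)  # mean 3 < 4 -> floor 4
        r = enrichment_ratio(ip, inp, PARAMS).values("X")
        assert r[0] == pytest.approx(0.0)  # log2(4/4)
        assert r[1] == pytest.approx(0.0)

    def test_zero_ip_positions_have_no_ratio(self):
        ip = make_track([0.0, 8.0] * 5)
        inp = make_track([4.0] * 10)
        r = enrichment_ratio(ip, inp, PARAMS).values("X")
        assert np.isnan(r[0]) and not np.isnan(r[1])

    def test_grid_mismatch_rejected(self):
        from compscan.tracks import TrackError

        with pytest.raises(TrackError):
            enrichment_ratio(make_track([1] * 5), make_track([1] * 6), PARAMS)


class TestMedianCenter:
    def test_simple_values(self):
        out = median_center(make_track([1.0, 2.0, 3.0])).values("X")
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_idempotent_on_centered_track(self):
        t = make_track([-1.0, 0.0, 1.0])
        out = median_center(t).values("X")
        np.testing.assert_allclose(out, t.values("X"))

    def test_shift_invariance(self):
        vals = np.array([0.5, 1.5, -2.0, 3.0, 0.0])
        a = median_center(make_track(vals)).values("X")
        b = median_center(make_track(vals + 7.3)).values("X")
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSmoothRatio:
    def test_sparse_window_discarded(self):
        # 9 points in every 200 bp window -> all discarded
        arr = np.full(60, np.nan)
        arr[:9] = 1.0
        out = smooth_ratio(make_track(arr), PARAMS).values("X")
        assert np.isnan(out).all()

    def test_ten_points_retained(self):
        arr = np.full(60, np.nan)
        arr[:10] = 1.0
        out = smooth_ratio(make_track(arr), PARAMS).values("X")
        assert out[4] == 1.0  # centered window covering all ten points

    def test_dense_constant_unchanged(self):
        arr = np.full(50, 2.5)
        out = smooth_ratio(make_track(arr), PARAMS).values("X")
        inner = out[10:-10]
        assert np.all(inner == 2.5)


class TestGeneBindingValue:
    def _gene_with_values(self, values):
        n = len(values)
        # one exon starting at 200 past a 200 bp excluded stub
        g = GeneModel("g", "X", 0, 200 + 10 * n, "+", ((0, 200 + 10 * n),))
        arr = np.full(20 + n, np.nan)
        arr[20:] = values
        return g, make_track(arr)

    def test_top_half_mean_of_twenty(self):
        g, t = self._gene_with_values(np.arange(1.0, 21.0))
        bv = gene_binding_value(g, t, PARAMS)
        assert bv.qualified and bv.value == pytest.approx(15.5)

    def test_nine_points_unqualified(self):
        g, t = self._gene_with_values(np.arange(1.0, 10.0))
        bv = gene_binding_value(g, t, PARAMS)
        assert not bv.qualified and np.isnan(bv.value) and bv.n_points == 9

    def test_odd_count_uses_ceiling(self):
        g, t = self._gene_with_values(np.arange(1.0, 12.0))
        bv = gene_binding_value(g, t, PARAMS)
        assert bv.value == pytest.approx(8.5)  # mean of {6..11}


class TestClassifyBinding:
    def _values_frame(self, x_values, ref_values):
        rows = [(f"x{i}", "X", v, 50, True) for i, v in enumerate(x_values)]
        rows += [(f"r{i}", "3L", v, 50, True) for i, v in enumerate(ref_values)]
        return pd.DataFrame(
            rows, columns=["gene_id", "arm", "value", "n_points", "qualified"]
        ).set_index("gene_id")

    def _annotation(self, frame):
        ann = GenomeAnnotation(arms={"X": 10**6, "3L": 10**6})
        for i, gid in enumerate(frame.index):
            arm = frame.loc[gid, "arm"]
            s = 1000 * (i + 1)
            ann.add(GeneModel(gid, arm, s, s + 500, "+", ((s, s + 500),)))
        return ann

    def test_published_cutoff_parameters(self):
        # reference mean 1.00, SD 0.48 -> cutoff 1.48; 1.50 is bound
        ref = [1.0 - 0.48, 1.0, 1.0 + 0.48, 1.0 - 0.48 * 3**0.5 * 0 + 1.0]
        # construct a reference arm with mean 1.0, sample SD 0.48 exactly
        ref = [1.0 - 0.48, 1.0 - 0.48, 1.0 + 0.48, 1.0 + 0.48]
        sd = float(np.std(ref, ddof=1))
        frame = self._values_frame([1.50, 1.0 + sd, 0.2], ref)
        calls, reference = classify_binding(frame, self._annotation(frame), "3L")
        assert reference.mean == pytest.approx(1.0)
        assert calls.loc["x0", "bound"] == (1.50 > reference.cutoff)

    def test_value_at_cutoff_is_unbound(self):
        frame = self._values_frame([1.48], [0.52, 1.0, 1.48])
        calls, reference = classify_binding(frame, self._annotation(frame), "3L")
        assert calls.loc["x0", "value"] == pytest.approx(reference.cutoff)
        assert not calls.loc["x0", "bound"]

    @pytest.mark.parametrize(
        "value,expected", [(3.5, "(3,4]"), (6.2, "(5,inf)"), (4.5, "(4,5]"), (2.0, "unassigned")]
    )
    def test_bin_assignment(self, value, expected):
        assert assign_bin(value, bound=True) == expected

    def test_unbound_bin(self):
        assert assign_bin(5.0, bound=False) == "Unbound"

    def test_insufficient_reference_errors(self):
        frame = self._values_frame([1.0], [1.0])
        with pytest.raises(ValueError, match="reference arm"):
            classify_binding(frame, self._annotation(frame), "3L")


class TestPipelineProperties:
    @pytest.fixture(scope="class")
    @staticmethod
    def study_tracks():
        cfg = SimulationConfig(
            seed=23, arms=[("X", 600_000), ("3L", 600_000)], genes_per_arm=60
        )
        ann = simulate_annotation(cfg)
        _, truth = simulate_expression(cfg, ann)
        bound = choose_bound_genes(cfg, truth)
        ip, im, _, folds = simulate_chip_tracks(cfg, ann, bound)
        return cfg, ann, bound, ip, im, folds

    def test_null_tracks_give_zero_mean_ratio(self):
        cfg = SimulationConfig(
            seed=5, arms=[("X", 300_000), ("3L", 300_000)], genes_per_arm=20,
            promoter_signal_fold=1.0,
        )
        ann = simulate_annotation(cfg)
        ip, im, _, _ = simulate_chip_tracks(cfg, ann, set())
        ratio = enrichment_pipeline(ip, im)
        assert abs(np.nanmean(ratio.all_values())) < 0.05

    def test_depth_robustness(self, study_tracks):
        cfg, ann, bound, ip, im, folds = study_tracks
        ratio1 = enrichment_pipeline(ip, im)
        v1 = gene_binding_values(ann, ratio1)
        ip3 = ip.map(lambda v: v * 3)
        im3 = im.map(lambda v: v * 3)
        v3 = gene_binding_values(ann, enrichment_pipeline(ip3, im3))
        q = v1["qualified"] & v3["qualified"]
        dv = (v1.loc[q, "value"] - v3.loc[q, "value"]).abs()
        assert dv.max() < 0.1

    def test_binding_value_tracks_true_fold(self, study_tracks):
        from scipy.stats import spearmanr

        cfg, ann, bound, ip, im, folds = study_tracks
        values = gene_binding_values(ann, enrichment_pipeline(ip, im))
        x = values[(values["arm"] == "X") & values["qualified"]]
        rho = spearmanr(folds.reindex(x.index), x["value"]).statistic
        assert rho > 0.9

    def test_promoter_signal_leaves_large_gene_values_unchanged(self):
        # deterministic expectation tracks isolate the promoter effect:
        # identical IP except promoter windows on autosomes
        cfg = SimulationConfig(
            seed=9, arms=[("3L", 400_000)], genes_per_arm=40,
        )
        ann = simulate_annotation(cfg)
        depth = 10.0
        n = 400_000
        base = np.full(n, depth)
        with_prom = base.copy()
        for g in ann.on_arm("3L"):
            a, b = max(g.tss - 200, 0), min(g.tss + 200, n)
            with_prom[a:b] *= 4.0
        inp = SignalTrack(1, {"3L": np.full(n, depth)})
        v0 = gene_binding_values(ann, enrichment_pipeline(SignalTrack(1, {"3L": base}), inp))
        v1 = gene_binding_values(ann, enrichment_pipeline(SignalTrack(1, {"3L": with_prom}), inp))
        q = v0["qualified"] & (v0["n_points"] >= 40)
        dv = (v1.loc[q, "value"] - v0.loc[q, "value"]).abs()
        assert dv.max() < 0.05
        # and the typical (median) gene is untouched regardless of size
        dq = (v1.loc[v0["qualified"], "value"] - v0.loc[v0["qualified"], "value"]).abs()
        assert dq.median() < 0.01
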