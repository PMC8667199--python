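import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajectome.chip import (
    ChipError,
    depth_normalize,
    diff_loglr,
    flag_strong_enrichment,
    promoter_coverage,
    rank_promoters,
    score_promoters,
    select_top_k,
)
from trajectome.io import PileupTrack
from trajectome.simulate import default_chip_samples, simulate_counts, simulate_pileups


def _track(rows, label="t"):
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return PileupTrack(intervals=iv, label=label)


def _gene_meta(rows):
    df = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand", "length"])
    return df.set_index("gene")


class TestPromoterCoverage:
    def test_manual_interval_arithmetic(self):
        # window [100, 300): 50 bp of value 2 + 150 bp of value 4 -> 3.5
        track = _track([("chr1", 0, 150, 2.0), ("chr1", 150, 400, 4.0)])
        gm = _gene_meta([("g1", "chr1", 200, "+", 1000)])
        cov = promoter_coverage(track, gm, flank=100)
        assert cov["g1"] == pytest.approx((50 * 2 + 150 * 4) / 200)

    def test_empty_track_zero(self):
        track = _track([])
        gm = _gene_meta([("g1", "chr1", 200, "+", 1000)])
        with pytest.warns(UserWarning, match="absent"):
            cov = promoter_coverage(track, gm, flank=100)
        assert cov["g1"] == 0.0

    def test_window_inside_single_interval(self):
        track = _track([("chr1", 0, 10_000, 7.25)])
        gm = _gene_meta([("g1", "chr1", 5000, "-", 1000)])
        assert promoter_coverage(track, gm, flank=500)["g1"] == pytest.approx(7.25)

    def test_partial_overlap_at_edges(self):
        track = _track([("chr1", 150, 250, 3.0)])
        gm = _gene_meta([("g1", "chr1", 200, "+", 1000)])
        # window [100, 300): only 100 bp covered at 3.0
        assert promoter_coverage(track, gm, flank=100)["g1"] == pytest.approx(1.5)

    def test_bad_flank(self):
        gm = _gene_meta([("g1", "chr1", 200, "+", 1000)])
        with pytest.raises(ChipError):
            promoter_coverage(_track([]), gm, flank=0)


class TestDepthNormalize:
    def test_arithmetic(self):
        cov = pd.DataFrame({"s1": [3.5]}, index=["g1"])
        out = depth_normalize(cov, pd.Series({"s1": 7e6}))
        assert out.loc["g1", "s1"] == pytest.approx(0.5)

    def test_whole_track_scaling_invariance(self):
        cov = pd.DataFrame({"s1": [1.0, 2.0, 3.0]})
        a = depth_normalize(cov, pd.Series({"s1": 100.0}))
        b = depth_normalize(cov * 2, pd.Series({"s1": 200.0}))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_error(self):
        cov = pd.DataFrame({"s1": [1.0]})
        with pytest.raises(ChipError):
            depth_normalize(cov, pd.Series({"s1": 0.0}))


class TestRanks:
    def test_basic(self):
        out = rank_promoters(pd.DataFrame({"s": [5.0, 1.0, 9.0]}))
        assert list(out["s"]) == [2.0, 1.0, 3.0]

    def test_tie_averaging(self):
        out = rank_promoters(pd.DataFrame({"s": [4.0, 4.0]}))
        assert list(out["s"]) == [1.5, 1.5]

    def test_too_few_promoters(self):
        with pytest.raises(ChipError):
            rank_promoters(pd.DataFrame({"s": [1.0]}))

    @given(st.lists(st.integers(min_value=0, max_value=10**6),
                    min_size=2, max_size=30, unique=True),
           st.sampled_from(["exp", "affine", "cube"]))
    @settings(max_examples=60, deadline=None)
    def test_monotone_transform_invariance(self, ints, fn):
        vals = [float(v) for v in ints]
        transforms = {
            "exp": lambda x: np.expm1(x / 1e6),
            "affine": lambda x: 3.0 * x + 7.0,
            "cube": lambda x: x ** 3,
        }
        a = rank_promoters(pd.DataFrame({"s": vals}))
        b = rank_promoters(pd.DataFrame({"s": transforms[fn](np.array(vals))}))
        pd.testing.assert_frame_equal(a, b)


class TestDiffLoglr:
    def test_zero_at_equality(self):
        assert diff_loglr(5.0, 5.0, pseudo=0.0) == 0.0

    def test_closed_form(self):
        expected = (20 * math.log(20 / 15) + 10 * math.log(10 / 15)) / math.log(10)
        got = diff_loglr(20.0, 10.0, pseudo=0.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.738, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0, 100, 100), rng.uniform(0, 100, 100)
        np.testing.assert_allclose(
            diff_loglr(x, y, 1.0), -diff_loglr(y, x, 1.0), atol=1e-12
        )

    def test_sign_matches_difference(self):
        assert diff_loglr(3.0, 1.0) > 0 > diff_loglr(1.0, 3.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ChipError):
            diff_loglr(-1.0, 2.0)


class TestFlagAndTopK:
    def _table(self, scores, rank_tbi=None, rank_sham=None):
        n = len(scores)
        idx = [f"g{i:03d}" for i in range(n)]
        return pd.DataFrame(
            {
                "score": scores,
                "rank_tbi": rank_tbi if rank_tbi is not None else np.linspace(0, 1, n),
                "rank_sham": rank_sham if rank_sham is not None else np.linspace(0, 1, n),
            },
            index=idx,
        )

    def test_flag_low_sham_high_tbi(self):
        t = self._table([1.0, 0.0], rank_tbi=[0.95, 0.5], rank_sham=[0.05, 0.5])
        flags = flag_strong_enrichment(t)
        assert list(flags) == [True, False]

    def test_flag_quantile_validation(self):
        with pytest.raises(ChipError):
            flag_strong_enrichment(self._table([0.0, 0.0]), sham_max_quantile=0.0)

    def test_top_k_basic(self):
        t = self._table([3.0, 1.0, -2.0])
        up, down = select_top_k(t, k=1)
        assert up == ["g000"] and down == ["g002"]

    def test_k_zero(self):
        up, down = select_top_k(self._table([1.0, -1.0]), k=0)
        assert up == [] and down == []

    def test_tie_break_lexicographic_and_deterministic(self):
        t = self._table([2.0, 2.0, 2.0, -1.0])
        runs = {tuple(select_top_k(t, k=2)[0]) for _ in range(5)}
        assert runs == {("g000", "g001")}

    def test_fewer_than_k_warns(self):
        with pytest.warns(UserWarning, match="fewer"):
            up, down = select_top_k(self._table([1.0, -1.0]), k=5)
        assert up == ["g000"] and down == ["g001"]


class TestEndToEnd:
    def _setup(self, noise=0.0, sensitivity=None, chip_shift=None, seed=8):
        cm, truth = simulate_counts(
            300, module_fractions={"iv": 0.1, "v": 0.1}, effect_scale=2.0,
            seed=seed, chip_shift=chip_shift,
        )
        cs = default_chip_samples("day1")
        tracks = simulate_pileups(
            truth, cm.gene_meta, cs, noise=noise,
            sensitivity=sensitivity, seed=seed + 1,
        )
        return cm, truth, cs, tracks

    def test_no_shift_no_noise_all_scores_zero(self):
        cm, truth, cs, tracks = self._setup()
        tbl = score_promoters(tracks, cs, cm.gene_meta)
        np.testing.assert_allclose(tbl["score"], 0.0, atol=1e-12)

    def test_sample_scaling_changes_nothing(self):
        """x c on one sample's pileup: ranks identical, scores identical."""
        cm, truth, cs, tracks = self._setup(
            chip_shift={"iv": (3.0, 1.0), "v": (0.4, 1.0)}
        )
        tbl = score_promoters(tracks, cs, cm.gene_meta)
        scaled = dict(tracks)
        key = next(iter(scaled))
        scaled[key] = scaled[key].scaled(7.5)
        tbl2 = score_promoters(scaled, cs, cm.gene_meta)
        np.testing.assert_allclose(tbl["score"], tbl2["score"], rtol=1e-9)
        np.testing.assert_allclose(tbl["rank_tbi"], tbl2["rank_tbi"])
        np.testing.assert_allclose(tbl["rank_sham"], tbl2["rank_sham"])

    def test_null_genes_near_diagonal(self):
        cm, truth, cs, tracks = self._setup(
            chip_shift={"iv": (3.0, 1.0), "v": (0.4, 1.0)}
        )
        tbl = score_promoters(tracks, cs, cm.gene_meta)
        null_genes = truth.genes_in_module("null")
        d = (tbl.loc[null_genes, "rank_tbi"] - tbl.loc[null_genes, "rank_sham"]).abs()
        assert d.median() < 0.05

    def test_shifted_genes_dominate_top_k(self):
        cm, truth, cs, tracks = self._setup(
            chip_shift={"iv": (4.0, 1.0)}, noise=1.0,
        )
        tbl = score_promoters(tracks, cs, cm.gene_meta)
        up, _ = select_top_k(tbl, k=30)
        planted = set(truth.genes_in_module("iv"))
        assert len(planted & set(up)) >= 0.8 * min(len(planted), 30)

    def test_strong_flag_recovery(self):
        """50 genes with near-zero sham signal and huge injury signal are
        exactly the flagged set at the default quantile box (0.2, 0.8)."""
        cm, truth = simulate_counts(300, module_fractions={}, seed=17)
        planted = list(truth.table.index[:50])
        truth.table.loc[planted, "base_mean"] = 0.05      # sham ~ undetectable
        truth.table.loc[planted, "chip_shift_day1"] = 5000.0
        cs = default_chip_samples("day1")
        tracks = simulate_pileups(truth, cm.gene_meta, cs, noise=0.0, seed=18)
        tbl = score_promoters(tracks, cs, cm.gene_meta)
        flags = flag_strong_enrichment(tbl)
        assert set(tbl.index[flags]) == set(planted)
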