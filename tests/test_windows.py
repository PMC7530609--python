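"""Window comparisons: subtraction, rank tests, region and boundary summaries,
spreading detection, per-gene signal, and concordance QC."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromsink as cs
from chromsink.windows import boundary_profile_frame, summarize_regions

from conftest import make_track


# ---------------------------------------------------------------------------
# subtraction tracks
# ---------------------------------------------------------------------------

class TestSubtraction:
    def test_self_subtraction_is_zero(self):
        a = make_track([1.0, 2.0, -0.5])
        np.testing.assert_array_equal(cs.subtraction_track(a, a).values, 0.0)

    def test_constant_offset(self):
        a = make_track([1.5, 2.5, 3.5])
        b = make_track([1.0, 2.0, 3.0])
        np.testing.assert_allclose(cs.subtraction_track(a, b).values, 0.5)
        np.testing.assert_allclose(cs.subtraction_track(a, b, absolute=True).values, 0.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = make_track(rng.standard_normal(20))
        b = make_track(rng.standard_normal(20))
        np.testing.assert_allclose(cs.subtraction_track(a, b).values,
                                   -cs.subtraction_track(b, a).values)

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical windows"):
            cs.subtraction_track(make_track([1.0]), make_track([1.0, 2.0]))

    def test_sink_fixture_difference_localizes_to_heterochromatin(self, genome):
        """X0-like minus XYY-like: positive in pericentromeres, ~0 in euchromatin."""
        sink = cs.SinkModel(spreading_bp_per_unit_deficit=0.0)
        tracks = {}
        for k in (cs.X0, cs.XYY):
            e = cs.simulate_chip_experiment(genome, k, sink, noise=False, seed=0)
            f = cs.spike_scaling_ratio(e.chip, e.input)
            sig = cs.window_signal(e.chip, e.input, f, mask=genome.crossmap_mask)
            tracks[k.label] = sig.to_windowtrack(genome.track(np.zeros(genome.n_windows)))
        diff = cs.subtraction_track(tracks["X0"], tracks["XYY"])
        block = genome.windows["block"].to_numpy()
        peri = diff.values[block == "pericentromere"]
        eu = diff.values[block == "euchromatin"]
        assert np.nanmean(peri) > 1.0
        assert abs(np.nanmean(eu)) < 0.05


# ---------------------------------------------------------------------------
# rank-sum test vs exhaustive enumeration
# ---------------------------------------------------------------------------

def exact_mannwhitney_p(x, y):
    """Oracle: enumerate all C(n+m, n) group labelings of the pooled data."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in idx if i not in comb]]
        us.append(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys))
    us = np.array(us)
    m = len(y)
    # two-sided: fold around the null mean n*m/2
    dev = abs(u_obs - n * m / 2)
    return np.mean(np.abs(us - n * m / 2) >= dev - 1e-12)


class TestRankSum:
    def test_textbook_example(self):
        u, p = cs.rank_sum_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = cs.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_for_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 7), rng.integers(2, 9)
        x = rng.permutation(np.arange(n + m, dtype=float))[:n]  # tie-free
        y = np.setdiff1d(np.arange(n + m, dtype=float), x)
        _, p = cs.rank_sum_test(x, y)
        assert p == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)

    def test_eight_vs_eight_matches_full_enumeration(self):
        rng = np.random.default_rng(7)
        vals = rng.permutation(np.arange(16, dtype=float))
        x, y = vals[:8], vals[8:]
        _, p = cs.rank_sum_test(x, y)
        assert p == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6, unique=True),
           st.lists(st.integers(51, 100), min_size=2, max_size=6, unique=True))
    def test_permutation_invariance(self, x, y):
        _, p1 = cs.rank_sum_test(x, y)
        _, p2 = cs.rank_sum_test(list(reversed(x)), list(reversed(y)))
        assert p1 == p2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.rank_sum_test([], [1.0])


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

class TestRegionSummary:
    def test_quartile_convention(self, genome):
        sig = genome.track(np.zeros(genome.n_windows))
        dot = (genome.windows["block"] == "dot").to_numpy()
        vals = np.full(genome.n_windows, np.nan)
        vals[np.flatnonzero(dot)[:5]] = [1, 2, 3, 4, 5]
        rs = cs.region_summary(sig.with_values(vals), genome, "dot")
        assert (rs.q1, rs.median, rs.q3) == (2, 3, 4)
        assert (rs.whisker_lo, rs.whisker_hi) == (1, 5)

    def test_identical_regions_give_p_one(self, genome):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, genome.n_windows)
        sig = genome.track(vals)
        rs = cs.region_summary(sig, genome, "dot", reference_signal=sig,
                               reference_label="self")
        assert rs.p_value == pytest.approx(1.0, abs=0.05)

    def test_planted_shift_detected(self, genome):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 2, genome.n_windows)
        peri = (genome.windows["block"] == "pericentromere").to_numpy()
        assert peri.sum() > 100  # enough windows for a decisive test
        shifted = base.copy()
        shifted[peri] *= 2.0
        rs = cs.region_summary(genome.track(shifted), genome, "pericentromere",
                               reference_signal=genome.track(base), reference_label="ref")
        assert rs.p_value < 1e-6

    def test_empty_region_error_names_region(self, genome):
        with pytest.raises(ValueError, match="nosuch"):
            cs.region_summary(genome.track(np.ones(genome.n_windows)), genome, "nosuch")

    def test_region_can_be_arm_specific(self, genome):
        sig = genome.track(np.arange(genome.n_windows, dtype=float))
        rs_all = cs.region_summary(sig, genome, "pericentromere")
        rs_2l = cs.region_summary(sig, genome, "pericentromere_2L")
        assert rs_2l.n_windows < rs_all.n_windows

    def test_summary_table_has_bh_qvalues(self, genome):
        rng = np.random.default_rng(2)
        sigs = {lab: genome.track(rng.uniform(1, 2, genome.n_windows)) for lab in ("a", "b")}
        frame = summarize_regions(sigs, genome, ["pericentromere", "dot"], {"a": "b"})
        assert {"sample", "region", "p_value", "q_value"} <= set(frame.columns)
        tested = frame["q_value"].notna()
        assert (frame.loc[tested, "q_value"] >= frame.loc[tested, "p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# boundary profiles and spreading
# ---------------------------------------------------------------------------

class TestBoundary:
    def test_flat_signal_no_contrast(self, genome):
        sig = genome.track(np.ones(genome.n_windows))
        prof = cs.boundary_profile(sig, genome, "2L", flank=100_000)
        assert prof.inside_mean == prof.outside_mean == 1.0
        assert prof.p_value == pytest.approx(1.0, abs=0.05)
        contrast, shift = cs.spreading_index(prof)
        assert contrast == 0.0
        assert shift is None

    def test_step_at_boundary(self, genome):
        b = genome.boundaries["2L"]["position"]
        mid = ((genome.windows["start"] + genome.windows["end"]) / 2).to_numpy()
        on_2l = (genome.windows["chrom"] == "2L").to_numpy()
        # het side of 2L is "right": heterochromatin above the boundary
        vals = np.where(on_2l & (mid >= b), 2.0, 1.0)
        prof = cs.boundary_profile(genome.track(vals), genome, "2L", flank=100_000)
        assert prof.inside_mean == 2.0 and prof.outside_mean == 1.0
        assert prof.p_value < 1e-6
        contrast, shift = cs.spreading_index(prof)
        assert contrast == pytest.approx(1 / 3)
        assert shift == pytest.approx(0.0, abs=genome.window_width)

    def test_moved_step_detected_as_spreading(self, genome):
        b = genome.boundaries["2L"]["position"]
        mid = ((genome.windows["start"] + genome.windows["end"]) / 2).to_numpy()
        on_2l = (genome.windows["chrom"] == "2L").to_numpy()
        # het extends 50 kb past the boundary into euchromatin (het side right)
        vals = np.where(on_2l & (mid >= b - 50_000), 2.0, 1.0)
        prof = cs.boundary_profile(genome.track(vals), genome, "2L", flank=100_000)
        _, shift = cs.spreading_index(prof)
        assert shift == pytest.approx(50_000, abs=genome.window_width)

    def test_flank_beyond_arm_warns(self, genome):
        sig = genome.track(np.ones(genome.n_windows))
        with pytest.warns(UserWarning, match="truncated"):
            cs.boundary_profile(sig, genome, "2L", flank=10**7)

    def test_long_format_frame(self, genome):
        sig = genome.track(np.ones(genome.n_windows))
        prof = cs.boundary_profile(sig, genome, "2L", flank=100_000)
        frame = boundary_profile_frame(prof)
        assert set(frame["side"]) == {"heterochromatin", "euchromatin"}
        assert (frame["distance_to_boundary"].abs() <= 100_000).all()


# ---------------------------------------------------------------------------
# per-gene signal
# ---------------------------------------------------------------------------

class TestGeneSignal:
    def test_gene_within_one_window(self):
        sig = make_track([1.0, 3.0], width=100)
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [60], "name": ["g"]})
        out = cs.gene_signal(sig, genes)
        assert out["mean_signal"].iloc[0] == 1.0

    def test_gene_spanning_two_windows_equally(self):
        sig = make_track([1.0, 3.0], width=100)
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150], "name": ["g"]})
        out = cs.gene_signal(sig, genes)
        assert out["mean_signal"].iloc[0] == 2.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 5, 40)
        sig = make_track(vals, width=10)
        per_base = np.repeat(vals, 10)
        genes = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.integers(0, 300, 15),
            "end": 0, "name": [f"g{i}" for i in range(15)],
        })
        genes["end"] = genes["start"] + rng.integers(5, 90, 15)
        out = cs.gene_signal(sig, genes)
        for row, (_, g) in zip(out.itertuples(index=False), genes.iterrows()):
            assert row.mean_signal == pytest.approx(per_base[g["start"]:g["end"]].mean())

    def test_gene_outside_assembly_flagged_not_fatal(self):
        sig = make_track([1.0], width=100)
        genes = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [50], "name": ["g"]})
        out = cs.gene_signal(sig, genes)
        assert bool(out["outside_assembly"].iloc[0])
        assert np.isnan(out["mean_signal"].iloc[0])

    def test_masked_overlap_flagged(self):
        sig = make_track([1.0, 2.0], width=100)
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150], "name": ["g"]})
        out = cs.gene_signal(sig, genes, mask=np.array([False, True]))
        assert bool(out["overlaps_mask"].iloc[0])


# ---------------------------------------------------------------------------
# concordance QC
# ---------------------------------------------------------------------------

class TestConcordance:
    def test_identical_tracks(self):
        a = make_track(np.arange(100, dtype=float))
        r, overlap = cs.qc_concordance(a, a)
        assert r == pytest.approx(1.0)
        assert overlap == 1.0

    def test_reversed_ranks_hit_combinatorial_floor(self):
        vals = np.arange(1000, dtype=float)
        a = make_track(vals)
        b = make_track(-vals)
        r, overlap = cs.qc_concordance(a, b, top_q=0.4)
        assert r == pytest.approx(-1.0)
        # floor max(0, (2q-1)n) / (qn) = 0 at q = 0.4
        assert overlap == 0.0
        # and at q = 0.75 the floor is (0.5 * n) / (0.75 * n) = 2/3
        _, overlap75 = cs.qc_concordance(a, b, top_q=0.75)
        assert overlap75 == pytest.approx(2 / 3, abs=0.01)

    def test_independent_tracks_overlap_near_q(self):
        rng = np.random.default_rng(4)
        a = make_track(rng.standard_normal(5000))
        b = make_track(rng.standard_normal(5000))
        r, overlap = cs.qc_concordance(a, b, top_q=0.4)
        assert abs(r) < 0.05
        assert overlap == pytest.approx(0.4, abs=0.05)

    def test_too_few_windows_rejected(self):
        a = make_track([1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            cs.qc_concordance(a, a)
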