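"""Consensus loop tables, normalisation factors, NB testing, connectivity classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chiatac.differential import (
    classify_connectivity_change,
    consensus_anchors,
    consensus_loop_table,
    merge_anchors,
    nb_test,
    prefilter_loops,
    size_factors_median_ratio,
    tmm_factors,
)
from chiatac.loops import Loop


def mk_loop(a, b, count, chrom="chr1", width=500):
    return Loop(chrom, a, a + width, chrom, b, b + width, pet_count=count)


class TestMergeAnchors:
    def test_overlapping_intervals_merge(self):
        df = pd.DataFrame([("chr1", 100, 200), ("chr1", 150, 250)],
                          columns=["chrom", "start", "end"])
        out = merge_anchors(df)
        assert out.values.tolist() == [["chr1", 100, 250]]

    def test_disjoint_and_touching_stay_separate(self):
        df = pd.DataFrame([("chr1", 100, 200), ("chr1", 200, 300), ("chr1", 400, 500)],
                          columns=["chrom", "start", "end"])
        out = merge_anchors(df)
        assert len(out) == 3  # half-open: touching does not overlap

    @given(
        ivs=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 50)), min_size=1, max_size=30
        )
    )
    def test_idempotent_and_base_preserving(self, ivs):
        df = pd.DataFrame([("chr1", s, s + w) for s, w in ivs],
                          columns=["chrom", "start", "end"])
        once = merge_anchors(df)
        assert merge_anchors(once).values.tolist() == once.values.tolist()
        cover = lambda d: {b for r in d.itertuples() for b in range(r.start, r.end)}
        assert cover(once) == cover(df)
        starts = once.start.to_numpy()
        ends = once.end.to_numpy()
        assert (starts[1:] >= ends[:-1]).all()  # non-overlapping, sorted


class TestConsensusTable:
    def test_shared_loop_one_row_two_columns(self):
        sets = {
            "lib1": [mk_loop(1000, 50_000, 12)],
            "lib2": [mk_loop(1200, 50_200, 15)],
        }
        table = consensus_loop_table(sets)
        assert len(table.counts) == 1
        assert table.counts.iloc[0].tolist() == [12, 15]

    def test_absent_loop_filled_with_zero(self):
        sets = {
            "lib1": [mk_loop(1000, 50_000, 12), mk_loop(200_000, 400_000, 20)],
            "lib2": [mk_loop(1000, 50_000, 11)],
        }
        table = consensus_loop_table(sets)
        col2 = table.counts["lib2"]
        assert sorted(col2.tolist()) == [0, 11]

    def test_column_sums_conserve_per_library_pets(self):
        rng = np.random.default_rng(5)
        sets = {}
        for lib in ("a", "b", "c"):
            loops = [mk_loop(int(s), int(s) + 20_000 + int(d), int(n))
                     for s, d, n in zip(rng.integers(0, 500_000, 40),
                                        rng.integers(0, 100_000, 40),
                                        rng.integers(11, 60, 40))]
            sets[lib] = loops
        table = consensus_loop_table(sets)
        for lib, loops in sets.items():
            assert table.counts[lib].sum() == sum(l.pet_count for l in loops)

    def test_self_loop_after_merge_dropped_with_warning(self):
        # the two anchors of lib2's loop merge into one region via lib1's anchors
        sets = {
            "lib1": [mk_loop(1000, 1800, 12, width=900)],
            "lib2": [mk_loop(1100, 2000, 15, width=600)],
        }
        with pytest.warns(UserWarning):
            table = consensus_loop_table(sets)
        assert table.counts.empty or table.counts["lib2"].sum() == 0

    def test_prefilter_is_strictly_greater_than_ten(self):
        loops = [mk_loop(0, 20_000, 10), mk_loop(0, 30_000, 11)]
        assert [l.pet_count for l in prefilter_loops(loops)] == [11]

    def test_anchor_merge_idempotence_via_consensus(self):
        sets = {"lib1": [mk_loop(1000, 50_000, 12), mk_loop(1400, 50_100, 12)]}
        anchors = consensus_anchors(sets)
        again = merge_anchors(anchors)
        assert anchors.values.tolist() == again.values.tolist()


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [40], [25]], (1, 4)))
        assert np.allclose(size_factors_median_ratio(counts), 1.0)

    def test_doubled_library_factor_ratio_two(self):
        base = np.array([10, 40, 25, 70, 15], dtype=float)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = size_factors_median_ratio(counts)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_matches_textbook_median_of_ratios(self):
        rng = np.random.default_rng(6)
        x = rng.integers(1, 500, size=(60, 5)).astype(float)
        got = size_factors_median_ratio(pd.DataFrame(x))
        # independent computation straight from the definition
        log_gm = np.exp(np.mean(np.log(x), axis=1))
        want = [float(np.median(x[:, j] / log_gm)) for j in range(5)]
        assert np.allclose(got, want, atol=1e-10)

    def test_no_all_positive_row_rejected(self):
        counts = pd.DataFrame([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            size_factors_median_ratio(counts)


def tmm_oracle(x, ls, trim_m=0.30, trim_a=0.05):
    """Independent TMM: plain-python double trim + precision-weighted mean."""
    n_lib = x.shape[1]
    frac = x / ls
    uq = [np.quantile(frac[:, j][x[:, j] > 0], 0.75) for j in range(n_lib)]
    ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
    logf = []
    for j in range(n_lib):
        if j == ref:
            logf.append(0.0)
            continue
        rows = [i for i in range(x.shape[0]) if x[i, j] > 0 and x[i, ref] > 0]
        m = [np.log2((x[i, j] / ls[j]) / (x[i, ref] / ls[ref])) for i in rows]
        a = [0.5 * np.log2((x[i, j] / ls[j]) * (x[i, ref] / ls[ref])) for i in rows]
        w = [1.0 / ((ls[j] - x[i, j]) / (ls[j] * x[i, j])
                    + (ls[ref] - x[i, ref]) / (ls[ref] * x[i, ref])) for i in rows]
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = [k for k in range(len(rows))
                if m_lo <= m[k] <= m_hi and a_lo <= a[k] <= a_hi]
        num = sum(w[k] * m[k] for k in keep)
        den = sum(w[k] for k in keep)
        logf.append(num / den)
    f = 2.0 ** np.array(logf)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        counts = pd.DataFrame(np.tile([[30], [80], [10], [55]], (1, 3)))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_factors_have_geometric_mean_one(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(1, 400, size=(80, 4)))
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 600, size=(100, 5)).astype(float)
        ls = x.sum(axis=0)
        assert np.allclose(tmm_factors(pd.DataFrame(x)), tmm_oracle(x, ls), atol=1e-10)

    def test_recovers_threefold_library_size(self):
        """Effective normalisation (factor x libsize) recovers a 3x depth ratio."""
        rng = np.random.default_rng(9)
        mu = rng.gamma(2, 25, size=2000)
        depth = np.array([1.0, 3.0, 1.0, 3.0])
        counts = np.vstack(
            [rng.negative_binomial(10, 1 / (1 + 0.1 * mu * d)) for d in depth]
        ).T
        f = tmm_factors(pd.DataFrame(counts))
        eff = f * counts.sum(axis=0)
        assert eff[1] / eff[0] == pytest.approx(3.0, rel=0.05)
        assert eff[3] / eff[2] == pytest.approx(3.0, rel=0.05)


def null_counts(rng, n=2000, mean=50.0, disp=0.1, libs=4):
    return pd.DataFrame(
        rng.negative_binomial(1 / disp, 1 / (1 + disp * mean), size=(libs, n)).T,
        columns=[f"lib{j}" for j in range(libs)],
    )


class TestNBTest:
    def test_all_zero_feature_untested(self):
        counts = pd.DataFrame([[0, 0, 0, 0], [10, 12, 50, 45]], index=["z", "f"])
        res = nb_test(counts, ["A", "A", "B", "B"])
        assert res.untested == ["z"]
        assert res.table.set_index("feature_id").loc["z", "call"] == "untested"

    def test_label_swap_negates_log2fc(self):
        rng = np.random.default_rng(10)
        counts = null_counts(rng, n=300)
        fwd = nb_test(counts, ["A", "A", "B", "B"])
        rev = nb_test(counts, ["B", "B", "A", "A"])
        assert np.allclose(fwd.table.log2fc, -rev.table.log2fc)
        assert np.allclose(fwd.table.q.dropna(), rev.table.q.dropna())

    def test_calls_invariant_under_global_depth_rescaling(self):
        """Size factors absorb a 5x depth change: identical calls, near-identical
        fold changes (the 0.5 reporting pseudocount leaves a sub-0.02 residual
        because median-of-ratios normalised counts rescale by 5^(1/4))."""
        rng = np.random.default_rng(11)
        counts = null_counts(rng, n=500)
        scaled = counts.copy()
        scaled["lib2"] = counts["lib2"] * 5
        a = nb_test(counts, ["A", "A", "B", "B"])
        b = nb_test(scaled, ["A", "A", "B", "B"])
        assert np.allclose(a.table.log2fc, b.table.log2fc, atol=0.02)
        assert (a.table.call == b.table.call).all()

    def test_null_false_call_rate_controlled(self):
        rng = np.random.default_rng(12)
        res = nb_test(null_counts(rng), ["A", "A", "B", "B"])
        assert res.table.call.isin(["up", "down"]).mean() <= 0.05

    def test_planted_fourfold_effects_detected(self):
        """Mean power >= 80% for 4-fold effects with the low side at mean 50,
        2 vs 2 (averaged over three simulations to damp binomial noise)."""
        n, n_de, disp = 2000, 500, 0.1
        powers, fprs = [], []
        for seed in (13, 14, 15):
            rng = np.random.default_rng(seed)
            mu_a = np.full(n, 50.0)
            mu_b = np.full(n, 50.0)
            mu_b[: n_de // 2] = 200.0
            mu_a[n_de // 2 : n_de] = 200.0
            a = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu_a), size=(2, n))
            b = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu_b), size=(2, n))
            counts = pd.DataFrame(np.vstack([a, b]).T, columns=["a1", "a2", "b1", "b2"])
            calls = nb_test(counts, ["A", "A", "B", "B"]).table.call
            powers.append(
                ((calls.iloc[: n_de // 2] == "up").sum()
                 + (calls.iloc[n_de // 2 : n_de] == "down").sum()) / n_de
            )
            fprs.append(calls.iloc[n_de:].isin(["up", "down"]).mean())
        assert np.mean(powers) >= 0.80
        assert np.mean(fprs) <= 0.05


class TestConnectivityChange:
    def _diff(self, calls):
        table = pd.DataFrame(
            dict(feature_id=[f"p{i}" for i in range(len(calls))],
                 base_mean=1.0, log2fc=0.0, dispersion=0.1, p=0.5, q=0.5, call=calls)
        )
        from chiatac.differential import DifferentialResult

        return DifferentialResult(table=table)

    def test_classification_rules_and_tie(self):
        diff = self._diff(["up", "up", "down"])
        conn = pd.DataFrame({"rest": [10, 10, 10], "stim": [30, 20, 2]})
        classes, summary = classify_connectivity_change(
            diff, conn, {"rest": 1.0, "stim": 2.0}
        )
        assert classes.tolist() == ["increased", "unchanged", "decreased"]
        assert summary["frac_up_with_increased_connectivity"] == 0.5
        assert summary["frac_down_with_decreased_connectivity"] == 1.0

    def test_coupled_simulation_fraction_recovered(self):
        """Accessibility-up peaks gain connectivity at rate 0.9 +/- 3 sigma."""
        rng = np.random.default_rng(14)
        n = 600
        diff = self._diff(["up"] * n)
        gain = rng.random(n) < 0.9
        base = rng.integers(20, 60, n).astype(float)
        stim = np.where(gain, base * 2.0, base * 0.5)
        classes, summary = classify_connectivity_change(
            diff, pd.DataFrame({"rest": base, "stim": stim}), {"rest": 1.0, "stim": 1.0}
        )
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert abs(summary["frac_up_with_increased_connectivity"] - 0.9) < 3 * sigma

    def test_mismatched_rows_rejected(self):
        diff = self._diff(["up", "down"])
        with pytest.raises(ValueError):
            classify_connectivity_change(
                diff, pd.DataFrame({"rest": [1], "stim": [2]}), {"rest": 1, "stim": 1}
            )
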