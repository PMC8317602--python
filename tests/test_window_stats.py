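"""Window assignment, Weir-Cockerham F_ST, pooled heterozygosity and
top-quantile selection, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import poolsweep as ps
from poolsweep.errors import ConfigError, DegenerateError
from poolsweep.window_stats import WindowKey

from conftest import CANDIDATE_TABLE


def anova_fst_from_arrays(k1, n1, k2, n2):
    """Two-level ANOVA oracle: build explicit haploid 0/1 samples and
    derive the F estimate from raw sums of squares, independently of the
    closed-form mean-square expressions."""
    y1 = np.concatenate([np.ones(k1), np.zeros(n1 - k1)])
    y2 = np.concatenate([np.ones(k2), np.zeros(n2 - k2)])
    y = np.concatenate([y1, y2])
    ssb = n1 * (y1.mean() - y.mean()) ** 2 + n2 * (y2.mean() - y.mean()) ** 2
    msb = ssb / (2 - 1)
    ssw = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
    msw = ssw / (n1 + n2 - 2)
    nc = 2 * n1 * n2 / (n1 + n2)
    return (msb - msw) / (msb + (nc - 1) * msw)


class TestAssignWindows:
    def test_boundary_positions(self):
        rows = [ps.VariantRecord("chr1", 25_000, "A", "G", 50.0, 1, 1, 1, 1),
                ps.VariantRecord("chr1", 25_001, "A", "G", 50.0, 1, 1, 1, 1)]
        windows = ps.assign_windows(ps.records_frame(rows))
        assert set(windows) == {WindowKey("chr1", 0, 25_000),
                                WindowKey("chr1", 25_000, 50_000)}

    def test_empty_input_yields_no_windows(self):
        empty = ps.records_frame([]).reindex(columns=ps.variant_io.VARIANT_COLUMNS)
        assert ps.assign_windows(empty) == {}

    def test_random_positions_partition_exactly(self):
        rng = np.random.default_rng(5)
        pos = rng.integers(1, 500_000, size=1000)
        rows = [ps.VariantRecord("chr1", int(p), "A", "G", 50.0, 1, 1, 1, 1)
                for p in np.sort(pos)]
        windows = ps.assign_windows(ps.records_frame(rows))
        assert sum(len(g) for g in windows.values()) == 1000
        for key, grp in windows.items():
            assert ((grp["pos"] > key.start) & (grp["pos"] <= key.end)).all()


class TestSiteFst:
    def test_fixed_difference_is_one(self):
        msp, msg, nc = ps.site_fst_components(1.0, 0.0, 70, 118)
        assert msg == 0
        assert ps.site_fst(1.0, 0.0, 70, 118) == 1.0

    def test_equal_frequencies_equal_pools(self):
        n = 50
        assert ps.site_fst(0.4, 0.4, n, n) == pytest.approx(-1 / (n - 1))

    def test_matches_anova_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1, n2 = int(rng.integers(4, 200)), int(rng.integers(4, 200))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if k1 * (n1 - k1) + k2 * (n2 - k2) == 0 and k1 / n1 == k2 / n2:
                continue  # denominator degenerate
            ours = ps.site_fst(k1 / n1, k2 / n2, n1, n2)
            oracle = anova_fst_from_arrays(k1, n1, k2, n2)
            assert abs(ours - oracle) < 1e-10

    def test_stated_example_against_mean_squares_route(self):
        """n1=70, n2=118, p1=0.8, p2=0.3 via the ANOVA SS/MS route written
        out longhand (p(1-p) as the within-group variance of 0/1 data)."""
        n1, n2, p1, p2 = 70, 118, 0.8, 0.3
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        msb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
        nc = 2 * n1 * n2 / (n1 + n2)
        expected = (msb - msw) / (msb + (nc - 1) * msw)
        assert ps.site_fst(p1, p2, n1, n2) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(DegenerateError):
            ps.site_fst_components(0.5, 0.5, 1, 1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1),
           st.integers(3, 500), st.integers(3, 500))
    def test_both_algebraic_forms_agree(self, p1, p2, n1, n2):
        msp, msg, nc = ps.site_fst_components(p1, p2, n1, n2)
        denom = msp + (nc - 1) * msg
        if denom <= 1e-12:
            return
        direct = (msp - msg) / denom
        published_form = 1 - nc * msg / denom
        assert direct == pytest.approx(published_form, abs=1e-12)


def _window_records(counts, start_pos=1, chrom="chr1"):
    """counts: list of (ref1, alt1, ref2, alt2)."""
    rows = [ps.VariantRecord(chrom, start_pos + i, "A", "G", 50.0, *c)
            for i, c in enumerate(counts)]
    return ps.records_frame(rows)


EQUAL_POOLS = (ps.PoolSpec(10), ps.PoolSpec(10))
STUDY_POOLS = (ps.PoolSpec(35), ps.PoolSpec(59))
ONE_SNP = ps.WindowingConfig(min_snps=1)


class TestWindowFst:
    def test_identical_frequencies_give_negative_floor(self):
        records = _window_records([(6, 4, 6, 4)] * 12)
        out = ps.window_fst(records, EQUAL_POOLS, ONE_SNP)
        n = EQUAL_POOLS[0].n_haploid
        assert out["fst"].iloc[0] == pytest.approx(-1 / (n - 1))

    def test_modes_agree_on_single_snp(self):
        records = _window_records([(30, 10, 10, 30)])
        a = ps.window_fst(records, STUDY_POOLS, ONE_SNP, mode="ratio-of-sums")
        b = ps.window_fst(records, STUDY_POOLS, ONE_SNP, mode="mean-of-ratios")
        assert a["fst"].iloc[0] == pytest.approx(b["fst"].iloc[0])
        assert a["fst"].iloc[0] == pytest.approx(
            float(ps.site_fst(10 / 40, 30 / 40, 70, 118)))

    def test_ratio_of_sums_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = [tuple(int(x) for x in rng.integers(1, 40, size=4))
                  for _ in range(20)]
        records = _window_records(counts)
        out = ps.window_fst(records, STUDY_POOLS, ONE_SNP)
        num = den = 0.0
        for r1, a1, r2, a2 in counts:
            p1, p2 = a1 / (r1 + a1), a2 / (r2 + a2)
            msp, msg, nc = ps.site_fst_components(p1, p2, 70, 118)
            num += msp - msg
            den += msp + (nc - 1) * msg
        assert out["fst"].iloc[0] == pytest.approx(num / den, abs=1e-12)

    def test_sparse_windows_dropped_not_zeroed(self):
        records = _window_records([(6, 4, 6, 4)] * 5)
        out = ps.window_fst(records, EQUAL_POOLS, ps.WindowingConfig(min_snps=10))
        assert out.empty

    def test_record_order_irrelevant(self, small_dataset):
        records = small_dataset["retained"]
        shuffled = records.sample(frac=1, random_state=1).reset_index(drop=True)
        config = small_dataset["config"]
        a = ps.window_fst(records, config.pools)
        b = ps.window_fst(shuffled, config.pools)
        pd.testing.assert_frame_equal(a, b)


class TestWindowHp:
    @pytest.mark.parametrize("counts,expected", [
        ([(20, 20, 1, 1)] * 2, 0.5),            # balanced: maximum
        ([(40, 0, 1, 1)] * 2, 0.0),             # monomorphic
        ([(15, 5, 1, 1), (15, 5, 1, 1)], 2 * 30 * 10 / 40 ** 2),  # 0.375
    ])
    def test_hand_evaluated_windows(self, counts, expected):
        out = ps.window_hp(_window_records(counts), 1, ONE_SNP)
        assert out["hp"].iloc[0] == pytest.approx(expected)

    def test_major_minor_is_per_snp(self):
        # one SNP alt-major, one ref-major: majors 30+30, minors 10+10
        out = ps.window_hp(_window_records([(30, 10, 1, 1), (10, 30, 1, 1)]),
                           1, ONE_SNP)
        assert out["hp"].iloc[0] == pytest.approx(2 * 60 * 20 / 80 ** 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=30).filter(
                        lambda cs: sum(a + b for a, b in cs) > 0))
    def test_bounds_and_symmetry_condition(self, counts):
        out = ps.window_hp(
            _window_records([(r, a, 1, 1) for r, a in counts]), 1, ONE_SNP)
        hp = out["hp"].iloc[0]
        assert 0.0 <= hp <= 0.5
        nmaj = sum(max(r, a) for r, a in counts)
        nmin = sum(min(r, a) for r, a in counts)
        assert (hp == 0.5) == (nmaj == nmin)


class TestZTransform:
    def test_centering_and_standardization(self):
        rng = np.random.default_rng(8)
        hp = rng.uniform(0, 0.5, size=200)
        zhp, params = ps.z_transform(hp)
        assert zhp.mean() == pytest.approx(0, abs=1e-12)
        assert zhp.std(ddof=0) == pytest.approx(1, abs=1e-12)
        assert params.apply(params.mu) == 0
        # strictly decreasing affine map
        assert np.all(np.diff(zhp[np.argsort(hp)]) <= 0)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DegenerateError):
            ps.z_transform([0.3] * 10)
        with pytest.raises(DegenerateError):
            ps.z_transform([0.3])

    def test_published_pairs_fit_single_affine_relation(self):
        """The 12 printed (Hp, -ZHp) pairs must be one affine transform:
        fitting a line leaves residuals within printing precision."""
        hp = CANDIDATE_TABLE["hp"].to_numpy()
        zhp = CANDIDATE_TABLE["zhp"].to_numpy()
        slope, intercept = np.polyfit(hp, zhp, 1)
        residuals = zhp - (slope * hp + intercept)
        assert np.abs(residuals).max() < 0.02
        assert slope < 0

    def test_params_solved_from_two_pairs_predict_the_rest(self):
        row_a = CANDIDATE_TABLE.iloc[0]   # CCDC61 window
        row_b = CANDIDATE_TABLE.iloc[1]   # ZNF382/ZNF461 window
        params = ps.ZTransformParams.solve(row_a.hp, row_a.zhp,
                                           row_b.hp, row_b.zhp)
        others = CANDIDATE_TABLE.iloc[2:]
        predicted = params.apply(others["hp"].to_numpy())
        assert np.abs(predicted - others["zhp"].to_numpy()).max() < 0.02


class TestTopQuantile:
    def _frame(self, values):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(values)) * 25_000,
            "end": (np.arange(len(values)) + 1) * 25_000,
            "v": values,
        })

    def test_study_scale_count(self):
        rng = np.random.default_rng(1)
        frame = self._frame(rng.normal(size=86_886))
        _, keys = ps.top_quantile(frame, "v", q=0.01)
        assert len(keys) == 869

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(size=1000)
        frame = self._frame(values)
        threshold, keys = ps.top_quantile(frame, "v", q=0.01)
        top_idx = np.argsort(values)[::-1][:10]
        expected = {WindowKey("chr1", int(i) * 25_000, (int(i) + 1) * 25_000)
                    for i in top_idx}
        assert set(keys) == expected
        assert threshold == pytest.approx(np.sort(values)[-10])

    def test_ties_break_deterministically(self):
        frame = self._frame(np.zeros(100))
        _, keys = ps.top_quantile(frame, "v", q=0.01)
        assert keys == [WindowKey("chr1", 0, 25_000)]
        _, keys5 = ps.top_quantile(frame, "v", q=0.05)
        assert len(keys5) == 5
        assert keys5 == sorted(keys5)

    def test_low_direction(self):
        frame = self._frame(np.arange(100.0))
        _, keys = ps.top_quantile(frame, "v", q=0.01, direction="low")
        assert keys == [WindowKey("chr1", 0, 25_000)]

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ConfigError):
            ps.top_quantile(self._frame([1.0]), "v", q=1.5)
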