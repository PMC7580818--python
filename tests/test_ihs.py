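"""EHH / iHH / iHS: pair-counting oracles, antisymmetry, standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from admixscan import ihs_scan
from admixscan.haplotypes import MISSING
from admixscan.ihs_scan import (
    EHHCurve,
    UndefinedEHHError,
    add_pvalues,
    ehh,
    ihh,
    ihs_pvalue,
    ihs_table,
    standardize,
    unstandardized_ihs,
    window_ihs,
)
from admixscan.genome_io import GenomicWindow, make_windows, WindowSpec

from conftest import make_hapset


def naive_side_ehh(matrix, positions, core, allele, step, max_gap, min_ehh):
    """Independent dict-based EHH walker used as the test oracle."""
    carriers = [h for h in range(matrix.shape[0]) if matrix[h, core] == allele]
    if len(carriers) < 2:
        return None
    offsets, values = [0], [1.0]
    prefix = {h: () for h in carriers}
    alive = set(carriers)
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= matrix.shape[1]:
            return offsets, values, "chrom-end"
        if abs(int(positions[jn]) - int(positions[j])) > max_gap:
            return offsets, values, "gap"
        for h in list(alive):
            if matrix[h, jn] == MISSING:
                alive.discard(h)
            else:
                prefix[h] = prefix[h] + (int(matrix[h, jn]),)
        if len(alive) < 2:
            return offsets, values, "too-few-carriers"
        groups = {}
        for h in alive:
            groups.setdefault(prefix[h], 0)
            groups[prefix[h]] += 1
        n = len(alive)
        val = sum(c * (c - 1) for c in groups.values()) / (n * (n - 1))
        offsets.append(abs(int(positions[jn]) - int(positions[core])))
        values.append(val)
        j = jn
        if val < min_ehh:
            return offsets, values, "below-cutoff"


def naive_uihs(haps, core, max_gap=20_000, min_ehh=0.05):
    sides = {}
    for allele in (0, 1):
        total = 0.0
        for step in (-1, 1):
            res = naive_side_ehh(haps.matrix, haps.positions, core, allele,
                                 step, max_gap, min_ehh)
            offs, vals, _ = res
            total += np.trapezoid(vals, offs)
        sides[allele] = total
    return np.log(sides[0] / sides[1])


class TestEHH:
    def test_distance_zero_is_one(self):
        haps = make_hapset([[0, 1, 0], [1, 1, 1], [1, 0, 1], [0, 0, 0]])
        curve = ehh(haps, 1, 1, "right")
        assert curve.values[0] == 1.0 and curve.offsets[0] == 0

    def test_identical_carriers_stay_at_one_until_chromosome_end(self):
        mat = np.zeros((5, 6), dtype=np.int8)
        mat[:3, 2] = 1           # three carriers, identical elsewhere
        haps = make_hapset(mat)
        curve = ehh(haps, 2, 1, "right")
        assert np.all(curve.values == 1.0)
        assert curve.truncation == "chrom-end"

    def test_pair_counting_three_carriers_split_two_one(self):
        # carriers' alleles at the next site are {0, 1, 1}: one intact pair
        # of C(3,2) = 3 -> EHH = 1/3
        mat = np.array([
            [1, 0], [1, 1], [1, 1], [0, 0], [0, 1],
        ], dtype=np.int8)
        haps = make_hapset(mat)
        curve = ehh(haps, 0, 1, "right")
        assert curve.values[1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_raises(self):
        haps = make_hapset([[1, 0], [0, 0], [0, 1], [0, 1]])
        with pytest.raises(UndefinedEHHError):
            ehh(haps, 0, 1, "right")

    def test_gap_rule_truncates_curve(self):
        mat = np.tile([[1], [1], [0], [0]], (1, 3)).astype(np.int8)
        haps = make_hapset(mat, positions=[0, 1000, 30_000])
        curve = ehh(haps, 0, 1, "right", max_gap=20_000)
        assert curve.truncation == "gap"
        assert curve.offsets[-1] == 1000

    def test_monotone_nonincreasing_and_bounded_on_random_data(self):
        rng = np.random.default_rng(29)
        mat = rng.integers(0, 2, size=(30, 120)).astype(np.int8)
        haps = make_hapset(mat, positions=np.sort(
            rng.choice(600_000, 120, replace=False)))
        for core in range(20, 100, 7):
            for allele in (0, 1):
                for side in ("left", "right"):
                    curve = ehh(haps, core, allele, side, max_gap=10**9,
                                min_ehh=0.0)
                    assert np.all(np.diff(curve.values) <= 1e-12)
                    assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_masked_carrier_drops_out_of_pair_count(self):
        mat = np.array([
            [1, 0, 0], [1, MISSING, 0], [1, 0, 1], [0, 0, 0],
        ], dtype=np.int8)
        haps = make_hapset(mat)
        curve = ehh(haps, 0, 1, "right")
        # carrier 1 drops; among {0, 2}: alleles {0, 0} then {0, 1}
        assert curve.values[1] == pytest.approx(1.0)
        assert curve.values[2] == pytest.approx(0.0)


class TestIHH:
    def test_closed_form_trapezoid(self):
        left = EHHCurve(0, "left", np.array([0]), np.array([1.0]), "chrom-end")
        right = EHHCurve(0, "right", np.array([0, 1000]),
                         np.array([1.0, 0.5]), "below-cutoff")
        assert ihh(left, right) == pytest.approx(750.0)

    def test_mirror_symmetric_sides_double_one_side(self):
        offs = np.array([0, 500, 1500])
        vals = np.array([1.0, 0.6, 0.1])
        left = EHHCurve(0, "left", offs, vals, "below-cutoff")
        right = EHHCurve(0, "right", offs, vals, "below-cutoff")
        one = EHHCurve(0, "left", np.array([0]), np.array([1.0]), "chrom-end")
        assert ihh(left, right) == pytest.approx(2 * ihh(one, right))

    def test_agrees_with_fine_grid_quadrature(self):
        rng = np.random.default_rng(4)
        offs = np.concatenate([[0], np.sort(rng.choice(
            np.arange(1, 50_000), 40, replace=False))])
        vals = np.concatenate([[1.0], np.sort(rng.random(40))[::-1]])
        curve = EHHCurve(0, "right", offs, vals, "below-cutoff")
        stub = EHHCurve(0, "left", np.array([0]), np.array([1.0]), "chrom-end")
        fine_x = np.linspace(0, offs[-1], 200_001)
        fine = np.trapezoid(np.interp(fine_x, offs, vals), fine_x)
        assert ihh(stub, curve) == pytest.approx(fine, rel=1e-9)


class TestUnstandardizedIHS:
    def test_symmetric_configuration_scores_zero(self):
        # alleles 0 and 1 play mirror roles at every site
        mat = np.array([
            [1, 1, 1, 1, 1],
            [0, 1, 1, 1, 0],
            [1, 0, 0, 0, 1],
            [0, 0, 0, 0, 0],
        ], dtype=np.int8)
        haps = make_hapset(mat)
        assert unstandardized_ihs(haps, 2) == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabeling_flips_sign(self, neutral_haps_5mb):
        haps = neutral_haps_5mb.take_sites(np.arange(400))
        flipped = make_hapset(np.where(haps.matrix == MISSING, MISSING,
                                       1 - haps.matrix),
                              positions=haps.positions)
        tab = ihs_table(haps, min_hap=2)
        tab_f = ihs_table(flipped, min_hap=2)
        both = tab["uihs"].notna() & tab_f["uihs"].notna()
        assert both.sum() > 50
        np.testing.assert_allclose(tab.loc[both, "uihs"],
                                   -tab_f.loc[both, "uihs"], atol=1e-10)

    def test_six_haplotype_worked_case_matches_hand_oracle(self):
        mat = np.array([
            [0, 1, 1, 0, 1, 0, 1],
            [1, 0, 1, 1, 1, 0, 0],
            [0, 1, 1, 1, 0, 1, 1],
            [1, 1, 0, 1, 1, 1, 0],
            [0, 0, 0, 0, 0, 0, 1],
            [1, 1, 0, 0, 1, 0, 0],
        ], dtype=np.int8)
        positions = np.array([0, 900, 2000, 3100, 4000, 5200, 6100])
        haps = make_hapset(mat, positions=positions)
        expected = naive_uihs(haps, 3, max_gap=10**6, min_ehh=0.0)
        got = unstandardized_ihs(haps, 3, max_gap=10**6, min_ehh=0.0)
        assert got == pytest.approx(expected, rel=1e-12)


class TestKernelAgainstReference:
    def test_scan_kernel_matches_per_core_reference(self, neutral_haps_5mb):
        haps = neutral_haps_5mb.take_sites(np.arange(600))
        tab = ihs_table(haps)
        scored = tab[tab["uihs"].notna()]
        assert len(scored) > 100
        rng = np.random.default_rng(0)
        for i in rng.choice(scored.index, 40, replace=False):
            core = int(np.searchsorted(haps.positions, scored.loc[i, "position"]))
            assert unstandardized_ihs(haps, core) == pytest.approx(
                scored.loc[i, "uihs"], rel=1e-9)

    def test_gap_and_border_cores_are_excluded(self, neutral_haps_5mb):
        haps = neutral_haps_5mb.take_sites(np.arange(300))
        tab = ihs_table(haps)
        # first/last cores cannot decay below cutoff both sides inside data
        assert np.isnan(tab["uihs"].iloc[0]) and np.isnan(tab["uihs"].iloc[-1])


class TestStandardize:
    def test_pair_standardizes_to_plus_minus_one(self):
        df = pd.DataFrame({"daf": [0.310, 0.312], "uihs": [0.7, -0.7]})
        out = standardize(df, n_bins=50, min_per_bin=1)
        assert sorted(out["ihs"]) == pytest.approx([-1.0, 1.0])

    def test_constant_bin_left_unscored(self):
        df = pd.DataFrame({"daf": [0.5] * 5, "uihs": [1.2] * 5})
        out = standardize(df, min_per_bin=1)
        assert out["ihs"].isna().all()

    def test_per_bin_mean_zero_sd_one(self):
        rng = np.random.default_rng(8)
        daf = rng.uniform(0.05, 0.95, 5000)
        df = pd.DataFrame({"daf": daf, "uihs": rng.normal(2 * daf, 1 + daf)})
        out = standardize(df)
        for b, grp in out.groupby("bin"):
            vals = grp["ihs"].dropna()
            if len(vals) >= 2:
                assert abs(vals.mean()) < 1e-10
                assert abs(vals.std(ddof=0) - 1) < 1e-10

    def test_frequency_dependent_shift_removed(self):
        # uiHS ~ N(mu(p), sigma(p)^2): pooled standardized scores are N(0,1)
        rng = np.random.default_rng(15)
        n = 10_000
        daf = rng.uniform(0.05, 0.95, n)
        mu_p = np.sin(daf * 3)
        sd_p = 0.5 + daf
        df = pd.DataFrame({"daf": daf,
                           "uihs": rng.normal(mu_p, sd_p)})
        out = standardize(df)
        pooled = out["ihs"].dropna()
        assert kstest(pooled, "norm").pvalue > 0.01

    def test_sparse_bins_merged(self):
        df = pd.DataFrame({
            "daf": np.concatenate([np.full(3, 0.11), np.full(20, 0.52)]),
            "uihs": np.arange(23.0),
        })
        out = standardize(df, min_per_bin=10)
        assert out["bin"].nunique() <= 2
        assert out["ihs"].notna().all()


class TestPvalues:
    def test_zero_score_gives_p_one(self):
        p, mlog = ihs_pvalue(np.array([0.0]))
        assert p[0] == 1.0 and mlog[0] == 0.0

    def test_published_scale_anchor(self):
        # |iHS| = 3.8906 corresponds to p ~ 1e-4 two-sided
        p, _ = ihs_pvalue(np.array([3.8906]))
        assert p[0] == pytest.approx(1.0e-4, rel=1e-3)

    def test_strictly_decreasing_in_magnitude(self):
        grid = np.linspace(0, 6, 50)
        p, _ = ihs_pvalue(grid)
        assert np.all(np.diff(p) < 0)


class TestWindowIHS:
    @staticmethod
    def _records(pos, ihs_vals, chrom="w"):
        df = pd.DataFrame({"chrom": chrom, "position": pos, "ihs": ihs_vals})
        df["mlog10p"] = -np.log10(2 * norm.sf(np.abs(df["ihs"])))
        return df

    def test_single_snp_window(self):
        rec = self._records([10_000], [-1.7])
        out = window_ihs(rec, [GenomicWindow("w", 0, 30_000)])
        assert out.loc[0, "mean_abs_ihs"] == pytest.approx(1.7)
        assert out.loc[0, "max_abs_ihs"] == pytest.approx(1.7)

    def test_mean_and_max_of_absolute_scores(self):
        rec = self._records([1000, 2000, 3000], [1.0, -2.0, 3.0])
        out = window_ihs(rec, [GenomicWindow("w", 0, 30_000)])
        assert out.loc[0, "mean_abs_ihs"] == pytest.approx(2.0)
        assert out.loc[0, "max_abs_ihs"] == pytest.approx(3.0)

    def test_empty_window_flagged_with_zero_count(self):
        rec = self._records([50_000], [1.0])
        out = window_ihs(rec, [GenomicWindow("w", 0, 30_000)])
        assert out.loc[0, "n"] == 0 and np.isnan(out.loc[0, "mean_abs_ihs"])

    def test_matches_bruteforce_aggregation(self):
        rng = np.random.default_rng(23)
        pos = np.sort(rng.choice(500_000, 300, replace=False))
        rec = self._records(pos, rng.normal(0, 1, 300))
        wins = make_windows(500_000, WindowSpec(30_000, 25_000), chrom="w")
        out = window_ihs(rec, wins)
        for k, w in enumerate(wins):
            sel = (pos >= w.start) & (pos < w.end)
            if sel.sum():
                assert out.loc[k, "mean_abs_ihs"] == pytest.approx(
                    np.abs(rec["ihs"][sel]).mean())
                assert out.loc[k, "n"] == sel.sum()

    def test_mean_never_exceeds_max(self, neutral_haps_5mb):
        tab = add_pvalues(standardize(ihs_table(neutral_haps_5mb)))
        wins = make_windows(5_000_000, WindowSpec(), chrom=neutral_haps_5mb.chrom)
        out = window_ihs(tab, wins)
        filled = out[out["n"] > 0]
        assert (filled["mean_abs_ihs"] <= filled["max_abs_ihs"] + 1e-12).all()
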