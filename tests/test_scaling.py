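import numpy as np
import pytest

from hicdelta.matrix import ContactMap, GenomeBinning
from hicdelta.scaling import (
    InterchromMatrix,
    ScalingCurve,
    cis_trans_ratio,
    fit_power_law,
    interchrom_enrichment,
    length_diff_correlation,
    ps_curve,
    ps_ratio,
)
from hicdelta.synthetic import SyntheticSpec, expected_matrix, generate_map

from .conftest import symmetric_random


def noiseless_map(alpha, chrom_bins=(60, 40), depth=1e6, trans=0.0):
    spec = SyntheticSpec(
        chrom_bins=chrom_bins, alpha={"a": alpha, "b": alpha},
        depth=depth, trans_weight=trans, seed=0,
    )
    e = expected_matrix(spec, "a")
    return ContactMap(spec.binning(), e, value_kind="corrected"), spec


class TestPsCurve:
    def test_single_separation(self):
        binning = GenomeBinning.from_bin_counts([5])
        m = np.zeros((5, 5))
        for i in range(4):
            m[i, i + 1] = m[i + 1, i] = 2.0
        curve = ps_curve(ContactMap(binning, m))
        assert curve.values[0] > 0
        assert np.all(curve.values[1:] == 0)

    def test_noiseless_power_law_proportionality(self):
        cmap, _ = noiseless_map(1.4)
        curve = ps_curve(cmap)
        s = curve.distances / cmap.binning.bin_size
        prediction = curve.values[0] * s ** -1.4
        np.testing.assert_allclose(curve.values, prediction, rtol=1e-9)

    def test_global_scale_linearity(self, rng):
        binning = GenomeBinning.from_bin_counts([30])
        m = symmetric_random(30, rng)
        c1 = ps_curve(ContactMap(binning, m))
        c2 = ps_curve(ContactMap(binning, m * 3.0))
        np.testing.assert_allclose(c2.values, 3.0 * c1.values, rtol=1e-12)

    def test_pair_counts_match_combinatorics(self):
        cmap, _ = noiseless_map(1.0, chrom_bins=(10, 6))
        curve = ps_curve(cmap)
        # separation 1: 9 pairs on chr1 + 5 on chr2
        assert curve.n_pairs[0] == 14

    def test_no_cis_contacts_error(self):
        binning = GenomeBinning.from_bin_counts([3, 3])
        m = np.zeros((6, 6))
        m[0, 4] = m[4, 0] = 5.0
        with pytest.raises(ValueError, match="intrachromosomal"):
            ps_curve(ContactMap(binning, m))

    def test_log_binning_pools(self):
        cmap, _ = noiseless_map(1.0)
        per_diag = ps_curve(cmap, "per_diagonal")
        logged = ps_curve(cmap, "log")
        assert len(logged.distances) < len(per_diag.distances)


class TestFitPowerLaw:
    def test_exact_recovery_noiseless(self):
        for alpha in (0.5, 1.07, 1.27, 2.0):
            cmap, _ = noiseless_map(alpha)
            fit = fit_power_law(ps_curve(cmap), min_pairs=1, drop_first=False)
            assert fit.exponent == pytest.approx(-alpha, abs=1e-9)
            assert fit.stderr == pytest.approx(0.0, abs=1e-7)

    def test_sampled_recovery(self):
        spec = SyntheticSpec(
            chrom_bins=(500,) * 5, alpha={"a": 1.27, "b": 1.27},
            depth=5e6, trans_weight=0.05, seed=0,
        )
        m = generate_map(spec, "a", np.random.default_rng(1))
        fit = fit_power_law(ps_curve(m))
        assert fit.exponent == pytest.approx(-1.27, abs=0.05)

    def test_too_few_points(self):
        curve = ScalingCurve([1e6, 2e6], [1.0, 0.5], [10, 10])
        with pytest.raises(ValueError):
            fit_power_law(curve, min_pairs=1, drop_first=False)

    def test_nonpositive_excluded_with_warning(self):
        curve = ScalingCurve(
            [1e6, 2e6, 3e6, 4e6], [8.0, 4.0, 0.0, 2.0], [50, 50, 50, 50]
        )
        with pytest.warns(UserWarning, match="non-positive"):
            fit_power_law(curve, min_pairs=1, drop_first=False)


class TestPsRatio:
    def test_identity(self):
        cmap, _ = noiseless_map(1.0)
        c = ps_curve(cmap)
        np.testing.assert_allclose(ps_ratio(c, c), 1.0)

    def test_exponent_difference_slope(self):
        a, _ = noiseless_map(1.07)
        b, _ = noiseless_map(1.27)
        ca, cb = ps_curve(a), ps_curve(b)
        r = ps_ratio(ca, cb)
        x = np.log10(ca.distances)
        slope = np.polyfit(x, np.log10(r), 1)[0]
        assert slope == pytest.approx(0.20, abs=1e-9)

    def test_zero_gives_missing(self):
        c1 = ScalingCurve([1e6, 2e6], [1.0, 1.0], [5, 5])
        c2 = ScalingCurve([1e6, 2e6], [1.0, 0.0], [5, 5])
        r = ps_ratio(c1, c2)
        assert np.isnan(r[1]) and r[0] == 1.0


class TestCisTransRatio:
    def test_toy_arithmetic(self):
        binning = GenomeBinning.from_bin_counts([3, 3])
        m = np.zeros((6, 6))
        m[0, 1] = m[1, 0] = 45.0  # intra chr1 block sum = 90
        m[0, 4] = m[4, 0] = 5.0   # trans sum seen from chr1 = 10
        m[3, 5] = m[5, 3] = 50.0
        per_chrom, _ = cis_trans_ratio(ContactMap(binning, m))
        assert per_chrom["chr1"] == pytest.approx(9.0)

    def test_block_diagonal_warns_infinite(self):
        binning = GenomeBinning.from_bin_counts([3, 3])
        m = np.zeros((6, 6))
        m[0, 1] = m[1, 0] = 5.0
        m[3, 4] = m[4, 3] = 5.0
        with pytest.warns(UserWarning):
            _, genome = cis_trans_ratio(ContactMap(binning, m))
        assert np.isinf(genome)

    def test_synthetic_trans_weight_recovered(self):
        spec = SyntheticSpec(
            chrom_bins=(80, 60), alpha={"a": 1.0, "b": 1.0},
            depth=4e6, trans_weight=0.2, seed=0,
        )
        m = generate_map(spec, "a", np.random.default_rng(9))
        _, genome = cis_trans_ratio(m)
        assert genome == pytest.approx(0.8 / 0.2, rel=0.05)


class TestInterchromEnrichment:
    def _three_chrom_map(self, s12, s13, s23, nb=2):
        binning = GenomeBinning.from_bin_counts([nb] * 3)
        m = np.zeros((3 * nb, 3 * nb))
        # spread each trans total uniformly over its block
        for (ci, cj), tot in {(0, 1): s12, (0, 2): s13, (1, 2): s23}.items():
            sli = binning.chrom_slice(ci)
            slj = binning.chrom_slice(cj)
            m[sli, slj] = tot / nb**2
            m[slj, sli] = tot / nb**2
        return ContactMap(binning, m)

    def test_hand_arithmetic(self):
        # pair-once convention: S_12=10, S_13=20, S_23=30 -> S_1=30,
        # S_2=40, S_3=50, T=60; expected_12 = 0.5*(1200/30 + 1200/20) = 50
        # -> enrichment 0.2
        ic = interchrom_enrichment(
            self._three_chrom_map(10, 20, 30), double_count_total=False
        )
        np.testing.assert_allclose(ic.totals, [30, 40, 50])
        assert ic.grand_total == 60
        assert ic.expected[0, 1] == pytest.approx(50.0)
        assert ic.enrichment[0, 1] == pytest.approx(0.2)

    def test_row_sums_invariant(self):
        ic = interchrom_enrichment(self._three_chrom_map(10, 20, 30))
        np.testing.assert_allclose(ic.totals, ic.observed.sum(axis=1))

    def test_scale_invariance(self):
        a = interchrom_enrichment(self._three_chrom_map(10, 20, 30))
        b = interchrom_enrichment(self._three_chrom_map(20, 40, 60))
        np.testing.assert_allclose(a.enrichment, b.enrichment, rtol=1e-12)

    def test_uniform_trans_near_unity(self):
        spec = SyntheticSpec(
            chrom_bins=(50, 50, 50, 50), alpha={"a": 1.0, "b": 1.0},
            depth=2e7, trans_weight=0.3, seed=0,
        )
        m = generate_map(spec, "a", np.random.default_rng(2))
        ic = interchrom_enrichment(m)
        off = ic.enrichment[np.triu_indices(4, k=1)]
        assert np.all((off > 0.9) & (off < 1.1))

    def test_as_printed_audit_mode_differs(self):
        m = self._three_chrom_map(10, 20, 30)
        sym = interchrom_enrichment(m)
        printed = interchrom_enrichment(m, as_printed=True)
        assert not np.allclose(sym.expected, printed.expected)

    def test_needs_three_chromosomes(self):
        binning = GenomeBinning.from_bin_counts([3, 3])
        m = np.ones((6, 6))
        with pytest.raises(ValueError, match="3 chromosomes"):
            interchrom_enrichment(ContactMap(binning, m))

    def test_zero_trans_chromosome_error(self):
        binning = GenomeBinning.from_bin_counts([2, 2, 2])
        m = np.zeros((6, 6))
        m[0, 2] = m[2, 0] = 5.0  # chr3 isolated
        with pytest.raises(ValueError, match="zero trans"):
            interchrom_enrichment(ContactMap(binning, m))


class TestLengthDiffCorrelation:
    def _binning(self, lengths):
        return GenomeBinning(
            tuple((f"chr{i+1}", l) for i, l in enumerate(lengths)), 1_000_000
        )

    def _matrix_from_enrichment(self, names, enr):
        n = len(names)
        ic = InterchromMatrix(
            chrom_names=tuple(names),
            observed=np.ones((n, n)),
            expected=np.ones((n, n)),
            enrichment=enr,
            totals=np.ones(n),
            grand_total=1.0,
        )
        return ic

    def test_linear_decrease_matches_oracle(self):
        from scipy import stats

        lengths = [10_000_000, 20_000_000, 40_000_000, 80_000_000]
        binning = self._binning(lengths)
        n = 4
        enr = np.zeros((n, n))
        xs, ys = [], []
        for i in range(n):
            for j in range(n):
                if i != j:
                    dl = abs(lengths[i] - lengths[j])
                    enr[i, j] = 2.0 - dl / 1e8
        ic = self._matrix_from_enrichment(binning.chrom_names, enr)
        r = length_diff_correlation(ic, binning)
        for i in range(n):
            for j in range(i + 1, n):
                xs.append(abs(lengths[i] - lengths[j]))
                ys.append(enr[i, j])
        assert r < 0
        assert r == pytest.approx(stats.pearsonr(xs, ys)[0], abs=1e-9)

    def test_constant_enrichment_error(self):
        lengths = [10_000_000, 20_000_000, 40_000_000]
        binning = self._binning(lengths)
        ic = self._matrix_from_enrichment(
            binning.chrom_names, np.ones((3, 3))
        )
        with pytest.raises(ValueError, match="constant"):
            length_diff_correlation(ic, binning)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        lengths = [10_000_000, 25_000_000, 40_000_000, 90_000_000]
        enr = rng.uniform(0.5, 2.0, size=(4, 4))
        enr = (enr + enr.T) / 2
        binning = self._binning(lengths)
        r1 = length_diff_correlation(
            self._matrix_from_enrichment(binning.chrom_names, enr), binning
        )
        perm = [2, 0, 3, 1]
        lengths_p = [lengths[i] for i in perm]
        binning_p = GenomeBinning(
            tuple((binning.chrom_names[i], lengths[i]) for i in perm), 1_000_000
        )
        enr_p = enr[np.ix_(perm, perm)]
        names_p = tuple(binning.chrom_names[i] for i in perm)
        r2 = length_diff_correlation(
            self._matrix_from_enrichment(names_p, enr_p), binning_p
        )
        assert r1 == pytest.approx(r2, rel=1e-12)
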