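import numpy as np
import pytest

import pointorder as po
from pointorder.paircorrelation import _triangular_shells
from pointorder.pattern import ObservationWindow

SPACING_1 = po.hexagonal_spacing(1.0)


def brute_force_gr(pattern, bin_width, n_bins):
    """Independent O(N^2) double loop over ordered pairs, same binning."""
    pts = pattern.points
    counts = np.zeros(n_bins)
    for i in range(len(pts)):
        for j in range(len(pts)):
            if i == j:
                continue
            d = float(np.hypot(*(pts[i] - pts[j])))
            k = int(np.floor(d / bin_width + 0.5))
            if 1 <= k <= n_bins:
                counts[k - 1] += 1
    centres = bin_width * np.arange(1, n_bins + 1)
    rho = pattern.intensity
    values = counts / pattern.n / (2 * np.pi * centres * bin_width * rho)
    return centres, counts, values


class TestGr:
    def test_two_points_single_bin(self):
        p = po.PointPattern([[1, 1], [1, 2.5]], ObservationWindow(0, 0, 4, 4))
        rdf = po.gr(p, bin_width=0.25, r_max=2.0)
        nz = np.nonzero(rdf.pair_counts)[0]
        assert list(nz) == [5]  # bin centred at 1.5
        assert rdf.pair_counts[5] == 2  # ordered pairs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_exactly(self, seed):
        p = po.csr(0.5, ObservationWindow(0, 0, 8, 8), seed=seed)
        p = po.PointPattern(p.points[:40], p.window)
        rdf = po.gr(p, bin_width=0.3, r_max=3.9)
        _, counts, values = brute_force_gr(p, 0.3, rdf.bin_centres.size)
        np.testing.assert_array_equal(rdf.pair_counts, counts)
        np.testing.assert_allclose(rdf.values, values, rtol=1e-12)

    def test_pair_count_conservation(self):
        p = po.csr(1.0, ObservationWindow(0, 0, 7, 7), seed=5)
        rdf = po.gr(p, bin_width=0.2, r_max=3.0)
        d = np.linalg.norm(p.points[:, None] - p.points[None], axis=2)
        iu = np.triu_indices(p.n, 1)
        in_range = (d[iu] >= 0.1) & (d[iu] < rdf.bin_centres[-1] + 0.1)
        assert rdf.pair_counts.sum() == 2 * int(in_range.sum())

    def test_large_csr_is_flat(self):
        # window much larger than r_max so uncorrected edge losses stay
        # inside the tolerance band
        p = po.csr(1.0, ObservationWindow(0, 0, 250, 250), seed=9)
        rdf = po.gr(p, bin_width=0.25, r_max=6.0)
        tail = rdf.values[rdf.bin_centres >= 2.0]
        assert np.all(np.abs(tail - 1.0) < 0.05)

    def test_edge_correction_lifts_tail(self):
        p = po.csr(1.0, ObservationWindow(0, 0, 40, 40), seed=12)
        raw = po.gr(p, bin_width=0.5, r_max=10.0)
        corr = po.gr(p, bin_width=0.5, r_max=10.0, edge_correction=True)
        assert corr.values[-1] > raw.values[-1]
        assert abs(corr.values[-1] - 1.0) < abs(raw.values[-1] - 1.0)

    def test_rigid_motion_invariance(self, hex_pattern):
        rdf = po.gr(hex_pattern, 0.1, 4.0)
        moved = hex_pattern.translated(3.7, -2.1)
        rdf2 = po.gr(moved, 0.1, 4.0)
        np.testing.assert_allclose(rdf.values, rdf2.values, rtol=1e-9)

    def test_r_max_warning(self, hex_pattern):
        with pytest.warns(RuntimeWarning, match="r_max"):
            po.gr(hex_pattern, 0.5, 10.0)

    def test_single_point_rejected(self):
        p = po.PointPattern([[0.5, 0.5]], ObservationWindow(0, 0, 1, 1))
        with pytest.raises(ValueError):
            po.gr(p, 0.1, 0.4)


class TestBootstrapGr:
    def test_zero_sigma_equals_gr(self, hex_pattern):
        raw = po.gr(hex_pattern, 0.1, 4.0)
        boot = po.bootstrap_gr(hex_pattern, 0.0, 50, seed=1, bin_width=0.1, r_max=4.0)
        np.testing.assert_array_equal(raw.values, boot.values)

    def test_small_sigma_approaches_gr(self, hex_pattern):
        raw = po.gr(hex_pattern, 0.2, 4.0)
        boot = po.bootstrap_gr(hex_pattern, 0.005, 50, seed=1, bin_width=0.2, r_max=4.0)
        # sup-norm agreement up to bin-quantization at peak edges
        assert np.max(np.abs(boot.values - raw.values)) < 0.35 * raw.values.max()

    def test_seed_convergence(self):
        base = po.hexagonal_lattice(1.0, ObservationWindow(0, 0, 12, 12))
        pat = po.hexatic_ensemble(po.HexaticSpec(base, 0.06, 1, seed=5))[0]
        a = po.bootstrap_gr(pat, 0.05, 200, seed=1, bin_width=0.1, r_max=4.0)
        b = po.bootstrap_gr(pat, 0.05, 200, seed=2, bin_width=0.1, r_max=4.0)
        assert np.max(np.abs(a.values - b.values)) < 0.01 * a.values.max() * 5

    def test_smooths_single_bin_spikes(self):
        base = po.hexagonal_lattice(1.0, ObservationWindow(0, 0, 15, 15))
        pat = po.hexatic_ensemble(po.HexaticSpec(base, 0.06, 1, seed=5))[0]
        raw = po.gr(pat, SPACING_1 / 20, 5 * SPACING_1)
        boot = po.bootstrap_gr(pat, 0.05, 200, seed=1,
                               bin_width=SPACING_1 / 20, r_max=5 * SPACING_1)
        second = lambda v: np.abs(np.diff(v, 2)).max()
        assert second(boot.values) < second(raw.values)


class TestNormalization:
    def test_distance_normalization_moves_first_peak_to_one(self, hex_pattern):
        rdf = po.gr(hex_pattern, SPACING_1 / 20, 3 * SPACING_1)
        norm = po.normalize_distance(rdf, SPACING_1)
        peaks = po.peak_positions(norm)
        assert peaks[0] == pytest.approx(1.0, abs=norm.bin_width)

    def test_double_distance_normalization_rejected(self, hex_pattern):
        rdf = po.normalize_distance(po.gr(hex_pattern, 0.1, 3.0), SPACING_1)
        with pytest.raises(ValueError, match="already"):
            po.normalize_distance(rdf, 2.0)

    def test_height_normalization_idempotent(self, hex_pattern):
        rdf = po.normalize_height(po.gr(hex_pattern, 0.1, 3.0))
        assert rdf.values.max() == pytest.approx(1.0)
        again = po.normalize_height(rdf)
        np.testing.assert_allclose(again.values, rdf.values)

    def test_flat_unit_rdf_unchanged(self):
        rdf = po.RadialDistribution(
            bin_centres=0.1 * np.arange(1, 11), values=np.ones(10),
            bin_width=0.1, density=1.0,
        )
        assert np.array_equal(po.normalize_height(rdf).values, rdf.values)

    def test_all_zero_rejected(self):
        rdf = po.RadialDistribution(
            bin_centres=0.1 * np.arange(1, 5), values=np.zeros(4),
            bin_width=0.1, density=1.0,
        )
        with pytest.raises(ValueError):
            po.normalize_height(rdf)


class TestHexagonalReference:
    def test_shell_structure(self):
        ref = po.hexagonal_reference_gr(0.05, 3.2)
        peaks = po.peak_positions(ref)
        np.testing.assert_allclose(peaks[:5], [1.0, 1.75, 2.0, 2.65, 3.0])

    def test_split_second_shell_outer_peak_at_two(self):
        ref = po.hexagonal_reference_gr(0.05, 2.5)
        peaks = po.peak_positions(ref)
        second_shell = peaks[(peaks > 1.5) & (peaks < 2.25)]
        assert second_shell.size == 2
        assert second_shell[1] == pytest.approx(2.0, abs=1e-12)
        assert second_shell[0] == pytest.approx(np.sqrt(3.0), abs=0.025)

    def test_shells_match_explicit_lattice_enumeration(self):
        # oracle: distances from the centre site of an explicit 30x30 lattice
        n = 15
        i, j = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
        disp = np.stack([i + 0.5 * j, np.sqrt(3) / 2 * j], axis=-1).reshape(-1, 2)
        d = np.linalg.norm(disp, axis=1)
        d = np.sort(d[d > 0])
        d = d[d <= 3.05]
        shell_d, shell_m = _triangular_shells(3.05)
        expanded = np.concatenate([
            np.full(int(m), dist) for dist, m in zip(shell_d, shell_m)
        ])
        np.testing.assert_allclose(np.sort(expanded), d, atol=1e-9)

    def test_matches_gr_of_generated_lattice(self):
        lam = 2.0 / np.sqrt(3.0)  # unit spacing
        pat = po.hexagonal_lattice(lam, ObservationWindow(0, 0, 32, 32))
        rdf = po.normalize_distance(po.gr(pat, 0.05, 3.2), 1.0)
        ref = po.hexagonal_reference_gr(0.05, 3.2)
        nz_data = set(np.nonzero(rdf.values > 0.01 * rdf.values.max())[0])
        nz_ref = set(np.nonzero(ref.values)[0])
        assert nz_ref == nz_data


class TestDifferenceSpectrum:
    @staticmethod
    def _norm(rdf, spacing=SPACING_1):
        return po.normalize_height(po.normalize_distance(rdf, spacing))

    def test_self_difference_is_zero(self, hex_pattern):
        a = self._norm(po.gr(hex_pattern, 0.1, 4.0))
        diff = po.difference_spectrum(a, a)
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-12)
        assert po.delta_rms(diff) == 0.0

    def test_requires_normalization(self, hex_pattern):
        raw = po.gr(hex_pattern, 0.1, 4.0)
        with pytest.raises(ValueError, match="normalized"):
            po.difference_spectrum(raw, raw)

    def test_csr_farthest_from_hexagonal_reference(self):
        win = ObservationWindow(0, 0, 25, 25)
        ref = po.normalize_height(po.hexagonal_reference_gr(0.05, 4.0))
        scores = {}
        for name, pat in {
            "csr": po.csr(1.0, win, seed=3),
            "hexatic": po.hexatic_ensemble(po.HexaticSpec(
                po.hexagonal_lattice(1.0, win), 0.02, 1, seed=3))[0],
            "hexagonal": po.hexagonal_lattice(1.0, win),
        }.items():
            spacing = po.disorder_estimate(po.tessellate(pat)).mean_spacing
            rdf = self._norm(po.gr(pat, 0.05 * spacing, 4.0 * spacing), spacing)
            scores[name] = po.delta_rms(po.difference_spectrum(rdf, ref))
        assert scores["csr"] > scores["hexatic"] > scores["hexagonal"]

    def test_delta_rms_of_constant_spectrum(self):
        diff = po.RadialDistribution(
            bin_centres=0.1 * np.arange(1, 11), values=np.full(10, -0.3),
            bin_width=0.1, density=1.0, kind="difference",
            distance_normalized=True, height_normalized=True,
        )
        assert po.delta_rms(diff) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            po.delta_rms(diff, (5.0, 6.0))

    def test_delta_rms_grows_with_jitter(self):
        win = ObservationWindow(0, 0, 20, 20)
        base = po.hexagonal_lattice(1.0, win)
        ref = po.normalize_height(po.hexagonal_reference_gr(0.05, 4.0))
        rms = []
        for k, frac in enumerate((0.02, 0.08, 0.2)):
            pat = po.hexatic_ensemble(
                po.HexaticSpec(base, frac * SPACING_1, 1, seed=30 + k))[0]
            rdf = self._norm(po.gr(pat, 0.05 * SPACING_1, 4.0 * SPACING_1))
            rms.append(po.delta_rms(po.difference_spectrum(rdf, ref)))
        assert rms[0] < rms[1] < rms[2]
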