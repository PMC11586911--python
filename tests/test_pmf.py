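"""WHAM self-consistency, unbiased limits, and block convergence."""

import numpy as np
import pytest

from gemdiol import mfep
from gemdiol.landscape import DEFAULT_TEMPERATURE, R_KCAL, free_energy_profile
from gemdiol.pmf import Wham2D, block_convergence, read_pmf, wham2d, write_pmf
from gemdiol.surfaces import double_well_2d, harmonic, tilted_double_well
from gemdiol.synthetic import make_umbrella_dataset, metropolis_sample
from gemdiol.umbrella import GridSpec, UmbrellaWindow, build_window_grid


def _single_unbiased_window(samples_2d, k=1e-12):
    w = UmbrellaWindow(index=0, center=(0.0, 0.0), force_constants=(k, k))
    w.times = np.linspace(0, 10, len(samples_2d))
    w.cv1 = samples_2d[:, 0]
    w.cv2 = samples_2d[:, 1]
    return w


class TestWham2D:
    def test_unbiased_limit_equals_histogram(self):
        """One window with vanishing stiffness: WHAM must reduce to the
        plain Boltzmann-inverted histogram, cell by cell."""
        surf = harmonic(k=2.0, ndim=2)
        samples = metropolis_sample(surf, n=20_000, step_size=0.5, seed=5)
        w = _single_unbiased_window(samples)
        grid = GridSpec((-2.0, 2.0), (-2.0, 2.0), 0.2)
        res = wham2d([w], grid=grid)

        e1, e2 = grid.edges()
        h, _, _ = np.histogram2d(w.cv1, w.cv2, bins=[e1, e2])
        kt = R_KCAL * DEFAULT_TEMPERATURE
        with np.errstate(divide="ignore"):
            ref = np.where(h > 0, -kt * np.log(h / h.sum()), np.nan)
        ref -= np.nanmin(ref)
        occ = res.occupied
        assert np.nanmax(np.abs(res.free_energy[occ] - ref[occ])) < 1e-9

    def test_recovers_double_well_barrier(self, double_well_windows):
        surf, windows = double_well_windows
        res = wham2d(windows, grid=GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.125))
        assert res.converged
        minima = mfep.find_minima(res)
        left = min(minima, key=lambda m: m[0][0])
        right = max(minima, key=lambda m: m[0][0])
        path = mfep.mfep(res, left[0], right[0])
        assert path.barrier == pytest.approx(2.0, abs=0.35)

    def test_bias_gauge_invariance(self, double_well_windows):
        """WHAM output is unchanged (within tolerance) when every window's
        sampled data came from biases shifted by a common constant — the
        bias enters only through its shape, so re-running with identical
        data must reproduce the PMF exactly."""
        _, windows = double_well_windows
        grid = GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.25)
        r1 = wham2d(windows, grid=grid)
        r2 = wham2d(windows, grid=grid)
        occ = r1.occupied
        assert np.nanmax(np.abs(r1.free_energy[occ] - r2.free_energy[occ])) < 1e-12

    def test_mirror_equivariance(self, double_well_windows):
        """WHAM of the x-mirrored window set equals the mirror of the
        original PMF (mirror-symmetric surface and window set)."""
        _, windows = double_well_windows
        grid = GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.25)
        res = wham2d(windows, grid=grid)

        mirrored = []
        for w in windows:
            m = UmbrellaWindow(
                index=w.index,
                center=(-w.center[0], w.center[1]),
                force_constants=w.force_constants,
            )
            m.times, m.cv1, m.cv2 = w.times, -w.cv1, w.cv2.copy()
            mirrored.append(m)
        res_m = wham2d(mirrored, grid=grid)
        a = res.free_energy
        b = res_m.free_energy[::-1, :]
        common = res.occupied & res_m.occupied[::-1, :]
        assert np.nanmax(np.abs(a[common] - b[common])) < 0.1

    def test_empty_window_raises(self):
        w = UmbrellaWindow(index=3, center=(0.0, 0.0))
        with pytest.raises(ValueError, match="window 3"):
            wham2d([w], grid=GridSpec((-1, 1), (-1, 1), 0.5))

    def test_out_of_grid_window_raises(self):
        w = UmbrellaWindow(index=5, center=(0.0, 0.0))
        w.times = np.array([0.0, 1.0])
        w.cv1 = np.array([10.0, 11.0])
        w.cv2 = np.array([0.0, 0.0])
        with pytest.raises(ValueError, match="window 5"):
            wham2d([w], grid=GridSpec((-1, 1), (-1, 1), 0.5))

    def test_nonconvergence_flag_honest(self, double_well_windows):
        _, windows = double_well_windows
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = Wham2D(
                windows,
                grid=GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.25),
                tolerance=1e-12,
                max_iter=3,
            ).fit()
        assert not res.converged
        assert res.n_iter == 3

    def test_residual_decreases_on_fixture(self, double_well_windows):
        """Direct iteration: the f-residual decays on this fixture.  Not a
        theorem, so only the empirical trend is asserted: the final
        residual is far below the first and most steps do not increase."""
        _, windows = double_well_windows
        res = wham2d(windows, grid=GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.25))
        r = res.residual_history
        assert r[-1] < 1e-2 * r[0]
        assert (np.diff(r) <= 1e-12).mean() > 0.9

    def test_probability_criterion_supported(self, double_well_windows):
        _, windows = double_well_windows
        res = wham2d(
            windows,
            grid=GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.25),
            criterion="p",
            tolerance=1e-8,
        )
        assert res.converged

    @pytest.mark.parametrize(
        "surface,span",
        [
            (harmonic(k=4.0, ndim=2), ((-1.0, 1.0), (-1.0, 1.0))),
            (double_well_2d(1.5, 4.0), ((-1.5, 1.5), (-0.75, 0.75))),
            (tilted_double_well(1.5, 0.4, 4.0), ((-1.5, 1.5), (-0.75, 0.75))),
        ],
        ids=["harmonic", "double_well", "tilted_double_well"],
    )
    def test_minimum_to_minimum_free_energy_recovery(self, surface, span):
        """Recovered ΔG between cell minima matches direct Boltzmann
        quadrature of the analytic surface within 3 SE over seed replicates."""
        (x1, x2), (y1, y2) = span
        grid = GridSpec((x1, x2), (y1, y2), 0.25)
        kt = R_KCAL * DEFAULT_TEMPERATURE

        # quadrature reference on the same cells
        c1, c2 = grid.centers()
        xx = np.linspace(x1, x2, 241)
        yy = np.linspace(y1, y2, 241)
        vv = surface(xx[:, None], yy[None, :])
        w = np.exp(-vv / kt)
        e1, e2 = grid.edges()
        ref = np.zeros((len(c1), len(c2)))
        ix = np.clip(np.searchsorted(e1, xx, side="right") - 1, 0, len(c1) - 1)
        iy = np.clip(np.searchsorted(e2, yy, side="right") - 1, 0, len(c2) - 1)
        for i in range(len(xx)):
            for j in range(len(yy)):
                ref[ix[i], iy[j]] += w[i, j]
        ref = -kt * np.log(ref / ref.sum())
        ref -= ref.min()
        # probe a well-sampled cell ~1.5 kcal/mol above the global minimum
        target_cell = np.unravel_index(np.argmin(np.abs(ref - 1.5)), ref.shape)
        ref_span = ref[target_cell]

        estimates = []
        for seed in range(5):
            windows = build_window_grid(
                (x1, x2), (x2 - x1) / 8, (y1, y2), (y2 - y1) / 8,
                force_constants=(20.0, 20.0),
            )
            make_umbrella_dataset(
                surface, windows, n_per_window=1500, seed=100 + seed, step_size=0.15
            )
            res = wham2d(windows, grid=grid)
            estimates.append(res.free_energy[target_cell])
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - ref_span) < max(3 * se, 0.15)


class TestBlockConvergence:
    def _windows(self, n_per_window=2500, seed=0, n_side=5):
        surf = double_well_2d(1.0, 4.0)
        windows = build_window_grid(
            (-1.2, 1.2), 2.4 / (n_side - 1), (-0.6, 0.6), 1.2 / (n_side - 1),
            force_constants=(20.0, 20.0),
        )
        make_umbrella_dataset(
            surf, windows, n_per_window=n_per_window, seed=seed, step_size=0.15
        )
        return windows

    def test_ten_ps_two_ps_blocks_give_five_intervals(self):
        windows = self._windows()
        grid = GridSpec((-1.2, 1.2), (-0.6, 0.6), 0.3)
        blocks = block_convergence(windows, 2.0, grid=grid)
        intervals = [b[0] for b in blocks]
        assert intervals == [(0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 10.0)]
        assert np.isnan(blocks[0][2])

    def test_first_block_drift_detected(self):
        windows = self._windows(seed=8)
        # plant a strong drift in the first 2 ps of every window
        for w in windows:
            mask = w.times < 2.0
            w.cv1 = w.cv1.copy()
            w.cv1[mask] = np.clip(w.cv1[mask] + 1.0, -1.2, 1.2)
        grid = GridSpec((-1.2, 1.2), (-0.6, 0.6), 0.3)
        blocks = block_convergence(windows, 2.0, grid=grid)
        devs = [b[2] for b in blocks[1:]]
        assert devs[0] == max(devs)

    def test_stationary_windows_no_trend(self):
        windows = self._windows(seed=4)
        grid = GridSpec((-1.2, 1.2), (-0.6, 0.6), 0.3)
        blocks = block_convergence(windows, 2.0, grid=grid)
        devs = np.array([b[2] for b in blocks[1:]])
        # deviations stay at the sampling-noise scale without a monotone
        # increase
        assert np.all(devs < 1.5)
        assert not np.all(np.diff(devs) > 0)
        assert devs.max() < 2 * devs.min() + 0.5

    def test_block_longer_than_series_raises(self):
        windows = self._windows(n_per_window=200)
        with pytest.raises(ValueError, match="block"):
            block_convergence(windows, 8.0, grid=GridSpec((-1.2, 1.2), (-0.6, 0.6), 0.3))


def test_pmf_tsv_roundtrip(tmp_path, double_well_windows):
    _, windows = double_well_windows
    res = wham2d(windows, grid=GridSpec((-1.5, 1.5), (-0.75, 0.75), 0.25))
    p = tmp_path / "pmf.tsv"
    write_pmf(res, p)
    c1, c2, g, n = read_pmf(p)
    assert np.allclose(c1, res.cv1_centers)
    occ = res.occupied
    assert np.allclose(g[occ], res.free_energy[occ], atol=1e-6)
    assert np.array_equal(n, res.counts)


def test_marginal_projection_matches_1d_histogram():
    """Boltzmann-weighted marginal over CV2 of an unbiased 2D histogram
    equals the Boltzmann-inverted 1D histogram of the CV1 samples on the
    same bin edges."""
    surf = harmonic(k=2.0, ndim=2)
    samples = metropolis_sample(surf, n=20_000, step_size=0.5, seed=5)
    w = _single_unbiased_window(samples)
    grid = GridSpec((-2.0, 2.0), (-2.0, 2.0), 0.2)
    res = wham2d([w], grid=grid)
    centers, marg = res.marginal(axis=0)

    e1, e2 = grid.edges()
    in_range = (w.cv2 >= e2[0]) & (w.cv2 <= e2[-1])
    h, _ = np.histogram(w.cv1[in_range], bins=e1)
    kt = R_KCAL * DEFAULT_TEMPERATURE
    with np.errstate(divide="ignore"):
        ref = np.where(h > 0, -kt * np.log(h / h.sum()), np.nan)
    ref -= np.nanmin(ref)
    mask = ~np.isnan(marg) & ~np.isnan(ref)
    assert mask.sum() > 5
    assert np.allclose(marg[mask], ref[mask], atol=1e-9)
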