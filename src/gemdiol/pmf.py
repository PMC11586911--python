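"""2D potential of mean force by the weighted histogram analysis method.

Biased samples from W umbrella windows are combined on a common grid by
self-consistent iteration of the WHAM equations

    p(x) = Σ_i n_i(x)  /  Σ_i N_i exp[(f_i − U_i(x)) / kT]
    f_i  = −kT ln Σ_x p(x) exp[−U_i(x) / kT]

where n_i(x) are window i's cell counts, N_i its total in-grid count,
U_i(x) its harmonic bias at the cell centre, and f_i its free-energy
shift constant (gauge-fixed to f_1 = 0).  Iteration stops when the
maximum change in the f_i (or, optionally, in the cell probabilities)
drops below the tolerance, default 1e-5.  All accumulations run in the
log domain, so stiff biases at low temperature do not underflow.

The estimator is exposed in model/results form: construct a
:class:`Wham2D` from windows and a grid, call :meth:`Wham2D.fit`, and
read the free-energy surface and diagnostics off the returned
:class:`PMFResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .landscape import DEFAULT_TEMPERATURE, R_KCAL
from .umbrella import GridSpec, UmbrellaWindow

__all__ = ["Wham2D", "PMFResult", "wham2d", "block_convergence", "write_pmf", "read_pmf"]


@dataclass
class PMFResult:
    """Fitted 2D free-energy surface plus estimation diagnostics.

    ``free_energy`` is min-shifted to zero over occupied cells and NaN
    where no window contributed samples.  ``f_windows`` are the window
    shift constants with the first window gauged to zero.
    """

    cv1_centers: np.ndarray
    cv2_centers: np.ndarray
    free_energy: np.ndarray  # (n1, n2), kcal/mol, NaN unsampled
    counts: np.ndarray  # (n1, n2) pooled histogram
    f_windows: np.ndarray  # (W,), kcal/mol, f_1 = 0
    temperature: float
    tolerance: float
    criterion: str
    n_iter: int
    converged: bool
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def marginal(self, axis: int = 0):
        """Boltzmann-weighted 1D projection onto one CV.

        Returns (centers, ΔG) with ΔG = −kT ln Σ_other exp(−G/kT),
        min-shifted.
        """
        kt = R_KCAL * self.temperature
        g = np.where(self.occupied, self.free_energy, np.inf)
        # integrate out the *other* axis
        proj = -kt * logsumexp(-g / kt, axis=1 - axis)
        proj[np.isinf(proj)] = np.nan
        proj -= np.nanmin(proj)
        centers = self.cv1_centers if axis == 0 else self.cv2_centers
        return centers, proj

    def summary(self) -> str:
        occ = self.occupied
        lines = [
            "2D-PMF (WHAM) results",
            "=" * 42,
            f"grid             : {len(self.cv1_centers)} x {len(self.cv2_centers)} cells",
            f"occupied cells   : {int(occ.sum())}",
            f"pooled samples   : {int(self.counts.sum())}",
            f"windows          : {len(self.f_windows)}",
            f"temperature      : {self.temperature:.2f} K",
            f"criterion        : max |d{self.criterion}| < {self.tolerance:g}",
            f"iterations       : {self.n_iter}",
            f"converged        : {self.converged}",
            f"G range (kcal/mol): 0.0 .. {np.nanmax(self.free_energy):.3f}",
            f"f_i range (kcal/mol): {self.f_windows.min():.3f} .. {self.f_windows.max():.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        from .plotting import plot_pmf

        return plot_pmf(self, ax=ax, **kwargs)


class Wham2D:
    """Self-consistent WHAM model over a set of umbrella windows.

    Parameters
    ----------
    windows : list of UmbrellaWindow
        Windows carrying CV time series, centres and force constants.
    grid : GridSpec
        Histogram grid; by default cells coincide with the production
        window spacing (0.1 Å).
    temperature : float
        Sampling temperature in K.
    tolerance : float
        Convergence threshold, kcal/mol on the f_i by default.
    criterion : {"f", "p"}
        Whether the threshold applies to window shift constants ("f")
        or to cell probabilities ("p").
    max_iter : int
        Direct-iteration cap.
    """

    def __init__(
        self,
        windows: list[UmbrellaWindow],
        grid: GridSpec | None = None,
        temperature: float = DEFAULT_TEMPERATURE,
        tolerance: float = 1e-5,
        criterion: str = "f",
        max_iter: int = 100_000,
    ):
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if criterion not in ("f", "p"):
            raise ValueError("criterion must be 'f' or 'p'")
        self.windows = windows
        self.grid = grid or GridSpec()
        self.temperature = temperature
        self.tolerance = tolerance
        self.criterion = criterion
        self.max_iter = max_iter

    def fit(self) -> PMFResult:
        kt = R_KCAL * self.temperature
        beta = 1.0 / kt
        e1, e2 = self.grid.edges()
        c1, c2 = self.grid.centers()
        n1, n2 = len(c1), len(c2)

        counts = np.zeros((n1, n2))
        n_window = np.zeros(len(self.windows))
        for i, w in enumerate(self.windows):
            if w.n_samples == 0:
                raise ValueError(f"window {w.index} has no samples")
            h, _, _ = np.histogram2d(w.cv1, w.cv2, bins=[e1, e2])
            if h.sum() == 0:
                raise ValueError(f"window {w.index} has no in-grid samples")
            counts += h
            n_window[i] = h.sum()

        occ = counts > 0
        cells = np.argwhere(occ)
        x1 = c1[cells[:, 0]]
        x2 = c2[cells[:, 1]]
        log_n = np.log(counts[occ])  # (M,)

        # bias energy of every window at every occupied cell centre
        centers = np.array([w.center for w in self.windows])  # (W, 2)
        ks = np.array([w.force_constants for w in self.windows])  # (W, 2)
        u = 0.5 * ks[:, 0:1] * (x1[None, :] - centers[:, 0:1]) ** 2 + 0.5 * ks[
            :, 1:2
        ] * (x2[None, :] - centers[:, 1:2]) ** 2  # (W, M)

        log_nw = np.log(n_window)  # (W,)
        bu = beta * u
        bf = np.zeros(len(self.windows))  # beta * f_i

        converged = False
        residuals = []
        log_p = None
        for it in range(1, self.max_iter + 1):
            # log p(x) = log n(x) − logsumexp_i(log N_i + βf_i − βU_i(x))
            denom = logsumexp(log_nw[:, None] + bf[:, None] - bu, axis=0)
            new_log_p = log_n - denom
            new_log_p -= logsumexp(new_log_p)
            # βf_i = −logsumexp_x(log p(x) − βU_i(x))
            new_bf = -logsumexp(new_log_p[None, :] - bu, axis=1)
            new_bf -= new_bf[0]

            if self.criterion == "f":
                resid = float(np.max(np.abs(new_bf - bf)) * kt)
            else:
                resid = (
                    float(np.max(np.abs(np.exp(new_log_p) - np.exp(log_p))))
                    if log_p is not None
                    else np.inf
                )
            residuals.append(resid)
            bf, log_p = new_bf, new_log_p
            if resid < self.tolerance:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"WHAM did not converge in {self.max_iter} iterations "
                f"(last residual {residuals[-1]:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )

        g_cells = -kt * log_p
        g_cells -= g_cells.min()
        g = np.full((n1, n2), np.nan)
        g[cells[:, 0], cells[:, 1]] = g_cells

        return PMFResult(
            cv1_centers=c1,
            cv2_centers=c2,
            free_energy=g,
            counts=counts.astype(int),
            f_windows=bf * kt,
            temperature=self.temperature,
            tolerance=self.tolerance,
            criterion=self.criterion,
            n_iter=it,
            converged=converged,
            residual_history=np.array(residuals),
        )


def wham2d(
    windows,
    grid: GridSpec | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = 1e-5,
    max_iter: int = 100_000,
    criterion: str = "f",
) -> PMFResult:
    """Functional wrapper: ``Wham2D(...).fit()``."""
    return Wham2D(
        windows,
        grid=grid,
        temperature=temperature,
        tolerance=tolerance,
        criterion=criterion,
        max_iter=max_iter,
    ).fit()


def block_convergence(
    windows,
    block_length: float,
    grid: GridSpec | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = 1e-5,
    max_iter: int = 100_000,
):
    """Per-time-block PMFs and their successive deviations.

    Each window's series is cut into consecutive blocks of
    ``block_length`` ps (e.g. a 10 ps series with 2 ps blocks gives the
    five intervals 0–2, 2–4, 4–6, 6–8, 8–10).  WHAM runs on each block;
    the deviation between consecutive blocks is the maximum absolute
    free-energy difference over their common occupied cells after
    min-shifting each PMF on those cells.

    Returns a list of ``(interval, PMFResult, deviation)``; the first
    block's deviation is NaN.
    """
    if block_length <= 0:
        raise ValueError("block length must be positive")
    spans = [w.times.max() - w.times.min() for w in windows]
    span = min(spans)
    if span < 2 * block_length - 1e-9:
        raise ValueError(
            f"series span {span:.3f} ps shorter than two blocks of "
            f"{block_length:.3f} ps"
        )
    t0 = min(w.times.min() for w in windows)
    n_blocks = int(np.floor((span + 1e-9) / block_length))

    results = []
    prev = None
    for b in range(n_blocks):
        lo = t0 + b * block_length
        hi = lo + block_length
        sub = []
        for w in windows:
            if b == n_blocks - 1:
                mask = (w.times >= lo - 1e-12) & (w.times <= hi + 1e-12)
            else:
                mask = (w.times >= lo - 1e-12) & (w.times < hi - 1e-12)
            sub.append(
                UmbrellaWindow(
                    index=w.index,
                    center=w.center,
                    force_constants=w.force_constants,
                    times=w.times[mask],
                    cv1=w.cv1[mask],
                    cv2=w.cv2[mask],
                )
            )
        res = wham2d(
            sub, grid=grid, temperature=temperature, tolerance=tolerance,
            max_iter=max_iter,
        )
        if prev is None:
            dev = np.nan
        else:
            common = prev.occupied & res.occupied
            a = prev.free_energy[common]
            bb = res.free_energy[common]
            a = a - a.min()
            bb = bb - bb.min()
            dev = float(np.max(np.abs(a - bb)))
        interval = (lo - t0, hi - t0)
        results.append((interval, res, dev))
        prev = res
    return results


def write_pmf(result: PMFResult, path) -> None:
    """Tab-separated `cv1 cv2 free_energy count` with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{result.temperature}\n")
        fh.write(f"# tolerance\t{result.tolerance}\n")
        fh.write(f"# criterion\t{result.criterion}\n")
        fh.write(f"# iterations\t{result.n_iter}\n")
        fh.write(f"# converged\t{result.converged}\n")
        fh.write("cv1\tcv2\tfree_energy\tcount\n")
        for i, a in enumerate(result.cv1_centers):
            for j, b in enumerate(result.cv2_centers):
                g = result.free_energy[i, j]
                gtxt = "unsampled" if np.isnan(g) else f"{g:.6f}"
                fh.write(f"{a:.6f}\t{b:.6f}\t{gtxt}\t{int(result.counts[i, j])}\n")


def read_pmf(path):
    """Read a PMF table back into (cv1_centers, cv2_centers, G, counts)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", na_values=["unsampled"])
    c1 = np.sort(df["cv1"].unique())
    c2 = np.sort(df["cv2"].unique())
    g = np.full((len(c1), len(c2)), np.nan)
    n = np.zeros((len(c1), len(c2)), dtype=int)
    i1 = np.searchsorted(c1, df["cv1"].to_numpy())
    i2 = np.searchsorted(c2, df["cv2"].to_numpy())
    g[i1, i2] = df["free_energy"].to_numpy()
    n[i1, i2] = df["count"].to_numpy()
    return c1, c2, g, n
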