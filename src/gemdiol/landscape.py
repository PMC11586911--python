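"""Histogram free-energy profiles and torsion log-probability maps.

The conformational free energy along a scalar coordinate x is the
Boltzmann inversion of its sampled distribution,

    ΔG(x) = −RT ln P(x),

estimated per histogram bin and shifted so the global minimum is zero.
Unsampled bins carry NaN (an explicit "unsampled" marker) rather than
+inf so downstream arithmetic must handle them deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "Profile1D",
    "LogProbMap2D",
    "free_energy_profile",
    "torsion_map",
    "profile_extrema",
    "write_profile",
]

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872041e-3

#: Simulation temperature (K) used throughout unless overridden.
DEFAULT_TEMPERATURE = 303.15


@dataclass
class Profile1D:
    """1D free-energy profile: −RT ln P per occupied bin, min-shifted to 0."""

    bin_centers: np.ndarray  # Å
    free_energy: np.ndarray  # kcal/mol; NaN where unsampled
    counts: np.ndarray  # int per bin
    temperature: float  # K
    bin_width: float  # Å

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def __post_init__(self) -> None:
        occ = self.counts > 0
        if occ.any():
            assert abs(np.nanmin(self.free_energy[occ])) < 1e-9


@dataclass
class LogProbMap2D:
    """2D log-probability map on a periodic torsion grid, natural-log units."""

    x_centers: np.ndarray  # degrees
    y_centers: np.ndarray  # degrees
    log_prob: np.ndarray  # shape (nx, ny); NaN where unsampled
    counts: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def free_energy_profile(
    samples, bin_width: float = 0.1, temperature: float = DEFAULT_TEMPERATURE
) -> Profile1D:
    """Boltzmann-invert a sample distribution into a free-energy profile.

    Parameters
    ----------
    samples : array-like of float
        Sampled coordinate values (Å).
    bin_width : float
        Histogram bin width (Å).  Bin edges are aligned to integer
        multiples of the width so profiles from different runs share a
        lattice.
    temperature : float
        Sampling temperature (K).

    Returns
    -------
    Profile1D
        ΔG = −RT ln(count/total) per occupied bin, global minimum at 0.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample list")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(samples, bins=edges)

    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        g = np.where(counts > 0, -rt * np.log(counts / counts.sum()), np.nan)
    g -= np.nanmin(g)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(
        bin_centers=centers,
        free_energy=g,
        counts=counts,
        temperature=temperature,
        bin_width=bin_width,
    )


def _wrap_degrees(x: np.ndarray) -> np.ndarray:
    """Map angles to the half-open interval (−180, 180]."""
    return -((-np.asarray(x, float) + 180.0) % 360.0 - 180.0)


def torsion_map(x_samples, y_samples, bins: int = 72) -> LogProbMap2D:
    """Log-probability map of a torsion pair on (−180, 180]².

    Angles are wrapped periodically before binning, so samples just
    either side of ±180° land in adjacent wrap-around cells and none are
    lost.  ``log_prob`` holds ln(count/total) for occupied cells; the
    normalisation is over in-range (i.e. all) samples.
    """
    x = _wrap_degrees(x_samples)
    y = _wrap_degrees(y_samples)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if bins < 2:
        raise ValueError("need at least 2 bins")

    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    counts = counts.astype(int)
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, np.log(counts / counts.sum()), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return LogProbMap2D(x_centers=centers, y_centers=centers, log_prob=logp, counts=counts)


def profile_extrema(profile: Profile1D):
    """Locate minima and the barriers separating consecutive minima.

    Works on the occupied, contiguous part of the profile by discrete
    neighbour comparison; flat plateaus collapse to their centre bin.

    Returns a list of ``(position Å, value kcal/mol, kind)`` with kind
    in {"minimum", "barrier"}, ordered by position.
    """
    occ = profile.occupied
    idx = np.flatnonzero(occ)
    if idx.size < 3:
        raise ValueError("need at least 3 occupied bins")
    # operate on the longest contiguous occupied run containing data
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = max(runs, key=len)
    if run.size < 3:
        raise ValueError("need at least 3 contiguous occupied bins")
    g = profile.free_energy[run]
    x = profile.bin_centers[run]

    minima_idx = _plateau_extrema(g, kind="min")
    results = [(float(x[i]), float(g[i]), "minimum") for i in minima_idx]
    # barrier = maximum between consecutive minima
    for a, b in zip(minima_idx[:-1], minima_idx[1:]):
        seg = slice(a, b + 1)
        j = a + int(np.argmax(g[seg]))
        results.append((float(x[j]), float(g[j]), "barrier"))
    results.sort(key=lambda t: t[0])
    return results


def _plateau_extrema(g: np.ndarray, kind: str) -> list[int]:
    """Indices of local minima of g, plateaus collapsed to their centre."""
    n = g.size
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and g[j + 1] == g[i]:
            j += 1
        left_ok = i == 0 or g[i - 1] > g[i]
        right_ok = j == n - 1 or g[j + 1] > g[j]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            out.append((i + j) // 2)
        elif i == 0 and j == n - 1:
            out.append((i + j) // 2)  # entirely flat: single centre minimum
        i = j + 1
    return out


def write_profile(profile: Profile1D, path) -> None:
    """Tab-separated profile with a comment header recording metadata."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{profile.temperature}\n")
        fh.write(f"# bin_width\t{profile.bin_width}\n")
        fh.write(f"# n_samples\t{int(profile.counts.sum())}\n")
        fh.write("bin_center\tfree_energy\tcount\n")
        for c, g, n in zip(profile.bin_centers, profile.free_energy, profile.counts):
            gtxt = "unsampled" if np.isnan(g) else f"{g:.6f}"
            fh.write(f"{c:.6f}\t{gtxt}\t{int(n)}\n")
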