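"""Analytic model potentials with known minima and barriers.

These play the role of the enzyme's unknown free-energy landscape in
tests and synthetic datasets: every surface is bounded below and its
stationary points are available in closed form or by dense scanning, so
estimator output can be compared against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .landscape import DEFAULT_TEMPERATURE, R_KCAL

__all__ = [
    "ModelSurface",
    "harmonic",
    "double_well_1d",
    "double_well_2d",
    "tilted_double_well",
    "three_well_1d",
    "quadrature_profile",
    "scan_barrier_1d",
]


@dataclass(frozen=True)
class ModelSurface:
    """A named analytic potential V(x[, y]) in kcal/mol, coordinates Å."""

    name: str
    ndim: int
    func: Callable = field(repr=False)
    params: dict = field(default_factory=dict)

    def __call__(self, x, y=None):
        if self.ndim == 1:
            return self.func(np.asarray(x, float))
        if y is None:
            xy = np.asarray(x, float)
            return self.func(xy[..., 0], xy[..., 1])
        return self.func(np.asarray(x, float), np.asarray(y, float))


def harmonic(k: float = 1.0, center: float = 0.0, ndim: int = 1) -> ModelSurface:
    """V = ½k Σ (q − center)²."""
    if ndim == 1:
        return ModelSurface(
            "harmonic", 1, lambda x: 0.5 * k * (x - center) ** 2, {"k": k, "center": center}
        )
    return ModelSurface(
        "harmonic",
        2,
        lambda x, y: 0.5 * k * ((x - center) ** 2 + (y - center) ** 2),
        {"k": k, "center": center},
    )


def double_well_1d(barrier: float = 2.0, half_separation: float = 1.0) -> ModelSurface:
    """V(x) = h((x/a)² − 1)²: minima at ±a (V=0), barrier h at x=0."""
    a = half_separation

    def v(x):
        return barrier * ((x / a) ** 2 - 1.0) ** 2

    return ModelSurface(
        "double_well_1d", 1, v, {"barrier": barrier, "half_separation": a}
    )


def double_well_2d(barrier: float = 2.0, ky: float = 4.0) -> ModelSurface:
    """V(x, y) = h(x² − 1)² + ½ ky y².

    Minima at (±1, 0) with V = 0; the saddle between them sits at the
    origin with height exactly ``barrier``.
    """

    def v(x, y):
        return barrier * (x**2 - 1.0) ** 2 + 0.5 * ky * y**2

    return ModelSurface("double_well_2d", 2, v, {"barrier": barrier, "ky": ky})


def tilted_double_well(
    barrier: float = 2.0, tilt: float = 0.5, ky: float = 4.0
) -> ModelSurface:
    """Asymmetric variant: V(x, y) = h(x² − 1)² + ½ ky y² + t·x."""

    def v(x, y):
        return barrier * (x**2 - 1.0) ** 2 + 0.5 * ky * y**2 + tilt * x

    return ModelSurface(
        "tilted_double_well", 2, v, {"barrier": barrier, "tilt": tilt, "ky": ky}
    )


def three_well_1d(
    positions: tuple = (4.5, 7.0, 8.5),
    depths: tuple = (2.5, 2.0, 1.8),
    width: float = 0.45,
) -> ModelSurface:
    """Three-well potential emulating a catalytic-dyad distance landscape.

    Built as the negative log of a Gaussian mixture, so well positions
    sit at the stated distances (Å) with controllable relative depths
    (kcal/mol, larger = deeper).  Barriers are obtained numerically by
    dense scan.
    """
    positions = np.asarray(positions, float)
    depths = np.asarray(depths, float)
    weights = np.exp(depths - depths.max())

    def v_raw(x):
        x = np.asarray(x, float)
        z = np.sum(
            weights[:, None]
            * np.exp(-((x[None, ...] - positions[:, None]) ** 2) / (2 * width**2)),
            axis=0,
        )
        return -np.log(np.maximum(z, 1e-300))

    shift = v_raw(positions).min()

    return ModelSurface(
        "three_well_1d",
        1,
        lambda x: v_raw(x) - shift,
        {"positions": tuple(positions), "depths": tuple(depths), "width": width},
    )


def quadrature_profile(
    surface: ModelSurface,
    edges: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    points_per_bin: int = 64,
) -> np.ndarray:
    """Exact binned free energies by Boltzmann integration of V.

    For each bin, G = −RT ln ∫_bin exp(−V/RT) dx (composite trapezoid),
    min-shifted — the quadrature oracle a histogram estimator should
    converge to.
    """
    if surface.ndim != 1:
        raise ValueError("quadrature_profile handles 1D surfaces")
    rt = R_KCAL * temperature
    g = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        x = np.linspace(lo, hi, points_per_bin)
        w = np.exp(-surface(x) / rt)
        g[i] = -rt * np.log(np.trapezoid(w, x))
    return g - g.min()


def scan_barrier_1d(
    surface: ModelSurface, lo: float, hi: float, n: int = 20001
) -> dict:
    """Dense-scan stationary points of a 1D potential on [lo, hi].

    Returns positions/values of local minima and of the maxima between
    consecutive minima.
    """
    x = np.linspace(lo, hi, n)
    v = surface(x)
    minima = [
        (float(x[i]), float(v[i]))
        for i in range(1, n - 1)
        if v[i] < v[i - 1] and v[i] < v[i + 1]
    ]
    barriers = []
    for (xa, _), (xb, _) in zip(minima[:-1], minima[1:]):
        seg = (x >= xa) & (x <= xb)
        j = np.argmax(np.where(seg, v, -np.inf))
        barriers.append((float(x[j]), float(v[j])))
    return {"minima": minima, "barriers": barriers}
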