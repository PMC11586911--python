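"""Umbrella-sampling window grids, seeding, and harmonic biases.

The reaction is followed on two collective variables: CV1 (proton
transfer from the protonated Asp to the carbonyl oxygen, d(O1–H) −
d(O–H)) and CV2 (nucleophilic attack / water proton abstraction,
d(Ow–Hw) − d(Ow–C1)), both in Å.  The production grid spans CV1 in
[−2.0, 2.0] and CV2 in [−2.0, 1.5] at 0.1 Å spacing — 41 × 36 = 1476
windows.  Each window is seeded with the exploratory (metadynamics-like)
sample closest to its centre in CV space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVSample",
    "UmbrellaWindow",
    "GridSpec",
    "PRODUCTION_CV1_RANGE",
    "PRODUCTION_CV2_RANGE",
    "PRODUCTION_STEP",
    "build_window_grid",
    "seed_windows",
    "harmonic_bias",
    "write_window_manifest",
    "read_window_manifest",
    "write_timeseries",
    "read_timeseries",
]

#: Production CV ranges (Å) and step used for the full 1476-window grid.
PRODUCTION_CV1_RANGE = (-2.0, 2.0)
PRODUCTION_CV2_RANGE = (-2.0, 1.5)
PRODUCTION_STEP = 0.1

#: Default harmonic restraint stiffness per CV, kcal/(mol·Å²).
DEFAULT_FORCE_CONSTANT = 100.0


@dataclass(frozen=True)
class CVSample:
    """One exploratory-phase structure's position in CV space."""

    index: int
    cv1: float
    cv2: float
    frame_id: int = -1

    def __post_init__(self):
        if not (np.isfinite(self.cv1) and np.isfinite(self.cv2)):
            raise ValueError("non-finite CV values")


@dataclass
class UmbrellaWindow:
    """One biased-sampling window: centre, stiffness, seed, time series."""

    index: int
    center: tuple[float, float]  # (cv1_ref, cv2_ref), Å
    force_constants: tuple[float, float] = (
        DEFAULT_FORCE_CONSTANT,
        DEFAULT_FORCE_CONSTANT,
    )
    seed_sample: CVSample | None = None
    times: np.ndarray = field(default_factory=lambda: np.empty(0))  # ps
    cv1: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv2: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if not all(k > 0 for k in self.force_constants):
            raise ValueError("force constants must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.cv1)

    def samples(self) -> np.ndarray:
        return np.column_stack([self.cv1, self.cv2])


@dataclass(frozen=True)
class GridSpec:
    """Regular 2D binning: (min, max) per axis and the cell width(s).

    ``width`` applies to CV1 and, unless ``width2`` is given, to CV2.
    """

    cv1_range: tuple[float, float] = PRODUCTION_CV1_RANGE
    cv2_range: tuple[float, float] = PRODUCTION_CV2_RANGE
    width: float = PRODUCTION_STEP
    width2: float | None = None

    @property
    def _w2(self) -> float:
        return self.width if self.width2 is None else self.width2

    def centers(self):
        c1 = _lattice(self.cv1_range, self.width)
        c2 = _lattice(self.cv2_range, self._w2)
        return c1, c2

    def edges(self):
        c1, c2 = self.centers()
        e1 = np.concatenate([c1 - self.width / 2, [c1[-1] + self.width / 2]])
        e2 = np.concatenate([c2 - self._w2 / 2, [c2[-1] + self._w2 / 2]])
        return e1, e2


def _lattice(rng: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = rng
    if hi < lo:
        raise ValueError(f"range max {hi} < min {lo}")
    if step <= 0:
        raise ValueError("step must be positive")
    n_float = (hi - lo) / step
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 * max(1.0, abs(n_float)):
        raise ValueError(f"range {rng} not commensurate with step {step}")
    return lo + step * np.arange(n + 1)


def build_window_grid(
    cv1_range: tuple[float, float] = PRODUCTION_CV1_RANGE,
    cv1_step: float = PRODUCTION_STEP,
    cv2_range: tuple[float, float] = PRODUCTION_CV2_RANGE,
    cv2_step: float = PRODUCTION_STEP,
    force_constants: tuple[float, float] = (
        DEFAULT_FORCE_CONSTANT,
        DEFAULT_FORCE_CONSTANT,
    ),
) -> list[UmbrellaWindow]:
    """Cartesian window grid over inclusive endpoint-to-endpoint centres.

    The production defaults give 41 × 36 = 1476 windows.  Raises
    ``ValueError`` if a range is not an integer number of steps.
    """
    c1 = _lattice(cv1_range, cv1_step)
    c2 = _lattice(cv2_range, cv2_step)
    windows = []
    idx = 0
    for a in c1:
        for b in c2:
            windows.append(
                UmbrellaWindow(
                    index=idx,
                    center=(float(a), float(b)),
                    force_constants=force_constants,
                )
            )
            idx += 1
    return windows


def seed_windows(
    samples: list[CVSample],
    windows: list[UmbrellaWindow],
    exponent: float = 2.0,
    weights: tuple[float, float] = (1.0, 1.0),
) -> list[UmbrellaWindow]:
    """Assign each window the exploratory sample nearest its centre.

    The selection value for window i and sample j is

        v_i(j) = w1·|CV1_j − CV1_i,ref|^p + w2·|CV2_j − CV2_i,ref|^p

    with p = 2 and unit weights by default (squared Euclidean distance in
    CV space).  Ties break to the smallest sample index j.  Windows are
    modified in place and returned.
    """
    if not samples:
        raise ValueError("empty sample list")
    pts = np.array([(s.cv1, s.cv2) for s in samples])  # (S, 2)
    centers = np.array([w.center for w in windows])  # (W, 2)
    d = np.abs(centers[:, None, :] - pts[None, :, :])  # (W, S, 2)
    v = weights[0] * d[:, :, 0] ** exponent + weights[1] * d[:, :, 1] ** exponent
    best = np.argmin(v, axis=1)  # first occurrence wins ties -> smallest j
    for w, j in zip(windows, best):
        w.seed_sample = samples[int(j)]
    return windows


def harmonic_bias(cv, center, k) -> float:
    """Bias energy ½k1(cv1−c1)² + ½k2(cv2−c2)², kcal/mol."""
    if any(ki <= 0 for ki in k):
        raise ValueError("force constants must be positive")
    return float(
        0.5 * k[0] * (cv[0] - center[0]) ** 2 + 0.5 * k[1] * (cv[1] - center[1]) ** 2
    )


# -- I/O --------------------------------------------------------------------


def write_window_manifest(windows, path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tcv1_ref\tcv2_ref\tk1\tk2\tseed_frame\n")
        for w in windows:
            seed = w.seed_sample.frame_id if w.seed_sample is not None else -1
            fh.write(
                f"{w.index}\t{w.center[0]:.6f}\t{w.center[1]:.6f}\t"
                f"{w.force_constants[0]:.6f}\t{w.force_constants[1]:.6f}\t{seed}\n"
            )


def read_window_manifest(path) -> list[UmbrellaWindow]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    windows = []
    for _, row in df.iterrows():
        windows.append(
            UmbrellaWindow(
                index=int(row["index"]),
                center=(float(row["cv1_ref"]), float(row["cv2_ref"])),
                force_constants=(float(row["k1"]), float(row["k2"])),
            )
        )
    return windows


def write_timeseries(window: UmbrellaWindow, path) -> None:
    """PLUMED-COLVAR-style layout: '#' comments, then time cv1 cv2."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv1 cv2\n")
        fh.write(
            f"# window {window.index} center {window.center[0]:.4f} "
            f"{window.center[1]:.4f} k {window.force_constants[0]:.4f} "
            f"{window.force_constants[1]:.4f}\n"
        )
        for t, a, b in zip(window.times, window.cv1, window.cv2):
            fh.write(f"{t:.6f}\t{a:.8f}\t{b:.8f}\n")


def read_timeseries(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1], data[:, 2]
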