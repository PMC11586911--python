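"""Matplotlib views of profiles, torsion maps, PMFs and paths."""

from __future__ import annotations

import numpy as np


def plot_profile(profile, ax=None, **kwargs):
    """1D free-energy profile; unsampled bins left blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.bin_centers, profile.free_energy, **kwargs)
    ax.set_xlabel(r"$dd_\mathrm{Asp}$ ($\mathrm{\AA}$)")
    ax.set_ylabel(r"$\Delta G$ (kcal/mol)")
    return ax


def plot_torsion_map(tmap, ax=None, **kwargs):
    """Log-probability heat map of a torsion pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(
        tmap.x_centers, tmap.y_centers, tmap.log_prob.T, shading="nearest", **kwargs
    )
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel(r"$\psi$ (deg)")
    ax.figure.colorbar(mesh, ax=ax, label=r"$\ln P$")
    return ax


def plot_pmf(result, ax=None, path=None, levels=20, **kwargs):
    """2D PMF contour map, optionally with an MFEP overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g = np.ma.masked_invalid(result.free_energy)
    cs = ax.contourf(
        result.cv1_centers, result.cv2_centers, g.T, levels=levels, **kwargs
    )
    ax.figure.colorbar(cs, ax=ax, label=r"$\Delta G$ (kcal/mol)")
    if path is not None:
        xs = [c[0] for c in path.coords]
        ys = [c[1] for c in path.coords]
        ax.plot(xs, ys, "w.-", lw=1.5, ms=4)
        if path.stationary:
            for name, k in path.stationary.items():
                ax.annotate(name, path.coords[k], color="red", fontweight="bold")
    ax.set_xlabel(r"CV1 ($\mathrm{\AA}$)")
    ax.set_ylabel(r"CV2 ($\mathrm{\AA}$)")
    return ax


def plot_path_profile(path, ax=None, **kwargs):
    """Free-energy profile along an MFEP with RS/TS/GD marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(range(len(path.profile)), path.profile, "k.-", **kwargs)
    if path.stationary:
        for name, k in path.stationary.items():
            ax.annotate(name, (k, path.profile[k]), color="red")
    ax.set_xlabel("path step")
    ax.set_ylabel(r"$\Delta G$ (kcal/mol)")
    return ax
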