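"""Ground-truth synthetic inputs for every pipeline stage.

Real inputs to this pipeline come out of microsecond-scale molecular
dynamics and QM/MM enhanced sampling.  For testing and desk-scale runs,
this module fabricates each input with *known* generating parameters:

* Metropolis Monte Carlo samples from analytic model potentials
  (optionally under a harmonic umbrella bias), whose exact Boltzmann
  distribution is computable by quadrature;
* umbrella-window CV time series on 2D model surfaces;
* geometry frames with planted active-sub-state fractions that the
  classifier must recover;
* per-residue energy tables with planted transition-state stabilization
  effects plus Gaussian noise and arbitrary per-snapshot gauge offsets;
* small multi-frame PDB structures exercising the geometry reader.

All generators are seed-deterministic; ``dataset_manifest`` records the
generating parameters and a content hash for reproducibility audits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math

import numpy as np

from .active_state import SUBTYPE_LABELS
from .geometry import Atom, GeometryFrame, StructureModel
from .landscape import DEFAULT_TEMPERATURE, R_KCAL
from .surfaces import ModelSurface
from .umbrella import UmbrellaWindow

logger = logging.getLogger(__name__)

__all__ = [
    "metropolis_sample",
    "make_umbrella_dataset",
    "make_geometry_frames",
    "make_energy_tables",
    "make_structure_frames",
    "dataset_manifest",
]

BURN_IN_FRACTION = 0.1


def metropolis_sample(
    surface: ModelSurface,
    temperature: float = DEFAULT_TEMPERATURE,
    n: int = 10_000,
    step_size: float = 0.2,
    seed: int = 0,
    bias=None,
    x0=None,
) -> np.ndarray:
    """Metropolis chain targeting exp[−(V + bias)/kT].

    ``bias`` is an optional callable on the same coordinates (e.g. a
    window's harmonic restraint).  The first 10% of the chain is
    discarded as burn-in; the acceptance rate is logged.  Returns an
    array of shape (n,) for 1D surfaces or (n, 2) for 2D.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    kt = R_KCAL * temperature
    ndim = surface.ndim

    def energy(q):
        e = surface(q) if ndim == 1 else surface(q[0], q[1])
        if bias is not None:
            e = e + (bias(q) if ndim == 1 else bias(q))
        return float(e)

    if x0 is None:
        x0 = 0.0 if ndim == 1 else np.zeros(2)
    q = np.asarray(x0, float) if ndim == 2 else float(x0)
    e = energy(q)

    n_burn = int(math.ceil(BURN_IN_FRACTION * n))
    total = n + n_burn
    steps = rng.uniform(-step_size, step_size, size=(total, ndim))
    accept_u = rng.random(total)

    out = np.empty((n, ndim))
    accepted = 0
    for t in range(total):
        prop = q + (steps[t, 0] if ndim == 1 else steps[t])
        e_prop = energy(prop)
        if e_prop <= e or accept_u[t] < math.exp(-(e_prop - e) / kt):
            q, e = prop, e_prop
            accepted += 1
        if t >= n_burn:
            out[t - n_burn] = q
    logger.info(
        "metropolis_sample(%s): acceptance rate %.3f", surface.name, accepted / total
    )
    return out[:, 0] if ndim == 1 else out


def make_umbrella_dataset(
    surface: ModelSurface,
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    n_per_window: int = 5000,
    seed: int = 0,
    step_size: float = 0.1,
    duration_ps: float = 10.0,
) -> list[UmbrellaWindow]:
    """Biased Metropolis series for every window, vectorised across windows.

    All windows advance in lock-step: one proposal per window per sweep,
    accepted against V(x, y) plus that window's harmonic bias.  Chains
    start at their window centres; 10% burn-in is discarded.  Timestamps
    span [0, duration_ps] uniformly.  Windows are filled in place and
    returned.
    """
    if not windows:
        raise ValueError("windows must be nonempty")
    if surface.ndim != 2:
        raise ValueError("umbrella datasets require a 2D surface")
    rng = np.random.default_rng(seed)
    kt = R_KCAL * temperature
    nw = len(windows)

    centers = np.array([w.center for w in windows])  # (W, 2)
    ks = np.array([w.force_constants for w in windows])  # (W, 2)

    def total_energy(q):  # q: (W, 2)
        v = surface(q[:, 0], q[:, 1])
        b = 0.5 * ks[:, 0] * (q[:, 0] - centers[:, 0]) ** 2 + 0.5 * ks[:, 1] * (
            q[:, 1] - centers[:, 1]
        ) ** 2
        return v + b

    q = centers.copy()
    e = total_energy(q)
    n_burn = int(math.ceil(BURN_IN_FRACTION * n_per_window))
    total = n_per_window + n_burn
    series = np.empty((n_per_window, nw, 2))
    accepted = 0
    for t in range(total):
        prop = q + rng.uniform(-step_size, step_size, size=(nw, 2))
        e_prop = total_energy(prop)
        take = rng.random(nw) < np.exp(np.minimum(0.0, -(e_prop - e) / kt))
        q[take] = prop[take]
        e[take] = e_prop[take]
        accepted += int(take.sum())
        if t >= n_burn:
            series[t - n_burn] = q
    logger.info(
        "make_umbrella_dataset: mean acceptance %.3f", accepted / (total * nw)
    )

    times = np.linspace(0.0, duration_ps, n_per_window)
    for i, w in enumerate(windows):
        w.times = times.copy()
        w.cv1 = series[:, i, 0].copy()
        w.cv2 = series[:, i, 1].copy()
    return windows


# -- geometry frames with planted sub-states --------------------------------

_DEFAULT_TEMPLATES = {
    "dd_asp": (7.0, 0.3),  # mean, sd (Å)
    "torsions": {
        "phi_V50": (-80.0, 15.0),
        "psi_L49": (120.0, 15.0),
        "phi_L49": (-120.0, 12.0),
        "psi_T48": (130.0, 12.0),
        "phi_M51": (-100.0, 12.0),
        "psi_V50": (110.0, 12.0),
    },
}


def _wrap(x):
    return -((-x + 180.0) % 360.0 - 180.0)


def make_geometry_frames(
    fractions: dict[str, float],
    n: int = 1000,
    seed: int = 0,
    templates: dict | None = None,
    hb_cutoffs: tuple[float, float] = (3.5, 135.0),
    dowc_max: float = 3.5,
) -> list[GeometryFrame]:
    """Frames whose hydrogen-bond geometries realise planted sub-states.

    ``fractions`` maps sub-state labels (all from one protonated system)
    to target fractions; the remainder of the n frames is inactive.  A
    frame planted as sub-state S is drawn so that exactly the criteria
    defining S pass under the given cutoffs, so a correct classifier
    recovers the planted fractions up to multinomial noise (exactly, for
    pure fractions).
    """
    total = sum(fractions.values())
    if total > 1 + 1e-12:
        raise ValueError(f"fractions sum to {total} > 1")
    labels = list(fractions)
    if labels:
        systems = {
            sys for sys, labs in SUBTYPE_LABELS.items() if any(l in labs for l in labels)
        }
        for lab in labels:
            if not any(lab in labs for labs in SUBTYPE_LABELS.values()):
                raise ValueError(f"unknown sub-state label {lab!r}")
        if len(systems) > 1:
            raise ValueError("fractions must come from a single protonated system")
        system = systems.pop()
    else:
        system = "D257-P"
    prot = "D257" if system == "D257-P" else "D385"
    deprot = "D385" if system == "D257-P" else "D257"

    tpl = templates or _DEFAULT_TEMPLATES
    rng = np.random.default_rng(seed)
    d_cut, a_cut = hb_cutoffs

    probs = np.array(list(fractions.values()) + [1.0 - total])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    choices = rng.choice(len(labels) + 1, size=n, p=probs)

    def passing_bond(donor, acceptor):
        return (
            float(rng.uniform(2.6, d_cut - 0.05)),
            float(rng.uniform(a_cut + 10.0, 180.0)),
            donor,
            acceptor,
        )

    def failing_bond(donor, acceptor):
        return (
            float(rng.uniform(d_cut + 0.5, d_cut + 3.0)),
            float(rng.uniform(60.0, a_cut - 10.0)),
            donor,
            acceptor,
        )

    frames = []
    for fid, c in enumerate(choices):
        mu, sd = tpl["dd_asp"]
        dd = max(float(rng.normal(mu, sd)), 0.1)
        torsions = {
            lab: float(_wrap(rng.normal(m, s))) for lab, (m, s) in tpl["torsions"].items()
        }

        if c < len(labels):
            label = labels[c]
            # parse "Asp<P><x>_<D><y>"
            first, second = label[3:].split("_")
            x = "no" if first.endswith("no") else first[-1]
            y = second[-1]
            c3_atom = "OD1" if y == "i" else "OD2"
            c3_other = "OD2" if y == "i" else "OD1"
            bonds = [passing_bond(prot, "SUB:O1")]
            d_owc = float(rng.uniform(2.8, dowc_max - 0.05))
            bonds.append(passing_bond("WAT:H1", f"{deprot}:{c3_atom}"))
            bonds.append(failing_bond("WAT:H1", f"{deprot}:{c3_other}"))
            if x == "no":
                bonds.append(failing_bond("WAT:H2", f"{prot}:OD1"))
                bonds.append(failing_bond("WAT:H2", f"{prot}:OD2"))
            else:
                c4_atom = "OD1" if x == "i" else "OD2"
                c4_other = "OD2" if x == "i" else "OD1"
                bonds.append(passing_bond("WAT:H2", f"{prot}:{c4_atom}"))
                bonds.append(failing_bond("WAT:H2", f"{prot}:{c4_other}"))
        else:
            # inactive: break one criterion at random (always criterion
            # geometries present so the classifier can evaluate them)
            broken = rng.integers(0, 3)
            bonds = []
            if broken == 0:
                bonds.append(failing_bond(prot, "SUB:O1"))
                d_owc = float(rng.uniform(2.8, dowc_max - 0.05))
                bonds.append(passing_bond("WAT:H1", f"{deprot}:OD1"))
            elif broken == 1:
                bonds.append(passing_bond(prot, "SUB:O1"))
                d_owc = float(rng.uniform(dowc_max + 0.1, dowc_max + 3.0))
                bonds.append(passing_bond("WAT:H1", f"{deprot}:OD1"))
            else:
                bonds.append(passing_bond(prot, "SUB:O1"))
                d_owc = float(rng.uniform(2.8, dowc_max - 0.05))
                bonds.append(failing_bond("WAT:H1", f"{deprot}:OD1"))
                bonds.append(failing_bond("WAT:H1", f"{deprot}:OD2"))
            bonds.append(failing_bond("WAT:H2", f"{prot}:OD1"))

        frames.append(
            GeometryFrame(
                frame_id=fid,
                dd_asp=dd,
                torsions=torsions,
                d_OwC=d_owc,
                hb_geometries=[
                    (d, a, dn if ":" in dn else f"{dn}:OH", an)
                    for d, a, dn, an in bonds
                ],
            )
        )
    return frames


def make_energy_tables(
    effects: dict[str, float],
    sigma: float = 0.3,
    n_per_state: int = 150,
    seed: int = 0,
    gauge_scale: float = 100.0,
):
    """Residue energy tables with planted TS-stabilization effects.

    For residue r the interaction energy ΔE is drawn N(0, σ) in RS
    snapshots and N(effect_r, σ) in TS snapshots, then decomposed into
    the four energy columns with arbitrary per-snapshot gauge offsets
    (which the analysis must cancel exactly).
    """
    from .decomposition import ResidueEnergyRecord

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    snap = 0
    for state in ("RS", "TS"):
        for _ in range(n_per_state):
            gauge = float(rng.uniform(-gauge_scale, gauge_scale))
            for residue, effect in effects.items():
                de = float(rng.normal(effect if state == "TS" else 0.0, sigma))
                base_qm = float(rng.uniform(-50.0, -10.0))
                base_mm = float(rng.uniform(-20.0, 20.0))
                e_qm_gly = base_qm + gauge
                e_qmmm_gly = base_qm + base_mm + gauge
                e_qm_res = base_qm + float(rng.uniform(-5.0, 5.0)) + gauge
                e_qmmm_res = e_qm_res + base_mm + de
                records.append(
                    ResidueEnergyRecord(
                        snapshot=snap,
                        state=state,
                        residue=residue,
                        e_qm_res=e_qm_res,
                        e_qmmm_res=e_qmmm_res,
                        e_qm_gly=e_qm_gly,
                        e_qmmm_gly=e_qmmm_gly,
                    )
                )
            snap += 1
    return records


# -- synthetic structures ----------------------------------------------------

# Minimal active-site template covering every selector in the default
# atom map: dyad Cγ atoms (chain B), substrate backbone T48..M51
# (chain S), lytic water (chain W).  Coordinates are synthetic - an
# extended-backbone sketch, not taken from any deposited structure.
_BACKBONE = {  # per-residue backbone offsets along an extended chain
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.46, 0.4, 0.3]),
    "C": np.array([2.4, 1.2, -0.5]),
}
_RES_STEP = np.array([3.6, 0.6, -0.4])
_SUB_RESNAMES = {48: "THR", 49: "LEU", 50: "VAL", 51: "MET"}


def make_structure_frames(
    n_frames: int = 3, seed: int = 0, jitter: float = 0.15
) -> list[StructureModel]:
    """Small synthetic multi-frame structures for the geometry reader.

    Each frame perturbs a fixed active-site sketch with Gaussian jitter,
    so frames differ but every atom required by the default atom map
    resolves.  Purely synthetic coordinates.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for fid in range(n_frames):
        atoms = []
        for k, resnum in enumerate(sorted(_SUB_RESNAMES)):
            origin = k * _RES_STEP + np.array([0.0, (-1) ** k * 0.8, 0.2 * k])
            for name, off in _BACKBONE.items():
                xyz = origin + off + rng.normal(0.0, jitter, 3)
                atoms.append(
                    Atom(
                        name=name,
                        resname=_SUB_RESNAMES[resnum],
                        resnum=resnum,
                        chain="S",
                        xyz=tuple(np.round(xyz, 3)),
                    )
                )
        for resnum, pos in ((257, (4.0, 6.0, 2.0)), (385, (9.5, 6.5, 1.0))):
            xyz = np.asarray(pos) + rng.normal(0.0, jitter, 3)
            atoms.append(
                Atom(
                    name="CG",
                    resname="ASP",
                    resnum=resnum,
                    chain="B",
                    xyz=tuple(np.round(xyz, 3)),
                )
            )
        owxyz = np.array([6.5, 3.5, 0.5]) + rng.normal(0.0, jitter, 3)
        atoms.append(
            Atom(name="O", resname="HOH", resnum=1, chain="W", xyz=tuple(np.round(owxyz, 3)))
        )
        frames.append(StructureModel(atoms=atoms, frame_id=fid))
    return frames


def dataset_manifest(spec: dict, payload) -> dict:
    """Reproducibility manifest: generating spec + content hash."""
    if isinstance(payload, np.ndarray):
        blob = payload.tobytes()
    elif isinstance(payload, bytes):
        blob = payload
    else:
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return {
        "spec": spec,
        "sha256": hashlib.sha256(blob).hexdigest(),
    }
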