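"""Active-site sub-state classification and occupancy statistics.

A frame of either protonated system (D257-P or D385-P) is *active* when
the catalytic machinery is poised for nucleophilic attack on the
scissile carbonyl.  Four geometric criteria define the active tiers:

1. a hydrogen bond from the protonated Asp to the scissile carbonyl
   oxygen (O1);
2. the lytic water oxygen within 3.5 Å of the carbonyl carbon
   (d_Ow–C < 3.5 Å);
3. a hydrogen bond from one lytic-water hydrogen to the deprotonated
   Asp (water activation);
4. a hydrogen bond from the *other* water hydrogen to the protonated
   Asp (water bridged across the dyad).

Frames meeting all four criteria belong to the double-bridged tier
("type12"); frames meeting only 1–3 belong to the single-bridged tier
("type34").  Within a tier, sub-states are resolved by which carboxylate
oxygen participates in each hydrogen bond: inner (i, OD1) or outer
(o, OD2); "no" in a label means the water→protonated-Asp bond is absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DEFAULT_HB_ANGLE, DEFAULT_HB_DISTANCE, GeometryFrame

__all__ = [
    "ProtonationSystem",
    "ActiveSubtype",
    "OccupancyTable",
    "SUBTYPE_LABELS",
    "classify_frame",
    "occupancy_table",
    "select_representative",
    "CRITERION2_DOWC_MAX",
]

#: Lytic-water proximity criterion (criterion 2), Å.
CRITERION2_DOWC_MAX = 3.5

#: Canonical sub-state labels per protonated system (tier order:
#: the two double-bridged states first, then the two single-bridged).
SUBTYPE_LABELS = {
    "D257-P": [
        "Asp257i_385i",
        "Asp257i_385o",
        "Asp257no_385o",
        "Asp257no_385i",
    ],
    "D385-P": [
        "Asp385i_257i",
        "Asp385i_257o",
        "Asp385no_257o",
        "Asp385no_257i",
    ],
}

INACTIVE = "inactive"


@dataclass(frozen=True)
class ProtonationSystem:
    """Which dyad aspartate carries the catalytic proton."""

    label: str  # "D257-P" or "D385-P"

    def __post_init__(self):
        if self.label not in ("D257-P", "D385-P"):
            raise ValueError(f"unknown protonation system {self.label!r}")

    @property
    def protonated(self) -> str:
        return "D257" if self.label == "D257-P" else "D385"

    @property
    def deprotonated(self) -> str:
        return "D385" if self.label == "D257-P" else "D257"


@dataclass(frozen=True)
class ActiveSubtype:
    """Classification outcome: a sub-state label and its tier."""

    label: str
    tier: str  # "type12", "type34", or "none"

    def __post_init__(self):
        all_labels = SUBTYPE_LABELS["D257-P"] + SUBTYPE_LABELS["D385-P"]
        if self.label != INACTIVE and self.label not in all_labels:
            raise ValueError(f"unknown subtype label {self.label!r}")
        if (self.label == INACTIVE) != (self.tier == "none"):
            raise ValueError("tier inconsistent with label")


def _tier_of(label: str) -> str:
    if label == INACTIVE:
        return "none"
    for labels in SUBTYPE_LABELS.values():
        if label in labels:
            return "type12" if labels.index(label) < 2 else "type34"
    raise ValueError(label)


def _passes(geom, cutoffs) -> bool:
    d_da, angle, _, _ = geom
    return d_da <= cutoffs[0] and angle >= cutoffs[1]


def classify_frame(
    frame: GeometryFrame,
    system: ProtonationSystem,
    hb_cutoffs: tuple[float, float] = (DEFAULT_HB_DISTANCE, DEFAULT_HB_ANGLE),
    dowc_max: float = CRITERION2_DOWC_MAX,
    inner_atom: str = "OD1",
    outer_atom: str = "OD2",
) -> ActiveSubtype:
    """Assign a frame to an active sub-state or ``inactive``.

    The frame's ``hb_geometries`` must use partner labels of the form
    ``"<residue>:<atom>"`` (e.g. ``"D385:OD1"``, ``"WAT:H1"``,
    ``"SUB:O1"``) so the classifier can locate each criterion's bond.

    Raises ``ValueError`` naming the criterion when the geometry needed
    to evaluate it is absent from the frame.
    """
    prot, deprot = system.protonated, system.deprotonated

    # index H-bond geometries by (donor residue, acceptor residue)
    bonds = []
    for geom in frame.hb_geometries:
        _, _, donor, acceptor = geom
        dres, _, datom = donor.partition(":")
        ares, _, aatom = acceptor.partition(":")
        bonds.append((dres, datom, ares, aatom, geom))

    def find(donor_res, acceptor_res):
        return [b for b in bonds if b[0] == donor_res and b[2] == acceptor_res]

    # criterion 1: protonated Asp (donor) -> scissile carbonyl O1
    c1_bonds = find(prot, "SUB")
    c1_bonds = [b for b in c1_bonds if b[3] == "O1"]
    if not c1_bonds:
        raise ValueError(
            f"criterion 1: no {prot}->SUB:O1 hydrogen-bond geometry in frame "
            f"{frame.frame_id}"
        )
    c1 = any(_passes(b[4], hb_cutoffs) for b in c1_bonds)

    # criterion 2: lytic water near the carbonyl carbon
    c2 = frame.d_OwC < dowc_max

    # criterion 3: water hydrogen -> deprotonated Asp
    c3_bonds = find("WAT", deprot)
    if not c3_bonds:
        raise ValueError(
            f"criterion 3: no WAT->{deprot} hydrogen-bond geometry in frame "
            f"{frame.frame_id}"
        )
    c3_pass = [b for b in c3_bonds if _passes(b[4], hb_cutoffs)]
    c3 = bool(c3_pass)

    # criterion 4: the *other* water hydrogen -> protonated Asp
    c4_bonds = find("WAT", prot)
    c3_hydrogens = {b[1] for b in c3_pass}
    c4_pass = [
        b for b in c4_bonds if _passes(b[4], hb_cutoffs) and b[1] not in c3_hydrogens
    ]
    c4 = bool(c4_pass)

    if not (c1 and c2 and c3):
        return ActiveSubtype(label=INACTIVE, tier="none")

    deprot_oxygen = c3_pass[0][3]
    y = "i" if deprot_oxygen == inner_atom else "o"
    pn, dn = prot[1:], deprot[1:]  # numeric parts, e.g. "257"

    if c4:
        prot_oxygen = c4_pass[0][3]
        x = "i" if prot_oxygen == inner_atom else "o"
        label = f"Asp{pn}{x}_{dn}{y}"
    else:
        label = f"Asp{pn}no_{dn}{y}"
    return ActiveSubtype(label=label, tier=_tier_of(label))


@dataclass
class OccupancyTable:
    """Per-subtype counts and probabilities over Ns sampled structures."""

    system: str
    counts: dict[str, int]
    n_total: int
    probabilities: dict[str, float]  # exact count/Ns, unrounded
    tier_probabilities: dict[str, float]  # "type12"/"type34", unrounded

    def rounded(self, decimals: int = 4) -> dict[str, float]:
        """Probabilities rounded half-away-from-zero to *decimals* places."""

        def _round(p):
            scale = 10**decimals
            return np.floor(p * scale + 0.5) / scale

        out = {k: float(_round(v)) for k, v in self.probabilities.items()}
        out.update({k: float(_round(v)) for k, v in self.tier_probabilities.items()})
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "subtype": k,
                "count": self.counts[k],
                "probability": round(self.probabilities[k], 4),
            }
            for k in self.counts
        ]
        return pd.DataFrame(rows)


def occupancy_table(labels, n_total: int, system: str = "D257-P") -> OccupancyTable:
    """Tabulate sub-state occupancies out of ``n_total`` sampled frames.

    ``labels`` may be ActiveSubtype instances, label strings, or a
    pre-counted {label: count} mapping.  Probabilities are exact
    fractions count/Ns; use :meth:`OccupancyTable.rounded` for the
    4-decimal presentation.
    """
    if n_total <= 0:
        raise ValueError("Ns must be positive")

    if isinstance(labels, dict):
        counts = {k: int(v) for k, v in labels.items()}
    else:
        counts = {}
        for lab in labels:
            name = lab.label if isinstance(lab, ActiveSubtype) else str(lab)
            if name == INACTIVE:
                continue
            counts[name] = counts.get(name, 0) + 1

    canonical = SUBTYPE_LABELS[system]
    full = {k: counts.get(k, 0) for k in canonical}
    for k in counts:
        if k not in full:
            raise ValueError(f"label {k!r} does not belong to system {system}")
    n_active = sum(full.values())
    if n_active > n_total:
        raise ValueError("active counts exceed Ns")

    probs = {k: v / n_total for k, v in full.items()}
    tier12 = sum(full[k] for k in canonical[:2]) / n_total
    tier34 = sum(full[k] for k in canonical[2:]) / n_total
    return OccupancyTable(
        system=system,
        counts=full,
        n_total=n_total,
        probabilities=probs,
        tier_probabilities={"type12": tier12, "type34": tier34},
    )


def _pairwise_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between coordinate sets after optimal superposition."""
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def select_representative(frames) -> int:
    """Medoid frame of an active ensemble by mean pairwise region RMSD.

    ``frames`` is a list of ``(frame_id, coords)`` where ``coords`` is an
    (n_atoms, 3) array over a fixed atom region (catalytic dyad plus the
    scissile-bond residues).  Returns the id of the frame minimising the
    mean RMSD (after optimal rigid superposition) to all others; ties
    break to the lowest frame id.
    """
    if not frames:
        raise ValueError("empty ensemble")
    ids = [fid for fid, _ in frames]
    coords = [np.asarray(c, dtype=float) for _, c in frames]
    n = len(coords)
    if n == 1:
        return ids[0]
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = _pairwise_rmsd(coords[i], coords[j])
    mean_rmsd = rmsd.sum(axis=1) / (n - 1)
    order = sorted(range(n), key=lambda i: (mean_rmsd[i], ids[i]))
    return ids[order[0]]
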