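"""Structure reading and scalar geometric observables.

Everything downstream of the raw coordinates is driven by a handful of
per-frame scalars: the Cγ–Cγ distance between the two catalytic
aspartates (``dd_asp``), backbone torsion pairs flanking the scissile
peptide bond, the lytic-water-oxygen to carbonyl-carbon distance
(``d_OwC``), and donor–H–acceptor hydrogen-bond geometries.  This module
parses PDB coordinate files (via Biopython) into a light
:class:`StructureModel` and computes those observables.

Torsions follow the IUPAC sign convention (clockwise positive looking
down the b→c bond) and are reported in the half-open interval
(−180°, 180°].
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "GeometryFrame",
    "TORSION_LABELS",
    "read_structure",
    "write_structure",
    "distance",
    "dihedral",
    "hydrogen_bond",
    "extract_frame_features",
    "frames_to_table",
    "write_feature_table",
    "read_feature_table",
]

#: The three backbone torsion pairs flanking the scissile bond, in the
#: order they are tabulated: (phi of residue X, psi of residue Y).
TORSION_LABELS = (
    ("phi_V50", "psi_L49"),
    ("phi_L49", "psi_T48"),
    ("phi_M51", "psi_V50"),
)

# Default donor–acceptor distance (Å) and donor–H–acceptor angle (deg)
# cutoffs for the hydrogen-bond predicate.  The distance matches the only
# printed geometric criterion (lytic water within 3.5 Å); the angle is the
# common MD-analysis convention.
DEFAULT_HB_DISTANCE = 3.5
DEFAULT_HB_ANGLE = 135.0


@dataclass(frozen=True)
class Atom:
    """One atom record: name, residue name/number, chain, coordinates (Å)."""

    name: str
    resname: str
    resnum: int
    chain: str
    xyz: tuple[float, float, float]
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resnum, self.icode, self.name)


@dataclass
class StructureModel:
    """A single coordinate frame as a flat list of atoms.

    ``(chain, residue number, insertion code, atom name)`` uniquely
    addresses an atom; duplicate keys (altlocs collapsed upstream) raise.
    """

    atoms: list[Atom]
    frame_id: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for atom in self.atoms:
            coords = np.asarray(atom.xyz, dtype=float)
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"non-finite coordinates for atom {atom}")
            if atom.key in self._index:
                raise ValueError(f"duplicate atom address {atom.key}")
            self._index[atom.key] = atom

    def __len__(self) -> int:
        return len(self.atoms)

    def get(self, chain: str, resnum: int, name: str, icode: str = "") -> Atom:
        try:
            return self._index[(chain, resnum, icode, name)]
        except KeyError:
            raise KeyError(
                f"no atom (chain={chain!r}, resnum={resnum}, icode={icode!r}, "
                f"name={name!r}) in frame {self.frame_id}"
            ) from None

    def coords(self, selectors: list[tuple[str, int, str]]) -> np.ndarray:
        """Coordinates (n, 3) for a list of (chain, resnum, atom name)."""
        return np.array([self.get(c, r, n).xyz for c, r, n in selectors], float)


@dataclass
class GeometryFrame:
    """Scalar geometric features of one trajectory snapshot.

    ``torsions`` is a flat {label: degrees} map over the six labels of
    the three canonical pairs (phi_V50/psi_L49, phi_L49/psi_T48,
    phi_M51/psi_V50).  ``hb_geometries`` entries are ``(d_DA Å,
    angle_DHA deg, donor_label, acceptor_label)`` — raw geometry, not
    yet thresholded; the hydrogen-bond predicate is applied downstream
    so cutoffs stay configurable.
    """

    frame_id: int
    dd_asp: float
    torsions: dict[str, float]
    d_OwC: float
    hb_geometries: list[tuple[float, float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dd_asp > 0:
            raise ValueError(f"dd_asp must be positive, got {self.dd_asp}")
        if not self.d_OwC > 0:
            raise ValueError(f"d_OwC must be positive, got {self.d_OwC}")
        for label, value in self.torsions.items():
            if not (-180.0 < value <= 180.0):
                raise ValueError(f"torsion {label} out of (-180, 180]: {value}")


def read_structure(path, frame_selector: int = 0) -> StructureModel:
    """Parse one MODEL of a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path : str or Path
        PDB file (single- or multi-MODEL).
    frame_selector : int
        Zero-based model index.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If a coordinate record cannot be parsed (the error names the
        line number) or the requested model does not exist.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("frame", str(path))
    except PDBConstructionException as exc:
        line = getattr(parser, "line_counter", None)
        raise ValueError(f"unparseable PDB record near line {line}: {exc}") from exc

    models = list(structure)
    if frame_selector >= len(models) or frame_selector < 0:
        raise ValueError(
            f"model {frame_selector} not in file ({len(models)} model(s) present)"
        )
    model = models[frame_selector]

    atoms = []
    for chain in model:
        for residue in chain:
            _, resnum, icode = residue.id
            for atom in residue:
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        resname=residue.get_resname(),
                        resnum=resnum,
                        chain=chain.id,
                        xyz=tuple(float(v) for v in atom.coord),
                        icode=icode.strip(),
                    )
                )
    return StructureModel(atoms=atoms, frame_id=frame_selector)


def write_structure(models, path) -> None:
    """Write one or more StructureModels as a (multi-MODEL) PDB file.

    Fixed-width ATOM records only; element column derived from the first
    letter of the atom name.  Intended for fixtures and round-tripping,
    not archival deposition.
    """
    if isinstance(models, StructureModel):
        models = [models]
    buf = io.StringIO()
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            buf.write(f"MODEL     {i:>4d}\n")
        for serial, a in enumerate(model.atoms, start=1):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.xyz
            buf.write(
                f"ATOM  {serial:>5d} {name:4s} {a.resname:<3s} {a.chain:1s}"
                f"{a.resnum:>4d}{(a.icode or ' '):1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.name[0]:>2s}\n"
            )
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def distance(a, b) -> float:
    """Euclidean distance (Å) between two points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def dihedral(a, b, c, d) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (−180, 180].

    IUPAC convention: looking from b towards c, clockwise rotation of the
    far bond (c→d) relative to the near bond (b→a) is positive.  Raises
    ``ValueError`` when three consecutive points are collinear (the
    torsion is undefined).
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: dihedral undefined")
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:  # map −180 → +180 so the range is half-open
        angle += 360.0
    return angle


def hydrogen_bond(
    donor,
    hydrogen,
    acceptor,
    cutoffs: tuple[float, float] = (DEFAULT_HB_DISTANCE, DEFAULT_HB_ANGLE),
) -> bool:
    """Geometric hydrogen-bond predicate.

    True iff donor–acceptor distance ≤ ``cutoffs[0]`` (Å) and the
    donor–H–acceptor angle ≥ ``cutoffs[1]`` (degrees).
    """
    d_cut, a_cut = cutoffs
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    if distance(donor, acceptor) > d_cut:
        return False
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return angle >= a_cut


# Atom map: which atoms realise each observable.  Keys are observable
# names; values are (chain, resnum, atom name) selectors.  The defaults
# follow the PS1 author numbering of the 6IYC cryo-EM structure (dyad
# D257/D385 on chain B, substrate T48..M51 on chain S) but every selector
# is configurable so renumbered inputs work.
DEFAULT_ATOM_MAP = {
    "dd_asp": [("B", 257, "CG"), ("B", 385, "CG")],
    "d_OwC": [("W", 1, "O"), ("S", 49, "C")],
    "torsions": {
        ("phi_V50", "psi_L49"): {
            "phi": [("S", 49, "C"), ("S", 50, "N"), ("S", 50, "CA"), ("S", 50, "C")],
            "psi": [("S", 49, "N"), ("S", 49, "CA"), ("S", 49, "C"), ("S", 50, "N")],
        },
        ("phi_L49", "psi_T48"): {
            "phi": [("S", 48, "C"), ("S", 49, "N"), ("S", 49, "CA"), ("S", 49, "C")],
            "psi": [("S", 48, "N"), ("S", 48, "CA"), ("S", 48, "C"), ("S", 49, "N")],
        },
        ("phi_M51", "psi_V50"): {
            "phi": [("S", 50, "C"), ("S", 51, "N"), ("S", 51, "CA"), ("S", 51, "C")],
            "psi": [("S", 50, "N"), ("S", 50, "CA"), ("S", 50, "C"), ("S", 51, "N")],
        },
    },
    # donor heavy atom, donor hydrogen, acceptor, labels (donor, acceptor)
    "hbonds": [],
}


def extract_frame_features(model: StructureModel, atom_map=None) -> GeometryFrame:
    """Compute all GeometryFrame scalars from one structure.

    Raises ``KeyError`` naming the missing selector when the atom map
    does not resolve.
    """
    amap = atom_map or DEFAULT_ATOM_MAP

    (c1, r1, n1), (c2, r2, n2) = amap["dd_asp"]
    dd = distance(model.get(c1, r1, n1).xyz, model.get(c2, r2, n2).xyz)

    (cw, rw, nw), (cc, rc, nc) = amap["d_OwC"]
    dwc = distance(model.get(cw, rw, nw).xyz, model.get(cc, rc, nc).xyz)

    torsions: dict[str, float] = {}
    for (phi_label, psi_label), defs in amap["torsions"].items():
        torsions[phi_label] = dihedral(
            *(model.get(c, r, n).xyz for c, r, n in defs["phi"])
        )
        torsions[psi_label] = dihedral(
            *(model.get(c, r, n).xyz for c, r, n in defs["psi"])
        )

    hbg = []
    for donor_sel, h_sel, acc_sel, dlabel, alabel in amap.get("hbonds", []):
        dxyz = np.asarray(model.get(*donor_sel).xyz, float)
        hxyz = np.asarray(model.get(*h_sel).xyz, float)
        axyz = np.asarray(model.get(*acc_sel).xyz, float)
        d_da = distance(dxyz, axyz)
        v1 = dxyz - hxyz
        v2 = axyz - hxyz
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        hbg.append((d_da, ang, dlabel, alabel))

    return GeometryFrame(
        frame_id=model.frame_id,
        dd_asp=dd,
        torsions=torsions,
        d_OwC=dwc,
        hb_geometries=hbg,
    )


# -- feature tables ---------------------------------------------------------

FEATURE_COLUMNS = [
    "frame",
    "dd_asp",
    "phi_V50",
    "psi_L49",
    "phi_L49",
    "psi_T48",
    "phi_M51",
    "psi_V50",
    "d_OwC",
]


def frames_to_table(frames):
    """GeometryFrames → pandas DataFrame with the canonical columns.

    When any frame carries hydrogen-bond geometries they are serialised
    into a JSON-encoded ``hb_geometries`` column so classification can
    run from the table alone.
    """
    import json

    import pandas as pd

    rows = []
    any_hb = any(f.hb_geometries for f in frames)
    for f in frames:
        row = {"frame": f.frame_id, "dd_asp": f.dd_asp, "d_OwC": f.d_OwC}
        row.update(f.torsions)
        if any_hb:
            row["hb_geometries"] = json.dumps(
                [[round(d, 6), round(a, 6), dn, an] for d, a, dn, an in f.hb_geometries]
            )
        rows.append(row)
    cols = FEATURE_COLUMNS + (["hb_geometries"] if any_hb else [])
    return pd.DataFrame(rows, columns=cols)


def table_to_frames(df) -> list[GeometryFrame]:
    """Inverse of :func:`frames_to_table`."""
    import json

    frames = []
    torsion_labels = [lab for pair in TORSION_LABELS for lab in pair]
    for row in df.itertuples(index=False):
        hbg = []
        raw = getattr(row, "hb_geometries", None)
        if isinstance(raw, str) and raw:
            hbg = [(float(d), float(a), dn, an) for d, a, dn, an in json.loads(raw)]
        frames.append(
            GeometryFrame(
                frame_id=int(row.frame),
                dd_asp=float(row.dd_asp),
                torsions={lab: float(getattr(row, lab)) for lab in torsion_labels},
                d_OwC=float(row.d_OwC),
                hb_geometries=hbg,
            )
        )
    return frames


def write_feature_table(frames, path) -> None:
    frames_to_table(frames).to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
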