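"""Per-residue transition-state stabilization by glycine substitution.

For each residue i surrounding the reactive (QM) region, its
interaction energy contribution to a snapshot is estimated from the
difference between the QM/MM and QM energies with the residue present
versus mutated to glycine:

    ΔE_i = (E_QM/MM − E_QM)_residue − (E_QM/MM − E_QM)_Gly

Averaged over reactant-state (RS) and transition-state (TS) snapshot
ensembles, the change

    ⟨ΔΔE_i⟩ = ⟨ΔE_i⟩_TS − ⟨ΔE_i⟩_RS

measures how much the residue stabilises (negative) or destabilises
(positive) the transition state, i.e. its effect on the barrier.  The
analysis consumes precomputed energy tables; it performs no QM or
force-field evaluation itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResidueEnergyRecord",
    "StabilizationResult",
    "residue_interaction",
    "stabilization",
    "select_state_snapshots",
    "net_environment_effect",
    "records_from_table",
    "records_to_table",
]

STATES = ("RS", "TS")


@dataclass(frozen=True)
class ResidueEnergyRecord:
    """Energies of one snapshot with residue present vs Gly-substituted."""

    snapshot: int
    state: str  # "RS" or "TS"
    residue: str
    e_qm_res: float
    e_qmmm_res: float
    e_qm_gly: float
    e_qmmm_gly: float

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"state must be RS or TS, got {self.state!r}")
        for name in ("e_qm_res", "e_qmmm_res", "e_qm_gly", "e_qmmm_gly"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"missing or non-finite energy {name} in {self}")


@dataclass(frozen=True)
class StabilizationResult:
    """⟨ΔΔE⟩ for one residue with its standard error and sample sizes."""

    residue: str
    delta_delta_e: float  # kcal/mol; negative = TS stabilization
    std_error: float
    n_rs: int
    n_ts: int


def residue_interaction(record: ResidueEnergyRecord) -> float:
    """ΔE_i = (E_QM/MM − E_QM)_residue − (E_QM/MM − E_QM)_Gly."""
    return (record.e_qmmm_res - record.e_qm_res) - (
        record.e_qmmm_gly - record.e_qm_gly
    )


def stabilization(records) -> list[StabilizationResult]:
    """Per-residue ⟨ΔΔE⟩ = ⟨ΔE⟩_TS − ⟨ΔE⟩_RS over snapshot ensembles.

    The standard error combines the per-state snapshot variances:
    SE² = s²_TS/n_TS + s²_RS/n_RS.  Raises ``ValueError`` naming any
    residue that lacks snapshots in either state.
    """
    by_residue: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        slot = by_residue.setdefault(rec.residue, {"RS": [], "TS": []})
        slot[rec.state].append(residue_interaction(rec))

    results = []
    for residue in by_residue:
        rs = np.asarray(by_residue[residue]["RS"])
        ts = np.asarray(by_residue[residue]["TS"])
        if rs.size == 0 or ts.size == 0:
            missing = "RS" if rs.size == 0 else "TS"
            raise ValueError(f"residue {residue} has no {missing} snapshots")
        dd = float(ts.mean() - rs.mean())
        var_rs = rs.var(ddof=1) / rs.size if rs.size > 1 else 0.0
        var_ts = ts.var(ddof=1) / ts.size if ts.size > 1 else 0.0
        results.append(
            StabilizationResult(
                residue=residue,
                delta_delta_e=dd,
                std_error=float(np.sqrt(var_rs + var_ts)),
                n_rs=int(rs.size),
                n_ts=int(ts.size),
            )
        )
    return results


def select_state_snapshots(
    times,
    cv1,
    cv2,
    state_center: tuple[float, float],
    tolerance: float = 0.1,
    n: int = 150,
    snapshot_ids=None,
):
    """Snapshots whose CVs lie within ``tolerance`` Å of a state centre.

    Both CV components must fall inside the box; when more than *n*
    snapshots qualify, a uniform stride reduces the selection to *n*.
    When fewer qualify, all are returned with a warning.
    """
    import warnings

    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cv1 = np.asarray(cv1, float)
    cv2 = np.asarray(cv2, float)
    if snapshot_ids is None:
        snapshot_ids = np.arange(len(cv1))
    snapshot_ids = np.asarray(snapshot_ids)
    mask = (np.abs(cv1 - state_center[0]) <= tolerance) & (
        np.abs(cv2 - state_center[1]) <= tolerance
    )
    chosen = snapshot_ids[mask]
    if chosen.size < n:
        warnings.warn(
            f"only {chosen.size} snapshots within {tolerance} Å of "
            f"{state_center} (requested {n})",
            RuntimeWarning,
            stacklevel=2,
        )
        return chosen
    stride = np.linspace(0, chosen.size - 1, n).round().astype(int)
    return chosen[stride]


def net_environment_effect(results, residue_subset) -> float:
    """Summed ⟨ΔΔE⟩ over a residue subset (e.g. all residues within
    5 Å of the reactive region).  kcal/mol; negative = net barrier
    lowering."""
    by_res = {r.residue: r for r in results}
    total = 0.0
    for residue in residue_subset:
        if residue not in by_res:
            raise ValueError(f"unknown residue {residue!r} in subset")
        total += by_res[residue].delta_delta_e
    return total


# -- I/O --------------------------------------------------------------------

TABLE_COLUMNS = [
    "snapshot",
    "state",
    "residue",
    "E_qm_res",
    "E_qmmm_res",
    "E_qm_gly",
    "E_qmmm_gly",
]


def records_to_table(records):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "snapshot": r.snapshot,
                "state": r.state,
                "residue": r.residue,
                "E_qm_res": r.e_qm_res,
                "E_qmmm_res": r.e_qmmm_res,
                "E_qm_gly": r.e_qm_gly,
                "E_qmmm_gly": r.e_qmmm_gly,
            }
            for r in records
        ],
        columns=TABLE_COLUMNS,
    )


def records_from_table(df) -> list[ResidueEnergyRecord]:
    return [
        ResidueEnergyRecord(
            snapshot=int(row.snapshot),
            state=str(row.state),
            residue=str(row.residue),
            e_qm_res=float(row.E_qm_res),
            e_qmmm_res=float(row.E_qmmm_res),
            e_qm_gly=float(row.E_qm_gly),
            e_qmmm_gly=float(row.E_qmmm_gly),
        )
        for row in df.itertuples(index=False)
    ]
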