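"""Attack-geometry measurement and near-attack-conformation (NAC) filtering.

For a reactivation reaction to start, the oximate oxygen (O_ox) must reach
the phosphorus of the serine-bound organophosphate in a geometry compatible
with in-line nucleophilic attack.  Working in the shared docking frame, each
pose is reduced to two numbers:

* ``d_op`` — the attack distance in Å.  The default definition is the
  distance between the OP phosphorus and the catalytic-serine Oγ
  (``p_to_serO``); the alternative ``oximeO_to_p`` measures O_ox↔P instead
  (see :class:`NACCriteria`).
* ``theta_opo`` — the O_ox–P–O_Ser angle in degrees, at the phosphorus.

A pose is a near attack conformation when it is low-energy, ``d_op`` is
strictly below ``d_max`` (default 10.00 Å) and ``theta_opo`` lies within
``theta_center ± theta_tol`` (default 180 ± 60°, inclusive).  "%NAC" — the
percentage of low-energy poses at the NAC — is the per-oxime statistic that
is later correlated with experimental reactivation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .structure_io import LigandPose, OximeSpec, PoseEnsemble, ReceptorComplex

__all__ = [
    "NACCriteria",
    "NACGeometry",
    "NACSummary",
    "BestPoseReport",
    "distance",
    "angle",
    "pose_geometry",
    "ensemble_geometry",
    "nac_summary",
    "summarize_geometry_table",
    "select_best_pose",
    "rmsd",
    "validate_redock",
    "geometry_dataframe",
]


@dataclass(frozen=True)
class NACCriteria:
    """Thresholds defining low-energy poses and the NAC window.

    Attributes
    ----------
    d_max : float
        Distance cutoff in Å; the test is strict (``d_op < d_max``).
    theta_center, theta_tol : float
        Angular window in degrees, inclusive on both sides.  With the
        default 180 ± 60° the accepted angles are [120°, 180°].
    energy_window : float or "all"
        kcal/mol above the ensemble minimum within which a pose counts as
        low-energy; the sentinel ``"all"`` accepts every pose.
    distance_definition : {"p_to_serO", "oximeO_to_p"}
        Which pair of atoms defines ``d_op``.
    denominator : {"low_energy", "all"}
        Whether %NAC divides the NAC count by the low-energy pose count or
        by the full ensemble size.
    """

    d_max: float = 10.00
    theta_center: float = 180.0
    theta_tol: float = 60.0
    energy_window: Union[float, str] = 5.0
    distance_definition: str = "p_to_serO"
    denominator: str = "low_energy"

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_tol <= 180:
            raise ValueError("theta_tol must be in (0, 180]")
        if self.distance_definition not in ("p_to_serO", "oximeO_to_p"):
            raise ValueError(f"unknown distance_definition {self.distance_definition!r}")
        if self.denominator not in ("low_energy", "all"):
            raise ValueError(f"unknown denominator {self.denominator!r}")
        if isinstance(self.energy_window, str) and self.energy_window != "all":
            raise ValueError("energy_window must be a number or 'all'")

    def in_window(self, d_op: float, theta_opo: float) -> bool:
        """Geometric NAC test: strict on distance, inclusive on angle."""
        return d_op < self.d_max and abs(theta_opo - self.theta_center) <= self.theta_tol


@dataclass(frozen=True)
class NACGeometry:
    """Measured attack geometry and classification of one pose."""

    pose_index: int
    d_op: float
    theta_opo: float
    oxime_O_used: Union[str, int]
    is_low_energy: bool
    is_nac: bool

    def __post_init__(self) -> None:
        if self.d_op < 0:
            raise ValueError("d_op must be ≥ 0")
        if not 0 <= self.theta_opo <= 180:
            raise ValueError("theta_opo must be in [0, 180]")


@dataclass(frozen=True)
class NACSummary:
    """Per-oxime pose counts and the %NAC statistic."""

    oxime: str
    complex_label: str
    n_poses: int
    n_low_energy: int
    n_nac: int
    pct_nac: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_nac <= self.n_low_energy <= self.n_poses:
            raise ValueError("require 0 ≤ n_nac ≤ n_low_energy ≤ n_poses")


@dataclass(frozen=True)
class BestPoseReport:
    """Best-pose geometry and energies, one row of a results table."""

    oxime: str
    pose_index: int
    d_op: float
    theta_opo: float
    energy_total: float
    energy_hbond: Optional[float] = None


def distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two points (Å)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("distance: inputs must be finite")
    return float(np.linalg.norm(p - q))


def angle(a: Sequence[float], vertex: Sequence[float], b: Sequence[float]) -> float:
    """Angle at ``vertex`` between arms to ``a`` and ``b``, in degrees [0, 180].

    Uses a clamped arc-cosine so nearly collinear arms cannot produce NaN.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float)
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle: zero-length arm")
    cosine = float(np.dot(u1, u2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosine))))


def _oxygen_geometries(
    pose: LigandPose,
    complex: ReceptorComplex,
    oxygen_indices: Sequence[int],
    oxygen_labels: Sequence[Union[str, int]],
    criteria: NACCriteria,
):
    """(d_op, theta, label) for every oxime oxygen of one pose."""
    d_anchor = distance(complex.op_P, complex.serine_O)
    out = []
    for idx, label in zip(oxygen_indices, oxygen_labels):
        o_ox = pose.coords[idx]
        theta = angle(o_ox, complex.op_P, complex.serine_O)
        d = (
            d_anchor
            if criteria.distance_definition == "p_to_serO"
            else distance(o_ox, complex.op_P)
        )
        out.append((d, theta, label))
    return out


def _pick_oxygen(cands, criteria: NACCriteria):
    """Bis-oxime rule: among oxygens passing the distance test keep the one
    maximizing θ; if none passes, keep the one with minimal d."""
    passing = [c for c in cands if c[0] < criteria.d_max]
    if passing:
        return max(passing, key=lambda c: c[1])
    return min(cands, key=lambda c: c[0])


def _resolve_oxygens(ensemble_or_names, oxime: OximeSpec, n_atoms: int):
    if isinstance(ensemble_or_names, PoseEnsemble):
        return ensemble_or_names.oxime_oxygen_indices()
    names = tuple(ensemble_or_names or ())
    out = []
    for sel in oxime.oxime_oxygen_atoms:
        if isinstance(sel, (int, np.integer)):
            if not 0 <= int(sel) < n_atoms:
                raise ValueError(f"oxime oxygen index {sel} out of range")
            out.append(int(sel))
        elif sel in names:
            out.append(names.index(sel))
        else:
            raise ValueError(f"cannot resolve oxime oxygen {sel!r} (no atom names)")
    return tuple(out)


def pose_geometry(
    pose: LigandPose,
    complex: ReceptorComplex,
    oxime: OximeSpec,
    criteria: NACCriteria = NACCriteria(),
    atom_names: Optional[Sequence[str]] = None,
    is_low_energy: bool = True,
) -> NACGeometry:
    """Measure the attack geometry of one pose and classify it.

    For bis-oximes both oximate oxygens are measured and the record keeps
    the one maximizing θ among those that satisfy the distance test (the
    oxygen with minimal d if none does).  ``is_low_energy`` must be supplied
    by the caller when an ensemble energy reference exists; a standalone
    pose is treated as low-energy.
    """
    indices = _resolve_oxygens(atom_names, oxime, pose.coords.shape[0])
    cands = _oxygen_geometries(
        pose, complex, indices, oxime.oxime_oxygen_atoms, criteria
    )
    d, theta, label = _pick_oxygen(cands, criteria)
    return NACGeometry(
        pose_index=pose.pose_index,
        d_op=d,
        theta_opo=theta,
        oxime_O_used=label,
        is_low_energy=is_low_energy,
        is_nac=is_low_energy and criteria.in_window(d, theta),
    )


def _low_energy_flags(ensemble: PoseEnsemble, criteria: NACCriteria):
    energies = np.array([p.energy_total for p in ensemble.poses])
    if criteria.energy_window == "all":
        return np.ones(len(energies), dtype=bool)
    return energies <= energies.min() + float(criteria.energy_window)


def ensemble_geometry(
    ensemble: PoseEnsemble,
    complex: ReceptorComplex,
    criteria: NACCriteria = NACCriteria(),
) -> list:
    """Per-pose :class:`NACGeometry` for a whole ensemble (file order)."""
    flags = _low_energy_flags(ensemble, criteria)
    return [
        pose_geometry(
            pose,
            complex,
            ensemble.oxime,
            criteria,
            atom_names=ensemble.atom_names,
            is_low_energy=bool(flags[i]),
        )
        for i, pose in enumerate(ensemble.poses)
    ]


def nac_summary(
    ensemble: PoseEnsemble,
    complex: ReceptorComplex,
    criteria: NACCriteria = NACCriteria(),
) -> NACSummary:
    """Count NAC poses and compute %NAC for one oxime/complex ensemble.

    %NAC = 100 × n_nac / denominator, where the denominator is the
    low-energy pose count (default) or the full ensemble size, per
    ``criteria.denominator``.  An empty denominator yields 0 with a warning.
    """
    geoms = ensemble_geometry(ensemble, complex, criteria)
    n_low = sum(g.is_low_energy for g in geoms)
    n_nac = sum(g.is_nac for g in geoms)
    denom = n_low if criteria.denominator == "low_energy" else len(geoms)
    if denom == 0:
        warnings.warn(
            f"{ensemble.oxime.name}: empty %NAC denominator; reporting 0",
            stacklevel=2,
        )
        pct = 0.0
    else:
        pct = 100.0 * n_nac / denom
    return NACSummary(
        oxime=ensemble.oxime.name,
        complex_label=ensemble.complex_label,
        n_poses=len(geoms),
        n_low_energy=n_low,
        n_nac=n_nac,
        pct_nac=pct,
    )


def summarize_geometry_table(
    table: pd.DataFrame,
    criteria: NACCriteria = NACCriteria(),
    oxime: str = "",
    complex_label: str = "",
) -> NACSummary:
    """%NAC from a plain per-pose geometry table (columns
    ``pose_index, d_op, theta_opo, energy``) — the coordinate-free route."""
    energies = table["energy"].to_numpy(dtype=float)
    if len(energies) == 0 or criteria.energy_window == "all":
        low = np.ones(len(energies), dtype=bool)
    else:
        low = energies <= energies.min() + float(criteria.energy_window)
    in_window = np.array(
        [criteria.in_window(d, t) for d, t in zip(table["d_op"], table["theta_opo"])],
        dtype=bool,
    )
    n_nac = int(np.sum(low & in_window))
    n_low = int(np.sum(low))
    denom = n_low if criteria.denominator == "low_energy" else len(energies)
    if denom == 0:
        warnings.warn("empty %NAC denominator; reporting 0", stacklevel=2)
        pct = 0.0
    else:
        pct = 100.0 * n_nac / denom
    return NACSummary(
        oxime=oxime,
        complex_label=complex_label,
        n_poses=len(energies),
        n_low_energy=n_low,
        n_nac=n_nac,
        pct_nac=pct,
    )


def select_best_pose(
    ensemble: PoseEnsemble,
    complex: ReceptorComplex,
    criteria: NACCriteria = NACCriteria(),
) -> BestPoseReport:
    """Select the best pose within the low-energy set.

    Lexicographic rule: minimal d_op first, then maximal θ_opo, then minimal
    total energy — following the ↓d/↑θ ordering convention of docking
    results tables.
    """
    geoms = ensemble_geometry(ensemble, complex, criteria)
    candidates = [
        (g, p) for g, p in zip(geoms, ensemble.poses) if g.is_low_energy
    ] or list(zip(geoms, ensemble.poses))
    best_g, best_p = min(
        candidates, key=lambda gp: (gp[0].d_op, -gp[0].theta_opo, gp[1].energy_total)
    )
    return BestPoseReport(
        oxime=ensemble.oxime.name,
        pose_index=best_p.pose_index,
        d_op=best_g.d_op,
        theta_opo=best_g.theta_opo,
        energy_total=best_p.energy_total,
        energy_hbond=best_p.energy_hbond,
    )


def rmsd(coords_a: Sequence, coords_b: Sequence) -> float:
    """Root-mean-square deviation over positionally paired atoms (Å).

    No superposition is applied — docking output shares one frame with the
    receptor — and no symmetry/automorphism search is done; correspondence
    is strictly by atom order.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"rmsd: shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def validate_redock(
    reference: Sequence,
    redocked: Sequence,
    threshold: float = 2.0,
) -> dict:
    """Redocking validation: RMSD of the redocked ligand against the
    crystallographic pose, passing iff RMSD is strictly under ``threshold``
    (default 2.0 Å)."""
    value = rmsd(reference, redocked)
    return {"rmsd": value, "pass": value < threshold, "threshold": threshold}


def geometry_dataframe(geoms: Sequence[NACGeometry], ensemble: PoseEnsemble) -> pd.DataFrame:
    """Per-pose geometry table (TSV-ready) matching the CLI output columns."""
    return pd.DataFrame(
        {
            "pose_index": [g.pose_index for g in geoms],
            "d_op": [g.d_op for g in geoms],
            "theta_opo": [g.theta_opo for g in geoms],
            "energy_total": [p.energy_total for p in ensemble.poses],
            "is_low_energy": [g.is_low_energy for g in geoms],
            "is_nac": [g.is_nac for g in geoms],
        }
    )
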