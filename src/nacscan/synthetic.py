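"""Synthetic inputs with known ground truth for every pipeline stage.

Docking engines and bench assays are replaced here by generators that
produce the same file dialects the readers accept — pose ensembles with a
controllable attack-geometry distribution, triplicate Ellman-style
activities (or traces) encoding a chosen true % reactivation,
pseudo-first-order inhibition time-courses, and rigidly perturbed ligand
copies — each carrying the ground truth recorded at construction time, so
recovery can be checked exactly (noiseless modes) or unbiasedly (noisy
modes).

The bundled reference table of % reactivation values (six oximes × two
cholinesterases × two concentrations, triplicate means ± SD) parameterizes
the assay scenarios used throughout the tests.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
import pandas as pd

from .assay import ActivityMeasurement
from .geometry import NACCriteria, NACSummary, rmsd as _rmsd
from .structure_io import (
    AtomRecord,
    LigandPose,
    OximeSpec,
    PoseEnsemble,
    ReceptorComplex,
)

__all__ = [
    "PoseScenario",
    "AssayScenario",
    "PoseGroundTruth",
    "AssayData",
    "fixture_table",
    "assay_scenario_for_row",
    "generate_pose_ensemble",
    "generate_receptor_pdb",
    "generate_assay_scenario",
    "generate_inhibition_course",
    "replicate_pct_R_sd",
    "perturb_ligand",
    "generate_correlated_pairs",
]


# ---------------------------------------------------------------------------
# Reference reactivation table (transcribed measurement means ± SD, %):
# six oximes × {AChE, BChE} × {100 µM, 10 µM}, triplicate determinations.
# ---------------------------------------------------------------------------

_FIXTURE_CSV = """\
oxime,enzyme,conc_uM,pct_R_mean,pct_R_sd
pralidoxime,AChE,100,18.2,0.7
pralidoxime,AChE,10,1.3,0.7
pralidoxime,BChE,100,5.5,0.1
pralidoxime,BChE,10,1.0,0.2
obidoxime,AChE,100,96.9,0.7
obidoxime,AChE,10,59.4,0.7
obidoxime,BChE,100,9.9,0.3
obidoxime,BChE,10,2.2,0.3
HI-6,AChE,100,16.1,0.0
HI-6,AChE,10,3.9,0.7
HI-6,BChE,100,2.3,0.2
HI-6,BChE,10,0.8,0.4
K131,AChE,100,1.7,0.0
K131,AChE,10,1.1,1.1
K131,BChE,100,0.3,0.3
K131,BChE,10,0.3,0.3
K142,AChE,100,7.0,1.0
K142,AChE,10,3.0,0.8
K142,BChE,100,1.1,0.2
K142,BChE,10,0.6,0.3
K153,AChE,100,9.8,1.0
K153,AChE,10,2.3,1.5
K153,BChE,100,2.0,0.5
K153,BChE,10,0.3,0.3
"""

OXIMES = ("pralidoxime", "obidoxime", "HI-6", "K131", "K142", "K153")


def fixture_table() -> pd.DataFrame:
    """The 24-row reference table of true %R values (mean, SD) used to
    parameterize synthetic assay scenarios."""
    return pd.read_csv(io.StringIO(_FIXTURE_CSV))


# ---------------------------------------------------------------------------
# Distribution helper
# ---------------------------------------------------------------------------

Distribution = Tuple


def _sample(dist: Distribution, rng: np.random.Generator, size=None):
    """Sample from a ("uniform", lo, hi) or ("normal", mu, sigma) spec."""
    family, a, b = dist
    if family == "uniform":
        return rng.uniform(a, b, size=size)
    if family == "normal":
        return rng.normal(a, b, size=size)
    raise ValueError(f"unknown distribution family {family!r}")


# ---------------------------------------------------------------------------
# Pose ensembles
# ---------------------------------------------------------------------------

#: Attack-distance and angle are sampled for the oximate oxygen relative to
#: the adduct phosphorus; the recorded ground truth therefore uses the
#: oximeO→P distance definition (the serine Oγ↔P separation is a fixed
#: receptor property and cannot carry a per-pose distribution).
GENERATOR_CRITERIA = NACCriteria(distance_definition="oximeO_to_p")

#: Rigid 5-heavy-atom dummy ligand: offsets of C1, N1, C2, C3 from the
#: oxime oxygen (Å).  Enough structure to exercise file I/O and RMSD.
_DUMMY_OFFSETS = np.array(
    [
        [1.30, 0.00, 0.00],
        [2.05, 1.10, 0.00],
        [3.40, 1.00, 0.10],
        [4.10, 2.20, 0.15],
    ]
)


@dataclass(frozen=True)
class PoseScenario:
    """Conditions for one synthetic pose ensemble.

    Defaults emulate a typical docking run: 100 returned poses, attack
    distances spread across and beyond the 10 Å cutoff, angles across and
    beyond the 120° bound, docking energies around −110 kcal/mol.
    """

    n_poses: int = 100
    distance_distribution: Distribution = ("uniform", 3.0, 15.0)
    angle_distribution: Distribution = ("uniform", 90.0, 180.0)
    energy_distribution: Distribution = ("normal", -110.0, 5.0)
    nac_fraction_target: Optional[float] = None
    n_oxime_oxygens: int = 1
    seed: int = 0
    oxime_name: str = "oxime"
    complex_label: str = "AChE/POX"
    anchor_distance: float = 4.0  # serine Oγ ↔ P separation, Å

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be ≥ 1")
        if self.n_oxime_oxygens not in (1, 2):
            raise ValueError("n_oxime_oxygens must be 1 or 2")
        if self.nac_fraction_target is not None and not 0 <= self.nac_fraction_target <= 1:
            raise ValueError("nac_fraction_target must be in [0, 1]")


@dataclass(frozen=True)
class PoseGroundTruth:
    """Construction record accompanying a generated ensemble."""

    summary: NACSummary
    criteria: NACCriteria
    d_op: np.ndarray
    theta_opo: np.ndarray
    is_nac: np.ndarray


def _minimal_receptor(scenario: PoseScenario) -> ReceptorComplex:
    p = np.zeros(3)
    ser = np.array([0.0, 0.0, scenario.anchor_distance])
    atoms = (
        AtomRecord("OG", "O", ser, "SER", 203, "A"),
        AtomRecord("P", "P", p, "POX", 999, "A"),
    )
    enzyme = scenario.complex_label.split("/")[0] or "AChE"
    return ReceptorComplex(enzyme_label=enzyme, atoms=atoms, serine_O=ser, op_P=p)


def _oxime_O_position(d: float, theta_deg: float, phi: float) -> np.ndarray:
    """Place the oximate O at distance d from P (origin) so the O–P–OSer
    angle equals theta (serine direction is +z)."""
    t = math.radians(theta_deg)
    return d * np.array([math.sin(t) * math.cos(phi), math.sin(t) * math.sin(phi), math.cos(t)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_geometry(
    rng: np.random.Generator,
    scenario: PoseScenario,
    criteria: NACCriteria,
    want_nac: Optional[bool],
    max_tries: int = 10000,
) -> Tuple[float, float]:
    """One (d, θ) draw, rejection-sampled into/out of the NAC window when
    ``want_nac`` is set."""
    for _ in range(max_tries):
        d = float(_sample(scenario.distance_distribution, rng))
        theta = float(np.clip(_sample(scenario.angle_distribution, rng), 0.0, 180.0))
        if d <= 0.1:
            continue
        if want_nac is None or criteria.in_window(d, theta) == want_nac:
            return d, theta
    raise ValueError(
        f"infeasible NAC target: could not draw a pose with in_window={want_nac} "
        f"from {scenario.distance_distribution} × {scenario.angle_distribution}"
    )


def generate_pose_ensemble(
    scenario: PoseScenario,
) -> Tuple[PoseEnsemble, PoseGroundTruth, ReceptorComplex]:
    """Generate a pose ensemble with known attack geometry.

    The adduct phosphorus sits at the origin and the serine Oγ at
    ``anchor_distance`` along +z.  Each pose embeds its oximate oxygen at a
    sampled (d, θ, azimuth) around the phosphorus and completes a rigid
    5-heavy-atom dummy ligand in a random orientation.  When
    ``nac_fraction_target`` is set, draws are stratified so the realized
    NAC fraction under :data:`GENERATOR_CRITERIA` equals
    ``round(target · n_poses) / n_poses`` exactly, and energies are
    compressed into the low-energy window so that the energy filter keeps
    every pose.

    Returns the ensemble, a :class:`PoseGroundTruth` construction record,
    and the minimal two-anchor receptor complex.
    """
    criteria = GENERATOR_CRITERIA
    ss = np.random.SeedSequence(scenario.seed)
    rng_geom, rng_energy, rng_orient = (np.random.default_rng(s) for s in ss.spawn(3))
    n = scenario.n_poses
    receptor = _minimal_receptor(scenario)

    if scenario.nac_fraction_target is not None:
        n_nac = int(round(scenario.nac_fraction_target * n))
        labels = np.zeros(n, dtype=bool)
        labels[:n_nac] = True
        labels = rng_geom.permutation(labels)
        geoms = [_sample_geometry(rng_geom, scenario, criteria, bool(w)) for w in labels]
    else:
        geoms = [_sample_geometry(rng_geom, scenario, criteria, None) for _ in range(n)]

    energies = np.asarray(_sample(scenario.energy_distribution, rng_energy, size=n), dtype=float)
    if scenario.nac_fraction_target is not None:
        # keep rank order but compress into < default window above the minimum
        span = np.ptp(energies)
        if span > 0:
            window = float(NACCriteria().energy_window)
            energies = energies.min() + (energies - energies.min()) / span * (0.8 * window)

    bis = scenario.n_oxime_oxygens == 2
    atom_names = ["O1", "C1", "N1", "C2", "C3"] + (["O2"] if bis else [])
    elements = ["O", "C", "N", "C", "C"] + (["O"] if bis else [])
    oxime = OximeSpec(
        name=scenario.oxime_name,
        oxime_oxygen_atoms=("O1", "O2") if bis else ("O1",),
        ionization_label="oximate",
        net_charge=-1,
    )

    poses = []
    d_eff = np.empty(n)
    theta_eff = np.empty(n)
    for i, (d, theta) in enumerate(geoms):
        phi = float(rng_geom.uniform(0.0, 2.0 * math.pi))
        o1 = _oxime_O_position(d, theta, phi)
        rot = _random_rotation(rng_orient)
        coords = [o1] + [o1 + rot @ off for off in _DUMMY_OFFSETS]
        d1, t1 = d, theta
        if bis:
            # second oximate O on the far side of O1, away from P: it always
            # fails the distance test, so O1 decides the pose classification
            # and stratified targets stay exact
            o2 = o1 + 20.0 * o1 / np.linalg.norm(o1)
            coords.append(o2)
        poses.append(
            LigandPose(
                pose_index=i,
                coords=np.asarray(coords),
                energy_total=float(energies[i]),
                energy_hbond=float(-abs(energies[i]) * 0.03),
            )
        )
        d_eff[i] = d1
        theta_eff[i] = t1

    is_nac = np.array([criteria.in_window(d, t) for d, t in zip(d_eff, theta_eff)])
    n_nac_realized = int(is_nac.sum())
    summary = NACSummary(
        oxime=scenario.oxime_name,
        complex_label=scenario.complex_label,
        n_poses=n,
        n_low_energy=n,
        n_nac=n_nac_realized,
        pct_nac=100.0 * n_nac_realized / n,
    )
    ensemble = PoseEnsemble(
        complex_label=scenario.complex_label,
        oxime=oxime,
        poses=tuple(poses),
        atom_names=tuple(atom_names),
        elements=tuple(elements),
    )
    truth = PoseGroundTruth(
        summary=summary, criteria=criteria, d_op=d_eff, theta_opo=theta_eff, is_nac=is_nac
    )
    return ensemble, truth, receptor


def generate_receptor_pdb(
    path: Union[str, Path],
    serine_xyz: Sequence[float] = (0.0, 0.0, 4.0),
    p_xyz: Sequence[float] = (0.0, 0.0, 0.0),
    enzyme: str = "AChE",
    serine_residue_id: int = 203,
    n_filler_residues: int = 18,
    seed: int = 0,
) -> Path:
    """Write a small synthetic receptor/adduct PDB with known anchors.

    Glycine filler residues surround one serine (Oγ at ``serine_xyz``) and
    one POX heteroresidue (phosphorus at ``p_xyz``); anchors placed here are
    the ground truth for anchor-resolution round-trip tests.
    """
    rng = np.random.default_rng(seed)
    serine_xyz = np.asarray(serine_xyz, dtype=float)
    p_xyz = np.asarray(p_xyz, dtype=float)

    structure = gemmi.Structure()
    structure.name = f"synthetic {enzyme} adduct"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")

    def add_residue(name, seqid, atoms, het=False):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        res.het_flag = "H" if het else "A"
        for aname, elem, pos in atoms:
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
        chain.add_residue(res)

    for i in range(n_filler_residues):
        seqid = i + 1 if i + 1 < serine_residue_id else serine_residue_id + (i + 1)
        center = rng.uniform(8.0, 25.0, size=3)
        add_residue(
            "GLY",
            int(seqid),
            [
                ("N", "N", center + [0.0, 1.3, 0.0]),
                ("CA", "C", center),
                ("C", "C", center + [1.4, 0.0, 0.0]),
                ("O", "O", center + [1.9, 1.0, 0.2]),
            ],
        )
    add_residue(
        "SER",
        serine_residue_id,
        [
            ("N", "N", serine_xyz + [1.0, 1.5, 0.5]),
            ("CA", "C", serine_xyz + [0.8, 1.0, 1.0]),
            ("CB", "C", serine_xyz + [0.5, 0.8, 0.0]),
            ("OG", "O", serine_xyz),
        ],
    )
    add_residue(
        "POX",
        900,
        [
            ("P", "P", p_xyz),
            ("O1P", "O", p_xyz + [1.4, 0.3, 0.2]),
            ("O2P", "O", p_xyz + [-1.2, 0.8, -0.3]),
        ],
        het=True,
    )
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    structure.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Assay scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayScenario:
    """Conditions for one synthetic reactivation measurement.

    ``inhibited_fraction`` defaults to 0.05: the enzyme is inhibited to 5 %
    of its original activity before reactivation.  Noise is multiplicative
    Gaussian with coefficient of variation ``noise_cv`` (default 2 %,
    matching the small replicate SDs of the reference table); triplicates
    are the default replication level.
    """

    label: str = "scenario"
    oxime: str = ""
    enzyme: str = "AChE"
    concentration: float = 1e-4  # mol/L
    true_pct_R: float = 50.0
    a0: float = 1.0
    inhibited_fraction: float = 0.05
    oximolysis_rate: float = 0.0
    noise_cv: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inhibited_fraction < 1:
            raise ValueError("inhibited_fraction must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be ≥ 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        if not self.a0 > 0:
            raise ValueError("a0 must be positive")


@dataclass(frozen=True)
class AssayData:
    """Generated measurements plus the construction ground truth."""

    scenario: AssayScenario
    measurements: tuple
    truth: dict


def assay_scenario_for_row(
    oxime: str,
    enzyme: str,
    conc_uM: float,
    seed: int = 0,
    **overrides,
) -> AssayScenario:
    """Build the scenario encoding one row of the reference %R table."""
    table = fixture_table()
    row = table[
        (table.oxime == oxime) & (table.enzyme == enzyme) & (table.conc_uM == conc_uM)
    ]
    if len(row) != 1:
        raise KeyError(f"no fixture row for ({oxime}, {enzyme}, {conc_uM} µM)")
    return AssayScenario(
        label=f"{oxime}/{enzyme}/{conc_uM}uM",
        oxime=oxime,
        enzyme=enzyme,
        concentration=conc_uM * 1e-6,
        true_pct_R=float(row.pct_R_mean.iloc[0]),
        seed=seed,
        **overrides,
    )


def generate_assay_scenario(scenario: AssayScenario) -> AssayData:
    """Generate per-replicate condition activities encoding a true %R.

    The noiseless activities are a0, ai = a0·inhibited_fraction, and
    ar_raw = ai + (true_pct_R/100)(a0 − ai) + oximolysis_rate, so the %R
    formula with oximolysis correction evaluates to ``true_pct_R`` exactly
    before noise.  Each replicate draws independent multiplicative Gaussian
    noise from its own child stream, so extending ``n_replicates`` never
    perturbs earlier replicates.
    """
    a0 = scenario.a0
    ai = a0 * scenario.inhibited_fraction
    ar = ai + scenario.true_pct_R / 100.0 * (a0 - ai)
    ar_raw = ar + scenario.oximolysis_rate
    clean = {
        "intact": a0,
        "inhibited": ai,
        "reactivated": ar_raw,
        "oximolysis_control": scenario.oximolysis_rate,
    }
    ss = np.random.SeedSequence(scenario.seed)
    measurements = []
    for rep, child in enumerate(ss.spawn(scenario.n_replicates), start=1):
        rng = np.random.default_rng(child)
        for condition in clean:
            noisy = clean[condition] * (1.0 + scenario.noise_cv * rng.standard_normal())
            measurements.append(
                ActivityMeasurement(condition=condition, replicate_id=rep, activity=noisy)
            )
    truth = {
        "true_pct_R": scenario.true_pct_R,
        "a0": a0,
        "ai": ai,
        "ar_raw": ar_raw,
        "oximolysis": scenario.oximolysis_rate,
    }
    return AssayData(scenario=scenario, measurements=tuple(measurements), truth=truth)


def replicate_pct_R_sd(scenario: AssayScenario) -> float:
    """True per-replicate SD of recovered %R under the scenario's noise model.

    First-order (delta-method) propagation of the independent multiplicative
    Gaussian errors on a0, ai and ar_raw through the %R formula; accurate to
    O(cv²) and used to set recovery tolerances from the known ground truth
    rather than from a noisy small-sample SD estimate.
    """
    a0 = scenario.a0
    ai = a0 * scenario.inhibited_fraction
    ar = ai + scenario.true_pct_R / 100.0 * (a0 - ai)
    ar_raw = ar + scenario.oximolysis_rate
    oxi = scenario.oximolysis_rate
    D = a0 - ai
    N = a0 - ar
    cv = scenario.noise_cv
    # ∂%R/∂x × σ_x for x ∈ {a0, ai, ar_raw, oximolysis}, σ_x = cv·x
    terms = [
        (-100.0 * (D - N) / D**2) * cv * a0,
        (-100.0 * N / D**2) * cv * ai,
        (100.0 / D) * cv * ar_raw,
        (-100.0 / D) * cv * oxi,
    ]
    return float(math.sqrt(sum(t * t for t in terms)))


def assay_traces(
    data: AssayData,
    duration_min: float = 4.0,
    n_points: int = 9,
    baseline: float = 0.05,
) -> pd.DataFrame:
    """Render generated activities as linear absorbance traces.

    Each measurement becomes an exactly linear trace with slope equal to its
    (already noisy) activity, so the trace-slope stage recovers the
    generated activities without further error.
    """
    times = np.linspace(0.0, duration_min, n_points)
    rows = []
    for m in data.measurements:
        for t in times:
            rows.append(
                {
                    "scenario": data.scenario.label,
                    "condition": m.condition,
                    "replicate": m.replicate_id,
                    "time_min": t,
                    "absorbance": baseline + m.activity * t,
                }
            )
    return pd.DataFrame(rows)


def generate_inhibition_course(
    T_half: float,
    n_points: int = 8,
    noise_cv: float = 0.0,
    seed: Optional[int] = None,
    a0: float = 1.0,
    t_max: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Exponential enzyme-inhibition time-course with known half-life.

    Residual activity a(t) = a0 · 2^(−t/T_half) sampled at ``n_points``
    times up to ``t_max`` (default 4 half-lives), with multiplicative
    Gaussian noise of CV ``noise_cv``.
    """
    if not T_half > 0:
        raise ValueError("T_half must be positive")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_max if t_max is not None else 4.0 * T_half, n_points)
    clean = a0 * np.power(2.0, -times / T_half)
    activities = clean * (1.0 + noise_cv * rng.standard_normal(n_points))
    truth = {"T_half": T_half, "k_obs": math.log(2) / T_half, "a0": a0}
    return times, activities, truth


def perturb_ligand(
    reference: Sequence,
    mode: str = "translate",
    magnitude: float = 1.0,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, float]:
    """Rigidly or randomly perturb ligand coordinates with known RMSD.

    ``translate`` shifts every atom by a random direction scaled to
    ``magnitude``, so the true RMSD equals ``magnitude`` exactly;
    ``jitter`` adds isotropic Gaussian noise of SD ``magnitude`` per
    coordinate and returns the realized RMSD.
    """
    coords = np.asarray(reference, dtype=float)
    if coords.size == 0:
        raise ValueError("reference coordinates are empty")
    rng = np.random.default_rng(seed)
    if mode == "translate":
        direction = rng.standard_normal(3)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        perturbed = coords + magnitude * direction
        return perturbed, float(abs(magnitude))
    if mode == "jitter":
        perturbed = coords + rng.normal(0.0, magnitude, size=coords.shape)
        return perturbed, _rmsd(coords, perturbed)
    raise ValueError(f"unknown perturbation mode {mode!r}")


def generate_correlated_pairs(
    n: int,
    r_true: float,
    seed: Optional[int] = None,
    x_scale: float = 30.0,
    x_offset: float = 40.0,
) -> list:
    """(x, y) pairs with a population Pearson correlation of ``r_true``,
    mapped onto a percentage-like scale."""
    if not -1 <= r_true <= 1:
        raise ValueError("r_true must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = r_true * x + math.sqrt(max(0.0, 1.0 - r_true**2)) * e
    return list(zip(x_offset + x_scale * x, x_offset + x_scale * y))
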