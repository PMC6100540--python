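"""Reading and writing receptor/adduct structures and docking-pose ensembles.

The geometric analysis downstream needs only two receptor anchors — the
catalytic-serine Oγ and the phosphorus of the organophosphate adduct — plus
per-pose ligand coordinates and docking energies.  This module resolves those
anchors from PDB files (via :mod:`gemmi`), reads pose ensembles from
multi-model PDB or SDF (via :mod:`rdkit`), and reads plain geometry tables
(CSV) for workflows where only per-pose d/θ/energy values are available.

All coordinates are Ångström in the shared docking frame; nothing here
superposes or rescales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "AnchorSpec",
    "ReceptorComplex",
    "OximeSpec",
    "LigandPose",
    "PoseEnsemble",
    "AnchorResolutionError",
    "PoseFileError",
    "DEFAULT_ANCHORS",
    "read_receptor_complex",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "read_geometry_table",
]


class AnchorResolutionError(ValueError):
    """An anchor selector matched zero or several atoms."""


class PoseFileError(ValueError):
    """A pose-ensemble file is malformed or inconsistent."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the receptor complex, in the docking frame (Å)."""

    name: str
    element: str
    coord: np.ndarray
    residue_name: str
    residue_id: int
    chain: str

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)


@dataclass(frozen=True)
class AnchorSpec:
    """Selectors for the two attack-geometry anchors.

    ``serine_residue_id``/``serine_atom_name`` pick the catalytic-serine Oγ;
    ``op_residue_selector`` (a residue name such as ``"POX"`` or a residue id)
    and ``op_atom_name`` pick the organophosphate phosphorus.  Each selector
    must resolve to exactly one atom.
    """

    serine_residue_id: int = 203
    serine_atom_name: str = "OG"
    op_residue_selector: Union[str, int] = "POX"
    op_atom_name: str = "P"


#: Catalytic serine is residue 203 in human AChE and 198 in human BChE
#: (standard numbering); override via config if a structure is renumbered.
DEFAULT_ANCHORS = {
    "AChE": AnchorSpec(serine_residue_id=203),
    "BChE": AnchorSpec(serine_residue_id=198),
}


@dataclass(frozen=True)
class ReceptorComplex:
    """Receptor atoms plus the two resolved anchor coordinates (Å)."""

    enzyme_label: str
    atoms: tuple
    serine_O: np.ndarray
    op_P: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.serine_O, dtype=float)
        p = np.asarray(self.op_P, dtype=float)
        if np.allclose(s, p):
            raise ValueError("serine Oγ and OP phosphorus coincide")
        object.__setattr__(self, "serine_O", s)
        object.__setattr__(self, "op_P", p)


@dataclass(frozen=True)
class OximeSpec:
    """Identity and attack-relevant atoms of one oxime reactivator.

    ``oxime_oxygen_atoms`` lists the oximate oxygen(s) as atom names or
    integer indices into the pose atom order — one entry for mono-oximes,
    two for bis-oximes such as obidoxime.  Ionization state and net charge
    are carried as metadata only; no protonation chemistry is done here.
    """

    name: str
    oxime_oxygen_atoms: tuple
    ionization_label: str = "oximate"
    net_charge: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "oxime_oxygen_atoms", tuple(self.oxime_oxygen_atoms))
        if not self.oxime_oxygen_atoms:
            raise ValueError(f"oxime {self.name}: needs at least one oxime oxygen")


@dataclass(frozen=True)
class LigandPose:
    """One docked pose: ordered ligand coordinates plus docking energies."""

    pose_index: int
    coords: np.ndarray
    energy_total: float
    energy_hbond: Optional[float] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("pose coordinates must be finite")
        if not np.isfinite(self.energy_total):
            raise ValueError("energy_total must be finite")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class PoseEnsemble:
    """All returned poses of one oxime docked into one complex.

    ``atom_names``/``elements`` describe the shared atom order so that oxime
    oxygens given by name in :class:`OximeSpec` can be resolved to indices.
    """

    complex_label: str
    oxime: OximeSpec
    poses: tuple
    atom_names: tuple = ()
    elements: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "poses", tuple(self.poses))
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        object.__setattr__(self, "elements", tuple(self.elements))
        if not self.poses:
            raise ValueError("ensemble must contain at least one pose")
        n = self.poses[0].coords.shape[0]
        for pose in self.poses:
            if pose.coords.shape[0] != n:
                raise ValueError("all poses must share the same atom count")
        if self.atom_names and len(self.atom_names) != n:
            raise ValueError("atom_names length must match pose atom count")

    @property
    def n_atoms(self) -> int:
        return self.poses[0].coords.shape[0]

    def oxime_oxygen_indices(self) -> tuple:
        """Resolve the oxime oxygen selectors of ``self.oxime`` to indices."""
        out = []
        for sel in self.oxime.oxime_oxygen_atoms:
            if isinstance(sel, (int, np.integer)):
                if not 0 <= int(sel) < self.n_atoms:
                    raise ValueError(f"oxime oxygen index {sel} out of range")
                out.append(int(sel))
            else:
                if sel not in self.atom_names:
                    raise ValueError(
                        f"oxime oxygen atom {sel!r} not found in ensemble atom names"
                    )
                out.append(self.atom_names.index(sel))
        return tuple(out)


def _iter_pdb_atoms(structure: gemmi.Structure):
    """Yield (residue, atom) over model 1, skipping waters, altloc B+ and
    insertion-coded residues (warned once each)."""
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.is_water() or residue.name in ("HOH", "WAT", "DOD"):
                continue
            if residue.seqid.icode not in ("", " "):
                warnings.warn(
                    f"skipping insertion-coded residue {residue.name} "
                    f"{residue.seqid.num}{residue.seqid.icode}",
                    stacklevel=3,
                )
                continue
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                yield chain, residue, atom


def read_receptor_complex(
    path: Union[str, Path],
    anchors: AnchorSpec,
    enzyme_label: str = "AChE",
) -> ReceptorComplex:
    """Read a receptor/OP-adduct PDB file and resolve the attack anchors.

    Parameters
    ----------
    path
        PDB file of the enzyme with its organophosphate adduct (covalent or
        placed); e.g. an AChE/paraoxon complex.
    anchors
        Selectors for the catalytic-serine Oγ and the OP phosphorus.
    enzyme_label
        Free label ("AChE"/"BChE") carried through to reports.

    Raises
    ------
    AnchorResolutionError
        If a selector matches no atom or more than one atom.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PoseFileError(f"cannot parse {path} as PDB: {exc}") from exc
    if len(structure) == 0:
        raise PoseFileError(f"{path}: no models in file")

    atoms = []
    serine_hits = []
    op_hits = []
    op_sel = anchors.op_residue_selector
    for chain, residue, atom in _iter_pdb_atoms(structure):
        rec = AtomRecord(
            name=atom.name,
            element=atom.element.name,
            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            residue_name=residue.name,
            residue_id=residue.seqid.num,
            chain=chain.name,
        )
        atoms.append(rec)
        if (
            rec.residue_id == anchors.serine_residue_id
            and rec.name == anchors.serine_atom_name
        ):
            serine_hits.append(rec)
        op_res_match = (
            rec.residue_name == op_sel
            if isinstance(op_sel, str)
            else rec.residue_id == int(op_sel)
        )
        if op_res_match and rec.name == anchors.op_atom_name:
            op_hits.append(rec)

    for hits, what in (
        (serine_hits, f"serine anchor {anchors.serine_atom_name} of residue "
                      f"{anchors.serine_residue_id}"),
        (op_hits, f"OP anchor {anchors.op_atom_name} of residue {op_sel!r}"),
    ):
        if len(hits) == 0:
            raise AnchorResolutionError(f"{path}: anchor not found: {what}")
        if len(hits) > 1:
            raise AnchorResolutionError(f"{path}: ambiguous anchor ({len(hits)} matches): {what}")

    return ReceptorComplex(
        enzyme_label=enzyme_label,
        atoms=tuple(atoms),
        serine_O=serine_hits[0].coord,
        op_P=op_hits[0].coord,
    )


# ---------------------------------------------------------------------------
# Pose ensembles
# ---------------------------------------------------------------------------

_ENERGY_TAG = "ENERGY"
_HBOND_TAG = "ENERGY_HBOND"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".energies.csv")


def _read_energy_sidecar(path: Path) -> pd.DataFrame:
    # round_trip parser: sidecar energies must survive write/read bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"pose_index", "energy_total"}
    if not required.issubset(df.columns):
        raise PoseFileError(f"{path}: energy sidecar needs columns {sorted(required)}")
    return df.set_index("pose_index")


def read_pose_ensemble(
    path: Union[str, Path],
    oxime: OximeSpec,
    complex_label: str = "",
    energies: Union[None, str, Path, pd.DataFrame] = None,
    require_energy: bool = True,
    energy_tag: str = _ENERGY_TAG,
) -> PoseEnsemble:
    """Read a docking pose ensemble from multi-model PDB or SDF.

    For PDB input, per-pose energies come from a sidecar CSV
    (``pose_index,energy_total[,energy_hbond]``), either passed explicitly or
    found at ``<path>.energies.csv``.  For SDF input, energies are read from
    the SD tag ``energy_tag`` (default ``ENERGY``) with optional
    ``ENERGY_HBOND``.  Poses keep file order; atom order must be identical
    across models/records.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        names, elements, raw = _read_poses_sdf(path, energy_tag)
    else:
        names, elements, raw = _read_poses_pdb(path)

    if not raw:
        raise PoseFileError(f"{path}: no poses found")

    # raw: list of (coords, energy_total_or_None, energy_hbond_or_None)
    n_atoms = raw[0][0].shape[0]
    for i, (coords, _, _) in enumerate(raw):
        if coords.shape[0] != n_atoms:
            raise PoseFileError(
                f"{path}: pose {i} has {coords.shape[0]} atoms, expected {n_atoms}"
            )

    table = None
    if isinstance(energies, pd.DataFrame):
        table = energies.set_index("pose_index") if "pose_index" in energies.columns else energies
    elif energies is not None:
        table = _read_energy_sidecar(Path(energies))
    elif suffix not in (".sdf", ".sd", ".mol") and _sidecar_path(path).exists():
        table = _read_energy_sidecar(_sidecar_path(path))

    poses = []
    for i, (coords, e_tot, e_hb) in enumerate(raw):
        if table is not None and i in table.index:
            e_tot = float(table.loc[i, "energy_total"])
            if "energy_hbond" in table.columns and pd.notna(table.loc[i, "energy_hbond"]):
                e_hb = float(table.loc[i, "energy_hbond"])
        if e_tot is None:
            if require_energy:
                raise PoseFileError(
                    f"{path}: pose {i} has no energy (provide a sidecar CSV, "
                    f"an SD tag {energy_tag!r}, or pass require_energy=False)"
                )
            e_tot = 0.0
        poses.append(
            LigandPose(pose_index=i, coords=coords, energy_total=e_tot, energy_hbond=e_hb)
        )

    return PoseEnsemble(
        complex_label=complex_label,
        oxime=oxime,
        poses=tuple(poses),
        atom_names=tuple(names),
        elements=tuple(elements),
    )


def _read_poses_pdb(path: Path):
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PoseFileError(f"cannot parse {path} as PDB: {exc}") from exc
    if len(structure) == 0:
        raise PoseFileError(f"{path}: no models in file")
    names: list = []
    elements: list = []
    raw = []
    for i, model in enumerate(structure):
        coords = []
        model_names = []
        model_elems = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    model_names.append(atom.name)
                    model_elems.append(atom.element.name)
        if i == 0:
            names, elements = model_names, model_elems
        elif len(model_names) != len(names):
            raise PoseFileError(
                f"{path}: model {i} has {len(model_names)} atoms, expected {len(names)}"
            )
        raw.append((np.asarray(coords, dtype=float), None, None))
    return names, elements, raw


def _read_poses_sdf(path: Path, energy_tag: str):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    names: list = []
    elements: list = []
    raw = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise PoseFileError(f"{path}: record {i} unreadable")
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(j)) for j in range(mol.GetNumAtoms())], dtype=float
        )
        e_tot = float(mol.GetProp(energy_tag)) if mol.HasProp(energy_tag) else None
        e_hb = float(mol.GetProp(_HBOND_TAG)) if mol.HasProp(_HBOND_TAG) else None
        if i == 0:
            elements = [a.GetSymbol() for a in mol.GetAtoms()]
            names = [f"{sym}{j + 1}" for j, sym in enumerate(elements)]
        elif mol.GetNumAtoms() != len(names):
            raise PoseFileError(
                f"{path}: record {i} has {mol.GetNumAtoms()} atoms, expected {len(names)}"
            )
        raw.append((coords, e_tot, e_hb))
    return names, elements, raw


def write_pose_ensemble(
    path: Union[str, Path],
    ensemble: PoseEnsemble,
    sidecar: Union[None, str, Path] = None,
) -> Path:
    """Write a pose ensemble as multi-model PDB (HETATM ligand records) or SDF.

    PDB output gets an energy sidecar CSV at ``<path>.energies.csv`` (or
    ``sidecar``); SDF output stores energies in SD tags, so no sidecar is
    written.  Returns the main output path.
    """
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".sd"):
        _write_poses_sdf(path, ensemble)
        return path

    structure = gemmi.Structure()
    structure.name = ensemble.oxime.name or "LIG"
    names = ensemble.atom_names or tuple(
        f"X{j + 1}" for j in range(ensemble.n_atoms)
    )
    elements = ensemble.elements or tuple("C" for _ in range(ensemble.n_atoms))
    for k, pose in enumerate(ensemble.poses):
        model = gemmi.Model(k + 1)
        chain = gemmi.Chain("L")
        residue = gemmi.Residue()
        residue.name = "LIG"
        residue.seqid = gemmi.SeqId(1, " ")
        residue.het_flag = "H"
        for j in range(ensemble.n_atoms):
            atom = gemmi.Atom()
            atom.name = names[j]
            atom.element = gemmi.Element(elements[j])
            atom.pos = gemmi.Position(*pose.coords[j])
            residue.add_atom(atom)
        chain.add_residue(residue)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))

    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    pd.DataFrame(
        {
            "pose_index": [p.pose_index for p in ensemble.poses],
            "energy_total": [p.energy_total for p in ensemble.poses],
            "energy_hbond": [p.energy_hbond for p in ensemble.poses],
        }
    ).to_csv(sidecar, index=False)
    return path


def _write_poses_sdf(path: Path, ensemble: PoseEnsemble) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    elements = ensemble.elements or tuple("C" for _ in range(ensemble.n_atoms))
    writer = Chem.SDWriter(str(path))
    try:
        for pose in ensemble.poses:
            mol = Chem.RWMol()
            for sym in elements:
                mol.AddAtom(Chem.Atom(sym))
            conf = Chem.Conformer(ensemble.n_atoms)
            for j in range(ensemble.n_atoms):
                conf.SetAtomPosition(j, Point3D(*pose.coords[j]))
            mol.AddConformer(conf)
            out = mol.GetMol()
            out.SetProp("_Name", f"{ensemble.oxime.name}_pose{pose.pose_index}")
            out.SetProp(_ENERGY_TAG, repr(pose.energy_total))
            if pose.energy_hbond is not None:
                out.SetProp(_HBOND_TAG, repr(pose.energy_hbond))
            writer.write(out)
    finally:
        writer.close()


def read_geometry_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-pose geometry table (CSV) with columns
    ``pose_index, d_op, theta_opo, energy``.

    Rows are kept in file order.  Validation: d_op must be ≥ 0 and
    theta_opo within [0, 180]; violations raise with the offending row
    number (0-based data row).
    """
    df = pd.read_csv(path)
    required = ["pose_index", "d_op", "theta_opo", "energy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for i, row in df.iterrows():
        if not np.isfinite(row["d_op"]) or row["d_op"] < 0:
            raise ValueError(f"{path}: row {i}: d_op must be ≥ 0, got {row['d_op']}")
        if not np.isfinite(row["theta_opo"]) or not 0 <= row["theta_opo"] <= 180:
            raise ValueError(
                f"{path}: row {i}: theta_opo must be in [0, 180], got {row['theta_opo']}"
            )
    return df[required].copy()
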