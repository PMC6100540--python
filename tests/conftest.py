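import math

import numpy as np
import pytest

from nacscan.structure_io import (
    AtomRecord,
    LigandPose,
    OximeSpec,
    PoseEnsemble,
    ReceptorComplex,
)

# Minimal receptor text fixture: catalytic-serine Oγ at the origin and the
# organophosphate phosphorus at (3, 0, 0), plus one backbone atom.
MINIMAL_PDB = """\
ATOM      1  CA  SER A 203       1.000   1.000   1.000  1.00  0.00           C
ATOM      2  OG  SER A 203       0.000   0.000   0.000  1.00  0.00           O
HETATM    3  P   POX A 900       3.000   0.000   0.000  1.00  0.00           P
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "receptor.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def receptor():
    """Two-anchor complex: P at origin, serine Oγ 4 Å along +z."""
    ser = np.array([0.0, 0.0, 4.0])
    p = np.zeros(3)
    atoms = (
        AtomRecord("OG", "O", ser, "SER", 203, "A"),
        AtomRecord("P", "P", p, "POX", 900, "A"),
    )
    return ReceptorComplex(enzyme_label="AChE", atoms=atoms, serine_O=ser, op_P=p)


def oxime_O_at(d: float, theta_deg: float, phi: float = 0.0) -> np.ndarray:
    """Place an oximate O at distance d from the origin so the O–P–OSer
    angle (serine direction +z) equals theta."""
    t = math.radians(theta_deg)
    return d * np.array(
        [math.sin(t) * math.cos(phi), math.sin(t) * math.sin(phi), math.cos(t)]
    )


def single_atom_ensemble(geometries, energies=None, name="ox"):
    """Ensemble of one-atom 'ligands' whose oxime O sits at the given
    (d, theta) placements; geometry of each pose is known by construction."""
    energies = energies if energies is not None else [-100.0] * len(geometries)
    poses = tuple(
        LigandPose(
            pose_index=i,
            coords=oxime_O_at(d, theta)[None, :],
            energy_total=float(e),
        )
        for i, ((d, theta), e) in enumerate(zip(geometries, energies))
    )
    oxime = OximeSpec(name=name, oxime_oxygen_atoms=("O1",))
    return PoseEnsemble(
        complex_label="AChE/POX",
        oxime=oxime,
        poses=poses,
        atom_names=("O1",),
        elements=("O",),
    )
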