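import math

import numpy as np
import pytest

from nacscan.geometry import (
    NACCriteria,
    angle,
    distance,
    nac_summary,
    pose_geometry,
    rmsd,
    select_best_pose,
    summarize_geometry_table,
    validate_redock,
)
from nacscan.structure_io import LigandPose, OximeSpec, PoseEnsemble

from conftest import oxime_O_at, single_atom_ensemble

ATTACK = NACCriteria(distance_definition="oximeO_to_p")


class TestDistanceAngle:
    @pytest.mark.parametrize(
        "p,q,expected",
        [((0, 0, 0), (3, 4, 0), 5.0), ((1, 2, 3), (1, 2, 3), 0.0)],
    )
    def test_distance_known_values(self, p, q, expected):
        assert distance(p, q) == pytest.approx(expected, abs=1e-12)

    def test_distance_matches_componentwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p, q = rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3)
            oracle = math.sqrt(math.fsum((a - b) ** 2 for a, b in zip(p, q)))
            assert distance(p, q) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize(
        "a,v,b,expected",
        [
            ((1, 0, 0), (0, 0, 0), (-1, 0, 0), 180.0),
            ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
            ((2, 0, 0), (0, 0, 0), (5, 0, 0), 0.0),
        ],
    )
    def test_angle_known_values(self, a, v, b, expected):
        assert angle(a, v, b) == pytest.approx(expected, abs=1e-9)

    def test_angle_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, v, b = (rng.uniform(-10, 10, 3) for _ in range(3))
            u1 = np.asarray(a - v, dtype=np.longdouble)
            u2 = np.asarray(b - v, dtype=np.longdouble)
            cos = (u1 @ u2) / (np.sqrt(u1 @ u1) * np.sqrt(u2 @ u2))
            oracle = float(np.degrees(np.arccos(np.clip(cos, -1, 1))))
            assert angle(a, v, b) == pytest.approx(oracle, abs=1e-9)

    def test_angle_zero_length_arm_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestNACClassification:
    def test_reference_best_pose_geometry_is_nac(self, receptor):
        # obidoxime-like best pose: 4.260 Å, 155.00° sits inside the window
        ens = single_atom_ensemble([(4.260, 155.00)])
        geom = pose_geometry(
            ens.poses[0], receptor, ens.oxime, ATTACK, atom_names=ens.atom_names
        )
        assert geom.d_op == pytest.approx(4.260, abs=1e-9)
        assert geom.theta_opo == pytest.approx(155.00, abs=1e-9)
        assert geom.is_nac

    @pytest.mark.parametrize(
        "d,theta,expected",
        [
            (5.0, 119.9, False),  # just below the inclusive angle bound
            (5.0, 120.0, True),   # 180 − 60 is included
            (10.0, 150.0, False),  # distance bound is strict
            (9.999999, 150.0, True),
        ],
    )
    def test_window_boundaries(self, d, theta, expected):
        assert ATTACK.in_window(d, theta) is expected

    def test_classification_from_measured_coordinates(self, receptor):
        # away from the exact bounds, classification through the measured
        # geometry agrees with the window test on the sampled values
        rng = np.random.default_rng(12)
        for _ in range(50):
            d, theta = rng.uniform(2, 14), rng.uniform(90, 180)
            ens = single_atom_ensemble([(d, theta)])
            geom = pose_geometry(
                ens.poses[0], receptor, ens.oxime, ATTACK, atom_names=ens.atom_names
            )
            assert geom.is_nac == ATTACK.in_window(d, theta)

    def test_literal_distance_definition_uses_receptor_anchors(self, receptor):
        # p_to_serO: d_op is the P↔Oγ separation (4 Å here), not the oxime O
        ens = single_atom_ensemble([(8.0, 150.0)])
        geom = pose_geometry(
            ens.poses[0], receptor, ens.oxime, NACCriteria(), atom_names=ens.atom_names
        )
        assert geom.d_op == pytest.approx(4.0)

    def test_bis_oxime_keeps_theta_maximizing_oxygen(self, receptor):
        coords = np.vstack([oxime_O_at(5.0, 130.0), oxime_O_at(4.0, 170.0)])
        pose = LigandPose(pose_index=0, coords=coords, energy_total=-100.0)
        oxime = OximeSpec(name="bis", oxime_oxygen_atoms=("OA", "OB"))
        geom = pose_geometry(pose, receptor, oxime, ATTACK, atom_names=("OA", "OB"))
        assert geom.oxime_O_used == "OB"
        assert geom.theta_opo == pytest.approx(170.0, abs=1e-9)

    def test_bis_oxime_falls_back_to_min_distance(self, receptor):
        coords = np.vstack([oxime_O_at(12.0, 170.0), oxime_O_at(15.0, 179.0)])
        pose = LigandPose(pose_index=0, coords=coords, energy_total=-100.0)
        oxime = OximeSpec(name="bis", oxime_oxygen_atoms=("OA", "OB"))
        geom = pose_geometry(pose, receptor, oxime, ATTACK, atom_names=("OA", "OB"))
        assert geom.oxime_O_used == "OA"
        assert not geom.is_nac

    def test_rigid_transform_invariance(self, receptor):
        rng = np.random.default_rng(7)
        ens = single_atom_ensemble([(6.0, 140.0)])
        base = pose_geometry(
            ens.poses[0], receptor, ens.oxime, ATTACK, atom_names=ens.atom_names
        )
        for _ in range(20):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )
            shift = rng.uniform(-30, 30, 3)
            moved = type(receptor)(
                enzyme_label=receptor.enzyme_label,
                atoms=receptor.atoms,
                serine_O=rot @ receptor.serine_O + shift,
                op_P=rot @ receptor.op_P + shift,
            )
            pose = LigandPose(
                pose_index=0,
                coords=(ens.poses[0].coords @ rot.T) + shift,
                energy_total=-100.0,
            )
            geom = pose_geometry(pose, moved, ens.oxime, ATTACK, atom_names=ens.atom_names)
            assert geom.d_op == pytest.approx(base.d_op, abs=1e-9)
            assert geom.theta_opo == pytest.approx(base.theta_opo, abs=1e-8)


class TestSummary:
    def test_all_poses_in_window(self, receptor):
        ens = single_atom_ensemble([(4.0, 170.0)] * 10)
        assert nac_summary(ens, receptor, ATTACK).pct_nac == 100.0

    def test_no_pose_in_angle_window(self, receptor):
        ens = single_atom_ensemble([(4.0, 100.0)] * 10)
        assert nac_summary(ens, receptor, ATTACK).pct_nac == 0.0

    def test_summary_matches_brute_force_recount(self, receptor):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 50))
            geoms = list(zip(rng.uniform(2, 15, n), rng.uniform(60, 180, n)))
            energies = rng.normal(-100, 4, n)
            ens = single_atom_ensemble(geoms, energies)
            summary = nac_summary(ens, receptor, ATTACK)
            # independent counting loop
            emin = min(energies)
            n_low = n_nac = 0
            for (d, theta), e in zip(geoms, energies):
                low = e <= emin + 5.0
                n_low += low
                if low and d < 10.0 and 120.0 <= theta <= 180.0:
                    n_nac += 1
            assert summary.n_low_energy == n_low
            assert summary.n_nac == n_nac
            assert summary.pct_nac == pytest.approx(
                100.0 * n_nac / n_low if n_low else 0.0
            )

    def test_pct_nac_monotone_in_window_size(self, receptor):
        rng = np.random.default_rng(3)
        geoms = list(zip(rng.uniform(2, 15, 60), rng.uniform(60, 180, 60)))
        ens = single_atom_ensemble(geoms)
        wide = nac_summary(ens, receptor, ATTACK)
        for tighten, value in (("d_max", 6.0), ("theta_tol", 30.0)):
            kwargs = {"distance_definition": "oximeO_to_p", tighten: value}
            narrow = nac_summary(ens, receptor, NACCriteria(**kwargs))
            assert narrow.pct_nac <= wide.pct_nac

    def test_shrinking_energy_window_never_grows_low_energy_set(self, receptor):
        rng = np.random.default_rng(4)
        geoms = list(zip(rng.uniform(2, 15, 40), rng.uniform(60, 180, 40)))
        ens = single_atom_ensemble(geoms, rng.normal(-100, 6, 40))
        counts = [
            nac_summary(
                ens, receptor, NACCriteria(distance_definition="oximeO_to_p", energy_window=w)
            ).n_low_energy
            for w in (12.0, 8.0, 4.0, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)
        everything = nac_summary(
            ens, receptor, NACCriteria(distance_definition="oximeO_to_p", energy_window="all")
        )
        assert everything.n_low_energy == 40

    def test_empty_denominator_warns_and_reports_zero(self, receptor):
        ens = single_atom_ensemble([(4.0, 170.0)], energies=[-100.0])
        crit = NACCriteria(distance_definition="oximeO_to_p", denominator="all")
        # force an empty low-energy set is impossible (min always qualifies);
        # the zero-denominator branch is reachable via the table route
        import pandas as pd

        table = pd.DataFrame(
            {"pose_index": [], "d_op": [], "theta_opo": [], "energy": []}
        )
        with pytest.warns(UserWarning, match="denominator"):
            s = summarize_geometry_table(table, crit)
        assert s.pct_nac == 0.0

    def test_table_route_matches_coordinate_route(self, receptor):
        rng = np.random.default_rng(9)
        geoms = list(zip(rng.uniform(2, 15, 30), rng.uniform(60, 180, 30)))
        energies = rng.normal(-100, 4, 30)
        ens = single_atom_ensemble(geoms, energies)
        import pandas as pd

        table = pd.DataFrame(
            {
                "pose_index": range(30),
                "d_op": [d for d, _ in geoms],
                "theta_opo": [t for _, t in geoms],
                "energy": energies,
            }
        )
        a = nac_summary(ens, receptor, ATTACK)
        b = summarize_geometry_table(table, ATTACK)
        assert (a.n_nac, a.n_low_energy, a.pct_nac) == (b.n_nac, b.n_low_energy, b.pct_nac)


class TestBestPose:
    def test_lower_distance_wins_first(self, receptor):
        ens = single_atom_ensemble(
            [(4.0, 150.0), (6.0, 179.0)], energies=[-100.0, -104.0]
        )
        best = select_best_pose(ens, receptor, ATTACK)
        assert best.pose_index == 0

    def test_theta_breaks_distance_ties(self, receptor):
        # both oxygens exactly 5 Å from P: (3,0,-4) at θ≈143°, (0,0,-5) at 180°
        oxime = OximeSpec(name="ox", oxime_oxygen_atoms=("O1",))
        poses = (
            LigandPose(0, np.array([[3.0, 0.0, -4.0]]), -103.0),
            LigandPose(1, np.array([[0.0, 0.0, -5.0]]), -100.0),
        )
        ens = PoseEnsemble("AChE/POX", oxime, poses, ("O1",), ("O",))
        assert select_best_pose(ens, receptor, ATTACK).pose_index == 1

    def test_energy_breaks_remaining_ties(self, receptor):
        ens = single_atom_ensemble(
            [(5.0, 160.0), (5.0, 160.0)], energies=[-100.0, -130.0]
        )
        assert select_best_pose(ens, receptor, ATTACK).pose_index == 1

    def test_single_pose_selected(self, receptor):
        ens = single_atom_ensemble([(7.0, 140.0)], energies=[-90.0])
        best = select_best_pose(ens, receptor, ATTACK)
        assert best.pose_index == 0
        assert best.energy_total == -90.0

    def test_selection_restricted_to_low_energy_set(self, receptor):
        # the closest pose is 20 kcal/mol above the minimum: excluded
        ens = single_atom_ensemble(
            [(3.0, 170.0), (6.0, 150.0)], energies=[-80.0, -100.0]
        )
        assert select_best_pose(ens, receptor, ATTACK).pose_index == 1


class TestRMSD:
    def test_identical_coordinates(self):
        coords = np.arange(15.0).reshape(5, 3)
        assert rmsd(coords, coords) == 0.0

    def test_uniform_translation(self):
        coords = np.arange(15.0).reshape(5, 3)
        assert rmsd(coords, coords + [1.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_accumulation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.uniform(-10, 10, (8, 3))
            b = a + rng.normal(0, 0.5, (8, 3))
            acc = math.fsum(
                (a[i, k] - b[i, k]) ** 2 for i in range(8) for k in range(3)
            )
            assert rmsd(a, b) == pytest.approx(math.sqrt(acc / 8), abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRedockValidation:
    def test_literature_grade_rmsd_passes(self):
        a = np.zeros((4, 3))
        b = a + [1.18 / math.sqrt(3)] * 3  # rigid shift of norm 1.18
        result = validate_redock(a, b)
        assert result["rmsd"] == pytest.approx(1.18, abs=1e-9)
        assert result["pass"]

    def test_threshold_is_strict(self):
        a = np.zeros((4, 3))
        b = a + [2.0, 0.0, 0.0]
        assert not validate_redock(a, b)["pass"]

    def test_constructed_perturbation_recovered(self):
        from nacscan.synthetic import perturb_ligand

        rng = np.random.default_rng(8)
        ref = rng.uniform(-5, 5, (6, 3))
        moved, true_rmsd = perturb_ligand(ref, mode="translate", magnitude=0.5, seed=3)
        result = validate_redock(ref, moved)
        assert result["rmsd"] == pytest.approx(0.5, abs=1e-9)
        assert result["pass"]
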