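"""Model parsing, pLDDT bands, Kabsch superposition, elongation, physchem, triage."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from morfkit.hits import AnnotationRecord, MorphologAssignment
from conftest import make_hit
from morfkit.fixtures import helix_coords
from morfkit.structure import (
    PLDDT_BANDS,
    ProteinModel,
    band_fractions,
    elongation_score,
    kabsch_superpose,
    net_charge,
    novel_fold_triage,
    parse_model,
    physchem,
    plddt_band,
)


def _pdb_line(serial, resname, resseq, x, y, z, b, altloc=" "):
    return (
        f"ATOM  {serial:5d}  CA {altloc}{resname} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C\n"
    )


class TestParseModel:
    def test_mean_plddt_from_b_factors(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(
            _pdb_line(1, "ALA", 1, 0, 0, 0, 90.0)
            + _pdb_line(2, "GLY", 2, 3.8, 0, 0, 70.0)
            + _pdb_line(3, "SER", 3, 7.6, 0, 0, 50.0)
            + "END\n"
        )
        model = parse_model(path)
        assert model.mean_plddt == pytest.approx(70.0)
        assert model.sequence == "AGS"
        assert [r[0] for r in model.residues] == [1, 2, 3]

    def test_no_atom_records_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError, match="C-alpha"):
            parse_model(path)

    def test_first_altloc_kept_count_unchanged(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            _pdb_line(1, "ALA", 1, 0.0, 0, 0, 90.0, altloc="A")
            + _pdb_line(2, "ALA", 1, 9.0, 0, 0, 10.0, altloc="B")
            + _pdb_line(3, "GLY", 2, 3.8, 0, 0, 80.0)
            + "END\n"
        )
        model = parse_model(path)
        assert len(model.residues) == 2
        assert model.residues[0][3] == pytest.approx(90.0)
        assert model.residues[0][2][0] == pytest.approx(0.0)


class TestPlddtBand:
    @pytest.mark.parametrize(
        "value, band",
        [
            (95, "very_high"),
            (90, "confident"),  # boundary goes to the lower band
            (70, "low"),
            (50, "very_low"),
            (0, "very_low"),
            (100, "very_high"),
        ],
    )
    def test_bands(self, value, band):
        assert plddt_band(value) == band

    def test_banding_partitions_the_range(self):
        for p in np.linspace(0, 100, 401):
            assert plddt_band(float(p)) in PLDDT_BANDS
        with pytest.raises(ValueError):
            plddt_band(101.0)

    def test_band_fractions_sum_to_one(self):
        model = ProteinModel(
            "m",
            tuple(
                (i + 1, "ALA", (float(i), 0.0, 0.0), p)
                for i, p in enumerate([95.0, 85.0, 60.0, 30.0])
            ),
        )
        fractions = band_fractions(model)
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert fractions["confident"] == pytest.approx(0.25)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(12, 3))
        result = kabsch_superpose(a, a)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert result.rotation == pytest.approx(np.eye(3), abs=1e-12)
        assert result.n_atoms == 12

    def test_recovers_planted_rigid_transform(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(25, 3)) * 5
            true_rot = Rotation.random(random_state=rng).as_matrix()
            true_t = rng.normal(size=3) * 10
            b = (true_rot @ a.T).T + true_t
            result = kabsch_superpose(a, b)
            assert result.rmsd < 1e-8
            assert np.abs(result.rotation - true_rot).max() < 1e-6
            assert np.abs(result.translation - true_t).max() < 1e-6

    def test_hand_example_collinear_scaled(self):
        a = [(-1, 0, 0), (1, 0, 0), (0, 0, 0)]
        b = [(-2, 0, 0), (2, 0, 0), (0, 0, 0)]
        result = kabsch_superpose(a, b)
        assert result.rmsd == pytest.approx(math.sqrt(2 / 3), abs=1e-9)

    def test_rotation_is_always_proper(self):
        # mirrored target would tempt a reflection; determinant must stay +1
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 0] *= -1
        result = kabsch_superpose(a, b)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError):
            kabsch_superpose([(0, 0, 0), (1, 1, 1)], [(0, 0, 0), (1, 1, 1)])
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        base = kabsch_superpose(a, b).rmsd
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(size=3)
        moved = kabsch_superpose((rot @ a.T).T + shift, (rot @ b.T).T + shift)
        assert moved.rmsd == pytest.approx(base, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        ours = kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert ours.rmsd == pytest.approx(rssd / math.sqrt(10), abs=1e-9)
        assert ours.rotation == pytest.approx(rot.as_matrix(), abs=1e-9)


class TestElongation:
    def test_long_helix_is_rodlike(self):
        assert elongation_score(helix_coords(100)) > 10

    def test_cubic_lattice_is_isotropic(self):
        grid = np.array(
            [(x, y, z) for x in range(5) for y in range(5) for z in range(5)],
            dtype=float,
        )
        assert elongation_score(grid) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points_give_infinity(self):
        line = np.array([(float(i), 0.0, 0.0) for i in range(5)])
        assert elongation_score(line) == math.inf

    def test_invariant_to_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(40, 3)) * np.array([4.0, 2.0, 1.0])
        base = elongation_score(coords)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = (rot @ coords.T).T + np.array([10.0, -3.0, 7.0])
        assert elongation_score(moved) == pytest.approx(base, rel=1e-9)


class TestPhysChem:
    def test_gravy_from_hydropathy_table(self):
        assert physchem("II").gravy == pytest.approx(4.5)
        # mean of Ile (4.5) and Arg (-4.5)
        assert physchem("IR").gravy == pytest.approx(0.0)

    def test_instability_is_scaled_dipeptide_weight(self):
        from Bio.SeqUtils.ProtParamData import DIWV

        assert physchem("GG").instability_index == pytest.approx(
            (10 / 2) * DIWV["G"]["G"]
        )

    def test_matches_biopython_protparam(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        ours = physchem(seq)
        ref = ProteinAnalysis(seq)
        assert ours.gravy == pytest.approx(ref.gravy())
        assert ours.instability_index == pytest.approx(
            ref.instability_index(), abs=1e-6
        )

    def test_pi_is_a_charge_root_on_random_peptides(self):
        rng = np.random.default_rng(6)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(5, 80))))
            pi = physchem(seq).isoelectric_point
            assert 0.0 < pi < 14.0
            assert abs(net_charge(seq, pi)) < 1e-4

    def test_unknown_residues_skipped_up_to_ten_percent(self):
        long_seq = "A" * 50
        assert physchem(long_seq + "X").gravy == pytest.approx(1.8)
        with pytest.raises(ValueError):
            physchem("AXXX")
        with pytest.raises(ValueError):
            physchem("")


def _model(model_id, plddt, helix=False, n=80):
    rng = np.random.default_rng(abs(hash(model_id)) % 2**31)
    coords = helix_coords(n) if helix else rng.normal(0, 6, size=(n, 3))
    return ProteinModel(
        model_id,
        tuple(
            (i + 1, "ALA", tuple(map(float, coords[i])), float(plddt))
            for i in range(n)
        ),
    )


class TestTriage:
    @staticmethod
    def _assignment(query, annotated=False, has_hit=True):
        return MorphologAssignment(
            query_id=query,
            overall_best=make_hit(query=query, bits=100.0) if has_hit else None,
            passes_cutoff=False,
            transferred=(
                AnnotationRecord(query, preferred_name="N", source="structure")
                if annotated
                else None
            ),
        )

    def test_rule_evaluation(self):
        assignments = [
            self._assignment("annotated", annotated=True),
            self._assignment("nohit_helix", has_hit=False),
            self._assignment("below_globule"),
            self._assignment("too_disordered"),
        ]
        models = {
            "annotated": _model("annotated", 95.0),
            "nohit_helix": _model("nohit_helix", 80.0, helix=True),
            "below_globule": _model("below_globule", 85.0),
            "too_disordered": _model("too_disordered", 60.0),
        }
        result = novel_fold_triage(assignments, models)
        assert result.no_hit_helix == ("nohit_helix",)
        assert result.below_cutoff_globular == ("below_globule",)
        assert result.no_hit_globular == ()
        assert result.below_cutoff_helix == ()

    def test_plddt_boundary_is_strict(self):
        assignments = [self._assignment("edge", has_hit=False)]
        result = novel_fold_triage(assignments, {"edge": _model("edge", 70.0)})
        assert result.no_hit_helix == result.no_hit_globular == ()

    def test_missing_model_is_skipped_not_fatal(self):
        assignments = [self._assignment("ghost", has_hit=False)]
        result = novel_fold_triage(assignments, {})
        assert result.skipped_no_model == ("ghost",)

    def test_order_invariant(self):
        assignments = [
            self._assignment(f"q{i}", has_hit=bool(i % 2)) for i in range(8)
        ]
        models = {
            f"q{i}": _model(f"q{i}", 80.0, helix=bool(i % 3 == 0)) for i in range(8)
        }
        forward = novel_fold_triage(assignments, models)
        backward = novel_fold_triage(assignments[::-1], models)
        assert forward == backward
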