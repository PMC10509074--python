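"""Box construction, residue sampling, binding rules and serialization."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.spatial.distance import cdist

from synthscreen.ligand_chem import (
    ACCEPTOR,
    DONOR,
    HYDROPHOBE,
    PharmacophoreAssignment,
    assign_pharmacophores,
)
from synthscreen.synth_generator import (
    HBA,
    HBD,
    HYDROPHOBIC,
    GenerationConfig,
    RejectedLigandError,
    SyntheticComplex,
    SyntheticProtein,
    evaluate_contribution,
    evaluate_polar,
    generate_complex,
    generate_conditioned,
    interaction_score,
    make_box,
    read_complex,
    sample_synthetic_protein,
    write_complex,
)

from conftest import ligand_from_smiles, ligand_with_coords


def manual_assignment(atom_types, rule):
    return PharmacophoreAssignment(
        atom_types=tuple(frozenset(t) for t in atom_types), rule=rule
    )


class TestMakeBox:
    def test_interval_arithmetic(self):
        lig = ligand_with_coords(
            "CCO", [[1.0, 0.0, 0.0], [2.5, 1.0, 1.0], [4.0, 2.0, 3.0]]
        )
        box = make_box(lig, pad=5.0)
        assert box.lo[0] == pytest.approx(-4.0)
        assert box.hi[0] == pytest.approx(9.0)

    def test_volume_of_cube(self):
        lig = ligand_with_coords(
            "CCO", [[0.0, 0.0, 0.0], [1.5, 1.5, 1.5], [3.0, 3.0, 3.0]]
        )
        assert make_box(lig, pad=5.0).volume == pytest.approx(13.0**3)

    def test_zero_pad_is_bounding_box(self):
        xyz = np.array([[0.0, 0, 0], [1, 2, 0.5], [3, 1, 2]])
        box = make_box(ligand_with_coords("CCO", xyz), pad=0.0)
        np.testing.assert_allclose(box.lo, xyz.min(axis=0))
        np.testing.assert_allclose(box.hi, xyz.max(axis=0))

    def test_single_atom_box(self):
        lig = ligand_with_coords("C", [[1.0, 1.0, 1.0]])
        box = make_box(lig, pad=5.0)
        np.testing.assert_allclose(box.lengths, [10.0, 10.0, 10.0])


class TestSampleSyntheticProtein:
    def test_residue_cap(self, small_ligands):
        lig = small_ligands[0]
        a = assign_pharmacophores(lig, "polar")
        cfg = GenerationConfig(rule="polar")
        prot = sample_synthetic_protein(lig, a, cfg, seed=11)
        assert prot.n_res <= cfg.n_ops // a.n_lig

    def test_geometry_invariants_over_seeds(self, small_ligands):
        cfg = GenerationConfig(rule="polar")
        checked = 0
        for i, lig in enumerate((small_ligands * 5)[:200]):
            a = assign_pharmacophores(lig, "polar")
            prot = sample_synthetic_protein(lig, a, cfg, seed=1000 + i)
            assert cdist(prot.coords, lig.coords()).min() >= cfg.clash_dist
            if prot.n_res > 1:
                d = cdist(prot.coords, prot.coords)
                np.fill_diagonal(d, np.inf)
                assert d.min() >= cfg.min_sep
            box = make_box(lig, cfg.pad)
            assert box.contains(prot.coords).all()
            assert set(prot.types) <= {HBA, HBD}
            checked += 1
        assert checked == 200

    def test_seeded_determinism(self, small_ligands):
        lig = small_ligands[1]
        a = assign_pharmacophores(lig, "polar")
        cfg = GenerationConfig(rule="polar")
        p1 = sample_synthetic_protein(lig, a, cfg, seed=11)
        p2 = sample_synthetic_protein(lig, a, cfg, seed=11)
        np.testing.assert_array_equal(p1.coords, p2.coords)
        assert p1.types == p2.types

    def test_rejects_ligand_without_groups(self):
        benzene = ligand_from_smiles("c1ccccc1")
        a = assign_pharmacophores(benzene, "polar")
        with pytest.raises(RejectedLigandError):
            sample_synthetic_protein(benzene, a, GenerationConfig(), seed=1)

    def test_contribution_rule_types(self, small_ligands):
        lig = small_ligands[2]
        a = assign_pharmacophores(lig, "contribution")
        cfg = GenerationConfig(rule="contribution")
        prot = sample_synthetic_protein(lig, a, cfg, seed=4)
        assert set(prot.types) <= {HBA, HBD, HYDROPHOBIC}


class TestInteractionScore:
    def test_matches_gamma_pdf_oracle(self):
        # independent oracle: scipy's Gamma(4, 1) density
        for d in (0.5, 1.0, 2.0, 3.0, 4.5, 8.0):
            assert interaction_score("HBond", d) == pytest.approx(
                10 * gamma_dist.pdf(d, a=4, scale=1), rel=1e-12
            )
            assert interaction_score("Hydrophobic", d) == pytest.approx(
                3 * gamma_dist.pdf(d, a=4, scale=1), rel=1e-12
            )

    def test_reference_values_at_mode(self):
        assert interaction_score("HBond", 3.0) == pytest.approx(2.2404, abs=1e-4)
        assert interaction_score("Hydrophobic", 3.0) == pytest.approx(0.6721, abs=1e-4)

    def test_hbond_hydrophobic_ratio(self):
        for d in (1.0, 3.0, 6.0):
            ratio = interaction_score("HBond", d) / interaction_score("Hydrophobic", d)
            assert ratio == pytest.approx(10 / 3, rel=1e-12)

    def test_unimodal_with_mode_at_three(self):
        # Gamma(4, 1) has mode shape - 1 = 3: increasing before, decreasing after
        grid = np.linspace(0.05, 15, 400)
        vals = np.array([interaction_score("HBond", d) for d in grid])
        peak = grid[np.argmax(vals)]
        assert peak == pytest.approx(3.0, abs=0.05)
        before = vals[grid < 2.95]
        after = vals[grid > 3.05]
        assert np.all(np.diff(before) > 0) and np.all(np.diff(after) < 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            interaction_score("HBond", 0.0)


class TestEvaluatePolar:
    def setup_method(self):
        self.cfg = GenerationConfig(rule="polar")
        # 3-atom ligand: donor amine-like atom at origin, acceptor at x=5
        self.lig = ligand_with_coords(
            "NCC(=O)O", np.array(
                [[0.0, 0, 0], [1.5, 0, 0], [2.9, 0.6, 0], [2.9, 2.0, 0], [5.0, 0, 0]]
            ), lig_id="toy"
        )
        self.assign = manual_assignment(
            [{DONOR}, set(), set(), {ACCEPTOR}, {ACCEPTOR, DONOR}], "polar"
        )

    def test_close_complementary_pair_activates(self):
        prot = SyntheticProtein(coords=np.array([[0.0, 2.8, 0.0]]), types=(HBA,))
        label, records, ind = evaluate_polar(self.lig, self.assign, prot, self.cfg)
        assert label == "active"
        assert len(records) == 1 and records[0].atom_idx == 0
        assert records[0].distance == pytest.approx(2.8)
        np.testing.assert_array_equal(ind, [1, 0, 0, 0, 0])

    def test_far_pair_yields_no_record(self):
        # complementary types but 4.5 A away: no interaction
        prot = SyntheticProtein(coords=np.array([[0.0, 4.5, 0.0]]), types=(HBA,))
        label, records, _ = evaluate_polar(self.lig, self.assign, prot, self.cfg)
        assert label == "inactive" and records == ()

    def test_mismatched_types_ignored(self):
        # donor-only ligand with a donor residue: complementary pairing
        # (HBD residue needs an acceptor atom) yields nothing
        donor_only = manual_assignment(
            [{DONOR}, set(), set(), set(), set()], "polar"
        )
        prot = SyntheticProtein(coords=np.array([[0.0, 2.8, 0.0]]), types=(HBD,))
        label, records, _ = evaluate_polar(self.lig, donor_only, prot, self.cfg)
        assert label == "inactive" and records == ()

    def test_cutoff_is_strict(self):
        prot = SyntheticProtein(coords=np.array([[0.0, 4.0, 0.0]]), types=(HBA,))
        label, records, _ = evaluate_polar(self.lig, self.assign, prot, self.cfg)
        assert label == "inactive"

    def test_empty_protein_inactive(self):
        prot = SyntheticProtein(coords=np.zeros((0, 3)), types=())
        label, records, ind = evaluate_polar(self.lig, self.assign, prot, self.cfg)
        assert label == "inactive" and records == () and not ind.any()

    def test_brute_force_oracle_equivalence(self, polar_oracle_complexes):
        # independent double loop over all (residue, atom) pairs
        for lig, assign, prot, cfg, label, records, ind in polar_oracle_complexes:
            exp_records = set()
            exp_ind = np.zeros(lig.mol.GetNumAtoms())
            from synthscreen.synth_generator import POLAR_PARTNER

            for r in range(prot.n_res):
                for a in range(lig.mol.GetNumAtoms()):
                    d = float(np.linalg.norm(prot.coords[r] - lig.coords()[a]))
                    if POLAR_PARTNER[prot.types[r]] in assign.atom_types[a] and d < cfg.polar_cutoff:
                        exp_records.add((r, a))
                        exp_ind[a] = 1
            assert {(rec.residue_idx, rec.atom_idx) for rec in records} == exp_records
            assert (label == "active") == bool(exp_records)
            np.testing.assert_array_equal(ind, exp_ind)

    def test_monotone_in_residues(self):
        # adding a residue never flips active -> inactive; deleting one never
        # flips inactive -> active
        prot = SyntheticProtein(coords=np.array([[0.0, 2.8, 0.0]]), types=(HBA,))
        label1, _, _ = evaluate_polar(self.lig, self.assign, prot, self.cfg)
        bigger = SyntheticProtein(
            coords=np.vstack([prot.coords, [[9.0, 9.0, 9.0]]]), types=(HBA, HBD)
        )
        label2, _, _ = evaluate_polar(self.lig, self.assign, bigger, self.cfg)
        assert label1 == "active" and label2 == "active"


@pytest.fixture(scope="module")
def polar_oracle_complexes(small_ligands):
    """100 random complexes with their polar-rule outputs, for oracle checks."""
    cfg = GenerationConfig(rule="polar")
    out = []
    for i, lig in enumerate((small_ligands * 3)[:100]):
        assign = assign_pharmacophores(lig, "polar")
        prot = sample_synthetic_protein(lig, assign, cfg, seed=5000 + i)
        label, records, ind = evaluate_polar(lig, assign, prot, cfg)
        out.append((lig, assign, prot, cfg, label, records, ind))
    return out


class TestEvaluateContribution:
    def setup_method(self):
        self.cfg = GenerationConfig(rule="contribution")
        self.lig = ligand_with_coords(
            "NCC(=O)O", np.array(
                [[0.0, 0, 0], [1.5, 0, 0], [2.9, 0.6, 0], [2.9, 2.0, 0], [5.0, 0, 0]]
            ), lig_id="toy"
        )
        self.assign = manual_assignment(
            [{DONOR}, {HYDROPHOBE}, set(), {ACCEPTOR}, set()], "contribution"
        )

    def test_single_hbond_at_mode_is_inactive(self):
        # the maximum single-pair score is 10*f(3) = 2.2404 < threshold 4,
        # so no single interaction can activate a complex
        prot = SyntheticProtein(coords=np.array([[0.0, 0.0, 3.0]]), types=(HBD,))
        label, records, contribs, total = evaluate_contribution(
            self.lig, self.assign, prot, self.cfg
        )
        assert total == pytest.approx(2.2404, abs=1e-4)
        assert label == "inactive"

    def test_two_hbonds_at_mode_activate(self):
        prot = SyntheticProtein(
            coords=np.array([[0.0, 0.0, 3.0], [0.0, 0.0, -3.0]]), types=(HBD, HBD)
        )
        label, _, _, total = evaluate_contribution(self.lig, self.assign, prot, self.cfg)
        assert total == pytest.approx(2 * 2.2404, abs=2e-4)
        assert label == "active"

    def test_mismatched_protein_scores_zero(self):
        # hydrophobic-only protein around the polar atoms: donor/acceptor
        # atoms never match, only the hydrophobe atom contributes
        prot = SyntheticProtein(
            coords=np.array([[0.0, 0.0, 3.0]]), types=(HYDROPHOBIC,)
        )
        _, records, contribs, _ = evaluate_contribution(
            self.lig, self.assign, prot, self.cfg
        )
        assert all(r.atom_idx == 1 for r in records)
        assert contribs[0] == 0 and contribs[3] == 0

    def test_purely_polar_ligand_with_hydrophobic_protein_inactive(self):
        assign = manual_assignment(
            [{DONOR}, set(), set(), {ACCEPTOR}, set()], "contribution"
        )
        prot = SyntheticProtein(
            coords=np.array([[0.0, 0.0, 3.0], [1.0, 1.0, 3.0]]),
            types=(HYDROPHOBIC, HYDROPHOBIC),
        )
        label, records, contribs, total = evaluate_contribution(
            self.lig, assign, prot, self.cfg
        )
        assert total == 0 and label == "inactive" and records == ()

    def test_score_conservation(self, small_ligands):
        cfg = GenerationConfig(rule="contribution")
        for i, lig in enumerate(small_ligands[:20]):
            cmplx = generate_complex(lig, cfg, seed=300 + i)
            rec_total = sum(r.score for r in cmplx.records)
            assert cmplx.total_score == pytest.approx(rec_total, rel=1e-9)
            assert cmplx.total_score == pytest.approx(
                cmplx.atom_contributions.sum(), rel=1e-9
            )


class TestGenerateComplex:
    def test_deterministic(self, small_ligands):
        cfg = GenerationConfig(rule="polar")
        c1 = generate_complex(small_ligands[0], cfg, seed=42)
        c2 = generate_complex(small_ligands[0], cfg, seed=42)
        assert c1.label == c2.label
        np.testing.assert_array_equal(c1.protein.coords, c2.protein.coords)
        np.testing.assert_array_equal(c1.atom_contributions, c2.atom_contributions)

    def test_polar_indicators_only_on_polar_atoms(self, small_ligands):
        cfg = GenerationConfig(rule="polar")
        for i, lig in enumerate(small_ligands[:10]):
            cmplx = generate_complex(lig, cfg, seed=50 + i)
            polar_atoms = {
                j
                for j, t in enumerate(cmplx.assignment.atom_types)
                if t & {ACCEPTOR, DONOR}
            }
            assert set(np.flatnonzero(cmplx.atom_contributions)) <= polar_atoms

    @pytest.mark.parametrize("rule", ["polar", "contribution"])
    def test_label_invariant_under_rigid_motion(self, small_ligands, rule):
        from scipy.spatial.transform import Rotation

        cfg = GenerationConfig(rule=rule)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([7.0, -3.0, 11.0])
        for i, lig in enumerate(small_ligands[:8]):
            cmplx = generate_complex(lig, cfg, seed=800 + i)
            moved_lig = ligand_with_coords(
                lig.source, lig.coords() @ rot.T + shift, lig_id=lig.id
            )
            moved_prot = SyntheticProtein(
                coords=cmplx.protein.coords @ rot.T + shift, types=cmplx.protein.types
            )
            if rule == "polar":
                label, _, ind = evaluate_polar(
                    moved_lig, cmplx.assignment, moved_prot, cfg
                )
                np.testing.assert_array_equal(ind, cmplx.atom_contributions)
            else:
                label, _, contribs, total = evaluate_contribution(
                    moved_lig, cmplx.assignment, moved_prot, cfg
                )
                assert total == pytest.approx(cmplx.total_score, rel=1e-9)
            assert label == cmplx.label


class TestGenerateConditioned:
    def test_returns_matching_label(self, small_ligands):
        cfg = GenerationConfig(rule="polar")
        cmplx = generate_conditioned(
            small_ligands[0], cfg, "active", seed=9, max_attempts=100
        )
        assert cmplx is not None and cmplx.label == "active"

    def test_unattainable_target_discarded(self, small_ligands):
        # an astronomically high score threshold makes "active" impossible
        cfg = GenerationConfig(rule="contribution", score_threshold=1e9)
        out = generate_conditioned(
            small_ligands[0], cfg, "active", seed=9, max_attempts=5
        )
        assert out is None

    def test_seeded_trajectory_reproducible(self, small_ligands):
        cfg = GenerationConfig(rule="polar")
        a = generate_conditioned(small_ligands[1], cfg, "inactive", seed=33)
        b = generate_conditioned(small_ligands[1], cfg, "inactive", seed=33)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.seed == b.seed
            np.testing.assert_array_equal(a.protein.coords, b.protein.coords)

    def test_invalid_args(self, small_ligands):
        cfg = GenerationConfig(rule="polar")
        with pytest.raises(ValueError):
            generate_conditioned(small_ligands[0], cfg, "active", seed=1, max_attempts=0)
        with pytest.raises(ValueError):
            generate_conditioned(small_ligands[0], cfg, "maybe", seed=1)


class TestSerialization:
    def test_round_trip(self, tmp_path, small_ligands):
        cfg = GenerationConfig(rule="contribution")
        cmplx = generate_complex(small_ligands[3], cfg, seed=77)
        paths = write_complex(cmplx, tmp_path / "cx")
        back = read_complex(paths)
        assert back.label == cmplx.label
        assert back.protein.types == cmplx.protein.types
        np.testing.assert_allclose(
            back.protein.coords, cmplx.protein.coords, atol=5e-4
        )
        np.testing.assert_allclose(
            back.atom_contributions, cmplx.atom_contributions, rtol=1e-9
        )
        assert back.total_score == pytest.approx(cmplx.total_score)
        assert back.config == cmplx.config

    def test_hetatm_count(self, tmp_path, small_ligands):
        cfg = GenerationConfig(rule="polar")
        cmplx = generate_complex(small_ligands[4], cfg, seed=78)
        paths = write_complex(cmplx, tmp_path / "cx")
        pdb_lines = open(paths["protein"]).read().splitlines()
        assert sum(1 for l in pdb_lines if l.startswith("HETATM")) == cmplx.protein.n_res

    def test_empty_protein_valid_pdb(self, tmp_path, small_ligands):
        cfg = GenerationConfig(rule="polar")
        cmplx = generate_complex(small_ligands[5], cfg, seed=79)
        empty = SyntheticComplex(
            ligand=cmplx.ligand,
            assignment=cmplx.assignment,
            protein=SyntheticProtein(coords=np.zeros((0, 3)), types=()),
            rule="polar",
            label="inactive",
            atom_contributions=np.zeros_like(cmplx.atom_contributions),
            records=(),
            config=cfg,
            seed=1,
        )
        paths = write_complex(empty, tmp_path / "cx0")
        back = read_complex(paths)
        assert back.protein.n_res == 0 and back.label == "inactive"

    def test_malformed_pdb_raises(self, tmp_path, small_ligands):
        cfg = GenerationConfig(rule="polar")
        cmplx = generate_complex(small_ligands[5], cfg, seed=80)
        paths = write_complex(cmplx, tmp_path / "cx")
        with open(paths["protein"], "a") as fh:
            fh.write("HETATM    9  PS  XXX A   9     bad coords here\n")
        with pytest.raises(ValueError, match="protein.pdb"):
            read_complex(paths)
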