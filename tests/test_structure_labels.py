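"""Structure parsing, surface area, contact numbers and dataset filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acconpred.structure_labels import (
    Atom,
    Chain,
    ChainNotFoundError,
    MAX_ASA_GXG,
    MissingBackboneError,
    Residue,
    StructureError,
    align_dssp_asa,
    compute_asa,
    contact_number,
    dataset_filter,
    discretize_rsa,
    label_chain,
    parse_dssp,
    parse_structure,
    relative_accessibility,
)
from acconpred.synthetic_data import make_helix_chain

from conftest import brute_force_asa, brute_force_contact_numbers, simple_residue


class TestParseStructure:
    def test_minimal_three_residue_chain(self, tri_pdb_text):
        chain = parse_structure(tri_pdb_text, "A")
        assert len(chain) == 3
        assert chain.sequence == "AGS"
        assert [r.seq_index for r in chain.residues] == [1, 2, 3]

    def test_missing_chain_errors(self, tri_pdb_text):
        with pytest.raises(ChainNotFoundError, match="chain not found"):
            parse_structure(tri_pdb_text, "B")

    def test_altloc_keeps_highest_occupancy(self, altloc_pdb_text):
        chain = parse_structure(altloc_pdb_text, "A")
        ca = chain.residues[0].atom("CA")
        assert ca.coord[0] == pytest.approx(1.700)  # occupancy 0.6 conformer

    def test_mse_maps_to_met(self, tri_pdb_text):
        text = tri_pdb_text.replace("ATOM      4  N   GLY", "HETATM    4  N   MSE") \
                           .replace("ATOM      5  CA  GLY", "HETATM    5  CA  MSE") \
                           .replace("ATOM      6  C   GLY", "HETATM    6  C   MSE")
        chain = parse_structure(text, "A")
        assert chain.residues[1].name == "MET"

    def test_missing_backbone_flags_residues(self, tri_pdb_text):
        lines = [ln for ln in tri_pdb_text.splitlines() if " CA  GLY" not in ln]
        with pytest.raises(MissingBackboneError) as exc:
            parse_structure("\n".join(lines), "A")
        assert exc.value.residues[0][0] == 2
        assert "CA" in exc.value.residues[0][2]


class TestComputeAsa:
    def test_single_atom_analytic_sphere(self):
        chain = Chain("A", [Residue("ALA", 1, [Atom("CA", "C", [0.0, 0.0, 0.0])])])
        asa = compute_asa(chain, probe_radius=1.4, n_points=960)
        r = 1.76 + 1.4
        assert asa[0] == pytest.approx(4 * math.pi * r * r, rel=1e-6)

    def test_distant_atoms_fully_exposed(self):
        chain = Chain("A", [
            Residue("ALA", 1, [Atom("CA", "C", [0.0, 0.0, 0.0])]),
            Residue("ALA", 2, [Atom("CA", "C", [100.0, 0.0, 0.0])]),
        ])
        asa = compute_asa(chain, 1.4, 960)
        full = 4 * math.pi * (1.76 + 1.4) ** 2
        assert np.allclose(asa, full, rtol=1e-6)

    def test_near_contact_matches_dense_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.4, 0.0, 0.0], [1.7, 2.6, 0.4]])
        chain = Chain("A", [Residue("ALA", i + 1, [Atom("CA", "C", c)])
                            for i, c in enumerate(coords)])
        got = compute_asa(chain, 1.4, 960)
        want = brute_force_asa(coords, [1.76] * 3, 1.4, n_points=10000)
        assert np.abs(got - want).max() / want.max() < 0.02

    def test_point_count_convergence_on_helix(self):
        chain = make_helix_chain(12)
        coarse = compute_asa(chain, 1.4, 960)
        fine = compute_asa(chain, 1.4, 10000)
        assert np.abs(coarse - fine).max() / fine.max() < 0.02

    def test_asa_bounded_by_full_sphere(self):
        chain = make_helix_chain(15)
        asa = compute_asa(chain, 1.4, 240)
        per_res_atoms = [len(r.atoms) for r in chain.residues]
        bound = np.array(per_res_atoms) * 4 * math.pi * (1.85 + 1.4) ** 2
        assert (asa >= 0).all() and (asa <= bound).all()

    def test_parameter_validation(self):
        chain = make_helix_chain(3)
        with pytest.raises(ValueError):
            compute_asa(chain, probe_radius=-1.0)
        with pytest.raises(ValueError):
            compute_asa(chain, n_points=10)

    def test_unknown_element_warns_and_uses_default(self):
        chain = Chain("A", [Residue("ALA", 1, [Atom("XX", "Q", [0.0, 0.0, 0.0])])])
        with pytest.warns(UserWarning, match="unknown element"):
            asa = compute_asa(chain, 1.4, 240)
        assert asa[0] == pytest.approx(4 * math.pi * (1.80 + 1.4) ** 2, rel=1e-6)


class TestDssp:
    def test_acc_column_extracted(self, dssp_text):
        recs = parse_dssp(dssp_text)
        assert [r["acc"] for r in recs] == [10.0, 20.0, 30.0]

    def test_break_rows_skipped(self, dssp_text):
        assert len(parse_dssp(dssp_text)) == 3  # '!' row dropped

    def test_malformed_header_raises(self):
        with pytest.raises(StructureError, match="RESIDUE"):
            parse_dssp("not a dssp file\nat all\n")

    def test_alignment_against_chain(self, dssp_text):
        chain = Chain("A", [simple_residue(n, i + 1, [3.0 * i, 0, 0])
                            for i, n in enumerate(["ALA", "GLY", "SER"])])
        asa = align_dssp_asa(chain, parse_dssp(dssp_text))
        assert asa.tolist() == [10.0, 20.0, 30.0]

    def test_numbering_mismatch_raises(self, dssp_text):
        chain = Chain("A", [simple_residue("ALA", i + 10, [3.0 * i, 0, 0]) for i in range(3)])
        with pytest.raises(StructureError, match="mismatch"):
            align_dssp_asa(chain, parse_dssp(dssp_text))


class TestRsaAndDiscretize:
    def test_normalization_constants(self):
        rsa = relative_accessibility(np.array([75.0, 105.0, 0.0]), ["GLY", "PHE", "MET"])
        assert rsa.tolist() == [1.0, 0.5, 0.0]

    def test_rsa_above_one_kept_unless_clipped(self):
        rsa = relative_accessibility(np.array([150.0]), ["GLY"])
        assert rsa[0] == pytest.approx(2.0)
        clipped = relative_accessibility(np.array([150.0]), ["GLY"], clip=True)
        assert clipped[0] == 1.0

    def test_unknown_residue_lists_positions(self):
        with pytest.raises(ValueError, match="max-ASA"):
            relative_accessibility(np.array([1.0, 2.0]), ["ALA", "UNK"])

    @pytest.mark.parametrize("rsa,label", [(0.05, "B"), (0.25, "I"), (0.40, "E"),
                                           (0.0, "B"), (0.10, "I"), (1.5, "E")])
    def test_three_state_thresholds(self, rsa, label):
        assert discretize_rsa(np.array([rsa]))[0] == label

    def test_negative_rsa_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            discretize_rsa(np.array([-0.1]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=30))
    def test_labels_recompute_consistently(self, vals):
        rsa = np.array(vals)
        lab = discretize_rsa(rsa)
        again = np.where(rsa < 0.10, "B", np.where(rsa < 0.40, "I", "E"))
        assert (lab == again).all()


class TestContactNumber:
    def test_short_chain_all_excluded(self):
        chain = make_helix_chain(6)
        cn_raw, cn_label = contact_number(chain, seq_exclusion=5)
        assert cn_raw.tolist() == [0] * 6 and cn_label.tolist() == [0] * 6

    def test_cap_applied_to_dense_cluster(self):
        rng = np.random.default_rng(0)
        residues = [simple_residue("ALA", 1, [0.0, 0.0, 0.0])]
        # 5 excluded neighbours far away, then 20 residues with CB near residue 1
        for i in range(2, 7):
            residues.append(simple_residue("ALA", i, [100.0 + 10 * i, 0, 0]))
        cb0 = residues[0].atom("CB").coord
        for i in range(7, 27):
            direction = rng.normal(0.0, 1.0, 3)
            center = cb0 + direction / np.linalg.norm(direction) * rng.uniform(3.0, 5.5)
            res = simple_residue("ALA", i, center - [0.0, -1.0, 1.1])  # CB lands at `center`
            residues.append(res)
        chain = Chain("A", residues)
        cn_raw, cn_label = contact_number(chain)
        n_close = sum(
            1 for j in range(6, 26)
            if np.linalg.norm(chain.residues[j].atom("CB").coord - cb0) < 7.5)
        assert n_close == 20
        assert cn_raw[0] == 20
        assert cn_label[0] == 14

    def test_matches_brute_force_on_helix(self):
        chain = make_helix_chain(40, jitter=0.3, seed=5)
        for excl in (2, 5):
            cn_raw, _ = contact_number(chain, seq_exclusion=excl)
            cb = np.array([r.atom("CB").coord if r.atom("CB") is not None
                           else np.nan * np.ones(3) for r in chain.residues])
            # fill virtual CBs exactly as the implementation does for GLY
            from acconpred.structure_labels import _cbeta_coords
            want = brute_force_contact_numbers(_cbeta_coords(chain), 7.5, excl)
            assert cn_raw.tolist() == want.tolist()

    def test_reversal_symmetry(self):
        chain = make_helix_chain(30, jitter=0.2, seed=9)
        cn, _ = contact_number(chain, seq_exclusion=2)
        rev = Chain("A", [Residue(r.name, i + 1, r.atoms)
                          for i, r in enumerate(reversed(chain.residues))])
        cn_rev, _ = contact_number(rev, seq_exclusion=2)
        assert cn.tolist() == cn_rev[::-1].tolist()

    def test_label_equals_raw_below_cap(self):
        chain = make_helix_chain(25, jitter=0.2, seed=2)
        cn_raw, cn_label = contact_number(chain, seq_exclusion=2)
        assert ((cn_label >= 0) & (cn_label <= 14)).all()
        below = cn_raw <= 14
        assert (cn_label[below] == cn_raw[below]).all()

    def test_single_residue_warns(self):
        chain = make_helix_chain(1)
        with pytest.warns(UserWarning, match="shorter than 2"):
            cn_raw, cn_label = contact_number(chain)
        assert cn_raw.tolist() == [0]


class TestDatasetFilter:
    def _labels(self, chain_id, burial):
        burial = np.array(burial)
        L = len(burial)
        z = np.zeros(L)
        return __import__("acconpred").structure_labels.ResidueLabels(
            chain_id, ["ALA"] * L, z, z, burial, z.astype(int), z.astype(int))

    def test_length_rule(self):
        lab = self._labels("short", ["B"] * 49)
        kept, report = dataset_filter([lab])
        assert not kept and report[0]["verdict"] == "rejected:length"

    def test_buried_ratio_rule(self):
        burial = ["B"] * 3 + ["E"] * 57  # 5% buried
        kept, report = dataset_filter([self._labels("exposed", burial)])
        assert not kept and report[0]["verdict"] == "rejected:buried_ratio"

    def test_retained_chain(self):
        burial = ["B"] * 18 + ["I"] * 21 + ["E"] * 21  # 30% buried, length 60
        kept, report = dataset_filter([self._labels("ok", burial)])
        assert len(kept) == 1 and report[0]["verdict"] == "retained"


def test_label_chain_consistency():
    """Stored burial labels agree with recomputation from rsa and thresholds."""
    chain = make_helix_chain(12)
    labels = label_chain(chain, n_points=240)
    again = discretize_rsa(labels.rsa)
    assert (labels.burial3 == again).all()
    assert (labels.cn_label == np.minimum(labels.cn_raw, 14)).all()
    assert set(labels.burial3) <= {"B", "I", "E"}
    # every residue name has a max-ASA entry consistent with rsa
    expect_rsa = labels.asa / np.array([MAX_ASA_GXG[n] for n in labels.residue_names])
    assert np.allclose(labels.rsa, expect_rsa)
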