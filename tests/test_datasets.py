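"""Coordinate-based contact extraction and the synthetic corpus generator."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribocontact import (
    ContactMap,
    DataError,
    ModelWeights,
    SyntheticConfig,
    contacts_from_coordinates,
    generate_synthetic,
    pdb_to_instances,
)
from ribocontact.datasets import Atom, random_dotbracket, write_corpus
from ribocontact.features import score_terms
from ribocontact.inference import InferenceProblem, check_constraints, predict_ip
from ribocontact.profiles import parse_dotbracket


class TestContactsFromCoordinates:
    def test_boundary_in(self):
        z = contacts_from_coordinates(
            [Atom(1, "CA", (0.0, 0.0, 0.0))], [Atom(1, "P", (0.0, 0.0, 3.9))]
        )
        assert z.contacts == frozenset({(1, 1)})

    def test_boundary_out(self):
        z = contacts_from_coordinates(
            [Atom(1, "CA", (0.0, 0.0, 0.0))], [Atom(1, "P", (0.0, 0.0, 4.1))]
        )
        assert z.contacts == frozenset()

    def test_only_close_residue_contacts(self):
        prot = [Atom(1, "CA", (50.0, 0.0, 0.0)), Atom(2, "CA", (0.0, 0.0, 1.0))]
        rna = [Atom(1, "P", (0.0, 0.0, 0.0))]
        z = contacts_from_coordinates(prot, rna)
        assert z.contacts == frozenset({(2, 1)})

    def test_hydrogens_ignored(self):
        prot = [Atom(1, "CA", (50.0, 0.0, 0.0)), Atom(1, "HB2", (0.0, 0.0, 0.1))]
        rna = [Atom(1, "P", (0.0, 0.0, 0.0))]
        assert contacts_from_coordinates(prot, rna).contacts == frozenset()

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            contacts_from_coordinates([], [Atom(1, "P", (0, 0, 0))])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        prot = [Atom(i + 1, "CA", tuple(rng.uniform(0, 10, 3))) for i in range(4)]
        rna = [Atom(j + 1, "P", tuple(rng.uniform(0, 10, 3))) for j in range(3)]
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-5, 5, 3)

        def move(atoms):
            return [
                Atom(a.index, a.name, tuple(rot @ np.array(a.xyz) + shift))
                for a in atoms
            ]

        assert (
            contacts_from_coordinates(prot, rna).contacts
            == contacts_from_coordinates(move(prot), move(rna)).contacts
        )


class TestRandomSamplers:
    def test_dotbrackets_well_formed_in_range(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            lo = int(rng.integers(5, 25))
            hi = lo + int(rng.integers(0, 20))
            s = random_dotbracket(rng, lo, hi)
            assert lo <= len(s) <= hi
            parse_dotbracket(s)  # raises if ill-formed

    def test_profile_states_all_reachable(self):
        from ribocontact.profiles import rna_profile

        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(200):
            seen |= set(rna_profile(random_dotbracket(rng, 20, 40)))
        assert seen == set("EHIBMS")


class TestGenerateSynthetic:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_pairs=2, protein_length_range=(6, 8),
                              rna_length_range=(9, 14), seed=4)
        a_inst, a_model = generate_synthetic(cfg)
        b_inst, b_model = generate_synthetic(cfg)
        assert a_model == b_model
        for a, b in zip(a_inst, b_inst):
            assert a.protein == b.protein and a.rna == b.rna
            assert a.z_true == b.z_true

    def test_all_negative_weights_give_empty_labels(self, tiny_corpus):
        instances, planted = tiny_corpus
        negative = ModelWeights({k: -1.0 - abs(w) for k, w in planted.weights.items()})
        cfg = SyntheticConfig(n_pairs=3, protein_length_range=(6, 9),
                              rna_length_range=(9, 14), seed=3)
        neg_instances, _ = generate_synthetic(cfg, planted=negative)
        assert all(i.z_true.contacts == frozenset() for i in neg_instances)

    def test_labels_feasible_and_self_consistent(self, tiny_corpus):
        """Every label satisfies the decoding constraints and is
        reproduced by plain decoding under the planted weights."""
        instances, planted = tiny_corpus
        for inst in instances:
            assert check_constraints(inst.z_true, 8, 8)
            terms = score_terms(inst.protein, inst.rna, planted)
            _, obj = predict_ip(InferenceProblem(terms, 8, 8))
            assert terms.objective(inst.z_true) == pytest.approx(obj, abs=1e-9)

    def test_degenerate_sparsity_warns(self):
        cfg = SyntheticConfig(n_pairs=1, protein_length_range=(4, 5),
                              rna_length_range=(9, 10), seed=0,
                              planted_sparsity=1e-9)
        with pytest.warns(UserWarning, match="no planted weights"):
            instances, _ = generate_synthetic(cfg)
        assert instances[0].z_true.contacts == frozenset()

    def test_corpus_round_trips_through_files(self, tmp_path, tiny_corpus):
        from ribocontact.io import (
            read_annotations,
            read_corpus_contacts,
            read_fasta,
            read_model,
        )

        instances, planted = tiny_corpus
        write_corpus(tmp_path, instances, planted)
        proteins = read_fasta(tmp_path / "protein.fasta")
        rnas = read_fasta(tmp_path / "rna.fasta", rna=True)
        ss8 = read_annotations(tmp_path / "ss8.tsv")
        db = read_annotations(tmp_path / "dotbracket.tsv")
        contacts = read_corpus_contacts(tmp_path / "contacts.tsv")
        assert [pid for pid, _ in proteins] == [i.protein.id for i in instances]
        for inst, (pid, pseq), (rid, rseq) in zip(instances, proteins, rnas):
            assert pseq == inst.protein.sequence and rseq == inst.rna.sequence
            assert ss8[pid] == inst.protein.ss8 and db[rid] == inst.rna.dotbracket
            assert contacts.get((pid, rid), set()) == set(inst.z_true.contacts)
        assert read_model(tmp_path / "planted_model.tsv") == planted


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


@pytest.fixture
def synthetic_pdb(tmp_path):
    """A synthetic two-chain complex (not a real PDB entry): two alanines
    on chain A and one uridine on chain B with hand-placed coordinates.
    Residue 2's CB sits 3.9 A from the uridine P; everything else is
    beyond 4.0 A."""
    lines = [
        _pdb_atom(1, "N", "ALA", "A", 1, (20.0, 0.0, 0.0), "N"),
        _pdb_atom(2, "CA", "ALA", "A", 1, (21.0, 0.0, 0.0), "C"),
        _pdb_atom(3, "N", "ALA", "A", 2, (0.0, 0.0, 5.5), "N"),
        _pdb_atom(4, "CB", "ALA", "A", 2, (0.0, 0.0, 3.9), "C"),
        _pdb_atom(5, "H", "ALA", "A", 2, (0.0, 0.0, 0.5), "H"),
        _pdb_atom(6, "P", "U", "B", 1, (0.0, 0.0, 0.0), "P"),
        _pdb_atom(7, "O2'", "U", "B", 1, (0.0, 4.2, 0.0), "O"),
        "END",
    ]
    path = tmp_path / "synthetic_complex.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestPdbToInstances:
    def test_contacts_match_hand_computation(self, synthetic_pdb):
        skel = pdb_to_instances(synthetic_pdb, "A", "B")
        assert skel.protein_sequence == "AA"
        assert skel.rna_sequence == "U"
        assert skel.contact_map == ContactMap(2, 1, frozenset({(2, 1)}))

    def test_missing_chain(self, synthetic_pdb):
        with pytest.raises(DataError, match="chain 'C'"):
            pdb_to_instances(synthetic_pdb, "A", "C")

    def test_all_hydrogen_chain_rejected(self, tmp_path):
        lines = [
            _pdb_atom(1, "H1", "ALA", "A", 1, (0.0, 0.0, 0.0), "H"),
            _pdb_atom(2, "P", "U", "B", 1, (0.0, 0.0, 3.0), "P"),
            "END",
        ]
        path = tmp_path / "h_only.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError):
            pdb_to_instances(path, "A", "B")
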