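import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probeal import descriptors as de
from probeal.dataset_prep import ACTIVE, INACTIVE, AnnotationTable

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestIdentityBlock:
    def test_unit_vector(self):
        assert de.identity_block(0, 3).values.tolist() == [1, 0, 0]
        assert de.identity_block(2, 3).values.tolist() == [0, 0, 1]

    def test_stack_is_identity_matrix(self):
        stacked = np.vstack([de.identity_block(i, 9).values for i in range(9)])
        assert np.array_equal(stacked, np.eye(9))

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            de.identity_block(3, 3)


class TestKmerBlock:
    def test_mkslp_2mers(self):
        b = de.kmer_block("MKSLP", 2)
        assert b.vocabulary == ("KS", "LP", "MK", "SL")
        assert b.values.tolist() == [1, 1, 1, 1]
        assert b.values.sum() == 4

    def test_mkslp_3mers(self):
        b = de.kmer_block("MKSLP", 3)
        assert set(b.vocabulary) == {"MKS", "KSL", "SLP"}
        assert all(v == 1 for v in b.values)

    def test_single_letter_repeat(self):
        b = de.kmer_block("AAAA", 1)
        assert b.vocabulary == ("A",) and b.values.tolist() == [4]

    def test_sequence_shorter_than_k_errors(self):
        with pytest.raises(ValueError, match="length"):
            de.kmer_block("MK", 3)

    def test_explicit_vocabulary_gives_zeros(self):
        b = de.kmer_block("MKSLP", 2, vocabulary=("AA", "MK", "ZZ"))
        assert b.values.tolist() == [0, 1, 0]

    def test_nonstandard_residues_dropped(self):
        b = de.kmer_block("MKXLP", 2)
        assert "KX" not in b.vocabulary and "XL" not in b.vocabulary
        assert b.values.sum() == 2  # MK, LP

    @given(
        st.text(alphabet=AA, min_size=4, max_size=60),
        st.integers(min_value=1, max_value=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_counts_sum_to_window_count(self, seq, k):
        b = de.kmer_block(seq, k)
        assert b.values.sum() == len(seq) - k + 1

    def test_vocabulary_union_and_order(self):
        vocab = de.build_kmer_vocabulary(["MKS", "KSL"], 2)
        assert vocab == ("KS", "MK", "SL")


class TestCatsBlock:
    def test_length_150(self):
        assert len(de.cats_block("CCO").values) == 150
        assert len(de.CATS_FEATURE_NAMES) == 15 * 10

    def test_single_atom_all_zero(self):
        assert de.cats_block("C").values.sum() == 0

    def test_ethanediol_hand_enumeration(self):
        # OCCO: both oxygens donor+acceptor, topological distance 3; the two
        # carbons have polar neighbours so are not lipophilic.  The ordered
        # type combinations of the one atom pair give D-D:3 once, A-A:3 once
        # and D-A:3 twice.
        b = de.cats_block("OCCO")
        nz = {n: v for n, v in zip(b.feature_names, b.values) if v}
        assert nz == {"cats:D-D:3": 1, "cats:D-A:3": 2, "cats:A-A:3": 1}

    def test_atom_order_invariance(self):
        a = de.cats_block("OCCO").values
        b = de.cats_block("C(O)CO").values
        assert np.array_equal(a, b)

    def test_aromatic_carbons_lipophilic(self):
        b = de.cats_block("c1ccccc1")
        nz = {n for n, v in zip(b.feature_names, b.values) if v}
        assert nz == {"cats:L-L:1", "cats:L-L:2", "cats:L-L:3"}

    def test_unparseable_smiles_names_compound(self):
        with pytest.raises(ValueError, match="widget"):
            de.cats_block("not_a_smiles", compound_id="widget")

    def test_counts_are_nonnegative_integers(self):
        v = de.cats_block("NC(=O)c1ccccc1O").values
        assert (v >= 0).all() and np.array_equal(v, v.round())


class TestFingerprintBlock:
    def test_deterministic(self):
        a = de.fingerprint_block("c1ccccc1CCO", 1024)
        b = de.fingerprint_block("c1ccccc1CCO", 1024)
        assert np.array_equal(a.values, b.values)

    def test_binary_values(self):
        v = de.fingerprint_block("c1ccccc1CCO", 512).values
        assert set(np.unique(v)) <= {0.0, 1.0}

    def test_folding_popcount_monotone(self):
        p512 = de.fingerprint_block("c1ccccc1CC(N)C(=O)O", 512).values.sum()
        p1024 = de.fingerprint_block("c1ccccc1CC(N)C(=O)O", 1024).values.sum()
        assert p512 <= p1024

    def test_popcount_bounded_by_environment_count(self):
        # oracle: count distinct unfolded environments up to radius 2
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        smiles = "CCOC(=O)C"
        mol = Chem.MolFromSmiles(smiles)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
        n_env = len(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
        for bits in (512, 1024, 4096):
            assert de.fingerprint_block(smiles, bits).values.sum() <= n_env

    def test_invalid_width(self):
        with pytest.raises(ValueError, match="n_bits"):
            de.fingerprint_block("CC", 256)


class TestPchemBlock:
    def test_length_matches_documented_blocks(self):
        assert sum(de.PCHEM_BLOCK_SIZES) - len(de.PCHEM_EXCLUDED) == 96
        assert len(de.pchem_block("CCO").values) == 96

    def test_methane_molecular_weight(self):
        b = de.pchem_block("C")
        mw = dict(zip(b.feature_names, b.values))["pchem:mol_weight"]
        assert mw == pytest.approx(16.04, abs=0.01)

    def test_benzene_aromatic_ring_count(self):
        b = de.pchem_block("c1ccccc1")
        vals = dict(zip(b.feature_names, b.values))
        assert vals["pchem:n_aromatic_rings"] == 1
        assert vals["pchem:ring_count"] == 1

    def test_unparseable_errors(self):
        with pytest.raises(ValueError, match="unparseable"):
            de.pchem_block("](")

    def test_all_finite(self):
        assert np.isfinite(de.pchem_block("O=C(O)c1ccccc1OC(C)=O").values).all()


class TestAssemblePairs:
    def toy(self):
        table = AnnotationTable.from_records(
            [
                ("c1", "T1", ACTIVE),
                ("c1", "T2", INACTIVE),
                ("c2", "T1", INACTIVE),
                ("c2", "T2", ACTIVE),
                ("c3", "T1", ACTIVE),
                ("c3", "T2", INACTIVE),
            ]
        )
        lig = de.raw_ligand_blocks(
            {"c1": [1.0, 2.0], "c2": [3.0, 4.0], "c3": [5.0, 6.0]}
        )
        tgt = {
            "T1": de.identity_block(0, 2, "T1"),
            "T2": de.identity_block(1, 2, "T2"),
        }
        return table, lig, tgt

    def test_hand_verified_design_matrix(self):
        table, lig, tgt = self.toy()
        pairs = de.assemble_pairs(table, lig, tgt)
        X, y, boundary = de.design_matrix(pairs)
        assert X.shape == (6, 4) and boundary == 2
        assert X[0].tolist() == [1.0, 2.0, 1.0, 0.0]  # c1 ligand then T1 one-hot
        assert X[3].tolist() == [3.0, 4.0, 0.0, 1.0]
        assert y.tolist() == [1, 0, 0, 1, 1, 0]

    def test_empty_table_gives_empty_list(self):
        import pandas as pd

        table = AnnotationTable(pd.DataFrame(columns=list(AnnotationTable.COLUMNS)))
        _, lig, tgt = self.toy()
        assert de.assemble_pairs(table, lig, tgt) == []

    def test_missing_descriptors_listed(self):
        table, lig, tgt = self.toy()
        del lig["c2"]
        with pytest.raises(ValueError, match="c2"):
            de.assemble_pairs(table, lig, tgt)

    def test_feature_names_align(self):
        table, lig, tgt = self.toy()
        pairs = de.assemble_pairs(table, lig, tgt)
        names = de.feature_names(pairs, lig, tgt)
        assert len(names) == 4
        assert names[2].startswith("target:")


class TestSchemes:
    def test_combined_scheme_concatenates(self):
        blocks = de.compute_ligand_blocks({"c": "CCO"}, "combined")
        assert len(blocks["c"].values) == 96 + 1024

    def test_target_scheme_k_mapping(self, small_dataset):
        blocks = de.compute_target_blocks(small_dataset.sequences, "tripeptide")
        lengths = {len(b.values) for b in blocks.values()}
        assert len(lengths) == 1  # shared run-wide vocabulary

    def test_unknown_schemes_error(self):
        with pytest.raises(ValueError):
            de.compute_ligand_blocks({"c": "CCO"}, "nope")
        with pytest.raises(ValueError):
            de.compute_target_blocks({"T": "MKSLP"}, "pentapeptide")


def test_write_descriptor_matrix(tmp_path):
    blocks = de.compute_ligand_blocks({"c1": "CCO", "c2": "c1ccccc1"}, "cats")
    path = tmp_path / "cats.tsv"
    de.write_descriptor_matrix(blocks, path)
    header = path.read_text().splitlines()[0].split("\t")
    assert header[0] == "id" and header[1:] == list(de.CATS_FEATURE_NAMES)

    tgt = de.compute_target_blocks({"T1": "MKSLP", "T2": "MKSAA"}, "dipeptide")
    tpath = tmp_path / "dipep.tsv"
    de.write_descriptor_matrix(tgt, tpath)
    assert tpath.read_text().startswith("id\ttarget:")
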