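import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecipred import (
    DescriptorSpec,
    DescriptorTable,
    aac_descriptor,
    build_chemical_table,
    build_sequence_table,
    composition50_descriptor,
    concat_pair_features,
    gaac_descriptor,
    gdpc_descriptor,
    permute_table,
    shuffle_sequences,
)
from ecipred.dataset_io import AA_ALPHABET
from ecipred.exceptions import DomainError, LookupError_, ValidationError

sequences = st.text(alphabet=AA_ALPHABET, min_size=2, max_size=60)


class TestCompositionDescriptors:
    def test_aac_single_letter(self):
        v = aac_descriptor("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_aac_uniform(self):
        v = aac_descriptor("ACDE")
        np.testing.assert_allclose(v[:4], 0.25)

    def test_aac_ignores_x(self):
        np.testing.assert_allclose(aac_descriptor("AAXX"), aac_descriptor("AA"))

    def test_aac_all_x_degenerate(self):
        with pytest.raises(DomainError):
            aac_descriptor("XXX")

    @pytest.mark.parametrize(
        "seq,group_index,value",
        [("GAVLMI", 0, 1.0), ("DE", 3, 1.0), ("KD", 2, 0.5)],
    )
    def test_gaac_groups(self, seq, group_index, value):
        assert gaac_descriptor(seq)[group_index] == pytest.approx(value)

    def test_gdpc_single_dipeptide(self):
        v = gdpc_descriptor("DE").reshape(5, 5)
        assert v[3, 3] == 1.0  # (negative, negative)

    def test_gdpc_kdkd(self):
        v = gdpc_descriptor("KDKD").reshape(5, 5)
        assert v[2, 3] == pytest.approx(2 / 3)  # (positive, negative)
        assert v[3, 2] == pytest.approx(1 / 3)  # (negative, positive)

    def test_gdpc_needs_two_residues(self):
        with pytest.raises(DomainError):
            gdpc_descriptor("A")

    @given(sequences)
    @settings(max_examples=30, deadline=None)
    def test_compositions_are_distributions(self, seq):
        for v in (aac_descriptor(seq), gaac_descriptor(seq), gdpc_descriptor(seq)):
            assert v.sum() == pytest.approx(1.0, abs=1e-12)
            assert (v >= 0).all()

    def test_composition50_concatenation(self):
        seq = "MKTAYIAKQR"
        v = composition50_descriptor(seq)
        assert v.shape == (50,)
        np.testing.assert_allclose(v[:20], aac_descriptor(seq))
        np.testing.assert_allclose(v[20:25], gaac_descriptor(seq))
        np.testing.assert_allclose(v[25:], gdpc_descriptor(seq))


class TestTables:
    def test_sequence_table_shape_and_determinism(self):
        ids = ("a", "b", "c")
        seqs = ("MKTAYIAKQR", "MKTAYIAKQR", "GGSSGGSSGG")
        t = build_sequence_table(ids, seqs, DescriptorSpec("composition50"))
        assert t.vectors.shape == (3, 50)
        np.testing.assert_array_equal(t.vectors[0], t.vectors[1])

    def test_external_alignment_and_missing_id(self, tmp_path):
        frame = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["b", "a"], columns=["d0", "d1"]
        )
        t = build_sequence_table(("a", "b"), ("ACD", "ACE"), DescriptorSpec("external", {"table": frame}))
        np.testing.assert_array_equal(t.vectors, [[3.0, 4.0], [1.0, 2.0]])
        with pytest.raises(LookupError_):
            build_sequence_table(("a", "z"), ("ACD", "ACE"), DescriptorSpec("external", {"table": frame}))

    def test_fingerprint_table_is_binary_2048(self):
        t = build_chemical_table(("c1", "c2"), ("CCO", "CCO"), DescriptorSpec("chem_fingerprint"))
        assert t.vectors.shape == (2, 2048)
        assert set(np.unique(t.vectors)) <= {0.0, 1.0}
        np.testing.assert_array_equal(t.vectors[0], t.vectors[1])

    def test_physchem_methane(self):
        t = build_chemical_table(("c",), ("C",), DescriptorSpec("chem_physchem"))
        # heavy atoms (last column) and donors (third)
        assert t.vectors[0, -1] == 1.0
        assert t.vectors[0, 2] == 0.0

    def test_parse_failure_names_chemical(self):
        with pytest.raises(DomainError, match="badchem"):
            build_chemical_table(("badchem",), ("xyz##",), DescriptorSpec("chem_fingerprint"))

    def test_randomized_table_requires_seed(self):
        with pytest.raises(ValidationError):
            DescriptorTable(("a",), np.zeros((1, 2)), "x", provenance="permuted")


class TestRandomizationStrategies:
    def test_shuffle_preserves_composition(self):
        seqs = ["MKTAYIAKQRMKTAYIAKQR", "GGSSAAGGSSPPLL"]
        shuffled = shuffle_sequences(seqs, seed=0)
        for orig, shuf in zip(seqs, shuffled):
            assert len(orig) == len(shuf)
            assert sorted(orig) == sorted(shuf)
            np.testing.assert_allclose(aac_descriptor(orig), aac_descriptor(shuf))
            np.testing.assert_allclose(gaac_descriptor(orig), gaac_descriptor(shuf))

    def test_shuffle_deterministic_and_seed_sensitive(self):
        seqs = ["MKTAYIAKQRMKTAYIAKQR"]
        assert shuffle_sequences(seqs, 3) == shuffle_sequences(seqs, 3)
        assert shuffle_sequences(seqs, 3) != shuffle_sequences(seqs, 4)

    def test_shuffle_breaks_gdpc_on_long_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA_ALPHABET), size=300))
        shuf = shuffle_sequences([seq], seed=1)[0]
        assert not np.allclose(gdpc_descriptor(seq), gdpc_descriptor(shuf))

    def test_permute_preserves_row_multiset(self):
        t = DescriptorTable(("a", "b", "c", "d"), np.arange(8.0).reshape(4, 2), "x")
        p = permute_table(t, seed=5)
        assert p.provenance == "permuted" and p.seed == 5
        assert sorted(map(tuple, p.vectors)) == sorted(map(tuple, t.vectors))
        assert p.object_ids == t.object_ids

    def test_permute_deterministic_and_invertible(self):
        t = DescriptorTable(tuple("abcdef"), np.arange(12.0).reshape(6, 2), "x")
        p1 = permute_table(t, seed=9)
        p2 = permute_table(t, seed=9)
        np.testing.assert_array_equal(p1.vectors, p2.vectors)
        perm = np.random.default_rng(9).permutation(6)
        inv = np.argsort(perm)
        np.testing.assert_array_equal(p1.vectors[inv], t.vectors)

    def test_permute_singleton_identity(self):
        t = DescriptorTable(("a",), np.array([[1.0, 2.0]]), "x")
        np.testing.assert_array_equal(permute_table(t, 0).vectors, t.vectors)


class TestPairFeatures:
    def test_concat_shapes_and_blocks(self):
        etab = DescriptorTable(("e1", "e2"), np.array([[1.0, 2.0], [3.0, 4.0]]), "e")
        ctab = DescriptorTable(("c1",), np.array([[9.0]]), "c")
        X = concat_pair_features(etab, ctab, [("e1", "c1"), ("e2", "c1")])
        np.testing.assert_array_equal(X, [[1, 2, 9], [3, 4, 9]])

    def test_empty_pairs_well_formed(self):
        etab = DescriptorTable(("e1",), np.ones((1, 3)), "e")
        ctab = DescriptorTable(("c1",), np.ones((1, 2)), "c")
        assert concat_pair_features(etab, ctab, []).shape == (0, 5)

    def test_unknown_id_lookup_error(self):
        etab = DescriptorTable(("e1",), np.ones((1, 3)), "e")
        ctab = DescriptorTable(("c1",), np.ones((1, 2)), "c")
        with pytest.raises(LookupError_):
            concat_pair_features(etab, ctab, [("eX", "c1")])
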