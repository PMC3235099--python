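"""Bin scheme, pair enumeration, accumulation, shuffled reference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldcube as fc
from foldcube.tensorize import (
    FoldTensor,
    IndexStore,
    PairIndexError,
    accumulate,
    build_observed,
    build_reference_tensor,
    decode_pair_index,
    default_bin_scheme,
    encode_pair_index,
    enumerate_pairs,
    functional_atom_distance,
    load_index,
    load_tensor,
    save_index,
    save_tensor,
    shuffle_chain,
)

from .conftest import naive_pairs, observations_as_set


class TestBinScheme:
    def test_shape_and_total_cells(self, scheme):
        assert scheme.shape == (20, 20, 12, 14, 4, 4, 12, 6)
        assert scheme.total_cells == 20 * 20 * 12 * 14 * 4 * 4 * 12 * 6
        assert scheme.total_cells == 77_414_400

    def test_printed_label_examples(self, scheme):
        assert scheme.sa_labels[scheme.sa_bin(35)] == "30<SA<=40"
        assert scheme.d_labels[scheme.d_bin(2.25)] == "1.75<D<=2.25"
        assert scheme.sa_labels[0] == "SA<=0"
        assert scheme.sa_labels[-1] == "SA>100"
        assert scheme.cl_labels[-1] == "CL>1000"
        assert scheme.sd_labels == ("0", "1", "2", "3", "4", ">4")

    @pytest.mark.parametrize("edge_idx,edge", [
        (i, e) for i, e in enumerate(
            [float(v) for v in range(0, 101, 10)])])
    def test_sa_edges_right_closed(self, scheme, edge_idx, edge):
        assert scheme.sa_bin(edge) == edge_idx
        assert scheme.sa_bin(edge + 1e-9) == edge_idx + 1

    @pytest.mark.parametrize("edge_idx,edge", [
        (i, round(1.75 + 0.5 * i, 2)) for i in range(14)])
    def test_d_edges_right_closed(self, scheme, edge_idx, edge):
        assert scheme.d_bin(edge) == edge_idx
        if edge < 8.25:
            assert scheme.d_bin(edge + 1e-9) == edge_idx + 1

    @pytest.mark.parametrize("edge_idx,edge", [
        (i, v) for i, v in enumerate(range(0, 1001, 100))])
    def test_cl_edges_right_closed(self, scheme, edge_idx, edge):
        assert scheme.cl_bin(edge) == edge_idx
        assert scheme.cl_bin(edge + 1) == edge_idx + 1 if edge < 1000 \
            else scheme.cl_bin(edge + 1) == 11

    def test_sd_bins(self, scheme):
        assert [scheme.sd_bin(k) for k in (0, 1, 2, 3, 4, 5, 400)] == [
            0, 1, 2, 3, 4, 5, 5]

    def test_aa_and_ss_bins_cover_all_labels(self, scheme):
        assert [scheme.aa_bin(aa) for aa in fc.AMINO_ACIDS] == list(range(20))
        assert [scheme.ss_bin(ss) for ss in fc.SS_CLASSES] == list(range(4))

    def test_distance_beyond_cutoff_rejected(self, scheme):
        with pytest.raises(ValueError):
            scheme.d_bin(8.26)


class TestFunctionalAtomDistance:
    def test_single_atom_pair(self):
        chain = fc.build_chain(fc.make_motif_chain("disulphide", seed=0))
        cys = [r for r in chain.residues if r.aa_type == "CYS"]
        d = functional_atom_distance(*cys)
        assert d == pytest.approx(np.linalg.norm(
            cys[0].functional_coords[0] - cys[1].functional_coords[0]))

    def test_minimum_over_combinations(self):
        r1 = fc.ResidueRecord("0TST", "A", 1, 1, "ARG",
                              functional_coords=np.array([[0, 0, 0], [2, 0, 0]]))
        r2 = fc.ResidueRecord("0TST", "A", 2, 2, "ASP",
                              functional_coords=np.array([[0, 3, 0], [5, 0, 0]]))
        # brute-force distances: 3.0, 5.0, sqrt(13), 3.0 -> min 3.0
        assert functional_atom_distance(r1, r2) == pytest.approx(3.0)

    def test_identical_coordinates(self):
        r = fc.ResidueRecord("0TST", "A", 1, 1, "CYS",
                             functional_coords=np.array([[1.0, 2.0, 3.0]]))
        assert functional_atom_distance(r, r) == 0.0

    def test_missing_functional_atoms_error(self):
        r = fc.ResidueRecord("0TST", "A", 1, 1, "CYS")
        with pytest.raises(ValueError):
            functional_atom_distance(r, r)


class TestEnumeratePairs:
    def test_toy_three_residue_chain(self, scheme):
        """Only the close same-shell Cys-Cys pair qualifies."""
        spec = fc.ToySpec(pdb_id="0TOY", residues=[
            fc.fixtures.ResidueSpec("CYS", "A", 1, "coil", 5.0,
                                    {"SG": (0.0, 0.0, 0.0)}),
            fc.fixtures.ResidueSpec("CYS", "A", 2, "coil", 5.0,
                                    {"SG": (2.0, 0.0, 0.0)}),
            fc.fixtures.ResidueSpec("LYS", "A", 3, "coil", 5.0,
                                    {"NZ": (20.0, 0.0, 0.0)}),
        ])
        obs = enumerate_pairs(fc.build_chain(spec), scheme)
        assert len(obs) == 1
        assert scheme.d_labels[obs[0].coords[3]] == "1.75<D<=2.25"
        assert observations_as_set(obs) == naive_pairs(fc.build_chain(spec))

    def test_same_distance_different_shell_is_no_pair(self, scheme):
        spec = fc.ToySpec(pdb_id="0TOY", residues=[
            fc.fixtures.ResidueSpec("CYS", "A", 1, "coil", 5.0,
                                    {"SG": (0.0, 0.0, 0.0)}),
            fc.fixtures.ResidueSpec("CYS", "A", 2, "coil", 15.0,
                                    {"SG": (2.8, 0.0, 0.0)}),
        ])
        assert enumerate_pairs(fc.build_chain(spec), scheme) == []

    @pytest.mark.parametrize("i,j,label", [(7, 11, "4"), (7, 12, ">4")])
    def test_sequence_distance_bins(self, scheme, i, j, label):
        chain = fc.build_chain(fc.random_chain(15, seed=4))
        for res in chain.residues:
            res.rel_sa = 5.0
            res.functional_coords = np.array(
                [[100.0 + 10.0 * res.seq_index, 0, 0]])
        for res in chain.residues:
            if res.seq_index in (i, j):
                res.functional_coords = np.array(
                    [[3.0 if res.seq_index == i else 0.0, 0.0, 0.0]])
        obs = enumerate_pairs(chain, scheme)
        close = [ob for ob in obs if ob.raw_distance == pytest.approx(3.0)]
        assert len(close) == 1
        assert scheme.sd_labels[close[0].coords[7]] == label

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 50))
    def test_oracle_equivalence_random_chains(self, scheme, seed, n):
        chain = fc.build_chain(fc.random_chain(n, seed=seed))
        assert observations_as_set(enumerate_pairs(chain, scheme)) == \
            naive_pairs(chain)


class TestAccumulateAndIndex:
    def test_single_observation(self, scheme, disulphide_chain):
        obs = enumerate_pairs(disulphide_chain, scheme)
        tensor = FoldTensor(shape=scheme.shape)
        index = IndexStore()
        accumulate(obs, tensor, index)
        assert tensor.total() == len(obs) == 1
        assert tensor.value(obs[0].coords) == 1

    def test_same_cell_twice_appends_two_strings(self, scheme):
        tensor = FoldTensor(shape=scheme.shape)
        index = IndexStore()
        ob = fc.PairObservation((0,) * 8, 1.0, ((1, "A"), (2, "A")), "0TOY")
        accumulate([ob, ob], tensor, index)
        assert tensor.value((0,) * 8) == 2
        assert len(index.cells[(0,) * 8]) == 2

    def test_empty_observations_noop(self, scheme):
        tensor = FoldTensor(shape=scheme.shape)
        accumulate([], tensor, None)
        assert tensor.total() == 0 and tensor.n_filled == 0

    def test_out_of_range_cell_is_internal_error(self, scheme):
        tensor = FoldTensor(shape=scheme.shape)
        with pytest.raises(IndexError):
            tensor.add((99,) + (0,) * 7)


class TestPairIndexStrings:
    def test_worked_example(self):
        assert encode_pair_index("1ABC", (102, "A"), (1030, "B")) == \
            "1ABC0102A1030B"
        assert decode_pair_index("1ABC0102A1030B") == \
            ("1ABC", (102, "A"), (1030, "B"))

    @settings(deadline=None, max_examples=50)
    @given(n1=st.integers(0, 9999), n2=st.integers(0, 9999),
           c1=st.sampled_from("ABZ9"), c2=st.sampled_from("ABZ9"))
    def test_roundtrip_property(self, n1, n2, c1, c2):
        s = encode_pair_index("1XYZ", (n1, c1), (n2, c2))
        assert len(s) == 14
        assert decode_pair_index(s) == ("1XYZ", (n1, c1), (n2, c2))

    @pytest.mark.parametrize("bad", [
        lambda: encode_pair_index("1ABC", (10000, "A"), (1, "B")),
        lambda: encode_pair_index("1ABC", (1, ""), (1, "B")),
        lambda: encode_pair_index("TOOLONG", (1, "A"), (1, "B")),
        lambda: decode_pair_index("1ABC0102A1030"),
        lambda: decode_pair_index("1ABC01x2A1030B"),
    ])
    def test_contract_violations(self, bad):
        with pytest.raises(PairIndexError):
            bad()


class TestShuffleAndReference:
    def test_composition_preserved(self):
        chain = fc.build_chain(fc.random_chain(30, seed=7))
        shuffled = shuffle_chain(chain, np.random.default_rng(0))
        assert sorted(r.aa_type for r in shuffled.residues) == \
            sorted(r.aa_type for r in chain.residues)
        # geometry and annotation stay with the position
        for a, b in zip(chain.residues, shuffled.residues):
            np.testing.assert_array_equal(a.functional_coords,
                                          b.functional_coords)
            assert a.ss_class == b.ss_class and a.rel_sa == b.rel_sa

    def test_uniform_type_chain_is_fixed_point(self, scheme):
        chain = fc.build_chain(fc.random_chain(10, seed=8))
        for res in chain.residues:
            res.aa_type = "ALA"
            res.functional_coords = res.functional_coords[:1]
        shuffled = shuffle_chain(chain, np.random.default_rng(1))
        assert [r.aa_type for r in shuffled.residues] == ["ALA"] * 10
        ref = build_reference_tensor([chain], scheme, n_shuffles=1, seed=0)
        obs, _ = build_observed([chain], scheme)
        assert dict(ref.items()) == dict(obs.items())

    def test_seeded_shuffle_reproducible(self):
        chain = fc.build_chain(fc.random_chain(20, seed=9))
        s1 = shuffle_chain(chain, np.random.default_rng(42))
        s2 = shuffle_chain(chain, np.random.default_rng(42))
        assert [r.aa_type for r in s1.residues] == \
            [r.aa_type for r in s2.residues]

    def test_reference_total_equals_observed_total(self, scheme, random_chains):
        obs, _ = build_observed(random_chains, scheme)
        ref = build_reference_tensor(random_chains, scheme, n_shuffles=3,
                                     seed=5)
        assert ref.total() == pytest.approx(obs.total())

    def test_non_aa_marginals_match_observed(self, scheme, random_chains):
        """Summing out the residue-type dimensions, shuffling is invisible:
        each remaining 6D cell keeps its exact count."""
        obs, _ = build_observed(random_chains, scheme)
        ref = build_reference_tensor(random_chains, scheme, n_shuffles=2,
                                     seed=6)

        def marginal(t):
            out = {}
            for c, v in t.items():
                out[c[2:]] = out.get(c[2:], 0) + v
            return out

        m_obs, m_ref = marginal(obs), marginal(ref)
        assert set(m_obs) == set(m_ref)
        for key in m_obs:
            assert m_ref[key] == pytest.approx(m_obs[key])

    def test_reference_order_independent(self, scheme, random_chains):
        ref_a = build_reference_tensor(random_chains, scheme, 2, seed=3)
        ref_b = build_reference_tensor(list(reversed(random_chains)),
                                       scheme, 2, seed=3)
        assert ref_a.counts == ref_b.counts

    def test_bad_shuffle_count(self, scheme):
        with pytest.raises(ValueError):
            build_reference_tensor([], scheme, n_shuffles=0)


class TestPersistence:
    def test_tensor_roundtrip(self, scheme, random_chains, tmp_path):
        obs, index = build_observed(random_chains[:5], scheme)
        ref = build_reference_tensor(random_chains[:5], scheme, 3, seed=2)
        for tensor, name in ((obs, "obs.tsv"), (ref, "ref.tsv")):
            save_tensor(tensor, tmp_path / name)
            back = load_tensor(tmp_path / name)
            assert back.kind == tensor.kind
            assert back.divisor == tensor.divisor
            assert back.shape == tensor.shape
            assert back.counts == tensor.counts
            assert back.scheme_fingerprint == scheme.fingerprint
        save_index(index, tmp_path / "idx.tsv")
        back_idx = load_index(tmp_path / "idx.tsv")
        assert {k: sorted(v) for k, v in back_idx.cells.items()} == \
            {k: sorted(v) for k, v in index.cells.items()}
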