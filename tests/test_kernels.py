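import numpy as np
import pytest

from lpifkl.data_io import (
    ExpressionProfile,
    GOAnnotation,
    InteractionMatrix,
    MoleculeRegistry,
    PSSMProfile,
    SequenceRecord,
)
from lpifkl.kernels import (
    AlignmentScoring,
    FeatureVector,
    GIPParams,
    KernelMatrix,
    annotation_vectors_share_terms,
    cosine_normalize,
    ct_features,
    embed_in_registry,
    expression_kernel,
    gip_kernel,
    go_kernel,
    psd_repair,
    psepssm_features,
    rbf_kernel,
    sw_kernel,
    sw_scores,
)
from oracles import sw_score_oracle


def random_rna(rng, length):
    return "".join("ACGU"[i] for i in rng.integers(4, size=length))


def random_protein(rng, length):
    return "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(20, size=length))


class TestGIP:
    def test_orthogonal_profiles_give_exp_minus_two(self):
        K = gip_kernel(np.array([[1.0, 0.0], [0.0, 1.0]]), "lnc")
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)
        assert np.allclose(np.diag(K.values), 1.0)

    def test_identical_profiles_give_one(self):
        K = gip_kernel(np.array([[1.0, 0.0], [1.0, 0.0]]), "lnc")
        assert K.values[0, 1] == 1.0

    def test_protein_space_uses_columns(self):
        F = np.array([[1.0, 0.0], [1.0, 0.0]])
        K = gip_kernel(F, "pro")
        # columns differ by (1,1) -> squared distance 2
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_masked_entries_never_leak(self):
        reg = MoleculeRegistry(("l1", "l2", "l3"), ("p1", "p2"))
        base = np.array([[1.0, 0], [0, 1], [1, 1]])
        mask = frozenset({(0, 1), (2, 0)})
        a = InteractionMatrix(base.copy(), reg, mask)
        flipped = base.copy()
        flipped[0, 1] = 1 - flipped[0, 1]
        flipped[2, 0] = 1 - flipped[2, 0]
        b = InteractionMatrix(flipped, reg, mask)
        for space in ("lnc", "pro"):
            assert np.array_equal(
                gip_kernel(a, space).values, gip_kernel(b, space).values
            )

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            GIPParams(sigma_lnc=0.0)


class TestSmithWaterman:
    def test_self_similarity_is_one_and_symmetric(self, rng):
        recs = [SequenceRecord(f"l{i}", random_rna(rng, int(l)))
                for i, l in enumerate(rng.integers(10, 30, size=6))]
        K = sw_kernel(recs, AlignmentScoring("rna"))
        assert np.allclose(np.diag(K.values), 1.0)
        assert np.array_equal(K.values, K.values.T)
        assert (K.values <= 1.0 + 1e-12).all()

    @pytest.mark.parametrize("alphabet", ["rna", "protein"])
    def test_matches_dp_oracle_exactly(self, rng, alphabet):
        scoring = AlignmentScoring(alphabet)
        make = random_rna if alphabet == "rna" else random_protein
        recs = [SequenceRecord(f"s{i}", make(rng, int(l)))
                for i, l in enumerate(rng.integers(8, 31, size=10))]
        S = sw_scores(recs, scoring)
        sub_matrix = scoring.substitution_matrix()
        sub = lambda a, b: float(sub_matrix[a, b])
        for i in range(len(recs)):
            for j in range(i, len(recs)):
                expected = sw_score_oracle(
                    recs[i].residues, recs[j].residues, sub,
                    scoring.gap_open, scoring.gap_extend,
                )
                assert S[i, j] == expected

    def test_zero_self_score_names_sequence(self):
        # an all-wildcard RNA sequence never scores positively against itself
        recs = [SequenceRecord("lbad", "NNNN"), SequenceRecord("l2", "ACGU")]
        with pytest.raises(ValueError, match="lbad"):
            sw_kernel(recs, AlignmentScoring("rna"))


class TestCTFeatures:
    def test_homopolymer_concentrates_on_one_triplet(self):
        [fv] = ct_features([SequenceRecord("l1", "AAAA")])
        v = np.array(fv.vector)
        assert v.sum() == 1.0 and np.linalg.norm(v) == 1.0

    def test_acgu_windows_enumerated(self):
        [fv] = ct_features([SequenceRecord("l1", "ACGU")])
        v = np.array(fv.vector)
        nz = np.nonzero(v)[0]
        assert len(nz) == 2 and np.allclose(v[nz], 1 / np.sqrt(2))

    def test_frequencies_partition_windows(self, rng):
        seq = random_rna(rng, 50)
        d = len(seq)
        v = np.zeros(64)
        for h in range(d - 2):
            idx = sum(4 ** (2 - k) * "ACGU".index(seq[h + k]) for k in range(3))
            v[idx] += 1 / (d - 2)
        assert v.sum() == pytest.approx(1.0)
        [fv] = ct_features([SequenceRecord("l1", seq)])
        assert np.allclose(fv.vector, v / np.linalg.norm(v))

    def test_wildcard_triplets_skipped_and_short_sequence_zero(self):
        [short] = ct_features([SequenceRecord("l1", "AC")])
        assert not any(short.vector)
        [wild] = ct_features([SequenceRecord("l2", "ANA")])
        assert not any(wild.vector)


class TestPsePSSM:
    def test_constant_profile_standardizes_to_zero(self):
        prof = PSSMProfile("p1", np.full((5, 20), 3.0))
        [fv] = psepssm_features([SequenceRecord("p1", "MKVMK")], {"p1": prof})
        assert not any(fv.vector)

    def test_three_residue_profile_by_hand(self):
        scores = np.zeros((3, 20))
        scores[:, 0] = [1.0, 2.0, 3.0]  # single nonconstant column
        prof = PSSMProfile("p1", scores)
        [fv] = psepssm_features([SequenceRecord("p1", "MKV")], {"p1": prof})
        v = np.array(fv.vector)
        # standardized column: (-1, 0, 1)/sqrt(2/3); means vanish, lag-1 msd:
        # two diffs of (-sqrt(3/2))^2 = 3/2 -> mean 3/2 at position 20
        assert v.shape == (40,)
        assert np.allclose(v[:20], 0.0)
        expected = np.zeros(20)
        expected[0] = 1.5
        assert np.allclose(v[20:], expected / np.linalg.norm(expected))

    @pytest.mark.parametrize("lag", [0, 1, 3])
    def test_output_length_follows_lag(self, lag):
        [fv] = psepssm_features([SequenceRecord("p1", "MKVMKV")], lag=lag)
        assert len(fv.vector) == 20 * (1 + lag)

    def test_row_count_mismatch_names_protein(self):
        prof = PSSMProfile("p1", np.zeros((2, 20)))
        with pytest.raises(ValueError, match="p1"):
            psepssm_features([SequenceRecord("p1", "MKV")], {"p1": prof})


class TestRBFAndExpression:
    def test_orthonormal_vectors_give_exp_minus_two(self):
        feats = [FeatureVector("a", (1.0, 0.0)), FeatureVector("b", (0.0, 1.0))]
        K = rbf_kernel(feats, gamma=1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0))
        assert np.allclose(np.diag(K.values), 1.0)

    def test_bad_gamma_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([FeatureVector("a", (1.0,)), FeatureVector("b", (0.0,))], 0.0)

    def test_expression_normalizes_then_delegates(self):
        profs = [ExpressionProfile("l1", (2.0, 0.0)), ExpressionProfile("l2", (0.0, 5.0))]
        K = expression_kernel(profs)
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0))

    def test_expression_dimension_mismatch(self):
        profs = [ExpressionProfile("l1", (1.0,)), ExpressionProfile("l2", (1.0, 2.0))]
        with pytest.raises(ValueError):
            expression_kernel(profs)


class TestGOKernel:
    def test_jaccard_values(self):
        anns = [
            GOAnnotation("p1", frozenset({"GO:1", "GO:2"})),
            GOAnnotation("p2", frozenset({"GO:2", "GO:3"})),
            GOAnnotation("p3", frozenset({"GO:1", "GO:2"})),
        ]
        K = go_kernel(anns).values
        assert K[0, 1] == pytest.approx(1 / 3)
        assert K[0, 2] == 1.0

    def test_empty_sets_are_neutral(self):
        anns = [GOAnnotation("p1", frozenset()), GOAnnotation("p2", frozenset()),
                GOAnnotation("p3", frozenset({"GO:1"}))]
        K = go_kernel(anns).values
        assert np.allclose(np.diag(K), 1.0)
        assert K[0, 1] == 0.0 and K[0, 2] == 0.0

    def test_bounds_and_equality_condition(self, rng):
        anns = [
            GOAnnotation(f"p{i}", frozenset(
                f"GO:{t}" for t in rng.choice(8, size=rng.integers(1, 6), replace=False)
            ))
            for i in range(12)
        ]
        K = go_kernel(anns).values
        assert ((K >= 0) & (K <= 1)).all()
        for i in range(12):
            for j in range(12):
                if K[i, j] == 1.0:
                    assert anns[i].terms == anns[j].terms

    def test_positional_common_terms_relation(self):
        s1, s2, s3 = (3, 1, 5), (3, 2, 5), (3, 2, 5)
        assert annotation_vectors_share_terms(s2, s3)
        assert not annotation_vectors_share_terms(s1, s2)


class TestNormalizeAndRepair:
    def test_cosine_normalize_matches_hand_example(self):
        K = KernelMatrix(np.array([[4.0, 2.0], [2.0, 9.0]]), ("a", "b"), "SW", "lnc")
        out = cosine_normalize(K).values
        assert np.allclose(out, [[1.0, 1 / 3], [1 / 3, 1.0]])

    def test_unit_diagonal_kernel_unchanged(self, rng, random_psd_factory):
        V = random_psd_factory(rng, 5)
        d = np.sqrt(np.diag(V))
        V = V / np.outer(d, d)
        K = KernelMatrix(V, tuple("abcde"), "SF", "lnc")
        assert np.allclose(cosine_normalize(K).values, V, atol=1e-12)

    def test_zero_diagonal_rows_left_zero(self):
        V = np.array([[1.0, 0.0], [0.0, 0.0]])
        out = cosine_normalize(KernelMatrix(V, ("a", "b"), "GO", "pro")).values
        assert out[0, 1] == 0.0 and out[1, 1] == 1.0

    def test_psd_repair_two_by_two_by_hand(self):
        K = KernelMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]), ("a", "b"), "SW", "lnc")
        out = psd_repair(K).values
        # eigenpairs: 3 on (1,1)/sqrt2, -1 clipped -> 1.5 everywhere
        assert np.allclose(out, 1.5)
        assert np.linalg.eigvalsh(out).min() >= -1e-8

    def test_psd_input_passes_through(self, rng, random_psd_factory):
        V = random_psd_factory(rng, 6)
        out = psd_repair(KernelMatrix(V, tuple("abcdef"), "SW", "lnc"))
        assert np.allclose(out.values, V, atol=1e-10)

    def test_random_indefinite_repaired(self, rng):
        for _ in range(5):
            V = rng.normal(size=(7, 7))
            V = 0.5 * (V + V.T)
            out = psd_repair(KernelMatrix(V, tuple("abcdefg"), "SW", "lnc"))
            assert np.linalg.eigvalsh(out.values).min() >= -1e-8

    def test_embed_adds_neutral_rows(self):
        K = KernelMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ("a", "c"), "EXP", "lnc")
        out = embed_in_registry(K, ("a", "b", "c"))
        assert out.values[0, 2] == 0.5 and out.values[0, 1] == 0.0
        assert np.allclose(np.diag(out.values), 1.0)


class TestBankProperties:
    def test_all_eight_kernels_symmetric_unit_diagonal_psd(self, small_dataset):
        from lpifkl.pipeline import build_banks, build_static_kernels

        bank_l, bank_p = build_banks(
            small_dataset.data.interactions, *build_static_kernels(small_dataset.data)
        )
        assert bank_l.names == ["GIP", "SW", "SF", "EXP"]
        assert bank_p.names == ["GIP", "SW", "SF", "GO"]
        for bank in (bank_l, bank_p):
            for K in bank.kernels:
                V = K.values
                assert np.abs(V - V.T).max() <= 1e-10
                assert np.allclose(np.diag(V), 1.0)
                assert np.linalg.eigvalsh(V).min() >= -1e-8
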