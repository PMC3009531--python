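import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmactive import (
    ProteinRecord,
    PropertyTable,
    fit_svd,
    project,
    window_features,
)
from tmactive.property_features import (
    FEATURE_NAMES,
    GROUP_SLICES,
    N_FEATURES,
)

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=16, max_size=60)


class TestWindowFeatures:
    def test_lysine_homopolymer(self, table):
        fs = window_features(ProteinRecord("k16", "K" * 16), table)
        assert fs.raw.shape == (1, 16)
        row = fs.raw[0]
        # K is charge-positive; the other two charge values are absent
        i = FEATURE_NAMES.index("charge-positive")
        assert row[i] == 16
        assert row[FEATURE_NAMES.index("charge-negative")] == 0
        assert row[FEATURE_NAMES.index("charge-neutral")] == 0
        for sl in GROUP_SLICES.values():
            assert row[sl].sum() == 16

    def test_window_count(self, table):
        fs = window_features(ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY"), table)
        assert fs.n_windows == 5  # L - l + 1
        assert fs.sequence_length == 20

    def test_too_short_errors(self, table):
        with pytest.raises(ValueError, match="shorter than window"):
            window_features(ProteinRecord("p", "A" * 15), table)

    def test_unknown_residue_errors(self, table):
        with pytest.raises(KeyError, match="absent"):
            window_features(ProteinRecord("p", "A" * 15 + "X"), table)

    @given(seq=sequences)
    def test_partition_sums(self, table, seq):
        """Each of the 5 property groups counts every window residue exactly
        once, so each group's counts sum to the window length."""
        fs = window_features(ProteinRecord("p", seq), table)
        for sl in GROUP_SLICES.values():
            assert (fs.raw[:, sl].sum(axis=1) == fs.window_length).all()

    def test_counts_match_naive_recount(self, table):
        """Cumulative-sum window counts equal a direct per-window recount."""
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        fs = window_features(ProteinRecord("p", seq), table)
        for i in range(fs.n_windows):
            naive = sum(
                (table.indicator(aa) for aa in seq[i : i + 16]),
                np.zeros(N_FEATURES, dtype=np.int64),
            )
            assert (fs.raw[i] == naive).all()


def _random_feature_sets(rng, n_proteins=6, table=None):
    table = table or PropertyTable.default()
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for i in range(n_proteins):
        L = int(rng.integers(20, 60))
        seq = "".join(rng.choice(alphabet, size=L))
        out.append(window_features(ProteinRecord(f"p{i}", seq), table))
    return out


class TestSVD:
    def test_rank_one_matrix_has_single_singular_value(self, table):
        fs = window_features(ProteinRecord("p", "K" * 30), table)  # identical rows
        model = fit_svd([fs])
        above = (model.singular_values > 1e-8).sum()
        assert above == 1

    def test_reconstruction_identity(self, table):
        rng = np.random.default_rng(0)
        sets = _random_feature_sets(rng, table=table)
        model = fit_svd(sets)
        A = np.concatenate([fs.raw for fs in sets]).astype(float)
        # U is orthogonal 16x16, so projecting and back reconstructs A exactly
        recon = A @ model.U @ model.U.T
        assert np.linalg.norm(A - recon) / np.linalg.norm(A) < 1e-8

    def test_energy_fractions_sum_to_one(self, table):
        rng = np.random.default_rng(1)
        model = fit_svd(_random_feature_sets(rng, 10, table))
        assert abs(model.energy_fractions.sum() - 1.0) < 1e-12
        assert 0.0 < model.energy_retained() <= 1.0

    def test_singular_values_nonincreasing_and_U_orthonormal(self, table):
        rng = np.random.default_rng(2)
        model = fit_svd(_random_feature_sets(rng, table=table))
        s = model.singular_values
        assert (np.diff(s) <= 1e-12).all() and (s >= 0).all()
        assert np.allclose(model.U.T @ model.U, np.eye(16), atol=1e-10)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fit_svd([])

    def test_refit_reproduces_factors_exactly(self, table):
        rng = np.random.default_rng(3)
        sets = _random_feature_sets(rng, table=table)
        m1, m2 = fit_svd(sets), fit_svd(sets)
        assert np.array_equal(m1.U, m2.U)
        assert np.array_equal(m1.singular_values, m2.singular_values)

    def test_save_load_roundtrip(self, table, tmp_path):
        from tmactive import SVDModel

        rng = np.random.default_rng(4)
        model = fit_svd(_random_feature_sets(rng, table=table))
        model.save(tmp_path / "svd.json")
        back = SVDModel.load(tmp_path / "svd.json")
        assert np.array_equal(back.U, model.U)
        assert back.k == model.k


class TestProjection:
    def test_training_projection_equals_scaled_right_factor(self, table):
        """Projecting the pooled matrix row-wise reproduces S V^T (top-k):
        the projected columns are orthogonal with norms equal to the
        singular values."""
        rng = np.random.default_rng(5)
        sets = _random_feature_sets(rng, 8, table)
        model = fit_svd(sets)
        A = np.concatenate([fs.raw for fs in sets]).astype(float)
        P = A @ model.U  # all 16 latent dims
        gram = P.T @ P
        assert np.allclose(
            gram, np.diag(model.singular_values**2), atol=1e-6 * gram.max()
        )

    def test_projection_is_linear(self, table):
        rng = np.random.default_rng(6)
        sets = _random_feature_sets(rng, table=table)
        model = fit_svd(sets)
        fs = project(sets[0], model)
        zero = np.zeros((1, 16))
        assert (zero @ model.U[:, : model.k] == 0).all()
        doubled = (2 * fs.raw.astype(float)) @ model.U[:, : model.k]
        assert np.allclose(doubled, 2 * fs.projected)

    def test_dimension_mismatch_errors(self, table):
        rng = np.random.default_rng(7)
        sets = _random_feature_sets(rng, table=table)
        model = fit_svd(sets)
        bad = sets[0]
        bad.raw = bad.raw[:, :10]
        with pytest.raises(ValueError, match="dimension mismatch"):
            project(bad, model)
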