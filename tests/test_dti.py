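"""Directed information: oracle equivalence, directionality, matrices."""

import numpy as np
import pytest

from dinet.dti import dti_matrix, dti_pair, mi_matrix
from dinet.estimators import EstimatorConfig, mi_bspline, mi_histogram_plugin

HIST = EstimatorConfig(method="histogram")


def _pooled_oracle(x, y):
    """Independent enumeration of sum_n [I(S_now) - I(S_lag)]."""
    total = 0.0
    for n in range(2, x.shape[1] + 1):
        total += mi_histogram_plugin(x[:, :n].ravel(), y[:, :n].ravel())
        total -= mi_histogram_plugin(x[:, 1:n].ravel(), y[:, : n - 1].ravel())
    return total


def _conditional_mi_oracle(x, y):
    """Exhaustive enumeration of sum_n I(X^n; Y_n | Y^{n-1}) over the
    empirical distribution of per-experiment vector samples."""
    from collections import Counter

    total = 0.0
    n_exp, n_steps = x.shape
    for n in range(2, n_steps + 1):
        triples = Counter(
            (tuple(x[e, :n]), y[e, n - 1], tuple(y[e, : n - 1]))
            for e in range(n_exp)
        )
        pc, pac, pbc = Counter(), Counter(), Counter()
        for (a, b, c), k in triples.items():
            pc[c] += k
            pac[a, c] += k
            pbc[b, c] += k
        for (a, b, c), k in triples.items():
            total += (
                k / n_exp
                * np.log(k * pc[c] / (pac[a, c] * pbc[b, c]))
            )
    return total


class TestDtiPair:
    def test_constant_series_give_zero(self):
        x = np.ones((5, 4))
        y = np.full((5, 4), 2.0)
        assert dti_pair(x, y) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pooled_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, size=(8, 4)).astype(float)
        y = r.integers(0, 2, size=(8, 4)).astype(float)
        assert dti_pair(x, y, HIST) == pytest.approx(_pooled_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_vector_mode_satisfies_conditional_mi_identity(self, seed):
        # the reformulation I(X^n;Y^n) - I(X^n;0Y^{n-1}) telescopes to
        # the conditional-MI definition exactly under plug-in estimation
        r = np.random.default_rng(100 + seed)
        x = r.integers(0, 3, size=(8, 4)).astype(float)
        y = r.integers(0, 3, size=(8, 4)).astype(float)
        value = dti_pair(x, y, HIST, sample_mode="vector")
        assert value == pytest.approx(_conditional_mi_oracle(x, y), abs=1e-12)

    def test_zero_pad_flag_changes_lag_sample_set(self):
        r = np.random.default_rng(7)
        x = r.normal(size=(10, 4))
        y = r.normal(size=(10, 4))
        assert dti_pair(x, y) != dti_pair(x, y, include_zero_pad=True)

    def test_directionality_of_lagged_coupling(self):
        wins = 0
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            x = r.normal(size=(19, 4))
            y = np.empty((19, 4))
            y[:, 0] = r.normal(size=19)
            y[:, 1:] = x[:, :3] + 0.3 * r.normal(size=(19, 3))
            if dti_pair(x, y) > dti_pair(y, x):
                wins += 1
        assert wins >= 40

    def test_shuffle_null_removes_directional_signal(self):
        # destroying the experiment pairing between x and y should
        # leave no systematic directed-information asymmetry; the
        # difference DTI(x->y) - DTI(y->x) cancels the documented
        # sample-size bias shared by both directions
        r = np.random.default_rng(3)
        x = r.normal(size=(19, 4))
        y = np.empty((19, 4))
        y[:, 0] = r.normal(size=19)
        y[:, 1:] = x[:, :3] + 0.3 * r.normal(size=(19, 3))
        coupled = dti_pair(x, y) - dti_pair(y, x)
        null = []
        for _ in range(100):
            perm = r.permutation(19)
            ys = y[perm]
            null.append(dti_pair(x, ys) - dti_pair(ys, x))
        null = np.asarray(null)
        # the shuffled mean sits centrally inside the null's 95% band,
        # while the coupled statistic lies far outside it
        assert abs(null.mean()) < 1.96 * null.std(ddof=1)
        assert coupled > null.mean() + 3 * null.std(ddof=1)

    def test_grid_mismatch_and_short_series_rejected(self):
        with pytest.raises(ValueError):
            dti_pair(np.zeros((3, 4)), np.zeros((3, 5)))
        with pytest.raises(ValueError):
            dti_pair(np.zeros((3, 1)), np.zeros((3, 1)))


class TestMatrices:
    def test_dti_matrix_matches_looped_pairs(self, small_grn, small_dataset):
        regs = list(small_grn.tf_ids)[:4]
        tgts = list(small_grn.gene_ids)[:10]
        mat = dti_matrix(small_dataset, regs, tgts)
        for i, rid in enumerate(regs):
            for j, tid in enumerate(tgts):
                if rid == tid:
                    assert np.isnan(mat.scores[i, j])
                    continue
                expected = dti_pair(
                    small_dataset.gene_series(rid), small_dataset.gene_series(tid)
                )
                assert mat.scores[i, j] == pytest.approx(expected, abs=1e-12)

    def test_match_samples_fast_path_matches_looped_pairs(self, small_grn, small_dataset):
        regs = list(small_grn.tf_ids)[:3]
        tgts = list(small_grn.gene_ids)[5:10]
        mat = dti_matrix(small_dataset, regs, tgts, match_samples=True)
        for i, rid in enumerate(regs):
            for j, tid in enumerate(tgts):
                expected = dti_pair(
                    small_dataset.gene_series(rid),
                    small_dataset.gene_series(tid),
                    match_samples=True,
                )
                assert mat.scores[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permuting_targets_permutes_columns(self, small_grn, small_dataset):
        regs = list(small_grn.tf_ids)[:3]
        tgts = list(small_grn.gene_ids)[5:11]
        mat = dti_matrix(small_dataset, regs, tgts)
        back = dti_matrix(small_dataset, regs, tgts[::-1])
        np.testing.assert_array_equal(mat.scores, back.scores[:, ::-1])

    def test_unknown_id_named_in_error(self, small_dataset):
        with pytest.raises(KeyError, match="nosuchgene"):
            dti_matrix(small_dataset, ["nosuchgene"], list(small_dataset.gene_ids)[:3])

    def test_mi_matrix_symmetric_on_shared_ids(self, small_grn, small_dataset):
        ids = list(small_grn.tf_ids)[:4]
        mat = mi_matrix(small_dataset, ids, ids)
        valid = ~np.isnan(mat.scores)
        np.testing.assert_allclose(
            mat.scores[valid], mat.scores.T[valid], atol=1e-12
        )

    def test_mi_matrix_equals_pooled_bspline(self, small_grn, small_dataset):
        regs = list(small_grn.tf_ids)[:2]
        tgts = list(small_grn.gene_ids)[6:9]
        mat = mi_matrix(small_dataset, regs, tgts)
        for i, rid in enumerate(regs):
            for j, tid in enumerate(tgts):
                expected = mi_bspline(
                    small_dataset.gene_series(rid).ravel(),
                    small_dataset.gene_series(tid).ravel(),
                )
                assert mat.scores[i, j] == pytest.approx(expected, abs=1e-12)

    def test_determinism(self, small_grn, small_dataset):
        regs = list(small_grn.tf_ids)[:3]
        tgts = list(small_grn.gene_ids)[:8]
        a = dti_matrix(small_dataset, regs, tgts)
        b = dti_matrix(small_dataset, regs, tgts)
        np.testing.assert_array_equal(a.scores, b.scores)
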