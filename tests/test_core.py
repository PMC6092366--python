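"""Ancestral-palette least squares, residual diagnostics, drift correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import grid_nnls, normal_equations_fit
from palettefit.core import (
    QMatrix,
    RankDeficiencyError,
    drift_correct,
    fit_ancestral_palettes,
    fit_ancestral_palettes_constrained,
    residual_summary,
)
from palettefit.painting import PaletteMatrix


def _random_row_stochastic(rng, n, k):
    a = rng.dirichlet(np.ones(k), size=n)
    return a


def _random_palettes(rng, k, p):
    return rng.dirichlet(np.ones(p), size=k)


# ---------------------------------------------------------------------------
# unconstrained fit
# ---------------------------------------------------------------------------

def test_identity_design_returns_palettes_verbatim(rng):
    C = _random_palettes(rng, 3, 5)
    fit = fit_ancestral_palettes(np.eye(3), C)
    np.testing.assert_allclose(fit.X.values, C, atol=1e-12)
    np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)


def test_single_component_gives_mean_palette():
    C = np.tile([0.6, 0.4], (4, 1))
    fit = fit_ancestral_palettes(np.ones((4, 1)), C)
    np.testing.assert_allclose(fit.X.values, [[0.6, 0.4]], atol=1e-12)
    np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)


def test_exact_recovery_and_normal_equations_oracle(rng):
    """Noise-free recovery to 1e-10, and agreement with an explicit
    (A^T A)^{-1} A^T C solve when noise is added."""
    A = _random_row_stochastic(rng, 6, 2)
    X_true = _random_palettes(rng, 2, 4)
    C = A @ X_true
    fit = fit_ancestral_palettes(A, C)
    np.testing.assert_allclose(fit.X.values, X_true, atol=1e-10)

    C_noisy = np.clip(C + rng.normal(0, 0.02, C.shape), 0, None)
    fit2 = fit_ancestral_palettes(A, C_noisy)
    np.testing.assert_allclose(fit2.X.values, normal_equations_fit(A, C_noisy),
                               atol=1e-10)
    # exact reconstruction identity C = predicted + residuals
    np.testing.assert_allclose(fit2.predicted + fit2.residuals, C_noisy, atol=1e-12)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_recovery_and_residual_row_conservation_property(seed):
    """For any full-rank row-stochastic A and any X_true:
    fit(A, A X_true).X == X_true; with row-stochastic C the residual rows
    sum to zero (1 in the column span of A)."""
    rng = np.random.default_rng(seed)
    n, k, p = 8, 3, 5
    A = _random_row_stochastic(rng, n, k)
    X_true = _random_palettes(rng, k, p)
    fit = fit_ancestral_palettes(A, A @ X_true)
    np.testing.assert_allclose(fit.X.values, X_true, atol=1e-10)

    C = _random_palettes(rng, n, p)  # arbitrary row-stochastic palettes
    fit2 = fit_ancestral_palettes(A, C)
    np.testing.assert_allclose(fit2.residuals.sum(axis=1), 0, atol=1e-9)
    np.testing.assert_allclose(fit2.predicted.sum(axis=1), 1, atol=1e-9)


def test_projection_idempotence(rng):
    A = _random_row_stochastic(rng, 7, 3)
    C = _random_palettes(rng, 7, 6)
    fit = fit_ancestral_palettes(A, C)
    refit = fit_ancestral_palettes(A, fit.predicted)
    assert np.max(np.abs(refit.X.values - fit.X.values)) < 1e-10


def test_rank_deficiency_raises_with_advice():
    A = np.tile([0.5, 0.5], (5, 1))  # two identical components
    with pytest.raises(RankDeficiencyError, match="smaller K"):
        fit_ancestral_palettes(A, np.tile([0.25] * 4, (5, 1)))


def test_negative_entries_flagged_not_clipped():
    A = np.array([[0.6, 0.4], [0.4, 0.6]])
    C = np.eye(2)
    with pytest.warns(UserWarning, match="donor groups"):
        fit = fit_ancestral_palettes(A, C)
    assert fit.negative_X_flag
    np.testing.assert_allclose(fit.X.values, [[3, -2], [-2, 3]], atol=1e-10)


# ---------------------------------------------------------------------------
# constrained fit
# ---------------------------------------------------------------------------

def test_constrained_matches_unconstrained_when_inactive(rng):
    A = _random_row_stochastic(rng, 6, 2)
    X_true = _random_palettes(rng, 2, 4)
    fit_u = fit_ancestral_palettes(A, A @ X_true)
    fit_c = fit_ancestral_palettes_constrained(A, A @ X_true)
    assert not fit_u.negative_X_flag
    np.testing.assert_allclose(fit_c.X.values, fit_u.X.values, atol=1e-8)


def test_constrained_zeroes_negative_entry_and_matches_grid_oracle():
    A = np.array([[0.6, 0.4], [0.4, 0.6]])
    C = np.eye(2)
    with pytest.warns(UserWarning):
        fit_u = fit_ancestral_palettes(A, C)
        fit_c = fit_ancestral_palettes_constrained(A, C)
    assert fit_u.negative_X_flag
    assert fit_c.X.values[1, 0] == 0.0 and fit_c.X.values[0, 1] == 0.0
    assert fit_c.sum_squared_residual >= fit_u.sum_squared_residual
    for p in range(2):
        x_grid, obj_grid = grid_nnls(A, C[:, p])
        obj_c = float(np.sum((A @ fit_c.X.values[:, p] - C[:, p]) ** 2))
        assert obj_c == pytest.approx(obj_grid, abs=1e-8)


def test_constrained_all_zero_palette():
    A = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
    with pytest.warns(UserWarning):
        fit = fit_ancestral_palettes_constrained(A, np.zeros((3, 2)))
    np.testing.assert_allclose(fit.X.values, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# residual summary
# ---------------------------------------------------------------------------

def test_zero_residuals_give_zero_summaries(rng):
    A = np.eye(3)
    C = _random_palettes(rng, 3, 3)
    fit = fit_ancestral_palettes(QMatrix(A, ["i1", "i2", "i3"], ["g1", "g2", "g3"]),
                                 PaletteMatrix(C, ["i1", "i2", "i3"],
                                               ["g1", "g2", "g3"]))
    summ = residual_summary(fit, ["g1", "g2", "g3"])
    assert summ.block_score == pytest.approx(0.0, abs=1e-12)
    assert summ.self_mean_overall == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(summ.group_means.to_numpy(), 0, atol=1e-12)


def test_residual_summary_requires_matching_columns(rng):
    A = _random_row_stochastic(rng, 4, 2)
    C = _random_palettes(rng, 4, 3)
    fit = fit_ancestral_palettes(A, C)
    with pytest.raises(ValueError, match="donor column"):
        residual_summary(fit, ["nope"] * 4)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def _labelled_problem(rng, per_group=4):
    groups = ["g1", "g2", "g3"]
    labels = [g for g in groups for _ in range(per_group)]
    n = len(labels)
    A = _random_row_stochastic(rng, n, 2)
    X_true = _random_palettes(rng, 2, 3)
    C = A @ X_true
    ids = [f"i{j}" for j in range(n)]
    pm = PaletteMatrix(C, ids, groups)
    return pm, A, labels, X_true


def test_drift_correct_noop_without_drift(rng):
    pm, A, labels, _ = _labelled_problem(rng)
    res = drift_correct(pm, A, labels)
    np.testing.assert_allclose(res.corrected.values, pm.values, atol=1e-8)
    np.testing.assert_allclose(res.excess.to_numpy(), 0, atol=1e-8)


@pytest.mark.parametrize("delta", [0.05, 0.1, 0.2])
def test_drift_correct_recovers_injected_self_excess(delta, rng):
    """Adding +delta to every self-group entry (rows renormalized) yields
    excess = delta/(1+delta) exactly and restores the original palettes.

    Derivation: perturbed rows are (C + delta e_self)/(1+delta); the masked
    refit sees only off-self entries, all scaled by 1/(1+delta), so the
    fitted X and the predictions scale the same way, and the excess is
    (C_self+delta)/(1+delta) - C_self/(1+delta) = delta/(1+delta).
    """
    pm, A, labels, _ = _labelled_problem(rng)
    C = pm.values.copy()
    col = {g: j for j, g in enumerate(pm.donor_groups)}
    rows = np.arange(C.shape[0])
    self_cols = np.array([col[l] for l in labels])
    C_pert = C.copy()
    C_pert[rows, self_cols] += delta
    C_pert /= C_pert.sum(axis=1, keepdims=True)
    res = drift_correct(PaletteMatrix(C_pert, pm.recipient_ids, pm.donor_groups),
                        A, labels)
    np.testing.assert_allclose(res.excess.to_numpy(), delta / (1 + delta), atol=1e-8)
    assert np.max(np.abs(res.excess.to_numpy() - delta)) <= delta ** 2 + 1e-8
    np.testing.assert_allclose(res.corrected.values, C, atol=1e-8)


def test_drift_correct_identity_design_preserves_off_diagonal(rng):
    gen = np.random.default_rng(0)
    groups = ["a", "b", "c"]
    labels = ["a", "a", "b", "b", "c", "c"]
    A = np.vstack([np.eye(3)[["a", "b", "c"].index(l)] for l in labels])
    # near-identity design with per-individual jitter so the design stays
    # full rank when any one group's rows are masked
    A = 0.8 * A + 0.2 * gen.dirichlet(np.ones(3), size=6)
    A /= A.sum(axis=1, keepdims=True)
    C = gen.dirichlet(np.ones(3), size=6)
    pm = PaletteMatrix(C, [f"i{j}" for j in range(6)], groups)
    res = drift_correct(pm, A, labels)
    col = {g: j for j, g in enumerate(groups)}
    mask_off = np.ones_like(C, dtype=bool)
    mask_off[np.arange(6), [col[l] for l in labels]] = False
    # off-diagonal structure preserved up to the row renormalization factor
    ratio = res.corrected.values[mask_off] / C[mask_off]
    ratio = ratio.reshape(6, 2)
    np.testing.assert_allclose(ratio[:, 0], ratio[:, 1], rtol=1e-9)


def test_drift_correct_unidentifiable_group_raises():
    labels = ["a"] * 3 + ["b"] * 3
    A = np.vstack([np.tile([1.0, 0.0], (3, 1)), np.tile([0.0, 1.0], (3, 1))])
    C = np.tile([0.5, 0.5], (6, 1))
    pm = PaletteMatrix(C, [f"i{j}" for j in range(6)], ["a", "b"])
    with pytest.raises(RankDeficiencyError, match="'a'"):
        with pytest.warns(UserWarning):
            drift_correct(pm, A, labels)


# ---------------------------------------------------------------------------
# QMatrix validation
# ---------------------------------------------------------------------------

def test_qmatrix_renormalizes_small_deviations_and_rejects_large():
    q = QMatrix(np.array([[0.5004, 0.5001]]), ["i"], ["a", "b"])
    assert q.values.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="sum to 1"):
        QMatrix(np.array([[0.7, 0.1]]), ["i"], ["a", "b"])
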