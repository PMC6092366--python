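"""Goodness-of-fit for admixture models via palette prediction.

Given an N x K admixture-proportion matrix A (rows on the simplex) and an
N x P copying-palette matrix C (per-individual genome fractions copied
from each donor group), the model states that admixed individuals'
palettes are mixtures of K ancestral palettes:

    A X = C,     X the K x P ancestral palette matrix.

X is estimated by least squares — algebraically X = (A^T A)^{-1} A^T C,
computed here via an orthogonal-decomposition solve — and the residual
matrix C - A X is the diagnostic: under a true recent-admixture history
the residuals are unstructured noise, while unmodelled drift or ghost
ancestry concentrates positive residuals on each group's own donor
column (a block-diagonal pattern).  Negative entries of X themselves
indicate a poor fit and are flagged, never clipped; a non-negative
constrained fit is available separately.

``drift_correct`` estimates what palettes would look like without
group-specific drift by refitting X with each individual's own-group
palette entry excluded from the objective, substituting the model's
prediction for that entry, and reporting the unexplained self-copying
excess separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .painting import PaletteMatrix

__all__ = [
    "QMatrix",
    "AncestralPalettes",
    "FitResult",
    "RankDeficiencyError",
    "fit_ancestral_palettes",
    "fit_ancestral_palettes_constrained",
    "residual_summary",
    "ResidualSummary",
    "drift_correct",
    "DriftCorrectionResult",
]

logger = logging.getLogger(__name__)

_RANK_RTOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """A^T A is rank deficient; its inverse does not exist."""


@dataclass
class QMatrix:
    """N x K admixture proportions; rows on the simplex."""

    values: np.ndarray
    individual_ids: list[str]
    component_names: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("Q matrix must be 2-D")
        n, k = v.shape
        if n != len(self.individual_ids) or k != len(self.component_names):
            raise ValueError("Q matrix shape does not match ids/components")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("admixture proportions must lie in [0, 1]")
        sums = v.sum(axis=1)
        off = np.max(np.abs(sums - 1.0)) if n else 0.0
        if off > 1e-6:
            if off <= 1e-3:
                logger.warning("renormalizing Q rows off by up to %.2e", off)
                v = v / sums[:, None]
            else:
                raise ValueError(f"Q rows must sum to 1 (max deviation {off:.3g})")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids,
                            columns=self.component_names)


@dataclass
class AncestralPalettes:
    """K x P palettes attributed to each ancestral population."""

    values: np.ndarray
    component_names: list[str]
    donor_groups: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("ancestral palettes must be finite")
        if v.shape != (len(self.component_names), len(self.donor_groups)):
            raise ValueError("ancestral palette shape does not match names")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.component_names,
                            columns=self.donor_groups)


@dataclass
class FitResult:
    """Least-squares palette fit: X, predictions A X, residuals C - A X."""

    X: AncestralPalettes
    predicted: np.ndarray
    residuals: np.ndarray
    negative_X_flag: bool
    condition_number: float        # of A^T A
    sum_squared_residual: float
    individual_ids: list[str] = field(default_factory=list)
    donor_groups: list[str] = field(default_factory=list)

    def residual_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.residuals, index=self.individual_ids,
                            columns=self.donor_groups)


def _as_matrices(A, C):
    if isinstance(A, QMatrix):
        a = A.values
        ids = A.individual_ids
        comps = A.component_names
    else:
        a = np.asarray(A, dtype=float)
        ids = [f"ind{i}" for i in range(a.shape[0])]
        comps = [f"comp{k}" for k in range(a.shape[1])]
    if isinstance(C, PaletteMatrix):
        c = C.values
        groups = C.donor_groups
    else:
        c = np.asarray(C, dtype=float)
        groups = [f"group{p}" for p in range(c.shape[1])]
    return a, c, ids, comps, groups


def _check_design(a: np.ndarray, c: np.ndarray):
    n, k = a.shape
    if c.shape[0] != n:
        raise ValueError(f"A has {n} rows but C has {c.shape[0]}")
    if k > n:
        raise ValueError(f"K={k} components exceed N={n} individuals")
    if c.shape[1] <= k:
        warnings.warn(
            f"P={c.shape[1]} donor groups <= K={k} components; the fit assumes "
            "more distinct ancestry profiles than ancestral populations",
            UserWarning, stacklevel=3,
        )
    s = np.linalg.svd(a, compute_uv=False)
    if s[-1] <= s[0] * _RANK_RTOL:
        raise RankDeficiencyError(
            "A^T A is rank deficient, so its inverse does not exist; the "
            "admixture components are collinear — consider a smaller K"
        )
    return (s[0] / s[-1]) ** 2


def fit_ancestral_palettes(A, C) -> FitResult:
    """Least-squares estimate of the ancestral palettes X (A X = C).

    Solves min ||A X - C||_F^2 by a numerically stable orthogonal
    decomposition (equivalent to X = (A^T A)^{-1} A^T C).  Negative
    entries of X are legal output but set ``negative_X_flag`` — they
    indicate the admixture model fits poorly.  Raises
    :class:`RankDeficiencyError` when A^T A is singular.
    """
    a, c, ids, comps, groups = _as_matrices(A, C)
    cond = _check_design(a, c)
    x, *_ = np.linalg.lstsq(a, c, rcond=None)
    predicted = a @ x
    residuals = c - predicted
    return FitResult(
        X=AncestralPalettes(x, list(comps), list(groups)),
        predicted=predicted,
        residuals=residuals,
        negative_X_flag=bool(np.any(x < -1e-12)),
        condition_number=float(cond),
        sum_squared_residual=float(np.sum(residuals ** 2)),
        individual_ids=list(ids),
        donor_groups=list(groups),
    )


def fit_ancestral_palettes_constrained(A, C) -> FitResult:
    """Non-negative least-squares fit of the ancestral palettes.

    Minimizes ||A X - C||_F^2 subject to X >= 0, column by column (each
    palette column is an independent NNLS problem).  Coincides with the
    unconstrained solution whenever that solution is already
    non-negative; otherwise its objective is necessarily larger.
    """
    a, c, ids, comps, groups = _as_matrices(A, C)
    cond = _check_design(a, c)
    x = np.empty((a.shape[1], c.shape[1]))
    for p in range(c.shape[1]):
        x[:, p], _ = scipy.optimize.nnls(a, c[:, p])
    predicted = a @ x
    residuals = c - predicted
    return FitResult(
        X=AncestralPalettes(x, list(comps), list(groups)),
        predicted=predicted,
        residuals=residuals,
        negative_X_flag=False,
        condition_number=float(cond),
        sum_squared_residual=float(np.sum(residuals ** 2)),
        individual_ids=list(ids),
        donor_groups=list(groups),
    )


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ResidualSummary:
    """Group-level residual diagnostics.

    ``group_means`` is a G x P table of mean residuals; ``self_means``
    holds each group's mean residual on its own donor column;
    ``block_score`` is computed on the group-mean matrix as mean
    |on-diagonal| minus mean |off-diagonal| entry — near zero for an
    adequate admixture fit (individual-level noise averages out), positive
    when misfit concentrates on each group's own donor column (drift-like
    or ghost-ancestry signal).
    """

    group_means: pd.DataFrame
    self_means: pd.Series
    self_mean_overall: float
    block_score: float
    per_individual_self: pd.Series


def residual_summary(fit: FitResult, labels: Sequence[str]) -> ResidualSummary:
    """Summarize residual structure relative to group labels.

    ``labels`` gives each individual's group; a group's "self" column is
    the palette column with the same name.  Every label must name a donor
    column.
    """
    labels = list(labels)
    if len(labels) != len(fit.individual_ids):
        raise ValueError(f"{len(fit.individual_ids)} individuals but {len(labels)} labels")
    col_index = {g: j for j, g in enumerate(fit.donor_groups)}
    missing = sorted(set(labels) - set(col_index))
    if missing:
        raise ValueError(f"labels without a matching donor column: {missing}")

    R = fit.residuals
    lab = np.asarray(labels, dtype=object)
    groups = list(dict.fromkeys(labels))
    gm = np.vstack([R[lab == g].mean(axis=0) for g in groups])
    group_means = pd.DataFrame(gm, index=groups, columns=fit.donor_groups)

    self_cols = np.array([col_index[l] for l in labels])
    diag = R[np.arange(R.shape[0]), self_cols]
    self_means = pd.Series({g: diag[lab == g].mean() for g in groups})

    gm_self = np.array([gm[i, col_index[g]] for i, g in enumerate(groups)])
    mask_off = np.ones_like(gm, dtype=bool)
    mask_off[np.arange(len(groups)), [col_index[g] for g in groups]] = False
    block_score = float(np.mean(np.abs(gm_self)) - np.mean(np.abs(gm[mask_off])))

    return ResidualSummary(
        group_means=group_means,
        self_means=self_means,
        self_mean_overall=float(diag.mean()),
        block_score=block_score,
        per_individual_self=pd.Series(diag, index=fit.individual_ids),
    )


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

@dataclass
class DriftCorrectionResult:
    """Palettes re-estimated without each group's own-column information.

    ``corrected`` substitutes the masked-refit prediction for every
    individual's self-group entry and renormalizes rows; ``excess`` is the
    observed-minus-predicted self-copying (floored at 0) — the part of the
    palette the admixture model cannot explain.
    """

    corrected: PaletteMatrix
    excess: pd.Series
    X: AncestralPalettes
    predicted: np.ndarray


def drift_correct(C: PaletteMatrix, A, labels: Sequence[str]) -> DriftCorrectionResult:
    """Estimate palettes in the absence of group-specific drift.

    Refits the ancestral palettes with each individual's own-group palette
    entry masked out of the least-squares objective: the column for donor
    group *g* is fitted using only individuals not labelled *g*.  The
    correction replaces each self-group entry by its masked prediction and
    renormalizes; the positive part of (observed - predicted) self-copying
    is returned as the unexplained excess.
    """
    a, c, ids, comps, groups = _as_matrices(A, C)
    labels = list(labels)
    if len(labels) != a.shape[0]:
        raise ValueError(f"{a.shape[0]} individuals but {len(labels)} labels")
    col_index = {g: j for j, g in enumerate(groups)}
    missing = sorted(set(labels) - set(col_index))
    if missing:
        raise ValueError(f"labels without a matching palette column: {missing}")
    _check_design(a, c)

    lab = np.asarray(labels, dtype=object)
    x = np.empty((a.shape[1], c.shape[1]))
    for p, g in enumerate(groups):
        keep = lab != g
        a_kept = a[keep]
        if a_kept.shape[0] < a.shape[1]:
            raise RankDeficiencyError(
                f"masking group {g!r} leaves too few individuals to fit column {g!r}"
            )
        s = np.linalg.svd(a_kept, compute_uv=False)
        if s[-1] <= s[0] * _RANK_RTOL:
            raise RankDeficiencyError(
                f"masking group {g!r} makes the design rank deficient; "
                f"column {g!r} is unidentifiable"
            )
        x[:, p], *_ = np.linalg.lstsq(a_kept, c[keep, p], rcond=None)

    predicted = a @ x
    self_cols = np.array([col_index[l] for l in labels])
    rows = np.arange(c.shape[0])
    corrected = c.copy()
    corrected[rows, self_cols] = predicted[rows, self_cols]
    corrected = np.clip(corrected, 0.0, None)
    corrected /= corrected.sum(axis=1, keepdims=True)
    excess = np.maximum(c[rows, self_cols] - predicted[rows, self_cols], 0.0)

    return DriftCorrectionResult(
        corrected=PaletteMatrix(corrected, list(ids), list(groups)),
        excess=pd.Series(excess, index=ids),
        X=AncestralPalettes(x, list(comps), list(groups)),
        predicted=predicted,
    )
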