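"""Supporting population-genetic computations.

* greedy LD pruning of SNPs (window in bp, r^2 ceiling), matching the
  pre-processing usually applied before running admixture inference;
* a small supervised maximum-likelihood estimator of admixture
  proportions given fixed source allele frequencies (EM on the binomial
  admixture likelihood), used for end-to-end testing in place of a full
  unsupervised run;
* the coancestry probability of two admixture vectors: the chance that
  two individuals draw the same ancestral source at a locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PruneParams",
    "ReferenceFrequencies",
    "ld_prune",
    "estimate_q_supervised",
    "coancestry_probability",
    "population_allele_frequencies",
]

_FREQ_EPS = 1e-6


@dataclass(frozen=True)
class PruneParams:
    """LD-pruning parameters: physical window and squared-correlation ceiling."""

    window_bp: int = 250_000
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must be in (0, 1]")


@dataclass
class ReferenceFrequencies:
    """K x L allele frequencies of designated source populations.

    Frequencies are clamped away from {0, 1} by 1e-6 on construction so
    likelihoods stay finite.
    """

    frequencies: np.ndarray
    population_names: list[str]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 2:
            raise ValueError("frequencies must be a (K, L) matrix")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if f.shape[0] != len(self.population_names):
            raise ValueError("population_names must match frequency rows")
        self.frequencies = np.clip(f, _FREQ_EPS, 1.0 - _FREQ_EPS)

    @property
    def n_populations(self) -> int:
        return self.frequencies.shape[0]


def population_allele_frequencies(haplotypes: np.ndarray, labels: Sequence[str],
                                  populations: Sequence[str]) -> ReferenceFrequencies:
    """Per-population alternate-allele frequencies from phased haplotypes.

    ``haplotypes`` is (2N, L); ``labels`` are per-individual.
    """
    labels = np.asarray(labels)
    rows = []
    for pop in populations:
        idx = np.where(labels == pop)[0]
        if idx.size == 0:
            raise KeyError(f"no individuals labelled {pop!r}")
        hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
        rows.append(haplotypes[hap_rows].mean(axis=0))
    return ReferenceFrequencies(np.vstack(rows), list(populations))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; 0 if either is constant."""
    vx = x - x.mean()
    vy = y - y.mean()
    denom = (vx @ vx) * (vy @ vy)
    if denom <= 0:
        return 0.0
    num = vx @ vy
    return float(num * num / denom)


def ld_prune(genotypes: np.ndarray, positions_bp: np.ndarray,
             params: PruneParams | None = None) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    Scans sites in position order; a candidate site is dropped if its r^2
    with any already-retained site within ``window_bp`` (closed interval)
    exceeds ``r2_max``.  On an offending pair the earlier (left) site is
    kept.  Monomorphic sites have undefined r^2; they are retained and
    never trigger a removal.  Returns retained site indices in order.
    """
    if params is None:
        params = PruneParams()
    genotypes = np.asarray(genotypes, dtype=float)
    positions_bp = np.asarray(positions_bp)
    if genotypes.shape[1] != len(positions_bp):
        raise ValueError("genotypes columns must match positions")
    if np.any(np.diff(positions_bp) < 0):
        raise ValueError("positions_bp must be sorted ascending")

    centered = genotypes - genotypes.mean(axis=0)
    ss = np.einsum("ij,ij->j", centered, centered)

    retained: list[int] = []
    for j in range(genotypes.shape[1]):
        drop = False
        if ss[j] > 0:
            for i in reversed(retained):
                if positions_bp[j] - positions_bp[i] > params.window_bp:
                    break
                if ss[i] <= 0:
                    continue
                num = centered[:, i] @ centered[:, j]
                if num * num / (ss[i] * ss[j]) > params.r2_max:
                    drop = True
                    break
        if not drop:
            retained.append(j)
    return np.asarray(retained, dtype=int)


# ---------------------------------------------------------------------------
# supervised admixture proportions
# ---------------------------------------------------------------------------

def estimate_q_supervised(genotypes: np.ndarray, ref: ReferenceFrequencies,
                          *, max_iter: int = 2000, tol: float = 1e-7,
                          return_converged: bool = False):
    """Maximum-likelihood admixture proportions for one individual.

    Maximizes the binomial admixture likelihood
    ``prod_l Bin(g_l; 2, sum_k q_k f_kl)`` over the simplex by EM, treating
    the two allele copies at each site as independent draws from the
    mixture.  Stops when ``max |dq| < tol`` or after ``max_iter``
    iterations (in which case the convergence flag is False).
    """
    g = np.asarray(genotypes, dtype=float)
    f = ref.frequencies
    K, L = f.shape
    if g.shape != (L,):
        raise ValueError(f"genotypes must be a length-{L} dosage vector")
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype dosages must be in {0, 1, 2}")
    if L < K:
        raise ValueError("need at least K sites")
    if K == 1:
        q = np.ones(1)
        return (q, True) if return_converged else q

    q = np.full(K, 1.0 / K)
    converged = False
    for _ in range(max_iter):
        p = q @ f                                  # (L,) mixture alt-allele prob
        # expected source counts over the 2L allele copies
        resp_alt = (q[:, None] * f) / p            # (K, L)
        resp_ref = (q[:, None] * (1.0 - f)) / (1.0 - p)
        q_new = (resp_alt @ g + resp_ref @ (2.0 - g)) / (2.0 * L)
        q_new /= q_new.sum()
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            converged = True
            break
        q = q_new
    return (q, converged) if return_converged else q


def admixture_log_likelihood(genotypes: np.ndarray, ref: ReferenceFrequencies,
                             q: np.ndarray) -> float:
    """Binomial admixture log-likelihood of one individual's dosages."""
    g = np.asarray(genotypes, dtype=float)
    p = np.asarray(q, dtype=float) @ ref.frequencies
    return float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# coancestry probability
# ---------------------------------------------------------------------------

def coancestry_probability(q1: Sequence[float], q2: Sequence[float]) -> float:
    """Probability that two individuals share an ancestral source at a locus.

    For admixture vectors ``q1``, ``q2`` on the K-simplex this is
    ``sum_k q1_k * q2_k``; e.g. two individuals with proportions
    (0.5, 0.35, 0.15) share a source 0.5^2 + 0.35^2 + 0.15^2 = 0.395 of
    the time.
    """
    a = np.asarray(q1, dtype=float)
    b = np.asarray(q2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"admixture vectors must have equal length, got {a.shape} and {b.shape}")
    for name, v in (("q1", a), ("q2", b)):
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not on the simplex (entries >= 0, sum 1)")
    return float(a @ b)
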