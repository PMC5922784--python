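"""EM estimation of the confusion/abundance decomposition.

The model: a read originates from one of M existing families with
probability ``beta_j = P(T = c_j)`` and, given origin ``c_j``, is aligned
to aligned family ``a_i`` with probability ``alpha_ij = P(A = a_i | T = c_j)``.
Only the aligned marginal is observed, as per-family read counts ``y_i``.
The observed-data log-likelihood is

    l(alpha, beta | y) = sum_i y_i * log( sum_j alpha_ij * beta_j )

and EM maximizes it with closed-form updates:

    E step:  Phi_ij = y_i * alpha_ij * beta_j / sum_s alpha_is * beta_s
    M step:  alpha_ij' = Phi_ij / Psi_j,   beta_j' = Psi_j / sum_i y_i

where ``Psi_j = sum_i Phi_ij`` is the expected number of reads from
origin ``c_j``. Iteration stops when no parameter (any entry of alpha or
beta) moves by ``tol`` or more (default 1e-6). The fit is fully
deterministic given its inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import List, Optional, Tuple

import numpy as np

from .filtering import FamilyUniverse
from .io import CountVector

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000

#: Mass given to an origin whose expected read count hits exactly zero in
#: an M step (its alpha column is then unidentified and kept as-is).
_ZERO_PSI_BETA = 1e-12


class UnreachableFamilyError(ValueError):
    """An aligned family has observed reads but zero probability under the
    current parameters — an initialization or modeling defect."""


@dataclasses.dataclass(frozen=True)
class ConfusionModel:
    """Parameters theta = (alpha, beta) tied to a family universe.

    ``alpha`` is N x M with each column on the simplex; ``beta`` is a
    length-M simplex vector.
    """

    alpha: np.ndarray
    beta: np.ndarray
    universe: FamilyUniverse

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        n, m = self.universe.n_aligned, self.universe.n_existing
        if alpha.shape != (n, m):
            raise ValueError(f"alpha must be {n}x{m}, got {alpha.shape}")
        if beta.shape != (m,):
            raise ValueError(f"beta must have length {m}, got {beta.shape}")
        if (alpha < -1e-12).any() or (alpha > 1 + 1e-9).any():
            raise ValueError("alpha entries must lie in [0, 1]")
        if (beta < -1e-12).any() or (beta > 1 + 1e-9).any():
            raise ValueError("beta entries must lie in [0, 1]")
        col_sums = alpha.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("every alpha column must sum to 1")
        if not np.isclose(beta.sum(), 1.0, atol=1e-9):
            raise ValueError("beta must sum to 1")


@dataclasses.dataclass(frozen=True)
class EMWorkspace:
    """E-step responsibilities aggregated over reads.

    ``phi[i, j]`` is the expected number of reads aligned to ``a_i`` that
    originate from ``c_j``; ``psi[j]`` its column sum. The per-read latent
    origins are never materialized — their conditional law is fully
    carried by phi.
    """

    phi: np.ndarray
    psi: np.ndarray


@dataclasses.dataclass(frozen=True)
class EMResult:
    model: ConfusionModel
    loglik_trace: Tuple[float, ...]
    iterations: int
    converged: bool


@dataclasses.dataclass(frozen=True)
class ProfileEstimate:
    """Fitted origin proportions and rounded corrected counts.

    ``count_hat[j] = round(total_reads * beta_hat[j])`` with half rounded
    away from zero; the rounded counts need not sum exactly to
    ``total_reads`` (off by at most M/2).
    """

    existing_ids: tuple
    beta_hat: np.ndarray
    count_hat: np.ndarray
    total_reads: int
    validate_total: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate_total: bool) -> None:
        beta = np.asarray(self.beta_hat, dtype=float)
        counts = np.asarray(self.count_hat, dtype=np.int64)
        object.__setattr__(self, "beta_hat", beta)
        object.__setattr__(self, "count_hat", counts)
        object.__setattr__(self, "existing_ids", tuple(self.existing_ids))
        m = len(self.existing_ids)
        if beta.shape != (m,) or counts.shape != (m,):
            raise ValueError("beta_hat/count_hat lengths must match existing_ids")
        if not np.isclose(beta.sum(), 1.0, atol=1e-9):
            raise ValueError("beta_hat must sum to 1")
        if validate_total and abs(int(counts.sum()) - self.total_reads) > m / 2:
            raise ValueError("rounded counts stray from the read total by > M/2")


def e_step(model: ConfusionModel, y: CountVector) -> EMWorkspace:
    """Compute expected per-(aligned, origin) read counts under the model.

    Rows with ``y_i = 0`` are all-zero. An aligned family with observed
    reads but zero marginal probability raises
    :class:`UnreachableFamilyError`.
    """
    counts = y.reindex(model.universe.aligned_ids).counts.astype(float)
    joint = model.alpha * model.beta[None, :]  # N x M
    marginal = joint.sum(axis=1)
    dead = (counts > 0) & (marginal <= 0.0)
    if dead.any():
        bad = [model.universe.aligned_ids[i] for i in np.flatnonzero(dead)]
        raise UnreachableFamilyError(
            f"aligned families unreachable under current parameters: {bad}"
        )
    safe = np.where(marginal > 0, marginal, 1.0)
    phi = counts[:, None] * joint / safe[:, None]
    phi[marginal <= 0, :] = 0.0
    return EMWorkspace(phi=phi, psi=phi.sum(axis=0))


def m_step(
    workspace: EMWorkspace, previous_alpha: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form maximizers given the E-step responsibilities.

    ``alpha'_ij = Phi_ij / Psi_j`` and ``beta'_j = Psi_j / sum(y)``. A
    column with ``Psi_j = 0`` explains no reads, so its alpha column is
    unidentified: it keeps the previous column (uniform if none is given)
    and its beta entry gets a vanishing positive mass before the final
    renormalization.
    """
    phi, psi = workspace.phi, workspace.psi
    total = psi.sum()
    if total <= 0:
        raise ValueError("workspace explains zero reads")
    n, m = phi.shape

    alive = psi > 0
    alpha = np.empty_like(phi)
    alpha[:, alive] = phi[:, alive] / psi[None, alive]
    if (~alive).any():
        if previous_alpha is not None:
            alpha[:, ~alive] = previous_alpha[:, ~alive]
        else:
            alpha[:, ~alive] = 1.0 / n
        beta = np.where(alive, psi / total, _ZERO_PSI_BETA)
        beta = beta / beta.sum()
    else:
        beta = psi / total
    return alpha, beta


def observed_log_likelihood(model: ConfusionModel, y: CountVector) -> float:
    """l(theta | y) = sum_i y_i log(sum_j alpha_ij beta_j), in nats.

    Returns ``-inf`` (with a warning) when a family with positive count
    has zero marginal probability.
    """
    counts = y.reindex(model.universe.aligned_ids).counts.astype(float)
    marginal = model.alpha @ model.beta
    positive = counts > 0
    if (marginal[positive] <= 0).any():
        warnings.warn(
            "zero marginal probability for an observed family; "
            "log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    return float(counts[positive] @ np.log(marginal[positive]))


def fit_plsa(
    alpha0: np.ndarray,
    beta0: np.ndarray,
    y: CountVector,
    universe: FamilyUniverse,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    *,
    update_alpha: bool = True,
) -> EMResult:
    """Run EM from the given initial values until every parameter settles.

    Convergence: the maximum absolute change over all alpha and beta
    entries between consecutive iterations is below ``tol``. The
    log-likelihood trace (one value per completed iteration, computed at
    the updated parameters) is non-decreasing by the EM guarantee.

    ``update_alpha=False`` keeps the confusion matrix fixed and fits beta
    alone — the observed log-likelihood is then concave in beta, so EM
    finds the global maximizer.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    model = ConfusionModel(np.array(alpha0, dtype=float),
                           np.array(beta0, dtype=float), universe)
    trace: List[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        workspace = e_step(model, y)
        new_alpha, new_beta = m_step(workspace, previous_alpha=model.alpha)
        if not update_alpha:
            new_alpha = model.alpha
        delta = max(
            float(np.abs(new_alpha - model.alpha).max()),
            float(np.abs(new_beta - model.beta).max()),
        )
        model = ConfusionModel(new_alpha, new_beta, universe)
        loglik = observed_log_likelihood(model, y)
        trace.append(loglik)
        logger.info(
            "EM iteration %d: loglik=%.10g max-param-change=%.3g",
            iterations, loglik, delta,
        )
        if delta < tol:
            converged = True
            break
    return EMResult(
        model=model,
        loglik_trace=tuple(trace),
        iterations=iterations,
        converged=converged,
    )


def corrected_profile(result: EMResult, y: CountVector) -> ProfileEstimate:
    """Corrected counts: ``y_hat_j = round(total * beta_hat_j)``.

    Rounds half away from zero. The beta estimates are carried at full
    precision; only the counts are rounded.
    """
    universe = result.model.universe
    total = int(y.reindex(universe.aligned_ids).counts.sum())
    beta_hat = result.model.beta
    count_hat = np.floor(total * beta_hat + 0.5).astype(np.int64)
    return ProfileEstimate(
        existing_ids=universe.existing_ids,
        beta_hat=beta_hat,
        count_hat=count_hat,
        total_reads=total,
    )


def uniform_initialization(
    y: CountVector, universe: FamilyUniverse, artificial_mass: float = 0.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Fallback initial values when no learning sample is available.

    ``alpha0`` has uniform columns; ``beta0`` is the observed proportion of
    each existing family's own aligned counts, with the EXTRA family
    receiving the mass of reads assigned to artificial (non-existing)
    families. Purely a documented fallback — a learned initialization is
    always preferable.
    """
    counts = y.reindex(universe.aligned_ids).counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("count vector has no reads")
    n, m = universe.n_aligned, universe.n_existing
    alpha0 = np.full((n, m), 1.0 / n)
    lookup = dict(zip(universe.aligned_ids, counts))
    beta0 = np.array(
        [lookup.get(c, 0.0) for c in universe.existing_ids[:-1]] + [0.0]
    )
    beta0[-1] = max(total - beta0.sum(), 0.0) + artificial_mass
    beta0 = np.maximum(beta0, 1e-12)
    return alpha0, beta0 / beta0.sum()
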