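"""Learned initialization of the EM parameters from a labeled sample.

A "learning sample" is a metagenomic sample whose reads have known true
origins, summarized as a joint (origin family x aligned family) count
matrix. Two empirical distributions are extracted:

* ``alpha_L[i, j]`` — fraction of reads from origin ``c_j`` that were
  aligned to ``a_i`` (column-stochastic over aligned families);
* ``gamma_L[j, i]`` — fraction of reads aligned to ``a_i`` that originate
  from ``c_j`` (column-stochastic over origins).

These transfer to a new sample under the assumption that per-origin
alignment frequencies, and per-aligned-family origin frequencies, are
similar across samples. Where the new sample has families the learning
sample never saw, the leftover probability mass is split evenly; existing
families entirely absent from the learning sample get a uniform column.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
import pandas as pd

from .filtering import FamilyUniverse
from .io import CountVector, JointCountMatrix

#: Floor applied to every initialized probability. EM's multiplicative
#: updates keep exact zeros at zero forever; the floor keeps every
#: parameter reachable.
EPSILON = 1e-12


@dataclasses.dataclass(frozen=True)
class LearnedPriors:
    """Empirical alignment and origin distributions of a learning sample.

    ``alpha_L`` is a DataFrame indexed by the learning sample's aligned
    families with one column per origin family that had at least one read;
    each column sums to 1. ``gamma_L`` is indexed by origin families with
    one column per aligned family that had at least one read; each column
    sums to 1.
    """

    alpha_L: pd.DataFrame
    gamma_L: pd.DataFrame

    @property
    def learning_aligned_ids(self) -> Tuple[str, ...]:
        return tuple(self.alpha_L.index)

    @property
    def learning_origin_ids(self) -> Tuple[str, ...]:
        return tuple(self.gamma_L.index)


def estimate_learning_distributions(joint: JointCountMatrix) -> LearnedPriors:
    """Row- and column-normalize the joint counts into alpha_L and gamma_L.

    Origins with zero total reads are dropped from ``alpha_L``; aligned
    families with zero total reads are dropped from ``gamma_L``. An
    all-zero matrix is an error.
    """
    counts = joint.counts.astype(float)  # origins x aligned
    if counts.sum() <= 0:
        raise ValueError("learning sample has no reads")
    origin_totals = counts.sum(axis=1)
    aligned_totals = counts.sum(axis=0)

    keep_origins = origin_totals > 0
    alpha = (counts[keep_origins] / origin_totals[keep_origins, None]).T
    alpha_L = pd.DataFrame(
        alpha,
        index=list(joint.aligned_ids),
        columns=[o for o, k in zip(joint.origin_ids, keep_origins) if k],
    )

    keep_aligned = aligned_totals > 0
    gamma = counts[:, keep_aligned] / aligned_totals[None, keep_aligned]
    gamma_L = pd.DataFrame(
        gamma,
        index=list(joint.origin_ids),
        columns=[a for a, k in zip(joint.aligned_ids, keep_aligned) if k],
    )
    return LearnedPriors(alpha_L=alpha_L, gamma_L=gamma_L)


def _floor_and_normalize(matrix: np.ndarray, eps: float = EPSILON) -> np.ndarray:
    """Floor entries at ``eps`` and renormalize columns to sum to exactly 1."""
    floored = np.maximum(matrix, eps)
    return floored / floored.sum(axis=0, keepdims=True)


def initialize_alpha(
    priors: LearnedPriors, universe: FamilyUniverse, eps: float = EPSILON
) -> np.ndarray:
    """Build the N x M initial confusion matrix from learned alpha_L.

    For an existing family also present among the learning sample's
    origins: aligned families seen in both samples copy ``alpha_L``;
    aligned families only in the new sample share the remaining mass
    ``1 - sum(copied)`` equally. Existing families the learning sample
    never saw (often the EXTRA family) get uniform ``1/N`` columns.
    Every column is floored at ``eps`` and renormalized to sum to 1.
    """
    n = universe.n_aligned
    m = universe.n_existing
    alpha0 = np.empty((n, m), dtype=float)
    learn_aligned = set(priors.learning_aligned_ids)
    known_origins = set(priors.alpha_L.columns)

    shared_mask = np.array([a in learn_aligned for a in universe.aligned_ids])
    new_only = int((~shared_mask).sum())

    for j, origin in enumerate(universe.existing_ids):
        if origin not in known_origins:
            alpha0[:, j] = 1.0 / n
            continue
        column = priors.alpha_L[origin]
        copied = np.array(
            [column.get(a, 0.0) if shared else 0.0
             for a, shared in zip(universe.aligned_ids, shared_mask)]
        )
        remaining = max(1.0 - copied.sum(), 0.0)
        if new_only:
            copied[~shared_mask] = remaining / new_only
        alpha0[:, j] = copied
    return _floor_and_normalize(alpha0, eps)


def initialize_beta(
    priors: LearnedPriors,
    counts: CountVector,
    universe: FamilyUniverse,
    eps: float = EPSILON,
) -> np.ndarray:
    """Build the length-M initial origin proportions from learned gamma_L.

    For an existing family ``c_j`` known to the learning sample,
    ``beta0_j = sum_i gamma_L[j, i] * y_i / sum(y)`` over aligned families
    present in both samples; existing families new to this sample share
    the remaining mass equally. The vector is floored at ``eps`` and
    renormalized.
    """
    y = counts.reindex(universe.aligned_ids).counts.astype(float)
    total = y.sum()
    if total <= 0:
        raise ValueError("count vector has no reads")

    known_origins = set(priors.learning_origin_ids)
    gamma = priors.gamma_L
    beta0 = np.zeros(universe.n_existing, dtype=float)
    new_only = [
        j for j, c in enumerate(universe.existing_ids) if c not in known_origins
    ]
    for j, origin in enumerate(universe.existing_ids):
        if origin not in known_origins:
            continue
        row = gamma.loc[origin]
        beta0[j] = sum(
            row.get(a, 0.0) * yi for a, yi in zip(universe.aligned_ids, y)
        ) / total
    if new_only:
        remaining = max(1.0 - beta0.sum(), 0.0)
        for j in new_only:
            beta0[j] = remaining / len(new_only)
    floored = np.maximum(beta0, eps)
    return floored / floored.sum()
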