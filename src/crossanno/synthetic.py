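"""Synthetic confusion models, multinomial read samples and truth labeling.

The generator instantiates the same generative structure the correction
model assumes: M existing origin families (the last being the EXTRA
catch-all), N aligned families, a sparse column-stochastic confusion
matrix alpha, a simplex of origin proportions beta, and multinomial read
sampling from the joint law ``P(aligned=i, origin=j) = alpha_ij * beta_j``.
Labeled draws (origin x aligned joint counts) emulate a learning sample;
unlabeled draws are the aligned marginal a real sample shows.

Each real family ``c_j`` has a "self" aligned family — the one its reads
hit when annotation goes right — receiving ``1 - cross_rate`` of its
column in expectation; the rest is cross-annotation mass spread over the
other aligned families. The EXTRA family has no self target: its column
is spread broadly.

``label_read_truth`` implements the truth-labeling rule used to grade a
simulated read's annotation from its genomic placement: the read must
match its reference with identity strictly greater than 95% and overlap a
family's coding sequence by at least 60 bases.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .em import ConfusionModel
from .filtering import EXTRA_FAMILY, FamilyUniverse
from .io import CountVector, JointCountMatrix

DEFAULT_MIN_OVERLAP = 60
DEFAULT_MIN_IDENTITY = 95.0


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic instance.

    ``n_existing`` counts the EXTRA family; ``n_aligned`` must be at least
    ``n_existing - 1`` so every real family can have a self target.
    ``cross_rate`` is the expected off-self mass per real-family column;
    ``concentration`` controls the sharpness of the Dirichlet draws used
    for beta and for the spread portions of alpha columns (1.0 = uniform
    over the simplex).
    """

    n_existing: int = 10
    n_aligned: int = 15
    total_reads: int = 100_000
    cross_rate: float = 0.3
    concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_existing < 2:
            raise ValueError("need at least one real family plus EXTRA")
        if self.n_existing > self.n_aligned + 1:
            raise ValueError("n_existing may exceed n_aligned by at most 1")
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if not 0.0 <= self.cross_rate < 1.0:
            raise ValueError("cross_rate must be in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclasses.dataclass(frozen=True)
class ReadPlacement:
    """A simulated read's best placement on a reference.

    Coordinates are 0-based half-open. ``cds_intervals`` lists labeled
    coding-sequence intervals as (family_id, start, end).
    """

    read_id: str
    start: int
    end: int
    identity: float
    cds_intervals: Tuple[Tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read interval must have end > start")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")


class AmbiguousTruthError(ValueError):
    """Two families' coding sequences overlap the read equally well."""


def _default_universe(config: SimulationConfig) -> FamilyUniverse:
    n_real = config.n_existing - 1
    real = [f"COG{j:04d}" for j in range(1, n_real + 1)]
    noise = [f"ART{i:04d}" for i in range(1, config.n_aligned - n_real + 1)]
    return FamilyUniverse(tuple(real + noise), tuple(real) + (EXTRA_FAMILY,))


def sample_truth(config: SimulationConfig) -> ConfusionModel:
    """Draw a ground-truth confusion model, deterministic given the seed.

    Real family ``c_j``'s column puts a Beta-distributed mass with mean
    ``1 - cross_rate`` on its self aligned family and spreads the rest by
    a Dirichlet draw over the other aligned families; the EXTRA column is
    a broad Dirichlet over all aligned families. beta is a Dirichlet draw
    over the M origins.
    """
    rng = np.random.default_rng(config.seed)
    universe = _default_universe(config)
    n, m = universe.n_aligned, universe.n_existing
    conc = config.concentration
    alpha = np.empty((n, m), dtype=float)

    aligned_index = universe.aligned_index
    for j, origin in enumerate(universe.existing_ids[:-1]):
        self_i = aligned_index[origin]
        if config.cross_rate == 0.0:
            column = np.zeros(n)
            column[self_i] = 1.0
        else:
            # sharpness ~10*conc keeps the self mass concentrated near its mean
            kappa = 10.0 * conc
            self_mass = rng.beta(
                kappa * (1.0 - config.cross_rate), kappa * config.cross_rate
            )
            spread = rng.dirichlet(np.full(n - 1, conc))
            column = np.insert((1.0 - self_mass) * spread, self_i, self_mass)
        alpha[:, j] = column
    alpha[:, m - 1] = rng.dirichlet(np.full(n, conc))  # EXTRA: broad
    beta = rng.dirichlet(np.full(m, conc))
    return ConfusionModel(alpha=alpha, beta=beta, universe=universe)


def simulate_counts(
    model: ConfusionModel,
    total_reads: int,
    seed: int,
    labeled: bool = False,
) -> Union[JointCountMatrix, CountVector]:
    """Multinomially sample reads from the model's joint law.

    ``labeled=True`` returns the full origin x aligned joint counts (a
    learning sample); ``labeled=False`` returns only the aligned marginal.
    Both are derived from the same underlying draw, so the marginal of a
    labeled draw equals the unlabeled result under the same seed.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    rng = np.random.default_rng(seed)
    joint_probs = model.alpha * model.beta[None, :]  # N x M
    flat = rng.multinomial(total_reads, joint_probs.ravel() / joint_probs.sum())
    joint = flat.reshape(joint_probs.shape)  # aligned x origin
    universe = model.universe
    if labeled:
        return JointCountMatrix(
            origin_ids=universe.existing_ids,
            aligned_ids=universe.aligned_ids,
            counts=joint.T,
        )
    return CountVector(universe.aligned_ids, joint.sum(axis=1))


def label_read_truth(
    placement: ReadPlacement,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Optional[str]:
    """Return the correct family for a placed read, or None.

    The read must match with identity strictly greater than
    ``min_identity`` and overlap a family's CDS by at least
    ``min_overlap`` bases (inclusive). When CDSs of several families
    qualify, the largest overlap wins; an exact tie between different
    families raises :class:`AmbiguousTruthError`.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0.0 <= min_identity <= 100.0:
        raise ValueError("min_identity must be in [0, 100]")
    if placement.identity <= min_identity:
        return None
    best: Dict[str, int] = {}
    for family, start, end in placement.cds_intervals:
        overlap = min(placement.end, end) - max(placement.start, start)
        if overlap >= min_overlap:
            best[family] = max(best.get(family, 0), overlap)
    if not best:
        return None
    top = max(best.values())
    winners = sorted(f for f, o in best.items() if o == top)
    if len(winners) > 1:
        raise AmbiguousTruthError(
            f"read {placement.read_id!r}: families {winners} tie at "
            f"{top} bases overlap"
        )
    return winners[0]
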