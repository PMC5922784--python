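"""Best-hit assignment, tallying, artificial-family flagging and the
family universe.

The workflow: every read's alignments are filtered by a similarity-score
cutoff (bit score strictly greater than 66 by default for BLAST output),
the read is assigned to the family of its highest-scoring surviving
alignment, per-family tallies become the observed count vector, and
families with zero support in an RPS-BLAST run filtered at 61 are flagged
as artificial. The estimated truly-existing families are the
non-artificial aligned families plus one reserved ``EXTRA`` family that
absorbs coding sequences outside the catalogue and non-coding sequence.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np

from .io import AlignmentRecord, CountVector, FamilyMap

#: Reserved id for the catch-all origin family (always last in existing_ids).
EXTRA_FAMILY = "EXTRA"

#: Default bit-score cutoff for BLAST(x) alignments of ~100-base reads.
DEFAULT_SCORE_CUTOFF = 66.0

#: Default bit-score cutoff for the RPS-BLAST artificial-family check.
DEFAULT_RPS_CUTOFF = 61.0


@dataclasses.dataclass(frozen=True)
class FamilyUniverse:
    """The N aligned families and M estimated-existing families.

    ``existing_ids`` always ends with :data:`EXTRA_FAMILY`; the other
    existing families are a subset of ``aligned_ids``. M <= N + 1.
    """

    aligned_ids: tuple
    existing_ids: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "aligned_ids", tuple(self.aligned_ids))
        object.__setattr__(self, "existing_ids", tuple(self.existing_ids))
        if not self.aligned_ids or not self.existing_ids:
            raise ValueError("universe needs at least one aligned and one existing family")
        if len(set(self.aligned_ids)) != len(self.aligned_ids):
            raise ValueError("duplicate aligned family ids")
        if len(set(self.existing_ids)) != len(self.existing_ids):
            raise ValueError("duplicate existing family ids")
        if EXTRA_FAMILY in self.aligned_ids:
            raise ValueError(
                f"reserved id {EXTRA_FAMILY!r} collides with an aligned family"
            )
        if self.existing_ids[-1] != EXTRA_FAMILY:
            raise ValueError(f"existing_ids must end with {EXTRA_FAMILY!r}")
        if self.existing_ids.count(EXTRA_FAMILY) != 1:
            raise ValueError(f"{EXTRA_FAMILY!r} must appear exactly once")

    @property
    def n_aligned(self) -> int:
        return len(self.aligned_ids)

    @property
    def n_existing(self) -> int:
        return len(self.existing_ids)

    @property
    def aligned_index(self) -> Dict[str, int]:
        return {f: i for i, f in enumerate(self.aligned_ids)}

    @property
    def existing_index(self) -> Dict[str, int]:
        return {f: j for j, f in enumerate(self.existing_ids)}


def assign_best_hit(
    records: Iterable[AlignmentRecord],
    family_map: FamilyMap,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    *,
    filter_mode: str = "bitscore",
    evalue_cutoff: Optional[float] = None,
) -> Dict[str, str]:
    """Assign each read to the family of its best retained alignment.

    With ``filter_mode="bitscore"`` an alignment survives iff its bit score
    is strictly greater than ``score_cutoff``; with ``filter_mode="evalue"``
    iff its e-value is at most ``evalue_cutoff`` (the conventional baseline
    filters, e.g. 1e-3 or 1e-5). Among survivors the best hit is the
    highest bit score, ties broken by lowest e-value, then lexicographically
    smallest subject id, so the result does not depend on input order.
    Reads with no surviving alignment are absent from the result.

    A surviving alignment whose subject is missing from ``family_map``
    raises ``KeyError`` — a silent drop would bias the counts.
    """
    if score_cutoff < 0:
        raise ValueError("score_cutoff must be >= 0")
    if filter_mode not in ("bitscore", "evalue"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    if filter_mode == "evalue" and evalue_cutoff is None:
        raise ValueError("evalue filter mode requires evalue_cutoff")

    best: Dict[str, AlignmentRecord] = {}
    for record in records:
        if filter_mode == "bitscore":
            if not record.bit_score > score_cutoff:
                continue
        else:
            if record.e_value > evalue_cutoff:
                continue
        if record.subject_id not in family_map:
            raise KeyError(
                f"subject {record.subject_id!r} (read {record.read_id!r}) "
                "is not in the family map"
            )
        incumbent = best.get(record.read_id)
        if incumbent is None or _hit_key(record) < _hit_key(incumbent):
            best[record.read_id] = record
    return {read: family_map[rec.subject_id] for read, rec in best.items()}


def _hit_key(record: AlignmentRecord):
    # sort key: best hit first (max bit score, then min e-value, then subject)
    return (-record.bit_score, record.e_value, record.subject_id)


def tally_family_counts(assignments: Mapping[str, str]) -> CountVector:
    """Tally read assignments into a per-family count vector.

    Families come out sorted lexicographically; the counts sum to the
    number of assigned reads.
    """
    tally = Counter(assignments.values())
    families = sorted(tally)
    return CountVector(
        tuple(families), np.array([tally[f] for f in families], dtype=np.int64)
    )


def flag_artificial_families(
    blast_counts: CountVector,
    rps_counts: CountVector,
    rps_cutoff: float = DEFAULT_RPS_CUTOFF,
) -> Set[str]:
    """Families in the BLAST tally without RPS-BLAST support.

    ``rps_counts`` must come from the same assign/tally path applied to
    RPS-BLAST alignments filtered at ``rps_cutoff`` (the parameter is
    documentation of that contract; the filtering itself happened
    upstream). A family is artificial when its RPS count is zero or it is
    absent from the RPS tally entirely.
    """
    del rps_cutoff  # applied upstream when rps_counts was built
    rps = rps_counts.as_dict()
    return {f for f in blast_counts.family_ids if rps.get(f, 0) == 0}


def build_family_universe(
    blast_counts: CountVector, artificial: Set[str]
) -> FamilyUniverse:
    """Assemble aligned and estimated-existing family lists.

    Aligned families are every family in the BLAST tally (reads assigned
    to artificial families keep their place in the N-vector); existing
    families are the non-artificial ones plus the ``EXTRA`` catch-all, so
    M = N - |artificial| + 1.
    """
    aligned = tuple(blast_counts.family_ids)
    if EXTRA_FAMILY in aligned:
        raise ValueError(
            f"reserved id {EXTRA_FAMILY!r} collides with a real aligned "
            "family; rename the input family"
        )
    unknown = artificial - set(aligned)
    if unknown:
        raise ValueError(f"artificial families not in the BLAST tally: {sorted(unknown)}")
    real = sorted(set(aligned) - artificial)
    if not real:
        raise ValueError(
            "every aligned family is artificial; no existing families to model"
        )
    return FamilyUniverse(aligned, tuple(real) + (EXTRA_FAMILY,))
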