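"""Readers and writers for the on-disk artifacts of the correction pipeline.

All formats are plain tab-separated text:

* BLAST tabular alignments (``-outfmt 6``, 12 columns, extra columns ignored);
* subject-to-family maps (2 columns: subject_id, family_id);
* per-family count vectors (``family_id``, ``count``);
* joint origin-by-aligned count matrices in long format
  (``origin_id``, ``aligned_id``, ``count``);
* corrected profiles (``family_id``, ``beta_hat``, ``count_hat``).

Family and read identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

#: A many-to-one mapping from database subject (protein) id to family id.
FamilyMap = Dict[str, str]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclasses.dataclass(frozen=True)
class AlignmentRecord:
    """One row of a BLAST tabular alignment.

    Only the fields the best-hit assignment needs are retained; the
    positional columns (mismatches, gap opens, coordinates) are parsed for
    validation but not stored.
    """

    read_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )
        if self.alignment_length < 1:
            raise ValueError(
                f"alignment_length must be >= 1, got {self.alignment_length}"
            )
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if not np.isfinite(self.bit_score):
            raise ValueError(f"bit_score must be finite, got {self.bit_score}")


@dataclasses.dataclass(frozen=True)
class CountVector:
    """Observed best-hit read counts over aligned families.

    ``counts[i]`` is the number of reads whose retained best hit falls in
    ``family_ids[i]``.
    """

    family_ids: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        if len(self.family_ids) != counts.shape[0]:
            raise ValueError("family_ids and counts must have equal length")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("duplicate family ids in count vector")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> Dict[str, int]:
        return {f: int(c) for f, c in zip(self.family_ids, self.counts)}

    def reindex(self, family_ids: Sequence[str]) -> "CountVector":
        """Return counts in the given family order, zero-filling absentees.

        Families present here but absent from ``family_ids`` are rejected:
        silently dropping observed reads would bias every downstream
        proportion.
        """
        wanted = set(family_ids)
        extra = [f for f in self.family_ids if f not in wanted]
        if extra:
            raise ValueError(f"count vector has families outside target order: {extra}")
        lookup = self.as_dict()
        return CountVector(
            tuple(family_ids),
            np.array([lookup.get(f, 0) for f in family_ids], dtype=np.int64),
        )


@dataclasses.dataclass(frozen=True)
class JointCountMatrix:
    """Learning-sample counts of (origin family, aligned family) read pairs.

    Rows are origin (true) families — the reserved ``EXTRA`` id may appear
    among them — and columns are aligned families.
    """

    origin_ids: tuple
    aligned_ids: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "origin_ids", tuple(self.origin_ids))
        object.__setattr__(self, "aligned_ids", tuple(self.aligned_ids))
        if counts.shape != (len(self.origin_ids), len(self.aligned_ids)):
            raise ValueError("counts shape does not match id lists")
        for name, ids in (("origin", self.origin_ids), ("aligned", self.aligned_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} family ids")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    def aligned_marginal(self) -> CountVector:
        """Column sums: the count vector an unlabeled draw would show."""
        return CountVector(self.aligned_ids, self.counts.sum(axis=0))


def parse_blast_tabular(path: PathLike) -> List[AlignmentRecord]:
    """Parse a 12-column BLAST tabular (``-outfmt 6``) file.

    Comment lines (leading ``#``) and blank lines are skipped. Columns
    beyond the standard 12 are ignored. Raises :class:`ParseError` naming
    the offending line on short rows or non-numeric score fields.
    """
    records: List[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                record = AlignmentRecord(
                    read_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(record)
    return records


def load_family_map(path: PathLike) -> FamilyMap:
    """Load a 2-column (subject_id, family_id) TSV into a dict.

    A subject listed twice with conflicting families is an error; an exact
    duplicate row is tolerated.
    """
    mapping: FamilyMap = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, found {len(fields)}"
                )
            subject, family = fields[0], fields[1]
            if subject in mapping and mapping[subject] != family:
                raise ParseError(
                    f"{path}: line {lineno}: subject {subject!r} maps to both "
                    f"{mapping[subject]!r} and {family!r}"
                )
            mapping[subject] = family
    return mapping


def write_family_map(mapping: FamilyMap, path: PathLike) -> None:
    with open(path, "w") as handle:
        for subject in sorted(mapping):
            handle.write(f"{subject}\t{mapping[subject]}\n")


def load_count_vector(path: PathLike) -> CountVector:
    """Load a (family_id, count) TSV with a header row."""
    frame = pd.read_csv(path, sep="\t", dtype={"family_id": str, "count": np.int64})
    if list(frame.columns[:2]) != ["family_id", "count"]:
        raise ParseError(f"{path}: expected header 'family_id\\tcount'")
    return CountVector(tuple(frame["family_id"]), frame["count"].to_numpy())


def write_count_vector(vector: CountVector, path: PathLike) -> None:
    frame = pd.DataFrame(
        {"family_id": list(vector.family_ids), "count": vector.counts}
    )
    frame.to_csv(path, sep="\t", index=False)


def load_joint_counts(path: PathLike) -> JointCountMatrix:
    """Load a long-format (origin_id, aligned_id, count) TSV with header.

    Absent pairs are zero; a pair listed twice is an error.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype={"origin_id": str, "aligned_id": str, "count": np.int64}
    )
    if list(frame.columns[:3]) != ["origin_id", "aligned_id", "count"]:
        raise ParseError(
            f"{path}: expected header 'origin_id\\taligned_id\\tcount'"
        )
    if frame.duplicated(subset=["origin_id", "aligned_id"]).any():
        raise ParseError(f"{path}: duplicate (origin_id, aligned_id) pairs")
    wide = (
        frame.pivot(index="origin_id", columns="aligned_id", values="count")
        .fillna(0)
        .astype(np.int64)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return JointCountMatrix(
        tuple(wide.index), tuple(wide.columns), wide.to_numpy()
    )


def write_joint_counts(joint: JointCountMatrix, path: PathLike) -> None:
    """Write long-format joint counts; zero cells are omitted."""
    rows = []
    for j, origin in enumerate(joint.origin_ids):
        for i, aligned in enumerate(joint.aligned_ids):
            count = int(joint.counts[j, i])
            if count:
                rows.append((origin, aligned, count))
    frame = pd.DataFrame(rows, columns=["origin_id", "aligned_id", "count"])
    frame.to_csv(path, sep="\t", index=False)


def write_profile(profile, path: PathLike) -> None:
    """Serialize a fitted profile (one row per existing family, incl. EXTRA).

    ``beta_hat`` is written at full float precision (repr round-trip).
    """
    with open(path, "w") as handle:
        handle.write("family_id\tbeta_hat\tcount_hat\n")
        for family, beta, count in zip(
            profile.existing_ids, profile.beta_hat, profile.count_hat
        ):
            handle.write(f"{family}\t{float(beta)!r}\t{int(count)}\n")


def load_profile(path: PathLike):
    """Read back a profile TSV written by :func:`write_profile`."""
    from .em import ProfileEstimate  # local import avoids a cycle

    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"family_id": str, "beta_hat": np.float64, "count_hat": np.int64},
    )
    if list(frame.columns[:3]) != ["family_id", "beta_hat", "count_hat"]:
        raise ParseError(
            f"{path}: expected header 'family_id\\tbeta_hat\\tcount_hat'"
        )
    return ProfileEstimate(
        existing_ids=tuple(frame["family_id"]),
        beta_hat=frame["beta_hat"].to_numpy(),
        count_hat=frame["count_hat"].to_numpy(),
        total_reads=int(frame["count_hat"].sum()),
        validate_total=False,
    )
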