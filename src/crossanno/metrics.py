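"""Profile-accuracy measurements and cross-annotation accounting.

Four measures compare an estimated origin-proportion vector ``beta_hat``
against the truth ``beta``, each summed over the real existing families
only (the catch-all EXTRA family, last in the vector, is excluded — its
"true" proportion is not a family abundance):

* RRMSE — root relative mean square error,
  ``sqrt( 1/(M-1) * sum_j ((bh_j - b_j)/b_j)^2 )``;
* AVGRE — average relative error, ``1/(M-1) * sum_j |bh_j - b_j|/b_j``;
* MAXRE — maximum relative error, ``max_j |bh_j - b_j|/b_j``;
* DTV — total variation distance, ``1/2 * sum_j |bh_j - b_j|``.

The cross-annotation summary reproduces the two-sided accounting of
best-hit misassignment: for each family, how many assigned reads came
from elsewhere (``misassigned_in``) and how many of its true reads went
elsewhere (``misassigned_out``).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, List, Sequence, Tuple

import numpy as np


@dataclasses.dataclass(frozen=True)
class AccuracyReport:
    rrmse: float
    avgre: float
    maxre: float
    dtv: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class CrossAnnotationRow:
    """Per-family best-hit accounting.

    ``true_count`` reads truly originate from the family,
    ``assigned_count`` were best-hit assigned to it, ``correct_count``
    both. ``misassigned_in = assigned - correct`` reads were assigned
    here but belong elsewhere; ``misassigned_out = true - correct`` reads
    from here were assigned elsewhere.
    """

    family_id: str
    true_count: int
    assigned_count: int
    correct_count: int
    misassigned_in: int
    misassigned_out: int

    def __post_init__(self) -> None:
        if min(self.true_count, self.assigned_count, self.correct_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.correct_count > min(self.true_count, self.assigned_count):
            raise ValueError(
                f"{self.family_id}: correct_count exceeds true or assigned count"
            )


def profile_accuracy(
    beta_hat: Sequence[float], beta_true: Sequence[float]
) -> AccuracyReport:
    """Compute RRMSE, AVGRE, MAXRE and DTV over the real families.

    Both vectors must be on the simplex in the same family order with the
    EXTRA family last; entries ``beta_true[0..M-2]`` must be positive
    (relative errors are undefined at zero).
    """
    bh = np.asarray(beta_hat, dtype=float)
    bt = np.asarray(beta_true, dtype=float)
    if bh.shape != bt.shape or bh.ndim != 1:
        raise ValueError("beta_hat and beta_true must be equal-length vectors")
    if bh.shape[0] < 2:
        raise ValueError("need at least one real family plus EXTRA")
    for name, v in (("beta_hat", bh), ("beta_true", bt)):
        if (v < -1e-12).any() or not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{name} is not on the simplex")
    bh, bt = bh[:-1], bt[:-1]  # drop EXTRA
    zero = np.flatnonzero(bt <= 0)
    if zero.size:
        raise ValueError(
            f"true proportion is zero at indices {zero.tolist()}; "
            "relative errors are undefined"
        )
    rel = (bh - bt) / bt
    return AccuracyReport(
        rrmse=float(np.sqrt(np.mean(rel**2))),
        avgre=float(np.mean(np.abs(rel))),
        maxre=float(np.max(np.abs(rel))),
        dtv=float(0.5 * np.sum(np.abs(bh - bt))),
    )


def cross_annotation_summary(
    rows: Iterable[Tuple[str, int, int, int]]
) -> List[CrossAnnotationRow]:
    """Expand (family, true, assigned, correct) tuples into the two-sided
    misassignment accounting, with a TOTAL row appended."""
    out: List[CrossAnnotationRow] = []
    for family_id, true_count, assigned_count, correct_count in rows:
        out.append(
            CrossAnnotationRow(
                family_id=family_id,
                true_count=int(true_count),
                assigned_count=int(assigned_count),
                correct_count=int(correct_count),
                misassigned_in=int(assigned_count) - int(correct_count),
                misassigned_out=int(true_count) - int(correct_count),
            )
        )
    if not out:
        raise ValueError("no rows to summarize")
    out.append(
        CrossAnnotationRow(
            family_id="TOTAL",
            true_count=sum(r.true_count for r in out),
            assigned_count=sum(r.assigned_count for r in out),
            correct_count=sum(r.correct_count for r in out),
            misassigned_in=sum(r.misassigned_in for r in out),
            misassigned_out=sum(r.misassigned_out for r in out),
        )
    )
    return out


def write_accuracy_report(report: AccuracyReport, path) -> None:
    with open(path, "w") as handle:
        handle.write("measure\tvalue\n")
        for key, value in report.as_dict().items():
            handle.write(f"{key}\t{value!r}\n")


def write_cross_annotation(rows: Sequence[CrossAnnotationRow], path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "family_id\ttrue_count\tassigned_count\tcorrect_count"
            "\tmisassigned_in\tmisassigned_out\n"
        )
        for r in rows:
            handle.write(
                f"{r.family_id}\t{r.true_count}\t{r.assigned_count}"
                f"\t{r.correct_count}\t{r.misassigned_in}\t{r.misassigned_out}\n"
            )
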