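"""Sequential (dynamic) classification with credible-interval allocation.

Individuals are scanned occasion by occasion. Under the credible-interval
scheme an individual is called a case only when the whole CrI of their
case-membership probability lies above the cutoff, a control only when it
lies wholly below, and left indeterminate otherwise; the point scheme
compares the point estimate alone and never leaves anyone indeterminate.
The first non-indeterminate allocation freezes: later occasions cannot
change it. The cutoff is the ROC threshold nearest the top-left corner,
minimizing d^2 = (1 - sensitivity)^2 + (1 - specificity)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DEFAULT_GRID, OccasionGrid
from .loda import ProbabilitySeries

SCHEMES = ("cri", "point")


@dataclass(frozen=True)
class AllocationConfig:
    cutoff: float
    scheme: str = "cri"
    cri_level: float = 0.99
    first_decision_occasion: int = 1

    def __post_init__(self):
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must be strictly inside (0, 1)")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class ClassificationOutcome:
    person_id: object
    final_label: str  # case | control | indeterminate
    decision_occasion: int | None
    decision_age: float | None  # upper age bound of the decision occasion
    series: ProbabilitySeries | None = None


def select_cutoff(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """d^2-optimal ROC cutoff over candidate thresholds.

    Candidates are midpoints between adjacent sorted unique probabilities
    plus 0 and 1; the prediction rule is case iff p > threshold. Ties in d^2
    are broken toward the threshold nearest 0.5 (then the smaller one).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in ("U", "S", "O"):
        y = y == "case"
    y = y.astype(bool)
    if not np.all(np.isfinite(p)):
        raise ValueError("probabilities must be finite")
    if y.all() or not y.any():
        raise ValueError("both case and control labels are required")
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cand = np.unique(np.concatenate([[0.0, 1.0], mids]))
    pred = p[:, None] > cand[None, :]  # (n, k)
    n_case = y.sum()
    n_control = (~y).sum()
    sens = pred[y].sum(axis=0) / n_case
    spec = (~pred[~y]).sum(axis=0) / n_control
    d2 = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    best = d2.min()
    tied = cand[np.isclose(d2, best, rtol=0, atol=1e-12)]
    order = np.lexsort((tied, np.abs(tied - 0.5)))
    return float(tied[order[0]])


def allocate(point: float, lower: float, upper: float, cfg: AllocationConfig) -> str:
    """Allocate one occasion's probability entry to case/control/indeterminate."""
    if lower > upper:
        raise ValueError("malformed credible interval: lower > upper")
    if cfg.scheme == "point":
        return "case" if point > cfg.cutoff else "control"
    if lower > cfg.cutoff:
        return "case"
    if upper < cfg.cutoff:
        return "control"
    return "indeterminate"


def classify_sequential(
    series: ProbabilitySeries,
    cfg: AllocationConfig,
    grid: OccasionGrid = DEFAULT_GRID,
) -> ClassificationOutcome:
    """Scan occasions in order; the first non-indeterminate allocation freezes."""
    for j in range(cfg.first_decision_occasion, series.n_occasions + 1):
        label = allocate(
            float(series.point[j - 1]),
            float(series.lower[j - 1]),
            float(series.upper[j - 1]),
            cfg,
        )
        if label != "indeterminate":
            return ClassificationOutcome(
                person_id=series.person_id,
                final_label=label,
                decision_occasion=j,
                decision_age=grid.occasion(j).age_hi,
                series=series,
            )
    return ClassificationOutcome(series.person_id, "indeterminate", None, None, series)


def label_at_occasion(outcome: ClassificationOutcome, occasion: int) -> str:
    """The frozen label as of a given occasion (indeterminate if undecided)."""
    if outcome.decision_occasion is not None and outcome.decision_occasion <= occasion:
        return outcome.final_label
    return "indeterminate"
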