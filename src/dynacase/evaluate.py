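"""Five-fold cross-validated evaluation of the case-ascertainment approaches.

For each fold the group MGLMMs are fit on the remaining folds, probability
series are computed for the held-out individuals, a d^2-optimal cutoff is
selected on the training data, and individuals are classified sequentially.
A confusion matrix that keeps the indeterminate category is tabulated after
the last occasion, and accuracy measures (sensitivity, specificity, PPV,
NPV with Wilson 95% CIs, AUC, probability of correct classification,
proportion indeterminate, mean classification time) are computed per fold
and averaged. The same confusion/accuracy code path scores the deterministic
definition (with an empty indeterminate column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .dynclass import (
    AllocationConfig,
    ClassificationOutcome,
    classify_sequential,
    label_at_occasion,
    select_cutoff,
)
from .grid import DEFAULT_GRID, OccasionGrid
from .loda import ProbabilitySeries, compute_probability_series
from .mglmm import JA_UTILIZATION_MODEL, McmcConfig, MGLMMSpec, fit_mglmm
from .simdata import IndividualRecord

_log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# folds


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Simple random partition into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed the cohort size")
    rng = np.random.default_rng(seed)
    fold = np.arange(n) % k
    return fold[rng.permutation(n)]


# ---------------------------------------------------------------------------
# confusion and accuracy


@dataclass
class ConfusionWithIndeterminate:
    tp: int = 0
    fn: int = 0
    ind_case: int = 0
    tn: int = 0
    fp: int = 0
    ind_control: int = 0

    @classmethod
    def from_labels(cls, truth, assigned) -> "ConfusionWithIndeterminate":
        c = cls()
        for t, a in zip(truth, assigned):
            if t == "case":
                if a == "case":
                    c.tp += 1
                elif a == "control":
                    c.fn += 1
                else:
                    c.ind_case += 1
            elif t == "control":
                if a == "control":
                    c.tn += 1
                elif a == "case":
                    c.fp += 1
                else:
                    c.ind_control += 1
            else:
                raise ValueError(f"unknown truth label {t!r}")
        return c

    def __add__(self, other: "ConfusionWithIndeterminate") -> "ConfusionWithIndeterminate":
        return ConfusionWithIndeterminate(
            self.tp + other.tp,
            self.fn + other.fn,
            self.ind_case + other.ind_case,
            self.tn + other.tn,
            self.fp + other.fp,
            self.ind_control + other.ind_control,
        )

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn + self.ind_case

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp + self.ind_control

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


def _rate(count: int, denom: int) -> tuple[float, tuple[float, float]]:
    if denom == 0:
        return float("nan"), (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, denom, alpha=0.05, method="wilson")
    return count / denom, (float(lo), float(hi))


@dataclass
class AccuracyReport:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    pcc: float
    prop_indeterminate: float
    variant: str
    auc: float | None = None
    mean_classification_time: float | None = None
    fold: object = None

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "pcc": self.pcc,
            "prop_indeterminate": self.prop_indeterminate,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.mean_classification_time is not None:
            d["mean_classification_time"] = self.mean_classification_time
        return d


def accuracy_measures(
    conf: ConfusionWithIndeterminate, variant: str = "all_data"
) -> AccuracyReport:
    """Accuracy rates with Wilson 95% CIs.

    ``all_data`` keeps indeterminates in the sensitivity/specificity (and
    PCC) denominators; ``classified_only`` removes them. PPV and NPV never
    include indeterminates (an indeterminate individual is not a labelled
    positive or negative).
    """
    if variant not in ("all_data", "classified_only"):
        raise ValueError(f"unknown variant {variant!r}")
    if conf.n_cases == 0 or conf.n_controls == 0:
        raise ValueError("confusion must contain both true cases and true controls")
    if variant == "all_data":
        sens_den = conf.n_cases
        spec_den = conf.n_controls
        total = conf.n_total
    else:
        sens_den = conf.tp + conf.fn
        spec_den = conf.tn + conf.fp
        total = conf.tp + conf.fn + conf.tn + conf.fp
    sens, sens_ci = _rate(conf.tp, sens_den)
    spec, spec_ci = _rate(conf.tn, spec_den)
    ppv, ppv_ci = _rate(conf.tp, conf.tp + conf.fp)
    npv, npv_ci = _rate(conf.tn, conf.tn + conf.fn)
    pcc = (conf.tp + conf.tn) / total if total else float("nan")
    prop_ind = (conf.ind_case + conf.ind_control) / conf.n_total
    return AccuracyReport(
        sens, sens_ci, spec, spec_ci, ppv, ppv_ci, npv, npv_ci,
        pcc, prop_ind, variant,
    )


def auc(probabilities: np.ndarray, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties averaged."""
    y = np.asarray(labels)
    if y.dtype.kind in ("U", "S", "O"):
        y = y == "case"
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("both classes are required to compute an AUC")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def mean_classification_time(outcomes: list[ClassificationOutcome]) -> float:
    """Mean decision age (years) over classified outcomes; nan if none."""
    ages = [o.decision_age for o in outcomes if o.final_label != "indeterminate"]
    if not ages:
        return float("nan")
    return float(np.mean(ages))


# ---------------------------------------------------------------------------
# deterministic-definition evaluation


def evaluate_deterministic(
    claims_by_person: dict,
    truth_by_person: dict,
    rule,
) -> tuple[AccuracyReport, ConfusionWithIndeterminate]:
    """Score the deterministic definition through the same confusion path."""
    from .casedef import classify_deterministic

    truth, assigned = [], []
    for pid, truth_label in truth_by_person.items():
        truth.append(truth_label)
        assigned.append(classify_deterministic(claims_by_person.get(pid, []), rule))
    conf = ConfusionWithIndeterminate.from_labels(truth, assigned)
    return accuracy_measures(conf, "all_data"), conf


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldResult:
    fold: int
    cutoff: float
    confusion: ConfusionWithIndeterminate
    all_data: AccuracyReport
    classified_only: AccuracyReport
    auc: float
    mean_classification_time: float
    outcomes: list[ClassificationOutcome] = field(repr=False, default_factory=list)
    series: list[ProbabilitySeries] = field(repr=False, default_factory=list)


@dataclass
class CVResult:
    fold_ids: np.ndarray
    folds: list[FoldResult]
    averaged: dict
    pooled_confusion: ConfusionWithIndeterminate
    pooled_all_data: AccuracyReport
    pooled_classified_only: AccuracyReport
    auc: float
    mean_classification_time: float
    evolution: pd.DataFrame

    @property
    def outcomes(self) -> list[ClassificationOutcome]:
        return [o for f in self.folds for o in f.outcomes]

    @property
    def series(self) -> list[ProbabilitySeries]:
        return [s for f in self.folds for s in f.series]


def _fold_seed(seed: int, fold: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, fold, tag]).generate_state(1)[0] & 0x7FFFFFFF)


def _evolution_table(
    outcomes: list[ClassificationOutcome],
    truth: dict,
    n_occasions: int,
) -> pd.DataFrame:
    rows = []
    for j in range(1, n_occasions + 1):
        assigned = [label_at_occasion(o, j) for o in outcomes]
        t = [truth[o.person_id] for o in outcomes]
        conf = ConfusionWithIndeterminate.from_labels(t, assigned)
        try:
            rep = accuracy_measures(conf, "all_data")
            sens, spec = rep.sensitivity, rep.specificity
        except ValueError:
            sens = spec = float("nan")
        ppv = conf.tp / (conf.tp + conf.fp) if (conf.tp + conf.fp) else float("nan")
        rows.append(
            {
                "occasion": j,
                "prop_unclassified": (conf.ind_case + conf.ind_control) / conf.n_total,
                "sensitivity": sens,
                "specificity": spec,
                "ppv": ppv,
            }
        )
    return pd.DataFrame(rows)


def run_cross_validation(
    cohort: list[IndividualRecord],
    spec: MGLMMSpec = JA_UTILIZATION_MODEL,
    mcmc: McmcConfig = McmcConfig(),
    approach: str = "random_effects",
    scheme: str = "cri",
    cri_level: float = 0.99,
    priors: tuple[float, float] = (0.5, 0.5),
    k: int = 5,
    seed: int = 0,
    cutoff: object = "auto",
    cutoff_occasion: int | None = None,
    grid: OccasionGrid = DEFAULT_GRID,
    n_nodes: int = 31,
) -> CVResult:
    """K-fold cross-validated dynamic classification.

    Per fold: fit case/control MGLMMs on the training folds, compute
    held-out probability series at all occasions, select the d^2-optimal
    cutoff on the training folds' final-occasion probabilities (unless a
    numeric ``cutoff`` is given), classify sequentially and tabulate the
    confusion after the last occasion.
    """
    n = len(cohort)
    fold_ids = kfold_split(n, k=k, seed=seed)
    truth = {ind.person_id: ind.group for ind in cohort}
    J = grid.n_occasions
    if cutoff_occasion is None:
        cutoff_occasion = J

    folds: list[FoldResult] = []
    for f in range(k):
        test = [ind for ind, fid in zip(cohort, fold_ids) if fid == f]
        train = [ind for ind, fid in zip(cohort, fold_ids) if fid != f]
        train_cases = [ind for ind in train if ind.group == "case"]
        train_controls = [ind for ind in train if ind.group == "control"]
        if not train_cases or not train_controls:
            raise ValueError(f"training set for fold {f} lacks one of the groups")
        _log.info("fold %d: fitting group models (train n=%d)", f, len(train))
        draws_case = fit_mglmm(
            train_cases, spec, replace(mcmc, seed=_fold_seed(seed, f, 1)), grid
        )
        draws_control = fit_mglmm(
            train_controls, spec, replace(mcmc, seed=_fold_seed(seed, f, 2)), grid
        )

        if cutoff == "auto":
            train_series = compute_probability_series(
                train, draws_case, draws_control, approach, priors, cri_level,
                grid, n_nodes,
                occasions="final" if cutoff_occasion == J else "all",
            )
            train_p = np.array([s.point[cutoff_occasion - 1] for s in train_series])
            train_y = np.array([ind.group for ind in train])
            fold_cutoff = select_cutoff(train_p, train_y)
            fold_cutoff = min(max(fold_cutoff, 1e-6), 1 - 1e-6)
        else:
            fold_cutoff = float(cutoff)

        series = compute_probability_series(
            test, draws_case, draws_control, approach, priors, cri_level,
            grid, n_nodes,
        )
        cfg = AllocationConfig(cutoff=fold_cutoff, scheme=scheme, cri_level=cri_level)
        outcomes = [classify_sequential(s, cfg, grid) for s in series]
        conf = ConfusionWithIndeterminate.from_labels(
            [truth[o.person_id] for o in outcomes],
            [o.final_label for o in outcomes],
        )
        test_p = np.array([s.point[J - 1] for s in series])
        test_y = np.array([ind.group for ind in test])
        fold_auc = auc(test_p, test_y)
        folds.append(
            FoldResult(
                fold=f,
                cutoff=fold_cutoff,
                confusion=conf,
                all_data=accuracy_measures(conf, "all_data"),
                classified_only=accuracy_measures(conf, "classified_only"),
                auc=fold_auc,
                mean_classification_time=mean_classification_time(outcomes),
                outcomes=outcomes,
                series=series,
            )
        )

    pooled_conf = ConfusionWithIndeterminate()
    for fr in folds:
        pooled_conf = pooled_conf + fr.confusion
    all_outcomes = [o for fr in folds for o in fr.outcomes]
    all_series = [s for fr in folds for s in fr.series]
    pooled_p = np.array([s.point[J - 1] for s in all_series])
    pooled_y = np.array([truth[s.person_id] for s in all_series])

    def _nanmean(vals):
        vals = [v for v in vals if v == v]  # drop nan
        return float(np.mean(vals)) if vals else float("nan")

    averaged = {}
    for variant in ("all_data", "classified_only"):
        for metric in ("sensitivity", "specificity", "ppv", "npv", "pcc"):
            averaged[f"{metric}_{variant}"] = _nanmean(
                [getattr(getattr(fr, variant), metric) for fr in folds]
            )
    averaged["auc"] = _nanmean([fr.auc for fr in folds])
    averaged["prop_indeterminate"] = _nanmean(
        [fr.all_data.prop_indeterminate for fr in folds]
    )
    averaged["mean_classification_time"] = _nanmean(
        [fr.mean_classification_time for fr in folds]
    )

    return CVResult(
        fold_ids=fold_ids,
        folds=folds,
        averaged=averaged,
        pooled_confusion=pooled_conf,
        pooled_all_data=accuracy_measures(pooled_conf, "all_data"),
        pooled_classified_only=accuracy_measures(pooled_conf, "classified_only"),
        auc=auc(pooled_p, pooled_y),
        mean_classification_time=mean_classification_time(all_outcomes),
        evolution=_evolution_table(all_outcomes, truth, J),
    )


def mean_probability_trajectories(
    series: list[ProbabilitySeries], truth: dict
) -> dict[str, np.ndarray]:
    """Mean point-estimate P(case) per occasion, split by gold-standard group."""
    out = {}
    for group in ("case", "control"):
        pts = [s.point for s in series if truth[s.person_id] == group]
        out[group] = np.mean(pts, axis=0) if pts else np.array([])
    return out


def plot_evolution(evolution: pd.DataFrame, path: str) -> None:
    """Save the accuracy-evolution curves (proportion unclassified,
    sensitivity, specificity, PPV by occasion) as a figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in ("prop_unclassified", "sensitivity", "specificity", "ppv"):
        ax.plot(evolution["occasion"], evolution[col], marker="o", label=col)
    ax.set_xlabel("measurement occasion")
    ax.set_ylabel("value")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
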