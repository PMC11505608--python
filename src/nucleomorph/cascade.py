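"""Subtractive-selection phenotype cascade.

Five nuclear-envelope staining phenotypes are assigned by an ordered decision
cascade.  Each step compares one 3D shape feature against a threshold that is
*relative to the control population*: threshold = multiplier x mean of the
feature over the control cells **not yet assigned** a phenotype by earlier
steps (the "running mean").  A cell takes the phenotype of the first step
whose criterion it meets; cells surviving all steps are split by a final
two-way rule.

Shipped default cascade (features from :mod:`nucleomorph.shape3d`):

1. ``punctate``     — object count high (multiplier 3.3): many disconnected
   stained spots.
2. ``invagination`` — ``moment3`` low: interior sheets add compact volume to
   the envelope, pulling det(Cov)/V² down.
3. ``diffuse``      — ``flatness`` low: a complete hollow shell has nearly
   isotropic depth, unlike the flatter bowl-like remainder.
4. final split      — ``moment3`` high -> ``ring``, else ``incomplete``: an
   envelope that fails to surround the nucleus is flatter and scores a lower
   moment3 than the intact ring.

Every direction and multiplier is configurable.  Boundary equality meets a
"high" criterion (>=) and fails a "low" criterion (strictly <).

The classifier follows the scikit-learn estimator protocol:
``CascadeClassifier(config).fit(control_measurements).predict(measurements)``.
``fit`` performs the control-population calibration, ``predict`` assigns one
phenotype per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportions_ztest

from .shape3d import Shape3DMeasurements

PHENOTYPES = ("ring", "diffuse", "punctate", "invagination", "incomplete")
NORMAL_PHENOTYPES = frozenset({"ring", "diffuse"})
ABNORMAL_PHENOTYPES = frozenset({"punctate", "invagination", "incomplete"})
GROUP_OF_PHENOTYPE = {p: ("normal" if p in NORMAL_PHENOTYPES else "abnormal") for p in PHENOTYPES}

_CASCADE_FEATURES = (
    "n_objects", "moment1", "moment2", "moment3", "moment4", "moment5",
    "flatness", "elongation",
)


@dataclass(frozen=True)
class CascadeStep:
    """One decision: ``feature`` compared ``direction`` against multiplier x running mean."""

    feature: str
    direction: str  # "high" or "low"
    multiplier: float
    assigns: str

    def __post_init__(self) -> None:
        if self.feature not in _CASCADE_FEATURES:
            raise ValueError(f"unknown cascade feature {self.feature!r}")
        if self.direction not in ("high", "low"):
            raise ValueError(f"direction must be 'high' or 'low', got {self.direction!r}")
        if not self.multiplier > 0:
            raise ValueError(f"multiplier must be positive, got {self.multiplier}")

    def meets(self, value: float, threshold: float) -> bool:
        """Equality meets a 'high' criterion and fails a 'low' criterion."""
        return value >= threshold if self.direction == "high" else value < threshold


@dataclass(frozen=True)
class CascadeConfig:
    """Ordered subtractive steps plus the final two-way split.

    ``steps`` assign (in order) punctate, invagination and diffuse; ``final``
    assigns its ``assigns`` phenotype to cells meeting it and
    ``final_otherwise`` to the rest.
    """

    steps: tuple[CascadeStep, ...]
    final: CascadeStep
    final_otherwise: str = "incomplete"

    def __post_init__(self) -> None:
        assigned = [s.assigns for s in self.steps] + [self.final.assigns, self.final_otherwise]
        if sorted(assigned) != sorted(PHENOTYPES):
            raise ValueError(
                f"cascade must assign each of {PHENOTYPES} exactly once, got {assigned}"
            )


#: Multipliers below (other than the published 3.3 for the object-count step)
#: were fixed by running :func:`tune_multiplier` on a clean labeled reference
#: population of 50 phantoms per class (seed 0); see docs/methods.md.
DEFAULT_MULTIPLIERS = {
    "punctate": 3.3,
    "invagination": 0.42,
    "diffuse": 0.84,
    "ring": 0.77,
}


def default_config(multipliers: dict[str, float] | None = None) -> CascadeConfig:
    """The shipped cascade: counts -> moment3 -> flatness -> moment3."""
    k = dict(DEFAULT_MULTIPLIERS)
    if multipliers:
        k.update(multipliers)
    return CascadeConfig(
        steps=(
            CascadeStep("n_objects", "high", k["punctate"], "punctate"),
            CascadeStep("moment3", "low", k["invagination"], "invagination"),
            CascadeStep("flatness", "low", k["diffuse"], "diffuse"),
        ),
        final=CascadeStep("moment3", "high", k["ring"], "ring"),
        final_otherwise="incomplete",
    )


@dataclass
class CalibratedCascade:
    """Absolute per-step thresholds derived from a control population."""

    config: CascadeConfig
    thresholds: tuple[float, ...]  # one per step, then the final split
    control_means: tuple[float, ...]
    control_sizes: tuple[int, ...]  # control cells remaining *before* each step
    provenance: str = ""

    @property
    def final_threshold(self) -> float:
        return self.thresholds[-1]


@dataclass
class PhenotypeCall:
    cell_id: str
    phenotype: str
    group_flag: str
    step_values: list[dict] = field(default_factory=list)


@dataclass
class PhenotypeSummary:
    group: str
    counts: dict[str, int]
    n_total: int
    percent_abnormal: float


# ---------------------------------------------------------------------------
# Feature access


def _feature_value(cell, name: str) -> float:
    if isinstance(cell, Shape3DMeasurements):
        return cell.feature(name)
    try:
        return float(cell[name])
    except (KeyError, TypeError) as exc:
        raise KeyError(f"measurement is missing feature {name!r}") from exc


def _cell_id(cell, fallback: str) -> str:
    if isinstance(cell, Shape3DMeasurements):
        return cell.cell_id
    try:
        return str(cell["cell_id"])
    except (KeyError, TypeError):
        return fallback


def features_frame(measurements) -> pd.DataFrame:
    """Cascade feature matrix (one row per cell) from measurement records."""
    rows = []
    for i, m in enumerate(measurements):
        row = {"cell_id": _cell_id(m, f"cell{i}")}
        row.update({f: _feature_value(m, f) for f in _CASCADE_FEATURES})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration and assignment


def calibrate(control, config: CascadeConfig | None = None, provenance: str = "") -> CalibratedCascade:
    """Derive absolute thresholds from the control population's running means.

    At each step the threshold is multiplier x mean(feature) over the control
    cells not yet assigned by earlier steps; cells meeting the criterion are
    then removed before the next step's mean is taken.  A step that removes
    *all* remaining control cells makes later steps uncalibratable and raises.
    """
    config = config or default_config()
    control = list(control)
    if not control:
        raise ValueError("control population must be non-empty")
    remaining = control
    thresholds: list[float] = []
    means: list[float] = []
    sizes: list[int] = []
    all_steps = list(config.steps) + [config.final]
    for step in all_steps:
        values = np.array([_feature_value(c, step.feature) for c in remaining], dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite {step.feature} in control population")
        mean = float(values.mean())
        thr = step.multiplier * mean
        sizes.append(len(remaining))
        means.append(mean)
        thresholds.append(thr)
        keep = [c for c, v in zip(remaining, values) if not step.meets(float(v), thr)]
        if step is not config.final and not keep:
            raise ValueError(
                f"degenerate calibration: step {step.assigns!r} removed every "
                "remaining control cell"
            )
        remaining = keep
    return CalibratedCascade(
        config=config,
        thresholds=tuple(thresholds),
        control_means=tuple(means),
        control_sizes=tuple(sizes),
        provenance=provenance,
    )


def assign_phenotype(cell, cal: CalibratedCascade, cell_id: str = "cell") -> PhenotypeCall:
    """Assign exactly one phenotype: first met criterion wins; final split otherwise."""
    cid = _cell_id(cell, cell_id)
    trace: list[dict] = []
    steps = list(cal.config.steps) + [cal.config.final]
    for step, thr in zip(steps, cal.thresholds):
        value = _feature_value(cell, step.feature)
        met = step.meets(value, thr)
        trace.append(
            {
                "feature": step.feature,
                "direction": step.direction,
                "value": value,
                "threshold": thr,
                "met": met,
            }
        )
        if met:
            pheno = step.assigns
            break
    else:
        pheno = cal.config.final_otherwise
    return PhenotypeCall(
        cell_id=cid,
        phenotype=pheno,
        group_flag=GROUP_OF_PHENOTYPE[pheno],
        step_values=trace,
    )


class CascadeClassifier(BaseEstimator):
    """Scikit-learn-style wrapper: ``fit`` calibrates on controls, ``predict`` assigns.

    Parameters
    ----------
    config : CascadeConfig or None
        Step definitions; ``None`` uses the shipped default cascade.

    Attributes (after ``fit``)
    --------------------------
    calibration_ : CalibratedCascade
    thresholds_ : tuple of float
    classes_ : ndarray of the five phenotype names
    """

    def __init__(self, config: CascadeConfig | None = None):
        self.config = config

    def fit(self, X, y=None):
        self.calibration_ = calibrate(self._as_cells(X), self.config)
        self.thresholds_ = self.calibration_.thresholds
        self.classes_ = np.array(PHENOTYPES)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.array([c.phenotype for c in self.predict_calls(X)])

    def predict_calls(self, X) -> list[PhenotypeCall]:
        """Full per-cell calls with the feature/threshold trace at each step."""
        self._check_fitted()
        cells = self._as_cells(X)
        return [assign_phenotype(c, self.calibration_, f"cell{i}") for i, c in enumerate(cells)]

    def _check_fitted(self):
        if not hasattr(self, "calibration_"):
            raise RuntimeError("CascadeClassifier must be fitted before predicting")

    @staticmethod
    def _as_cells(X):
        if isinstance(X, pd.DataFrame):
            return [row for _, row in X.iterrows()]
        return list(X)


def calibration_to_dict(cal: CalibratedCascade) -> dict:
    """JSON-serialisable form of a calibrated cascade (thresholds + provenance)."""
    steps = list(cal.config.steps) + [cal.config.final]
    return {
        "steps": [
            {
                "feature": s.feature,
                "direction": s.direction,
                "multiplier": s.multiplier,
                "assigns": s.assigns,
            }
            for s in steps
        ],
        "final_otherwise": cal.config.final_otherwise,
        "thresholds": list(cal.thresholds),
        "control_means": list(cal.control_means),
        "control_sizes": list(cal.control_sizes),
        "provenance": cal.provenance,
    }


def calibration_from_dict(d: dict) -> CalibratedCascade:
    steps = [CascadeStep(**s) for s in d["steps"]]
    config = CascadeConfig(
        steps=tuple(steps[:-1]), final=steps[-1], final_otherwise=d["final_otherwise"]
    )
    return CalibratedCascade(
        config=config,
        thresholds=tuple(float(t) for t in d["thresholds"]),
        control_means=tuple(float(m) for m in d["control_means"]),
        control_sizes=tuple(int(n) for n in d["control_sizes"]),
        provenance=d.get("provenance", ""),
    )


# ---------------------------------------------------------------------------
# Multiplier tuning


def tune_multiplier(labeled, step: CascadeStep, grid) -> float:
    """Grid-search a step's multiplier against manually labeled cells.

    ``labeled`` is a sequence of ``(measurements, true_phenotype)``.  For each
    candidate multiplier the threshold is multiplier x mean(feature over all
    labeled cells) and the objective is (# target-class cells meeting the
    criterion) − (# other cells meeting it).  Returns the midpoint of the
    optimal multiplier plateau; a completely flat objective returns the grid
    midpoint with a warning.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("multiplier grid must be non-empty")
    labeled = list(labeled)
    truths = [t for _, t in labeled]
    if step.assigns not in truths:
        raise ValueError(f"labeled set contains no {step.assigns!r} cells")
    if all(t == step.assigns for t in truths):
        raise ValueError("labeled set must contain at least one non-target cell")
    values = np.array([_feature_value(c, step.feature) for c, _ in labeled], dtype=float)
    is_target = np.array([t == step.assigns for t in truths])
    mean = float(values.mean())
    scores = np.empty(grid.size)
    for i, k in enumerate(np.sort(grid)):
        thr = k * mean
        met = np.array([step.meets(v, thr) for v in values])
        scores[i] = int(np.sum(met & is_target)) - int(np.sum(met & ~is_target))
    grid_sorted = np.sort(grid)
    if np.ptp(scores) == 0:
        if scores.max() <= 0:
            warnings.warn(
                f"objective is flat over the grid for step {step.assigns!r} "
                "(classes inseparable on this feature); returning grid midpoint"
            )
        # a uniformly optimal grid is one large plateau either way
        return float((grid_sorted[0] + grid_sorted[-1]) / 2)
    best = scores == scores.max()
    optimal = grid_sorted[best]
    return float((optimal.min() + optimal.max()) / 2)


# ---------------------------------------------------------------------------
# Summaries and validation


def summarize(calls, group_of) -> list[PhenotypeSummary]:
    """Per-group phenotype counts and percent-abnormal.

    ``percent_abnormal`` = 100 x (punctate + invagination + incomplete) / n.
    Every cell must appear in ``group_of`` (cell_id -> group name).
    """
    by_group: dict[str, list[PhenotypeCall]] = {}
    for call in calls:
        try:
            group = group_of[call.cell_id]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"cell {call.cell_id!r} has no group assignment") from exc
        by_group.setdefault(str(group), []).append(call)
    out = []
    for group in sorted(by_group):
        members = by_group[group]
        counts = {p: 0 for p in PHENOTYPES}
        for call in members:
            counts[call.phenotype] += 1
        n = len(members)
        abnormal = sum(counts[p] for p in ABNORMAL_PHENOTYPES)
        out.append(
            PhenotypeSummary(
                group=group, counts=counts, n_total=n,
                percent_abnormal=100.0 * abnormal / n,
            )
        )
    return out


@dataclass
class AgreementReport:
    """Manual vs automatic normal/abnormal agreement."""

    table: np.ndarray  # rows: manual normal/abnormal; cols: auto normal/abnormal
    percent_agreement: float
    statistic: float
    p_value: float


def compare_manual_vs_auto(manual, auto) -> AgreementReport:
    """2x2 agreement of manual normal/abnormal labels with automatic calls.

    Includes a two-tailed two-proportion z-test on the normal/abnormal split
    (degenerate proportions yield a NaN statistic).
    """
    manual = [str(m) for m in manual]
    auto_flags = [c.group_flag if isinstance(c, PhenotypeCall) else str(c) for c in auto]
    if len(manual) != len(auto_flags):
        raise ValueError(f"length mismatch: {len(manual)} manual vs {len(auto_flags)} auto")
    for lab in manual + auto_flags:
        if lab not in ("normal", "abnormal"):
            raise ValueError(f"labels must be 'normal'/'abnormal', got {lab!r}")
    idx = {"normal": 0, "abnormal": 1}
    table = np.zeros((2, 2), dtype=int)
    for m, a in zip(manual, auto_flags):
        table[idx[m], idx[a]] += 1
    n = len(manual)
    agreement = 100.0 * (table[0, 0] + table[1, 1]) / n
    counts = np.array([sum(m == "abnormal" for m in manual), sum(a == "abnormal" for a in auto_flags)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate proportions produce 0/0
        stat, p = proportions_ztest(counts, np.array([n, n]), alternative="two-sided")
    return AgreementReport(
        table=table, percent_agreement=agreement,
        statistic=float(stat), p_value=float(p),
    )
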