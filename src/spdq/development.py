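"""Instrument-development pipeline: discriminant weighting, integerization,
cutoff optimization and stepwise short-form selection.

The weighting scheme is a two-group Fisher (canonical) discriminant: the
direction w proportional to W^-1 (m_case - m_control), with W the pooled
within-group scatter, maximizes the ratio of between-group to within-group
variance of the projected scores.  Raw coefficients are scaled and rounded
to small integers (a screening instrument must be hand-scorable), the
score threshold is chosen to maximize sensitivity + specificity, and the
threshold is folded into the instrument's constant so the published-style
cutoff ">= 0" applies.

Short-form selection is stepwise discriminant analysis: items enter and
leave on the partial F test derived from Wilks' lambda, with entry/stay
significance levels of 0.15 (the conventional stepwise-discriminant
defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .evaluation import EvaluationResult, evaluate_instrument
from .instruments import (
    ALL_SCORED_ITEMS,
    SENSORY_ITEMS,
    Instrument,
    QuestionnaireRecord,
)

__all__ = [
    "DiscriminantFit",
    "CutoffResult",
    "StepwiseStep",
    "StepwiseTrace",
    "DevelopmentResult",
    "SingularScatterError",
    "DegenerateFitError",
    "fit_discriminant",
    "integerize_weights",
    "optimize_cutoff",
    "stepwise_select",
    "develop_instrument",
    "design_matrix",
]


class SingularScatterError(ValueError):
    """Pooled within-group scatter is singular; remove collinear/constant
    items or pass a ridge term."""


class DegenerateFitError(ValueError):
    """The fit carries no between-group separation (identical group means)."""


@dataclass(frozen=True)
class DiscriminantFit:
    """Two-group Fisher discriminant direction and its ingredients."""

    items: tuple[str, ...]
    direction: np.ndarray  # oriented so the case group projects higher
    mean_case: np.ndarray
    mean_control: np.ndarray
    pooled_within_scatter: np.ndarray
    degenerate: bool  # True when group means coincide

    def separation(self) -> float:
        """Projected between-group mean difference (case minus control)."""
        return float(self.direction @ (self.mean_case - self.mean_control))


def fit_discriminant(
    responses: np.ndarray,
    labels: Sequence[bool],
    *,
    items: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> DiscriminantFit:
    """Fisher direction W^-1 (m_case - m_control) for a two-group cohort.

    Parameters
    ----------
    responses : (n, p) array of item encodings
    labels : boolean case indicators, both classes with >= 2 members
    ridge : optional non-negative multiple of mean(diag(W)) added to W's
        diagonal; 0 (default) means singularity is a hard error.
    """
    X = np.asarray(responses, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("responses must be (n, p) with one label per row")
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError(f"each group needs >= 2 members (got {n_case} cases, {n_ctrl} controls)")
    p = X.shape[1]
    names = tuple(items) if items is not None else tuple(f"x{i}" for i in range(p))
    if len(names) != p:
        raise ValueError("items length must match number of columns")

    Xc, Xn = X[y], X[~y]
    m1, m0 = Xc.mean(axis=0), Xn.mean(axis=0)
    W = (Xc - m1).T @ (Xc - m1) + (Xn - m0).T @ (Xn - m0)
    if ridge > 0:
        W = W + ridge * (np.trace(W) / p) * np.eye(p)
    diff = m1 - m0

    # Reject near-singular scatter explicitly rather than pseudo-inverting:
    # a silent pinv would hand back arbitrary weights on collinear items.
    if np.linalg.cond(W) > 1e10:
        raise SingularScatterError(
            "pooled within-group scatter is (near-)singular; drop constant or "
            "collinear items, or pass ridge > 0"
        )
    direction = np.linalg.solve(W, diff)
    degenerate = bool(np.allclose(diff, 0.0))
    if degenerate:
        direction = np.zeros(p)
    elif direction @ diff < 0:  # cannot happen for PD W; kept as a guard
        direction = -direction
    return DiscriminantFit(names, direction, m1, m0, W, degenerate)


def integerize_weights(
    fit: DiscriminantFit | np.ndarray,
    max_abs_weight: int = 9,
) -> dict[str, int]:
    """Scale raw coefficients and round to integers with |weight| <= cap.

    The scale c > 0 minimizing the relative rounding error
    ||c d - round(c d)|| / ||c d|| subject to max|round(c d)| <= cap is found
    by scanning exact candidate scales (those mapping some coefficient to an
    integer) plus a dense grid; among equally good scales the largest is
    taken, so the integer weights use the full available resolution.
    """
    if isinstance(fit, DiscriminantFit):
        d = np.asarray(fit.direction, dtype=float)
        names = fit.items
        if fit.degenerate:
            raise DegenerateFitError("cannot integerize a degenerate (no-separation) fit")
    else:
        d = np.asarray(fit, dtype=float)
        names = tuple(f"x{i}" for i in range(d.size))
    if max_abs_weight < 1:
        raise ValueError("max_abs_weight must be >= 1")
    m = np.max(np.abs(d))
    if m == 0:
        raise DegenerateFitError("all-zero direction")
    c_max = max_abs_weight / m
    candidates: set[float] = set()
    for di in np.abs(d):
        if di > 0:
            for k in range(1, max_abs_weight + 1):
                c = k / di
                if 0 < c <= c_max + 1e-12:
                    candidates.add(min(c, c_max))
    candidates.update(np.linspace(c_max / 2048, c_max, 2048))
    norm_d = float(np.linalg.norm(d))
    best_c, best_err = None, np.inf
    for c in sorted(candidates):
        w = np.round(c * d)
        if np.max(np.abs(w)) > max_abs_weight or not np.any(w):
            continue
        err = float(np.linalg.norm(c * d - w)) / (c * norm_d)
        if err < best_err - 1e-12 or (err <= best_err + 1e-12 and (best_c is None or c > best_c)):
            best_c, best_err = c, min(err, best_err)
    if best_c is None:
        raise DegenerateFitError("no scale yields a nonzero integer weight vector")
    weights = np.round(best_c * d).astype(int)
    return {name: int(w) for name, w in zip(names, weights)}


@dataclass(frozen=True)
class CutoffResult:
    """Score threshold maximizing sensitivity + specificity.

    ``constant`` is the additive constant (-round(threshold)) that shifts
    scores so the positivity rule becomes "shifted score >= 0"; an
    instrument stores the same quantity as the value it subtracts.
    """

    threshold: float
    sensitivity_at: float
    specificity_at: float
    youden_sum: float
    constant: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity_at": self.sensitivity_at,
            "specificity_at": self.specificity_at,
            "youden_sum": self.youden_sum,
            "constant": self.constant,
        }


def optimize_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> CutoffResult:
    """Scan every observed score as a candidate threshold (rule: score >= t).

    Ties in sensitivity + specificity break toward the lowest threshold —
    the screening convention that favors sensitivity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("length mismatch")
    if y.all() or not y.any():
        raise ValueError("cutoff optimization requires both groups")
    n1, n0 = int(y.sum()), int((~y).sum())
    thresholds = np.unique(s)  # ascending
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])
    total = sens + spec
    best = int(np.argmax(total))  # argmax takes the first (lowest) on ties
    t = float(thresholds[best])
    return CutoffResult(
        threshold=t,
        sensitivity_at=float(sens[best]),
        specificity_at=float(spec[best]),
        youden_sum=float(total[best]),
        constant=-int(round(t)),
    )


@dataclass(frozen=True)
class StepwiseStep:
    item: str
    partial_f: float
    p_value: float
    action: str  # "enter" | "remove"


@dataclass(frozen=True)
class StepwiseTrace:
    steps: tuple[StepwiseStep, ...]
    selected: tuple[str, ...]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"item": s.item, "partial_f": s.partial_f, "p_value": s.p_value, "action": s.action}
                for s in self.steps
            ],
            "selected": list(self.selected),
            "note": self.note,
        }


def _wilks_lambda(X: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> float:
    """Wilks' lambda det(W)/det(T) for the given column subset (1.0 if empty)."""
    if not cols:
        return 1.0
    Z = X[:, list(cols)]
    mu = Z.mean(axis=0)
    T = (Z - mu).T @ (Z - mu)
    Z1, Z0 = Z[y], Z[~y]
    m1, m0 = Z1.mean(axis=0), Z0.mean(axis=0)
    W = (Z1 - m1).T @ (Z1 - m1) + (Z0 - m0).T @ (Z0 - m0)
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        return 1.0  # collinear/constant subset carries no usable information
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(
    X: np.ndarray, y: np.ndarray, base: Sequence[int], extra: int
) -> tuple[float, float]:
    """Partial F (and p) for adding column `extra` to subset `base` (2 groups)."""
    n = X.shape[0]
    df2 = n - 2 - len(base)
    if df2 <= 0:
        return 0.0, 1.0
    lam_base = _wilks_lambda(X, y, base)
    lam_full = _wilks_lambda(X, y, list(base) + [extra])
    if lam_full <= 0 or lam_full >= lam_base:
        f = 0.0 if lam_full >= lam_base else np.inf
    else:
        f = (lam_base / lam_full - 1.0) * df2
    p = float(stats.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
    return float(f), p


def stepwise_select(
    responses: np.ndarray,
    labels: Sequence[bool],
    *,
    items: Sequence[str] | None = None,
    significance_to_enter: float = 0.15,
    significance_to_stay: float = 0.15,
    forward_only: bool = False,
) -> StepwiseTrace:
    """Stepwise discriminant item selection by Wilks' lambda partial F.

    Forward steps enter the candidate with the largest partial F whose p is
    <= ``significance_to_enter``; after each entry, items whose partial F
    given the rest has p > ``significance_to_stay`` are removed (worst
    first) unless ``forward_only``.  Ties break by larger F, then by input
    item order.  Deterministic given the input column order; a repeated
    selected-set state terminates the loop (guards enter/remove cycles).
    """
    X = np.asarray(responses, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("responses must be (n, p) with one label per row")
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise ValueError("each group needs >= 2 members")
    p = X.shape[1]
    names = tuple(items) if items is not None else tuple(f"x{i}" for i in range(p))

    selected: list[int] = []
    steps: list[StepwiseStep] = []
    seen_states: set[frozenset[int]] = set()
    note = ""
    for _ in range(4 * p + 8):
        state = frozenset(selected)
        if state in seen_states and selected:
            note = "terminated: selected set revisited (enter/remove cycle)"
            break
        seen_states.add(state)

        if not forward_only and selected:
            # Removal pass: drop the weakest item while it fails the stay test.
            removed = True
            while removed and selected:
                removed = False
                worst = None
                for idx in selected:
                    base = [j for j in selected if j != idx]
                    f, pv = _partial_f(X, y, base, idx)
                    if pv > significance_to_stay and (worst is None or f < worst[1]):
                        worst = (idx, f, pv)
                if worst is not None:
                    idx, f, pv = worst
                    selected.remove(idx)
                    steps.append(StepwiseStep(names[idx], f, pv, "remove"))
                    removed = True

        # Entry pass: best remaining candidate, tie-break larger F then order.
        best = None
        for idx in range(p):
            if idx in selected:
                continue
            f, pv = _partial_f(X, y, selected, idx)
            if pv <= significance_to_enter and (best is None or f > best[1] + 1e-12):
                best = (idx, f, pv)
        if best is None:
            break
        idx, f, pv = best
        selected.append(idx)
        steps.append(StepwiseStep(names[idx], f, pv, "enter"))

    if not steps:
        note = "no item met the entry criterion"
    return StepwiseTrace(tuple(steps), tuple(names[i] for i in selected), note)


def design_matrix(
    records: Sequence[QuestionnaireRecord],
    items: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Complete-case design matrix of item encodings plus case labels.

    Returns (X, labels, n_excluded); rows missing any requested item or the
    group label are dropped (complete-case rule, no imputation).
    """
    rows, labels = [], []
    excluded = 0
    for rec in records:
        is_case = rec.is_case()
        vals = [rec.item_score(i) for i in items]
        if is_case is None or any(v is None for v in vals):
            excluded += 1
            continue
        rows.append(vals)
        labels.append(is_case)
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=bool), excluded


@dataclass(frozen=True)
class DevelopmentResult:
    instrument: Instrument
    fit: DiscriminantFit
    cutoff: CutoffResult
    stepwise: StepwiseTrace | None
    evaluation: EvaluationResult
    n_complete: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument.to_dict(),
            "cutoff": self.cutoff.to_dict(),
            "stepwise": None if self.stepwise is None else self.stepwise.to_dict(),
            "development_metrics": self.evaluation.to_dict(),
            "n_complete": self.n_complete,
            "n_excluded": self.n_excluded,
        }


def develop_instrument(
    records: Sequence[QuestionnaireRecord],
    *,
    items: Sequence[str] | None = None,
    select: bool = False,
    significance_to_enter: float = 0.15,
    significance_to_stay: float = 0.15,
    forward_only: bool = False,
    max_abs_weight: int = 9,
    ridge: float = 0.0,
    name: str = "developed",
) -> DevelopmentResult:
    """End-to-end development: (stepwise ->) discriminant -> integer weights
    -> cutoff -> instrument with cutoff >= 0.

    ``items`` defaults to all nine scored items.  With ``select=True`` a
    stepwise pass first reduces the item set (short-form construction).
    """
    items = tuple(items) if items is not None else ALL_SCORED_ITEMS
    for it in items:
        if it not in ALL_SCORED_ITEMS:
            raise ValueError(f"unknown item {it!r}")
    X, y, excluded = design_matrix(records, items)
    if X.size == 0 or y.all() or not y.any():
        raise ValueError("development requires complete cases in both groups")

    trace: StepwiseTrace | None = None
    if select:
        trace = stepwise_select(
            X,
            y,
            items=items,
            significance_to_enter=significance_to_enter,
            significance_to_stay=significance_to_stay,
            forward_only=forward_only,
        )
        if not trace.selected:
            raise ValueError(f"stepwise selection kept no items ({trace.note})")
        keep = [items.index(i) for i in trace.selected]
        # preserve questionnaire order in the final instrument
        keep.sort()
        items = tuple(items[i] for i in keep)
        X = X[:, keep]

    fit = fit_discriminant(X, y, items=items, ridge=ridge)
    if fit.degenerate:
        raise DegenerateFitError("group means coincide on the chosen items")
    weights = integerize_weights(fit, max_abs_weight=max_abs_weight)

    w = np.array([weights[i] for i in items], dtype=float)
    raw_scores = X @ w
    cut = optimize_cutoff(raw_scores, y)

    instrument = Instrument(
        name=name,
        item_weights={i: weights[i] for i in items if i in SENSORY_ITEMS},
        course_weight=weights.get("course_pattern", 0),
        radiating_weight=weights.get("radiating", 0),
        uses_course="course_pattern" in items,
        uses_radiating="radiating" in items,
        constant=-cut.constant,  # additive constant -> subtracted magnitude
        cutoff=0,
    )
    evaluation = evaluate_instrument(records, instrument)
    return DevelopmentResult(
        instrument=instrument,
        fit=fit,
        cutoff=cut,
        stepwise=trace,
        evaluation=evaluation,
        n_complete=int(X.shape[0]),
        n_excluded=excluded,
    )
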