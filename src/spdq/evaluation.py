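"""Diagnostic-accuracy and agreement statistics for binary screens.

Sensitivity, specificity, predictive values and likelihood ratios are
computed as exact rationals from the confusion-matrix counts, with a display
rounding policy of half-up to one decimal (percents and ratios alike) —
the convention the published validation tables use.  The AUC uses the
tie-aware Mann-Whitney estimator, appropriate for integer-valued scores
where ties are common.  Test-retest agreement uses Cohen's kappa with the
conventional interpretation bands (poor / fair / moderate / good / very
good).

Metrics whose denominator is zero are surfaced explicitly as ``None``
("undefined" in display views), never silently as NaN or 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .instruments import Instrument, QuestionnaireRecord, score_instrument

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "KappaResult",
    "EvaluationResult",
    "confusion_matrix",
    "diagnostic_metrics",
    "auc",
    "cohens_kappa",
    "kappa_band",
    "evaluate_instrument",
    "round_half_up",
]


def round_half_up(x: Fraction | float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 83.35 -> 83.4, never banker's 83.4/83.2 drift)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 screen-vs-gold-standard counts (positive screen, case truth)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


def confusion_matrix(classifications: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    """Tally screen-positive flags against gold-standard case flags."""
    pred = np.asarray(classifications, dtype=bool)
    y = np.asarray(truth, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {y.shape}")
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
        tn=int(np.sum(~pred & ~y)),
    )


@dataclass(frozen=True)
class DiagnosticReport:
    """Accuracy metrics as exact fractions, plus rounded display views.

    ``None`` marks a metric whose denominator is zero (e.g. specificity with
    no controls).  Display views show percents and ratios rounded half-up to
    one decimal; undefined metrics display as the string ``"undefined"``.
    """

    cm: ConfusionMatrix
    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    lr_plus: Fraction | None
    lr_minus: Fraction | None
    auc: float | None = None

    @property
    def n_cases(self) -> int:
        return self.cm.n_cases

    @property
    def n_controls(self) -> int:
        return self.cm.n_controls

    def display(self) -> dict:
        """Rounded view matching the published reporting convention."""

        def pct(v: Fraction | None) -> float | str:
            return "undefined" if v is None else round_half_up(100 * v, 1)

        def ratio(v: Fraction | None) -> float | str:
            return "undefined" if v is None else round_half_up(v, 1)

        out = {
            "n": self.cm.n,
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "lr_plus": ratio(self.lr_plus),
            "lr_minus": ratio(self.lr_minus),
        }
        out["auc"] = None if self.auc is None else round(self.auc, 2)
        return out

    def to_dict(self) -> dict:
        raw = {
            name: (None if v is None else float(v))
            for name, v in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("lr_plus", self.lr_plus),
                ("lr_minus", self.lr_minus),
            )
        }
        raw["auc"] = self.auc
        return {
            "counts": {"tp": self.cm.tp, "fp": self.cm.fp, "fn": self.cm.fn, "tn": self.cm.tn},
            "raw": raw,
            "display": self.display(),
        }


def _safe_div(num: int | Fraction, den: int | Fraction) -> Fraction | None:
    return None if den == 0 else Fraction(num) / Fraction(den)


def diagnostic_metrics(cm: ConfusionMatrix, auc: float | None = None) -> DiagnosticReport:
    """Exact-rational sensitivity/specificity/PPV/NPV and likelihood ratios.

    lr+ = sens / (1 - spec) and lr- = (1 - sens) / spec; each is undefined
    when its own denominator vanishes.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    sens = _safe_div(cm.tp, cm.tp + cm.fn)
    spec = _safe_div(cm.tn, cm.tn + cm.fp)
    ppv = _safe_div(cm.tp, cm.tp + cm.fp)
    npv = _safe_div(cm.tn, cm.tn + cm.fn)
    lr_plus = None
    if sens is not None and spec is not None and spec != 1:
        lr_plus = sens / (1 - spec)
    lr_minus = None
    if sens is not None and spec is not None and spec != 0:
        lr_minus = (1 - sens) / spec
    return DiagnosticReport(cm, sens, spec, ppv, npv, lr_plus, lr_minus, auc=auc)


def auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the empirical ROC curve, tie-aware.

    Mann-Whitney formulation P(score_case > score_control) + 1/2 P(tie),
    computed from midranks; identical to the trapezoidal area under the ROC
    built from all distinct thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("length mismatch between scores and truth")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def kappa_band(kappa: float) -> str:
    """Interpretation bands: <=0.20 poor, fair, moderate, good, >0.80 very good."""
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "good"
    return "very good"


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    band: str | None
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: first +/-, cols: second +/-
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "band": self.band,
            "table": [list(r) for r in self.table],
            "degenerate": self.degenerate,
        }


def cohens_kappa(first: Sequence[bool], second: Sequence[bool]) -> KappaResult:
    """Chance-corrected agreement between two binary administrations.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the marginals; if the
    marginals force p_e = 1 (both administrations constant) kappa is
    undefined and flagged degenerate.
    """
    a = np.asarray(first, dtype=bool)
    b = np.asarray(second, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch between administrations")
    n = a.size
    if n == 0:
        raise ValueError("empty input")
    pp = int(np.sum(a & b))
    pn = int(np.sum(a & ~b))
    np_ = int(np.sum(~a & b))
    nn = int(np.sum(~a & ~b))
    table = ((pp, pn), (np_, nn))
    p_o = Fraction(pp + nn, n)
    p1 = Fraction(pp + pn, n)  # first positive marginal
    p2 = Fraction(pp + np_, n)  # second positive marginal
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e == 1:
        return KappaResult(None, None, table, degenerate=True)
    kappa = float((p_o - p_e) / (1 - p_e))
    return KappaResult(kappa, kappa_band(kappa), table)


@dataclass(frozen=True)
class EvaluationResult:
    """Instrument accuracy on a labeled cohort, complete cases only."""

    instrument_name: str
    report: DiagnosticReport
    n_incomplete_cases: int
    n_incomplete_controls: int
    n_unlabeled: int
    scores: tuple[int, ...] = field(repr=False, default=())
    truth: tuple[bool, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        d = self.report.to_dict()
        d["instrument"] = self.instrument_name
        d["excluded"] = {
            "incomplete_cases": self.n_incomplete_cases,
            "incomplete_controls": self.n_incomplete_controls,
            "unlabeled": self.n_unlabeled,
        }
        return d


def evaluate_instrument(
    records: Sequence[QuestionnaireRecord], instrument: Instrument
) -> EvaluationResult:
    """Score a labeled cohort and report accuracy at the instrument's cutoff.

    Records missing a required item or the group label are excluded
    (complete-case rule) and accounted for separately; the AUC is computed
    on the continuous totals, the confusion matrix at total >= cutoff.
    """
    scores: list[int] = []
    truth: list[bool] = []
    inc_cases = inc_controls = unlabeled = 0
    for rec in records:
        is_case = rec.is_case()
        if is_case is None:
            unlabeled += 1
            continue
        result = score_instrument(rec, instrument)
        if not result.complete:
            if is_case:
                inc_cases += 1
            else:
                inc_controls += 1
            continue
        scores.append(result.total)
        truth.append(is_case)
    if not truth or all(truth) or not any(truth):
        raise ValueError("evaluation requires complete cases in both groups")
    pred = [s >= instrument.cutoff for s in scores]
    cm = confusion_matrix(pred, truth)
    report = diagnostic_metrics(cm, auc=auc(scores, truth))
    return EvaluationResult(
        instrument_name=instrument.name,
        report=report,
        n_incomplete_cases=inc_cases,
        n_incomplete_controls=inc_controls,
        n_unlabeled=unlabeled,
        scores=tuple(scores),
        truth=tuple(truth),
    )
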