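"""Figures of merit for a binary discriminant test.

Confusion counts, sensitivity/specificity/accuracy with Clopper-Pearson
exact binomial 95% confidence intervals, positive and negative
likelihood ratios with log-method (Simel-type) intervals, the rank-sum
AUROC, and predictive values re-evaluated at externally specified prior
prevalences (Bayes' rule), as used when a surveillance test is projected
onto recurrence-risk groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats


class DiagnosticsError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def confusion(predicted, truth, positive) -> ConfusionCounts:
    """Confusion counts with `positive` as the positive class."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise DiagnosticsError("predicted and truth lengths differ")
    labels = set(truth)
    if len(labels - {positive}) > 1:
        raise DiagnosticsError(f"more than two classes in truth: {sorted(labels)}")
    tp = fn = tn = fp = 0
    for pred, act in zip(predicted, truth):
        if act == positive:
            if pred == positive:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float, float]:
    """Exact (Clopper-Pearson) binomial interval, in percent.

    Returns (point, lower, upper) = (100 k/n, exact bounds).  The bounds
    are beta-distribution quantiles; k = 0 pins the lower bound at 0 and
    k = n pins the upper at 100.
    """
    if n < 1:
        raise DiagnosticsError("n must be >= 1")
    if not 0 <= k <= n:
        raise DiagnosticsError("k must be in [0, n]")
    point = 100.0 * k / n
    lower = 0.0 if k == 0 else 100.0 * stats.beta.ppf(alpha / 2, k, n - k + 1)
    upper = 100.0 if k == n else 100.0 * stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return point, float(lower), float(upper)


@dataclass
class RatioWithCI:
    value: float
    lower: float
    upper: float
    degenerate: bool = False


def likelihood_ratios(counts: ConfusionCounts, alpha: float = 0.05
                      ) -> tuple[RatioWithCI, RatioWithCI]:
    """PLR = sens/(1-spec) and NLR = (1-sens)/spec with log-method CIs.

    SE(ln PLR) = sqrt((1-sens)/(n_pos sens) + spec/(n_neg (1-spec)))
    SE(ln NLR) = sqrt(sens/(n_pos (1-sens)) + (1-spec)/(n_neg spec))

    fp = 0 makes the PLR infinite and fn = 0 makes the NLR zero; those
    are returned flagged, with the CI undefined on the degenerate side.
    """
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise DiagnosticsError("need at least one sample in each class")
    sens = counts.tp / counts.n_pos
    spec = counts.tn / counts.n_neg
    z = stats.norm.ppf(1 - alpha / 2)

    if counts.fp == 0:
        plr = RatioWithCI(math.inf, math.nan, math.inf, degenerate=True)
    else:
        v = sens / (1 - spec)
        se = math.sqrt(
            (1 - sens) / (counts.n_pos * sens) + spec / (counts.n_neg * (1 - spec))
        ) if sens > 0 else math.nan
        if math.isnan(se):
            plr = RatioWithCI(v, math.nan, math.nan, degenerate=True)
        else:
            plr = RatioWithCI(v, v * math.exp(-z * se), v * math.exp(z * se))

    if counts.fn == 0:
        nlr = RatioWithCI(0.0, 0.0, math.nan, degenerate=True)
    else:
        v = (1 - sens) / spec if spec > 0 else math.inf
        if not math.isfinite(v):
            nlr = RatioWithCI(v, math.nan, math.nan, degenerate=True)
        else:
            se = math.sqrt(
                sens / (counts.n_pos * (1 - sens))
                + (1 - spec) / (counts.n_neg * spec)
            )
            nlr = RatioWithCI(v, v * math.exp(-z * se), v * math.exp(z * se))
    return plr, nlr


def auroc(scores, truth, positive) -> float:
    """Rank-sum AUROC: P(random positive outscores a random negative).

    Ties count one half (midrank / Mann-Whitney formulation).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(list(truth))
    pos = scores[truth == positive]
    neg = scores[truth != positive]
    if pos.size == 0 or neg.size == 0:
        raise DiagnosticsError("both classes must be present for AUROC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


@dataclass
class PrevalenceAdjustedPV:
    prevalence: float
    npv: float
    ppv: float


def predictive_values(sens: float, spec: float, prevalence: float) -> PrevalenceAdjustedPV:
    """NPV and PPV at an external prior prevalence (Bayes' rule)."""
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise DiagnosticsError(f"{name} must be in [0, 1]")
    p = prevalence
    npv_den = (1 - sens) * p + spec * (1 - p)
    ppv_den = sens * p + (1 - spec) * (1 - p)
    npv = spec * (1 - p) / npv_den if npv_den > 0 else math.nan
    ppv = sens * p / ppv_den if ppv_den > 0 else math.nan
    return PrevalenceAdjustedPV(prevalence=p, npv=npv, ppv=ppv)


@dataclass
class DiscriminantMetrics:
    counts: ConfusionCounts
    sensitivity: tuple[float, float, float]  # percent (point, lower, upper)
    specificity: tuple[float, float, float]
    accuracy: tuple[float, float, float]
    plr: RatioWithCI
    nlr: RatioWithCI
    auroc: float
    predictive: list[PrevalenceAdjustedPV] = field(default_factory=list)

    def to_dict(self) -> dict:
        c = self.counts
        def _san(x):
            return None if (isinstance(x, float) and not math.isfinite(x)) else x
        return {
            "confusion": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp},
            "sensitivity_pct": list(self.sensitivity),
            "specificity_pct": list(self.specificity),
            "accuracy_pct": list(self.accuracy),
            "plr": {"value": _san(self.plr.value), "ci": [_san(self.plr.lower), _san(self.plr.upper)],
                    "degenerate": self.plr.degenerate},
            "nlr": {"value": _san(self.nlr.value), "ci": [_san(self.nlr.lower), _san(self.nlr.upper)],
                    "degenerate": self.nlr.degenerate},
            "auroc": self.auroc,
            "predictive_values": [
                {"prevalence": pv.prevalence, "npv": pv.npv, "ppv": pv.ppv}
                for pv in self.predictive
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def metrics_from_counts(counts: ConfusionCounts, scores=None, truth=None,
                        positive=None, prevalences=(), alpha: float = 0.05
                        ) -> DiscriminantMetrics:
    """All figures of merit from confusion counts (plus AUROC if scores given)."""
    sens = proportion_ci(counts.tp, counts.n_pos, alpha)
    spec = proportion_ci(counts.tn, counts.n_neg, alpha)
    acc = proportion_ci(counts.tp + counts.tn, counts.n, alpha)
    plr, nlr = likelihood_ratios(counts, alpha)
    roc = auroc(scores, truth, positive) if scores is not None else math.nan
    pvs = [predictive_values(sens[0] / 100, spec[0] / 100, p) for p in prevalences]
    return DiscriminantMetrics(counts, sens, spec, acc, plr, nlr, roc, pvs)


def evaluate(y_hat, truth, positive: str, negative: str, theta: float = 0.5,
             prevalences=(), alpha: float = 0.05) -> DiscriminantMetrics:
    """Score continuous predictions against true labels.

    Labels >= theta are called `positive`.  Assembles confusion counts,
    exact CIs, likelihood ratios, AUROC and prevalence-adjusted
    predictive values; deterministic given inputs.
    """
    y_hat = np.asarray(y_hat, float)
    predicted = [positive if v >= theta else negative for v in y_hat]
    counts = confusion(predicted, truth, positive)
    return metrics_from_counts(counts, scores=y_hat, truth=truth,
                               positive=positive, prevalences=prevalences, alpha=alpha)


# report formatting: 1 decimal for percents and PLR >= 1, 2 decimals for NLR < 1
def format_metrics(m: DiscriminantMetrics) -> dict:
    def pct(t):
        return f"{t[0]:.1f} ({t[1]:.1f}-{t[2]:.1f})%"

    def ratio(r: RatioWithCI):
        fmt = (lambda v: f"{v:.1f}") if r.value >= 1 else (lambda v: f"{v:.2f}")
        if not math.isfinite(r.value):
            return "inf"
        lo = "-" if not math.isfinite(r.lower) else fmt(r.lower)
        hi = "-" if not math.isfinite(r.upper) else fmt(r.upper)
        return f"{fmt(r.value)} ({lo}-{hi})"

    return {
        "sensitivity": pct(m.sensitivity),
        "specificity": pct(m.specificity),
        "accuracy": pct(m.accuracy),
        "PLR": ratio(m.plr),
        "NLR": ratio(m.nlr),
        "AUROC": f"{m.auroc:.2f}" if math.isfinite(m.auroc) else "-",
    }
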