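"""Classification metrics, repeat aggregation and hierarchy-consistency rates.

Thresholded metrics use the convention that a prediction is positive
iff its score is strictly greater than the threshold (default 0.5).
Across-repeat summaries report mean, sample SD and a 95% CI of the form
``mean ± t_{0.975, n-1} · sd`` — the descriptive interval that matches
the reporting style "mean ± sd (lo, hi)"; ``ci_mode="sem"`` gives the
conventional standard-error interval instead.

Two inconsistency-error rates quantify violations of the label
hierarchy by a paired (malignancy, nodal) score ``(y1, y2)``:

* type 1 — thresholded contradiction: predicted node-positive
  (``y2 > tau``) yet predicted benign (``y1 <= tau``);
* type 2 — continuous margin violation: ``y2 - y1 > m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

NA = float("nan")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RepeatSummary:
    values: list[float]
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass
class MetricsReport:
    """Per-metric across-repeat summaries plus inconsistency rates."""

    metrics: dict[str, RepeatSummary] = field(default_factory=dict)
    inconsistency_type1: float = NA
    inconsistency_type2: float = NA


def confusion_at_threshold(scores, labels, tau: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix at threshold ``tau`` (positive iff score > tau)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0:
        raise ValueError("cannot compute a confusion matrix on empty input")
    if s.shape != y.shape:
        raise ValueError(f"scores and labels differ in length: {s.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = s > tau
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()), fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()), fn=int((~pred & pos).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else NA


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """acc/se/sp/prec/f1 from counts; undefined ratios are NaN, never an error."""
    acc = _safe_div(c.tp + c.tn, c.n)
    se = _safe_div(c.tp, c.tp + c.fn)
    sp = _safe_div(c.tn, c.tn + c.fp)
    prec = _safe_div(c.tp, c.tp + c.fp)
    f1 = f1_from_prec_se(prec, se)
    return {"acc": acc, "se": se, "sp": sp, "prec": prec, "f1": f1}


def f1_from_prec_se(prec: float, se: float) -> float:
    """Harmonic mean of precision and sensitivity (NaN if undefined)."""
    if math.isnan(prec) or math.isnan(se) or (prec + se) == 0:
        return NA
    return 2.0 * prec * se / (prec + se)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC (trapezoidal over all thresholds, ties counted half) plus ROC points.

    Returns ``(auc, points)`` with points as an (n, 2) array of
    (false-positive rate, true-positive rate).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC requires both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr])


def inconsistency_rates(score_pairs, tau: float = 0.5, m: float = 0.1) -> tuple[float, float]:
    """(type1, type2) hierarchy-violation rates over (y1, y2) pairs."""
    pairs = np.asarray(score_pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("inconsistency rates of an empty set are undefined")
    y1, y2 = pairs[:, 0], pairs[:, 1]
    type1 = float(((y2 > tau) & (y1 <= tau)).mean())
    type2 = float(((y2 - y1) > m).mean())
    return type1, type2


def aggregate_repeats(values, ci_mode: str = "sd") -> RepeatSummary:
    """Mean, sample SD and 95% CI across repeats.

    ``ci_mode="sd"`` uses mean ± t·sd (descriptive band);
    ``ci_mode="sem"`` uses mean ± t·sd/sqrt(n).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no repeat values to aggregate")
    mean = float(v.mean())
    if v.size == 1:
        return RepeatSummary(values=list(v), mean=mean, sd=NA, ci95=(NA, NA))
    sd = float(v.std(ddof=1))
    t = float(stats.t.ppf(0.975, v.size - 1))
    half = t * sd / (math.sqrt(v.size) if ci_mode == "sem" else 1.0)
    return RepeatSummary(values=list(v), mean=mean, sd=sd, ci95=(mean - half, mean + half))


def compare_models(values_a, reference) -> float:
    """Two-sided p-value for repeats A against a scalar baseline or second vector.

    One-sample t-test against a scalar; Welch two-sample t-test for
    vector vs vector.  Zero variance with zero mean difference returns
    p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    if a.size < 2:
        return NA
    if np.isscalar(reference) or np.asarray(reference).ndim == 0:
        ref = float(reference)
        if a.std(ddof=1) == 0.0:
            return 1.0 if a.mean() == ref else 0.0
        return float(stats.ttest_1samp(a, ref).pvalue)
    b = np.asarray(reference, dtype=float)
    if b.size < 2:
        return NA
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def make_burden_labels(records, n_min: int) -> np.ndarray:
    """Binary nodal-burden labels (node_count >= n_min) over ALNM-defined records.

    ``n_min=1`` coincides with the ALNM label itself.
    """
    if n_min not in (1, 2, 3, 4):
        raise ValueError(f"n_min must be in 1..4, got {n_min}")
    bad = [r.image_id for r in records if not r.alnm_defined]
    if bad:
        raise ValueError(f"burden labels require alnm_defined records; offending: {bad[:3]}")
    return np.array([1 if r.node_count >= n_min else 0 for r in records], dtype=int)


def evaluate_scores(scores, labels, tau: float = 0.5) -> dict[str, float]:
    """Single-repeat metric set: thresholded metrics plus AUC (if computable)."""
    c = confusion_at_threshold(scores, labels, tau)
    out = metrics_from_confusion(c)
    try:
        out["auc"], _ = roc_auc(scores, labels)
    except ValueError:
        out["auc"] = NA
    # prevalence-weighted identity: acc == (se*P + sp*N) / (P+N)
    p, n_neg = c.tp + c.fn, c.tn + c.fp
    if p > 0 and n_neg > 0:
        assert abs(out["acc"] - (out["se"] * p + out["sp"] * n_neg) / (p + n_neg)) < 1e-12
    return out


def summarize_repeats(per_repeat: list[dict[str, float]], ci_mode: str = "sd",
                      ) -> dict[str, RepeatSummary]:
    """Aggregate a list of per-repeat metric dicts metric-by-metric."""
    keys = per_repeat[0].keys()
    return {k: aggregate_repeats([r[k] for r in per_repeat], ci_mode=ci_mode) for k in keys}
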