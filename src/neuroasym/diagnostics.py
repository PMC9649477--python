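"""Diagnostic-accuracy machinery: ROC, Youden cutoffs, exact CIs, combined rules.

Conventions fixed throughout the package: Parkinson's disease (PD) is the
positive class for the recovery-cycle asymmetry index (higher AI = PD-like),
corticobasal syndrome (CBS) is the positive class for the MRI asymmetry
index (higher AI = CBS-like). Cutoffs classify by *strict* comparison
("greater than the cutoff"). Reported cutoffs are midpoints between
adjacent observed scores, so strict and non-strict comparison coincide.

Sensitivity/specificity carry exact (Clopper–Pearson) 95% confidence
intervals; the binormal identity AUC = Φ(|μ₁−μ₀|/√(σ₁²+σ₀²)) links printed
group summaries to an implied AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .errors import DataError, DegenerateROCError, DomainError


@dataclass
class ROCResult:
    """Empirical ROC curve with Youden-optimal operating point.

    ``points`` run from (0,0) to (1,1); ``cutoffs[k]`` is the midpoint
    threshold realising point k under the rule "positive if score beyond
    cutoff in ``positive_direction``" (±inf at the ends).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    positive_direction: str
    positive_label: object

    @property
    def points(self):
        return list(zip(self.fpr, self.tpr))


@dataclass
class BinaryMetrics:
    """Confusion counts with exact-CI sensitivity and specificity."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    sens_ci: tuple = field(init=False)
    spec_ci: tuple = field(init=False)
    level: float = 0.95

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise DomainError("confusion counts must be non-negative")
        npos, nneg = self.tp + self.fn, self.tn + self.fp
        if npos == 0 or nneg == 0:
            raise DegenerateROCError("need at least one case in each class")
        self.sensitivity = self.tp / npos
        self.specificity = self.tn / nneg
        self.sens_ci = exact_binomial_ci(self.tp, npos, self.level)
        self.spec_ci = exact_binomial_ci(self.tn, nneg, self.level)


def _validate_scores_labels(scores, labels, positive_label):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be 1-D and of equal length")
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    y = labels == positive_label
    if y.all() or not y.any():
        raise DegenerateROCError("both classes must be present")
    return scores, y


def empirical_roc(scores, labels, positive_label, direction: str = "greater") -> ROCResult:
    """Empirical ROC curve, trapezoidal AUC and Youden-optimal cutoff.

    Parameters
    ----------
    scores, labels : array-like
        Per-patient marker values and group labels.
    positive_label :
        Label of the positive class.
    direction : {"greater", "less"}
        Whether positives score above ("greater") or below ("less") the
        cutoff. Equal scores are treated as a single threshold step.
    """
    if direction not in ("greater", "less"):
        raise DomainError(f"direction must be 'greater' or 'less', got {direction!r}")
    scores, y = _validate_scores_labels(scores, labels, positive_label)
    s = scores if direction == "greater" else -scores

    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))

    # Midpoint cutoffs: point k (k>=1) corresponds to "positive iff
    # s > c" for any c between thr[k] and the next lower unique score;
    # report the midpoint, with ±inf at the two ends.
    cutoffs = np.empty_like(thr)
    cutoffs[0] = np.inf
    for k in range(1, len(thr)):
        nxt = thr[k + 1] if k + 1 < len(thr) else -np.inf
        cutoffs[k] = (thr[k] + nxt) / 2.0 if np.isfinite(nxt) else -np.inf
    if direction == "less":
        cutoffs = -cutoffs

    # Youden selection in exact integer arithmetic: J = tp/P - fp/N is
    # compared via tp*N - fp*P so float rounding cannot scramble ties.
    n_pos, n_neg = int(np.sum(y)), int(np.sum(~y))
    tps = np.rint(tpr * n_pos).astype(int)
    fps = np.rint(fpr * n_neg).astype(int)
    best = int(max(range(len(tps)),
                   key=lambda k: (tps[k] * n_neg - fps[k] * n_pos, -fps[k])))
    j = tpr - fpr
    res = ROCResult(
        fpr=fpr,
        tpr=tpr,
        cutoffs=cutoffs,
        auc=auc,
        youden_cutoff=float(cutoffs[best]),
        youden_j=float(j[best]),
        positive_direction=direction,
        positive_label=positive_label,
    )
    return res


def youden_optimal_cutoff(roc: ROCResult) -> tuple:
    """(cutoff, J) maximising J = sensitivity + specificity − 1.

    Among thresholds with equal J the one with the higher specificity is
    chosen; the cutoff is the midpoint between adjacent observed scores.
    """
    if len(roc.fpr) < 2:
        raise DegenerateROCError("ROC has no interior structure")
    return roc.youden_cutoff, roc.youden_j


def binormal_auc(mean_pos, sd_pos, mean_neg, sd_neg) -> float:
    """AUC implied by Gaussian score distributions in the two classes.

    Φ(|μ₊ − μ₋| / √(σ₊² + σ₋²)). With both SDs zero, distinct means give 1
    and equal means are undefined.
    """
    if sd_pos < 0 or sd_neg < 0:
        raise DomainError("standard deviations must be non-negative")
    denom = float(np.hypot(sd_pos, sd_neg))
    delta = abs(mean_pos - mean_neg)
    if denom == 0:
        if delta == 0:
            raise DomainError("binormal AUC undefined: equal means, zero SDs")
        return 1.0
    return float(stats.norm.cdf(delta / denom))


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple:
    """Clopper–Pearson exact binomial confidence interval.

    Lower bound is 0 when successes = 0 and the upper bound 1 when
    successes = n; the interval is conservative (coverage ≥ level).
    """
    if not (0 < level < 1):
        raise DomainError("level must be in (0,1)")
    if not (0 <= successes <= n) or n < 1:
        raise DomainError(f"invalid counts: {successes}/{n}")
    ci = stats.binomtest(successes, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


def evaluate_rule(scores, labels, cutoff: float, direction: str = "greater",
                  positive_label=None, level: float = 0.95) -> BinaryMetrics:
    """Confusion counts and exact-CI sensitivity/specificity at a fixed cutoff.

    Classification is strict: positive iff score > cutoff (direction
    "greater") or score < cutoff ("less").
    """
    scores, y = _validate_scores_labels(scores, labels, positive_label)
    pred = scores > cutoff if direction == "greater" else scores < cutoff
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    return BinaryMetrics(tp=tp, fn=fn, tn=tn, fp=fp, level=level)


@dataclass
class CombinedRule:
    """Two-marker combination rule.

    ``sequential_rule``: call PD when the recovery-cycle AI exceeds its
    cutoff; otherwise call CBS when the MRI AI exceeds its cutoff;
    otherwise PD (the doubly-negative cell is PD-like). ``logistic_score``:
    in-sample logistic fit on the two AIs, classified at the Youden cutoff
    of the fitted score.
    """

    r2brrc_cutoff: float = 0.75
    mri_cutoff: float = 0.014
    mode: str = "sequential_rule"
    coefficients: dict | None = None

    def __post_init__(self):
        if not (0 <= self.r2brrc_cutoff <= 1 and 0 <= self.mri_cutoff <= 1):
            raise DomainError("cutoffs must lie in [0,1]")
        if self.mode not in ("sequential_rule", "logistic_score"):
            raise DomainError(f"unknown combination mode {self.mode!r}")


@dataclass
class CombinedResult:
    """Output of :func:`combined_classify`."""

    predicted: np.ndarray        # "PD"/"CBS" per patient
    score: np.ndarray            # PD-positive continuous score
    rule: CombinedRule
    separable: bool = False      # logistic mode hit complete separation
    coefficients: dict | None = None
    score_cutoff: float | None = None


def _sequential_margin(ai_r2, ai_mri, rule: CombinedRule):
    """Signed PD score of the sequential rule: > 0 ⇔ labelled PD."""
    branch1 = ai_r2 > rule.r2brrc_cutoff
    margin = np.where(branch1, ai_r2 - rule.r2brrc_cutoff, rule.mri_cutoff - ai_mri)
    return margin


def _fit_logistic_score(ai_r2, ai_mri, y):
    """In-sample logistic PD-score on the two AIs.

    Tries a plain ML fit first; under (quasi-)complete separation the MLE
    does not exist, so a weakly ridge-penalised fit on standardised
    features supplies a finite separating direction and the result is
    flagged ``separable``.
    """
    import statsmodels.api as sm

    X = np.column_stack([ai_r2, ai_mri])
    Xc = sm.add_constant(X)
    separable = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")  # promote separation warnings
            fit = sm.Logit(y.astype(float), Xc).fit(disp=0, maxiter=200)
        p = fit.predict(Xc)
        if np.all(np.abs(p - y) < 1e-6):
            separable = True
        score = Xc @ fit.params
        coefs = {"intercept": fit.params[0], "ai_r2brrc": fit.params[1], "ai_mri": fit.params[2]}
    except Exception:
        separable = True
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(X)
        lr = LogisticRegression(C=1e3, max_iter=10_000).fit(scaler.transform(X), y)
        score = lr.decision_function(scaler.transform(X))
        w = lr.coef_[0] / scaler.scale_
        b = lr.intercept_[0] - np.sum(lr.coef_[0] * scaler.mean_ / scaler.scale_)
        coefs = {"intercept": float(b), "ai_r2brrc": float(w[0]), "ai_mri": float(w[1])}
    return np.asarray(score, float), separable, coefs


def combined_classify(ai_r2brrc, ai_mri, labels, rule: CombinedRule | None = None,
                      positive_label: str = "PD") -> CombinedResult:
    """Classify patients from the two asymmetry indices.

    Returns per-patient labels plus a continuous PD-positive score suitable
    for ROC analysis. In logistic mode labels are assigned at the
    Youden-optimal cutoff of the in-sample score.
    """
    rule = rule or CombinedRule()
    ai_r2 = np.asarray(ai_r2brrc, dtype=float)
    ai_m = np.asarray(ai_mri, dtype=float)
    if ai_r2.shape != ai_m.shape:
        raise DataError("AI vectors must have equal length")
    if not (np.all(np.isfinite(ai_r2)) and np.all(np.isfinite(ai_m))):
        raise DataError("missing or non-finite AI values")
    labels = np.asarray(labels)
    y = labels == positive_label

    if rule.mode == "sequential_rule":
        score = _sequential_margin(ai_r2, ai_m, rule)
        pred = np.where(score > 0, "PD", "CBS")
        return CombinedResult(predicted=pred, score=score, rule=rule)

    score, separable, coefs = _fit_logistic_score(ai_r2, ai_m, y)
    roc = empirical_roc(score, labels, positive_label=positive_label, direction="greater")
    cut, _ = youden_optimal_cutoff(roc)
    pred = np.where(score > cut, "PD", "CBS")
    return CombinedResult(
        predicted=pred, score=score, rule=rule, separable=separable,
        coefficients=coefs, score_cutoff=cut,
    )
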