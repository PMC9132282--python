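"""Multi-label evaluation machinery.

Macro-averaged metrics average per-kinase precision/recall/F1 (or FDR/TPR)
over the kinase set, so well-studied kinases cannot dominate.  Any term
undefined by division by zero is set to 0 before averaging.

Also provides constrained repeated k-fold cross-validation (every fold
containing a kinase holds at least one positive and one negative site for
it), metric curves over score cutoffs with trapezoidal ROC AUC, and the
logistic calibration that maps a kinase's PSSM scores to Naive Bayes
posterior probabilities (its inflection is the PSSM score equivalent to
posterior 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import FoldError, InputError

DEFAULT_CUTOFFS = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class MacroMetrics:
    precision: float
    recall: float
    f1: float


def counts_from_predictions(df: pd.DataFrame) -> pd.DataFrame:
    """Per-kinase TP/FP/FN/TN from a frame with kinase_id, label, assigned."""
    lab = df["label"].astype(bool)
    asg = df["assigned"].astype(bool)
    out = pd.DataFrame({
        "kinase_id": df["kinase_id"],
        "tp": (lab & asg).astype(int),
        "fp": (~lab & asg).astype(int),
        "fn": (lab & ~asg).astype(int),
        "tn": (~lab & ~asg).astype(int),
    })
    return out.groupby("kinase_id").sum()


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the undefined-goes-to-zero convention."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    return out


def macro_metrics(counts: pd.DataFrame) -> MacroMetrics:
    """Macro-averaged precision, recall and F1 over the kinase set.

    ``counts`` has one row per kinase with columns tp, fp, fn.  Per-kinase
    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2pr/(p+r); undefined
    terms are 0; the arithmetic mean is taken over kinases.
    """
    if len(counts) == 0:
        raise InputError("empty kinase set")
    tp = counts["tp"].to_numpy(dtype=float)
    fp = counts["fp"].to_numpy(dtype=float)
    fn = counts["fn"].to_numpy(dtype=float)
    p = _safe_div(tp, tp + fp)
    r = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * p * r, p + r)
    return MacroMetrics(float(p.mean()), float(r.mean()), float(f1.mean()))


def macro_fdr_tpr(counts: pd.DataFrame) -> tuple[float, float]:
    """Macro-averaged false discovery rate and true positive rate.

    FDR_K = FP/(TP+FP); TPR_K = TP/(TP+FN) (identical to recall);
    undefined terms are 0.
    """
    if len(counts) == 0:
        raise InputError("empty kinase set")
    tp = counts["tp"].to_numpy(dtype=float)
    fp = counts["fp"].to_numpy(dtype=float)
    fn = counts["fn"].to_numpy(dtype=float)
    fdr = _safe_div(fp, tp + fp)
    tpr = _safe_div(tp, tp + fn)
    return float(fdr.mean()), float(tpr.mean())


def crossval_folds(pairs: pd.DataFrame, k: int = 10, repeats: int = 10,
                   seed: int = 0, constraint: str | None = "kinase-pos-neg"):
    """Repeated k-fold partitions of (kinase, site, label) pairs.

    With the default constraint, any test fold containing a kinase holds at
    least one positive and one negative pair for it: each kinase's
    positives and negatives are shuffled, zipped into couples, and couples
    dealt to folds together (leftovers go to folds that already hold both
    classes for the kinase).  Returns ``repeats`` lists of ``k`` index
    arrays (positional indices into ``pairs``).  Deterministic under seed.
    """
    n = len(pairs)
    if n < k:
        raise FoldError(f"cannot split {n} pairs into {k} folds")
    rng = np.random.default_rng(seed)
    all_repeats = []
    for _ in range(repeats):
        folds = [[] for _ in range(k)]
        if constraint is None:
            perm = rng.permutation(n)
            for i, idx in enumerate(perm):
                folds[i % k].append(idx)
        elif constraint == "kinase-pos-neg":
            labels = pairs["label"].astype(bool).to_numpy()
            kinase_col = pairs["kinase_id"].to_numpy()
            sizes = np.zeros(k, dtype=int)
            for kinase in np.unique(kinase_col):
                loc = np.flatnonzero(kinase_col == kinase)
                pos = loc[labels[loc]]
                neg = loc[~labels[loc]]
                if len(pos) == 0 or len(neg) == 0:
                    raise FoldError(
                        f"kinase {kinase} lacks a positive or negative pair")
                pos = rng.permutation(pos)
                neg = rng.permutation(neg)
                m = min(len(pos), len(neg))
                used = []
                for i in range(m):
                    f = int(np.argmin(sizes + rng.random(k) * 0.5))
                    folds[f].extend((pos[i], neg[i]))
                    sizes[f] += 2
                    used.append(f)
                for extra in np.concatenate([pos[m:], neg[m:]]):
                    f = used[int(rng.integers(len(used)))]
                    folds[f].append(extra)
                    sizes[f] += 1
        else:
            raise InputError(f"unknown constraint {constraint!r}")
        all_repeats.append([np.sort(np.array(f, dtype=int)) for f in folds])
    return all_repeats


def curve_over_cutoffs(df: pd.DataFrame, metric: str = "F1",
                       cutoffs: np.ndarray | None = None):
    """Macro metrics recomputed over a cutoff grid.

    ``df`` has columns kinase_id, score, label.  For metric "PR"/"F1" the
    returned frame has cutoff, precision, recall, f1.  For "ROC" it has
    cutoff, fpr, tpr and the function returns (frame, auc) with
    trapezoidal AUC; single-class labels raise :class:`InputError`.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_CUTOFFS
    kinases = df["kinase_id"].to_numpy()
    scores = df["score"].to_numpy(dtype=float)
    labels = df["label"].astype(bool).to_numpy()
    if metric == "ROC" and (labels.all() or not labels.any()):
        raise InputError("ROC AUC undefined for single-class labels")
    uniq = np.unique(kinases)
    rows = []
    for c in cutoffs:
        assigned = scores > c
        tp = np.zeros(len(uniq))
        fp = np.zeros(len(uniq))
        fn = np.zeros(len(uniq))
        tn = np.zeros(len(uniq))
        for i, kin in enumerate(uniq):
            m = kinases == kin
            tp[i] = np.sum(labels[m] & assigned[m])
            fp[i] = np.sum(~labels[m] & assigned[m])
            fn[i] = np.sum(labels[m] & ~assigned[m])
            tn[i] = np.sum(~labels[m] & ~assigned[m])
        if metric == "ROC":
            rows.append((c, _safe_div(fp, fp + tn).mean(),
                         _safe_div(tp, tp + fn).mean()))
        else:
            p = _safe_div(tp, tp + fp)
            r = _safe_div(tp, tp + fn)
            f1 = _safe_div(2 * p * r, p + r)
            rows.append((c, p.mean(), r.mean(), f1.mean()))
    if metric == "ROC":
        out = pd.DataFrame(rows, columns=["cutoff", "fpr", "tpr"])
        order = np.lexsort((out["tpr"].to_numpy(), out["fpr"].to_numpy()))
        fpr = np.concatenate([[0.0], out["fpr"].to_numpy()[order], [1.0]])
        tpr = np.concatenate([[0.0], out["tpr"].to_numpy()[order], [1.0]])
        auc = float(np.trapezoid(tpr, fpr))
        return out, auc
    return pd.DataFrame(rows, columns=["cutoff", "precision", "recall", "f1"])


@dataclass
class CalibrationFit:
    """Logistic fit of PSSM score versus Naive Bayes posterior for a kinase."""

    kinase_id: str | None
    inflection: float
    slope: float
    n_substrates: int | None
    converged: bool
    in_range: bool


def fit_logistic_calibration(pssm_scores, nb_posteriors,
                             n_substrates: int | None = None,
                             kinase_id: str | None = None) -> CalibrationFit:
    """Least-squares fit of posterior = 1/(1 + exp(-slope*(score - inflection))).

    The fitted inflection is the PSSM score equivalent to posterior 0.5.
    Requires >= 10 paired points; if the posteriors do not span both sides
    of 0.5 or the optimizer fails, the fit is returned flagged as
    non-converged (callers exclude it from trend analyses).
    """
    x = np.asarray(pssm_scores, dtype=float)
    y = np.asarray(nb_posteriors, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("scores and posteriors must be equal-length vectors")
    if len(x) < 10:
        raise InputError("need at least 10 paired points for calibration")
    spans = bool((y > 0.5).any() and (y < 0.5).any())

    def model(s, slope, inflection):
        return expit(slope * (s - inflection))

    x0 = float(x[np.argmin(np.abs(y - 0.5))])
    span = float(x.max() - x.min()) or 1.0
    converged = True
    try:
        popt, _ = curve_fit(model, x, y, p0=[4.0 / span, x0], maxfev=10000)
        slope, inflection = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        slope, inflection = np.nan, np.nan
    in_range = bool(converged and x.min() <= inflection <= x.max())
    return CalibrationFit(kinase_id, inflection, slope, n_substrates,
                          converged and spans, in_range)


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha)))
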