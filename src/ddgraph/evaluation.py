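"""Regression, antisymmetry and classification metrics.

Antisymmetry of a stability predictor is audited on paired predictions:
``r_d_i`` is the Pearson correlation between direct (wild -> mutant) and
inverse (mutant -> wild) predictions of the same mutations (ideal -1), and
``delta_mean`` is the mean of the paired sums (ideal 0, since thermodynamics
forces ddG_inverse = -ddG_direct).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass
class EvalReport:
    pcc: float
    spearman: float
    rmse: float
    n: int
    r_d_i: float | None = None
    delta_mean: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def __str__(self) -> str:
        lines = [
            f"n        {self.n:d}",
            f"PCC      {self.pcc:.4f}",
            f"Spearman {self.spearman:.4f}",
            f"RMSE     {self.rmse:.4f} kcal/mol",
        ]
        if self.r_d_i is not None:
            lines.append(f"r_d-i    {self.r_d_i:.4f}")
        if self.delta_mean is not None:
            lines.append(f"<delta>  {self.delta_mean:.4f} kcal/mol")
        return "\n".join(lines)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with an exact denominator when both variances coincide.

    For mirrored inputs (y = -x) the centred cross-sum equals minus the
    centred square-sum bit-for-bit, so r is exactly -1; routing the equal-
    variance case around the square root preserves that exactness.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    denom = sxx if sxx == syy else float(np.sqrt(sxx * syy))
    return sxy / denom


def regression_metrics(pred, obs) -> EvalReport:
    """Pearson r, Spearman rho (average ranks on ties) and RMSE.

    A zero-variance input leaves the correlations undefined: they are
    reported as NaN, never coerced to 0.
    """
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    if pred.size < 3:
        raise ValueError("need at least 3 points for correlation metrics")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
        raise ValueError("non-finite values in metric inputs")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return EvalReport(pcc=float("nan"), spearman=float("nan"), rmse=rmse, n=pred.size)
    pcc = _pearson(pred, obs)
    rho = float(stats.spearmanr(pred, obs).statistic)
    return EvalReport(pcc=pcc, spearman=rho, rmse=rmse, n=pred.size)


def antisymmetry_metrics(pred_direct, pred_inverse) -> tuple[float, float]:
    """(r_d_i, delta_mean) over paired direct/inverse predictions.

    Pair i must be the same mutation predicted in both directions.
    delta_mean is the signed mean of (direct_i + inverse_i); an
    absolute-value variant is available via :func:`antisymmetry_bias`.
    """
    d = np.asarray(pred_direct, dtype=np.float64)
    i = np.asarray(pred_inverse, dtype=np.float64)
    if d.shape != i.shape:
        raise ValueError("direct and inverse prediction vectors must pair up")
    if np.std(d) == 0.0 or np.std(i) == 0.0:
        r = float("nan")
    else:
        r = _pearson(d, i)
    # math.fsum-style pairing is unnecessary: the mean of exactly opposite
    # pairs is exactly zero because each elementwise sum is exactly zero
    return r, float(np.mean(d + i))


def antisymmetry_bias(pred_direct, pred_inverse, absolute: bool = False) -> float:
    """Mean paired sum; ``absolute=True`` averages |direct + inverse| instead."""
    s = np.asarray(pred_direct, dtype=np.float64) + np.asarray(pred_inverse, dtype=np.float64)
    return float(np.mean(np.abs(s) if absolute else s))


def auc_score(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """AUC plus confusion-matrix metrics at ``score > threshold`` = positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    calls = scores > threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    accuracy = (tp + tn) / labels.size
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else float("nan")
    )
    return {
        "auc": auc_score(scores, labels),
        "recall": recall,
        "precision": precision,
        "accuracy": accuracy,
        "f1": f1,
    }
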