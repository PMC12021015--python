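"""Zero-shot downstream analyses of a trained stability model.

Two analyses are implemented:

* **Pathogenicity screening** — a variant is called benign when
  |ddG| <= 1 kcal/mol and pathogenic otherwise (stabilising *and*
  destabilising changes both count: either direction of a large stability
  perturbation can impair function).
* **Optimum-growth-temperature (OGT) cross-prediction** — because the
  shared-weight encoder accepts arbitrary sequence pairs, "mutating" one
  whole protein into an unrelated one is well-defined.  Averaging predicted
  ddG over organism temperature classes (psychrophile < 20 °C <= mesophile
  < 45 °C <= thermophile < 80 °C <= hyperthermophile) probes whether the
  model has internalised the stability gradient along thermal adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import network as net
from .evaluation import classification_metrics
from .graphs import ProteinGraph
from .network import ModelConfig, ModelParams
from .records import MutationRecord

PATHOGENIC_DDG_THRESHOLD = 1.0  # kcal/mol
TEMP_CLASSES = ("psychrophile", "mesophile", "thermophile", "hyperthermophile")
#: lower class bounds in degrees Celsius (half-open intervals, left-closed)
TEMP_BOUNDS = (20.0, 45.0, 80.0)
DEFAULT_DDG_BINS = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, float("inf"))
MAX_CLINICAL_SEQ_LEN = 1000


@dataclass
class VariantCall:
    record: MutationRecord
    predicted_ddg: float
    call: str


def classify_variant(ddg: float, threshold: float = PATHOGENIC_DDG_THRESHOLD) -> str:
    """Benign iff |ddG| <= threshold; pathogenic otherwise (either sign)."""
    if not np.isfinite(ddg):
        raise ValueError("ddG must be finite")
    return "benign" if abs(ddg) <= threshold else "pathogenic"


def harmonize_clinical_label(label: str) -> int | None:
    """Map free-text clinical significance to binary (1 pathogenic, 0 benign).

    Any label containing "pathogenic" is positive, any containing "benign"
    negative; conflicting or uninformative strings map to None.
    """
    s = label.strip().lower()
    has_p = "pathogenic" in s
    has_b = "benign" in s
    if has_p == has_b:
        return None
    return 1 if has_p else 0


def pathogenicity_report(
    predicted_ddg: Sequence[float],
    labels: Sequence[int],
    threshold: float = PATHOGENIC_DDG_THRESHOLD,
    bins: Sequence[float] = DEFAULT_DDG_BINS,
) -> dict:
    """Stability-based pathogenicity screen summary.

    Scores are |ddG| (both signs count as perturbing); AUC is rank-based on
    |ddG|, the confusion-matrix metrics apply the |ddG| > threshold rule, and
    the binned curve gives the pathogenic fraction per |ddG| interval.
    """
    ddg = np.asarray(predicted_ddg, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if ddg.shape != y.shape:
        raise ValueError("predictions and labels lengths differ")
    score = np.abs(ddg)
    report: dict = {"n": int(y.size), "threshold": threshold}
    report["mean_abs_ddg_pathogenic"] = (
        float(score[y == 1].mean()) if np.any(y == 1) else None
    )
    report["mean_abs_ddg_benign"] = float(score[y == 0].mean()) if np.any(y == 0) else None
    if report["mean_abs_ddg_pathogenic"] is None or report["mean_abs_ddg_benign"] is None:
        report["single_class"] = True
    report.update(classification_metrics(score, y, threshold))

    edges = np.asarray(bins, dtype=np.float64)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (score >= lo) & (score < hi)
        rows.append(
            {
                "abs_ddg_lo": lo,
                "abs_ddg_hi": hi,
                "n": int(mask.sum()),
                "pathogenic_fraction": float(y[mask].mean()) if mask.any() else float("nan"),
            }
        )
    report["bins"] = rows
    return report


def temp_class_of(t_opt: float) -> str:
    """Temperature class from the half-open boundaries at 20/45/80 °C."""
    if not np.isfinite(t_opt):
        raise ValueError("t_opt must be finite")
    for cls, upper in zip(TEMP_CLASSES[:-1], TEMP_BOUNDS):
        if t_opt < upper:
            return cls
    return TEMP_CLASSES[-1]


@dataclass
class TempClassMatrix:
    classes: tuple[str, ...]
    mean_ddg: np.ndarray  # 4x4, NaN where no pairs sampled
    counts: np.ndarray  # 4x4 int

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = list(self.classes)
        return (
            pd.DataFrame(self.mean_ddg, index=idx, columns=idx),
            pd.DataFrame(self.counts, index=idx, columns=idx),
        )


def ogt_class_matrix(
    proteins: Sequence[tuple[ProteinGraph, float]],
    params: ModelParams,
    cfg: ModelConfig,
    max_pairs: int = 2000,
    seed: int = 0,
) -> TempClassMatrix:
    """Mean predicted ddG between temperature classes.

    Unordered protein pairs are sampled (uniformly, seeded, when the full
    grid exceeds ``max_pairs``) and every sampled pair is predicted in both
    directions (p as wild, q as mutant and vice versa), so the count matrix
    is symmetric and an architecturally antisymmetric model produces an
    exactly antisymmetric mean matrix on the same pairs.
    """
    classes = [temp_class_of(t) for _, t in proteins]
    if len(set(classes)) < 2:
        raise ValueError("need proteins from at least 2 temperature classes")
    n = len(proteins)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(all_pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(all_pairs), size=max_pairs, replace=False)
        pairs = [all_pairs[k] for k in sorted(chosen)]
    else:
        pairs = all_pairs

    sums = np.zeros((4, 4))
    counts = np.zeros((4, 4), dtype=np.int64)
    cls_idx = {c: k for k, c in enumerate(TEMP_CLASSES)}
    batch: list[tuple[int, int]] = []

    def flush(batch_pairs: list[tuple[int, int]]) -> None:
        if not batch_pairs:
            return
        bw = net.make_batch([net.pack_graph(proteins[i][0], cfg) for i, _ in batch_pairs])
        bm = net.make_batch([net.pack_graph(proteins[j][0], cfg) for _, j in batch_pairs])
        preds = net.forward_pairs(bw, bm, params, cfg).value[:, 0]
        for (i, j), p in zip(batch_pairs, preds):
            sums[cls_idx[classes[i]], cls_idx[classes[j]]] += p
            counts[cls_idx[classes[i]], cls_idx[classes[j]]] += 1

    for i, j in pairs:
        batch.extend([(i, j), (j, i)])
        if len(batch) >= 256:
            flush(batch)
            batch = []
    flush(batch)

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TempClassMatrix(classes=TEMP_CLASSES, mean_ddg=mean, counts=counts)


def plot_ogt_matrix(matrix: TempClassMatrix, path: str | Path) -> None:
    """Render the class-vs-class mean ddG heatmap to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    finite = matrix.mean_ddg[np.isfinite(matrix.mean_ddg)]
    vmax = float(np.abs(finite).max()) if finite.size else 1.0
    im = ax.imshow(matrix.mean_ddg, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(4), matrix.classes, rotation=45, ha="right")
    ax.set_yticks(range(4), matrix.classes)
    ax.set_xlabel("mutant class")
    ax.set_ylabel("wild class")
    fig.colorbar(im, ax=ax, label="mean predicted ddG (kcal/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
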