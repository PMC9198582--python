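"""Patch scoring, threshold optimization, and stratified accuracy.

A patch's anomaly score is the spatial mean of the pixel-wise loss map
(l1, MSE, or BCE) between the patch and its deterministic reconstruction
(the VAE scores with eps = 0).  Healthy/anomalous classification uses a
single score threshold chosen to maximize accuracy: the optimizer
exhaustively evaluates every cut between consecutive sorted unique scores
(plus below-min and above-max), which is exact and O(n log n).
Ties in accuracy resolve to the smaller threshold.  Stratified evaluation
reuses the globally optimized threshold within each growth-stage stratum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .losses import pixel_loss_map, PIXEL_METRICS
from .patches import Patch

__all__ = [
    "ScoreRecord",
    "ThresholdResult",
    "score_patches",
    "optimize_threshold",
    "evaluate_stratified",
    "score_histogram",
    "write_scores",
    "read_scores",
]


@dataclass(frozen=True)
class ScoreRecord:
    patch_id: str
    score: float
    metric: str
    label: str
    stage_tag: str


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int
    metric: str

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def score_patches(model, patches: list[Patch], metric: str = "mse",
                  batch_size: int = 64) -> list[ScoreRecord]:
    """Score every patch by its mean reconstruction loss (eval mode).

    ``model`` must expose ``reconstruct(batch) -> batch``; the VAE's
    reconstruct uses the deterministic eps = 0 pass, so scores are
    reproducible across calls.
    """
    if metric not in PIXEL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {PIXEL_METRICS}")
    records: list[ScoreRecord] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start:start + batch_size]
        batch = np.stack([p.pixels for p in chunk]).astype(np.float32)
        recon = model.reconstruct(batch)
        for p, x, xh in zip(chunk, batch, recon):
            _, score = pixel_loss_map(x, xh, metric)
            records.append(ScoreRecord(patch_id=p.patch_id, score=score,
                                       metric=metric, label=p.label,
                                       stage_tag=p.stage_tag))
    return records


def _counts_at(scores: np.ndarray, labels: np.ndarray,
               threshold: float) -> tuple[int, int, int, int]:
    pred = scores > threshold           # high reconstruction error => anomalous
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return tp, tn, fp, fn


def optimize_threshold(records: list[ScoreRecord]) -> ThresholdResult:
    """Exact accuracy-maximizing threshold over all candidate cuts.

    Candidates are the midpoints between consecutive sorted unique scores
    plus one cut below the minimum and one above the maximum; the rule is
    ``score > threshold => anomalous``.
    """
    if not records:
        raise ValueError("no score records given")
    labels = np.array([r.label == "anomalous" for r in records])
    if labels.all() or not labels.any():
        raise ValueError("threshold optimization needs both healthy and "
                         "anomalous records; got a single class")
    metric = records[0].metric
    scores = np.array([r.score for r in records], dtype=np.float64)
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]])
    # vectorized: for each candidate count correct predictions
    pred = scores[None, :] > candidates[:, None]
    correct = (pred == labels[None, :]).sum(axis=1)
    best = int(np.argmax(correct))      # argmax returns the first (smallest) tie
    thr = float(candidates[best])
    tp, tn, fp, fn = _counts_at(scores, labels, thr)
    return ThresholdResult(threshold=thr, accuracy=(tp + tn) / len(records),
                           tp=tp, tn=tn, fp=fp, fn=fn, metric=metric)


def evaluate_stratified(records: list[ScoreRecord], threshold: float,
                        strata: str = "stage_tag") -> dict[str, ThresholdResult]:
    """Accuracy at a fixed threshold, jointly and per stratum.

    Returns a mapping with a ``"joint"`` entry plus one entry per stratum
    value; all rows use the same global threshold, so the per-stratum
    counts sum to the joint counts.
    """
    if not records:
        raise ValueError("no score records given")
    if any(not hasattr(r, strata) for r in records):
        raise ValueError(f"records lack stratum field {strata!r}")
    metric = records[0].metric

    def result_for(sub: list[ScoreRecord]) -> ThresholdResult:
        scores = np.array([r.score for r in sub], dtype=np.float64)
        labels = np.array([r.label == "anomalous" for r in sub])
        tp, tn, fp, fn = _counts_at(scores, labels, threshold)
        return ThresholdResult(threshold=float(threshold),
                               accuracy=(tp + tn) / len(sub),
                               tp=tp, tn=tn, fp=fp, fn=fn, metric=metric)

    out = {"joint": result_for(records)}
    values = sorted({getattr(r, strata) for r in records})
    for v in values:
        out[v] = result_for([r for r in records if getattr(r, strata) == v])
    return out


def score_histogram(records: list[ScoreRecord],
                    bins: int = 30) -> dict[str, np.ndarray]:
    """Per-label histograms over shared bin edges.

    Returns ``{"edges": ..., "<label>": counts, ...}``; counts per label
    sum to that label's record count.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    scores = np.array([r.score for r in records], dtype=np.float64)
    lo, hi = scores.min(), scores.max()
    if lo == hi:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, bins + 1)
    out: dict[str, np.ndarray] = {"edges": edges}
    for label in sorted({r.label for r in records}):
        vals = np.array([r.score for r in records if r.label == label])
        out[label], _ = np.histogram(vals, bins=edges)
    return out


def write_scores(records: list[ScoreRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r)) + "\n")
    return path


def read_scores(path: str | Path) -> list[ScoreRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            records.append(ScoreRecord(**json.loads(line)))
    return records
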