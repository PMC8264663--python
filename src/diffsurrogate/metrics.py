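"""Residual-based evaluation of surrogate field predictions.

All metrics operate on the per-pixel residual |y - yhat| between ground
truth and prediction, pooled over every pixel of every evaluated pair:

* mean / 99th-percentile / maximum residual (the percentile by linear
  interpolation between order statistics);
* relative residual |y - yhat| / y, masked where y falls below a floor --
  the field vanishes toward the absorbing boundary, where relative error
  diverges and is not meaningful;
* slice statistics: residual mean and standard deviation within ground-truth
  value bands [0.1 (i-1), 0.1 i), i = 1..10 (last band closed at 1), which
  compensates for the rarity of high field values;
* value-distribution (PDF) comparison between predicted and true fields.

Standard deviations use the population convention (divide by n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Histogram",
    "ResidualReport",
    "residual_map",
    "relative_residual_map",
    "summarize_residuals",
    "slice_statistics",
    "slice_aggregate",
    "field_pdf",
    "histogram_intersection",
    "evaluate_model",
]


def _pool(pred, target) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.size == 0:
        raise ValueError("empty evaluation set")
    return pred.ravel(), target.ravel()


def residual_map(prediction: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Elementwise absolute error |y - yhat|."""
    prediction = np.asarray(prediction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {target.shape}")
    return np.abs(target - prediction)


def relative_residual_map(
    prediction: np.ndarray, target: np.ndarray, floor: float = 1e-3
) -> np.ma.MaskedArray:
    """Relative error |y - yhat| / y, masked where y < floor.

    Masked pixels are excluded from any downstream summary; the result never
    contains non-finite values.
    """
    if not (floor > 0):
        raise ValueError("floor must be positive")
    res = residual_map(prediction, target)
    target = np.asarray(target, dtype=np.float64)
    mask = target < floor
    safe = np.where(mask, 1.0, target)
    return np.ma.MaskedArray(res / safe, mask=mask)


def summarize_residuals(
    prediction_set: np.ndarray, target_set: np.ndarray
) -> tuple[float, float, float]:
    """(mean, 99th percentile, max) over the pooled pixel residuals."""
    pred, target = _pool(prediction_set, target_set)
    res = np.abs(target - pred)
    return (
        float(res.mean()),
        float(np.percentile(res, 99.0)),
        float(res.max()),
    )


def slice_statistics(
    prediction_set: np.ndarray, target_set: np.ndarray, n_slices: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residual mean/std/count within equal ground-truth value bands on [0, 1].

    Band k (0-based) is [k/n, (k+1)/n), the last closed at 1; ground-truth
    values above 1 land in the last band. Empty bands report count 0 and NaN
    statistics.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    pred, target = _pool(prediction_set, target_set)
    res = np.abs(target - pred)
    bands = np.minimum((target * n_slices).astype(int), n_slices - 1)
    bands[target < 0] = 0
    counts = np.bincount(bands, minlength=n_slices)
    sums = np.bincount(bands, weights=res, minlength=n_slices)
    sqsums = np.bincount(bands, weights=res**2, minlength=n_slices)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 0, sqsums / np.maximum(counts, 1) - means**2, np.nan)
    stds = np.sqrt(np.maximum(var, 0.0))
    return means, stds, counts


def slice_aggregate(
    per_slice_mean: np.ndarray, per_slice_std: np.ndarray
) -> dict[str, float]:
    """Unweighted average and max over populated slices, for mean and std.

    Gives each band equal weight regardless of how many pixels fall in it,
    compensating for the value imbalance of the field.
    """
    mean = np.asarray(per_slice_mean, dtype=np.float64)
    std = np.asarray(per_slice_std, dtype=np.float64)
    ok = np.isfinite(mean)
    if not ok.any():
        raise ValueError("all slices are empty")
    return {
        "avg_slice_mean": float(mean[ok].mean()),
        "max_slice_mean": float(mean[ok].max()),
        "avg_slice_std": float(std[ok].mean()),
        "max_slice_std": float(std[ok].max()),
    }


@dataclass
class Histogram:
    """Density-normalized histogram on [0, 1]; integrates to 1."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_clipped: int = 0  # values outside [0, 1] clipped into range

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "density": self.density.tolist(),
            "n_clipped": self.n_clipped,
        }


def field_pdf(image_set: np.ndarray, n_bins: int = 100) -> Histogram:
    """Probability density of field values over [0, 1] with equal-width bins."""
    values = np.asarray(image_set, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty image set")
    clipped = int(np.count_nonzero((values < 0) | (values > 1)))
    values = np.clip(values, 0.0, 1.0)
    density, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0), density=True)
    return Histogram(edges, density, clipped)


def histogram_intersection(a: Histogram, b: Histogram) -> float:
    """Overlap of two densities on a shared binning: sum of min * bin width.

    1 means identical distributions, 0 means disjoint support.
    """
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(
        a.bin_edges, b.bin_edges
    ):
        raise ValueError("histograms must share bin edges")
    widths = np.diff(a.bin_edges)
    return float(np.sum(np.minimum(a.density, b.density) * widths))


@dataclass
class ResidualReport:
    """Full evaluation summary for one model on one set of pairs."""

    mean_residual: float
    p99_residual: float
    max_residual: float
    mean_relative_residual: float
    per_slice_mean: list[float]
    per_slice_std: list[float]
    slice_counts: list[int]
    slice_aggregates: dict[str, float]
    pdf_predicted: Histogram
    pdf_truth: Histogram
    pdf_overlap: float
    n_pairs: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mean_residual": self.mean_residual,
            "p99_residual": self.p99_residual,
            "max_residual": self.max_residual,
            "mean_relative_residual": self.mean_relative_residual,
            "per_slice_mean": self.per_slice_mean,
            "per_slice_std": self.per_slice_std,
            "slice_counts": self.slice_counts,
            "slice_aggregates": self.slice_aggregates,
            "pdf_predicted": self.pdf_predicted.to_dict(),
            "pdf_truth": self.pdf_truth.to_dict(),
            "pdf_overlap": self.pdf_overlap,
            "n_pairs": self.n_pairs,
        }
        d.update(self.extra)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_model(
    model,
    inputs: np.ndarray,
    targets: np.ndarray,
    batch_size: int = 32,
    relative_floor: float = 1e-3,
    n_slices: int = 10,
    pdf_bins: int = 100,
) -> ResidualReport:
    """Predict every pair in batches and compute the full residual report."""
    preds = np.concatenate(
        [
            model.predict(np.asarray(inputs[i : i + batch_size], dtype=np.float64))
            for i in range(0, len(inputs), batch_size)
        ]
    )
    mean_r, p99_r, max_r = summarize_residuals(preds, targets)
    rel = relative_residual_map(preds, targets, floor=relative_floor)
    means, stds, counts = slice_statistics(preds, targets, n_slices=n_slices)
    pdf_pred = field_pdf(preds, n_bins=pdf_bins)
    pdf_true = field_pdf(targets, n_bins=pdf_bins)
    return ResidualReport(
        mean_residual=mean_r,
        p99_residual=p99_r,
        max_residual=max_r,
        mean_relative_residual=float(rel.mean()) if not rel.mask.all() else float("nan"),
        per_slice_mean=[float(v) for v in means],
        per_slice_std=[float(v) for v in stds],
        slice_counts=[int(c) for c in counts],
        slice_aggregates=slice_aggregate(means, stds),
        pdf_predicted=pdf_pred,
        pdf_truth=pdf_true,
        pdf_overlap=histogram_intersection(pdf_pred, pdf_true),
        n_pairs=len(inputs),
    )
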