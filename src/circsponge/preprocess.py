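"""Normalization and probe filtering.

Raw intensities are log2-transformed (with a small offset guarding zeros),
quantile-normalized on the log2 scale so every array shares the mean
distribution of order statistics, and then low-intensity probes -- probes that
never rise convincingly above the per-array background quantile -- are dropped.
The pipeline applies the steps in exactly that order: log2, quantile
normalization, filtering.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "filter_low_intensity",
    "EmptyMatrixError",
]


class EmptyMatrixError(ValueError):
    """Filtering removed every probe; the pipeline cannot continue."""


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset) for a raw-scale matrix.

    ``offset`` (default 1.0) keeps zero intensities finite; set it to 0 only
    for strictly positive data.
    """
    if m.scale != "raw":
        raise ValidationError("log2_transform expects a raw-scale matrix")
    vals = m.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("negative intensities cannot be log-transformed")
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    shifted = vals + offset
    if (shifted <= 0).any():
        raise ValidationError("zero intensities require a positive offset")
    out = m.values.copy()
    out.loc[:, :] = np.log2(shifted)
    return m.with_values(out, scale="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean distribution of order statistics.

    After normalization the sorted values of every column are identical (the
    cross-column mean of order statistics).  Ties within a column receive the
    mean of the reference values at their tied ranks, which makes the
    operation deterministic and idempotent.
    """
    if m.scale != "log2":
        raise ValidationError("quantile_normalize expects a log2-scale matrix")
    X = m.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        out = copy.copy(m)  # shallow, skips re-validation of the degenerate design
        out.values = m.values.copy()
        return out
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_probes)
        assigned[order] = reference
        # average the reference values over tied input values
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inverse, minlength=len(uniq))
        out[:, j] = (sums / counts)[inverse]
    df = m.values.copy()
    df.loc[:, :] = out
    return m.with_values(df)


def filter_low_intensity(
    m: ExpressionMatrix, quantile_cut: float = 0.2, min_samples: int = 3
) -> ExpressionMatrix:
    """Keep probes exceeding the per-sample ``quantile_cut`` quantile in at
    least ``min_samples`` samples.

    The rule is scale-free (works on raw or log2 values).  ``quantile_cut <= 0``
    keeps every probe.
    """
    if not 0 <= quantile_cut < 1:
        raise ValidationError("quantile_cut must lie in [0, 1)")
    n_samples = m.values.shape[1]
    if min_samples > n_samples:
        raise ValidationError("min_samples exceeds the number of samples")
    if quantile_cut <= 0:
        return m.with_values(m.values.copy())
    X = m.values.to_numpy(dtype=float)
    thresholds = np.quantile(X, quantile_cut, axis=0)
    keep = (X > thresholds[None, :]).sum(axis=1) >= min_samples
    if not keep.any():
        raise EmptyMatrixError(
            "low-intensity filter removed every probe; relax quantile_cut"
        )
    return m.with_values(m.values.loc[keep])
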