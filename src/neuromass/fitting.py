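"""Goodness-of-fit metrics and sweep orchestration.

FC matrices are compared with a global structural similarity index (SSIM)
computed over the full matrix with the standard stabilizing constants;
relative-power vectors are compared with the Clarkson similarity
1 - (1/2)||x/|x| - y/|y|||.  Dual (EEG + fMRI) fitting masks the grid by an
EEG-power similarity threshold (0.85) and maximizes SSIM over the
surviving cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ssim",
    "clarkson_similarity",
    "SweepResult",
    "grid_sweep",
    "masked_dual_fit",
    "cohens_d",
    "strength_inhibition_slope",
]


def ssim(a: np.ndarray, b: np.ndarray, k1: float = 0.01, k2: float = 0.03) -> float:
    """Global structural similarity between two equally shaped matrices.

    Uses the single-window SSIM formula over all entries, with the dynamic
    range L taken as max - min over both matrices jointly.  Symmetric, and
    ssim(a, a) = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have identical shapes")
    data_range = max(a.max(), b.max()) - min(a.min(), b.min())
    if data_range == 0:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("zero dynamic range with unequal matrices")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def clarkson_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """1 - (1/2)||x/|x| - y/|y||| (Euclidean); scale-invariant per argument."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cannot normalize a zero vector")
    return float(1.0 - 0.5 * np.linalg.norm(x / nx - y / ny))


@dataclass
class SweepResult:
    """Tidy record of a parameter-grid sweep: one row dict per cell with the
    parameter values, per-seed metric values, and their mean."""

    axes: dict[str, np.ndarray]
    rows: list[dict[str, Any]] = field(default_factory=list)

    def grid(self, key: str) -> np.ndarray:
        """Metric means reshaped onto the sweep grid (axis order as given)."""
        shape = tuple(len(v) for v in self.axes.values())
        out = np.full(shape, np.nan)
        names = list(self.axes)
        for row in self.rows:
            idx = tuple(
                int(np.argmin(np.abs(self.axes[name] - row[name]))) for name in names
            )
            out[idx] = row[key]
        return out


def grid_sweep(
    axes: Mapping[str, Sequence[float]],
    objective: Callable[..., Mapping[str, float]],
    seeds: Sequence[int],
) -> SweepResult:
    """Evaluate ``objective(seed=..., **cell_params)`` on the full cartesian
    grid; per-seed values are stored and averaged per cell.

    Cells are independent and the result does not depend on evaluation
    order; a cell whose objective raises is recorded with NaN metrics
    rather than aborting the sweep.
    """
    axes = {name: np.asarray(vals, dtype=float) for name, vals in axes.items()}
    result = SweepResult(axes=axes)
    names = list(axes)
    for values in product(*axes.values()):
        cell = dict(zip(names, (float(v) for v in values)))
        per_seed: dict[str, list[float]] = {}
        failed = False
        for seed in seeds:
            try:
                metrics = objective(seed=int(seed), **cell)
            except FloatingPointError:
                failed = True
                break
            for key, val in metrics.items():
                per_seed.setdefault(key, []).append(float(val))
        row = dict(cell)
        row["seeds"] = list(int(s) for s in seeds)
        row["diverged"] = failed
        for key, vals in per_seed.items():
            row[key] = float("nan") if failed else float(np.mean(vals))
        result.rows.append(row)
    return result


def masked_dual_fit(
    fc_scores: np.ndarray,
    eeg_scores: np.ndarray,
    threshold: float = 0.85,
) -> dict[str, Any]:
    """Best grid cell by SSIM among cells whose EEG-power similarity is at
    least ``threshold``.

    Returns {"index": (i, j, ...), "fc_score": ..., "eeg_score": ...,
    "feasible": bool}; ties break by higher EEG score, then lexicographic
    cell index.  An empty mask yields feasible=False instead of raising.
    """
    fc = np.asarray(fc_scores, dtype=float)
    eeg = np.asarray(eeg_scores, dtype=float)
    if fc.shape != eeg.shape:
        raise ValueError("score grids must have identical shapes")
    mask = eeg >= threshold
    if not np.any(mask):
        return {"index": None, "fc_score": None, "eeg_score": None, "feasible": False}
    best = None
    for idx in np.ndindex(fc.shape):
        if not mask[idx]:
            continue
        key = (fc[idx], eeg[idx], tuple(-i for i in idx))
        if best is None or key > best[0]:
            best = (key, idx)
    idx = best[1]
    return {
        "index": idx,
        "fc_score": float(fc[idx]),
        "eeg_score": float(eeg[idx]),
        "feasible": True,
    }


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Effect size (mean x - mean y) / pooled SD.

    Conventional magnitude labels: <0.2 very small, 0.2-0.5 small, 0.5-0.8
    moderate, 0.8-1.2 large, 1.2-2 very large.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least two observations")
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def strength_inhibition_slope(
    strengths: np.ndarray, mean_c4: np.ndarray
) -> tuple[float, float, float]:
    """OLS regression of time-averaged c4 on nodal strength across regions;
    returns (slope, intercept, r)."""
    s = np.asarray(strengths, dtype=float)
    c = np.asarray(mean_c4, dtype=float)
    if s.size != c.size or s.size < 3:
        raise ValueError("need matched vectors of at least three regions")
    if s.std() == 0:
        raise ValueError("constant strengths: regression undefined")
    fit = stats.linregress(s, c)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
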