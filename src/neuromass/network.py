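"""Structural connectome handling and the inter-regional coupling term.

Connectomes are symmetric, zero-diagonal, nonnegative N x N weight matrices
normalized so the maximum weight is 1.  Long-range projections couple only
pyramidal populations: region i receives K * C * sum_j M_ij * S(x1_j - x2_j).

A synthetic generator stands in for diffusion-imaging connectomes: it emits
log-normal weights with block-modular structure and hemispheric mirror
symmetry, ordered so that homotopic (left/right counterpart) region pairs
sit on the matrix anti-diagonal, the convention used when reinforcing
inter-hemispheric connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "validate_connectome",
    "reinforce_homotopic",
    "synthetic_connectome",
    "nodal_strength",
    "coupling_input",
    "load_connectome",
    "save_connectome",
]


@dataclass
class Connectome:
    """Symmetric [0, 1]-normalized weight matrix with region labels."""

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.labels:
            self.labels = [str(i) for i in range(self.weights.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def validate_connectome(
    raw: np.ndarray,
    labels: list[str] | None = None,
    asym_tol: float = 1e-8,
) -> Connectome:
    """Validate and canonicalize a raw weight matrix.

    Symmetrizes as (M + M.T)/2 when the asymmetry is within ``asym_tol``
    (relative to the largest weight), zeroes the diagonal, and rescales to a
    maximum weight of 1.  Negative, non-finite or non-square input is
    rejected.
    """
    m = np.asarray(raw, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("connectome contains non-finite entries")
    if np.any(m < 0):
        raise ValueError("connectome contains negative weights")
    scale = max(m.max(), 1.0)
    if np.max(np.abs(m - m.T)) > asym_tol * scale:
        raise ValueError("connectome asymmetry exceeds tolerance")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    top = m.max()
    if top > 0:
        m = m / top
    if labels is not None and len(labels) != m.shape[0]:
        raise ValueError("label count does not match matrix size")
    return Connectome(weights=m, labels=list(labels) if labels else [])


def reinforce_homotopic(c: Connectome, weight: float) -> Connectome:
    """Raise anti-diagonal (homotopic pair) weights to at least ``weight``.

    Assumes the node ordering places each region's contralateral homolog at
    the mirrored index (AAL-style ordering), i.e. pairs (i, N-1-i).  Entries
    are set to max(existing, weight), symmetry is preserved, and the matrix
    is renormalized to a maximum of 1.  Requires an even node count so no
    region pairs with itself.
    """
    if not (0.0 <= weight <= 1.0):
        raise ValueError("reinforcement weight must lie in [0, 1]")
    n = c.n_nodes
    if n % 2 == 1:
        raise ValueError("odd node count: center node would pair with itself")
    m = c.weights.copy()
    for i in range(n):
        j = n - 1 - i
        if m[i, j] < weight:
            m[i, j] = m[j, i] = weight
    top = m.max()
    if top > 0:
        m = m / top
    return Connectome(weights=m, labels=list(c.labels))


def synthetic_connectome(
    n_nodes: int,
    seed: int,
    density: float = 0.3,
    modules: int = 2,
    within_boost: float = 3.0,
    sigma: float = 0.8,
) -> Connectome:
    """Generate a random modular, hemispherically mirrored connectome.

    One hemisphere of n_nodes/2 regions is drawn with log-normal weights on
    a ``density``-sparse support, ``modules`` blocks of elevated within-block
    weight, then mirrored onto the second hemisphere and given homotopic
    links so the whole graph is connected.  Node ordering is AAL-style:
    the second hemisphere is reversed, so homotopic pairs are (i, N-1-i).
    """
    if n_nodes < 4 or n_nodes % 2:
        raise ValueError("n_nodes must be even and at least 4")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    half = n_nodes // 2
    if modules < 1 or modules > half:
        raise ValueError("modules must lie in [1, n_nodes/2]")
    rng = np.random.default_rng(seed)

    w = np.exp(rng.normal(0.0, sigma, size=(half, half)))
    w = np.triu(w, k=1)
    keep = np.triu(rng.random((half, half)) < density, k=1)
    w = w * keep
    block = np.array_split(np.arange(half), modules)
    for idx in block:
        sub = np.ix_(idx, idx)
        w[sub] = w[sub] * within_boost
    # ring backbone keeps each hemisphere connected at any density
    for i in range(half - 1):
        if w[i, i + 1] == 0:
            w[i, i + 1] = np.exp(rng.normal(0.0, sigma))
    w = w + w.T

    m = np.zeros((n_nodes, n_nodes))
    m[:half, :half] = w
    mirror = w[::-1, ::-1]  # reversed ordering in the second hemisphere
    m[half:, half:] = mirror
    # sparse, weaker non-homotopic callosal links
    cross = 0.3 * np.exp(rng.normal(0.0, sigma, size=(half, half)))
    cross = cross * (rng.random((half, half)) < density)
    m[:half, half:] = cross
    m[half:, :half] = cross.T
    for i in range(half):  # homotopic bridges on the anti-diagonal
        j = n_nodes - 1 - i
        m[i, j] = m[j, i] = np.exp(rng.normal(0.0, sigma))
    labels = [f"R{i}-L" for i in range(half)] + [f"R{i}-R" for i in range(half)][::-1]
    return validate_connectome(m, labels=labels)


def nodal_strength(c: Connectome) -> np.ndarray:
    """Row sums of the weight matrix (equal to column sums by symmetry)."""
    return c.weights.sum(axis=1)


def coupling_input(
    pyr_outputs: np.ndarray,
    c: Connectome,
    K: float,
    C: float = 135.0,
) -> np.ndarray:
    """Network drive per region: K * C * sum_{j != i} M_ij * S(x1_j - x2_j).

    The diagonal of a validated connectome is zero, so a plain matrix-vector
    product implements the j != i sum.
    """
    rates = np.asarray(pyr_outputs, dtype=float)
    if rates.shape != (c.n_nodes,):
        raise ValueError("rate vector length does not match connectome size")
    return K * C * (c.weights @ rates)


def save_connectome(c: Connectome, path: str | Path) -> None:
    """Write as CSV with a header row of region labels."""
    pd.DataFrame(c.weights, columns=c.labels).to_csv(path, index=False)


def load_connectome(path: str | Path) -> Connectome:
    """Read a delimited-text connectome (CSV/TSV, optional label header)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    first = path.read_text().splitlines()[0]
    has_header = any(
        not tok.replace(".", "", 1).replace("-", "", 1).replace("e", "", 1)
        .replace("E", "", 1).replace("+", "", 1).isdigit()
        for tok in first.split(sep)
        if tok.strip()
    )
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    labels = [str(col) for col in df.columns] if has_header else None
    return validate_connectome(df.to_numpy(dtype=float), labels=labels)
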