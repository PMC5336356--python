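"""Two-coordinate MDS lens by least-squares stress minimization.

The lens embeds the patient dissimilarity matrix into the plane by
minimizing the raw stress sum over patient pairs

    stress(Z) = sum_{i<j} (d_ij - ||z_i - z_j||)^2 .

Optimization is deterministic: a classical (Torgerson) MDS solution of the
double-centered squared-dissimilarity matrix provides the start, and SMACOF
majorization (Guttman transform) descends from there; the stress sequence is
provably non-increasing.  Axes are ordered by sample variance (coordinate 1
carries the most), a fixed sign convention removes reflections, and each
coordinate is finally range-scaled to [0, 1] (Gower scaling) so that cover
construction downstream is well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .syndromic_distance import DistanceMatrix


@dataclass
class LensEmbedding:
    """Per-patient lens coordinates.

    ``coords`` holds the range-normalized coordinates in [0, 1]; ``raw_coords``
    the pre-normalization solution on which the variance ordering holds.
    """

    coords: np.ndarray
    raw_coords: np.ndarray
    stress: float
    patient_ids: list[str]
    normalized: bool = True
    iterations: int = 0
    stress_history: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.coords,
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=[f"mds{k + 1}" for k in range(self.coords.shape[1])],
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# stress={self.stress!r} iterations={self.iterations}\n")
            frame.to_csv(fh)


def classical_mds(d: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centered squared
    dissimilarities, axes ordered by eigenvalue, signs fixed."""
    n = d.n
    if n < 3:
        raise ValueError("classical MDS needs at least 3 patients")
    if k > n - 1:
        raise ValueError("embedding dimension must be at most n - 1")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    # numerically-zero eigenvalues give exactly flat axes, not noise axes
    lam[lam < 1e-9 * max(lam.max(), 1e-300)] = 0.0
    coords = evecs[:, order] * np.sqrt(lam)
    return _fix_signs(coords)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Flip each axis so the lowest-index patient among those with maximal
    absolute coordinate has positive sign (removes reflection ambiguity)."""
    coords = coords.copy()
    for a in range(coords.shape[1]):
        col = coords[:, a]
        amax = np.abs(col).max()
        if amax <= 0:
            continue
        leader = int(np.flatnonzero(np.abs(col) >= amax - 1e-12)[0])
        if col[leader] < 0:
            coords[:, a] = -col
    return coords


def stress(d: DistanceMatrix, z: np.ndarray) -> float:
    """Raw stress: sum over unordered pairs of squared residuals between the
    input dissimilarities and the embedded Euclidean distances."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != d.n:
        raise ValueError("coordinate matrix must be n_patients x k")
    emb = pdist(z)
    target = squareform(d.values, checks=False)
    return float(((target - emb) ** 2).sum())


def _smacof(
    d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, list[float]]:
    """Unweighted SMACOF majorization with stress tracking."""
    n = d.shape[0]
    x = x0.copy()
    target = squareform(d, checks=False)
    emb = pdist(x)
    history = [float(((target - emb) ** 2).sum())]
    for _ in range(max_iter):
        dist = squareform(emb, checks=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, d / np.where(dist > 0, dist, 1.0), 0.0)
        b = -ratio
        b[np.arange(n), np.arange(n)] = ratio.sum(axis=1)
        x = b @ x / n
        emb = pdist(x)
        s = float(((target - emb) ** 2).sum())
        history.append(s)
        prev = history[-2]
        if prev - s <= tol * max(prev, 1e-30):
            break
    return x, history


def optimize_lens(
    d: DistanceMatrix, max_iter: int = 300, tol: float = 1e-6, k: int = 2
) -> LensEmbedding:
    """MDS lens: classical start, SMACOF descent, variance-ordered axes,
    fixed signs, Gower range scaling of each coordinate to [0, 1].

    Non-convergence within ``max_iter`` produces a warning, not an error;
    the best (latest) configuration is returned.  A degenerate axis (all
    patients identical) is normalized to the midpoint 0.5 with a warning.
    """
    x0 = classical_mds(d, k)
    x, history = _smacof(d.values, x0, max_iter, tol)
    if len(history) - 1 >= max_iter:
        final_drop = history[-2] - history[-1]
        if final_drop > tol * max(history[-2], 1e-30):
            warnings.warn(
                f"lens optimization did not converge in {max_iter} iterations"
            )
    order = np.argsort(x.var(axis=0))[::-1]
    x = _fix_signs(x[:, order])

    coords = np.empty_like(x)
    spans = x.max(axis=0) - x.min(axis=0)
    span_scale = max(spans.max(), 1e-300)
    for a in range(x.shape[1]):
        lo, hi = x[:, a].min(), x[:, a].max()
        if hi - lo <= 1e-9 * span_scale:
            warnings.warn(f"degenerate lens coordinate {a + 1}: set to 0.5")
            coords[:, a] = 0.5
        else:
            coords[:, a] = (x[:, a] - lo) / (hi - lo)
    return LensEmbedding(
        coords=coords,
        raw_coords=x,
        stress=history[-1],
        patient_ids=list(d.patient_ids),
        normalized=True,
        iterations=len(history) - 1,
        stress_history=history,
    )
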