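"""Deterministic 1-D k-means used to initialize EM fits."""

from __future__ import annotations

import numpy as np


def kmeans1d(x: np.ndarray, k: int, max_iter: int = 100):
    """Lloyd's algorithm on scalars, seeded uniformly across the data range.

    Deterministic: centers start at the midpoints of k equal slices of
    [min, max] — quantile seeding piles every seed into a dominant mode
    when cluster weights are very unequal, which matters for landing-
    event and FRET-state data — and assignment ties break toward the
    lower center. Returns ``(centers, labels)`` with centers sorted
    ascending; a center that captures no points keeps its position.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    centers = lo + (np.arange(k) + 0.5) / k * (hi - lo)
    labels = np.zeros(x.size, dtype=int)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = labels == j
            if np.any(sel):
                new[j] = x[sel].mean()
        new = np.sort(new)
        if np.allclose(new, centers, rtol=0, atol=1e-12):
            centers = new
            break
        centers = new
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    return centers, labels
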