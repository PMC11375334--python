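"""Principal coordinates analysis (classical metric scaling).

Double-centers the squared distance matrix and eigendecomposes it;
coordinates are the eigenvectors scaled by the square roots of positive
eigenvalues.  Negative eigenvalues — expected for semi-metric
dissimilarities such as Bray-Curtis — are reported as-is, never clipped
silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, normalize_tss

METRICS = ("braycurtis", "euclidean")


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray         # all eigenvalues, descending (may be < 0)
    proportion_explained: np.ndarray  # lambda / sum(positive lambdas)


def pcoa(table: AbundanceTable, metric: str = "braycurtis") -> OrdinationResult:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if table.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if metric == "braycurtis" and not table.is_relative:
        warnings.warn(
            "Bray-Curtis on a non-relative table: applying total-sum scaling",
            stacklevel=2,
        )
        table = normalize_tss(table)
    X = table.values()
    D = squareform(pdist(X, metric=metric))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords,
        index=table.data.index,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    pos_sum = eigvals[pos].sum()
    proportion = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    return OrdinationResult(
        coordinates=frame, eigenvalues=eigvals, proportion_explained=proportion
    )
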