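"""Shared helpers: ground-truth spot images and point matching."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from stain3d import synthetic
from stain3d.types import CellPoints


def sample_separated_points(
    n: int,
    extent: tuple[float, float],
    min_separation: float,
    rng: np.random.Generator,
    margin: float = 0.1,
) -> CellPoints:
    """Rejection-sample n points with a pairwise minimum separation (mm)."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError("could not place separated points")
        cand = np.array(
            [rng.uniform(margin, extent[0] - margin), rng.uniform(margin, extent[1] - margin)]
        )
        if all(np.hypot(*(cand - p)) > min_separation for p in pts):
            pts.append(cand)
    arr = np.array(pts)
    return CellPoints(arr[:, 0], arr[:, 1])


def match_points(
    detected: CellPoints,
    truth: CellPoints,
    tol: float,
) -> tuple[float, float, float]:
    """(recall, precision, mean matched distance) with nearest-neighbor
    matching at tolerance ``tol`` (mm)."""
    if len(detected) == 0:
        return 0.0, 0.0, np.inf
    d_truth, _ = cKDTree(detected.coordinates).query(truth.coordinates)
    d_det, _ = cKDTree(truth.coordinates).query(detected.coordinates)
    recall = float((d_truth < tol).mean())
    precision = float((d_det < tol).mean())
    matched = d_truth[d_truth < tol]
    mean_err = float(matched.mean()) if matched.size else np.inf
    return recall, precision, mean_err


@pytest.fixture
def default_phantom():
    return synthetic.generate_phantom(synthetic.PhantomSpec(seed=0))
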