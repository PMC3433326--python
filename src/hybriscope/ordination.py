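"""Group-anchored two-dimensional ordination of dominant-marker genotypes.

Hybrid/parent relationships are not hierarchical, so instead of a tree the
similarity structure is shown as a 2D map: predefined reference groups are
anchored first (their centroids embedded by classical scaling of the
centroid-centroid Euclidean distance matrix, which places the groups at
maximal mutual separation in the plane), and every sample is then positioned
so its 2D distances to the fixed centroids match its original-space distances
to those centroids as closely as possible (least squares, deterministic
multi-start).  A hybrid therefore lands between its parents' groups.

The quality of the map is summarised by the mapping error

    err = sum_{i<j} |d2D(i,j) - d(i,j)| / sum_{i<j} d(i,j),

the relative absolute distortion of pairwise distances.  A configuration that
embeds perfectly in the plane scores 0.

``mode='mds'`` bypasses the group anchoring and returns a plain classical
(metric) MDS of all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError
from .io_model import MarkerMatrix


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coords: np.ndarray  # (n, 2)
    centroids: dict[str, np.ndarray]
    reference_groups: dict[str, list[str]]
    mapping_error: float

    def coord(self, sample_id: str) -> np.ndarray:
        return self.coords[self.sample_ids.index(sample_id)]

    def projection_parameter(self, sample_id: str, group_a: str, group_b: str) -> float:
        """Position of a sample along the segment between two group centroids:
        0 at A's centroid, 1 at B's (orthogonal projection)."""
        ca, cb = self.centroids[group_a], self.centroids[group_b]
        axis = cb - ca
        denom = float(axis @ axis)
        if denom == 0:
            raise AnalysisError("coincident centroids: projection undefined")
        return float((self.coord(sample_id) - ca) @ axis / denom)


def classical_mds(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix into k dimensions."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    # deterministic orientation: first coordinate of the first point nonneg
    for dim in range(k):
        col = coords[:, dim]
        pivot = next((c for c in col if abs(c) > 1e-12), 1.0)
        if pivot < 0:
            coords[:, dim] = -col
    return coords


def mapping_error(d_orig: np.ndarray, coords: np.ndarray) -> float:
    """Relative absolute distortion of pairwise distances in the 2D map."""
    d_orig = np.asarray(d_orig, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = d_orig.shape[0]
    if coords.shape[0] != n:
        raise AnalysisError("coords and distance matrix index sets differ")
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(n, 1)
    denom = d_orig[iu].sum()
    if denom == 0:
        raise AnalysisError("mapping error undefined: zero total original distance")
    return float(np.abs(d2[iu] - d_orig[iu]).sum() / denom)


def _place_sample(targets: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """2D point whose distances to fixed centroids best match `targets`.

    Deterministic multi-start: each centroid, the centroid mean, and a 3x3
    grid over the (padded) centroid bounding box; best final cost wins, ties
    resolved by start order.
    """

    def residual(p: np.ndarray) -> np.ndarray:
        return np.sqrt(((p - centroids) ** 2).sum(axis=1)) - targets

    lo = centroids.min(axis=0)
    hi = centroids.max(axis=0)
    pad = 0.5 * (hi - lo + 1.0)
    grid = [
        np.array([gx, gy])
        for gx in np.linspace(lo[0] - pad[0], hi[0] + pad[0], 3)
        for gy in np.linspace(lo[1] - pad[1], hi[1] + pad[1], 3)
    ]
    starts = [centroids.mean(axis=0)] + [c.copy() for c in centroids] + grid
    best, best_cost = None, np.inf
    for s in starts:
        sol = least_squares(residual, s, method="lm", xtol=1e-12, ftol=1e-12)
        if sol.cost < best_cost - 1e-15:
            best, best_cost = sol.x, sol.cost
    return best


def embed(
    m: MarkerMatrix,
    reference_groups: Mapping[str, Sequence[str]],
    focal_samples: Sequence[str] | None = None,
    mode: str = "anchored",
) -> OrdinationResult:
    """Two-stage anchored ordination (or plain MDS with mode='mds').

    ``reference_groups`` maps labels to member sample ids; ``focal_samples``
    default to every matrix sample not in a reference group.  All samples
    (reference members included) are placed by the distance-matching solver so
    that the map is a single consistent configuration.
    """
    if mode not in ("anchored", "mds"):
        raise AnalysisError(f"unknown ordination mode {mode!r}")
    if len(reference_groups) < 2:
        raise AnalysisError("need at least 2 reference groups")
    for g, members in reference_groups.items():
        if not members:
            raise AnalysisError(f"reference group {g!r} is empty")
        for s in members:
            if s not in m.sample_ids:
                raise AnalysisError(f"reference sample {s!r} not in matrix")
    ref_members = {s for ms in reference_groups.values() for s in ms}
    if focal_samples is None:
        focal_samples = [s for s in m.sample_ids if s not in ref_members]
    order = list(dict.fromkeys(list(ref_members) + list(focal_samples)))
    order = [s for s in m.sample_ids if s in set(order)]  # keep matrix order

    x = m.to_frame().astype(float)
    if mode == "mds":
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x.loc[order].values))
        coords = classical_mds(d, 2)
        centroids = {
            g: coords[[order.index(s) for s in ms]].mean(axis=0)
            for g, ms in reference_groups.items()
        }
        return OrdinationResult(order, coords, centroids, dict(
            (g, list(ms)) for g, ms in reference_groups.items()
        ), mapping_error(d, coords))

    group_labels = list(reference_groups)
    centroid_vecs = np.array(
        [x.loc[list(reference_groups[g])].mean(axis=0).values for g in group_labels]
    )
    cd = np.sqrt(
        ((centroid_vecs[:, None, :] - centroid_vecs[None, :, :]) ** 2).sum(axis=2)
    )
    if np.allclose(cd, 0):
        warnings.warn("all reference centroids coincide; map is degenerate")
    c2d = classical_mds(cd, 2)
    centroids = {g: c2d[i] for i, g in enumerate(group_labels)}

    coords = np.zeros((len(order), 2))
    for i, s in enumerate(order):
        targets = np.sqrt(((x.loc[s].values - centroid_vecs) ** 2).sum(axis=1))
        coords[i] = _place_sample(targets, c2d)

    from scipy.spatial.distance import pdist, squareform

    d_orig = squareform(pdist(x.loc[order].values))
    err = mapping_error(d_orig, coords)
    return OrdinationResult(
        sample_ids=order,
        coords=coords,
        centroids=centroids,
        reference_groups={g: list(ms) for g, ms in reference_groups.items()},
        mapping_error=err,
    )
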