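"""Jaccard distances on dominant markers and Neighbor-Net circular splits.

Neighbor-Net generalises neighbor joining: instead of committing to a tree it
agglomerates taxa into a circular ordering and estimates nonnegative weights
for all splits compatible with that ordering (arcs of the circle).  The
resulting weighted split system can be drawn as a splits graph by
SplitsTree-class viewers via the NEXUS export in io_model.

The agglomeration follows the canonical scheme: clusters of one or two linked
nodes, neighbor-joining-style selection first between clusters (using averaged
distances) and then between their member nodes, and 3-point reductions that
replace a path x–y–z by two new nodes u, v with

    d(u,s) = 2/3 d(x,s) + 1/3 d(y,s)
    d(v,s) = 1/3 d(y,s) + 2/3 d(z,s)
    d(u,v) = 1/3 (d(x,y) + d(y,z) + d(x,z)).

Unwinding the reductions yields the circular ordering; split weights are then
fit by nonnegative least squares of the pairwise distances on the n(n-1)/2
circular splits.  Splits with weight at or below a small floor (numerical
dust from the NNLS) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .errors import AnalysisError
from .io_model import MarkerMatrix

DEFAULT_WEIGHT_FLOOR = 1e-6


def jaccard_distance(m: MarkerMatrix) -> np.ndarray:
    """Pairwise Jaccard distances d = 1 - a/(a+b+c); shared absences ignored.

    a = bands present in both samples, b + c = bands present in exactly one.
    A pair of all-zero rows has no defined distance and raises.
    """
    v = m.values.astype(np.int64)
    a = v @ v.T
    totals = v.sum(axis=1)
    union = totals[:, None] + totals[None, :] - a
    if (union == 0).any():
        i, j = map(int, np.argwhere(union == 0)[0])
        raise AnalysisError(
            f"Jaccard distance undefined for all-absent pair "
            f"({m.sample_ids[i]}, {m.sample_ids[j]})"
        )
    d = 1.0 - a / union
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SplitSystem:
    """Weighted bipartitions compatible with a circular taxon ordering.

    ``cycle`` lists taxon indices in circular order; each split is stored as
    (frozenset of taxon indices on one side, weight), the side chosen not to
    contain cycle[0].
    """

    taxa: list[str]
    cycle: list[int]
    splits: list[tuple[frozenset, float]]

    def __post_init__(self) -> None:
        if sorted(self.cycle) != list(range(len(self.taxa))):
            raise AnalysisError("cycle must be a permutation of taxon indices")
        if any(w < 0 for _, w in self.splits):
            raise AnalysisError("split weights must be nonnegative")

    def nontrivial_splits(self) -> list[tuple[frozenset, float]]:
        n = len(self.taxa)
        return [(s, w) for s, w in self.splits if 1 < len(s) < n - 1]

    def split_sets_by_labels(self, nontrivial_only: bool = True) -> set[frozenset]:
        """Canonical label-sets (smaller side; lexicographic tie-break)."""
        src = self.nontrivial_splits() if nontrivial_only else self.splits
        out = set()
        for side, _ in src:
            labels = frozenset(self.taxa[i] for i in side)
            other = frozenset(t for t in self.taxa if t not in labels)
            out.add(min(labels, other, key=lambda s: (len(s), sorted(s))))
        return out

    def induced_distance(self) -> np.ndarray:
        """d_hat(i,j) = sum of weights of splits separating i and j."""
        n = len(self.taxa)
        d = np.zeros((n, n))
        for side, w in self.splits:
            mask = np.zeros(n, dtype=bool)
            mask[list(side)] = True
            sep = mask[:, None] != mask[None, :]
            d[sep] += w
        return d


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise AnalysisError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise AnalysisError("distance matrix must be symmetric")
    if (d < -1e-12).any() or not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise AnalysisError("distances must be nonnegative with a zero diagonal")
    return d


def neighbor_net_cycle(d: np.ndarray) -> list[int]:
    """Circular taxon ordering by canonical Neighbor-Net agglomeration.

    Ties in the selection criteria are broken toward the lowest node index so
    the ordering is deterministic.
    """
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if n <= 3:
        return list(range(n))

    dist: dict[int, dict[int, float]] = {
        i: {j: float(d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    clusters: list[list[int]] = [[i] for i in range(n)]
    next_id = n
    reductions: list[tuple[int, int, tuple[int, int, int]]] = []

    def dbar(x: int, cluster: list[int]) -> float:
        return sum(dist[x][y] for y in cluster) / len(cluster)

    def cluster_dist(a: list[int], b: list[int]) -> float:
        return sum(dist[x][y] for x in a for y in b) / (len(a) * len(b))

    def reduce_triple(x: int, y: int, z: int) -> tuple[int, int]:
        """Replace path x-y-z by new nodes u, v."""
        nonlocal next_id
        u, v = next_id, next_id + 1
        next_id += 2
        others = [w for w in dist if w not in (x, y, z)]
        dist[u] = {}
        dist[v] = {}
        for s in others:
            du = (2 / 3) * dist[x][s] + (1 / 3) * dist[y][s]
            dv = (1 / 3) * dist[y][s] + (2 / 3) * dist[z][s]
            dist[u][s] = du
            dist[s][u] = du
            dist[v][s] = dv
            dist[s][v] = dv
        duv = (dist[x][y] + dist[y][z] + dist[x][z]) / 3
        dist[u][v] = duv
        dist[v][u] = duv
        for w in (x, y, z):
            del dist[w]
        for s in others:
            for w in (x, y, z):
                dist[s].pop(w, None)
        reductions.append((u, v, (x, y, z)))
        return u, v

    while len(clusters) > 1:
        m = len(clusters)
        # --- cluster selection (NJ criterion on averaged distances)
        cd = {}
        for i, j in combinations(range(m), 2):
            cd[(i, j)] = cluster_dist(clusters[i], clusters[j])
        r = [sum(cd[tuple(sorted((i, k)))] for k in range(m) if k != i) for i in range(m)]
        best, best_q = None, np.inf
        for i, j in combinations(range(m), 2):
            q = (m - 2) * cd[(i, j)] - r[i] - r[j]
            if q < best_q - 1e-12:
                best_q, best = q, (i, j)
        ai, bi = best
        A, B = clusters[ai], clusters[bi]

        # --- node selection: other clusters count as averaged units,
        #     nodes of A and B count individually
        other_clusters = [clusters[k] for k in range(m) if k not in (ai, bi)]
        units_m = len(other_clusters) + len(A) + len(B)
        best_pair, best_q = None, np.inf
        for x in A:
            for y in B:
                rx = sum(dbar(x, C) for C in other_clusters) + sum(
                    dist[x][z] for z in A + B if z != x
                )
                ry = sum(dbar(y, C) for C in other_clusters) + sum(
                    dist[y][z] for z in A + B if z != y
                )
                q = (units_m - 2) * dist[x][y] - rx - ry
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best_pair is not None and (x, y) < best_pair
                ):
                    best_q, best_pair = q, (x, y)
        x, y = best_pair

        # --- merge: chain = [other(A)?, x, y, other(B)?], then reduce to <= 2
        chain = [z for z in A if z != x] + [x, y] + [z for z in B if z != y]
        while len(chain) > 2:
            u, v = reduce_triple(chain[0], chain[1], chain[2])
            chain = [u, v] + chain[3:]
        clusters = [clusters[k] for k in range(m) if k not in (ai, bi)] + [chain]

    # --- expansion: unwind reductions into the circular ordering
    order = list(clusters[0])
    for u, v, (x, y, z) in reversed(reductions):
        iu = order.index(u)
        iv = order.index(v)
        if (iu + 1) % len(order) == iv:
            order[iu : iu + 1] = [x, y]
            order[order.index(v)] = z
        elif (iv + 1) % len(order) == iu:
            order[iv : iv + 1] = [z, y]
            order[order.index(u)] = x
        else:  # pragma: no cover - adjacency is preserved by construction
            raise AnalysisError("internal error: reduced nodes not adjacent in cycle")
    # rotate so taxon 0 leads (canonical presentation)
    i0 = order.index(0)
    return order[i0:] + order[:i0]


def circular_splits(cycle: Sequence[int]) -> list[frozenset]:
    """All n(n-1)/2 splits compatible with a circular ordering, each
    represented by the side not containing cycle[0]."""
    n = len(cycle)
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(cycle[i : j + 1]))
    return out


def fit_split_weights(
    d: np.ndarray, cycle: Sequence[int], weight_floor: float = DEFAULT_WEIGHT_FLOOR
) -> list[tuple[frozenset, float]]:
    """Nonnegative least squares of pairwise distances on the circular splits."""
    d = _check_distance_matrix(d)
    n = d.shape[0]
    sides = circular_splits(cycle)
    masks = np.zeros((len(sides), n), dtype=bool)
    for k, side in enumerate(sides):
        masks[k, list(side)] = True
    iu = np.triu_indices(n, 1)
    # A[p, k] = 1 if split k separates pair p
    sep = masks[:, iu[0]] != masks[:, iu[1]]
    A = sep.T.astype(float)
    y = d[iu]
    w, _ = nnls(A, y)
    return [(side, float(wk)) for side, wk in zip(sides, w) if wk > weight_floor]


def neighbor_net(
    d: np.ndarray,
    taxa: Sequence[str] | None = None,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> SplitSystem:
    """Full Neighbor-Net: circular ordering plus NNLS split weights."""
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if n < 4:
        raise AnalysisError("Neighbor-Net needs at least 4 taxa")
    if taxa is None:
        taxa = [str(i) for i in range(n)]
    cycle = neighbor_net_cycle(d)
    splits = fit_split_weights(d, cycle, weight_floor)
    return SplitSystem(taxa=list(taxa), cycle=cycle, splits=splits)


def group_cohesion(
    groups: Mapping[str, Sequence[str]],
    splits: SplitSystem | None = None,
    d: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> dict:
    """Per predefined group: is it isolated by a positive-weight split (or by
    one isolating a union of whole groups containing it), and what are the
    mean within/between distances?

    Pass a SplitSystem, a distance matrix with its sample_ids, or both.
    """
    report: dict = {}
    if splits is not None:
        taxa = set(splits.taxa)
        for g, members in groups.items():
            missing = [s for s in members if s not in taxa]
            if missing:
                raise AnalysisError(f"group {g!r} members not among taxa: {missing}")
        group_sets = {g: frozenset(m) for g, m in groups.items()}
        all_sides = set()
        for side, w in splits.nontrivial_splits():
            labels = frozenset(splits.taxa[i] for i in side)
            all_sides.add(labels)
            all_sides.add(frozenset(splits.taxa) - labels)
        for g, members in group_sets.items():
            exact = members in all_sides
            supers = [
                side
                for side in all_sides
                if members <= side
                and _is_union_of_groups(side, group_sets.values())
                and side != frozenset(splits.taxa)
            ]
            report[g] = {"isolated": exact, "isolated_in_supergroup": bool(supers) or exact}
    if d is not None:
        d = _check_distance_matrix(d)
        if sample_ids is None:
            raise AnalysisError("sample_ids required with a raw distance matrix")
        index = {s: i for i, s in enumerate(sample_ids)}
        labels = list(groups)
        for g in labels:
            idx = [index[s] for s in groups[g]]
            entry = report.setdefault(g, {})
            if len(idx) > 1:
                sub = d[np.ix_(idx, idx)]
                entry["mean_within"] = float(sub[np.triu_indices(len(idx), 1)].mean())
            else:
                entry["mean_within"] = 0.0
            between = []
            for h in labels:
                if h == g:
                    continue
                jdx = [index[s] for s in groups[h]]
                between.append(float(d[np.ix_(idx, jdx)].mean()))
            entry["mean_between"] = float(np.mean(between)) if between else None
    return report


def _is_union_of_groups(side: frozenset, group_sets) -> bool:
    covered: set = set()
    for g in group_sets:
        if g <= side:
            covered |= set(g)
        elif g & side:
            return False
    return covered == set(side)


def euclidean_distance(m: MarkerMatrix) -> np.ndarray:
    """Plain Euclidean distances on the 0/1 rows (the ordination metric)."""
    from scipy.spatial.distance import pdist

    return squareform(pdist(m.values.astype(float), metric="euclidean"))
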