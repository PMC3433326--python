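"""Clone assignment on dominant markers and genotype-diversity indices.

Individuals with identical (or nearly identical) multilocus fingerprints are
grouped into clones.  Because replicated samples differ by a few bands through
scoring error alone, clone assignment tolerates up to a threshold number of
band differences; the threshold is suggested either from the observed
replicate differences or from the first gap in the distribution of pairwise
genotype differences.  Clusters are single-linkage connected components, which
is the only choice under which a difference threshold behaves transitively.

Genotype diversity is the bias-corrected Nei index
    D_g = n/(n-1) * (1 - sum_i (s_i/n)^2)
over clone sizes s_i; D_g = 1 iff every individual is its own clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AnalysisError
from .io_model import MarkerMatrix, SampleTable


def pairwise_differences(m: MarkerMatrix, samples: Sequence[str] | None = None) -> np.ndarray:
    """Symmetric matrix of Hamming band differences between sample rows."""
    if samples is None:
        samples = m.sample_ids
    if len(samples) < 2:
        raise AnalysisError("pairwise differences need >= 2 samples")
    sub = m.subset(list(samples))  # raises on unknown ids
    v = sub.values.astype(np.int16)
    return np.abs(v[:, None, :] - v[None, :, :]).sum(axis=2)


def suggest_threshold(
    replicate_diffs: Sequence[int], genotype_diffs: Sequence[int]
) -> dict:
    """Two data-driven clone thresholds; the caller picks (the larger is the
    conservative choice when they disagree).

    replicate-based: the largest difference observed between replicate pairs
    (differences up to this size are attributable to scoring error alone).
    distribution-based: the largest difference below the first empty integer
    bin in the histogram of genotype pairwise differences (the within-clone
    mode is assumed to be separated from between-genotype differences by a gap).
    """
    replicate_diffs = list(replicate_diffs)
    genotype_diffs = list(genotype_diffs)
    if not replicate_diffs and not genotype_diffs:
        raise AnalysisError("no replicate or genotype differences supplied")
    out: dict = {"replicate_based": None, "distribution_based": None}
    if replicate_diffs:
        out["replicate_based"] = int(max(replicate_diffs))
    if genotype_diffs:
        present = set(int(d) for d in genotype_diffs)
        top = max(present)
        k = 0
        while k in present:
            k += 1
        out["distribution_based"] = k - 1 if k <= top else top
    return out


@dataclass
class ClonePartition:
    """Threshold-based clone partition of one population's samples."""

    population: str
    threshold: int
    clusters: list[list[str]]

    @property
    def nb(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def nb_geno(self) -> int:
        return len(self.clusters)

    @property
    def cluster_sizes(self) -> list[int]:
        return sorted((len(c) for c in self.clusters), reverse=True)

    @property
    def d_g(self) -> float:
        return genotype_diversity(self.cluster_sizes)


def assign_clones(
    diffs: np.ndarray,
    threshold: int,
    sample_ids: Sequence[str] | None = None,
    population: str = "",
) -> ClonePartition:
    """Single-linkage clone clusters: connected components of the graph joining
    sample pairs with <= threshold band differences.

    Threshold 0 reproduces the strict reading of a clone (no band difference
    at all, up to chaining through exact duplicates).
    """
    if threshold < 0:
        raise AnalysisError("threshold must be >= 0")
    diffs = np.asarray(diffs)
    n = diffs.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    adj = csr_matrix(diffs <= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for sid, lab in zip(sample_ids, labels):
        clusters[lab].append(sid)
    clusters.sort(key=lambda c: (-len(c), c))
    return ClonePartition(population=population, threshold=int(threshold), clusters=clusters)


def genotype_diversity(cluster_sizes: Sequence[int]) -> float:
    """Bias-corrected Nei genotype diversity over clone sizes.

    D_g = n/(n-1) * (1 - sum (s_i/n)^2); the n/(n-1) correction makes a sample
    of all-distinct genotypes score exactly 1.
    """
    sizes = [int(s) for s in cluster_sizes]
    if not sizes or any(s <= 0 for s in sizes):
        raise AnalysisError("cluster sizes must be positive integers")
    n = sum(sizes)
    if n < 2:
        raise AnalysisError("genotype diversity needs n >= 2 individuals")
    p2 = sum((s / n) ** 2 for s in sizes)
    return n / (n - 1) * (1.0 - p2)


def clonal_diversity_table(
    m: MarkerMatrix,
    meta: SampleTable,
    populations: Sequence[str],
    threshold: int,
) -> list[ClonePartition]:
    """Per-population clone partitions (excluded samples and replicate
    re-runs are dropped first)."""
    parts = []
    for pop in populations:
        samples = [
            r.sample_id
            for r in meta.non_excluded()
            if r.population == pop and r.replicate_of is None and r.sample_id in m.sample_ids
        ]
        if len(samples) < 2:
            raise AnalysisError(f"population {pop!r} has fewer than 2 usable samples")
        d = pairwise_differences(m, samples)
        parts.append(assign_clones(d, threshold, samples, population=pop))
    return parts


def shared_clones_across_populations(
    m: MarkerMatrix, meta: SampleTable, populations: Sequence[str], threshold: int
) -> list[dict]:
    """Clone clusters spanning more than one population (joint clustering)."""
    samples = [
        r.sample_id
        for r in meta.non_excluded()
        if r.population in populations and r.replicate_of is None and r.sample_id in m.sample_ids
    ]
    if len(samples) < 2:
        return []
    d = pairwise_differences(m, samples)
    part = assign_clones(d, threshold, samples)
    out = []
    for cluster in part.clusters:
        pops = sorted({meta.get(s).population for s in cluster})
        if len(pops) > 1:
            out.append({"members": cluster, "populations": pops})
    return out
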