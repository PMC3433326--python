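"""Plastid haplotype networks by statistical parsimony.

Workflow: drop alignment columns flagged as unalignable (poly-A stretches),
code each distinct indel (a gap run with identical start/end across the
sequences that show it) as a single binary presence/absence character, collapse
identical coded sequences into haplotypes, and join haplotypes by unit
mutational steps up to a connection limit.  A k-step connection inserts k-1
inferred intermediate haplotypes (unobserved but required to link the observed
ones).  Connected components of the resulting graph are the haplotype groups.

The classical convention sets the connection limit so that longer connections
are rejected once the probability of a non-homoplasious (parsimonious) multi-
step link drops below 95%.  That probability routine is pluggable here; the
default configuration exposes an explicit integer step limit (default 3) so
that single-step links always join while deeply separated groups never do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .io_model import HaploAlignment, SampleTable

DEFAULT_STEP_LIMIT = 3


@dataclass
class CodedAlignment:
    """Character matrix after region exclusion and indel coding.

    Characters are nucleotide columns plus appended binary indel characters
    ('1' = gap present).  ``n_nucleotide`` counts the former.
    """

    sequence_ids: list[str]
    characters: np.ndarray  # (n_seq, n_char) of single characters
    n_nucleotide: int
    n_indel: int
    indel_runs: list[tuple[int, int]]  # 1-based inclusive, original coordinates

    @property
    def n_characters(self) -> int:
        return self.characters.shape[1]

    def row(self, sequence_id: str) -> np.ndarray:
        return self.characters[self.sequence_ids.index(sequence_id)]


def code_alignment(aln: HaploAlignment) -> CodedAlignment:
    """Apply region exclusions and code indels as binary characters.

    Each maximal gap run (identical start and end in every sequence carrying
    it) becomes one character; the columns it covers are removed from the
    nucleotide matrix.  Distinct gap runs that overlap cannot be coded
    automatically and raise, demanding manual coding input.
    """
    arr = np.array([list(s) for s in aln.sequences], dtype="<U1")
    keep = ~aln.excluded_columns()
    arr = arr[:, keep]

    # maximal gap runs per sequence, in post-exclusion coordinates
    runs: set[tuple[int, int]] = set()
    for row in arr:
        isgap = row == "-"
        if not isgap.any():
            continue
        padded = np.concatenate(([False], isgap, [False])).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        for start, end in zip(edges[::2], edges[1::2]):
            runs.add((int(start), int(end)))  # 0-based half-open
    sorted_runs = sorted(runs)
    for (s1, e1), (s2, e2) in zip(sorted_runs, sorted_runs[1:]):
        if s2 < e1:
            raise ValidationError(
                f"overlapping distinct gap runs {(s1 + 1, e1)} and {(s2 + 1, e2)}: "
                "manual indel coding required"
            )

    indel_chars = []
    covered = np.zeros(arr.shape[1], dtype=bool)
    for start, end in sorted_runs:
        has_gap = (arr[:, start:end] == "-").all(axis=1)
        indel_chars.append(np.where(has_gap, "1", "0"))
        covered[start:end] = True
    nucl = arr[:, ~covered]

    # map retained run coordinates back to original 1-based columns
    orig_cols = np.flatnonzero(keep)
    runs_1based = [(int(orig_cols[s]) + 1, int(orig_cols[e - 1]) + 1) for s, e in sorted_runs]

    parts = [nucl] + [c[:, None] for c in indel_chars]
    chars = np.hstack(parts) if parts else nucl
    return CodedAlignment(
        sequence_ids=list(aln.sequence_ids),
        characters=chars,
        n_nucleotide=nucl.shape[1],
        n_indel=len(indel_chars),
        indel_runs=runs_1based,
    )


def step_distance(h1: np.ndarray | str, h2: np.ndarray | str) -> int:
    """Mutational steps between coded haplotypes: one per substitution or
    indel-character mismatch.  Positions with 'N' in either sequence are
    skipped (ambiguity is not evidence of a step)."""
    a = np.asarray(list(h1) if isinstance(h1, str) else h1)
    b = np.asarray(list(h2) if isinstance(h2, str) else h2)
    if a.shape != b.shape:
        raise AnalysisError(f"character count mismatch: {a.shape[0]} vs {b.shape[0]}")
    informative = (a != "N") & (b != "N")
    return int(((a != b) & informative).sum())


@dataclass
class Haplotype:
    label: str
    characters: np.ndarray
    carriers: list[str] = field(default_factory=list)


def collapse_haplotypes(
    coded: CodedAlignment, meta: SampleTable | None = None
) -> list[Haplotype]:
    """Collapse identical coded sequences into haplotypes with carrier lists.

    Labels come from the metadata's haplotype codes when every carrier agrees
    on one; otherwise haplotypes are labelled H1, H2, ... in order of first
    appearance.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i in range(len(coded.sequence_ids)):
        key = "".join(coded.characters[i])
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    haplos = []
    for k, key in enumerate(order):
        idx = groups[key]
        carriers = [coded.sequence_ids[i] for i in idx]
        label = carriers[0] if len(carriers) == 1 else f"H{k + 1}"
        if meta is not None:
            codes = {
                meta.get(c).haplotype
                for c in carriers
                if c in meta and meta.get(c).haplotype is not None
            }
            if len(codes) == 1:
                label = codes.pop()
        haplos.append(Haplotype(label=label, characters=coded.characters[idx[0]], carriers=carriers))
    return haplos


def parsimony_connection_limit(n_characters: int, confidence: float = 0.95) -> int:
    """Step limit from a parsimony-probability argument (95% convention).

    Approximation: with j observed differences over L characters, the Poisson-
    corrected per-site substitution load is theta = -ln(1 - j/L); the chance
    that no character was hit twice (so the parsimony count equals the true
    count) is [e^-theta (1+theta)]^L.  The limit is the largest j for which
    that probability still exceeds ``confidence``.  Swap in an exact routine
    via build_network(limit=...) if desired.
    """
    if n_characters < 2:
        return 1
    best = 1
    for j in range(1, n_characters):
        p = j / n_characters
        if p >= 1:
            break
        theta = -log(1 - p)
        prob = exp(n_characters * (log(1 + theta) - theta))
        if prob >= confidence:
            best = j
        else:
            break
    return max(best, 1)


@dataclass
class HaploNetwork:
    """Unit-step haplotype graph; components are the haplotype groups."""

    graph: nx.Graph
    haplotypes: list[Haplotype]
    connection_limit: int

    @property
    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def observed_components(self) -> list[set[str]]:
        """Components restricted to observed haplotype labels."""
        observed = {h.label for h in self.haplotypes}
        return [c & observed for c in self.components]

    def group_of(self, haplotype_label: str) -> int:
        for i, comp in enumerate(self.components):
            if haplotype_label in comp:
                return i
        raise KeyError(haplotype_label)


def build_network(
    haplotypes: Sequence[Haplotype], limit: int | str = DEFAULT_STEP_LIMIT
) -> HaploNetwork:
    """Statistical-parsimony network over coded haplotypes.

    Pairs are connected in increasing step order; a k-step connection inserts
    k-1 inferred intermediate nodes.  A connection is added only if the pair is
    not already linked by a path of at most its step length, so equal-step
    alternative connections are all retained (the graph may contain cycles),
    while redundant longer connections are not.  Connections above ``limit``
    steps are never made.  ``limit='auto'`` derives the limit from the
    parsimony-probability routine and the character count.
    """
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise AnalysisError("no haplotypes supplied")
    if limit == "auto":
        limit = parsimony_connection_limit(haplotypes[0].characters.shape[0])
    limit = int(limit)
    if limit <= 0:
        raise AnalysisError("connection limit must be a positive step count")

    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.label, observed=True, carriers=list(h.carriers))

    pairs = []
    for i in range(len(haplotypes)):
        for j in range(i + 1, len(haplotypes)):
            d = step_distance(haplotypes[i].characters, haplotypes[j].characters)
            pairs.append((d, haplotypes[i].label, haplotypes[j].label))
    pairs.sort()

    n_inferred = 0
    k = 0
    while k < len(pairs):
        step = pairs[k][0]
        if step > limit:
            break
        batch = [p for p in pairs if p[0] == step]
        k += len(batch)
        # connectivity state frozen at batch start so that equal-step
        # alternatives are judged on the same footing (cycles retained)
        lengths = {}
        for _, a, b in batch:
            if a not in lengths:
                lengths[a] = nx.single_source_shortest_path_length(g, a, cutoff=step)
        for d, a, b in batch:
            if d == 0:
                continue  # identical haplotypes are collapsed upstream
            if lengths[a].get(b, np.inf) <= step:
                continue
            prev = a
            for s in range(1, d):
                n_inferred += 1
                mid = f"i{n_inferred}"
                g.add_node(mid, observed=False, carriers=[])
                g.add_edge(prev, mid)
                prev = mid
            g.add_edge(prev, b)
    return HaploNetwork(graph=g, haplotypes=haplotypes, connection_limit=limit)


def haplotype_table(network: HaploNetwork, meta: SampleTable) -> pd.DataFrame:
    """Per-haplotype carriers with their taxa and populations, plus group index."""
    rows = []
    for h in network.haplotypes:
        known = [c for c in h.carriers if c in meta]
        rows.append(
            {
                "haplotype": h.label,
                "n_carriers": len(h.carriers),
                "carriers": ",".join(h.carriers),
                "taxa": ",".join(sorted({meta.get(c).taxon for c in known})),
                "populations": ",".join(sorted({meta.get(c).population for c in known})),
                "group": network.group_of(h.label),
            }
        )
    return pd.DataFrame(rows)


def network_from_alignment(
    aln: HaploAlignment, meta: SampleTable | None = None, limit: int | str = DEFAULT_STEP_LIMIT
) -> tuple[HaploNetwork, CodedAlignment]:
    """Convenience: code, collapse, and build in one call."""
    coded = code_alignment(aln)
    haplos = collapse_haplotypes(coded, meta)
    return build_network(haplos, limit=limit), coded


def write_network_graphml(network: HaploNetwork, path) -> None:
    g = network.graph.copy()
    for _, data in g.nodes(data=True):
        data["carriers"] = ",".join(data.get("carriers", []))
    nx.write_graphml(g, path)
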