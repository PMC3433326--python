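"""AFLPdat-style fragment accounting on dominant-marker matrices.

Totals and polymorphism, group fragment sets, shared-fragment counts between
groups, private (group-specific) fragments, and replicate repeatability.

A group "carries" a fragment if at least one non-excluded member does; this is
the convention that reproduces the published shared-fragment arithmetic for
dominant markers.  Percentages are rounded half-up to 2 decimals, matching how
such tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .io_model import MarkerMatrix, SampleTable, round_half_up


@dataclass
class GroupFragmentSet:
    """Fragments present in >= 1 non-excluded member of a labelled sample group."""

    label: str
    members: list[str]
    fragments: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.fragments)


def build_group_sets(
    m: MarkerMatrix,
    meta: SampleTable,
    by: str | Callable[[object], str | None] = "taxon",
    drop_replicates: bool = True,
) -> list[GroupFragmentSet]:
    """Build per-group fragment sets, dropping excluded samples first.

    ``by`` is either a metadata attribute name ('taxon', 'population', ...) or
    a callable mapping a SampleRecord to a group label (None = skip sample).
    Taxa with known cytotype can be split by using a callable such as
    ``lambda r: f"{r.taxon} {r.cytotype}x"``.
    """
    if callable(by):
        key = by
    else:
        key = lambda r: getattr(r, by)  # noqa: E731
    groups: dict[str, list[str]] = {}
    for r in meta.non_excluded():
        if r.sample_id not in m.sample_ids:
            continue
        if drop_replicates and r.replicate_of is not None:
            continue
        label = key(r)
        if label is None:
            continue
        groups.setdefault(str(label), []).append(r.sample_id)
    out = []
    for label, members in groups.items():
        sub = m.subset(members)
        present = np.asarray(sub.values).any(axis=0)
        frags = frozenset(l for l, p in zip(m.locus_labels, present) if p)
        out.append(GroupFragmentSet(label=label, members=members, fragments=frags))
    return out


def fragment_totals(m: MarkerMatrix, meta: SampleTable | None = None) -> dict:
    """Total and polymorphic fragment counts over non-excluded samples.

    A locus is counted at all if present in >= 1 sample and polymorphic if it
    shows both a presence and an absence.  Percent polymorphic is
    100 * polymorphic / total, to 2 decimals.
    """
    if meta is not None:
        keep = [
            r.sample_id
            for r in meta.non_excluded()
            if r.sample_id in m.sample_ids and r.replicate_of is None
        ]
        if not keep:
            raise AnalysisError("all samples are excluded")
        m = m.subset(keep)
    v = m.values
    present = v.any(axis=0)
    total = int(present.sum())
    polymorphic = int((present & ~v.all(axis=0)).sum())
    pct = round_half_up(100.0 * polymorphic / total, 2) if total else 0.0
    return {
        "n_samples": m.n_samples,
        "n_loci_scored": m.n_loci,
        "total_fragments": total,
        "polymorphic_fragments": polymorphic,
        "percent_polymorphic": pct,
    }


def shared_fragments(a: GroupFragmentSet, b: GroupFragmentSet) -> tuple[int, float]:
    """Fragments of group ``a`` also present in group ``b``.

    Returns (count, percent) with percent = 100 * count / |F_a| — the
    denominator is the FIRST group's fragment count, so the measure is
    directional (the published table convention).
    """
    if not a.fragments or not b.fragments:
        raise AnalysisError("shared_fragments requires nonempty fragment sets")
    count = len(a.fragments & b.fragments)
    return count, round_half_up(100.0 * count / len(a.fragments), 2)


def private_fragments(
    groups: Sequence[GroupFragmentSet],
    hybrid_groups: Sequence[GroupFragmentSet] = (),
    allow_overlap: bool = False,
) -> dict:
    """Fragments private to exactly one group, and which of those hybrids carry.

    A locus is private to group g iff present in g and absent from every other
    listed group.  ``hybrid_groups`` are scored against the parents' private
    sets but do not themselves count as groups (a hybrid is expected to carry
    parental private bands).
    """
    if len(groups) < 2:
        raise AnalysisError("private fragments need >= 2 groups")
    if not allow_overlap:
        seen: dict[str, str] = {}
        for g in groups:
            for s in g.members:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} belongs to groups {seen[s]!r} and {g.label!r}"
                    )
                seen[s] = g.label
    private: dict[str, frozenset[str]] = {}
    for g in groups:
        others: set[str] = set()
        for h in groups:
            if h is not g:
                others |= h.fragments
        private[g.label] = frozenset(g.fragments - others)
    carried = {
        h.label: {
            g: sorted(h.fragments & priv) for g, priv in private.items() if priv
        }
        for h in hybrid_groups
    }
    return {
        "private": {g: sorted(p) for g, p in private.items()},
        "carried_by_hybrids": carried,
    }


def replicate_error_rate(m: MarkerMatrix, meta: SampleTable) -> dict:
    """Per replicate-pair difference counts and repeatability percentages.

    Repeatability of a pair = 100 * (1 - differences / loci); the mean over
    pairs estimates the per-dataset scoring reliability.  With no replicates an
    explicit 'no replicates' result is returned rather than raising.
    """
    pairs = [
        (a, b) for a, b in meta.replicate_pairs() if a in m.sample_ids and b in m.sample_ids
    ]
    if not pairs:
        return {"n_pairs": 0, "pairs": [], "mean_repeatability": None, "note": "no replicates"}
    rows = []
    for orig, rep in pairs:
        diff = int((m.row(orig) != m.row(rep)).sum())
        rows.append(
            {
                "original": orig,
                "replicate": rep,
                "differences": diff,
                "repeatability": round_half_up(100.0 * (1 - diff / m.n_loci), 2),
            }
        )
    mean = round_half_up(float(np.mean([r["repeatability"] for r in rows])), 2)
    return {"n_pairs": len(rows), "pairs": rows, "mean_repeatability": mean}


def shared_fragment_table(
    focal_groups: Sequence[GroupFragmentSet], candidate_groups: Sequence[GroupFragmentSet]
) -> pd.DataFrame:
    """Directional shared-fragment matrix: rows = candidates, columns = focal groups."""
    data = {}
    for f in focal_groups:
        col = {}
        for c in candidate_groups:
            cnt, pct = shared_fragments(f, c)
            col[c.label] = f"{cnt}/{pct:.2f}"
        data[f"{f.label} ({f.count})"] = col
    return pd.DataFrame(data)
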