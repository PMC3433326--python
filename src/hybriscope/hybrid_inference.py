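"""Hybrid-origin inference: ploidy from flow cytometry, gamete-ploidy cross
enumeration, maternal assignment from plastid haplotypes, fragment-sharing
parentage scores, band additivity, and lineage definition.

The core test of single- versus multiple-event origin works as follows.  Each
candidate parent (taxon or cytotype) contributes male gametes via meiosis and
female gametes via meiosis or, in facultatively apomictic cytotypes, apomeiosis
(unreduced egg cells); the plastid haplotype is transmitted maternally.  A
hybrid lineage of observed ploidy p and haplotype group h is explainable by a
single crossing event iff some (mother, father, egg, pollen) combination with
egg + pollen = p and the mother's haplotype group equal to h also matches the
lineage's genomic composition: the expected maternal genome fraction
egg/(egg+pollen) predicts whether the lineage should share more fragments with
the mother or with the father.  Lineages failing every combination on the
haplotype clause and/or the composition clause require a more complex history
(multiple events, backcrossing/introgression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .fragment_stats import GroupFragmentSet, shared_fragments
from .io_model import FcmRecord, SampleTable, round_half_up

DEFAULT_CV_LIMIT = 5.0  # percent; FCM records at or above are excluded
DEFAULT_ANEUPLOID_TOL = 0.03  # relative residual above which a sample is flagged
DEFAULT_DEAD_BAND = 0.05  # composition dead-band around maternal fraction 0.5


# ---------------------------------------------------------------------------
# Gamete model and cross enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GameteTaxon:
    """Gamete ploidies put out by one parental taxon/cytotype.

    ``female_gametes`` may include unreduced (apomeiotic) egg ploidies in
    addition to or instead of reduced ones; pollen is assumed meiotic.
    ``haplogroup`` is the haplotype group this taxon transmits maternally.
    """

    label: str
    male_gametes: frozenset
    female_gametes: frozenset
    haplogroup: str

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.male_gametes | self.female_gametes):
            raise AnalysisError(f"gamete ploidies of {self.label!r} must be positive")


GameteModel = Sequence[GameteTaxon]


def default_gamete_model() -> list[GameteTaxon]:
    """The study system's gamete model (male / female gamete ploidies):

    1x / 1x for diploid P. argentea; 3x / 6x (unreduced eggs) for hexaploid
    P. argentea; 2x,3x / 2x,3x,5x,6x,7x for the P. pusilla cytotypes.
    Haplotype groups: the argentea-type plastids (E/F/G/I/Q) versus the
    verna-group plastids carried by P. pusilla (W, J-U).
    """
    return [
        GameteTaxon("P. argentea 2x", frozenset({1}), frozenset({1}), "argentea"),
        GameteTaxon("P. argentea 6x", frozenset({3}), frozenset({6}), "argentea"),
        GameteTaxon(
            "P. pusilla", frozenset({2, 3}), frozenset({2, 3, 5, 6, 7}), "pusilla"
        ),
    ]


@dataclass(frozen=True)
class CrossHypothesis:
    mother: str
    father: str
    egg_ploidy: int
    pollen_ploidy: int

    @property
    def offspring_ploidy(self) -> int:
        return self.egg_ploidy + self.pollen_ploidy

    @property
    def maternal_fraction(self) -> float:
        return self.egg_ploidy / self.offspring_ploidy

    def describe(self) -> str:
        return (
            f"{self.mother} egg {self.egg_ploidy}x × {self.father} "
            f"pollen {self.pollen_ploidy}x → {self.offspring_ploidy}x"
        )


def enumerate_crosses(
    model: GameteModel,
    target_ploidy: int,
    target_haplogroup: str | None,
    allow_selfing: bool = False,
) -> list[CrossHypothesis]:
    """All single-event crosses yielding the target ploidy with a maternally
    compatible haplotype group.  ``target_haplogroup=None`` skips the maternal
    filter (for runs without haplotype data).  Same-taxon crosses count as
    selfing and are excluded unless ``allow_selfing``."""
    if not model:
        raise AnalysisError("empty gamete model")
    if target_ploidy < 2:
        raise AnalysisError("offspring ploidy below 2x is not a gamete fusion")
    out = []
    for mother in model:
        if target_haplogroup is not None and mother.haplogroup != target_haplogroup:
            continue
        for father in model:
            if not allow_selfing and father.label == mother.label:
                continue
            for egg in sorted(int(g) for g in mother.female_gametes):
                pollen = target_ploidy - egg
                if pollen in {int(g) for g in father.male_gametes}:
                    out.append(CrossHypothesis(mother.label, father.label, egg, pollen))
    return out


def validate_cross(model: GameteModel, hypothesis: CrossHypothesis) -> None:
    """Raise 'impossible cross' if the gametes are outside the parents' sets."""
    by_label = {t.label: t for t in model}
    mother = by_label.get(hypothesis.mother)
    father = by_label.get(hypothesis.father)
    if mother is None or father is None:
        raise AnalysisError(f"impossible cross: unknown parent in {hypothesis.describe()}")
    if hypothesis.egg_ploidy not in {int(g) for g in mother.female_gametes}:
        raise AnalysisError(
            f"impossible cross: {mother.label} puts out no {hypothesis.egg_ploidy}x eggs"
        )
    if hypothesis.pollen_ploidy not in {int(g) for g in father.male_gametes}:
        raise AnalysisError(
            f"impossible cross: {father.label} puts out no {hypothesis.pollen_ploidy}x pollen"
        )


# ---------------------------------------------------------------------------
# Ploidy from flow cytometry
# ---------------------------------------------------------------------------


def infer_ploidy_from_fcm(
    records: Sequence[FcmRecord],
    references: Sequence[tuple[str, int]],
    cv_limit: float = DEFAULT_CV_LIMIT,
    aneuploid_tol: float = DEFAULT_ANEUPLOID_TOL,
    max_ploidy: int = 12,
) -> pd.DataFrame:
    """DNA ploidy per sample from sample/standard fluorescence ratios.

    Per species, the ratios of chromosome-counted reference individuals are
    regressed through the origin (ratio = beta * ploidy, least squares); every
    sample of that species is then assigned the integer ploidy k minimising
    |ratio - beta*k|.  Records failing the CV filter are excluded with reason;
    species without any usable reference get status 'cannot_attribute'; a best
    assignment whose relative residual exceeds ``aneuploid_tol`` is flagged as
    a possible aneuploid.
    """
    by_id = {r.sample_id: r for r in records}
    ref_ploidy = dict(references)
    betas: dict[str, float] = {}
    for species in sorted({r.species for r in records}):
        pairs = [
            (by_id[s].ratio, k)
            for s, k in references
            if s in by_id and by_id[s].species == species and by_id[s].cv_percent < cv_limit
        ]
        if pairs:
            ratios = np.array([p[0] for p in pairs])
            ks = np.array([p[1] for p in pairs], dtype=float)
            betas[species] = float((ratios * ks).sum() / (ks * ks).sum())
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "species": r.species,
            "ratio": r.ratio,
            "cv_percent": r.cv_percent,
            "ploidy": None,
            "relative_residual": None,
            "possible_aneuploid": False,
            "is_reference": r.sample_id in ref_ploidy,
        }
        if r.cv_percent >= cv_limit:
            row["status"] = "excluded_cv"
            row["reason"] = f"CV {r.cv_percent:.2f}% >= {cv_limit:g}%"
        elif r.species not in betas:
            row["status"] = "cannot_attribute"
            row["reason"] = f"no reference chromosome count for {r.species}"
        else:
            beta = betas[r.species]
            ks = np.arange(1, max_ploidy + 1)
            resid = np.abs(r.ratio - beta * ks)
            k = int(ks[np.argmin(resid)])
            rel = float(abs(r.ratio - beta * k) / (beta * k))
            row.update(
                status="assigned",
                reason="",
                ploidy=k,
                relative_residual=rel,
                possible_aneuploid=rel > aneuploid_tol,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["betas"] = betas
    return df


# ---------------------------------------------------------------------------
# Parentage scores and band additivity
# ---------------------------------------------------------------------------


def parentage_scores(
    lineage: GroupFragmentSet,
    candidates: Sequence[GroupFragmentSet],
    private_table: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Rank candidate parents by the share of the lineage's fragments they
    carry (percent of the lineage's fragment count), plus how many of each
    candidate's private fragments the lineage contains."""
    if not candidates:
        raise AnalysisError("no candidate parent groups supplied")
    rows = []
    for cand in candidates:
        cnt, pct = shared_fragments(lineage, cand)
        priv = set(private_table.get(cand.label, ())) if private_table else set()
        rows.append(
            {
                "candidate": cand.label,
                "candidate_fragments": cand.count,
                "shared_count": cnt,
                "shared_percent": pct,
                "private_carried": len(lineage.fragments & priv),
                "private_total": len(priv),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["shared_percent", "candidate"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


@dataclass
class AdditivityResult:
    additive: int
    lost: int
    de_novo: int
    union_size: int
    n_loci: int

    @property
    def loss_rate(self) -> float:
        return self.lost / self.union_size if self.union_size else 0.0

    @property
    def de_novo_rate(self) -> float:
        outside = self.n_loci - self.union_size
        return self.de_novo / outside if outside else 0.0


def classify_additivity(
    hybrid: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> AdditivityResult:
    """Partition loci into additive / lost / de-novo relative to the parental
    band union: union band kept by the hybrid -> additive, dropped -> lost;
    band absent from both parents but shown by the hybrid -> de novo."""
    h = np.asarray(hybrid, dtype=bool)
    m = np.asarray(mother, dtype=bool)
    f = np.asarray(father, dtype=bool)
    if not (h.shape == m.shape == f.shape):
        raise AnalysisError("hybrid and parents must be scored over the same loci")
    union = m | f
    return AdditivityResult(
        additive=int((union & h).sum()),
        lost=int((union & ~h).sum()),
        de_novo=int((~union & h).sum()),
        union_size=int(union.sum()),
        n_loci=int(h.size),
    )


# ---------------------------------------------------------------------------
# Lineages and the single-event verdict
# ---------------------------------------------------------------------------


@dataclass
class Lineage:
    label: str
    members: list[str]
    cytotype: int
    haplotype: str
    cluster: object = None


def define_lineages(
    meta: SampleTable,
    samples: Sequence[str],
    clusters: Mapping[str, object],
    cytotypes: Mapping[str, int] | None = None,
    haplotypes: Mapping[str, str] | None = None,
) -> tuple[list[Lineage], list[dict]]:
    """Maximal sample sets homogeneous in (cluster, cytotype, haplotype).

    Cytotype and haplotype default to the metadata annotations; explicit
    mappings (e.g. FCM-inferred ploidies, network-derived haplotypes) override
    them.  Samples missing any of the three annotations are returned in the
    unassignable list rather than raising.  Lineages are labelled a, b, c, ...
    by decreasing size.
    """
    cytotypes = dict(cytotypes or {})
    haplotypes = dict(haplotypes or {})
    groups: dict[tuple, list[str]] = {}
    unassignable = []
    for s in samples:
        rec = meta.get(s) if s in meta else None
        cyt = cytotypes.get(s, rec.cytotype if rec else None)
        hap = haplotypes.get(s, rec.haplotype if rec else None)
        clu = clusters.get(s)
        missing = [
            name
            for name, v in (("cluster", clu), ("cytotype", cyt), ("haplotype", hap))
            if v is None
        ]
        if missing:
            unassignable.append({"sample_id": s, "missing": missing})
            continue
        groups.setdefault((clu, int(cyt), hap), []).append(s)
    keys = sorted(groups, key=lambda k: (-len(groups[k]), str(k)))
    lineages = [
        Lineage(
            label=chr(ord("a") + i) if i < 26 else f"lin{i}",
            members=groups[k],
            cytotype=k[1],
            haplotype=k[2],
            cluster=k[0],
        )
        for i, k in enumerate(keys)
    ]
    return lineages, unassignable


def explain_lineage(
    lineage: Lineage,
    hypotheses: Sequence[CrossHypothesis],
    scores: pd.DataFrame,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> dict:
    """Single-event verdict for a hybrid lineage.

    ``hypotheses`` must already be haplotype-compatible (the output of
    enumerate_crosses for this lineage's ploidy and haplotype group); an empty
    list therefore means no single cross can even transmit the right plastid.
    For each hypothesis the composition clause checks that the lineage's
    shared-fragment percentages lean toward the parent contributing the larger
    genome fraction: maternal fraction > 0.5 + dead_band requires
    mother-leaning similarity, < 0.5 - dead_band father-leaning, and fractions
    inside the dead band accept either ranking (fragment-sharing differences of
    a few points must not flip verdicts given band-scoring noise).
    """
    pct = dict(zip(scores["candidate"], scores["shared_percent"]))
    if not hypotheses:
        return {
            "lineage": lineage.label,
            "verdict": "not-single-event",
            "reasons": ["no haplotype-compatible cross"],
            "supporting": [],
        }
    reasons = []
    supporting = []
    for hyp in hypotheses:
        sm = pct.get(hyp.mother)
        sf = pct.get(hyp.father)
        if sm is None or sf is None:
            missing = hyp.mother if sm is None else hyp.father
            reasons.append(f"{hyp.describe()}: no parentage score for {missing!r}")
            continue
        f = hyp.maternal_fraction
        if f > 0.5 + dead_band and not sm > sf:
            reasons.append(
                f"{hyp.describe()}: expected mother-leaning composition "
                f"(maternal fraction {f:.2f}) but shared% {sm} (mother) <= {sf} (father)"
            )
        elif f < 0.5 - dead_band and not sf > sm:
            reasons.append(
                f"{hyp.describe()}: expected father-leaning composition "
                f"(maternal fraction {f:.2f}) but shared% {sf} (father) <= {sm} (mother)"
            )
        else:
            supporting.append(hyp.describe())
    verdict = "single-event" if supporting else "not-single-event"
    return {
        "lineage": lineage.label,
        "verdict": verdict,
        "reasons": reasons,
        "supporting": supporting,
    }


def lineage_summary_table(
    lineages: Sequence[Lineage],
    scores_by_lineage: Mapping[str, pd.DataFrame],
    verdicts: Mapping[str, dict],
    meta: SampleTable,
) -> pd.DataFrame:
    """Report combining haplotype, top parentage shares, specific-band carriage
    and the single-event verdict per lineage."""
    rows = []
    for lin in lineages:
        sc = scores_by_lineage.get(lin.label)
        top = ""
        specific = ""
        if sc is not None and len(sc):
            top = "; ".join(
                f"{round_half_up(r.shared_percent, 2):.2f}/{r.candidate}"
                for r in sc.itertuples()
            )
            specific = "; ".join(
                f"{r.private_carried}/{r.private_total} {r.candidate}"
                for r in sc.itertuples()
                if r.private_total
            )
        pops = sorted({meta.get(s).population for s in lin.members if s in meta})
        rows.append(
            {
                "lineage": lin.label,
                "cytotype": f"{lin.cytotype}x",
                "haplotype": lin.haplotype,
                "n_members": len(lin.members),
                "populations": ",".join(pops),
                "shared_percent_by_taxon": top,
                "species_specific_bands": specific,
                "verdict": verdicts.get(lin.label, {}).get("verdict", ""),
            }
        )
    return pd.DataFrame(rows)
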