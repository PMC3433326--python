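"""Synthetic data with the statistical structure the analysis assumes.

The generator stands in for field-collected AFLP fingerprints, plastid
sequences and flow-cytometry measurements, so that every pipeline stage can be
tested against a known ground truth.  It emulates:

* taxon-specific band-frequency profiles (each sample a per-locus Bernoulli
  draw from its taxon's frequencies);
* clonal replication with independent per-band scoring error (default rate
  1.24%, the complement of a 98.76% mean replicate repeatability);
* hybrid band additivity: a hybrid carries the union of its parents' bands,
  each union band lost with probability 0.17 and absent bands appearing de
  novo with probability 0.024 (rates observed in synthetic allopolyploid
  fingerprint studies);
* maternal plastid inheritance and offspring ploidy as egg + pollen gamete
  ploidy sums;
* per-species flow-cytometry fluorescence ratios proportional to ploidy with
  multiplicative Gaussian noise, the proportionality slope differing between
  species so each species requires its own calibration regression.

The default 'alpicola' scenario plants two *P. argentea* cytotypes (2x, 6x)
and tetraploid *P. pusilla* as parents, three hybrid lineages (a: pentaploid
F1, b and c: hexaploids from crosses outside the inference gamete model) and
one backcross-chain lineage, mirroring the study system's structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io_model import (
    FcmRecord,
    HaploAlignment,
    MarkerMatrix,
    SampleRecord,
    SampleTable,
)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class TaxonProfile:
    """Generative description of one taxon/cytotype."""

    name: str
    cytotype: int
    band_freq: np.ndarray  # per-locus band probability in [0, 1]
    haplotype_pool: tuple[str, ...]
    hap_group: str
    female_gametes: frozenset
    male_gametes: frozenset
    fcm_beta: float  # fluorescence ratio per ploidy unit

    def __post_init__(self) -> None:
        f = np.asarray(self.band_freq, dtype=float)
        if (f < 0).any() or (f > 1).any():
            raise AnalysisError(f"band frequencies of {self.name!r} outside [0, 1]")
        object.__setattr__(self, "band_freq", f)


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_loci: int = 241
    epsilon: float = 0.0124  # per-band scoring error (1 - 0.9876 repeatability)
    loss: float = 0.17  # parental-band loss rate in hybrids
    denovo: float = 0.024  # de-novo band gain rate in hybrids
    fcm_noise: float = 0.01  # multiplicative sd of fluorescence ratios
    n_per_parent_pop: int = 8
    backcross_depth: int = 5  # generations in the planted backcross chain
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epsilon", "loss", "denovo"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise AnalysisError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def simulate_parental_panel(
    profile: TaxonProfile,
    n: int,
    seed_or_rng,
    population: str = "Pop000",
    id_prefix: str | None = None,
) -> tuple[MarkerMatrix, list[SampleRecord]]:
    """n independent individuals drawn per-locus Bernoulli(frequency), each
    with a haplotype drawn uniformly from the taxon's pool."""
    if n < 1:
        raise AnalysisError("panel size must be >= 1")
    rng = _rng(seed_or_rng)
    values = (rng.random((n, profile.band_freq.size)) < profile.band_freq).astype(np.int8)
    prefix = id_prefix or profile.name.replace(" ", "").replace(".", "")[:6]
    ids = [f"{prefix}-{i + 1:02d}" for i in range(n)]
    haps = rng.choice(list(profile.haplotype_pool), size=n)
    loci = [f"L{j + 1:03d}" for j in range(profile.band_freq.size)]
    meta = [
        SampleRecord(
            sample_id=ids[i],
            taxon=profile.name,
            population=population,
            cytotype=profile.cytotype,
            haplotype=str(haps[i]),
        )
        for i in range(n)
    ]
    return MarkerMatrix(ids, loci, values), meta


def simulate_clones(
    founder: np.ndarray, n: int, epsilon: float, seed_or_rng
) -> np.ndarray:
    """n observed re-scorings of one genotype: independent per-band flips at
    the scoring error rate."""
    if not 0 <= epsilon <= 1:
        raise AnalysisError("error rate must be in [0, 1]")
    if n < 1:
        raise AnalysisError("clone count must be >= 1")
    rng = _rng(seed_or_rng)
    founder = np.asarray(founder, dtype=np.int8)
    flips = rng.random((n, founder.size)) < epsilon
    return np.where(flips, 1 - founder[None, :], founder[None, :]).astype(np.int8)


def simulate_hybrid(
    mother: TaxonProfile,
    mother_row: np.ndarray,
    father: TaxonProfile,
    father_row: np.ndarray,
    egg_ploidy: int,
    pollen_ploidy: int,
    loss: float,
    denovo: float,
    seed_or_rng,
    mother_haplotype: str | None = None,
    enforce_gametes: bool = True,
) -> tuple[np.ndarray, dict]:
    """One hybrid offspring: parental band union with loss, de-novo gains on
    loci absent from both parents, maternal haplotype, ploidy = egg + pollen.

    ``enforce_gametes=False`` permits crosses outside the declared gamete sets
    (the ground truth may contain events the inference model excludes).
    """
    if enforce_gametes:
        if egg_ploidy not in {int(g) for g in mother.female_gametes}:
            raise AnalysisError(
                f"impossible cross: {mother.name} puts out no {egg_ploidy}x eggs"
            )
        if pollen_ploidy not in {int(g) for g in father.male_gametes}:
            raise AnalysisError(
                f"impossible cross: {father.name} puts out no {pollen_ploidy}x pollen"
            )
    rng = _rng(seed_or_rng)
    m = np.asarray(mother_row, dtype=bool)
    f = np.asarray(father_row, dtype=bool)
    union = m | f
    kept = union & (rng.random(union.size) >= loss)
    gained = ~union & (rng.random(union.size) < denovo)
    row = (kept | gained).astype(np.int8)
    hap = mother_haplotype if mother_haplotype is not None else mother.haplotype_pool[0]
    info = {
        "cytotype": int(egg_ploidy + pollen_ploidy),
        "haplotype": hap,
        "hap_group": mother.hap_group,
        "mother": mother.name,
        "father": father.name,
        "egg_ploidy": int(egg_ploidy),
        "pollen_ploidy": int(pollen_ploidy),
    }
    return row, info


# ---------------------------------------------------------------------------
# Haplotype sequence simulation
# ---------------------------------------------------------------------------


def simulate_haplotypes(
    group_haplotypes: Mapping[str, Sequence[str]],
    between_steps: int = 6,
    length: int = 550,
    n_indels: int = 0,
    n_polya: int = 2,
    seed_or_rng=0,
) -> tuple[HaploAlignment, dict]:
    """Aligned haplotype sequences with a star-per-group mutational topology.

    The first group's first haplotype is the root.  Every other group's centre
    diverges from the root by ``between_steps`` steps (substitutions, plus one
    step per coded indel when ``n_indels`` > 0: all non-root groups share the
    same gap runs).  Within a group every non-centre haplotype sits exactly one
    substitution from the centre, at a site of its own.  Optional poly-A
    stretches are written as runs of A (with ragged gap ends in non-root
    groups) and reported as excluded regions.  Returns the alignment (one
    sequence per haplotype, ids = haplotype codes) and a haplotype -> group
    truth map.
    """
    rng = _rng(seed_or_rng)
    groups = {g: list(h) for g, h in group_haplotypes.items()}
    if not groups or any(not h for h in groups.values()):
        raise AnalysisError("every group needs at least one haplotype code")
    if between_steps < 1:
        raise AnalysisError("between_steps must be >= 1")
    if n_indels > between_steps:
        raise AnalysisError("cannot spend more steps on indels than between_steps")

    base = rng.choice(list("ACGT"), size=length)
    blocked = np.zeros(length, dtype=bool)

    excluded: list[tuple[int, int]] = []
    polya_cols: list[np.ndarray] = []
    for k in range(n_polya):
        start = int(length * (0.18 + 0.4 * k))
        span = 12 - 2 * k
        cols = np.arange(start, start + span)
        base[cols] = "A"
        blocked[cols] = True
        excluded.append((start + 1, start + span))
        polya_cols.append(cols)

    indel_runs: list[np.ndarray] = []
    indel_lengths = [4, 1, 6, 2, 3][:n_indels]
    pos = int(length * 0.05)
    for ln in indel_lengths:
        while blocked[pos : pos + ln + 2].any():
            pos += 5
        cols = np.arange(pos, pos + ln)
        indel_runs.append(cols)
        blocked[cols] = True
        pos += ln + 10

    free = np.flatnonzero(~blocked)
    group_names = list(groups)
    n_centre_subs = {g: 0 if i == 0 else between_steps - n_indels for i, g in enumerate(group_names)}
    n_within = sum(max(0, len(h) - 1) for h in groups.values())
    needed = sum(n_centre_subs.values()) + n_within
    if needed > free.size:
        raise AnalysisError("alignment too short for the requested mutation count")
    sites = rng.choice(free, size=needed, replace=False)
    site_iter = iter(sites)

    def mutate(seq: np.ndarray, col: int) -> None:
        alternatives = [b for b in "ACGT" if b != seq[col]]
        seq[col] = alternatives[int(rng.integers(len(alternatives)))]

    seqs: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}
    for gi, g in enumerate(group_names):
        centre = base.copy()
        for _ in range(n_centre_subs[g]):
            mutate(centre, int(next(site_iter)))
        if gi > 0:
            for cols in indel_runs:
                centre[cols] = "-"
            for cols in polya_cols:  # ragged poly-A ends, excluded anyway
                centre[cols[-2:]] = "-"
        for hi, hap in enumerate(groups[g]):
            seq = centre.copy()
            if hi > 0:
                mutate(seq, int(next(site_iter)))
            seqs[hap] = seq
            truth[hap] = g
    aln = HaploAlignment(
        sequence_ids=list(seqs),
        sequences=["".join(s) for s in seqs.values()],
        excluded_regions=excluded,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# The default study scenario
# ---------------------------------------------------------------------------

#: locus blocks for the default profiles at 241 loci:
#: (label, size, frequency in {arg2x, arg6x, pusilla})
_BLOCKS = (
    ("common", 25, (0.90, 0.90, 0.90)),
    ("arg_shared", 20, (0.80, 0.80, 0.0)),
    ("arg2_specific", 30, (0.60, 0.0, 0.0)),
    ("arg6_specific", 70, (0.0, 0.90, 0.0)),
    ("arg6_private", 6, (0.0, 0.90, 0.0)),
    ("pus_specific", 70, (0.0, 0.0, 0.60)),
    ("pus_private", 6, (0.0, 0.0, 0.90)),
    ("rare", 14, (0.05, 0.05, 0.05)),
)

HAP_GROUPS = {"argentea": ["E", "F", "G", "I"], "pusilla": ["W", "J", "K"]}


def alpicola_profiles(n_loci: int = 241) -> dict[str, TaxonProfile]:
    """Parental taxon profiles over a blocked band-frequency spectrum (a
    mixture of widespread, taxon-diagnostic and rare bands)."""
    total = sum(b[1] for b in _BLOCKS)
    sizes = [max(1, round(b[1] * n_loci / total)) for b in _BLOCKS]
    while sum(sizes) != n_loci:
        sizes[0] += 1 if sum(sizes) < n_loci else -1
    freqs = np.zeros((3, n_loci))
    start = 0
    for (label, _, f), size in zip(_BLOCKS, sizes):
        freqs[:, start : start + size] = np.array(f)[:, None]
        start += size
    common = dict(fcm_beta=0.50)
    return {
        "P. argentea 2x": TaxonProfile(
            "P. argentea",
            2,
            freqs[0],
            ("E",),
            "argentea",
            female_gametes=frozenset({1}),
            male_gametes=frozenset({1}),
            **common,
        ),
        "P. argentea 6x": TaxonProfile(
            "P. argentea",
            6,
            freqs[1],
            ("F", "G", "I"),
            "argentea",
            female_gametes=frozenset({6}),
            male_gametes=frozenset({3}),
            **common,
        ),
        "P. pusilla": TaxonProfile(
            "P. pusilla",
            4,
            freqs[2],
            ("W", "J", "K"),
            "pusilla",
            female_gametes=frozenset({2, 3, 5, 6, 7}),
            male_gametes=frozenset({2, 3}),
            fcm_beta=0.55,
        ),
    }


@dataclass
class SimulatedDataset:
    matrix: MarkerMatrix
    meta: SampleTable
    alignment: HaploAlignment
    fcm: list[FcmRecord]
    fcm_references: list[tuple[str, int]]
    truth_clones: dict[str, str]
    truth_lineages: dict[str, str]
    truth_lineage_defs: dict[str, dict]
    truth_ploidy: dict[str, float]
    profiles: dict[str, TaxonProfile]
    config: SimConfig

    def truth_frame(self) -> pd.DataFrame:
        ids = self.matrix.sample_ids
        return pd.DataFrame(
            {
                "sample_id": ids,
                "clone": [self.truth_clones.get(s, "") for s in ids],
                "lineage": [self.truth_lineages.get(s, "") for s in ids],
                "ploidy": [self.truth_ploidy.get(s, "") for s in ids],
            }
        )


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """The default 'alpicola' scenario: three parental panels, three hybrid
    lineages (one F1, two from crosses outside the inference gamete model) and
    one backcross-chain lineage, with replicate re-scorings, per-sample plastid
    sequences and FCM records.  Deterministic under the config seed."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    profiles = alpicola_profiles(cfg.n_loci)
    arg2, arg6, pus = (
        profiles["P. argentea 2x"],
        profiles["P. argentea 6x"],
        profiles["P. pusilla"],
    )
    alpicola_beta = 0.52

    rows: list[np.ndarray] = []
    ids: list[str] = []
    meta: list[SampleRecord] = []
    truth_clones: dict[str, str] = {}
    truth_lineages: dict[str, str] = {}
    truth_ploidy: dict[str, float] = {}
    fcm: list[FcmRecord] = []
    fcm_refs: list[tuple[str, int]] = []
    sample_hap: dict[str, str] = {}

    def fcm_ratio(beta: float, ploidy: float) -> float:
        return beta * ploidy * (1 + cfg.fcm_noise * rng.standard_normal())

    def add_sample(sid, row, taxon, pop, cytotype, hap, beta, species, replicate_of=None):
        ids.append(sid)
        rows.append(np.asarray(row, dtype=np.int8))
        meta.append(
            SampleRecord(
                sample_id=sid,
                taxon=taxon,
                population=pop,
                cytotype=cytotype,
                haplotype=hap,
                replicate_of=replicate_of,
            )
        )
        truth_ploidy[sid] = float(cytotype)
        sample_hap[sid] = hap
        if replicate_of is None:
            fcm.append(
                FcmRecord(
                    sample_id=sid,
                    ratio=fcm_ratio(beta, cytotype),
                    cv_percent=float(np.round(1.5 + 3.0 * rng.random(), 2)),
                    species=species,
                )
            )

    # --- parental panels
    panels = {}
    for key, profile, pop, prefix in (
        ("P. argentea 2x", arg2, "Pop088", "A2"),
        ("P. argentea 6x", arg6, "Pop093", "A6"),
        ("P. pusilla", pus, "Pop085", "PU"),
    ):
        mat, recs = simulate_parental_panel(
            profile, cfg.n_per_parent_pop, rng, population=pop, id_prefix=prefix
        )
        panels[key] = mat
        for rec, row in zip(recs, mat.values):
            add_sample(
                rec.sample_id,
                row,
                profile.name,
                pop,
                profile.cytotype,
                rec.haplotype,
                profile.fcm_beta,
                profile.name,
            )
        fcm_refs.append((recs[0].sample_id, profile.cytotype))

    # --- replicate re-scorings (scoring error only)
    for orig in ("PU-01", "PU-02", "A6-01", "A6-02"):
        rep_row = simulate_clones(rows[ids.index(orig)], 1, cfg.epsilon, rng)[0]
        rec = meta[ids.index(orig)]
        add_sample(
            f"{orig}-rep",
            rep_row,
            rec.taxon,
            rec.population,
            rec.cytotype,
            rec.haplotype,
            0.5,
            rec.taxon,
            replicate_of=orig,
        )
        fcm.pop()  # replicates are AFLP re-runs, not separate FCM measurements
        del truth_ploidy[f"{orig}-rep"]

    def fresh(profile: TaxonProfile) -> np.ndarray:
        return (rng.random(cfg.n_loci) < profile.band_freq).astype(np.int8)

    lineage_defs: dict[str, dict] = {}

    def plant_lineage(label, founder_row, info, pops_sizes, taxon, prefix, species):
        lineage_defs[label] = info | {"founder_prefix": prefix}
        k = 0
        for pop, size in pops_sizes:
            observed = simulate_clones(founder_row, size, cfg.epsilon, rng)
            for row in observed:
                k += 1
                sid = f"{prefix}-{k:02d}"
                add_sample(
                    sid, row, taxon, pop, info["cytotype"], info["haplotype"],
                    alpicola_beta, species,
                )
                truth_clones[sid] = f"clone_{label}"
                truth_lineages[sid] = label

    # lineage a: single-event F1, P. pusilla egg 2x (haplotype W) x 6x
    # P. argentea pollen 3x -> pentaploid
    row_a, info_a = simulate_hybrid(
        pus, fresh(pus), arg6, fresh(arg6), 2, 3, cfg.loss, cfg.denovo, rng,
        mother_haplotype="W",
    )
    plant_lineage("a", row_a, info_a, [("Pop086", 6)], "P. alpicola", "LA", "P. alpicola")

    # lineage b: hexaploid with an argentea-type plastid (haplotype G); the
    # generating cross uses a reduced 3x egg of hexaploid P. argentea, a
    # gamete mode the inference model excludes -> no single-event explanation
    row_b, info_b = simulate_hybrid(
        arg6, fresh(arg6), pus, fresh(pus), 3, 3, cfg.loss, cfg.denovo, rng,
        mother_haplotype="G", enforce_gametes=False,
    )
    plant_lineage(
        "b", row_b, info_b, [("Pop102", 6), ("Pop200", 4)], "P. alpicola", "LB",
        "P. alpicola",
    )

    # lineage c: hexaploid, haplotype F, mother again via an off-model reduced
    # egg; father is the lineage-a hybrid genotype (second-generation event)
    row_c, info_c = simulate_hybrid(
        arg6, fresh(arg6), pus, row_a, 3, 3, cfg.loss, cfg.denovo, rng,
        mother_haplotype="F", enforce_gametes=False,
    )
    info_c["father"] = "lineage a hybrid"
    plant_lineage("c", row_c, info_c, [("Pop087", 5)], "P. alpicola", "LC", "P. alpicola")

    # lineage d: repeated backcrossing of the F1 into P. pusilla (pollen of the
    # previous hybrid onto fresh 2x P. pusilla eggs); ploidy and haplotype stay
    # compatible with the single-event hypothesis but the genome composition
    # drifts far toward P. pusilla
    row_d, info_d = simulate_hybrid(
        pus, fresh(pus), arg6, fresh(arg6), 2, 3, cfg.loss, cfg.denovo, rng,
        mother_haplotype="W",
    )
    for _ in range(cfg.backcross_depth):
        row_d, info_d = simulate_hybrid(
            pus, fresh(pus), pus, row_d, 2, 3, cfg.loss, cfg.denovo, rng,
            mother_haplotype="W", enforce_gametes=False,
        )
    info_d["father"] = "backcross chain"
    info_d["backcross_depth"] = cfg.backcross_depth
    plant_lineage(
        "d", row_d, info_d, [("Pop201", 5)], "P. alpicola/pusilla", "BX",
        "P. alpicola/pusilla",
    )
    fcm_refs.append(("LA-01", 5))
    fcm_refs.append(("LB-01", 6))
    fcm_refs.append(("BX-01", 5))

    # FCM edge cases: a measurement failing the CV filter and a possible
    # aneuhexaploid (ratio 6.3 x the per-ploidy slope)
    fcm.append(
        FcmRecord(
            sample_id="PU-highcv", ratio=0.55 * 4, cv_percent=5.13, species="P. pusilla"
        )
    )
    fcm.append(
        FcmRecord(
            sample_id="LB-aneu",
            ratio=alpicola_beta * 6.3,
            cv_percent=2.1,
            species="P. alpicola",
        )
    )
    truth_ploidy["LB-aneu"] = 6.3

    # --- plastid sequences: one per non-replicate sample, from its haplotype
    hap_aln, hap_truth = simulate_haplotypes(
        HAP_GROUPS, between_steps=12, length=550, n_indels=3, n_polya=2, seed_or_rng=rng
    )
    hap_seq = dict(zip(hap_aln.sequence_ids, hap_aln.sequences))
    seq_ids, seqs = [], []
    for rec in meta:
        if rec.replicate_of is None:
            seq_ids.append(rec.sample_id)
            seqs.append(hap_seq[sample_hap[rec.sample_id]])
    alignment = HaploAlignment(seq_ids, seqs, excluded_regions=hap_aln.excluded_regions)

    loci = [f"L{j + 1:03d}" for j in range(cfg.n_loci)]
    matrix = MarkerMatrix(ids, loci, np.vstack(rows))
    return SimulatedDataset(
        matrix=matrix,
        meta=SampleTable(meta),
        alignment=alignment,
        fcm=fcm,
        fcm_references=fcm_refs,
        truth_clones=truth_clones,
        truth_lineages=truth_lineages,
        truth_lineage_defs=lineage_defs,
        truth_ploidy=truth_ploidy,
        profiles=profiles,
        config=cfg,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write all pipeline inputs plus truth tables to a directory."""
    import os

    from .io_model import write_alignment, write_fcm, write_marker_matrix, write_metadata

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "markers.tsv"),
        "meta": os.path.join(out_dir, "meta.tsv"),
        "alignment": os.path.join(out_dir, "haplotypes.fasta"),
        "fcm": os.path.join(out_dir, "fcm.tsv"),
        "truth": os.path.join(out_dir, "truth_samples.tsv"),
        "exclusions": os.path.join(out_dir, "excluded_regions.tsv"),
        "references": os.path.join(out_dir, "fcm_references.tsv"),
    }
    write_marker_matrix(ds.matrix, paths["matrix"])
    write_metadata(ds.meta, paths["meta"])
    write_alignment(ds.alignment, paths["alignment"])
    write_fcm(ds.fcm, paths["fcm"])
    ds.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["exclusions"], "w") as fh:
        fh.write("start\tend\n")
        for a, b in ds.alignment.excluded_regions:
            fh.write(f"{a}\t{b}\n")
    with open(paths["references"], "w") as fh:
        fh.write("sample_id\tploidy\n")
        for sid, k in ds.fcm_references:
            fh.write(f"{sid}\t{k}\n")
    return paths
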