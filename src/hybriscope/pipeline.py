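"""End-to-end orchestration: simulate/load -> fragment stats -> clones ->
haplotype network -> splits -> ordination -> hybrid-origin verdicts.

All stage outputs are written to an output directory together with a combined
``report.json``; every random choice flows through one seeded generator, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import clonal, fragment_stats, haplonet, hybrid_inference, ordination, splits
from .errors import AnalysisError, HybriscopeError
from .io_model import (
    read_alignment,
    read_fcm,
    read_marker_matrix,
    read_metadata,
    read_region_exclusions,
    write_splits_nexus,
)
from .synthetic_data import SimConfig, simulate_dataset, write_dataset

log = logging.getLogger("hybriscope")

DEFAULT_FOCAL_TAXA = ("P. alpicola", "P. alpicola/pusilla")


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and thresholds for one pipeline run."""

    # either simulate=True (inputs generated under `seed`) or explicit paths
    simulate: bool = True
    matrix_path: str | None = None
    meta_path: str | None = None
    alignment_path: str | None = None
    exclusions_path: str | None = None
    fcm_path: str | None = None
    fcm_references_path: str | None = None

    run_haplonet: bool = True
    run_splits: bool = True
    run_ordination: bool = True
    run_hybrids: bool = True

    clone_threshold: int = 5  # band differences tolerated within a clone
    cluster_threshold: int = 20  # coarser threshold defining lineage clusters
    connection_limit: int | str = haplonet.DEFAULT_STEP_LIMIT
    weight_floor: float = splits.DEFAULT_WEIGHT_FLOOR
    fcm_tolerance: float = hybrid_inference.DEFAULT_ANEUPLOID_TOL
    dead_band: float = hybrid_inference.DEFAULT_DEAD_BAND
    splits_max_samples: int = 60  # stride-subsample cap for the NNLS fit
    focal_taxa: tuple = DEFAULT_FOCAL_TAXA

    seed: int = 0
    out_dir: str = "hybriscope_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise AnalysisError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.focal_taxa, list):
            cfg.focal_taxa = tuple(cfg.focal_taxa)
        return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _group_key(rec) -> str:
    if rec.cytotype is not None and rec.taxon == "P. argentea":
        return f"{rec.taxon} {rec.cytotype}x"
    return rec.taxon


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the combined report (also written to
    ``out_dir/report.json``).  A stage failure aborts with the stage name."""
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"seed": config.seed, "config": {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
    }}
    stage = "inputs"
    try:
        if config.simulate:
            ds = simulate_dataset(SimConfig(seed=config.seed))
            write_dataset(ds, os.path.join(config.out_dir, "inputs"))
            matrix, meta, alignment = ds.matrix, ds.meta, ds.alignment
            fcm, fcm_refs = ds.fcm, ds.fcm_references
        else:
            if not (config.matrix_path and config.meta_path):
                raise AnalysisError("matrix_path and meta_path are required")
            matrix = read_marker_matrix(config.matrix_path)
            meta = read_metadata(config.meta_path)
            alignment = None
            if config.alignment_path:
                excl = (
                    read_region_exclusions(config.exclusions_path)
                    if config.exclusions_path
                    else ()
                )
                alignment = read_alignment(config.alignment_path, excl)
            fcm = read_fcm(config.fcm_path) if config.fcm_path else []
            fcm_refs = []
            if config.fcm_references_path:
                with open(config.fcm_references_path) as fh:
                    next(fh)
                    fcm_refs = [
                        (ln.split("\t")[0].strip(), int(ln.split("\t")[1]))
                        for ln in fh
                        if ln.strip()
                    ]
        log.info("stage inputs done (%.2fs)", time.time() - t0)

        focal = [
            r.sample_id
            for r in meta.non_excluded()
            if r.taxon in config.focal_taxa and r.replicate_of is None
        ]
        parent_groups = sorted(
            {
                _group_key(r)
                for r in meta.non_excluded()
                if r.taxon not in config.focal_taxa and r.replicate_of is None
            }
        )

        # ------------------------------------------------ fragment statistics
        stage = "fragment_stats"
        ts = time.time()
        totals = fragment_stats.fragment_totals(matrix, meta)
        repeat = fragment_stats.replicate_error_rate(matrix, meta)
        groups = fragment_stats.build_group_sets(matrix, meta, by=_group_key)
        by_label = {g.label: g for g in groups}
        parents = [by_label[g] for g in parent_groups if g in by_label]
        priv = (
            fragment_stats.private_fragments(
                parents, hybrid_groups=[g for g in groups if g.label in config.focal_taxa]
            )
            if len(parents) >= 2
            else {"private": {}, "carried_by_hybrids": {}}
        )
        report["fragment_stats"] = {
            "totals": totals,
            "repeatability": repeat,
            "group_fragment_counts": {g.label: g.count for g in groups},
            "private_fragments": {
                g: len(loci) for g, loci in priv["private"].items()
            },
        }
        log.info("stage fragment_stats done (%.2fs)", time.time() - ts)

        # ------------------------------------------------------------- clones
        stage = "clonal"
        ts = time.time()
        focal_pops = sorted(
            {r.population for r in meta.non_excluded() if r.sample_id in set(focal)}
        )
        partitions = clonal.clonal_diversity_table(
            matrix, meta, focal_pops, config.clone_threshold
        )
        shared = clonal.shared_clones_across_populations(
            matrix, meta, focal_pops, config.clone_threshold
        )
        report["clonal"] = {
            "threshold": config.clone_threshold,
            "populations": [
                {
                    "population": p.population,
                    "Nb": p.nb,
                    "Nb_geno": p.nb_geno,
                    "D_g": round(p.d_g, 3),
                }
                for p in partitions
            ],
            "shared_clones_across_populations": shared,
        }
        log.info("stage clonal done (%.2fs)", time.time() - ts)

        # ---------------------------------------------------- haplotype network
        hap_group_of_sample: dict[str, str] = {}
        network = None
        if config.run_haplonet and alignment is not None:
            stage = "haplonet"
            ts = time.time()
            network, coded = haplonet.network_from_alignment(
                alignment, meta, limit=config.connection_limit
            )
            table = haplonet.haplotype_table(network, meta)
            table.to_csv(os.path.join(config.out_dir, "haplotypes.tsv"), sep="\t", index=False)
            haplonet.write_network_graphml(
                network, os.path.join(config.out_dir, "haplonet.graphml")
            )
            for h in network.haplotypes:
                comp = network.group_of(h.label)
                for carrier in h.carriers:
                    hap_group_of_sample[carrier] = f"group{comp}"
            report["haplonet"] = {
                "n_haplotypes": len(network.haplotypes),
                "n_groups": len(network.components),
                "characters": coded.n_characters,
                "coded_indels": coded.n_indel,
                "connection_limit": network.connection_limit,
            }
            log.info("stage haplonet done (%.2fs)", time.time() - ts)

        # ------------------------------------------------------------- splits
        if config.run_splits:
            stage = "splits"
            ts = time.time()
            usable = [
                r.sample_id
                for r in meta.non_excluded()
                if r.replicate_of is None and r.sample_id in matrix.sample_ids
            ]
            stride = max(1, -(-len(usable) // config.splits_max_samples))
            chosen = usable[::stride]
            sub = matrix.subset(chosen)
            d_j = splits.jaccard_distance(sub)
            system = splits.neighbor_net(d_j, taxa=chosen, weight_floor=config.weight_floor)
            write_splits_nexus(system, os.path.join(config.out_dir, "splits.nex"))
            group_members = {}
            for s in chosen:
                group_members.setdefault(_group_key(meta.get(s)), []).append(s)
            cohesion = splits.group_cohesion(
                group_members, splits=system, d=d_j, sample_ids=chosen
            )
            report["splits"] = {
                "n_taxa": len(chosen),
                "n_splits": len(system.splits),
                "group_cohesion": cohesion,
            }
            log.info("stage splits done (%.2fs)", time.time() - ts)

        # ---------------------------------------------------------- ordination
        if config.run_ordination and len(parent_groups) >= 2:
            stage = "ordination"
            ts = time.time()
            refs = {
                g: [
                    r.sample_id
                    for r in meta.non_excluded()
                    if _group_key(r) == g and r.replicate_of is None
                ]
                for g in parent_groups
            }
            result = ordination.embed(matrix, refs, focal)
            coords = {
                s: [round(float(x), 6), round(float(y), 6)]
                for s, (x, y) in zip(result.sample_ids, result.coords)
            }
            with open(os.path.join(config.out_dir, "coords.tsv"), "w") as fh:
                fh.write("sample_id\tx\ty\n")
                for s, (x, y) in coords.items():
                    fh.write(f"{s}\t{x}\t{y}\n")
            report["ordination"] = {
                "mapping_error": round(result.mapping_error, 6),
                "centroids": {g: c.tolist() for g, c in result.centroids.items()},
            }
            log.info("stage ordination done (%.2fs)", time.time() - ts)

        # ------------------------------------------------------------ hybrids
        if config.run_hybrids:
            stage = "hybrid_inference"
            ts = time.time()
            model = hybrid_inference.default_gamete_model()
            ploidy_df = None
            ploidy_of: dict[str, int] = {}
            if fcm and fcm_refs:
                ploidy_df = hybrid_inference.infer_ploidy_from_fcm(
                    fcm, fcm_refs, aneuploid_tol=config.fcm_tolerance
                )
                ploidy_df.to_csv(
                    os.path.join(config.out_dir, "ploidy.tsv"), sep="\t", index=False
                )
                ploidy_of = {
                    r.sample_id: int(r.ploidy)
                    for r in ploidy_df.itertuples()
                    if r.status == "assigned"
                }

            diffs = clonal.pairwise_differences(matrix, focal)
            part = clonal.assign_clones(diffs, config.cluster_threshold, focal)
            clusters = {
                s: f"cluster{k}" for k, cl in enumerate(part.clusters) for s in cl
            }
            lineages, unassignable = hybrid_inference.define_lineages(
                meta, focal, clusters, cytotypes=ploidy_of
            )

            # map each model taxon's haplogroup name to a network component
            comp_name_of: dict[str, str] = {}
            if network is not None:
                for t in model:
                    carriers = [
                        r.sample_id
                        for r in meta.non_excluded()
                        if _group_key(r) == t.label and r.sample_id in hap_group_of_sample
                    ]
                    comps = {hap_group_of_sample[c] for c in carriers}
                    if len(comps) == 1:
                        comp_name_of[t.label] = comps.pop()

            verdicts = {}
            scores_by_lineage = {}
            for lin in lineages:
                lin_set = fragment_stats.GroupFragmentSet(
                    label=f"lineage {lin.label}",
                    members=lin.members,
                    fragments=frozenset(
                        l
                        for l, p in zip(
                            matrix.locus_labels,
                            matrix.subset(lin.members).values.any(axis=0),
                        )
                        if p
                    ),
                )
                scores = hybrid_inference.parentage_scores(
                    lin_set, parents, priv["private"]
                )
                scores_by_lineage[lin.label] = scores
                if network is not None:
                    member_groups = {
                        hap_group_of_sample.get(s)
                        for s in lin.members
                        if s in hap_group_of_sample
                    } - {None}
                    target = member_groups.pop() if len(member_groups) == 1 else None
                    taxon_group = {t.label: comp_name_of.get(t.label) for t in model}
                    remodel = [
                        hybrid_inference.GameteTaxon(
                            t.label, t.male_gametes, t.female_gametes,
                            taxon_group[t.label] or f"unmapped:{t.label}",
                        )
                        for t in model
                    ]
                    hyps = (
                        hybrid_inference.enumerate_crosses(
                            remodel, lin.cytotype, target
                        )
                        if target is not None
                        else []
                    )
                    verdict = hybrid_inference.explain_lineage(
                        lin, hyps, scores, dead_band=config.dead_band
                    )
                else:
                    hyps = hybrid_inference.enumerate_crosses(
                        model, lin.cytotype, target_haplogroup=None
                    )
                    verdict = hybrid_inference.explain_lineage(
                        lin, hyps, scores, dead_band=config.dead_band
                    )
                    verdict["maternal_clause"] = "unknown (haplotype network disabled)"
                verdicts[lin.label] = verdict

            summary = hybrid_inference.lineage_summary_table(
                lineages, scores_by_lineage, verdicts, meta
            )
            summary.to_csv(
                os.path.join(config.out_dir, "lineages.tsv"), sep="\t", index=False
            )
            report["hybrid_inference"] = {
                "lineages": [
                    {
                        "label": lin.label,
                        "members": lin.members,
                        "cytotype": lin.cytotype,
                        "haplotype": lin.haplotype,
                    }
                    for lin in lineages
                ],
                "unassignable": unassignable,
                "verdicts": verdicts,
                "parentage": {
                    lab: df.to_dict(orient="records")
                    for lab, df in scores_by_lineage.items()
                },
                "ploidy_flags": (
                    ploidy_df[ploidy_df.status != "assigned"][
                        ["sample_id", "status", "reason"]
                    ].to_dict(orient="records")
                    if ploidy_df is not None
                    else []
                ),
            }
            log.info("stage hybrid_inference done (%.2fs)", time.time() - ts)
    except HybriscopeError as e:
        raise AnalysisError(f"pipeline stage {stage!r} failed: {e}") from e

    log.info("pipeline done (%.2fs)", time.time() - t0)
    # no timing data in the report: a rerun with the same seed and config must
    # produce a byte-identical file
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report
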