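import numpy as np
import pandas as pd
import pytest

from hybriscope.errors import AnalysisError
from hybriscope.fragment_stats import GroupFragmentSet
from hybriscope.hybrid_inference import (
    CrossHypothesis,
    GameteTaxon,
    Lineage,
    classify_additivity,
    default_gamete_model,
    define_lineages,
    enumerate_crosses,
    explain_lineage,
    infer_ploidy_from_fcm,
    parentage_scores,
    validate_cross,
)
from hybriscope.io_model import FcmRecord, SampleRecord, SampleTable

MODEL = default_gamete_model()


class TestEnumerateCrosses:
    def test_pentaploid_with_pusilla_plastid(self):
        hyps = enumerate_crosses(MODEL, 5, "pusilla")
        combos = {(h.mother, h.father, h.egg_ploidy, h.pollen_ploidy) for h in hyps}
        assert ("P. pusilla", "P. argentea 6x", 2, 3) in combos
        # all hypotheses re-validate against the model (closure invariant)
        for h in hyps:
            validate_cross(MODEL, h)
            assert h.offspring_ploidy == 5

    def test_hexaploid_with_argentea_plastid_has_no_single_event(self):
        # argentea mothers give 1x or unreduced 6x eggs; no pollen ploidy in
        # the model completes either to exactly 6
        assert enumerate_crosses(MODEL, 6, "argentea") == []

    def test_empty_female_sets_give_empty_list(self):
        model = [GameteTaxon("X", frozenset({2}), frozenset({9}), "h")]
        assert enumerate_crosses(model, 5, "h", allow_selfing=True) == []

    def test_selfing_excluded_by_default_but_switchable(self):
        without = enumerate_crosses(MODEL, 5, "pusilla")
        with_self = enumerate_crosses(MODEL, 5, "pusilla", allow_selfing=True)
        assert all(h.mother != h.father for h in without)
        assert any(h.mother == h.father for h in with_self)

    def test_sub_diploid_target_rejected(self):
        with pytest.raises(AnalysisError):
            enumerate_crosses(MODEL, 1, "pusilla")

    def test_impossible_cross_validation(self):
        bad = CrossHypothesis("P. argentea 2x", "P. pusilla", 4, 2)
        with pytest.raises(AnalysisError, match="impossible cross"):
            validate_cross(MODEL, bad)


class TestInferPloidy:
    def _records(self, beta=0.52, noise=0.0, seed=0, ploidies=(2, 3, 4, 5, 6, 7)):
        rng = np.random.default_rng(seed)
        recs = [
            FcmRecord(f"s{k}", beta * k * (1 + noise * rng.standard_normal()), 2.5, "X")
            for k in ploidies
        ]
        return recs

    def test_exact_proportional_ratios_assign_interpolated_ploidy(self):
        recs = self._records(ploidies=(2, 5, 6))
        refs = [("s2", 2), ("s6", 6)]
        out = infer_ploidy_from_fcm(recs, refs)
        row = out[out.sample_id == "s5"].iloc[0]
        assert row.status == "assigned" and row.ploidy == 5
        assert not row.possible_aneuploid

    def test_one_percent_noise_recovers_2x_to_7x_exactly(self):
        recs = self._records(noise=0.01, seed=1)
        out = infer_ploidy_from_fcm(recs, [("s2", 2), ("s6", 6)])
        for r in out.itertuples():
            assert r.ploidy == int(r.sample_id[1:])

    def test_cv_filter_excludes_at_5_13_percent(self):
        recs = [FcmRecord("hi", 1.0, 5.13, "X"), FcmRecord("ok", 1.04, 1.50, "X")]
        out = infer_ploidy_from_fcm(recs, [("ok", 2)])
        assert out[out.sample_id == "hi"].iloc[0].status == "excluded_cv"

    def test_aneuploid_flagged_at_3_percent_tolerance(self):
        beta = 0.52
        recs = [FcmRecord("ref", beta * 6, 2.0, "X"), FcmRecord("an", beta * 6.3, 2.0, "X")]
        out = infer_ploidy_from_fcm(recs, [("ref", 6)])
        row = out[out.sample_id == "an"].iloc[0]
        assert row.ploidy == 6 and row.possible_aneuploid

    def test_species_without_reference_cannot_attribute(self):
        recs = [FcmRecord("a", 1.0, 2.0, "P. frigida")]
        out = infer_ploidy_from_fcm(recs, [])
        assert out.iloc[0].status == "cannot_attribute"


class TestParentageScores:
    def test_published_style_percentages_and_ranking(self):
        lineage = GroupFragmentSet("a", [], frozenset(f"L{i}" for i in range(115)))
        pus = GroupFragmentSet(
            "P. pusilla", [], frozenset(f"L{i}" for i in range(107)) | {f"P{i}" for i in range(98)}
        )
        arg = GroupFragmentSet(
            "P. argentea 6x", [], frozenset(f"L{i}" for i in range(104)) | {f"A{i}" for i in range(73)}
        )
        scores = parentage_scores(lineage, [arg, pus], {"P. pusilla": [f"L{i}" for i in range(2)] + ["P0", "P1", "P2", "P3"]})
        assert scores.iloc[0].candidate == "P. pusilla"
        assert scores.iloc[0].shared_percent == 93.04
        assert f"{scores.iloc[0].private_carried}/{scores.iloc[0].private_total}" == "2/6"
        assert scores.iloc[1].shared_percent == 90.43

    def test_empty_candidate_list_rejected(self):
        lineage = GroupFragmentSet("a", [], frozenset({"L1"}))
        with pytest.raises(AnalysisError):
            parentage_scores(lineage, [])


class TestClassifyAdditivity:
    def test_exact_union_has_no_loss_or_gain(self):
        m = np.array([1, 1, 0, 0, 1])
        f = np.array([0, 1, 1, 0, 0])
        out = classify_additivity(m | f, m, f)
        assert (out.lost, out.de_novo) == (0, 0)
        assert out.additive == out.union_size == 4

    def test_all_zero_hybrid_loses_entire_union(self):
        m = np.array([1, 0, 1])
        f = np.array([0, 0, 1])
        out = classify_additivity(np.zeros(3, dtype=int), m, f)
        assert out.lost == out.union_size == 2

    def test_counts_partition_loci_exactly(self):
        rng = np.random.default_rng(0)
        h, m, f = (rng.integers(0, 2, 100) for _ in range(3))
        out = classify_additivity(h, m, f)
        union = (m | f).sum()
        assert out.additive + out.lost == union
        assert out.de_novo <= 100 - union

    def test_simulated_rates_within_three_binomial_se(self):
        from hybriscope.synthetic_data import alpicola_profiles, simulate_hybrid

        profiles = alpicola_profiles()
        pus, arg6 = profiles["P. pusilla"], profiles["P. argentea 6x"]
        rng = np.random.default_rng(1)
        n = 10_000
        m = (rng.random(n) < 0.5).astype(np.int8)
        f = (rng.random(n) < 0.5).astype(np.int8)
        h, _ = simulate_hybrid(pus, m, arg6, f, 2, 3, 0.17, 0.024, rng)
        out = classify_additivity(h, m, f)
        se_loss = np.sqrt(0.17 * 0.83 / out.union_size)
        se_dn = np.sqrt(0.024 * 0.976 / (n - out.union_size))
        assert abs(out.loss_rate - 0.17) < 3 * se_loss
        assert abs(out.de_novo_rate - 0.024) < 3 * se_dn

    def test_mismatched_loci_rejected(self):
        with pytest.raises(AnalysisError):
            classify_additivity(np.zeros(3), np.zeros(4), np.zeros(4))


class TestDefineLineages:
    def test_all_identical_annotations_one_lineage(self):
        meta = SampleTable(
            [SampleRecord(f"s{i}", "H", "P", cytotype=6, haplotype="G") for i in range(4)]
        )
        lins, un = define_lineages(meta, [f"s{i}" for i in range(4)], {f"s{i}": 0 for i in range(4)})
        assert len(lins) == 1 and not un
        assert lins[0].cytotype == 6 and lins[0].haplotype == "G"

    def test_missing_annotation_goes_to_unassignable(self):
        meta = SampleTable([SampleRecord("s0", "H", "P", cytotype=6)])  # no haplotype
        lins, un = define_lineages(meta, ["s0"], {"s0": 0})
        assert not lins and un[0]["missing"] == ["haplotype"]

    def test_scenario_recovery(self, dataset):
        from hybriscope.clonal import assign_clones, pairwise_differences

        focal = [
            r.sample_id
            for r in dataset.meta.non_excluded()
            if r.taxon in ("P. alpicola", "P. alpicola/pusilla") and r.replicate_of is None
        ]
        part = assign_clones(pairwise_differences(dataset.matrix, focal), 20, focal)
        clusters = {s: i for i, cl in enumerate(part.clusters) for s in cl}
        lins, un = define_lineages(dataset.meta, focal, clusters)
        assert not un
        got = {frozenset(l.members) for l in lins}
        want = {
            frozenset(s for s, lab in dataset.truth_lineages.items() if lab == k)
            for k in "abcd"
        }
        assert got == want


class TestExplainLineage:
    def _scores(self, mother_pct, father_pct, mother="P. pusilla", father="P. argentea 6x"):
        return pd.DataFrame(
            {
                "candidate": [mother, father],
                "shared_percent": [mother_pct, father_pct],
            }
        )

    def test_father_leaning_f1_is_single_event(self):
        hyps = enumerate_crosses(MODEL, 5, "pusilla")
        lin = Lineage("a", ["x"], 5, "W")
        out = explain_lineage(lin, hyps, self._scores(48.0, 63.0))
        assert out["verdict"] == "single-event"

    def test_composition_clause_fails_pusilla_heavy_pentaploid(self):
        hyps = enumerate_crosses(MODEL, 5, "pusilla")
        lin = Lineage("d", ["x"], 5, "W")
        out = explain_lineage(lin, hyps, self._scores(69.0, 45.0))
        assert out["verdict"] == "not-single-event"
        assert any("father-leaning" in r for r in out["reasons"])

    def test_haplotype_clause_fails_without_hypotheses(self):
        lin = Lineage("b", ["x"], 6, "G")
        out = explain_lineage(lin, [], self._scores(50.0, 50.0))
        assert out["verdict"] == "not-single-event"
        assert out["reasons"] == ["no haplotype-compatible cross"]

    def test_dead_band_accepts_either_ranking(self):
        hyp = CrossHypothesis("P. pusilla", "P. argentea 6x", 3, 3)  # fraction 0.5
        lin = Lineage("x", ["x"], 6, "W")
        for sm, sf in ((60.0, 40.0), (40.0, 60.0)):
            out = explain_lineage(lin, [hyp], self._scores(sm, sf))
            assert out["verdict"] == "single-event"
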