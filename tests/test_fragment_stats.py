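import numpy as np
import pytest

from hybriscope.errors import AnalysisError, ValidationError
from hybriscope.fragment_stats import (
    GroupFragmentSet,
    build_group_sets,
    fragment_totals,
    private_fragments,
    replicate_error_rate,
    shared_fragments,
)
from hybriscope.io_model import MarkerMatrix, SampleRecord, SampleTable


def _matrix_with_polymorphism(n_total=241, n_poly=233):
    """Two samples; n_poly loci differ between them, the rest are fixed present."""
    values = np.ones((2, n_total), dtype=int)
    values[0, :n_poly] = 0
    return MarkerMatrix(["s1", "s2"], [f"L{i}" for i in range(n_total)], values)


class TestFragmentTotals:
    def test_percent_polymorphic_published_arithmetic(self):
        m = _matrix_with_polymorphism(241, 233)
        out = fragment_totals(m)
        assert out["total_fragments"] == 241
        assert out["polymorphic_fragments"] == 233
        assert out["percent_polymorphic"] == 96.68

    def test_all_fixed_present_is_zero_percent(self):
        m = MarkerMatrix(["a", "b"], ["L1", "L2"], np.ones((2, 2)))
        assert fragment_totals(m)["percent_polymorphic"] == 0.0

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(0)
        m = MarkerMatrix(
            [f"s{i}" for i in range(20)],
            [f"L{j}" for j in range(30)],
            rng.integers(0, 2, (20, 30)),
        )
        out = fragment_totals(m)
        total = poly = 0
        for j in range(30):
            col = m.values[:, j]
            if col.any():
                total += 1
                if not col.all():
                    poly += 1
        assert out["total_fragments"] == total
        assert out["polymorphic_fragments"] == poly

    def test_all_excluded_rejected(self):
        m = MarkerMatrix(["a"], ["L1"], np.ones((1, 1)))
        meta = SampleTable([SampleRecord("a", "T", "P", excluded=True, exclusion_reason="x")])
        with pytest.raises(AnalysisError):
            fragment_totals(m, meta)


class TestSharedFragments:
    def test_published_percentages(self):
        lineage_a = GroupFragmentSet("a", [], frozenset(f"L{i}" for i in range(115)))
        arg2 = GroupFragmentSet(
            "arg2", [], frozenset(f"L{i}" for i in range(58)) | {f"X{i}" for i in range(20)}
        )
        assert shared_fragments(lineage_a, arg2) == (58, 50.43)
        collina = GroupFragmentSet("col", [], frozenset(f"L{i}" for i in range(164)))
        arg6 = GroupFragmentSet(
            "arg6", [], frozenset(f"L{i}" for i in range(149)) | {f"Y{i}" for i in range(28)}
        )
        assert shared_fragments(collina, arg6) == (149, 90.85)

    def test_self_comparison_is_total(self):
        g = GroupFragmentSet("g", [], frozenset({"L1", "L2", "L3"}))
        assert shared_fragments(g, g) == (3, 100.0)

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fa = frozenset(f"L{i}" for i in rng.choice(100, rng.integers(5, 60), replace=False))
            fb = frozenset(f"L{i}" for i in rng.choice(100, rng.integers(5, 60), replace=False))
            cnt, pct = shared_fragments(
                GroupFragmentSet("a", [], fa), GroupFragmentSet("b", [], fb)
            )
            assert cnt == len(fa & fb)
            assert pct == pytest.approx(round(100 * len(fa & fb) / len(fa), 2), abs=0.011)

    def test_empty_set_rejected(self):
        g = GroupFragmentSet("g", [], frozenset({"L1"}))
        e = GroupFragmentSet("e", [], frozenset())
        with pytest.raises(AnalysisError):
            shared_fragments(g, e)


class TestPrivateFragments:
    def test_disjoint_single_band_groups(self):
        a = GroupFragmentSet("a", ["s1"], frozenset({"L1"}))
        b = GroupFragmentSet("b", ["s2"], frozenset({"L2"}))
        out = private_fragments([a, b])
        assert out["private"] == {"a": ["L1"], "b": ["L2"]}

    def test_band_in_two_of_five_groups_private_to_none(self):
        groups = [
            GroupFragmentSet(f"g{i}", [f"s{i}"], frozenset({"SH"} if i < 2 else {f"L{i}"}))
            for i in range(5)
        ]
        out = private_fragments(groups)
        assert out["private"]["g0"] == [] and out["private"]["g1"] == []

    def test_additive_hybrid_carries_all_parental_private_bands(self):
        from hybriscope.synthetic_data import alpicola_profiles, simulate_hybrid

        profiles = alpicola_profiles()
        pus, arg6 = profiles["P. pusilla"], profiles["P. argentea 6x"]
        rng = np.random.default_rng(0)
        mrow = (rng.random(241) < pus.band_freq).astype(np.int8)
        frow = (rng.random(241) < arg6.band_freq).astype(np.int8)
        hrow, _ = simulate_hybrid(pus, mrow, arg6, frow, 2, 3, 0.0, 0.0, rng)
        loci = [f"L{j}" for j in range(241)]
        sets = {
            name: GroupFragmentSet(name, [name], frozenset(l for l, p in zip(loci, row) if p))
            for name, row in (("pus", mrow), ("arg6", frow))
        }
        hyb = GroupFragmentSet("hyb", ["h"], frozenset(l for l, p in zip(loci, hrow) if p))
        out = private_fragments(list(sets.values()), hybrid_groups=[hyb])
        for parent in ("pus", "arg6"):
            assert out["carried_by_hybrids"]["hyb"][parent] == out["private"][parent]

    def test_private_sets_pairwise_disjoint_and_bounded(self):
        rng = np.random.default_rng(3)
        loci = [f"L{i}" for i in range(50)]
        groups = [
            GroupFragmentSet(
                f"g{i}", [f"s{i}"],
                frozenset(l for l in loci if rng.random() < 0.4),
            )
            for i in range(4)
        ]
        out = private_fragments(groups)
        all_private = [l for p in out["private"].values() for l in p]
        assert len(all_private) == len(set(all_private))
        assert len(all_private) <= len(loci)

    def test_overlapping_membership_rejected(self):
        a = GroupFragmentSet("a", ["s1"], frozenset({"L1"}))
        b = GroupFragmentSet("b", ["s1"], frozenset({"L2"}))
        with pytest.raises(ValidationError):
            private_fragments([a, b])


class TestReplicateError:
    def _with_replicates(self, diffs):
        n = 241
        base = np.zeros(n, dtype=int)
        rep = base.copy()
        rep[:diffs] = 1
        m = MarkerMatrix(["s1", "s1r"], [f"L{i}" for i in range(n)], np.vstack([base, rep]))
        meta = SampleTable(
            [SampleRecord("s1", "T", "P"), SampleRecord("s1r", "T", "P", replicate_of="s1")]
        )
        return m, meta

    def test_identical_pair_is_100_percent(self):
        m, meta = self._with_replicates(0)
        out = replicate_error_rate(m, meta)
        assert out["pairs"][0]["repeatability"] == 100.0

    def test_three_differences_of_241(self):
        m, meta = self._with_replicates(3)
        out = replicate_error_rate(m, meta)
        assert out["pairs"][0]["repeatability"] == 98.76

    def test_no_replicates_is_explicit_result(self, tiny_matrix, tiny_meta):
        out = replicate_error_rate(tiny_matrix, tiny_meta)
        assert out["n_pairs"] == 0 and out["note"] == "no replicates"

    def test_simulated_replicates_match_closed_form(self):
        from hybriscope.synthetic_data import simulate_clones

        eps, loci, pairs = 0.0124, 241, 300
        founder = np.zeros(loci, dtype=int)
        ids, rows, recs = [], [], []
        rng = np.random.default_rng(9)
        for i in range(pairs):
            a, b = simulate_clones(founder, 2, eps, rng)
            ids += [f"o{i}", f"r{i}"]
            rows += [a, b]
            recs += [
                SampleRecord(f"o{i}", "T", "P"),
                SampleRecord(f"r{i}", "T", "P", replicate_of=f"o{i}"),
            ]
        m = MarkerMatrix(ids, [f"L{j}" for j in range(loci)], np.vstack(rows))
        out = replicate_error_rate(m, SampleTable(recs))
        p = 2 * eps * (1 - eps)
        expect = 100 * (1 - p)
        sigma = 100 * np.sqrt(p * (1 - p) / loci / pairs)
        assert abs(out["mean_repeatability"] - expect) < 3 * sigma


class TestGroupSets:
    def test_excluded_samples_never_contribute(self):
        m = MarkerMatrix(["s1", "s2"], ["L1", "L2"], np.array([[1, 0], [0, 1]]))
        meta = SampleTable(
            [
                SampleRecord("s1", "T", "P"),
                SampleRecord("s2", "T", "P", excluded=True, exclusion_reason="misidentified"),
            ]
        )
        (g,) = build_group_sets(m, meta, by="taxon")
        assert g.fragments == frozenset({"L1"})

    def test_group_presence_is_any_member(self, dataset):
        groups = build_group_sets(dataset.matrix, dataset.meta, by="taxon")
        for g in groups:
            sub = dataset.matrix.subset(g.members)
            expected = frozenset(
                l for l, p in zip(dataset.matrix.locus_labels, sub.values.any(axis=0)) if p
            )
            assert g.fragments == expected
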