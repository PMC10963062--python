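import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from micoval.consistency import (
    ConsistencyRecord,
    consistency_score,
    consistency_table,
    fb_ratio_cross_project,
    pathway_consistency,
    records_frame,
    sankey_edges,
    select_consistent,
    stratified_consistency,
    weighted_consistency_score,
)
from micoval.differential import compare_features
from micoval.io import (
    Lineage,
    TaxonomyMap,
    ValidationError,
    collapse_to_rank,
    enumerate_comparisons,
)
from micoval.preprocess import default_pipeline
from micoval.simulate import (
    PlantedEffect,
    SimulationSpec,
    consistent_effects,
    simulate_multiproject,
    taxonomy_for,
)

from conftest import make_result


class TestConsistencyScore:
    @pytest.mark.parametrize(
        "n1,n2,denom,expected",
        [(3, 0, 3, 1.0), (0, 2, 2, -1.0), (4, 1, 5, 0.6)],
    )
    def test_printed_examples(self, n1, n2, denom, expected):
        assert consistency_score(n1, n2, denom) == pytest.approx(expected)

    def test_brute_force_enumeration_both_denominators(self):
        # all (n1, n2) with 1 <= n1+n2 <= 6, plus extra evaluated comparisons
        for n1 in range(7):
            for n2 in range(7 - n1):
                n_sig = n1 + n2
                if n_sig == 0:
                    continue
                assert consistency_score(n1, n2, n_sig) == pytest.approx(
                    (n1 - n2) / n_sig
                )
                for extra in range(3):
                    total = n_sig + extra
                    assert consistency_score(n1, n2, total) == pytest.approx(
                        (n1 - n2) / total
                    )
                assert abs(consistency_score(n1, n2, n_sig)) <= 1
                if n1 == 0 or n2 == 0:  # unanimity attains the bounds exactly
                    assert abs(consistency_score(n1, n2, n_sig)) == 1.0

    def test_zero_denominator_undefined(self):
        with pytest.raises(ValidationError):
            consistency_score(0, 0, 0)


class TestWeightedConsistencyScore:
    def test_examples(self):
        assert weighted_consistency_score([2, 1, -1]) == pytest.approx(0.5)
        assert weighted_consistency_score([0.3, 1.7, 2.2]) == 1.0
        assert weighted_consistency_score([1.3, -1.3]) == 0.0

    def test_unanimous_down_is_minus_one(self):
        assert weighted_consistency_score([-0.5, -3.0]) == -1.0

    @given(
        st.lists(
            st.floats(-10, 10).filter(lambda v: abs(v) > 1e-6),
            min_size=1,
            max_size=12,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_always_within_unit_interval(self, fcs):
        assert -1 <= weighted_consistency_score(fcs) <= 1

    def test_empty_list_undefined(self):
        with pytest.raises(ValidationError):
            weighted_consistency_score([])


class TestConsistencyTable:
    def test_unanimous_and_mixed_patterns(self):
        results = [
            make_result(f"P{i}:case_vs_control", {
                "up_all": (1.0, 0.01, True),
                "mixed": ((1.2 if i < 4 else -0.8), (0.01 if i != 5 else 0.5), i != 5),
                "never": (0.3, 0.9, False),
            }) for i in range(1, 6)
        ]
        records = {r.feature: r for r in consistency_table(results)}
        assert records["up_all"].cs == 1.0
        assert records["up_all"].wcs == 1.0
        # mixed: significant up in P1-P3 (3), down in P4 (1), not significant in P5
        assert records["mixed"].n1 == 3 and records["mixed"].n2 == 1
        assert records["mixed"].cs == pytest.approx(2 / 4)
        assert records["mixed"].n_total == 5
        assert "never" not in records

    def test_total_denominator_convention(self):
        results = [
            make_result(f"P{i}:c_vs_c", {"t": (1.0, 0.01, i < 3)}) for i in range(1, 6)
        ]
        sig = {r.feature: r for r in consistency_table(results, "significant")}
        tot = {r.feature: r for r in consistency_table(results, "total")}
        assert sig["t"].cs == 1.0
        assert tot["t"].cs == pytest.approx(2 / 5)

    def test_missing_feature_reduces_n_total(self):
        results = [
            make_result("P1:c", {"t": (1.0, 0.01, True)}),
            make_result("P2:c", {"other": (1.0, 0.01, True)}),
        ]
        rec = {r.feature: r for r in consistency_table(results)}["t"]
        assert rec.n_total == 1

    def test_deterministic_ordering(self):
        results = [
            make_result("P1:c", {
                "b": (1.0, 0.01, True), "a": (1.0, 0.01, True), "c": (-0.2, 0.01, True),
            }),
            make_result("P2:c", {
                "b": (1.0, 0.01, True), "a": (1.0, 0.01, True), "c": (0.2, 0.01, True),
            }),
        ]
        feats = [r.feature for r in consistency_table(results)]
        assert feats == ["a", "b", "c"]  # |CS| desc, then |WCS| desc, then name

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValidationError):
            consistency_table([])


class TestSelectConsistent:
    def _rec(self, n1, n2, cs=None, n_total=None):
        n_sig = n1 + n2
        cs = cs if cs is not None else (n1 - n2) / n_sig
        return ConsistencyRecord("t", n1, n2, n_total or n_sig, cs, cs)

    def test_boundary_rules(self):
        kept = self._rec(3, 0, cs=0.61)
        too_few = self._rec(2, 0, cs=1.0)
        at_threshold = self._rec(5, 0, cs=0.6)
        out = select_consistent([kept, too_few, at_threshold])
        assert out == [kept]

    def test_negative_cs_selected_by_magnitude(self):
        rec = self._rec(0, 4, cs=-1.0)
        assert select_consistent([rec]) == [rec]


class TestEndToEndRecovery:
    def _run(self, seed, n_projects=5, pattern=None, log2fc=1.5):
        effects = pattern or consistent_effects(
            ["Taxon_04"], [], n_projects, log2fc
        )
        spec = SimulationSpec(
            n_projects=n_projects,
            n_taxa=40,
            samples_per_group=18,
            planted_effects=effects,
            seed=seed,
        )
        datasets, _ = simulate_multiproject(spec)
        results = []
        for table, meta in datasets:
            norm = default_pipeline(table)
            design = enumerate_comparisons(meta, "case", "control")[0]
            results.append(compare_features(norm, design, meta))
        return results

    def test_taxon_planted_up_everywhere_scores_one(self):
        results = self._run(seed=1)
        rec = {r.feature: r for r in consistency_table(results)}["Taxon_04"]
        assert rec.cs == 1.0
        assert rec.wcs == 1.0

    def test_mixed_pattern_gives_intermediate_cs(self):
        # planted up in 3 projects, down in 1, absent in 1
        pattern = [PlantedEffect("Taxon_04", (1, 1, 1, -1, 0), 2.0)]
        results = self._run(seed=2, pattern=pattern, log2fc=2.0)
        rec = {r.feature: r for r in consistency_table(results)}["Taxon_04"]
        # with all four planted effects called correctly: CS = (3-1)/4
        assert rec.n1 >= 3 and rec.n2 >= 1
        assert rec.cs == pytest.approx((rec.n1 - rec.n2) / (rec.n1 + rec.n2))
        assert 0 < rec.cs < 1


class TestFBRatioCrossProject:
    def test_log2_p_arithmetic(self):
        assert np.log2(0.05) == pytest.approx(-4.32, abs=0.01)

    def _phylum_setup(self, fb_shift, seed=0):
        spec = SimulationSpec(
            n_projects=2, n_taxa=30, samples_per_group=15,
            planted_effects=fb_shift, seed=seed,
        )
        datasets, _ = simulate_multiproject(spec)
        tax = taxonomy_for(spec)
        designs, metas, tables = [], {}, {}
        for table, meta in datasets:
            d = enumerate_comparisons(meta, "case", "control")[0]
            designs.append(d)
            metas[d.comparison_id] = meta
            phylum = collapse_to_rank(table, tax, "phylum")
            tables[d.comparison_id] = default_pipeline(phylum)
        return tables, designs, metas, tax

    def test_planted_firmicutes_shift_raises_fold_change(self):
        # push every Firmicutes taxon up to raise the F/B ratio in cases
        probe = SimulationSpec(n_projects=2, n_taxa=30, samples_per_group=15, seed=0)
        tax = taxonomy_for(probe)
        firmicutes = [
            t for t in probe.taxon_names() if tax.level(t, "phylum") == "Firmicutes"
        ]
        effects = consistent_effects(firmicutes, [], 2, log2fc=1.0)
        tables, designs, metas, _ = self._phylum_setup(effects)
        out = fb_ratio_cross_project(tables, designs, metas)
        assert len(out) == 2
        assert (out["fold_change"] > 1.3).all()
        assert (out["p"] < 0.05).all()

    def test_null_fold_change_near_one(self):
        tables, designs, metas, _ = self._phylum_setup([], seed=3)
        out = fb_ratio_cross_project(tables, designs, metas)
        assert np.allclose(out["fold_change"], 1.0, atol=0.35)


class TestPathwayConsistency:
    def test_masking_and_ordering(self):
        results = [
            make_result(f"P{i}:c", {
                "pw_down": (-1.5, 0.001, True, 3.2),
                "pw_at_threshold": (1.0, 0.001, True, 2.0),
                "pw_weak_p": (1.0, 0.2, True, 3.0),
                "pw_partial": (1.0, 0.001, True, 2.5 if i < 3 else np.nan),
            }) for i in range(1, 5)
        ]
        mat = pathway_consistency(results)
        assert mat.loc["pw_down"].notna().sum() == 4
        assert (mat.loc["pw_down"].dropna() < 0).all()
        assert "pw_at_threshold" not in mat.index  # strict > 2
        assert "pw_weak_p" not in mat.index  # needs p < 0.05 too
        assert mat.index.tolist() == ["pw_down", "pw_partial"]

    def test_no_passing_pathway_gives_empty_matrix(self):
        results = [make_result("P1:c", {"pw": (1.0, 0.001, True, 1.0)})]
        assert pathway_consistency(results).empty


class TestStratifiedConsistency:
    def _results(self, stratum, sign, n=3, significant=True):
        return [
            make_result(
                f"{stratum}P{i}:c", {"t": (sign * 1.5, 0.01, significant)},
                phenotype=stratum,
            )
            for i in range(n)
        ]

    def test_concordant_down_in_both_strata(self):
        by_stratum = {
            "obesity": self._results("ob", -1),
            "NAFLD": self._results("na", -1),
        }
        out = stratified_consistency(by_stratum)
        assert out.loc["t", "CS_obesity"] <= -0.6
        assert out.loc["t", "CS_NAFLD"] <= -0.6
        assert bool(out.loc["t", "concordant"])

    def test_selected_in_one_stratum_only(self):
        by_stratum = {
            "A": self._results("a", 1),
            "B": self._results("b", 1, significant=False),
        }
        out = stratified_consistency(by_stratum)
        assert bool(out.loc["t", "selected_A"])
        assert not bool(out.loc["t", "selected_B"])

    def test_single_stratum_rejected(self):
        with pytest.raises(ValidationError):
            stratified_consistency({"only": self._results("o", 1)})


def test_sankey_edge_bookkeeping():
    tax = TaxonomyMap(
        {
            "g1": Lineage(("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                           "Lactobacillaceae", "g1", "")),
            "g2": Lineage(("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                           "Streptococcaceae", "g2", "")),
        }
    )
    recs = [
        ConsistencyRecord("g1", 3, 0, 3, 1.0, 1.0),
        ConsistencyRecord("g2", 3, 0, 3, 1.0, 1.0),
    ]
    edges = sankey_edges(recs, tax, to_rank="genus")
    kp = edges[edges["level"] == "kingdom->phylum"]
    assert kp["weight"].tolist() == [2]
    fam = edges[edges["level"] == "family->genus"]
    assert len(fam) == 2 and (fam["weight"] == 1).all()


def test_records_frame_columns():
    recs = [ConsistencyRecord("t", 2, 1, 4, 1 / 3, 0.2)]
    frame = records_frame(recs)
    assert frame.loc["t", "n_sig"] == 3
    assert frame.loc["t", "n_total"] == 4
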