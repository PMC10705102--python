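"""Tests of AF-matrix construction, clustering, relatedness and selection."""

import numpy as np
import pandas as pd
import pytest

from clonmet.clonality import test_lnm_af_enrichment as lnm_af_enrichment_test
from clonmet.clonality import (
    AlleleFractionMatrix,
    build_af_matrix,
    classify_clonal_relatedness,
    cluster_samples_by_af,
    common_ancestor_fraction,
    relatedness_to_frame,
)
from conftest import fisher_oracle, variant_frame


def raw_counts(rows):
    return variant_frame(rows)


class TestBuildAfMatrix:
    def test_backfill_zero_alt_is_zero_not_missing(self):
        filtered = variant_frame([("A", "chr1", 100, "A", "T", 60, 40)])
        raw = raw_counts(
            [
                ("A", "chr1", 100, "A", "T", 60, 40),
                ("B", "chr1", 100, "A", "T", 100, 0),
            ]
        )
        mat = build_af_matrix(filtered, raw)
        assert mat.af.loc["chr1:100:A:T", "B"] == 0.0
        assert mat.af.loc["chr1:100:A:T", "A"] == pytest.approx(0.4)

    def test_low_depth_entry_is_missing(self):
        filtered = variant_frame([("A", "chr1", 100, "A", "T", 60, 40)])
        raw = raw_counts(
            [
                ("A", "chr1", 100, "A", "T", 60, 40),
                ("B", "chr1", 100, "A", "T", 15, 5),  # depth 20 < 40
            ]
        )
        mat = build_af_matrix(filtered, raw)
        assert np.isnan(mat.af.loc["chr1:100:A:T", "B"])
        assert mat.depth.loc["chr1:100:A:T", "B"] == 20

    def test_values_bounded_and_rows_are_union(self):
        filtered = variant_frame(
            [
                ("A", "chr1", 100, "A", "T", 60, 40),
                ("B", "chr1", 200, "G", "C", 50, 50),
            ]
        )
        raw = raw_counts(
            [
                ("A", "chr1", 100, "A", "T", 60, 40),
                ("A", "chr1", 200, "G", "C", 90, 10),
                ("B", "chr1", 100, "A", "T", 80, 20),
                ("B", "chr1", 200, "G", "C", 50, 50),
            ]
        )
        mat = build_af_matrix(filtered, raw)
        assert sorted(mat.variants) == ["chr1:100:A:T", "chr1:200:G:C"]
        assert ((mat.af >= 0) & (mat.af <= 1)).all().all()

    def test_empty_filtered_rejected(self):
        with pytest.raises(ValueError, match="no significant"):
            build_af_matrix(variant_frame([]), variant_frame([]))

    def test_truncal_variants_visible_in_all_related_samples(self, small_config):
        from clonmet.simulate import simulate_patient
        from clonmet.somatic_filter import FilterParams, call_somatic_significant

        tree, samples, variants, truth = simulate_patient("P1", small_config)
        site = {s.sample_id: s.site_label for s in samples}
        tumor = variants[variants["sample_id"].map(site) != "BLN"]
        normal = variants[variants["sample_id"].map(site) == "BLN"]
        filt = call_somatic_significant(tumor, normal, FilterParams())
        mat = build_af_matrix(filt, tumor)
        truncal_muts = tree.branch_mutations[tree.tumor_clones[0]]
        key_by_mut = variants.drop_duplicates("mutation").set_index("mutation")
        for m in sorted(truncal_muts)[:10]:
            row = key_by_mut.loc[m]
            key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
            vals = mat.af.loc[key].dropna()
            assert (vals > 0).all()


class TestClustering:
    def make_matrix(self, data, samples):
        af = pd.DataFrame(data, columns=samples)
        af.index = [f"v{i}" for i in range(len(af))]
        depth = af.notna() * 100.0
        return AlleleFractionMatrix(af=af, depth=depth)

    def test_identical_columns_merge_at_zero(self):
        mat = self.make_matrix(
            {"A": [0.4, 0.2, 0.1], "B": [0.4, 0.2, 0.1], "C": [0.0, 0.0, 0.45]},
            ["A", "B", "C"],
        )
        res = cluster_samples_by_af(mat)
        assert res.distances.loc["A", "B"] == 0.0
        assert res.linkage[0, 2] == 0.0  # first merge at distance zero

    def test_column_order_invariance(self):
        data = {"A": [0.4, 0.2, 0.1], "B": [0.39, 0.22, 0.1], "C": [0.0, 0.0, 0.45]}
        m1 = self.make_matrix(data, ["A", "B", "C"])
        m2 = self.make_matrix(data, ["C", "A", "B"])
        r1 = cluster_samples_by_af(m1)
        r2 = cluster_samples_by_af(m2)
        assert r1.leaf_order == r2.leaf_order
        pd.testing.assert_frame_equal(r1.distances, r2.distances)

    def test_disjoint_sample_is_singleton_outlier(self, caplog):
        # sample C shares no observed variants with A or B
        af = pd.DataFrame(
            {
                "A": [0.4, 0.3, np.nan, np.nan],
                "B": [0.41, 0.28, np.nan, np.nan],
                "C": [np.nan, np.nan, 0.2, 0.5],
            },
            index=[f"v{i}" for i in range(4)],
        )
        mat = AlleleFractionMatrix(af=af, depth=af.notna() * 100.0)
        with caplog.at_level("WARNING"):
            res = cluster_samples_by_af(mat)
        assert "singleton" in caplog.text
        assert res.leaf_order[0] == "C" or res.leaf_order[-1] == "C"

    def test_independent_focus_merges_last_on_simulated_patients(self):
        """A clonally independent focus should be the leaf joined in the
        final linkage step for nearly all simulated patients."""
        from clonmet.simulate import SimulationConfig, simulate_patient
        from clonmet.somatic_filter import FilterParams, call_somatic_significant

        hits = trials = 0
        for seed in range(400):
            cfg = SimulationConfig(
                seed=seed,
                n_patients=1,
                n_primary_foci=3,
                n_lnm=1,
                fraction_independent_foci=0.35,
            )
            _, samples, variants, _ = simulate_patient("P1", cfg)
            independent = [
                s.sample_id for s in samples if s.truth_relatedness == "independent"
            ]
            if len(independent) != 1:
                continue
            trials += 1
            site = {s.sample_id: s.site_label for s in samples}
            tumor = variants[variants["sample_id"].map(site) != "BLN"]
            normal = variants[variants["sample_id"].map(site) == "BLN"]
            filt = call_somatic_significant(tumor, normal, FilterParams())
            mat = build_af_matrix(filt, tumor)
            res = cluster_samples_by_af(mat)
            # the final merge should join the independent focus as a singleton
            n = len(res.sample_ids)
            left, right = int(res.linkage[-1, 0]), int(res.linkage[-1, 1])
            singletons = [i for i in (left, right) if i < n]
            if any(res.sample_ids[i] == independent[0] for i in singletons):
                hits += 1
            if trials >= 100:
                break
        assert trials >= 50
        assert hits / trials >= 0.95


class TestRelatedness:
    def make_presence_matrix(self, cols):
        af = pd.DataFrame(cols)
        af.index = [f"v{i}" for i in range(len(af))]
        return AlleleFractionMatrix(af=af, depth=af.notna() * 100.0)

    def test_identical_focus_is_metastatic_clone(self):
        v = [0.4] * 10
        mat = self.make_presence_matrix({"P1_PTF1": v, "P1_LNM1": v})
        calls = classify_clonal_relatedness(
            mat, {"P1_PTF1": "PTF", "P1_LNM1": "LNM"}
        )
        by_id = {c.sample_id: c for c in calls}
        assert by_id["P1_PTF1"].call == "metastatic-clone"
        assert by_id["P1_PTF1"].jaccard["P1_LNM1"] == 1.0
        assert by_id["P1_LNM1"].call == "metastatic-clone"

    def test_disjoint_focus_is_independent(self):
        a = [0.4] * 5 + [0.0] * 5
        b = [0.0] * 5 + [0.4] * 5
        mat = self.make_presence_matrix({"P1_PTF1": a, "P1_LNM1": b})
        calls = classify_clonal_relatedness(mat, {"P1_PTF1": "PTF", "P1_LNM1": "LNM"})
        by_id = {c.sample_id: c for c in calls}
        assert by_id["P1_PTF1"].call == "independent"

    def test_no_lnm_means_non_metastatic_by_convention(self):
        v = [0.4] * 10
        mat = self.make_presence_matrix({"P1_PTF1": v, "P1_PTF2": v})
        calls = classify_clonal_relatedness(
            mat, {"P1_PTF1": "PTF", "P1_PTF2": "PTF"}
        )
        assert all(c.call == "non-metastatic-clone" for c in calls)

    def test_order_invariance_of_calls(self):
        rng = np.random.default_rng(3)
        af = pd.DataFrame(
            rng.uniform(0, 0.5, size=(20, 4)),
            columns=["P1_PTF1", "P1_PTF2", "P1_LNM1", "P1_LNM2"],
            index=[f"v{i}" for i in range(20)],
        )
        labels = {c: ("LNM" if "LNM" in c else "PTF") for c in af.columns}
        m1 = AlleleFractionMatrix(af=af, depth=af.notna() * 100.0)
        shuffled = af.iloc[::-1, ::-1]
        m2 = AlleleFractionMatrix(af=shuffled, depth=shuffled.notna() * 100.0)
        c1 = relatedness_to_frame(classify_clonal_relatedness(m1, labels))
        c2 = relatedness_to_frame(classify_clonal_relatedness(m2, labels))
        pd.testing.assert_frame_equal(c1, c2)

    def test_empty_tumor_set_warns(self, caplog):
        mat = self.make_presence_matrix({"P1_BLN": [0.0] * 3})
        with caplog.at_level("WARNING"):
            assert classify_clonal_relatedness(mat, {"P1_BLN": "BLN"}) == []


class TestCommonAncestorFraction:
    def _calls(self, n_related, n_independent, patient="P1"):
        from clonmet.clonality import RelatednessCall

        calls = [
            RelatednessCall(f"{patient}_PTF{i}", "metastatic-clone", 0)
            for i in range(n_related)
        ]
        calls += [
            RelatednessCall(f"{patient}_PTF{n_related + i}", "independent", 0)
            for i in range(n_independent)
        ]
        return calls

    def test_thirteen_of_hundred_gives_87_percent(self):
        calls = self._calls(87, 13)
        labels = {c.sample_id: "PTF" for c in calls}
        frac, (lo, hi), per_patient = common_ancestor_fraction({"P1": calls}, labels)
        assert frac == pytest.approx(0.87)
        assert lo < 0.87 < hi

    def test_all_related_gives_one(self):
        calls = self._calls(5, 0)
        labels = {c.sample_id: "PTF" for c in calls}
        frac, _, _ = common_ancestor_fraction({"P1": calls}, labels)
        assert frac == 1.0

    def test_no_foci_rejected(self):
        with pytest.raises(ValueError):
            common_ancestor_fraction({"P1": []}, {})


class TestLnmAfEnrichment:
    def test_identical_pooled_counts_give_p_one(self):
        raw = variant_frame(
            [
                ("P1_LNM1", "chr1", 100, "A", "T", 60, 40),
                ("P1_PTF1", "chr1", 100, "A", "T", 60, 40),
            ]
        )
        labels = {"P1_LNM1": "LNM", "P1_PTF1": "PTF"}
        res = lnm_af_enrichment_test(raw, labels)
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "status"] == "none"

    def test_enriched_variant_matches_oracle(self):
        raw = variant_frame(
            [
                ("P1_LNM1", "chr1", 100, "A", "T", 60, 40),
                ("P1_PTF1", "chr1", 100, "A", "T", 295, 5),
            ]
        )
        labels = {"P1_LNM1": "LNM", "P1_PTF1": "PTF"}
        res = lnm_af_enrichment_test(raw, labels)
        assert res.loc[0, "p"] == pytest.approx(fisher_oracle(40, 60, 5, 295), abs=1e-12)
        assert res.loc[0, "status"] == "enriched"
        assert res.loc[0, "af_delta"] > 0

    def test_depleted_never_reported_enriched(self):
        raw = variant_frame(
            [
                ("P1_LNM1", "chr1", 100, "A", "T", 295, 5),
                ("P1_PTF1", "chr1", 100, "A", "T", 60, 40),
            ]
        )
        labels = {"P1_LNM1": "LNM", "P1_PTF1": "PTF"}
        res = lnm_af_enrichment_test(raw, labels)
        assert res.loc[0, "status"] == "depleted"

    def test_pooling_sums_counts_across_samples(self):
        raw = variant_frame(
            [
                ("P1_LNM1", "chr1", 100, "A", "T", 30, 20),
                ("P1_LNM2", "chr1", 100, "A", "T", 30, 20),
                ("P1_PTF1", "chr1", 100, "A", "T", 145, 5),
                ("P1_PTF2", "chr1", 100, "A", "T", 150, 0),
            ]
        )
        labels = {s: ("LNM" if "LNM" in s else "PTF") for s in raw["sample_id"]}
        res = lnm_af_enrichment_test(raw, labels)
        assert res.loc[0, "lnm_alt"] == 40 and res.loc[0, "lnm_ref"] == 60
        assert res.loc[0, "primary_alt"] == 5 and res.loc[0, "primary_ref"] == 295

    def test_missing_class_rejected(self):
        raw = variant_frame([("P1_PTF1", "chr1", 100, "A", "T", 60, 40)])
        with pytest.raises(ValueError, match="LNM"):
            lnm_af_enrichment_test(raw, {"P1_PTF1": "PTF"})
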