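"""Response-type taxonomy, annotation-guided clustering, permutation test."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ecmsom.errors import AnnotationError
from ecmsom.response_types import (
    RESPONSE_TYPE_ORDER,
    SUSTAINED_TYPE_ID,
    TRANSITIONS,
    build_hierarchy,
    classify_profiles,
    classify_response,
    cluster_genes,
    count_types,
    permutation_test,
    response_type_id,
)
from ecmsom.synthetic import GeneTemplate, SimDesign, simulate_counts

_FLIP = {"U": "D", "D": "U", "S": "S"}


class TestCanonicalOrder:
    def test_bijection_over_all_27_triples(self):
        ids = {response_type_id(t) for t in product("UDS", repeat=3)}
        assert len(ids) == 27
        assert len(RESPONSE_TYPE_ORDER) == 27

    def test_all_sustained_is_last(self):
        assert RESPONSE_TYPE_ORDER[-1] == ("S", "S", "S")
        assert response_type_id(("S", "S", "S")) == SUSTAINED_TYPE_ID

    def test_complementary_pairs_adjacent_with_up_first(self):
        changing = RESPONSE_TYPE_ORDER[:-1]
        for i in range(0, len(changing), 2):
            first, second = changing[i], changing[i + 1]
            assert tuple(_FLIP[s] for s in first) == second
            first_change = next(s for s in first if s != "S")
            assert first_change == "U"

    def test_sorted_by_earliest_transition_of_change(self):
        def first_change(t):
            return next(i for i, s in enumerate(t) if s != "S")

        idx = [first_change(t) for t in RESPONSE_TYPE_ORDER[:-1]]
        assert idx == sorted(idx)


class TestHierarchy:
    def test_two_leaves_make_four_nodes(self):
        table = pd.DataFrame({"gene_id": ["g1", "g2"],
                              "category_path": ["A/B", "A/C"]})
        h = build_hierarchy(table)
        assert h.nodes == {"", "A", "A/B", "A/C"}

    def test_partition_from_top_level_prefix(self):
        table = pd.DataFrame({
            "gene_id": ["g1", "g2"],
            "category_path": ["SOM/CAZyme/GH28", "MET/Carbohydrate/TCA"]})
        h = build_hierarchy(table)
        assert h.partition["g1"] == "SOM-interaction"
        assert h.partition["g2"] == "metabolism"

    def test_empty_table_gives_root_only(self):
        h = build_hierarchy(pd.DataFrame(columns=["gene_id", "category_path"]))
        assert h.nodes == {""}
        assert not h.gene_to_node

    def test_conflicting_paths_name_the_gene(self):
        table = pd.DataFrame({"gene_id": ["g1", "g1"],
                              "category_path": ["A/B", "A/C"]})
        with pytest.raises(AnnotationError, match="g1"):
            build_hierarchy(table)


class TestClusterGenes:
    def _hier(self, genes, path="SOM/CAZyme/GH5"):
        return build_hierarchy(pd.DataFrame(
            {"gene_id": genes, "category_path": [path] * len(genes)}))

    def test_identical_profiles_share_one_cluster(self):
        profiles = pd.DataFrame([[0, 1, 2, 3], [0, 1, 2, 3]],
                                index=["g1", "g2"], dtype=float)
        cl = cluster_genes(profiles, self._hier(["g1", "g2"]))
        assert cl["cluster_id"].nunique() == 1

    def test_anticorrelated_profiles_split(self):
        profiles = pd.DataFrame([[0, 1, 2, 3], [3, 2, 1, 0]],
                                index=["g1", "g2"], dtype=float)
        cl = cluster_genes(profiles, self._hier(["g1", "g2"]))
        assert cl["cluster_id"].nunique() == 2

    def test_five_profile_groups_recovered(self):
        """Five low-correlation profile shapes with replicate-level noise
        are recovered at adjusted Rand index > 0.8."""
        shapes = np.array([[0, 2, 2, 2], [2, 0, 0, 0], [0, 0, 2, 0],
                           [2, 2, 0, 2], [0, 0, 0, 2]], float)
        rng = np.random.default_rng(1)
        genes, profs, labels = [], [], []
        for gidx, shape in enumerate(shapes):
            for i in range(12):
                genes.append(f"c{gidx}_{i}")
                profs.append(shape + rng.normal(0, 0.15, 4))
                labels.append(gidx)
        profiles = pd.DataFrame(profs, index=genes)
        cl = cluster_genes(profiles, self._hier(genes))
        ari = adjusted_rand_score(labels, pd.factorize(cl["cluster_id"])[0])
        assert ari > 0.8

    def test_unannotated_gene_rejected(self):
        profiles = pd.DataFrame([[0, 1, 2, 3]], index=["mystery"], dtype=float)
        with pytest.raises(AnnotationError):
            cluster_genes(profiles, self._hier(["g1"]))


class TestClassify:
    def test_single_gene_wrapper(self):
        states, rid = classify_response(
            {"ND": 2.0, "CD": -2.0, "pCD": 0.0},
            {"ND": 1e-5, "CD": 1e-5, "pCD": 0.5})
        assert states == ("U", "D", "S")
        assert rid == response_type_id(("U", "D", "S"))

    def test_gene_order_permutation_equivariance(self, cohort_pairwise):
        prof = classify_profiles(cohort_pairwise)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(prof))
        shuffled = {t: f.iloc[perm] for t, f in cohort_pairwise.items()}
        prof2 = classify_profiles(shuffled)
        pd.testing.assert_frame_equal(prof.iloc[perm], prof2)

    def test_transient_nd_upregulation_recovered(self, cohort, cohort_pairwise):
        """Genes seeded with the 'specifically upregulated during ND'
        archetype (up at ND, back down at CD) land in the (U,D,S) type."""
        truth = cohort["truth"]
        prof = classify_profiles(cohort_pairwise)
        uds = truth.index[truth["pattern"] == "UDS"]
        expected = response_type_id(("U", "D", "S"))
        frac = (prof.loc[uds, "response_type"] == expected).mean()
        assert frac >= 0.95

    def test_sustained_triple_never_counts_as_changing(self):
        prof = pd.DataFrame({
            "ND": ["S"], "CD": ["S"], "pCD": ["S"],
            "response_type": [SUSTAINED_TYPE_ID], "changing": [False]})
        counts, n = count_types(prof)
        assert n == 0 and counts.sum() == 0


class TestCountTypes:
    def test_homogeneous_input_is_one_type(self):
        prof = pd.DataFrame({
            "ND": ["U"] * 10, "CD": ["S"] * 10, "pCD": ["S"] * 10,
            "response_type": [response_type_id(("U", "S", "S"))] * 10,
            "changing": [True] * 10})
        counts, n = count_types(prof)
        assert n == 1
        assert counts.iloc[0] == 10

    def test_counts_partition_changing_genes(self, cohort_pairwise):
        prof = classify_profiles(cohort_pairwise)
        counts, _ = count_types(prof)
        assert counts.sum() == int(prof["changing"].sum())


class TestEndToEndRecovery:
    def test_response_types_recovered_for_95_percent_of_genes(
            self, cohort, cohort_pairwise):
        """At the default effect size (log2FC = 2) and n = 3, the
        classified triple matches the seeded template for >= 95% of
        changing genes, and exactly the 15 seeded types are observed
        among time-DEGs."""
        truth = cohort["truth"]
        prof = classify_profiles(cohort_pairwise)
        pred = prof["ND"] + prof["CD"] + prof["pCD"]
        changing = truth["pattern"] != "SSS"
        agree = (pred[changing] == truth.loc[changing, "pattern"]).mean()
        assert agree >= 0.95

    def test_fifteen_distinct_types_observed(self, cohort, cohort_pairwise,
                                             cohort_time_course):
        prof = classify_profiles(cohort_pairwise)
        degs = cohort_time_course.index[cohort_time_course["time_deg"]]
        _, n_types = count_types(prof.loc[degs])
        assert n_types == 15


class TestPermutationTest:
    def test_b_below_19_rejected(self, cohort, cohort_hierarchy):
        with pytest.raises(ValueError):
            permutation_test(cohort["counts"], cohort["meta"],
                             cohort_hierarchy, B=10)

    def test_strong_enrichment_reaches_p_floor(self, cohort, cohort_hierarchy):
        """A type whose observed SOM count exceeds every null draw gets
        the smallest attainable p, 1/(B+1)."""
        res = permutation_test(cohort["counts"], cohort["meta"],
                               cohort_hierarchy, B=999, seed=0)
        tab = res.table[res.table["observed_nonzero"]]
        assert tab["p_emp"].min() == pytest.approx(1.0 / 1000.0)
        assert (tab["p_emp"] >= 1.0 / 1000.0).all()

    def test_seeded_enrichment_is_significant(self, cohort_hierarchy):
        """40 SOM-interaction genes seeded into one response type against
        a null background are detected at p <= 0.01."""
        tpl = [GeneTemplate(gene_id=f"s{i:03d}", pattern=("U", "S", "S"),
                            lfc_magnitude=2.0, base_mean=400.0, dispersion=0.02,
                            category_path="SOM/CAZyme/GH5")
               for i in range(40)]
        tpl += [GeneTemplate(gene_id=f"n{i:03d}", pattern=("S", "S", "S"),
                             base_mean=400.0, dispersion=0.02,
                             category_path="MET/Path/P1" if i % 2 else
                             "SOM/Oxidoreductase/AA1")
                for i in range(400)]
        annot = pd.DataFrame({"gene_id": [t.gene_id for t in tpl],
                              "category_path": [t.category_path for t in tpl]})
        hier = build_hierarchy(annot)
        counts, meta = simulate_counts(SimDesign(seed=4), tpl)
        res = permutation_test(counts, meta, hier, B=999, seed=1)
        rid = response_type_id(("U", "S", "S"))
        assert res.table.loc[rid, "observed"] == 40
        assert res.table.loc[rid, "p_emp"] <= 0.01
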