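import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import epimutkit as ek
from epimutkit.association import fisher_test, _pearson_chi2

from conftest import GENS


def _annotation(n_genes=4, elements_per_gene=1):
    rows = []
    pos = 0
    for i in range(n_genes):
        g = f"g{i}"
        rows.append(("I", pos, pos + 100, g, "gene", g, "Active"))
        pos += 200
        for j in range(elements_per_gene):
            rows.append(("I", pos, pos + 50, f"{g}_e{j}", "regulatory_element", g, "Active"))
            pos += 100
    return ek.AnnotationTable(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "locus_id",
                                    "locus_class", "gene_id", "domain"])
    )


def _runs_from_vec(locus, vec, lineage="A", assay="expression"):
    return ek.detect_runs(vec, GENS, locus, lineage, assay)


class TestFisher:
    def test_balanced_table_is_null(self):
        res = fisher_test([[10, 10], [10, 10]])
        assert res.odds_ratio == 1.0
        assert res.p == pytest.approx(1.0)

    def test_perfect_separation_enumeration(self):
        # margins (5,5,5,5): only a=0 and a=5 are as extreme; p = 2/C(10,5)
        res = fisher_test([[5, 0], [0, 5]])
        assert np.isinf(res.odds_ratio)
        assert res.p == pytest.approx(2 / 252)

    def test_two_sided_p_equals_hypergeometric_enumeration(self):
        # exhaustive check against the hypergeometric definition of the
        # two-sided Fisher p over a sweep of small-margin tables
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            table = np.array([[a, b], [c, d]])
            n, r1, c1 = table.sum(), a + b, a + c
            support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
            pmf = hypergeom.pmf(support, n, r1, c1)
            p_oracle = pmf[pmf <= pmf[support == a][0] * (1 + 1e-9)].sum()
            assert fisher_test(table).p == pytest.approx(min(1.0, p_oracle), rel=1e-9)


class TestGeneRecords:
    def test_ugt26_style_overlap(self):
        ann = _annotation(n_genes=2)
        expr = _runs_from_vec("g0", [0, 1, 0, 1, 1, 1, 1, 1, 1, 1])
        partner = _runs_from_vec("g0_e0", [0, 0, 0, 1, 1, 0, 0, 0, 1, 0],
                                 assay="atac")
        rec = ek.build_gene_records(expr, partner, ann).set_index("gene_id")
        r = rec.loc["g0"]
        assert r["expr_inherited"] and r["partner_inherited"]
        assert r["simultaneous"] and bool(r["concordant"]) is True
        assert not rec.loc["g1", "has_expr_change"]

    def test_simultaneous_but_discordant(self):
        ann = _annotation(n_genes=1)
        expr = _runs_from_vec("g0", [0, 0, 0, 1, 1, 1, 1, 1, 1, 1])
        partner = _runs_from_vec("g0_e0", [0, 0, 0, -1, -1, 0, 0, 0, 0, 0],
                                 assay="atac")
        rec = ek.build_gene_records(expr, partner, ann).iloc[0]
        assert rec["simultaneous"] and bool(rec["concordant"]) is False

    def test_non_overlapping_runs_not_simultaneous(self):
        ann = _annotation(n_genes=1)
        expr = _runs_from_vec("g0", [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        partner = _runs_from_vec("g0_e0", [0, 0, 0, 0, 0, 0, 1, 1, 0, 0],
                                 assay="atac")
        rec = ek.build_gene_records(expr, partner, ann).iloc[0]
        assert not rec["simultaneous"]
        assert rec["concordant"] is pd.NA

    def test_order_independence(self):
        ann = _annotation(n_genes=3)
        expr = (_runs_from_vec("g0", [0, 1, 1, 0, 0, 0, 0, 0, 0, 0])
                + _runs_from_vec("g2", [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]))
        partner = _runs_from_vec("g0_e0", [0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                                 assay="atac")
        rec1 = ek.build_gene_records(expr, partner, ann)
        rec2 = ek.build_gene_records(list(reversed(expr)), partner, ann)
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_unmapped_partner_locus_rejected(self):
        ann = _annotation(n_genes=1)
        partner = _runs_from_vec("mystery", [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                                 assay="atac")
        with pytest.raises(ValueError, match="no gene mapping"):
            ek.build_gene_records([], partner, ann)


def _records(n, rng, partner_doubles_inheritance=False):
    rows = []
    for i in range(n):
        has_partner = rng.random() < 0.3
        has_expr = rng.random() < 0.4
        p_inh = 0.2
        if partner_doubles_inheritance and has_partner:
            p_inh = 0.4
        inh = has_expr and rng.random() < p_inh
        simultaneous = has_expr and has_partner and rng.random() < 0.5
        rows.append(
            dict(gene_id=f"g{i}", lineage_id="A", has_expr_change=has_expr,
                 expr_inherited=inh, has_partner_epimutation=has_partner,
                 partner_inherited=has_partner and rng.random() < 0.5,
                 simultaneous=simultaneous,
                 concordant=(rng.random() < 0.5) if simultaneous else pd.NA)
        )
    return pd.DataFrame(rows)


class TestStepwiseFisher:
    def test_backgrounds_are_nested(self):
        rng = np.random.default_rng(0)
        records = _records(500, rng)
        res = ek.stepwise_fisher(records)
        n3 = res[2].table.sum()
        n4 = res[3].table.sum()
        assert n4 <= n3 <= res[0].table.sum()
        a3, a4 = res[2].table[0, 0], res[3].table[0, 0]
        assert a4 <= a3

    def test_independent_channels_or_near_one(self):
        rng = np.random.default_rng(1)
        records = _records(4000, rng)
        res = ek.stepwise_fisher(records)
        assert res[0].p > 0.001  # no spurious association
        assert 0.7 < res[0].odds_ratio < 1.4

    def test_partner_conditional_inheritance_detected(self):
        rng = np.random.default_rng(2)
        records = _records(2000, rng, partner_doubles_inheritance=True)
        res = ek.stepwise_fisher(records)
        test2 = res[1]
        assert test2.odds_ratio > 1
        assert test2.p < 0.05

    def test_element_gene_restriction(self):
        rng = np.random.default_rng(3)
        records = _records(100, rng)
        subset = {f"g{i}" for i in range(50)}
        res = ek.stepwise_fisher(records, element_genes=subset)
        assert res[0].table.sum() == 50

    def test_empty_background_rejected(self):
        records = _records(10, np.random.default_rng(0))
        with pytest.raises(ValueError, match="background"):
            ek.stepwise_fisher(records, element_genes=set())


class TestConcordance:
    def test_all_concordant_leaves_discordant_arm_undefined(self):
        rng = np.random.default_rng(4)
        records = _records(200, rng)
        records.loc[records["simultaneous"].astype(bool), "concordant"] = True
        res = ek.concordance_association(records)
        assert res["discordant"] is None
        assert res["concordant"] is not None

    def test_no_simultaneity_rejected(self):
        rng = np.random.default_rng(5)
        records = _records(50, rng)
        records["simultaneous"] = False
        records["concordant"] = pd.NA
        with pytest.raises(ValueError, match="no simultaneous"):
            ek.concordance_association(records)

    def test_equal_enrichment_for_both_signs(self):
        # generator enriches inheritance equally for concordant and
        # discordant partners; the two arms' odds ratios should agree
        rng = np.random.default_rng(6)
        rows = []
        for i in range(4000):
            has_expr = True
            sim = rng.random() < 0.4
            conc = (rng.random() < 0.5) if sim else pd.NA
            p_inh = 0.4 if sim else 0.2
            rows.append(dict(gene_id=f"g{i}", lineage_id="A",
                             has_expr_change=has_expr,
                             expr_inherited=rng.random() < p_inh,
                             has_partner_epimutation=sim, simultaneous=sim,
                             partner_inherited=False, concordant=conc))
        res = ek.concordance_association(pd.DataFrame(rows))
        or_c, or_d = res["concordant"].odds_ratio, res["discordant"].odds_ratio
        assert 0.6 < or_c / or_d < 1.6
        assert res["concordant"].log2_odds_ratio > 0


class TestDomainEnrichment:
    def test_class_drawn_from_single_domain(self):
        domains = {f"l{i}": ("piRNA_cluster" if i < 20 else "Active")
                   for i in range(200)}
        classes = pd.DataFrame(
            {"longevity": ["long_lived"] * 15},
            index=pd.Index([f"l{i}" for i in range(15)], name="locus_id"),
        )
        grid = ek.domain_enrichment(classes, domains)
        row = grid[(grid["longevity"] == "long_lived")
                   & (grid["domain"] == "piRNA_cluster")].iloc[0]
        assert row["odds_ratio"] > 1
        assert row["p_bonferroni"] == grid["p_bonferroni"].min()
        assert row["significant"]

    def test_uniform_assignment_not_significant(self):
        rng = np.random.default_rng(7)
        domains = {f"l{i}": ["Active", "Regulated"][i % 2] for i in range(400)}
        chosen = rng.choice(400, 60, replace=False)
        classes = pd.DataFrame(
            {"longevity": ["short_lived"] * 60},
            index=pd.Index([f"l{i}" for i in chosen], name="locus_id"),
        )
        grid = ek.domain_enrichment(classes, domains)
        assert not grid["significant"].any()

    def test_bonferroni_identity(self):
        rng = np.random.default_rng(8)
        domains = {f"l{i}": f"d{i % 5}" for i in range(300)}
        classes = pd.DataFrame(
            {"longevity": (["long_lived"] * 20 + ["short_lived"] * 20
                           + ["non_inherited"] * 20)},
            index=pd.Index([f"l{i}" for i in rng.choice(300, 60, replace=False)],
                           name="locus_id"),
        )
        grid = ek.domain_enrichment(classes, domains)
        assert len(grid) == 15
        assert np.allclose(grid["p_bonferroni"], np.minimum(1.0, 15 * grid["p"]))

    def test_unlabelled_locus_rejected(self):
        classes = pd.DataFrame({"longevity": ["long_lived"]},
                               index=pd.Index(["ghost"], name="locus_id"))
        with pytest.raises(ValueError, match="ghost"):
            ek.domain_enrichment(classes, {"other": "Active"})


class TestOntologyEnrichment:
    def test_pearson_chi2_hand_oracle(self):
        # [[20,80],[5,95]]: expected cells 12.5/87.5 -> chi2 = 2*(4.5 + 0.643)
        assert _pearson_chi2(np.array([[20, 80], [5, 95]])) == pytest.approx(
            10.2857, abs=1e-3
        )

    def test_enriched_term_scores_high(self):
        rng = np.random.default_rng(9)
        test = [f"t{i}" for i in range(40)]
        bg = [f"b{i}" for i in range(200)]
        term_map = {g: ["hot"] for g in test[:20]}
        term_map.update({g: ["hot"] for g in bg[:10]})
        term_map.update({g: ["cold"] for g in bg[10:30]})
        res = ek.ontology_enrichment(test, bg, term_map, seed=0)
        hot = res[res["term"] == "hot"].iloc[0]
        assert hot["mode"] == "fisher_direct"
        assert hot["enriched"] and hot["p"] < 0.01

    def test_min_genes_exclusion(self):
        test = [f"t{i}" for i in range(10)]
        bg = [f"b{i}" for i in range(50)]
        term_map = {"t0": ["rare"], "t1": ["rare"], "b0": ["rare"], "b1": ["rare"]}
        res = ek.ontology_enrichment(test, bg, term_map, min_genes=5, seed=0)
        assert "rare" not in set(res["term"])

    def test_sampling_mode_on_large_background(self):
        rng = np.random.default_rng(10)
        test = [f"t{i}" for i in range(60)]
        bg = [f"b{i}" for i in range(300)]
        term_map = {g: ["ubiq"] for g in test[:30]}
        term_map.update({g: ["ubiq"] for g in bg[:15]})
        res = ek.ontology_enrichment(test, bg, term_map, n_samples=10,
                                     sample_size=200, seed=3)
        row = res[res["term"] == "ubiq"].iloc[0]
        assert row["mode"] == "chi2_sampled"
        assert row["statistic"] > 0 and row["enriched"]

    def test_empty_term_map_rejected(self):
        with pytest.raises(ValueError, match="empty term_map"):
            ek.ontology_enrichment(["a"], ["b"], {})
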