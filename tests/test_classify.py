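import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reprogkit as rk
from reprogkit.classify import (
    CATEGORY_ORDER,
    Category,
    build_report,
    category_counts,
    classify_all,
    classify_gene,
    percent,
    select_signature_genes,
    shared_categories,
)
from reprogkit.de import DEResult


def de_result(genes, q, mu_a, mu_b, label="x"):
    n = len(genes)
    table = pd.DataFrame(
        {
            "base_mean_a": np.broadcast_to(mu_a, n).astype(float),
            "base_mean_b": np.broadcast_to(mu_b, n).astype(float),
            "log2fc": 0.0, "se": 1.0, "wald_z": 0.0,
            "pvalue": np.broadcast_to(q, n).astype(float),
            "qvalue": np.broadcast_to(q, n).astype(float),
            "flag": "ok",
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(label=label, table=table)


class TestSignatureSelection:
    def test_either_contrast_is_a_union(self):
        genes = ["g1", "g2", "g3"]
        es1 = de_result(genes, [0.01, 0.2, 0.2], 10.0, 100.0)
        es2 = de_result(genes, [0.9, 0.01, 0.2], 10.0, 200.0)
        sig = select_signature_genes(es1, es2, alpha_sig=0.05)
        assert sig.gene_ids == ["g1", "g2"]
        assert sig.table.loc["g1", "mu_es_pooled"] == pytest.approx(150.0)

    def test_mismatched_gene_universes_rejected(self):
        es1 = de_result(["g1"], 0.01, 10.0, 100.0)
        es2 = de_result(["g2"], 0.01, 10.0, 100.0)
        with pytest.raises(ValueError, match="universe"):
            select_signature_genes(es1, es2)

    def test_different_ef_reference_rejected(self):
        es1 = de_result(["g1"], 0.01, 10.0, 100.0)
        es2 = de_result(["g1"], 0.01, 99.0, 100.0)
        with pytest.raises(ValueError, match="reference"):
            select_signature_genes(es1, es2)

    def test_matches_bruteforce_union_filter(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(300)]
        q1, q2 = rng.random(300), rng.random(300)
        sig = select_signature_genes(
            de_result(genes, q1, 10.0, 100.0), de_result(genes, q2, 10.0, 100.0),
            alpha_sig=0.1,
        )
        expected = {g for g, a, b in zip(genes, q1, q2) if a < 0.1 or b < 0.1}
        assert set(sig.gene_ids) == expected


class TestClassifyGene:
    @pytest.mark.parametrize(
        "q_ef,q_es1,q_es2,mu_ips,expected",
        [
            # not different from both ES lines -> correct, regardless of EF test
            (0.001, 0.9, 0.8, 100.0, Category.CORRECT),
            # different from both ES but EF-like -> somatic memory
            (0.5, 1e-6, 1e-5, 100.0, Category.NOT_REPROGRAMMED),
            # different from everything, strictly between EF and ES -> intermediate
            (1e-4, 1e-6, 1e-6, 100.0, Category.INTERMEDIATE),
            # outside the EF-ES interval -> novel
            (1e-4, 1e-6, 1e-6, 5000.0, Category.NOVEL),
            # boundary tie is not 'between'
            (1e-4, 1e-6, 1e-6, 1000.0, Category.NOVEL),
        ],
    )
    def test_decision_tree(self, q_ef, q_es1, q_es2, mu_ips, expected):
        got = classify_gene(q_ef, q_es1, q_es2, mu_ef=10.0, mu_es_pooled=1000.0,
                            mu_ips=mu_ips, alpha_sig=0.05)
        assert got is expected

    def test_missing_test_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_gene(np.nan, 0.1, 0.1, 10.0, 100.0, 50.0)


def signature_of(genes, mu_ef=10.0, mu_es=1000.0):
    table = pd.DataFrame(
        {
            "sig_vs_es1": True, "sig_vs_es2": True,
            "mu_ef": mu_ef, "mu_es1": mu_es, "mu_es2": mu_es, "mu_es_pooled": mu_es,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return rk.SignatureGeneSet(table=table, alpha_sig=0.05)


class TestClassifyAll:
    def test_vectorized_matches_scalar_rule(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(400)]
        sig = signature_of(genes)
        tests = pd.DataFrame(
            {
                "q_vs_ef": rng.random(400),
                "q_vs_es1": rng.random(400) * 0.2,
                "q_vs_es2": rng.random(400) * 0.2,
                "mu_ips": rng.uniform(1.0, 5000.0, 400),
            },
            index=genes,
        )
        labels = classify_all(sig, {"iPS1": tests})
        for g in genes[:100]:
            expected = classify_gene(
                tests.loc[g, "q_vs_ef"], tests.loc[g, "q_vs_es1"], tests.loc[g, "q_vs_es2"],
                10.0, 1000.0, tests.loc[g, "mu_ips"], 0.05)
            got = labels.loc[(labels.gene_id == g), "category"].iloc[0]
            assert got == expected.value

    def test_partition_exactly_one_category_per_gene_line(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(500)]
        sig = signature_of(genes)
        tests = {
            line: pd.DataFrame(
                {
                    "q_vs_ef": rng.random(500), "q_vs_es1": rng.random(500),
                    "q_vs_es2": rng.random(500), "mu_ips": rng.uniform(1, 2000, 500),
                },
                index=genes,
            )
            for line in ("iPS1", "iPS2")
        }
        labels = classify_all(sig, tests)
        assert len(labels) == 1000
        counts = category_counts(labels)
        assert (counts.sum(axis=1) == 500).all()

    def test_missing_signature_gene_rejected(self):
        sig = signature_of(["g1", "g2"])
        tests = pd.DataFrame(
            {"q_vs_ef": [0.5], "q_vs_es1": [0.5], "q_vs_es2": [0.5], "mu_ips": [5.0]},
            index=["g1"])
        with pytest.raises(ValueError, match="missing"):
            classify_all(sig, {"iPS1": tests})

    def test_correct_sets_nested_in_alpha(self):
        """With fixed q-values, CORRECT is exactly the set of genes with
        max(q_es1, q_es2) >= alpha_sig, so raising alpha_sig can only
        shrink it: every gene CORRECT at a larger threshold is CORRECT at
        any smaller one."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(300)]
        sig = signature_of(genes)
        tests = pd.DataFrame(
            {
                "q_vs_ef": rng.random(300), "q_vs_es1": rng.random(300),
                "q_vs_es2": rng.random(300), "mu_ips": rng.uniform(1, 2000, 300),
            },
            index=genes,
        )
        correct_sets = []
        for alpha in (0.01, 0.05, 0.2, 0.5):
            labels = classify_all(sig, {"iPS1": tests}, alpha_sig=alpha)
            correct_sets.append(set(labels.loc[labels.category == "correct", "gene_id"]))
        for smaller, larger in zip(correct_sets, correct_sets[1:]):
            assert larger <= smaller


class TestRecoveryOnCopiedSamples:
    """Degenerate constructions where the right answer is known exactly."""

    def test_ips_copied_from_es_is_all_correct(self, study_sheet):
        rng = np.random.default_rng(30)
        n = 800
        mu = rng.lognormal(np.log(200), 1.0, n)
        sig_mask = rng.random(n) < 0.3
        mu_es = np.where(sig_mask, mu * 2.0 ** (4 * rng.choice([-1, 1], n)), mu)
        cols = {}
        for line in ("EF", "ES1", "ES2", "iPS1", "iPS2"):
            base = mu if line == "EF" else mu_es
            for rep in (1, 2, 3):
                size = 1 / 0.05
                cols[f"{line}_r{rep}"] = rng.negative_binomial(size, size / (size + base))
        # iPS columns literally copied from ES1 columns: no iPS-vs-ES signal
        for rep in (1, 2, 3):
            cols[f"iPS1_r{rep}"] = cols[f"ES1_r{rep}"]
            cols[f"iPS2_r{rep}"] = cols[f"ES1_r{rep}"]
        matrix = rk.CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(n)]))
        stage = rk.run_de(matrix, study_sheet)
        result = rk.run_classify(stage, study_sheet)
        assert (result.labels["category"] == "correct").all()

    def test_ips_copied_from_ef_shows_somatic_memory(self, study_sheet):
        rng = np.random.default_rng(31)
        n = 800
        mu = rng.lognormal(np.log(200), 1.0, n)
        sig_mask = rng.random(n) < 0.3
        mu_es = np.where(sig_mask, mu * 2.0 ** (4 * rng.choice([-1, 1], n)), mu)
        cols = {}
        for line in ("EF", "ES1", "ES2"):
            base = mu if line == "EF" else mu_es
            for rep in (1, 2, 3):
                size = 1 / 0.05
                cols[f"{line}_r{rep}"] = rng.negative_binomial(size, size / (size + base))
        # iPS columns literally copied from EF: no iPS-vs-EF signal by construction
        for rep in (1, 2, 3):
            cols[f"iPS1_r{rep}"] = cols[f"EF_r{rep}"]
            cols[f"iPS2_r{rep}"] = cols[f"EF_r{rep}"]
        matrix = rk.CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(n)]))
        stage = rk.run_de(matrix, study_sheet)
        result = rk.run_classify(stage, study_sheet)
        cats = set(result.labels["category"])
        assert cats <= {"correct", "not_reprogrammed"}
        frac_nr = (result.labels["category"] == "not_reprogrammed").mean()
        assert frac_nr > 0.5


class TestSharedCategories:
    def test_identical_labelings_share_everything(self):
        labels = pd.DataFrame({
            "gene_id": ["g1", "g2", "g1", "g2"],
            "ips_line": ["a", "a", "b", "b"],
            "category": ["correct", "novel", "correct", "novel"],
        })
        assert shared_categories(labels) == {
            "correct": 1, "intermediate": 0, "not_reprogrammed": 0, "novel": 1}

    def test_disjoint_labelings_share_nothing(self):
        labels = pd.DataFrame({
            "gene_id": ["g1", "g2", "g1", "g2"],
            "ips_line": ["a", "a", "b", "b"],
            "category": ["correct", "novel", "novel", "correct"],
        })
        assert all(v == 0 for v in shared_categories(labels).values())

    def test_single_line_rejected(self):
        labels = pd.DataFrame({"gene_id": ["g1"], "ips_line": ["a"], "category": ["correct"]})
        with pytest.raises(ValueError, match=">= 2"):
            shared_categories(labels)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, derandomize=True)
    def test_matches_bruteforce_intersection(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(40)]
        cats = [c.value for c in CATEGORY_ORDER]
        frames = []
        assign = {}
        for line in ("a", "b", "c"):
            labels = rng.choice(cats, size=40)
            assign[line] = dict(zip(genes, labels))
            frames.append(pd.DataFrame({"gene_id": genes, "ips_line": line, "category": labels}))
        got = shared_categories(pd.concat(frames, ignore_index=True))
        for cat in cats:
            expected = sum(
                all(assign[line][g] == cat for line in ("a", "b", "c")) for g in genes)
            assert got[cat] == expected
        per_line_min = {
            cat: min(sum(assign[line][g] == cat for g in genes) for line in ("a", "b", "c"))
            for cat in cats
        }
        assert all(got[cat] <= per_line_min[cat] for cat in cats)


class TestPercentAndReport:
    @pytest.mark.parametrize(
        "count,total,decimals,expected",
        [
            (2569, 3201, 2, 80.26),
            (2232, 3201, 2, 69.73),
            (722, 60000, 1, 1.2),
            (0, 10, 2, 0.0),
            (1, 8, 2, 12.5),
            (1, 3, 2, 33.33),
        ],
    )
    def test_half_up_rounding(self, count, total, decimals, expected):
        assert percent(count, total, decimals) == expected

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            percent(1, 0)
        with pytest.raises(ValueError):
            percent(5, 3)

    def test_report_percentages_from_counts(self):
        counts = pd.DataFrame(
            [[2569, 213, 239, 180], [2579, 223, 224, 175]],
            index=["lineA", "lineB"],
            columns=[c.value for c in CATEGORY_ORDER],
        )
        report = build_report(counts, None, total=3201)
        a = report.rows[report.rows.row_id == "lineA"].set_index("category")["percent"]
        assert list(a[[c.value for c in CATEGORY_ORDER]]) == [80.26, 6.65, 7.47, 5.62]
        b = report.rows[report.rows.row_id == "lineB"].set_index("category")["percent"]
        assert list(b[[c.value for c in CATEGORY_ORDER]]) == [80.57, 6.97, 7.00, 5.47]

    def test_degenerate_single_category_report(self):
        counts = pd.DataFrame([[3201, 0, 0, 0]], index=["line"],
                              columns=[c.value for c in CATEGORY_ORDER])
        report = build_report(counts, None, total=3201)
        assert list(report.rows["percent"]) == [100.00, 0.00, 0.00, 0.00]

    def test_counts_not_summing_to_total_rejected(self):
        counts = pd.DataFrame([[10, 0, 0, 0]], index=["line"],
                              columns=[c.value for c in CATEGORY_ORDER])
        with pytest.raises(ValueError, match="sum"):
            build_report(counts, None, total=11)

    def test_text_report_is_table_shaped(self):
        counts = pd.DataFrame([[2, 1, 1, 0]], index=["lineA"],
                              columns=[c.value for c in CATEGORY_ORDER])
        report = build_report(counts, {"correct": 2, "intermediate": 0,
                                       "not_reprogrammed": 1, "novel": 0}, total=4)
        text = report.format_text()
        assert "Correctly reprogrammed" in text
        assert "2 (50.00%)" in text
        assert "Shared between lineA" in text
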