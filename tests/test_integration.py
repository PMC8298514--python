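import itertools
import math

import numpy as np
import pandas as pd
import pytest

from enhdiff.elements import ENHANCER, Element
from enhdiff.integration import (
    BiomarkerPanel,
    assign_nearest_gene,
    classify_priming,
    classify_sample_signature,
    correlate_signal_expression,
    cpm_filter,
    de_test,
    enhancer_dose_response,
    hierarchical_clustering,
    hypergeometric_enrichment,
    pca,
    select_biomarkers,
)
from enhdiff.io_formats import ConfigError, GenomicInterval, TssRecord


def el(chrom, start, end, eid):
    return Element(GenomicInterval(chrom, start, end), eid, ENHANCER, 0)


class TestNearestGene:
    def test_nearest_tss_wins(self):
        links = assign_nearest_gene(
            [el("chr1", 4500, 5500, "e")],
            [TssRecord("geneA", "chr1", 4000), TssRecord("geneB", "chr1", 7000)],
        )
        assert links.loc["e", "gene_id"] == "geneA"
        assert links.loc["e", "distance"] == 1000

    def test_equidistant_tie_breaks_lexicographically(self):
        links = assign_nearest_gene(
            [el("chr1", 4500, 5500, "e")],
            [TssRecord("geneB", "chr1", 4000), TssRecord("geneA", "chr1", 6000)],
        )
        assert links.loc["e", "gene_id"] == "geneA"

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(12)
        tss = [TssRecord(f"g{i:03d}", "chr1", int(p)) for i, p in enumerate(rng.integers(0, 10**6, 120))]
        els = [
            el("chr1", int(s), int(s) + 500, f"e{i}") for i, s in enumerate(rng.integers(0, 10**6, 400))
        ]
        links = assign_nearest_gene(els, tss)
        for e in els:
            mid = e.interval.midpoint
            best = min(tss, key=lambda t: (abs(t.tss - mid), t.gene_id))
            assert links.loc[e.element_id, "gene_id"] == best.gene_id


class TestCpmFilter:
    def test_cpm_arithmetic(self):
        counts = pd.DataFrame({"s1": [15, 999_985]}, index=["g1", "g2"])
        kept = cpm_filter(counts, cpm_min=1.0, min_samples=1)
        assert "g1" in kept  # 15 / 1e6 * 1e6 = 15 cpm > 1

    def test_silent_gene_dropped(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 100]}, index=["g1", "g2"])
        kept = cpm_filter(counts, min_samples=1)
        assert list(kept) == ["g2"]

    def test_zero_min_samples_keeps_everything(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
        assert len(cpm_filter(counts, min_samples=0)) == 2

    def test_min_samples_beyond_columns_rejected(self):
        with pytest.raises(ConfigError):
            cpm_filter(pd.DataFrame({"s1": [1]}), min_samples=2)


class TestDeTest:
    def test_identical_groups_not_de(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 0.2, size=(20, 5))
        m = pd.DataFrame(np.hstack([base, base]), columns=[f"c{i}" for i in range(10)])
        out = de_test(m, [f"c{i}" for i in range(5)], [f"c{i}" for i in range(5, 10)])
        assert (out["direction"] == "ns").all()

    def test_planted_fourfold_shift_detected(self):
        rng = np.random.default_rng(42)
        detected = 0
        reps = 40
        for _ in range(reps):
            m = pd.DataFrame(
                rng.normal(5, 0.3, size=(30, 20)), columns=[f"c{i}" for i in range(20)]
            )
            m.iloc[0, :10] += 2.0  # 4-fold on the log2 scale
            out = de_test(m, [f"c{i}" for i in range(10)], [f"c{i}" for i in range(10, 20)])
            detected += out.iloc[0]["direction"] == "up"
        assert detected / reps >= 0.99

    def test_degenerate_constant_rows(self):
        m = pd.DataFrame(
            [[1.0] * 8, [2.0] * 4 + [1.0] * 4], columns=[f"c{i}" for i in range(8)]
        )
        out = de_test(m, [f"c{i}" for i in range(4)], [f"c{i}" for i in range(4, 8)])
        assert out.iloc[0]["pvalue"] == 1.0
        assert out.iloc[1]["pvalue"] == 0.0


class TestDoseResponse:
    def test_planted_dose_gives_strictly_increasing_medians(self, default_cohort):
        from enhdiff.differential import assign_groups, call_differential, pairwise_change
        from enhdiff.integration import expression_fc

        c = default_cohort
        enh = [e.element_id for e in c.enhancers]
        sig = c.signal.loc[enh]
        calls = {
            comp: call_differential(
                pairwise_change(sig, c.sample_sheet.pairs(comp), comp), recurrence_min=6
            )
            for comp in ("EC_vs_Nor", "LNC_vs_Nor")
        }
        groups = assign_groups(calls["EC_vs_Nor"], calls["LNC_vs_Nor"])
        links = assign_nearest_gene(c.enhancers, c.tss)
        fc = expression_fc(
            c.expression_tpm, c.sample_sheet.samples_for("EC"), c.sample_sheet.samples_for("Nor")
        )
        dose = enhancer_dose_response(links, groups, fc, direction="gained")
        medians = dose["median_fc"].tolist()
        assert medians == sorted(medians) and len(set(medians)) == len(medians)
        assert (dose["p_vs_previous"] < 0.01).all()

    def test_all_genes_dose_zero_gives_empty_table(self):
        links = pd.DataFrame({"gene_id": ["g1"], "distance": [0]}, index=["e1"])
        groups = pd.Series(["none"], index=["e1"])
        fc = pd.Series({"g1": 1.0, "g2": 1.2})
        out = enhancer_dose_response(links, groups, fc)
        assert out.empty

    def test_wilcoxon_on_identical_distributions_is_large(self):
        rng = np.random.default_rng(3)
        links = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(8)], "distance": 0},
            index=[f"e{i}" for i in range(8)],
        )
        groups = pd.Series(["G1"] * 8, index=links.index)
        values = rng.normal(2.0, 0.5, 16)
        fc = pd.Series(values, index=[f"g{i}" for i in range(16)])
        out = enhancer_dose_response(links, groups, fc, buckets=(1,))
        # dose-1 genes and dose-0 genes drawn from the same distribution
        assert out["p_vs_previous"].iloc[0] > 0.05


def spearman_oracle(x, y):
    """Tie-corrected rank formula: Pearson correlation of average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestCorrelation:
    @staticmethod
    def _setup(x, y):
        samples = [f"s{i}" for i in range(len(x))]
        links = pd.DataFrame({"gene_id": ["g"], "distance": [0]}, index=["e"])
        signal = pd.DataFrame([x], index=["e"], columns=samples)
        expr = pd.DataFrame([y], index=["g"], columns=samples)
        return links, signal, expr, samples

    def test_monotone_pair_is_one(self):
        r = correlate_signal_expression(*self._setup([1, 2, 3, 4], [10, 20, 30, 40]))
        assert r.loc["e"] == pytest.approx(1.0)

    def test_reversed_monotone_is_minus_one(self):
        r = correlate_signal_expression(*self._setup([1, 2, 3, 4], [9, 7, 5, 3]))
        assert r.loc["e"] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        r = correlate_signal_expression(*self._setup([2, 2, 2, 2], [1, 2, 3, 4]))
        assert np.isnan(r.loc["e"])

    def test_matches_tie_corrected_rank_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.integers(0, 6, size=20).astype(float)  # heavy ties
            y = rng.normal(size=20)
            r = correlate_signal_expression(*self._setup(x, y))
            assert r.loc["e"] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            correlate_signal_expression(*self._setup([1, 2], [1, 2]))


class TestBiomarkers:
    def test_positive_correlation_filter_then_fc_ranking(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(200)]
        r = pd.Series(rng.uniform(-1, 1, 200), index=genes)
        fc = pd.Series(rng.uniform(0.5, 8, 200), index=genes)
        panel = select_biomarkers(r, fc, "g1", top_corr=100, top_n=10)
        positive = r[r > 0]
        pool = set(positive.sort_values(ascending=False).head(100).index)
        assert set(panel.genes) <= pool
        assert panel.table["fc"].is_monotonic_decreasing

    def test_loss_subgroup_ranks_ascending(self):
        genes = ["a", "b", "c"]
        r = pd.Series([0.9, 0.8, 0.7], index=genes)
        fc = pd.Series([0.5, 0.1, 0.9], index=genes)
        panel = select_biomarkers(r, fc, "g6", top_n=2)
        assert panel.genes == ["b", "a"]

    def test_no_positive_correlation_gives_empty_panel(self):
        r = pd.Series([-0.5, -0.1], index=["a", "b"])
        fc = pd.Series([2.0, 3.0], index=["a", "b"])
        assert select_biomarkers(r, fc, "g1").genes == []

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        r = pd.Series(rng.choice([0.5, 0.7, 0.9], 50), index=genes)
        fc = pd.Series(rng.choice([1.5, 2.5], 50), index=genes)
        p1 = select_biomarkers(r, fc, "g3", top_corr=20, top_n=10)
        perm = rng.permutation(50)
        p2 = select_biomarkers(r.iloc[perm], fc.iloc[perm], "g3", top_corr=20, top_n=10)
        assert p1.genes == p2.genes


class TestSignature:
    def test_pattern_matching(self):
        genes = {sg: [f"{sg}_gene"] for sg in ("g1", "g2", "g3", "g6")}
        panels = {
            sg: BiomarkerPanel(sg, genes[sg], pd.DataFrame()) for sg in genes
        }
        # two samples per tissue-like profile, scores driven by panel genes
        data = {
            "nor1": [0.0, 0.0, 0.0, 10.0],
            "nor2": [0.1, 0.1, 0.1, 9.0],
            "ec1": [10.0, 0.0, 10.0, 0.0],
            "ec2": [9.0, 0.1, 9.0, 0.1],
            "lnc1": [0.0, 10.0, 10.0, 0.0],
            "lnc2": [0.1, 9.0, 9.0, 0.1],
        }
        expr = pd.DataFrame(data, index=["g1_gene", "g2_gene", "g3_gene", "g6_gene"])
        labels = classify_sample_signature(panels, expr)
        assert labels["nor1"] == "Nor" and labels["ec1"] == "EC" and labels["lnc1"] == "LNC"

    def test_no_panels_rejected(self):
        with pytest.raises(ConfigError):
            classify_sample_signature({}, pd.DataFrame({"s": [1.0]}))


class TestPriming:
    @staticmethod
    def de(direction_by_gene):
        return pd.DataFrame(
            {"direction": pd.Series(direction_by_gene)},
        )

    def test_rules(self):
        groups = pd.Series(["G3", "G3", "G6"], index=["e1", "e2", "e3"])
        links = pd.DataFrame(
            {"gene_id": ["gA", "gB", "gC"], "distance": 0}, index=["e1", "e2", "e3"]
        )
        de_ec = self.de({"gA": "ns", "gB": "up", "gC": "ns"})
        de_lnc = self.de({"gA": "up", "gB": "up", "gC": "down"})
        pre_act, pre_sil = classify_priming(groups, de_ec, de_lnc, links)
        assert pre_act == ["gA"]  # up only in the metastasis
        assert "gB" not in pre_act  # already up in the primary tumor
        assert pre_sil == ["gC"]


class TestHypergeometric:
    def test_complete_overlap_hand_example(self):
        universe = {f"u{i}" for i in range(10)}
        query = {f"u{i}" for i in range(5)}
        out = hypergeometric_enrichment(query, {"set": set(query)}, universe)
        assert out.loc["set", "pvalue"] == pytest.approx(1 / 252)

    def test_zero_overlap_is_one(self):
        universe = {"a", "b", "c", "d"}
        out = hypergeometric_enrichment({"a"}, {"s": {"b"}}, universe)
        assert out.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_matches_pmf_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            M = int(rng.integers(5, 20))
            universe = set(range(M))
            query = set(rng.choice(M, size=int(rng.integers(1, M)), replace=False).tolist())
            aset = set(rng.choice(M, size=int(rng.integers(1, M)), replace=False).tolist())
            out = hypergeometric_enrichment(query, {"s": aset}, universe)
            K, N, k = len(aset), len(query), len(aset & query)
            expected = sum(
                math.comb(K, j) * math.comb(M - K, N - j) / math.comb(M, N)
                for j in range(k, min(K, N) + 1)
            )
            assert out.loc["s", "pvalue"] == pytest.approx(expected, abs=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigError):
            hypergeometric_enrichment(set(), {"s": set()}, set())


class TestPca:
    def test_separated_clouds_split_along_pc1(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(30, 5))
        b = rng.normal(4, 0.1, size=(30, 5))
        m = pd.DataFrame(np.hstack([a, b]), columns=[f"s{i}" for i in range(10)])
        out = pca(m)
        pc1 = out["scores"]["PC1"]
        assert (pc1[:5] < pc1[5:].min()).all() or (pc1[:5] > pc1[5:].max()).all()
        assert out["variance_ratio"]["PC1"] > out["variance_ratio"]["PC2"]

    def test_hand_computed_variance_proportions(self):
        # orthogonal centered features with variances 5/3 and 4/3
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, -1.0, -1.0, 1.0]], columns=list("abcd")
        )
        out = pca(m, n_components=2)
        assert out["variance_ratio"].tolist() == pytest.approx([5 / 9, 4 / 9])

    def test_sign_convention_is_deterministic(self):
        m = pd.DataFrame(np.random.default_rng(4).normal(size=(20, 6)))
        s1 = pca(m)["scores"]
        s2 = pca(m)["scores"]
        pd.testing.assert_frame_equal(s1, s2)
        assert (pca(m)["loadings"].abs().max() == pca(m)["loadings"].max()).all()


class TestClustering:
    def test_duplicated_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        out = hierarchical_clustering(m)
        Z = out["linkage"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_three_group_cohort_recovered(self, default_cohort):
        c = default_cohort
        planted = c.truth.planted()
        m = c.signal.loc[planted]
        out = hierarchical_clustering(np.log2(m + 1), k=3)
        labels = out["labels"]
        tissues = c.sample_sheet.frame.set_index("sample_id")["tissue"]
        agree = 0
        for cluster in (1, 2, 3):
            members = tissues[labels[labels == cluster].index]
            agree += (members == members.mode()[0]).sum()
        assert agree / len(labels) >= 0.9

    def test_no_linkage_inversions(self, small_cohort):
        m = small_cohort.signal.iloc[:200]
        Z = hierarchical_clustering(np.log2(m + 1))["linkage"]
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_constant_column_named_in_error(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ConfigError, match="flat"):
            hierarchical_clustering(m)
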