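"""Promoter environments, enhancer classification/linking, mark stratification."""

import numpy as np
import pandas as pd
import pytest

from chromenv.environment import (
    assign_region_state,
    category_by_class_contrast,
    classify_enhancers,
    enhancer_expression,
    gene_promoter_environment,
    h3k79_gene_category,
    link_enhancer_genes,
    split_regions_by_mark,
)
from chromenv.genome import GenomeAssembly, Interval, PeakSet, gene_table, make_gene
from chromenv.hmm import Segmentation, state_priority

from test_intervals import random_segmentation


def predominant_oracle(region, seg):
    """Per-base counting oracle with the documented tie-break."""
    counts = {}
    for pos in range(region.start, region.end):
        lab = "unannotated"
        for l, s, e in seg.runs.get(region.chrom, []):
            if s <= pos < e:
                lab = l
                break
        counts[lab] = counts.get(lab, 0) + 1
    best = sorted(counts.items(), key=lambda kv: (-kv[1], state_priority(kv[0])))[0]
    return best[0], best[1] / (region.end - region.start)


class TestAssignRegionState:
    def test_majority_state(self):
        seg = Segmentation({"chr1": [("TxWk", 0, 600), ("Quies", 600, 1000)]})
        state, frac, second, frac2 = assign_region_state(Interval("chr1", 0, 1000), seg)
        assert (state, frac) == ("TxWk", 0.6)
        assert (second, frac2) == ("Quies", 0.4)

    def test_exact_tie_resolved_by_priority(self):
        seg = Segmentation({"chr1": [("Quies", 0, 500), ("EnhA", 500, 1000)]})
        state, frac, _, _ = assign_region_state(Interval("chr1", 0, 1000), seg)
        assert (state, frac) == ("EnhA", 0.5)

    def test_unannotated_region(self):
        seg = Segmentation({"chr2": [("TxWk", 0, 100)]})
        state, frac, _, _ = assign_region_state(Interval("chr1", 0, 100), seg)
        assert (state, frac) == ("unannotated", 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed + 11)
        seg = random_segmentation(rng, labels=("TxWk", "Quies", "EnhA", "ReprPC"))
        for _ in range(60):
            s = int(rng.integers(0, 9500))
            region = Interval("chr1", s, s + int(rng.integers(1, 500)))
            state, frac, _, _ = assign_region_state(region, seg)
            o_state, o_frac = predominant_oracle(region, seg)
            assert (state, frac) == (o_state, pytest.approx(o_frac))

    def test_second_never_beats_first(self, rng):
        seg = random_segmentation(rng)
        for _ in range(40):
            s = int(rng.integers(0, 9000))
            region = Interval("chr1", s, s + int(rng.integers(1, 800)))
            _, frac, _, frac2 = assign_region_state(region, seg)
            assert frac2 <= frac


class TestPromoterEnvironment:
    def test_fully_bivalent_promoter(self):
        seg = Segmentation({"chr1": [("TssBiv", 0, 50_000)]})
        genes = [make_gene("g1", "chr1", 10_000, 20_000, "+")]
        env = gene_promoter_environment(genes, seg)
        assert env.loc[0, "predominant_state"] == "TssBiv"
        assert env.loc[0, "coverage_fraction"] == 1.0

    def test_off_chromosome_window_clipped(self):
        asm = GenomeAssembly([("chr1", 5000)])
        seg = Segmentation({"chr1": [("Quies", 0, 5000)]})
        genes = [make_gene("g1", "chr1", 100, 4900, "-")]  # TSS 4899, window clipped
        env = gene_promoter_environment(genes, seg, window=3000, assembly=asm)
        assert env.loc[0, "predominant_state"] == "Quies"

    def test_planted_state_class_association(self, rng):
        # genes alternate between ReprPC-promoter and Tx-promoter blocks
        runs, genes, classes = [], [], []
        pos = 0
        for i in range(60):
            label = "ReprPC" if i % 2 == 0 else "Tx"
            runs.append((label, pos, pos + 20_000))
            genes.append(make_gene(f"g{i}", "chr1", pos + 8_000, pos + 12_000, "+"))
            classes.append("up" if label == "ReprPC" else "not")
            pos += 20_000
        seg = Segmentation({"chr1": runs})
        env = gene_promoter_environment(genes, seg).set_index("gene_id")
        de = pd.Series(classes, index=[g.gene_id for g in genes])
        res = category_by_class_contrast(env["predominant_state"].rename("h3k79_category"), de)
        assert res["p"] < 1e-6


class TestSplitByMark:
    def _regions(self):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [0, 1000, 2000],
            "end": [500, 1500, 2500],
            "state": ["Tx", "Quies", "Tx"],
        })

    def test_covered_region_plus(self):
        marks = PeakSet("m", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]}))
        out = split_regions_by_mark(self._regions(), marks)
        assert out["mark"].tolist() == ["+", "-", "-"]

    def test_zero_overlap_minus(self):
        marks = PeakSet("m", pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1000]}))
        out = split_regions_by_mark(self._regions(), marks)
        assert (out["mark"] == "-").all()

    def test_empty_mark_set_all_minus(self):
        marks = PeakSet("m", pd.DataFrame(columns=["chrom", "start", "end"]))
        out = split_regions_by_mark(self._regions(), marks)
        assert (out["mark"] == "-").all()

    def test_null_placement_gives_unbiased_p(self):
        """Random mark placement: per-state contrast p-values not systematically small."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(60):
            n = 200
            starts = np.sort(rng.choice(50_000, size=n, replace=False)) * 10
            regions = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 8,
                                    "state": rng.choice(["Tx", "Quies"], size=n)})
            m0 = np.sort(rng.choice(500_000, size=50, replace=False))
            marks = PeakSet("m", pd.DataFrame({"chrom": "chr1", "start": m0, "end": m0 + 40}))
            out = split_regions_by_mark(regions, marks)
            contrast = out.attrs["contrast"]
            ps.extend(contrast["p"].dropna().tolist())
        assert np.mean(np.array(ps) < 0.05) < 0.15


class TestEnhancers:
    def _segmentation(self):
        return Segmentation({"chr1": [
            ("Quies", 0, 1000), ("EnhA", 1000, 1400), ("EnhA", 1400, 1800),
            ("Tx", 1800, 3000), ("EnhG", 3000, 3600), ("Quies", 3600, 10_000),
        ]}, vocabulary=["Quies", "EnhA", "Tx", "EnhG", "EnhW", "EnhBiv"])

    def test_adjacent_bins_one_record(self):
        # adjacent equal-label runs are merged on relabel/pooling; classify on
        # the merged segmentation yields one EnhA record
        seg = self._segmentation().relabel({s: s for s in self._segmentation().vocabulary})
        enh = classify_enhancers(seg)
        enha = enh[enh["class"] == "EnhA"]
        assert len(enha) == 1
        assert (enha.iloc[0]["start"], enha.iloc[0]["end"]) == (1000, 1800)

    def test_mark_status_attached(self):
        seg = self._segmentation().relabel({s: s for s in self._segmentation().vocabulary})
        marks = PeakSet("m", pd.DataFrame({"chrom": ["chr1"], "start": [3100], "end": [3200]}))
        enh = classify_enhancers(seg, mark_peaks=marks)
        by_class = enh.set_index("class")["h3k79me2"]
        assert by_class["EnhG"] == "+" and by_class["EnhA"] == "-"

    def test_record_count_matches_per_bin_oracle(self, rng):
        labels = rng.choice(["EnhA", "EnhW", "Quies", "Tx"], size=500)
        seg = Segmentation.from_label_vector({"chr1": labels}, 200,
                                             vocabulary=["EnhA", "EnhW", "Quies", "Tx"])
        enh = classify_enhancers(seg)
        runs = 0
        prev = None
        for lab in labels:
            if lab in ("EnhA", "EnhW") and lab != prev:
                runs += 1
            prev = lab
        assert len(enh) == runs

    def test_no_enhancer_vocabulary_rejected(self):
        seg = Segmentation({"chr1": [("Quies", 0, 100)]}, vocabulary=["Quies"])
        with pytest.raises(ValueError, match="enhancer"):
            classify_enhancers(seg)


class TestLinks:
    def _enh(self):
        return pd.DataFrame({"enhancer_id": ["e1"], "chrom": ["chr1"],
                             "start": [200_000], "end": [201_000], "class": ["EnhA"]})

    def test_nearest_vs_all(self):
        genes = [make_gene("near", "chr1", 251_000, 260_000, "+"),   # 50 kb away
                 make_gene("far", "chr1", 281_000, 290_000, "+")]    # 80 kb away
        nearest = link_enhancer_genes(self._enh(), genes, mode="nearest")
        assert nearest["gene_id"].tolist() == ["near"]
        assert nearest["distance"].tolist() == [50_000]
        both = link_enhancer_genes(self._enh(), genes, mode="all")
        assert sorted(both["gene_id"]) == ["far", "near"]

    def test_100kb_boundary(self):
        genes = [make_gene("in", "chr1", 301_000, 302_000, "+"),       # exactly 100 kb
                 make_gene("out", "chr1", 301_002, 302_002, "-")]
        links = link_enhancer_genes(self._enh(), [genes[0]], mode="all")
        assert links["gene_id"].tolist() == ["in"]
        links = link_enhancer_genes(pd.DataFrame({
            "enhancer_id": ["e1"], "chrom": ["chr1"], "start": [200_000],
            "end": [201_000], "class": ["EnhA"]}), [genes[1]], mode="all")
        assert links.empty

    def test_overlap_distance_zero(self):
        genes = [make_gene("host", "chr1", 199_000, 205_000, "+")]
        links = link_enhancer_genes(self._enh(), genes)
        assert links["distance"].tolist() == [0]

    @pytest.mark.parametrize("mode", ["nearest", "all"])
    def test_matches_brute_force(self, rng, mode):
        genes = []
        pos = 0
        for i in range(50):
            l = int(rng.integers(1000, 5000))
            gap = int(rng.integers(0, 60_000))
            genes.append(make_gene(f"g{i}", "chr1", pos + gap, pos + gap + l, "+"))
            pos += gap + l
        genes_df = gene_table(genes)
        starts = rng.integers(0, pos, size=40)
        enh = pd.DataFrame({"enhancer_id": [f"e{i}" for i in range(40)], "chrom": "chr1",
                            "start": starts, "end": starts + 500, "class": "EnhA"})
        links = link_enhancer_genes(enh, genes_df, mode=mode)
        for e in enh.itertuples():
            dists = {}
            for g in genes_df.itertuples():
                if min(e.end, g.end) > max(e.start, g.start):
                    d = 0
                else:
                    d = min(abs(g.start - e.end) if g.start >= e.end else 10**12,
                            abs(e.start - g.end) if g.end <= e.start else 10**12)
                if d <= 100_000:
                    dists[g.gene_id] = d
            got = links[links["enhancer_id"] == e.enhancer_id]
            if mode == "all":
                assert dict(zip(got["gene_id"], got["distance"])) == dists
            elif dists:
                dmin = min(dists.values())
                assert set(got["gene_id"]) == {g for g, d in dists.items() if d == dmin}
            else:
                assert got.empty


class TestEnhancerExpression:
    def _frame(self, n=40, rng=None):
        rng = rng or np.random.default_rng(0)
        enh = pd.DataFrame({
            "enhancer_id": [f"e{i}" for i in range(n)],
            "class": "EnhA",
            "h3k79me2": ["+"] * (n // 2) + ["-"] * (n - n // 2),
        })
        links = pd.DataFrame({"enhancer_id": enh["enhancer_id"],
                              "gene_id": [f"g{i}" for i in range(n)]})
        return enh, links

    def test_identical_expression_p_one(self):
        enh, links = self._frame()
        expr = pd.Series(5.0, index=links["gene_id"])
        out = enhancer_expression(enh, links, expr)
        assert out.loc[0, "mean_cpm_plus"] == out.loc[0, "mean_cpm_minus"] == 5.0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_single_gene_link_mean_is_gene_cpm(self):
        enh, links = self._frame(n=4)
        expr = pd.Series([1.0, 2.0, 3.0, 4.0], index=links["gene_id"])
        out = enhancer_expression(enh, links, expr)
        per = out.attrs["per_enhancer"].set_index("enhancer_id")["mean_cpm"]
        assert per.tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_planted_doubling_detected(self):
        rng = np.random.default_rng(5)
        n = 400
        enh, links = self._frame(n=n, rng=rng)
        expr_plus = rng.gamma(4, 2.0, size=n // 2)
        expr_minus = rng.gamma(4, 1.0, size=n - n // 2)
        expr = pd.Series(np.concatenate([expr_plus, expr_minus]), index=links["gene_id"])
        out = enhancer_expression(enh, links, expr)
        assert out.loc[0, "mean_cpm_plus"] > out.loc[0, "mean_cpm_minus"]
        assert out.loc[0, "p"] < 0.05

    def test_small_group_missing_p(self):
        enh, links = self._frame(n=3)
        enh["h3k79me2"] = ["+", "-", "-"]
        expr = pd.Series([1.0, 2.0, 3.0], index=links["gene_id"])
        out = enhancer_expression(enh, links, expr)
        assert np.isnan(out.loc[0, "p"])


class TestGeneCategories:
    def _setup(self):
        genes = [make_gene("gb_only", "chr1", 0, 10_000, "+"),
                 make_gene("enh_only", "chr1", 50_000, 60_000, "+"),
                 make_gene("both", "chr1", 100_000, 110_000, "+"),
                 make_gene("none", "chr1", 150_000, 160_000, "+")]
        marks = PeakSet("m", pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [5000, 105_000, 70_000],
            "end": [6000, 106_000, 71_000],
        }))
        enh = pd.DataFrame({"enhancer_id": ["e1", "e2"], "chrom": ["chr1"] * 2,
                            "start": [70_000, 170_000], "end": [71_000, 171_000],
                            "class": ["EnhA", "EnhA"], "h3k79me2": ["+", "-"]})
        links = pd.DataFrame({"enhancer_id": ["e1", "e1", "e2"],
                              "gene_id": ["enh_only", "both", "none"],
                              "distance": [10_000, 20_000, 9_000]})
        return genes, marks, enh, links

    def test_examples_and_partition(self):
        genes, marks, enh, links = self._setup()
        cats = h3k79_gene_category(genes, marks, links, enh)
        assert cats.to_dict() == {"gb_only": "GB", "enh_only": "ENH",
                                  "both": "GB-ENH", "none": "none"}

    def test_planted_contrast_detected(self):
        rng = np.random.default_rng(9)
        n = 300
        cats = pd.Series(rng.choice(["GB", "none"], size=n),
                         index=[f"g{i}" for i in range(n)], name="h3k79_category")
        up = pd.Series("not", index=cats.index, name="de_class")
        up[(cats == "none") & (rng.random(n) < 0.8)] = "up"
        res = category_by_class_contrast(cats, up)
        assert res["p"] < 0.01
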