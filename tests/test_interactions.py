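"""Cumulative-binomial calling, anchor annotation, hubs, Fisher differentials, APA."""

import math

import numpy as np
import pandas as pd
import pytest

from heatloop import interactions as ix
from heatloop.core import ContactMatrix, GeneAnnotation, GenomeLayout
from heatloop.synth import SynthConfig, generate_dataset

from conftest import loop_construction, sample_nonloop_pairs


def brute_binomial_tail(k, n, p):
    """Direct log-space summation of the binomial upper tail."""
    if k <= 0:
        return 1.0
    logs = []
    lp, lq = math.log(p), math.log1p(-p)
    for x in range(k, n + 1):
        logs.append(math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
                    + x * lp + (n - x) * lq)
    m = max(logs)
    return math.exp(m) * math.fsum(math.exp(l - m) for l in logs)


class TestBinomialTail:
    @pytest.mark.parametrize("k,n,p", [
        (10, 100, 0.02), (1, 50, 0.5), (500, 2000, 0.2), (1999, 2000, 0.9),
        (3, 2000, 0.001), (40, 1000, 0.02),
    ])
    def test_matches_bruteforce_summation(self, k, n, p):
        got = float(ix.binomial_tail_pvalue(k, n, p))
        want = brute_binomial_tail(k, n, p)
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_count_gives_one(self):
        assert float(ix.binomial_tail_pvalue(0, 100, 0.3)) == 1.0


class TestCallInteractions:
    def test_recovers_planted_loops(self):
        recalls, precisions = [], []
        for seed in (1, 2):
            ds = loop_construction(seed)
            cm = ds.contacts[("CHiC", "1h")]
            loops = [(l.chrom, min(l.bin1, l.bin2), max(l.bin1, l.bin2))
                     for l in ds.truth.loops]
            cands = loops + sample_nonloop_pairs(ds, 200, seed + 1000)
            called = ix.call_interactions(cm, candidates=cands, correction="BH")
            got = {(r["chrom"], r["bin1"], r["bin2"]) for _, r in called.iterrows()}
            tp = len(got & set(loops))
            recalls.append(tp / len(loops))
            precisions.append(tp / max(len(got), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.8

    def test_order_invariant_and_deterministic(self):
        ds = loop_construction(3)
        cm = ds.contacts[("CHiC", "1h")]
        a = ix.call_interactions(cm, 2, 60, correction="BH", return_all=True)
        b = ix.call_interactions(cm, 2, 60, correction="BH", return_all=True)
        pd.testing.assert_frame_equal(a, b)

    def test_balanced_input_rejected(self, tiny_layout):
        n = tiny_layout.n_bins("c1")
        cm = ContactMatrix(tiny_layout, {"c1": np.ones((n, n))}, balanced=True)
        with pytest.raises(ValueError):
            ix.call_interactions(cm)

    def test_empty_matrix_rejected(self, tiny_layout):
        n = tiny_layout.n_bins("c1")
        cm = ContactMatrix(tiny_layout, {"c1": np.zeros((n, n))})
        with pytest.raises(ValueError, match="N = 0"):
            ix.call_interactions(cm)


def annotated(df_rows):
    return pd.DataFrame(df_rows, columns=["chrom", "bin1", "bin2", "start1", "end1",
                                          "start2", "end2", "count"])


class TestAnnotateAnchors:
    @pytest.fixture()
    def genes(self):
        return GeneAnnotation(pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["c1"], "start": [12_000], "end": [14_000],
            "strand": ["+"]}))

    def test_self_loops_removed(self, genes):
        ints = annotated([("c1", 1, 1, 10_000, 20_000, 10_000, 20_000, 5)])
        assert len(ix.annotate_anchors(ints, genes)) == 0

    def test_duplicates_collapsed(self, genes):
        ints = annotated([
            ("c1", 1, 5, 10_000, 20_000, 50_000, 60_000, 5),
            ("c1", 5, 1, 50_000, 60_000, 10_000, 20_000, 5),
        ])
        ints.loc[1, ["bin1", "bin2"]] = [1, 5]  # unordered duplicate, same key
        out = ix.annotate_anchors(ints, genes)
        assert len(out) == 1

    def test_no_gene_annotation_removed(self, genes):
        ints = annotated([("c1", 30, 40, 300_000, 310_000, 400_000, 410_000, 5)])
        assert len(ix.annotate_anchors(ints, genes)) == 0

    def test_promoter_and_re_labels(self, genes):
        peaks = pd.DataFrame({"chrom": ["c1"], "start": [51_000], "end": [51_400],
                              "class": ["distal"]})
        ints = annotated([("c1", 1, 5, 10_000, 20_000, 50_000, 60_000, 5)])
        out = ix.annotate_anchors(ints, genes, peaks)
        assert out.loc[0, "anchor1_class"] == "promoter"
        assert out.loc[0, "anchor2_class"] == "RE"
        assert out.loc[0, "genes1"] == ["g1"]

    def test_require_both_flag(self, genes):
        ints = annotated([("c1", 1, 5, 10_000, 20_000, 50_000, 60_000, 5)])
        assert len(ix.annotate_anchors(ints, genes, require_both=False)) == 1
        assert len(ix.annotate_anchors(ints, genes, require_both=True)) == 0


class TestStrata:
    def test_counting_overlaps(self):
        ints = annotated([("c1", 1, 5, 10_000, 20_000, 50_000, 60_000, 5)])
        oe = {"c1": np.full((10, 10), 2.0)}
        peaks2 = pd.DataFrame({"chrom": ["c1", "c1"], "start": [11_000, 52_000],
                               "end": [11_500, 52_500]})
        out, _ = ix.accessibility_strata(ints, peaks2, oe)
        assert out.loc[0, "acc_category"] == 2
        out0, _ = ix.accessibility_strata(ints, peaks2.iloc[:0], oe)
        assert out0.loc[0, "acc_category"] == 0
        assert out.loc[0, "strength"] == 2.0

    def test_coupled_strength_ordering(self):
        from scipy.stats import mannwhitneyu
        from heatloop.compartments import oe_by_chrom

        p21, p10 = [], []
        for seed in (1, 2, 3):
            cfg = SynthConfig(loop_categories=((12, 1.5, 0), (12, 2.5, 1), (12, 4.0, 2)),
                              n_gained_loops=0, n_stable_loops=0,
                              contact_assays=(("CHiC", "0h"),),
                              generate_sequences=False, generate_fine_tracks=False)
            ds = generate_dataset(cfg, seed=seed)
            oe = oe_by_chrom(ds.contacts[("CHiC", "0h")])
            bs = ds.layout.bin_size
            ints = pd.DataFrame([
                {"chrom": l.chrom, "bin1": min(l.bin1, l.bin2), "bin2": max(l.bin1, l.bin2),
                 "start1": min(l.bin1, l.bin2) * bs, "end1": (min(l.bin1, l.bin2) + 1) * bs,
                 "start2": max(l.bin1, l.bin2) * bs, "end2": (max(l.bin1, l.bin2) + 1) * bs}
                for l in ds.truth.loops])
            acc = ds.peaks[ds.peaks["accessible_0h"]]
            out, _ = ix.accessibility_strata(ints, acc, oe)
            g = [out.loc[out["acc_category"] == c, "strength"] for c in (0, 1, 2)]
            assert g[0].mean() < g[1].mean() < g[2].mean()
            p21.append(mannwhitneyu(g[2], g[1], alternative="greater").pvalue)
            p10.append(mannwhitneyu(g[1], g[0], alternative="greater").pvalue)
        assert np.median(p21) < 0.01 and np.median(p10) < 0.01


class TestHubs:
    def hub_input(self, rows):
        df = annotated([r[:8] for r in rows])
        df["anchor1_class"] = [r[8] for r in rows]
        df["anchor2_class"] = [r[9] for r in rows]
        return df

    def test_promoter_centric_hub(self):
        ints = self.hub_input([
            ("c1", 1, 5, 0, 1, 0, 1, 1, "promoter", "RE"),
            ("c1", 1, 9, 0, 1, 0, 1, 1, "promoter", "RE"),
        ])
        rep = ix.detect_hubs(ints)
        assert ("c1", 1) in rep.promoter_hubs
        assert len(rep.promoter_hubs[("c1", 1)]) == 2
        assert not rep.re_hubs

    def test_re_centric_hub(self):
        ints = self.hub_input([
            ("c1", 3, 10, 0, 1, 0, 1, 1, "RE", "promoter"),
            ("c1", 3, 14, 0, 1, 0, 1, 1, "RE", "promoter"),
            ("c1", 3, 18, 0, 1, 0, 1, 1, "RE", "promoter"),
        ])
        rep = ix.detect_hubs(ints)
        assert len(rep.re_hubs[("c1", 3)]) == 3

    def test_single_edge_no_hub(self):
        ints = self.hub_input([("c1", 1, 5, 0, 1, 0, 1, 1, "promoter", "RE")])
        rep = ix.detect_hubs(ints)
        assert not rep.promoter_hubs and not rep.re_hubs


def brute_fisher_two_sided(table):
    """Exhaustive hypergeometric enumeration in log space."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logpmf(x):
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - c1 + x + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = logpmf(a)
    terms = [logpmf(x) for x in range(lo, hi + 1) if logpmf(x) <= obs + 1e-12]
    m = max(terms)
    return math.exp(m) * math.fsum(math.exp(t - m) for t in terms)


class TestDifferential:
    def mk(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count"])

    def test_identical_margins_no_call(self):
        a = self.mk([("c1", 1, 5, 20)])
        b = self.mk([("c1", 1, 5, 20)])
        out = ix.differential_interactions(a, b, 1e6, 1e6)
        assert out.loc[0, "pvalue"] == pytest.approx(1.0)
        assert out.loc[0, "direction"] == "ns"

    def test_fisher_matches_hypergeometric_enumeration(self):
        a = self.mk([("c1", 1, 5, 2)])
        b = self.mk([("c1", 1, 5, 20)])
        out = ix.differential_interactions(a, b, 1_000_000, 1_000_000)
        want = brute_fisher_two_sided([[20, 1_000_000 - 20], [2, 1_000_000 - 2]])
        assert out.loc[0, "pvalue"] == pytest.approx(want, rel=1e-10)

    def test_group_swap_symmetry(self):
        a = self.mk([("c1", 1, 5, 2)])
        b = self.mk([("c1", 1, 5, 40)])
        fwd = ix.differential_interactions(a, b, 1e6, 1e6)
        rev = ix.differential_interactions(b, a, 1e6, 1e6)
        assert fwd.loc[0, "pvalue"] == pytest.approx(rev.loc[0, "pvalue"], rel=1e-12)
        assert {fwd.loc[0, "direction"], rev.loc[0, "direction"]} == {"gained", "lost"}

    def test_zero_library_size_rejected(self):
        a = self.mk([("c1", 1, 5, 2)])
        with pytest.raises(ValueError):
            ix.differential_interactions(a, a, 0, 1e6)

    def test_planted_heat_gained_loops_recovered(self, preset_ds):
        ds = preset_ds
        cm0 = ds.contacts[("CHiC", "0h")]
        cm1 = ds.contacts[("CHiC", "1h")]
        c0 = ix.call_interactions(cm0, 2, 100, correction="BH")
        c1 = ix.call_interactions(cm1, 2, 100, correction="BH")
        out = ix.differential_interactions(c0, c1, cm0.total_pairs(), cm1.total_pairs(),
                                           cm_a=cm0, cm_b=cm1)
        dirs = {(r["chrom"], r["bin1"], r["bin2"]): r["direction"]
                for _, r in out.iterrows()}
        key = lambda l: (l.chrom, min(l.bin1, l.bin2), max(l.bin1, l.bin2))
        gained = sum(dirs.get(key(l)) == "gained" for l in ds.truth.loops if l.hsfa1a)
        false_lost = sum(dirs.get(key(l)) == "lost" for l in ds.truth.loops if not l.hsfa1a)
        assert gained >= 8
        assert false_lost == 0


class TestAPA:
    def test_all_ones_oe_scores_one(self, tiny_layout):
        n = tiny_layout.n_bins("c1")
        oe = {"c1": np.ones((n, n))}
        cm = ContactMatrix(tiny_layout, {"c1": np.ones((n, n))})
        res = ix.apa(cm, [("c1", 20, 50)], oe_maps=oe)
        assert res.score == pytest.approx(1.0)
        np.testing.assert_allclose(res.matrix, 1.0)

    def test_edge_and_short_loops_excluded(self, tiny_layout):
        n = tiny_layout.n_bins("c1")
        oe = {"c1": np.ones((n, n))}
        cm = ContactMatrix(tiny_layout, {"c1": np.ones((n, n))})
        res = ix.apa(cm, [("c1", 2, 50), ("c1", 20, 25), ("c1", 20, 50)], oe_maps=oe)
        assert res.n_loops == 1 and res.n_excluded == 2
        with pytest.raises(ValueError):
            ix.apa(cm, [("c1", 2, 50)], oe_maps=oe)

    def test_center_score_recovers_planted_fold(self):
        scores, nulls = [], []
        for seed in (1, 2, 3, 4, 5):
            cfg = SynthConfig(amplitude=0.0, n_gained_loops=0, n_stable_loops=12,
                              stable_fold=3.0, aa_boost=1.0, bb_damp=1.0,
                              contact_assays=(("HiC", "0h"),),
                              generate_sequences=False, generate_fine_tracks=False)
            ds = generate_dataset(cfg, seed=seed)
            cm = ds.contacts[("HiC", "0h")]
            loops = [(l.chrom, l.bin1, l.bin2) for l in ds.truth.loops]
            scores.append(ix.apa(cm, loops).score)
            nulls.append(ix.apa(cm, sample_nonloop_pairs(ds, 20, seed + 50,
                                                         min_d=13, max_d=80)).score)
        assert np.mean(scores) == pytest.approx(3.0, abs=0.3)
        assert np.mean(nulls) == pytest.approx(1.0, abs=0.15)

    def test_heat_strengthened_loops_score_higher_at_1h(self, preset_ds):
        ds = preset_ds
        gained = [(l.chrom, l.bin1, l.bin2) for l in ds.truth.loops if l.hsfa1a]
        s1 = ix.apa(ds.contacts[("HiC", "1h")], gained).score
        s0 = ix.apa(ds.contacts[("HiC", "0h")], gained).score
        assert s1 > s0
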