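import numpy as np
import pytest
from scipy.special import comb

from diffenh.annotation import Gene, GenomeAnnotation
from diffenh.calls import EnhancerCall
from diffenh.linking import (
    ChiaPetPair,
    chiapet_link,
    fisher_association,
    nearest_tss_link,
    tss_pair_events,
    tss_rnapii_enrichment,
)


def make_ann(genes, sizes=None):
    gd = {g[0]: Gene(id=g[0], chrom=g[1], strand=g[2], start=g[3], end=g[4],
                     tss=list(g[5])) for g in genes}
    chroms = {g.chrom for g in gd.values()}
    return GenomeAnnotation(chrom_sizes=sizes or {c: 10_000_000 for c in chroms},
                            genes=gd, transcripts={})


def call(chrom, start, end, cls="active", context="intergenic", host=""):
    return EnhancerCall(chrom=chrom, start=start, end=end, cls=cls,
                        context=context, host_gene=host)


class TestNearestTss:
    def test_distance_band_example(self):
        """Call [10000,12000) with TSSs at 9000/20000 links at 1000 -> filtered."""
        ann = make_ann([("g1", "c", "+", 8_000, 9_500, [9_000]),
                        ("g2", "c", "+", 20_000, 30_000, [20_000])])
        links = nearest_tss_link([call("c", 10_000, 12_000)], ann)
        assert len(links) == 0  # 1000 < d_min
        links2 = nearest_tss_link([call("c", 10_000, 12_000)], ann, d_min=500)
        assert links2.iloc[0]["gene_id"] == "g1"
        assert links2.iloc[0]["distance"] == 1_000

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 900_000))
            tss = sorted(int(t) for t in rng.integers(s, s + 5_000, rng.integers(1, 4)))
            genes.append((f"g{i:02d}", "c", "+", s, s + 6_000, tss))
        ann = make_ann(genes)
        calls = [call("c", int(s), int(s) + int(rng.integers(500, 4_000)))
                 for s in rng.integers(0, 900_000, 250)]
        got = nearest_tss_link(calls, ann)
        # brute force over every (call, tss) pair
        for i, c in enumerate(calls):
            best = None
            for gid, _, _, _, _, tsss in genes:
                for t in tsss:
                    d = 0 if c.start <= t < c.end else (
                        c.start - t if t < c.start else t - c.end)
                    if best is None or (d, gid) < best[:2]:
                        best = (d, gid, t)
            row = got[got["call_index"] == i]
            if 2_000 <= best[0] <= 100_000:
                assert len(row) == 1
                assert row.iloc[0]["gene_id"] == best[1]
                assert row.iloc[0]["distance"] == best[0]
            else:
                assert len(row) == 0


class TestChiaPet:
    def ann(self):
        return make_ann([("g", "c", "+", 50_000, 80_000, [50_000])])

    def pairs(self, n, enh=(10_000, 12_000), tss=50_000):
        return [ChiaPetPair("c", enh[0] + 100, enh[0] + 300,
                            "c", tss - 500 + i, tss - 300 + i) for i in range(n)]

    def test_min_pairs_threshold(self):
        c = [call("c", 10_000, 12_000)]
        assert len(chiapet_link(c, self.pairs(3), self.ann())) == 1
        assert len(chiapet_link(c, self.pairs(2), self.ann())) == 0

    def test_both_anchors_on_enhancer_not_counted(self):
        c = [call("c", 10_000, 12_000)]
        pairs = [ChiaPetPair("c", 10_100, 10_300, "c", 11_000, 11_200)] * 5
        assert len(chiapet_link(c, pairs, self.ann())) == 0

    def test_monotone_in_min_pairs(self):
        rng = np.random.default_rng(0)
        calls = [call("c", int(s), int(s) + 2_000) for s in rng.integers(0, 40_000, 5)]
        pairs = []
        for c in calls:
            for _ in range(int(rng.integers(1, 7))):
                pairs.append(ChiaPetPair("c", c.start, c.start + 200,
                                         "c", 49_500, 49_800))
        ann = self.ann()
        prev = None
        for t in range(1, 8):
            links = chiapet_link(calls, pairs, ann, min_pairs=t)
            cur = set(map(tuple, links[["call_index", "gene_id"]].to_numpy()))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestTssPairEvents:
    def ann(self):
        return make_ann([
            ("far", "c", "+", 100_000, 200_000, [100_000, 125_000]),
            ("near", "c", "+", 300_000, 400_000, [300_000, 315_000]),
        ])

    def test_separation_threshold(self):
        evs = tss_pair_events(self.ann(), [])
        assert [e.gene_id for e in evs] == ["far"]  # 25 kb kept, 15 kb dropped

    def test_enhancer_attachment_gap(self):
        # 800 bp from TSS2 -> not attached; 5 kb away -> attached
        close = call("c", 122_200, 124_200, context="intragenic", host="far")
        ok = call("c", 110_000, 112_000, context="intragenic", host="far")
        evs = tss_pair_events(self.ann(), [close, ok])
        ev = [e for e in evs if e.gene_id == "far"][0]
        assert [i for i, _ in ev.enhancers_between] == [1]

    def test_upstream_veto(self):
        upstream = call("c", 45_000, 50_000)  # 50 kb upstream of 'far' TSS1
        evs = tss_pair_events(self.ann(), [upstream])
        assert [e.gene_id for e in evs] == []

    def test_attached_enhancers_strictly_between(self):
        rng = np.random.default_rng(1)
        calls = [call("c", int(s), int(s) + 2_000, context="intragenic", host="far")
                 for s in rng.integers(95_000, 130_000, 40)]
        evs = tss_pair_events(self.ann(), calls)
        for ev in evs:
            lo, hi = sorted((ev.tss_upstream, ev.tss_downstream))
            for i, _ in ev.enhancers_between:
                assert lo < calls[i].start and calls[i].end <= hi


def test_rnapii_grouping_orders_medians():
    ann = make_ann([(f"g{i}", "c", "+", i * 100_000, i * 100_000 + 60_000,
                     [i * 100_000, i * 100_000 + 30_000]) for i in range(30)])
    calls, z_at = [], {}
    rng = np.random.default_rng(2)
    for i, g in enumerate(sorted(ann.genes)):
        t1, t2 = ann.genes[g].tss
        base = float(rng.normal(0, 0.3))
        if i % 3 == 0:  # planted active enhancer between, +2 z at both TSSs
            calls.append(call("c", t1 + 5_000, t1 + 7_000, "active",
                              "intragenic", g))
            z_at[t1], z_at[t2] = base + 2, base + 2
        elif i % 3 == 1:  # silent between, -2
            calls.append(call("c", t1 + 5_000, t1 + 7_000, "silent",
                              "intragenic", g))
            z_at[t1], z_at[t2] = base - 2, base - 2
        else:
            z_at[t1], z_at[t2] = base, base
    evs = tss_pair_events(ann, calls)
    grouped = tss_rnapii_enrichment(evs, z_at)
    med = grouped.groupby("group")["z"].median()
    assert med["active"] > med["all"] > med["silent"]


def test_rnapii_missing_tss_skipped():
    ann = make_ann([("g", "c", "+", 0, 60_000, [0, 30_000])])
    evs = tss_pair_events(ann, [])
    out = tss_rnapii_enrichment(evs, {0: 1.0})  # TSS2 window missing
    assert len(out) == 0


class TestFisher:
    @staticmethod
    def brute_force_p(a, b, c, d):
        """Two-sided Fisher by exhaustive hypergeometric summation."""
        n, r1, c1 = a + b + c + d, a + b, a + c
        def prob(x):
            return (comb(r1, x, exact=True) * comb(n - r1, c1 - x, exact=True)
                    / comb(n, c1, exact=True))
        p_obs = prob(a)
        return sum(prob(x) for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
                   if prob(x) <= p_obs * (1 + 1e-12))

    def test_matches_hypergeometric_oracle(self):
        odds, p = fisher_association(10, 100, 1, 100)
        assert p == pytest.approx(self.brute_force_p(10, 90, 1, 99), rel=1e-9)
        assert odds == pytest.approx((10 / 90) / (1 / 99))

    def test_identical_proportions(self):
        _, p = fisher_association(5, 100, 5, 100)
        assert p == pytest.approx(1.0)

    def test_row_swap_inverts_odds(self):
        o1, p1 = fisher_association(10, 100, 3, 100)
        o2, p2 = fisher_association(3, 100, 10, 100)
        assert o1 == pytest.approx(1 / o2)
        assert p1 == pytest.approx(p2)

    def test_zero_margin(self):
        odds, p = fisher_association(0, 0, 5, 100)
        assert np.isnan(odds) and p == 1.0

    def test_counts_exceed_totals(self):
        with pytest.raises(ValueError):
            fisher_association(10, 5, 0, 10)


def test_tss_windows_centered_and_keyed():
    from diffenh.linking import tss_windows

    ann = make_ann([("g1", "c", "+", 100_000, 160_000, [100_000, 130_000]),
                    ("g2", "c", "-", 300_000, 360_000, [359_999])])
    ws, keys = tss_windows(ann)
    assert len(ws) == 3 and len(keys) == 3
    for (chrom, t), row in zip(keys, ws.df.itertuples()):
        assert row.chrom == chrom
        assert row.start <= t < row.end
        assert row.end - row.start == 1500
        assert abs((row.start + row.end) // 2 - t) <= 1
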