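"""Link enhancer calls to genes and analyse alternative-TSS usage.

Enhancers are assigned to genes either by the globally nearest TSS (kept in
a 2-100 kb distance band) or by requiring at least 3 chromatin-interaction
(ChIA-PET) pairs connecting the call to a 1 kb zone around a TSS of the
gene.  Consecutive TSS pairs per gene define alternative-transcription
events; enhancers strictly between a pair (and >= 1 kb from each TSS) are
attached, and events in genes with an intergenic call within 100 kb
upstream are vetoed.  Distances are edge gaps: 0 when the point lies inside
the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .calls import EnhancerCall
from .windows import INTERGENIC

__all__ = [
    "ChiaPetPair",
    "TssPairEvent",
    "read_bedpe",
    "nearest_tss_link",
    "chiapet_link",
    "tss_pair_events",
    "tss_rnapii_enrichment",
    "fisher_association",
]


@dataclass
class ChiaPetPair:
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    support: int = 1


@dataclass
class TssPairEvent:
    gene_id: str
    tss_upstream: int
    tss_downstream: int
    distance: int
    #: (call index, class) for enhancers strictly between the TSS pair
    enhancers_between: list = field(default_factory=list)
    rank: int = 1  # 1 = TSS1-TSS2, 2 = TSS2-TSS3, ...


def read_bedpe(path: str | Path) -> list[ChiaPetPair]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(6),
                     names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
                     dtype={"chrom1": str, "chrom2": str})
    return [ChiaPetPair(*row) for row in df.itertuples(index=False)]


def _edge_distance(start: int, end: int, point: int) -> int:
    """Gap from interval [start, end) to a point; 0 if the point is inside."""
    if start <= point < end:
        return 0
    return start - point if point < start else point - end


def nearest_tss_link(
    calls: list[EnhancerCall],
    ann: GenomeAnnotation,
    d_min: int = 2000,
    d_max: int = 100000,
) -> pd.DataFrame:
    """Link each call to the gene owning its globally nearest TSS.

    Links are kept iff d_min <= distance <= d_max; the nearest-TSS tie is
    broken toward the smaller gene id.  Returns a DataFrame with columns
    call_index, gene_id, distance, tss.
    """
    per_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in ann.genes.values()}:
        entries = sorted(
            (t, g.id) for g in ann.genes.values() if g.chrom == chrom for t in g.tss
        )
        per_chrom[chrom] = (np.array([t for t, _ in entries]),
                            [gid for _, gid in entries])
    rows = []
    for i, c in enumerate(calls):
        if c.chrom not in per_chrom:
            continue
        tss, gids = per_chrom[c.chrom]
        if len(tss) == 0:
            continue
        lo = np.searchsorted(tss, c.start) - 1
        hi = np.searchsorted(tss, c.end) + 1
        best = None  # (distance, gene_id, tss)
        for j in range(max(lo, 0), min(hi + 1, len(tss))):
            d = _edge_distance(c.start, c.end, int(tss[j]))
            cand = (d, gids[j], int(tss[j]))
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, gid, t = best
        if d_min <= d <= d_max:
            rows.append((i, gid, d, t))
    return pd.DataFrame(rows, columns=["call_index", "gene_id", "distance", "tss"])


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and e1 > s2


def chiapet_link(
    calls: list[EnhancerCall],
    pairs: list[ChiaPetPair],
    ann: GenomeAnnotation,
    min_pairs: int = 3,
    tss_flank: int = 1000,
) -> pd.DataFrame:
    """(call, gene) pairs supported by >= ``min_pairs`` interaction pairs.

    A pair qualifies when one anchor overlaps the call and the other anchor
    overlaps [tss - tss_flank, tss + tss_flank) for any TSS of the gene; a
    pair with both anchors on the enhancer does not count.  Returns columns
    call_index, gene_id, n_pairs.
    """
    tss_zones = []  # (chrom, lo, hi, gene_id)
    for g in ann.genes.values():
        tss_zones.extend((g.chrom, t - tss_flank, t + tss_flank, g.id) for t in g.tss)

    support: dict[tuple[int, str], int] = {}
    for p in pairs:
        anchors = [(p.chrom1, p.start1, p.end1), (p.chrom2, p.start2, p.end2)]
        for enh_anchor, tss_anchor in (anchors, anchors[::-1]):
            for i, c in enumerate(calls):
                if enh_anchor[0] != c.chrom or not _overlaps(
                        enh_anchor[1], enh_anchor[2], c.start, c.end):
                    continue
                # the other anchor must hit a TSS zone, not the enhancer itself
                if tss_anchor[0] == c.chrom and _overlaps(
                        tss_anchor[1], tss_anchor[2], c.start, c.end):
                    continue
                for chrom, lo, hi, gid in tss_zones:
                    if tss_anchor[0] == chrom and _overlaps(tss_anchor[1], tss_anchor[2], lo, hi):
                        support[(i, gid)] = support.get((i, gid), 0) + p.support
                        break
            if anchors[0] == anchors[1]:
                break  # symmetric anchors: avoid double counting
    rows = [(i, gid, n) for (i, gid), n in sorted(support.items()) if n >= min_pairs]
    return pd.DataFrame(rows, columns=["call_index", "gene_id", "n_pairs"])


def tss_pair_events(
    ann: GenomeAnnotation,
    calls: list[EnhancerCall],
    min_sep: int = 20000,
    enh_min_gap: int = 1000,
    upstream_veto: int = 100000,
) -> list[TssPairEvent]:
    """Consecutive-TSS alternative-transcription events with attached enhancers.

    Pairs (TSS1-TSS2, TSS2-TSS3, ...) are kept when separated by more than
    ``min_sep``.  Enhancers are attached when they lie strictly between the
    two TSSs and at edge-gap distance >= ``enh_min_gap`` from each.  Events
    of a gene with any intergenic call within ``upstream_veto`` upstream of
    the gene's first TSS are dropped.
    """
    events: list[TssPairEvent] = []
    for g in ann.genes.values():
        if len(g.tss) < 2:
            continue
        # upstream veto zone relative to strand
        t1 = g.tss[0]
        if g.strand == "+":
            veto_lo, veto_hi = t1 - upstream_veto, t1
        else:
            veto_lo, veto_hi = t1 + 1, t1 + 1 + upstream_veto
        vetoed = any(
            c.context == INTERGENIC and c.chrom == g.chrom
            and _overlaps(c.start, c.end, veto_lo, veto_hi)
            for c in calls
        )
        if vetoed:
            continue
        for rank, (ta, tb) in enumerate(zip(g.tss, g.tss[1:]), start=1):
            sep = abs(tb - ta)
            if sep <= min_sep:
                continue
            lo, hi = min(ta, tb), max(ta, tb)
            between = []
            for i, c in enumerate(calls):
                if c.chrom != g.chrom or c.start <= lo or c.end > hi:
                    continue  # not strictly between
                if (_edge_distance(c.start, c.end, lo) < enh_min_gap
                        or _edge_distance(c.start, c.end, hi) < enh_min_gap):
                    continue
                between.append((i, c.cls))
            events.append(TssPairEvent(
                gene_id=g.id, tss_upstream=ta, tss_downstream=tb,
                distance=sep, enhancers_between=between, rank=rank,
            ))
    return events


def tss_windows(ann: GenomeAnnotation, width: int = 1500):
    """One window of ``width`` centered on every TSS, for the RNAPII analysis.

    Returns a WindowSet (context intragenic, host = owning gene) aligned
    with a list of (chrom, tss) keys so per-window z-scores can be mapped
    back to TSS coordinates.
    """
    import pandas as pd

    from .windows import INTRAGENIC, WindowSet

    rows, keys = [], []
    half = width // 2
    for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.start, g.id)):
        size = ann.chrom_sizes[g.chrom]
        for t in g.tss:
            s = min(max(t - half, 0), size - width)
            rows.append((g.chrom, s, s + width, INTRAGENIC, g.id))
            keys.append((g.chrom, t))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "context", "host_gene"])
    df = df.drop_duplicates(["chrom", "start", "end", "host_gene"])
    keys = [keys[i] for i in df.index]
    # WindowSet sorts rows (stable); pre-sort with the same key so the
    # (chrom, tss) mapping stays aligned row-for-row
    order = df.reset_index(drop=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort").index
    df_sorted = df.reset_index(drop=True).loc[order].reset_index(drop=True)
    keys_sorted = [keys[i] for i in order]
    return WindowSet(df_sorted, {"width": width}), keys_sorted


def tss_rnapii_enrichment(
    events: list[TssPairEvent],
    rnapii_z_at_tss: dict[int, float] | dict[tuple[str, int], float],
    ann: GenomeAnnotation | None = None,
) -> pd.DataFrame:
    """Group per-event RNAPII z at the upstream/downstream TSS by enhancer class.

    ``rnapii_z_at_tss`` maps a TSS coordinate (or (chrom, coordinate)) to the
    z-score of a window centered on it.  Every event contributes to the
    ``all`` background group; events with an active (resp. silent) enhancer
    between the TSSs also contribute to the ``active`` (``silent``) group.
    Events whose TSSs have no computed window are skipped.
    """
    chrom_of = {}
    if ann is not None:
        for g in ann.genes.values():
            chrom_of[g.id] = g.chrom

    def lookup(gene_id, t):
        if t in rnapii_z_at_tss:
            return rnapii_z_at_tss[t]
        key = (chrom_of.get(gene_id), t)
        return rnapii_z_at_tss.get(key)

    rows = []
    for ev in events:
        z_up = lookup(ev.gene_id, ev.tss_upstream)
        z_dn = lookup(ev.gene_id, ev.tss_downstream)
        if z_up is None or z_dn is None:
            continue
        groups = ["all"]
        classes = {cls for _, cls in ev.enhancers_between}
        groups.extend(sorted(classes))
        for grp in groups:
            rows.append((ev.gene_id, grp, "upstream", z_up))
            rows.append((ev.gene_id, grp, "downstream", z_dn))
    return pd.DataFrame(rows, columns=["gene_id", "group", "tss", "z"])


def fisher_association(
    genes_with_enh_regulated: int,
    genes_with_enh_total: int,
    genes_without_enh_regulated: int,
    genes_without_enh_total: int,
):
    """Two-sided Fisher exact test of regulation vs enhancer presence.

    Returns (odds_ratio, p_value).  A zero-margin table yields
    (nan, 1.0).
    """
    a = genes_with_enh_regulated
    b = genes_with_enh_total - a
    c = genes_without_enh_regulated
    d = genes_without_enh_total - c
    if min(a, b, c, d) < 0:
        raise ValueError("group counts exceed totals")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
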