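"""Genome-wide sliding-window grids and randomized-position controls.

Windows are fixed-width (default 1500 bp) intervals placed every ``shift``
(default 500 bp) along each chromosome, so neighbouring windows overlap by
design.  Two grids are built: an *intergenic* grid that avoids gene bodies
and TSS-proximal zones, and an *intragenic* grid confined to gene bodies,
starting downstream of the first TSS and skipping flanks around internal
alternative TSSs.

Distance from a TSS ``t`` to a window ``[s, e)`` is the edge gap: 0 if
``s <= t < e``, else ``s - t`` when the TSS is left of the window and
``t - e`` when it is right of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

__all__ = [
    "WindowSet",
    "generate_intergenic_windows",
    "generate_intragenic_windows",
    "drop_signalless_windows",
    "randomize_positions",
]

INTERGENIC = "intergenic"
INTRAGENIC = "intragenic"

_COLUMNS = ["chrom", "start", "end", "context", "host_gene"]


@dataclass
class WindowSet:
    """An ordered, duplicate-free set of genomic windows.

    ``df`` has columns chrom, start, end, context, host_gene and is sorted
    by (chrom, start, end).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.loc[:, _COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "start", "end", "context", "host_gene"]).any():
            raise ValueError("duplicate windows")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def to_bed(self, path: str | Path, track_line: str | None = None) -> None:
        out = self.df.copy()
        name = out["context"].str.cat(out["host_gene"].fillna(""), sep=":")
        bed = pd.DataFrame(
            {
                "chrom": out["chrom"],
                "start": out["start"],
                "end": out["end"],
                "name": name,
                "score": 0,
                "strand": ".",
            }
        )
        with open(path, "w") as fh:
            if track_line:
                fh.write(track_line.rstrip("\n") + "\n")
            bed.to_csv(fh, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, provenance: dict | None = None) -> "WindowSet":
        with open(path) as fh:
            first = fh.readline()
        skip = 1 if first.startswith(("track", "browser", "#")) else 0
        rows = pd.read_csv(
            path, sep="\t", header=None, skiprows=skip,
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6), dtype={"chrom": str},
        )
        split = rows["name"].astype(str).str.split(":", n=1, expand=True)
        rows["context"] = split[0]
        rows["host_gene"] = split[1].fillna("") if split.shape[1] > 1 else ""
        return cls(rows[_COLUMNS], provenance or {})


def _grid_starts(chrom_len: int, window_len: int, shift: int) -> np.ndarray:
    """Starts 0, shift, 2*shift, ... with start + window_len <= chrom_len."""
    if chrom_len < window_len:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, chrom_len - window_len + 1, shift, dtype=np.int64)


def _tss_edge_distance(starts: np.ndarray, ends: np.ndarray, tss_sorted: np.ndarray) -> np.ndarray:
    """Edge-gap distance from each window to its nearest TSS (0 if inside)."""
    if len(tss_sorted) == 0:
        return np.full(len(starts), np.inf)
    idx = np.searchsorted(tss_sorted, starts)
    # candidate TSSs: nearest at or left of start, and the following ones
    dist = np.full(len(starts), np.inf)
    for off in (-1, 0, 1):
        j = np.clip(idx + off, 0, len(tss_sorted) - 1)
        t = tss_sorted[j]
        inside = (starts <= t) & (t < ends)
        d = np.where(inside, 0, np.where(t < starts, starts - t, t - ends))
        dist = np.minimum(dist, d)
    return dist


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps_any(starts: np.ndarray, ends: np.ndarray, merged: list[tuple[int, int]]) -> np.ndarray:
    """Boolean mask: window overlaps one of the merged, sorted intervals."""
    if not merged:
        return np.zeros(len(starts), dtype=bool)
    ms = np.array([s for s, _ in merged])
    me = np.array([e for _, e in merged])
    # interval i overlaps window iff ms[i] < end and me[i] > start
    j = np.searchsorted(me, starts, side="right")  # first interval with me > start
    mask = np.zeros(len(starts), dtype=bool)
    ok = j < len(ms)
    mask[ok] = ms[j[ok]] < ends[ok]
    return mask


def generate_intergenic_windows(
    ann: GenomeAnnotation,
    window_len: int = 1500,
    shift: int = 500,
    tss_excl: int = 500,
) -> WindowSet:
    """Sliding windows outside gene bodies and >= ``tss_excl`` from every TSS.

    Windows start at multiples of ``shift`` per chromosome.  A window is
    discarded if its edge-gap distance to any TSS is < ``tss_excl`` or if it
    overlaps any gene span by >= 1 bp.
    """
    if window_len <= 0 or shift <= 0:
        raise ValueError("window_len and shift must be positive")
    if not ann.genes:
        warnings.warn("empty annotation: all windows retained")

    frames = []
    for chrom, size in ann.chrom_sizes.items():
        starts = _grid_starts(size, window_len, shift)
        if len(starts) == 0:
            continue
        ends = starts + window_len
        tss = np.sort([t for g in ann.genes.values() if g.chrom == chrom for t in g.tss])
        keep = _tss_edge_distance(starts, ends, tss) >= tss_excl
        spans = _merge_intervals([(g.start, g.end) for g in ann.genes.values() if g.chrom == chrom])
        keep &= ~_overlaps_any(starts, ends, spans)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts[keep], "end": ends[keep],
                 "context": INTERGENIC, "host_gene": ""}
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_COLUMNS)
    return WindowSet(df, {"window_len": window_len, "shift": shift, "tss_excl": tss_excl,
                          "context": INTERGENIC})


def generate_intragenic_windows(
    ann: GenomeAnnotation,
    window_len: int = 1500,
    shift: int = 500,
    first_tss_offset: int = 500,
    internal_tss_flank: int = 1000,
) -> WindowSet:
    """Sliding windows inside gene bodies, downstream of the first TSS.

    The first allowed window begins ``first_tss_offset`` downstream of TSS1
    (gene orientation respected) and windows overlapping
    ``[t - internal_tss_flank, t + internal_tss_flank)`` around any internal
    (non-first) TSS ``t`` are removed.  Genes shorter than ``window_len``
    contribute no windows.
    """
    if window_len <= 0 or shift <= 0:
        raise ValueError("window_len and shift must be positive")
    frames = []
    for g in ann.genes.values():
        if g.end - g.start < window_len or not g.tss:
            continue
        t0 = g.tss[0]
        if g.strand == "+":
            first = t0 + first_tss_offset
            starts = np.arange(first, g.end - window_len + 1, shift, dtype=np.int64)
        else:
            # downstream of a minus-strand TSS means decreasing coordinate;
            # windows must end at or before t0 + 1 - first_tss_offset
            last_end = t0 + 1 - first_tss_offset
            ends = np.arange(last_end, g.start + window_len - 1, -shift, dtype=np.int64)
            starts = np.sort(ends - window_len)
        starts = starts[(starts >= g.start) & (starts + window_len <= g.end)]
        if len(starts) == 0:
            continue
        ends = starts + window_len
        internal = g.tss[1:]
        if internal:
            flanks = _merge_intervals(
                [(t - internal_tss_flank, t + internal_tss_flank) for t in internal]
            )
            keep = ~_overlaps_any(starts, ends, flanks)
            starts, ends = starts[keep], ends[keep]
        frames.append(
            pd.DataFrame({"chrom": g.chrom, "start": starts, "end": ends,
                          "context": INTRAGENIC, "host_gene": g.id})
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_COLUMNS)
    return WindowSet(df, {"window_len": window_len, "shift": shift,
                          "first_tss_offset": first_tss_offset,
                          "internal_tss_flank": internal_tss_flank,
                          "context": INTRAGENIC})


def drop_signalless_windows(ws: WindowSet, counts, min_total: int = 1) -> WindowSet:
    """Keep windows whose summed raw count across all ChIP datasets >= ``min_total``.

    ``counts`` is a :class:`~diffenh.signal.CountMatrix` (or a DataFrame of
    raw counts) indexed row-for-row by the windows of ``ws``.
    """
    df = counts.counts if hasattr(counts, "counts") else counts
    if len(df) != len(ws):
        raise ValueError(f"count matrix has {len(df)} rows but window set has {len(ws)}")
    total = np.asarray(df.sum(axis=1))
    keep = total >= min_total
    out = ws.df.loc[keep].reset_index(drop=True)
    prov = dict(ws.provenance, min_total=min_total)
    return WindowSet(out, prov)


def _n_runs(seq: str, min_run: int = 50) -> list[tuple[int, int]]:
    """Intervals of runs of >= ``min_run`` consecutive N/n in ``seq``."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord("N")
    if not arr.any():
        return []
    edges = np.diff(np.concatenate(([0], arr.view(np.int8), [0])))
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def randomize_positions(
    calls,
    ann: GenomeAnnotation,
    context: str,
    seed: int,
    genome=None,
    gene_pad: int = 500,
    internal_tss_flank: int = 1000,
    retry_budget: int = 1000,
    min_n_run: int = 50,
) -> WindowSet:
    """Randomized-position controls conserving count and length multiset.

    Intergenic mode: uniform placements at least ``gene_pad`` from any gene
    span, avoiding assembly gaps (runs of >= ``min_n_run`` N when ``genome``
    is supplied) and previously placed randoms.  Intragenic mode: a random
    location inside the same host gene, avoiding ``internal_tss_flank``
    around internal TSSs and prior randoms.  Deterministic per ``seed``.

    ``calls`` may be a WindowSet, an EnhancerCall list, or a DataFrame with
    chrom/start/end (+ host_gene for intragenic mode).
    """
    df = _as_interval_df(calls)
    if (df.get("context") is not None and len(df) and
            not (df["context"] == context).all()):
        raise ValueError("context does not match the calls' context")
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {}

    if genome is not None and context == INTERGENIC:
        gap_iv = {
            chrom: _n_runs(str(genome[chrom][:]), min_n_run) for chrom in ann.chrom_sizes
            if chrom in _genome_keys(genome)
        }
    else:
        gap_iv = {}
        if genome is None and context == INTERGENIC:
            warnings.warn("no genome supplied: assembly-gap avoidance skipped")

    if context == INTERGENIC:
        forbidden = {
            chrom: _merge_intervals(
                [(g.start - gene_pad, g.end + gene_pad) for g in ann.genes.values() if g.chrom == chrom]
                + gap_iv.get(chrom, [])
            )
            for chrom in ann.chrom_sizes
        }
        chroms = list(ann.chrom_sizes)
        sizes = np.array([ann.chrom_sizes[c] for c in chroms], dtype=float)
        probs = sizes / sizes.sum()

    rows = []
    for rec in df.itertuples(index=False):
        length = rec.end - rec.start
        ok = False
        for _ in range(retry_budget):
            if context == INTERGENIC:
                chrom = chroms[rng.choice(len(chroms), p=probs)]
                hi = ann.chrom_sizes[chrom] - length
                if hi <= 0:
                    continue
                s = int(rng.integers(0, hi + 1))
                bad = forbidden[chrom]
                host = ""
            else:
                g = ann.genes[rec.host_gene]
                chrom = g.chrom
                hi = g.end - length
                if hi < g.start:
                    continue
                s = int(rng.integers(g.start, hi + 1))
                bad = _merge_intervals(
                    [(t - internal_tss_flank, t + internal_tss_flank) for t in g.tss[1:]]
                )
                host = g.id
            e = s + length
            if _hits(s, e, bad) or _hits(s, e, placed.get(chrom, [])):
                continue
            placed.setdefault(chrom, []).append((s, e))
            placed[chrom].sort()
            rows.append((chrom, s, e, context, host))
            ok = True
            break
        if not ok:
            where = rec.host_gene if context == INTRAGENIC else f"{rec.chrom}:{rec.start}-{rec.end}"
            raise RuntimeError(f"could not place random region for {where} "
                               f"within {retry_budget} tries")
    out = pd.DataFrame(rows, columns=_COLUMNS)
    return WindowSet(out, {"randomized_from": len(df), "seed": seed, "context": context})


def _hits(s: int, e: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < ie and e > is_ for is_, ie in intervals)


def _genome_keys(genome) -> set:
    try:
        return set(genome.keys())
    except AttributeError:
        return set()


def _as_interval_df(calls) -> pd.DataFrame:
    if isinstance(calls, WindowSet):
        return calls.df
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
        if "host_gene" not in df:
            df["host_gene"] = ""
        return df
    # list of EnhancerCall-like objects
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "context": [getattr(c, "context", "") for c in calls],
            "host_gene": [getattr(c, "host_gene", "") or "" for c in calls],
        }
    )
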