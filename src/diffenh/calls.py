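"""Merge retained classified windows into enhancer calls and filter by length.

Maximal chains of same-class, same-context windows whose consecutive members
overlap by >= 1 bp are merged into one call spanning their union; abutting
(zero-overlap) windows are not merged.  Calls longer than 5 kb are filtered
out, matching the observed length distribution of validated enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mixture import Classification
from .windows import WindowSet

__all__ = ["EnhancerCall", "merge_windows", "filter_length", "write_calls_bed", "calls_to_frame"]


@dataclass
class EnhancerCall:
    chrom: str
    start: int
    end: int
    cls: str  # active | silent
    context: str  # intergenic | intragenic
    host_gene: str = ""
    n_windows: int = 0
    max_posterior: float = 0.0
    mean_posterior: float = 0.0
    window_ids: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_windows(kept: Classification, ws: WindowSet) -> list[EnhancerCall]:
    """Merge overlapping retained windows of the same class and context.

    ``kept`` indexes rows of ``ws.df`` (its index must be valid row labels of
    the window set, as produced by classifying that window set).
    """
    df = ws.df.loc[kept.df.index].copy()
    df["class"] = kept.df["class"].to_numpy()
    df["posterior"] = kept.df["posterior"].to_numpy()
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")

    calls: list[EnhancerCall] = []
    for (chrom, cls, context, host), sub in df.groupby(
            ["chrom", "class", "context", "host_gene"], sort=True):
        cur = None
        for row in sub.itertuples():
            if cur is not None and row.start < cur.end:
                cur.end = max(cur.end, row.end)
                cur.window_ids.append(row.Index)
                cur.max_posterior = max(cur.max_posterior, row.posterior)
                cur._post_sum += row.posterior
                cur.n_windows += 1
            else:
                if cur is not None:
                    cur.mean_posterior = cur._post_sum / cur.n_windows
                    calls.append(cur)
                cur = EnhancerCall(
                    chrom=chrom, start=int(row.start), end=int(row.end), cls=cls,
                    context=context, host_gene=host, n_windows=1,
                    max_posterior=row.posterior, window_ids=[row.Index],
                )
                cur._post_sum = row.posterior
        if cur is not None:
            cur.mean_posterior = cur._post_sum / cur.n_windows
            calls.append(cur)
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.cls))
    for c in calls:
        del c._post_sum
    return calls


def filter_length(calls: list[EnhancerCall], max_len: int = 5000) -> list[EnhancerCall]:
    """Drop calls strictly longer than ``max_len`` (5 kb default)."""
    kept = [c for c in calls if c.length <= max_len]
    return kept


def calls_to_frame(calls: list[EnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "class": [c.cls for c in calls],
            "context": [c.context for c in calls],
            "host_gene": [c.host_gene for c in calls],
            "n_windows": [c.n_windows for c in calls],
            "max_posterior": [c.max_posterior for c in calls],
            "mean_posterior": [c.mean_posterior for c in calls],
        }
    )


def write_calls_bed(calls: list[EnhancerCall], path: str | Path,
                    track_line: str | None = None) -> None:
    """BED6+2: name = class:context:hostgene, score = round(1000*max_posterior)."""
    with open(path, "w") as fh:
        if track_line:
            fh.write(track_line.rstrip("\n") + "\n")
        for c in calls:
            name = f"{c.cls}:{c.context}:{c.host_gene}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t"
                f"{round(1000 * c.max_posterior)}\t.\t{c.n_windows}\t"
                f"{c.mean_posterior:.4f}\n"
            )
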