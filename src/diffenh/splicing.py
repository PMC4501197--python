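"""Exon-skipping events and percent-spliced-in (PSI) from junction reads.

A cassette event is an exon triple E1-E2-E3 where one transcript of a gene
supports the inclusion junctions J12 (E1-E2) and J23 (E2-E3) and another
transcript of the same gene supports the skipping junction J13 with the
same outer boundaries.  Inclusion of the middle exon is quantified from
junction-spanning reads only:

    PSI = (n12 + n23) / (n12 + n23 + 2 * n13)

and is undefined below a minimum junction coverage (default 20 reads).
Events are called regulated when |dPSI| exceeds 0.1 in at least one
index-paired replicate comparison between the two conditions, and unchanged
when |dPSI| stays below 0.05 in all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

__all__ = [
    "SkippingEvent",
    "extract_skipping_events",
    "compute_psi",
    "psi_table",
    "call_regulated",
    "read_junction_counts",
]

REGULATED, UNCHANGED, AMBIGUOUS = "regulated", "unchanged", "ambiguous"


@dataclass
class SkippingEvent:
    gene_id: str
    chrom: str
    strand: str
    e1: tuple[int, int]
    e2: tuple[int, int]
    e3: tuple[int, int]
    #: junctions as (donor, acceptor) = 0-based half-open intron interval
    j12: tuple[int, int] = field(init=False)
    j23: tuple[int, int] = field(init=False)
    j13: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not (self.e1[1] <= self.e2[0] and self.e2[1] <= self.e3[0]):
            raise ValueError("exon triple not in genomic order")
        self.j12 = (self.e1[1], self.e2[0])
        self.j23 = (self.e2[1], self.e3[0])
        self.j13 = (self.e1[1], self.e3[0])

    @property
    def key(self) -> tuple:
        return (self.chrom, self.j12, self.j23, self.j13)

    @property
    def span(self) -> tuple[int, int]:
        return (self.e1[0], self.e3[1])


def extract_skipping_events(ann: GenomeAnnotation) -> list[SkippingEvent]:
    """Cassette-exon events supported by an inclusion and a skipping isoform.

    Deduplicated by junction triple; events whose genomic span overlaps any
    other extracted event are discarded (both of them), keeping only events
    that do not overlap other alternative-splicing events.
    """
    by_gene_junctions: dict[str, set[tuple[int, int]]] = {}
    for tr in ann.transcripts.values():
        js = {(e1[1], e2[0]) for e1, e2 in zip(tr.exons, tr.exons[1:])}
        by_gene_junctions.setdefault(tr.gene_id, set()).update(js)

    seen: dict[tuple, SkippingEvent] = {}
    for tr in ann.transcripts.values():
        if len(tr.exons) < 3:
            continue
        gene_js = by_gene_junctions[tr.gene_id]
        for e1, e2, e3 in zip(tr.exons, tr.exons[1:], tr.exons[2:]):
            skip_j = (e1[1], e3[0])
            if skip_j not in gene_js:
                continue
            ev = SkippingEvent(gene_id=tr.gene_id, chrom=tr.chrom,
                               strand=tr.strand, e1=e1, e2=e2, e3=e3)
            seen.setdefault(ev.key, ev)

    events = sorted(seen.values(), key=lambda e: (e.chrom, e.span))
    # discard events overlapping any other event (both sides)
    overlapping = set()
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            if b.chrom != a.chrom or b.span[0] >= a.span[1]:
                break
            overlapping.add(a.key)
            overlapping.add(b.key)
    return [e for e in events if e.key not in overlapping]


def compute_psi(n12, n23, n13, min_total: int = 20):
    """PSI = (n12 + n23) / (n12 + n23 + 2*n13); NaN below the read filter.

    Undefined (NaN) when n12 + n23 + n13 < ``min_total`` or when all three
    counts are zero.  Accepts scalars or aligned arrays.
    """
    n12 = np.asarray(n12, dtype=float)
    n23 = np.asarray(n23, dtype=float)
    n13 = np.asarray(n13, dtype=float)
    if (n12 < 0).any() or (n23 < 0).any() or (n13 < 0).any():
        raise ValueError("junction counts must be non-negative")
    total = n12 + n23 + n13
    denom = n12 + n23 + 2 * n13
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where((total >= min_total) & (denom > 0),
                       (n12 + n23) / denom, np.nan)
    return float(psi) if psi.ndim == 0 else psi


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    """Junction TSV: chrom, donor, acceptor (0-based half-open intron) + samples."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index(["chrom", "donor", "acceptor"])


def count_junctions_from_alignments(alignments, sample: str = "sample") -> pd.DataFrame:
    """Thin split-read junction counter over a SAM/BAM file.

    Every N operation in a mapped primary read's CIGAR contributes one count
    to the junction (donor, acceptor) = the skipped reference interval,
    0-based half-open.  Returns a table indexed by (chrom, donor, acceptor)
    with one count column.  Annotated-junction filtering is left to the
    caller (intersect with the junctions of extracted events).
    """
    import pysam

    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    counts: dict[tuple, int] = {}
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        pos = read.reference_start
        for op, length in read.cigartuples or ():
            if op == 3:  # N: skipped region = intron
                key = (read.reference_name, pos, pos + length)
                counts[key] = counts.get(key, 0) + 1
            if op in (0, 2, 3, 7, 8):  # consumes reference
                pos += length
    if own:
        af.close()
    idx = pd.MultiIndex.from_tuples(sorted(counts) or [],
                                    names=["chrom", "donor", "acceptor"])
    return pd.DataFrame({sample: [counts[k] for k in sorted(counts)]}, index=idx)


def psi_table(events: list[SkippingEvent], junctions: pd.DataFrame,
              samples: list[str] | None = None, min_total: int = 20) -> pd.DataFrame:
    """Per-event, per-sample PSI from a junction count table.

    ``junctions`` is indexed by (chrom, donor, acceptor); missing junctions
    count as zero reads.
    """
    samples = samples or list(junctions.columns)
    rows = {}
    for ev in events:
        vals = {}
        for s in samples:
            def cnt(j):
                try:
                    return float(junctions.loc[(ev.chrom, *j), s])
                except KeyError:
                    return 0.0
            vals[s] = compute_psi(cnt(ev.j12), cnt(ev.j23), cnt(ev.j13), min_total)
        rows[ev.key] = vals
    out = pd.DataFrame(list(rows.values()))[samples]
    out.index = pd.Index(list(rows.keys()), tupleize_cols=False, name="event")
    return out


def call_regulated(
    psi: pd.DataFrame,
    cond_a_replicates: list[str],
    cond_b_replicates: list[str],
    reg_threshold: float = 0.1,
    null_threshold: float = 0.05,
) -> pd.Series:
    """Label events regulated / unchanged / ambiguous between two conditions.

    Replicates are paired by index: (a1, b1), (a2, b2), ...  An event is
    regulated iff |dPSI| > ``reg_threshold`` in at least one evaluable
    pairing, unchanged iff |dPSI| < ``null_threshold`` in all evaluable
    pairings, otherwise ambiguous.  Pairings with an undefined PSI are
    skipped; events with no evaluable pairing are dropped.
    """
    pairs = list(zip(cond_a_replicates, cond_b_replicates))
    if not pairs:
        raise ValueError("need at least one replicate per condition")
    labels = {}
    for ev, row in psi.iterrows():
        deltas = [row[a] - row[b] for a, b in pairs
                  if np.isfinite(row[a]) and np.isfinite(row[b])]
        if not deltas:
            continue
        abs_d = np.abs(deltas)
        if (abs_d > reg_threshold).any():
            labels[ev] = REGULATED
        elif (abs_d < null_threshold).all():
            labels[ev] = UNCHANGED
        else:
            labels[ev] = AMBIGUOUS
    return pd.Series(labels, name="label")
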