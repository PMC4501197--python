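"""Genome annotation model: chromosomes, genes, ordered TSS lists, transcripts.

All coordinates are 0-based, half-open internally.  GTF input (1-based,
closed intervals) is converted on read.  A gene's TSS list is deduplicated
and ordered 5'→3' in the gene's own orientation, so ``tss[0]`` is always the
most upstream start site (TSS1) regardless of strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd

__all__ = [
    "Gene",
    "Transcript",
    "GenomeAnnotation",
    "load_annotation",
    "read_chrom_sizes",
]


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    #: TSS coordinates, deduplicated, ordered 5'→3' in gene orientation
    tss: list[int] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    #: sorted, disjoint (start, end) intervals
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (point coordinate of the first base)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1


@dataclass
class GenomeAnnotation:
    chrom_sizes: dict[str, int]
    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.start < 0 or g.end > size:
                raise ValueError(f"gene {g.id} outside chromosome bounds")
            for t in g.tss:
                if not (g.start <= t < g.end):
                    raise ValueError(f"TSS {t} of gene {g.id} outside gene span")
        for tr in self.transcripts.values():
            for (s1, e1), (s2, e2) in zip(tr.exons, tr.exons[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise ValueError(f"exons of transcript {tr.id} not sorted/disjoint")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], usecols=[0, 1])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def load_annotation(gtf_source: str | Path, chrom_sizes: dict[str, int] | str | Path) -> GenomeAnnotation:
    """Parse a GENCODE-style GTF into a :class:`GenomeAnnotation`.

    One TSS per transcript, deduplicated per gene and ordered 5'→3'; each
    gene's span is the union of its transcripts.  A record on a chromosome
    absent from ``chrom_sizes`` is a hard error; a transcript without exons
    is skipped with a warning.
    """
    if not isinstance(chrom_sizes, dict):
        chrom_sizes = read_chrom_sizes(chrom_sizes)

    db = gffutils.create_db(
        str(gtf_source),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    transcripts: dict[str, Transcript] = {}
    exon_lists: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)

    for ex in db.features_of_type("exon"):
        if ex.seqid not in chrom_sizes:
            raise ValueError(
                f"record on unknown chromosome {ex.seqid!r}: "
                f"{ex.seqid}:{ex.start}-{ex.end} ({ex.attributes.get('transcript_id')})"
            )
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes["gene_id"][0]
        # GTF is 1-based closed; convert to 0-based half-open
        exon_lists.setdefault(tid, []).append((ex.start - 1, ex.end))
        meta[tid] = (gid, ex.seqid, ex.strand)

    # transcripts declared but exon-less
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        if tid not in exon_lists:
            warnings.warn(f"transcript {tid} has no exons; skipped")

    genes: dict[str, Gene] = {}
    for tid, exons in exon_lists.items():
        gid, chrom, strand = meta[tid]
        exons = sorted(exons)
        transcripts[tid] = Transcript(id=tid, gene_id=gid, chrom=chrom, strand=strand, exons=exons)
        tr = transcripts[tid]
        g = genes.get(gid)
        if g is None:
            genes[gid] = Gene(id=gid, chrom=chrom, strand=strand, start=tr.start, end=tr.end)
        else:
            g.start = min(g.start, tr.start)
            g.end = max(g.end, tr.end)

    for tr in transcripts.values():
        g = genes[tr.gene_id]
        if tr.tss not in g.tss:
            g.tss.append(tr.tss)
    for g in genes.values():
        g.tss.sort(reverse=(g.strand == "-"))

    ann = GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes, transcripts=transcripts)
    ann.validate()
    return ann


def all_tss(ann: GenomeAnnotation, chrom: str | None = None) -> list[tuple[str, int, str]]:
    """Flat list of (chrom, tss, gene_id), optionally restricted to one chromosome."""
    out = []
    for g in ann.genes.values():
        if chrom is not None and g.chrom != chrom:
            continue
        out.extend((g.chrom, t, g.id) for t in g.tss)
    return out
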