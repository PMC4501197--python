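import numpy as np
import pytest

from diffenh import annotation, signal, simulate, windows

SIM_SEED = 11  # fixed study-condition seed for the shared synthetic dataset


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default synthetic dataset: genome, annotation, windows, counts, z.

    One shared instance per session; ~10 s to build.
    """
    from pyfaidx import Fasta

    out = tmp_path_factory.mktemp("sim")
    fasta, gtf, truth = simulate.make_genome_and_annotation(seed=SIM_SEED, out_dir=out)
    sizes = {"chr1": 10_000_000, "chr2": 10_000_000}
    ann = annotation.load_annotation(gtf, sizes)
    ws = windows.generate_intergenic_windows(ann)
    gc, _ = signal.compute_gc(Fasta(str(fasta)), ws)
    cm = simulate.plant_chip_counts(truth, ws, gc, seed=SIM_SEED + 1)
    keep = np.asarray(cm.counts.sum(axis=1)) >= 1
    ws_sig = windows.drop_signalless_windows(ws, cm)
    cm_sig = signal.CountMatrix(
        counts=cm.counts.loc[keep].reset_index(drop=True),
        samples=cm.samples, gc=cm.gc[keep],
    )
    z, cals = signal.build_enrichment_matrix(cm_sig, "A", "B", seed=SIM_SEED + 2)
    return {
        "dir": out, "fasta": fasta, "gtf": gtf, "truth": truth, "ann": ann,
        "windows": ws, "windows_signal": ws_sig, "counts": cm,
        "counts_signal": cm_sig, "gc": gc, "z": z, "calibrations": cals,
    }


@pytest.fixture()
def three_gene_gtf(tmp_path):
    """Hand-written 3-gene annotation with known TSS structure.

    gA (+): two transcripts sharing a start -> 1 TSS.
    gB (-): transcripts ending at 5000 and 8000 -> TSS order [7999, 4999].
    gC (+): single transcript, one TSS, three exons (no cassette partner).
    """
    lines = []

    def feat(chrom, kind, start1, end1, strand, gene, tx=None):
        attrs = f'gene_id "{gene}";'
        if tx:
            attrs += f' transcript_id "{tx}";'
        lines.append(f"{chrom}\tt\t{kind}\t{start1}\t{end1}\t.\t{strand}\t.\t{attrs}")

    feat("chr1", "exon", 1001, 1200, "+", "gA", "gA.t1")
    feat("chr1", "exon", 1501, 1700, "+", "gA", "gA.t1")
    feat("chr1", "exon", 1001, 1100, "+", "gA", "gA.t2")  # same start as t1
    feat("chr1", "exon", 1801, 2000, "+", "gA", "gA.t2")
    feat("chr1", "exon", 4001, 4200, "-", "gB", "gB.t1")
    feat("chr1", "exon", 4801, 5000, "-", "gB", "gB.t1")  # transcript end 5000
    feat("chr1", "exon", 4001, 4200, "-", "gB", "gB.t2")
    feat("chr1", "exon", 7801, 8000, "-", "gB", "gB.t2")  # transcript end 8000
    feat("chr2", "exon", 101, 200, "+", "gC", "gC.t1")
    feat("chr2", "exon", 301, 400, "+", "gC", "gC.t1")
    feat("chr2", "exon", 501, 600, "+", "gC", "gC.t1")
    path = tmp_path / "three_genes.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path, {"chr1": 20_000, "chr2": 20_000}
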