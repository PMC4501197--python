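"""Self-contained synthetic dataset generator with an exported truth table.

Emulates the data model the predictor consumes: a random genome with a GC
gradient, a multi-gene annotation with alternative TSSs and cassette-exon
isoform pairs, per-window ChIP counts with GC-linked negative-binomial
background and condition-dependent enrichment planted at enhancer loci in
the activation marks, chromatin-interaction (ChIA-PET) pairs supporting
planted enhancer-gene links, and junction read counts with planted
inclusion-level (PSI) differences.  Everything is deterministic per seed.

The generator does not emulate read-level sequence errors, mappability or
copy-number structure of real genomes; see the methods note for what
passing recovery tests does and does not show about real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import DEFAULT_PREDICTOR_PRESET
from .signal import CountMatrix, ma_transform
from .windows import INTERGENIC, WindowSet

__all__ = [
    "TruthTable",
    "make_genome_and_annotation",
    "plant_chip_counts",
    "plant_chiapet_and_junctions",
    "make_mixture_seed",
    "make_selection_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthTable:
    """Planted ground truth for every pipeline stage."""

    params: dict
    genes: pd.DataFrame  # id, chrom, strand, start, end, tss (list)
    enhancers: pd.DataFrame  # chrom, start, end, cls, effect_z, context
    psi_events: pd.DataFrame  # gene_id, chrom, junction coords, psi per condition
    links: pd.DataFrame  # enh_index, gene_id, tss, support
    selected_marks: list = field(default_factory=lambda: list(DEFAULT_PREDICTOR_PRESET))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "genes": self.genes.assign(tss=self.genes["tss"].apply(list)).to_dict("records"),
            "enhancers": self.enhancers.to_dict("records"),
            "psi_events": self.psi_events.to_dict("records"),
            "links": self.links.to_dict("records"),
            "selected_marks": self.selected_marks,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=int))


def _write_fasta(seqs: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = arr.tobytes().decode()
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")


def _gc_gradient_sequence(rng, length: int, gc_lo=0.35, gc_hi=0.65, block=10000) -> np.ndarray:
    """Random sequence whose GC fraction varies sinusoidally along the chromosome."""
    n_blocks = int(np.ceil(length / block))
    x = np.arange(n_blocks) / max(n_blocks - 1, 1)
    gc = gc_lo + (gc_hi - gc_lo) * 0.5 * (1 + np.sin(2 * np.pi * 3 * x))
    out = np.empty(length, dtype=np.uint8)
    for i in range(n_blocks):
        lo, hi = i * block, min((i + 1) * block, length)
        p = gc[i]
        probs = [(1 - p) / 2, p / 2, p / 2, (1 - p) / 2]  # A C G T
        out[lo:hi] = _BASES[rng.choice(4, size=hi - lo, p=probs)]
    return out


def _gtf_attr(gene: str, tx: str | None = None) -> str:
    s = f'gene_id "{gene}";'
    if tx:
        s += f' transcript_id "{tx}";'
    return s


def make_genome_and_annotation(
    seed: int,
    n_chroms: int = 2,
    chrom_len: int = 10_000_000,
    n_genes: int = 100,
    n_active: int = 200,
    n_silent: int = 200,
    enh_len: int = 2500,
    effect_z: float = 3.0,
    n_links: int = 30,
    link_support: int = 4,
    delta_psi_levels: tuple = (0.0, 0.2, 0.5),
    out_dir: str | Path | None = None,
):
    """Generate FASTA + GTF + truth table.

    Genes carry 1-3 TSSs (two-TSS genes are separated by >20 kb) and ~40 %
    of them a cassette-exon isoform pair with a planted inclusion change.
    Enhancer loci (active/silent) are placed on the 500-bp window grid in
    intergenic space, at least 1 kb away from any gene.  Returns
    ``(fasta_path_or_seqs, gtf_path_or_lines, truth)``; files are written
    when ``out_dir`` is given.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {c: _gc_gradient_sequence(rng, chrom_len) for c in chroms}

    # --- genes: one per evenly spaced slot, so spans never overlap ---------
    genes_rows = []
    gtf_lines = []
    psi_rows = []
    per_chrom = int(np.ceil(n_genes / n_chroms))
    slot = chrom_len // (per_chrom + 1)
    gid_n = 0
    for c in chroms:
        for s in range(per_chrom):
            if gid_n >= n_genes:
                break
            L = int(rng.integers(60_000, 100_000))
            margin = slot - L - 10_000
            if margin <= 0:
                raise ValueError("chromosome too short for requested genes")
            start = (s + 1) * slot - L // 2 + int(rng.integers(-margin // 4, margin // 4))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"G{gid_n:04d}"
            gid_n += 1

            n_tss = int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))
            offs = [0]
            if n_tss >= 2:
                offs.append(int(22_000 + rng.integers(0, 8_000)))  # > 20 kb pair
            if n_tss >= 3:
                offs.append(offs[1] + int(rng.integers(6_000, 12_000)))  # < 20 kb pair

            has_cassette = rng.random() < 0.4
            base = L - 9_000  # cassette triple sits in the 3' part
            cassette = None
            if has_cassette and base > max(offs) + 1_500:
                cassette = (
                    (base, base + 200),
                    (base + 1_200, base + 1_380),
                    (base + 2_400, base + 2_600),
                )

            g5 = start if strand == "+" else start + L - 1

            def to_genomic(a, b):
                if strand == "+":
                    return g5 + a, g5 + b
                return g5 - b + 1, g5 - a + 1

            tx_plans = []  # list of (tx suffix, exon offset intervals)
            for i, d in enumerate(offs):
                exons = [(d, d + 200)]
                if i == 0 and cassette:
                    exons.extend(cassette)
                exons.append((L - 1_000, L - 800))
                tx_plans.append((f"T{i}", exons))
            if cassette:
                tx_plans.append(("Tskip", [(0, 200), cassette[0], cassette[2], (L - 1_000, L - 800)]))

            tss_coords = [to_genomic(d, d + 1)[0] if strand == "+" else to_genomic(d, d + 1)[1] - 1
                          for d in offs]
            genes_rows.append({"id": gid, "chrom": c, "strand": strand,
                               "start": start, "end": start + L, "tss": tss_coords})

            gtf_lines.append(f"{c}\tsim\tgene\t{start + 1}\t{start + L}\t.\t{strand}\t.\t{_gtf_attr(gid)}")
            for suffix, exoffs in tx_plans:
                tid = f"{gid}.{suffix}"
                ex_genomic = sorted(to_genomic(a, b) for a, b in exoffs)
                gtf_lines.append(
                    f"{c}\tsim\ttranscript\t{ex_genomic[0][0] + 1}\t{ex_genomic[-1][1]}\t.\t{strand}\t.\t{_gtf_attr(gid, tid)}"
                )
                for a, b in ex_genomic:
                    gtf_lines.append(f"{c}\tsim\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t{_gtf_attr(gid, tid)}")

            if cassette:
                (e1, e2, e3) = [to_genomic(a, b) for a, b in cassette]
                e1, e2, e3 = sorted([e1, e2, e3])
                psi_rows.append({
                    "gene_id": gid, "chrom": c,
                    "j12_donor": e1[1], "j12_acceptor": e2[0],
                    "j23_donor": e2[1], "j23_acceptor": e3[0],
                    "j13_donor": e1[1], "j13_acceptor": e3[0],
                })

    genes = pd.DataFrame(genes_rows)

    # planted delta-PSI per cassette event, cycling through the levels
    psi_events = pd.DataFrame(psi_rows)
    if len(psi_events):
        levels = np.array(delta_psi_levels)[np.arange(len(psi_events)) % len(delta_psi_levels)]
        base_psi = rng.uniform(0.25, 0.75, size=len(psi_events))
        sign = rng.choice([-1.0, 1.0], size=len(psi_events))
        psi_a = np.clip(base_psi + sign * levels / 2, 0.02, 0.98)
        psi_b = np.clip(base_psi - sign * levels / 2, 0.02, 0.98)
        psi_events["psi_a"] = psi_a
        psi_events["psi_b"] = psi_b
        psi_events["delta"] = levels

    # --- planted enhancers on the window grid, clear of genes --------------
    forbidden = {
        c: sorted((int(r.start) - 1_500, int(r.end) + 1_500)
                  for r in genes.itertuples() if r.chrom == c)
        for c in chroms
    }
    enh_rows = []
    taken: dict[str, list[tuple[int, int]]] = {c: list(forbidden[c]) for c in chroms}
    n_each = {"active": n_active, "silent": n_silent}
    for cls, n_cls in n_each.items():
        placed = 0
        attempts = 0
        while placed < n_cls:
            attempts += 1
            if attempts > 200 * (n_cls + 1):
                raise RuntimeError("could not place all planted enhancers")
            c = chroms[int(rng.integers(n_chroms))]
            s = int(rng.integers(2, (chrom_len - enh_len) // 500)) * 500
            e = s + enh_len
            if any(s < ie and e > is_ for is_, ie in taken[c]):
                continue
            taken[c].append((s - 1_000, e + 1_000))  # keep plants separated
            enh_rows.append({"chrom": c, "start": s, "end": e, "cls": cls,
                             "effect_z": effect_z, "context": INTERGENIC})
            placed += 1
    enhancers = pd.DataFrame(enh_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    # --- planted enhancer-gene links (nearest TSS within 2-100 kb) ---------
    link_rows = []
    for i, e in enhancers.iterrows():
        best = None
        for r in genes.itertuples():
            if r.chrom != e["chrom"]:
                continue
            for t in r.tss:
                d = 0 if e["start"] <= t < e["end"] else (
                    e["start"] - t if t < e["start"] else t - e["end"])
                if 2_000 <= d <= 100_000 and (best is None or d < best[0]):
                    best = (d, r.id, t)
        if best is not None:
            link_rows.append({"enh_index": i, "gene_id": best[1], "tss": best[2],
                              "support": link_support, "distance": best[0]})
        if len(link_rows) >= n_links:
            break
    links = pd.DataFrame(link_rows)

    truth = TruthTable(
        params={"seed": seed, "n_chroms": n_chroms, "chrom_len": chrom_len,
                "n_genes": n_genes, "n_active": n_active, "n_silent": n_silent,
                "enh_len": enh_len, "effect_z": effect_z,
                "delta_psi_levels": list(delta_psi_levels)},
        genes=genes, enhancers=enhancers, psi_events=psi_events, links=links,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "genome.fa"
        gtf = out / "annotation.gtf"
        _write_fasta(seqs, fasta)
        gtf.write_text("\n".join(gtf_lines) + "\n")
        sizes = out / "chrom.sizes"
        sizes.write_text("".join(f"{c}\t{chrom_len}\n" for c in chroms))
        truth.to_json(out / "truth.json")
        return fasta, gtf, truth
    return seqs, gtf_lines, truth


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial draw with Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def _sigma_m(mean: float, dispersion: float, rng, n: int = 20000, pseudocount: float = 1.0) -> float:
    """Replicate-null sd of the log2 ratio M at a given mean, by simulation."""
    a = _nb_draw(rng, np.full(n, mean), dispersion)
    b = _nb_draw(rng, np.full(n, mean), dispersion)
    M, _ = ma_transform(a, b, pseudocount)
    return float(M.std())


def _generate_counts(rng, base_mean, dispersion, marks, selected, fold,
                     active_mask, silent_mask, n_reps, cond_a, cond_b):
    counts = {}
    meta = []
    for mark in marks:
        role = "Input" if mark == "Input" else ("Control" if mark == "Control" else "mark")
        planted = role == "mark" and mark in selected
        for cond in (cond_a, cond_b):
            mean = base_mean
            if planted and cond == cond_a:
                mean = np.where(active_mask, base_mean * fold, base_mean)
            elif planted and cond == cond_b:
                mean = np.where(silent_mask, base_mean * fold, base_mean)
            for rep in range(1, n_reps + 1):
                name = f"{mark}.{cond}.rep{rep}"
                counts[name] = _nb_draw(rng, mean, dispersion)
                meta.append({"sample": name, "mark": mark, "condition": cond,
                             "replicate": rep, "role": role})
    samples = pd.DataFrame(meta).set_index("sample")
    return CountMatrix(counts=pd.DataFrame(counts), samples=samples)


def _calibrate_fold(rng, effect_z, gc, depth, gc_bias, dispersion, marks, selected,
                    n_reps, cond_a, cond_b, planted_frac=0.05, n_mini=6000):
    """Fold change such that the pipeline's mean z at planted loci ~ effect_z.

    Runs the actual normalization + calibration + z pipeline on a small
    background-only matrix with a trial fold and rescales the log-fold by
    the measured-to-target z ratio (the normalization slightly compresses
    extreme values, so a closed-form fold would overshoot).
    """
    from .signal import build_enrichment_matrix

    sigma0 = _sigma_m(n_reps * depth, dispersion, rng)
    trial = 2.0 ** (effect_z * sigma0)
    idx = rng.choice(len(gc), size=min(n_mini, len(gc)), replace=False)
    gz = (gc[idx] - gc.mean()) / max(gc.std(), 1e-9)
    base = depth * np.exp(gc_bias * gz)
    n_plant = max(int(planted_frac * len(idx) / 2), 50)
    active = np.zeros(len(idx), bool)
    silent = np.zeros(len(idx), bool)
    active[rng.choice(len(idx), 2 * n_plant, replace=False)] = True
    silent[active.nonzero()[0][n_plant:]] = True
    active[silent] = False
    fold = trial
    for _ in range(2):  # fixed-point iteration on the log-fold
        cm = _generate_counts(rng, base, dispersion, marks, selected, fold,
                              active, silent, n_reps, cond_a, cond_b)
        cm = CountMatrix(counts=cm.counts, samples=cm.samples, gc=gc[idx])
        z, _ = build_enrichment_matrix(cm, cond_a, cond_b,
                                       seed=int(rng.integers(2**31 - 1)))
        z_meas = float(z.loc[active, list(selected)].mean().mean())
        if z_meas <= 0:
            return fold
        fold = 2.0 ** (np.log2(fold) * effect_z / z_meas)
    return fold


def plant_chip_counts(
    truth: TruthTable,
    ws: WindowSet,
    gc: np.ndarray,
    marks: list[str] | None = None,
    effect_z: float | None = None,
    depth: float = 30.0,
    gc_bias: float = 0.5,
    dispersion: float = 0.1,
    n_reps: int = 2,
    seed: int = 0,
    cond_a: str = "A",
    cond_b: str = "B",
) -> CountMatrix:
    """Negative-binomial window counts with GC bias and planted enrichment.

    Background mean per window is ``depth * exp(gc_bias * standardized GC)``.
    At planted active loci the condition-A mean of every selected mark is
    scaled so the expected pipeline z-score is about ``+effect_z`` (silent
    loci scale condition B, giving about ``-effect_z``); Input and Control
    carry no planted effect.  Two replicates per condition per dataset.
    """
    rng = np.random.default_rng(seed)
    if marks is None:
        marks = list(truth.selected_marks) + ["Input", "Control"]
    effect_z = truth.params.get("effect_z", 3.0) if effect_z is None else effect_z

    gc = np.asarray(gc, dtype=float)
    gz = (gc - gc.mean()) / max(gc.std(), 1e-9)
    base_mean = depth * np.exp(gc_bias * gz)

    if effect_z == 0:
        fold = 1.0
    else:
        fold = _calibrate_fold(rng, effect_z, gc, depth, gc_bias, dispersion,
                               marks, truth.selected_marks, n_reps, cond_a, cond_b)

    df = ws.df
    in_cls = {}
    for cls in ("active", "silent"):
        mask = np.zeros(len(df), dtype=bool)
        sub = truth.enhancers[truth.enhancers["cls"] == cls]
        for c, grp in sub.groupby("chrom"):
            sel = df["chrom"] == c
            starts = df.loc[sel, "start"].to_numpy()
            ends = df.loc[sel, "end"].to_numpy()
            m = np.zeros(sel.sum(), dtype=bool)
            for r in grp.itertuples():
                m |= (starts >= r.start) & (ends <= r.end)  # windows fully inside
            mask[np.where(sel)[0]] = m
        in_cls[cls] = mask

    cm = _generate_counts(rng, base_mean, dispersion, marks, truth.selected_marks,
                          fold, in_cls["active"], in_cls["silent"], n_reps,
                          cond_a, cond_b)
    return CountMatrix(counts=cm.counts, samples=cm.samples, gc=gc)


def plant_chiapet_and_junctions(
    truth: TruthTable,
    link_support: int = 4,
    junction_depth: int = 50,
    seed: int = 0,
    anchor_len: int = 200,
    tss_flank: int = 1000,
    n_reps: int = 2,
    out_dir: str | Path | None = None,
):
    """Interaction pairs for planted links and junction counts for planted PSI.

    Each planted link receives exactly ``link_support`` anchor pairs spanning
    enhancer <-> TSS +/- 1 kb; junction counts are binomial around the planted
    per-condition PSI at the given read depth.  Returns ``(bedpe, junctions)``
    DataFrames (and writes TSVs when ``out_dir`` is given).
    """
    rng = np.random.default_rng(seed)
    bedpe_rows = []
    for link in truth.links.itertuples():
        e = truth.enhancers.iloc[int(link.enh_index)]
        for _ in range(int(link_support if link.support is None else link.support)):
            a1 = int(rng.integers(e["start"], max(e["end"] - anchor_len, e["start"] + 1)))
            a2 = int(rng.integers(link.tss - tss_flank, link.tss + tss_flank - anchor_len))
            bedpe_rows.append((e["chrom"], a1, a1 + anchor_len,
                               e["chrom"], a2, a2 + anchor_len))
    bedpe = pd.DataFrame(bedpe_rows, columns=["chrom1", "start1", "end1",
                                              "chrom2", "start2", "end2"])

    jrows = []
    for ev in truth.psi_events.itertuples():
        row = {"chrom": ev.chrom}
        counts = {}
        for cond, psi in (("A", ev.psi_a), ("B", ev.psi_b)):
            for rep in range(1, n_reps + 1):
                k = rng.binomial(junction_depth, psi)  # inclusion reads
                m = junction_depth - k
                counts[f"{cond}.rep{rep}"] = (k, k, m)  # (n12, n23, n13)
        for jname, pos, slot in (("j12", (ev.j12_donor, ev.j12_acceptor), 0),
                                 ("j23", (ev.j23_donor, ev.j23_acceptor), 1),
                                 ("j13", (ev.j13_donor, ev.j13_acceptor), 2)):
            r = {"chrom": ev.chrom, "donor": pos[0], "acceptor": pos[1]}
            for s, triple in counts.items():
                r[s] = triple[slot]
            jrows.append(r)
    junctions = pd.DataFrame(jrows)
    if len(junctions):
        junctions = junctions.groupby(["chrom", "donor", "acceptor"], as_index=False).sum()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bedpe.to_csv(out / "chiapet.bedpe", sep="\t", header=False, index=False)
        junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
    return bedpe, junctions


def make_mixture_seed(
    n: int = 15000,
    d: int = 7,
    separation: float = 3.0,
    weights: tuple = (0.04, 0.04, 0.92),
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic 3-component attribute matrix mimicking the seed composition.

    Component means are +separation / -separation / 0 in every attribute
    with unit covariance; returns (z matrix, true component labels with
    0 = active-like, 1 = silent-like, 2 = background).
    """
    rng = np.random.default_rng(seed)
    means = np.vstack([np.full(d, separation), np.full(d, -separation), np.zeros(d)])
    labels = rng.choice(3, size=n, p=np.asarray(weights))
    X = rng.normal(size=(n, d)) + means[labels]
    cols = columns or (list(DEFAULT_PREDICTOR_PRESET)[:d]
                       if d <= len(DEFAULT_PREDICTOR_PRESET)
                       else [f"attr{i}" for i in range(d)])
    return pd.DataFrame(X, columns=cols), labels


def make_selection_fixture(
    n: int = 2000,
    n_informative: int = 5,
    n_noise: int = 5,
    effect: float = 3.0,
    seed: int = 0,
):
    """Attribute matrix with a latent activity factor driving the informative marks.

    Returns ``(z, informative_names)`` where z has columns I0..I{k-1}
    (informative: latent factor + unit noise), N0.. (pure noise), and the
    null pair Control / H4K20me1 plus an Input column.  The first two
    informative marks play the roles of the activity proxies.
    """
    rng = np.random.default_rng(seed)
    latent = np.zeros(n)
    cls = rng.choice(3, size=n, p=[0.04, 0.04, 0.92])
    latent[cls == 0] = effect
    latent[cls == 1] = -effect
    latent += rng.normal(0, 0.5, n)
    cols = {}
    informative = [f"I{i}" for i in range(n_informative)]
    for name in informative:
        cols[name] = latent + rng.normal(0, 1.0, n)
    for i in range(n_noise):
        cols[f"N{i}"] = rng.normal(0, 1.0, n)
    cols["Input"] = rng.normal(0, 1.0, n)
    cols["Control"] = rng.normal(0, 1.0, n)
    cols["H4K20me1"] = rng.normal(0, 1.0, n)
    return pd.DataFrame(cols), informative
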