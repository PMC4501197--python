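"""Self-contained recovery experiments on synthetic data.

Each function generates its own inputs from a seed, runs the package's own
operations, and returns the measured quantities.  They are shared by the
test suite and by the reproduction script so both report the same
computations.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from . import signal as sig
from .annotation import load_annotation
from .mixture import EnhancerMixtureClassifier
from .pipeline import predict_enhancers, reciprocal_overlap_stats
from .selection import build_correlation_class, choose_predictors, run_selection
from .simulate import (
    TruthTable,
    make_genome_and_annotation,
    make_mixture_seed,
    make_selection_fixture,
    plant_chiapet_and_junctions,
    plant_chip_counts,
)
from .splicing import SkippingEvent, call_regulated, compute_psi, psi_table
from .windows import drop_signalless_windows, generate_intergenic_windows

__all__ = [
    "psi_grid_check",
    "null_calibration_check",
    "quantile_norm_check",
    "model_selection_experiment",
    "end_to_end_experiment",
    "feature_selection_experiment",
    "regulated_event_experiment",
]


def psi_grid_check(n_max: int = 30) -> dict:
    """compute_psi vs the brute-force formula on the exhaustive integer grid."""
    grid = np.array(list(itertools.product(range(n_max + 1), repeat=3)))
    n12, n23, n13 = grid.T
    got = compute_psi(n12, n23, n13)
    max_err = 0.0
    n_defined = 0
    for (a, b, c), g in zip(grid, got):
        if a + b + c < 20:
            assert np.isnan(g)
            continue
        n_defined += 1
        max_err = max(max_err, abs(g - (a + b) / (a + b + 2 * c)))
    return {"max_abs_error": max_err, "n_defined": n_defined, "n_total": len(grid)}


def null_calibration_check(seed: int = 0, n: int = 50_000, dispersion: float = 0.1) -> dict:
    """Replicate-vs-replicate z over synthetic negative-binomial windows.

    Calibrates on one independent replicate pair and scores another drawn
    from the same per-window means; the z distribution should be ~N(0, 1).
    """
    rng = np.random.default_rng(seed)
    mean = rng.uniform(10, 100, n)
    shape = 1.0 / dispersion
    draw = lambda: rng.negative_binomial(shape, shape / (shape + mean))
    cal = sig.calibrate(draw(), draw())
    z = sig.enrichment_z(draw(), draw(), cal)["z"]
    return {"mean": float(z.mean()), "sd": float(z.std()), "n": n}


def quantile_norm_check(seed: int = 0, n: int = 20_000) -> dict:
    """Between-sample invariant and GC-bias removal on a planted-bias fixture."""
    rng = np.random.default_rng(seed)
    gc = rng.uniform(0.3, 0.7, n)
    mean = 30 * np.exp(2.0 * (gc - 0.5))
    X = pd.DataFrame({f"s{i}": rng.poisson(mean) for i in range(4)})
    r_before = float(np.corrcoef(gc, X["s0"])[0, 1])
    out = sig.QuantileGCNormalizer().fit_transform(X, gc=gc)
    sorted0 = np.sort(out["s0"].to_numpy())
    spread = max(
        float(np.max(np.abs(np.sort(out[c].to_numpy()) - sorted0)))
        for c in out.columns[1:]
    )
    r_after = float(np.corrcoef(gc, out["s0"])[0, 1])
    return {"corr_before": r_before, "corr_after": r_after,
            "sorted_max_spread": spread, "n": n}


def model_selection_experiment(seed: int = 0, n_runs: int = 20, n: int = 15_000,
                               d: int = 7, separation: float = 3.0) -> dict:
    """K chosen by BIC on repeated planted 3-component seed sets (4/4/92%)."""
    ks = []
    for r in range(n_runs):
        z, _ = make_mixture_seed(n=n, d=d, separation=separation,
                                 seed=seed * 1000 + r)
        model = EnhancerMixtureClassifier(random_state=seed + r).fit(z)
        ks.append(model.k_)
    ks = np.asarray(ks)
    return {"k_values": ks.tolist(), "k3_rate": float((ks == 3).mean()),
            "n_runs": n_runs}


def end_to_end_experiment(seed: int = 0, out_dir=None) -> dict:
    """Full pipeline on the default simulation, scored against planted truth.

    Windows -> GC -> counts -> normalization -> z -> seed mixture ->
    classification -> merging -> length filter, then precision/recall at
    >=50% reciprocal overlap and the false-positive rate over background
    windows.
    """
    import tempfile

    from pyfaidx import Fasta

    with tempfile.TemporaryDirectory() as tmp:
        fasta, gtf, truth = make_genome_and_annotation(seed=seed,
                                                       out_dir=out_dir or tmp)
        sizes = {f"chr{i + 1}": truth.params["chrom_len"]
                 for i in range(truth.params["n_chroms"])}
        ann = load_annotation(gtf, sizes)
        ws = generate_intergenic_windows(ann)
        gc, _ = sig.compute_gc(Fasta(str(fasta)), ws)
    cm = plant_chip_counts(truth, ws, gc, seed=seed + 1)
    keep = np.asarray(cm.counts.sum(axis=1)) >= 1
    ws_sig = drop_signalless_windows(ws, cm)
    cm_sig = sig.CountMatrix(counts=cm.counts.loc[keep].reset_index(drop=True),
                             samples=cm.samples, gc=cm.gc[keep])
    z, _ = sig.build_enrichment_matrix(cm_sig, "A", "B", seed=seed + 2)
    res = predict_enhancers(z[list(truth.selected_marks)], ws_sig, seed=seed + 3)
    stats = reciprocal_overlap_stats(res.calls, truth.enhancers)
    planted_windows = 0
    df = ws_sig.df
    for r in truth.enhancers.itertuples():
        planted_windows += int((((df["chrom"] == r.chrom)
                                 & (df["start"] >= r.start)
                                 & (df["end"] <= r.end))).sum())
    background = len(ws_sig) - planted_windows
    fp_calls = stats["n_calls"] - stats["matched_calls"]
    stats.update({"k": res.k, "fp_calls": fp_calls,
                  "fp_rate": fp_calls / background,
                  "n_windows": len(ws_sig), "background_windows": background})
    return stats


def feature_selection_experiment(seed: int = 0, n_reps: int = 10, n: int = 2_000,
                                 runs: int = 10, max_iter: int = 20) -> dict:
    """Exact recovery of the informative attribute set over seeded repetitions.

    Five informative attributes driven by a latent activity factor, five
    pure-noise attributes, plus Input and a Control/H4K20me1 null pair; two
    correlation classes (the first two informative marks minus Input) and
    the consistency-plus-controls decision rule.
    """
    exact = 0
    selected_sets = []
    for rep in range(n_reps):
        z, informative = make_selection_fixture(n=n, seed=seed * 1000 + rep)
        reports = []
        for proxy in informative[:2]:
            target, candidates = build_correlation_class(z, proxy, "Input")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                reports.append(run_selection(candidates, target, runs=runs,
                                             subset=5000, max_iter=max_iter,
                                             seed=seed * 77 + rep))
        got = choose_predictors(reports, ["Control", "H4K20me1"])
        selected_sets.append(got)
        exact += got == sorted(informative)
    return {"exact_rate": exact / n_reps, "n_reps": n_reps,
            "selected_sets": selected_sets}


def regulated_event_experiment(seed: int = 0, n_events: int = 300,
                               depth: int = 1_500,
                               deltas=(0.0, 0.2, 0.5)) -> dict:
    """Sensitivity/specificity of regulated/unchanged calls on planted dPSI.

    Junction counts are binomial around the planted per-condition inclusion
    levels at high read depth (chosen by power analysis so that the
    +-0.05/0.1 thresholds reflect the plant rather than counting noise; see
    the methods note).
    """
    rng = np.random.default_rng(seed)
    rows, events = [], []
    level = [deltas[i % len(deltas)] for i in range(n_events)]
    for i in range(n_events):
        base = 500_000 * i
        e1, e2, e3 = (base, base + 100), (base + 200, base + 300), (base + 400, base + 500)
        events.append(SkippingEvent(gene_id=f"g{i}", chrom="chr1", strand="+",
                                    e1=e1, e2=e2, e3=e3))
        psi_b = float(rng.uniform(0.25, 0.75))
        sign = float(rng.choice([-1.0, 1.0]))
        psi_a = float(np.clip(psi_b + sign * level[i], 0.02, 0.98))
        rows.append({"gene_id": f"g{i}", "chrom": "chr1",
                     "j12_donor": e1[1], "j12_acceptor": e2[0],
                     "j23_donor": e2[1], "j23_acceptor": e3[0],
                     "j13_donor": e1[1], "j13_acceptor": e3[0],
                     "psi_a": psi_a, "psi_b": psi_b, "delta": level[i]})
    truth = TruthTable(params={"seed": seed}, genes=pd.DataFrame(),
                       enhancers=pd.DataFrame(columns=["chrom", "start", "end", "cls"]),
                       psi_events=pd.DataFrame(rows),
                       links=pd.DataFrame(columns=["enh_index", "gene_id", "tss",
                                                   "support"]))
    _, junctions = plant_chiapet_and_junctions(truth, junction_depth=depth,
                                               seed=seed + 1)
    psi = psi_table(events, junctions.set_index(["chrom", "donor", "acceptor"]),
                    samples=["A.rep1", "A.rep2", "B.rep1", "B.rep2"])
    labels = call_regulated(psi, ["A.rep1", "A.rep2"], ["B.rep1", "B.rep2"])
    truth_delta = pd.Series(level, index=psi.index)
    reg_keys = truth_delta.index[truth_delta.abs() > 0.1]
    null_keys = truth_delta.index[truth_delta == 0.0]
    # an event dropped by the read filter counts as a miss for its group
    reg = labels.reindex(reg_keys)
    null = labels.reindex(null_keys)
    return {"sensitivity": float((reg == "regulated").mean()),
            "specificity": float((null == "unchanged").mean()),
            "n_regulated_truth": int(len(reg)), "n_null_truth": int(len(null)),
            "depth": depth}
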