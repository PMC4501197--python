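"""Per-window read counting, normalization and relative-enrichment z-scores.

The enrichment statistic compares two conditions window by window on the MA
scale: M = log2((a+c)/(b+c)) and A = 0.5*log2((a+c)*(b+c)) with pseudocount
c.  The null distribution of M given A is learned from replicate-vs-replicate
comparisons (real replicates, or pseudo-replicates obtained by binomially
splitting pooled counts) in equal-occupancy bins over A; the z-score of a
window is (M - mu_bin)/sigma_bin.  Positive z means enrichment in condition
A.  Before the MA step, counts are GC-corrected within each sample
(full-quantile across equal-occupancy GC strata) and full-quantile
normalized between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .windows import WindowSet

__all__ = [
    "CountMatrix",
    "CalibrationModel",
    "count_reads",
    "compute_gc",
    "normalize_counts",
    "QuantileGCNormalizer",
    "simulate_replicates",
    "calibrate",
    "enrichment_z",
    "z_to_pvalue",
    "build_enrichment_matrix",
]

MARK, INPUT, CONTROL, RNA = "mark", "Input", "Control", "RNA"


@dataclass
class CountMatrix:
    """Windows x samples read counts with optional per-window GC.

    ``counts``: DataFrame, one row per window, one column per sample.
    ``samples``: DataFrame indexed by sample name with columns
    mark / condition / replicate / role.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gc: np.ndarray | None = None
    high_n: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)}")
        if self.gc is not None and len(self.gc) != len(self.counts):
            raise ValueError("gc vector length mismatch")

    def columns_for(self, mark: str, condition: str | None = None) -> list[str]:
        sel = self.samples["mark"] == mark
        if condition is not None:
            sel &= self.samples["condition"] == condition
        return list(self.samples.index[sel])


def count_reads(alignments, ws: WindowSet, return_skipped: bool = False):
    """Count mapped primary reads per window (>=1 bp overlap increments).

    ``alignments`` is a pysam.AlignmentFile or a path to a SAM/BAM file.
    Overlapping windows intentionally share reads.  Reads on chromosomes
    absent from the window set are skipped and tallied.
    """
    import pysam

    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments

    df = ws.df
    counts = np.zeros(len(df), dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        max_len = int((ends - starts).max()) if len(sub) else 0
        by_chrom[str(chrom)] = (starts, ends, sub.index.to_numpy(), max_len)

    skipped = 0
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        chrom = read.reference_name
        if chrom not in by_chrom:
            skipped += 1
            continue
        a, b = read.reference_start, read.reference_end
        if b is None:
            b = a + read.query_length
        starts, ends, idx, max_len = by_chrom[chrom]
        lo = np.searchsorted(starts, a - max_len)
        hi = np.searchsorted(starts, b)
        for k in range(lo, hi):
            if ends[k] > a:
                counts[idx[k]] += 1
    if own:
        af.close()
    return (counts, skipped) if return_skipped else counts


def compute_gc(genome, ws: WindowSet, n_flag_frac: float = 0.5):
    """GC fraction per window: (#G + #C) / window length, case-insensitive.

    N bases count in the denominator.  Returns ``(gc, high_n)`` where
    ``high_n`` flags windows with more than ``n_flag_frac`` N.  ``genome``
    is a pyfaidx.Fasta or any mapping chrom -> sliceable sequence.
    """
    gc = np.empty(len(ws))
    high_n = np.zeros(len(ws), dtype=bool)
    for i, rec in enumerate(ws.df.itertuples(index=False)):
        try:
            seq = str(genome[rec.chrom][rec.start:rec.end]).upper()
        except (KeyError, IndexError) as exc:
            raise ValueError(f"window {rec.chrom}:{rec.start}-{rec.end} not covered by genome") from exc
        if len(seq) < rec.end - rec.start:
            raise ValueError(f"window {rec.chrom}:{rec.start}-{rec.end} beyond sequence end")
        length = rec.end - rec.start
        gc[i] = (seq.count("G") + seq.count("C")) / length
        high_n[i] = seq.count("N") / length > n_flag_frac
    return gc, high_n


def _ordinal_ranks(x: np.ndarray) -> np.ndarray:
    """Stable ordinal ranks 0..n-1 (ties broken by original position)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[order] = np.arange(len(x))
    return ranks


def _gc_bin_ids(gc: np.ndarray, gc_bins: int) -> np.ndarray:
    """Equal-occupancy GC strata (contiguous chunks of the GC order)."""
    n = len(gc)
    order = np.argsort(gc, kind="mergesort")
    ids = np.empty(n, dtype=np.int64)
    ids[order] = np.minimum((np.arange(n) * gc_bins) // n, gc_bins - 1)
    return ids


def _within_sample_gc_correct(col: np.ndarray, bin_ids: np.ndarray) -> np.ndarray:
    """Full-quantile normalize GC strata within one sample.

    Each stratum is mapped, by within-stratum rank, onto the sample's
    overall count distribution, so all strata share one distribution and the
    count-GC trend is removed.
    """
    out = np.empty(len(col), dtype=float)
    sorted_all = np.sort(col)
    n = len(col)
    for b in np.unique(bin_ids):
        m = bin_ids == b
        nb = int(m.sum())
        q = (_ordinal_ranks(col[m]) + 0.5) / nb
        out[m] = np.interp(q * n - 0.5, np.arange(n), sorted_all)
    return out


def _between_sample_quantile(df: pd.DataFrame) -> pd.DataFrame:
    """Full-quantile normalization across samples (ordinal tie rule).

    After this step every sample's sorted vector equals the across-sample
    mean of sorted vectors, exactly.
    """
    arr = df.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = target[_ordinal_ranks(arr[:, j])]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


class QuantileGCNormalizer(BaseEstimator, TransformerMixin):
    """GC-stratified within-sample + between-sample full-quantile normalizer.

    Step 1 removes the count-GC trend within each sample by full-quantile
    normalizing equal-occupancy GC strata onto the sample's own count
    distribution; step 2 full-quantile normalizes across samples so every
    sample shares the identical sorted value vector.

    Parameters
    ----------
    gc_bins : int
        Number of equal-occupancy GC strata (default 10).
    """

    def __init__(self, gc_bins: int = 10):
        self.gc_bins = gc_bins

    def fit(self, X, y=None, gc=None):
        self.fit_transform(X, gc=gc)
        return self

    def fit_transform(self, X, y=None, gc=None):
        df = pd.DataFrame(X).astype(float)
        if df.shape[1] < 2:
            raise ValueError("need >= 2 samples")
        if (df.sum(axis=0) == 0).any():
            bad = list(df.columns[df.sum(axis=0) == 0])
            raise ValueError(f"sample(s) with all-zero counts: {bad}")
        if gc is not None:
            bin_ids = _gc_bin_ids(np.asarray(gc, dtype=float), self.gc_bins)
            for c in df.columns:
                df[c] = _within_sample_gc_correct(df[c].to_numpy(dtype=float), bin_ids)
        out = _between_sample_quantile(df)
        self.reference_distribution_ = np.sort(out.iloc[:, 0].to_numpy())
        self.n_features_in_ = df.shape[1]
        return out

    def transform(self, X):
        """Map new samples onto the fitted reference distribution by rank."""
        if not hasattr(self, "reference_distribution_"):
            raise RuntimeError("normalizer is not fitted")
        df = pd.DataFrame(X).astype(float)
        ref = self.reference_distribution_
        out = np.empty(df.shape)
        for j, c in enumerate(df.columns):
            q = (_ordinal_ranks(df[c].to_numpy()) + 0.5) / len(df)
            out[:, j] = np.interp(q * len(ref) - 0.5, np.arange(len(ref)), ref)
        return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_counts(cm: CountMatrix, gc_bins: int = 10) -> CountMatrix:
    """Return a new CountMatrix with GC-corrected, quantile-normalized counts."""
    norm = QuantileGCNormalizer(gc_bins=gc_bins).fit_transform(cm.counts, gc=cm.gc)
    return CountMatrix(counts=norm, samples=cm.samples.copy(), gc=cm.gc, high_n=cm.high_n)


def simulate_replicates(counts_a, counts_b, seed: int):
    """Split pooled counts into two pseudo-replicates by binomial halving.

    rep1 + rep2 equals the pooled vector exactly; deterministic per seed.
    """
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    pooled = np.rint(a + b).astype(np.int64)
    rng = np.random.default_rng(seed)
    rep1 = rng.binomial(pooled, 0.5)
    return rep1, pooled - rep1


@dataclass
class CalibrationModel:
    """Replicate-null model of M given A in equal-occupancy A bins."""

    inner_edges: np.ndarray  # len n_bins - 1, A values separating bins
    mu: np.ndarray
    sigma: np.ndarray  # floored at sigma_floor
    n: np.ndarray
    pseudocount: float = 1.0

    def bin_of(self, A: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.inner_edges, A)  # A outside range -> nearest bin


def ma_transform(a, b, pseudocount: float = 1.0):
    a = np.asarray(a, dtype=float) + pseudocount
    b = np.asarray(b, dtype=float) + pseudocount
    return np.log2(a / b), 0.5 * np.log2(a * b)


def calibrate(ref_a, ref_b, n_bins: int = 100, min_bin: int = 50,
              pseudocount: float = 1.0, sigma_floor: float = 1e-6) -> CalibrationModel:
    """Fit the replicate-vs-replicate null of M across equal-occupancy A bins.

    ``ref_a``/``ref_b`` are aligned replicate count vectors (each may also be
    a list of vectors; pairs are pooled by concatenation).  Bins hold at
    least ``min_bin`` points (the sparse tail is merged); per-bin sigma is
    floored at ``sigma_floor``.
    """
    if isinstance(ref_a, (list, tuple)) and not np.isscalar(ref_a[0]):
        M_parts, A_parts = [], []
        for a, b in zip(ref_a, ref_b):
            m, aa = ma_transform(a, b, pseudocount)
            M_parts.append(m)
            A_parts.append(aa)
        M, A = np.concatenate(M_parts), np.concatenate(A_parts)
    else:
        M, A = ma_transform(ref_a, ref_b, pseudocount)

    n = len(M)
    order = np.argsort(A, kind="mergesort")
    if n < 2 * min_bin:
        warnings.warn(f"only {n} windows: single global calibration bin")
        bounds = [0, n]
    else:
        per = max(min_bin, int(np.ceil(n / n_bins)))
        bounds = list(range(0, n, per))
        if n - bounds[-1] < min_bin:
            bounds.pop()  # merge sparse tail into previous bin
        bounds.append(n)

    mu, sd, cnt, edges = [], [], [], []
    A_sorted = A[order]
    M_sorted = M[order]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mu.append(M_sorted[lo:hi].mean())
        sd.append(max(M_sorted[lo:hi].std(), sigma_floor))
        cnt.append(hi - lo)
        if hi < n:
            edges.append(0.5 * (A_sorted[hi - 1] + A_sorted[hi]))
    return CalibrationModel(
        inner_edges=np.asarray(edges), mu=np.asarray(mu), sigma=np.asarray(sd),
        n=np.asarray(cnt), pseudocount=pseudocount,
    )


def enrichment_z(exp_a, exp_b, cal: CalibrationModel) -> pd.DataFrame:
    """Per-window M, A and calibrated z for condition A vs condition B.

    z = (M - mu_bin(A)) / sigma_bin(A); positive z = enrichment in A; A
    outside the calibrated range uses the nearest bin.
    """
    M, A = ma_transform(exp_a, exp_b, cal.pseudocount)
    b = cal.bin_of(A)
    z = (M - cal.mu[b]) / cal.sigma[b]
    return pd.DataFrame({"M": M, "A": A, "z": z})


def z_to_pvalue(z, tail: str):
    """One-tailed standard-normal p-value.

    ``tail='left'`` tests enrichment in condition A (small p for large
    positive z); ``tail='right'`` tests enrichment in condition B.  The two
    tails sum to 1 for any z.
    """
    if tail == "left":
        return stats.norm.sf(z)
    if tail == "right":
        return stats.norm.cdf(z)
    raise ValueError(f"tail must be 'left' or 'right', got {tail!r}")


def build_enrichment_matrix(
    cm: CountMatrix,
    cond_a: str,
    cond_b: str,
    gc_bins: int = 10,
    n_bins: int = 100,
    min_bin: int = 50,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, CalibrationModel]]:
    """Normalize a CountMatrix and compute one z column per dataset (mark).

    Replicates are summed per condition for the experimental M; calibration
    pools every available replicate-vs-replicate comparison for the mark.  A
    dataset without replicates gets pseudo-replicates by binomially splitting
    its pooled normalized counts (deterministic per seed and mark).

    Returns the windows x marks z-score matrix ("attributes") and the
    per-mark calibration models.
    """
    cm_norm = normalize_counts(cm, gc_bins=gc_bins)
    z_cols: dict[str, np.ndarray] = {}
    cals: dict[str, CalibrationModel] = {}
    for k, mark in enumerate(cm.samples["mark"].unique()):
        cols_a = cm_norm.columns_for(mark, cond_a)
        cols_b = cm_norm.columns_for(mark, cond_b)
        if not cols_a or not cols_b:
            raise ValueError(f"dataset {mark!r} missing samples in one condition")
        # replicate means: same M as summing when replicate counts are equal,
        # but A stays on the single-replicate scale the calibration bins use
        na = cm_norm.counts[cols_a].mean(axis=1).to_numpy()
        nb = cm_norm.counts[cols_b].mean(axis=1).to_numpy()
        ref_a, ref_b = [], []
        if len(cols_a) >= 2:
            ref_a.append(cm_norm.counts[cols_a[0]].to_numpy())
            ref_b.append(cm_norm.counts[cols_a[1]].to_numpy())
        if len(cols_b) >= 2:
            ref_a.append(cm_norm.counts[cols_b[0]].to_numpy())
            ref_b.append(cm_norm.counts[cols_b[1]].to_numpy())
        if not ref_a:
            r1, r2 = simulate_replicates(na, nb, seed=seed + 1009 * (k + 1))
            ref_a, ref_b = [r1], [r2]
        cal = calibrate(ref_a, ref_b, n_bins=n_bins, min_bin=min_bin, pseudocount=pseudocount)
        z_cols[mark] = enrichment_z(na, nb, cal)["z"].to_numpy()
        cals[mark] = cal
    return pd.DataFrame(z_cols, index=cm.counts.index), cals
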