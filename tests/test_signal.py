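import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from diffenh.signal import (
    CalibrationModel,
    CountMatrix,
    QuantileGCNormalizer,
    calibrate,
    compute_gc,
    count_reads,
    enrichment_z,
    ma_transform,
    normalize_counts,
    simulate_replicates,
    z_to_pvalue,
)
from diffenh.windows import WindowSet


def make_ws(intervals, chrom="c"):
    return WindowSet(pd.DataFrame({
        "chrom": chrom, "start": [s for s, _ in intervals],
        "end": [e for _, e in intervals], "context": "intergenic", "host_gene": ""}))


def write_sam(path, reads, chroms=("c",), size=100_000):
    lines = [f"@SQ\tSN:{ch}\tLN:{size}" for ch in chroms]
    for i, (chrom, pos, length) in enumerate(reads):
        lines.append(f"r{i}\t0\t{chrom}\t{pos + 1}\t60\t{length}M\t*\t0\t0\t"
                     f"{'A' * length}\t{'I' * length}")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestCountReads:
    def test_read_overlapping_two_windows(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("c", 600, 100)])
        ws = make_ws([(0, 1500), (500, 2000)])
        assert count_reads(sam, ws).tolist() == [1, 1]

    def test_empty_stream(self, tmp_path):
        sam = write_sam(tmp_path / "b.sam", [])
        ws = make_ws([(0, 1500), (500, 2000)])
        assert count_reads(sam, ws).tolist() == [0, 0]

    def test_unknown_chromosome_tallied(self, tmp_path):
        sam = write_sam(tmp_path / "c.sam", [("other", 10, 50), ("c", 10, 50)],
                        chroms=("c", "other"))
        ws = make_ws([(0, 1500)])
        counts, skipped = count_reads(sam, ws, return_skipped=True)
        assert counts.tolist() == [1] and skipped == 1

    def test_matches_brute_force_scan(self, tmp_path):
        rng = np.random.default_rng(0)
        reads = [("c", int(rng.integers(0, 9_000)), int(rng.integers(30, 150)))
                 for _ in range(2_000)]
        sam = write_sam(tmp_path / "d.sam", reads, size=20_000)
        ws = make_ws([(s, s + 1500) for s in range(0, 8_501, 500)])
        got = count_reads(sam, ws)
        expect = np.zeros(len(ws), dtype=int)
        for _, pos, length in reads:
            for i, (s, e) in enumerate(zip(ws.df["start"], ws.df["end"])):
                if pos < e and pos + length > s:
                    expect[i] += 1
        assert got.tolist() == expect.tolist()


class TestComputeGC:
    def test_conventions(self):
        genome = {"c": "G" * 1500 + "GC" * 375 + "A" * 750 + "N" * 1500}
        ws = make_ws([(0, 1500), (1500, 3000), (3000, 4500)])
        gc, high_n = compute_gc(genome, ws)
        assert gc.tolist() == [1.0, 0.5, 0.0]
        assert high_n.tolist() == [False, False, True]

    def test_window_beyond_sequence_end(self):
        with pytest.raises(ValueError):
            compute_gc({"c": "ACGT" * 100}, make_ws([(0, 1500)]))


class TestNormalization:
    def test_sorted_vectors_identical_after_between_sample(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({f"s{i}": rng.poisson(30 * (i + 1), 3_000) for i in range(4)})
        out = QuantileGCNormalizer().fit_transform(X)
        ref = np.sort(out["s0"].to_numpy())
        for c in out.columns[1:]:
            assert np.array_equal(np.sort(out[c].to_numpy()), ref)

    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(2)
        v = rng.poisson(20, 1_000).astype(float)
        out = QuantileGCNormalizer().fit_transform(pd.DataFrame({"a": v, "b": v}))
        # target is the mean of identical sorted vectors = the vectors themselves
        assert np.allclose(np.sort(out["a"]), np.sort(v))

    def test_gc_bias_removed(self):
        rng = np.random.default_rng(3)
        n = 20_000
        gc = rng.uniform(0.3, 0.7, n)
        mean = 30 * np.exp(2.0 * (gc - 0.5))
        X = pd.DataFrame({"a": rng.poisson(mean), "b": rng.poisson(mean)})
        assert np.corrcoef(gc, X["a"])[0, 1] > 0.5  # planted bias
        out = QuantileGCNormalizer().fit_transform(X, gc=gc)
        assert abs(np.corrcoef(gc, out["a"])[0, 1]) < 0.05

    def test_all_zero_sample_is_error(self):
        X = pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            QuantileGCNormalizer().fit_transform(X)


class TestSimulateReplicates:
    def test_conservation_and_determinism(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(20, 10_000)
        b = rng.poisson(25, 10_000)
        r1, r2 = simulate_replicates(a, b, seed=7)
        assert np.array_equal(r1 + r2, a + b)
        r1b, _ = simulate_replicates(a, b, seed=7)
        assert np.array_equal(r1, r1b)

    def test_binomial_expectation(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(30, 10_000)
        b = rng.poisson(30, 10_000)
        r1, _ = simulate_replicates(a, b, seed=1)
        pooled = a + b
        sd = np.sqrt((pooled * 0.25).sum()) / len(pooled)
        assert abs(r1.mean() - pooled.mean() / 2) < 3 * sd


class TestCalibrate:
    def test_identical_replicates_floor_sigma(self):
        v = np.arange(1, 20_001, dtype=float)
        cal = calibrate(v, v)
        assert np.allclose(cal.mu, 0)
        assert (cal.sigma == 1e-6).all()

    def test_null_mu_near_zero(self):
        rng = np.random.default_rng(6)
        mean = rng.uniform(30, 100, 50_000)
        a = rng.poisson(mean)
        b = rng.poisson(mean)
        cal = calibrate(a, b, n_bins=50)  # 1000 points/bin
        assert np.abs(cal.mu).max() < 0.05
        assert len(cal.mu) <= 50  # n_bins honored

    def test_small_input_single_bin(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="single global"):
            cal = calibrate(rng.poisson(20, 60), rng.poisson(20, 60))
        assert len(cal.mu) == 1


class TestEnrichmentZ:
    def test_self_calibration_zero(self):
        v = np.arange(1, 10_001, dtype=float)
        cal = calibrate(v, v)
        z = enrichment_z(v, v, cal)["z"]
        assert np.abs(z).max() < 1e-9

    def test_known_bin_arithmetic(self):
        cal = CalibrationModel(inner_edges=np.array([]), mu=np.array([0.0]),
                               sigma=np.array([0.5]), n=np.array([1]))
        # a=3, b=1, pseudocount 1 -> M = log2(4/2) = 1 -> z = (1-0)/0.5 = 2
        z = enrichment_z(np.array([3.0]), np.array([1.0]), cal)["z"]
        assert z.iloc[0] == pytest.approx(2.0)

    def test_null_is_standard_normal(self):
        """Replicate-vs-replicate z over 5e4 synthetic windows is ~N(0,1)."""
        rng = np.random.default_rng(8)
        mean = rng.uniform(10, 80, 50_000)
        cal = calibrate(rng.poisson(mean), rng.poisson(mean))
        z = enrichment_z(rng.poisson(mean), rng.poisson(mean), cal)["z"]
        assert abs(z.mean()) <= 0.05
        assert 0.9 <= z.std() <= 1.1

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(9)
        mean = rng.uniform(10, 80, 20_000)
        a, b = rng.poisson(mean), rng.poisson(mean)
        cal = calibrate(rng.poisson(mean), rng.poisson(mean))
        z_ab = enrichment_z(a, b, cal)["z"]
        z_ba = enrichment_z(b, a, cal)["z"]
        M_ab, A = ma_transform(a, b)
        M_ba, _ = ma_transform(b, a)
        assert np.allclose(M_ab, -M_ba)
        # A is symmetric in (a, b), so both directions share the bin and
        # z_ab + z_ba = -2 mu_bin / sigma_bin exactly
        bins = cal.bin_of(A)
        assert np.allclose(z_ab + z_ba, -2 * cal.mu[bins] / cal.sigma[bins])


class TestZToPvalue:
    def test_conventions(self):
        assert z_to_pvalue(0.0, "left") == pytest.approx(0.5)
        assert z_to_pvalue(0.0, "right") == pytest.approx(0.5)
        zc = stats.norm.isf(0.01)
        assert z_to_pvalue(zc, "left") == pytest.approx(0.01)
        with pytest.raises(ValueError):
            z_to_pvalue(1.0, "both")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(z=st.floats(-6, 6))
    def test_tails_sum_to_one(self, z):
        assert z_to_pvalue(z, "left") + z_to_pvalue(z, "right") == pytest.approx(1.0)


def test_normalize_counts_roundtrip(sim_bundle):
    """Pipeline CountMatrix normalization keeps shape and sample metadata."""
    cm = sim_bundle["counts_signal"]
    out = normalize_counts(cm)
    assert out.counts.shape == cm.counts.shape
    assert list(out.samples.index) == list(cm.samples.index)
    s0 = np.sort(out.counts.iloc[:, 0].to_numpy())
    for j in range(1, out.counts.shape[1]):
        assert np.array_equal(np.sort(out.counts.iloc[:, j].to_numpy()), s0)


def test_countmatrix_validation():
    samples = pd.DataFrame({"mark": ["m"], "condition": ["A"],
                            "replicate": [1], "role": ["mark"]}, index=["s1"])
    with pytest.raises(ValueError, match="non-negative"):
        CountMatrix(counts=pd.DataFrame({"s1": [-1]}), samples=samples)
    with pytest.raises(ValueError, match="metadata"):
        CountMatrix(counts=pd.DataFrame({"s2": [1]}), samples=samples)
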