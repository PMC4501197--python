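"""End-to-end orchestration: windows -> counts -> z -> mixture -> calls.

Thin composition of the module operations, used by the command-line
interface and by recovery experiments on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mixture
from .calls import EnhancerCall, filter_length, merge_windows
from .mixture import EnhancerMixtureClassifier, sample_seed
from .windows import WindowSet

__all__ = ["PredictionResult", "predict_enhancers", "reciprocal_overlap_stats"]


@dataclass
class PredictionResult:
    model: EnhancerMixtureClassifier
    classification: mixture.Classification
    kept: mixture.Classification
    calls: list[EnhancerCall]

    @property
    def k(self) -> int:
        return self.model.k_


def predict_enhancers(
    z: pd.DataFrame,
    ws: WindowSet,
    seed_n: int = 15000,
    seed: int = 0,
    posterior_threshold: float = 0.95,
    max_len: int = 5000,
    force_k: int | None = None,
    k_range=range(1, 10),
    attribute_subset: list[str] | None = None,
) -> PredictionResult:
    """Fit the seed mixture, classify all windows, merge and length-filter.

    ``z`` rows must align with ``ws.df`` rows (same order).  The seed is an
    arbitrary subsample of the supplied windows, as in the reference
    protocol of sampling intergenic windows with signal.
    """
    if len(z) != len(ws):
        raise ValueError("z matrix and window set sizes differ")
    if attribute_subset is not None:
        z = z[attribute_subset]
    seed_ws = sample_seed(ws, n=seed_n, seed=seed)
    # recover positional indices of the sampled windows
    key = pd.MultiIndex.from_frame(ws.df[["chrom", "start", "end", "context", "host_gene"]])
    seed_key = pd.MultiIndex.from_frame(
        seed_ws.df[["chrom", "start", "end", "context", "host_gene"]])
    pos = key.get_indexer(seed_key)
    model = EnhancerMixtureClassifier(k_range=k_range, force_k=force_k,
                                      posterior_threshold=posterior_threshold,
                                      random_state=seed).fit(z.iloc[pos])
    classification = model.classify(z)
    kept = model.filter(classification)
    calls = filter_length(merge_windows(kept, ws), max_len=max_len)
    return PredictionResult(model=model, classification=classification,
                            kept=kept, calls=calls)


def reciprocal_overlap_stats(
    calls: list[EnhancerCall],
    truth: pd.DataFrame,
    min_frac: float = 0.5,
    match_class: bool = True,
) -> dict:
    """Precision/recall of calls against truth intervals.

    A call matches a truth interval when their overlap covers at least
    ``min_frac`` of both (reciprocal overlap) and, if ``match_class``, the
    class labels agree (truth column ``cls``).
    """
    matched_truth = np.zeros(len(truth), dtype=bool)
    matched_call = np.zeros(len(calls), dtype=bool)
    t = truth.reset_index(drop=True)
    for i, c in enumerate(calls):
        sel = t.index[(t["chrom"] == c.chrom)]
        for j in sel:
            row = t.loc[j]
            ov = min(c.end, row["end"]) - max(c.start, row["start"])
            if ov <= 0:
                continue
            if ov < min_frac * (c.end - c.start) or ov < min_frac * (row["end"] - row["start"]):
                continue
            if match_class and row.get("cls") is not None and row["cls"] != c.cls:
                continue
            matched_truth[j] = True
            matched_call[i] = True
    precision = matched_call.mean() if len(calls) else float("nan")
    recall = matched_truth.mean() if len(t) else float("nan")
    return {"precision": float(precision), "recall": float(recall),
            "n_calls": len(calls), "n_truth": len(t),
            "matched_calls": int(matched_call.sum()),
            "matched_truth": int(matched_truth.sum())}
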