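"""Shadow-feature wrapper selection of informative chromatin attributes.

The wrapper scores each candidate attribute against a *correlation class*
(a mark's enrichment minus the Input level) by iteratively fitting a forest
regressor on the attributes plus one permuted "shadow" copy of each; an
attribute scores a hit when its importance exceeds the best shadow.  Hits
accumulate over iterations and a two-sided binomial test (p = 0.5) accepts
or rejects each attribute.  The protocol repeats the whole procedure on
random window subsets and an attribute is a final predictor only if it is
accepted consistently under two correlation classes and outscores the
negative-control datasets in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import ExtraTreesRegressor

__all__ = [
    "DEFAULT_PREDICTOR_PRESET",
    "FeatureReport",
    "ShadowFeatureSelector",
    "build_correlation_class",
    "run_selection",
    "choose_predictors",
]

#: Activation-mark predictor set shipped as a preset so the pipeline can
#: skip selection.
DEFAULT_PREDICTOR_PRESET = [
    "P300", "H3K27ac", "H3K9ac", "H3K4me1", "H3K4me2", "H3K4me3", "H2A.Z",
]

ACCEPTED, REJECTED, TENTATIVE = "accepted", "rejected", "tentative"


def _default_forest(seed=None):
    # shallow extremely-randomized trees with subsampled split candidates:
    # shadows must have a real chance to be picked at every split, otherwise
    # tiny chance correlations of noise attributes outrank the shadow null;
    # this also keeps the repeated-run protocol affordable on one CPU
    return ExtraTreesRegressor(n_estimators=100, max_depth=5, max_features="sqrt",
                               random_state=seed, n_jobs=1)


class ShadowFeatureSelector(BaseEstimator):
    """Boruta-style all-relevant feature selector (regression).

    Parameters
    ----------
    estimator : sklearn regressor with ``feature_importances_`` or None
        Forest engine; default ExtraTreesRegressor(100 trees, depth 5).
    alpha : float
        Two-sided binomial test level for accept/reject decisions.
    max_iter : int
        Maximum shadow iterations.
    min_iter : int
        Iterations before any decision is attempted.
    random_state : int or None

    Attributes
    ----------
    decision_ : pd.Series of {accepted, rejected, tentative} per feature
    hits_ : pd.Series of shadow-beating counts per feature
    n_iter_ : iterations actually run
    mean_importance_ : pd.Series, mean importance over iterations
    support_ : boolean ndarray (accepted features)
    """

    def __init__(self, estimator=None, alpha: float = 0.01, max_iter: int = 100,
                 min_iter: int = 5, random_state=None):
        self.estimator = estimator
        self.alpha = alpha
        self.max_iter = max_iter
        self.min_iter = min_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("degenerate correlation class: target is constant")
        rng = np.random.default_rng(self.random_state)
        cols = list(X.columns)
        decision = pd.Series(TENTATIVE, index=cols)
        hits = pd.Series(0, index=cols, dtype=int)
        trials = pd.Series(0, index=cols, dtype=int)
        imp_sum = pd.Series(0.0, index=cols)
        imp_n = pd.Series(0, index=cols, dtype=int)

        it = 0
        while it < self.max_iter and (decision == TENTATIVE).any():
            it += 1
            active = [c for c in cols if decision[c] != REJECTED]
            Xa = X[active].to_numpy(dtype=float)
            shadows = np.empty_like(Xa)
            for j in range(Xa.shape[1]):
                shadows[:, j] = rng.permutation(Xa[:, j])
            design = np.hstack([Xa, shadows])
            est = self.estimator
            model = clone(est) if est is not None else _default_forest()
            try:
                model.set_params(random_state=int(rng.integers(2**31 - 1)))
            except ValueError:
                pass
            model.fit(design, y)
            imp = np.asarray(model.feature_importances_)
            real, shadow = imp[: len(active)], imp[len(active):]
            thresh = shadow.max()
            for c, v in zip(active, real):
                imp_sum[c] += v
                imp_n[c] += 1
                if decision[c] != TENTATIVE:
                    continue
                trials[c] += 1
                if v > thresh:
                    hits[c] += 1
            if it >= self.min_iter:
                for c in cols:
                    if decision[c] != TENTATIVE:
                        continue
                    p = stats.binomtest(int(hits[c]), int(trials[c]), 0.5).pvalue
                    if p < self.alpha:
                        decision[c] = ACCEPTED if hits[c] > trials[c] / 2 else REJECTED

        self.n_iter_ = it
        self.decision_ = decision
        self.hits_ = hits
        self.trials_ = trials
        self.mean_importance_ = imp_sum / imp_n.clip(lower=1)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.support_ = (decision == ACCEPTED).to_numpy()
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        return pd.DataFrame(X).loc[:, self.feature_names_in_[self.support_]]


@dataclass
class FeatureReport:
    """Per-attribute selection outcome over repeated subset runs."""

    #: index = attribute; columns run_0..run_{r-1} with decisions
    decisions: pd.DataFrame
    #: mean importance per attribute over all runs/iterations
    mean_importance: pd.Series
    #: shadow-beating hit counts summed over runs
    hits: pd.Series
    meta: dict = field(default_factory=dict)

    def accepted_fraction(self) -> pd.Series:
        return (self.decisions == ACCEPTED).mean(axis=1)


def build_correlation_class(z: pd.DataFrame, mark: str, input_name: str):
    """Target = z[mark] - z[input]; both columns are withheld from candidates.

    Returns ``(target, candidates)`` where candidates is the z matrix without
    the proxy mark and Input columns.
    """
    for c in (mark, input_name):
        if c not in z.columns:
            raise KeyError(f"column {c!r} not in enrichment matrix")
    target = z[mark] - z[input_name]
    candidates = z.drop(columns=[mark, input_name])
    return target, candidates


def run_selection(
    z: pd.DataFrame,
    target,
    runs: int = 10,
    subset: int = 5000,
    max_iter: int = 100,
    seed: int = 0,
    estimator=None,
    alpha: float = 0.01,
) -> FeatureReport:
    """Repeat the shadow-feature wrapper on random window subsets.

    Each run samples ``subset`` windows (all windows, with a warning, when
    fewer are available), runs the selector to completion, and records the
    per-attribute decision and importances.
    """
    target = np.asarray(target, dtype=float)
    if np.ptp(target) == 0:
        raise ValueError("degenerate correlation class: target is constant")
    rng = np.random.default_rng(seed)
    n = len(z)
    if n < subset:
        warnings.warn(f"only {n} windows available; using all instead of {subset}")
    decisions = {}
    imps = []
    hits = pd.Series(0, index=z.columns, dtype=int)
    for r in range(runs):
        idx = rng.choice(n, size=min(subset, n), replace=False) if n > subset else np.arange(n)
        sel = ShadowFeatureSelector(
            estimator=estimator, alpha=alpha, max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(z.iloc[idx], target[idx])
        decisions[f"run_{r}"] = sel.decision_
        imps.append(sel.mean_importance_)
        hits += sel.hits_
    report = FeatureReport(
        decisions=pd.DataFrame(decisions),
        mean_importance=pd.concat(imps, axis=1).mean(axis=1),
        hits=hits,
        meta={"runs": runs, "subset": subset, "seed": seed},
    )
    return report


def choose_predictors(
    reports: list[FeatureReport],
    negative_controls: list[str],
    majority: float = 0.6,
) -> list[str]:
    """Attributes accepted consistently under every report and above controls.

    An attribute is selected iff, in every report in which it appears as a
    candidate, it is accepted in at least ``majority`` of runs AND its mean
    importance exceeds every negative control's mean importance.  A
    correlation-class proxy mark is withheld from its own report, so it can
    qualify through the other report(s), matching the protocol of adding
    the proxies back to the final predictor set.
    """
    union: set = set()
    for rep in reports:
        union |= set(rep.decisions.index)
    for ctrl in negative_controls:
        for rep in reports:
            if ctrl not in rep.mean_importance.index:
                raise KeyError(f"negative control {ctrl!r} absent from report")
    selected = []
    for attr in sorted(union):
        if attr in negative_controls:
            continue
        ok = False
        for rep in reports:
            if attr not in rep.decisions.index:
                continue
            frac = rep.accepted_fraction()[attr]
            ctrl_max = rep.mean_importance[negative_controls].max()
            if frac < majority or not rep.mean_importance[attr] > ctrl_max:
                ok = False
                break
            ok = True
        if ok:
            selected.append(attr)
    return selected
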