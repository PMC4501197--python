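"""Semi-supervised three-class Gaussian mixture over enrichment attributes.

A mixture is fitted to a seed of intergenic windows (default 15,000) over
the selected attribute z-scores, the number of components is chosen where
the BIC curve plateaus (with an option to force K = 3), components are
labeled active / silent / no-change by the sign of their mean enrichment in
activation marks, and the fitted model classifies genome-wide windows.
Predictions are kept only above a posterior cutoff (default 0.95, strict).

BIC here is reported as ``2 log L - p log n`` (larger is better).  The
default covariance family is unconstrained full covariances; a constrained
family with per-component volume and orientation but a shared shape
(``covariance="vev"``) is available behind a flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .windows import WindowSet

__all__ = [
    "ACTIVE", "SILENT", "NO_CHANGE",
    "Classification",
    "EnhancerMixtureClassifier",
    "sample_seed",
    "fit_seed_model",
    "label_components",
    "classify",
    "filter_posterior",
]

ACTIVE, SILENT, NO_CHANGE = "active", "silent", "no_change"


def sample_seed(ws: WindowSet, n: int = 15000, seed: int = 0) -> WindowSet:
    """Uniform sample of seed windows without replacement (deterministic)."""
    rng = np.random.default_rng(seed)
    total = len(ws)
    if total < n:
        warnings.warn(f"only {total} windows available; using all as seed")
        return WindowSet(ws.df.copy(), dict(ws.provenance, seed=seed))
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return WindowSet(ws.df.iloc[idx].reset_index(drop=True), dict(ws.provenance, seed=seed))


@dataclass
class Classification:
    """Per-window argmax class with its posterior probability."""

    df: pd.DataFrame  # columns: class, posterior (+ component)

    def __len__(self) -> int:
        return len(self.df)


def _vev_covariances(scatters, counts, d, tol=1e-4, max_iter=100):
    """Constrained M-step: Sigma_k = lambda_k * D_k A D_k^T with shared
    diagonal shape A (det 1), per-component scale and orientation."""
    K = len(scatters)
    omegas, rotations = [], []
    for W in scatters:
        vals, vecs = linalg.eigh(W)
        omegas.append(np.clip(vals[::-1], 1e-12, None))  # descending
        rotations.append(vecs[:, ::-1])
    lam = np.array([om.sum() / (d * n) for om, n in zip(omegas, counts)])
    A = np.ones(d)
    for _ in range(max_iter):
        num = sum(om / l for om, l in zip(omegas, lam))
        A_new = num / np.exp(np.mean(np.log(num)))  # det(A) = 1
        lam_new = np.array([(om / A_new).sum() / (d * n) for om, n in zip(omegas, counts)])
        if np.max(np.abs(A_new - A)) < tol and np.max(np.abs(lam_new - lam)) < tol:
            A, lam = A_new, lam_new
            break
        A, lam = A_new, lam_new
    covs = np.empty((K, d, d))
    for k in range(K):
        covs[k] = lam[k] * rotations[k] @ np.diag(A) @ rotations[k].T
    return covs


def _log_gauss(X, means, covs):
    n, d = X.shape
    K = len(means)
    out = np.empty((n, K))
    for k in range(K):
        chol = linalg.cholesky(covs[k] + 1e-9 * np.eye(d), lower=True)
        sol = linalg.solve_triangular(chol, (X - means[k]).T, lower=True)
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + (sol**2).sum(axis=0)) \
            - np.log(np.diag(chol)).sum()
    return out


class _VEVMixture:
    """EM for the shared-shape covariance family, initialised from a fitted
    full-covariance mixture."""

    def __init__(self, init: GaussianMixture, tol=1e-4, max_iter=300):
        self.weights_ = init.weights_.copy()
        self.means_ = init.means_.copy()
        self.covariances_ = init.covariances_.copy()
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X):
        n, d = X.shape
        prev = -np.inf
        self.ll_trace_: list[float] = []
        for it in range(self.max_iter):
            logp = _log_gauss(X, self.means_, self.covariances_) + np.log(self.weights_)
            mx = logp.max(axis=1, keepdims=True)
            ll = (mx.squeeze() + np.log(np.exp(logp - mx).sum(axis=1))).mean()
            self.ll_trace_.append(float(ll))
            resp = np.exp(logp - mx)
            resp /= resp.sum(axis=1, keepdims=True)
            nk = resp.sum(axis=0) + 1e-10
            self.weights_ = nk / n
            self.means_ = (resp.T @ X) / nk[:, None]
            scatters = []
            for k in range(len(nk)):
                diff = X - self.means_[k]
                scatters.append((resp[:, k][:, None] * diff).T @ diff)
            self.covariances_ = _vev_covariances(scatters, nk, d)
            # it == 0 evaluates the unconstrained init: the first constrained
            # M-step may drop the likelihood across the family switch, so the
            # convergence test only applies within the constrained family
            if it > 1 and ll - prev < self.tol:
                break
            prev = ll
        self.lower_bound_ = prev
        return self

    def predict_proba(self, X):
        logp = _log_gauss(X, self.means_, self.covariances_) + np.log(self.weights_)
        mx = logp.max(axis=1, keepdims=True)
        resp = np.exp(logp - mx)
        return resp / resp.sum(axis=1, keepdims=True)

    def score_samples_sum(self, X):
        logp = _log_gauss(X, self.means_, self.covariances_) + np.log(self.weights_)
        mx = logp.max(axis=1, keepdims=True)
        return float((mx.squeeze() + np.log(np.exp(logp - mx).sum(axis=1))).sum())


class EnhancerMixtureClassifier(BaseEstimator):
    """Gaussian-mixture chromatin-state classifier with BIC model selection.

    Parameters
    ----------
    k_range : iterable of int
        Candidate component counts (default 1..9).
    n_init, tol, max_iter :
        EM restarts / convergence settings per candidate K.
    covariance : {"full", "vev"}
        "full" = unconstrained covariances; "vev" = per-component volume and
        orientation with a shared shape, refined from the best full fit.
    force_k : int or None
        Skip model selection and use this K.
    k_selection : {"bic_max", "elbow"}
        "bic_max" (default) picks the K with the best BIC, the standard
        finite-mixture criterion.  "elbow" picks the smallest K whose BIC
        improvement going to K+1 falls below ``elbow_frac`` of the total
        BIC range (argmax-BIC if the curve never flattens); it can stop
        early when a dominant first jump dwarfs the gain from small,
        well-separated components.
    elbow_frac : float
        Plateau threshold for ``k_selection="elbow"``.
    activation_marks : list of column names or None
        Attributes used to score components for labeling (default: all).
    posterior_threshold : float
        Strict cutoff used by :meth:`filter`.
    random_state : int or None

    Attributes (after fit)
    ----------------------
    k_ : selected component count
    weights_, means_, covariances_ : mixture parameters
    bic_trace_ : pd.Series, BIC (2 logL - p log n, larger better) per K
    class_of_component_ : dict component index -> class label
    feature_names_in_ : attribute order used in training
    """

    def __init__(self, k_range=range(1, 10), n_init: int = 2, tol: float = 1e-4,
                 max_iter: int = 300, covariance: str = "full", force_k: int | None = None,
                 k_selection: str = "bic_max", elbow_frac: float = 0.05,
                 activation_marks=None,
                 posterior_threshold: float = 0.95, random_state=None):
        self.k_range = k_range
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.covariance = covariance
        self.force_k = force_k
        self.k_selection = k_selection
        self.elbow_frac = elbow_frac
        self.activation_marks = activation_marks
        self.posterior_threshold = posterior_threshold
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        arr = X.to_numpy(dtype=float)
        n, d = arr.shape

        ks = sorted(self.k_range)
        if self.force_k is not None:
            ks = sorted(set(ks) | {self.force_k})
        fits: dict[int, GaussianMixture] = {}
        bic = {}
        for K in ks:
            gm = GaussianMixture(
                n_components=K, covariance_type="full", n_init=self.n_init,
                tol=self.tol, max_iter=self.max_iter, init_params="k-means++",
                random_state=self.random_state,
            ).fit(arr)
            if not gm.converged_:
                warnings.warn(f"EM did not fully converge for K={K}")
            fits[K] = gm
            bic[K] = -gm.bic(arr)  # sklearn: smaller better; flip convention
        self.bic_trace_ = pd.Series(bic).sort_index()

        if self.force_k is not None:
            self.k_ = self.force_k
        elif self.k_selection == "bic_max":
            self.k_ = int(self.bic_trace_.idxmax())
        elif self.k_selection == "elbow":
            self.k_ = self._elbow(self.bic_trace_)
        else:
            raise ValueError(f"unknown k_selection {self.k_selection!r}")
        best = fits[self.k_]
        self.weights_ = best.weights_.copy()
        self.means_ = best.means_.copy()
        self.covariances_ = best.covariances_.copy()
        self._gm = best
        if self.covariance == "vev":
            vev = _VEVMixture(best, tol=self.tol).fit(arr)
            self.weights_, self.means_, self.covariances_ = (
                vev.weights_, vev.means_, vev.covariances_)
            self._gm = vev
        elif self.covariance != "full":
            raise ValueError(f"unknown covariance family {self.covariance!r}")
        self._label_components()
        return self

    def _elbow(self, trace: pd.Series) -> int:
        ks = list(trace.index)
        if len(ks) == 1:
            return ks[0]
        rng_total = float(trace.max() - trace.min())
        if rng_total == 0:
            return ks[0]
        for k, k_next in zip(ks[:-1], ks[1:]):
            if trace[k_next] - trace[k] < self.elbow_frac * rng_total:
                return k
        return int(trace.idxmax())

    def _label_components(self):
        cols = self.activation_marks
        names = list(self.feature_names_in_)
        idx = [names.index(c) for c in cols] if cols else list(range(len(names)))
        scores = self.means_[:, idx].mean(axis=1)
        order = np.argsort(scores, kind="mergesort")
        if len(scores) > 1 and scores[order[-1]] == scores[order[-2]] and "H3K27ac" in names:
            k27 = self.means_[:, names.index("H3K27ac")]
            order = np.lexsort((k27, scores))
        labels = {int(k): NO_CHANGE for k in range(len(scores))}
        labels[int(order[-1])] = ACTIVE
        if len(scores) > 1:
            labels[int(order[0])] = SILENT
        if np.abs(scores).max() < 0.25:
            warnings.warn("no differential classes detected: all component "
                          "centroids are near zero")
        self.class_of_component_ = labels
        self.component_scores_ = scores

    # -- prediction --------------------------------------------------------

    def _check_columns(self, X: pd.DataFrame):
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError(
                f"attribute columns {list(X.columns)} do not match training "
                f"order {list(self.feature_names_in_)}")

    def predict_proba(self, X) -> np.ndarray:
        """Per-window component posteriors (columns in component order)."""
        X = pd.DataFrame(X)
        self._check_columns(X)
        return self._gm.predict_proba(X.to_numpy(dtype=float))

    def predict(self, X) -> np.ndarray:
        """Argmax class label per window."""
        return self.classify(X).df["class"].to_numpy()

    def classify(self, X) -> Classification:
        """Classification with the posterior of the assigned class.

        The class posterior sums the responsibilities of all components
        sharing the argmax component's label.
        """
        resp = self.predict_proba(X)
        comp = resp.argmax(axis=1)
        labels = np.asarray([self.class_of_component_[int(k)] for k in comp])
        post = np.zeros(len(resp))
        for cls in (ACTIVE, SILENT, NO_CHANGE):
            members = [k for k, v in self.class_of_component_.items() if v == cls]
            if members:
                post = np.where(labels == cls, resp[:, members].sum(axis=1), post)
        df = pd.DataFrame({"class": labels, "posterior": post, "component": comp},
                          index=pd.DataFrame(X).index)
        return Classification(df)

    def filter(self, c: Classification, threshold: float | None = None) -> Classification:
        return filter_posterior(c, threshold if threshold is not None
                                else self.posterior_threshold)

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "k": int(self.k_),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covariances_.tolist(),
            "class_of_component": {str(k): v for k, v in self.class_of_component_.items()},
            "attributes": list(self.feature_names_in_),
            "bic_trace": {str(k): float(v) for k, v in self.bic_trace_.items()},
            "covariance_family": self.covariance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EnhancerMixtureClassifier":
        """Rebuild a fitted classifier from :meth:`to_json` output."""
        from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        k = int(payload["k"])
        model = cls(k_range=[k], force_k=k, covariance=payload.get("covariance_family", "full"))
        model.k_ = k
        model.weights_ = np.asarray(payload["weights"])
        model.means_ = np.asarray(payload["means"])
        model.covariances_ = np.asarray(payload["covariances"])
        model.feature_names_in_ = np.asarray(payload["attributes"], dtype=object)
        model.class_of_component_ = {int(i): v for i, v in payload["class_of_component"].items()}
        model.bic_trace_ = pd.Series({int(i): v for i, v in payload["bic_trace"].items()})
        gm = GaussianMixture(n_components=k, covariance_type="full")
        gm.weights_ = model.weights_
        gm.means_ = model.means_
        gm.covariances_ = model.covariances_
        gm.precisions_cholesky_ = _compute_precision_cholesky(model.covariances_, "full")
        model._gm = gm
        return model


def fit_seed_model(z_seed: pd.DataFrame, k_range=range(1, 10), n_init: int = 2,
                   tol: float = 1e-4, max_em: int = 300, seed: int = 0,
                   covariance: str = "full", force_k: int | None = None,
                   elbow_frac: float = 0.05) -> EnhancerMixtureClassifier:
    """Fit the seed mixture over candidate K and select K* on the BIC plateau."""
    return EnhancerMixtureClassifier(
        k_range=k_range, n_init=n_init, tol=tol, max_iter=max_em,
        covariance=covariance, force_k=force_k, elbow_frac=elbow_frac,
        random_state=seed,
    ).fit(z_seed)


def label_components(model: EnhancerMixtureClassifier) -> EnhancerMixtureClassifier:
    """(Re-)derive active/silent/no-change labels from component centroids."""
    model._label_components()
    return model


def classify(model: EnhancerMixtureClassifier, z_all: pd.DataFrame) -> Classification:
    return model.classify(z_all)


def filter_posterior(c: Classification, threshold: float = 0.95) -> Classification:
    """Keep active/silent windows with posterior strictly above threshold."""
    df = c.df
    keep = df["class"].isin([ACTIVE, SILENT]) & (df["posterior"] > threshold)
    return Classification(df.loc[keep].copy())
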