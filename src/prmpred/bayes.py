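"""Naive Bayes evidence integration and evaluation.

Two independent naive Bayes classifiers score each candidate interaction:
one over the peptide-level features (DR, SA, PC, SC) of the binding site
and one over the protein-pair features (CC, BP, MF, EX, SS).  Continuous
features are discretized into bins and class-conditional bin likelihoods
are estimated with Laplace smoothing; a missing feature simply contributes
no factor to the product, which under the independence assumption equals
marginalizing it out.  The two posteriors are then combined with Bayes'
theorem under classifier independence:

    P(Y | pep, pro) = (p1 p2 / prior) /
                      (p1 p2 / prior + (1 - p1)(1 - p2) / (1 - prior))

so an uninformative classifier (posterior == prior) leaves the other's
posterior unchanged.

The classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict_proba`` / ``get_params``) and accept NaN as the missing-value
marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DegenerateTraining, NoEvidence, UndefinedMetric

#: Feature order of the two classifier scopes.
PEPTIDE_FEATURES = ("DR", "SA", "PC", "SC")
PROTEIN_FEATURES = ("CC", "BP", "MF", "EX", "SS")

#: Value bounds per named feature; None means unbounded (quantile bins).
FEATURE_BOUNDS = {
    "DR": (0.0, 1.0), "SA": (0.0, 1.0), "PC": None, "SC": (0.0, 1.0),
    "CC": (0.0, 1.0), "BP": (0.0, 1.0), "MF": (0.0, 1.0),
    "EX": (-1.0, 1.0), "SS": None,
}

DEFAULT_DECISION_THRESHOLD = 0.9
_EPS = 1e-12


class BinnedNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes over binned continuous features with missing-value
    tolerance.

    Parameters
    ----------
    n_bins : int
        Number of bins per feature (>= 2).
    smoothing : float
        Laplace smoothing added to every bin count.
    prior : float or None
        Fixed P(Y=1); None learns the empirical class frequency.  The
        default 0.5 matches training on balanced positive and negative
        pairs.
    feature_bounds : sequence of (low, high) or None per feature, optional
        Bounded features get equal-width bins over their range; unbounded
        ones (entry None) get quantile bins estimated on the training
        data.  When omitted entirely all features use quantile bins.

    Attributes
    ----------
    classes_ : ndarray [0, 1]
    bin_edges_ : list of ndarray, inner edges per feature
    likelihoods_ : ndarray (2, n_features, n_bins), rows sum to 1 per
        (class, feature)
    prior_ : float, P(Y=1) used at prediction time
    """

    def __init__(self, n_bins=10, smoothing=1.0, prior=0.5,
                 feature_bounds=None):
        self.n_bins = n_bins
        self.smoothing = smoothing
        self.prior = prior
        self.feature_bounds = feature_bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateTraining("training data contains a single class")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("labels must be 0/1")
        n_features = X.shape[1]
        bounds = self.feature_bounds
        if bounds is None:
            bounds = [None] * n_features
        if len(bounds) != n_features:
            raise ValueError("feature_bounds length must match n_features")

        self.n_features_in_ = n_features
        self.classes_ = np.array([0, 1])
        self.bin_edges_ = []
        like = np.zeros((2, n_features, self.n_bins))
        counts = np.zeros((2, n_features, self.n_bins))
        for f in range(n_features):
            col = X[:, f]
            present = ~np.isnan(col)
            if bounds[f] is not None:
                lo, hi = bounds[f]
                edges = np.linspace(lo, hi, self.n_bins + 1)
            else:
                vals = col[present]
                if vals.size == 0:
                    edges = np.linspace(0, 1, self.n_bins + 1)
                else:
                    qs = np.quantile(vals, np.linspace(0, 1, self.n_bins + 1))
                    edges = qs
            inner = np.asarray(edges[1:-1], dtype=float)
            self.bin_edges_.append(inner)
            idx = np.searchsorted(inner, col[present], side="right")
            yy = y[present]
            for c in (0, 1):
                binned = np.bincount(idx[yy == c], minlength=self.n_bins)
                counts[c, f, :] = binned
                total = binned.sum()
                like[c, f, :] = (binned + self.smoothing) / (
                    total + self.smoothing * self.n_bins
                )
        self.counts_ = counts
        self.likelihoods_ = like
        if self.prior is None:
            self.prior_ = float((y == 1).mean())
        else:
            if not (0 < self.prior < 1):
                raise ValueError("prior must be in (0, 1)")
            self.prior_ = float(self.prior)
        return self

    def _bin_indices(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        idx = np.zeros(X.shape, dtype=int)
        for f in range(self.n_features_in_):
            idx[:, f] = np.searchsorted(
                self.bin_edges_[f], X[:, f], side="right"
            )
        return X, np.clip(idx, 0, self.n_bins - 1)

    def predict_proba(self, X):
        """Posterior P(Y | present features) per row; NaN entries are
        treated as missing and contribute no likelihood factor.  A row
        with every feature missing raises :class:`NoEvidence`."""
        X, idx = self._bin_indices(X)
        present = ~np.isnan(X)
        if np.any(~present.any(axis=1)):
            raise NoEvidence("row with all features missing")
        n = X.shape[0]
        logp = np.zeros((n, 2))
        logp[:, 0] = np.log(1 - self.prior_)
        logp[:, 1] = np.log(self.prior_)
        for f in range(self.n_features_in_):
            ok = present[:, f]
            for c in (0, 1):
                logp[ok, c] += np.log(self.likelihoods_[c, f, idx[ok, f]])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def predict(self, X, threshold: float = DEFAULT_DECISION_THRESHOLD):
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)


def fit_naive_bayes(X, y, scope: str, n_bins: int = 10,
                    smoothing: float = 1.0, prior: float = 0.5):
    """Fit a classifier for one scope ('pep' or 'pro') with the standard
    feature order and bounds for that scope."""
    names = PEPTIDE_FEATURES if scope == "pep" else PROTEIN_FEATURES
    bounds = [FEATURE_BOUNDS[f] for f in names]
    model = BinnedNaiveBayes(
        n_bins=n_bins, smoothing=smoothing, prior=prior, feature_bounds=bounds
    )
    model.fit(X, y)
    model.scope_ = scope
    model.feature_names_ = names
    return model


def class_posterior(model: BinnedNaiveBayes, vector) -> float:
    """P(Y=1 | non-missing features of one candidate)."""
    return float(model.predict_proba(np.asarray(vector, dtype=float)[None, :])[0, 1])


def combine_posteriors(p_pep: float, p_pro: float, prior: float = 0.5) -> float:
    """Bayes-theorem combination of two independent classifiers' posteriors.

    Since each posterior already contains one factor of the prior, the
    product is divided by it once; boundary probabilities are clipped to
    (0, 1) open interval to keep the odds finite.
    """
    p1 = min(max(p_pep, _EPS), 1 - _EPS)
    p2 = min(max(p_pro, _EPS), 1 - _EPS)
    pr = min(max(prior, _EPS), 1 - _EPS)
    pos = p1 * p2 / pr
    neg = (1 - p1) * (1 - p2) / (1 - pr)
    return float(pos / (pos + neg))


@dataclass(frozen=True)
class PredictionRecord:
    """Scored candidate: per-classifier posteriors, their combination and
    the thresholded decision for one (domain protein, target, site)."""

    candidate_id: str
    p_pep: float | None
    p_pro: float | None
    combined: float
    features: dict
    decision: bool


@dataclass(frozen=True)
class MetricsReport:
    auroc: float
    auprc: float
    brier: float
    f1: float
    mcc: float
    acc: float
    threshold: float

    def as_dict(self):
        return {
            "AUROC": self.auroc, "AUPRC": self.auprc, "BRIER": self.brier,
            "F1": self.f1, "MCC": self.mcc, "ACC": self.acc,
        }


def evaluate(y_true, scores, threshold: float = DEFAULT_DECISION_THRESHOLD) -> MetricsReport:
    """Standard evaluation: AUROC (rank statistic with tie averaging),
    AUPRC (step-wise average precision), Brier score, and F1 / MCC /
    accuracy at the given decision threshold."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedMetric("need both classes to evaluate")
    pred = (s >= threshold).astype(int)
    return MetricsReport(
        auroc=float(skmetrics.roc_auc_score(y, s)),
        auprc=float(skmetrics.average_precision_score(y, s)),
        brier=float(skmetrics.brier_score_loss(y, np.clip(s, 0, 1))),
        f1=float(skmetrics.f1_score(y, pred, zero_division=0)),
        mcc=float(skmetrics.matthews_corrcoef(y, pred)),
        acc=float(skmetrics.accuracy_score(y, pred)),
        threshold=float(threshold),
    )


def aggregate_pairs(records, how: str = "max"):
    """Collapse per-site records to per-protein-pair scores.

    ``candidate_id`` is '<domain_protein>|<target>|<site>'; the pair key
    drops the site.  'max' keeps the best site (one true site suffices
    for an interaction); 'noisy-or' combines sites as independent
    chances.
    """
    pairs = {}
    for rec in records:
        key = "|".join(rec.candidate_id.split("|")[:2])
        pairs.setdefault(key, []).append(rec.combined)
    out = {}
    for key, vals in pairs.items():
        if how == "max":
            out[key] = max(vals)
        elif how == "noisy-or":
            prod = 1.0
            for v in vals:
                prod *= 1 - v
            out[key] = 1 - prod
        else:
            raise ValueError("how must be 'max' or 'noisy-or'")
    return out
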