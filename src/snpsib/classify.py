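"""The two classifiers: Fisher LDA and the sequential information bottleneck.

The sequential information bottleneck (sIB) is an unsupervised hard
clustering adapted for classification.  Each training sample x is
represented as a distribution p(y|x) over genotype feature tokens
(SNP, category) — for an s-SNP subset the profile puts mass 1/s on the
observed category of each SNP — and the algorithm seeks the K-cluster
hard partition C minimizing

    L = I(C; X) - beta * I(C; Y)

by repeatedly drawing single samples and re-inserting them into the
cluster of least L, over several random restarts.  Class labels enter
only afterwards: each non-empty cluster is labelled by its dominant
training class, and new samples are routed to the cheapest cluster by a
Jensen-Shannon insertion cost with the model frozen.

Fisher LDA is the classical linear rule maximizing the ratio of
between-class to within-class covariance, with a small ridge on the
pooled covariance for singular cases.

Both classifiers follow the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``get_params``) and compose with its model
selection utilities; ``sib_fit`` / ``lda_fit`` etc. are thin functional
wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _sib_kernel
from .genio import MISSING, GenotypeMatrix

__all__ = [
    "entropy",
    "mutual_information",
    "js_divergence",
    "ProfileSet",
    "build_sample_profiles",
    "ib_objective",
    "SIBClassifier",
    "FisherLDA",
    "sib_fit",
    "sib_predict",
    "lda_fit",
    "lda_predict",
]

_NORM_TOL = 1e-6


def _check_dist(p, name="distribution"):
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} has negative mass")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} is not normalized (sum={p.sum()!r})")
    return p


def _xlog2x(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v, dtype=float)
    nz = v > 0
    out[nz] = v[nz] * np.log2(v[nz])
    return out


def entropy(dist) -> float:
    """Shannon entropy in bits, with 0*log0 := 0."""
    p = _check_dist(dist)
    return float(-_xlog2x(p).sum())


def mutual_information(joint) -> float:
    """Mutual information (bits) of a joint probability table."""
    p = np.asarray(joint, dtype=float)
    _check_dist(p.ravel(), "joint table")
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    ratio = np.ones_like(p)
    ratio[nz] = p[nz] / (px @ py)[nz]
    return float((p[nz] * np.log2(ratio[nz])).sum())


def js_divergence(p, q, weights=(0.5, 0.5)) -> float:
    """Weighted Jensen-Shannon divergence in bits.

    JS_w(p, q) = w1*KL(p||m) + w2*KL(q||m) with m = w1*p + w2*q; the
    weights must be positive and sum to 1.
    """
    p = _check_dist(p, "p")
    q = _check_dist(q, "q")
    w1, w2 = float(weights[0]), float(weights[1])
    if w1 <= 0 or w2 <= 0 or abs(w1 + w2 - 1.0) > _NORM_TOL:
        raise ValueError("weights must be positive and sum to 1")
    m = w1 * p + w2 * q

    def kl(a):
        nz = a > 0
        return float((a[nz] * np.log2(a[nz] / m[nz])).sum())

    return w1 * kl(p) + w2 * kl(q)


@dataclass
class ProfileSet:
    """Sample profiles over the token space of one SNP subset.

    ``matrix`` is (n_samples, n_tokens) with each row a distribution
    putting mass 1/s on the observed (SNP, category) token of each of the
    s subset SNPs; ``tokens`` labels the columns; the prior p(x) is
    uniform 1/n.
    """

    matrix: np.ndarray
    tokens: list[tuple[str, int]]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def prior(self) -> float:
        return 1.0 / self.matrix.shape[0]


def build_sample_profiles(G, snp_ids=None, sample_idx=None) -> ProfileSet:
    """Build token profiles from genotype codes.

    ``G`` may be a GenotypeMatrix or a plain (n, s) code array; ``snp_ids``
    restricts/orders the SNPs (GenotypeMatrix input), ``sample_idx``
    restricts the rows.  The matrix must be complete (imputed).
    """
    if isinstance(G, GenotypeMatrix):
        ids = list(snp_ids) if snp_ids is not None else list(G.snp_ids)
        codes = G.subset_snps(ids).codes
    else:
        codes = np.asarray(G)
        ids = [f"f{j}" for j in range(codes.shape[1])]
    if sample_idx is not None:
        codes = codes[np.asarray(sample_idx)]
    if codes.ndim != 2 or codes.shape[1] == 0:
        raise ValueError("need a non-empty SNP subset")
    if (codes == MISSING).any():
        raise ValueError("profiles require complete (imputed) genotypes")
    n, s = codes.shape
    mat = np.zeros((n, 3 * s))
    cols = 3 * np.arange(s) + codes
    mat[np.arange(n)[:, None], cols] = 1.0 / s
    tokens = [(sid, cat) for sid in ids for cat in range(3)]
    return ProfileSet(matrix=mat, tokens=tokens)


def ib_objective(partition, profiles: ProfileSet, beta: float) -> float:
    """Information-bottleneck functional L = I(C;X) - beta*I(C;Y).

    For a hard partition with uniform p(x), I(C;X) reduces to H(C); I(C;Y)
    is computed from the induced joint p(c, y) = sum_{x in c} p(x) p(y|x).
    """
    part = np.asarray(partition)
    n = profiles.n_samples
    if part.shape != (n,):
        raise ValueError("partition must assign every profile")
    clusters = np.unique(part)
    joint = np.stack([profiles.matrix[part == c].sum(axis=0) / n for c in clusters])
    masses = joint.sum(axis=1)
    return float(entropy(masses) - beta * mutual_information(joint))


class SIBClassifier(ClassifierMixin, BaseEstimator):
    """Sequential information-bottleneck clustering as a binary classifier.

    Parameters
    ----------
    n_clusters : int or "auto", default "auto"
        Number of hard clusters K.  "auto" resolves the full genotype
        pattern space of small subsets, K = min(3^n_snps, 9, n_samples):
        for the 1- and 2-SNP subsets of the exhaustive searches the
        dominant-class labelling then acts as a genotype-cell majority
        rule.  A fixed small K (e.g. 2) compresses harder but ties the
        partition to coarse genotype groupings that need not align with
        case/control structure.
    beta : float, default 10.0
        Relevance weight in L = I(C;X) - beta*I(C;Y); large beta puts the
        optimization in the regime where preserving token information
        dominates compression.
    n_restarts : int, default 10
        Random restarts; the partition with minimal L wins.
    max_sweeps : int, default 50
        Cap on full passes through the data per restart; a restart stops
        earlier as soon as a sweep makes no reassignment.
    random_state : int, default 0
        Seed for the restart initializations and the per-sweep sample order.

    Attributes (after fit)
    ----------------------
    assignment_ : (n,) cluster index per training sample (hard).
    cluster_mass_ : (K,) p(c).
    cluster_profile_ : (K, T) p(y|c); zero rows for empty clusters.
    cluster_label_ : (K,) majority training class per cluster (ties ->
        control); -1 marks an empty cluster, skipped at prediction.
    objective_ : final value of L for the winning restart.
    """

    def __init__(self, n_clusters="auto", beta=10.0, n_restarts=10, max_sweeps=50,
                 random_state=0):
        self.n_clusters = n_clusters
        self.beta = beta
        self.n_restarts = n_restarts
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    # -- internal -------------------------------------------------------
    @staticmethod
    def _tokens(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be (n_samples, n_snps) with >=1 SNP")
        if X.size and (int(X.min()) < 0 or int(X.max()) > 2):
            raise ValueError("genotype codes must be 0/1/2 (impute missing first)")
        return (3 * np.arange(X.shape[1])[None, :] + X).astype(np.int32)

    def fit(self, X, y, record_trace: bool = False):
        tokens = self._tokens(X)
        y = np.asarray(y)
        n, s = tokens.shape
        if self.n_clusters == "auto":
            K = int(min(3**min(s, 2), 9, n))
        else:
            K = int(self.n_clusters)
        if y.shape != (n,):
            raise ValueError("y length must match X")
        if not np.isin(y, (0, 1)).all() or len(np.unique(y)) < 2:
            raise ValueError("y must be binary with both classes present")
        if K > n:
            raise ValueError(f"n_clusters={K} exceeds n_samples={n}")
        seed = int(self.random_state) % (2**31 - 1 - self.n_restarts)
        assign, L, trace_L, trace_r = _sib_kernel.sib_sweeps(
            tokens, 3 * s, K, float(self.beta), int(self.n_restarts),
            int(self.max_sweeps), seed, record_trace,
        )
        self.n_features_in_ = s
        self.classes_ = np.array([0, 1])
        self.n_train_ = n
        self.assignment_ = assign
        self.objective_ = float(L)
        counts = np.bincount(assign, minlength=K).astype(float)
        self.cluster_mass_ = counts / n
        prof = np.zeros((K, 3 * s))
        labels = np.full(K, -1, dtype=np.int8)
        mat = np.zeros((n, 3 * s))
        cols = 3 * np.arange(s) + np.asarray(X)
        mat[np.arange(n)[:, None], cols.astype(int)] = 1.0 / s
        for c in range(K):
            members = assign == c
            if members.any():
                prof[c] = mat[members].sum(axis=0) / counts[c]
                n_case = int(y[members].sum())
                labels[c] = 1 if n_case > members.sum() - n_case else 0
        self.cluster_profile_ = prof
        self.cluster_label_ = labels
        if record_trace:
            self.trace_objective_ = trace_L
            self.trace_restart_ = trace_r
        return self

    def _insertion_costs(self, X) -> np.ndarray:
        """(n, K) frozen JS insertion cost; inf for empty clusters."""
        tokens = self._tokens(X)
        n, s = tokens.shape
        if s != self.n_features_in_:
            raise ValueError(
                f"token space mismatch: model has {self.n_features_in_} SNPs, X has {s}"
            )
        inv_s = 1.0 / s
        p_x = 1.0 / self.n_train_
        K = self.cluster_mass_.size
        costs = np.full((n, K), np.inf)
        for c in range(K):
            p_c = self.cluster_mass_[c]
            if self.cluster_label_[c] < 0 or p_c == 0.0:
                continue
            w1 = p_x / (p_x + p_c)
            w2 = 1.0 - w1
            pc_tok = self.cluster_profile_[c][tokens]  # (n, s)
            m_tok = w1 * inv_s + w2 * pc_tok
            kl_x = (inv_s * np.log2(inv_s / m_tok)).sum(axis=1)
            nz = pc_tok > 0
            contrib = np.zeros_like(pc_tok)
            contrib[nz] = pc_tok[nz] * np.log2(pc_tok[nz] / m_tok[nz])
            kl_c = np.log2(1.0 / w2) * (1.0 - pc_tok.sum(axis=1)) + contrib.sum(axis=1)
            costs[:, c] = (p_x + p_c) * (w1 * kl_x + w2 * kl_c)
        return costs

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "assignment_"):
            raise ValueError("model is not fitted")
        costs = self._insertion_costs(X)
        if not np.isfinite(costs).any(axis=1).all():
            raise ValueError("all clusters are empty")
        best = costs.argmin(axis=1)  # ties -> lowest cluster index
        return self.cluster_label_[best].astype(np.int8)

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        """Serialize the fitted model to a documented JSON text form."""
        if not hasattr(self, "assignment_"):
            raise ValueError("model is not fitted")
        return json.dumps(
            {
                "model": "sib",
                "params": self.get_params(),
                "n_features_in": int(self.n_features_in_),
                "n_train": int(self.n_train_),
                "assignment": self.assignment_.tolist(),
                "cluster_mass": self.cluster_mass_.tolist(),
                "cluster_profile": self.cluster_profile_.tolist(),
                "cluster_label": self.cluster_label_.tolist(),
                "objective": self.objective_,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SIBClassifier":
        d = json.loads(text)
        if d.get("model") != "sib":
            raise ValueError("not a serialized SIBClassifier")
        model = cls(**d["params"])
        model.n_features_in_ = d["n_features_in"]
        model.n_train_ = d["n_train"]
        model.classes_ = np.array([0, 1])
        model.assignment_ = np.array(d["assignment"], dtype=np.int32)
        model.cluster_mass_ = np.array(d["cluster_mass"])
        model.cluster_profile_ = np.array(d["cluster_profile"])
        model.cluster_label_ = np.array(d["cluster_label"], dtype=np.int8)
        model.objective_ = d["objective"]
        return model


class FisherLDA(ClassifierMixin, BaseEstimator):
    """Fisher linear discriminant for two classes on genotype codes.

    The weight vector solves (S_w + ridge*I) w = mu_case - mu_control with
    S_w the unbiased pooled within-class covariance and
    ridge = ridge_eps * trace(S_w)/d, escalated tenfold until the system
    solves.  The threshold is w . (mu_case + mu_control)/2 (equal priors);
    a sample on the boundary is called a case.
    """

    def __init__(self, ridge_eps: float = 1e-8):
        self.ridge_eps = ridge_eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-D with at least one feature")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X")
        if not np.isin(y, (0, 1)).all() or len(np.unique(y)) < 2:
            raise ValueError("y must be binary with both classes present")
        n, d = X.shape
        mu1 = X[y == 1].mean(axis=0)
        mu0 = X[y == 0].mean(axis=0)
        Xc = X.copy()
        Xc[y == 1] -= mu1
        Xc[y == 0] -= mu0
        Sw = (Xc.T @ Xc) / (n - 2) if n > 2 else np.zeros((d, d))
        tr = float(np.trace(Sw))
        ridge = self.ridge_eps * tr / d if tr > 0 else self.ridge_eps
        diff = mu1 - mu0
        w = None
        for _ in range(40):
            try:
                cand = np.linalg.solve(Sw + ridge * np.eye(d), diff)
            except np.linalg.LinAlgError:
                cand = None
            if cand is not None and np.isfinite(cand).all():
                w = cand
                break
            ridge = ridge * 10 if ridge > 0 else max(1e-8 * tr / d, 1e-12)
        if w is None:
            raise np.linalg.LinAlgError("pooled covariance could not be regularized")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        self.coef_ = w
        self.class_means_ = np.stack([mu0, mu1])
        self.ridge_ = float(ridge)
        self.threshold_ = float(w @ (mu1 + mu0) / 2.0)
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ - self.threshold_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(np.int8)

    def to_json(self) -> str:
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        return json.dumps(
            {
                "model": "lda",
                "params": self.get_params(),
                "weights": self.coef_.tolist(),
                "threshold": self.threshold_,
                "class_means": self.class_means_.tolist(),
                "ridge": self.ridge_,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FisherLDA":
        d = json.loads(text)
        if d.get("model") != "lda":
            raise ValueError("not a serialized FisherLDA")
        model = cls(**d["params"])
        model.classes_ = np.array([0, 1])
        model.coef_ = np.array(d["weights"])
        model.n_features_in_ = model.coef_.size
        model.threshold_ = d["threshold"]
        model.class_means_ = np.array(d["class_means"])
        model.ridge_ = d["ridge"]
        return model


# -- functional wrappers ------------------------------------------------

def sib_fit(X, y, K="auto", beta=10.0, n_restarts=10, max_sweeps=50, seed=0,
            record_trace=False) -> SIBClassifier:
    """Fit a sequential-IB model on genotype codes; returns the fitted classifier."""
    return SIBClassifier(
        n_clusters=K, beta=beta, n_restarts=n_restarts, max_sweeps=max_sweeps,
        random_state=seed,
    ).fit(X, y, record_trace=record_trace)


def sib_predict(model: SIBClassifier, X) -> np.ndarray:
    return model.predict(X)


def lda_fit(X, y, ridge_eps: float = 1e-8) -> FisherLDA:
    return FisherLDA(ridge_eps=ridge_eps).fit(X, y)


def lda_predict(model: FisherLDA, X) -> np.ndarray:
    return model.predict(X)
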