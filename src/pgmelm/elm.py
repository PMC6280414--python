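"""Extreme-learning-machine family: ELM, ELM-AE (FISTA), H-ELM, W-ELM,
and the self-adaptive multilayer classifier (PGM-ELM decision stack).

All variants share the same recipe: a random (here orthogonalized) input
projection a, b, a sigmoid feature map H = g(X a + b), and a closed-form
ridge solve for the output weights

    beta = H' (I/C + H H')^{-1} T          (dual form)
         = (I/C + H' H)^{-1} H' T          (primal form, identical)

Desired outputs are 1 for the minority class and 0 for the majority class;
prediction thresholds the raw decision output at 0.5.

The multilayer classifier stacks Q unsupervised ELM-autoencoder feature
layers of P nodes each (layer weights from an l1-penalized reconstruction
solved with FISTA), then one supervised ELM decision layer.  P and Q are
not tuned by hand: they are set from the sample/feature counts and the
change of imbalance ratio produced by balancing,

    P = ceil((1 - dIR) * N/M + dIR * N'/M'),   Q = max(1, ceil(dIR * M')).

A larger ratio change (more generated samples) yields a deeper, wider net.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

_CEIL_EPS = 1e-9


def sigmoid(u: np.ndarray) -> np.ndarray:
    """Logistic activation g(u) = 1/(1 + exp(-u)), slope fixed at 1."""
    return expit(u)


def orthogonal_random_weights(d_in: int, nodes: int,
                              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random input weights a (d_in x nodes) and bias b (nodes,).

    Columns of a are orthonormalized by QR when nodes <= d_in; otherwise the
    transpose is orthonormalized (orthonormal rows).  b is a unit-norm
    random vector.
    """
    g = rng.standard_normal((d_in, nodes))
    if nodes <= d_in:
        a, _ = np.linalg.qr(g)
    else:
        q, _ = np.linalg.qr(g.T)
        a = q.T
    b = rng.standard_normal(nodes)
    b = b / np.linalg.norm(b)
    return a, b


def elm_solve(H: np.ndarray, T: np.ndarray, C: float) -> np.ndarray:
    """Regularized least-squares output weights (dual/primal equivalent)."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if C <= 0:
        raise ValueError("regularization C must be > 0")
    if not (np.isfinite(H).all() and np.isfinite(T).all()):
        raise ValueError("non-finite entries in H or T")
    n, L = H.shape
    if n <= L:  # dual: invert the n x n Gram matrix
        K = H @ H.T
        beta = H.T @ np.linalg.solve(np.eye(n) / C + K, T)
    else:       # primal: invert the L x L normal matrix (same solution)
        K = H.T @ H
        beta = np.linalg.solve(np.eye(L) / C + K, H.T @ T)
    return beta


def elm_ae_fit(X: np.ndarray, nodes: int, l1: float = 1e-3, iters: int = 50,
               seed: int = 0, return_trace: bool = False):
    """ELM-autoencoder layer weights by FISTA.

    Minimizes ||H beta - X||_F^2 + l1 * ||beta||_1 over beta, where
    H = g(X a + b) is a fixed random sigmoid feature map with orthogonal
    a, b.  Step size is 1/L with L = 2 * sigma_max(H)^2, the Lipschitz
    constant of the smooth part's gradient.

    Returns beta of shape (nodes, d); with ``return_trace`` also the
    per-iteration objective values.
    """
    X = np.asarray(X, dtype=float)
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    if l1 < 0:
        raise ValueError("l1 must be >= 0")
    rng = np.random.default_rng(seed)
    a, b = orthogonal_random_weights(X.shape[1], nodes, rng)
    H = sigmoid(X @ a + b)

    smax = np.linalg.norm(H, 2)
    L = 2.0 * smax * smax
    if L < 1e-12:
        beta = np.zeros((nodes, X.shape[1]))
        return (beta, [0.0]) if return_trace else beta
    step = 1.0 / L

    def objective(B):
        r = H @ B - X
        return float(np.sum(r * r) + l1 * np.sum(np.abs(B)))

    beta = np.zeros((nodes, X.shape[1]))
    yk = beta.copy()
    t = 1.0
    trace = []
    for it in range(iters):
        grad = 2.0 * H.T @ (H @ yk - X)
        z = yk - step * grad
        beta_new = np.sign(z) * np.maximum(np.abs(z) - step * l1, 0.0)
        obj = objective(beta_new)
        if not np.isfinite(obj):
            raise RuntimeError(f"FISTA objective diverged at iteration {it}")
        t_new = (1.0 + math.sqrt(1.0 + 4.0 * t * t)) / 2.0
        yk = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        trace.append(obj)
    return (beta, trace) if return_trace else beta


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class ELMLayer:
    """One layer: feature layers carry only ``beta`` (the forward mapping,
    d_in x nodes, from the transposed ELM-AE reconstruction weights);
    the decision layer also carries the random projection a, b."""

    beta: np.ndarray
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    C: float | None = None


@dataclass
class MLELMModel:
    """Stacked ELM-AE feature layers plus one ELM decision layer.

    ``layers`` holds Q feature layers followed by the decision layer
    (Q + 1 entries).  ``n_nodes`` (P) and ``n_layers`` (Q) record the
    self-adaptive structure; ``seed`` the single source of randomness.
    """

    layers: list[ELMLayer] = field(default_factory=list)
    n_nodes: int = 0
    n_layers: int = 0
    C: float = 1.0
    seed: int = 0

    @property
    def decision_layer(self) -> ELMLayer:
        return self.layers[-1]


@dataclass
class SingleELMModel:
    """Plain (or weighted) single-hidden-layer ELM."""

    a: np.ndarray = None
    b: np.ndarray = None
    beta: np.ndarray = None
    C: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# structure selection
# ---------------------------------------------------------------------------

def adaptive_structure(n_samples: int, n_features: int, n_samples_new: int,
                       n_components: int, d_ir: float) -> tuple[int, int]:
    """Self-adaptive (P, Q): hidden nodes per layer and layer count.

    P interpolates between the raw samples-per-feature ratio N/M and the
    balanced ratio N'/M' by the imbalance-ratio change dIR; Q grows with
    dIR * M' and is clamped to >= 1 so a model always exists (an already
    balanced set gives dIR = 0, hence a single layer of ceil(N/M) nodes).
    """
    if min(n_samples, n_features, n_samples_new, n_components) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0.0 <= d_ir < 1.0:
        raise ValueError(f"delta IR must be in [0, 1), got {d_ir}")
    p = math.ceil((1.0 - d_ir) * n_samples / n_features
                  + d_ir * n_samples_new / n_components - _CEIL_EPS)
    q = max(1, math.ceil(d_ir * n_components - _CEIL_EPS))
    return max(1, p), q


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _feature_stack(Z, P, Q, l1, iters, rng):
    layers = []
    cur = np.asarray(Z, dtype=float)
    for _ in range(Q):
        beta_ae = elm_ae_fit(cur, P, l1=l1, iters=iters,
                             seed=int(rng.integers(2**31 - 1)))
        W = beta_ae.T                      # d_in x P forward mapping
        layers.append(ELMLayer(beta=W))
        cur = sigmoid(cur @ W)
    return layers, cur


def helm_forward(X: np.ndarray, model: MLELMModel) -> np.ndarray:
    """Propagate through the feature layers: H_i = g(H_{i-1} beta_i)."""
    cur = np.atleast_2d(np.asarray(X, dtype=float))
    for layer in model.layers[: model.n_layers]:
        if cur.shape[1] != layer.beta.shape[0]:
            raise ValueError(
                f"layer expects {layer.beta.shape[0]} inputs, got {cur.shape[1]}"
            )
        cur = sigmoid(cur @ layer.beta)
    return cur


def pgmelm_fit(Z: np.ndarray, y: np.ndarray, P: int, Q: int, C: float = 1.0,
               seed: int = 0, l1: float = 1e-3, fista_iters: int = 50) -> MLELMModel:
    """Fit the multilayer classifier on a (balanced) component matrix.

    Q ELM-AE feature layers of P nodes each are trained layer-wise, then a
    supervised decision layer with orthogonal random a, b solves the ridge
    system against targets 1 (minority) / 0 (majority).  All randomness
    derives from ``seed``.
    """
    if P < 1 or Q < 1:
        raise ValueError(f"invalid structure P={P}, Q={Q}")
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    layers, H_feat = _feature_stack(Z, P, Q, l1, fista_iters, rng)
    a, b = orthogonal_random_weights(H_feat.shape[1], P, rng)
    H = sigmoid(H_feat @ a + b)
    beta = elm_solve(H, y[:, None], C)
    layers.append(ELMLayer(beta=beta, a=a, b=b, C=C))
    return MLELMModel(layers=layers, n_nodes=P, n_layers=Q, C=C, seed=seed)


def elm_fit(X: np.ndarray, y: np.ndarray, nodes: int, C: float = 1.0,
            seed: int = 0) -> SingleELMModel:
    """Plain single-hidden-layer ELM with orthogonal random projection."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    a, b = orthogonal_random_weights(X.shape[1], nodes, rng)
    H = sigmoid(X @ a + b)
    beta = elm_solve(H, y[:, None], C)
    return SingleELMModel(a=a, b=b, beta=beta, C=C, seed=seed)


def welm_fit(X: np.ndarray, y: np.ndarray, nodes: int, C: float = 1.0,
             seed: int = 0) -> SingleELMModel:
    """Weighted ELM: per-sample weights w_i = 1/n_class(i).

    Solves beta = (I/C + H'WH)^{-1} H'WT with diagonal W, which counters the
    majority-class pull by giving every class the same total weight (the
    diagonal sums to the number of classes).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("weighted ELM needs both classes present")
    w = np.empty_like(y)
    for cls, cnt in zip(classes, counts):
        w[y == cls] = 1.0 / cnt
    rng = np.random.default_rng(seed)
    a, b = orthogonal_random_weights(X.shape[1], nodes, rng)
    H = sigmoid(X @ a + b)
    L = H.shape[1]
    Hw = H * w[:, None]
    beta = np.linalg.solve(np.eye(L) / C + H.T @ Hw, Hw.T @ y[:, None])
    return SingleELMModel(a=a, b=b, beta=beta, C=C, seed=seed)


def helm_fit(X: np.ndarray, y: np.ndarray, P: int, Q: int = 2, C: float = 1.0,
             seed: int = 0, l1: float = 1e-3, fista_iters: int = 50) -> MLELMModel:
    """Hierarchical ELM baseline: Q fixed ELM-AE layers + decision ELM."""
    return pgmelm_fit(X, y, P=P, Q=Q, C=C, seed=seed, l1=l1,
                      fista_iters=fista_iters)


def predict(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw decision scores and thresholded 0/1 labels (cut at 0.5)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(model, MLELMModel):
        H_feat = helm_forward(X, model)
        dec = model.decision_layer
        H = sigmoid(H_feat @ dec.a + dec.b)
        scores = (H @ dec.beta).ravel()
    elif isinstance(model, SingleELMModel):
        if X.shape[1] != model.a.shape[0]:
            raise ValueError(
                f"model expects {model.a.shape[0]} features, got {X.shape[1]}"
            )
        H = sigmoid(X @ model.a + model.b)
        scores = (H @ model.beta).ravel()
    else:
        raise TypeError(f"unknown model type {type(model)!r}")
    return scores, (scores >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _arr(x):
    return None if x is None else np.asarray(x).tolist()


def save_model(model, path) -> None:
    """Serialize a fitted model to one portable JSON file."""
    if isinstance(model, MLELMModel):
        doc = {
            "kind": "mlelm",
            "n_nodes": model.n_nodes, "n_layers": model.n_layers,
            "C": model.C, "seed": model.seed,
            "layers": [
                {"beta": _arr(l.beta), "a": _arr(l.a), "b": _arr(l.b),
                 "C": l.C}
                for l in model.layers
            ],
        }
    elif isinstance(model, SingleELMModel):
        doc = {"kind": "elm", "a": _arr(model.a), "b": _arr(model.b),
               "beta": _arr(model.beta), "C": model.C, "seed": model.seed}
    else:
        raise TypeError(f"cannot serialize {type(model)!r}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Load a model saved by :func:`save_model`; predictions round-trip
    bit-exactly (weights are stored at full repr precision)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc["kind"] == "mlelm":
        layers = [
            ELMLayer(beta=np.asarray(l["beta"]),
                     a=None if l["a"] is None else np.asarray(l["a"]),
                     b=None if l["b"] is None else np.asarray(l["b"]),
                     C=l["C"])
            for l in doc["layers"]
        ]
        return MLELMModel(layers=layers, n_nodes=doc["n_nodes"],
                          n_layers=doc["n_layers"], C=doc["C"], seed=doc["seed"])
    if doc["kind"] == "elm":
        return SingleELMModel(a=np.asarray(doc["a"]), b=np.asarray(doc["b"]),
                              beta=np.asarray(doc["beta"]), C=doc["C"],
                              seed=doc["seed"])
    raise ValueError(f"unknown model kind {doc['kind']!r}")
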