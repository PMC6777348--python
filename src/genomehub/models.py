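"""Built-in executable model kinds behind the unified predict API.

Three kinds cover the registry's closed set:

* :class:`PWMModel` — position-weight-matrix scanning; the per-sequence
  score is the maximum log2 odds over all windows on both strands.
* :class:`LinearModel` — dot product plus bias with an identity or
  sigmoid link; also the "head" object produced by transfer learning
  and ensemble fitting.
* :class:`LayeredModel` — a small fully-connected net (affine +
  relu/sigmoid/identity per layer) exposing intermediate activations,
  the substrate for activation-based transfer learning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataloading import one_hot_reverse_complement

# ---------------------------------------------------------------------------
# weight-matrix TSV IO (header row + numeric body)


def read_matrix_tsv(path: str | os.PathLike) -> np.ndarray:
    """Read a numeric matrix from TSV with a header row. Non-numeric
    cells raise with their row/column location."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    ncol = len(lines[0].split("\t"))
    rows = []
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != ncol:
            raise ValueError(f"{path}: row {r} has {len(cells)} cells, expected {ncol}")
        vals = []
        for c, cell in enumerate(cells, start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {r}, column {c}"
                ) from None
        rows.append(vals)
    return np.asarray(rows, dtype=np.float64)


def write_matrix_tsv(
    mat: np.ndarray, path: str | os.PathLike, header: Sequence[str] | None = None
) -> None:
    mat = np.atleast_2d(np.asarray(mat, dtype=np.float64))
    if header is None:
        header = [f"c{i}" for i in range(mat.shape[1])]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in mat:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWMModel:
    """Probabilistic motif model scored as summed log2 odds against a
    background distribution.

    Pseudocount handling: the odds of base b at motif position j are
    (probs[j,b] + pc*bg[b]) / ((1+pc)*bg[b]), which keeps every odds
    finite for pc > 0 while renormalising. An all-zero (N) input row has
    base probability 0 and contributes log2(pc/(1+pc)).
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a motif_len x 4 matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each probs row must sum to 1 (within 1e-6)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def motif_len(self) -> int:
        return self.probs.shape[0]

    def log_odds_matrix(self) -> np.ndarray:
        pc, bg = self.pseudocount, self.background
        with np.errstate(divide="ignore"):
            return np.log2((self.probs + pc * bg) / ((1.0 + pc) * bg))

    def zero_row_term(self) -> float:
        # contribution of an N position: base probability 0
        pc = self.pseudocount
        if pc == 0.0:
            return -np.inf
        return float(np.log2(pc / (1.0 + pc)))


def _scan_one_strand(model: PWMModel, onehot: np.ndarray) -> np.ndarray:
    m = model.motif_len
    L = onehot.shape[0]
    M = model.log_odds_matrix()
    windows = np.lib.stride_tricks.sliding_window_view(onehot, (m, 4)).reshape(
        L - m + 1, m, 4
    )
    # with pseudocount 0 some log-odds are -inf; split them out so that
    # 0 * -inf never poisons the window sums
    neg_inf = np.isneginf(M)
    finite = np.einsum("wjb,jb->w", windows, np.where(neg_inf, 0.0, M))
    inf_hits = np.einsum("wjb,jb->w", windows, neg_inf.astype(np.float64))
    scores = np.where(inf_hits > 0, -np.inf, finite)
    n_zero = m - windows.sum(axis=(1, 2))
    zterm = model.zero_row_term()
    if np.isneginf(zterm):
        scores = np.where(n_zero > 0, -np.inf, scores)
    else:
        scores = scores + n_zero * zterm
    return scores


def pwm_scan_score(model: PWMModel, seq_onehot: np.ndarray) -> float:
    """Maximum windowed log2-odds of the motif over a one-hot sequence,
    scanning the forward strand and (by default) the reverse complement."""
    seq_onehot = np.asarray(seq_onehot, dtype=np.float64)
    L, m = seq_onehot.shape[0], model.motif_len
    if L < m:
        raise ValueError(f"sequence length {L} shorter than motif length {m}")
    best = _scan_one_strand(model, seq_onehot).max()
    if model.scan_both_strands:
        rc = one_hot_reverse_complement(seq_onehot)
        best = max(best, _scan_one_strand(model, rc).max())
    return float(best)


# ---------------------------------------------------------------------------
# linear / layered


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_LINKS = {"identity": lambda z: z, "sigmoid": _sigmoid}


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float = 0.0
    link: str = "identity"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.weights.size < 1:
            raise ValueError("weights must have length >= 1")
        if self.link not in _LINKS:
            raise ValueError(f"link must be one of {sorted(_LINKS)}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return _LINKS[self.link](X @ self.weights + self.bias)


_NONLINEARITIES = {
    "relu": lambda z: np.maximum(z, 0.0),
    "sigmoid": _sigmoid,
    "identity": lambda z: z,
}


@dataclass
class Layer:
    weight: np.ndarray  # (n_in, n_out)
    bias: np.ndarray  # (n_out,)
    nonlinearity: str = "identity"

    def __post_init__(self) -> None:
        self.weight = np.atleast_2d(np.asarray(self.weight, dtype=np.float64))
        self.bias = np.asarray(self.bias, dtype=np.float64).ravel()
        if self.bias.shape[0] != self.weight.shape[1]:
            raise ValueError("bias length must equal weight output dimension")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"nonlinearity must be one of {sorted(_NONLINEARITIES)}")

    def forward(self, X: np.ndarray) -> np.ndarray:
        return _NONLINEARITIES[self.nonlinearity](X @ self.weight + self.bias)


@dataclass
class LayeredModel:
    """Fully-connected net; layer ids run 1..D, id 0 being the input."""

    layers: list[Layer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        for a, b in zip(self.layers, self.layers[1:]):
            if a.weight.shape[1] != b.weight.shape[0]:
                raise ValueError("adjacent layer dimensions incompatible")

    @property
    def depth(self) -> int:
        return len(self.layers)

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=np.float64)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def activations(self, layer_id: int, X: np.ndarray) -> np.ndarray:
        if not 0 <= layer_id <= self.depth:
            raise ValueError(
                f"layer_id {layer_id} out of range; valid range is 0..{self.depth}"
            )
        h = np.asarray(X, dtype=np.float64)
        for layer in self.layers[:layer_id]:
            h = layer.forward(h)
        return h


BuiltinModel = PWMModel | LinearModel | LayeredModel


def _flatten_batch(batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float64)
    return batch.reshape(batch.shape[0], -1)


def predict_on_batch(model: BuiltinModel, batch: np.ndarray) -> np.ndarray:
    """Uniform predict contract: (batch, ...) in, (batch, T) out, row
    order preserved. PWM models take (batch, L, 4) one-hot input; linear
    and layered models flatten trailing dimensions to features."""
    batch = np.asarray(batch, dtype=np.float64)
    if isinstance(model, PWMModel):
        if batch.ndim != 3 or batch.shape[2] != 4:
            raise ValueError("PWM models require a (batch, L, 4) one-hot batch")
        return np.array([[pwm_scan_score(model, row)] for row in batch])
    X = _flatten_batch(batch)
    if isinstance(model, LinearModel):
        if X.shape[1] != model.weights.size:
            raise ValueError(
                f"expected {model.weights.size} features, got {X.shape[1]}"
            )
        return model.predict(X)[:, None]
    if isinstance(model, LayeredModel):
        out = model.forward(X)
        return out if out.ndim == 2 else out[:, None]
    raise TypeError(f"unsupported model type {type(model).__name__}")


def layer_activations(model: LayeredModel, layer_id: int, batch: np.ndarray) -> np.ndarray:
    """Activations after layer ``layer_id``; id 0 is the flattened
    input, id D equals :func:`predict_on_batch`."""
    return model.activations(layer_id, _flatten_batch(batch))


# ---------------------------------------------------------------------------
# training


def fit_head_on_activations(
    activations: np.ndarray,
    labels: np.ndarray,
    l2: float = 1.0,
    seed: int = 0,
) -> LinearModel:
    """L2-penalised maximum-likelihood logistic regression on
    (precomputed) activations — the transfer-learning head.

    Minimises sum of log-losses + (l2/2)*||w||^2 (intercept unpenalised),
    solved to tolerance 1e-8; deterministic given the data.
    """
    from sklearn.linear_model import LogisticRegression

    activations = np.asarray(activations, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if activations.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class; need both classes")
    clf = LogisticRegression(
        C=1.0 / l2, solver="lbfgs", tol=1e-8, max_iter=20000, random_state=seed,
    )
    clf.fit(activations, labels)
    return LinearModel(
        weights=clf.coef_.ravel(), bias=float(clf.intercept_[0]), link="sigmoid"
    )


def init_layered_model(
    layer_sizes: Sequence[int], seed: int = 0, final_nonlinearity: str = "sigmoid"
) -> LayeredModel:
    """Random He-scaled initialisation; hidden layers relu, final layer
    sigmoid (binary outputs) by default."""
    rng = np.random.default_rng(seed)
    layers = []
    for i, (n_in, n_out) in enumerate(zip(layer_sizes, layer_sizes[1:])):
        W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        nl = final_nonlinearity if i == len(layer_sizes) - 2 else "relu"
        layers.append(Layer(W, np.zeros(n_out), nl))
    return LayeredModel(layers)


def train_layered_model(
    X: np.ndarray,
    y: np.ndarray,
    hidden_sizes: Sequence[int] = (16,),
    lr: float = 0.5,
    epochs: int = 100,
    seed: int = 0,
    model: LayeredModel | None = None,
) -> LayeredModel:
    """Train a sigmoid-output net on binary labels by full-batch
    gradient descent on the logistic loss.

    Deliberately plain (fixed step, fixed epoch count, seeded init) so
    that fixture pretraining is deterministic across platforms. Pass a
    ``model`` to continue training from existing parameters.
    """
    X = _flatten_batch(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    n, k = X.shape
    if model is None:
        model = init_layered_model([k, *hidden_sizes, 1], seed=seed)
    for _ in range(epochs):
        # forward pass, caching pre-activations
        hs = [X]
        zs = []
        h = X
        for layer in model.layers:
            z = h @ layer.weight + layer.bias
            zs.append(z)
            h = _NONLINEARITIES[layer.nonlinearity](z)
            hs.append(h)
        p = hs[-1].ravel()
        # gradient of mean logistic loss wrt final pre-activation (sigmoid out)
        delta = ((p - y) / n)[:, None]
        for li in range(model.depth - 1, -1, -1):
            layer = model.layers[li]
            gW = hs[li].T @ delta
            gb = delta.sum(axis=0)
            if li > 0:
                delta = delta @ layer.weight.T
                prev = model.layers[li - 1]
                if prev.nonlinearity == "relu":
                    delta = delta * (zs[li - 1] > 0)
                elif prev.nonlinearity == "sigmoid":
                    s = _NONLINEARITIES["sigmoid"](zs[li - 1])
                    delta = delta * s * (1 - s)
            layer.weight = layer.weight - lr * gW
            layer.bias = layer.bias - lr * gb
    return model
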