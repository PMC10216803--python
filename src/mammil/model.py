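"""The clustering-constrained gated-attention MIL network.

Given a bag of K patch embeddings ``H = {h_1 .. h_K}`` (rows of a K x M
matrix), the network

1. reduces each embedding to M' = 256 features with an FC + ReLU layer,
2. scores each patch with gated attention,

   ``a_k = softmax_k( w^T ( tanh(V h'_k) * sigmoid(U h'_k) ) )``

   where ``w in R^L``, ``V, U in R^{L x M'}`` are learnable and ``*`` is
   element-wise — the sigmoid gate restores non-linearity where tanh is
   near-linear, and the softmax makes the weights a probability vector so
   bags of different sizes are comparable,
3. pools the bag embedding ``B = sum_k a_k h'_k`` and classifies it with a
   256-unit hidden layer + sigmoid output (bag probability, BCE loss),
4. sorts attention scores and takes the k highest / k lowest patches as
   positive / negative evidence; a shared two-way instance classifier is
   trained on these with pseudo-labels (1 = positive evidence) under
   cross-entropy, constraining the instance feature space,
5. combines the losses as ``0.7 * BCE_bag + 0.3 * CCE_instance``.

Everything here is plain NumPy: the forward pass stores a cache from which
``backward_bag`` evaluates the exact analytic gradients (verified against
finite differences in the test suite). Dropout (rate 0.25) is applied after
the attention module's FC layers during training only, with inverted
scaling so evaluation needs no correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = [
    "MILParams",
    "AttentionState",
    "EvidenceSet",
    "init_params",
    "reduce_features",
    "gated_attention",
    "pool_bag",
    "classify_bag",
    "select_evidence",
    "instance_loss",
    "total_loss",
    "forward_bag",
    "backward_bag",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass
class MILParams:
    """All learnable arrays of the MIL head, by layer.

    ``Wr/br`` — reduction FC (M -> M'); ``V/U/w`` — gated attention;
    ``Wb1/bb1/wb2/bb2`` — bag classifier (M' -> 256 -> 1);
    ``Wi1/bi1/Wi2/bi2`` — instance classifier (M' -> 256 -> 2).
    """

    Wr: np.ndarray
    br: np.ndarray
    V: np.ndarray
    U: np.ndarray
    w: np.ndarray
    Wb1: np.ndarray
    bb1: np.ndarray
    wb2: np.ndarray
    bb2: np.ndarray
    Wi1: np.ndarray
    bi1: np.ndarray
    Wi2: np.ndarray
    bi2: np.ndarray

    def names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.names()}

    def copy(self) -> "MILParams":
        return MILParams(**{n: v.copy() for n, v in self.as_dict().items()})

    #: parameter names subject to L2 weight decay (weight matrices only;
    #: biases are exempt, as is common practice)
    DECAYED = ("Wr", "V", "U", "w", "Wb1", "wb2", "Wi1", "Wi2")

    @property
    def feature_dim(self) -> int:
        return self.Wr.shape[0]

    @property
    def reduced_dim(self) -> int:
        return self.Wr.shape[1]

    @property
    def attention_dim(self) -> int:
        return self.V.shape[0]


def _xavier(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[1] if len(shape) > 1 else 1
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    feature_dim: int,
    reduced_dim: int = 256,
    attention_dim: int = 256,
    hidden_dim: int = 256,
    seed: int | np.random.Generator = 0,
) -> MILParams:
    """Glorot-uniform weights, zero biases, reproducible from ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MILParams(
        Wr=_xavier(rng, (feature_dim, reduced_dim)),
        br=np.zeros(reduced_dim),
        V=_xavier(rng, (attention_dim, reduced_dim)),
        U=_xavier(rng, (attention_dim, reduced_dim)),
        w=_xavier(rng, (attention_dim,)),
        Wb1=_xavier(rng, (reduced_dim, hidden_dim)),
        bb1=np.zeros(hidden_dim),
        wb2=_xavier(rng, (hidden_dim,)),
        bb2=np.zeros(1),
        Wi1=_xavier(rng, (reduced_dim, hidden_dim)),
        bi1=np.zeros(hidden_dim),
        Wi2=_xavier(rng, (hidden_dim, 2)),
        bi2=np.zeros(2),
    )


# ---------------------------------------------------------------------------
# functional pieces (each independently testable)


@dataclass
class AttentionState:
    """Per-patch attention: pre-softmax scores and normalised weights."""

    raw_scores: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.raw_scores)):
            bad = int(np.flatnonzero(~np.isfinite(self.raw_scores))[0])
            raise FloatingPointError(f"non-finite attention score at patch {bad}")
        if abs(float(self.a.sum()) - 1.0) > 1e-6 or np.any(self.a < 0):
            raise ValueError("attention weights must form a probability vector")


@dataclass
class EvidenceSet:
    """Top-k / bottom-k attended patches with their pseudo-cluster labels."""

    positive_idx: np.ndarray
    negative_idx: np.ndarray
    k_eff: int

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.positive_idx, self.negative_idx])

    @property
    def pseudo_labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(self.k_eff, dtype=int), np.zeros(self.k_eff, dtype=int)]
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def reduce_features(H: np.ndarray, Wr: np.ndarray, br: np.ndarray) -> np.ndarray:
    """FC + ReLU dimensionality reduction: K x M -> K x M', entries >= 0."""
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if H.shape[1] != Wr.shape[0]:
        raise ValueError(f"feature dim {H.shape[1]} does not match weights {Wr.shape[0]}")
    return np.maximum(H @ Wr + br, 0.0)


def gated_attention(Hp: np.ndarray, V: np.ndarray, U: np.ndarray, w: np.ndarray) -> AttentionState:
    """Gated attention scores and softmax weights over a bag.

    ``raw_k = w^T (tanh(V h'_k) * sigmoid(U h'_k))``; weights are the
    softmax of the raw scores over the K patches (computed in one pass with
    the usual max-shift, which is exact for softmax).
    """
    Hp = np.atleast_2d(np.asarray(Hp, dtype=np.float64))
    raw = (np.tanh(Hp @ V.T) * _sigmoid(Hp @ U.T)) @ np.asarray(w).ravel()
    return AttentionState(raw_scores=raw, a=_softmax(raw))


def pool_bag(a: np.ndarray, Hp: np.ndarray) -> np.ndarray:
    """Attention-weighted bag embedding ``B = sum_k a_k h'_k``."""
    a = np.asarray(a, dtype=np.float64).ravel()
    Hp = np.atleast_2d(np.asarray(Hp, dtype=np.float64))
    if a.shape[0] != Hp.shape[0]:
        raise ValueError(f"{a.shape[0]} weights for {Hp.shape[0]} patches")
    return a @ Hp


def classify_bag(B: np.ndarray, params: MILParams) -> float:
    """Bag probability in (0, 1) from the 256-unit-hidden sigmoid classifier."""
    hidden = np.maximum(np.asarray(B, dtype=np.float64) @ params.Wb1 + params.bb1, 0.0)
    logit = hidden @ params.wb2 + params.bb2[0]
    return float(_sigmoid(np.array([logit]))[0])


def select_evidence(scores: np.ndarray | AttentionState, k: int = 8) -> EvidenceSet:
    """k highest- and k lowest-scoring patches, clamped to floor(K/2).

    Ties are broken toward the lower patch index (stable sort) so the
    selection is deterministic. Requires K >= 2 so the two evidence sets
    can be disjoint.
    """
    if isinstance(scores, AttentionState):
        scores = scores.raw_scores
    scores = np.asarray(scores, dtype=np.float64).ravel()
    K = scores.shape[0]
    if K < 2:
        raise ValueError(f"evidence selection needs at least 2 patches, got {K}")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, K // 2)
    asc = np.argsort(scores, kind="stable")
    desc = np.argsort(-scores, kind="stable")
    return EvidenceSet(
        positive_idx=desc[:k_eff].copy(), negative_idx=asc[:k_eff].copy(), k_eff=k_eff
    )


def _instance_logits(X: np.ndarray, params: MILParams) -> tuple[np.ndarray, np.ndarray]:
    z = X @ params.Wi1 + params.bi1
    r = np.maximum(z, 0.0)
    return z, r @ params.Wi2 + params.bi2


def instance_loss(
    H_selected: np.ndarray, pseudo_labels: np.ndarray, params: MILParams
) -> float:
    """Mean two-class cross-entropy of the instance classifier on evidence."""
    X = np.atleast_2d(np.asarray(H_selected, dtype=np.float64))
    t = np.asarray(pseudo_labels, dtype=int).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty evidence set")
    if X.shape[0] != t.shape[0]:
        raise ValueError("pseudo label count does not match instance count")
    _, logits = _instance_logits(X, params)
    logp = logits - _logsumexp_rows(logits)
    return float(-logp[np.arange(t.size), t].mean())


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    return m + np.log(np.exp(x - m).sum(axis=1, keepdims=True))


def total_loss(bag_bce: float, instance_cce: float, weights: tuple[float, float] = (0.7, 0.3)) -> float:
    """Weighted sum of bag and instance losses (defaults 0.7 / 0.3)."""
    if bag_bce < 0 or instance_cce < 0:
        raise ValueError("losses must be non-negative")
    return weights[0] * bag_bce + weights[1] * instance_cce


# ---------------------------------------------------------------------------
# full forward / backward over one bag


def forward_bag(
    params: MILParams,
    H: np.ndarray,
    y: int | None = None,
    *,
    k_evidence: int = 8,
    loss_weights: tuple[float, float] = (0.7, 0.3),
    dropout: float = 0.0,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """One bag through the whole head; returns outputs plus a backward cache.

    With ``train=True`` dropout masks are drawn from ``rng`` and the cache
    holds every intermediate needed by :func:`backward_bag`. ``y`` may be
    None for pure inference (no losses computed).
    """
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if not np.all(np.isfinite(H)):
        bad = int(np.flatnonzero(~np.isfinite(H).all(axis=1))[0])
        raise FloatingPointError(f"non-finite feature row at patch {bad}")
    K = H.shape[0]
    Z1 = H @ params.Wr + params.br
    R = np.maximum(Z1, 0.0)
    if train and dropout > 0.0:
        if rng is None:
            raise ValueError("training with dropout requires an rng")
        q = 1.0 - dropout
        M0 = (rng.random(R.shape) < q) / q
    else:
        M0 = None
    Hr = R if M0 is None else R * M0

    TA = Hr @ params.V.T
    SA = Hr @ params.U.T
    T = np.tanh(TA)
    S = _sigmoid(SA)
    G = T * S
    if train and dropout > 0.0:
        q = 1.0 - dropout
        M1 = (rng.random(G.shape) < q) / q
        Gd = G * M1
    else:
        M1 = None
        Gd = G
    raw = Gd @ params.w
    if not np.all(np.isfinite(raw)):
        bad = int(np.flatnonzero(~np.isfinite(raw))[0])
        raise FloatingPointError(f"non-finite attention score at patch {bad}")
    a = _softmax(raw)
    B = a @ Hr

    zb = B @ params.Wb1 + params.bb1
    rb = np.maximum(zb, 0.0)
    logit = float(rb @ params.wb2 + params.bb2[0])
    prob = float(_sigmoid(np.array([logit]))[0])

    out = {
        "prob": prob,
        "raw_scores": raw,
        "a": a,
        "B": B,
        "Hr": Hr,
        "K": K,
    }
    if y is None:
        return out

    eps = 1e-12
    bag_bce = -(y * np.log(prob + eps) + (1 - y) * np.log(1.0 - prob + eps))

    if K >= 2:
        ev = select_evidence(raw, k=k_evidence)
        Xi = Hr[ev.indices]
        zi, logits2 = _instance_logits(Xi, params)
        logp = logits2 - _logsumexp_rows(logits2)
        t = ev.pseudo_labels
        inst_cce = float(-logp[np.arange(t.size), t].mean())
        pi = np.exp(logp)
    else:  # singleton bag: no disjoint evidence exists, skip the constraint
        ev, Xi, zi, pi, t = None, None, None, None, None
        inst_cce = 0.0

    loss = total_loss(float(bag_bce), inst_cce, loss_weights)
    out.update(
        loss=loss,
        bag_bce=float(bag_bce),
        inst_cce=inst_cce,
        evidence=ev,
        cache={
            "H": H, "Z1": Z1, "M0": M0, "Hr": Hr, "TA": TA, "SA": SA, "T": T,
            "S": S, "M1": M1, "Gd": Gd, "raw": raw, "a": a, "B": B, "zb": zb,
            "rb": rb, "prob": prob, "y": y, "ev": ev, "Xi": Xi, "zi": zi,
            "pi": pi, "t": t, "loss_weights": loss_weights,
        },
    )
    return out


def backward_bag(params: MILParams, cache: dict) -> dict[str, np.ndarray]:
    """Analytic gradients of the combined loss w.r.t. every parameter.

    The evidence selection indices are treated as constants (the sort is
    piecewise constant in the scores), as in the reference formulation of
    clustering-constrained attention.
    """
    wb, wi = cache["loss_weights"]
    H, Hr, a = cache["H"], cache["Hr"], cache["a"]
    g = {n: np.zeros_like(v) for n, v in params.as_dict().items()}

    # bag classifier
    dlogit = wb * (cache["prob"] - cache["y"])
    g["wb2"] = dlogit * cache["rb"]
    g["bb2"] = np.array([dlogit])
    dzb = dlogit * params.wb2 * (cache["zb"] > 0)
    g["Wb1"] = np.outer(cache["B"], dzb)
    g["bb1"] = dzb
    dB = params.Wb1 @ dzb

    # pooling: B = a @ Hr
    da = Hr @ dB
    dHr = np.outer(a, dB)

    # instance branch
    if cache["ev"] is not None:
        n = cache["t"].size
        dlogits2 = cache["pi"].copy()
        dlogits2[np.arange(n), cache["t"]] -= 1.0
        dlogits2 *= wi / n
        ri = np.maximum(cache["zi"], 0.0)
        g["Wi2"] = ri.T @ dlogits2
        g["bi2"] = dlogits2.sum(axis=0)
        dzi = (dlogits2 @ params.Wi2.T) * (cache["zi"] > 0)
        g["Wi1"] = cache["Xi"].T @ dzi
        g["bi1"] = dzi.sum(axis=0)
        np.add.at(dHr, cache["ev"].indices, dzi @ params.Wi1.T)

    # softmax over raw scores
    draw = a * (da - float(da @ a))
    g["w"] = cache["Gd"].T @ draw
    dGd = np.outer(draw, params.w)
    dG = dGd if cache["M1"] is None else dGd * cache["M1"]
    T, S = cache["T"], cache["S"]
    dTA = dG * S * (1.0 - T * T)
    dSA = dG * T * S * (1.0 - S)
    g["V"] = dTA.T @ Hr
    g["U"] = dSA.T @ Hr
    dHr += dTA @ params.V + dSA @ params.U

    # reduction FC
    dR = dHr if cache["M0"] is None else dHr * cache["M0"]
    dZ1 = dR * (cache["Z1"] > 0)
    g["Wr"] = H.T @ dZ1
    g["br"] = dZ1.sum(axis=0)
    return g


# ---------------------------------------------------------------------------
# checkpoint I/O: one .npz of named arrays + a JSON sidecar


def save_checkpoint(
    path: str | Path,
    params: MILParams,
    meta: dict,
    extractor_norm: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write ``<path>.npz`` (parameter arrays, bit-exact) and ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = dict(params.as_dict())
    for key, val in (extractor_norm or {}).items():
        arrays[f"extractor.{key}"] = val
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> tuple[MILParams, dict, dict[str, np.ndarray]]:
    """Inverse of :func:`save_checkpoint`; returns (params, meta, extractor_norm)."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    extractor_norm = {
        k.split(".", 1)[1]: v for k, v in arrays.items() if k.startswith("extractor.")
    }
    param_arrays = {k: v for k, v in arrays.items() if not k.startswith("extractor.")}
    params = MILParams(**param_arrays)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return params, meta, extractor_norm
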