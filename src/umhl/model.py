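"""Three-branch hypergraph convolutional classifier with soft voting.

Each view (prior / local / global) runs the same two-layer hypergraph
convolution

    X' = delta( H_hat . Mask( H_hat^T X Theta ) )

where H_hat is the incidence matrix, optionally degree-normalised as
D_v^{-1/2} H D_e^{-1} H^T D_v^{-1/2} for numerical stability, and
Mask() drops whole hyperedge-feature rows at random during training
(inverted-scaling convention, identity at evaluation).  The prior and
local views mean-pool node features per (disjoint) hyperedge and
concatenate; the global view concatenates coordinate-wise max and mean
pools.  Per-view MLP heads produce class logits which are fused by
soft voting: softmax of the summed pre-softmax logits.

The forward and backward passes are written directly in numpy; the
gradients are exact (verified against finite differences in the test
suite), which keeps the dependency surface small and the arithmetic
deterministic.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fc import FCMatrix, fisher_z
from .hypergraph import Hypergraph

__all__ = [
    "ConvLayerParams",
    "BranchOutput",
    "ModelConfig",
    "UMHLModel",
    "hgconv",
    "local_pool",
    "global_pool",
    "branch_forward",
    "soft_vote",
    "softmax",
]

BRANCHES = ("prior", "local", "global")


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def incidence_operators(hg: Hypergraph, normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Node-scatter L and edge-gather R operators of a hypergraph.

    Unnormalised: L = H, R = H^T, so one conv layer is
    delta(H Mask(H^T X Theta)).  Normalised, the composition L @ R is
    the symmetric operator D_v^{-1/2} H D_e^{-1} H^T D_v^{-1/2}:
    L = D_v^{-1/2} H and R = D_e^{-1} H^T D_v^{-1/2}.  Zero degrees
    (possible only for empty views) invert to 0.
    """
    h = hg.incidence()
    if not normalize:
        return h, h.T
    dv = h.sum(axis=1)
    de = h.sum(axis=0)
    with np.errstate(divide="ignore"):
        dv_is = np.where(dv > 0, 1.0 / np.sqrt(dv), 0.0)
        de_inv = np.where(de > 0, 1.0 / de, 0.0)
    left = dv_is[:, None] * h
    right = de_inv[:, None] * (h.T * dv_is[None, :])
    return left, right


@dataclass
class ConvLayerParams:
    """One hypergraph convolution layer: weights + behaviour switches."""

    weight: np.ndarray
    activation: str = "relu"  # "relu" or "identity"
    mask_rate: float = 0.0
    normalize: bool = True

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if self.weight.ndim != 2 or not np.isfinite(self.weight).all():
            raise ValueError("conv weight must be a finite 2-D matrix")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.mask_rate < 1.0:
            raise ValueError("mask_rate must lie in [0, 1)")


@dataclass
class BranchOutput:
    """Result of one view: pooled embedding and pre-softmax class logits."""

    embedding: np.ndarray
    logits: np.ndarray
    branch: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.logits).all():
            raise ValueError("branch logits must be finite")


def mask_vector(n_edges: int, mask_rate: float, training: bool, rng: np.random.Generator | None) -> np.ndarray:
    """Per-hyperedge dropout multipliers (inverted scaling)."""
    if not training or mask_rate <= 0.0:
        return np.ones(n_edges)
    if rng is None:
        raise ValueError("training-time masking needs an rng")
    keep = rng.random(n_edges) >= mask_rate
    return keep.astype(float) / (1.0 - mask_rate)


def hgconv(
    x: np.ndarray,
    hg: Hypergraph,
    params: ConvLayerParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One hypergraph convolution: delta(L . Mask(R x Theta))."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != hg.n_vertices:
        raise ValueError(
            f"feature matrix has {x.shape[0] if x.ndim == 2 else '?'} rows, "
            f"hypergraph has {hg.n_vertices} vertices"
        )
    if x.shape[1] != params.weight.shape[0]:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match weight rows {params.weight.shape[0]}"
        )
    left, right = incidence_operators(hg, params.normalize)
    edge_feat = (right @ x) @ params.weight
    m = mask_vector(hg.n_edges, params.mask_rate, training, rng)
    z = left @ (m[:, None] * edge_feat)
    return relu(z) if params.activation == "relu" else z


def local_pool(x: np.ndarray, hg: Hypergraph, max_edges: int | None = None) -> np.ndarray:
    """Mean-pool node rows per disjoint hyperedge, concatenated.

    With ``max_edges`` the concatenation is padded with zero blocks so
    the embedding length is independent of how many hyperedges this
    particular subject produced.
    """
    x = np.asarray(x, dtype=float)
    seen: set[int] = set()
    for e in hg.hyperedges:
        if seen.intersection(e):
            raise ValueError("local pooling requires disjoint hyperedges")
        seen.update(e)
    n_e, d = hg.n_edges, x.shape[1]
    slots = n_e if max_edges is None else int(max_edges)
    if n_e > slots:
        raise ValueError(f"{n_e} hyperedges exceed the {slots} embedding slots")
    out = np.zeros((slots, d))
    for j, e in enumerate(hg.hyperedges):
        out[j] = x[list(e)].mean(axis=0)
    return out.ravel()


def global_pool(x: np.ndarray) -> np.ndarray:
    """Concatenate coordinate-wise max and mean over all nodes."""
    x = np.asarray(x, dtype=float)
    return np.concatenate([x.max(axis=0), x.mean(axis=0)])


def soft_vote(branch_outputs: Sequence[BranchOutput | np.ndarray], vote: str = "logits") -> np.ndarray:
    """Fuse branch logits into final class probabilities.

    ``vote="logits"`` (default): softmax of the summed pre-softmax
    logits.  ``vote="probs"``: each branch is softmaxed first and the
    summed probabilities are softmaxed again (compresses scale; kept as
    an alternative).
    """
    logits = [b.logits if isinstance(b, BranchOutput) else np.asarray(b, dtype=float) for b in branch_outputs]
    if not logits:
        raise ValueError("need at least one branch")
    if vote == "logits":
        return softmax(np.sum(logits, axis=0))
    if vote == "probs":
        return softmax(np.sum([softmax(l) for l in logits], axis=0))
    raise ValueError(f"unknown vote rule {vote!r}")


def predict_class(probs: np.ndarray) -> int:
    """Argmax with ties resolved toward the lower class index."""
    return int(np.argmax(probs))


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and regularisation switches of the full classifier.

    ``max_edges`` fixes the number of embedding slots of the local
    branch so its MLP input size is subject-independent; the default
    used by the trainer is ceil(sqrt(N)) * 2**d_max capped at N.
    """

    n_rois: int
    n_prior_edges: int
    max_edges: int
    hidden_dim: int = 64
    n_classes: int = 2
    mask_rate: float = 0.2
    normalize: bool = True
    vote: str = "logits"
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.n_classes < 2:
            raise ValueError("hidden_dim >= 1 and n_classes >= 2 required")
        if not 0.0 <= self.mask_rate < 1.0:
            raise ValueError("mask_rate must lie in [0, 1)")
        if self.vote not in ("logits", "probs"):
            raise ValueError(f"unknown vote rule {self.vote!r}")

    def pool_dim(self, branch: str) -> int:
        h = self.hidden_dim
        if branch == "prior":
            return self.n_prior_edges * h
        if branch == "local":
            return self.max_edges * h
        if branch == "global":
            return 2 * h
        raise ValueError(f"unknown branch {branch!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_rois", "n_prior_edges", "max_edges", "hidden_dim", "n_classes",
            "mask_rate", "normalize", "vote", "fisher_z",
        )}

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SubjectCache:
    """Precomputed per-subject quantities reused every epoch.

    For each branch: L (node scatter), R (edge gather), P = R @ X0
    (fixed first-layer edge input) and the mean-pool matrix B for
    partition-type views.
    """

    x0: np.ndarray
    ops: dict[str, dict] = field(default_factory=dict)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class UMHLModel:
    """Parameter container + forward/backward for the three-view net.

    Parameters live in a flat name -> array dict ("prior/theta1", ...)
    so a generic Adam loop can walk them.  Each branch owns two conv
    weights and a one-hidden-layer MLP head; branches never share
    parameters.
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    @classmethod
    def initialize(cls, config: ModelConfig, rng: np.random.Generator) -> "UMHLModel":
        d0, h, c = config.n_rois, config.hidden_dim, config.n_classes
        params: dict[str, np.ndarray] = {}
        for b in BRANCHES:
            pd = config.pool_dim(b)
            params[f"{b}/theta1"] = _glorot(rng, d0, h)
            params[f"{b}/theta2"] = _glorot(rng, h, h)
            params[f"{b}/w1"] = _glorot(rng, pd, h)
            params[f"{b}/b1"] = np.zeros(h)
            params[f"{b}/w2"] = _glorot(rng, h, c)
            params[f"{b}/b2"] = np.zeros(c)
        return cls(config, params)

    # -- cache construction --------------------------------------------------

    def build_cache(self, fc: FCMatrix, views: dict[str, Hypergraph]) -> SubjectCache:
        x0 = fisher_z(fc) if self.config.fisher_z else fc.features()
        cache = SubjectCache(x0=x0)
        for b in BRANCHES:
            hg = views[b]
            left, right = incidence_operators(hg, self.config.normalize)
            entry: dict = {
                "L": left,
                "R": right,
                "P": right @ x0,
                "n_edges": hg.n_edges,
            }
            if b in ("prior", "local"):
                pool = np.zeros((hg.n_edges, hg.n_vertices))
                for j, e in enumerate(hg.hyperedges):
                    pool[j, list(e)] = 1.0 / len(e)
                entry["B"] = pool
            cache.ops[b] = entry
        return cache

    # -- forward -------------------------------------------------------------

    def _branch_forward(
        self,
        b: str,
        cache: SubjectCache,
        training: bool,
        rng: np.random.Generator | None,
    ) -> dict:
        cfg = self.config
        op = cache.ops[b]
        left, right, p = op["L"], op["R"], op["P"]
        th1, th2 = self.params[f"{b}/theta1"], self.params[f"{b}/theta2"]
        w1, b1 = self.params[f"{b}/w1"], self.params[f"{b}/b1"]
        w2, b2 = self.params[f"{b}/w2"], self.params[f"{b}/b2"]

        m1 = mask_vector(op["n_edges"], cfg.mask_rate, training, rng)
        e1 = p @ th1
        z1 = left @ (m1[:, None] * e1)
        x1 = relu(z1)

        m2 = mask_vector(op["n_edges"], cfg.mask_rate, training, rng)
        q = right @ x1
        e2 = q @ th2
        z2 = left @ (m2[:, None] * e2)
        x2 = relu(z2)

        if b == "global":
            amax = np.argmax(x2, axis=0)
            emb = np.concatenate([x2[amax, np.arange(x2.shape[1])], x2.mean(axis=0)])
            pooled_shape = None
        else:
            pooled = op["B"] @ x2  # (E, h)
            emb = np.zeros(cfg.pool_dim(b))
            emb[: pooled.size] = pooled.ravel()
            amax = None
            pooled_shape = pooled.shape

        a_pre = emb @ w1 + b1
        a = relu(a_pre)
        logits = a @ w2 + b2
        return {
            "m1": m1, "z1": z1, "x1": x1, "m2": m2, "q": q, "z2": z2, "x2": x2,
            "emb": emb, "a_pre": a_pre, "a": a, "logits": logits,
            "amax": amax, "pooled_shape": pooled_shape,
        }

    def forward_subject(
        self,
        cache: SubjectCache,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict[str, dict]:
        return {b: self._branch_forward(b, cache, training, rng) for b in BRANCHES}

    def fused_probs(self, acts: dict[str, dict]) -> np.ndarray:
        return soft_vote([acts[b]["logits"] for b in BRANCHES], vote=self.config.vote)

    # -- backward ------------------------------------------------------------

    def backward_subject(
        self,
        cache: SubjectCache,
        acts: dict[str, dict],
        dlogits: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
    ) -> None:
        """Accumulate parameter gradients for one subject into ``grads``."""
        cfg = self.config
        for b in BRANCHES:
            op = cache.ops[b]
            st = acts[b]
            left, right, p = op["L"], op["R"], op["P"]
            th2 = self.params[f"{b}/theta2"]
            w1, w2 = self.params[f"{b}/w1"], self.params[f"{b}/w2"]
            dl = dlogits[b]

            grads[f"{b}/b2"] += dl
            grads[f"{b}/w2"] += np.outer(st["a"], dl)
            da = w2 @ dl
            da_pre = da * (st["a_pre"] > 0)
            grads[f"{b}/b1"] += da_pre
            grads[f"{b}/w1"] += np.outer(st["emb"], da_pre)
            demb = w1 @ da_pre

            h = cfg.hidden_dim
            if b == "global":
                dx2 = np.tile(demb[h:] / st["x2"].shape[0], (st["x2"].shape[0], 1))
                dx2[st["amax"], np.arange(h)] += demb[:h]
            else:
                n_e, _ = st["pooled_shape"]
                dpooled = demb[: n_e * h].reshape(n_e, h)
                dx2 = op["B"].T @ dpooled

            dz2 = dx2 * (st["z2"] > 0)
            dm2 = st["m2"][:, None] * (left.T @ dz2)
            grads[f"{b}/theta2"] += st["q"].T @ dm2
            dq = dm2 @ th2.T
            dx1 = right.T @ dq
            dz1 = dx1 * (st["z1"] > 0)
            dm1 = st["m1"][:, None] * (left.T @ dz1)
            grads[f"{b}/theta1"] += p.T @ dm1

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: all parameter arrays + config hash."""
        meta = json.dumps({"config": self.config.to_dict(), "hash": self.config.hash()})
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "UMHLModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            params = {k: npz[k] for k in npz.files if k != "__meta__"}
        return cls(ModelConfig(**meta["config"]), params)


def branch_forward(
    fc: FCMatrix,
    hg: Hypergraph,
    conv_stack: Sequence[ConvLayerParams],
    pool: str,
    mlp: Sequence[tuple[np.ndarray, np.ndarray]],
    max_edges: int | None = None,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> BranchOutput:
    """Reference single-branch forward pass built from the public ops.

    ``pool`` is "local" (per-hyperedge mean + concat, optionally padded
    to ``max_edges`` slots) or "global" (max|mean concat).  ``mlp`` is a
    list of (weight, bias) pairs with ReLU between all but the last.
    """
    x = fc.features()
    for layer in conv_stack:
        x = hgconv(x, hg, layer, training=training, rng=rng)
    if pool == "local":
        emb = local_pool(x, hg, max_edges=max_edges)
    elif pool == "global":
        emb = global_pool(x)
    else:
        raise ValueError(f"unknown pooling {pool!r}")
    a = emb
    for i, (w, b) in enumerate(mlp):
        a = a @ w + b
        if i < len(mlp) - 1:
            a = relu(a)
    tag = "global" if pool == "global" else ("prior" if hg.provenance == "prior" else "local")
    return BranchOutput(embedding=emb, logits=a, branch=tag)
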