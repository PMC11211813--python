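"""Residual MLP classifier over precomputed protein embeddings.

The classifier maps a fixed-length embedding vector x (5120-dimensional
protein-language-model vectors in the intended use) to one logit per
ontology class.  It stacks two MLP blocks, each computing

    Block(x) = Dropout(BatchNorm(ReLU(W x + b)))

with the second block wired as a residual update, h <- h + Block(h), followed
by a linear classification head.  Note the block applies batch
normalization *after* the ReLU; this order is intentional and is covered by
a regression test, since it differs from the more common norm-first layout.

Everything is implemented directly on numpy arrays with hand-written
backpropagation, which keeps the forward pass a pure deterministic function
of (parameters, input) in eval mode and makes training bit-reproducible
from a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable

import numpy as np

CHECKPOINT_FORMAT = "pufun-checkpoint-v1"


@dataclass
class EmbeddingMatrix:
    """Ordered protein ids with an n x d real feature matrix."""

    proteins: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.proteins):
            raise ValueError("embedding matrix shape does not match protein list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embeddings must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for prot, row in zip(self.proteins, self.values):
                fh.write(prot + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_embeddings_tsv(path) -> EmbeddingMatrix:
    proteins: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            proteins.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    return EmbeddingMatrix(proteins, np.vstack(rows))


@dataclass
class ScoreMatrix:
    """proteins x classes real matrix of raw logits or sigmoid scores."""

    proteins: list[str]
    index: "ClassIndex"
    values: np.ndarray
    kind: str = "logit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.proteins), len(self.index)):
            raise ValueError("score matrix shape mismatch")
        if self.kind not in ("logit", "probability"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.kind == "probability" and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("probability scores must lie in [0, 1]")


@dataclass
class ModelSpec:
    """Architecture hyperparameters of the residual MLP."""

    output_dim: int
    input_dim: int = 5120
    hidden_dim: int = 2048
    dropout: float = 0.1
    seed: int = 0
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.output_dim, self.input_dim, self.hidden_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def parameter_count(spec: ModelSpec) -> int:
    """Number of trainable parameters (affine weights/biases + BN scale/shift)."""
    d, h, k = spec.input_dim, spec.hidden_dim, spec.output_dim
    block1 = d * h + h + 2 * h
    block2 = h * h + h + 2 * h
    head = h * k + k
    return block1 + block2 + head


class ResidualMLP:
    """Two MLP blocks with a residual connection and a linear head.

    Parameters are initialized deterministically from ``spec.seed`` (He
    initialization for the affine weights, identity scale for the
    normalization layers).
    """

    PARAM_NAMES = ("W1", "b1", "g1", "be1", "W2", "b2", "g2", "be2", "W3", "b3")

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        d, h, k = spec.input_dim, spec.hidden_dim, spec.output_dim
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
            "b1": np.zeros(h),
            "g1": np.ones(h),
            "be1": np.zeros(h),
            "W2": rng.normal(0.0, np.sqrt(2.0 / h), size=(h, h)),
            "b2": np.zeros(h),
            "g2": np.ones(h),
            "be2": np.zeros(h),
            "W3": rng.normal(0.0, np.sqrt(2.0 / h), size=(h, k)),
            "b3": np.zeros(k),
        }
        self.running: dict[str, np.ndarray] = {
            "rm1": np.zeros(h),
            "rv1": np.ones(h),
            "rm2": np.zeros(h),
            "rv2": np.ones(h),
        }

    # -- forward -----------------------------------------------------------

    def _block(self, x, idx, mode, rng, cache):
        p, r, spec = self.params, self.running, self.spec
        W, b = p[f"W{idx}"], p[f"b{idx}"]
        g, be = p[f"g{idx}"], p[f"be{idx}"]
        z = x @ W + b
        a = np.maximum(z, 0.0)
        if mode == "train":
            m = a.shape[0]
            if m < 2:
                raise ValueError("train-mode forward needs batch size >= 2")
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            xhat = (a - mu) / np.sqrt(var + spec.bn_eps)
            mom = spec.bn_momentum
            var_unbiased = var * m / max(m - 1, 1)
            r[f"rm{idx}"] = (1 - mom) * r[f"rm{idx}"] + mom * mu
            r[f"rv{idx}"] = (1 - mom) * r[f"rv{idx}"] + mom * var_unbiased
        else:
            mu, var = r[f"rm{idx}"], r[f"rv{idx}"]
            xhat = (a - mu) / np.sqrt(var + spec.bn_eps)
        y = g * xhat + be
        if mode == "train" and spec.dropout > 0.0:
            mask = (rng.random(y.shape) >= spec.dropout) / (1.0 - spec.dropout)
            out = y * mask
        else:
            mask = None
            out = y
        cache[f"blk{idx}"] = {
            "x": x, "z": z, "xhat": xhat, "var": var, "mask": mask, "mode": mode,
        }
        return out

    def forward(self, X: np.ndarray, mode: str = "eval", rng: np.random.Generator | None = None):
        """Compute logits; returns ``(logits, cache)``.

        ``mode='train'`` uses batch normalization statistics (updating the
        running estimates) and applies dropout via ``rng``; ``mode='eval'``
        uses the running statistics and no dropout, making the output a pure
        function of (parameters, input).
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.spec.input_dim}), got {X.shape}"
            )
        if mode not in ("train", "eval"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "train" and self.spec.dropout > 0.0 and rng is None:
            raise ValueError("train mode with dropout requires an rng")
        cache: dict = {}
        h1 = self._block(X, 1, mode, rng, cache)
        h = h1 + self._block(h1, 2, mode, rng, cache)
        logits = h @ self.params["W3"] + self.params["b3"]
        cache["h1"], cache["h"] = h1, h
        return logits, cache

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, mode="eval")[0]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid of eval-mode logits; entries in (0, 1)."""
        from scipy.special import expit

        return expit(self.predict_logits(X))

    # -- backward ----------------------------------------------------------

    def _block_backward(self, dout, idx, cache, grads):
        p, spec = self.params, self.spec
        c = cache[f"blk{idx}"]
        g = p[f"g{idx}"]
        if c["mask"] is not None:
            dout = dout * c["mask"]
        grads[f"g{idx}"] = (dout * c["xhat"]).sum(axis=0)
        grads[f"be{idx}"] = dout.sum(axis=0)
        dxhat = dout * g
        inv_std = 1.0 / np.sqrt(c["var"] + spec.bn_eps)
        if c["mode"] == "train":
            m = dxhat.shape[0]
            da = (inv_std / m) * (
                m * dxhat
                - dxhat.sum(axis=0)
                - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0)
            )
        else:
            da = dxhat * inv_std
        dz = da * (c["z"] > 0)
        grads[f"W{idx}"] = c["x"].T @ dz
        grads[f"b{idx}"] = dz.sum(axis=0)
        return dz @ p[f"W{idx}"].T

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate a gradient w.r.t. the logits through the network."""
        grads: dict[str, np.ndarray] = {}
        grads["W3"] = cache["h"].T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W3"].T
        dh1 = dh + self._block_backward(dh, 2, cache, grads)
        self._block_backward(dh1, 1, cache, grads)
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays.update({f"running_{k}": v for k, v in self.running.items()})
        header = json.dumps({"format": CHECKPOINT_FORMAT, "spec": asdict(self.spec)})
        np.savez(path, __header__=np.array(header), **arrays)

    @classmethod
    def load(cls, path) -> "ResidualMLP":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["__header__"]))
            if header.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format: {header.get('format')}")
            model = cls(ModelSpec(**header["spec"]))
            for k in model.params:
                model.params[k] = data[f"param_{k}"]
            for k in model.running:
                model.running[k] = data[f"running_{k}"]
        return model

    def state_equal(self, other: "ResidualMLP") -> bool:
        return all(
            np.array_equal(self.params[k], other.params[k]) for k in self.params
        ) and all(
            np.array_equal(self.running[k], other.running[k]) for k in self.running
        )


class Adam:
    """Adam optimizer over a named parameter dict (bias-corrected moments)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


class CyclicLR:
    """Triangular cyclic learning-rate schedule bounded by [min_lr, max_lr]."""

    def __init__(self, min_lr: float, max_lr: float, step_size_up: int):
        if not 0 < min_lr < max_lr:
            raise ValueError("require 0 < min_lr < max_lr")
        if step_size_up < 1:
            raise ValueError("step_size_up must be >= 1")
        self.min_lr = min_lr
        self.max_lr = max_lr
        self.step_size_up = step_size_up

    def lr(self, step: int) -> float:
        cycle_pos = step % (2 * self.step_size_up)
        frac = cycle_pos / self.step_size_up
        if frac > 1.0:
            frac = 2.0 - frac
        return self.min_lr + (self.max_lr - self.min_lr) * frac
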