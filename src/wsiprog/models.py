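"""Dual-branch risk models.

Each branch is: convolutional encoder -> K-dimensional feature (2048 for the
reference backbones) -> fully-connected + batch-norm + ReLU projection to a
32-dimensional embedding -> linear head producing a scalar risk score. The
fused model drops both branch heads, concatenates the two embeddings
(64-dim) and predicts through a small MLP fusion head. Risk kinds are
``macro`` (tissue-organization map input, 8 channels), ``micro`` (stacked
patch tensor input, 3x27 = 81 channels) and ``fused``.

Backbones
---------
``tiny_test``
    A two-stage CNN (stride-2 convs, batch norm, global average pooling)
    small enough for CPU test suites; interchangeable with the reference
    backbone behind :class:`EncoderSpec`.
``reference_large``
    A residual bottleneck encoder in the ResNet-50 family (four stages,
    widths 256/512/1024/2048, depth reduced to one block per stage) ending
    in a 2048-dimensional pooled feature. The micro variant uses grouped
    3x3 convolutions (cardinality 32), ResNeXt-style. First layers are
    constructed at the required channel count (8 or 81) with fresh random
    initialization.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import nn
from .categories import N_CATEGORIES

__all__ = ["EncoderSpec", "BranchNet", "MacroNet", "MicroNet", "FusedNet",
           "EMBED_DIM", "REFERENCE_FEATURE_DIM"]

EMBED_DIM = 32
REFERENCE_FEATURE_DIM = 2048


@dataclass
class EncoderSpec:
    """Backbone choice for one branch."""

    backbone: str = "tiny_test"          # or "reference_large"
    in_channels: int = N_CATEGORIES
    feature_dim: int = 32                # forced to 2048 for reference_large
    grouped: bool = False                # ResNeXt-style grouped convs

    def __post_init__(self):
        if self.backbone not in ("tiny_test", "reference_large"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "reference_large":
            self.feature_dim = REFERENCE_FEATURE_DIM


def _tiny_encoder(spec: EncoderSpec, rng) -> nn.Sequential:
    w1 = max(8, spec.feature_dim // 2)
    w2 = spec.feature_dim
    return nn.Sequential([
        nn.Conv2d(spec.in_channels, w1, 3, rng, stride=2, padding=1),
        nn.BatchNorm2d(w1), nn.ReLU(),
        nn.Conv2d(w1, w2, 3, rng, stride=2, padding=1),
        nn.BatchNorm2d(w2), nn.ReLU(),
        nn.GlobalAvgPool(),
    ])


def _bottleneck(c_in: int, c_out: int, stride: int, rng, groups: int) -> nn.Residual:
    mid = c_out // 4
    body = nn.Sequential([
        nn.Conv2d(c_in, mid, 1, rng), nn.BatchNorm2d(mid), nn.ReLU(),
        nn.Conv2d(mid, mid, 3, rng, stride=stride, padding=1, groups=groups),
        nn.BatchNorm2d(mid), nn.ReLU(),
        nn.Conv2d(mid, c_out, 1, rng), nn.BatchNorm2d(c_out),
    ])
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential([nn.Conv2d(c_in, c_out, 1, rng, stride=stride),
                                  nn.BatchNorm2d(c_out)])
    return nn.Residual(body, shortcut)


def _reference_encoder(spec: EncoderSpec, rng) -> nn.Sequential:
    groups = 32 if spec.grouped else 1
    layers: list[nn.Layer] = [
        nn.Conv2d(spec.in_channels, 64, 3, rng, stride=2, padding=1),
        nn.BatchNorm2d(64), nn.ReLU(),
    ]
    c_in = 64
    for c_out, stride in ((256, 1), (512, 2), (1024, 2), (2048, 2)):
        layers.append(_bottleneck(c_in, c_out, stride, rng, groups))
        c_in = c_out
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers)


def build_encoder(spec: EncoderSpec, rng) -> nn.Sequential:
    if spec.backbone == "tiny_test":
        return _tiny_encoder(spec, rng)
    return _reference_encoder(spec, rng)


class BranchNet:
    """Encoder + 32-d projection + linear risk head for one branch."""

    kind = "branch"

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.encoder = build_encoder(spec, rng)
        self.project = nn.Sequential([
            nn.Linear(spec.feature_dim, EMBED_DIM, rng),
            nn.BatchNorm1d(EMBED_DIM), nn.ReLU(),
        ])
        self.head = nn.Linear(EMBED_DIM, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.project.params() + self.head.params()

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"{type(self).__name__} expects (N, {self.spec.in_channels}, H, W), "
                f"got {x.shape}")
        return x

    def embed(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        feat = self.encoder.forward(self._check_input(x), train=train)
        return self.project.forward(feat, train=train)

    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (embedding (N, 32), risk (N,))."""
        emb = self.embed(x, train=train)
        risk = self.head.forward(emb, train=train)[:, 0]
        return emb, risk

    def backward(self, d_risk: np.ndarray) -> None:
        g = self.head.backward(d_risk[:, None])
        g = self.project.backward(g)
        self.encoder.backward(g)

    def predict_risk(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)[1]

    def clone(self) -> "BranchNet":
        return copy.deepcopy(self)


class MacroNet(BranchNet):
    """Risk from the 8-channel tissue-organization map."""

    kind = "macro"

    def __init__(self, spec: EncoderSpec | None = None, seed: int = 0):
        spec = spec or EncoderSpec(in_channels=N_CATEGORIES)
        if spec.in_channels != N_CATEGORIES:
            raise ValueError("macro branch requires 8 input channels")
        super().__init__(spec, seed=seed)


class MicroNet(BranchNet):
    """Risk from the stacked patch tensor (S tiles -> 3S channels)."""

    kind = "micro"

    def __init__(self, spec: EncoderSpec | None = None, n_slots: int = 27,
                 seed: int = 0):
        self.n_slots = n_slots
        spec = spec or EncoderSpec(in_channels=3 * n_slots)
        if spec.in_channels != 3 * n_slots:
            raise ValueError(f"micro branch with {n_slots} slots requires "
                             f"{3 * n_slots} input channels")
        super().__init__(spec, seed=seed)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 5:  # (N, S, h, w, 3) stacked tiles
            if x.shape[1] != self.n_slots:
                raise ValueError(f"expected {self.n_slots} slots, got {x.shape[1]}")
            n, s, h, w, _ = x.shape
            x = x.transpose(0, 1, 4, 2, 3).reshape(n, 3 * s, h, w)
        return super()._check_input(x)


class FusedNet:
    """Dual-branch model: both embeddings -> MLP fusion head -> fused risk.

    Branch risk heads are unused in fused mode; gradients flow end-to-end
    into both encoders. Hidden widths default to (64, 32).
    """

    kind = "fused"

    def __init__(self, macro: MacroNet, micro: MicroNet,
                 hidden: tuple[int, ...] = (64, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.macro = macro
        self.micro = micro
        layers: list[nn.Layer] = []
        d = 2 * EMBED_DIM
        for h in hidden:
            layers += [nn.Linear(d, h, rng), nn.ReLU()]
            d = h
        layers.append(nn.Linear(d, 1, rng))
        self.fusion = nn.Sequential(layers)

    def params(self) -> list[nn.Param]:
        return self.macro.params() + self.micro.params() + self.fusion.params()

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    def forward(self, x, train: bool = True):
        """``x`` is a (macro_batch, micro_batch) pair.

        Returns (embeddings pair, fused risk (N,)).
        """
        xm, xu = x
        em = self.macro.embed(xm, train=train)
        eu = self.micro.embed(xu, train=train)
        z = np.concatenate([em, eu], axis=1)
        risk = self.fusion.forward(z, train=train)[:, 0]
        return (em, eu), risk

    def backward(self, d_risk: np.ndarray) -> None:
        g = self.fusion.backward(d_risk[:, None])
        gm, gu = g[:, :EMBED_DIM], g[:, EMBED_DIM:]
        g2 = self.macro.project.backward(gm)
        self.macro.encoder.backward(g2)
        g2 = self.micro.project.backward(gu)
        self.micro.encoder.backward(g2)

    def predict_risk(self, x) -> np.ndarray:
        return self.forward(x, train=False)[1]

    def clone(self) -> "FusedNet":
        return copy.deepcopy(self)
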