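"""The three networks: feature extractor F, domain discriminator D, classifier C.

F is a multi-scale bank of three parallel two-block convolutional
branches with kernels (3, 5), (5, 8) and (8, 10); their flattened
outputs are concatenated into one feature vector (length 9408 for the
default 411-sample input).  D consumes that vector as a 1-channel
sequence through three convolutional blocks and two fully connected
layers, emitting a source/target probability.  C reduces the feature
vector through two fully connected blocks to 10 units, fuses them with
the six RR time features and projects the 16-vector to 4 class logits.

Two reduced variants are available for ablation: ``model_a`` (a single
kernel-3 branch, no RR fusion) and ``model_a_rr`` (the same branch with
RR fusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features_balance import N_TIME_FEATURES
from .preprocess import DEFAULT_D

N_CLASSES = 4
VARIANTS = ("multi_scale", "model_a", "model_a_rr")

#: (kernel, channels) per block for each parallel branch of the
#: multi-scale extractor; every block is Conv -> Dropout -> ReLU -> MaxPool(2,2).
MULTI_SCALE_BRANCHES = (
    ((3, 16), (5, 32)),
    ((5, 16), (8, 32)),
    ((8, 16), (10, 32)),
)
#: Single-scale ablation branch: three kernel-3 blocks.
MODEL_A_BRANCH = ((3, 16), (3, 32), (3, 32))


@dataclass
class ConvBlockSpec:
    """One convolution block: unpadded conv + optional pool."""

    kernel: int
    channels: int
    stride: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2
    dropout: float = 0.0
    batch_norm: bool = False


def output_length(L: int, spec: ConvBlockSpec) -> int:
    """Temporal length after one conv block (closed-form shape oracle)."""
    if L < spec.kernel:
        raise ValueError(f"input length {L} shorter than kernel {spec.kernel}")
    conv_len = (L - spec.kernel) // spec.stride + 1
    if conv_len < spec.pool_kernel:
        raise ValueError(f"conv output {conv_len} shorter than pool {spec.pool_kernel}")
    return (conv_len - spec.pool_kernel) // spec.pool_stride + 1


def branch_lengths(D: int, branch: tuple[tuple[int, int], ...]) -> list[int]:
    """Temporal length after each block of a branch, for input length D."""
    lengths = []
    L = D
    for kernel, channels in branch:
        L = output_length(L, ConvBlockSpec(kernel, channels))
        lengths.append(L)
    return lengths


def feature_length(D: int, variant: str = "multi_scale") -> int:
    """Flattened feature-vector length produced by F for input length D."""
    branches = _branches_for(variant)
    return sum(
        branch_lengths(D, br)[-1] * br[-1][1] for br in branches
    )


def _branches_for(variant: str) -> tuple[tuple[tuple[int, int], ...], ...]:
    if variant == "multi_scale":
        return MULTI_SCALE_BRANCHES
    if variant in ("model_a", "model_a_rr"):
        return (MODEL_A_BRANCH,)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


class FeatureExtractor(nn.Layer):
    """Parallel convolutional branches; outputs are flattened and concatenated."""

    def __init__(self, D: int, variant: str, dropout: float,
                 rng: np.random.Generator, dropout_seed: int) -> None:
        super().__init__()
        self.D = D
        self.variant = variant
        self.branches: list[nn.Sequential] = []
        for b, branch in enumerate(_branches_for(variant)):
            layers: list[nn.Layer] = []
            c_in = 1
            for blk, (kernel, channels) in enumerate(branch):
                layers += [
                    nn.Conv1d(c_in, channels, kernel, rng),
                    nn.Dropout(dropout, nn.derive_seed(dropout_seed, f"F{b}.{blk}")),
                    nn.ReLUMaxPool2(),
                ]
                c_in = channels
            layers.append(nn.Flatten())
            self.branches.append(nn.Sequential(layers))
        self.children = self.branches
        self._split: list[int] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, :, None]  # channels-last single lead
        if x.shape[1] != self.D:
            raise ValueError(f"expected input length {self.D}, got {x.shape[1]}")
        outs = [br.forward(x, train) for br in self.branches]
        self._split = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        grads = np.split(g, np.cumsum(self._split)[:-1], axis=1)
        dx = sum(br.backward(gb) for br, gb in zip(self.branches, grads))
        return dx


class Classifier(nn.Layer):
    """Two FC blocks to 10 units, optional RR fusion, linear head, logits.

    ``forward`` takes the feature vector and (when ``use_rr``) the
    (B, 6) RR-feature matrix; returns class logits (apply softmax for
    probabilities).  ``backward`` returns the gradient w.r.t. the
    feature vector (RR features are inputs, not trained).
    """

    def __init__(self, n_features: int, use_rr: bool,
                 rng: np.random.Generator, dropout_seed: int,
                 dropout: float = 0.2) -> None:
        super().__init__()
        self.use_rr = use_rr
        self.body = nn.Sequential([
            nn.Linear(n_features, 100, rng),
            nn.Dropout(dropout, nn.derive_seed(dropout_seed, "C.0")),
            nn.BatchNorm(100),
            nn.ReLU(),
            nn.Linear(100, 10, rng),
            nn.Dropout(dropout, nn.derive_seed(dropout_seed, "C.1")),
            nn.BatchNorm(10),
            nn.ReLU(),
        ])
        head_in = 10 + (N_TIME_FEATURES if use_rr else 0)
        self.head = nn.Linear(head_in, N_CLASSES, rng)
        self.children = [self.body, self.head]

    def forward(self, f: np.ndarray, rr: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        h = self.body.forward(f, train)
        if self.use_rr:
            if rr is None:
                raise ValueError("this classifier variant requires RR features")
            if rr.shape[1] != N_TIME_FEATURES:
                raise ValueError(f"expected {N_TIME_FEATURES} RR features")
            h = np.concatenate([h, rr], axis=1)
        return self.head.forward(h, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gh = self.head.backward(g)
        if self.use_rr:
            gh = gh[:, :10]
        return self.body.backward(gh)


class Discriminator(nn.Layer):
    """Convolutional source/target discriminator over the feature vector.

    Three conv blocks (kernels 8, 10, 10; 6 channels; the last two with
    batch normalization), then FC -> 100 -> 1.  ``forward`` returns a
    logit; apply a sigmoid for the domain probability.  The FC input
    width is derived from the actual shapes.
    """

    def __init__(self, n_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        L = n_features
        specs = [
            ConvBlockSpec(8, 6),
            ConvBlockSpec(10, 6, batch_norm=True),
            ConvBlockSpec(10, 6, batch_norm=True),
        ]
        layers: list[nn.Layer] = [nn.Reshape1d()]
        c_in = 1
        for spec in specs:
            layers += [nn.Conv1d(c_in, spec.channels, spec.kernel, rng),
                       nn.ReLUMaxPool2()]
            if spec.batch_norm:
                layers.append(nn.BatchNorm(spec.channels))
            c_in = spec.channels
            L = output_length(L, spec)
        layers += [nn.Flatten(), nn.Linear(L * c_in, 100, rng), nn.ReLU(),
                   nn.Linear(100, 1, rng)]
        self.net = nn.Sequential(layers)
        self.children = [self.net]

    def forward(self, f: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(f, train)[:, 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g[:, None])


@dataclass
class ModelParams:
    """The three networks plus the hyperparameters that bind them."""

    F: FeatureExtractor
    C: Classifier
    D: Discriminator
    lambda_: float
    input_length: int
    variant: str
    seed: int

    @property
    def omega_f(self):
        return nn.collect_params(self.F)

    @property
    def omega_c(self):
        return nn.collect_params(self.C)

    @property
    def omega_d(self):
        return nn.collect_params(self.D)


def build_model(D: int = DEFAULT_D, variant: str = "multi_scale",
                lambda_: float = 0.2, dropout: float = 0.2,
                seed: int = 0) -> ModelParams:
    """Construct F, C, D with seed-controlled initialization."""
    rng = np.random.default_rng(nn.derive_seed(seed, "init"))
    drop_seed = nn.derive_seed(seed, "dropout")
    n_feat = feature_length(D, variant)
    F = FeatureExtractor(D, variant, dropout, rng, drop_seed)
    C = Classifier(n_feat, use_rr=(variant != "model_a"), rng=rng,
                   dropout_seed=drop_seed, dropout=dropout)
    Dnet = Discriminator(n_feat, rng)
    return ModelParams(F=F, C=C, D=Dnet, lambda_=lambda_, input_length=D,
                       variant=variant, seed=seed)


def save_model(params: ModelParams, path: str) -> None:
    """Serialize networks + architecture config to an NPZ container."""
    import json

    st = nn.get_state(params.F, params.C, params.D)
    meta = json.dumps({
        "D": params.input_length, "variant": params.variant,
        "lambda_": params.lambda_, "seed": params.seed,
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **st)


def load_model(path: str) -> ModelParams:
    import json

    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    params = build_model(D=meta["D"], variant=meta["variant"],
                         lambda_=meta["lambda_"], seed=meta["seed"])
    st = {k: data[k] for k in data.files if k != "__meta__"}
    nn.set_state(st, params.F, params.C, params.D)
    return params
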