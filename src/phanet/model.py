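"""Four-path convolutional association network.

A phage contig and a candidate host contig are each encoded at two
granularities (base-level ``L x 4`` and codon-level ``R x 64`` one-hots) and
pushed through convolutional paths ending in a global pooling layer, which
produces a fixed-length feature vector per path regardless of contig length.
By default the phage and host sides *share* path weights — the extractor is
role-agnostic, like a k-mer frequency profile — and the codon input is
obtained from the base input by the fixed (never trained) codon transformer.
The four pooled feature blocks are concatenated in the fixed order
(phage-base, phage-codon, host-base, host-codon) and fed to a fully
connected head whose sigmoid output is the association probability.

The convolutional part doubles as a general feature extractor: with the
default two paths of 256 features each, every contig maps to a 512-vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .encoding import ContigRecord, encode_bases, apply_codon_transformer

__all__ = [
    "ModelConfig",
    "AssociationModel",
    "init_model",
    "extract_features",
    "predict_association",
    "save_model",
    "load_model",
]

CHECKPOINT_FORMAT_VERSION = 1

_PATH_ORDER = ("base", "codon")
_IN_CHANNELS = {"base": 4, "codon": 64}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``features_per_path`` is the per-path pooled feature width; with both
    paths enabled each contig yields ``2 * features_per_path`` features and
    the head input width is twice that again (phage + host).  ``pooling``
    selects the global reduction over positions: ``"mean"`` (default; the
    pooled activations behave like k-mer frequencies) or ``"max"``.
    """

    share_weights: bool = True
    paths: Tuple[str, ...] = ("base", "codon")
    features_per_path: int = 256
    conv_channels: Optional[Tuple[int, ...]] = None
    base_kernel_sizes: Tuple[int, ...] = (7, 5)
    codon_kernel_sizes: Tuple[int, ...] = (3, 3)
    local_pool: int = 4
    fc_hidden: Tuple[int, ...] = (256,)
    pooling: str = "mean"
    head_init: str = "difference"
    min_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        paths = tuple(self.paths)
        if not paths:
            raise ValueError("paths must be a non-empty subset of {'base', 'codon'}")
        for p in paths:
            if p not in _PATH_ORDER:
                raise ValueError(f"unknown path {p!r}")
        object.__setattr__(self, "paths", tuple(p for p in _PATH_ORDER if p in paths))
        if self.conv_channels is None:
            object.__setattr__(self, "conv_channels", (64, self.features_per_path))
        channels = tuple(self.conv_channels)
        object.__setattr__(self, "conv_channels", channels)
        if channels[-1] != self.features_per_path:
            raise ValueError(
                "last conv channel width must equal features_per_path "
                f"({channels[-1]} != {self.features_per_path})")
        for ks in (self.base_kernel_sizes, self.codon_kernel_sizes):
            if len(ks) != len(channels):
                raise ValueError("kernel_sizes and conv_channels must have equal length")
        if self.pooling not in ("max", "mean"):
            raise ValueError("pooling must be 'max' or 'mean'")
        if self.head_init not in ("difference", "uniform"):
            raise ValueError("head_init must be 'difference' or 'uniform'")
        object.__setattr__(self, "fc_hidden", tuple(self.fc_hidden))
        object.__setattr__(self, "base_kernel_sizes", tuple(self.base_kernel_sizes))
        object.__setattr__(self, "codon_kernel_sizes", tuple(self.codon_kernel_sizes))

    @property
    def features_per_contig(self) -> int:
        return self.features_per_path * len(self.paths)

    @property
    def head_in_width(self) -> int:
        return self.features_per_contig * 2

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """A reduced-width configuration for laptop-scale experiments."""
        base = dict(features_per_path=64, conv_channels=(32, 64), fc_hidden=(64,))
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("paths", "conv_channels", "base_kernel_sizes",
                    "codon_kernel_sizes", "fc_hidden"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _build_path(path: str, config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    kernel_sizes = (config.base_kernel_sizes if path == "base"
                    else config.codon_kernel_sizes)
    layers: List[nn.Layer] = []
    in_ch = _IN_CHANNELS[path]
    for ch, k in zip(config.conv_channels, kernel_sizes):
        layers.append(nn.Conv1d(in_ch, ch, k, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1d(config.local_pool))
        in_ch = ch
    layers.append(nn.GlobalMaxPool() if config.pooling == "max" else nn.GlobalMeanPool())
    return nn.Sequential(layers)


class AssociationModel:
    """The network: role-keyed convolutional paths plus the sigmoid head.

    With ``share_weights=True`` (default) the phage-side and host-side path
    objects are literally the same storage, so one gradient step updates
    both roles at once.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.paths: Dict[str, Dict[str, nn.Sequential]] = {}
        if config.share_weights:
            shared = {p: _build_path(p, config, rng) for p in config.paths}
            self.paths = {"phage": shared, "host": dict(shared)}
        else:
            self.paths = {
                role: {p: _build_path(p, config, rng) for p in config.paths}
                for role in ("phage", "host")
            }
        head_layers: List[nn.Layer] = []
        width = config.head_in_width
        for h in config.fc_hidden:
            head_layers.append(nn.Dense(width, h, rng))
            head_layers.append(nn.ReLU())
            width = h
        head_layers.append(nn.Dense(width, 1, rng))
        self.head = nn.Sequential(head_layers)
        if config.head_init == "difference":
            self._init_difference_head(rng)

    def _init_difference_head(self, rng: np.random.Generator) -> None:
        """Start the head as a learned dissimilarity between the role blocks.

        The head's job is a distance measure between the phage and host
        feature blocks, but with plain random weights a concatenation MLP
        begins in a near-linear regime where no matching interaction is
        expressible and optimization stalls.  Re-drawing the first layer's
        weights in antisymmetric pairs — rows ``(u, -u)`` and ``(-u, u)``
        over the (phage | host) blocks — makes each unit pair a signed
        projection of the feature difference, so rectified units encode
        ``|u . (f_phage - f_host)|`` and the output layer alone can already
        express a compositional-distance score.  Training is free to move
        away from this structure.
        """
        first = self.head.layers[0]
        H, width = first.W.value.shape
        half = width // 2
        n_pairs = H // 2
        if n_pairs == 0:
            return
        bound = 1.0 / np.sqrt(half)
        U = rng.uniform(-bound, bound, size=(n_pairs, half)).astype(np.float32)
        first.W.value[0:2 * n_pairs:2, :half] = U
        first.W.value[0:2 * n_pairs:2, half:] = -U
        first.W.value[1:2 * n_pairs:2, :half] = -U
        first.W.value[1:2 * n_pairs:2, half:] = U

    # ---- parameters ----------------------------------------------------
    def named_params(self) -> List[Tuple[str, nn.Param]]:
        out: List[Tuple[str, nn.Param]] = []
        seen = set()
        for role in ("phage", "host"):
            for path, net in self.paths[role].items():
                for i, p in enumerate(net.params()):
                    if id(p) not in seen:
                        seen.add(id(p))
                        out.append((f"{role}.{path}.{i}", p))
        for i, p in enumerate(self.head.params()):
            out.append((f"head.{i}", p))
        return out

    def params(self) -> List[nn.Param]:
        return [p for _, p in self.named_params()]

    # ---- encoding ------------------------------------------------------
    def _check_length(self, contig: Union[ContigRecord, str]) -> str:
        seq = contig.sequence if isinstance(contig, ContigRecord) else contig
        if len(seq) < self.config.min_length:
            raise ValueError(
                f"contig length {len(seq)} is below the model minimum of "
                f"{self.config.min_length} bases")
        return seq

    @staticmethod
    def encode_inputs(sequences: Sequence[str]) -> Dict[str, np.ndarray]:
        """Encode equal-length sequences into batched path inputs.

        Returns channel-first float32 arrays: base ``(B, 4, L)`` and codon
        ``(B, 64, R)``.  The codon matrix is produced by the fixed codon
        transformer applied to the base matrix.
        """
        bases = [encode_bases(s) for s in sequences]
        codons = [apply_codon_transformer(b) for b in bases]
        base_x = np.stack([b.matrix.T for b in bases]).astype(np.float32)
        codon_x = np.stack([c.matrix.T for c in codons]).astype(np.float32)
        return {"base": base_x, "codon": codon_x}

    # ---- forward/backward ---------------------------------------------
    def features_batch(self, inputs: Dict[str, np.ndarray], role: str,
                       with_cache: bool = False):
        """Pooled features (B, features_per_contig) for one role."""
        feats, caches = [], {}
        for p in self.config.paths:
            y, c = self.paths[role][p].forward(inputs[p])
            feats.append(y)
            caches[p] = c
        out = np.concatenate(feats, axis=1)
        return (out, caches) if with_cache else out

    def forward_pair_batch(self, phage_inputs: Dict[str, np.ndarray],
                           host_inputs: Dict[str, np.ndarray],
                           with_cache: bool = False):
        """Logits (B,) for a batch of (phage, host) contig pairs."""
        pf = self.features_batch(phage_inputs, "phage", with_cache=with_cache)
        hf = self.features_batch(host_inputs, "host", with_cache=with_cache)
        if with_cache:
            pf, pc = pf
            hf, hc = hf
        feat = np.concatenate([pf, hf], axis=1)
        logits, head_cache = self.head.forward(feat)
        logits = logits[:, 0]
        if not with_cache:
            return logits
        return logits, {"phage": pc, "host": hc, "head": head_cache,
                        "widths": (pf.shape[1], hf.shape[1])}

    def center_head_biases(self, pair_features: np.ndarray) -> None:
        """Data-dependent bias initialization for the head.

        Pooled composition features carry a large sample-independent
        component, which leaves every head unit saturated on one side of its
        rectifier at initialization; in that near-linear regime the head
        cannot express the phage-host matching interaction and optimization
        stalls on a long plateau.  Centering each dense layer's
        pre-activations over a calibration batch of pair features (one row =
        concatenated phage + host features) puts the units astride their
        nonlinearity from the first step.  Called once before training;
        prediction is unaffected thereafter.
        """
        x = np.asarray(pair_features, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.config.head_in_width:
            raise ValueError(
                f"expected (n, {self.config.head_in_width}) pair features")
        for layer in self.head.layers:
            if isinstance(layer, nn.Dense):
                pre = x @ layer.W.value.T + layer.b.value
                layer.b.value -= pre.mean(axis=0)
            x, _ = layer.forward(x)

    def backward_pair_batch(self, cache, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(cache["head"], dlogits[:, None])
        wp, _ = cache["widths"]
        chunks = {"phage": dfeat[:, :wp], "host": dfeat[:, wp:]}
        for role in ("phage", "host"):
            start = 0
            for p in self.config.paths:
                width = self.config.features_per_path
                dpath = chunks[role][:, start:start + width]
                self.paths[role][p].backward(cache[role][p], dpath)
                start += width


def init_model(config: Optional[ModelConfig] = None) -> AssociationModel:
    """Build a freshly initialized model from ``config`` (default config if None)."""
    return AssociationModel(config or ModelConfig())


@dataclass(frozen=True, eq=False)
class ContigFeatures:
    """Fixed-length pooled feature vector for one contig."""

    vector: np.ndarray


@dataclass(frozen=True)
class AssociationScore:
    """Sigmoid association probability, strictly inside (0, 1)."""

    probability: float


def extract_features(model: AssociationModel,
                     contig: Union[ContigRecord, str],
                     role: str = "phage") -> ContigFeatures:
    """Run the enabled paths on one contig and return its pooled features.

    The output length is ``features_per_path * |paths|`` (512 under the
    defaults) for any contig at least ``min_length`` bases long.  With
    shared weights the result is independent of ``role``.
    """
    seq = model._check_length(contig)
    if isinstance(contig, ContigRecord):
        role = contig.role.value
    inputs = model.encode_inputs([seq])
    feats = model.features_batch(inputs, role)
    return ContigFeatures(vector=feats[0])


def predict_association(model: AssociationModel,
                        phage: Union[ContigRecord, str],
                        host: Union[ContigRecord, str]) -> AssociationScore:
    """Score one (phage, host) contig pair.

    Deterministic given fixed parameters; the probability is clamped away
    from exactly 0/1 so downstream log-odds stay finite.
    """
    probs = predict_association_batch(model, [phage], [host])
    return AssociationScore(probability=float(probs[0]))


def predict_association_batch(model: AssociationModel,
                              phages: Sequence[Union[ContigRecord, str]],
                              hosts: Sequence[Union[ContigRecord, str]]) -> np.ndarray:
    """Probabilities for equal-shape batches of phage and host contigs.

    Within each role the contigs must share one length (the training regime
    draws one length per batch); mixed lengths should be scored pair by pair.
    """
    if len(phages) != len(hosts):
        raise ValueError("phage and host batches must have equal size")
    pseqs = [model._check_length(c) for c in phages]
    hseqs = [model._check_length(c) for c in hosts]
    probs = np.empty(len(pseqs), dtype=np.float64)
    # group into same-length sub-batches per role
    for pl in set(map(len, pseqs)):
        for hl in set(map(len, hseqs)):
            idx = [i for i in range(len(pseqs))
                   if len(pseqs[i]) == pl and len(hseqs[i]) == hl]
            if not idx:
                continue
            pi = model.encode_inputs([pseqs[i] for i in idx])
            hi = model.encode_inputs([hseqs[i] for i in idx])
            logits = model.forward_pair_batch(pi, hi)
            probs[idx] = nn.sigmoid(logits)
    return np.clip(probs, 1e-12, 1.0 - 1e-12)


# ---- serialization -----------------------------------------------------

def save_model(model: AssociationModel, path) -> None:
    """Write a checkpoint (config + parameters) to ``path`` (.npz)."""
    arrays = {name: p.value for name, p in model.named_params()}
    meta = json.dumps({"format_version": CHECKPOINT_FORMAT_VERSION,
                       "config": model.config.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> AssociationModel:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta.get('format_version')!r}")
        model = AssociationModel(ModelConfig.from_dict(meta["config"]))
        for name, p in model.named_params():
            p.value[...] = data[name]
    return model
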