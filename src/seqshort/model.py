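"""Full weakly-supervised slide classifier.

Pipeline, in order: optional 2-D patch-location sinusoid added to the
input features -> sequence shortening (``shortener``) -> prepend a
learnable [CLS] vector -> add learnable positional embeddings over the
``S+1`` sequence slots -> a stack of post-norm transformer encoder
blocks -> an MLP head on the final [CLS] representation.

The encoder follows the BERT-class layout (multi-head self-attention and
a two-layer feed-forward block, each wrapped in residual + layer norm),
so a 12-layer, width-768, FFN-3072 configuration carries the familiar
~85M encoder parameters of which only the 36,864 layer-norm scale/shift
values are trained under the ``normalization-only`` policy.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from ._autograd import Tensor, concat, gelu, layer_norm, softmax
from .bags import FeatureBag
from .errors import ConfigurationError, ShapeError, ValidationError
from .shortener import (
    INIT_STD,
    AttentionMap,
    QuerySet,
    ShortenerWeights,
    ShortSequence,
    _shorten_graph,
    seqshort_mac_count,
)

__all__ = [
    "ModelConfig",
    "Model",
    "TrainableSelection",
    "assemble",
    "encode_patch_locations",
    "select_trainable",
    "count_parameters",
    "estimate_flops",
    "encoder_mac_count",
    "classify",
    "load_preset",
    "PRESET_DIR",
]

PRESET_DIR = Path(__file__).parent / "presets"

POLICIES = ("normalization-only", "all", "head-only")


@dataclass
class ModelConfig:
    """Shape and policy of one classifier instance."""

    S: int = 256  # shortened sequence length
    h: int = 768  # hidden width (shortener output = encoder width)
    k: int = 4  # shortener attention heads
    d: int = 1280  # input patch-feature width
    encoder_layers: int = 12
    encoder_heads: int = 12
    encoder_ffn_width: int = 3072
    num_classes: int = 2
    backbone: str = "scratch-random"  # or a path to a named-weights .npz archive
    trainability_policy: str = "normalization-only"
    pos_seq: bool = True  # learnable sequence-order embeddings
    pos_wsi: bool = False  # fixed 2-D patch-location sinusoid
    seed: int = 0
    seqshort_d_h: float | None = None  # scaling override; default h/k
    bias: bool = True
    head_hidden: int | None = None  # MLP head hidden width; default h

    def __post_init__(self):
        for name in ("S", "h", "k", "d", "num_classes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.h % self.k:
            raise ConfigurationError(f"k={self.k} must divide h={self.h}")
        if self.encoder_layers and self.h % self.encoder_heads:
            raise ConfigurationError(
                f"encoder_heads={self.encoder_heads} must divide h={self.h}"
            )
        if self.trainability_policy not in POLICIES:
            raise ConfigurationError(
                f"unknown trainability policy '{self.trainability_policy}'; options: {POLICIES}"
            )
        if self.head_hidden is None:
            self.head_hidden = self.h

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def load_preset(name: str) -> ModelConfig:
    """Load a shipped preset ('lnm' or 'subtype') or a YAML config path."""
    import yaml

    path = PRESET_DIR / f"{name}.yaml"
    if not path.exists():
        path = Path(name)
    if not path.exists():
        raise ConfigurationError(f"no preset or config file named '{name}'")
    with open(path) as f:
        return ModelConfig.from_dict(yaml.safe_load(f))


# ----------------------------------------------------------------------
def encode_patch_locations(coords: np.ndarray, d: int) -> np.ndarray:
    """Fixed sinusoidal encoding of 2-D tile-grid positions.

    The first ``d/2`` channels encode the row index, the last ``d/2`` the
    column index; within each half, sine/cosine pairs with geometrically
    spaced wavelengths between 1 and 10000 (the classic transformer
    recipe).  Parameter-free and deterministic.
    """
    coords = np.asarray(coords)
    if d % 2:
        raise ValidationError(f"location encoding needs an even width, got d={d}")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ShapeError(f"coords must be (M, 2), got {coords.shape}")
    if (coords < 0).any():
        raise ValidationError("tile coordinates must be non-negative")
    half = d // 2

    def sinusoid(pos: np.ndarray) -> np.ndarray:
        chan = np.arange(half)
        freq = 10000.0 ** (-(2 * (chan // 2)) / half)
        angle = pos[:, None] * freq[None, :]
        enc = np.where(chan[None, :] % 2 == 0, np.sin(angle), np.cos(angle))
        return enc

    return np.concatenate([sinusoid(coords[:, 0]), sinusoid(coords[:, 1])], axis=1)


# ----------------------------------------------------------------------
class Model:
    """Assembled classifier; parameters are named autodiff tensors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        p: "OrderedDict[str, Tensor]" = OrderedDict()

        def add(name, arr):
            p[name] = Tensor(arr, name=name)
            return p[name]

        z = lambda *s: rng.normal(0.0, INIT_STD, size=s)
        dh = c.h // c.k
        add("seqshort.queries", z(c.S, c.h))
        add("seqshort.wq", z(c.k, c.h, dh))
        add("seqshort.wk", z(c.k, c.d, dh))
        add("seqshort.wv", z(c.k, c.d, dh))
        add("seqshort.wo", z(c.h, c.h))
        if c.bias:
            add("seqshort.bq", np.zeros((c.k, dh)))
            add("seqshort.bk", np.zeros((c.k, dh)))
            add("seqshort.bv", np.zeros((c.k, dh)))
            add("seqshort.bo", np.zeros(c.h))
        add("cls", z(c.h))
        add("pos_embed", z(c.S + 1, c.h))
        for i in range(c.encoder_layers):
            pre = f"encoder.{i}."
            for nm in ("attn.wq", "attn.wk", "attn.wv", "attn.wo"):
                add(pre + nm, z(c.h, c.h))
                add(pre + nm.replace("w", "b"), np.zeros(c.h))
            add(pre + "ln1.gamma", np.ones(c.h))
            add(pre + "ln1.beta", np.zeros(c.h))
            add(pre + "ffn.w1", z(c.h, c.encoder_ffn_width))
            add(pre + "ffn.b1", np.zeros(c.encoder_ffn_width))
            add(pre + "ffn.w2", z(c.encoder_ffn_width, c.h))
            add(pre + "ffn.b2", np.zeros(c.h))
            add(pre + "ln2.gamma", np.ones(c.h))
            add(pre + "ln2.beta", np.zeros(c.h))
        add("head.w1", z(c.h, c.head_hidden))
        add("head.b1", np.zeros(c.head_hidden))
        add("head.w2", z(c.head_hidden, c.num_classes))
        add("head.b2", np.zeros(c.num_classes))
        self.params = p
        if c.backbone != "scratch-random":
            self._load_backbone(c.backbone)

    def _load_backbone(self, ref: str) -> None:
        """Named-weights adapter: load encoder parameters from an .npz archive.

        Keys must match the model's encoder parameter names; anything
        else in the archive (e.g. a vocabulary embedding table) is
        ignored, mirroring how a text-pretrained encoder is reused for
        image bags.
        """
        path = Path(ref)
        if not path.exists():
            raise ConfigurationError(f"backbone reference '{ref}' not found")
        archive = np.load(path)
        for key in archive.files:
            if key in self.params and key.startswith("encoder."):
                if self.params[key].data.shape != archive[key].shape:
                    raise ConfigurationError(
                        f"backbone parameter '{key}' has shape {archive[key].shape}, "
                        f"expected {self.params[key].data.shape}"
                    )
                self.params[key].data = np.asarray(archive[key], dtype=np.float64)

    # -- parameter bookkeeping -----------------------------------------
    @staticmethod
    def group_of(name: str) -> str:
        if name.startswith("seqshort."):
            return "seqshort"
        if name == "cls":
            return "cls"
        if name == "pos_embed":
            return "pos_embed"
        if name.startswith("encoder."):
            return "encoder_norm" if ".ln" in name else "encoder_backbone"
        if name.startswith("head."):
            return "head"
        raise KeyError(name)

    def named_parameters(self) -> "OrderedDict[str, Tensor]":
        return self.params

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64)

    def save(self, path) -> None:
        """Checkpoint: named-parameter archive + the exact config used."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in self.params.items()})
        with open(path.with_suffix(".json"), "w") as f:
            json.dump(self.config.to_dict(), f, indent=2)

    @classmethod
    def load(cls, path) -> "Model":
        path = Path(path)
        with open(path.with_suffix(".json")) as f:
            config = ModelConfig.from_dict(json.load(f))
        model = cls(config)
        archive = np.load(path.with_suffix(".npz"))
        model.load_state_dict({k: archive[k] for k in archive.files})
        return model

    # -- forward pass ---------------------------------------------------
    def forward(self, bag: FeatureBag) -> tuple[Tensor, dict]:
        """Return class logits and all cached head-mean attention maps."""
        c = self.config
        if bag.d != c.d:
            raise ShapeError(
                f"bag feature axis d={bag.d} does not match the configured d={c.d}"
            )
        feats = bag.features
        if c.pos_wsi:
            if bag.coords is None:
                raise ConfigurationError(
                    "pos_wsi is enabled but the bag carries no tile coordinates"
                )
            feats = feats + encode_patch_locations(bag.coords, c.d)
        p = self.params
        get = lambda nm: p.get(nm)
        x = Tensor(feats)
        short, ss_probs = _shorten_graph(
            x,
            p["seqshort.queries"],
            p["seqshort.wq"],
            p["seqshort.wk"],
            p["seqshort.wv"],
            p["seqshort.wo"],
            get("seqshort.bq"),
            get("seqshort.bk"),
            get("seqshort.bv"),
            get("seqshort.bo"),
            c.seqshort_d_h if c.seqshort_d_h is not None else c.h / c.k,
        )
        seq = concat([p["cls"].reshape(1, c.h), short], axis=0)  # (S+1, h)
        if c.pos_seq:
            seq = seq + p["pos_embed"]
        caches = {
            "seqshort_per_head": ss_probs,
            "seqshort": ss_probs.mean(axis=0),
            "encoder": [],
        }
        for i in range(c.encoder_layers):
            seq, attn = self._encoder_block(seq, i)
            caches["encoder"].append(attn)
        logits = self._head(seq[0])
        return logits, caches

    def _encoder_block(self, x: Tensor, i: int) -> tuple[Tensor, np.ndarray]:
        c, p = self.config, self.params
        pre = f"encoder.{i}."
        nh = c.encoder_heads
        dh = c.h // nh
        L = x.shape[0]

        def proj(nm):
            return (x @ p[pre + f"attn.w{nm}"] + p[pre + f"attn.b{nm}"]).reshape(
                L, nh, dh
            ).transpose(1, 0, 2)

        q, k, v = proj("q"), proj("k"), proj("v")
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
        probs = softmax(scores, axis=-1)  # (nh, L, L)
        att = (probs @ v).transpose(1, 0, 2).reshape(L, c.h)
        att = att @ p[pre + "attn.wo"] + p[pre + "attn.bo"]
        x = layer_norm(x + att, p[pre + "ln1.gamma"], p[pre + "ln1.beta"])
        ff = gelu(x @ p[pre + "ffn.w1"] + p[pre + "ffn.b1"]) @ p[pre + "ffn.w2"] + p[
            pre + "ffn.b2"
        ]
        x = layer_norm(x + ff, p[pre + "ln2.gamma"], p[pre + "ln2.beta"])
        return x, probs.data.mean(axis=0)

    def _head(self, cls_repr: Tensor) -> Tensor:
        p = self.params
        hdn = gelu(cls_repr.reshape(1, -1) @ p["head.w1"] + p["head.b1"])
        return (hdn @ p["head.w2"] + p["head.b2"]).reshape(-1)

    # convenience accessors for the functional shortener surface
    def query_set(self) -> QuerySet:
        return QuerySet(self.params["seqshort.queries"].data)

    def shortener_weights(self) -> ShortenerWeights:
        p, c = self.params, self.config
        g = lambda nm: p[nm].data if nm in p else None
        return ShortenerWeights(
            wq=p["seqshort.wq"].data,
            wk=p["seqshort.wk"].data,
            wv=p["seqshort.wv"].data,
            wo=p["seqshort.wo"].data,
            bq=g("seqshort.bq"),
            bk=g("seqshort.bk"),
            bv=g("seqshort.bv"),
            bo=g("seqshort.bo"),
            d_h=c.seqshort_d_h if c.seqshort_d_h is not None else c.h / c.k,
        )


def assemble(config: ModelConfig) -> Model:
    """Build the classifier described by ``config`` (seeded, deterministic)."""
    return Model(config)


# ----------------------------------------------------------------------
@dataclass
class TrainableSelection:
    """Exhaustive partition of model parameters into named groups."""

    policy: str
    groups: dict = field(default_factory=dict)  # group -> {"names", "count", "trainable"}

    @property
    def total(self) -> int:
        return sum(g["count"] for g in self.groups.values())

    @property
    def trainable(self) -> int:
        return sum(g["count"] for g in self.groups.values() if g["trainable"])

    def trainable_names(self) -> list[str]:
        return [
            n for g in self.groups.values() if g["trainable"] for n in g["names"]
        ]


#: groups updated under each policy; everything else stays frozen
_POLICY_GROUPS = {
    "normalization-only": {"seqshort", "cls", "pos_embed", "encoder_norm", "head"},
    "head-only": {"head"},
    "all": {"seqshort", "cls", "pos_embed", "encoder_norm", "encoder_backbone", "head"},
}


def select_trainable(model: Model, policy: str | None = None) -> TrainableSelection:
    """Flag parameter groups trainable/frozen according to ``policy``.

    Under ``normalization-only`` the heavy encoder weights (attention and
    feed-forward) are frozen and only the layer-norm scale/shift values
    train, together with the shortener, [CLS], positional embeddings and
    the head — the parameter-efficient regime the model is designed for.
    """
    policy = policy or model.config.trainability_policy
    if policy not in _POLICY_GROUPS:
        raise ConfigurationError(
            f"unknown trainability policy '{policy}'; options: {sorted(_POLICY_GROUPS)}"
        )
    on = _POLICY_GROUPS[policy]
    groups: dict[str, dict] = {}
    for name, tensor in model.named_parameters().items():
        grp = Model.group_of(name)
        entry = groups.setdefault(grp, {"names": [], "count": 0, "trainable": grp in on})
        entry["names"].append(name)
        entry["count"] += tensor.size
        tensor.requires_grad = grp in on
    return TrainableSelection(policy=policy, groups=groups)


def count_parameters(selection: TrainableSelection) -> tuple[int, int, float]:
    """(total, trainable, trainable/total); fraction reported as 0 if empty."""
    total, trainable = selection.total, selection.trainable
    return total, trainable, (trainable / total if total else 0.0)


# ----------------------------------------------------------------------
class FlopEstimate(NamedTuple):
    seqshort_flops: int
    encoder_flops: int
    total: int


def encoder_mac_count(L: int, layers: int, h: int, ffn: int) -> int:
    """Analytic MACs of a post-norm encoder stack on a length-``L`` sequence."""
    per_layer = 4 * L * h * h + 2 * L * L * h + 2 * L * h * ffn
    return int(layers * per_layer)


def estimate_flops(config: ModelConfig, M: int) -> FlopEstimate:
    """Analytic multiply-accumulate counts for one forward pass on a bag of ``M``.

    The shortener term is affine in ``M``; the encoder term depends only
    on the fixed length ``S+1``, so the deep stack's cost is constant in
    the slide size — the point of shortening the sequence up front.
    """
    if M < 1:
        raise ValidationError("bag size M must be >= 1")
    c = config
    ss = seqshort_mac_count(M, c.S, c.h, c.d, c.k, bias=c.bias)
    enc = encoder_mac_count(c.S + 1, c.encoder_layers, c.h, c.encoder_ffn_width)
    head = c.h * c.head_hidden + c.head_hidden * c.num_classes
    return FlopEstimate(ss, enc, ss + enc + head)


# ----------------------------------------------------------------------
def classify(model: Model, bag: FeatureBag) -> tuple[np.ndarray, dict]:
    """Class probabilities for one bag plus all cached attention maps.

    The caches hold the shortener's head-mean query-over-patch map
    (``S x M``) and each encoder layer's head-mean self-attention
    (``(S+1) x (S+1)``) in forward order — exactly the inputs the
    rollout interpretability pass needs.
    """
    logits, caches = model.forward(bag)
    z = logits.data - logits.data.max()
    e = np.exp(z)
    return e / e.sum(), caches
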