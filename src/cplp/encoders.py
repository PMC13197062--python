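"""Trainable modality encoders projecting into a shared embedding space.

Image head: a time-distance transformer over a patient's (up to three)
per-scan feature vectors. Sinusoidal encodings of the days elapsed since
the patient's earliest scan are added to the real tokens, self-attention
runs under a padding mask so absent scans are never attended to, and the
output token at the chronologically latest real scan is linearly projected
into the shared space and L2-normalized.

Text head: an MLP over the frozen text-model embedding of the serialized
clinical paragraph, projected into the same space and L2-normalized. The
same head doubles as the tabular head when the text model is ablated.

The upstream feature extractor and the text model are frozen inputs — only
the transformer, the MLPs and the projections carry gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, parameter

__all__ = [
    "TimeEncodingConfig",
    "ImageEncoderConfig",
    "TextHeadConfig",
    "EmbeddingPair",
    "time_encoding",
    "ImageEncoder",
    "TextHead",
    "encode_images",
    "encode_text",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5
_MASK_BIAS = -1e9


@dataclass
class TimeEncodingConfig:
    """Sinusoidal time-encoding geometry.

    `day_scale` is the number of days per unit position; at the default of
    30 days, annual screening intervals sit roughly 12 positions apart.
    """

    dim: int = 256
    base: float = 10000.0
    day_scale: float = 30.0

    def __post_init__(self):
        if self.dim % 2:
            raise ValueError("time-encoding dim must be even")
        if self.base <= 1:
            raise ValueError("base must exceed 1")
        if self.day_scale <= 0:
            raise ValueError("day_scale must be positive")


@dataclass
class ImageEncoderConfig:
    seq_len: int = 3
    layers: int = 1
    heads: int = 4
    model_dim: int = 256
    feedforward_dim: int = 256
    dropout: float = 0.3  # active in pretraining passes only
    projection_dim: int = 256
    time: TimeEncodingConfig = field(default_factory=TimeEncodingConfig)

    def __post_init__(self):
        if self.seq_len != 3:
            raise ValueError("sequence length is fixed at 3 screens")
        if self.model_dim % self.heads:
            raise ValueError("model_dim must be divisible by heads")
        if self.time.dim != self.model_dim:
            self.time = TimeEncodingConfig(
                dim=self.model_dim, base=self.time.base,
                day_scale=self.time.day_scale)


@dataclass
class TextHeadConfig:
    input_dim: int = 256
    hidden: tuple[int, ...] = (256,)
    projection_dim: int = 256


@dataclass(frozen=True)
class EmbeddingPair:
    """Matched unit-norm image and text embeddings for one patient."""

    patient_id: str
    image_embedding: np.ndarray
    text_embedding: np.ndarray

    def __post_init__(self):
        for v in (self.image_embedding, self.text_embedding):
            if abs(np.linalg.norm(v) - 1.0) > 1e-5:
                raise ValueError("embeddings must be unit-norm")


def time_encoding(relative_day: float | np.ndarray,
                  cfg: TimeEncodingConfig) -> np.ndarray:
    """Sinusoidal encoding of position = relative_day / day_scale.

    Layout is [sin block | cos block]; at day 0 all sines are 0 and all
    cosines are 1, and the first sine component equals sin(day/day_scale).
    """
    day = np.asarray(relative_day, dtype=np.float64)
    if np.any(day < 0):
        raise ValueError("relative days must be non-negative")
    half = cfg.dim // 2
    freqs = cfg.base ** (-2.0 * np.arange(half) / cfg.dim)
    angle = (day[..., None] / cfg.day_scale) * freqs
    return np.concatenate([np.sin(angle), np.cos(angle)], axis=-1)


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    W = parameter(rng.normal(0.0, fan_in ** -0.5, (fan_in, fan_out)).astype(np.float32))
    b = parameter(np.zeros(fan_out, dtype=np.float32))
    return W, b


def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + _LN_EPS).sqrt() * g + b


class _ParamModule:
    """Tiny base: named parameters in insertion order."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, t: Tensor) -> Tensor:
        self.params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            arr = np.asarray(state[k])
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k!r}: "
                                 f"{arr.shape} vs {v.data.shape}")
            v.data = arr.copy()


class ImageEncoder(_ParamModule):
    """Pre-norm transformer over padded scan sequences with latest-token
    pooling and a linear projection to the shared space."""

    def __init__(self, cfg: ImageEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d, f = cfg.model_dim, cfg.feedforward_dim
        for l in range(cfg.layers):
            p = f"l{l}_"
            self._add(p + "ln1_g", parameter(np.ones(d, dtype=np.float32)))
            self._add(p + "ln1_b", parameter(np.zeros(d, dtype=np.float32)))
            for nm in ("q", "k", "v", "o"):
                W, b = _linear_init(rng, d, d)
                self._add(p + f"W{nm}", W)
                self._add(p + f"b{nm}", b)
            self._add(p + "ln2_g", parameter(np.ones(d, dtype=np.float32)))
            self._add(p + "ln2_b", parameter(np.zeros(d, dtype=np.float32)))
            W1, b1 = _linear_init(rng, d, f)
            W2, b2 = _linear_init(rng, f, d)
            self._add(p + "Wf1", W1)
            self._add(p + "bf1", b1)
            self._add(p + "Wf2", W2)
            self._add(p + "bf2", b2)
        self._add("lnf_g", parameter(np.ones(d, dtype=np.float32)))
        self._add("lnf_b", parameter(np.zeros(d, dtype=np.float32)))
        Wp, bp = _linear_init(rng, d, cfg.projection_dim)
        self._add("Wp", Wp)
        self._add("bp", bp)

    @staticmethod
    def _dropout(x: Tensor, rate: float,
                 rng: np.random.Generator | None) -> Tensor:
        if rng is None or rate <= 0.0:
            return x
        keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
        return x * keep

    def _attention(self, h: Tensor, key_bias: np.ndarray, layer: int) -> Tensor:
        cfg = self.cfg
        B = h.shape[0]
        H, dh = cfg.heads, cfg.model_dim // cfg.heads
        p = f"l{layer}_"

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, cfg.seq_len, H, dh).transpose(0, 2, 1, 3)

        q = heads(h @ self.params[p + "Wq"] + self.params[p + "bq"])
        k = heads(h @ self.params[p + "Wk"] + self.params[p + "bk"])
        v = heads(h @ self.params[p + "Wv"] + self.params[p + "bv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5) + key_bias
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, cfg.seq_len, cfg.model_dim)
        return ctx @ self.params[p + "Wo"] + self.params[p + "bo"]

    def forward(self, features: np.ndarray, days: np.ndarray,
                mask: np.ndarray,
                dropout_rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """Encode a padded batch.

        features (B, 3, D); days (B, 3) absolute acquisition days (padded
        slots arbitrary); mask (B, 3) booleans flagging real scans, padded
        on the right. Returns the pre-normalization projection and the
        unit-norm embedding. Pass `dropout_rng` during training to enable
        dropout (cfg.dropout); without it the forward pass is deterministic
        (eval mode).
        """
        cfg = self.cfg
        features = np.asarray(features, dtype=np.float32)
        mask = np.asarray(mask, dtype=bool)
        if features.ndim != 3 or features.shape[1] != cfg.seq_len:
            raise ValueError("features must be (B, 3, D)")
        if features.shape[2] != cfg.model_dim:
            raise ValueError(f"feature dim {features.shape[2]} != model_dim "
                             f"{cfg.model_dim}")
        if not mask.any(axis=1).all():
            raise ValueError("every sequence needs at least one real scan")
        if not (np.cumsum(~mask, axis=1) * mask).sum() == 0:
            raise ValueError("mask must be right-padded (real scans first)")

        # relative days within the retained window; padded slots zeroed
        days = np.where(mask, days, 0).astype(np.float64)
        first = np.where(mask, days, np.inf).min(axis=1, keepdims=True)
        rel = np.where(mask, days - first, 0.0)
        te = time_encoding(rel, cfg.time).astype(np.float32)
        m3 = mask[:, :, None].astype(np.float32)
        x = Tensor((features + te) * m3)  # padded tokens exactly zero

        x = self._dropout(x, cfg.dropout, dropout_rng)
        key_bias = ((~mask)[:, None, None, :] * _MASK_BIAS).astype(np.float32)
        for l in range(cfg.layers):
            p = f"l{l}_"
            h = _layer_norm(x, self.params[p + "ln1_g"], self.params[p + "ln1_b"])
            x = x + self._dropout(self._attention(h, key_bias, l),
                                  cfg.dropout, dropout_rng)
            h = _layer_norm(x, self.params[p + "ln2_g"], self.params[p + "ln2_b"])
            ff = (h @ self.params["%sWf1" % p] + self.params["%sbf1" % p]).relu()
            x = x + self._dropout(
                ff @ self.params["%sWf2" % p] + self.params["%sbf2" % p],
                cfg.dropout, dropout_rng)
        x = _layer_norm(x, self.params["lnf_g"], self.params["lnf_b"])

        latest = mask.sum(axis=1) - 1  # right-padded => last real index
        pooled = x[np.arange(x.shape[0]), latest]
        proj = pooled @ self.params["Wp"] + self.params["bp"]
        return {"projection": proj, "embedding": proj.l2_normalize()}


class TextHead(_ParamModule):
    """MLP over frozen text (or imputed tabular) vectors, projected to the
    shared space."""

    def __init__(self, cfg: TextHeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        dims = (cfg.input_dim, *cfg.hidden, cfg.projection_dim)
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            W, bb = _linear_init(rng, a, b)
            self._add(f"W{i}", W)
            self._add(f"b{i}", bb)
        self.n_layers = len(dims) - 1

    def forward(self, vectors: np.ndarray | Tensor) -> dict[str, Tensor]:
        x = vectors if isinstance(vectors, Tensor) else Tensor(
            np.asarray(vectors, dtype=np.float32))
        if x.shape[-1] != self.cfg.input_dim:
            raise ValueError(f"input dim {x.shape[-1]} != {self.cfg.input_dim}")
        for i in range(self.n_layers):
            x = x @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                x = x.relu()
        return {"projection": x, "embedding": x.l2_normalize()}


def encode_images(encoder: ImageEncoder, features: np.ndarray,
                  days: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Unit-norm image embeddings as a plain array (no gradient)."""
    return encoder.forward(features, days, mask)["embedding"].data


def encode_text(head: TextHead, vectors: np.ndarray) -> np.ndarray:
    """Unit-norm text embeddings as a plain array (no gradient)."""
    return head.forward(vectors)["embedding"].data


def save_checkpoint(path, modules: dict[str, _ParamModule],
                    config: dict, seed: int | None = None) -> None:
    """Single-archive checkpoint: every module's weights plus a JSON header
    with configs and the seed."""
    arrays = {}
    for mod_name, mod in modules.items():
        for k, v in mod.state_dict().items():
            arrays[f"{mod_name}/{k}"] = v
    header = json.dumps({"config": config, "seed": seed})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, modules: dict[str, _ParamModule]) -> dict:
    """Load weights into `modules` (shape-validated); returns the header."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        for mod_name, mod in modules.items():
            state = {k.split("/", 1)[1]: z[k] for k in z.files
                     if k.startswith(mod_name + "/")}
            mod.load_state_dict(state)
    return header
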