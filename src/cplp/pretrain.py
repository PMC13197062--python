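"""Contrastive patient-level pretraining.

Image and text embeddings of the same patient form a positive pair; all
cross-patient, cross-modal combinations within the batch are negatives
(pairs are always image-to-text). The objective is the symmetric cross
entropy over the matrix of cosine similarities scaled by a learnable
temperature: rows treat each image as a query over the batch's texts,
columns treat each text as a query over the images, and the matched patient
sits on the diagonal.

Optimization is Adam under a cosine-annealed learning rate with warm
restarts; training stops when the epoch training loss has not improved for
`patience_epochs` epochs. Pretraining paragraphs include the follow-up
length and the true outcome sentence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, CosineWarmRestarts, Tensor, parameter
from .cohort import Cohort, PatientRecord, truncate_to_window
from .encoders import ImageEncoder, TextHead
from .textser import (DEFAULT_REGISTRY, HashedTextEmbedder, TemplateRegistry,
                      TextEmbedder, embed_paragraph, to_paragraph)

__all__ = [
    "ClipConfig",
    "similarity_matrix",
    "symmetric_ce_loss",
    "make_batches",
    "steps_per_epoch",
    "pack_image_batch",
    "text_matrix",
    "alignment_gap",
    "pretrain",
    "PretrainResult",
]


@dataclass
class ClipConfig:
    batch_size: int = 2401
    temperature_init: float = 0.07  # learnable, parameterized on log scale
    lr: float = 1e-3
    t0: int = 100          # warm-restart cycle length in epochs
    t_mult: int = 2
    patience_epochs: int = 1000
    max_epochs: int = 300
    checkpoint_every: int | None = None  # snapshot period for later probing
    mixed_precision: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrast needs negatives)")
        if self.temperature_init <= 0:
            raise ValueError("temperature must be positive")


def similarity_matrix(I_batch: np.ndarray, T_batch: np.ndarray,
                      temperature: float = 1.0) -> np.ndarray:
    """Temperature-scaled cosine similarities; entry (i, j) pairs image i
    with text j, so the diagonal holds the same-patient pairs."""
    I_batch = np.asarray(I_batch, dtype=float)
    T_batch = np.asarray(T_batch, dtype=float)
    if I_batch.shape != T_batch.shape:
        raise ValueError("image and text batches must have equal shapes")
    if not np.allclose(np.linalg.norm(I_batch, axis=1), 1.0, atol=1e-4) or \
       not np.allclose(np.linalg.norm(T_batch, axis=1), 1.0, atol=1e-4):
        raise ValueError("rows must be unit-norm")
    return (I_batch @ T_batch.T) / temperature


def symmetric_ce_loss(sim_matrix: np.ndarray) -> float:
    """Mean of the image->text and text->image cross entropies with the
    diagonal as targets."""
    s = np.asarray(sim_matrix, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    diag = np.diag(s)
    lse_rows = _logsumexp(s, axis=1)
    lse_cols = _logsumexp(s, axis=0)
    return float(0.5 * ((lse_rows - diag).mean() + (lse_cols - diag).mean()))


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis)
    return m + np.log(np.exp(x - np.expand_dims(m, axis)).sum(axis=axis))


def _symmetric_ce_loss_t(sim: Tensor) -> Tensor:
    n = sim.shape[0]
    idx = np.arange(n)
    loss_i = -sim.log_softmax(axis=1)[idx, idx].mean()
    loss_t = -sim.log_softmax(axis=0)[idx, idx].mean()
    return (loss_i + loss_t) * 0.5


def steps_per_epoch(n_patients: int, batch_size: int) -> int:
    """Optimizer steps per epoch when the final partial batch is kept."""
    if n_patients <= 0 or batch_size <= 0:
        raise ValueError("n_patients and batch_size must be positive")
    return math.ceil(n_patients / batch_size)


def make_batches(patient_ids, batch_size: int,
                 rng: np.random.Generator) -> list[list[str]]:
    """One epoch's shuffled partition into batches; the final partial batch
    is kept."""
    ids = ([p.patient_id for p in patient_ids.patients]
           if isinstance(patient_ids, Cohort) else list(patient_ids))
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    if batch_size > len(ids):
        raise ValueError("batch_size exceeds number of patients")
    order = np.asarray(ids, dtype=object)
    rng.shuffle(order)
    return [list(order[i:i + batch_size])
            for i in range(0, len(order), batch_size)]


def pack_image_batch(patients: list[PatientRecord], feature_dim: int,
                     seq_len: int = 3):
    """Pad each patient's latest-`seq_len` scan window to fixed length.

    Returns (features (n, L, D), days (n, L), mask (n, L)); padded slots are
    zero and masked.
    """
    n = len(patients)
    feats = np.zeros((n, seq_len, feature_dim), dtype=np.float32)
    days = np.zeros((n, seq_len), dtype=np.int64)
    mask = np.zeros((n, seq_len), dtype=bool)
    for i, p in enumerate(patients):
        p = truncate_to_window(p, seq_len)
        t = len(p.scans)
        feats[i, :t] = [s.features for s in p.scans]
        days[i, :t] = [s.acquisition_day for s in p.scans]
        mask[i, :t] = True
    return feats, days, mask


def text_matrix(patients: list[PatientRecord], provider: TextEmbedder,
                outcome_mode: str,
                registry: TemplateRegistry = DEFAULT_REGISTRY) -> np.ndarray:
    """Frozen text-model embeddings of every patient's paragraph."""
    return np.stack([
        embed_paragraph(provider, to_paragraph(
            p.variables, outcome_mode, label=p.label,
            followup_days=p.followup_days, registry=registry))
        for p in patients])


def alignment_gap(I: np.ndarray, T: np.ndarray) -> float:
    """Mean matched-pair cosine minus mean mismatched cosine — how much the
    two modalities have been pulled together at the patient level."""
    sims = np.asarray(I, dtype=float) @ np.asarray(T, dtype=float).T
    n = sims.shape[0]
    matched = float(np.trace(sims) / n)
    mismatched = float((sims.sum() - np.trace(sims)) / (n * (n - 1)))
    return matched - mismatched


@dataclass
class PretrainResult:
    image_state: dict[str, np.ndarray]
    text_state: dict[str, np.ndarray]
    log_temperature: float
    loss_history: list[float]
    lr_history: list[float]
    best_epoch: int
    #: periodic (epoch, image_state, text_state) snapshots for checkpoint
    #: probing: the finetune stage can train from each and keep the one
    #: with the best validation performance
    checkpoints: list[tuple[int, dict, dict]] = field(default_factory=list)

    @property
    def temperature(self) -> float:
        return float(np.exp(-self.log_temperature))


def pretrain(cohort: Cohort, image_encoder: ImageEncoder, text_head: TextHead,
             cfg: ClipConfig, provider: TextEmbedder | None = None,
             registry: TemplateRegistry = DEFAULT_REGISTRY,
             text_vectors: np.ndarray | None = None) -> PretrainResult:
    """Run contrastive pretraining on the cohort's train split.

    `text_vectors` lets the caller substitute the frozen-text pathway (the
    tabular ablation passes imputed tabular vectors); by default paragraphs
    with outcome_mode='include' are embedded with `provider`.
    """
    train = cohort.split_subset("train").patients
    if not train:
        raise ValueError("train split is empty")
    provider = provider or HashedTextEmbedder()
    feats, days, mask = pack_image_batch(train, cohort.feature_dim)
    tvecs = (np.asarray(text_vectors, dtype=np.float32) if text_vectors is not None
             else text_matrix(train, provider, "include", registry))
    if cfg.mixed_precision:
        # store the frozen inputs at half precision; compute stays single
        feats = feats.astype(np.float16).astype(np.float32)
        tvecs = tvecs.astype(np.float16).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    # learnable scale: sim = cos * exp(log_scale), i.e. temperature = exp(-log_scale)
    log_scale = parameter(np.array(np.log(1.0 / cfg.temperature_init), dtype=np.float32))
    params = image_encoder.parameters() + text_head.parameters() + [log_scale]
    opt = Adam(params, lr=cfg.lr)
    sched = CosineWarmRestarts(cfg.lr, t0=cfg.t0, t_mult=cfg.t_mult)

    batch_size = min(cfg.batch_size, len(train))
    if batch_size < 2:
        raise ValueError("need at least 2 training patients")
    index = np.arange(len(train))

    history: list[float] = []
    lrs: list[float] = []
    checkpoints: list[tuple[int, dict, dict]] = []
    best_loss = np.inf
    best_epoch = -1
    best_state = None
    for epoch in range(cfg.max_epochs):
        opt.lr = sched.lr_at(epoch)
        lrs.append(opt.lr)
        rng.shuffle(index)
        epoch_losses = []
        for start in range(0, len(index), batch_size):
            sel = index[start:start + batch_size]
            if len(sel) < 2:
                continue  # a 1-patient tail batch has no negatives
            I = image_encoder.forward(feats[sel], days[sel], mask[sel],
                                      dropout_rng=rng)["embedding"]
            T = text_head.forward(tvecs[sel])["embedding"]
            sim = (I @ T.transpose()) * log_scale.exp()
            loss = _symmetric_ce_loss_t(sim)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"contrastive loss diverged at epoch {epoch} "
                    f"(loss={float(loss.data)!r}); lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        epoch_loss = float(np.mean(epoch_losses))
        history.append(epoch_loss)
        if epoch_loss < best_loss - 1e-9:
            best_loss = epoch_loss
            best_epoch = epoch
            best_state = (image_encoder.state_dict(), text_head.state_dict(),
                          float(log_scale.data))
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            checkpoints.append((epoch + 1, image_encoder.state_dict(),
                                text_head.state_dict()))
        if epoch - best_epoch >= cfg.patience_epochs:
            break

    image_state, text_state, log_temp_scale = best_state
    image_encoder.load_state_dict(image_state)
    text_head.load_state_dict(text_state)
    # log_scale is log(1/temperature); store log(temperature)
    return PretrainResult(image_state=image_state, text_state=text_state,
                          log_temperature=-log_temp_scale,
                          loss_history=history, lr_history=lrs,
                          best_epoch=best_epoch, checkpoints=checkpoints)
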