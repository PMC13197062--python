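"""Downstream risk prediction: zero-shot, finetune fusion, and baselines.

Zero-shot: for each test patient, the paragraph is rebuilt twice with the
two candidate outcome sentences in place of the true label; the image
embedding's cosine similarity to each candidate text embedding is compared,
and the continuous score is their difference (positive means the model
leans towards "developed lung cancer").

Finetune: the image and text projections are concatenated and fed through
an MLP + sigmoid trained with binary cross entropy; encoder parameters
train at `encoder_lr_ratio` (default one tenth) of the classifier rate.
Paragraphs exclude the outcome and follow-up sentences in this phase.

Variants (identical splits and seeds, so comparisons are paired):

* ``clip_finetune`` — fusion classifier initialized from contrastive
  pretraining;
* ``mm_lang``      — the same architecture from random initialization;
* ``mm_tabular``   — supervised fusion with the imputed tabular vector in
  place of the frozen text embedding;
* ``clip_tabular`` — contrastive pretraining and finetuning with the
  tabular vector in place of the text embedding;
* ``sybil_tdvit``  — longitudinal imaging only (transformer + MLP);
* ``sybil_cs``     — cross-sectional imaging only (latest scan's raw
  features + MLP).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

from .autodiff import Adam, Tensor, concatenate, parameter
from .cohort import (CATEGORICAL_VARIABLES, MISSING, NUMERIC_VARIABLES,
                     SCHEMA_VARIABLES, Cohort, PatientRecord,
                     truncate_to_window)
from .encoders import (ImageEncoder, ImageEncoderConfig, TextHead,
                       TextHeadConfig, _linear_init, _ParamModule)
from .pretrain import (ClipConfig, PretrainResult, pack_image_batch, pretrain,
                       text_matrix)
from .textser import (DEFAULT_REGISTRY, HashedTextEmbedder, TemplateRegistry,
                      TextEmbedder, embed_paragraph, to_paragraph)

__all__ = [
    "ModelVariant",
    "FinetuneConfig",
    "RiskModel",
    "zero_shot_score",
    "zero_shot_scores",
    "finetune",
    "train_variant",
    "impute_tabular",
    "tabular_matrix",
]


class ModelVariant(str, enum.Enum):
    CLIP_FINETUNE = "clip_finetune"
    CLIP_ZEROSHOT = "clip_zeroshot"
    MM_LANG = "mm_lang"
    MM_TABULAR = "mm_tabular"
    CLIP_TABULAR = "clip_tabular"
    SYBIL_TDVIT = "sybil_tdvit"
    SYBIL_CS = "sybil_cs"


@dataclass
class FinetuneConfig:
    hidden: tuple[int, ...] = (128,)
    lr: float = 3e-3
    encoder_lr_ratio: float = 0.1
    patience: int = 40        # epochs without validation improvement
    batch_size: int = 256
    max_epochs: int = 50
    val_fraction: float = 0.1
    seed: int = 0


class _MLP(_ParamModule):
    """Plain MLP with ReLU hidden layers; final layer linear."""

    def __init__(self, dims: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        self.dims = dims
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            W, bb = _linear_init(rng, a, b)
            self._add(f"W{i}", W)
            self._add(f"b{i}", bb)

    def forward(self, x: Tensor) -> Tensor:
        n = len(self.dims) - 1
        for i in range(n):
            x = x @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < n - 1:
                x = x.relu()
        return x


def _bce_from_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable binary cross entropy: mean softplus(x) - y*x."""
    absx = logits.relu() + (-logits).relu()
    softplus = logits.relu() + ((-absx).exp() + 1.0).log()
    return (softplus - Tensor(np.asarray(y, dtype=np.float32)) * logits).mean()


# --------------------------------------------------------------------------
# zero-shot
# --------------------------------------------------------------------------

def zero_shot_scores(patients: list[PatientRecord], image_encoder: ImageEncoder,
                     text_head: TextHead, provider: TextEmbedder,
                     registry: TemplateRegistry = DEFAULT_REGISTRY,
                     feature_dim: int | None = None) -> np.ndarray:
    """cos(I, T_pos) - cos(I, T_neg) per patient; > 0 predicts a case and a
    tie predicts the negative class."""
    feature_dim = feature_dim or image_encoder.cfg.model_dim
    feats, days, mask = pack_image_batch(patients, feature_dim)
    I = image_encoder.forward(feats, days, mask)["embedding"].data
    scores = np.empty(len(patients))
    for i, p in enumerate(patients):
        tpos = embed_paragraph(provider, to_paragraph(
            p.variables, "override_positive", registry=registry))
        tneg = embed_paragraph(provider, to_paragraph(
            p.variables, "override_negative", registry=registry))
        Tpair = text_head.forward(np.stack([tpos, tneg]))["embedding"].data
        scores[i] = float(I[i] @ Tpair[0] - I[i] @ Tpair[1])
    return scores


def zero_shot_score(patient: PatientRecord, image_encoder: ImageEncoder,
                    text_head: TextHead, provider: TextEmbedder,
                    registry: TemplateRegistry = DEFAULT_REGISTRY) -> float:
    return float(zero_shot_scores([patient], image_encoder, text_head,
                                  provider, registry)[0])


# --------------------------------------------------------------------------
# imputation and tabular vectors
# --------------------------------------------------------------------------

def impute_tabular(clinical_table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Complete missing clinical variables by chained linear imputation.

    Each incomplete variable is iteratively regressed on the others (max 20
    rounds, parameter tolerance 1e-3); categorical variables are one-hot
    encoded for the regressions and decoded by argmax; imputed numerics are
    clamped to the observed per-variable range. Deterministic given `seed`.
    A single completed table is returned.
    """
    schema_cols = [c for c in SCHEMA_VARIABLES if c in clinical_table.columns]
    work = clinical_table[schema_cols].copy()
    work = work.map(lambda v: np.nan if v is MISSING or v == "" else v)

    blocks: list[np.ndarray] = []
    spans: list[tuple[str, list]] = []  # (variable, categories or None)
    for col in schema_cols:
        if col in NUMERIC_VARIABLES:
            vals = pd.to_numeric(work[col], errors="coerce").to_numpy(dtype=float)
            if np.isnan(vals).all():
                raise ValueError(f"variable {col!r} is missing in every row")
            blocks.append(vals[:, None])
            spans.append((col, None))
        else:
            s = work[col].astype(object)
            cats = sorted({v for v in s if isinstance(v, str)})
            if not cats:
                raise ValueError(f"variable {col!r} is missing in every row")
            onehot = np.full((len(s), len(cats)), np.nan)
            for i, v in enumerate(s):
                if isinstance(v, str):
                    onehot[i] = [1.0 if v == c else 0.0 for c in cats]
            blocks.append(onehot)
            spans.append((col, cats))

    X = np.hstack(blocks)
    mins = np.nanmin(X, axis=0)
    maxs = np.nanmax(X, axis=0)
    imputer = IterativeImputer(estimator=LinearRegression(), max_iter=20,
                               tol=1e-3, random_state=seed,
                               min_value=mins, max_value=maxs)
    Xc = imputer.fit_transform(X)

    out = clinical_table.copy()
    pos = 0
    for col, cats in spans:
        if cats is None:
            out[col] = Xc[:, pos]
            pos += 1
        else:
            block = Xc[:, pos:pos + len(cats)]
            out[col] = [cats[j] for j in block.argmax(axis=1)]
            pos += len(cats)
    return out


def _patients_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {v: p.variables.get(v, MISSING) for v in SCHEMA_VARIABLES}
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SCHEMA_VARIABLES))


def tabular_matrix(patients: list[PatientRecord], seed: int = 0) -> np.ndarray:
    """Imputed, standardized numeric design matrix (z-scored numerics plus
    one-hot categoricals) used by the tabular ablations."""
    completed = impute_tabular(_patients_frame(patients), seed=seed)
    cols = []
    for v in NUMERIC_VARIABLES:
        x = completed[v].to_numpy(dtype=float)
        sd = x.std()
        cols.append(((x - x.mean()) / (sd if sd > 0 else 1.0))[:, None])
    for v in CATEGORICAL_VARIABLES:
        s = completed[v].astype(str)
        for cat in sorted(s.unique()):
            cols.append((s == cat).to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


# --------------------------------------------------------------------------
# supervised training
# --------------------------------------------------------------------------

@dataclass
class RiskModel:
    """A trained variant: holds its modules and a vectorized scorer."""

    variant: ModelVariant
    modules: dict[str, _ParamModule]
    _scorer: callable
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_scores(self, patients: list[PatientRecord]) -> np.ndarray:
        """Risk probabilities in (0, 1), one per patient."""
        return self._scorer(patients)


def _safe_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(labels, scores))


def _stratified_val_split(labels: np.ndarray, val_fraction: float,
                          rng: np.random.Generator):
    labels = np.asarray(labels)
    val_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        k = max(1, int(round(len(idx) * val_fraction)))
        val_idx.extend(idx[:k])
    val = np.sort(np.asarray(val_idx))
    train = np.setdiff1d(np.arange(len(labels)), val)
    if len(np.unique(labels[val])) < 2:
        raise ValueError("validation split has a single class")
    return train, val


def _fit_supervised(logits_fn, modules: dict[str, _ParamModule],
                    lr_mults: dict[str, float], y: np.ndarray,
                    cfg: FinetuneConfig, rng: np.random.Generator):
    """Generic Adam + early-stopping loop over index minibatches.

    `logits_fn(sel)` returns the logit Tensor for patient indices `sel`;
    early stopping monitors validation loss with `cfg.patience`.
    """
    tr_idx, va_idx = _stratified_val_split(y, cfg.val_fraction, rng)
    params, mults = [], []
    for name, mod in modules.items():
        for p in mod.parameters():
            params.append(p)
            mults.append(lr_mults.get(name, 1.0))
    opt = Adam(params, lr=cfg.lr, lr_mult=mults)

    best = np.inf
    best_epoch = -1
    best_state = None
    hist_tr, hist_va = [], []
    for epoch in range(cfg.max_epochs):
        order = tr_idx.copy()
        rng.shuffle(order)
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            loss = _bce_from_logits(logits_fn(sel), y[sel])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training loss diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        va_loss = float(_bce_from_logits(logits_fn(va_idx), y[va_idx]).data)
        hist_tr.append(float(np.mean(losses)))
        hist_va.append(va_loss)
        if va_loss < best - 1e-9:
            best, best_epoch = va_loss, epoch
            best_state = {k: m.state_dict() for k, m in modules.items()}
        if epoch - best_epoch >= cfg.patience:
            break
    for k, m in modules.items():
        m.load_state_dict(best_state[k])
    return {"train_loss": hist_tr, "val_loss": hist_va, "best_epoch": best_epoch,
            "val_idx": va_idx}


def finetune(cohort: Cohort, cfg: FinetuneConfig,
             pretrained: PretrainResult | None = None,
             image_cfg: ImageEncoderConfig | None = None,
             text_cfg: TextHeadConfig | None = None,
             provider: TextEmbedder | None = None,
             registry: TemplateRegistry = DEFAULT_REGISTRY,
             text_vectors_fn=None,
             variant: ModelVariant = ModelVariant.CLIP_FINETUNE) -> RiskModel:
    """Train the fusion classifier [image proj ‖ text proj] -> MLP -> sigmoid.

    With `pretrained` the encoders start from the contrastive weights
    (clip_finetune); without, from random weights (mm_lang). The text
    pathway can be swapped by `text_vectors_fn(patients) -> matrix` (the
    tabular variants pass imputed vectors).
    """
    provider = provider or HashedTextEmbedder()
    image_cfg = image_cfg or ImageEncoderConfig(model_dim=cohort.feature_dim,
                                                projection_dim=cohort.feature_dim)
    rng = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(cfg.seed + 1)

    train = cohort.split_subset("train").patients
    if not train:
        raise ValueError("train split is empty")
    if text_vectors_fn is None:
        text_vectors_fn = lambda pts: text_matrix(pts, provider, "exclude", registry)
    tvecs = text_vectors_fn(train)
    text_cfg = text_cfg or TextHeadConfig(input_dim=tvecs.shape[1],
                                          projection_dim=image_cfg.projection_dim)

    image_encoder = ImageEncoder(image_cfg, init_rng)
    text_head = TextHead(text_cfg, init_rng)
    if pretrained is not None:
        image_encoder.load_state_dict(pretrained.image_state)
        text_head.load_state_dict(pretrained.text_state)

    clf = _MLP((2 * image_cfg.projection_dim, *cfg.hidden, 1), init_rng)
    feats, days, mask = pack_image_batch(train, cohort.feature_dim)
    y = np.asarray([p.label for p in train], dtype=float)

    def logits_fn(sel):
        I = image_encoder.forward(feats[sel], days[sel], mask[sel])["projection"]
        T = text_head.forward(tvecs[sel])["projection"]
        return clf.forward(concatenate([I, T], axis=-1)).reshape(-1)

    modules = {"image": image_encoder, "text": text_head, "clf": clf}
    mults = {"image": cfg.encoder_lr_ratio, "text": cfg.encoder_lr_ratio,
             "clf": 1.0}
    history = _fit_supervised(logits_fn, modules, mults, y, cfg, rng)
    va = history.pop("val_idx")
    history["val_auc"] = _safe_auc(logits_fn(va).data, y[va])

    def scorer(patients: list[PatientRecord]) -> np.ndarray:
        f, d, m = pack_image_batch(patients, cohort.feature_dim)
        I = image_encoder.forward(f, d, m)["projection"]
        T = text_head.forward(text_vectors_fn(patients))["projection"]
        logits = clf.forward(concatenate([I, T], axis=-1)).reshape(-1)
        return 1.0 / (1.0 + np.exp(-logits.data))

    return RiskModel(variant=variant, modules=modules, _scorer=scorer,
                     history=history)


def _image_only_model(cohort: Cohort, cfg: FinetuneConfig,
                      image_cfg: ImageEncoderConfig,
                      cross_sectional: bool) -> RiskModel:
    rng = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(cfg.seed + 1)
    train = cohort.split_subset("train").patients
    y = np.asarray([p.label for p in train], dtype=float)

    if cross_sectional:
        latest = np.stack([truncate_to_window(p, 1).scans[-1].features
                           for p in train]).astype(np.float32)
        clf = _MLP((cohort.feature_dim, *cfg.hidden, 1), init_rng)

        def logits_fn(sel):
            return clf.forward(Tensor(latest[sel])).reshape(-1)

        modules = {"clf": clf}
        history = _fit_supervised(logits_fn, modules, {}, y, cfg, rng)
        va = history.pop("val_idx")
        history["val_auc"] = _safe_auc(logits_fn(va).data, y[va])

        def scorer(patients):
            x = np.stack([truncate_to_window(p, 1).scans[-1].features
                          for p in patients]).astype(np.float32)
            logits = clf.forward(Tensor(x)).reshape(-1)
            return 1.0 / (1.0 + np.exp(-logits.data))

        return RiskModel(ModelVariant.SYBIL_CS, modules, scorer, history)

    image_encoder = ImageEncoder(image_cfg, init_rng)
    clf = _MLP((image_cfg.projection_dim, *cfg.hidden, 1), init_rng)
    feats, days, mask = pack_image_batch(train, cohort.feature_dim)

    def logits_fn(sel):
        I = image_encoder.forward(feats[sel], days[sel], mask[sel])["projection"]
        return clf.forward(I).reshape(-1)

    modules = {"image": image_encoder, "clf": clf}
    history = _fit_supervised(logits_fn, modules, {}, y, cfg, rng)
    va = history.pop("val_idx")
    history["val_auc"] = _safe_auc(logits_fn(va).data, y[va])

    def scorer(patients):
        f, d, m = pack_image_batch(patients, cohort.feature_dim)
        I = image_encoder.forward(f, d, m)["projection"]
        logits = clf.forward(I).reshape(-1)
        return 1.0 / (1.0 + np.exp(-logits.data))

    return RiskModel(ModelVariant.SYBIL_TDVIT, modules, scorer, history)


def train_variant(cohort: Cohort, variant: ModelVariant | str,
                  cfg: FinetuneConfig,
                  pretrained: PretrainResult | None = None,
                  clip_cfg: ClipConfig | None = None,
                  image_cfg: ImageEncoderConfig | None = None,
                  text_cfg: TextHeadConfig | None = None,
                  provider: TextEmbedder | None = None,
                  registry: TemplateRegistry = DEFAULT_REGISTRY) -> RiskModel:
    """Train one of the comparison variants (see module docstring)."""
    variant = ModelVariant(variant)
    provider = provider or HashedTextEmbedder()
    image_cfg = image_cfg or ImageEncoderConfig(model_dim=cohort.feature_dim,
                                                projection_dim=cohort.feature_dim)

    if variant is ModelVariant.CLIP_FINETUNE:
        if pretrained is None:
            raise ValueError("clip_finetune needs a PretrainResult")
        # probe every stored pretraining checkpoint: finetune from each and
        # keep the model with the best validation AUC (checkpoint selection
        # is part of the method; with no stored checkpoints the final
        # pretrained weights are used directly)
        candidates = [PretrainResult(image_state=img, text_state=txt,
                                     log_temperature=pretrained.log_temperature,
                                     loss_history=[], lr_history=[],
                                     best_epoch=ep)
                      for ep, img, txt in pretrained.checkpoints]
        if not candidates:
            candidates = [pretrained]
        best = None
        for cand in candidates:
            model = finetune(cohort, cfg, pretrained=cand, image_cfg=image_cfg,
                             text_cfg=text_cfg, provider=provider,
                             registry=registry, variant=variant)
            model.history["pretrain_epoch"] = cand.best_epoch
            if best is None or model.history["val_auc"] > best.history["val_auc"]:
                best = model
        return best
    if variant is ModelVariant.MM_LANG:
        return finetune(cohort, cfg, pretrained=None, image_cfg=image_cfg,
                        text_cfg=text_cfg, provider=provider, registry=registry,
                        variant=variant)
    if variant in (ModelVariant.MM_TABULAR, ModelVariant.CLIP_TABULAR):
        # one imputation over the whole cohort so train and test share columns
        allpts = cohort.patients
        tab = tabular_matrix(allpts, seed=cfg.seed)
        index = {p.patient_id: i for i, p in enumerate(allpts)}

        def tab_fn(pts):
            return tab[[index[p.patient_id] for p in pts]]

        tcfg = text_cfg or TextHeadConfig(input_dim=tab.shape[1],
                                          projection_dim=image_cfg.projection_dim)
        pre = None
        if variant is ModelVariant.CLIP_TABULAR:
            clip_cfg = clip_cfg or ClipConfig(seed=cfg.seed)
            init_rng = np.random.default_rng(clip_cfg.seed + 1)
            enc = ImageEncoder(image_cfg, init_rng)
            head = TextHead(tcfg, init_rng)
            train = cohort.split_subset("train").patients
            pre = pretrain(cohort, enc, head, clip_cfg,
                           text_vectors=tab_fn(train))
        return finetune(cohort, cfg, pretrained=pre, image_cfg=image_cfg,
                        text_cfg=tcfg, provider=provider, registry=registry,
                        text_vectors_fn=tab_fn, variant=variant)
    if variant is ModelVariant.SYBIL_TDVIT:
        return _image_only_model(cohort, cfg, image_cfg, cross_sectional=False)
    if variant is ModelVariant.SYBIL_CS:
        return _image_only_model(cohort, cfg, image_cfg, cross_sectional=True)
    raise ValueError(f"unknown variant {variant!r}")
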