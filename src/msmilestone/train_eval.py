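"""Training orchestration: staged metric-learning + decoder training,
minority resampling, stratified 5-fold cross-validation, metrics and
attention-based explainability.

Stages per training fold:

1. *Metric stage.*  Each MRI-sequence channel and the note channel are
   trained with the fixed-anchor triplet margin loss to separate milestone-
   positive from milestone-negative patients in embedding space, with
   minority-class 10-fold resampling and validation-based early stopping
   (best-validation checkpoint restored).
2. *Decoder stage.*  With the metric encoders frozen, the structured-EHR
   attention channels and the fusion decoder are trained jointly with binary
   cross-entropy on the milestone label.

Preprocessing statistics (feature-prevalence filter, min-max ranges,
demographics encoding) are refit on each training split.  Evaluation folds
are never resampled and never influence any fitted statistic.

Feature importance for the structured tables is gradient-weighted attention:
the importance of feature j in table k is the mean over evaluation patients
and time bins of ``alpha_k[m] * |d o / d D_k[m, j]|``, normalized to sum to
one within the table.  (Per-timestamp attention alone carries no per-feature
resolution; the gradient factor supplies it.)
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import Adam, Tensor, concat, stack
from .ehr_encoder import EHRChannel, default_channel_config
from .fusion import (DEFAULT_ROW_ORDER, DecoderConfig, FusionDecoder,
                     bce_loss, build_fusion_matrix)
from .image_encoder import (ImageEncoderConfig, ResidualVolumeEncoder,
                            augment, normalize_intensity, select_scan,
                            triplet_margin_loss)
from .preprocess import (DemographicsEncoder, FeatureScaler, LongitudinalTable,
                         THREE_YEARS, bin_observations, derive_labels,
                         filter_features, truncate_history)
from .synthetic import SyntheticCohort, SyntheticPatient
from .text_encoder import GraphNoteEncoder, build_word_graph, tokenize

logger = logging.getLogger(__name__)

EHR_KINDS = ("lab", "vital", "medication")


@dataclass
class StageConfig:
    epochs: int = 500
    patience: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 128
    weight_decay: float = 0.0


@dataclass
class TrainConfig:
    folds: int = 5
    milestone: float = 4.0
    horizon_years: float = 3.0
    seed: int = 7
    min_fraction: float = 0.10
    resample_factor: int = 10
    resample_target: str = "minority"      # 'minority' | 'negative' | 'positive'
    val_fraction: float = 0.10
    threshold: float = 0.5
    notes_mode: str = "concat"             # 'concat' | 'last'
    sequences: tuple[str, ...] | None = None   # None: all sequences in the data
    image: StageConfig = field(default_factory=lambda: StageConfig(
        epochs=500, patience=50, learning_rate=1e-5, batch_size=10))
    text: StageConfig = field(default_factory=lambda: StageConfig(
        epochs=500, patience=50, learning_rate=1e-3, batch_size=128))
    decoder: StageConfig = field(default_factory=lambda: StageConfig(
        epochs=200, patience=20, learning_rate=1e-3, batch_size=32,
        weight_decay=1e-4))
    image_encoder: ImageEncoderConfig = field(default_factory=ImageEncoderConfig)
    text_d_node: int = 64
    text_window: int = 10
    text_passes: int = 2
    decoder_hidden: int = 512
    decoder_layers: int = 4
    attention_channels: int = 8
    #: optional per-kind overrides of the EHR conv geometry
    encoder_channels: dict | None = None

    def channel_config(self, kind: str):
        if self.encoder_channels and kind in self.encoder_channels:
            return self.encoder_channels[kind]
        return default_channel_config(kind)

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        for stage in (self.image, self.text, self.decoder):
            if stage.patience > stage.epochs:
                raise ValueError("patience must not exceed epochs")


@dataclass
class EvalReport:
    per_fold: list[dict]
    threshold: float

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([f[metric] for f in self.per_fold])
        return float(vals.mean()), float(vals.std())

    def summary(self) -> dict:
        out = {"threshold": self.threshold, "folds": len(self.per_fold)}
        for m in ("auroc", "auprc", "sensitivity", "specificity", "accuracy"):
            mean, sd = self.mean_sd(m)
            out[m] = {"mean": mean, "sd": sd}
        return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """AUROC (rank statistic, tie-corrected), AUPRC (step integration), and
    thresholded sensitivity / specificity / accuracy."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "accuracy": (tp + tn) / len(labels),
    }


def resample_minority(indices: np.ndarray, labels: np.ndarray, factor: int = 10,
                      target: str = "minority") -> np.ndarray:
    """Duplicate the targeted class's training examples ``factor`` times.

    Applies only to training data; evaluation folds must never pass through
    here.  ``target='minority'`` picks whichever class is rarer (the paper's
    imbalance remedy), 'negative'/'positive' force a class.
    """
    if factor < 1:
        raise ValueError("resampling factor must be at least 1")
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    if factor == 1:
        return indices.copy()
    if target == "minority":
        pos_rate = labels.mean()
        chosen = 1 if pos_rate <= 0.5 else 0
    elif target == "negative":
        chosen = 0
    elif target == "positive":
        chosen = 1
    else:
        raise ValueError(f"unknown resample target {target!r}")
    hit = indices[labels == chosen]
    rest = indices[labels != chosen]
    return np.concatenate([rest] + [hit] * factor)


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Disjoint, exhaustive, label-stratified folds (list of test-index arrays)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("cross-validation needs both classes present")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# Early-stopped training harness
# ---------------------------------------------------------------------------


def train_stage(model, step_fn, val_fn, epochs: int, patience: int,
                name: str = "stage") -> dict:
    """Run ``step_fn(epoch)`` per epoch, track ``val_fn()`` (higher is
    better), stop after ``patience`` consecutive non-improving epochs, and
    restore the best-validation checkpoint (not the last).

    Returns a history dict with per-epoch losses/scores and the stop epoch.
    """
    best_score = -np.inf
    best_state = model.state_dict()
    bad = 0
    history = {"loss": [], "val": [], "stopped_at": epochs, "best_epoch": 0}
    t0 = time.perf_counter()
    for epoch in range(1, epochs + 1):
        loss = step_fn(epoch)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"{name}: non-finite training loss {loss} at epoch {epoch}"
            )
        score = val_fn()
        history["loss"].append(float(loss))
        history["val"].append(float(score))
        if score > best_score:
            best_score = score
            best_state = model.state_dict()
            history["best_epoch"] = epoch
            bad = 0
        else:
            bad += 1
            if bad >= max(patience, 1):
                history["stopped_at"] = epoch
                break
    model.load_state_dict(best_state)
    logger.info("%s: stopped at epoch %d (best %d, val %.4f, %.1fs)", name,
                history["stopped_at"], history["best_epoch"], best_score,
                time.perf_counter() - t0)
    return history


# ---------------------------------------------------------------------------
# Per-patient model-ready bundles
# ---------------------------------------------------------------------------


@dataclass
class PatientBundle:
    patient_id: str
    label: int
    tables: dict[str, LongitudinalTable]       # scaled, truncated, binned
    dem: np.ndarray
    volumes: dict[str, np.ndarray]             # sequence -> last-scan volume
    note_graph: object | None                  # WordGraph or None
    blobs: dict[str, list] = field(default_factory=dict)


def prepare_bundles(cohort: SyntheticCohort, train_ids: list[str],
                    cfg: TrainConfig) -> tuple[list[PatientBundle], dict]:
    """Fit preprocessing on the training patients and build model-ready
    bundles for the whole cohort.  Returns (bundles, schema)."""
    import datetime as dt

    horizon = dt.timedelta(days=cfg.horizon_years * 365.25)
    train_set = set(train_ids)
    patients = cohort.patients

    # labels (rule is split-independent)
    visit_rows = []
    for p in patients:
        for _, r in p.visits.iterrows():
            visit_rows.append((p.patient_id, r.visit_time, r.edss))
    visits = pd.DataFrame(visit_rows, columns=["patient_id", "visit_time", "edss"])
    labels = {rec.patient_id: rec
              for rec in derive_labels(visits, cfg.milestone, horizon)}

    # cohort-wide schema and scaling ranges from the training split only
    schema: dict = {"features": {}, "scalers": {}}
    for kind in EHR_KINDS:
        frames = []
        for p in patients:
            if p.patient_id in train_set and not p.events[kind].empty:
                df = p.events[kind].copy()
                df["patient_id"] = p.patient_id
                frames.append(df)
        stream = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=["patient_id", "feature", "value"]))
        feats = filter_features(stream, n_patients=len(train_set),
                                min_fraction=cfg.min_fraction)
        scaler = FeatureScaler(passthrough=(kind == "medication")).fit(stream)
        schema["features"][kind] = feats
        schema["scalers"][kind] = scaler

    demo_train = pd.DataFrame(
        [{**p.demographics} for p in patients if p.patient_id in train_set])
    dem_enc = DemographicsEncoder().fit(demo_train)
    schema["demographics"] = dem_enc

    bundles = []
    for p in patients:
        rec = labels[p.patient_id]
        # the index visit's own data counts as history: cut at the end of the
        # encounter containing the index visit, not at its first minute
        cut = rec.index_time
        for kind in EHR_KINDS:
            ev = p.events[kind]
            if len(ev):
                starts = pd.to_datetime(ev.encounter_start)
                ends = pd.to_datetime(ev.encounter_end)
                within = ends[starts <= rec.index_time]
                if len(within):
                    cut = max(cut, within.max().to_pydatetime())
        tables = {}
        for kind in EHR_KINDS:
            scaled = schema["scalers"][kind].transform(p.events[kind])
            table = bin_observations(scaled, schema["features"][kind], kind=kind)
            tables[kind] = truncate_history(table, cut)
        last = select_scan(p.sessions)
        volumes = dict(last["volumes"]) if last else {}
        blobs = dict(last["blobs"]) if last else {}
        note_graph = None
        texts = [t for _, t in p.notes]
        if texts:
            text = texts[-1] if cfg.notes_mode == "last" else " ".join(texts)
            toks = tokenize(text)
            if toks:
                note_graph = build_word_graph(toks, window=cfg.text_window)
        bundles.append(PatientBundle(
            patient_id=p.patient_id, label=rec.label, tables=tables,
            dem=dem_enc.transform_one(p.demographics), volumes=volumes,
            note_graph=note_graph, blobs=blobs,
        ))
    return bundles, schema


# ---------------------------------------------------------------------------
# Stage 1: metric-learning encoders
# ---------------------------------------------------------------------------


def _metric_val_score(model_embed, items, labels, anchor) -> float:
    """Negative-mean hinge-free criterion: anchor-distance separation
    (mean negative-class distance minus mean positive-class distance)."""
    dists = np.array([np.linalg.norm(model_embed(x) - anchor) for x in items])
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        return -float(dists.mean())
    return float(dists[labels == 0].mean() - dists[labels == 1].mean())


def train_image_channel(model: ResidualVolumeEncoder, volumes: list[np.ndarray],
                        labels: np.ndarray, cfg: TrainConfig,
                        rng: np.random.Generator) -> dict:
    """Triplet metric training of one MRI-sequence channel."""
    stage = cfg.image
    labels = np.asarray(labels)
    idx = np.arange(len(volumes))
    if len(set(labels.tolist())) < 2:
        raise ValueError("metric training needs both classes")
    tr, va = train_test_split(idx, test_size=max(cfg.val_fraction, 2 / len(idx)),
                              stratify=labels,
                              random_state=int(rng.integers(2**31)))
    n_unique = len(tr)  # epoch length counts distinct examples, not copies
    tr = resample_minority(tr, labels[tr], cfg.resample_factor, cfg.resample_target)
    anchor = model.cfg.anchor_point()
    opt = Adam(model.parameters(), lr=stage.learning_rate)
    margin = model.cfg.margin

    def step(_epoch):
        model.train()
        pos_pool = tr[labels[tr] == 1]
        neg_pool = tr[labels[tr] == 0]
        n_batches = max(n_unique // max(stage.batch_size, 1), 1)
        total = 0.0
        for _ in range(n_batches):
            m = max(stage.batch_size // 2, 1)
            p_idx = rng.choice(pos_pool, size=m)
            n_idx = rng.choice(neg_pool, size=m)
            p_vols = np.stack([augment(volumes[i], rng) for i in p_idx])
            n_vols = np.stack([augment(volumes[i], rng) for i in n_idx])
            p_emb = model(p_vols)
            n_emb = model(n_vols)
            loss = triplet_margin_loss(anchor, p_emb, n_emb, margin) / m
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        return total / n_batches

    def val():
        model.eval()
        return _metric_val_score(
            lambda v: model(normalize_intensity(v))[0].numpy(),
            [volumes[i] for i in va], labels[va], anchor)

    return train_stage(model, step, val, stage.epochs, stage.patience,
                       name="image-metric")


def train_text_channel(model: GraphNoteEncoder, graphs: list, labels: np.ndarray,
                       cfg: TrainConfig, rng: np.random.Generator) -> dict:
    """Triplet metric training of the note channel on prebuilt word graphs."""
    stage = cfg.text
    labels = np.asarray(labels)
    idx = np.arange(len(graphs))
    if len(set(labels.tolist())) < 2:
        raise ValueError("metric training needs both classes")
    tr, va = train_test_split(idx, test_size=max(cfg.val_fraction, 2 / len(idx)),
                              stratify=labels,
                              random_state=int(rng.integers(2**31)))
    n_unique = len(tr)
    tr = resample_minority(tr, labels[tr], cfg.resample_factor, cfg.resample_target)
    anchor = np.zeros(model.d_node)
    margin = cfg.image_encoder.margin  # shared loss definition across channels
    opt = Adam(model.parameters(), lr=stage.learning_rate)

    def step(_epoch):
        model.train()
        pos_pool = tr[labels[tr] == 1]
        neg_pool = tr[labels[tr] == 0]
        n_batches = max(n_unique // max(stage.batch_size, 1), 1)
        total = 0.0
        for _ in range(n_batches):
            m = max(stage.batch_size // 2, 1)
            p_emb = stack([model.embed_graph(graphs[i])
                           for i in rng.choice(pos_pool, size=m)])
            n_emb = stack([model.embed_graph(graphs[i])
                           for i in rng.choice(neg_pool, size=m)])
            loss = triplet_margin_loss(anchor, p_emb, n_emb, margin) / m
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        return total / n_batches

    def val():
        model.eval()
        return _metric_val_score(
            lambda g: model.embed_graph(g).numpy(),
            [graphs[i] for i in va], labels[va], anchor)

    return train_stage(model, step, val, stage.epochs, stage.patience,
                       name="text-metric")


# ---------------------------------------------------------------------------
# Stage 2: EHR channels + decoder (BCE)
# ---------------------------------------------------------------------------


class MilestonePipeline:
    """All trained components for one fold, with end-to-end prediction."""

    def __init__(self, cfg: TrainConfig, schema: dict, sequences: tuple[str, ...],
                 rng: np.random.Generator):
        self.cfg = cfg
        self.schema = schema
        self.sequences = tuple(sequences)
        self.row_order = tuple(
            m for m in DEFAULT_ROW_ORDER
            if m in EHR_KINDS or m == "note" or m in self.sequences
        )
        self.ehr_channels = {
            kind: EHRChannel(cfg.channel_config(kind), rng)
            for kind in EHR_KINDS
        }
        self.image_models: dict[str, ResidualVolumeEncoder] = {
            seq: ResidualVolumeEncoder(cfg.image_encoder, rng)
            for seq in self.sequences
        }
        vocab = schema.get("vocab", [])
        self.text_model = GraphNoteEncoder(
            vocab, rng, d_node=cfg.text_d_node, n_passes=cfg.text_passes,
            window=cfg.text_window)
        widths = [len(schema["features"][k]) for k in EHR_KINDS]
        self.d = max(widths + [cfg.image_encoder.embedding_dim, cfg.text_d_node])
        self.decoder = FusionDecoder(DecoderConfig(
            input_size=self.d,
            demographics_dim=schema["demographics"].dim,
            hidden=cfg.decoder_hidden, layers=cfg.decoder_layers,
            attention_channels=cfg.attention_channels,
            row_order=self.row_order,
        ), rng)
        self._frozen_cache: dict[str, dict[str, np.ndarray | None]] = {}

    # frozen-modality embeddings -------------------------------------------
    def frozen_embeddings(self, bundle: PatientBundle) -> dict[str, np.ndarray | None]:
        cached = self._frozen_cache.get(bundle.patient_id)
        if cached is not None:
            return cached
        emb: dict[str, np.ndarray | None] = {}
        for seq in self.sequences:
            vol = bundle.volumes.get(seq)
            emb[seq] = self.image_models[seq].embed(vol) if vol is not None else None
        if bundle.note_graph is not None:
            self.text_model.eval()
            emb["note"] = self.text_model.embed_graph(bundle.note_graph).numpy()
        else:
            emb["note"] = None
        self._frozen_cache[bundle.patient_id] = emb
        return emb

    def _pad_row(self, vec) -> Tensor:
        if vec is None:
            return Tensor(np.zeros(self.d))
        if isinstance(vec, Tensor):
            pad = self.d - vec.shape[0]
            return concat([vec, Tensor(np.zeros(pad))]) if pad else vec
        out = np.zeros(self.d)
        v = np.asarray(vec).ravel()
        out[: v.shape[0]] = v
        return Tensor(out)

    def fusion_tensor(self, bundle: PatientBundle,
                      table_tensors: dict[str, Tensor] | None = None) -> Tensor:
        """E for one patient as a graph tensor (EHR rows differentiable)."""
        frozen = self.frozen_embeddings(bundle)
        rows = []
        for name in self.row_order:
            if name in EHR_KINDS:
                table = bundle.tables[name]
                if table.is_empty():
                    rows.append(Tensor(np.zeros(self.d)))
                else:
                    src = (table_tensors or {}).get(name)
                    x = src if src is not None else Tensor(table.values)
                    rows.append(self._pad_row(self.ehr_channels[name](x)))
            else:
                rows.append(self._pad_row(frozen.get(name)))
        return stack(rows)

    def forward_batch(self, bundles: list[PatientBundle]) -> Tensor:
        e = stack([self.fusion_tensor(b) for b in bundles])
        dem = np.stack([b.dem for b in bundles])
        return self.decoder(e, dem)

    def predict(self, bundle: PatientBundle) -> float:
        """Milestone probability for one patient (eval mode, deterministic)."""
        self._set_eval()
        return float(self.forward_batch([bundle]).numpy()[0])

    def predict_with_embeddings(self, bundle: PatientBundle):
        """Probability plus the per-modality embedding dict (explainability)."""
        self._set_eval()
        emb = dict(self.frozen_embeddings(bundle))
        for kind in EHR_KINDS:
            table = bundle.tables[kind]
            emb[kind] = (np.zeros(table.f_k) if table.is_empty()
                         else self.ehr_channels[kind](Tensor(table.values)).numpy())
        prob = float(self.forward_batch([bundle]).numpy()[0])
        return prob, emb

    def _set_eval(self):
        for ch in self.ehr_channels.values():
            ch.eval()
        for m in self.image_models.values():
            m.eval()
        self.text_model.eval()
        self.decoder.eval()

    def _set_train_stage2(self):
        for ch in self.ehr_channels.values():
            ch.train()
        self.decoder.train()

    def stage2_parameters(self):
        params = self.decoder.parameters()
        for ch in self.ehr_channels.values():
            params += ch.parameters()
        return params

    def stage2_state(self):
        state = {"decoder": self.decoder.state_dict()}
        for kind, ch in self.ehr_channels.items():
            state[kind] = ch.state_dict()
        return state

    def load_stage2_state(self, state):
        self.decoder.load_state_dict(state["decoder"])
        for kind, ch in self.ehr_channels.items():
            ch.load_state_dict(state[kind])


class _Stage2Shim:
    """Adapter exposing state_dict/load_state_dict over the joint stage-2
    parameters so the generic early-stopping harness can checkpoint them."""

    def __init__(self, pipeline: MilestonePipeline):
        self.pipeline = pipeline

    def state_dict(self):
        return copy.deepcopy(self.pipeline.stage2_state())

    def load_state_dict(self, state):
        self.pipeline.load_stage2_state(state)


def train_decoder_stage(pipeline: MilestonePipeline, bundles: list[PatientBundle],
                        train_idx: np.ndarray, cfg: TrainConfig,
                        rng: np.random.Generator) -> dict:
    labels = np.array([bundles[i].label for i in train_idx])
    tr, va = train_test_split(np.asarray(train_idx),
                              test_size=max(cfg.val_fraction, 2 / len(train_idx)),
                              stratify=labels,
                              random_state=int(rng.integers(2**31)))
    tr_labels = np.array([bundles[i].label for i in tr])
    n_unique = len(tr)
    tr = resample_minority(tr, tr_labels, cfg.resample_factor, cfg.resample_target)
    stage = cfg.decoder
    opt = Adam(pipeline.stage2_parameters(), lr=stage.learning_rate,
               weight_decay=stage.weight_decay)

    def step(_epoch):
        # epoch length counts distinct patients; batches are drawn from the
        # resampled pool, preserving the re-weighted class mix in expectation
        pipeline._set_train_stage2()
        order = rng.choice(tr, size=n_unique, replace=True)
        total, count = 0.0, 0
        for lo in range(0, len(order), stage.batch_size):
            chunk = order[lo : lo + stage.batch_size]
            batch = [bundles[i] for i in chunk]
            probs = pipeline.forward_batch(batch)
            loss = bce_loss(probs, np.array([b.label for b in batch]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(chunk)
            count += len(chunk)
        return total / count

    def val():
        # ranking-first selection: validation AUROC, with class-balanced BCE
        # as a small tiebreak.  Minority resampling shifts the probability
        # calibration, so raw BCE degrades even while discrimination improves;
        # AUROC is immune to the shift and the tiebreak resolves its coarse
        # granularity on small validation splits.
        pipeline._set_eval()
        probs = pipeline.forward_batch([bundles[i] for i in va]).numpy()
        y = np.array([bundles[i].label for i in va])
        auc = roc_auc_score(y, probs) if y.min() != y.max() else 0.5
        balanced = np.mean([
            bce_loss(Tensor(probs[y == cls]), y[y == cls]).item()
            for cls in (0, 1) if (y == cls).any()
        ])
        return float(auc - 0.01 * balanced)

    return train_stage(_Stage2Shim(pipeline), step, val, stage.epochs,
                       stage.patience, name="decoder")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def train_fold(cohort: SyntheticCohort, train_ids: list[str], cfg: TrainConfig,
               seed: int) -> tuple[MilestonePipeline, list[PatientBundle]]:
    """Fit preprocessing + all training stages on one training split."""
    rng = np.random.default_rng(seed)
    bundles, schema = prepare_bundles(cohort, train_ids, cfg)
    by_id = {b.patient_id: b for b in bundles}
    train_bundles = [by_id[i] for i in train_ids]

    # vocabulary for the note channel: words seen in training notes
    vocab = sorted({w for b in train_bundles if b.note_graph is not None
                    for w in b.note_graph.nodes[:-1]})
    schema["vocab"] = vocab

    sequences = cfg.sequences
    if sequences is None:
        sequences = tuple(sorted({s for b in bundles for s in b.volumes}))
    pipeline = MilestonePipeline(cfg, schema, sequences, rng)

    for seq in pipeline.sequences:
        have = [b for b in train_bundles if seq in b.volumes]
        y = np.array([b.label for b in have])
        if len(have) >= 10 and 0 < y.sum() < len(y):
            train_image_channel(pipeline.image_models[seq],
                                [b.volumes[seq] for b in have], y, cfg, rng)
        else:
            logger.warning("sequence %s: too few training volumes, left at init", seq)

    noted = [b for b in train_bundles if b.note_graph is not None]
    y = np.array([b.label for b in noted])
    if len(noted) >= 10 and 0 < y.sum() < len(y):
        train_text_channel(pipeline.text_model, [b.note_graph for b in noted],
                           y, cfg, rng)
    elif vocab:
        logger.warning("too few training notes, text channel left at init")

    idx_of = {b.patient_id: i for i, b in enumerate(bundles)}
    train_idx = np.array([idx_of[i] for i in train_ids])
    train_decoder_stage(pipeline, bundles, train_idx, cfg, rng)
    return pipeline, bundles


def cross_validate(cohort: SyntheticCohort, cfg: TrainConfig,
                   return_models: bool = False):
    """Stratified k-fold CV of the full staged pipeline.

    Returns an :class:`EvalReport` (and per-fold ``(pipeline, bundles,
    test_idx)`` triples when ``return_models``)."""
    labels = cohort.labels
    folds = stratified_folds(labels, cfg.folds, cfg.seed)
    ids = [p.patient_id for p in cohort.patients]
    per_fold, models, predictions = [], [], []
    for fold_no, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_ids = [ids[i] for i in range(len(ids)) if i not in test_set]
        pipeline, bundles = train_fold(cohort, train_ids, cfg,
                                       seed=cfg.seed + 1000 * (fold_no + 1))
        by_id = {b.patient_id: b for b in bundles}
        scores = np.array([pipeline.predict(by_id[ids[i]]) for i in test_idx])
        y = labels[test_idx]
        per_fold.append(compute_metrics(scores, y, cfg.threshold))
        for i, s in zip(test_idx, scores):
            predictions.append({"patient_id": ids[i], "fold": fold_no,
                                "score": float(s), "label": int(labels[i])})
        if return_models:
            models.append((pipeline, bundles, test_idx))
        logger.info("fold %d: AUROC %.3f", fold_no, per_fold[-1]["auroc"])
    report = EvalReport(per_fold=per_fold, threshold=cfg.threshold)
    report.predictions = pd.DataFrame(predictions)  # type: ignore[attr-defined]
    if return_models:
        return report, models
    return report


# ---------------------------------------------------------------------------
# Explainability
# ---------------------------------------------------------------------------


def feature_importance(pipeline: MilestonePipeline,
                       bundles: list[PatientBundle]) -> dict[str, pd.Series]:
    """Gradient-weighted attention importance per structured-EHR feature.

    importance_j = mean over patients and bins of alpha[m] * |d o / d D[m, j]|,
    normalized to sum to one within each table; all-zero gradients fall back
    to a uniform distribution.
    """
    pipeline._set_eval()
    sums = {k: np.zeros(len(pipeline.schema["features"][k])) for k in EHR_KINDS}
    for bundle in bundles:
        tensors = {}
        for kind in EHR_KINDS:
            table = bundle.tables[kind]
            if not table.is_empty():
                t = Tensor(table.values, requires_grad=True)
                tensors[kind] = t
        e = stack([pipeline.fusion_tensor(bundle, table_tensors=tensors)])
        prob = pipeline.decoder(e, bundle.dem.reshape(1, -1))
        prob.backward(np.ones(1))
        for kind, t in tensors.items():
            if t.grad is None:
                continue
            alpha = pipeline.ehr_channels[kind].attention(
                Tensor(bundle.tables[kind].values)).numpy()
            sums[kind] += (alpha[:, None] * np.abs(t.grad)).mean(axis=0)
    out = {}
    for kind in EHR_KINDS:
        feats = pipeline.schema["features"][kind]
        total = sums[kind].sum()
        if total <= 0:
            vals = (np.full(len(feats), 1.0 / len(feats)) if feats
                    else np.zeros(0))
        else:
            vals = sums[kind] / total
        out[kind] = pd.Series(vals, index=feats, name="importance")
    return out
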