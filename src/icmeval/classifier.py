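"""CNN false-positive triage of device-detected AF episodes.

Each device-detected episode stores a 90-second electrogram snippet (30 s
pre-trigger + 60 s post-trigger).  A deep 1-D CNN — stacked blocks of
Conv1D → ReLU → batch normalization → dropout, with periodic max pooling,
a global average pooling layer, dense layers and a sigmoid output — scores
each snippet as true AF (1) vs false detection (0).  Training uses the
binary focal cross-entropy loss with the Adam optimizer, with a
patient-level train/validation split so no patient contributes to both.

Used as a *filter*: episodes scoring below the operating threshold are
rejected before the performance metrics are recomputed.  The default
threshold policy rejects as many validation false episodes as possible
subject to retaining every validation true episode (zero true-positive
loss), which leaves sensitivity untouched by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_io import IcmEpisode, IcmEpisodeLog
from .cnn import (
    Adam, BatchNorm1D, Conv1D, Dense, Dropout, GlobalAvgPool, MaxPool1D, ReLU,
    SequentialNet, focal_loss, focal_loss_grad_logit, sigmoid,
)
from .synthetic import EgmSnippet

THRESHOLD_POLICIES = ("fixed", "max_rejection_zero_tp_loss")


class ClassifierConfigError(ValueError):
    pass


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters.

    Defaults are sized for desk-scale training (a few minutes on one CPU for
    ~10^3 snippets) while keeping the stated structure: filter counts and
    dropout rates non-decreasing with depth, periodic max pooling, global
    average pooling, dense head, sigmoid output, focal loss + Adam.
    """

    n_conv_blocks: int = 4
    filters_per_block: tuple[int, ...] = (8, 8, 16, 16)
    kernel_size: int = 9
    dropout_per_block: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2)
    pool_every: int = 1
    dense_units: tuple[int, ...] = (32,)
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    learning_rate: float = 3e-3
    epochs: int = 12
    batch_size: int = 32
    seed: int = 0
    threshold_policy: str = "max_rejection_zero_tp_loss"
    fixed_threshold: float = 0.5
    threshold_margin: float = 1e-6
    #: integer factor by which raw snippets are average-pooled before the
    #: first conv layer (anti-aliased decimation; cuts compute ~linearly)
    input_downsample: int = 2
    val_fraction: float = 0.3

    def __post_init__(self) -> None:
        self.filters_per_block = tuple(int(f) for f in self.filters_per_block)
        self.dropout_per_block = tuple(float(d) for d in self.dropout_per_block)
        self.dense_units = tuple(int(u) for u in self.dense_units)
        if len(self.filters_per_block) != self.n_conv_blocks:
            raise ClassifierConfigError("filters_per_block length != n_conv_blocks")
        if len(self.dropout_per_block) != self.n_conv_blocks:
            raise ClassifierConfigError("dropout_per_block length != n_conv_blocks")
        if list(self.filters_per_block) != sorted(self.filters_per_block):
            raise ClassifierConfigError("filter counts must be non-decreasing with depth")
        if list(self.dropout_per_block) != sorted(self.dropout_per_block):
            raise ClassifierConfigError("dropout rates must be non-decreasing with depth")
        if not all(0.0 <= d < 1.0 for d in self.dropout_per_block):
            raise ClassifierConfigError("dropout rates must lie in [0, 1)")
        if self.threshold_policy not in THRESHOLD_POLICIES:
            raise ClassifierConfigError(f"unknown threshold_policy {self.threshold_policy!r}")
        if self.focal_gamma < 0 or not 0.0 < self.focal_alpha < 1.0:
            raise ClassifierConfigError("focal_gamma >= 0 and focal_alpha in (0,1) required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainedClassifier:
    config: ClassifierConfig
    net: SequentialNet
    input_len: int
    operating_threshold: float = 0.5
    history: list[dict] = field(default_factory=list)
    validation_summary: dict = field(default_factory=dict)

    def score(self, snippets: Sequence[EgmSnippet] | np.ndarray) -> np.ndarray:
        x = prepare_inputs(snippets, self.config.input_downsample)
        if x.shape[2] != self.input_len:
            raise ValueError(
                f"snippet length {x.shape[2]} != model input length {self.input_len}"
            )
        return self.net.predict_proba(x)


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def prepare_inputs(
    snippets: Sequence[EgmSnippet] | np.ndarray, downsample: int = 1
) -> np.ndarray:
    """Stack snippets into a (N, 1, L) float32 array.

    Each snippet is decimated by block-averaging (``downsample`` consecutive
    samples) and z-scored, so the classifier sees amplitude-normalized
    waveforms.
    """
    if isinstance(snippets, np.ndarray):
        arr = np.asarray(snippets, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[None, :]
    else:
        arr = np.stack([np.asarray(s.samples, dtype=np.float64) for s in snippets])
    if downsample > 1:
        L = (arr.shape[1] // downsample) * downsample
        arr = arr[:, :L].reshape(arr.shape[0], -1, downsample).mean(axis=2)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    arr = (arr - mu) / np.maximum(sd, 1e-8)
    return arr[:, None, :].astype(np.float32)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_model(config: ClassifierConfig, input_len: int) -> SequentialNet:
    """Assemble the CNN for snippets of ``input_len`` samples (post-decimation).

    Structure: [Conv1D → ReLU → BatchNorm → Dropout] × n, max pool every
    ``pool_every`` blocks, global average pooling, dense layers with ReLU,
    and a single-logit head (sigmoid applied at scoring time).  Raises a
    configuration error when pooling would shrink the signal below 8
    samples.
    """
    rng = np.random.default_rng(config.seed)
    layers: list = []
    c_in, L = 1, int(input_len)
    for b in range(config.n_conv_blocks):
        c_out = config.filters_per_block[b]
        layers += [
            Conv1D(c_in, c_out, config.kernel_size, rng),
            ReLU(),
            BatchNorm1D(c_out),
            Dropout(config.dropout_per_block[b], rng),
        ]
        c_in = c_out
        if config.pool_every > 0 and (b + 1) % config.pool_every == 0:
            layers.append(MaxPool1D())
            L //= 2
            if L < 8:
                raise ClassifierConfigError(
                    f"input length {input_len} incompatible with pooling depth "
                    f"(collapses to {L} samples at block {b + 1})"
                )
    layers.append(GlobalAvgPool())
    n_in = c_in
    for u in config.dense_units:
        layers += [Dense(n_in, u, rng), ReLU()]
        n_in = u
    layers.append(Dense(n_in, 1, rng))
    return SequentialNet(layers)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _patient_split(
    patient_ids: Sequence[str], labels: np.ndarray, val_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level split keeping both classes in both partitions."""
    pids = np.asarray(patient_ids)
    uniq = sorted(set(pids))
    # stratify patients by whether they contribute any true-AF snippet
    pos_patients = sorted({p for p, y in zip(pids, labels) if y == 1})
    neg_patients = [p for p in uniq if p not in set(pos_patients)]
    mixed = [p for p in pos_patients]  # patients may contribute both classes
    val_patients: set[str] = set()
    for group in (mixed, neg_patients):
        g = list(group)
        rng.shuffle(g)
        n_val = max(1, int(round(val_fraction * len(g)))) if g else 0
        val_patients.update(g[:n_val])
    val_mask = np.isin(pids, sorted(val_patients))
    # both classes must appear on both sides
    for side, m in (("training", ~val_mask), ("validation", val_mask)):
        if len(set(labels[m])) < 2:
            raise ValueError(f"{side} split lacks one class; need more patients")
    return ~val_mask, val_mask


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based AUROC (Mann–Whitney)."""
    from scipy.stats import rankdata

    s = np.concatenate([scores_pos, scores_neg])
    r = rankdata(s)
    n1, n0 = len(scores_pos), len(scores_neg)
    if n1 == 0 or n0 == 0:
        return float("nan")
    return float((r[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def train(
    snippets: Sequence[EgmSnippet],
    labels: Sequence[int],
    patient_ids: Sequence[str],
    config: ClassifierConfig,
) -> TrainedClassifier:
    """Fit the CNN and pick the operating threshold on held-out patients.

    ``labels``: 1 = true AF episode, 0 = false detection.  The split is by
    patient (no patient in both partitions).  Per-epoch training and
    validation focal loss is recorded in ``history``.
    """
    y = np.asarray(labels, dtype=np.float64)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    x = prepare_inputs(snippets, config.input_downsample)
    if len({xi.shape for xi in x}) > 1:  # pragma: no cover - stack already enforces
        raise ValueError("snippets must be length-homogeneous")
    rng = np.random.default_rng(config.seed)
    tr_mask, va_mask = _patient_split(patient_ids, y, config.val_fraction, rng)
    xtr, ytr = x[tr_mask], y[tr_mask]
    xva, yva = x[va_mask], y[va_mask]

    net = build_model(config, x.shape[2])
    opt = Adam(net, lr=config.learning_rate)
    history = []
    n = len(xtr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            logits = net.forward(xb, train=True)
            p = sigmoid(logits)
            loss = focal_loss(p, yb, config.focal_gamma, config.focal_alpha)
            ep_loss += float(loss.sum())
            g = focal_loss_grad_logit(p, yb, config.focal_gamma, config.focal_alpha)
            net.backward(g / len(yb))
            opt.step()
        pva = net.predict_proba(xva)
        val_loss = float(
            focal_loss(pva, yva, config.focal_gamma, config.focal_alpha).mean()
        )
        history.append({
            "epoch": epoch + 1,
            "train_loss": ep_loss / n,
            "val_loss": val_loss,
        })

    pva = net.predict_proba(xva)
    threshold = select_threshold(pva, yva, config)
    summary = {
        "n_train": int(n),
        "n_val": int(len(xva)),
        "val_auroc": auroc(pva[yva == 1], pva[yva == 0]),
        "val_fp_rejected": int(((pva < threshold) & (yva == 0)).sum()),
        "val_fp_total": int((yva == 0).sum()),
        "val_tp_retained": int(((pva >= threshold) & (yva == 1)).sum()),
        "val_tp_total": int((yva == 1).sum()),
    }
    return TrainedClassifier(config, net, x.shape[2], threshold, history, summary)


def select_threshold(
    scores: np.ndarray, labels: np.ndarray, config: ClassifierConfig
) -> float:
    """Operating threshold; episodes with score >= threshold are retained.

    ``max_rejection_zero_tp_loss``: the largest threshold that retains every
    validation true episode (i.e. the minimum true-episode score), minus a
    safety margin ε — this rejects the most false episodes achievable at zero
    true-positive loss.  Any threshold between the highest rejected false
    score and the minimum true score rejects exactly the same validation
    episodes, so ε is set to half that gap: the midpoint maximizes the
    distance to both score clouds and is robust for borderline episodes
    outside the validation set.  ``fixed``: the configured value.
    """
    if config.threshold_policy == "fixed":
        return float(config.fixed_threshold)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    if len(pos) == 0:
        raise ValueError("validation set has no true episode; cannot set threshold")
    t_max = float(pos.min())
    neg_below = scores[(labels == 0) & (scores < t_max)]
    floor = float(neg_below.max()) if len(neg_below) else 0.0
    eps = max(0.5 * (t_max - floor), config.threshold_margin)
    return float(t_max - eps)


# ---------------------------------------------------------------------------
# Applying the classifier to an episode log
# ---------------------------------------------------------------------------

def classify_log(
    icm_log: IcmEpisodeLog,
    trained: TrainedClassifier,
    egms: dict[tuple[str, str], EgmSnippet],
) -> tuple[IcmEpisodeLog, list[str]]:
    """Score every episode and set ``ai_score``/``ai_retained``.

    Episode boundaries and ordering are untouched — the classifier only
    marks the retained subset.  An episode with no snippet is retained by
    default (fail-safe toward sensitivity) and reported in the error list.
    """
    errors: list[str] = []
    with_snippet: list[int] = []
    snippets: list[EgmSnippet] = []
    for i, ep in enumerate(icm_log.episodes):
        snip = egms.get((icm_log.patient_id, ep.episode_id))
        if snip is None:
            errors.append(f"{icm_log.patient_id}/{ep.episode_id}: missing EGM snippet; retained")
        else:
            with_snippet.append(i)
            snippets.append(snip)
    scores = trained.score(snippets) if snippets else np.empty(0)
    new_eps: list[IcmEpisode] = []
    score_by_idx = dict(zip(with_snippet, scores))
    for i, ep in enumerate(icm_log.episodes):
        if i in score_by_idx:
            s = float(score_by_idx[i])
            new_eps.append(replace(ep, ai_score=s,
                                   ai_retained=bool(s >= trained.operating_threshold)))
        else:
            new_eps.append(replace(ep, ai_score=None, ai_retained=True))
    return IcmEpisodeLog(icm_log.patient_id, new_eps), errors


# ---------------------------------------------------------------------------
# Persistence (config + weights + threshold + training log)
# ---------------------------------------------------------------------------

def save_classifier(trained: TrainedClassifier, model_dir) -> None:
    d = Path(model_dir)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": trained.config.to_dict(),
        "input_len": trained.input_len,
        "operating_threshold": trained.operating_threshold,
        "history": trained.history,
        "validation_summary": trained.validation_summary,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    np.savez(d / "weights.npz", **trained.net.state_dict())


def load_classifier(model_dir) -> TrainedClassifier:
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    cfg_dict = meta["config"]
    for key in ("filters_per_block", "dropout_per_block", "dense_units"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ClassifierConfig(**cfg_dict)
    net = build_model(cfg, meta["input_len"])
    with np.load(d / "weights.npz") as state:
        net.load_state_dict({k: state[k] for k in state.files})
    return TrainedClassifier(
        cfg, net, int(meta["input_len"]), float(meta["operating_threshold"]),
        meta.get("history", []), meta.get("validation_summary", {}),
    )
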