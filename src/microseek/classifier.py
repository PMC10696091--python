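"""Training, scoring and evaluation of the read-origin classifier.

Training selects, across epochs, the checkpoint with the best mean
one-vs-all AUPRC on the validation split.  Scoring applies the read
normalization rules (N exclusion/replacement, 3' padding) and returns one
probability triple (human, viral, bacterial) per retained read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import evaluate_scores, mean_metric
from .network import Adam, ClassifierConfig, ReadOriginNet, one_hot
from .normalize import NormalizedRead, normalize_read
from .segmentation import Datasets, SegmentDataset
from .simulate import ORIGIN_LABELS, ReadRecord

SCORE_COLUMNS = ["read_id", "p_human", "p_viral", "p_bacterial", "excluded"]


@dataclass
class TrainedClassifier:
    net: ReadOriginNet
    best_epoch: int
    best_val_auprc: float
    history: list[dict] = field(default_factory=list)


def _check_split(ds: SegmentDataset, name: str, require_all: bool = True) -> None:
    if len(ds) == 0:
        raise ValueError(f"{name} split is empty")
    if require_all and len(np.unique(ds.labels)) < 3:
        raise ValueError(f"{name} split is missing a class")


def train_classifier(datasets: Datasets, config: ClassifierConfig | None = None) -> TrainedClassifier:
    """Train with Adam/cross-entropy; keep the best-validation checkpoint.

    With ``epochs=0`` the returned model is the (reproducible) initialization
    and validation metrics are still computed once.
    """
    config = config or ClassifierConfig()
    _check_split(datasets.train, "train")
    _check_split(datasets.val, "validation")

    x_tr = one_hot(datasets.train.segments, config.input_length)
    y_tr = datasets.train.labels
    x_va = one_hot(datasets.val.segments, config.input_length)
    y_va = datasets.val.labels

    net = ReadOriginNet(config)
    opt = Adam(lr=config.learning_rate)
    rng = np.random.default_rng(config.rng_seed)

    def val_auprc() -> float:
        probs = net.predict_proba(x_va)
        return mean_metric(evaluate_scores(probs, y_va), "auprc")

    best = val_auprc()
    best_params = net.get_params()
    best_epoch = 0
    history = [{"epoch": 0, "val_mean_auprc": best}]

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            loss, grads = net.loss_and_grads(x_tr[idx], y_tr[idx])
            opt.step(net.params, grads)
            losses.append(loss)
        score = val_auprc()
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_mean_auprc": score})
        if score > best:
            best, best_params, best_epoch = score, net.get_params(), epoch

    net.set_params(best_params)
    return TrainedClassifier(net, best_epoch, best, history)


def score_reads(
    model: ReadOriginNet | TrainedClassifier,
    reads: list[ReadRecord],
    rng: np.random.Generator | int = 0,
) -> tuple[pd.DataFrame, dict[str, NormalizedRead]]:
    """Score reads, applying the normalization rules first.

    Returns the score table (read_id, p_human, p_viral, p_bacterial,
    excluded) and the per-read normalization records, which preserve any
    random N replacement for reuse by assembly.
    """
    net = model.net if isinstance(model, TrainedClassifier) else model
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    norm: dict[str, NormalizedRead] = {}
    keep_ids: list[str] = []
    keep_seqs: list[str] = []
    for r in reads:
        nr = normalize_read(r.sequence, net.config.input_length, rng)
        norm[r.read_id] = nr
        if not nr.excluded:
            keep_ids.append(r.read_id)
            keep_seqs.append(nr.scoring_sequence)

    rows = []
    if keep_seqs:
        probs = net.predict_proba(one_hot(keep_seqs, net.config.input_length))
        for rid, p in zip(keep_ids, probs):
            rows.append((rid, float(p[0]), float(p[1]), float(p[2]), False))
    for r in reads:
        if norm[r.read_id].excluded:
            rows.append((r.read_id, np.nan, np.nan, np.nan, True))
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    # restore input order
    order = {r.read_id: i for i, r in enumerate(reads)}
    table = table.sort_values("read_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return table, norm


def evaluate_classifier(
    model: ReadOriginNet | TrainedClassifier, test: SegmentDataset
) -> dict[str, dict[str, float] | None]:
    """One-vs-all AUPRC/AUROC per class on a labeled segment set."""
    net = model.net if isinstance(model, TrainedClassifier) else model
    if len(test) == 0:
        raise ValueError("test set is empty")
    probs = net.predict_proba(one_hot(test.segments, net.config.input_length))
    return evaluate_scores(probs, test.labels, ORIGIN_LABELS)
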