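"""Leave-one-subject-out training and evaluation.

LOSO cross-validation holds out every subject once: all clips of the held
subject form the test fold and the network is trained from scratch on the
remaining subjects. Class priors for the logit-adjusted loss are estimated
on each training split only, so no information about the held-out subject
leaks into the adjustment. Predictions are pooled over folds into a single
confusion matrix, from which the report derives pooled accuracy, per-class
accuracy (recall) and F1, and their unweighted means UAR and UF1.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .autodiff import Tensor
from .losses import get_loss, prior_adjustment
from .network import FlowNet
from .nn import Adam
from .types import (
    DatasetManifest,
    EvalReport,
    InputError,
    NetConfig,
    TrainConfig,
    TripletDataset,
)

__all__ = ["loso_splits", "augment", "flip_flow", "train_fold",
           "evaluate_loso", "report_from_predictions", "fit"]


def loso_splits(manifest: DatasetManifest) -> List[Tuple[list, list]]:
    """One (train_ids, test_ids) pair per subject, ordered by subject id."""
    subjects = manifest.subjects
    if len(subjects) < 2:
        raise InputError("LOSO needs at least 2 subjects")
    splits = []
    for subj in subjects:
        test = [r.sample_id for r in manifest.records if r.subject_id == subj]
        train = [r.sample_id for r in manifest.records if r.subject_id != subj]
        splits.append((train, test))
    return splits


def flip_flow(u: np.ndarray, v: np.ndarray,
              os_map: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Horizontal mirror of a raw flow field.

    Mirroring a face swaps left and right, so the horizontal displacement
    changes sign while the vertical displacement and the (sign-free) strain
    magnitude are purely mirrored. Applying the operation twice restores the
    original field exactly.
    """
    return -u[:, ::-1], v[:, ::-1], os_map[:, ::-1]


def augment(triplet: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flip and per-channel affine colour dither.

    Operates on a normalized (3, S, S) triplet. The flip mirrors all three
    channels and maps the u channel through x -> 1 - x: min-max
    normalisation is affine with positive scale, so this is exactly the
    normalized image of the sign-flipped raw u field. Dithering scales each
    channel by a factor in [0.9, 1.1] and shifts it by [-0.05, 0.05], then
    clips back to [0, 1].
    """
    out = np.array(triplet, dtype=np.float32, copy=True)
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
        out[0] = 1.0 - out[0]
    scale = rng.uniform(0.9, 1.1, size=3).astype(np.float32)
    shift = rng.uniform(-0.05, 0.05, size=3).astype(np.float32)
    out = out * scale[:, None, None] + shift[:, None, None]
    return np.clip(out, 0.0, 1.0)


def train_fold(train: TripletDataset, train_cfg: TrainConfig,
               net_cfg: NetConfig,
               callback: Optional[Callable[[int, float], None]] = None
               ) -> Tuple[FlowNet, List[float]]:
    """Train a fresh network on one split; returns (model, per-epoch mean loss).

    The optimiser is Adam with L2 weight decay; shuffling and augmentation
    draw from a generator seeded by ``train_cfg.seed`` so a fixed seed gives
    an identical loss history. Class priors for the adjusted losses come
    from this split alone.
    """
    if len(train) == 0:
        raise InputError("empty training split")
    classes_present = np.unique(train.y)
    if len(classes_present) < 2:
        raise InputError(
            f"training split contains a single class ({classes_present.tolist()}); "
            "cannot fit a classifier"
        )
    n_classes = net_cfg.n_classes
    adj = prior_adjustment(train.y, n_classes, tau=train_cfg.tau,
                           eps=train_cfg.eps)
    loss_fn = get_loss(train_cfg.loss, adj=adj, gamma=train_cfg.gamma)
    model = FlowNet(net_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.lr,
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    history: List[float] = []
    n = len(train)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        model.train()
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo: lo + train_cfg.batch_size]
            xb = train.X[idx]
            if train_cfg.augment:
                xb = np.stack([augment(x, rng) for x in xb])
            logits = model(Tensor(np.ascontiguousarray(xb)))
            loss = loss_fn(logits, train.y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss))
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss)
    if not all(np.all(np.isfinite(p.data)) for p in model.parameters()):
        raise RuntimeError("training diverged: non-finite weights")
    return model, history


fit = train_fold  # convenience alias


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            label_vocab: Sequence[str],
                            per_fold: Optional[list] = None,
                            per_sample: Optional[dict] = None,
                            seed: Optional[int] = None,
                            config: Optional[dict] = None) -> EvalReport:
    """Build an :class:`EvalReport` from pooled truth/prediction vectors.

    Per-class accuracy is recall TP_c / N_c; F1_c = 2 TP_c / (2 TP_c + FP_c
    + FN_c); UF1 and UAR are the unweighted means over classes. Classes
    absent from the pooled test set have undefined recall/F1 and are
    excluded from the unweighted means with a warning entry in the report.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    c = len(label_vocab)
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(c))
    tp = np.diag(cm).astype(np.float64)
    support = cm.sum(axis=1).astype(np.float64)       # N_c, rows = truth
    fp = cm.sum(axis=0) - tp
    fn = support - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        acc_c = np.where(support > 0, tp / support, np.nan)
        f1_c = np.where(2 * tp + fp + fn > 0,
                        2 * tp / (2 * tp + fp + fn), np.nan)
        f1_c = np.where(support > 0, f1_c, np.nan)
    present = support > 0
    excluded = [label_vocab[i] for i in range(c) if not present[i]]
    mean_fold = (float(np.mean([f["acc"] for f in per_fold]))
                 if per_fold else float("nan"))
    return EvalReport(
        confusion=cm,
        label_vocab=list(label_vocab),
        acc=float(tp.sum() / cm.sum()) if cm.sum() else float("nan"),
        acc_per_class=acc_c,
        f1_per_class=f1_c,
        uf1=float(np.nanmean(f1_c[present])) if present.any() else float("nan"),
        uar=float(np.nanmean(acc_c[present])) if present.any() else float("nan"),
        macro_f1=float(np.nanmean(f1_c[present])) if present.any() else float("nan"),
        mean_fold_acc=mean_fold,
        per_fold=per_fold or [],
        per_sample=per_sample or {},
        excluded_classes=excluded,
        seed=seed,
        config=config or {},
    )


def evaluate_loso(data: TripletDataset, train_cfg: TrainConfig,
                  net_cfg: Optional[NetConfig] = None,
                  verbose: bool = False) -> EvalReport:
    """Full leave-one-subject-out evaluation of the flow network.

    Trains one model per subject fold and pools per-sample predictions into
    a single confusion matrix. Per-fold accuracies are also recorded; the
    headline ``acc`` is the pooled accuracy.
    """
    net_cfg = net_cfg or NetConfig(n_classes=len(data.label_vocab),
                                   seed=train_cfg.seed)
    if net_cfg.n_classes != len(data.label_vocab):
        raise InputError("net_cfg.n_classes must match the label vocabulary")
    manifest = data.to_manifest()
    subjects = manifest.subjects
    if len(subjects) < 2:
        raise InputError("LOSO needs at least 2 subjects")
    ids, trues, preds, per_fold = [], [], [], []
    for subj in subjects:
        test_mask = data.subjects == subj
        train_split = data.subset(~test_mask)
        test_split = data.subset(test_mask)
        try:
            model, history = train_fold(train_split, train_cfg, net_cfg)
        except InputError as err:
            raise InputError(f"fold {subj!r}: {err}") from err
        fold_pred = model.predict(test_split.X)
        ids.extend(test_split.sample_ids.tolist())
        trues.extend(test_split.y.tolist())
        preds.extend(fold_pred.tolist())
        fold_acc = float(np.mean(fold_pred == test_split.y))
        per_fold.append({
            "subject": str(subj),
            "n_test": int(test_mask.sum()),
            "acc": fold_acc,
            "final_loss": history[-1],
        })
        if verbose:
            print(f"fold {subj}: n={test_mask.sum()} acc={fold_acc:.3f}")
    per_sample = {
        "sample_id": ids,
        "y_true": [int(t) for t in trues],
        "y_pred": [int(p) for p in preds],
    }
    return report_from_predictions(
        np.array(trues), np.array(preds), data.label_vocab,
        per_fold=per_fold, per_sample=per_sample, seed=train_cfg.seed,
        config={"train": train_cfg.to_dict(), "net": net_cfg.to_dict()},
    )
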