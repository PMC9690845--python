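"""Training loop, k-fold cross-validation and size-stratified reporting.

All randomness (fold assignment, weight initialization, batch shuffling,
phantom generation upstream) funnels through explicit integer seeds, so a
single-threaded run is bit-reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._autodiff import Adam, SGD, batch_dice_loss
from .config import NetConfig, TrainConfig
from .dataio import ImageSample, assign_size_group, make_folds, resize_for_net
from .evalmetrics import METRIC_NAMES, MetricReport, evaluate_sample
from .net import Model, build_model

log = logging.getLogger(__name__)


@dataclass
class TrainResult:
    model: Model
    loss_history: list[float]
    epochs_run: int
    final_train_dsc: float | None = None


@dataclass
class FoldResult:
    fold: int
    reports: list[MetricReport]
    means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.means:
            self.means = metric_means(self.reports)


def prepare_arrays(samples: Sequence[ImageSample], side: int = 256):
    """Stack resized images and masks into (N, side, side) float/uint8 arrays."""
    imgs, masks = [], []
    for s in samples:
        img, mask = resize_for_net(s, side)
        imgs.append(img)
        masks.append(mask)
    return np.stack(imgs).astype(np.float32), np.stack(masks).astype(np.float32)


def train_dsc(model: Model, images: np.ndarray, masks: np.ndarray,
              threshold: float = 0.5) -> float:
    """Mean per-sample Dice of thresholded predictions on the training set."""
    probs = model.predict(images)
    scores = []
    for p, m in zip(probs, masks):
        pred = p > threshold
        tp = float(np.logical_and(pred, m > 0).sum())
        denom = pred.sum() + float((m > 0).sum())
        scores.append(2 * tp / denom if denom else 1.0)
    return float(np.mean(scores))


def train(model: Model, samples: Sequence[ImageSample], cfg: TrainConfig,
          side: int = 256) -> TrainResult:
    """Minimize the Dice loss by seeded mini-batch gradient descent.

    Records the mean training loss per epoch; aborts on a non-finite loss.
    With ``cfg.early_stop_dsc`` set, training stops as soon as the
    thresholded training Dice exceeds that value (checked every
    ``cfg.eval_every`` epochs).
    """
    cfg = cfg.validate()
    if len(samples) == 0:
        raise ValueError("need at least one training sample")
    images, masks = prepare_arrays(samples, side)
    targets = masks[..., None]
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer == "adam":
        opt = Adam(model.params, lr=cfg.lr)
    else:
        opt = SGD(model.params, lr=cfg.lr)
    history: list[float] = []
    n = len(images)
    dsc = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, tb = images[idx], targets[idx]
            if cfg.augment_flip and rng.random() < 0.5:
                xb, tb = xb[:, :, ::-1], tb[:, :, ::-1]
            if cfg.augment_shift:
                sh = int(rng.integers(-4, 5))
                xb, tb = np.roll(xb, sh, axis=2), np.roll(tb, sh, axis=2)
            pred = model.forward(xb)
            loss = batch_dice_loss(pred, np.ascontiguousarray(tb), eps=cfg.dice_eps)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch}, batch start {start}; "
                    f"lr={cfg.lr}, optimizer={cfg.optimizer}")
            if cfg.lr > 0:
                opt.zero_grad()
                loss.backward()
                opt.step()
            epoch_losses.append(lval)
        history.append(float(np.mean(epoch_losses)))
        if (cfg.early_stop_dsc is not None
                and (epoch + 1) % cfg.eval_every == 0):
            dsc = train_dsc(model, images, masks)
            if dsc > cfg.early_stop_dsc:
                log.info("early stop at epoch %d (train DSC %.3f)", epoch + 1, dsc)
                break
    if dsc is None:
        dsc = train_dsc(model, images, masks)
    return TrainResult(model=model, loss_history=history,
                       epochs_run=len(history), final_train_dsc=dsc)


def _fold_seed(master: int, fold: int) -> int:
    return int(np.random.SeedSequence((master, fold)).generate_state(1)[0] % (2 ** 31))


def evaluate_samples(model: Model, samples: Sequence[ImageSample],
                     side: int = 256, threshold: float = 0.5) -> list[MetricReport]:
    """Per-sample metric reports; empty-ground-truth samples are skipped."""
    reports = []
    for s in samples:
        if s.empty_mask:
            log.warning("sample %s skipped: empty ground-truth mask", s.id)
            continue
        img, mask = resize_for_net(s, side)
        prob = model.predict(img[None])[0]
        grp = assign_size_group(s.axis_px)
        reports.append(evaluate_sample(prob, mask, sample_id=s.id,
                                       threshold=threshold, group=grp.label,
                                       is_small=grp.is_small, axis_px=s.axis_px))
    return reports


def cross_validate(samples: Sequence[ImageSample], net_cfg: NetConfig,
                   train_cfg: TrainConfig, k: int = 5, side: int = 256,
                   variant: str = "estan") -> list[FoldResult]:
    """k-fold cross-validation: each fold trains a freshly initialized model
    on the other k-1 folds and evaluates the held-out fold, so every sample
    is test-predicted exactly once."""
    ids = [s.id for s in samples]
    by_id = {s.id: s for s in samples}
    plan = make_folds(ids, k=k, seed=train_cfg.seed)
    results = []
    for fold in range(k):
        train_ids, test_ids = plan.split(fold)
        test_samples = [by_id[i] for i in test_ids if not by_id[i].empty_mask]
        if not test_samples:
            raise ValueError(f"fold {fold} has no evaluable (nonempty-mask) samples")
        seed = _fold_seed(train_cfg.seed, fold)
        model = build_model(net_cfg, seed=seed, variant=variant)
        fold_cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
        train(model, [by_id[i] for i in train_ids], fold_cfg, side=side)
        reports = evaluate_samples(model, test_samples, side=side)
        results.append(FoldResult(fold=fold, reports=reports))
        log.info("fold %d: %d test samples, mean DSC %.3f", fold,
                 len(reports), results[-1].means.get("dsc", float("nan")))
    return results


def metric_means(reports: Sequence[MetricReport]) -> dict[str, float]:
    """Mean of each metric; hd/mae averaged over defined values only, with
    the exclusion count reported."""
    out: dict[str, float] = {"n": float(len(reports))}
    if not reports:
        for m in METRIC_NAMES:
            out[m] = float("nan")
        out["hd_mae_excluded"] = 0.0
        return out
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=np.float64)
        if m in ("hd", "mae"):
            defined = vals[np.isfinite(vals)]
            out[m] = float(defined.mean()) if defined.size else float("nan")
        else:
            out[m] = float(vals.mean())
    out["hd_mae_excluded"] = float(sum(1 for r in reports if r.flags == "empty_pred"))
    return out


def reports_to_dataframe(reports: Sequence[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def stratified_report(reports: Sequence[MetricReport]) -> dict[str, pd.DataFrame]:
    """The three report tables: overall means of all seven metrics, the same
    restricted to small tumors (axis <= 120 px), and per-size-group JI/FPR."""
    reports = list(reports)

    def row(subset, label):
        d = metric_means(subset)
        d["subset"] = label
        return d

    overall = pd.DataFrame([row(reports, "all")]).set_index("subset")
    small = pd.DataFrame(
        [row([r for r in reports if r.is_small], "small")]).set_index("subset")
    group_rows = []
    for g in ("G1", "G2", "G3", "G4"):
        sub = [r for r in reports if r.group == g]
        if sub:
            m = metric_means(sub)
            group_rows.append({"group": g, "n": int(m["n"]),
                               "ji": m["ji"], "fpr": m["fpr"]})
        else:
            group_rows.append({"group": g, "n": 0,
                               "ji": float("nan"), "fpr": float("nan")})
    groups = pd.DataFrame(group_rows).set_index("group")
    return {"overall": overall, "small": small, "groups": groups}


def write_outputs(results: Sequence[FoldResult], out_dir: str | Path) -> dict:
    """Write per-sample metrics CSV, fold-summary JSON and report tables."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_reports = [r for fr in results for r in fr.reports]
    df = reports_to_dataframe(all_reports)
    df.to_csv(out / "per_sample_metrics.csv", index=False, float_format="%.10g")
    fold_summary = {str(fr.fold): fr.means for fr in results}
    with open(out / "fold_summary.json", "w") as fh:
        json.dump(fold_summary, fh, indent=2, default=float)
    tables = stratified_report(all_reports)
    for name, table in tables.items():
        table.to_csv(out / f"report_{name}.csv", float_format="%.10g")
    return {"per_sample": df, "fold_summary": fold_summary, "tables": tables}
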