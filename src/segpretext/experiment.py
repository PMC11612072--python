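"""Training frameworks, patient-wise cross-validation and statistics.

Five frameworks are compared: ``non`` (random initialization), ``contrastive``
(siamese patch-pair pretraining, encoder transfer), ``selflearn``
(entropy-guided inpainting pretraining, head swap), ``defaug`` (random
initialization, training set expanded with registration-based synthetic
subjects) and ``selflearn_defaug`` (inpainting pretraining fine-tuned on the
augmented set).  Fine-tuning always minimizes the hybrid loss — soft Dice plus
per-pixel cross-entropy, summed with unit weights.

Splits are patient-wise: a subject's slices never straddle the train/test
boundary, and synthetic subjects are admissible only when both their source
and their registration target are training subjects (asserted at run time).

Statistics follow the evaluation protocol: pairwise paired t-tests per metric
(α = 0.05), one-way ANOVA across frameworks and Tukey-HSD simultaneous
confidence intervals.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import metrics as seg_metrics
from .contrastive import pretrain_contrastive, transfer_encoder
from .deform_aug import RegistrationConfig, SyntheticSubject, augment_dataset
from .io_preprocess import InvalidInputError, SliceSample
from .nn import Adam, ContrastiveEncoder, SegmentationNet, lr_schedule
from .selflearn import adapt_head, build_backbone, plateau_reached, pretrain_inpainting

__all__ = [
    "FRAMEWORKS",
    "TrainConfig",
    "FoldSplit",
    "StudyScale",
    "soft_dice_loss",
    "hybrid_seg_loss",
    "hybrid_seg_loss_grad",
    "train_segmentation",
    "predict_mask",
    "evaluate_model",
    "patientwise_kfold",
    "run_framework",
    "run_study",
    "size_sweep",
    "compare_frameworks",
    "LeakageError",
]

FRAMEWORKS = ("non", "contrastive", "selflearn", "defaug", "selflearn_defaug")

# canonical training-size ladder for full-scale sweeps
SWEEP_SIZES_DEFAULT = (100, 150, 200, 250, 300, 350, 400, 450, 500, 550)

# per-framework fine-tuning schedules (batch, lr_start, lr_end, epochs)
FRAMEWORK_SCHEDULES = {
    "non": dict(batch=40, lr_start=0.005, lr_end=0.0001, epochs=10),
    "contrastive": dict(batch=50, lr_start=0.005, lr_end=0.0001, epochs=10),
    "selflearn": dict(batch=40, lr_start=0.005, lr_end=0.0001, epochs=10),
    "defaug": dict(batch=40, lr_start=0.01, lr_end=0.0001, epochs=20),
    "selflearn_defaug": dict(batch=40, lr_start=0.01, lr_end=0.0001, epochs=20),
}


class LeakageError(AssertionError):
    """A subject crossed the train/test boundary."""


@dataclasses.dataclass
class TrainConfig:
    framework: str = "non"
    batch: int = 40
    lr_start: float = 0.005
    lr_end: float = 0.0001
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise InvalidInputError(f"unknown framework {self.framework!r}")
        if self.batch < 1:
            raise InvalidInputError("batch must be >= 1")
        if not (self.lr_start >= self.lr_end > 0):
            raise InvalidInputError("need lr_start >= lr_end > 0")


@dataclasses.dataclass
class FoldSplit:
    fold_id: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.train_ids = frozenset(self.train_ids)
        self.test_ids = frozenset(self.test_ids)
        if self.train_ids & self.test_ids:
            raise LeakageError(f"fold {self.fold_id}: train and test sets overlap")


@dataclasses.dataclass
class StudyScale:
    """Desk-scale knobs: model size and step budgets for one-CPU runs."""

    layers: int = 6
    width: int = 8
    embed_dim: int = 32
    finetune_steps: int = 150
    proxy_steps: int = 100
    contrastive_steps: int = 60
    contrastive_batch: int = 16
    batch: int = 8
    crop_px: int | None = 64
    aug_policy: str = "k_random"
    aug_k: int = 3
    registration: RegistrationConfig = dataclasses.field(default_factory=RegistrationConfig)


# ---------------------------------------------------------------------------
# Losses


def _fg_probs(scores: np.ndarray) -> np.ndarray:
    """Foreground probability map from (..., 2, H, W) class scores or an
    already-collapsed probability map."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim >= 3 and scores.shape[-3] == 2:
        return scores[..., 1, :, :]
    return scores


def soft_dice_loss(scores, mask, eps: float = 1.0) -> float:
    """1 − soft Dice of the foreground probability against the mask, with
    smoothing ``eps`` in numerator and denominator."""
    p = _fg_probs(scores)
    m = np.asarray(mask, dtype=np.float64)
    if p.shape != m.shape:
        raise InvalidInputError(f"scores/mask shape mismatch: {p.shape} vs {m.shape}")
    num = 2.0 * (p * m).sum() + eps
    den = p.sum() + m.sum() + eps
    return float(1.0 - num / den)


def _soft_dice_grad(p: np.ndarray, m: np.ndarray, eps: float = 1.0) -> np.ndarray:
    num = 2.0 * (p * m).sum() + eps
    den = p.sum() + m.sum() + eps
    return -(2.0 * m * den - num) / den**2


def cross_entropy_loss(scores, mask, clip: float = 1e-7) -> float:
    """Mean per-pixel cross-entropy of 2-class probabilities against the mask."""
    scores = np.asarray(scores, dtype=np.float64)
    m = np.asarray(mask)
    p_fg = np.clip(_fg_probs(scores), clip, 1 - clip)
    return float(-(m * np.log(p_fg) + (1 - m) * np.log(1 - p_fg)).mean())


def hybrid_seg_loss(scores, mask) -> float:
    """Sum of soft Dice loss and mean per-pixel cross-entropy (unit weights)."""
    return soft_dice_loss(scores, mask) + cross_entropy_loss(scores, mask)


def hybrid_seg_loss_grad(scores, mask):
    """Hybrid loss and its gradient with respect to the class probabilities
    (shape (..., 2, H, W))."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim < 3 or scores.shape[-3] != 2:
        raise InvalidInputError("gradient form requires (..., 2, H, W) class probabilities")
    m = np.asarray(mask, dtype=np.float64)
    p_fg = scores[..., 1, :, :]
    if p_fg.shape != m.shape:
        raise InvalidInputError(f"scores/mask shape mismatch: {p_fg.shape} vs {m.shape}")
    loss = hybrid_seg_loss(scores, mask)
    clip = 1e-7
    n = m.size
    p_c = np.clip(p_fg, clip, 1 - clip)
    g_fg = _soft_dice_grad(p_fg, m) + (-(m / p_c) + (1 - m) / (1 - p_c)) / n
    grad = np.zeros_like(scores)
    grad[..., 1, :, :] = g_fg
    return loss, grad


# ---------------------------------------------------------------------------
# Fine-tuning and evaluation


def _crop_offsets(shape, crop_px, rng):
    r0 = int(rng.integers(0, max(shape[0] - crop_px, 0) + 1))
    c0 = int(rng.integers(0, max(shape[1] - crop_px, 0) + 1))
    return r0, c0


def train_segmentation(model: SegmentationNet, samples: Sequence[SliceSample],
                       steps: int | None = None, epochs: int = 10, batch: int = 40,
                       lr_start: float = 0.005, lr_end: float = 0.0001,
                       crop_px: int | None = None, patience: int | None = None,
                       rng: np.random.Generator | int | None = None):
    """Fine-tune a softmax-headed model on labeled slices with the hybrid
    loss; returns ``(model, per-step loss history)``.

    ``crop_px`` trains on random square crops (image and mask cropped
    jointly); the fully convolutional model still evaluates at full size.
    ``patience`` enables early stopping once the smoothed loss plateaus.
    """
    if model.head_kind != "softmax":
        raise InvalidInputError("segmentation training requires the softmax head")
    if not samples:
        raise InvalidInputError("no training samples")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if steps is None:
        steps = max(1, epochs * math.ceil(len(samples) / batch))
    opt = Adam(model.params(), lr=lr_start)
    lrs = lr_schedule(lr_start, lr_end, steps)
    history: list[float] = []
    for t in range(steps):
        idx = rng.integers(len(samples), size=batch)
        imgs, msks = [], []
        for i in idx:
            img, msk = samples[i].image, samples[i].mask
            if crop_px is not None and min(img.shape) > crop_px:
                r0, c0 = _crop_offsets(img.shape, crop_px, rng)
                img = img[r0:r0 + crop_px, c0:c0 + crop_px]
                msk = msk[r0:r0 + crop_px, c0:c0 + crop_px]
            imgs.append(img)
            msks.append(msk)
        x = np.stack(imgs)[:, None]
        m = np.stack(msks).astype(np.float64)
        scores, cache = model.forward(x)
        loss, grad = hybrid_seg_loss_grad(scores, m)
        if not np.isfinite(loss):
            raise RuntimeError(f"segmentation loss diverged at step {t}")
        opt.zero_grad()
        model.backward(grad.astype(np.float32), cache)
        opt.step(lr=lrs[t])
        history.append(loss)
        if patience is not None and plateau_reached(history, patience):
            break
    return model, history


def predict_mask(model: SegmentationNet, image: np.ndarray) -> np.ndarray:
    """Binary prediction for one slice (foreground = argmax class)."""
    scores = model.predict(np.asarray(image)[None, None])
    return (scores[0, 1] > scores[0, 0]).astype(np.uint8)


def evaluate_model(model: SegmentationNet, cohort: dict[str, list[SliceSample]],
                   subject_ids: Iterable[str]) -> list[dict]:
    """Per-subject metric rows: slices are predicted independently, stacked
    into a per-subject volume and scored against the stacked reference."""
    rows = []
    for sid in sorted(subject_ids):
        samples = cohort[sid]
        pred = np.stack([predict_mask(model, s.image) for s in samples], axis=-1)
        ref = np.stack([s.mask for s in samples], axis=-1)
        row = {"subject_id": sid}
        row.update(seg_metrics.evaluate_pair(ref, pred))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Splits


def patientwise_kfold(subject_ids: Iterable[str], k: int = 5,
                      rng: np.random.Generator | int | None = None) -> list[FoldSplit]:
    """Split subjects (never slices) into k folds of near-equal size."""
    ids = sorted(set(subject_ids))
    if k < 1 or k > len(ids):
        raise InvalidInputError(f"k={k} invalid for {len(ids)} subjects")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = [ids[i] for i in rng.permutation(len(ids))]
    folds = np.array_split(perm, k)
    out = []
    for fid, test in enumerate(folds):
        test_set = frozenset(test.tolist())
        out.append(FoldSplit(fid, frozenset(ids) - test_set, test_set))
    return out


def _assert_no_leakage(synthetic: Sequence[SyntheticSubject],
                       train_ids: frozenset[str], test_ids: frozenset[str]) -> None:
    for syn in synthetic:
        if syn.source_id in test_ids or syn.target_id in test_ids:
            raise LeakageError(
                f"synthetic subject {syn.subject_id} touches test subjects")
        if syn.source_id not in train_ids or syn.target_id not in train_ids:
            raise LeakageError(
                f"synthetic subject {syn.subject_id} uses subjects outside the training fold")


# ---------------------------------------------------------------------------
# Frameworks


def _flatten(cohort: dict[str, list[SliceSample]], ids: Iterable[str]) -> list[SliceSample]:
    out: list[SliceSample] = []
    for sid in sorted(ids):
        out.extend(cohort[sid])
    return out


def _augmented_training_set(cohort, train_ids, scale: StudyScale, rng,
                            cache: dict | None):
    key = tuple(sorted(train_ids))
    if cache is not None and key in cache:
        return cache[key]
    sub = {sid: cohort[sid] for sid in train_ids}
    synthetic = augment_dataset(sub, policy=scale.aug_policy, k=scale.aug_k,
                                rng=rng, config=scale.registration)
    _assert_no_leakage(synthetic, frozenset(train_ids), frozenset())
    result = synthetic
    if cache is not None:
        cache[key] = result
    return result


def _pretrained_backbone(cohort, train_ids, scale: StudyScale, seed: int,
                         cache: dict | None):
    key = (tuple(sorted(train_ids)), seed)
    if cache is not None and key in cache:
        return cache[key]
    rng = np.random.default_rng([seed % (2**31), 11])
    model = build_backbone(layers=scale.layers, width=scale.width, head="sigmoid", rng=rng)
    model, _ = pretrain_inpainting(model, _flatten(cohort, train_ids),
                                   steps=scale.proxy_steps, batch=scale.batch,
                                   crop_px=scale.crop_px,
                                   rng=np.random.default_rng([seed % (2**31), 12]))
    if cache is not None:
        cache[key] = model
    return model


def run_framework(config: TrainConfig, cohort: dict[str, list[SliceSample]],
                  splits: Sequence[FoldSplit], scale: StudyScale | None = None,
                  pretrain_cache: dict | None = None,
                  aug_cache: dict | None = None) -> list[dict]:
    """Run one framework over the folds and return per-subject metric rows.

    Evaluation is always on untouched test subjects; synthetic subjects are
    built strictly within the training fold (asserted).
    """
    scale = scale or StudyScale()
    fw = config.framework
    if fw in ("contrastive",) and len(cohort) < 2:
        raise InvalidInputError("contrastive framework needs >= 2 subjects")
    rows: list[dict] = []
    for split in splits:
        if split.train_ids & split.test_ids:
            raise LeakageError("train/test overlap")
        seed32 = config.seed % (2**31)
        rng = np.random.default_rng([seed32, split.fold_id, 1])
        train_samples = _flatten(cohort, split.train_ids)
        if fw == "non":
            model = build_backbone(layers=scale.layers, width=scale.width,
                                   head="softmax", rng=rng)
        elif fw == "contrastive":
            enc = ContrastiveEncoder(layers=scale.layers, width=scale.width,
                                     embed_dim=scale.embed_dim, rng=rng)
            sub = {sid: cohort[sid] for sid in split.train_ids}
            enc, _ = pretrain_contrastive(
                enc, sub, steps=scale.contrastive_steps, batch=scale.contrastive_batch,
                rng=np.random.default_rng([seed32, split.fold_id, 2]))
            model = transfer_encoder(enc, rng=rng)
        elif fw == "selflearn":
            pre = _pretrained_backbone(cohort, split.train_ids, scale, config.seed,
                                       pretrain_cache)
            model = adapt_head(pre, rng=rng)
        elif fw == "defaug":
            model = build_backbone(layers=scale.layers, width=scale.width,
                                   head="softmax", rng=rng)
            synthetic = _augmented_training_set(
                cohort, split.train_ids, scale,
                np.random.default_rng([seed32, split.fold_id, 3]), aug_cache)
            _assert_no_leakage(synthetic, split.train_ids, split.test_ids)
            train_samples = train_samples + [s for syn in synthetic for s in syn.samples]
        else:  # selflearn_defaug
            pre = _pretrained_backbone(cohort, split.train_ids, scale, config.seed,
                                       pretrain_cache)
            model = adapt_head(pre, rng=rng)
            synthetic = _augmented_training_set(
                cohort, split.train_ids, scale,
                np.random.default_rng([seed32, split.fold_id, 3]), aug_cache)
            _assert_no_leakage(synthetic, split.train_ids, split.test_ids)
            train_samples = train_samples + [s for syn in synthetic for s in syn.samples]

        model, _ = train_segmentation(
            model, train_samples, steps=scale.finetune_steps, batch=scale.batch,
            lr_start=config.lr_start, lr_end=config.lr_end, crop_px=scale.crop_px,
            rng=np.random.default_rng([seed32, split.fold_id, 4]))
        for row in evaluate_model(model, cohort, split.test_ids):
            row.update(framework=fw, fold=split.fold_id, seed=config.seed)
            rows.append(row)
    return rows


def run_study(cohort: dict[str, list[SliceSample]],
              frameworks: Sequence[str] = FRAMEWORKS, k: int = 5, seed: int = 0,
              scale: StudyScale | None = None) -> pd.DataFrame:
    """Run several frameworks over one shared patient-wise k-fold split.

    Inpainting pretraining and augmentation are computed once per training
    fold and shared between the frameworks that use them (the pretrained
    weights and synthetic subjects are identical either way).
    """
    scale = scale or StudyScale()
    splits = patientwise_kfold(cohort.keys(), k=k, rng=np.random.default_rng(seed % (2**31)))
    pretrain_cache: dict = {}
    aug_cache: dict = {}
    rows: list[dict] = []
    for fw in frameworks:
        sched = FRAMEWORK_SCHEDULES[fw]
        config = TrainConfig(framework=fw, seed=seed, lr_start=sched["lr_start"],
                             lr_end=sched["lr_end"], epochs=sched["epochs"],
                             batch=sched["batch"])
        rows.extend(run_framework(config, cohort, splits, scale,
                                  pretrain_cache=pretrain_cache, aug_cache=aug_cache))
    return pd.DataFrame(rows)


def size_sweep(cohort: dict[str, list[SliceSample]], sizes: Sequence[int] | None,
               frameworks: Sequence[str], seeds: Sequence[int] = (0,),
               test_ids: Iterable[str] | None = None,
               scale: StudyScale | None = None) -> pd.DataFrame:
    """Train each framework at several training-set sizes (paired subsampling:
    at a given size and seed every framework sees the same subjects) and
    report mean ± sd test Dice per (size, framework, seed).

    ``sizes=None`` uses the canonical ladder ``SWEEP_SIZES_DEFAULT``
    (100…550), which presumes a cohort of several hundred subjects."""
    scale = scale or StudyScale()
    sizes = list(sizes) if sizes is not None else list(SWEEP_SIZES_DEFAULT)
    ids = sorted(cohort)
    if test_ids is None:
        n_test = max(1, len(ids) // 4)
        test_ids = ids[-n_test:]
    test_ids = sorted(set(test_ids))
    pool = [i for i in ids if i not in set(test_ids)]
    if max(sizes) > len(pool):
        raise InvalidInputError(f"size {max(sizes)} exceeds {len(pool)} available training subjects")
    rows = []
    for seed in seeds:
        seed32 = seed % (2**31)
        for size in sizes:
            rng = np.random.default_rng([seed32, size])
            chosen = frozenset(pool[i] for i in rng.choice(len(pool), size=size, replace=False))
            split = FoldSplit(0, chosen, frozenset(test_ids))
            pretrain_cache: dict = {}
            aug_cache: dict = {}
            for fw in frameworks:
                sched = FRAMEWORK_SCHEDULES[fw]
                config = TrainConfig(framework=fw, seed=seed, lr_start=sched["lr_start"],
                                     lr_end=sched["lr_end"], batch=sched["batch"])
                res = run_framework(config, cohort, [split], scale,
                                    pretrain_cache=pretrain_cache, aug_cache=aug_cache)
                dices = [r["dice"] for r in res]
                rows.append(dict(size=size, framework=fw, seed=seed,
                                 mean_dice=float(np.nanmean(dices)),
                                 sd_dice=float(np.nanstd(dices, ddof=1)) if len(dices) > 1 else 0.0))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics


METRIC_COLUMNS = ("dice", "jc", "sensitivity", "rvd_pct", "hd_mm", "masd_mm")


def compare_frameworks(report: pd.DataFrame, alpha: float = 0.05,
                       metrics: Sequence[str] = ("dice",)) -> dict[str, pd.DataFrame]:
    """Pairwise paired t-tests plus one-way ANOVA with Tukey-HSD intervals.

    ``report`` must hold one row per (framework, subject) with matched
    subjects across frameworks — the pairing unit of the paired t-test.
    Returns ``{"pairwise": ..., "tukey": ...}`` tables.
    """
    needed = {"framework", "subject_id"}
    if not needed.issubset(report.columns):
        raise InvalidInputError(f"report must contain columns {sorted(needed)}")
    frameworks = sorted(report["framework"].unique())
    if len(frameworks) < 2:
        raise InvalidInputError("need >= 2 frameworks to compare")
    pair_cols = ["subject_id"] + (["fold"] if "fold" in report.columns else []) \
        + (["seed"] if "seed" in report.columns else [])
    pairwise_rows = []
    tukey_rows = []
    for metric in metrics:
        wide = report.pivot_table(index=pair_cols, columns="framework",
                                  values=metric, aggfunc="mean")
        if wide[frameworks].isna().any().any():
            raise InvalidInputError(f"unpaired rows: some subjects lack a {metric} "
                                    "value under every framework")
        for i, fa in enumerate(frameworks):
            for fb in frameworks[i + 1:]:
                a, b = wide[fa].to_numpy(), wide[fb].to_numpy()
                diff = a - b
                if np.allclose(diff, 0.0):
                    t_stat, p_val = 0.0, 1.0
                else:
                    t_stat, p_val = stats.ttest_rel(a, b)
                pairwise_rows.append(dict(metric=metric, framework_a=fa, framework_b=fb,
                                          mean_diff=float(diff.mean()), t=float(t_stat),
                                          p=float(p_val), significant=bool(p_val < alpha)))
        groups = [wide[f].to_numpy() for f in frameworks]
        f_stat, anova_p = stats.f_oneway(*groups)  # NaN for degenerate groups
        tk = pairwise_tukeyhsd(np.concatenate(groups),
                               np.repeat(frameworks, [len(g) for g in groups]),
                               alpha=alpha)
        for row in tk.summary().data[1:]:
            tukey_rows.append(dict(metric=metric, anova_F=float(f_stat),
                                   anova_p=float(anova_p),
                                   group1=str(row[0]), group2=str(row[1]),
                                   meandiff=float(row[2]), p_adj=float(row[3]),
                                   ci_lower=float(row[4]), ci_upper=float(row[5]),
                                   reject=bool(row[6])))
    return {"pairwise": pd.DataFrame(pairwise_rows), "tukey": pd.DataFrame(tukey_rows)}
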