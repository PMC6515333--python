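"""End-to-end myocardium detector: training orchestration and inference.

Training (``train_detector``) runs, per training slice: proposal generation,
IoU labeling against the ground-truth box (positive above ``iou_pos``,
negative below ``iou_neg``, the band between is ignored), crop extraction
and resizing; then greedy SSAE pretraining on the pooled crops, softmax
fine-tuning with class-balanced batches, feature encoding, WCNP C-SVC
fitting, one round of hard-negative mining (confidently misclassified
background with IoU < ``iou_hard`` re-injected, classifier refit and SSAE
briefly re-fine-tuned), and finally the MIMO epsilon-SVR trained on
proposals overlapping ground truth above ``iou_regress``, with targets
encoding the ground-truth box relative to each proposal.

Inference (``detect``) proposes, encodes, classifies, keeps
positively-classified candidates (falling back to the single best-scoring
proposal when none pass), suppresses near-duplicates with NMS, refines each
survivor with the regressor, and reports the top-scoring refined box.

Evaluation treats every pixel of a detected or ground-truth box equally:
Tpr, Ppv and F1 are micro-averaged pixel rates over slices; AUC is reported
both per-proposal (validation level) and per-slice (detection level); the
overlap ratio 2|A∩B|/|A∪B| is reported alongside the classical Dice
2|A∩B|/(|A|+|B|).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .boxes import BoundingBox, bbox_decode, bbox_encode, box_mask, iou, nms
from .config import DetectorConfig
from .phantom import PhantomDataset, Slice
from .proposal import (
    ProposalFilter,
    RegionProposal,
    hierarchical_merge,
    proposals_from_regions,
    supervoxel_segment,
)
from .similarity import SimilarityConfig
from .ssae import SSAEModel, prepare_crop, ssae_encode, ssae_finetune, ssae_pretrain
from .wcnp import (
    KernelSpec,
    WCNPClassifier,
    WCNPRegressor,
    csvc_decision,
    csvc_fit,
    msvr_fit,
    msvr_predict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSample",
    "DetectorBundle",
    "DetectionResult",
    "EvalReport",
    "propose_slice",
    "label_proposals",
    "extract_crop",
    "train_detector",
    "hard_negative_mine",
    "detect",
    "evaluate",
    "dice_ratio",
]


@dataclass
class LabeledSample:
    """One proposal crop with its IoU-derived label."""

    box: BoundingBox
    crop: np.ndarray  # tau x tau, [0, 1]
    label: int  # +1 positive, -1 negative, 0 ignored
    iou_with_gt: float
    slice_ref: tuple[int, int] = (0, 0)  # (subject, slice index)
    feature: np.ndarray | None = None


@dataclass
class DetectorBundle:
    """Everything needed to run detection on a new slice."""

    ssae: SSAEModel
    classifier: WCNPClassifier
    regressor: WCNPRegressor | None
    config: DetectorConfig
    training_log: dict = field(default_factory=dict)


@dataclass
class DetectionResult:
    """Final refined boxes for one slice, probabilities descending."""

    boxes: list[BoundingBox]
    probabilities: np.ndarray
    unrefined_boxes: list[BoundingBox]
    n_proposals: int
    n_positive: int
    n_after_nms: int
    fallback: bool = False  # no proposal classified positive

    @property
    def empty(self) -> bool:
        return len(self.boxes) == 0

    @property
    def top_box(self) -> BoundingBox | None:
        return self.boxes[0] if self.boxes else None


@dataclass
class EvalReport:
    """Pixelwise detection metrics, micro-averaged over slices."""

    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    ppv: float
    f1: float
    auc_detection: float
    auc_validation: float
    dr: float  # 2|A.B|/|AuB| as printed (clipped at 1)
    dice_classical: float
    detection_rate_iou50: float
    mean_iou: float
    n_slices: int


def propose_slice(
    image: np.ndarray, config: DetectorConfig
) -> tuple[list[RegionProposal], "np.ndarray"]:
    """Run the proposal stack on one slice; returns proposals and the PC map.

    Proposals are emitted at the K = ``n_merged`` stop of the merge
    dendrogram and, optionally, at the coarser ``extra_merge_levels`` stops
    (continuing the same agglomeration), deduplicated on box corners —
    targets split across many regions at the fine level often appear whole
    one level up.
    """
    sim_cfg = SimilarityConfig(p=config.patch_side)
    labeling = supervoxel_segment(image, M=config.n_supervoxels, cfg=sim_cfg)
    filt = ProposalFilter(
        aspect_ratio_range=config.aspect_ratio_range,
        area_range=config.area_range,
        border_margin=config.border_margin,
    )
    merged = hierarchical_merge(labeling, K=config.n_merged, cfg=sim_cfg)
    proposals = proposals_from_regions(merged, filt)
    seen = {
        (p.box.x0, p.box.y0, p.box.x1, p.box.y1) for p in proposals
    }
    for level in sorted(config.extra_merge_levels, reverse=True):
        if level >= merged.n_regions:
            continue
        merged = hierarchical_merge(merged, K=level, cfg=sim_cfg)
        for p in proposals_from_regions(merged, filt):
            key = (p.box.x0, p.box.y0, p.box.x1, p.box.y1)
            if key not in seen:
                seen.add(key)
                proposals.append(p)
    return proposals, labeling.pc


def label_proposals(
    proposals: list[RegionProposal],
    gt: BoundingBox,
    config: DetectorConfig,
) -> list[tuple[RegionProposal, int, float]]:
    """IoU-band labeling: +1 above iou_pos, -1 below iou_neg, 0 between."""
    out = []
    for pr in proposals:
        v = iou(pr.box, gt)
        if v > config.iou_pos:
            lab = 1
        elif v < config.iou_neg:
            lab = -1
        else:
            lab = 0
        out.append((pr, lab, v))
    return out


def _expanded(box: BoundingBox, factor: float) -> BoundingBox:
    """Scale a box about its center (context window for regressor crops)."""
    if factor == 1.0:
        return box
    return BoundingBox(box.x_center, box.y_center, box.width * factor, box.height * factor)


def extract_crop(image: np.ndarray, box: BoundingBox, tau: int) -> np.ndarray:
    """Cut the box region (clipped, half-open int bounds) and resize to tau."""
    h, w = image.shape
    x0 = int(np.clip(np.floor(box.x0), 0, w - 1))
    y0 = int(np.clip(np.floor(box.y0), 0, h - 1))
    x1 = int(np.clip(np.ceil(box.x1), x0 + 1, w))
    y1 = int(np.clip(np.ceil(box.y1), y0 + 1, h))
    return prepare_crop(image[y0:y1, x0:x1], tau)


def _collect_samples(
    slices: list[Slice], config: DetectorConfig, rng: np.random.Generator
) -> tuple[list[LabeledSample], list[LabeledSample]]:
    """Propose + label + crop every training slice.

    Returns (pool, extras): the training pool caps negatives at
    ``neg_per_pos`` per positive (deterministic subsample); the remaining
    negatives are kept as the mining pool — hard-negative mining scores
    every training proposal, not just the subsampled ones.
    """
    pool: list[LabeledSample] = []
    extras: list[LabeledSample] = []
    for s in slices:
        proposals, _ = propose_slice(s.image, config)
        labeled = label_proposals(proposals, s.gt_box, config)
        pos = [(p, l, v) for p, l, v in labeled if l == 1]
        band = [(p, l, v) for p, l, v in labeled if l == 0 and v > config.iou_regress]
        neg = [(p, l, v) for p, l, v in labeled if l == -1]
        n_keep = max(config.neg_per_pos * max(len(pos), 1), 8)
        kept = set()
        if len(neg) > n_keep:
            kept = set(rng.choice(len(neg), n_keep, replace=False).tolist())
        else:
            kept = set(range(len(neg)))

        def make(p, l, v):
            return LabeledSample(
                box=p.box,
                crop=extract_crop(s.image, p.box, config.tau).astype(np.float32),
                label=l,
                iou_with_gt=v,
                slice_ref=(s.subject, s.index),
            )

        for p, l, v in pos + band:
            pool.append(make(p, l, v))
        for i, (p, l, v) in enumerate(neg):
            (pool if i in kept else extras).append(make(p, l, v))
    return pool, extras


def hard_negative_mine(
    classifier: WCNPClassifier,
    features: np.ndarray,
    samples: list[LabeledSample],
    config: DetectorConfig,
) -> list[int]:
    """Indices of hard negatives: negatives scored positive with IoU below
    ``iou_hard``. Disjoint from the positive set by construction."""
    scores, _ = csvc_decision(classifier, features)
    hard = [
        i
        for i, s in enumerate(samples)
        if s.label == -1 and scores[i] > 0 and s.iou_with_gt < config.iou_hard
    ]
    return hard


def _kernel_for(feats: np.ndarray, config: DetectorConfig) -> KernelSpec:
    """Kernel width: fixed config value, or the median heuristic
    r = 1 / median ||x - x'||^2 over (a subsample of) the training set."""
    if not config.kernel_r_auto:
        return KernelSpec(r=config.kernel_r)
    from scipy.spatial.distance import pdist

    sub = feats[:: max(len(feats) // 500, 1)]
    med = float(np.median(pdist(sub, "sqeuclidean")))
    return KernelSpec(r=1.0 / max(med, 1e-6))


def _fit_classifier(feats, labels, config):
    return csvc_fit(
        feats,
        labels,
        C=config.svm_C,
        kernel=_kernel_for(feats, config),
        eta=config.eta,
        t=config.graph_t,
    )


def train_detector(
    dataset: PhantomDataset,
    config: DetectorConfig | None = None,
    seed: int = 0,
) -> DetectorBundle:
    """Train the full detector on the dataset's training split.

    Stages: proposal + labeling -> SSAE pretrain + fine-tune -> encode ->
    C-SVC fit -> hard-negative mining round(s) with classifier refit and a
    short SSAE re-fine-tune -> MIMO epsilon-SVR on high-overlap proposals.
    Deterministic for a fixed seed.
    """
    if config is None:
        config = DetectorConfig()
    t_start = time.time()
    rng = np.random.default_rng(seed)
    log: dict = {"stage_seconds": {}}

    train_slices = dataset.slices(split="train")
    if len({s.subject for s in train_slices}) < 2:
        raise ValueError("need at least 2 training subjects")

    t0 = time.time()
    samples, mining_extras = _collect_samples(train_slices, config, rng)
    log["stage_seconds"]["proposals"] = time.time() - t0
    n_pos = sum(1 for s in samples if s.label == 1)
    n_neg = sum(1 for s in samples if s.label == -1)
    log["n_samples"] = len(samples)
    log["n_positive"], log["n_negative"] = n_pos, n_neg
    if n_pos == 0:
        raise RuntimeError(
            "no positive samples: no proposal exceeded "
            f"iou_pos={config.iou_pos} on any training slice"
        )
    logger.info("collected %d samples (%d pos / %d neg)", len(samples), n_pos, n_neg)

    crops = np.stack([s.crop for s in samples]).reshape(len(samples), -1)
    cls_idx = [i for i, s in enumerate(samples) if s.label != 0]
    if len(cls_idx) > config.max_classifier_samples:
        # keep every positive, subsample negatives deterministically
        pos_i = [i for i in cls_idx if samples[i].label == 1]
        neg_i = [i for i in cls_idx if samples[i].label == -1]
        n_neg = max(config.max_classifier_samples - len(pos_i), config.neg_per_pos)
        if len(neg_i) > n_neg:
            sel = rng.choice(len(neg_i), n_neg, replace=False)
            neg_i = [neg_i[j] for j in sorted(sel)]
        cls_idx = sorted(pos_i + neg_i)
        log["n_classifier_capped"] = len(cls_idx)
    y_cls = np.array([samples[i].label for i in cls_idx])

    t0 = time.time()
    ssae = ssae_pretrain(
        crops,
        list(config.layer_sizes),
        tau=config.tau,
        lam=config.lam,
        beta=config.beta,
        rho=config.rho,
        max_iter=config.pretrain_max_iter,
        seed=int(rng.integers(2**31)),
    )
    log["stage_seconds"]["pretrain"] = time.time() - t0

    t0 = time.time()
    ssae = ssae_finetune(
        ssae,
        crops[cls_idx],
        (y_cls > 0).astype(int),
        epochs=config.finetune_epochs,
        batch_size=config.finetune_batch,
        learning_rate=config.finetune_lr,
        seed=int(rng.integers(2**31)),
    )
    log["stage_seconds"]["finetune"] = time.time() - t0

    feats_all = ssae_encode(ssae, np.stack([s.crop for s in samples]))
    for i, s in enumerate(samples):
        s.feature = feats_all[i]

    t0 = time.time()
    classifier = _fit_classifier(feats_all[cls_idx], y_cls, config)
    log["stage_seconds"]["csvc"] = time.time() - t0

    # hard-negative mining over every training proposal (pool + extras):
    # confidently misclassified low-IoU negatives join the refit
    mined_total = 0
    all_samples = samples + mining_extras
    for round_i in range(config.mining_rounds):
        feats_extra = (
            ssae_encode(ssae, np.stack([s.crop for s in mining_extras]))
            if mining_extras
            else np.empty((0, ssae.n_feature))
        )
        feats_full = np.vstack([feats_all, feats_extra])
        hard = hard_negative_mine(classifier, feats_full, all_samples, config)
        if len(hard) > config.mining_max:
            scores, _ = csvc_decision(classifier, feats_full[hard])
            order = np.argsort(-scores, kind="stable")[: config.mining_max]
            hard = [hard[i] for i in order]
        log[f"mined_round_{round_i}"] = len(hard)
        mined_total += len(hard)
        if not hard:
            break
        mined_crops = np.stack([all_samples[i].crop for i in hard]).reshape(len(hard), -1)
        aug_crops = np.vstack([crops[cls_idx], mined_crops])
        y_aug = np.concatenate([y_cls, -np.ones(len(hard), dtype=int)])
        epochs = max(int(config.finetune_epochs * config.mining_finetune_frac), 1)
        ssae = ssae_finetune(
            ssae,
            aug_crops,
            (y_aug > 0).astype(int),
            epochs=epochs,
            batch_size=config.finetune_batch,
            learning_rate=config.finetune_lr * 0.5,
            seed=int(rng.integers(2**31)),
        )
        feats_all = ssae_encode(ssae, np.stack([s.crop for s in samples]))
        for i, s in enumerate(samples):
            s.feature = feats_all[i]
        aug_feats = np.vstack(
            [feats_all[cls_idx], ssae_encode(ssae, np.stack([all_samples[i].crop for i in hard]))]
        )
        classifier = _fit_classifier(aug_feats, y_aug, config)
    log["n_mined"] = mined_total

    # box regressor on high-overlap proposals: targets encode gt relative to
    # the proposal (anchor)
    t0 = time.time()
    gt_by_ref = {(s.subject, s.index): s.gt_box for s in train_slices}
    img_by_ref = {(s.subject, s.index): s.image for s in train_slices}
    ctx = config.regress_context
    reg_idx = [i for i, s in enumerate(samples) if s.iou_with_gt > config.iou_regress]
    if ctx == 1.0:
        reg_feats = [feats_all[i] for i in reg_idx]
    else:
        ctx_crops = [
            extract_crop(
                img_by_ref[samples[i].slice_ref], _expanded(samples[i].box, ctx), config.tau
            )
            for i in reg_idx
        ]
        reg_feats = list(ssae_encode(ssae, np.stack(ctx_crops))) if ctx_crops else []
    reg_targets = [
        bbox_encode(samples[i].box, gt_by_ref[samples[i].slice_ref]) for i in reg_idx
    ]
    log["n_regress"] = len(reg_idx)
    # diversify anchors with jittered ground-truth boxes, kept only when
    # they clear the same IoU eligibility bar as natural proposals
    if config.regress_jitter > 0:
        jit_crops, jit_targets = [], []
        for s in train_slices:
            gt = s.gt_box
            for _ in range(config.regress_jitter):
                jit = BoundingBox(
                    gt.x_center + rng.uniform(-0.15, 0.15) * gt.width,
                    gt.y_center + rng.uniform(-0.15, 0.15) * gt.height,
                    gt.width * rng.uniform(0.75, 1.25),
                    gt.height * rng.uniform(0.75, 1.25),
                )
                if iou(jit, gt) <= config.iou_regress:
                    continue
                jit_crops.append(extract_crop(s.image, _expanded(jit, ctx), config.tau))
                jit_targets.append(bbox_encode(jit, gt))
        if jit_crops:
            reg_feats.extend(ssae_encode(ssae, np.stack(jit_crops)))
            reg_targets.extend(jit_targets)
        log["n_regress_jitter"] = len(jit_targets)
    regressor = None
    if len(reg_feats) >= config.graph_t + 2:
        reg_X = np.stack(reg_feats)
        regressor = msvr_fit(
            reg_X,
            np.stack(reg_targets),
            C=config.svr_C,
            epsilon=config.svr_epsilon,
            kernel=_kernel_for(reg_X, config),
            eta=config.eta,
            t=min(config.graph_t, len(reg_feats) - 2),
        )
    log["stage_seconds"]["msvr"] = time.time() - t0
    log["total_seconds"] = time.time() - t_start

    return DetectorBundle(
        ssae=ssae, classifier=classifier, regressor=regressor, config=config,
        training_log=log,
    )


def detect(bundle: DetectorBundle, s: Slice | np.ndarray, top_k: int | None = None) -> DetectionResult:
    """Detect the myocardium box on one slice.

    Proposals are encoded and classified; positively classified candidates
    (or, failing any, the single best-scoring proposal) pass through NMS and
    the epsilon-SVR refinement; boxes are reported by descending
    probability, truncated to ``top_k`` (config default: the single most
    probable box — the task has one target per slice).
    """
    config = bundle.config
    image = s.image if isinstance(s, Slice) else np.asarray(s, dtype=float)
    if top_k is None:
        top_k = config.top_k
    proposals, _ = propose_slice(image, config)
    if not proposals:
        return DetectionResult([], np.empty(0), [], 0, 0, 0, fallback=True)

    crops = np.stack([extract_crop(image, p.box, config.tau) for p in proposals])
    feats = ssae_encode(bundle.ssae, crops)
    scores, probs = csvc_decision(bundle.classifier, feats)

    pos_idx = np.where(scores > 0)[0]
    fallback = pos_idx.size == 0
    if fallback:
        pos_idx = np.array([int(np.argmax(probs))])
    boxes = [proposals[i].box for i in pos_idx]
    box_probs = probs[pos_idx]
    keep = nms(boxes, box_probs, threshold=config.nms_threshold)
    n_after = len(keep)

    order = keep[: max(top_k, 1)]
    final_unrefined = [boxes[i] for i in order]
    final_probs = box_probs[list(order)]
    final_boxes = []
    for b in final_unrefined:
        if bundle.regressor is not None:
            crop = extract_crop(image, _expanded(b, config.regress_context), config.tau)
            z = msvr_predict(bundle.regressor, ssae_encode(bundle.ssae, crop))
            z = np.asarray(z).ravel()
            if z[2] > 0 and z[3] > 0:
                final_boxes.append(bbox_decode(b, z, image_shape=image.shape))
            else:
                final_boxes.append(b)
        else:
            final_boxes.append(b)
    return DetectionResult(
        boxes=final_boxes,
        probabilities=np.asarray(final_probs),
        unrefined_boxes=final_unrefined,
        n_proposals=len(proposals),
        n_positive=int((scores > 0).sum()),
        n_after_nms=n_after,
        fallback=fallback,
    )


def dice_ratio(a: np.ndarray, b: np.ndarray, formula: str = "printed") -> float:
    """Overlap ratio of two boolean masks.

    ``printed`` uses 2|A∩B|/|A∪B| (twice the IoU — it can reach 2 on
    identical masks and is clipped to 1, with the clip logged); ``classical``
    is the Dice coefficient 2|A∩B|/(|A|+|B|).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    inter = np.logical_and(a, b).sum()
    if formula == "classical":
        denom = a.sum() + b.sum()
        return 2.0 * inter / denom if denom else 0.0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    val = 2.0 * inter / union
    if val > 1.0:
        logger.debug("printed overlap ratio %.3f exceeds 1; clipping", val)
        return 1.0
    return val


def _safe_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        return float("nan")
    return float(roc_auc_score(y_true, scores))


def evaluate(
    results: list[DetectionResult],
    slices: list[Slice],
    proposal_labels: tuple[np.ndarray, np.ndarray] | None = None,
) -> EvalReport:
    """Pixelwise metrics of the top-1 boxes against ground truth.

    tp/fp/fn/tn count pixels over all slices (every pixel weighted equally
    toward its bounding box). ``proposal_labels`` — optional (labels,
    probabilities) over candidate proposals — feeds the validation-level
    AUC; the detection-level AUC scores each slice's top probability against
    whether its final box hits at IoU 0.5.
    """
    if len(results) != len(slices):
        raise ValueError("results and ground-truth slice counts differ")
    tp = fp = fn = tn = 0
    hits, top_probs, ious = [], [], []
    inter_sum = union_sum = size_sum = 0
    for res, s in zip(results, slices):
        gt_mask = box_mask(s.gt_box, s.image.shape)
        if res.empty:
            fn += int(gt_mask.sum())
            tn += int((~gt_mask).sum())
            hits.append(0)
            top_probs.append(0.0)
            ious.append(0.0)
            continue
        det_mask = box_mask(res.top_box, s.image.shape)
        tp += int(np.logical_and(det_mask, gt_mask).sum())
        fp += int(np.logical_and(det_mask, ~gt_mask).sum())
        fn += int(np.logical_and(~det_mask, gt_mask).sum())
        tn += int(np.logical_and(~det_mask, ~gt_mask).sum())
        v = iou(res.top_box, s.gt_box)
        ious.append(v)
        hits.append(int(v > 0.5))
        top_probs.append(float(res.probabilities[0]))
        inter_sum += int(np.logical_and(det_mask, gt_mask).sum())
        union_sum += int(np.logical_or(det_mask, gt_mask).sum())
        size_sum += int(det_mask.sum() + gt_mask.sum())

    tpr = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tpr * ppv / (tpr + ppv) if tpr + ppv else 0.0
    dr = min(2.0 * inter_sum / union_sum, 1.0) if union_sum else 0.0
    dice = 2.0 * inter_sum / size_sum if size_sum else 0.0
    auc_det = _safe_auc(np.array(hits), np.array(top_probs))
    auc_val = float("nan")
    if proposal_labels is not None:
        auc_val = _safe_auc(proposal_labels[0], proposal_labels[1])
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn, tpr=tpr, ppv=ppv, f1=f1,
        auc_detection=auc_det, auc_validation=auc_val, dr=dr,
        dice_classical=dice,
        detection_rate_iou50=float(np.mean(hits)) if hits else 0.0,
        mean_iou=float(np.mean(ious)) if ious else 0.0,
        n_slices=len(slices),
    )
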