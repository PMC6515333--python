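"""Detector configuration: every tunable of the pipeline in one dataclass.

Defaults follow the reference operating point: M=500 initial supervoxels
merged to K=100 regions, 60x60 crops through a {3600,1600,750,350} stacked
sparse autoencoder (lambda=1e-2, beta=0.3, rho=0.2), Gaussian kernel r=2,
C=0.5, eta=2, t=7 for both the classifier and the box regressor
(epsilon=1.5), IoU bands 0.5/0.3 for labeling, <0.1 for hard-negative
mining, >0.6 for regressor eligibility and 0.3 for NMS.

``small()`` returns the reduced desk-scale configuration (tau=24, layers
{576,400,300,200}) used for fast end-to-end benchmarks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["DetectorConfig"]


@dataclass
class DetectorConfig:
    # proposal stage
    n_supervoxels: int = 500  # M
    n_merged: int = 100  # K
    # extra, coarser stops of the merge dendrogram to emit proposals from
    # (hierarchical clustering yields a box set per level); () = K only
    extra_merge_levels: tuple[int, ...] = ()
    patch_side: int = 9
    aspect_ratio_range: tuple[float, float] = (1 / 3, 3.0)
    area_range: tuple[float, float] = (0.002, 0.40)
    border_margin: int = 2

    # SSAE
    tau: int = 60
    layer_sizes: tuple[int, ...] = (3600, 1600, 750, 350)
    lam: float = 1e-2
    beta: float = 0.3
    rho: float = 0.2
    pretrain_max_iter: int = 400
    finetune_epochs: int = 30
    finetune_batch: int = 128
    finetune_lr: float = 0.1

    # kernel machines
    kernel_r: float = 2.0
    kernel_r_auto: bool = False  # median heuristic r = 1/median ||x-x'||^2
    svm_C: float = 0.5
    eta: float = 2.0
    graph_t: int = 7
    svr_C: float = 0.5
    svr_epsilon: float = 1.5

    # IoU thresholds
    iou_pos: float = 0.5
    iou_neg: float = 0.3
    iou_hard: float = 0.1
    iou_regress: float = 0.6
    nms_threshold: float = 0.3

    # training orchestration
    mining_rounds: int = 1
    mining_finetune_frac: float = 0.25  # fraction of finetune_epochs reused
    mining_max: int = 1000  # cap on hard negatives added per round
    neg_per_pos: int = 3  # negatives kept per positive in the crop pool
    max_classifier_samples: int = 2500  # cap on the kernel-machine batch
    regress_jitter: int = 3  # jittered gt anchors per slice for the SVR
    regress_context: float = 1.0  # crop scale around the anchor for the SVR
    top_k: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.iou_hard < self.iou_neg < self.iou_pos <= 1):
            raise ValueError("need iou_hard < iou_neg < iou_pos within [0, 1]")
        if self.layer_sizes[0] != self.tau**2:
            raise ValueError("layer_sizes[0] must equal tau^2")

    @classmethod
    def small(cls, **overrides) -> "DetectorConfig":
        """Reduced configuration for desk-scale runs: 24x24 crops through a
        {576,400,300,200} stack, shorter optimization schedules, and the box
        regressor's insensitivity zone rescaled to the spread of the
        box-encoding targets (joint residual norms are ~0.1-0.5 there, so
        the full-size default would leave the regressor entirely inside its
        dead zone). The Gaussian kernel width uses the median heuristic
        (r = 1/median squared distance), matching the kernel to the scale
        of this configuration's feature space."""
        base = dict(
            tau=24,
            layer_sizes=(576, 400, 300, 200),
            pretrain_max_iter=120,
            finetune_epochs=12,
            svr_epsilon=0.05,
            svr_C=30.0,
            svm_C=8.0,
            kernel_r_auto=True,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)
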