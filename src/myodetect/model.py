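"""Model/Results facade over the detection pipeline.

``MyocardiumDetector`` is constructed from a dataset plus a configuration;
``fit`` trains every stage and returns a ``MyocardiumDetectorResults``
carrying the fitted bundle, training diagnostics, and detection/evaluation
methods, with a ``summary()`` table in the spirit of statistical modelling
packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DetectorConfig
from .phantom import PhantomDataset, Slice
from .pipeline import (
    DetectionResult,
    DetectorBundle,
    EvalReport,
    detect,
    evaluate,
    train_detector,
)

__all__ = ["MyocardiumDetector", "MyocardiumDetectorResults"]


class MyocardiumDetector:
    """Trainable myocardium detector over a subject-organized dataset.

    Parameters
    ----------
    dataset : PhantomDataset
        Slices with ground-truth boxes and train/val/test split tags.
    config : DetectorConfig, optional
        Full pipeline configuration; defaults to the reference operating
        point (60x60 crops, {3600,1600,750,350} SSAE).
    """

    def __init__(self, dataset: PhantomDataset, config: DetectorConfig | None = None):
        self.dataset = dataset
        self.config = config if config is not None else DetectorConfig()

    @classmethod
    def from_directory(cls, path: str | Path, config: DetectorConfig | None = None):
        """Build from a directory of PNG slices + ground_truth.csv box table."""
        import csv

        import imageio.v3 as iio

        from .boxes import BoundingBox

        path = Path(path)
        rows = list(csv.DictReader(open(path / "ground_truth.csv")))
        subjects: dict[int, list[Slice]] = {}
        for r in rows:
            sid, idx = int(r["subject"]), int(r["slice"])
            img = iio.imread(path / f"subject{sid:03d}_slice{idx:02d}.png").astype(float)
            img /= max(img.max(), 1e-9)
            box = BoundingBox(
                float(r["x_center"]), float(r["y_center"]),
                float(r["width"]), float(r["height"]),
            )
            subjects.setdefault(sid, []).append(Slice(img, box, sid, idx))
        ds = PhantomDataset(
            subjects=[sorted(v, key=lambda s: s.index) for _, v in sorted(subjects.items())],
            split={sid: "train" for sid in subjects},
        )
        return cls(ds, config)

    def fit(self, seed: int = 0) -> "MyocardiumDetectorResults":
        """Train every stage; returns the results object."""
        bundle = train_detector(self.dataset, self.config, seed=seed)
        return MyocardiumDetectorResults(model=self, bundle=bundle)


@dataclass
class MyocardiumDetectorResults:
    """Fitted detector: bundle, diagnostics and evaluation helpers."""

    model: MyocardiumDetector
    bundle: DetectorBundle
    _eval_cache: dict = field(default_factory=dict)

    @property
    def training_log(self) -> dict:
        return self.bundle.training_log

    def detect(self, s: Slice | np.ndarray, top_k: int | None = None) -> DetectionResult:
        return detect(self.bundle, s, top_k=top_k)

    def evaluate(self, split: str = "test", mid_stack_only: bool = False) -> EvalReport:
        """Detect on every slice of the split and compute pixelwise metrics."""
        key = (split, mid_stack_only)
        if key not in self._eval_cache:
            slices = self.model.dataset.slices(split=split, mid_stack_only=mid_stack_only)
            results = [self.detect(s) for s in slices]
            self._eval_cache[key] = evaluate(results, slices)
        return self._eval_cache[key]

    def summary(self, split: str = "test") -> str:
        """Fixed-width summary of the fit and held-out performance."""
        log = self.training_log
        cfg = self.bundle.config
        rep = self.evaluate(split=split)
        lines = [
            "          Myocardium Detection Model Results",
            "=" * 56,
            f"{'Training samples:':<28}{log.get('n_samples', 'n/a')}",
            f"{'  positives / negatives:':<28}"
            f"{log.get('n_positive', '?')} / {log.get('n_negative', '?')}",
            f"{'Hard negatives mined:':<28}{log.get('n_mined', 0)}",
            f"{'Regressor samples:':<28}{log.get('n_regress', 0)}",
            f"{'SSAE layers:':<28}{cfg.layer_sizes}",
            f"{'Kernel r / C / eta / t:':<28}"
            f"{'auto' if cfg.kernel_r_auto else cfg.kernel_r} / "
            f"{cfg.svm_C} / {cfg.eta} / {cfg.graph_t}",
            f"{'SVR epsilon / C:':<28}{cfg.svr_epsilon} / {cfg.svr_C}",
            f"{'Training time (s):':<28}{log.get('total_seconds', float('nan')):.1f}",
            "-" * 56,
            f"Evaluation on split '{split}' ({rep.n_slices} slices)",
            f"{'  Tpr (recall):':<28}{rep.tpr:.3f}",
            f"{'  Ppv (precision):':<28}{rep.ppv:.3f}",
            f"{'  F1:':<28}{rep.f1:.3f}",
            f"{'  AUC (detection level):':<28}{rep.auc_detection:.3f}",
            f"{'  Overlap 2|AnB|/|AuB|:':<28}{rep.dr:.3f}",
            f"{'  Dice (classical):':<28}{rep.dice_classical:.3f}",
            f"{'  Detection rate IoU>0.5:':<28}{rep.detection_rate_iou50:.3f}",
            f"{'  Mean IoU:':<28}{rep.mean_iou:.3f}",
            "=" * 56,
        ]
        return "\n".join(lines)
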