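"""Synthetic short-axis cardiac MR phantoms with known myocardium boxes.

Each phantom slice mimics the salient appearance of a mid-ventricular
short-axis acquisition: a bright left-ventricular blood pool inside a
mid-intensity myocardial annulus, dark papillary muscles inside the pool,
an adjacent right-ventricular crescent, a low-signal lung region, weak and
spatially varying epicardial contrast, a smooth multiplicative bias field
and Rician magnitude noise. The tight axis-aligned box of the epicardial
disk (myocardium plus pool) is the ground truth for detection.

Subject "stacks" are lists of 2-D slices whose ventricular radii shrink
toward the apex, so apical slices carry small, low-contrast targets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .boxes import BoundingBox

__all__ = [
    "PhantomParams",
    "Slice",
    "PhantomDataset",
    "rician_noise",
    "make_slice",
    "make_dataset",
    "save_dataset",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one phantom slice.

    Intensities are arbitrary units in [0, 1]; radii and coordinates are in
    pixels. ``bias_amplitude`` is the peak-to-peak fraction of the dynamic
    range covered by the multiplicative bias field, ``noise_sigma`` the
    Gaussian channel noise level of the Rician model.
    """

    image_size: tuple[int, int] = (160, 160)
    lv_center: tuple[float, float] = (80.0, 80.0)
    r_endo: float = 14.0
    r_epi: float = 24.0
    intensity_pool: float = 0.85
    intensity_myo: float = 0.45
    intensity_bg: float = 0.30
    intensity_lung: float = 0.08
    papillary_count: int = 2
    rv_present: bool = True
    bias_amplitude: float = 0.15
    noise_sigma: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if not (0 < self.r_endo < self.r_epi < min(h, w) / 2):
            raise ValueError("radii must satisfy 0 < r_endo < r_epi < min(H,W)/2")
        for name in ("intensity_pool", "intensity_myo", "intensity_bg", "intensity_lung"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.intensity_pool <= self.intensity_myo:
            raise ValueError("blood pool must be brighter than myocardium")
        cx, cy = self.lv_center
        if not (self.r_epi <= cx <= w - self.r_epi and self.r_epi <= cy <= h - self.r_epi):
            raise ValueError("epicardial disk must lie fully inside the image")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be non-negative")


@dataclass
class Slice:
    """One 2-D grayscale slice with optional ground-truth box."""

    image: np.ndarray
    gt_box: BoundingBox | None = None
    subject: int = 0
    index: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


@dataclass
class PhantomDataset:
    """Subject-organized phantom slices with train/val/test split tags."""

    subjects: list[list[Slice]] = field(default_factory=list)
    split: dict[int, str] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def slices(self, split: str | None = None, mid_stack_only: bool = False) -> list[Slice]:
        """Flatten to a slice list, optionally filtered by split tag.

        ``mid_stack_only`` drops the first and last slice of each stack
        (the most apical/basal slices with the smallest, faintest targets).
        """
        out: list[Slice] = []
        for sid, stack in enumerate(self.subjects):
            if split is not None and self.split.get(sid) != split:
                continue
            chosen = stack[1:-1] if (mid_stack_only and len(stack) > 2) else stack
            out.extend(chosen)
        return out


def rician_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Corrupt an intensity map with Rician magnitude noise.

    MR magnitude images are the modulus of a complex signal with independent
    Gaussian noise on both channels: out = sqrt((x + n1)^2 + n2^2).
    sigma = 0 returns |image| exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = np.asarray(image, dtype=float)
    if sigma == 0:
        return np.abs(x)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, x.shape)
    n2 = rng.normal(0.0, sigma, x.shape)
    return np.sqrt((x + n1) ** 2 + n2**2)


def _bias_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: a random low-order 2-D polynomial surface
    rescaled to 1 +/- amplitude/2."""
    h, w = shape
    if amplitude == 0:
        return np.ones(shape)
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - w / 2) / (w / 2)
    v = (yy - h / 2) / (h / 2)
    coef = rng.normal(0.0, 1.0, 6)
    surf = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u**2 + coef[4] * v**2 + coef[5]
    lo, hi = surf.min(), surf.max()
    if hi - lo < 1e-12:
        return np.ones(shape)
    surf = (surf - lo) / (hi - lo)  # [0, 1]
    return 1.0 + amplitude * (surf - 0.5)


def make_slice(params: PhantomParams) -> Slice:
    """Render one phantom slice from its parameters.

    The noiseless construction paints, in order: background tissue, lung,
    RV crescent, epicardial disk at myocardial intensity, endocardial pool,
    papillary spots; then multiplies by the bias field and applies Rician
    noise. The ground-truth box tightly encloses the epicardial disk.
    """
    params.validate()
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    cx, cy = params.lv_center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # air outside the body, an elliptical body cross-section at background
    # tissue intensity, and a bright subcutaneous-fat rim at the body surface
    img = np.full((h, w), 0.04)
    body_a, body_b = 0.52 * w, 0.46 * h
    body = ((xx - w / 2) / body_a) ** 2 + ((yy - h / 2) / body_b) ** 2
    rim_width = 0.06
    img[body <= 1.0] = min(params.intensity_pool * 0.95, 0.9)  # fat rim
    img[body <= (1.0 - rim_width)] = params.intensity_bg

    # low-signal lung fields flanking the heart
    lung_cx = w * 0.80 if cx < w / 2 else w * 0.20
    lung_cy = h * 0.35
    lung = ((xx - lung_cx) / (0.20 * w)) ** 2 + ((yy - lung_cy) / (0.30 * h)) ** 2 <= 1.0
    lung &= body <= (1.0 - rim_width)
    img[lung] = params.intensity_lung
    # a second, smaller lung field on the opposite side
    lung2_cx = w - lung_cx
    lung2 = ((xx - lung2_cx) / (0.13 * w)) ** 2 + ((yy - lung_cy) / (0.22 * h)) ** 2 <= 1.0
    lung2 &= body <= (1.0 - rim_width)
    img[lung2] = params.intensity_lung * 1.2

    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    if params.rv_present:
        # RV crescent: a pool-bright disk left of the LV, clipped by the epicardium
        rv_r = params.r_epi * 1.05
        rv_cx = cx - params.r_epi * 1.5
        rv = ((xx - rv_cx) ** 2 + (yy - cy) ** 2 <= rv_r**2) & (d2 > params.r_epi**2)
        img[rv] = params.intensity_pool * 0.9

    img[d2 <= params.r_epi**2] = params.intensity_myo
    pool = d2 <= params.r_endo**2
    img[pool] = params.intensity_pool

    if params.papillary_count > 0:
        pap_r = max(params.r_endo * 0.22, 1.2)
        for k in range(params.papillary_count):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.3, 0.7) * params.r_endo
            px, py = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            pap = ((xx - px) ** 2 + (yy - py) ** 2 <= pap_r**2) & pool
            img[pap] = params.intensity_myo * 0.9

    img *= _bias_field((h, w), params.bias_amplitude, rng)
    img = rician_noise(img, params.noise_sigma, int(rng.integers(2**31)))
    img = np.clip(img, 0.0, None)

    # tight half-open box of the epicardial disk: pixels with d2 <= r^2
    r = params.r_epi
    x0, x1 = int(np.ceil(cx - r)), int(np.floor(cx + r)) + 1
    y0, y1 = int(np.ceil(cy - r)), int(np.floor(cy + r)) + 1
    gt = BoundingBox.from_corners(x0, y0, x1, y1)
    return Slice(image=img.astype(np.float64), gt_box=gt)


_DEFAULT_VARIABILITY: dict[str, tuple[float, float]] = {
    "image_size": (128, 256),
    # basal epicardial radius as a fraction of image width: the LV spans
    # roughly 20-30% of a short-axis FOV irrespective of matrix size
    # (matrix and in-plane resolution covary on real scanners)
    "r_epi_frac": (0.10, 0.16),
    "r_endo_frac": (0.5, 0.65),  # r_endo / r_epi
    "intensity_pool": (0.75, 0.95),
    "intensity_myo": (0.35, 0.55),
    "intensity_bg": (0.20, 0.38),
    "bias_amplitude": (0.05, 0.25),
    "noise_sigma": (0.01, 0.05),
    "apex_shrink": (0.45, 0.7),  # apical r_epi as a fraction of basal r_epi
}


def make_dataset(
    n_subjects: int,
    slices_per_subject: int = 8,
    seed: int = 0,
    variability: dict[str, tuple[float, float]] | None = None,
    splits: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> PhantomDataset:
    """Generate a subject-organized phantom dataset.

    Per-subject parameters are drawn from ``variability`` ranges with an
    independent random stream derived from ``seed``, so regeneration with the
    same seed is bit-identical. Within a stack the epicardial radius shrinks
    monotonically toward the apical end, mimicking base-to-apex anatomy.
    Subjects are tagged train/val/test in the given proportions.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if slices_per_subject < 1:
        raise ValueError("slices_per_subject must be >= 1")
    var = dict(_DEFAULT_VARIABILITY)
    if variability:
        var.update(variability)
    for k, (lo, hi) in var.items():
        if hi < lo:
            raise ValueError(f"empty range for {k}")

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    subjects: list[list[Slice]] = []
    for sid in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[sid])
        size = int(rng.uniform(*var["image_size"]))
        r_epi_base = float(rng.uniform(*var["r_epi_frac"])) * size
        r_epi_base = min(max(r_epi_base, 8.0), size / 2 - 4)
        endo_frac = float(rng.uniform(*var["r_endo_frac"]))
        pool_i = float(rng.uniform(*var["intensity_pool"]))
        myo_i = float(rng.uniform(*var["intensity_myo"]))
        bg_i = float(rng.uniform(*var["intensity_bg"]))
        bias = float(rng.uniform(*var["bias_amplitude"]))
        noise = float(rng.uniform(*var["noise_sigma"]))
        shrink = float(rng.uniform(*var["apex_shrink"]))
        # LV center jittered but kept well inside the frame
        margin = r_epi_base + 6
        cx = float(rng.uniform(margin, size - margin))
        cy = float(rng.uniform(margin, size - margin))

        stack: list[Slice] = []
        for j in range(slices_per_subject):
            # basal slice first; radius decays linearly to shrink * base at the apex
            frac = 1.0 if slices_per_subject == 1 else 1.0 - (1.0 - shrink) * j / (slices_per_subject - 1)
            r_epi = max(r_epi_base * frac, 6.0)
            r_endo = max(r_epi * endo_frac, 2.5)
            p = PhantomParams(
                image_size=(size, size),
                lv_center=(cx, cy),
                r_endo=r_endo,
                r_epi=r_epi,
                intensity_pool=pool_i,
                intensity_myo=myo_i,
                intensity_bg=bg_i,
                papillary_count=int(rng.integers(1, 4)),
                rv_present=bool(rng.uniform() < 0.9),
                bias_amplitude=bias,
                noise_sigma=noise,
                seed=int(rng.integers(2**31)),
            )
            s = make_slice(p)
            s.subject, s.index = sid, j
            stack.append(s)
        subjects.append(stack)

    split: dict[int, str] = {}
    n_train = int(round(splits[0] * n_subjects))
    n_val = int(round(splits[1] * n_subjects))
    for sid in range(n_subjects):
        split[sid] = "train" if sid < n_train else ("val" if sid < n_train + n_val else "test")
    return PhantomDataset(subjects=subjects, split=split)


def save_dataset(dataset: PhantomDataset, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write slices (8-bit PNG or float32 NIfTI stacks) plus a ground-truth
    CSV box table (subject, slice, x_center, y_center, width, height)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, stack in enumerate(dataset.subjects):
        if fmt == "nifti":
            import nibabel as nib

            vol = np.stack([s.image for s in stack], axis=-1).astype(np.float32)
            nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), out / f"subject{sid:03d}.nii.gz")
        else:
            import imageio.v3 as iio

            for s in stack:
                img8 = np.clip(s.image / max(s.image.max(), 1e-9) * 255, 0, 255).astype(np.uint8)
                iio.imwrite(out / f"subject{sid:03d}_slice{s.index:02d}.png", img8)
        for s in stack:
            b = s.gt_box
            rows.append((sid, s.index, b.x_center, b.y_center, b.width, b.height))
    with open(out / "ground_truth.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["subject", "slice", "x_center", "y_center", "width", "height"])
        wr.writerows(rows)
    import yaml

    manifest = {
        "format": fmt,
        "n_subjects": dataset.n_subjects,
        "slices_per_subject": [len(s) for s in dataset.subjects],
        "splits": {str(k): v for k, v in dataset.split.items()},
        "box_convention": "0-based half-open pixel boxes (center x, center y, width, height)",
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out
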