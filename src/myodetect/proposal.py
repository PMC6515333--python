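"""Candidate-region generation.

Three stages produce axis-aligned box proposals for a slice:

1. ``supervoxel_segment`` — SLIC-style over-segmentation in which the usual
   color+space distance is replaced by the hybrid structural similarity
   (``similarity.hybrid_similarity`` in patch mode): each pixel joins the
   nearby seed it is most similar to, seeds being summarized by their running
   region statistics and centroid patch.
2. ``hierarchical_merge`` — bottom-up agglomeration: repeatedly merge the
   adjacent region pair with the highest region-mode hybrid similarity until
   a target region count remains.
3. ``proposals_from_regions`` — tight boxes of the surviving regions plus
   unions of adjacent pairs (targets split across two regions), filtered by
   aspect ratio, area and border margin.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boxes import BoundingBox
from .similarity import (
    SimilarityConfig,
    build_log_gabor_bank,
    normalize_image,
    phase_congruency,
    s_cm,
    s_im,
    s_pm,
    s_sm,
)

__all__ = [
    "SupervoxelLabeling",
    "ProposalFilter",
    "RegionProposal",
    "supervoxel_segment",
    "region_adjacency",
    "hierarchical_merge",
    "proposals_from_regions",
]

_N_BINS = 32


@dataclass
class SupervoxelLabeling:
    """Per-pixel region labels plus per-region summaries.

    ``stats`` maps region id -> dict with keys n, sum, sumsq, pc_sum,
    cy_sum, cx_sum, hist (intensity bin counts); derived properties (mean,
    std, centroid) are computed on demand. ``image`` and ``pc`` are kept so
    merging can recompute exact statistics.
    """

    labels: np.ndarray
    image: np.ndarray
    pc: np.ndarray
    stats: dict[int, dict] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.stats.keys())

    @property
    def n_regions(self) -> int:
        return len(self.stats)


@dataclass
class ProposalFilter:
    """Box filters: height/width aspect band, area band (fraction of image),
    and minimum distance of the box from the image border."""

    aspect_ratio_range: tuple[float, float] = (1 / 3, 3.0)
    area_range: tuple[float, float] = (0.002, 0.40)
    border_margin: int = 2

    def __post_init__(self) -> None:
        if self.aspect_ratio_range[0] > self.aspect_ratio_range[1]:
            raise ValueError("aspect_ratio_range must be (min, max)")
        if self.area_range[0] > self.area_range[1]:
            raise ValueError("area_range must be (min, max)")


@dataclass
class RegionProposal:
    box: BoundingBox
    region_ids: tuple[int, ...]
    score: float = 0.0


def _region_stats_from_labels(labels: np.ndarray, image: np.ndarray, pc: np.ndarray) -> dict[int, dict]:
    """Exact per-region pooled statistics via bincount."""
    flat = labels.ravel()
    n_lab = int(flat.max()) + 1
    counts = np.bincount(flat, minlength=n_lab)
    sums = np.bincount(flat, weights=image.ravel(), minlength=n_lab)
    sumsq = np.bincount(flat, weights=(image**2).ravel(), minlength=n_lab)
    pc_sum = np.bincount(flat, weights=pc.ravel(), minlength=n_lab)
    yy, xx = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    cy = np.bincount(flat, weights=yy.ravel().astype(float), minlength=n_lab)
    cx = np.bincount(flat, weights=xx.ravel().astype(float), minlength=n_lab)
    bins = np.minimum((image * _N_BINS).astype(int), _N_BINS - 1)
    hist2 = np.bincount(flat * _N_BINS + bins.ravel(), minlength=n_lab * _N_BINS)
    hist2 = hist2.reshape(n_lab, _N_BINS)
    stats = {}
    for r in range(n_lab):
        if counts[r] == 0:
            continue
        stats[r] = {
            "n": int(counts[r]),
            "sum": float(sums[r]),
            "sumsq": float(sumsq[r]),
            "pc_sum": float(pc_sum[r]),
            "cy_sum": float(cy[r]),
            "cx_sum": float(cx[r]),
            "hist": hist2[r].astype(float),
        }
    return stats


def _mean(st: dict) -> float:
    return st["sum"] / st["n"]


def _std(st: dict) -> float:
    if st["n"] < 2:
        return 0.0
    var = (st["sumsq"] - st["sum"] ** 2 / st["n"]) / (st["n"] - 1)
    return float(np.sqrt(max(var, 0.0)))


def _centroid(st: dict) -> tuple[float, float]:
    return st["cy_sum"] / st["n"], st["cx_sum"] / st["n"]


def _region_similarity(sa: dict, sb: dict, cfg: SimilarityConfig, alpha: float) -> float:
    """Region-mode hybrid similarity from pooled statistics.

    The structure term correlates the two regions' intensity histograms
    (densities), since regions differ in pixel count.
    """
    b1, b2, b3, b4, b5 = cfg.beta
    t_pm = s_pm(sa["pc_sum"] / sa["n"], sb["pc_sum"] / sb["n"], cfg.c1)
    t_im = s_im(_mean(sa), _mean(sb), cfg.c2)
    t_cm = s_cm(_std(sa), _std(sb), cfg.c3)
    t_sm = s_sm(sa["hist"] / sa["n"], sb["hist"] / sb["n"], cfg.c4)
    ca, cb = _centroid(sa), _centroid(sb)
    d2 = (ca[0] - cb[0]) ** 2 + (ca[1] - cb[1]) ** 2
    t_dm = float(np.exp(-alpha * d2))
    return float(t_pm**b1 * t_im**b2 * t_cm**b3 * t_sm**b4 * t_dm**b5)


def _enforce_connectivity(labels: np.ndarray) -> np.ndarray:
    """Relabel stranded fragments into the nearest surviving region.

    Each 4-connected component that is not the largest component of its
    region id is absorbed into the closest main-component region.
    """
    from skimage.measure import label as cc_label

    comp = cc_label(labels + 1, connectivity=1, background=0)
    n_comp = int(comp.max())
    # components of the same region id are separated by ndimage.label only if
    # disconnected; find the main (largest) component per region id
    comp_sizes = np.bincount(comp.ravel())
    out = labels.copy()
    # map component -> region id via one representative pixel
    reps = ndimage.minimum_position(
        np.arange(labels.size).reshape(labels.shape), labels=comp, index=np.arange(1, n_comp + 1)
    )
    comp_region = np.empty(n_comp + 1, dtype=int)
    for ci, (ry, rx) in enumerate(reps, start=1):
        comp_region[ci] = labels[ry, rx]
    main_comp: dict[int, int] = {}
    for ci in range(1, n_comp + 1):
        r = comp_region[ci]
        if r not in main_comp or comp_sizes[ci] > comp_sizes[main_comp[r]]:
            main_comp[r] = ci
    stray = np.isin(comp, [ci for ci in range(1, n_comp + 1) if main_comp[comp_region[ci]] != ci])
    if not stray.any():
        return out
    # iteratively absorb stray pixels into the nearest non-stray region
    dist, (iy, ix) = ndimage.distance_transform_edt(stray, return_indices=True)
    out[stray] = out[iy[stray], ix[stray]]
    return out


def supervoxel_segment(
    image: np.ndarray,
    M: int = 500,
    cfg: SimilarityConfig | None = None,
    max_iter: int = 10,
    pc: np.ndarray | None = None,
    seed_perturb: bool = True,
) -> SupervoxelLabeling:
    """SLIC-style over-segmentation with the hybrid similarity as affinity.

    Seeds start on a regular grid with step g = sqrt(N/M), perturbed to the
    lowest-gradient position in a 3x3 neighborhood. Each assignment sweep
    lets every pixel within +/-g of a seed centroid compete for it, keeping
    the seed of maximal patch-mode hybrid similarity (the pixel patch and PC
    against the seed region's running statistics and centroid patch).
    Iterates until fewer than 0.1% of pixels change label or ``max_iter``
    sweeps. Stranded fragments are relabeled to the dominant adjacent region.
    """
    img = normalize_image(image)
    h, w = img.shape
    n_pix = h * w
    if not (2 <= M <= n_pix):
        raise ValueError("M must be in [2, pixel count]")
    if cfg is None:
        cfg = SimilarityConfig()
    alpha = SimilarityConfig.alpha_for(M, n_pix)

    if pc is None:
        bank = build_log_gabor_bank(
            img.shape, cfg.n_scales, cfg.n_orientations, cfg.min_wavelength,
            cfg.scale_multiplier, cfg.sigma_r, cfg.sigma_theta_factor,
        )
        pc = phase_congruency(img, bank, cfg.amplitude_floor)

    p = cfg.p
    r = p // 2
    d = p * p
    padded = np.pad(img, r, mode="reflect").astype(np.float32)
    patches = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(padded, (p, p)).reshape(h, w, d)
    )
    patch_sum = patches.sum(axis=2, dtype=np.float64)
    patch_sumsq = np.einsum("ijk,ijk->ij", patches, patches, dtype=np.float64)
    patch_mean = (patch_sum / d).astype(np.float32)
    patch_var = (patch_sumsq - patch_sum**2 / d) / (d - 1)
    patch_std = np.sqrt(np.maximum(patch_var, 0.0)).astype(np.float32)

    # regular seed grid with ~M sites, aspect-matched to the image
    g = int(max(np.sqrt(n_pix / M), 2.0))
    ny = max(int(round(np.sqrt(M * h / w))), 1)
    nx = max(int(round(M / ny)), 1)
    ys = np.linspace(0, h, 2 * ny + 1)[1::2]
    xs = np.linspace(0, w, 2 * nx + 1)[1::2]
    seeds = [(int(y), int(x)) for y in ys for x in xs]
    if seed_perturb:
        gy, gx = np.gradient(img)
        grad = gy**2 + gx**2
        moved = []
        for (y, x) in seeds:
            y0, y1 = max(y - 1, 0), min(y + 2, h)
            x0, x1 = max(x - 1, 0), min(x + 2, w)
            sub = grad[y0:y1, x0:x1]
            dy, dx = np.unravel_index(np.argmin(sub), sub.shape)
            moved.append((y0 + int(dy), x0 + int(dx)))
        seeds = moved
    k = len(seeds)

    cy = np.array([s[0] for s in seeds], dtype=float)
    cx = np.array([s[1] for s in seeds], dtype=float)
    s_mean = np.array([patch_mean[s] for s in seeds])
    s_std = np.array([patch_std[s] for s in seeds])
    s_pcm = np.array([pc[s] for s in seeds])
    s_patch = np.array([patches[s] for s in seeds])  # (k, d)

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.full((h, w), -1, dtype=int)
    b1, b2, b3, b4, b5 = cfg.beta
    win = g  # half-window

    for it in range(max_iter):
        best = np.full((h, w), -np.inf)
        new_labels = np.full((h, w), -1, dtype=int)
        for kk in range(k):
            y0 = max(int(cy[kk]) - win, 0)
            y1 = min(int(cy[kk]) + win + 1, h)
            x0 = max(int(cx[kk]) - win, 0)
            x1 = min(int(cx[kk]) + win + 1, w)
            if y0 >= y1 or x0 >= x1:
                continue
            pm = patch_mean[y0:y1, x0:x1]
            ps = patch_std[y0:y1, x0:x1]
            ppc = pc[y0:y1, x0:x1]
            pw = patches[y0:y1, x0:x1]  # (wy, wx, d)
            t_im = (2 * pm * s_mean[kk] + cfg.c2) / (pm**2 + s_mean[kk] ** 2 + cfg.c2)
            t_cm = (2 * ps * s_std[kk] + cfg.c3) / (ps**2 + s_std[kk] ** 2 + cfg.c3)
            t_pm = (2 * ppc * s_pcm[kk] + cfg.c1) / (ppc**2 + s_pcm[kk] ** 2 + cfg.c1)
            sp = s_patch[kk]
            sp_mean = sp.mean()
            sp_centered = sp - sp_mean
            sp_sd = np.sqrt((sp_centered @ sp_centered) / (d - 1))
            dot = pw @ sp  # (wy, wx)
            cov = (dot - d * pm * sp_mean) / (d - 1)
            t_sm = np.clip(np.abs(2 * cov + cfg.c4) / (ps * sp_sd + cfg.c4), 0.0, 1.0)
            d2 = (yy[y0:y1, x0:x1] - cy[kk]) ** 2 + (xx[y0:y1, x0:x1] - cx[kk]) ** 2
            t_dm = np.exp(-alpha * d2)
            sim = t_pm**b1 * t_im**b2 * t_cm**b3 * t_sm**b4 * t_dm**b5
            upd = sim > best[y0:y1, x0:x1]
            best[y0:y1, x0:x1][upd] = sim[upd]
            new_labels[y0:y1, x0:x1][upd] = kk

        # orphans (outside every window): nearest assigned pixel's label
        if (new_labels < 0).any():
            mask = new_labels < 0
            _, (iy, ix) = ndimage.distance_transform_edt(mask, return_indices=True)
            new_labels[mask] = new_labels[iy[mask], ix[mask]]

        changed = np.count_nonzero(new_labels != labels)
        labels = new_labels
        # update seed summaries from current regions
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=k).astype(float)
        nonzero = counts > 0
        sums = np.bincount(flat, weights=img.ravel(), minlength=k)
        sumsq = np.bincount(flat, weights=(img**2).ravel(), minlength=k)
        pcs = np.bincount(flat, weights=pc.ravel(), minlength=k)
        cys = np.bincount(flat, weights=yy.ravel().astype(float), minlength=k)
        cxs = np.bincount(flat, weights=xx.ravel().astype(float), minlength=k)
        with np.errstate(invalid="ignore"):
            cy = np.where(nonzero, cys / counts, cy)
            cx = np.where(nonzero, cxs / counts, cx)
            s_mean = np.where(nonzero, sums / counts, s_mean)
            var = np.where(counts > 1, (sumsq - sums**2 / np.maximum(counts, 1)) / np.maximum(counts - 1, 1), 0.0)
            s_std = np.where(nonzero, np.sqrt(np.maximum(var, 0.0)), s_std)
            s_pcm = np.where(nonzero, pcs / counts, s_pcm)
        iy = np.clip(np.round(cy).astype(int), 0, h - 1)
        ix = np.clip(np.round(cx).astype(int), 0, w - 1)
        s_patch = patches[iy, ix]
        if changed < 0.001 * n_pix and it > 0:
            break

    labels = _enforce_connectivity(labels)
    # compact region ids
    uniq, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(h, w)
    stats = _region_stats_from_labels(labels, img, pc)
    return SupervoxelLabeling(labels=labels, image=img, pc=pc, stats=stats)


def region_adjacency(labeling: SupervoxelLabeling | np.ndarray) -> set[tuple[int, int]]:
    """Undirected 4-connectivity adjacency over region ids.

    Edge (a, b) with a < b iff some pixel of a is a 4-neighbor of a pixel
    of b.
    """
    labels = labeling.labels if isinstance(labeling, SupervoxelLabeling) else np.asarray(labeling)
    edges: set[tuple[int, int]] = set()
    for sa, sb in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = sa != sb
        a = sa[diff]
        b = sb[diff]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        edges.update(zip(lo.tolist(), hi.tolist()))
    return edges


def hierarchical_merge(
    labeling: SupervoxelLabeling,
    K: int = 100,
    cfg: SimilarityConfig | None = None,
) -> SupervoxelLabeling:
    """Agglomerate adjacent regions until ``K`` remain.

    At each step the adjacent pair with the highest region-mode hybrid
    similarity is merged (ties broken by the lexicographically smallest id
    pair), merged statistics are recomputed exactly from pooled sums, and
    only the merged region's edges are re-scored. The coordinate-measure
    decay uses alpha = 2K/N with K the target count.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > labeling.n_regions:
        raise ValueError("K exceeds current region count")
    if cfg is None:
        cfg = SimilarityConfig()
    if K == labeling.n_regions:
        return labeling

    stats = {r: dict(s, hist=s["hist"].copy()) for r, s in labeling.stats.items()}
    n_pix = labeling.labels.size
    alpha = SimilarityConfig.alpha_for(K, n_pix)

    neighbors: dict[int, set[int]] = {r: set() for r in stats}
    for a, b in region_adjacency(labeling):
        neighbors[a].add(b)
        neighbors[b].add(a)

    parent: dict[int, int] = {r: r for r in stats}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    version = {r: 0 for r in stats}
    heap: list[tuple[float, int, int, int, int]] = []

    def push(a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        sim = _region_similarity(stats[a], stats[b], cfg, alpha)
        heapq.heappush(heap, (-sim, a, b, version[a], version[b]))

    seen = set()
    for a in neighbors:
        for b in neighbors[a]:
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                push(*key)

    alive = set(stats.keys())
    while len(alive) > K and heap:
        negsim, a, b, va, vb = heapq.heappop(heap)
        if a not in alive or b not in alive or version[a] != va or version[b] != vb:
            continue
        # merge b into a (a < b by construction)
        sa, sb = stats[a], stats[b]
        sa["n"] += sb["n"]
        sa["sum"] += sb["sum"]
        sa["sumsq"] += sb["sumsq"]
        sa["pc_sum"] += sb["pc_sum"]
        sa["cy_sum"] += sb["cy_sum"]
        sa["cx_sum"] += sb["cx_sum"]
        sa["hist"] += sb["hist"]
        del stats[b]
        alive.discard(b)
        parent[b] = a
        version[a] += 1
        nb = (neighbors[a] | neighbors[b]) - {a, b}
        nb = {find(x) for x in nb} - {a}
        neighbors[a] = nb
        del neighbors[b]
        for x in nb:
            neighbors[x].discard(b)
            neighbors[x].add(a)
            push(min(a, x), max(a, x))

    mapping = np.arange(int(labeling.labels.max()) + 1)
    for r in range(mapping.size):
        mapping[r] = find(r) if r in parent else r
    new_labels = mapping[labeling.labels]
    uniq, compact = np.unique(new_labels, return_inverse=True)
    compact = compact.reshape(labeling.labels.shape)
    remap = {int(u): i for i, u in enumerate(uniq)}
    new_stats = {remap[r]: s for r, s in stats.items()}
    return SupervoxelLabeling(
        labels=compact, image=labeling.image, pc=labeling.pc, stats=new_stats
    )


def _tight_box(mask_or_coords) -> BoundingBox:
    ys, xs = mask_or_coords
    return BoundingBox.from_corners(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def proposals_from_regions(
    labeling: SupervoxelLabeling,
    filt: ProposalFilter | None = None,
) -> list[RegionProposal]:
    """Tight boxes of regions and of adjacent-pair unions, filtered.

    Filters: height/width aspect ratio band, box area band (fraction of the
    image), and a minimum margin between the box and the image border.
    Duplicate boxes (identical corners) are emitted once, single regions
    taking precedence over pair unions.
    """
    if filt is None:
        filt = ProposalFilter()
    labels = labeling.labels
    h, w = labels.shape
    n_pix = h * w

    objs = ndimage.find_objects(labels + 1)
    boxes: dict[int, tuple[int, int, int, int]] = {}
    for r in labeling.region_ids:
        sl = objs[r]
        if sl is None:
            continue
        boxes[r] = (sl[1].start, sl[0].start, sl[1].stop, sl[0].stop)  # x0, y0, x1, y1

    def passes(x0: int, y0: int, x1: int, y1: int) -> bool:
        bw, bh = x1 - x0, y1 - y0
        if bw <= 0 or bh <= 0:
            return False
        ar = bh / bw
        if not (filt.aspect_ratio_range[0] <= ar <= filt.aspect_ratio_range[1]):
            return False
        frac = (bw * bh) / n_pix
        if not (filt.area_range[0] <= frac <= filt.area_range[1]):
            return False
        m = filt.border_margin
        if x0 < m or y0 < m or x1 > w - m or y1 > h - m:
            return False
        return True

    out: list[RegionProposal] = []
    emitted: set[tuple[int, int, int, int]] = set()
    for r in sorted(boxes):
        x0, y0, x1, y1 = boxes[r]
        if passes(x0, y0, x1, y1) and (x0, y0, x1, y1) not in emitted:
            emitted.add((x0, y0, x1, y1))
            out.append(RegionProposal(BoundingBox.from_corners(x0, y0, x1, y1), (r,)))
    for a, b in sorted(region_adjacency(labeling)):
        if a not in boxes or b not in boxes:
            continue
        xa0, ya0, xa1, ya1 = boxes[a]
        xb0, yb0, xb1, yb1 = boxes[b]
        u = (min(xa0, xb0), min(ya0, yb0), max(xa1, xb1), max(ya1, yb1))
        if passes(*u) and u not in emitted:
            emitted.add(u)
            out.append(RegionProposal(BoundingBox.from_corners(*u), (a, b)))
    return out
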