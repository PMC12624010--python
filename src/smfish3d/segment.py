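"""Nuclear and cell segmentation.

Nuclei are segmented in 3D from DAPI by classical per-plane processing
(smoothing, Otsu threshold, hole filling, distance-transform watershed)
followed by z-stitching: labels in adjacent planes are merged when their
pairwise IoU reaches ``stitch_threshold`` -- the same stitching semantics
CellPose uses for its 3D mode, so externally produced CellPose label masks
drop in via :func:`import_masks`.

Cell outlines are 2D, derived from the diffuse background fluorescence of
the RNA channel (the cue used for real T cells, which are round suspension
cells): a maximum-intensity projection is smoothed and thresholded, and
connected regions are linked to the nuclei whose centroids project inside
them.  A region containing two nuclei is a cell in division and is kept as
one outline for the downstream QC filter to flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .config import PipelineConfig
from .detect import ImageStack

log = logging.getLogger("smfish3d")


@dataclass
class NuclearMask3D:
    """Labeled 3D nuclei (0 = background) with per-label statistics."""

    labels: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    stats: pd.DataFrame = field(default=None)  # label, volume_voxels,
    #                                            centroid_*, equivalent_diameter_um

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("NuclearMask3D requires a 3D label array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.stats is None:
            self.stats = _label_stats_3d(self.labels, self.voxel_size_nm)

    @property
    def n_labels(self) -> int:
        return int(len(self.stats))


@dataclass
class CellOutline2D:
    """Labeled 2D cell outlines over (y, x) linked to their nuclei."""

    labels: np.ndarray
    stats: pd.DataFrame = field(default=None)  # label, bbox, touches_border
    contained_nucleus_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("CellOutline2D requires a 2D label array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.stats is None:
            self.stats = _label_stats_2d(self.labels)


def _label_stats_3d(labels: np.ndarray, voxel_size_nm) -> pd.DataFrame:
    rows = []
    voxel_um3 = float(np.prod(voxel_size_nm)) / 1e9
    for rp in regionprops(labels):
        vol = int(rp.area)
        d_um = (6.0 * vol * voxel_um3 / math.pi) ** (1.0 / 3.0)
        rows.append({
            "label": rp.label, "volume_voxels": vol,
            "centroid_z": rp.centroid[0], "centroid_y": rp.centroid[1],
            "centroid_x": rp.centroid[2], "equivalent_diameter_um": d_um,
        })
    return pd.DataFrame(
        rows, columns=["label", "volume_voxels", "centroid_z", "centroid_y",
                       "centroid_x", "equivalent_diameter_um"])


def _label_stats_2d(labels: np.ndarray) -> pd.DataFrame:
    ny, nx = labels.shape
    rows = []
    for rp in regionprops(labels):
        y0, x0, y1, x1 = rp.bbox
        rows.append({
            "label": rp.label, "area": int(rp.area),
            "bbox_y0": y0, "bbox_x0": x0, "bbox_y1": y1, "bbox_x1": x1,
            "touches_border": bool(y0 == 0 or x0 == 0 or y1 == ny or x1 == nx),
        })
    return pd.DataFrame(
        rows, columns=["label", "area", "bbox_y0", "bbox_x0", "bbox_y1",
                       "bbox_x1", "touches_border"])


# ---------------------------------------------------------------------------
# 3D nuclear segmentation
# ---------------------------------------------------------------------------

def _segment_plane(plane: np.ndarray, thr: float, min_dist_px: int) -> np.ndarray:
    """Threshold one smoothed plane and split touching nuclei by watershed."""
    binary = plane > thr
    if not binary.any():
        return np.zeros(plane.shape, dtype=np.int32)
    binary = ndimage.binary_fill_holes(binary)
    dist = ndimage.distance_transform_edt(binary)
    # watershed markers: maxima of the distance transform, one per nucleus lobe
    mx = ndimage.maximum_filter(dist, size=2 * min_dist_px + 1)
    peaks = (dist == mx) & (dist > 2.0)
    markers, n = ndimage.label(peaks)
    if n == 0:
        markers, _ = ndimage.label(binary)
        return markers.astype(np.int32)
    # collapse plateau fragments closer than min_dist
    labeled = watershed(-dist, markers, mask=binary)
    return labeled.astype(np.int32)


def segment_nuclei_3d(
    dapi: ImageStack,
    expected_diameter_um: float = 6.0,
    stitch_threshold: float = 0.25,
    config: PipelineConfig | None = None,
) -> NuclearMask3D:
    """Segment nuclei plane by plane, then stitch across z by IoU.

    A plane-k object merges into a plane-(k+1) object when their pairwise
    IoU is at least ``stitch_threshold`` (greedy, best IoU first, one-to-one
    per plane pair).  Stitched objects spanning fewer than 3 planes, or with
    volume outside 25--400% of the expected-diameter sphere, are removed.
    An empty DAPI stack yields an empty mask with a warning.
    """
    if expected_diameter_um <= 0:
        raise ValueError("expected_diameter_um must be positive")
    if not 0.0 < stitch_threshold < 1.0:
        raise ValueError("stitch_threshold must be in (0, 1)")
    cfg = config or PipelineConfig()
    img = np.asarray(dapi.voxels, dtype=float)
    vs = dapi.voxel_size_nm
    smoothed = ndimage.gaussian_filter(img, sigma=(1.0, 2.0, 2.0))
    from .detect import robust_noise_sd
    signal = float(np.percentile(smoothed, 99.9) - np.median(smoothed))
    if signal < 10.0 * (robust_noise_sd(smoothed) + 1e-9):
        # no contrast beyond the smoothed noise floor: nothing to segment
        log.warning("no nuclei found in DAPI stack; returning empty mask")
        return NuclearMask3D(np.zeros(img.shape, dtype=np.int32), vs)
    thr = threshold_otsu(smoothed)
    min_dist_px = max(3, int(0.4 * expected_diameter_um * 1000.0 / vs[1]))

    nz = img.shape[0]
    out = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    prev_plane = None
    for k in range(nz):
        cur = _segment_plane(smoothed[k], thr, min_dist_px)
        if cur.max() == 0:
            prev_plane = cur
            out[k] = 0
            continue
        mapped = np.zeros_like(cur)
        taken_new, taken_prev = set(), set()
        if prev_plane is not None and prev_plane.max() > 0:
            pairs = []
            for rp in regionprops(cur):
                mask = cur == rp.label
                for plab in np.unique(prev_plane[mask]):
                    if plab == 0:
                        continue
                    inter = np.count_nonzero(mask & (prev_plane == plab))
                    union = rp.area + np.count_nonzero(prev_plane == plab) - inter
                    pairs.append((inter / union, rp.label, plab))
            for iou, clab, plab in sorted(pairs, reverse=True):
                if iou < stitch_threshold:
                    break
                if clab in taken_new or plab in taken_prev:
                    continue
                mapped[cur == clab] = out[k - 1][prev_plane == plab].max()
                taken_new.add(clab)
                taken_prev.add(plab)
        for rp in regionprops(cur):
            if rp.label in taken_new:
                continue
            mapped[cur == rp.label] = next_label
            next_label += 1
        out[k] = mapped
        prev_plane = cur

    out = _filter_objects(out, expected_diameter_um, vs,
                          cfg.min_z_planes, cfg.volume_bounds)
    if out.max() == 0:
        log.warning("no nuclei survive size filtering; returning empty mask")
    return NuclearMask3D(out, vs)


def _filter_objects(labels, expected_diameter_um, voxel_size_nm,
                    min_z_planes, volume_bounds):
    voxel_um3 = float(np.prod(voxel_size_nm)) / 1e9
    expected_vol = math.pi / 6.0 * expected_diameter_um ** 3 / voxel_um3
    lo, hi = volume_bounds
    out = np.zeros_like(labels)
    next_label = 1
    for rp in regionprops(labels):
        zspan = rp.bbox[3] - rp.bbox[0]
        if zspan < min_z_planes:
            continue
        if not lo * expected_vol <= rp.area <= hi * expected_vol:
            continue
        out[labels == rp.label] = next_label
        next_label += 1
    return out


def estimate_diameter(mask: NuclearMask3D) -> float:
    """Mean volume-equivalent sphere diameter over all nuclei, in um."""
    if mask.n_labels == 0:
        raise ValueError("cannot estimate diameter from an empty mask")
    return float(mask.stats["equivalent_diameter_um"].mean())


# ---------------------------------------------------------------------------
# 2D cell outlines
# ---------------------------------------------------------------------------

def segment_cells_2d(
    rna_background: ImageStack,
    nuclear_mask: NuclearMask3D,
    cell_diameter_um: float = 9.0,
    config: PipelineConfig | None = None,
) -> CellOutline2D:
    """Derive 2D cell outlines from diffuse RNA-channel background fluorescence.

    The z maximum-intensity projection is smoothed and Otsu-thresholded;
    connected foreground regions become cells.  A region whose contained
    nucleus centroids are farther apart than ~0.75 cell diameters is split
    by a nucleus-seeded watershed (two separate cells touching); closer
    nucleus pairs are left as one outline (a dividing cell).  Regions
    containing no nucleus centroid are dropped with a warning.
    """
    img = np.asarray(rna_background.voxels, dtype=float)
    vs = rna_background.voxel_size_nm
    mip = img.max(axis=0)
    # suppress the bright single-molecule spots so the threshold separates
    # diffuse cell body from background rather than spots from everything
    despot = ndimage.median_filter(mip, size=9)
    smoothed = ndimage.gaussian_filter(despot, sigma=3.0)
    if smoothed.max() - smoothed.min() <= 1e-12:
        return CellOutline2D(np.zeros(mip.shape, dtype=np.int32))
    thr = threshold_otsu(smoothed)
    fg = ndimage.binary_fill_holes(smoothed > thr)
    min_area = 0.1 * math.pi * (cell_diameter_um * 1000.0 / vs[1] / 2.0) ** 2
    comp, _ = ndimage.label(fg)
    split_dist_px = 0.75 * cell_diameter_um * 1000.0 / vs[1]

    nuc_pts = nuclear_mask.stats[["label", "centroid_y", "centroid_x"]].to_numpy()
    out = np.zeros(mip.shape, dtype=np.int32)
    next_label = 1
    contained: dict[int, list[int]] = {}
    for rp in regionprops(comp):
        if rp.area < min_area:
            continue
        mask = comp == rp.label
        inside = [
            (int(lab), yy, xx) for lab, yy, xx in nuc_pts
            if 0 <= int(round(yy)) < mask.shape[0]
            and 0 <= int(round(xx)) < mask.shape[1]
            and mask[int(round(yy)), int(round(xx))]
        ]
        if not inside:
            log.warning("cell region %d contains no nucleus; dropped", rp.label)
            continue
        pts = np.array([(yy, xx) for _, yy, xx in inside])
        spread = 0.0
        if len(pts) > 1:
            d = pts[:, None, :] - pts[None, :, :]
            spread = float(np.sqrt((d ** 2).sum(-1)).max())
        if len(inside) > 1 and spread > split_dist_px:
            markers = np.zeros(mip.shape, dtype=np.int32)
            for i, (_, yy, xx) in enumerate(inside, start=1):
                markers[int(round(yy)), int(round(xx))] = i
            ws = watershed(-smoothed, markers, mask=mask)
            for i, (nuc_id, _, _) in enumerate(inside, start=1):
                piece = ws == i
                if not piece.any():
                    continue
                out[piece] = next_label
                contained[next_label] = [nuc_id]
                next_label += 1
        else:
            out[mask] = next_label
            contained[next_label] = [nuc_id for nuc_id, _, _ in inside]
            next_label += 1

    result = CellOutline2D(out)
    result.contained_nucleus_ids = contained
    return result


# ---------------------------------------------------------------------------
# external masks
# ---------------------------------------------------------------------------

def import_masks(path, expect_3d: bool | None = None,
                 voxel_size_nm: tuple[float, float, float] = (200.0, 65.0, 65.0)):
    """Load an externally produced integer label TIFF (e.g. a CellPose mask).

    Labels are validated (integer-valued, correct dimensionality), relabeled
    consecutively from 1 (the mapping is logged), and per-label statistics
    recomputed.  Returns :class:`NuclearMask3D` for 3D input or
    :class:`CellOutline2D` for 2D input.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: expected a 2D or 3D label image, got {arr.ndim}D")
    if expect_3d is True and arr.ndim == 2:
        raise ValueError(f"{path}: 2D mask supplied where a 3D mask was expected")
    if expect_3d is False and arr.ndim == 3:
        raise ValueError(f"{path}: 3D mask supplied where a 2D mask was expected")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: float-valued mask is not a label image")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0:
        raise ValueError(f"{path}: negative labels are invalid")

    old = np.unique(arr)
    old = old[old > 0]
    relabeled = np.zeros(arr.shape, dtype=np.int32)
    mapping = {}
    for new, lab in enumerate(old, start=1):
        relabeled[arr == lab] = new
        mapping[int(lab)] = new
    if any(k != v for k, v in mapping.items()):
        log.info("relabeled mask %s: %s", path, mapping)

    if arr.ndim == 3:
        return NuclearMask3D(relabeled, voxel_size_nm)
    return CellOutline2D(relabeled)
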