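"""Object extraction: threshold, 26-connected labeling, marker separation.

The chain mirrors a block-face SEM segmentation workflow: a grayscale
threshold selects the (dark) chromosomal material, maximal 26-connected
voxel sets become objects, and touching objects are separated by a
marker-controlled watershed whose markers are the H-maxima of the
anisotropy-aware Euclidean distance transform — maxima shallower than a
contrast depth ``h`` (the working range is 5–7) are suppressed so each
chromosome core yields exactly one marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from chromovol.volume_io import LabelVolume, VoxelGrid

log = logging.getLogger(__name__)

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the threshold -> label -> separate -> filter chain.

    ``h`` is the marker contrast (H-extrema depth) on the separation
    landscape; ``h_units='voxel'`` expresses the distance transform in
    units of the smallest voxel pitch (the convention the 5–7 working
    range belongs to), ``'nm'`` uses calibrated distances. ``invert``
    states that objects are dark, as in contrast-stained EM.
    """

    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    h: float = 6.0
    h_units: str = "voxel"
    min_size_um3: float = 0.05
    invert: bool = True

    def validate(self) -> None:
        if self.threshold_mode not in ("otsu", "manual"):
            raise ValueError("threshold_mode must be 'otsu' or 'manual'")
        if self.threshold_mode == "manual" and self.threshold_value is None:
            raise ValueError("manual threshold mode needs threshold_value")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.h_units not in ("voxel", "nm"):
            raise ValueError("h_units must be 'voxel' or 'nm'")
        if self.min_size_um3 < 0:
            raise ValueError("min_size_um3 must be >= 0")


def threshold(grid: VoxelGrid, params: SegmentationParams) -> tuple[np.ndarray, float]:
    """Binary object mask plus the threshold actually used.

    With ``invert`` (dark objects) the mask is ``data <= t``; an Otsu
    threshold on a constant image is an explicit error.
    """
    params.validate()
    data = np.asarray(grid.data)
    if data.size == 0:
        raise ValueError("empty image")
    if params.threshold_mode == "otsu":
        if data.min() == data.max():
            raise ValueError("constant image: Otsu threshold is undefined")
        t = float(threshold_otsu(data))
    else:
        t = float(params.threshold_value)
    mask = data <= t if params.invert else data >= t
    log.info("threshold=%.3f selects %.2f%% of voxels", t, 100 * mask.mean())
    return mask, t


def label_components(mask: np.ndarray, spacing_nm) -> LabelVolume:
    """26-connected components, labels sorted by descending voxel count.

    Adjacency counts face, edge and corner neighbours, so two voxels
    touching only at a corner are one object. Ties in size break by the
    original scan-order label for determinism.
    """
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    if n == 0:
        return LabelVolume(labels=raw.astype(np.int32), spacing_nm=tuple(spacing_nm))
    counts = np.bincount(raw.ravel())[1:]
    order = np.argsort(-counts, kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1)
    return LabelVolume(labels=remap[raw], spacing_nm=tuple(spacing_nm))


def _distance_landscape(mask: np.ndarray, spacing_nm, h_units: str) -> np.ndarray:
    spacing = np.asarray(spacing_nm, dtype=float)
    if h_units == "voxel":
        sampling = spacing / spacing.min()
    else:
        sampling = spacing
    return ndimage.distance_transform_edt(mask, sampling=sampling)


def separate_objects(mask: np.ndarray, spacing_nm, params: SegmentationParams) -> LabelVolume:
    """Split touching objects via H-maxima markers and watershed.

    The anisotropy-aware Euclidean distance transform of the mask is the
    separation landscape; maxima shallower than ``params.h`` are
    suppressed, surviving maxima seed a watershed on the negated
    landscape. A connected component none of whose maxima survive keeps a
    single fallback marker at its distance argmax, so objects are never
    merged or dropped: every output label is a subset of one input
    component, and components with a single core stay whole.
    """
    params.validate()
    mask = np.asarray(mask, dtype=bool)
    comps = label_components(mask, spacing_nm)
    if comps.n_labels == 0:
        return comps
    dist = _distance_landscape(mask, spacing_nm, params.h_units)

    # H-maxima with 26-connectivity throughout: morphological
    # reconstruction of (dist - h) under dist, then its regional maxima.
    # A ridge plateau must stay one marker, so plateau connectivity
    # matters and must match the 26-neighbour object criterion.
    rec = reconstruction(dist - params.h, dist, method="dilation", footprint=CONNECTIVITY_26)
    peaks = local_maxima(rec, connectivity=3) & mask
    markers, n_markers = ndimage.label(peaks, structure=CONNECTIVITY_26)
    # fallback marker for components whose relief is entirely below h
    has_marker = np.zeros(comps.n_labels + 1, dtype=bool)
    has_marker[np.unique(comps.labels[peaks])] = True
    flat = dist.ravel()
    for comp_id in range(1, comps.n_labels + 1):
        if has_marker[comp_id]:
            continue
        comp_idx = np.flatnonzero(comps.labels.ravel() == comp_id)
        best = comp_idx[np.argmax(flat[comp_idx])]
        n_markers += 1
        markers.ravel()[best] = n_markers

    ws = watershed(-dist, markers=markers, mask=mask, connectivity=CONNECTIVITY_26)
    # enforce the never-merge guarantee: relabel watershed basins within
    # each input component, then compact by descending size
    pair = ws.astype(np.int64) * (comps.n_labels + 1) + comps.labels
    pair[~mask] = 0
    uniq, inv = np.unique(pair, return_inverse=True)
    dense = inv.reshape(mask.shape)
    if uniq[0] != 0:  # no background voxel present
        dense = dense + 1
    counts = np.bincount(dense.ravel())
    n_out = len(counts) - 1
    order = np.argsort(-counts[1:], kind="stable") + 1
    remap = np.zeros(n_out + 1, dtype=np.int32)
    remap[order] = np.arange(1, n_out + 1)
    out = remap[dense]
    log.info("separated %d components into %d objects (h=%.2f %s)",
             comps.n_labels, n_out, params.h, params.h_units)
    return LabelVolume(labels=out, spacing_nm=tuple(spacing_nm))


def filter_small(labels: LabelVolume, min_size_um3: float) -> LabelVolume:
    """Drop labels below a physical-volume cutoff; recompact ids to 1..N."""
    if min_size_um3 < 0:
        raise ValueError("min_size_um3 must be >= 0")
    if labels.n_labels == 0 or min_size_um3 == 0:
        return labels
    vols = labels.volumes_um3()
    keep = np.flatnonzero(vols >= min_size_um3) + 1
    remap = np.zeros(labels.n_labels + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return LabelVolume(labels=remap[labels.labels], spacing_nm=labels.spacing_nm)


def region_grow(grid: VoxelGrid, seeds_vox, tolerance: float) -> np.ndarray:
    """Seeded region grow (non-interactive stand-in for manual picking).

    Grows 26-connected regions from seed voxels, accepting voxels whose
    gray value lies within ``tolerance`` of the seed's value.
    """
    data = np.asarray(grid.data, dtype=float)
    out = np.zeros(data.shape, dtype=bool)
    for seed in seeds_vox:
        seed = tuple(int(c) for c in seed)
        ref = data[seed]
        within = np.abs(data - ref) <= tolerance
        lab, _ = ndimage.label(within, structure=CONNECTIVITY_26)
        out |= lab == lab[seed]
    return out


def segment(grid: VoxelGrid, params: SegmentationParams | None = None) -> tuple[LabelVolume, float]:
    """Full chain: threshold -> separate (26-conn, H-maxima) -> size filter."""
    params = params or SegmentationParams()
    mask, t = threshold(grid, params)
    labels = separate_objects(mask, grid.spacing_nm, params)
    return filter_small(labels, params.min_size_um3), t
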