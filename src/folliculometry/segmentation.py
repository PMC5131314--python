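"""Follicle, theca, lumen and COC mask extraction from cleared-ovary stacks.

Follicles in cleared, fluorescently stained ovary stacks present as bright
thecal shells around dark interiors; the clearing-induced delamination of
the granulosa from the theca leaves a dark gap that cleanly demarcates the
theca inner edge.  The automated pipeline exploits exactly that contrast:
smooth, threshold the bright structures, close the shells, fill the enclosed
lumens, and label connected components.  A manual-mask ingestion path adopts
externally produced label volumes verbatim, for studies where follicles were
segmented by hand.

Connectivity conventions: 26-connectivity for component labelling (robust
components), 6-connectivity (shared faces) for boundary adjacency (thin,
consistent boundaries).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.segmentation import watershed

from .stack import ImageStack

__all__ = [
    "LabelVolume",
    "FollicleMaskSet",
    "SegmentationParams",
    "ShellNotClosedError",
    "segment_follicles",
    "discriminate_vessels",
    "extract_shell_masks",
    "detect_cocs",
    "COCDetection",
    "ingest_manual_masks",
    "shell_mask_set_from_masks",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)


class ShellNotClosedError(RuntimeError):
    """The thecal shell of a follicle does not enclose its lumen."""


@dataclass
class LabelVolume:
    """Integer-labelled segmentation aligned to a stack; 0 = background."""

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=dict)  # label -> follicle|vessel|...
    params: "SegmentationParams | None" = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")

    def follicle_ids(self) -> list[int]:
        return [l for l, k in sorted(self.class_map.items()) if k == "follicle"]

    def ids(self) -> list[int]:
        present = np.unique(self.labels)
        return [int(l) for l in present if l != 0]


@dataclass
class FollicleMaskSet:
    """Per-follicle decomposition into wall and interior compartments.

    ``whole`` is the filled outer region; ``theca`` the bright shell;
    ``gap`` the dark delamination band inside the theca; ``lumen`` everything
    interior to the gap (granulosa lining plus antrum).  Boundary sets are
    theca voxels sharing a face with the exterior (outer) or with interior
    non-theca voxels (inner).  Small pre-antral follicles have no resolvable
    shell; they carry an empty theca and ``has_shell`` False.
    """

    follicle_id: int
    whole: np.ndarray
    theca: np.ndarray
    gap: np.ndarray
    lumen: np.ndarray
    outer_boundary: np.ndarray
    inner_boundary: np.ndarray

    @property
    def has_shell(self) -> bool:
        return bool(self.outer_boundary.any() and self.inner_boundary.any())

    def validate(self) -> None:
        if (self.theca & ~self.whole).any() or (self.lumen & ~self.whole).any():
            raise ValueError("theca and lumen must be subsets of the whole mask")
        if (self.theca & self.lumen).any():
            raise ValueError("theca and lumen must be disjoint")
        if (self.outer_boundary & ~self.theca).any() or (self.inner_boundary & ~self.theca).any():
            raise ValueError("boundary sets must be subsets of the theca mask")


@dataclass
class SegmentationParams:
    """Tunable parameters of the automated pipeline (lengths in micrometres)."""

    smooth_sigma_um: float = 5.0
    threshold: float | None = None  # absolute override; None -> Otsu
    closing_radius_um: float = 12.0
    min_diameter_um: float = 40.0
    small_blob_min_um: float = 40.0  # lower bound of the primordial-candidate pass
    small_blob_max_um: float = 100.0
    vessel_elongation_threshold: float = 4.0
    split_touching: bool = True
    seed_merge_radius_um: float = 20.0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _ellipsoidal_structure(radius_um: float, spacing) -> np.ndarray:
    """Binary ellipsoid footprint of a physical radius under anisotropic spacing."""
    half = [max(int(np.floor(radius_um / d)), 0) for d in spacing]
    zz, yy, xx = np.ogrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    r = max(radius_um, 1e-9)
    return (
        (zz * spacing[0] / r) ** 2 + (yy * spacing[1] / r) ** 2 + (xx * spacing[2] / r) ** 2
    ) <= 1.0


def _equivalent_diameter_um(voxel_count: int, spacing) -> float:
    vol = voxel_count * spacing[0] * spacing[1] * spacing[2]
    return (6.0 * vol / np.pi) ** (1.0 / 3.0)


def segment_follicles(stack: ImageStack, params: SegmentationParams | None = None) -> LabelVolume:
    """Detect follicles as filled bright-shell components.

    Pipeline: Gaussian denoise -> threshold (Otsu by default) -> morphological
    closing -> 3D hole filling of enclosed lumens -> watershed split of
    touching follicles (seeded at lumen cavities) -> 26-connected components
    -> physical size filter.  Components below the size filter but in the
    small-blob band and solid are labelled ``primordial_candidate`` (egg-nest
    counting); everything else below the filter is dropped.
    """
    params = params or SegmentationParams()
    spacing = stack.spacing
    v = np.asarray(stack.voxels, np.float32)
    if v.size and np.issubdtype(stack.voxels.dtype, np.integer):
        limit = np.iinfo(stack.voxels.dtype).max
        if (stack.voxels == limit).mean() > 0.001:
            log.warning("stack appears saturated (%.2f%% voxels at dtype max)",
                        100 * (stack.voxels == limit).mean())
    sigma = [params.smooth_sigma_um / d for d in spacing]
    smoothed = ndi.gaussian_filter(v, sigma=sigma)
    if params.threshold is not None:
        thr = float(params.threshold)
    else:
        lo, hi = float(smoothed.min()), float(smoothed.max())
        if hi - lo < 1e-6:
            return LabelVolume(np.zeros(stack.shape, np.int32), {}, params)
        thr = float(threshold_otsu(smoothed))
    bright = smoothed > thr
    if not bright.any():
        return LabelVolume(np.zeros(stack.shape, np.int32), {}, params)
    struct = _ellipsoidal_structure(params.closing_radius_um, spacing)
    closed = ndi.binary_closing(bright, structure=struct)
    filled = ndi.binary_fill_holes(closed)
    labels, _ = ndi.label(filled, structure=_STRUCT26)
    if params.split_touching:
        labels = _split_touching(filled, closed, labels, spacing, params)
    # classify and size-filter
    out = np.zeros(stack.shape, np.int32)
    class_map: dict[int, str] = {}
    next_id = 1
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        n = int(comp.sum())
        d = _equivalent_diameter_um(n, spacing)
        if d < params.min_diameter_um:
            if params.small_blob_min_um <= d <= params.small_blob_max_um:
                if _is_solid(comp):
                    out[sl][comp] = next_id
                    class_map[next_id] = "primordial_candidate"
                    next_id += 1
            continue
        out[sl][comp] = next_id
        class_map[next_id] = "follicle"
        next_id += 1
    result = LabelVolume(out, class_map, params)
    return discriminate_vessels(result, spacing, params.vessel_elongation_threshold)


def _is_solid(comp: np.ndarray) -> bool:
    return not (ndi.binary_fill_holes(comp) & ~comp).any()


def _split_touching(filled, closed, labels, spacing, params: SegmentationParams):
    """Distance-transform watershed, seeded at lumen cavities.

    Each enclosed dark cavity (a hole of the closed bright mask) seeds one
    region; cavities closer than ``seed_merge_radius_um`` are merged first so
    that the concentric delamination gap and antrum of one follicle count as
    a single seed.  Components with at most one seed group are left intact;
    the watershed runs only on multi-seed components, on the negated
    Euclidean distance transform in physical units.
    """
    holes = filled & ~closed
    if not holes.any():
        return labels
    merge_struct = _ellipsoidal_structure(params.seed_merge_radius_um, spacing)
    merged = ndi.binary_dilation(holes, structure=merge_struct)
    seed_labels, n_seeds = ndi.label(merged, structure=_STRUCT26)
    seed_labels[~holes] = 0
    if n_seeds == 0:
        return labels
    # map each seed group to the component it sits in, count groups per component
    seed_comp = ndi.labeled_comprehension(
        labels, seed_labels, np.arange(1, n_seeds + 1), lambda x: x.max() if x.size else 0, int, 0
    )
    per_comp = Counter(int(c) for c in np.atleast_1d(seed_comp) if c > 0)
    multi = {c for c, k in per_comp.items() if k > 1}
    if not multi:
        return labels
    out = labels.copy()
    objects = ndi.find_objects(labels)
    for comp_id in multi:
        sl = objects[comp_id - 1]
        sub_mask = labels[sl] == comp_id
        sub_seeds = np.where(sub_mask, seed_labels[sl], 0)
        edt = ndi.distance_transform_edt(sub_mask, sampling=spacing)
        ws = watershed(-edt, markers=sub_seeds, mask=sub_mask)
        # renumber watershed regions into fresh labels beyond the current max
        base = int(out.max())
        region_ids = np.unique(ws)
        region_ids = region_ids[region_ids != 0]
        for i, rid in enumerate(region_ids, start=1):
            out[sl][ws == rid] = base + i
    return out


def discriminate_vessels(
    label_volume: LabelVolume,
    spacing: tuple[float, float, float],
    elongation_threshold: float = 4.0,
) -> LabelVolume:
    """Reclassify elongated components as vessels.

    Blood vessels extend through many planes while follicles appear and
    disappear quickly; in 3D this is a principal-axis elongation criterion.
    Components whose longest/second-longest principal axis ratio (physical
    units) exceeds the threshold become ``vessel``; single-voxel and
    degenerate components default to ``follicle``.
    """
    labels = label_volume.labels
    class_map = dict(label_volume.class_map)
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None or class_map.get(lab) == "primordial_candidate":
            continue
        comp = labels[sl] == lab
        coords = np.argwhere(comp).astype(float)
        coords += np.array([s.start for s in sl], float)
        coords *= np.asarray(spacing)
        if coords.shape[0] < 2:
            class_map.setdefault(lab, "follicle")
            continue
        cov = np.cov(coords.T)
        eig = np.clip(np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1], 0.0, None)
        if eig[1] > 0:
            ratio = float(np.sqrt(eig[0] / eig[1]))
        elif eig[0] > 0:
            ratio = np.inf  # a perfectly straight 1-voxel-wide filament
        else:
            ratio = 1.0  # a single point has no elongation
        class_map[lab] = "vessel" if ratio > elongation_threshold else "follicle"
    # ensure every present label has a class
    for lab in label_volume.ids():
        class_map.setdefault(lab, "follicle")
    return LabelVolume(labels, class_map, label_volume.params)


def _face_boundary(theca: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Theca voxels sharing a face (6-connectivity) with ``other`` voxels."""
    return theca & ndi.binary_dilation(other, structure=_STRUCT6)


def shell_mask_set_from_masks(
    follicle_id: int, whole: np.ndarray, theca: np.ndarray, gap: np.ndarray | None = None
) -> FollicleMaskSet:
    """Assemble a :class:`FollicleMaskSet` from known whole/theca masks.

    Useful for phantom ground truth and for analytically constructed shells;
    boundary sets are derived with the same 6-connectivity rule as the
    intensity-based path.  An empty theca yields a shell-less set (no lumen,
    no boundaries): without a wall there is no interior to delimit.
    """
    whole = whole.astype(bool)
    theca = theca.astype(bool) & whole
    if not theca.any():
        empty = np.zeros_like(whole)
        return FollicleMaskSet(
            follicle_id=follicle_id,
            whole=whole,
            theca=empty,
            gap=empty.copy(),
            lumen=empty.copy(),
            outer_boundary=empty.copy(),
            inner_boundary=empty.copy(),
        )
    interior = whole & ~theca
    gap = (gap.astype(bool) & interior) if gap is not None else np.zeros_like(whole)
    lumen = interior & ~gap
    return FollicleMaskSet(
        follicle_id=follicle_id,
        whole=whole,
        theca=theca,
        gap=gap,
        lumen=lumen,
        outer_boundary=_face_boundary(theca, ~whole),
        inner_boundary=_face_boundary(theca, interior),
    )


def extract_shell_masks(
    stack: ImageStack,
    label_volume: LabelVolume,
    follicle_id: int,
    smooth_sigma_um: float = 3.0,
) -> FollicleMaskSet:
    """Decompose one labelled follicle into theca / gap / lumen compartments.

    The theca is recovered as the bright voxels (per-follicle Otsu threshold
    inside the component, compensating inter-follicle intensity variation)
    connected to the component's outer rind.  Inside the shell a second
    threshold separates the dark delamination band face-adjacent to the theca
    (the gap) from the granulosa lining and antrum (the lumen).  Follicles
    without a coherent interior cavity — small pre-antral follicles that
    image as solid blobs — come back shell-less (empty theca, ``has_shell``
    False).  Raises :class:`ShellNotClosedError` if a shell exists but does
    not enclose the interior.
    """
    labels = label_volume.labels
    spacing = stack.spacing
    if follicle_id not in label_volume.ids():
        raise KeyError(f"label {follicle_id} not present in the label volume")
    objects = ndi.find_objects((labels == follicle_id).astype(np.int8))
    sl = objects[0]
    # pad by one voxel so face-adjacency to the exterior is well defined
    sl = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(sl, labels.shape)
    )
    whole_c = labels[sl] == follicle_id
    v_c = np.asarray(stack.voxels, np.float32)[sl]
    if smooth_sigma_um > 0:
        v_c = ndi.gaussian_filter(v_c, sigma=[smooth_sigma_um / d for d in stack.spacing])
    vals = v_c[whole_c]
    lo, hi = float(vals.min()), float(vals.max())

    def shell_less():
        empty = np.zeros(labels.shape, bool)
        whole = np.zeros(labels.shape, bool)
        whole[sl] = whole_c
        return FollicleMaskSet(
            follicle_id=follicle_id,
            whole=whole,
            theca=empty,
            gap=empty.copy(),
            lumen=empty.copy(),
            outer_boundary=empty.copy(),
            inner_boundary=empty.copy(),
        )

    if hi - lo < 1e-6 or np.unique(vals).size < 4:
        return shell_less()  # uniform component: no resolvable shell
    # three intensity classes inside the component: dark (gap/antrum and the
    # blur skirt at the outer margin), intermediate (granulosa), bright
    # (theca and COC)
    try:
        thr_lo, thr_hi = threshold_multiotsu(vals, classes=3)
    except ValueError:
        return shell_less()
    bright_c = whole_c & (v_c > thr_hi)
    # theca = bright voxels connected (26) to the outer rind of the component;
    # the COC is bright too but floats inside the lumen, so it stays out
    rind = whole_c & ~ndi.binary_erosion(whole_c, structure=_STRUCT6)
    lab_b, _ = ndi.label(bright_c, structure=_STRUCT26)
    rind_labels = np.unique(lab_b[rind & bright_c])
    rind_labels = rind_labels[rind_labels != 0]
    theca_c = np.isin(lab_b, rind_labels) if rind_labels.size else np.zeros_like(whole_c)
    if not theca_c.any():
        return shell_less()
    # the multi-Otsu cut sits above the half-intensity edge and erodes the
    # shell by ~1-2 voxels per side; grow it back to the half-max level with
    # a short constrained dilation (the dark gap blocks leakage into the
    # granulosa, and two steps cannot propagate far even where it does not)
    dark_vals = vals[vals <= thr_lo]
    bright_vals = vals[vals > thr_hi]
    if dark_vals.size and bright_vals.size:
        thr_half = 0.5 * (float(np.median(dark_vals)) + float(np.median(bright_vals)))
        grow = v_c > thr_half
        for _ in range(2):
            theca_c = theca_c | (ndi.binary_dilation(theca_c, structure=_STRUCT6) & grow)
    # compartments live inside the filled shell hull; the segmentation label
    # may carry a dim blur margin outside the shell, which stays in the whole
    # mask (it tracks the half-intensity edge) but belongs to no compartment
    fill_plain = ndi.binary_fill_holes(theca_c)
    closed_small = ndi.binary_closing(theca_c, structure=_ellipsoidal_structure(8.0, spacing))
    cavity = ndi.binary_fill_holes(closed_small) & ~theca_c
    if int(cavity.sum()) < max(0.02 * whole_c.sum(), 30):
        return shell_less()  # solid blob: no resolvable lumen
    leak = cavity & ~fill_plain
    if int(leak.sum()) > 0.02 * cavity.sum():
        raise ShellNotClosedError(
            f"follicle {follicle_id}: thecal shell does not enclose its lumen "
            f"({int(leak.sum())} leaked voxels)"
        )
    whole_c = whole_c | fill_plain | theca_c
    interior_c = fill_plain & ~theca_c
    # the delamination gap is the dark band face-adjacent to the theca inner
    # edge; the granulosa lining keeps it separate from the antrum
    dark_c = interior_c & (v_c <= thr_lo)
    if dark_c.any():
        lab_d, _ = ndi.label(dark_c, structure=_STRUCT26)
        touch = np.unique(lab_d[dark_c & ndi.binary_dilation(theca_c, structure=_STRUCT6)])
        touch = touch[touch != 0]
        gap_c = np.isin(lab_d, touch)
    else:
        gap_c = np.zeros_like(whole_c)
    lumen_c = interior_c & ~gap_c

    def full(mask_c):
        m = np.zeros(labels.shape, bool)
        m[sl] = mask_c
        return m

    whole = full(whole_c)
    theca = full(theca_c)
    hull = full(theca_c | interior_c)
    interior = full(interior_c)
    return FollicleMaskSet(
        follicle_id=follicle_id,
        whole=whole,
        theca=theca,
        gap=full(gap_c),
        lumen=full(lumen_c),
        outer_boundary=_face_boundary(theca, ~hull),
        inner_boundary=_face_boundary(theca, interior),
    )


@dataclass
class COCDetection:
    """Accepted COC mask (if any) plus rejected/secondary candidates."""

    accepted: np.ndarray | None
    candidates: list[np.ndarray] = field(default_factory=list)


def detect_cocs(
    stack: ImageStack,
    mask_set: FollicleMaskSet,
    min_diameter_um: float = 25.0,
    max_diameter_um: float = 150.0,
    attach_tolerance_um: float = 30.0,
) -> COCDetection:
    """Find the cumulus-oophorus complex inside a follicle's lumen.

    COCs are bright connected blobs within the lumen, attached to the inner
    wall (within ``attach_tolerance_um`` of the lumen's outer surface), with
    a maximal physical extent in the configured diameter band.  At most one
    COC is accepted per follicle (the largest); detached or out-of-band blobs
    are reported as candidates.  An empty result is normal: COCs are
    detectable in only ~70% of follicles.
    """
    lumen = mask_set.lumen
    spacing = stack.spacing
    # need room for at least a minimal COC inside the lumen
    min_coc_voxels = (np.pi / 6.0) * min_diameter_um**3 / np.prod(spacing)
    if int(lumen.sum()) < 2 * min_coc_voxels:
        return COCDetection(accepted=None)
    v = np.asarray(stack.voxels, np.float32)
    objects = ndi.find_objects(lumen.astype(np.int8))
    sl = objects[0]
    sl = tuple(slice(max(s.start - 2, 0), min(s.stop + 2, n)) for s, n in zip(sl, lumen.shape))
    lum_c = lumen[sl]
    v_c = ndi.gaussian_filter(v[sl], sigma=[3.0 / d for d in spacing])
    vals = v_c[lum_c]
    if vals.size < 10 or float(vals.max() - vals.min()) < 1e-6:
        return COCDetection(accepted=None)
    t1 = float(threshold_otsu(vals))
    bright = lum_c & (v_c > t1)
    vals2 = v_c[bright]
    if vals2.size < 10:
        return COCDetection(accepted=None)
    # above t1 the lumen holds the granulosa lining and (if present) the much
    # brighter COC; when the granulosa dominates that population, cut midway
    # between its median and the brightest tail, otherwise t1 already
    # isolated the blob
    med2 = float(np.median(vals2))
    peak2 = float(np.percentile(vals2, 99.5))
    if med2 < 0.7 * peak2:
        t2 = 0.5 * (med2 + peak2)
        cand_mask = lum_c & (v_c > t2)
    else:
        # no brighter-than-lining population; if "bright" is most of the
        # lumen it is the lining itself, not a COC
        if vals2.size > 0.5 * vals.size:
            return COCDetection(accepted=None)
        cand_mask = bright
    if not cand_mask.any():
        return COCDetection(accepted=None)
    lab, n = ndi.label(cand_mask, structure=_STRUCT26)
    # distance of every lumen voxel to the lumen's outer surface, once
    wall_dist = ndi.distance_transform_edt(lum_c, sampling=spacing)
    accepted = []
    near_miss = []  # (n_vox, local slice, local mask); speckle is dropped outright
    objs = ndi.find_objects(lab)
    for i, osl in enumerate(objs, start=1):
        if osl is None:
            continue
        comp_local = lab[osl] == i
        n_vox = int(comp_local.sum())
        d_equiv = _equivalent_diameter_um(n_vox, spacing)
        if d_equiv < 0.5 * min_diameter_um:
            continue
        extent = np.array([(s.stop - s.start) for s in osl]) * np.asarray(spacing)
        in_band = d_equiv >= 0.7 * min_diameter_um and float(extent.max()) <= max_diameter_um
        attached = bool(float(wall_dist[osl][comp_local].min()) <= attach_tolerance_um)
        # a COC is a solid blob; a mis-thresholded granulosa lining is a shell
        filled = ndi.binary_fill_holes(comp_local)
        solid = n_vox >= 0.7 * int(filled.sum())
        if in_band and attached and solid:
            accepted.append((n_vox, osl, comp_local))
        else:
            near_miss.append((n_vox, osl, comp_local))

    def materialize(items, limit=10):
        out = []
        for n_vox, osl, comp_local in sorted(items, key=lambda t: -t[0])[:limit]:
            comp = np.zeros_like(lum_c)
            comp[osl] = comp_local
            out.append(_full(comp, sl, lumen.shape))
        return out

    if not accepted:
        return COCDetection(accepted=None, candidates=materialize(near_miss))
    accepted.sort(key=lambda t: -t[0])
    _, bsl, bloc = accepted[0]
    best = np.zeros_like(lum_c)
    best[bsl] = bloc
    # the second-level cut erodes the blob below its half-intensity edge;
    # grow back within the lumen, blocked by the dark antrum
    dark = vals[vals <= t1]
    if dark.size:
        thr_size = 0.5 * (float(np.median(dark)) + float(np.median(v_c[best])))
        grow = lum_c & (v_c > thr_size)
        for _ in range(4):
            best = best | (ndi.binary_dilation(best, structure=_STRUCT6) & grow)
    rest = materialize(accepted[1:]) + materialize(near_miss)
    return COCDetection(accepted=_full(best, sl, lumen.shape), candidates=rest)


def _full(mask_c, sl, shape):
    m = np.zeros(shape, bool)
    m[sl] = mask_c
    return m


def ingest_manual_masks(label_tiff_path, stack: ImageStack) -> LabelVolume:
    """Adopt an externally supplied (e.g. manually segmented) label TIFF."""
    import tifffile

    labels = tifffile.imread(label_tiff_path)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.shape != stack.shape:
        raise ValueError(
            f"manual label volume shape {labels.shape} does not match stack {stack.shape}"
        )
    labels = labels.astype(np.int32)
    class_map = {int(l): "follicle" for l in np.unique(labels) if l != 0}
    return LabelVolume(labels, class_map, None)
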