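"""Folliculometric measurements from per-follicle mask sets.

All quantities are computed in physical units from anisotropic voxel grids:

* volume ``V`` as the voxel integral of the whole-follicle mask (mm^3);
* equivalent diameter ``d = (6V/pi)^(1/3)`` in micrometres, the diameter of
  the sphere of the same volume;
* the equatorial plane as the z-plane of maximal cross-sectional area;
* the asymmetry parameter as the major/minor axis ratio of the second-moment
  ellipse of the equatorial cross-section (anisotropy-corrected);
* the thecal wall thickness distribution as, for each pixel on the outer
  theca edge in the equatorial plane, the shortest in-plane distance to the
  inner edge — one sample per outer-edge pixel, so wall irregularity shows
  up as spread, not bias;
* the classical histology estimator — two orthogonal chords, the second
  through the midpoint of the first — implemented for comparison, since it
  is biased on aspherical follicles;
* the COC diameter as the equivalent-circle diameter of its middle
  (maximal-area) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import StageThresholds, classify_stage
from .segmentation import FollicleMaskSet, detect_cocs
from .stack import ImageStack

__all__ = [
    "ThicknessDistribution",
    "FollicleMeasurement",
    "follicle_volume",
    "equivalent_diameter",
    "equatorial_plane",
    "equatorial_asymmetry",
    "theca_thickness_distribution",
    "orthogonal_diameter_estimate",
    "coc_diameter",
    "measure_follicle",
    "nearest_boundary_distances_sq",
]


@dataclass
class ThicknessDistribution:
    """Per-plane wall-thickness samples (um), one per outer-edge pixel."""

    samples: np.ndarray
    plane: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.size < 3:
            raise ValueError("a thickness distribution needs at least 3 samples")
        if (self.samples <= 0).any():
            raise ValueError("thickness samples must be positive")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if self.n > 1 else 0.0

    def quantiles(self, q=(25, 50, 75)) -> np.ndarray:
        return np.percentile(self.samples, q)


@dataclass
class FollicleMeasurement:
    """One follicle's folliculometric record; absent fields are None."""

    follicle_id: int
    voxel_count: int
    volume_mm3: float
    equivalent_diameter_um: float
    equatorial_plane: int
    asymmetry: float  # major/minor, >= 1
    asymmetry_inverse: float  # minor/major, <= 1 (alternate plotting convention)
    stage: str
    centroid_um: tuple[float, float, float]
    thickness: ThicknessDistribution | None = None
    coc_diameter_um: float | None = None
    orthogonal_diameter_um: float | None = None

    def __post_init__(self) -> None:
        if self.volume_mm3 <= 0:
            raise ValueError("volume must be positive")
        d = (6.0 * self.volume_mm3 / np.pi) ** (1.0 / 3.0) * 1000.0
        if abs(d - self.equivalent_diameter_um) > 1e-6 * max(d, 1.0):
            raise ValueError("equivalent diameter inconsistent with volume")
        if self.asymmetry < 1:
            raise ValueError("asymmetry must be >= 1")


def follicle_volume(whole_mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Voxel-integral volume of the whole-follicle mask, in mm^3."""
    n = int(np.count_nonzero(whole_mask))
    if n == 0:
        raise ValueError("empty follicle mask")
    dz, dy, dx = spacing
    return n * dz * dy * dx * 1e-9


def equivalent_diameter(volume_mm3: float) -> float:
    """Diameter (um) of the sphere with the given volume: d = (6V/pi)^(1/3)."""
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0) * 1000.0)


def equatorial_plane(whole_mask: np.ndarray) -> int:
    """Index of the z-plane of maximal cross-sectional area (ties -> lowest)."""
    areas = np.count_nonzero(whole_mask, axis=(1, 2))
    if areas.sum() == 0:
        raise ValueError("empty follicle mask")
    return int(np.argmax(areas))  # argmax returns the first (lowest) maximum


def _equatorial_coords(whole_mask, spacing):
    plane = equatorial_plane(whole_mask)
    yx = np.argwhere(whole_mask[plane])
    return plane, yx.astype(float) * np.asarray(spacing[1:], float)


def equatorial_asymmetry(whole_mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Major/minor axis ratio of the equatorial cross-section's moment ellipse.

    Pixel coordinates are scaled to micrometres before the second moments are
    taken, so anisotropic in-plane sampling cannot masquerade as shape
    asymmetry.  Returns a dimensionless ratio >= 1.
    """
    _, pts = _equatorial_coords(whole_mask, spacing)
    if pts.shape[0] < 5:
        raise ValueError("equatorial cross-section needs at least 5 pixels")
    cov = np.cov((pts - pts.mean(axis=0)).T)
    lam = np.linalg.eigvalsh(cov)
    if lam[0] <= 0:
        raise ValueError("degenerate (collinear) equatorial cross-section")
    return float(np.sqrt(lam[1] / lam[0]))


def nearest_boundary_distances_sq(
    outer_px: np.ndarray, inner_px: np.ndarray, spacing_yx: tuple[float, float]
) -> np.ndarray:
    """Squared shortest physical distance from each outer pixel to the inner set.

    ``outer_px``/``inner_px`` are integer (n, 2) arrays of (row, col) pixel
    indices in one plane.  The computation is a vectorized, chunked minimum of
    ``(dj*dy)**2 + (dk*dx)**2`` over integer index offsets; squared distances
    are returned so downstream consumers choose when to take the root.
    """
    outer_px = np.asarray(outer_px, np.int64)
    inner_px = np.asarray(inner_px, np.int64)
    if outer_px.size == 0 or inner_px.size == 0:
        raise ValueError("both boundary pixel sets must be non-empty")
    dy, dx = float(spacing_yx[0]), float(spacing_yx[1])
    out = np.empty(outer_px.shape[0], float)
    chunk = max(1, int(4_000_000 // max(inner_px.shape[0], 1)))
    for start in range(0, outer_px.shape[0], chunk):
        o = outer_px[start : start + chunk]
        dj = o[:, 0:1] - inner_px[None, :, 0].astype(np.int64)
        dk = o[:, 1:2] - inner_px[None, :, 1].astype(np.int64)
        d2 = (dj * dy) ** 2 + (dk * dx) ** 2
        out[start : start + o.shape[0]] = d2.min(axis=1)
    return out


def theca_thickness_distribution(
    mask_set: FollicleMaskSet, spacing: tuple[float, float, float]
) -> ThicknessDistribution:
    """Wall-thickness distribution on the equatorial plane.

    The analysis plane is the equatorial plane of the whole-follicle mask;
    for every outer-boundary pixel of the theca in that plane the sample is
    the shortest physical distance to the inner edge in the same plane.  The
    inner edge is where the dark delamination band begins — the first
    interior non-theca pixels touching the theca — which keeps the
    pixel-centre distances centred on the true wall width instead of biased
    one pixel short from each side.
    """
    from scipy import ndimage as ndi

    plane = equatorial_plane(mask_set.whole)
    outer = np.argwhere(mask_set.outer_boundary[plane])
    theca2d = mask_set.theca[plane]
    interior2d = (mask_set.gap | mask_set.lumen)[plane]
    inner_edge = interior2d & ndi.binary_dilation(
        theca2d, structure=ndi.generate_binary_structure(2, 1)
    )
    inner = np.argwhere(inner_edge)
    if outer.size == 0 or inner.size == 0:
        raise ValueError(
            f"follicle {mask_set.follicle_id}: theca boundaries empty in plane {plane}"
        )
    d2 = nearest_boundary_distances_sq(outer, inner, spacing[1:])
    return ThicknessDistribution(samples=np.sqrt(d2), plane=plane)


def _boundary_pixels_2d(section: np.ndarray) -> np.ndarray:
    """Pixels of a 2D mask with at least one 4-neighbour outside the mask."""
    from scipy import ndimage as ndi

    eroded = ndi.binary_erosion(section, structure=ndi.generate_binary_structure(2, 1))
    return np.argwhere(section & ~eroded)


def orthogonal_diameter_estimate(
    whole_mask: np.ndarray,
    spacing: tuple[float, float, float],
    angular_tolerance_deg: float = 2.0,
) -> float:
    """The two-orthogonal-chord diameter convention of histological sections.

    First measurement: the longest chord between boundary pixels lying on
    (anti)parallel rays through the cross-section centroid, within an angular
    tolerance.  Second: the chord through the first's midpoint perpendicular
    to it.  Returns the average, in micrometres.  On aspherical follicles
    this estimator is biased relative to the equivalent diameter — which is
    the point of implementing it.
    """
    plane = equatorial_plane(whole_mask)
    section = whole_mask[plane]
    if section.sum() < 5:
        raise ValueError("degenerate equatorial cross-section")
    dyx = np.asarray(spacing[1:], float)
    pts = _boundary_pixels_2d(section).astype(float) * dyx
    centroid = np.argwhere(section).astype(float).mean(axis=0) * dyx
    rel = pts - centroid
    ang = np.arctan2(rel[:, 0], rel[:, 1])
    tol = np.deg2rad(angular_tolerance_deg)
    best = 0.0
    best_pair = None
    # pair each boundary pixel with those on the opposite ray
    opp = (ang + np.pi + np.pi) % (2 * np.pi) - np.pi
    for i in range(pts.shape[0]):
        dang = np.abs(((ang - opp[i]) + np.pi) % (2 * np.pi) - np.pi)
        js = np.nonzero(dang <= tol)[0]
        if js.size == 0:
            continue
        d = np.linalg.norm(pts[js] - pts[i], axis=1)
        k = int(np.argmax(d))
        if d[k] > best:
            best = float(d[k])
            best_pair = (pts[i], pts[js[k]])
    if best_pair is None:
        raise ValueError("no opposed boundary pixel pair found through the centroid")
    p, q = best_pair
    mid = (p + q) / 2.0
    direction = (q - p) / np.linalg.norm(q - p)
    perp = np.array([-direction[1], direction[0]])
    second = _chord_length_through(section, dyx, mid, perp)
    return float((best + second) / 2.0)


def _chord_length_through(section, dyx, point, direction, step_um: float = 1.0) -> float:
    """Length of the in-mask run along ``direction`` containing ``point``."""
    ny, nx = section.shape
    max_extent = float(np.hypot(ny * dyx[0], nx * dyx[1]))
    ts = np.arange(-max_extent, max_extent + step_um, step_um)
    samples = point[None, :] + ts[:, None] * direction[None, :]
    idx = np.round(samples / dyx).astype(int)
    valid = (idx[:, 0] >= 0) & (idx[:, 0] < ny) & (idx[:, 1] >= 0) & (idx[:, 1] < nx)
    inside = np.zeros(ts.size, bool)
    inside[valid] = section[idx[valid, 0], idx[valid, 1]]
    mid_i = int(np.argmin(np.abs(ts)))
    if not inside[mid_i]:
        hits = np.nonzero(inside)[0]
        if hits.size == 0:
            return 0.0
        mid_i = hits[np.argmin(np.abs(ts[hits]))]
    lo = mid_i
    while lo - 1 >= 0 and inside[lo - 1]:
        lo -= 1
    hi = mid_i
    while hi + 1 < ts.size and inside[hi + 1]:
        hi += 1
    return float(ts[hi] - ts[lo] + step_um)


def coc_diameter(coc_mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Equivalent-circle diameter (um) of the COC's maximal-area plane."""
    areas = np.count_nonzero(coc_mask, axis=(1, 2))
    if areas.sum() == 0:
        raise ValueError("empty COC mask")
    plane = int(np.argmax(areas))
    area_um2 = float(areas[plane]) * spacing[1] * spacing[2]
    return float(2.0 * np.sqrt(area_um2 / np.pi))


def measure_follicle(
    stack: ImageStack,
    mask_set: FollicleMaskSet,
    spacing: tuple[float, float, float] | None = None,
    thresholds: StageThresholds = StageThresholds(),
    detect_coc: bool = True,
) -> FollicleMeasurement:
    """Aggregate all folliculometric quantities for one follicle.

    Fields that cannot be computed — wall thickness for follicles without a
    resolvable shell, COC diameter when no COC is detected — are left absent
    (None), never zero-filled.  Component errors are re-raised with the
    follicle id attached.
    """
    spacing = spacing or stack.spacing
    fid = mask_set.follicle_id
    try:
        vol = follicle_volume(mask_set.whole, spacing)
        d = equivalent_diameter(vol)
        plane = equatorial_plane(mask_set.whole)
        asym = equatorial_asymmetry(mask_set.whole, spacing)
        idx = np.argwhere(mask_set.whole).astype(float)
        centroid = tuple(float(c) for c in idx.mean(axis=0) * np.asarray(spacing))
        try:
            ortho = orthogonal_diameter_estimate(mask_set.whole, spacing)
        except ValueError:
            ortho = None
        thickness = None
        if mask_set.has_shell:
            try:
                thickness = theca_thickness_distribution(mask_set, spacing)
            except ValueError:
                thickness = None
        coc_d = None
        if detect_coc and mask_set.lumen.any():
            det = detect_cocs(stack, mask_set)
            if det.accepted is not None:
                coc_d = coc_diameter(det.accepted, spacing)
    except Exception as exc:
        raise type(exc)(f"follicle {fid}: {exc}") from exc
    return FollicleMeasurement(
        follicle_id=fid,
        voxel_count=int(np.count_nonzero(mask_set.whole)),
        volume_mm3=vol,
        equivalent_diameter_um=d,
        equatorial_plane=plane,
        asymmetry=asym,
        asymmetry_inverse=1.0 / asym,
        stage=classify_stage(d, thresholds),
        centroid_um=centroid,
        thickness=thickness,
        coc_diameter_um=coc_d,
        orthogonal_diameter_um=ortho,
    )
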