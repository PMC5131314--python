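"""Synthetic cleared-ovary light-sheet phantoms with machine-readable ground truth.

The generator emulates what a cleared porcine ovary fragment looks like in a
selective-plane-illumination (SPIM) stack: follicles appear as bright
ellipsoidal thecal shells around a dark delamination gap, an intermediate
granulosa lining, and a dark antral lumen, with the cumulus-oophorus complex
(COC) as a bright blob attached to the inner wall; blood vessels are long
bright tubes; primordial follicles cluster in egg nests near the cortex.
Imaging physics is reduced to the two effects that matter for morphometry:
a depth-dependent axial blur (the light sheet thickens away from its waist)
and shot + read noise.

All geometry is specified in micrometres in ``(z, y, x)`` order matching the
stack axes; orientation matrices act on ``(x, y, z)`` vectors with the
semi-axes ``(a, b, c)`` mapped to the matrix columns, so the identity
orientation puts the major axis in the imaging plane along x.

Every follicle is built as a radially layered star-convex body: along each
direction ``u`` from the centre the outer surface sits at the ellipsoid radius
``r(u)`` and the theca/gap/granulosa/lumen interfaces at ``r(u) - t(u)``,
``r(u) - t(u) - gap`` and so on, where the wall thickness ``t(u)`` carries a
smooth low-order angular modulation so per-follicle thickness distributions
are nondegenerate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi
from scipy.spatial.transform import Rotation

from .cohort import classify_stage
from .stack import ImageStack

__all__ = [
    "FolliclePhantom",
    "VesselPhantom",
    "EggNestPhantom",
    "ImagingModel",
    "PhantomSpec",
    "TruthRecord",
    "GroundTruth",
    "voxelize_ellipsoid",
    "build_phantom",
    "apply_lightsheet_psf",
    "apply_noise",
    "inplane_rotation",
    "load_phantom_spec",
    "save_phantom_spec",
    "example_cohort_spec",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# default abstract grayscale levels (no radiometric calibration is attempted);
# ordering theca > vessel > granulosa > background > gap ~ lumen, COC brightest
DEFAULT_INTENSITIES = {
    "theca": 200.0,
    "granulosa": 120.0,
    "coc": 240.0,
    "lumen": 10.0,
    "gap": 12.0,
    "vessel": 190.0,
    "nest": 210.0,
}


def inplane_rotation(angle_deg: float) -> np.ndarray:
    """Rotation about the stack z axis: keeps the major axis in the imaging plane."""
    return Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()


# --------------------------------------------------------------------------
# scene description
# --------------------------------------------------------------------------


@dataclass
class FolliclePhantom:
    """One synthetic follicle.

    ``semi_axes`` are the outer (thecal) surface semi-axes sorted descending,
    micrometres.  If the wall layers consume the whole radius (small
    pre-antral follicles) the body degenerates gracefully into a solid bright
    blob, which is how primary follicles are modelled.
    """

    center: tuple[float, float, float]  # (z, y, x) um
    semi_axes: tuple[float, float, float]  # (a, b, c), a >= b >= c, um
    orientation: np.ndarray | None = None  # 3x3, columns = a,b,c directions (x,y,z)
    theca_thickness_base: float = 60.0  # um
    theca_thickness_modulation: float = 0.0  # in [0, 1)
    modulation_phase_deg: float = 0.0
    gap_width: float = 10.0  # um, delamination band
    granulosa_width: float = 15.0  # um
    coc_diameter: float | None = None  # um, in [40, 110] by default
    coc_anchor_deg: float = 0.0  # in-plane direction of the anchor point
    intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi_axes must be positive and sorted descending, got {self.semi_axes}")
        if self.theca_thickness_base <= 0:
            raise ValueError("theca_thickness_base must be > 0")
        if not 0 <= self.theca_thickness_modulation < 1:
            raise ValueError("theca_thickness_modulation must be in [0, 1)")
        if self.orientation is None:
            self.orientation = np.eye(3)
        self.orientation = np.asarray(self.orientation, float)
        if self.coc_diameter is not None:
            lumen_min = c - self.theca_thickness_base - self.gap_width - self.granulosa_width
            if self.coc_diameter >= lumen_min:
                raise ValueError(
                    f"coc diameter {self.coc_diameter} um does not fit the lumen "
                    f"(smallest inner-lumen semi-axis {lumen_min:.1f} um)"
                )

    # -- analytic geometry helpers (follicle frame, micrometres) ------------

    def _radius_along(self, u_f: np.ndarray) -> np.ndarray:
        """Outer-surface radius along unit direction(s) in the follicle frame."""
        axes = np.asarray(self.semi_axes, float)
        scaled = u_f / axes
        return 1.0 / np.sqrt(np.einsum("...i,...i->...", scaled, scaled))

    def _thickness_along(self, u_f: np.ndarray) -> np.ndarray:
        """Radial wall thickness along unit direction(s) in the follicle frame.

        Modulation is a smooth degree-2 angular field cos(2*phi + phase) *
        sin^2(theta) = (ux^2 - uy^2) cos(phase) + 2 ux uy sin(phase), bounded
        in [-1, 1], so thickness stays within base * (1 +/- modulation).
        """
        base = self.theca_thickness_base
        m = self.theca_thickness_modulation
        if m == 0:
            return np.full(u_f.shape[:-1], base)
        ph = np.deg2rad(self.modulation_phase_deg)
        ux, uy = u_f[..., 0], u_f[..., 1]
        g = (ux**2 - uy**2) * np.cos(ph) + 2.0 * ux * uy * np.sin(ph)
        return base * (1.0 + m * g)

    def equatorial_contours(self, n_outer: int = 360, n_inner: int = 2160):
        """Outer and inner-wall contours in the lab plane z = center_z.

        Returns two arrays of (x, y) points, micrometres, relative to the
        follicle centre.  Used to generate analytic thickness ground truth.
        """
        R = self.orientation

        def contour(n: int):
            psi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
            d_lab = np.stack([np.cos(psi), np.sin(psi), np.zeros(n)], axis=-1)
            u_f = d_lab @ R  # R.T applied to each row
            r_out = self._radius_along(u_f)
            t = self._thickness_along(u_f)
            return d_lab[:, :2], r_out, t

        d2o, r_o, _ = contour(n_outer)
        d2i, r_i_out, t_i = contour(n_inner)
        outer = d2o * r_o[:, None]
        inner = d2i * np.clip(r_i_out - t_i, 0.0, None)[:, None]
        return outer, inner

    def truth_thickness_samples(self, n_outer: int = 360) -> np.ndarray:
        """Per-angle wall thickness in the equatorial plane (min distance
        from outer-contour points to a densely sampled inner contour)."""
        outer, inner = self.equatorial_contours(n_outer=n_outer)
        d2 = ((outer[:, None, :] - inner[None, :, :]) ** 2).sum(axis=-1)
        return np.sqrt(d2.min(axis=1))

    def equatorial_axis_ratio(self) -> float:
        """Analytic major/minor ratio of the central-plane cross-section."""
        axes = np.asarray(self.semi_axes, float)
        R = self.orientation
        M = R @ np.diag(1.0 / axes**2) @ R.T
        # cross-section at z=0 of x^T M x = 1 -> 2D form with the (x, y) block
        lam = np.linalg.eigvalsh(M[:2, :2])
        return float(np.sqrt(lam[1] / lam[0]))

    def outer_volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return (4.0 / 3.0) * np.pi * a * b * c * 1e-9

    def inner_volume_mm3(self) -> float:
        t = self.theca_thickness_base
        a, b, c = (max(s - t, 0.0) for s in self.semi_axes)
        return (4.0 / 3.0) * np.pi * a * b * c * 1e-9


@dataclass
class VesselPhantom:
    """A blood vessel: a tube of given radius around a polyline (um, (z,y,x))."""

    polyline: list[tuple[float, float, float]]
    radius: float = 18.0
    intensity: float = DEFAULT_INTENSITIES["vessel"]

    def __post_init__(self) -> None:
        if len(self.polyline) < 2:
            raise ValueError("vessel polyline needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("vessel radius must be > 0")


@dataclass
class EggNestPhantom:
    """A cluster of primordial follicles near the cortex surface."""

    center: tuple[float, float, float]  # (z, y, x) um
    count: int = 6
    member_diameter: float = 80.0  # um, ~70-100
    intensity: float = DEFAULT_INTENSITIES["nest"]

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("egg nest needs count >= 1")


@dataclass
class ImagingModel:
    """Reduced SPIM imaging physics.

    The light sheet is thinnest at its waist (a line through the volume centre
    perpendicular to the propagation direction, taken along x) and thickens
    with lateral distance from the centre; the axial PSF FWHM is interpolated
    linearly between ``sheet_waist_thickness`` at the waist and
    ``sheet_edge_thickness`` at ``sheet_edge_distance``, clamped beyond.
    In-plane resolution is a single Gaussian of FWHM ``lateral_psf_fwhm``.
    Noise is shot noise (Poisson at ``photon_scale`` photons per intensity
    unit) plus additive Gaussian read noise.
    """

    voxel_spacing: tuple[float, float, float] = (16.0, 4.0, 4.0)  # (dz, dy, dx) um
    lateral_psf_fwhm: float = 6.0  # um
    sheet_waist_thickness: float = 11.0  # um (the 16 um calibration is a valid override)
    sheet_edge_thickness: float = 60.0  # um
    sheet_edge_distance: float = 3000.0  # um
    photon_scale: float = 2.0  # photons per intensity unit
    read_noise_sd: float = 1.0  # electrons, i.e. intensity units after gain

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing components must be > 0")
        if self.sheet_edge_thickness < self.sheet_waist_thickness:
            raise ValueError("sheet_edge_thickness must be >= sheet_waist_thickness")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")

    def axial_fwhm_at(self, lateral_distance_um: np.ndarray | float) -> np.ndarray:
        """Axial PSF FWHM (um) at given lateral distance from the waist axis."""
        frac = np.clip(np.asarray(lateral_distance_um, float) / self.sheet_edge_distance, 0.0, 1.0)
        return self.sheet_waist_thickness + frac * (
            self.sheet_edge_thickness - self.sheet_waist_thickness
        )


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic ovary scene."""

    volume_shape: tuple[int, int, int]  # (nz, ny, nx)
    follicles: list[FolliclePhantom] = field(default_factory=list)
    vessels: list[VesselPhantom] = field(default_factory=list)
    egg_nests: list[EggNestPhantom] = field(default_factory=list)
    imaging: ImagingModel = field(default_factory=ImagingModel)
    background_level: float = 40.0
    seed: int = 0
    blur: bool = True
    noise: bool = True
    overlap_tolerance_voxels: int = 0


@dataclass
class TruthRecord:
    """Ground truth for one structure in the phantom."""

    id: int
    klass: str  # follicle | vessel | egg_nest
    center_um: tuple[float, float, float]
    true_volume_mm3: float  # analytic outer-surface volume (follicles)
    true_inner_volume_mm3: float | None = None
    true_equatorial_ratio: float | None = None
    true_mean_theca_thickness_um: float | None = None
    true_thickness_samples_um: list[float] | None = None
    true_coc_diameter_um: float | None = None
    true_coc_center_um: tuple[float, float, float] | None = None
    true_stage: str | None = None
    voxel_count: int = 0

    def __post_init__(self) -> None:
        if self.true_volume_mm3 <= 0:
            raise ValueError("true_volume must be > 0")
        if self.true_equatorial_ratio is not None and self.true_equatorial_ratio < 1:
            raise ValueError("major/minor ratio must be >= 1")


@dataclass
class GroundTruth:
    """Truth manifest plus a voxelized truth label volume aligned to the stack."""

    structures: list[TruthRecord]
    labels: np.ndarray  # int32 (nz, ny, nx); 0 = background
    spacing: tuple[float, float, float]

    def follicles(self) -> list[TruthRecord]:
        return [s for s in self.structures if s.klass == "follicle"]

    def to_json_dict(self) -> dict:
        recs = []
        for s in self.structures:
            d = dataclasses.asdict(s)
            recs.append(d)
        return {"spacing_um": list(self.spacing), "structures": recs}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @staticmethod
    def records_from_json(path: str | Path) -> list[TruthRecord]:
        data = json.loads(Path(path).read_text())
        out = []
        for d in data["structures"]:
            d = dict(d)
            for key in ("center_um", "true_coc_center_um"):
                if d.get(key) is not None:
                    d[key] = tuple(d[key])
            out.append(TruthRecord(**d))
        return out


# --------------------------------------------------------------------------
# voxelization and painting
# --------------------------------------------------------------------------


def _bbox_ranges(center, radius, spacing, shape):
    """Index ranges of the axis-aligned bounding box of a radius-`radius` ball."""
    los, his = [], []
    for c, d, n in zip(center, spacing, shape):
        lo = int(np.floor((c - radius) / d))
        hi = int(np.ceil((c + radius) / d)) + 1
        los.append(max(lo, 0))
        his.append(min(hi, n))
    return los, his


def voxelize_ellipsoid(
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    orientation: np.ndarray | None,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Binary mask of a rotated ellipsoid: a voxel is set iff its physical
    centre lies inside.

    ``center`` is (z, y, x) micrometres; voxel (i, j, k) has physical centre
    (i*dz, j*dy, k*dx).  ``orientation`` columns are the (a, b, c) axis
    directions in (x, y, z) space; identity puts the major axis along x.
    """
    semi_axes = tuple(float(s) for s in semi_axes)
    if any(s <= 0 for s in semi_axes):
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    R = np.eye(3) if orientation is None else np.asarray(orientation, float)
    (z0, y0, x0), (z1, y1, x1) = _bbox_ranges(center, semi_axes[0], spacing, shape)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        raise ValueError("ellipsoid lies entirely outside the volume")
    dz, dy, dx = spacing
    cz, cy, cx = center
    axes = np.asarray(semi_axes, float)
    ys = np.arange(y0, y1) * dy - cy
    xs = np.arange(x0, x1) * dx - cx
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    any_set = False
    for iz in range(z0, z1):
        Z = iz * dz - cz
        # follicle-frame coordinates f = R^T d for d = (x, y, z)
        fx = R[0, 0] * X + R[1, 0] * Y + R[2, 0] * Z
        fy = R[0, 1] * X + R[1, 1] * Y + R[2, 1] * Z
        fz = R[0, 2] * X + R[1, 2] * Y + R[2, 2] * Z
        inside = (fx / axes[0]) ** 2 + (fy / axes[1]) ** 2 + (fz / axes[2]) ** 2 <= 1.0
        if inside.any():
            any_set = True
            mask[iz, y0:y1, x0:x1] = inside
    if not any_set:
        raise ValueError("ellipsoid lies entirely outside the volume")
    return mask


def _paint_follicle(canvas, labels, fol: FolliclePhantom, spacing, label_id, tol_voxels):
    """Paint one layered follicle into ``canvas`` and its outer region into
    ``labels``; returns the voxel count of the outer region."""
    shape = canvas.shape
    (z0, y0, x0), (z1, y1, x1) = _bbox_ranges(fol.center, fol.semi_axes[0], spacing, shape)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        raise ValueError(f"follicle at {fol.center} lies outside the volume")
    dz, dy, dx = spacing
    cz, cy, cx = fol.center
    R = fol.orientation
    axes = np.asarray(fol.semi_axes, float)
    ints = fol.intensities
    ys = np.arange(y0, y1) * dy - cy
    xs = np.arange(x0, x1) * dx - cx
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    count = 0
    overlap = 0
    for iz in range(z0, z1):
        Z = iz * dz - cz
        fx = R[0, 0] * X + R[1, 0] * Y + R[2, 0] * Z
        fy = R[0, 1] * X + R[1, 1] * Y + R[2, 1] * Z
        fz = R[0, 2] * X + R[1, 2] * Y + R[2, 2] * Z
        q = np.sqrt((fx / axes[0]) ** 2 + (fy / axes[1]) ** 2 + (fz / axes[2]) ** 2)
        inside = q <= 1.0
        if not inside.any():
            continue
        rho = np.sqrt(fx**2 + fy**2 + fz**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_out = np.where(q > 0, rho / q, axes[2])
        # angular thickness modulation (see FolliclePhantom._thickness_along)
        ph = np.deg2rad(fol.modulation_phase_deg)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho2 = np.where(rho > 0, rho**2, 1.0)
            g = ((fx**2 - fy**2) * np.cos(ph) + 2.0 * fx * fy * np.sin(ph)) / rho2
        t = fol.theca_thickness_base * (1.0 + fol.theca_thickness_modulation * g)
        r1 = np.clip(r_out - t, 0.0, None)  # theca inner
        r2 = np.clip(r1 - fol.gap_width, 0.0, None)  # gap inner / granulosa outer
        r3 = np.clip(r2 - fol.granulosa_width, 0.0, None)  # granulosa inner / lumen
        level = np.where(
            rho > r1,
            ints["theca"],
            np.where(rho > r2, ints["gap"], np.where(rho > r3, ints["granulosa"], ints["lumen"])),
        )
        cslab = canvas[iz, y0:y1, x0:x1]
        lslab = labels[iz, y0:y1, x0:x1]
        overlap += int((inside & (lslab != 0)).sum())
        cslab[inside] = level[inside]
        lslab[inside] = label_id
        count += int(inside.sum())
    if overlap > tol_voxels:
        raise ValueError(
            f"follicle {label_id} overlaps a previously painted structure by "
            f"{overlap} voxels (tolerance {tol_voxels})"
        )
    # COC: a bright sphere tangent to the granulosa inner surface
    coc_center = None
    if fol.coc_diameter is not None:
        psi = np.deg2rad(fol.coc_anchor_deg)
        d_lab = np.array([np.cos(psi), np.sin(psi), 0.0])  # (x, y, z)
        u_f = R.T @ d_lab
        r_out_dir = float(fol._radius_along(u_f))
        t_dir = float(fol._thickness_along(u_f))
        r_lumen = r_out_dir - t_dir - fol.gap_width - fol.granulosa_width
        # +2 um bite into the granulosa guarantees voxel-level attachment
        rad_center = r_lumen - fol.coc_diameter / 2.0 + 2.0
        coc_center = (
            cz + 0.0,
            cy + rad_center * float(np.sin(psi)),
            cx + rad_center * float(np.cos(psi)),
        )
        coc_mask = voxelize_ellipsoid(
            coc_center, (fol.coc_diameter / 2.0,) * 3, None, spacing, shape
        )
        canvas[coc_mask] = ints["coc"]
    return count, coc_center


def _paint_vessel(canvas, labels, ves: VesselPhantom, spacing, label_id, tol_voxels):
    pts = np.asarray(ves.polyline, float)
    shape = canvas.shape
    dz, dy, dx = spacing
    count = 0
    overlap = 0
    for p0, p1 in zip(pts[:-1], pts[1:]):
        lo = np.minimum(p0, p1) - ves.radius
        hi = np.maximum(p0, p1) + ves.radius
        idx_lo = [max(int(np.floor(l / d)), 0) for l, d in zip(lo, spacing)]
        idx_hi = [min(int(np.ceil(h / d)) + 1, n) for h, d, n in zip(hi, spacing, shape)]
        if any(a >= b for a, b in zip(idx_lo, idx_hi)):
            continue
        zz = np.arange(idx_lo[0], idx_hi[0]) * dz
        yy = np.arange(idx_lo[1], idx_hi[1]) * dy
        xx = np.arange(idx_lo[2], idx_hi[2]) * dx
        Zg, Yg, Xg = np.meshgrid(zz, yy, xx, indexing="ij")
        P = np.stack([Zg, Yg, Xg], axis=-1)
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        tproj = np.clip(((P - p0) @ seg) / max(seg_len2, 1e-12), 0.0, 1.0)
        closest = p0 + tproj[..., None] * seg
        dist2 = ((P - closest) ** 2).sum(axis=-1)
        inside = dist2 <= ves.radius**2
        sl = (
            slice(idx_lo[0], idx_hi[0]),
            slice(idx_lo[1], idx_hi[1]),
            slice(idx_lo[2], idx_hi[2]),
        )
        lslab = labels[sl]
        overlap += int((inside & (lslab != 0) & (lslab != label_id)).sum())
        canvas[sl][inside] = ves.intensity
        new = inside & (lslab != label_id)
        lslab[inside] = label_id
        count += int(new.sum())
    if overlap > tol_voxels:
        raise ValueError(f"vessel {label_id} overlaps another structure by {overlap} voxels")
    return count


# --------------------------------------------------------------------------
# imaging model
# --------------------------------------------------------------------------


def apply_lightsheet_psf(stack: ImageStack, imaging: ImagingModel) -> ImageStack:
    """Blur a stack with the depth-dependent light-sheet PSF.

    In-plane blur is a uniform Gaussian at ``lateral_psf_fwhm``.  The axial
    (z) Gaussian width grows linearly with lateral distance of the image
    column from the waist axis (the y-line through the volume centre), from
    the waist thickness to the edge thickness at ``sheet_edge_distance``.
    Columns are grouped into quantized width bins for speed.
    """
    dz, dy, dx = stack.spacing
    nz, ny, nx = stack.shape
    max_sigma_vox = imaging.sheet_edge_thickness * _FWHM_TO_SIGMA / dz
    if 2 * 4 * max_sigma_vox > nz:
        raise ValueError(
            f"axial kernel ({imaging.sheet_edge_thickness:.0f} um FWHM) is wider "
            f"than the stack extent ({nz * dz:.0f} um)"
        )
    out = np.asarray(stack.voxels, dtype=np.float32).copy()
    sig_y = imaging.lateral_psf_fwhm * _FWHM_TO_SIGMA / dy
    sig_x = imaging.lateral_psf_fwhm * _FWHM_TO_SIGMA / dx
    if imaging.lateral_psf_fwhm > 0:
        ndi.gaussian_filter(out, sigma=(0.0, sig_y, sig_x), output=out, mode="nearest")
    # axial: one 1D filter per quantized sheet-thickness bin
    xc = (nx - 1) / 2.0 * dx
    dist = np.abs(np.arange(nx) * dx - xc)
    fwhm = imaging.axial_fwhm_at(dist)
    sigma_vox = fwhm * _FWHM_TO_SIGMA / dz
    n_bins = 24
    edges = np.linspace(sigma_vox.min(), sigma_vox.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(sigma_vox, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        cols = np.nonzero(which == b)[0]
        if cols.size == 0:
            continue
        s = float(sigma_vox[cols].mean())
        if s <= 0:
            continue
        sub = ndi.gaussian_filter1d(out[:, :, cols], sigma=s, axis=0, mode="nearest")
        out[:, :, cols] = sub
    return ImageStack(out, stack.spacing)


def apply_noise(stack: ImageStack, imaging: ImagingModel, seed: int) -> ImageStack:
    """Shot (Poisson) plus Gaussian read noise, seeded and reproducible."""
    v = np.asarray(stack.voxels, dtype=np.float64)
    if v.min() < 0:
        raise ValueError("noise model requires non-negative intensities")
    rng = np.random.default_rng(seed)
    photons = rng.poisson(v * imaging.photon_scale).astype(np.float64)
    out = photons / imaging.photon_scale
    if imaging.read_noise_sd > 0:
        out += rng.normal(0.0, imaging.read_noise_sd, size=v.shape)
    np.clip(out, 0.0, None, out=out)
    return ImageStack(out.astype(np.float32), stack.spacing)


# --------------------------------------------------------------------------
# scene assembly
# --------------------------------------------------------------------------


def build_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a phantom scene and its ground-truth manifest.

    Painting is back-to-front: background, vessels, egg nests, then each
    follicle's concentric regions outer->inner (theca, gap, granulosa, lumen)
    with the COC painted last inside the lumen.  The imaging model (blur then
    noise) is applied afterwards if enabled; ``spec.seed`` fully determines
    the output.
    """
    spacing = spec.imaging.voxel_spacing
    shape = tuple(int(n) for n in spec.volume_shape)
    extent = [n * d for n, d in zip(shape, spacing)]
    canvas = np.full(shape, spec.background_level, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    rng = np.random.default_rng(spec.seed)
    records: list[TruthRecord] = []
    next_id = 1
    tol = spec.overlap_tolerance_voxels

    for ves in spec.vessels:
        count = _paint_vessel(canvas, labels, ves, spacing, next_id, tol)
        pts = np.asarray(ves.polyline, float)
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        records.append(
            TruthRecord(
                id=next_id,
                klass="vessel",
                center_um=tuple(pts.mean(axis=0)),
                true_volume_mm3=np.pi * ves.radius**2 * length * 1e-9,
                voxel_count=count,
            )
        )
        next_id += 1

    for nest in spec.egg_nests:
        nest_radius = nest.member_diameter * (1.0 + 0.8 * nest.count ** (1.0 / 3.0))
        placed: list[np.ndarray] = []
        tries = 0
        while len(placed) < nest.count and tries < 2000:
            tries += 1
            offset = rng.uniform(-1.0, 1.0, size=3)
            if np.linalg.norm(offset) > 1.0:
                continue
            c = np.asarray(nest.center) + offset * nest_radius
            if any(np.linalg.norm(c - p) < 1.1 * nest.member_diameter for p in placed):
                continue
            if any(ci - nest.member_diameter / 2 < 0 or ci + nest.member_diameter / 2 > e
                   for ci, e in zip(c, extent)):
                continue
            placed.append(c)
        if len(placed) < nest.count:
            raise ValueError(f"could not place {nest.count} egg-nest members without overlap")
        for c in placed:
            r = nest.member_diameter / 2.0
            mask = voxelize_ellipsoid(tuple(c), (r, r, r), None, spacing, shape)
            if int((mask & (labels != 0)).sum()) > tol:
                raise ValueError("egg-nest member overlaps another structure")
            canvas[mask] = nest.intensity
            labels[mask] = next_id
            records.append(
                TruthRecord(
                    id=next_id,
                    klass="egg_nest",
                    center_um=tuple(float(x) for x in c),
                    true_volume_mm3=(4.0 / 3.0) * np.pi * r**3 * 1e-9,
                    true_stage="primordial",
                    voxel_count=int(mask.sum()),
                )
            )
            next_id += 1

    for fol in spec.follicles:
        count, coc_center = _paint_follicle(canvas, labels, fol, spacing, next_id, tol)
        thick = fol.truth_thickness_samples()
        eq_d = float((6.0 * fol.outer_volume_mm3() / np.pi) ** (1.0 / 3.0) * 1000.0)
        records.append(
            TruthRecord(
                id=next_id,
                klass="follicle",
                center_um=tuple(float(x) for x in fol.center),
                true_volume_mm3=fol.outer_volume_mm3(),
                true_inner_volume_mm3=fol.inner_volume_mm3(),
                true_equatorial_ratio=fol.equatorial_axis_ratio(),
                true_mean_theca_thickness_um=float(thick.mean()),
                true_thickness_samples_um=[float(t) for t in thick],
                true_coc_diameter_um=fol.coc_diameter,
                true_coc_center_um=coc_center,
                true_stage=classify_stage(eq_d),
                voxel_count=count,
            )
        )
        next_id += 1

    stack = ImageStack(canvas, spacing)
    if spec.blur:
        stack = apply_lightsheet_psf(stack, spec.imaging)
    if spec.noise:
        stack = apply_noise(stack, spec.imaging, seed=spec.seed)
    return stack, GroundTruth(structures=records, labels=labels, spacing=spacing)


# --------------------------------------------------------------------------
# YAML round-trip
# --------------------------------------------------------------------------


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    d = {
        "volume_shape": list(spec.volume_shape),
        "background_level": spec.background_level,
        "seed": spec.seed,
        "blur": spec.blur,
        "noise": spec.noise,
        "overlap_tolerance_voxels": spec.overlap_tolerance_voxels,
        "imaging": dataclasses.asdict(spec.imaging) | {
            "voxel_spacing": list(spec.imaging.voxel_spacing)
        },
        "follicles": [
            {
                "center": list(f.center),
                "semi_axes": list(f.semi_axes),
                "euler_z_deg": float(
                    Rotation.from_matrix(f.orientation).as_euler("zyx", degrees=True)[0]
                ),
                "theca_thickness_base": f.theca_thickness_base,
                "theca_thickness_modulation": f.theca_thickness_modulation,
                "modulation_phase_deg": f.modulation_phase_deg,
                "gap_width": f.gap_width,
                "granulosa_width": f.granulosa_width,
                "coc_diameter": f.coc_diameter,
                "coc_anchor_deg": f.coc_anchor_deg,
            }
            for f in spec.follicles
        ],
        "vessels": [
            {"polyline": [list(p) for p in v.polyline], "radius": v.radius}
            for v in spec.vessels
        ],
        "egg_nests": [
            {"center": list(n.center), "count": n.count, "member_diameter": n.member_diameter}
            for n in spec.egg_nests
        ],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"{path}: phantom spec must be a YAML mapping")
    try:
        imaging = ImagingModel(
            **{**d.get("imaging", {}),
               "voxel_spacing": tuple(d.get("imaging", {}).get("voxel_spacing", (16.0, 4.0, 4.0)))}
        )
        follicles = [
            FolliclePhantom(
                center=tuple(f["center"]),
                semi_axes=tuple(f["semi_axes"]),
                orientation=inplane_rotation(float(f.get("euler_z_deg", 0.0))),
                theca_thickness_base=f.get("theca_thickness_base", 60.0),
                theca_thickness_modulation=f.get("theca_thickness_modulation", 0.0),
                modulation_phase_deg=f.get("modulation_phase_deg", 0.0),
                gap_width=f.get("gap_width", 10.0),
                granulosa_width=f.get("granulosa_width", 15.0),
                coc_diameter=f.get("coc_diameter"),
                coc_anchor_deg=f.get("coc_anchor_deg", 0.0),
            )
            for f in d.get("follicles", [])
        ]
        vessels = [
            VesselPhantom(polyline=[tuple(p) for p in v["polyline"]], radius=v.get("radius", 18.0))
            for v in d.get("vessels", [])
        ]
        nests = [
            EggNestPhantom(
                center=tuple(n["center"]),
                count=n.get("count", 6),
                member_diameter=n.get("member_diameter", 80.0),
            )
            for n in d.get("egg_nests", [])
        ]
        return PhantomSpec(
            volume_shape=tuple(d["volume_shape"]),
            follicles=follicles,
            vessels=vessels,
            egg_nests=nests,
            imaging=imaging,
            background_level=d.get("background_level", 40.0),
            seed=int(d.get("seed", 0)),
            blur=bool(d.get("blur", True)),
            noise=bool(d.get("noise", True)),
            overlap_tolerance_voxels=int(d.get("overlap_tolerance_voxels", 0)),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: phantom spec missing required field {exc}") from exc


# --------------------------------------------------------------------------
# reference scene
# --------------------------------------------------------------------------


def example_cohort_spec(seed: int = 0) -> PhantomSpec:
    """A 10-follicle scene spanning primary, antral and Graafian stages.

    Geometry mirrors the anatomy the measurements are designed for: mildly
    ovoid follicles from ~60 um (solid primary follicles) to a ~940 um
    Graafian follicle, walls scaled to follicle size, COCs of 45-105 um
    attached to the inner wall of the antral/Graafian follicles, and two
    vessels threading the stack.  Volume is 110 x 512 x 512 voxels at
    (16, 4, 4) um, i.e. ~1.8 x 2 x 2 mm of tissue.
    """

    def fol(center, axes, angle, t, gap, gran, mod, phase, coc=None, anchor=0.0):
        return FolliclePhantom(
            center=center,
            semi_axes=axes,
            orientation=inplane_rotation(angle),
            theca_thickness_base=t,
            theca_thickness_modulation=mod,
            modulation_phase_deg=phase,
            gap_width=gap,
            granulosa_width=gran,
            coc_diameter=coc,
            coc_anchor_deg=anchor,
        )

    follicles = [
        # Graafian
        fol((880, 560, 560), (500, 460, 450), 20, 90, 15, 25, 0.15, 10, coc=105, anchor=40),
        # antral, large to small
        fol((480, 1650, 520), (320, 295, 285), 55, 90, 12, 20, 0.15, 70, coc=95, anchor=200),
        fol((480, 460, 1600), (215, 200, 190), -30, 60, 10, 18, 0.12, 140, coc=80, anchor=110),
        fol((1500, 230, 230), (160, 150, 140), 80, 40, 10, 15, 0.12, 200, coc=70, anchor=320),
        fol((1350, 1750, 1750), (130, 125, 120), 10, 35, 10, 15, 0.10, 260, coc=55, anchor=80),
        fol((250, 1100, 1550), (105, 100, 95), -60, 28, 8, 12, 0.10, 320, coc=45, anchor=250),
        fol((1450, 950, 1100), (82, 80, 78), 35, 25, 8, 12, 0.08, 30),
        # primary: wall layers consume the whole radius -> solid bright blobs
        fol((180, 250, 1050), (44, 43, 42), 0, 50, 0, 0, 0.0, 0),
        fol((1600, 1500, 600), (40, 39, 38), 0, 45, 0, 0, 0.0, 0),
        fol((900, 1750, 1300), (32, 31, 30), 0, 40, 0, 0, 0.0, 0),
    ]
    vessels = [
        VesselPhantom(
            polyline=[(40, 100, 1900), (870, 60, 1980), (1700, 180, 1950)], radius=18
        ),
        VesselPhantom(
            polyline=[(60, 1950, 120), (900, 1990, 90), (1680, 1960, 60)], radius=16
        ),
    ]
    return PhantomSpec(
        volume_shape=(110, 512, 512),
        follicles=follicles,
        vessels=vessels,
        imaging=ImagingModel(),
        seed=seed,
    )
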