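"""Synthetic tumor shape families and ground-truth depth/concentration maps.

Three shape families emulate oral ("iceberg") tumors that are flush with the
tissue surface and infiltrate downward:

* cylinders -- proof-of-concept shapes with a flat depth profile;
* spherical harmonics (SH) -- a 10 mm sphere perturbed by one real spherical
  harmonic, anisotropically scaled, cut at the surface;
* composite spherical harmonics (CSH) -- four SH surfaces merged as
  curvilinear quadrants delimited by two reciprocal (hyperbola) curves,
  rotated, shifted downward, scaled, and cut at the surface.

All generated training shapes have footprint widths in [10, 40] mm and depths
in [1, 10] mm.  Depth at a pixel follows the iceberg convention: the distance
from the surface plane z = 0 (or from the protruding tumor apex, for patient
meshes) to the bottom tumor surface.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import sph_harm_y

from .grid import DEFAULT_GRID, GridSpec

__all__ = [
    "ShapeVolume",
    "SphericalHarmonicParams",
    "CSHParams",
    "GroundTruthMaps",
    "EmptyShapeError",
    "make_cylinder",
    "make_spherical_harmonic",
    "make_csh",
    "cut_above_surface",
    "ground_truth_maps",
    "augment_mesh",
    "random_cylinder",
    "random_spherical_harmonic",
    "random_csh",
    "synthetic_tumor_mesh",
    "footprint_width_mm",
    "max_depth_mm",
]

WIDTH_RANGE_MM = (10.0, 40.0)
DEPTH_RANGE_MM = (1.0, 10.0)
SH_ORDER_RANGE = (2, 20)
SH_AMPLITUDE_RANGE = (0.1, 0.3)
SH_BASE_RADIUS_MM = 10.0
CSH_BLEND_BAND_MM = 2.0


class EmptyShapeError(RuntimeError):
    """Raised when a shape has no occupancy below the surface after cutting."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ShapeVolume:
    """Voxelized tumor occupancy on the simulation grid.

    ``occupancy[ix, iy, iz]`` is True where the voxel center lies inside the
    tumor surface (center-in-surface voxelization rule).
    """

    grid: GridSpec
    occupancy: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.grid.nx, self.grid.ny, self.grid.nz)
        if self.occupancy.shape != expected:
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != grid {expected}"
            )
        self.occupancy = self.occupancy.astype(bool)

    @property
    def footprint(self) -> np.ndarray:
        """Boolean (nx, ny) map of columns containing any occupancy."""
        return self.occupancy.any(axis=2)


@dataclass(frozen=True)
class SphericalHarmonicParams:
    """One real spherical harmonic perturbation of a 10 mm sphere.

    ``l`` is the degree index (the harmonic "order" in common parlance) and
    ``m`` the order index with \\|m\\| <= l.  The harmonic is normalized to unit
    maximum magnitude so ``amplitude`` directly bounds the relative radial
    perturbation; amplitude >= 1 would produce a negative radius and is
    rejected.
    """

    l: int
    m: int
    amplitude: float
    base_radius_mm: float = SH_BASE_RADIUS_MM

    def __post_init__(self) -> None:
        if not (SH_ORDER_RANGE[0] <= self.l <= SH_ORDER_RANGE[1]):
            raise ValueError(f"l={self.l} outside {SH_ORDER_RANGE}")
        if abs(self.m) > self.l:
            raise ValueError(f"|m|={abs(self.m)} exceeds l={self.l}")
        if self.amplitude >= 1.0:
            raise ValueError("amplitude >= 1 produces a negative radius")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class CSHParams:
    """Parameters of a composite spherical harmonic.

    Two reciprocal curves x*y = c1 (c1 > 0) and x*y = c2 (c2 < 0) partition
    the base XY plane into four curvilinear quadrants; each quadrant carries
    one SH radial function, blended across a cosine transition band.  The
    merged shape is rotated about X, Y, Z, shifted downward along z, scaled
    per axis to the target widths/depth, and cut at the surface.
    """

    quadrants: tuple  # four SphericalHarmonicParams
    c1_mm2: float
    c2_mm2: float
    rot_x_deg: float
    rot_y_deg: float
    rot_z_deg: float
    z_shift_mm: float
    target_width_x_mm: float
    target_width_y_mm: float
    target_depth_mm: float

    def __post_init__(self) -> None:
        if len(self.quadrants) != 4:
            raise ValueError("exactly four quadrant spherical harmonics required")
        if self.c1_mm2 <= 0 or self.c2_mm2 >= 0:
            raise ValueError("require c1 > 0 and c2 < 0")
        lo, hi = WIDTH_RANGE_MM
        if not (lo <= self.target_width_x_mm <= hi and lo <= self.target_width_y_mm <= hi):
            raise ValueError("target widths outside training range")
        lo, hi = DEPTH_RANGE_MM
        if not (lo <= self.target_depth_mm <= hi):
            raise ValueError("target depth outside training range")


@dataclass
class GroundTruthMaps:
    """Per-pixel tumor depth (mm) and fluorophore concentration (ug/mL)."""

    depth_mm: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        if self.depth_mm.shape != self.concentration.shape:
            raise ValueError("depth and concentration maps must share a shape")


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (polar angle theta, azimuth phi)."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


_SH_TABLE_N_THETA = 361
_SH_TABLE_N_PHI = 721


@functools.lru_cache(maxsize=512)
def _sh_table(l: int, m: int) -> np.ndarray:
    """Unit-max normalized real SH tabulated on a dense (theta, phi) grid.

    The table is built separably -- an associated Legendre profile along
    theta times a cos/sin profile along phi -- so it costs only 1-D special
    function evaluations.  Generated shapes use degrees up to 20, whose
    angular scale (~pi/20 rad) is far coarser than the table spacing, so
    bilinear interpolation is accurate to a small fraction of a percent.
    """
    from scipy.special import lpmv

    theta = np.linspace(0.0, np.pi, _SH_TABLE_N_THETA)
    phi = np.linspace(0.0, 2 * np.pi, _SH_TABLE_N_PHI)  # wrap column included
    leg = lpmv(abs(m), l, np.cos(theta))
    if m == 0:
        trig = np.ones_like(phi)
    elif m > 0:
        trig = np.cos(m * phi)
    else:
        trig = np.sin(abs(m) * phi)
    tab = np.outer(leg, trig)
    peak = np.unravel_index(np.argmax(np.abs(tab)), tab.shape)
    scale = np.abs(tab[peak])
    # fix the overall sign against the exact real harmonic at the peak
    ref = real_sph_harm(l, m, theta[peak[0]], phi[peak[1]])
    sign = 1.0 if ref * tab[peak] >= 0 else -1.0
    return sign * tab / scale


def _sph_harm_max_abs(l: int, m: int) -> float:
    theta = np.linspace(0.0, np.pi, 181)
    phi = np.linspace(0.0, 2 * np.pi, 361, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    return float(np.abs(real_sph_harm(l, m, tt, pp)).max())


def _sh_unit(l: int, m: int, theta, phi) -> np.ndarray:
    """Bilinear interpolation of the tabulated unit-max real SH."""
    tab = _sh_table(l, m)
    dt = np.pi / (_SH_TABLE_N_THETA - 1)
    dp = 2 * np.pi / (_SH_TABLE_N_PHI - 1)
    ft = np.clip(np.asarray(theta) / dt, 0, _SH_TABLE_N_THETA - 1 - 1e-9)
    fp = np.clip(np.mod(phi, 2 * np.pi) / dp, 0, _SH_TABLE_N_PHI - 1 - 1e-9)
    it = ft.astype(np.intp)
    ip = fp.astype(np.intp)
    wt = ft - it
    wp = fp - ip
    return (
        tab[it, ip] * (1 - wt) * (1 - wp)
        + tab[it + 1, ip] * wt * (1 - wp)
        + tab[it, ip + 1] * (1 - wt) * wp
        + tab[it + 1, ip + 1] * wt * wp
    )


def _sh_radius(params: SphericalHarmonicParams, theta, phi) -> np.ndarray:
    """Radial surface r(theta, phi) of a unit-max normalized SH perturbation."""
    y = _sh_unit(params.l, params.m, theta, phi)
    return params.base_radius_mm * (1.0 + params.amplitude * y)


# ---------------------------------------------------------------------------
# cylinder
# ---------------------------------------------------------------------------


def make_cylinder(
    width_mm: float, depth_mm: float, grid: GridSpec = DEFAULT_GRID
) -> ShapeVolume:
    """Right circular cylinder, axis along z, top flush with the surface."""
    if not (WIDTH_RANGE_MM[0] <= width_mm <= WIDTH_RANGE_MM[1]):
        raise ValueError(f"width {width_mm} mm outside {WIDTH_RANGE_MM}")
    if not (DEPTH_RANGE_MM[0] <= depth_mm <= DEPTH_RANGE_MM[1]):
        raise ValueError(f"depth {depth_mm} mm outside {DEPTH_RANGE_MM}")
    if width_mm > min(grid.nx, grid.ny) * grid.pixel_mm or depth_mm > grid.z_max_mm:
        raise ValueError("cylinder does not fit the simulation grid")
    x = grid.x_mm[:, None, None]
    y = grid.y_mm[None, :, None]
    z = grid.z_mm[None, None, :]
    inside = (x**2 + y**2 <= (width_mm / 2.0) ** 2) & (z >= 0.0) & (z <= depth_mm)
    return ShapeVolume(
        grid=grid,
        occupancy=inside,
        provenance={"family": "cylinder", "width_mm": width_mm, "depth_mm": depth_mm},
    )


# ---------------------------------------------------------------------------
# spherical harmonic shape
# ---------------------------------------------------------------------------


def _surface_cloud_sh(params: SphericalHarmonicParams, n_theta=121, n_phi=241):
    """Dense surface points of the unscaled SH restricted to z >= 0."""
    theta = np.linspace(0.0, np.pi / 2.0, n_theta)  # z = r cos(theta) >= 0
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    r = _sh_radius(params, tt, pp)
    x = r * np.sin(tt) * np.cos(pp)
    y = r * np.sin(tt) * np.sin(pp)
    z = r * np.cos(tt)
    return x.ravel(), y.ravel(), z.ravel()


def sh_scale_for_targets(
    params: SphericalHarmonicParams,
    target_width_x_mm: float,
    target_width_y_mm: float,
    target_depth_mm: float,
) -> tuple:
    """Per-axis scale factors mapping the cut SH to the target extents."""
    x, y, z = _surface_cloud_sh(params)
    sx = target_width_x_mm / (x.max() - x.min())
    sy = target_width_y_mm / (y.max() - y.min())
    sz = target_depth_mm / z.max()
    return (sx, sy, sz)


def _polar_angles(x: np.ndarray, y: np.ndarray, z: np.ndarray):
    """Radius, polar angle from +z, and azimuth of cartesian points."""
    r = np.sqrt(x**2 + y**2 + z**2)
    cos_t = np.ones_like(r)
    np.divide(z, r, out=cos_t, where=r > 0)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = np.arctan2(y, x)
    return r, theta, phi


def make_spherical_harmonic(
    params: SphericalHarmonicParams,
    scale_xyz: Sequence[float],
    grid: GridSpec = DEFAULT_GRID,
) -> ShapeVolume:
    """Voxelize one SH surface, anisotropically scaled and cut at z = 0."""
    sx, sy, sz = scale_xyz
    if min(sx, sy, sz) <= 0:
        raise ValueError("scale factors must be positive")
    zg = grid.z_mm
    keep = zg >= 0.0  # the cut removes everything above the surface
    x, y, z = np.meshgrid(grid.x_mm / sx, grid.y_mm / sy, zg[keep] / sz, indexing="ij")
    r, theta, phi = _polar_angles(x, y, z)
    # no SH surface extends beyond base_radius * (1 + amplitude)
    cand = r <= params.base_radius_mm * (1.0 + params.amplitude)
    inside = np.zeros(r.shape, dtype=bool)
    inside[cand] = r[cand] <= _sh_radius(params, theta[cand], phi[cand])
    occ = np.zeros((grid.nx, grid.ny, grid.nz), dtype=bool)
    occ[:, :, keep] = inside
    return ShapeVolume(
        grid=grid,
        occupancy=occ,
        provenance={
            "family": "sh",
            "l": params.l,
            "m": params.m,
            "amplitude": params.amplitude,
            "scale_xyz": (float(sx), float(sy), float(sz)),
        },
    )


# ---------------------------------------------------------------------------
# composite spherical harmonic
# ---------------------------------------------------------------------------


def _cos_step(t: np.ndarray) -> np.ndarray:
    """Cosine smoothstep: 0 for t <= -1, 1 for t >= 1."""
    return np.where(t <= -1, 0.0, np.where(t >= 1, 1.0, 0.5 * (1 + np.sin(np.pi * t / 2))))


def _quadrant_weights(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> np.ndarray:
    """Blend weights (4, ...) of the four SH over the base XY plane.

    Away from the curves x*y = c1 (> 0) and x*y = c2 (< 0) the weights are a
    hard assignment to curvilinear quadrants; within a ~2 mm band they blend
    with a cosine ramp so the merged surface has no seam discontinuity.
    """
    band = CSH_BLEND_BAND_MM
    rho = np.maximum(np.hypot(x, y), 0.5)  # |grad(xy)| scale, mm
    alpha = _cos_step((x * y - c1) / (band * rho))  # beyond the c1 branches
    beta = _cos_step((x * y - c2) / (band * rho))  # above the c2 branches
    sx = _cos_step(x / band)
    sy = _cos_step(y / band)
    sd = _cos_step((x + y) / band)
    sa = _cos_step((x - y) / band)
    w = np.empty((4,) + np.broadcast(x, y).shape)
    # central region: sign quadrants; outer c1 region: split by x+y;
    # outer c2 region: split by x-y
    mid = (1 - alpha) * beta
    w[0] = alpha * sd + mid * sx * sy
    w[1] = mid * (1 - sx) * sy + (1 - beta) * (1 - sa)
    w[2] = alpha * (1 - sd) + mid * (1 - sx) * (1 - sy)
    w[3] = mid * sx * (1 - sy) + (1 - beta) * sa
    return w / w.sum(axis=0)


def _csh_base_radius(params: CSHParams, theta, phi) -> np.ndarray:
    """Blended radial surface of the base (untransformed) CSH.

    The blend weights live on the XY plane, so the surface radius is solved
    by a short fixed-point iteration: evaluate weights at the current surface
    estimate's lateral coordinates, update the radius, repeat.
    """
    radii = np.stack([_sh_radius(p, theta, phi) for p in params.quadrants])
    r = radii.mean(axis=0)
    st = np.sin(theta)
    for _ in range(3):
        x = r * st * np.cos(phi)
        y = r * st * np.sin(phi)
        w = _quadrant_weights(x, y, params.c1_mm2, params.c2_mm2)
        r = (w * radii).sum(axis=0)
    return r


def _rotation_matrix(params: CSHParams) -> np.ndarray:
    ax, ay, az = np.deg2rad([params.rot_x_deg, params.rot_y_deg, params.rot_z_deg])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _csh_transformed_cloud(params: CSHParams, n_theta=91, n_phi=181):
    """Rotated + shifted (unscaled) surface points of the base CSH."""
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    r = _csh_base_radius(params, tt, pp)
    pts = np.stack(
        [
            (r * np.sin(tt) * np.cos(pp)).ravel(),
            (r * np.sin(tt) * np.sin(pp)).ravel(),
            (r * np.cos(tt)).ravel(),
        ]
    )
    pts = _rotation_matrix(params) @ pts
    pts[2] += params.z_shift_mm
    return pts


def make_csh(params: CSHParams, grid: GridSpec = DEFAULT_GRID) -> ShapeVolume:
    """Voxelize a composite spherical harmonic on the grid.

    Pipeline: merge four SH as curvilinear quadrants -> rotate about X, Y, Z
    -> shift downward along z -> scale per axis to the target widths/depth ->
    cut above the surface.  Scale factors are solved from a dense surface
    point cloud restricted to the part that survives the cut, then verified
    against the voxelized result and refined if quantization pushed the
    measured width/depth outside the requested targets.
    """
    pts = _csh_transformed_cloud(params)
    below = pts[:, pts[2] > 1e-9]
    if below.shape[1] == 0:
        raise EmptyShapeError("shape lies entirely above the surface after shift")
    sx = params.target_width_x_mm / (below[0].max() - below[0].min())
    sy = params.target_width_y_mm / (below[1].max() - below[1].min())
    sz = params.target_depth_mm / below[2].max()

    rot_inv = _rotation_matrix(params).T
    for _ in range(3):
        occ = _voxelize_csh(params, grid, (sx, sy, sz), rot_inv)
        if not occ.any():
            raise EmptyShapeError("voxelized shape empty after cut")
        shape = ShapeVolume(grid=grid, occupancy=occ)
        wx, wy = footprint_width_mm(shape)
        d = max_depth_mm(shape)
        ok_w = WIDTH_RANGE_MM[0] <= wx <= WIDTH_RANGE_MM[1] and (
            WIDTH_RANGE_MM[0] <= wy <= WIDTH_RANGE_MM[1]
        )
        ok_d = DEPTH_RANGE_MM[0] <= d <= DEPTH_RANGE_MM[1]
        if ok_w and ok_d:
            break
        # refine scales toward targets using the measured voxel extents
        sx *= params.target_width_x_mm / wx
        sy *= params.target_width_y_mm / wy
        sz *= params.target_depth_mm / d
    shape.provenance = {
        "family": "csh",
        "targets_mm": (
            params.target_width_x_mm,
            params.target_width_y_mm,
            params.target_depth_mm,
        ),
        "rot_deg": (params.rot_x_deg, params.rot_y_deg, params.rot_z_deg),
        "z_shift_mm": params.z_shift_mm,
        "scale_xyz": (float(sx), float(sy), float(sz)),
    }
    return shape


def _voxelize_csh(params, grid, scale_xyz, rot_inv) -> np.ndarray:
    sx, sy, sz = scale_xyz
    zg = grid.z_mm
    keep = zg >= 0.0
    xx, yy, zz = np.meshgrid(grid.x_mm / sx, grid.y_mm / sy, zg[keep] / sz, indexing="ij")
    q = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])
    q[2] -= params.z_shift_mm
    q = rot_inv @ q
    r, theta, phi = _polar_angles(q[0], q[1], q[2])
    max_r = max(p.base_radius_mm * (1.0 + p.amplitude) for p in params.quadrants)
    cand = r <= max_r
    rc, tc, pc = r[cand], theta[cand], phi[cand]
    radii = np.stack([_sh_radius(p, tc, pc) for p in params.quadrants])
    w = _quadrant_weights(q[0][cand], q[1][cand], params.c1_mm2, params.c2_mm2)
    inside = np.zeros(r.shape, dtype=bool)
    inside[cand] = rc <= (w * radii).sum(axis=0)
    occ = np.zeros((grid.nx, grid.ny, grid.nz), dtype=bool)
    occ[:, :, keep] = inside.reshape(grid.nx, grid.ny, keep.sum())
    return occ


# ---------------------------------------------------------------------------
# surface cut and ground truth
# ---------------------------------------------------------------------------


def cut_above_surface(shape: ShapeVolume) -> ShapeVolume:
    """Zero occupancy above the tissue surface (z < 0).  Idempotent."""
    occ = shape.occupancy.copy()
    occ[:, :, shape.grid.z_mm < 0] = False
    return ShapeVolume(grid=shape.grid, occupancy=occ, provenance=dict(shape.provenance))


def ground_truth_maps(
    shape: ShapeVolume,
    concentration: float,
    allow_protrusion: bool = False,
) -> GroundTruthMaps:
    """Per-pixel depth and concentration targets under the iceberg rule.

    For each occupied column the tumor spans [ztop, zbot] (outer voxel
    faces).  Depth is ``zbot - min(ztop, 0)``: for buried tops (ztop > 0) the
    depth is measured from the surface plane down to the bottom surface; for
    protruding tops (ztop < 0, patient-mesh mode) it is the full apex-to-base
    thickness.  Internal per-column gaps are filled for depth purposes.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    grid, occ = shape.grid, shape.occupancy
    any_col = occ.any(axis=2)
    iz_first = occ.argmax(axis=2)
    iz_last = occ.shape[2] - 1 - occ[:, :, ::-1].argmax(axis=2)
    half = grid.dz_mm / 2.0
    ztop = grid.z_mm[iz_first] - half
    zbot = grid.z_mm[iz_last] + half
    if not allow_protrusion and np.any(any_col & (ztop < -1e-9)):
        raise ValueError(
            "occupancy above the surface; apply cut_above_surface or pass "
            "allow_protrusion=True (patient-mesh mode)"
        )
    depth = np.where(any_col, zbot - np.minimum(ztop, 0.0), 0.0)
    conc = np.where(any_col, float(concentration), 0.0)
    return GroundTruthMaps(depth_mm=depth, concentration=conc)


# ---------------------------------------------------------------------------
# surface meshes (patient-mesh surrogates)
# ---------------------------------------------------------------------------


def _mesh_column_intervals(vertices: np.ndarray, faces: np.ndarray, xy: np.ndarray):
    """Intersect vertical rays at lateral positions ``xy`` with a closed mesh.

    Returns a list (one entry per column) of sorted crossing depths; inside
    intervals are consecutive pairs (even crossing parity for a watertight
    mesh).  Implemented directly because it only needs axis-parallel rays.
    """
    tri = vertices[faces]  # (T, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    n_cols = xy.shape[0]
    crossings: list = [[] for _ in range(n_cols)]
    # 2-D edge functions of the projected triangles, evaluated per column
    d = np.stack([b[:, :2] - a[:, :2], c[:, :2] - b[:, :2], a[:, :2] - c[:, :2]])
    for j in range(n_cols):
        p = xy[j]
        e0 = d[0, :, 0] * (p[1] - a[:, 1]) - d[0, :, 1] * (p[0] - a[:, 0])
        e1 = d[1, :, 0] * (p[1] - b[:, 1]) - d[1, :, 1] * (p[0] - b[:, 0])
        e2 = d[2, :, 0] * (p[1] - c[:, 1]) - d[2, :, 1] * (p[0] - c[:, 0])
        hit = ((e0 >= 0) & (e1 >= 0) & (e2 >= 0)) | ((e0 <= 0) & (e1 <= 0) & (e2 <= 0))
        idx = np.nonzero(hit)[0]
        if idx.size == 0:
            continue
        # barycentric interpolation of z on the triangle plane
        ta, tb, tc = a[idx], b[idx], c[idx]
        det = (tb[:, 0] - ta[:, 0]) * (tc[:, 1] - ta[:, 1]) - (
            tc[:, 0] - ta[:, 0]
        ) * (tb[:, 1] - ta[:, 1])
        ok = np.abs(det) > 1e-12
        if not ok.any():
            continue
        ta, tb, tc, det = ta[ok], tb[ok], tc[ok], det[ok]
        w1 = ((p[0] - ta[:, 0]) * (tc[:, 1] - ta[:, 1]) - (tc[:, 0] - ta[:, 0]) * (p[1] - ta[:, 1])) / det
        w2 = ((tb[:, 0] - ta[:, 0]) * (p[1] - ta[:, 1]) - (p[0] - ta[:, 0]) * (tb[:, 1] - ta[:, 1])) / det
        z = ta[:, 2] + w1 * (tb[:, 2] - ta[:, 2]) + w2 * (tc[:, 2] - ta[:, 2])
        crossings[j] = sorted(z.tolist())
    return crossings


def voxelize_mesh(mesh, grid: GridSpec = DEFAULT_GRID, provenance: dict | None = None) -> ShapeVolume:
    """Voxelize a watertight surface mesh by vertical-ray crossing parity."""
    import trimesh as _trimesh

    if not isinstance(mesh, _trimesh.Trimesh):
        mesh = _trimesh.Trimesh(vertices=np.asarray(mesh[0]), faces=np.asarray(mesh[1]))
    if not mesh.is_watertight:
        raise ValueError("mesh is not watertight (open boundary or duplicate faces)")
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces)
    occ = np.zeros((grid.nx, grid.ny, grid.nz), dtype=bool)
    xmin, ymin = verts[:, 0].min(), verts[:, 1].min()
    xmax, ymax = verts[:, 0].max(), verts[:, 1].max()
    ix = np.nonzero((grid.x_mm >= xmin) & (grid.x_mm <= xmax))[0]
    iy = np.nonzero((grid.y_mm >= ymin) & (grid.y_mm <= ymax))[0]
    if ix.size == 0 or iy.size == 0:
        return ShapeVolume(grid=grid, occupancy=occ, provenance=provenance or {})
    # tiny lateral jitter avoids rays passing exactly through mesh edges
    eps = 1e-7
    cols = np.array([(grid.x_mm[i] + eps, grid.y_mm[j] + eps) for i in ix for j in iy])
    crossings = _mesh_column_intervals(verts, faces, cols)
    zc = grid.z_mm
    k = 0
    for i in ix:
        for j in iy:
            zs = crossings[k]
            k += 1
            if len(zs) < 2:
                continue
            if len(zs) % 2 == 1:  # degenerate grazing hit; drop the closest pair
                zs = zs[:-1]
            inside = np.zeros(grid.nz, dtype=bool)
            for lo, hi in zip(zs[0::2], zs[1::2]):
                inside |= (zc >= lo) & (zc <= hi)
            occ[i, j] = inside
    return ShapeVolume(grid=grid, occupancy=occ, provenance=provenance or {})


def augment_mesh(
    mesh,
    scale_xyz: Sequence[float],
    rot_z_deg: float,
    grid: GridSpec = DEFAULT_GRID,
) -> ShapeVolume:
    """Scale a patient-style mesh per axis, rotate about z, and voxelize.

    Protrusion above the surface (z < 0) is preserved -- patient meshes are
    not cut, and their depth maps use the protruding-apex rule.
    """
    import trimesh as _trimesh

    if not isinstance(mesh, _trimesh.Trimesh):
        raise TypeError("expected a trimesh.Trimesh")
    if not mesh.is_watertight:
        raise ValueError("mesh is not watertight (open boundary or duplicate faces)")
    sx, sy, sz = scale_xyz
    ang = np.deg2rad(rot_z_deg)
    cz, s = np.cos(ang), np.sin(ang)
    rz = np.array([[cz, -s, 0], [s, cz, 0], [0, 0, 1]], dtype=float)
    verts = (rz @ np.asarray(mesh.vertices, dtype=float).T).T * np.array([sx, sy, sz])
    out = _trimesh.Trimesh(vertices=verts, faces=np.asarray(mesh.faces), process=False)
    return voxelize_mesh(
        out,
        grid,
        provenance={
            "family": "mesh",
            "scale_xyz": (float(sx), float(sy), float(sz)),
            "rot_z_deg": float(rot_z_deg),
        },
    )


def synthetic_tumor_mesh(rng: np.random.Generator, protrude_mm: float = 1.0):
    """Synthetic stand-in for a contoured tongue-tumor surface mesh.

    Patient MRI contours are not publicly available, so this builds a
    watertight surrogate: an icosphere perturbed radially by two random
    low-order real spherical harmonics, flattened along z, and positioned so
    a small cap protrudes above the surface plane (z < 0), exercising the
    same protruding-tumor code paths as a contoured mesh.
    """
    import trimesh as _trimesh

    base = _trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    v = np.asarray(base.vertices, dtype=float)
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    bump = np.zeros_like(r)
    for _ in range(2):
        l = int(rng.integers(2, 7))
        m = int(rng.integers(-l, l + 1))
        amp = rng.uniform(0.08, 0.2)
        y = real_sph_harm(l, m, theta, phi)
        bump += amp * y / _sph_harm_max_abs(l, m)
    v = v * (1.0 + bump)[:, None]
    v[:, 2] *= rng.uniform(0.5, 0.8)  # oral tumors are wider than deep
    v[:, 2] -= v[:, 2].min() + protrude_mm  # apex protrudes above the surface
    return _trimesh.Trimesh(vertices=v, faces=np.asarray(base.faces), process=False)


# ---------------------------------------------------------------------------
# random draws (training distributions)
# ---------------------------------------------------------------------------


def random_cylinder(rng: np.random.Generator, grid: GridSpec = DEFAULT_GRID) -> ShapeVolume:
    shape = make_cylinder(rng.uniform(*WIDTH_RANGE_MM), rng.uniform(*DEPTH_RANGE_MM), grid)
    return shape


def _random_sh_params(rng: np.random.Generator) -> SphericalHarmonicParams:
    l = int(rng.integers(SH_ORDER_RANGE[0], SH_ORDER_RANGE[1] + 1))
    m = int(rng.integers(-l, l + 1))
    amp = rng.uniform(*SH_AMPLITUDE_RANGE)
    return SphericalHarmonicParams(l=l, m=m, amplitude=amp)


def random_spherical_harmonic(
    rng: np.random.Generator, grid: GridSpec = DEFAULT_GRID
) -> ShapeVolume:
    params = _random_sh_params(rng)
    wx, wy = rng.uniform(*WIDTH_RANGE_MM, size=2)
    d = rng.uniform(*DEPTH_RANGE_MM)
    sx, sy, sz = sh_scale_for_targets(params, wx, wy, d)
    for _ in range(3):
        shape = make_spherical_harmonic(params, (sx, sy, sz), grid)
        mx, my = footprint_width_mm(shape)
        md = max_depth_mm(shape)
        lo_w, hi_w = WIDTH_RANGE_MM
        lo_d, hi_d = DEPTH_RANGE_MM
        if lo_w <= mx <= hi_w and lo_w <= my <= hi_w and lo_d <= md <= hi_d:
            break
        # voxel quantization can nudge the measured extent outside the
        # training range near its endpoints; nudge the scales back
        sx *= wx / max(mx, grid.pixel_mm)
        sy *= wy / max(my, grid.pixel_mm)
        sz *= d / max(md, grid.dz_mm)
    shape.provenance.update({"targets_mm": (wx, wy, d)})
    return shape


def random_csh(
    rng: np.random.Generator, grid: GridSpec = DEFAULT_GRID, max_retries: int = 20
) -> ShapeVolume:
    """Draw one composite spherical harmonic from the training distribution.

    Rotations about X and Y are limited to +/-30 deg (shape stays roughly
    surface-facing), rotation about Z spans the full circle, and the downward
    z-shift of 0-2 mm buries part of the top surface.
    """
    for _ in range(max_retries):
        params = CSHParams(
            quadrants=tuple(_random_sh_params(rng) for _ in range(4)),
            c1_mm2=rng.uniform(4.0, 50.0),
            c2_mm2=-rng.uniform(4.0, 50.0),
            rot_x_deg=rng.uniform(-30.0, 30.0),
            rot_y_deg=rng.uniform(-30.0, 30.0),
            rot_z_deg=rng.uniform(-180.0, 180.0),
            z_shift_mm=rng.uniform(0.0, 2.0),
            target_width_x_mm=rng.uniform(*WIDTH_RANGE_MM),
            target_width_y_mm=rng.uniform(*WIDTH_RANGE_MM),
            target_depth_mm=rng.uniform(*DEPTH_RANGE_MM),
        )
        try:
            return make_csh(params, grid)
        except EmptyShapeError:
            continue
    raise EmptyShapeError(f"no valid CSH after {max_retries} draws")


# ---------------------------------------------------------------------------
# measurements and IO
# ---------------------------------------------------------------------------


def footprint_width_mm(shape: ShapeVolume) -> tuple:
    """Axis-aligned bounding-box side lengths (mm) of the tumor footprint."""
    fp = shape.footprint
    if not fp.any():
        return (0.0, 0.0)
    ix = np.nonzero(fp.any(axis=1))[0]
    iy = np.nonzero(fp.any(axis=0))[0]
    p = shape.grid.pixel_mm
    # center-to-center span: boundary voxels whose centers sit exactly on the
    # surface are counted without adding the half-voxel overhang on each side
    return (float((ix[-1] - ix[0]) * p), float((iy[-1] - iy[0]) * p))


def max_depth_mm(shape: ShapeVolume, allow_protrusion: bool = False) -> float:
    """Maximum of the ground-truth depth map (mm)."""
    if not shape.occupancy.any():
        return 0.0
    gt = ground_truth_maps(shape, 1.0, allow_protrusion=allow_protrusion)
    return float(gt.depth_mm.max())


def save_volume(path, shape: ShapeVolume) -> None:
    """Persist occupancy + grid metadata as a compressed lattice container."""
    import json

    np.savez_compressed(
        path,
        occupancy=np.packbits(shape.occupancy),
        shape=np.array(shape.occupancy.shape),
        grid=np.frombuffer(json.dumps(shape.grid.to_dict()).encode(), dtype=np.uint8),
        provenance=np.frombuffer(
            json.dumps(shape.provenance, default=str).encode(), dtype=np.uint8
        ),
    )


def load_volume(path) -> ShapeVolume:
    import json

    with np.load(path) as f:
        dims = tuple(f["shape"])
        occ = np.unpackbits(f["occupancy"])[: int(np.prod(dims))].reshape(dims).astype(bool)
        grid = GridSpec.from_dict(json.loads(f["grid"].tobytes().decode()))
        prov = json.loads(f["provenance"].tobytes().decode())
    return ShapeVolume(grid=grid, occupancy=occ, provenance=prov)


def shape_to_mesh(shape: ShapeVolume):
    """Triangulate the occupancy surface (marching cubes) for STL export."""
    import trimesh as _trimesh
    from skimage import measure

    vol = np.pad(shape.occupancy.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5)
    g = shape.grid
    verts = (verts - 1) * np.array([g.pixel_mm, g.pixel_mm, g.dz_mm])
    verts[:, 0] += g.x_mm[0]
    verts[:, 1] += g.y_mm[0]
    verts[:, 2] += g.z_mm[0]
    return _trimesh.Trimesh(vertices=verts, faces=faces, process=False)
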