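"""Diffusion-theory SFDI forward simulator.

Implements the standard spatial-frequency-domain closed forms for a
homogeneous semi-infinite turbid medium with a partial-current (extrapolated)
boundary:

* calibrated diffuse reflectance ``Rd(fx)``;
* the 1-D modulated planar-source excitation fluence ``phi(z; fx)``;
* a dipole image-source escape kernel ``E(rho, z)`` for emitted fluorescence;

and a first-Born perturbation sum over the voxelized tumor that produces the
fluorescence image stack across the six acquisition frequencies, with Poisson
shot noise.  Emission-wavelength optical properties are taken equal to the
excitation properties (single-property simplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .grid import GridSpec
from .shapes import GroundTruthMaps, ShapeVolume, ground_truth_maps

__all__ = [
    "SPATIAL_FREQUENCIES_MM",
    "LUT_FREQUENCIES_MM",
    "OpticalProperties",
    "FluorophoreSpec",
    "SFDIStack",
    "diffuse_reflectance",
    "excitation_fluence",
    "emission_escape",
    "emission_escape_plane",
    "simulate_fluorescence",
    "simulate_sample",
    "add_poisson_noise",
]

#: The six acquisition spatial frequencies (mm^-1).
SPATIAL_FREQUENCIES_MM = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
#: The two frequencies used for lookup-table property inversion (mm^-1).
LUT_FREQUENCIES_MM = (0.0, 0.2)

MU_A_RANGE = (0.0015, 0.015)  # mm^-1, training range
MU_S_PRIME_RANGE = (0.75, 2.0)  # mm^-1, training range
CONCENTRATION_RANGE = (1.0, 10.0)  # ug/mL, training range

DEFAULT_PHOTON_BUDGET = 1.0e4  # expected counts at the brightest pixel
_KERNEL_TRUNCATION = 1.0e-6  # escape kernel cut relative to its on-axis value


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced scattering (mm^-1) of the background medium."""

    mu_a: float
    mu_s_prime: float
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("optical properties must be positive")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_tr(self) -> float:
        return self.mu_a + self.mu_s_prime

    @property
    def a_prime(self) -> float:
        """Reduced albedo mu_s' / mu_tr."""
        return self.mu_s_prime / self.mu_tr

    @property
    def mu_eff(self) -> float:
        return float(np.sqrt(3.0 * self.mu_a * self.mu_tr))

    @property
    def r_eff(self) -> float:
        """Effective internal reflection coefficient (index-mismatch polynomial)."""
        n = self.n
        return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2

    @property
    def boundary_a(self) -> float:
        """Boundary coefficient A = (1 - R_eff) / (2 (1 + R_eff))."""
        return (1.0 - self.r_eff) / (2.0 * (1.0 + self.r_eff))

    @property
    def diffusion_d(self) -> float:
        """Diffusion coefficient D = 1 / (3 mu_tr), mm."""
        return 1.0 / (3.0 * self.mu_tr)

    @property
    def z_b(self) -> float:
        """Extrapolated boundary distance 2 D (1 + R_eff)/(1 - R_eff), mm."""
        return 2.0 * self.diffusion_d * (1.0 + self.r_eff) / (1.0 - self.r_eff)

    def mu_eff_prime(self, fx) -> np.ndarray:
        """Frequency-augmented attenuation sqrt(mu_eff^2 + (2 pi fx)^2)."""
        fx = np.asarray(fx, dtype=float)
        return np.sqrt(self.mu_eff**2 + (2.0 * np.pi * fx) ** 2)


@dataclass(frozen=True)
class FluorophoreSpec:
    """PpIX-like fluorophore: quantum efficiency and concentration scaling.

    ``epsilon_c`` converts concentration (ug/mL) to fluorophore absorption
    mu_af (mm^-1); its absolute value only sets the (arbitrary) fluorescence
    units, which cancel between simulation and network training.
    """

    concentration: float  # ug/mL
    eta: float = 0.046
    epsilon_c: float = 0.02  # mm^-1 per ug/mL

    def __post_init__(self) -> None:
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("quantum efficiency must be in (0, 1]")
        if self.concentration < 0 or self.epsilon_c < 0:
            raise ValueError("concentration and epsilon_c must be non-negative")

    @property
    def mu_af(self) -> float:
        return self.epsilon_c * self.concentration


@dataclass
class SFDIStack:
    """Reflectance + fluorescence images across the acquisition frequencies."""

    fx: tuple
    reflectance: np.ndarray  # (n_fx, nx, ny), calibrated diffuse reflectance
    fluorescence: np.ndarray  # (n_fx, nx, ny), calibrated (arbitrary) units
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reflectance.shape != self.fluorescence.shape:
            raise ValueError("reflectance/fluorescence shapes differ")
        if self.reflectance.shape[0] != len(self.fx):
            raise ValueError("frame count does not match fx list")

    def frame(self, channel: str, fx: float) -> np.ndarray:
        """Image for one channel at one spatial frequency."""
        idx = [i for i, f in enumerate(self.fx) if abs(f - fx) < 1e-9]
        if not idx:
            raise KeyError(f"no frame at fx={fx} (have {self.fx})")
        return getattr(self, channel)[idx[0]]


# ---------------------------------------------------------------------------
# closed-form diffusion kernels
# ---------------------------------------------------------------------------


def diffuse_reflectance(props: OpticalProperties, fx) -> np.ndarray:
    """Calibrated diffuse reflectance at spatial frequency fx (mm^-1)."""
    a = props.boundary_a
    r = props.mu_eff_prime(fx) / props.mu_tr
    rd = 3.0 * a * props.a_prime / ((r + 1.0) * (r + 3.0 * a))
    return rd if rd.ndim else float(rd)


def excitation_fluence(z, fx: float, props: OpticalProperties, p0: float = 1.0):
    """Excitation fluence of a modulated planar source at depth z (mm).

    Solution of the 1-D diffusion equation with source mu_s' exp(-mu_tr z)
    and partial-current boundary; fx enters through the frequency-augmented
    attenuation.  The removable singularity at mu_eff' = mu_tr is handled by
    its analytic limit.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0 (inside the tissue)")
    a = props.boundary_a
    mu_tr = props.mu_tr
    r = float(props.mu_eff_prime(fx)) / mu_tr
    if abs(r - 1.0) < 1.0e-9:
        out = (
            3.0 * p0 * props.a_prime / 2.0
            * (1.0 / (1.0 + 3.0 * a) + mu_tr * z)
            * np.exp(-mu_tr * z)
        )
    else:
        b = (3.0 * a + 1.0) / (r + 3.0 * a)
        out = (
            3.0 * p0 * props.a_prime / (r**2 - 1.0)
            * (np.exp(-mu_tr * z) - b * np.exp(-r * mu_tr * z))
        )
    return out if out.ndim else float(out)


def emission_escape(rho, z, props: OpticalProperties):
    """Surface-escape kernel of an isotropic emitter at depth z, offset rho.

    Dipole (image-source) construction across the extrapolated boundary: the
    escaping signal is proportional to the surface fluence of the source at
    +z minus its image at -(z + 2 z_b).  Units are relative (one calibration
    constant for the whole fluorescence channel).
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0")
    d = props.diffusion_d
    mu = props.mu_eff
    r1 = np.maximum(np.sqrt(rho**2 + z**2), 1.0e-6)
    r2 = np.sqrt(rho**2 + (z + 2.0 * props.z_b) ** 2)
    out = (np.exp(-mu * r1) / r1 - np.exp(-mu * r2) / r2) / (4.0 * np.pi * d)
    return out if out.ndim else float(out)


def emission_escape_plane(z, props: OpticalProperties):
    """Lateral integral of the escape kernel over the whole plane.

    Closed form used by the homogeneous-slab limit of the Born sum:
    integral of exp(-mu r)/(4 pi D r) over the plane at depth z equals
    exp(-mu z) / (2 D mu).
    """
    z = np.asarray(z, dtype=float)
    d, mu = props.diffusion_d, props.mu_eff
    out = (np.exp(-mu * z) - np.exp(-mu * (z + 2.0 * props.z_b))) / (2.0 * d * mu)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Born-perturbation fluorescence
# ---------------------------------------------------------------------------


_GAUSS_NODES, _GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(5)


def _slice_mean_fluence(z: float, dz: float, fx: float, props: OpticalProperties):
    """Average excitation fluence over a voxel slice [z - dz/2, z + dz/2].

    The fluence decays on the transport length (as short as ~0.5 mm), so a
    midpoint sample would bias the per-slice Born weight by a few percent;
    a 5-point Gauss average makes the depth quadrature effectively exact.
    """
    lo = max(z - dz / 2.0, 0.0)
    hi = z + dz / 2.0
    zz = 0.5 * (hi - lo) * _GAUSS_NODES + 0.5 * (hi + lo)
    return float(np.dot(_GAUSS_WEIGHTS, excitation_fluence(zz, fx, props)) / 2.0)


def _escape_kernel_image(z: float, props: OpticalProperties, grid: GridSpec):
    """Escape kernel sampled on the lateral offset lattice, truncated."""
    p = grid.pixel_mm
    off_x = np.arange(-(grid.nx - 1), grid.nx) * p
    off_y = np.arange(-(grid.ny - 1), grid.ny) * p
    rho = np.hypot(off_x[:, None], off_y[None, :])
    k = emission_escape(rho, z, props)
    k[k < _KERNEL_TRUNCATION * emission_escape(0.0, z, props)] = 0.0
    return k


def simulate_fluorescence(
    shape: ShapeVolume,
    props: OpticalProperties,
    fluor: FluorophoreSpec,
    fx: Sequence[float] = SPATIAL_FREQUENCIES_MM,
    bg_fraction: float = 0.0,
) -> np.ndarray:
    """First-Born fluorescence images (n_fx, nx, ny), noiseless.

    F(rho_d; fx) = eta * sum_r mu_af(r) phi(z_r; fx) E(|rho_d - rho_r|, z_r) dV
    with mu_af = epsilon_c * C inside the tumor and bg_fraction times that in
    the healthy tissue (z >= 0) outside it.  The sum is evaluated per depth
    slice as a lateral FFT convolution; because the escape kernel does not
    depend on fx, each slice costs one convolution shared by all frequencies.
    """
    if not (0.0 <= bg_fraction <= 0.5):
        raise ValueError("bg_fraction must be in [0, 0.5]")
    grid = shape.grid
    fx = np.asarray(fx, dtype=float)
    out = np.zeros((fx.size, grid.nx, grid.ny))
    if fluor.mu_af == 0.0:
        return out
    zs = grid.z_mm
    occ = shape.occupancy
    dv = grid.voxel_volume_mm3
    for iz in np.nonzero(zs >= 0)[0]:
        z = float(zs[iz])
        sl = occ[:, :, iz].astype(float)
        if bg_fraction > 0.0:
            sl = sl + bg_fraction * (1.0 - sl)
        elif not sl.any():
            continue
        mu_af_slice = fluor.mu_af * sl
        kernel = _escape_kernel_image(z, props, grid)
        conv = fftconvolve(mu_af_slice, kernel, mode="same")
        phi = np.array([_slice_mean_fluence(z, grid.dz_mm, f, props) for f in fx])
        out += phi[:, None, None] * conv[None]
    out *= fluor.eta * dv
    return np.maximum(out, 0.0)


def add_poisson_noise(
    image: np.ndarray, photon_budget: float, rng: np.random.Generator
) -> np.ndarray:
    """Shot noise: scale the peak to ``photon_budget`` expected counts,
    Poisson-sample, and rescale.  An all-zero image is returned unchanged."""
    if photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    peak = float(image.max())
    if peak == 0.0:
        return image.copy()
    scale = photon_budget / peak
    return rng.poisson(image * scale).astype(float) / scale


def simulate_sample(
    shape: ShapeVolume,
    props: OpticalProperties,
    fluor: FluorophoreSpec,
    rng: np.random.Generator,
    fx: Sequence[float] = SPATIAL_FREQUENCIES_MM,
    photon_budget: float = DEFAULT_PHOTON_BUDGET,
    bg_fraction: float = 0.0,
    allow_protrusion: bool = False,
) -> tuple:
    """Simulate one training/test sample: SFDI stack + ground-truth maps.

    Reflectance frames are the homogeneous-medium Rd(fx), spatially flat
    before noise (per-sample constant optical properties); fluorescence comes
    from the Born sum.  Poisson shot noise is applied to both channels.
    Pass ``photon_budget=None`` (or inf) for a noiseless stack.
    """
    grid = shape.grid
    fx = tuple(float(f) for f in fx)
    refl = np.empty((len(fx), grid.nx, grid.ny))
    for i, f in enumerate(fx):
        refl[i] = diffuse_reflectance(props, f)
    fluo = simulate_fluorescence(shape, props, fluor, fx, bg_fraction)
    noiseless = photon_budget is None or not np.isfinite(photon_budget)
    if not noiseless:
        refl = np.stack([add_poisson_noise(f, photon_budget, rng) for f in refl])
        fluo = np.stack([add_poisson_noise(f, photon_budget, rng) for f in fluo])
    gt = ground_truth_maps(shape, fluor.concentration, allow_protrusion)
    if bg_fraction > 0.0:
        conc = gt.concentration.copy()
        conc[conc == 0.0] = bg_fraction * fluor.concentration
        gt = GroundTruthMaps(depth_mm=gt.depth_mm, concentration=conc)
    stack = SFDIStack(
        fx=fx,
        reflectance=refl,
        fluorescence=fluo,
        meta={
            "mu_a": props.mu_a,
            "mu_s_prime": props.mu_s_prime,
            "n": props.n,
            "concentration": fluor.concentration,
            "eta": fluor.eta,
            "epsilon_c": fluor.epsilon_c,
            "bg_fraction": bg_fraction,
            "photon_budget": None if noiseless else photon_budget,
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# stack IO: multi-frame TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def save_stack(path, stack: SFDIStack) -> None:
    """Write the stack as multi-frame TIFF (reflectance frames then
    fluorescence frames) with a JSON sidecar holding fx and metadata."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    frames = np.concatenate([stack.reflectance, stack.fluorescence]).astype(np.float64)
    tifffile.imwrite(path, frames)
    sidecar = {"fx": list(stack.fx), "meta": stack.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_stack(path) -> SFDIStack:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    n = len(sidecar["fx"])
    return SFDIStack(
        fx=tuple(sidecar["fx"]),
        reflectance=frames[:n],
        fluorescence=frames[n:],
        meta=sidecar["meta"],
    )
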