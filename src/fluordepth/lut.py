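"""Two-frequency SFDI lookup-table inversion for optical properties.

A dense grid of (mu_a, mu_s') pairs is forward-simulated to reflectance at
fx = 0 and 0.2 mm^-1; per-pixel inversion interpolates the inverse map in
measurement space (Delaunay-triangulated linear interpolation).  Measurement
pairs outside the tabulated image set are clamped to the nearest tabulated
node and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .optics import (
    LUT_FREQUENCIES_MM,
    MU_A_RANGE,
    MU_S_PRIME_RANGE,
    OpticalProperties,
    SFDIStack,
    diffuse_reflectance,
)

__all__ = ["LUT", "build_lut", "invert_pixel", "optical_property_maps", "OpticalPropertyMaps"]

# default tabulated domain: a little wider than the training property box so
# shot-noise scatter around in-range pixels still inverts without clamping
DEFAULT_MU_A_SPAN = (0.0010, 0.020)
DEFAULT_MU_S_SPAN = (0.60, 2.40)


@dataclass
class LUT:
    """Tabulated forward map (mu_a, mu_s') -> (Rd at fx=0, Rd at fx=0.2)."""

    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    rd0: np.ndarray  # (n_mu_a, n_mu_s)
    rd1: np.ndarray
    n: float = 1.4
    fx: tuple = LUT_FREQUENCIES_MM
    _interp_a: LinearNDInterpolator | None = field(default=None, repr=False)
    _interp_s: LinearNDInterpolator | None = field(default=None, repr=False)
    _tree: cKDTree | None = field(default=None, repr=False)

    @property
    def measurement_points(self) -> np.ndarray:
        return np.column_stack([self.rd0.ravel(), self.rd1.ravel()])

    @property
    def property_points(self) -> np.ndarray:
        aa, ss = np.meshgrid(self.mu_a_grid, self.mu_s_grid, indexing="ij")
        return np.column_stack([aa.ravel(), ss.ravel()])

    def _ensure_interpolators(self) -> None:
        if self._interp_a is None:
            pts = self.measurement_points
            vals = self.property_points
            self._interp_a = LinearNDInterpolator(pts, vals[:, 0])
            # reuse the triangulation built for the first interpolant
            self._interp_s = LinearNDInterpolator(self._interp_a.tri, vals[:, 1])
            self._tree = cKDTree(pts)

    def save(self, path) -> None:
        header = {
            "n": self.n,
            "fx": list(self.fx),
            "shape": list(self.rd0.shape),
        }
        np.savez_compressed(
            path,
            mu_a_grid=self.mu_a_grid,
            mu_s_grid=self.mu_s_grid,
            rd0=self.rd0,
            rd1=self.rd1,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "LUT":
        with np.load(path) as f:
            header = json.loads(f["header"].tobytes().decode())
            return cls(
                mu_a_grid=f["mu_a_grid"],
                mu_s_grid=f["mu_s_grid"],
                rd0=f["rd0"],
                rd1=f["rd1"],
                n=header["n"],
                fx=tuple(header["fx"]),
            )


def build_lut(
    mu_a_span: tuple = DEFAULT_MU_A_SPAN,
    mu_s_span: tuple = DEFAULT_MU_S_SPAN,
    resolution: int = 200,
    n: float = 1.4,
    check_injectivity: bool = True,
) -> LUT:
    """Tabulate the forward reflectance map on a dense property grid.

    The map must be injective for the inverse interpolation to be well posed;
    this is verified by checking that every tabulated node's nearest neighbour
    in (Rd0, Rd0.2) space is one of its grid neighbours (a fold in the map
    would bring distant property pairs close together in measurement space).
    """
    if resolution < 2:
        raise ValueError("LUT grid must have at least 2 nodes per axis")
    if mu_a_span[0] > MU_A_RANGE[0] or mu_a_span[1] < MU_A_RANGE[1]:
        raise ValueError("mu_a span must cover the training range")
    if mu_s_span[0] > MU_S_PRIME_RANGE[0] or mu_s_span[1] < MU_S_PRIME_RANGE[1]:
        raise ValueError("mu_s' span must cover the training range")
    mu_a = np.linspace(*mu_a_span, resolution)
    mu_s = np.linspace(*mu_s_span, resolution)
    rd0 = np.empty((resolution, resolution))
    rd1 = np.empty_like(rd0)
    for i, a in enumerate(mu_a):
        for j, s in enumerate(mu_s):
            props = OpticalProperties(a, s, n)
            rd0[i, j] = diffuse_reflectance(props, LUT_FREQUENCIES_MM[0])
            rd1[i, j] = diffuse_reflectance(props, LUT_FREQUENCIES_MM[1])
    lut = LUT(mu_a_grid=mu_a, mu_s_grid=mu_s, rd0=rd0, rd1=rd1, n=n)
    if check_injectivity:
        _check_injectivity(lut)
    return lut


def _check_injectivity(lut: LUT) -> None:
    pts = lut.measurement_points
    nn = pts.shape[0]
    res_a = lut.mu_a_grid.size
    res_s = lut.mu_s_grid.size
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=2)
    neigh = idx[:, 1]
    i0, j0 = np.divmod(np.arange(nn), res_s)
    i1, j1 = np.divmod(neigh, res_s)
    bad = (np.abs(i0 - i1) > 1) | (np.abs(j0 - j1) > 1)
    if bad.any():
        pairs = list(zip(np.nonzero(bad)[0][:5].tolist(), neigh[bad][:5].tolist()))
        raise ValueError(
            f"LUT forward map is not injective: {bad.sum()} nodes have a "
            f"non-adjacent nearest neighbour in measurement space, e.g. {pairs}"
        )


def invert_pixel(rd0: float, rd1: float, lut: LUT) -> tuple:
    """Invert one (Rd0, Rd0.2) pair -> (mu_a, mu_s', out_of_domain_flag)."""
    mu_a, mu_s, flag = _invert_array(np.atleast_1d(rd0), np.atleast_1d(rd1), lut)
    return float(mu_a[0]), float(mu_s[0]), bool(flag[0])


def _invert_array(rd0: np.ndarray, rd1: np.ndarray, lut: LUT):
    if np.any(~np.isfinite(rd0)) or np.any(~np.isfinite(rd1)):
        raise ValueError("non-finite reflectance input")
    lut._ensure_interpolators()
    pts = np.column_stack([rd0.ravel(), rd1.ravel()])
    mu_a = lut._interp_a(pts)
    mu_s = lut._interp_s(pts)
    flag = ~np.isfinite(mu_a) | ~np.isfinite(mu_s)
    if flag.any():
        # outside the convex hull of the tabulated image: clamp to nearest node
        _, idx = lut._tree.query(pts[flag])
        props = lut.property_points[idx]
        mu_a[flag] = props[:, 0]
        mu_s[flag] = props[:, 1]
    return mu_a.reshape(rd0.shape), mu_s.reshape(rd0.shape), flag.reshape(rd0.shape)


@dataclass
class OpticalPropertyMaps:
    """Per-pixel recovered (mu_a, mu_s') with an out-of-domain flag mask."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    flag: np.ndarray


def optical_property_maps(stack: SFDIStack, lut: LUT) -> OpticalPropertyMaps:
    """LUT-invert a stack's reflectance frames at fx = 0 and 0.2 mm^-1."""
    rd0 = stack.frame("reflectance", lut.fx[0])
    rd1 = stack.frame("reflectance", lut.fx[1])
    mu_a, mu_s, flag = _invert_array(rd0, rd1, lut)
    return OpticalPropertyMaps(mu_a=mu_a, mu_s_prime=mu_s, flag=flag)
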