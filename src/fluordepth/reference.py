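"""Independent numerical references for the diffusion closed forms.

These solvers share no code with :mod:`fluordepth.optics`: the fluence and
reflectance come from a finite-difference two-point boundary-value solve of
the 1-D diffusion equation, and the slab fluorescence limit from adaptive
quadrature.  They exist to validate the closed-form kernels (and are reused
by the acceptance checks); they are far too slow to run inside the image
simulator itself.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, sparse
from scipy.sparse.linalg import spsolve

from .optics import FluorophoreSpec, OpticalProperties

__all__ = [
    "fd_fluence_profile",
    "fd_fluence",
    "fd_reflectance",
    "escape_lateral_integral",
    "slab_fluorescence_center",
]


def fd_fluence_profile(
    fx: float, props: OpticalProperties, n_nodes: int = 6000, length_mm: float | None = None
):
    """Finite-difference fluence of the modulated planar source.

    Solves -D phi'' + (mu_a + D k^2) phi = mu_s' exp(-mu_tr z) on [0, L]
    with the partial-current boundary phi(0) = 2 A_pc D phi'(0)
    (A_pc = (1 + R_eff)/(1 - R_eff), second-order one-sided derivative) and
    phi(L) = 0.  Returns (z_nodes, phi).
    """
    k = 2.0 * np.pi * fx
    d = props.diffusion_d
    mu_tr = props.mu_tr
    decay = min(props.mu_eff, mu_tr)
    length = length_mm if length_mm is not None else max(150.0, 14.0 / decay)
    z = np.linspace(0.0, length, n_nodes)
    h = z[1] - z[0]
    a_pc = (1.0 + props.r_eff) / (1.0 - props.r_eff)

    main = np.full(n_nodes, 2.0 * d / h**2 + props.mu_a + d * k**2)
    lower = np.full(n_nodes - 1, -d / h**2)
    upper = np.full(n_nodes - 1, -d / h**2)
    mat = sparse.lil_matrix(sparse.diags([lower, main, upper], [-1, 0, 1]))
    rhs = props.mu_s_prime * np.exp(-mu_tr * z)
    # boundary rows
    c = 2.0 * a_pc * d / (2.0 * h)
    mat[0, 0] = 1.0 + 3.0 * c
    mat[0, 1] = -4.0 * c
    mat[0, 2] = c
    rhs[0] = 0.0
    mat[-1, :] = 0.0
    mat[-1, -1] = 1.0
    rhs[-1] = 0.0
    phi = spsolve(sparse.csr_matrix(mat), rhs)
    return z, phi


def fd_fluence(z_eval, fx: float, props: OpticalProperties, **kw):
    """Finite-difference fluence interpolated at the requested depths."""
    z, phi = fd_fluence_profile(fx, props, **kw)
    return np.interp(np.asarray(z_eval, dtype=float), z, phi)


def fd_reflectance(fx: float, props: OpticalProperties, **kw) -> float:
    """Diffuse reflectance from the finite-difference fluence.

    Escaping flux (1 - R_eff) * (phi(0)/4 + D phi'(0)/2) per unit incident
    power -- evaluated from the numerical solution, not the closed form.
    """
    z, phi = fd_fluence_profile(fx, props, **kw)
    h = z[1] - z[0]
    dphi0 = (-3.0 * phi[0] + 4.0 * phi[1] - phi[2]) / (2.0 * h)
    return float(
        (1.0 - props.r_eff) * (phi[0] / 4.0 + props.diffusion_d * dphi0 / 2.0)
    )


def escape_lateral_integral(z: float, props: OpticalProperties) -> float:
    """2 pi * integral of rho * E(rho, z) d rho by adaptive quadrature."""
    from .optics import emission_escape

    val, _ = integrate.quad(
        lambda rho: rho * emission_escape(rho, z, props),
        0.0,
        np.inf,
        limit=200,
    )
    return float(2.0 * np.pi * val)


def slab_fluorescence_center(
    depth_mm: float,
    fx: float,
    props: OpticalProperties,
    fluor: FluorophoreSpec,
) -> float:
    """Center-pixel fluorescence of a laterally infinite surface slab.

    For a slab of thickness d the Born sum collapses to the 1-D integral
    eta * mu_af * int_0^d phi(z; fx) E_plane(z) dz, with E_plane the lateral
    integral of the escape kernel.  Both factors are evaluated by quadrature.
    """
    from .optics import emission_escape_plane, excitation_fluence

    val, _ = integrate.quad(
        lambda z: excitation_fluence(z, fx, props) * emission_escape_plane(z, props),
        0.0,
        depth_mm,
        limit=200,
    )
    return float(fluor.eta * fluor.mu_af * val)
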