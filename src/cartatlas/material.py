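"""Fibril-reinforced poroviscoelastic (FRPVE) cartilage material.

The total stress of the mixture is

    sigma_t = sigma_nf + sigma_f - p * I

where ``sigma_nf`` is the effective stress of the porous non-fibrillar
matrix (compressible neo-Hookean, parameterized by its small-strain
modulus ``E_m`` and Poisson ratio ``nu_m``), ``sigma_f`` is the summed
tension-only stress of the collagen fibril network, and ``p`` is the
interstitial fluid (pore) pressure.

Fibril law (adopted form; the constitutive split is standard in the FRPVE
literature). Each fibril direction carries a uniaxial stress built from

* an equilibrium spring with strain-dependent tangent modulus
  ``E_0 + E_eps * eps`` i.e. stress ``sigma_eq(eps) = E_0*eps
  + 0.5*E_eps*eps**2`` for tensile strain ``eps > 0``, zero otherwise, and
* a Maxwell branch (spring of the same tangent modulus in series with a
  damper ``eta``) carrying the viscous overstress ``sigma_v`` with

      d(sigma_v)/dt = E_br(eps) * d(eps+)/dt - (E_br(eps)/eta) * sigma_v,
      E_br = E_0 + E_eps * eps+

  integrated by backward Euler:

      sigma_v[n+1] = (sigma_v[n] + E_br * d_eps) / (1 + E_br*dt/eta).

At constant strain the overstress relaxes to zero, so the long-time
stress is the equilibrium spring alone; with ``eta = 0`` the damper
offers no resistance and the response is the purely elastic spring.
Fibrils never carry compression: the tensile clamp ``eps+ = max(eps, 0)``
feeds the whole update and the summed stress is clamped at zero.

Primary fibrils follow the depth-dependent Benninghoff arcade (parallel
to the split lines at the articular surface, perpendicular to the bone
at full depth); 13 secondary fibrils take fixed quasi-uniform
orientations. A primary fibril is ``primary_density_ratio`` times as
dense as a secondary one; the per-fibril weights are normalized to sum
to one so (E_0, E_eps) are network-aggregate moduli.

Units: MPa, mm, s, N. Permeability is stored in the conventional
1e-15 m^4/(N s) and converted to mm^4/(N s) on access
(1e-15 m^4/(N s) = 1e-3 mm^4/(N s)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "FRPVEParams", "MaterialPointState", "FEMORAL", "TIBIAL",
    "fluid_fraction", "primary_fibril_directions", "secondary_fibril_directions",
    "fibril_stress_update", "nonfibrillar_stress", "total_stress",
    "load_material_config",
]


@dataclass(frozen=True)
class FRPVEParams:
    e_m: float            # nonfibrillar matrix modulus, MPa
    e_0: float            # initial fibril network modulus, MPa
    e_eps: float          # strain-dependent fibril network modulus, MPa
    nu_m: float           # Poisson ratio of the nonfibrillar matrix
    eta: float            # fibril viscoelastic damping coefficient, MPa s
    k_perm: float         # permeability, 1e-15 m^4/(N s)
    n_f_surface: float = 0.8
    n_f_slope: float = 0.15
    n_secondary: int = 13
    primary_density_ratio: float = 3.0
    linear_matrix: bool = False  # exact Hooke matrix (linear-elastic limit)

    def __post_init__(self):
        if self.e_m <= 0 or self.k_perm <= 0:
            raise ValueError("e_m and k_perm must be > 0")
        if not (0.0 <= self.nu_m < 0.5):
            raise ValueError("nu_m must be in [0, 0.5)")
        if self.e_0 < 0 or self.e_eps < 0 or self.eta < 0:
            raise ValueError("fibril moduli and eta must be >= 0")

    @property
    def k_mm(self) -> float:
        """Permeability in mm^4/(N s)."""
        return self.k_perm * 1e-3

    @property
    def lame(self) -> tuple[float, float]:
        """Small-strain Lame constants (lam, mu) of the matrix, MPa."""
        e, nu = self.e_m, self.nu_m
        return (e * nu / ((1 + nu) * (1 - 2 * nu)), e / (2 * (1 + nu)))


# Defaults: femoral and tibial cartilage parameter sets.
FEMORAL = FRPVEParams(e_m=0.215, e_0=0.92, e_eps=150.0, nu_m=0.15,
                      eta=1062.0, k_perm=6.0)
TIBIAL = FRPVEParams(e_m=0.106, e_0=0.18, e_eps=23.06, nu_m=0.15,
                     eta=1062.0, k_perm=18.0)


@dataclass
class MaterialPointState:
    """State of one material point between stress updates."""

    strain: np.ndarray                # symmetric 3x3
    pore_pressure: float              # MPa
    depth: float                      # normalized depth h_z in [0, 1]
    primary_dirs: np.ndarray          # (n_p, 3) unit vectors
    secondary_dirs: np.ndarray        # (13, 3) unit vectors
    fibril_overstress: np.ndarray | None = None   # per-fibril sigma_v
    fibril_strain_prev: np.ndarray | None = None  # per-fibril clamped strain

    def n_fibrils(self) -> int:
        return len(self.primary_dirs) + len(self.secondary_dirs)


def fluid_fraction(h_z, surface: float = 0.8, slope: float = 0.15):
    """Depth-dependent fluid (water) fraction ``n_f = surface - slope*h_z``.

    ``h_z`` is normalized depth: 0 at the articular surface, 1 at the
    bone interface; defaults give 0.8 at the surface and 0.65 at depth.
    """
    h = np.asarray(h_z, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("h_z must lie in [0, 1]")
    out = surface - slope * h
    return float(out) if np.isscalar(h_z) else out


def primary_fibril_directions(h_z: float, split_line: np.ndarray,
                              surface_normal: np.ndarray,
                              tol: float = 1e-8) -> np.ndarray:
    """The two primary (arcade) fibril directions at normalized depth h_z.

    At the surface both run along the split line (opposite senses); with
    depth they bend continuously toward the surface normal, reaching it
    at the bone interface — the Benninghoff arcade.
    """
    s = np.asarray(split_line, dtype=float)
    n = np.asarray(surface_normal, dtype=float)
    s = s / np.linalg.norm(s)
    n = n / np.linalg.norm(n)
    if abs(float(s @ n)) > max(tol, 1e-6):
        raise ValueError("split_line and surface_normal must be orthogonal")
    if not (0.0 <= h_z <= 1.0):
        raise ValueError("h_z must lie in [0, 1]")
    theta = 0.5 * np.pi * h_z
    d1 = np.cos(theta) * s + np.sin(theta) * n
    d2 = -np.cos(theta) * s + np.sin(theta) * n
    return np.vstack([d1, d2])


def secondary_fibril_directions() -> np.ndarray:
    """The fixed quasi-uniform set of 13 secondary fibril directions.

    Axes (3), body diagonals (4) and face diagonals (6) of the unit cube
    — deterministic, unit-norm, pairwise non-parallel.
    """
    axes = np.eye(3)
    body = np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]],
                    dtype=float) / np.sqrt(3.0)
    face = np.array([[1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
                     [0, 1, 1], [0, 1, -1]], dtype=float) / np.sqrt(2.0)
    return np.vstack([axes, body, face])


def fibril_weights(n_primary: int, n_secondary: int,
                   ratio: float) -> np.ndarray:
    w = np.concatenate([np.full(n_primary, ratio), np.ones(n_secondary)])
    return w / w.sum()


# C1 smoothing widths for the tension-only clamps. Far above these
# scales the law is exact; the blends only round the kinks at zero
# stress / zero strain so that Newton solvers see a continuous tangent.
SMOOTH_SIGMA_MPA = 1e-3
SMOOTH_EPS = 1e-4


def _smooth_plus(x, w):
    """C1 ramp: max(x, 0) with a quadratic blend on |x| < w."""
    return np.where(x >= w, x, np.where(x <= -w, 0.0,
                                        (x + w) ** 2 / (4.0 * w)))


def _smooth_plus_d(x, w):
    return np.clip((x + w) / (2.0 * w), 0.0, 1.0)


def _smoothstep(x, w):
    t = np.clip(x / w, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _smoothstep_d(x, w):
    t = np.clip(x / w, 0.0, 1.0)
    return 6.0 * t * (1.0 - t) / w


def _fibril_parts(eps_f, state, dt, params):
    """Shared pieces of the backward-Euler fibril update.

    Returns ``(eps+, sigma_eq, sigma_v, e_br, visc)`` where ``visc`` is
    the derivative d(sigma_v)/d(eps+) of the discrete update. The
    strain-stiffening branch modulus is evaluated at the strain of the
    previous step (one-step lag): this keeps the discrete strain->stress
    map monotone with a non-negative tangent for arbitrarily large
    increments, at the cost of a modulus lag that vanishes with the step
    size. At constant strain the lag is exact, so equilibrium and
    relaxation behavior are unaffected.
    """
    eps = np.maximum(np.asarray(eps_f, dtype=float), 0.0)
    sigma_v_old, eps_prev = state
    sigma_v_old = np.asarray(sigma_v_old, dtype=float)
    eps_prev = np.asarray(eps_prev, dtype=float)
    e_br = params.e_0 + params.e_eps * eps
    sigma_eq = params.e_0 * eps + 0.5 * params.e_eps * eps ** 2
    if params.eta == 0.0:
        sigma_v = np.zeros_like(sigma_eq)
        visc = np.zeros_like(sigma_eq)
    else:
        e_lag = params.e_0 + params.e_eps * eps_prev
        denom = 1.0 + e_lag * dt / params.eta
        sigma_v = (sigma_v_old + e_lag * (eps - eps_prev)) / denom
        visc = e_lag / denom
    return eps, sigma_eq, sigma_v, e_br, visc


def fibril_stress_update(eps_f, state, dt: float, params: FRPVEParams):
    """One backward-Euler step of the fibril law for scalar or array input.

    ``state`` is ``(sigma_v, eps_prev)`` (both zero-initialized); returns
    ``(stress, new_state)``. Tension only: compressed fibrils carry zero
    stress (the clamp is C1-smoothed over a negligible width so the
    stress-strain map stays differentiable). Vectorizes over arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    eps, sigma_eq, sigma_v, _, _ = _fibril_parts(eps_f, state, dt, params)
    raw = sigma_eq + sigma_v
    stress = _smooth_plus(raw, SMOOTH_SIGMA_MPA) * \
        _smoothstep(np.asarray(eps_f, dtype=float), SMOOTH_EPS)
    if np.isscalar(eps_f):
        return float(stress), (float(sigma_v), float(eps))
    return stress, (sigma_v, eps)


def fibril_tangent(eps_f, state, dt: float, params: FRPVEParams):
    """d(stress)/d(eps) of the backward-Euler fibril update (FE tangents)."""
    eps_in = np.asarray(eps_f, dtype=float)
    eps, sigma_eq, sigma_v, e_br, visc = _fibril_parts(eps_f, state, dt,
                                                       params)
    raw = sigma_eq + sigma_v
    s = _smooth_plus(raw, SMOOTH_SIGMA_MPA)
    sd = _smooth_plus_d(raw, SMOOTH_SIGMA_MPA)
    h = _smoothstep(eps_in, SMOOTH_EPS)
    hd = _smoothstep_d(eps_in, SMOOTH_EPS)
    draw = (e_br + visc) * (eps_in > 0.0)
    return sd * draw * h + s * hd


def _strain_tensor(eps):
    eps = np.asarray(eps, dtype=float)
    if eps.shape[-2:] != (3, 3):
        raise ValueError("strain must be 3x3")
    if not np.allclose(eps, np.swapaxes(eps, -1, -2), atol=1e-10):
        raise ValueError("strain must be symmetric")
    return eps


def nonfibrillar_stress(strain, params: FRPVEParams):
    """Effective stress of the non-fibrillar matrix (batched over leading axes).

    Compressible neo-Hookean evaluated on the stretch ``U = I + eps``:
    ``sigma = mu/J (B - I) + lam ln(J)/J I`` with ``B = U @ U`` and
    ``J = det U``. At infinitesimal strain this is Hooke's law with
    (E_m, nu_m). With ``linear_matrix`` set, Hooke's law is used exactly
    (the linear-elastic limit used in solver verification).
    """
    eps = _strain_tensor(strain)
    lam, mu = params.lame
    eye = np.eye(3)
    if params.linear_matrix:
        tr = np.trace(eps, axis1=-2, axis2=-1)[..., None, None]
        return 2.0 * mu * eps + lam * tr * eye
    U = eps + eye
    J = np.linalg.det(U)[..., None, None]
    if np.any(J <= 0):
        raise ValueError("volumetric collapse: det(I + strain) <= 0")
    B = U @ U
    return mu / J * (B - eye) + lam * np.log(J) / J * eye


def total_stress(state: MaterialPointState, params: FRPVEParams, dt: float):
    """Total Cauchy stress sigma_nf + sigma_f - p*I at one material point.

    Returns ``(stress, new_state)``; the new state carries the updated
    per-fibril overstresses and clamped strains.
    """
    eps = _strain_tensor(state.strain)
    dirs = np.vstack([state.primary_dirs, state.secondary_dirs])
    nf = len(dirs)
    w = fibril_weights(len(state.primary_dirs), len(state.secondary_dirs),
                       params.primary_density_ratio)
    eps_fib = np.einsum("fi,ij,fj->f", dirs, eps, dirs)
    sv = state.fibril_overstress
    ep = state.fibril_strain_prev
    hist = (np.zeros(nf) if sv is None else sv,
            np.zeros(nf) if ep is None else ep)
    sig_f, new_hist = fibril_stress_update(eps_fib, hist, dt, params)
    sigma_f = np.einsum("f,fi,fj->ij", w * sig_f, dirs, dirs)
    sigma = (nonfibrillar_stress(eps, params) + sigma_f
             - state.pore_pressure * np.eye(3))
    new_state = replace(state, fibril_overstress=new_hist[0],
                        fibril_strain_prev=new_hist[1])
    return sigma, new_state


def load_material_config(path) -> dict[str, FRPVEParams]:
    """Load femoral/tibial FRPVE parameter blocks from YAML.

    Missing blocks or fields fall back to the packaged defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {}
    for tissue, default in (("femoral", FEMORAL), ("tibial", TIBIAL)):
        block = cfg.get(tissue, {})
        out[tissue] = replace(default, **block) if block else default
    return out
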