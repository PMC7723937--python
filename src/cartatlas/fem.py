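"""Small-scale mixed displacement/pore-pressure poroelastic FE solver.

Solves quasistatic biphasic (poroelastic) problems on hexahedral meshes
with the FRPVE effective stress:

    div(sigma_eff) - grad(p) = 0
    d/dt(div u) - div(k grad p) = 0

discretized with trilinear displacement / trilinear pressure hexahedra
(2x2x2 Gauss quadrature), backward-Euler time stepping and Newton
iteration on the monolithic symmetric system. Equal-order interpolation
is stabilized with a local pressure-projection term (penalizing the
deviation of p from its element mean, scaled by 1/(2*mu)), which leaves
smooth pressure fields untouched but suppresses checkerboard modes at
small time steps.

Contact against a rigid, impermeable counter-surface (plane, sphere or
ellipsoid) uses a node-based penalty law: a penetrating contact node
feels a force ``penalty * area * depth`` along the surface normal
(compression only). Free faces are drained (p = 0) except where a node
is in contact (sealed there); the bone interface is sealed.

Units: mm, N, MPa, s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .material import (FRPVEParams, fibril_stress_update, fibril_tangent,
                       fibril_weights, nonfibrillar_stress,
                       primary_fibril_directions, secondary_fibril_directions)

__all__ = [
    "FEProblem", "FieldHistory", "RigidPlane", "RigidSphere", "RigidEllipsoid",
    "contact_step", "solve", "run_gait", "make_column_mesh",
    "terzaghi_problem", "terzaghi_series",
    "SingularSystemError", "NonConvergenceError",
]

# ---------------------------------------------------------------- exceptions


class SingularSystemError(RuntimeError):
    pass


class NonConvergenceError(RuntimeError):
    pass


# ----------------------------------------------------------- rigid surfaces

_CONTACT_W = 1e-3  # mm; C1 blend width of the penalty ramp at zero gap


class RigidPlane:
    """Half-space ``(x - point) . inward > 0`` is forbidden.

    ``inward`` points from the admissible side into the forbidden side;
    the contact force on a penetrating node acts along ``-inward``.
    """

    def __init__(self, point, inward):
        self.point = np.asarray(point, dtype=float)
        m = np.asarray(inward, dtype=float)
        self.inward = m / np.linalg.norm(m)

    def gap_normal(self, x):
        g = (x - self.point) @ self.inward
        n = np.broadcast_to(-self.inward, x.shape)
        return g, n


class RigidEllipsoid:
    """Forbidden region: the interior of an axis-aligned ellipsoid."""

    def __init__(self, center, radii):
        self.center = np.asarray(center, dtype=float)
        self.radii = np.broadcast_to(np.asarray(radii, dtype=float), (3,)).copy()

    def translated(self, offset):
        return RigidEllipsoid(self.center + np.asarray(offset, dtype=float),
                              self.radii)

    def gap_normal(self, x):
        d = x - self.center
        rho = np.linalg.norm(d, axis=-1)
        rho = np.maximum(rho, 1e-12)
        u = d / rho[..., None]
        a_u = np.linalg.norm(u / self.radii, axis=-1)       # |Lam^-1 u|
        phi = rho * a_u                                     # level-set value
        g = (1.0 - phi) / a_u                               # radial depth
        n = d / self.radii ** 2                             # outward normal dir
        n = n / np.maximum(np.linalg.norm(n, axis=-1, keepdims=True), 1e-12)
        return g, n


class RigidSphere(RigidEllipsoid):
    def __init__(self, center, radius):
        super().__init__(center, [radius, radius, radius])


def contact_step(positions, areas, surface, penalty, active=None):
    """Penalty contact of nodes against a rigid counter-surface.

    Returns ``(forces (n,3), flags (n,), stiffness (n,3,3))`` where the
    per-node stiffness is ``penalty*area*n(x)n`` for penetrating nodes.
    Compression only: non-penetrating nodes carry zero force.

    ``active`` optionally freezes the active set (an anti-chattering
    device for the Newton loop): frozen-active nodes keep their spring
    even at slightly negative penetration. ``flags`` always reports true
    penetration (g > 0).
    """
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    positions = np.asarray(positions, dtype=float)
    g, n = surface.gap_normal(positions)
    flags = g > 0.0
    if active is None:
        # C1-smoothed ramp: exact penalty*g above the (negligible) blend
        # width, zero force and stiffness when separated
        mag = penalty * areas * _CONTACT_W * \
            np.where(g >= _CONTACT_W, g / _CONTACT_W,
                     np.where(g <= -_CONTACT_W, 0.0,
                              (g / _CONTACT_W + 1.0) ** 2 / 4.0))
        dmag = penalty * areas * np.clip(
            (g / _CONTACT_W + 1.0) / 2.0, 0.0, 1.0)
    else:
        mag = np.where(active, penalty * areas * g, 0.0)
        dmag = penalty * areas * active
    forces = mag[:, None] * n
    stiff = dmag[:, None, None] * np.einsum("ni,nj->nij", n, n)
    return forces, flags, stiff


# ------------------------------------------------------------ hex8 elements

_XI_CORNERS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
_GP = _XI_CORNERS / np.sqrt(3.0)   # 2x2x2 Gauss points, weight 1 each


def _shape(xi):
    return 0.125 * np.prod(1.0 + _XI_CORNERS * xi, axis=1)


def _dshape(xi):
    g = np.empty((8, 3))
    for i, (a, b, c) in enumerate(_XI_CORNERS):
        g[i] = 0.125 * np.array([
            a * (1 + b * xi[1]) * (1 + c * xi[2]),
            (1 + a * xi[0]) * b * (1 + c * xi[2]),
            (1 + a * xi[0]) * (1 + b * xi[1]) * c])
    return g


_NP_GP = np.stack([_shape(xi) for xi in _GP])        # (8gp, 8)
_DN_GP = np.stack([_dshape(xi) for xi in _GP])       # (8gp, 8, 3)

_VOIGT_ROWS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2))


def _linear_D(lam, mu):
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


def _voigt_to_tensor(v):
    t = np.empty(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = 0.5 * v[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = 0.5 * v[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = 0.5 * v[..., 5]
    return t


def _tensor_to_voigt(t):
    v = np.empty(t.shape[:-2] + (6,))
    v[..., 0] = t[..., 0, 0]
    v[..., 1] = t[..., 1, 1]
    v[..., 2] = t[..., 2, 2]
    v[..., 3] = t[..., 0, 1]
    v[..., 4] = t[..., 1, 2]
    v[..., 5] = t[..., 0, 2]
    return v


# -------------------------------------------------------------- problem def


@dataclass
class FEProblem:
    """A poroelastic problem on a hexahedral mesh.

    ``fix`` maps axis name ('x'|'y'|'z') to node indices with zero
    displacement on that axis. ``drained`` nodes have p = 0 (unless in
    contact when ``seal_contact``). ``f_ext`` is ``None`` or a callable
    ``(step, t) -> (3n,) nodal force vector``. ``contact_nodes`` (with
    per-node tributary ``contact_areas``) meet ``surface_fn(step, t)``
    under ``penalty``.
    """

    nodes: np.ndarray
    elements: np.ndarray
    params: FRPVEParams
    times: np.ndarray
    split_line: np.ndarray | None = None
    fix: dict = field(default_factory=dict)
    drained: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    f_ext: object = None
    contact_nodes: np.ndarray | None = None
    contact_areas: np.ndarray | None = None
    surface_fn: object = None
    penalty: float = 100.0            # MPa/mm
    seal_contact: bool = True
    surface_normal: tuple = (0.0, 0.0, 1.0)
    newton_tol: float = 1e-6
    pressure_tol: float = 1e-8
    max_newton: int = 25


@dataclass
class FieldHistory:
    """Stored solution frames of one simulation."""

    times: np.ndarray
    u: np.ndarray              # (T, n, 3) mm
    p: np.ndarray              # (T, n) MPa
    stress: np.ndarray         # (T, e, 8, 6) total stress, Voigt, MPa
    strain: np.ndarray         # (T, e, 8, 6) Voigt (engineering shears)
    fibril_strain: np.ndarray  # (T, e, 8) max tensile fibril strain
    contact_flags: np.ndarray  # (T, n) bool
    nodes: np.ndarray
    elements: np.ndarray
    stance_pct: np.ndarray | None = None

    def save_h5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("times", "u", "p", "stress", "strain",
                         "fibril_strain", "contact_flags", "nodes", "elements"):
                f.create_dataset(name, data=getattr(self, name))
            if self.stance_pct is not None:
                f.create_dataset("stance_pct", data=self.stance_pct)

    @classmethod
    def load_h5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            kw = {name: f[name][()] for name in f.keys()}
        return cls(**kw)


# ------------------------------------------------------------------ system


class _System:
    """Precomputed element operators and constant matrices for one mesh."""

    def __init__(self, problem: FEProblem):
        self.pb = problem
        nodes = np.asarray(problem.nodes, dtype=float)
        elems = np.asarray(problem.elements, dtype=int)
        self.nodes, self.elems = nodes, elems
        ne, nn = len(elems), len(nodes)
        self.ne, self.nn = ne, nn
        X = nodes[elems]                                   # (e, 8, 3)
        J = np.einsum("gia,eib->egab", _DN_GP, X)          # (e, g, 3, 3)
        detJ = np.linalg.det(J)
        if detJ.min() <= 0:
            raise ValueError("mesh contains non-positive Jacobians")
        Jinv = np.linalg.inv(J)
        self.dNdx = np.einsum("gia,egab->egib", _DN_GP, Jinv)  # (e,g,8,3)
        self.wdet = detJ                                   # weights are 1

        B = np.zeros((ne, 8, 6, 24))
        d = self.dNdx
        for i in range(8):
            c = 3 * i
            B[:, :, 0, c + 0] = d[:, :, i, 0]
            B[:, :, 1, c + 1] = d[:, :, i, 1]
            B[:, :, 2, c + 2] = d[:, :, i, 2]
            B[:, :, 3, c + 0] = d[:, :, i, 1]
            B[:, :, 3, c + 1] = d[:, :, i, 0]
            B[:, :, 4, c + 1] = d[:, :, i, 2]
            B[:, :, 4, c + 2] = d[:, :, i, 1]
            B[:, :, 5, c + 0] = d[:, :, i, 2]
            B[:, :, 5, c + 2] = d[:, :, i, 0]
        self.B = B
        self.Bvol = B[:, :, 0, :] + B[:, :, 1, :] + B[:, :, 2, :]  # (e,g,24)

        # displacement / pressure dof maps
        self.edof_u = (3 * elems[:, :, None] + np.arange(3)).reshape(ne, 24)
        self.edof_p = elems

        par = problem.params
        lam, mu = par.lame
        self.D_lin = _linear_D(lam, mu)
        kmm = par.k_mm

        Q_e = np.einsum("egi,gk,eg->eik", self.Bvol, _NP_GP, self.wdet)
        H_e = kmm * np.einsum("egia,egja,eg->eij", self.dNdx, self.dNdx,
                              self.wdet)
        Me = np.einsum("gi,gj,eg->eij", _NP_GP, _NP_GP, self.wdet)
        ve = np.einsum("gi,eg->ei", _NP_GP, self.wdet)
        Ve = self.wdet.sum(axis=1)
        alpha = 0.1 / (2.0 * mu)
        S_e = alpha * (Me - np.einsum("ei,ej->eij", ve, ve) / Ve[:, None, None])

        ru = np.repeat(self.edof_u, 8, axis=1).ravel()
        cp = np.tile(self.edof_p, (1, 24)).ravel()
        self.Q = sp.coo_matrix((Q_e.ravel(), (ru, cp)),
                               shape=(3 * nn, nn)).tocsr()
        rp = np.repeat(self.edof_p, 8, axis=1).ravel()
        cp2 = np.tile(self.edof_p, (1, 8)).ravel()
        self.H = sp.coo_matrix((H_e.ravel(), (rp, cp2)), shape=(nn, nn)).tocsr()
        self.S = sp.coo_matrix((S_e.ravel(), (rp, cp2)), shape=(nn, nn)).tocsr()
        self._Krow = np.repeat(self.edof_u, 24, axis=1).ravel()
        self._Kcol = np.tile(self.edof_u, (1, 24)).ravel()

        # fibril geometry per Gauss point
        zs = nodes[:, 2]
        z_top, z_bot = zs.max(), zs.min()
        gp_xyz = np.einsum("gi,eia->ega", _NP_GP, X)
        thick = max(z_top - z_bot, 1e-12)
        self.h_z = np.clip((z_top - gp_xyz[:, :, 2]) / thick, 0.0, 1.0)
        normal = np.asarray(problem.surface_normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        split = problem.split_line
        if split is None:
            split = np.tile([1.0, 0.0, 0.0], (ne, 1))
        split = np.asarray(split, dtype=float)
        sec = secondary_fibril_directions()
        n_sec = len(sec)
        dirs = np.empty((ne, 8, 2 + n_sec, 3))
        for e in range(ne):
            for g in range(8):
                dirs[e, g, :2] = primary_fibril_directions(
                    self.h_z[e, g], split[e], normal)
            dirs[e, :, 2:] = sec
        self.fib_dirs = dirs
        m = np.empty((ne, 8, 2 + n_sec, 6))
        dd = dirs
        m[..., 0] = dd[..., 0] ** 2
        m[..., 1] = dd[..., 1] ** 2
        m[..., 2] = dd[..., 2] ** 2
        m[..., 3] = dd[..., 0] * dd[..., 1]
        m[..., 4] = dd[..., 1] * dd[..., 2]
        m[..., 5] = dd[..., 0] * dd[..., 2]
        self.fib_m = m
        self.fib_w = fibril_weights(2, n_sec, par.primary_density_ratio)
        self.nf = 2 + n_sec

        # free dof masks
        free_u = np.ones(3 * nn, dtype=bool)
        for axis, idx in problem.fix.items():
            free_u[3 * np.asarray(idx, dtype=int) + "xyz".index(axis)] = False
        self.free_u = free_u

    # ---------------------------------------------------------- material

    def gp_strain(self, u):
        ue = u[self.edof_u]                                # (e, 24)
        return np.einsum("egij,ej->egi", self.B, ue)       # (e, g, 6)

    def material(self, eps_v, hist, dt):
        """Stress, tangent and new history at every Gauss point.

        The matrix tangent is the consistent derivative of the
        neo-Hookean law (forward differences on the Voigt strain; exact
        and cheaper constant Hooke matrix in the linear limit); the
        fibril tangent is the exact derivative of the backward-Euler
        fibril update.
        """
        par = self.pb.params
        eps_t = _voigt_to_tensor(eps_v)
        sig_nf = nonfibrillar_stress(eps_t, par)
        sig_v = _tensor_to_voigt(sig_nf)
        if par.linear_matrix:
            D = np.broadcast_to(self.D_lin, (self.ne, 8, 6, 6)).copy()
        else:
            D = np.empty((self.ne, 8, 6, 6))
            h = 1e-7
            for j in range(6):
                pert = eps_v.copy()
                pert[..., j] += h
                sig_j = _tensor_to_voigt(
                    nonfibrillar_stress(_voigt_to_tensor(pert), par))
                D[..., j] = (sig_j - sig_v) / h
            D = 0.5 * (D + np.swapaxes(D, -1, -2))
        fib_eps_max = np.zeros((self.ne, 8))
        if par.e_0 > 0 or par.e_eps > 0:
            eps_fib = np.einsum("egfi,egi->egf", self.fib_m, eps_v)
            sig_fib, new_hist = fibril_stress_update(eps_fib, hist, dt, par)
            tang = fibril_tangent(eps_fib, hist, dt, par)
            w = self.fib_w
            sig_v = sig_v + np.einsum("f,egf,egfi->egi", w, sig_fib, self.fib_m)
            D = D + np.einsum("f,egf,egfi,egfj->egij", w, tang,
                              self.fib_m, self.fib_m)
            fib_eps_max = np.maximum(eps_fib, 0.0).max(axis=2)
        else:
            new_hist = hist
        return sig_v, D, new_hist, fib_eps_max

    def internal_force(self, sig_v):
        fe = np.einsum("egij,egi,eg->ej", self.B, sig_v, self.wdet)
        f = np.zeros(3 * self.nn)
        np.add.at(f, self.edof_u.ravel(), fe.ravel())
        return f

    def stiffness(self, D):
        BT = self.B.transpose(0, 1, 3, 2)            # (e, g, 24, 6)
        Ke = (BT @ D @ self.B) * self.wdet[..., None, None]
        Ke = Ke.sum(axis=1)                          # (e, 24, 24)
        return sp.coo_matrix((Ke.ravel(), (self._Krow, self._Kcol)),
                             shape=(3 * self.nn, 3 * self.nn)).tocsr()

    def check_rigid_modes(self, K):
        """Name unconstrained rigid-body translations (diagnostic)."""
        loose = []
        for axis in range(3):
            mode = np.zeros(3 * self.nn)
            mode[axis::3] = 1.0
            mode = mode[self.free_u]
            r = K[self.free_u][:, self.free_u] @ mode
            if np.linalg.norm(r) < 1e-10 * max(1.0, abs(K.diagonal()).max()):
                loose.append("xyz"[axis])
        return loose


def _reduce(A, mask):
    return A[mask][:, mask]


def solve(problem: FEProblem, store_stance=None) -> FieldHistory:
    """Implicit time-march of the coupled u-p system. Returns all frames.

    The state at ``times[0]`` is the unloaded zero state; each subsequent
    time is one backward-Euler step solved by Newton iteration.
    """
    sys_ = _System(problem)
    nn, ne = sys_.nn, sys_.ne
    times = np.asarray(problem.times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    T = len(times)

    u = np.zeros(3 * nn)
    p = np.zeros(nn)
    hist = (np.zeros((ne, 8, sys_.nf)), np.zeros((ne, 8, sys_.nf)))

    U = np.zeros((T, nn, 3))
    P = np.zeros((T, nn))
    SIG = np.zeros((T, ne, 8, 6))
    EPS = np.zeros((T, ne, 8, 6))
    FIB = np.zeros((T, ne, 8))
    FLAGS = np.zeros((T, nn), dtype=bool)

    cn = problem.contact_nodes
    prev_flags = np.zeros(0 if cn is None else len(cn), dtype=bool)
    for step in range(1, T):
        t, dt = times[step], times[step] - times[step - 1]
        f_ext = (problem.f_ext(step, t) if problem.f_ext is not None
                 else np.zeros(3 * nn))
        surface = (problem.surface_fn(step, t)
                   if problem.surface_fn is not None else None)
        u, p, hist, res = _newton_step(
            sys_, u, p, hist, dt, f_ext, surface, prev_flags)
        prev_flags = res["flags"]
        U[step] = u.reshape(nn, 3)
        P[step] = p
        SIG[step] = res["stress"]
        EPS[step] = res["strain"]
        FIB[step] = res["fibril"]
        if cn is not None:
            FLAGS[step, cn] = res["flags"]

    return FieldHistory(times=times, u=U, p=P, stress=SIG, strain=EPS,
                        fibril_strain=FIB, contact_flags=FLAGS,
                        nodes=sys_.nodes, elements=sys_.elems,
                        stance_pct=store_stance)


def _newton_step(sys_, u0, p0, hist0, dt, f_ext, surface, sealed_flags):
    """One backward-Euler step from (u0, p0, hist0); returns new state.

    Damped Newton on the monolithic symmetric system: full steps while
    the residual shrinks, backtracking (up to five halvings) when the
    contact set or fibril recruitment makes a full step overshoot.
    """
    pb = sys_.pb
    nn = sys_.nn
    u, p = u0.copy(), p0.copy()

    drained = np.zeros(nn, dtype=bool)
    drained[pb.drained] = True
    if pb.seal_contact and pb.contact_nodes is not None and len(sealed_flags):
        drained[pb.contact_nodes[sealed_flags]] = False
    free_p = ~drained
    free_u = sys_.free_u
    nfu = int(free_u.sum())
    ref = {"force": max(np.linalg.norm(f_ext), 1e-6)}
    ref0 = ref["force"]   # fixed scale for line-search merit comparisons

    frozen = {"active": None}  # anti-chattering: set after stalled iterations

    def residual(u_, p_):
        eps_v = sys_.gp_strain(u_)
        sig_v, D, new_hist, fib = sys_.material(eps_v, hist0, dt)
        f_int = sys_.internal_force(sig_v)
        f_con = np.zeros(3 * nn)
        Kc = None
        flags = np.zeros(0, dtype=bool)
        if surface is not None and pb.contact_nodes is not None:
            cn = pb.contact_nodes
            pos = sys_.nodes[cn] + u_.reshape(nn, 3)[cn]
            forces, flags, stiff = contact_step(pos, pb.contact_areas,
                                                surface, pb.penalty,
                                                active=frozen["active"])
            idx = (3 * cn[:, None] + np.arange(3)).ravel()
            np.add.at(f_con, idx, forces.ravel())
            Kc = (cn, stiff)
            ref["force"] = max(ref["force"], np.linalg.norm(forces))
        Ru = f_int - sys_.Q @ p_ - f_ext - f_con
        Rp = sys_.Q.T @ (u_ - u0) + dt * (sys_.H @ p_) + sys_.S @ (p_ - p0)
        ru = np.linalg.norm(Ru[free_u])
        rp = np.linalg.norm(Rp[free_p])
        rp_ref = max(np.linalg.norm(sys_.Q.T @ (u_ - u0)), 1e-9)
        merit = ru / ref0 + rp / rp_ref
        return {"Ru": Ru, "Rp": Rp, "ru": ru, "rp": rp, "rp_ref": rp_ref,
                "merit": merit, "D": D, "Kc": Kc, "sig_v": sig_v,
                "eps_v": eps_v, "fib": fib, "flags": flags,
                "new_hist": new_hist}

    st = residual(u, p)
    for it in range(pb.max_newton):
        if it == 12 and frozen["active"] is None and len(st["flags"]):
            # stalled steps are almost always contact-set chattering:
            # freeze the active set (penetrations at the chattering nodes
            # are ~penalty-tolerance small, so the force error is tiny)
            frozen["active"] = st["flags"].copy()
            st = residual(u, p)
        if st["ru"] <= pb.newton_tol * ref["force"] and st["rp"] <= max(
                pb.pressure_tol * st["rp_ref"], 1e-14):
            p_gp = np.einsum("gk,ek->eg", _NP_GP, p[sys_.edof_p])
            total = st["sig_v"].copy()
            total[..., :3] -= p_gp[..., None]
            return u, p, st["new_hist"], {
                "stress": total, "strain": st["eps_v"],
                "fibril": st["fib"], "flags": st["flags"]}

        K = sys_.stiffness(st["D"])
        if st["Kc"] is not None:
            cn, stiff = st["Kc"]
            rows = np.repeat(3 * cn[:, None] + np.arange(3), 3, axis=1).ravel()
            cols = np.tile(3 * cn[:, None] + np.arange(3), (1, 3)).ravel()
            K = K + sp.coo_matrix((stiff.ravel(), (rows, cols)),
                                  shape=K.shape).tocsr()

        A = sp.bmat([
            [_reduce(K, free_u), -sys_.Q[free_u][:, free_p]],
            [-sys_.Q[free_u][:, free_p].T,
             -_reduce(dt * sys_.H + sys_.S, free_p)]], format="csc")
        rhs = np.concatenate([-st["Ru"][free_u], st["Rp"][free_p]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                dx = splu(A).solve(rhs)
        except Exception as exc:
            loose = sys_.check_rigid_modes(K)
            msg = "singular coupled system"
            if loose:
                msg += f"; unconstrained rigid translation(s): {loose}"
            raise SingularSystemError(msg) from exc
        if not np.all(np.isfinite(dx)) or np.linalg.norm(dx) > 1e10 * (
                1.0 + np.linalg.norm(u)):
            loose = sys_.check_rigid_modes(K)
            msg = "singular or near-singular coupled system"
            if loose:
                msg += f"; unconstrained rigid translation(s): {loose}"
            raise SingularSystemError(msg)

        scale = 1.0
        trial = None
        for _ls in range(10):
            u_t, p_t = u.copy(), p.copy()
            u_t[free_u] += scale * dx[:nfu]
            p_t[free_p] += scale * dx[nfu:]
            p_t[drained] = 0.0
            try:
                trial = residual(u_t, p_t)
            except ValueError:  # e.g. volumetric collapse on overshoot
                scale *= 0.5
                trial = None
                continue
            if trial["merit"] <= st["merit"] * (1.0 + 1e-9) or scale <= 1 / 16:
                break
            scale *= 0.5
        if trial is None:
            raise NonConvergenceError("line search failed to find an "
                                      "evaluable Newton step")
        u, p, st = u_t, p_t, trial
    raise NonConvergenceError(
        f"Newton failed: step residual {st['ru']:.3e} "
        f"(force ref {ref['force']:.3e}), pressure residual "
        f"{st['rp']:.3e} after {pb.max_newton} iterations")


# ----------------------------------------------------------- gait driver


def run_gait(problem: FEProblem, loading, stance_duration: float = 0.6,
             base_surface: RigidEllipsoid | None = None,
             rolling_fraction: float = 0.3,
             force_rel_tol: float = 0.01) -> FieldHistory:
    """Force-controlled stance simulation against a rigid counter-surface.

    The stance grid of ``loading`` maps to time (100% stance =
    ``stance_duration`` seconds). The vertical position of the rigid
    femoral counter-surface is an extra Newton unknown at every stance
    point, constrained by the force balance "total vertical contact
    force = medial_force_n(t)" (monolithic force control; converged to
    ``force_rel_tol``). Knee flexion translates the contact point
    anteriorly by ``rolling_fraction * r_x * sin(flexion)`` (rolling
    approximation of counter-surface reorientation).
    """
    if base_surface is None:
        raise ValueError("base_surface (rigid femoral counter-surface) required")
    stance = np.asarray(loading.stance_pct, dtype=float)
    forces = np.asarray(loading.medial_force_n, dtype=float)
    flex = np.radians(np.asarray(loading.flexion_deg, dtype=float))
    times = stance / 100.0 * stance_duration
    T = len(times)
    sys_ = _System(problem)
    nn, ne = sys_.nn, sys_.ne

    u = np.zeros(3 * nn)
    p = np.zeros(nn)
    hist = (np.zeros((ne, 8, sys_.nf)), np.zeros((ne, 8, sys_.nf)))

    U = np.zeros((T, nn, 3))
    P = np.zeros((T, nn))
    SIG = np.zeros((T, ne, 8, 6))
    EPS = np.zeros((T, ne, 8, 6))
    FIB = np.zeros((T, ne, 8))
    FLAGS = np.zeros((T, nn), dtype=bool)

    cn = problem.contact_nodes
    prev_flags = np.zeros(len(cn), dtype=bool)
    r_x = base_surface.radii[0]
    thickness = sys_.nodes[:, 2].max() - sys_.nodes[:, 2].min()
    d_cap = 0.9 * thickness          # never command a crush of the layer
    delta = min(0.05, 0.25 * d_cap)  # warm-start indentation guess

    def advance(u, p, hist, flags_in, delta, dt, tgt0, tgt1, sh0, sh1,
                depth=0):
        """Advance one (sub)step; bisect the step on non-convergence."""
        try:
            return _force_step(sys_, u, p, hist, dt, tgt1, base_surface,
                               sh1, flags_in, delta, d_cap, force_rel_tol)
        except NonConvergenceError:
            if depth >= 3:
                raise
            mid_t = 0.5 * (tgt0 + tgt1)
            mid_s = 0.5 * (sh0 + sh1)
            u1, p1, h1, res1, d1 = advance(u, p, hist, flags_in, delta,
                                           0.5 * dt, tgt0, mid_t, sh0, mid_s,
                                           depth + 1)
            return advance(u1, p1, h1, res1["flags"], d1, 0.5 * dt,
                           mid_t, tgt1, mid_s, sh1, depth + 1)

    shift_prev = np.array([rolling_fraction * r_x * np.sin(flex[0]), 0.0, 0.0])
    target_prev = forces[0]
    for step in range(T):
        dt = times[step] - times[step - 1] if step else times[1] - times[0]
        target = forces[step]
        shift = np.array([rolling_fraction * r_x * np.sin(flex[step]),
                          0.0, 0.0])
        try:
            u, p, hist, res, delta = advance(u, p, hist, prev_flags, delta,
                                             dt, target_prev, target,
                                             shift_prev, shift)
        except NonConvergenceError as exc:
            raise NonConvergenceError(
                f"force control failed at stance {stance[step]:.1f}% "
                f"(target {target:.1f} N): {exc}") from exc
        target_prev, shift_prev = target, shift
        prev_flags = res["flags"]
        U[step] = u.reshape(nn, 3)
        P[step] = p
        SIG[step] = res["stress"]
        EPS[step] = res["strain"]
        FIB[step] = res["fibril"]
        FLAGS[step, cn] = res["flags"]

    return FieldHistory(times=times, u=U, p=P, stress=SIG, strain=EPS,
                        fibril_strain=FIB, contact_flags=FLAGS,
                        nodes=sys_.nodes, elements=sys_.elems,
                        stance_pct=stance)


def _force_step(sys_, u0, p0, hist0, dt, target, base_surface, shift,
                sealed_flags, d0, d_cap, force_rel_tol):
    """One backward-Euler step with the indentation depth as an unknown.

    Solves the augmented system [coupled u-p residual; total vertical
    contact force - target] by damped Newton; the extra column/row pair
    is the contact-force derivative with respect to the counter-surface
    depth, which keeps the augmented matrix symmetric.
    """
    pb = sys_.pb
    nn = sys_.nn
    cn = pb.contact_nodes
    u, p, d = u0.copy(), p0.copy(), float(np.clip(d0, 1e-4, d_cap))

    drained = np.zeros(nn, dtype=bool)
    drained[pb.drained] = True
    if pb.seal_contact and len(sealed_flags):
        drained[cn[sealed_flags]] = False
    free_p = ~drained
    free_u = sys_.free_u
    nfu = int(free_u.sum())
    ref_t = max(target, 1.0)
    ref = {"force": ref_t}
    frozen = {"active": None}
    f_tol = max(force_rel_tol * target, 0.5)

    def residual(u_, p_, d_):
        eps_v = sys_.gp_strain(u_)
        sig_v, D, new_hist, fib = sys_.material(eps_v, hist0, dt)
        f_int = sys_.internal_force(sig_v)
        surf = base_surface.translated(shift + [0.0, 0.0, -d_])
        pos = sys_.nodes[cn] + u_.reshape(nn, 3)[cn]
        fcn, flags, stiff = contact_step(pos, pb.contact_areas, surf,
                                         pb.penalty, active=frozen["active"])
        f_con = np.zeros(3 * nn)
        idx = (3 * cn[:, None] + np.arange(3)).ravel()
        np.add.at(f_con, idx, fcn.ravel())
        ref["force"] = max(ref["force"], np.linalg.norm(fcn))
        fz = float(-fcn[:, 2].sum())
        # depth-derivative column: stiff @ e_z per node (= dmag * n_z * n)
        bvec = np.zeros(3 * nn)
        np.add.at(bvec, idx, stiff[:, :, 2].ravel())
        alpha = float(stiff[:, 2, 2].sum())
        Ru = f_int - sys_.Q @ p_ - f_con
        Rp = sys_.Q.T @ (u_ - u0) + dt * (sys_.H @ p_) + sys_.S @ (p_ - p0)
        rF = fz - target
        ru = np.linalg.norm(Ru[free_u])
        rp = np.linalg.norm(Rp[free_p])
        rp_ref = max(np.linalg.norm(sys_.Q.T @ (u_ - u0)), 1e-9)
        # merit uses fixed scales so line-search comparisons are consistent
        merit = ru / ref_t + rp / rp_ref + abs(rF) / ref_t
        return {"Ru": Ru, "Rp": Rp, "rF": rF, "ru": ru, "rp": rp,
                "rp_ref": rp_ref, "merit": merit, "D": D, "stiff": stiff,
                "bvec": bvec, "alpha": alpha, "sig_v": sig_v,
                "eps_v": eps_v, "fib": fib, "flags": flags,
                "new_hist": new_hist, "fz": fz}

    st = residual(u, p, d)
    for it in range(pb.max_newton):
        if it == 12 and frozen["active"] is None and st["flags"].any():
            # persistent stalls are contact-set chattering: freeze the set
            frozen["active"] = st["flags"].copy()
            st = residual(u, p, d)
        if (st["ru"] <= pb.newton_tol * ref["force"]
                and st["rp"] <= max(pb.pressure_tol * st["rp_ref"], 1e-14)
                and abs(st["rF"]) <= f_tol):
            p_gp = np.einsum("gk,ek->eg", _NP_GP, p[sys_.edof_p])
            total = st["sig_v"].copy()
            total[..., :3] -= p_gp[..., None]
            return u, p, st["new_hist"], {
                "stress": total, "strain": st["eps_v"],
                "fibril": st["fib"], "flags": st["flags"]}, d

        K = sys_.stiffness(st["D"])
        stiff = st["stiff"]
        rows = np.repeat(3 * cn[:, None] + np.arange(3), 3, axis=1).ravel()
        cols = np.tile(3 * cn[:, None] + np.arange(3), (1, 3)).ravel()
        K = K + sp.coo_matrix((stiff.ravel(), (rows, cols)),
                              shape=K.shape).tocsr()
        b = st["bvec"][free_u][:, None]
        alpha = max(st["alpha"], 1e-8)
        A = sp.bmat([
            [_reduce(K, free_u), -sys_.Q[free_u][:, free_p],
             sp.csr_matrix(b)],
            [-sys_.Q[free_u][:, free_p].T,
             -_reduce(dt * sys_.H + sys_.S, free_p), None],
            [sp.csr_matrix(b.T), None, sp.csr_matrix([[alpha]])]],
            format="csc")
        rhs = np.concatenate([-st["Ru"][free_u], st["Rp"][free_p],
                              [-st["rF"]]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                dx = splu(A).solve(rhs)
        except Exception as exc:
            loose = sys_.check_rigid_modes(K)
            msg = "singular augmented system"
            if loose:
                msg += f"; unconstrained rigid translation(s): {loose}"
            raise SingularSystemError(msg) from exc
        # the depth component is excluded from the blow-up check: with no
        # contact yet, its floor-regularized row commands a huge (clipped)
        # depth move, which is how the surface finds the mesh
        if not np.all(np.isfinite(dx)) or np.linalg.norm(dx[:-1]) > 1e10 * (
                1.0 + np.linalg.norm(u)):
            loose = sys_.check_rigid_modes(K)
            msg = "singular or near-singular augmented system"
            if loose:
                msg += f"; unconstrained rigid translation(s): {loose}"
            raise SingularSystemError(msg)

        scale = 1.0
        trial = None
        for _ls in range(10):
            u_t, p_t = u.copy(), p.copy()
            u_t[free_u] += scale * dx[:nfu]
            p_t[free_p] += scale * dx[nfu:-1]
            p_t[drained] = 0.0
            d_t = float(np.clip(d + scale * dx[-1], 1e-4, d_cap))
            try:
                trial = residual(u_t, p_t, d_t)
            except ValueError:   # volumetric collapse on overshoot
                scale *= 0.5
                trial = None
                continue
            if trial["merit"] <= st["merit"] * (1.0 + 1e-9) or scale <= 1 / 16:
                break
            scale *= 0.5
        if trial is None:
            raise NonConvergenceError("line search failed to find an "
                                      "evaluable Newton step")
        u, p, d, st = u_t, p_t, d_t, trial
    raise NonConvergenceError(
        f"augmented Newton failed: residuals force {st['ru']:.3e}, "
        f"pressure {st['rp']:.3e}, balance {st['rF']:.3e} N at depth "
        f"{d:.3f} mm after {pb.max_newton} iterations")


def _total_contact_force(sys_, pb_nodes, u, surf, areas, penalty):
    pos = sys_.nodes[pb_nodes] + u.reshape(sys_.nn, 3)[pb_nodes]
    forces, _, _ = contact_step(pos, areas, surf, penalty)
    return float(-forces[:, 2].sum())  # push on mesh is -z; report magnitude


def face_areas(nodes, quads):
    """Areas of bilinear quad faces (vector cross of the diagonals / 2)."""
    X = nodes[quads]
    d1 = X[:, 2] - X[:, 0]
    d2 = X[:, 3] - X[:, 1]
    return 0.5 * np.linalg.norm(np.cross(d1, d2), axis=1)


def tributary_areas(nodes, elements, surface_nodes):
    """Per-node tributary area of a surface node set (quarter-face shares)."""
    on = np.zeros(len(nodes), dtype=bool)
    on[surface_nodes] = True
    faces = []
    local_faces = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
                   (2, 3, 7, 6), (0, 3, 7, 4), (1, 2, 6, 5)]
    for lf in local_faces:
        f = elements[:, lf]
        keep = on[f].all(axis=1)
        faces.append(f[keep])
    faces = np.vstack(faces)
    area = np.zeros(len(nodes))
    A = face_areas(nodes, faces)
    for j in range(4):
        np.add.at(area, faces[:, j], 0.25 * A)
    return area[surface_nodes]


# --------------------------------------------------- verification fixtures


def make_column_mesh(nz: int, lx: float = 1.0, ly: float = 1.0,
                     h: float = 1.0):
    """A 1 x 1 x nz hexahedral column of height ``h`` (mm).

    Returns ``(nodes, elements, sets)`` with node sets 'top', 'bottom',
    'all'.
    """
    zs = np.linspace(0.0, h, nz + 1)
    xs, ys = [0.0, lx], [0.0, ly]
    nodes = np.array([[x, y, z] for z in zs for y in ys for x in xs])
    elements = []
    for k in range(nz):
        base = 4 * k
        elements.append([base, base + 1, base + 3, base + 2,
                         base + 4, base + 5, base + 7, base + 6])
    elements = np.array(elements, dtype=int)
    nn = len(nodes)
    sets = {"bottom": np.arange(4), "top": np.arange(nn - 4, nn),
            "all": np.arange(nn)}
    return nodes, elements, sets


def terzaghi_problem(nz: int, params: FRPVEParams, sigma0: float,
                     times, h: float = 1.0, drained: bool = True) -> FEProblem:
    """Confined-compression consolidation column under a step load.

    Lateral displacement is blocked everywhere (confined compression),
    the bottom is fixed and sealed, the top carries a constant traction
    ``sigma0`` and is drained unless ``drained=False`` (sealed column,
    the undrained-limit configuration).
    """
    nodes, elements, sets = make_column_mesh(nz, h=h)
    top = sets["top"]
    f = np.zeros(3 * len(nodes))
    f[3 * top + 2] = -sigma0 * 1.0 * 1.0 / len(top)  # unit cross-section

    return FEProblem(
        nodes=nodes, elements=elements, params=params,
        times=np.asarray(times, dtype=float),
        fix={"x": sets["all"], "y": sets["all"], "z": sets["bottom"]},
        drained=top if drained else np.array([], dtype=int),
        f_ext=lambda step, t: f,
    )


def terzaghi_series(zeta, Tv, n_terms: int = 200):
    """Analytic consolidation pressure ratio p/p0.

    ``zeta`` is depth below the drained surface divided by the drainage
    path length (0 at the drained top, 1 at the sealed bottom), ``Tv``
    the dimensionless time factor ``c_v t / h^2``.
    """
    zeta = np.asarray(zeta, dtype=float)
    m = np.arange(n_terms)
    M = 0.5 * np.pi * (2 * m + 1)
    return np.einsum("m,mz->z", 2.0 / M * np.exp(-M ** 2 * Tv),
                     np.sin(np.outer(M, zeta)))


def consolidation_coefficient(params: FRPVEParams) -> float:
    """c_v = k (lam + 2 mu) in mm^2/s for the linear-matrix limit."""
    lam, mu = params.lame
    return params.k_mm * (lam + 2.0 * mu)
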