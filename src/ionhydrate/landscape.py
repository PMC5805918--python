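"""Transition states, pathways and disconnectivity analysis.

Minima from global optimization are connected in three stages:

1. an initial band between two endpoint minima, built by linear
   interpolation of the translational coordinates and spherical linear
   quaternion interpolation (slerp) of the orientations;
2. doubly nudged elastic band (DNEB) relaxation of the band, whose
   interior energy maxima are candidate transition states;
3. hybrid eigenvector-following refinement of each candidate: walk uphill
   along the lowest Hessian eigenvector (estimated with gradient-only,
   finite-difference curvature products) while minimizing in the
   orthogonal subspace, then fall off both sides of the converged saddle
   to identify the two connected minima.

The resulting network of minima and transition states supports min-max
("lowest highest barrier") pathway extraction and disconnectivity trees.

All machinery below the cluster-specific helpers works on flat coordinate
vectors through a potential object exposing ``energy_gradient(x)``, so toy
surfaces plug in through the same interface as rigid-body clusters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.sparse.linalg import LinearOperator, eigsh
from scipy.spatial.transform import Rotation

from .energy import ClusterPotential
from .forcefield import ClusterConfig, SpeciesSpec
from .optimize import MinimaDatabase, local_minimize, structure_fingerprint

__all__ = [
    "interpolate_path",
    "align_clusters",
    "dneb",
    "DNEBResult",
    "hybrid_ef_refine",
    "EFResult",
    "TransitionState",
    "LandscapeDB",
    "connect_database",
    "connect_pair",
    "build_disconnectivity",
    "DisconnectivityTree",
    "extract_pathway",
    "Pathway",
    "lowest_mode",
    "hessian_fd",
]

# eigenvalues with |lambda| below this are treated as rigid-body zero modes
ZERO_MODE_TOL = 1e-4


# ---------------------------------------------------------------------------
# endpoint alignment and interpolation (cluster-specific)
# ---------------------------------------------------------------------------

def _symmetry_rotations(sp: SpeciesSpec) -> list[Rotation]:
    """Proper body-frame symmetry rotations (about the canonical z axis).

    Detected numerically: a candidate rotation belongs to the group if it
    permutes identical-label sites onto each other within 1e-6 A.
    """
    rots = [Rotation.identity()]
    body = sp.body_positions
    labels = sp.labels
    for k in (2, 3):
        for j in range(1, k):
            cand = Rotation.from_rotvec([0, 0, 2 * np.pi * j / k])
            newpos = cand.apply(body)
            ok = True
            for i in range(len(body)):
                d = np.linalg.norm(body - newpos[i], axis=1)
                match = np.argmin(d)
                if d[match] > 1e-6 or labels[match] != labels[i]:
                    ok = False
                    break
            if ok and not any(
                np.allclose(cand.as_matrix(), r.as_matrix()) for r in rots
            ):
                rots.append(cand)
    return rots


def align_clusters(a: ClusterConfig, b: ClusterConfig, n_rounds: int = 8,
                   n_random_starts: int = 12) -> ClusterConfig:
    """Rigidly align ``b`` onto ``a``: remove global translation/rotation,
    permute identical molecules (Hungarian assignment on COM distances) and
    reduce per-molecule orientations by body-frame symmetry.

    The assignment/rotation iteration is non-convex, so several candidate
    global rotations are tried: rotations matching the ion's orientation
    (one per ion proper-symmetry operation) when an ion is present, plus
    deterministic quasi-random starts; the lowest-RMSD result wins.
    Returns the aligned copy of ``b``; ``a`` is untouched.
    """
    from scipy.optimize import linear_sum_assignment

    if sorted(s.name for s in a.species_list) != sorted(
        s.name for s in b.species_list
    ):
        raise ValueError("clusters have different compositions")
    Ta = a.translations - a.centre_of_mass()
    Tb = b.translations - b.centre_of_mass()
    Pb = b.orientations.copy()
    masses = np.array([sp.mass for sp in a.species_list])
    groups: dict[str, list[int]] = {}
    for i, sp in enumerate(a.species_list):
        groups.setdefault(sp.name, []).append(i)

    def refine(R0):
        R_glob = R0
        perm = np.arange(a.n_molecules)
        for _ in range(n_rounds):
            Tb_r = R_glob.apply(Tb)
            new_perm = np.arange(a.n_molecules)
            for name, idx in groups.items():
                idx = np.array(idx)
                D = np.linalg.norm(Ta[idx][:, None, :] - Tb_r[idx][None, :, :], axis=2)
                r, c = linear_sum_assignment(D)
                new_perm[idx[r]] = idx[c]
            perm = new_perm
            # weighted Kabsch for the global rotation: Tb[perm] -> Ta
            P = Tb[perm]
            H = (Ta * masses[:, None]).T @ P
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(U @ Vt))
            R_glob = Rotation.from_matrix(U @ np.diag([1.0, 1.0, d]) @ Vt)
        return R_glob, perm

    com_a = a.centre_of_mass()

    def materialize(R_glob, perm):
        out = b.copy()
        out.translations = R_glob.apply(Tb[perm]) + com_a
        out.orientations = (R_glob * Rotation.from_rotvec(Pb[perm])).as_rotvec()
        out.species_list = tuple(b.species_list[i] for i in perm)
        # per-molecule symmetry reduction: pick the body symmetry operation
        # minimizing the residual rotation angle relative to a
        for m, sp in enumerate(out.species_list):
            Ra = Rotation.from_rotvec(a.orientations[m])
            Rb = Rotation.from_rotvec(out.orientations[m])
            best_rot, best_ang = None, np.inf
            for s in _symmetry_rotations(sp):
                cand = Rb * s
                ang = (Ra.inv() * cand).magnitude()
                if ang < best_ang:
                    best_rot, best_ang = cand, ang
            out.orientations[m] = best_rot.as_rotvec()
        out.energy = b.energy
        return out

    ref_sites = np.vstack(a.site_positions())

    def site_rmsd(out):
        pos = np.vstack(out.site_positions())
        return float(np.sqrt(((pos - ref_sites) ** 2).sum(axis=1).mean()))

    candidates = [Rotation.identity()]
    ion_a, ion_b = a.ion_index, b.ion_index
    if ion_a is not None and ion_b is not None:
        Ra = Rotation.from_rotvec(a.orientations[ion_a])
        Rb = Rotation.from_rotvec(b.orientations[ion_b])
        for s in _symmetry_rotations(a.species_list[ion_a]):
            candidates.append(Ra * s * Rb.inv())
    rng = np.random.default_rng(1905)
    for _ in range(n_random_starts):
        candidates.append(Rotation.random(random_state=rng))
    best_out, best_score = None, np.inf
    for R0 in candidates:
        out = materialize(*refine(R0))
        score = site_rmsd(out)
        if score < best_score:
            best_out, best_score = out, score
    return best_out


def _slerp(qa: np.ndarray, qb: np.ndarray, t: float) -> np.ndarray:
    """Shortest-arc quaternion slerp (scalar-last convention)."""
    dot = float(np.dot(qa, qb))
    if dot < 0:
        qb = -qb
        dot = -dot
    dot = min(dot, 1.0)
    if dot > 1 - 1e-12:
        q = (1 - t) * qa + t * qb
        return q / np.linalg.norm(q)
    omega = math.acos(dot)
    so = math.sin(omega)
    return (math.sin((1 - t) * omega) * qa + math.sin(t * omega) * qb) / so


def make_cluster_interpolator(species_list: tuple):
    """Flat-coordinate interpolator: linear translations + slerp orientations."""
    M = len(species_list)

    def interp(xa: np.ndarray, xb: np.ndarray, t: float) -> np.ndarray:
        Xa = xa.reshape(M, 6)
        Xb = xb.reshape(M, 6)
        out = np.empty_like(Xa)
        out[:, :3] = (1 - t) * Xa[:, :3] + t * Xb[:, :3]
        qa = Rotation.from_rotvec(Xa[:, 3:]).as_quat()
        qb = Rotation.from_rotvec(Xb[:, 3:]).as_quat()
        for m in range(M):
            q = _slerp(qa[m], qb[m], t)
            out[m, 3:] = Rotation.from_quat(q).as_rotvec()
        return out.reshape(-1)

    return interp


def interpolate_path(
    a: ClusterConfig, b: ClusterConfig, n_images: int, align: bool = True
) -> list[ClusterConfig]:
    """Path of ``n_images`` interior images between a and b (endpoints included).

    Image k sits at t = k/(n_images+1); translations interpolate linearly
    and orientations along the shortest quaternion arc.
    """
    if tuple(s.name for s in a.species_list) != tuple(s.name for s in b.species_list):
        raise ValueError("clusters have different species lists")
    bb = align_clusters(a, b) if align else b
    interp = make_cluster_interpolator(a.species_list)
    xa, xb = a.coords, bb.coords
    path = [a.copy()]
    for k in range(1, n_images + 1):
        t = k / (n_images + 1)
        path.append(a.with_coords(interp(xa, xb, t)))
    path.append(bb.copy())
    return path


# ---------------------------------------------------------------------------
# DNEB
# ---------------------------------------------------------------------------

@dataclass
class DNEBResult:
    images: np.ndarray          # (n_images+2, dof) including endpoints
    energies: np.ndarray
    candidates: list[np.ndarray]  # interior local maxima along the band
    converged: bool
    rms_perp: float


def _upwind_tangent(x_prev, x_here, x_next, e_prev, e_here, e_next):
    """Henkelman-Jonsson energy-weighted upwind tangent."""
    tp = x_next - x_here
    tm = x_here - x_prev
    if e_next > e_here and e_here > e_prev:
        tau = tp
    elif e_next < e_here and e_here < e_prev:
        tau = tm
    else:
        dmax = max(abs(e_next - e_here), abs(e_prev - e_here))
        dmin = min(abs(e_next - e_here), abs(e_prev - e_here))
        if e_next > e_prev:
            tau = tp * dmax + tm * dmin
        else:
            tau = tp * dmin + tm * dmax
    n = np.linalg.norm(tau)
    return tau / n if n > 0 else tau


def dneb(
    potential,
    xa: np.ndarray,
    xb: np.ndarray,
    n_images: int = 11,
    k_spring: float | None = None,
    tol: float = 1e-3,
    maxiter: int = 1000,
    interpolator=None,
) -> DNEBResult:
    """Doubly nudged elastic band between two minima (flat coordinates).

    The band force on each interior image is the perpendicular true
    gradient plus the parallel spring force plus the doubly nudged portion
    of the perpendicular spring force; relaxation uses FIRE.  Convergence
    is on the RMS perpendicular true gradient.
    """
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    if np.allclose(xa, xb):
        e = potential.energy_gradient(xa)[0]
        return DNEBResult(np.array([xa, xb]), np.array([e, e]), [], True, 0.0)
    if interpolator is None:
        interpolator = lambda a, b, t: (1 - t) * a + t * b
    n_tot = n_images + 2
    images = np.array(
        [interpolator(xa, xb, k / (n_tot - 1)) for k in range(n_tot)]
    )
    energies = np.empty(n_tot)
    grads = np.empty_like(images)
    for i in (0, n_tot - 1):
        energies[i], grads[i] = potential.energy_gradient(images[i])
    if k_spring is None:
        k_spring = max(1.0, abs(energies[-1] - energies[0]))

    # FIRE parameters
    dt, dt_max = 0.05, 0.2
    alpha0 = 0.1
    alpha = alpha0
    n_up = 0
    vel = np.zeros_like(images)
    rms = np.inf
    converged = False
    for it in range(maxiter):
        for i in range(1, n_tot - 1):
            energies[i], grads[i] = potential.energy_gradient(images[i])
        forces = np.zeros_like(images)
        rms_acc = 0.0
        for i in range(1, n_tot - 1):
            tau = _upwind_tangent(
                images[i - 1], images[i], images[i + 1],
                energies[i - 1], energies[i], energies[i + 1],
            )
            g = grads[i]
            g_par = np.dot(g, tau) * tau
            g_perp = g - g_par
            f_spring = k_spring * (
                (images[i + 1] - images[i]) - (images[i] - images[i - 1])
            )
            f_par = np.dot(f_spring, tau) * tau
            f_perp = f_spring - f_par
            gp_norm = np.linalg.norm(g_perp)
            if gp_norm > 1e-12:
                ghat = g_perp / gp_norm
                f_dn = f_perp - np.dot(f_perp, ghat) * ghat
            else:
                f_dn = f_perp
            forces[i] = -g_perp + f_par + f_dn
            rms_acc += gp_norm**2
        rms = math.sqrt(rms_acc / (n_images * images.shape[1]))
        if rms < tol:
            converged = True
            break
        # FIRE update
        power = float(np.vdot(forces, vel))
        if power > 0:
            n_up += 1
            fnorm = np.linalg.norm(forces)
            vnorm = np.linalg.norm(vel)
            if fnorm > 0:
                vel = (1 - alpha) * vel + alpha * vnorm * forces / fnorm
            if n_up > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            vel[:] = 0.0
            dt *= 0.5
            alpha = alpha0
            n_up = 0
        vel += dt * forces
        step = dt * vel
        # cap per-image displacement
        norms = np.linalg.norm(step, axis=1)
        big = norms > 0.2
        if big.any():
            step[big] *= (0.2 / norms[big])[:, None]
        images[1:-1] += step[1:-1]
    for i in range(1, n_tot - 1):
        energies[i], grads[i] = potential.energy_gradient(images[i])
    candidates = [
        images[i].copy()
        for i in range(1, n_tot - 1)
        if energies[i] > energies[i - 1] and energies[i] > energies[i + 1]
    ]
    return DNEBResult(images, energies.copy(), candidates, converged, rms)


# ---------------------------------------------------------------------------
# curvature tools and hybrid eigenvector following
# ---------------------------------------------------------------------------

def hessian_fd(potential, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Dense finite-difference Hessian from analytic gradients (symmetrized)."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xp[i] += h
        xm = x.copy()
        xm[i] -= h
        gp = potential.energy_gradient(xp)[1]
        gm = potential.energy_gradient(xm)[1]
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def lowest_mode(
    potential, x: np.ndarray, v0: np.ndarray | None = None, h: float = 1e-4
) -> tuple[float, np.ndarray]:
    """Lowest Hessian eigenpair via gradient-only FD curvature products."""
    n = len(x)

    def hv(v):
        v = np.asarray(v).reshape(-1)
        nv = np.linalg.norm(v)
        if nv == 0:
            return np.zeros(n)
        step = h / nv
        gp = potential.energy_gradient(x + step * v)[1]
        gm = potential.energy_gradient(x - step * v)[1]
        return (gp - gm) / (2 * step)

    op = LinearOperator((n, n), matvec=hv)
    try:
        vals, vecs = eigsh(op, k=1, which="SA", v0=v0, maxiter=400, tol=1e-7)
        lam, v = float(vals[0]), vecs[:, 0]
    except Exception:
        H = hessian_fd(potential, x, h)
        w, V = np.linalg.eigh(H)
        lam, v = float(w[0]), V[:, 0]
    if v0 is not None and np.dot(v, v0) < 0:
        v = -v
    return lam, v / np.linalg.norm(v)


def count_negative_modes(
    potential, x: np.ndarray, zero_tol: float = ZERO_MODE_TOL
) -> tuple[int, int]:
    """(number of negative, number of near-zero) Hessian eigenvalues.

    Rigid-body zero modes (global translation/rotation) show up in the
    near-zero count; curvature statements refer to the remaining modes.
    """
    H = hessian_fd(potential, x)
    w = np.linalg.eigvalsh(H)
    return int(np.sum(w < -zero_tol)), int(np.sum(np.abs(w) <= zero_tol))


def _perp_minimize(potential, x, v, tol, maxiter=30):
    """Relax x in the subspace orthogonal to v (projected-gradient FIRE)."""
    dt, dt_max, alpha0 = 0.02, 0.1, 0.1
    alpha, n_up = alpha0, 0
    vel = np.zeros_like(x)
    for _ in range(maxiter):
        _, g = potential.energy_gradient(x)
        gp = g - np.dot(g, v) * v
        if np.abs(gp).max() < tol:
            break
        f = -gp
        power = float(np.dot(f, vel))
        if power > 0:
            n_up += 1
            fn, vn = np.linalg.norm(f), np.linalg.norm(vel)
            if fn > 0:
                vel = (1 - alpha) * vel + alpha * vn * f / fn
            if n_up > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            vel[:] = 0.0
            dt *= 0.5
            alpha, n_up = alpha0, 0
        vel += dt * f
        step = dt * vel
        sn = np.linalg.norm(step)
        if sn > 0.1:
            step *= 0.1 / sn
        x = x + step
    return x


@dataclass
class EFResult:
    x: np.ndarray
    energy: float
    eigenvalue: float
    eigenvector: np.ndarray
    converged: bool
    n_negative: int | None = None


def hybrid_ef_refine(
    potential,
    x0: np.ndarray,
    tol: float = 1e-5,
    max_uphill: float = 0.25,
    maxiter: int = 200,
    check_index: bool = True,
) -> EFResult:
    """Refine a saddle candidate by hybrid eigenvector following.

    Alternates a Newton step uphill along the lowest eigenvector with
    projected minimization in the orthogonal subspace.  Fails (converged
    False) if the walk collapses to a minimum or a higher-index saddle.
    """
    x = np.asarray(x0, float).copy()
    v = None
    lam = 0.0
    non_negative = 0
    for it in range(maxiter):
        lam, v = lowest_mode(potential, x, v0=v)
        e, g = potential.energy_gradient(x)
        if np.abs(g).max() <= tol and lam < -ZERO_MODE_TOL:
            break
        if lam < -ZERO_MODE_TOL:
            step = -np.dot(g, v) / lam
            step = float(np.clip(step, -max_uphill, max_uphill))
            x = x + step * v
            x = _perp_minimize(potential, x, v, tol, maxiter=25)
            non_negative = 0
        else:
            non_negative += 1
            if non_negative > 8:
                e, g = potential.energy_gradient(x)
                return EFResult(x, e, lam, v, False)
            # push along the softest mode, away from the basin bottom
            sign = 1.0 if np.dot(g, v) <= 0 else -1.0
            x = x + sign * 0.1 * v
    e, g = potential.energy_gradient(x)
    ok = np.abs(g).max() <= tol and lam < -ZERO_MODE_TOL
    n_neg = None
    if ok and check_index and len(x) <= 120:
        n_neg, _ = count_negative_modes(potential, x)
        if n_neg != 1:
            ok = False
    return EFResult(x, e, lam, v, ok, n_neg)


def generic_quench(potential, x, tol=1e-6, maxiter=3000):
    res = _scipy_minimize(
        potential.energy_gradient, x, jac=True, method="L-BFGS-B",
        options=dict(maxiter=maxiter, ftol=1e-15, gtol=tol / 10),
    )
    return res.x, float(res.fun)


def fall_off(
    potential, ts_x: np.ndarray, v: np.ndarray, delta: float = 0.2, tol: float = 1e-5,
    quench=None,
):
    """Quench small +/- displacements along the TS eigenvector; returns the
    two (x, energy) endpoint minima."""
    quench = quench or (lambda p, x: generic_quench(p, x, tol))
    plus = quench(potential, ts_x + delta * v)
    minus = quench(potential, ts_x - delta * v)
    return plus, minus


# ---------------------------------------------------------------------------
# landscape database
# ---------------------------------------------------------------------------

@dataclass
class TransitionState:
    config: ClusterConfig | None
    energy: float
    connected_minima: tuple[int, int]
    lowest_eigenvalue: float
    x: np.ndarray | None = None


class LandscapeDB:
    """Minima + transition states + undirected connectivity multigraph.

    Minimum ids are stable insertion indices (not energy ranks); use
    :meth:`gm_id` for the lowest-energy minimum.
    """

    def __init__(self, dedup_tolerance: float = 1e-4, structural_tolerance: float = 1e-3):
        self.dedup_tolerance = dedup_tolerance
        self.structural_tolerance = structural_tolerance
        self.minima: list[tuple[float, ClusterConfig | None]] = []
        self._fps: list[np.ndarray | None] = []
        self.transition_states: list[TransitionState] = []
        self.graph = nx.MultiGraph()

    @classmethod
    def from_minima(cls, db: MinimaDatabase, k: int | None = None) -> "LandscapeDB":
        ldb = cls(db.dedup_tolerance)
        for rec in db.records[: (k or len(db.records))]:
            ldb.add_minimum(rec.energy, rec.config)
        return ldb

    # -- minima -------------------------------------------------------------
    def add_minimum(self, energy: float, config: ClusterConfig | None) -> int:
        idx = self.find_minimum(energy, config)
        if idx is not None:
            return idx
        self.minima.append((energy, config))
        self._fps.append(structure_fingerprint(config) if config is not None else None)
        i = len(self.minima) - 1
        self.graph.add_node(i)
        return i

    def find_minimum(self, energy: float, config: ClusterConfig | None) -> int | None:
        fp = structure_fingerprint(config) if config is not None else None
        for i, (e, _) in enumerate(self.minima):
            if abs(e - energy) > self.dedup_tolerance:
                continue
            other = self._fps[i]
            if fp is None or other is None:
                return i
            if other.shape == fp.shape and np.max(np.abs(other - fp)) <= self.structural_tolerance:
                return i
        return None

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.minima])

    def gm_id(self) -> int:
        return int(np.argmin(self.energies))

    # -- transition states ----------------------------------------------------
    def add_transition_state(
        self,
        energy: float,
        pair: tuple[int, int],
        config: ClusterConfig | None = None,
        lowest_eigenvalue: float = 0.0,
        x: np.ndarray | None = None,
    ) -> int:
        i, j = pair
        # keep only one TS per (pair, energy) within tolerance
        for idx, ts in enumerate(self.transition_states):
            if set(ts.connected_minima) == {i, j} and abs(ts.energy - energy) <= self.dedup_tolerance:
                return idx
        ts = TransitionState(config, energy, (i, j), lowest_eigenvalue, x)
        self.transition_states.append(ts)
        k = len(self.transition_states) - 1
        self.graph.add_edge(i, j, key=k, ts=k, energy=energy)
        return k

    def gm_component(self) -> set[int]:
        return set(nx.node_connected_component(self.graph, self.gm_id()))


# ---------------------------------------------------------------------------
# connecting minima
# ---------------------------------------------------------------------------

def _cluster_quench(species_list, tol):
    def q(potential, x):
        cfg = ClusterConfig(
            species_list, x.reshape(-1, 6)[:, :3], x.reshape(-1, 6)[:, 3:]
        )
        c, e = local_minimize(cfg, tolerance=tol, potential=potential)
        return c.coords, e

    return q


def connect_pair(
    ldb: LandscapeDB,
    potential: ClusterPotential,
    i: int,
    j: int,
    n_images: int = 11,
    dneb_tol: float = 1e-3,
    dneb_maxiter: int = 600,
    ef_tol: float = 1e-5,
    quench_tol: float = 1e-5,
    check_index: bool = False,
    attempt: int = 0,
) -> list[int]:
    """DNEB + EF between minima i and j of ``ldb``; inserts discovered TSs
    (and any new fall-off minima) and returns the new TS ids.

    ``attempt`` makes repeated tries of the same pair explore differently:
    the band gets more images and a small deterministic transverse kick.
    """
    ea, ca = ldb.minima[i]
    eb, cb = ldb.minima[j]
    cb_al = align_clusters(ca, cb)
    interp = make_cluster_interpolator(ca.species_list)
    n_img = n_images + 6 * attempt
    if attempt > 0:
        rng = np.random.default_rng(7000 + attempt)
        base = interp

        def interp_kicked(xa, xb, t, _rng=rng, _base=base):
            x = _base(xa, xb, t)
            kick = 0.12 * attempt * math.sin(math.pi * t)
            return x + kick * rng.normal(size=x.shape)

        interp_used = interp_kicked
    else:
        interp_used = interp
    band = dneb(
        potential, ca.coords, cb_al.coords, n_images=n_img,
        tol=dneb_tol, maxiter=dneb_maxiter + 200 * attempt,
        interpolator=interp_used,
    )
    quench = _cluster_quench(ca.species_list, quench_tol)
    new_ts = []
    for cand in band.candidates:
        ef = hybrid_ef_refine(potential, cand, tol=ef_tol, check_index=check_index)
        if not ef.converged:
            continue
        (xp, ep), (xm, em) = fall_off(potential, ef.x, ef.eigenvector, quench=quench)
        cp = ca.with_coords(xp, energy=ep).wrapped()
        cm = ca.with_coords(xm, energy=em).wrapped()
        ip = ldb.add_minimum(ep, cp)
        im = ldb.add_minimum(em, cm)
        ts_cfg = ca.with_coords(ef.x, energy=ef.energy).wrapped()
        k = ldb.add_transition_state(
            ef.energy, (ip, im), ts_cfg, ef.eigenvalue, ef.x
        )
        new_ts.append(k)
    return new_ts


class _DistanceCache:
    """Aligned all-site RMSD between landscape minima, memoized."""

    def __init__(self, ldb: LandscapeDB):
        self.ldb = ldb
        self._cache: dict[tuple[int, int], float] = {}

    def __call__(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self._cache:
            ca = self.ldb.minima[key[0]][1]
            cb = self.ldb.minima[key[1]][1]
            if ca is None or cb is None:
                d = abs(self.ldb.minima[i][0] - self.ldb.minima[j][0])
            else:
                cb2 = align_clusters(ca, cb)
                d = float(
                    np.sqrt(
                        (
                            (np.vstack(ca.site_positions()) - np.vstack(cb2.site_positions()))
                            ** 2
                        )
                        .sum(axis=1)
                        .mean()
                    )
                )
            self._cache[key] = d
        return self._cache[key]


def connect_minima(
    ldb: LandscapeDB,
    potential: ClusterPotential,
    ia: int,
    ib: int,
    budget: int = 25,
    distance_cache: "_DistanceCache | None" = None,
    attempt_counts: dict | None = None,
    **connect_kwargs,
) -> bool:
    """Establish a TS path between minima ia and ib (missing-connection
    algorithm): repeatedly Dijkstra an auxiliary graph whose unconnected
    edges are weighted by squared structural distance (repeat attempts are
    penalized), and run DNEB + EF on the best unconnected gap.

    Returns True when the two minima end up in the same component.
    """
    dist = distance_cache or _DistanceCache(ldb)
    attempts = attempt_counts if attempt_counts is not None else {}
    # escalated direct attempts first: for structurally close endpoints the
    # direct band usually holds the lowest saddle
    direct = (min(ia, ib), max(ia, ib))
    spent = 0
    while attempts.get(direct, 0) < 3 and spent < budget:
        if nx.has_path(ldb.graph, ia, ib):
            return True
        attempts[direct] = attempts.get(direct, 0) + 1
        spent += 1
        connect_pair(ldb, potential, ia, ib, attempt=attempts[direct] - 1,
                     **connect_kwargs)
    for _ in range(budget - spent):
        if nx.has_path(ldb.graph, ia, ib):
            return True
        n = len(ldb.minima)
        aux = nx.Graph()
        aux.add_nodes_from(range(n))
        for u, v in ldb.graph.edges():
            if u != v:
                aux.add_edge(u, v, weight=1e-6, connected=True)
        for u in range(n):
            for v in range(u + 1, n):
                if aux.has_edge(u, v):
                    continue
                key = (u, v)
                d = dist(u, v)
                w = d * d * (4.0 ** attempts.get(key, 0))
                aux.add_edge(u, v, weight=w, connected=False)
        try:
            path = nx.dijkstra_path(aux, ia, ib)
        except nx.NetworkXNoPath:  # pragma: no cover
            return False
        gaps = [
            (u, v)
            for u, v in zip(path[:-1], path[1:])
            if not aux.edges[u, v]["connected"]
        ]
        if not gaps:
            return True
        # attack the narrowest unconnected gap on the candidate path
        u, v = min(gaps, key=lambda p: dist(*p))
        key = (min(u, v), max(u, v))
        attempts[key] = attempts.get(key, 0) + 1
        connect_pair(ldb, potential, u, v, attempt=attempts[key] - 1,
                     **connect_kwargs)
    return nx.has_path(ldb.graph, ia, ib)


def refine_barrier(
    ldb: LandscapeDB,
    potential: ClusterPotential,
    ia: int,
    ib: int,
    budget: int = 30,
    margin: float = 0.05,
    distance_cache: "_DistanceCache | None" = None,
    attempt_counts: dict | None = None,
    **connect_kwargs,
) -> float:
    """Drive the min-max barrier between two connected minima downward.

    Each round looks for a candidate path all of whose existing TSs lie
    below the current barrier (minus ``margin``), treating pairs without
    such a TS as gaps weighted by structural distance, and attempts to
    close the narrowest gap with DNEB + EF.  Stops when no structurally
    plausible better path remains or the attempt budget is exhausted.
    Returns the final barrier (relative to minimum ``ia``).
    """
    dist = distance_cache or _DistanceCache(ldb)
    attempts = attempt_counts if attempt_counts is not None else {}
    direct = (min(ia, ib), max(ia, ib))
    spent = 0
    while attempts.get(direct, 0) < 3 and spent < budget:
        attempts[direct] = attempts.get(direct, 0) + 1
        spent += 1
        connect_pair(ldb, potential, ia, ib, attempt=attempts[direct] - 1,
                     **connect_kwargs)
    for _ in range(budget - spent):
        pw = extract_pathway(ldb, ia, ib)
        b_abs = ldb.minima[ia][0] + pw.barrier
        cut = b_abs - margin
        n = len(ldb.minima)
        # best TS energy per pair
        best_ts: dict[tuple[int, int], float] = {}
        for ts in ldb.transition_states:
            u, v = ts.connected_minima
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            if key not in best_ts or ts.energy < best_ts[key]:
                best_ts[key] = ts.energy
        aux = nx.Graph()
        aux.add_nodes_from(i for i in range(n) if ldb.minima[i][0] < cut)
        if ia not in aux or ib not in aux:
            break
        for u in aux.nodes:
            for v in aux.nodes:
                if v <= u:
                    continue
                key = (u, v)
                if key in best_ts and best_ts[key] <= cut:
                    aux.add_edge(u, v, weight=1e-6, connected=True)
                else:
                    d = dist(u, v)
                    aux.add_edge(
                        u, v, weight=d * d * (4.0 ** attempts.get(key, 0)),
                        connected=False,
                    )
        try:
            path = nx.dijkstra_path(aux, ia, ib)
        except nx.NetworkXNoPath:
            break
        gaps = [
            (u, v) for u, v in zip(path[:-1], path[1:])
            if not aux.edges[u, v]["connected"]
        ]
        if not gaps:  # should not happen: such a path would lower the barrier
            break
        u, v = min(gaps, key=lambda p: dist(*p))
        key = (min(u, v), max(u, v))
        if attempts.get(key, 0) >= 5:
            # refuse to hammer one gap forever
            attempts[key] += 1
            continue
        attempts[key] = attempts.get(key, 0) + 1
        connect_pair(ldb, potential, u, v, attempt=attempts[key] - 1,
                     **connect_kwargs)
    return extract_pathway(ldb, ia, ib).barrier


def connect_database(
    db: MinimaDatabase | LandscapeDB,
    potential: ClusterPotential | None = None,
    budget: int = 50,
    k_lowest: int | None = 20,
    **connect_kwargs,
) -> LandscapeDB:
    """Build a landscape network around the global minimum.

    Works through the initial minima in ascending energy order, driving a
    missing-connection search from the GM to each; stops once ``budget``
    DNEB attempts have been spent.  Best-effort: the GM's connected
    component may not cover every minimum at small budgets.
    """
    if isinstance(db, LandscapeDB):
        ldb = db
    else:
        ldb = LandscapeDB.from_minima(db, k=k_lowest)
    if not ldb.minima:
        return ldb
    if potential is None:
        cfg = next(c for _, c in ldb.minima if c is not None)
        potential = ClusterPotential(cfg.species_list)
    n_initial = len(ldb.minima)
    gm = ldb.gm_id()
    dist = _DistanceCache(ldb)
    attempts: dict = {}
    spent = 0
    order = list(np.argsort(ldb.energies[:n_initial]))
    for j in order:
        j = int(j)
        if j == gm or spent >= budget:
            continue
        share = min(budget - spent, max(5, budget // max(1, n_initial - 1)))
        before = sum(attempts.values())
        connect_minima(
            ldb, potential, gm, j, budget=share,
            distance_cache=dist, attempt_counts=attempts, **connect_kwargs,
        )
        spent += sum(attempts.values()) - before
    return ldb


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

@dataclass
class Pathway:
    """Alternating minimum/TS sequence: ids, energies, and the barrier
    relative to the start minimum."""

    minima: list[int]
    transition_states: list[int]
    energies: list[float]          # alternating min, ts, min, ts, ... , min
    barrier: float

    @property
    def first_ts_energy(self) -> float | None:
        if not self.transition_states:
            return None
        return self.energies[1]


def extract_pathway(ldb: LandscapeDB, min_a: int, min_b: int) -> Pathway:
    """Min-max pathway: minimizes the highest intervening TS energy.

    barrier = (highest TS on the path) - E(min_a); an empty path with zero
    barrier is returned when min_a == min_b.
    """
    ea = ldb.minima[min_a][0]
    if min_a == min_b:
        return Pathway([min_a], [], [ea], 0.0)
    g = ldb.graph
    if not nx.has_path(g, min_a, min_b):
        raise ValueError(f"minima {min_a} and {min_b} are not connected")
    # threshold = lowest TS energy at which a and b join (union-find sweep)
    edges = sorted(
        ((d["energy"], u, v, d["ts"]) for u, v, d in g.edges(data=True)),
        key=lambda t: t[0],
    )
    import networkx.utils as nxu

    uf = nxu.UnionFind(g.nodes)
    threshold = None
    for e_ts, u, v, k in edges:
        uf.union(u, v)
        if uf[min_a] == uf[min_b]:
            threshold = e_ts
            break
    assert threshold is not None
    # shortest path restricted to TSs at or below the threshold
    sub_edges = [
        (u, v, k) for u, v, k, d in g.edges(keys=True, data=True)
        if d["energy"] <= threshold + 1e-12
    ]
    sub = nx.Graph()
    sub.add_nodes_from(g.nodes)
    best_edge: dict[tuple[int, int], int] = {}
    for u, v, k in sub_edges:
        ts_id = g.edges[u, v, k]["ts"]
        e = g.edges[u, v, k]["energy"]
        key = (min(u, v), max(u, v))
        if key not in best_edge or ldb.transition_states[best_edge[key]].energy > e:
            best_edge[key] = ts_id
        sub.add_edge(u, v)
    nodes = nx.shortest_path(sub, min_a, min_b)
    ts_ids = []
    energies = [ldb.minima[nodes[0]][0]]
    for u, v in zip(nodes[:-1], nodes[1:]):
        ts_id = best_edge[(min(u, v), max(u, v))]
        ts_ids.append(ts_id)
        energies.append(ldb.transition_states[ts_id].energy)
        energies.append(ldb.minima[v][0])
    barrier = max(ldb.transition_states[t].energy for t in ts_ids) - ea
    return Pathway(nodes, ts_ids, energies, barrier)


# ---------------------------------------------------------------------------
# disconnectivity
# ---------------------------------------------------------------------------

@dataclass
class DisconnectivityTree:
    """Superbasin tree: at each energy level, groups of minima mutually
    reachable through TSs at or below that level."""

    levels: np.ndarray                      # ascending level energies
    superbasins: list[list[frozenset]]      # per level, sets of minimum ids
    minima_energies: np.ndarray

    def n_branches(self, level_idx: int) -> int:
        return len(self.superbasins[level_idx])

    def to_dict(self) -> dict:
        return {
            "levels": self.levels.tolist(),
            "superbasins": [
                [sorted(sb) for sb in level] for level in self.superbasins
            ],
            "minima_energies": self.minima_energies.tolist(),
        }

    def segments(self) -> list[dict]:
        """Plot-ready vertical line segments (one per superbasin & level)."""
        segs = []
        for li, level in enumerate(self.superbasins):
            for sb in level:
                segs.append(
                    {
                        "level": float(self.levels[li]),
                        "minima": sorted(sb),
                        "lowest": float(self.minima_energies[sorted(sb)].min()),
                    }
                )
        return segs


def build_disconnectivity(
    ldb: LandscapeDB, delta_e: float = 0.35, e_max: float | None = None
) -> DisconnectivityTree:
    """Union-find superbasin analysis at uniformly spaced energy levels.

    Levels run from just above the GM energy up to ``e_max`` (default: the
    highest TS energy plus one spacing).  Minima above a level, and minima
    only reachable over TSs above it, sit in separate superbasins.
    """
    E = ldb.energies
    if len(E) == 0:
        raise ValueError("no minima")
    e0 = E.min()
    ts_list = ldb.transition_states
    if e_max is None:
        top = max((ts.energy for ts in ts_list), default=e0)
        e_max = max(top, E.max()) + delta_e
    n_levels = max(1, int(math.ceil((e_max - e0) / delta_e)))
    levels = e0 + delta_e * np.arange(1, n_levels + 1)
    import networkx.utils as nxu

    superbasins = []
    for lev in levels:
        uf = nxu.UnionFind(i for i in range(len(E)) if E[i] <= lev)
        for ts in ts_list:
            i, j = ts.connected_minima
            if ts.energy <= lev and E[i] <= lev and E[j] <= lev:
                uf.union(i, j)
        groups: dict = {}
        for i in range(len(E)):
            if E[i] <= lev:
                groups.setdefault(uf[i], set()).add(i)
        superbasins.append([frozenset(s) for s in groups.values()])
    return DisconnectivityTree(levels, superbasins, E.copy())
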