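"""Total interaction energy and analytic rigid-body gradient.

The energy is a sum of Coulomb and Lennard-Jones terms over all
inter-molecular site pairs,

    U = sum_{i<j} 4 eps_ij [ (sig_ij/r_ij)^12 - (sig_ij/r_ij)^6 ]
               + k_C q_i q_j / r_ij ,

with no cutoff and no periodic images (gas-phase clusters).  Unlike-site
LJ parameters use a configurable combining rule: "geometric" (default,
OPLS/TIP4P convention: geometric mean for both sigma and epsilon) or
"lorentz_berthelot" (arithmetic sigma, geometric epsilon).

Gradients are with respect to rigid-body coordinates: per-molecule COM
translation and rotation-vector components.  The rotational part goes
through the analytic derivative of the rotation matrix (``_rotation``).
"""
from __future__ import annotations

import numpy as np

from . import _kernels
from ._rotation import rotation_matrices, rotation_matrix_derivatives
from .constants import K_COULOMB, OVERLAP_FLOOR
from .forcefield import ClusterConfig, SpeciesSpec

__all__ = [
    "pair_site_energy",
    "total_energy",
    "analytic_gradient",
    "ClusterPotential",
    "EnergyGradient",
    "OverlapError",
]

COMBINING_RULES = ("geometric", "lorentz_berthelot")


class OverlapError(ValueError):
    """Two inter-molecular sites are closer than the hard overlap floor."""


def pair_site_energy(
    r_ij: float, sigma_ij: float, epsilon_ij: float, q_i: float, q_j: float
) -> float:
    """Energy (kcal/mol) of one site pair at separation r_ij (Angstrom).

    The LJ term is omitted when epsilon_ij or sigma_ij is zero.
    """
    if r_ij <= 0:
        raise OverlapError(f"non-positive site separation {r_ij}")
    e = K_COULOMB * q_i * q_j / r_ij
    if epsilon_ij > 0 and sigma_ij > 0:
        sr6 = (sigma_ij / r_ij) ** 6
        e += 4.0 * epsilon_ij * (sr6 * sr6 - sr6)
    return e


# ---------------------------------------------------------------------------
# site-pair kernels (numba-accelerated with a pure-numpy fallback)
# ---------------------------------------------------------------------------

def _numpy_kernel(pos, q, eps, sig, molid, geometric, k_c):
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    inter = molid[:, None] != molid[None, :]
    iu = np.triu(inter, k=1)
    r2p = np.where(inter, r2, 1.0)
    rmin = float(np.sqrt(r2[iu].min())) if iu.any() else np.inf
    r = np.sqrt(r2p)
    inv_r = 1.0 / r
    qq = q[:, None] * q[None, :]
    e_c = k_c * qq * inv_r
    de_c = -e_c * inv_r
    epsij = np.sqrt(eps[:, None] * eps[None, :])
    if geometric:
        sigij = np.sqrt(sig[:, None] * sig[None, :])
    else:
        has = (sig[:, None] > 0) & (sig[None, :] > 0)
        sigij = np.where(has, 0.5 * (sig[:, None] + sig[None, :]), 0.0)
    sr6 = (sigij * inv_r) ** 6
    e_lj = 4.0 * epsij * (sr6 * sr6 - sr6)
    de_lj = 4.0 * epsij * (-12.0 * sr6 * sr6 + 6.0 * sr6) * inv_r
    e = np.where(iu, e_c + e_lj, 0.0)
    dudr = np.where(inter, de_c + de_lj, 0.0)
    U = float(e.sum())
    coef = dudr * inv_r
    g = np.einsum("ij,ijk->ik", coef, diff)
    return U, g, rmin


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    @njit(cache=True)
    def _numba_kernel(pos, q, eps, sig, molid, geometric, k_c):  # pragma: no cover
        n = pos.shape[0]
        U = 0.0
        g = np.zeros((n, 3))
        rmin = 1e30
        for i in range(n - 1):
            for j in range(i + 1, n):
                if molid[i] == molid[j]:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = np.sqrt(r2)
                if r < rmin:
                    rmin = r
                e = 0.0
                dudr = 0.0
                qq = q[i] * q[j]
                if qq != 0.0:
                    ec = k_c * qq / r
                    e += ec
                    dudr -= ec / r
                if eps[i] > 0.0 and eps[j] > 0.0 and sig[i] > 0.0 and sig[j] > 0.0:
                    epsij = np.sqrt(eps[i] * eps[j])
                    if geometric:
                        sigij = np.sqrt(sig[i] * sig[j])
                    else:
                        sigij = 0.5 * (sig[i] + sig[j])
                    s2 = sigij * sigij / r2
                    sr6 = s2 * s2 * s2
                    sr12 = sr6 * sr6
                    e += 4.0 * epsij * (sr12 - sr6)
                    dudr += 4.0 * epsij * (-12.0 * sr12 + 6.0 * sr6) / r
                U += e
                c = dudr / r
                g[i, 0] += c * dx
                g[i, 1] += c * dy
                g[i, 2] += c * dz
                g[j, 0] -= c * dx
                g[j, 1] -= c * dy
                g[j, 2] -= c * dz
        return U, g, rmin

    _KERNEL = _numba_kernel
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _KERNEL = _numpy_kernel
    HAVE_NUMBA = False


class EnergyGradient:
    """Energy + per-molecule translational and rotational gradients."""

    __slots__ = ("energy", "translational", "rotational")

    def __init__(self, energy: float, translational: np.ndarray, rotational: np.ndarray):
        self.energy = energy
        self.translational = translational
        self.rotational = rotational

    @property
    def flat(self) -> np.ndarray:
        """Gradient in the packed (6M,) coordinate layout."""
        return np.concatenate(
            [np.concatenate([t, p]) for t, p in zip(self.translational, self.rotational)]
        )

    def max_abs(self) -> float:
        return float(np.abs(self.flat).max())


class ClusterPotential:
    """Precompiled energy/gradient evaluator for a fixed species list.

    Operates on the packed coordinate vector x (6M,); site parameter arrays
    are flattened once at construction so repeated evaluation inside
    optimizers stays cheap.
    """

    def __init__(
        self,
        species_list: tuple[SpeciesSpec, ...],
        combining_rule: str = "geometric",
    ):
        if combining_rule not in COMBINING_RULES:
            raise ValueError(f"combining_rule must be one of {COMBINING_RULES}")
        self.species_list = tuple(species_list)
        self.combining_rule = combining_rule
        body, eps, sig, q, molid = [], [], [], [], []
        for m, sp in enumerate(self.species_list):
            for s in sp.sites:
                body.append(s.body_position)
                eps.append(s.epsilon)
                sig.append(s.sigma)
                q.append(s.charge)
                molid.append(m)
        self.body = np.array(body)
        self.eps = np.array(eps)
        self.sig = np.array(sig)
        self.q = np.array(q)
        self.molid = np.array(molid, dtype=np.int64)
        self.n_sites = len(molid)
        self.n_molecules = len(self.species_list)
        self.n_dof = 6 * self.n_molecules

    # -- coordinate helpers -------------------------------------------------
    def site_positions(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(self.n_molecules, 6)
        R = rotation_matrices(x[:, 3:])
        return (
            np.einsum("nij,nj->ni", R[self.molid], self.body)
            + x[:, :3][self.molid]
        )

    def _eval(self, x):
        pos = self.site_positions(x)
        U, gsite, rmin = _KERNEL(
            pos, self.q, self.eps, self.sig, self.molid,
            self.combining_rule == "geometric", K_COULOMB,
        )
        if rmin < OVERLAP_FLOOR:
            raise OverlapError(
                f"inter-molecular site separation {rmin:.2e} A below overlap floor"
            )
        return U, gsite

    def energy(self, x: np.ndarray) -> float:
        if _kernels.HAVE_NUMBA:
            return self.energy_gradient(x)[0]
        return self._eval(x)[0]

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy and packed gradient d U / d x."""
        if _kernels.HAVE_NUMBA:
            xf = np.ascontiguousarray(x, dtype=float).reshape(-1)
            U, g, rmin = _kernels.eval_energy_gradient(
                xf, self.body, self.eps, self.sig, self.q, self.molid,
                self.n_molecules, self.combining_rule == "geometric", K_COULOMB,
            )
            if rmin < OVERLAP_FLOOR:
                raise OverlapError(
                    f"inter-molecular site separation {rmin:.2e} A below overlap floor"
                )
            return U, g
        return self._energy_gradient_numpy(x)

    def _energy_gradient_numpy(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(x, dtype=float).reshape(self.n_molecules, 6)
        U, gsite = self._eval(x)
        gT = np.zeros((self.n_molecules, 3))
        np.add.at(gT, self.molid, gsite)
        dR = rotation_matrix_derivatives(x[:, 3:])  # (M, 3, 3, 3)
        # v[s, k, :] = dR/dp_k (molecule of s) . body_s
        v = np.einsum("nkij,nj->nki", dR[self.molid], self.body)
        contrib = np.einsum("ni,nki->nk", gsite, v)
        gP = np.zeros((self.n_molecules, 3))
        np.add.at(gP, self.molid, contrib)
        g = np.concatenate([gT, gP], axis=1).reshape(-1)
        return U, g

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.energy_gradient(x)[1]

    # scipy-style objective
    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        return self.energy_gradient(x)


def _potential_for(cluster: ClusterConfig, combining_rule: str) -> ClusterPotential:
    return ClusterPotential(cluster.species_list, combining_rule)


def total_energy(cluster: ClusterConfig, combining_rule: str = "geometric") -> float:
    """Total interaction energy of a cluster (kcal/mol).

    Intra-molecular pairs are excluded (rigid bodies); a single molecule
    has zero interaction energy.
    """
    if cluster.n_molecules == 0:
        raise ValueError("empty cluster")
    if cluster.n_molecules == 1:
        return 0.0
    pot = _potential_for(cluster, combining_rule)
    return pot.energy(cluster.coords)


def analytic_gradient(
    cluster: ClusterConfig, combining_rule: str = "geometric"
) -> EnergyGradient:
    """Energy and analytic gradient w.r.t. rigid-body coordinates."""
    pot = _potential_for(cluster, combining_rule)
    U, g = pot.energy_gradient(cluster.coords)
    g = g.reshape(-1, 6)
    return EnergyGradient(U, g[:, :3].copy(), g[:, 3:].copy())
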