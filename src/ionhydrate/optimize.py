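"""Local quenches and basin-hopping global optimization.

Basin-hopping walks over the transformed landscape of minima: every
proposed geometry perturbation is followed by a local quench, and the
Metropolis test is applied to quenched energies.  Moves are applied in
blocks of ``block_size`` consecutive moves of the same class, cycling
translate -> rotate -> cycle-invert.  Every distinct quenched minimum is
recorded in a deduplicated :class:`MinimaDatabase`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from . import _kernels
from ._rotation import compose_rotvec, minimal_rotation_between, random_rotvec
from .constants import K_COULOMB
from .energy import ClusterPotential
from .forcefield import ClusterConfig
from .hbond import HBondCriterion, detect_hbonds, directed_water_cycles

__all__ = [
    "BasinHoppingConfig",
    "MinimumRecord",
    "MinimaDatabase",
    "QuenchFailure",
    "local_minimize",
    "move_translate",
    "move_rotate",
    "move_cycle_invert",
    "run_basin_hopping",
    "random_initial_cluster",
]

#: quenched structures with any inter-molecular site pair closer than this
#: are treated as charge-collapse artifacts and rejected
COLLAPSE_FLOOR = 0.9


class QuenchFailure(RuntimeError):
    """Local minimization failed to converge within its iteration cap."""


@dataclass
class BasinHoppingConfig:
    """Parameters of one basin-hopping run.

    ``kT`` is the Metropolis acceptance temperature in kcal/mol (the
    analysis temperature used for Boltzmann-weighted observables is a
    separate concept).  ``translate_subset`` moves only that many randomly
    chosen molecules per translation move; None moves all of them.
    """

    n_steps: int = 10000
    block_size: int = 100
    kT: float = 1.0
    move_classes: tuple[str, ...] = ("translate", "rotate", "cycle_invert")
    translate_step: float = 1.0
    rotate_range: float = math.pi
    seed: int = 0
    quench_tolerance: float = 1e-5
    quench_maxiter: int = 1500
    dedup_tolerance: float = 1e-4
    structural_check: bool = True
    translate_subset: int | None = None
    combining_rule: str = "geometric"
    hbond_criterion: HBondCriterion = field(default_factory=HBondCriterion)
    max_cycle_len: int = 8

    def __post_init__(self):
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.translate_step <= 0 or self.rotate_range <= 0:
            raise ValueError("step sizes must be positive")

    @classmethod
    def from_temperature(cls, temperature_K: float, **kwargs) -> "BasinHoppingConfig":
        from .constants import K_BOLTZMANN

        return cls(kT=K_BOLTZMANN * temperature_K, **kwargs)


@dataclass
class MinimumRecord:
    energy: float
    config: ClusterConfig
    first_found_step: int
    hit_count: int = 1


def structure_fingerprint(config: ClusterConfig) -> np.ndarray:
    """Sorted multiset of inter-molecular COM distances (permutation-invariant)."""
    T = config.translations
    M = len(T)
    iu = np.triu_indices(M, k=1)
    d = np.linalg.norm(T[iu[0]] - T[iu[1]], axis=1)
    return np.sort(d)


class MinimaDatabase:
    """Deduplicated store of quenched minima, retrievable sorted by energy.

    Two quenches are the same minimum when their energies agree within
    ``dedup_tolerance`` AND (if ``structural_check``) their sorted
    COM-distance multisets agree within ``structural_tolerance`` — the
    structural check keeps accidental energy degeneracies (e.g. ring
    direction isomers, enantiomers) as separate records.
    """

    def __init__(
        self,
        dedup_tolerance: float = 1e-4,
        structural_check: bool = True,
        structural_tolerance: float = 1e-3,
    ):
        self.dedup_tolerance = dedup_tolerance
        self.structural_check = structural_check
        self.structural_tolerance = structural_tolerance
        self._records: list[MinimumRecord] = []
        self._energies: list[float] = []
        self._fingerprints: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> list[MinimumRecord]:
        """Records sorted ascending by energy (the putative GM first)."""
        return self._records

    @property
    def energies(self) -> np.ndarray:
        return np.array(self._energies)

    @property
    def global_minimum(self) -> MinimumRecord:
        if not self._records:
            raise ValueError("empty database")
        return self._records[0]

    def _matches(self, i: int, config: ClusterConfig, fp: np.ndarray) -> bool:
        if not self.structural_check:
            return True
        other = self._fingerprints[i]
        if other.shape != fp.shape:
            return False
        return bool(np.max(np.abs(other - fp), initial=0.0) <= self.structural_tolerance)

    def _insert(self, energy: float, config: ClusterConfig, step: int) -> tuple[bool, int]:
        import bisect

        fp = structure_fingerprint(config)
        lo = bisect.bisect_left(self._energies, energy - self.dedup_tolerance)
        hi = bisect.bisect_right(self._energies, energy + self.dedup_tolerance)
        for i in range(lo, hi):
            if self._matches(i, config, fp):
                self._records[i].hit_count += 1
                return False, i
        pos = bisect.bisect_left(self._energies, energy)
        self._energies.insert(pos, energy)
        self._records.insert(pos, MinimumRecord(energy, config.copy(), step))
        self._fingerprints.insert(pos, fp)
        return True, pos

    def insert(self, energy: float, config: ClusterConfig, step: int = 0) -> bool:
        """Insert a quenched minimum; returns True if a new record was created."""
        return self._insert(energy, config, step)[0]

    def merge(self, other: "MinimaDatabase") -> "MinimaDatabase":
        """Merge records from another database (dedup applies, hit counts add)."""
        for rec in other.records:
            created, idx = self._insert(rec.energy, rec.config, rec.first_found_step)
            self._records[idx].hit_count += rec.hit_count - 1
        return self

    def lowest(self, k: int) -> list[MinimumRecord]:
        return self._records[:k]


def db_insert(db: MinimaDatabase, energy: float, config: ClusterConfig, step: int = 0) -> bool:
    """Functional wrapper over :meth:`MinimaDatabase.insert`."""
    return db.insert(energy, config, step)


def refine_database(
    db: MinimaDatabase,
    tolerance: float = 1e-5,
    k: int | None = None,
    combining_rule: str = "geometric",
) -> MinimaDatabase:
    """Re-quench the k lowest records tightly and rebuild the database.

    Loosely quenched walks can record near-flat saddle regions as minima;
    tight re-quenching collapses those onto their true minima (the dedup
    rules then merge them).  Records that fail to re-converge are dropped.
    """
    out = MinimaDatabase(db.dedup_tolerance, db.structural_check,
                         db.structural_tolerance)
    pot = None
    for rec in db.records[: (k or len(db.records))]:
        if pot is None:
            pot = ClusterPotential(rec.config.species_list, combining_rule)
        try:
            cfg, e = local_minimize(rec.config, tolerance, potential=pot)
        except QuenchFailure:
            continue
        created, idx = out._insert(e, cfg, rec.first_found_step)
        out._records[idx].hit_count += rec.hit_count - 1
    return out


# ---------------------------------------------------------------------------
# local quench
# ---------------------------------------------------------------------------

def _quench_flat(
    pot: ClusterPotential, x: np.ndarray, tolerance: float, maxiter: int
) -> tuple[np.ndarray, float, float, bool]:
    """Quench a flat coordinate vector; returns (x, E, gmax, converged)."""
    if _kernels.HAVE_NUMBA:
        xq, f, gmax, conv, _ = _kernels.lbfgs_quench(
            np.ascontiguousarray(x, dtype=float), pot.body, pot.eps, pot.sig,
            pot.q, pot.molid, pot.n_molecules,
            pot.combining_rule == "geometric", K_COULOMB, tolerance, maxiter,
        )
        if conv or not np.isfinite(f):
            return xq, f, gmax, bool(conv)
        # polish a stalled quench with scipy's line search
        x = xq
    res = _scipy_minimize(
        pot.energy_gradient, x, jac=True, method="L-BFGS-B",
        options=dict(maxiter=maxiter, ftol=1e-14, gtol=tolerance / 10),
    )
    gmax = float(np.abs(res.jac).max())
    return res.x, float(res.fun), gmax, gmax <= tolerance


def local_minimize(
    cluster: ClusterConfig,
    tolerance: float = 1e-5,
    maxiter: int = 3000,
    combining_rule: str = "geometric",
    potential: ClusterPotential | None = None,
) -> tuple[ClusterConfig, float]:
    """Quench a configuration to the nearest local minimum.

    The returned configuration has gradient max-norm <= ``tolerance``
    (kcal/mol/A) and energy <= the starting energy; orientations are
    wrapped back to |p| <= pi.
    """
    pot = potential or ClusterPotential(cluster.species_list, combining_rule)
    x0 = cluster.wrapped().coords
    xq, f, gmax, conv = _quench_flat(pot, x0, tolerance, maxiter)
    if not conv:
        raise QuenchFailure(
            f"quench did not reach |g|max <= {tolerance} (got {gmax:.2e})"
        )
    return cluster.with_coords(xq, energy=f).wrapped(), f


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------

def move_translate(
    cluster: ClusterConfig,
    step: float,
    rng: np.random.Generator,
    subset: int | None = None,
) -> ClusterConfig:
    """Displace molecule COMs by independent random vectors of norm <= step."""
    M = cluster.n_molecules
    new = cluster.copy()
    idx = np.arange(M)
    if subset is not None and subset < M:
        idx = rng.choice(M, size=subset, replace=False)
    # uniform in the ball of radius `step`
    d = rng.normal(size=(len(idx), 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    radii = step * rng.random(len(idx)) ** (1.0 / 3.0)
    new.translations[idx] += d * radii[:, None]
    new.energy = None
    return new


def move_rotate(
    cluster: ClusterConfig, rot_range: float, rng: np.random.Generator
) -> ClusterConfig:
    """Compose every molecule's orientation with a random rotation <= rot_range."""
    M = cluster.n_molecules
    new = cluster.copy()
    delta = random_rotvec(rng, rot_range, M)
    new.orientations = compose_rotvec(delta, new.orientations)
    new.energy = None
    return new


def move_cycle_invert(
    cluster: ClusterConfig,
    rng: np.random.Generator,
    criterion: HBondCriterion | None = None,
    max_len: int = 8,
    graph=None,
) -> ClusterConfig | None:
    """Reverse the donor->acceptor direction of one hydrogen-bond cycle.

    Picks a directed water cycle uniformly at random and re-orients each
    member (rotation about its own COM, COM fixed) so that the O-H that
    donated to the next cycle member now points at the previous member's
    oxygen.  Returns None when the configuration has no directed cycle
    (caller falls back to a rotation move).
    """
    g = graph if graph is not None else detect_hbonds(cluster, criterion)
    cycles = directed_water_cycles(g, max_len=max_len)
    if not cycles:
        return None
    cycle = cycles[rng.integers(len(cycles))]
    k = len(cycle)
    # edge lookup: donor -> (H site, acceptor)
    donated = {}
    members = set(cycle)
    for e in g.edges:
        if e.donor_mol in members and e.acceptor_mol in members:
            donated[(e.donor_mol, e.acceptor_mol)] = e
    positions = cluster.site_positions()

    def water_o(m):
        sp = cluster.species_list[m]
        o_idx = next(i for i, s in enumerate(sp.sites) if s.label == "O")
        return positions[m][o_idx]

    new = cluster.copy()
    for i, m in enumerate(cycle):
        nxt = cycle[(i + 1) % k]
        prv = cycle[(i - 1) % k]
        e = donated.get((m, nxt))
        if e is None:  # cycle edge list inconsistent; abort move
            return None
        h_pos = positions[m][e.donor_h_site]
        o_pos = water_o(m)
        u = h_pos - o_pos  # current donated O-H direction
        v = water_o(prv) - o_pos  # new target: previous member's oxygen
        R = minimal_rotation_between(u, v)
        new.orientations[m] = (
            R * Rotation.from_rotvec(cluster.orientations[m])
        ).as_rotvec()
    new.energy = None
    return new


# ---------------------------------------------------------------------------
# initial configurations
# ---------------------------------------------------------------------------

def random_initial_cluster(
    species_list: tuple,
    rng: np.random.Generator,
    min_separation: float = 2.2,
    radius: float | None = None,
) -> ClusterConfig:
    """Random start: molecules uniformly in a sphere of radius ~ N^(1/3),
    random orientations, overlaps resolved by re-draw; any ion is placed
    first at the centre."""
    M = len(species_list)
    if radius is None:
        radius = 2.0 * M ** (1.0 / 3.0) + 1.0
    T = np.zeros((M, 3))
    order = sorted(range(M), key=lambda i: species_list[i].net_charge == 0.0)
    placed = []
    for i in order:
        if species_list[i].net_charge != 0.0 and not placed:
            T[i] = 0.0
            placed.append(T[i])
            continue
        for _ in range(2000):
            cand = rng.normal(size=3)
            cand /= np.linalg.norm(cand)
            cand *= radius * rng.random() ** (1.0 / 3.0)
            if all(np.linalg.norm(cand - p) >= min_separation for p in placed):
                T[i] = cand
                placed.append(cand)
                break
        else:
            raise RuntimeError("could not place molecules without overlap")
    P = random_rotvec(rng, math.pi, M)
    return ClusterConfig(tuple(species_list), T, P)


# ---------------------------------------------------------------------------
# basin-hopping driver
# ---------------------------------------------------------------------------

@dataclass
class BasinHoppingStats:
    proposed: int = 0
    accepted: int = 0
    quench_failures: int = 0
    cycle_fallbacks: int = 0
    evaporations: int = 0
    per_block: list = field(default_factory=list)


def _evaporated(T: np.ndarray, n_mol: int) -> bool:
    centroid = T.mean(axis=0)
    r = np.linalg.norm(T - centroid, axis=1)
    r_ref = 2.5 * n_mol ** (1.0 / 3.0) + 2.0
    return bool(np.any(r > 3.0 * r_ref))


def run_basin_hopping(
    initial: ClusterConfig,
    config: BasinHoppingConfig,
    db: MinimaDatabase | None = None,
    return_stats: bool = False,
):
    """Run seeded basin-hopping from ``initial``; returns a MinimaDatabase.

    Fully reproducible given ``config.seed``: all randomness flows from a
    single ``numpy`` Generator and quenches are deterministic.
    """
    rng = np.random.default_rng(config.seed)
    pot = ClusterPotential(initial.species_list, config.combining_rule)
    if db is None:
        db = MinimaDatabase(config.dedup_tolerance, config.structural_check)
    stats = BasinHoppingStats()

    current, e_cur = local_minimize(
        initial, config.quench_tolerance, config.quench_maxiter, potential=pot
    )
    db.insert(e_cur, current, step=0)

    n_classes = len(config.move_classes)
    fail_window: list[bool] = []
    block_accepts = 0
    for step in range(config.n_steps):
        cls = config.move_classes[(step // config.block_size) % n_classes]
        if cls == "translate":
            proposal = move_translate(
                current, config.translate_step, rng, config.translate_subset
            )
        elif cls == "rotate":
            proposal = move_rotate(current, config.rotate_range, rng)
        elif cls == "cycle_invert":
            proposal = move_cycle_invert(
                current, rng, config.hbond_criterion, config.max_cycle_len
            )
            if proposal is None:
                stats.cycle_fallbacks += 1
                proposal = move_rotate(current, config.rotate_range, rng)
        else:
            raise ValueError(f"unknown move class {cls!r}")
        stats.proposed += 1

        x0 = proposal.wrapped().coords
        xq, e_new, gmax, conv = _quench_flat(
            pot, x0, config.quench_tolerance, config.quench_maxiter
        )
        bad = (not conv) or (not np.isfinite(e_new))
        if not bad:
            quenched = current.with_coords(xq, energy=e_new).wrapped()
            if _evaporated(quenched.translations, quenched.n_molecules):
                stats.evaporations += 1
                bad = True
        fail_window.append(bad)
        if len(fail_window) > 200:
            fail_window.pop(0)
            if sum(fail_window) > 100:
                raise QuenchFailure(
                    "more than 50% quench failures over the last 200 steps"
                )
        if bad:
            stats.quench_failures += 0 if conv else 1
            continue

        db.insert(e_new, quenched, step=step + 1)
        du = e_new - e_cur
        if du <= 0 or rng.random() < math.exp(-du / config.kT):
            # accept; recentre to keep the walk from drifting
            quenched.translations -= quenched.translations.mean(axis=0)
            current, e_cur = quenched, e_new
            stats.accepted += 1
            block_accepts += 1
        if (step + 1) % config.block_size == 0:
            stats.per_block.append(
                {"move_class": cls, "acceptance": block_accepts / config.block_size}
            )
            block_accepts = 0

    if return_stats:
        return db, stats
    return db
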