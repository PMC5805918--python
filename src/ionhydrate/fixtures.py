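"""Deterministic test-geometry generators.

Canonical hydrogen-bonded motifs (linear dimer, trimeric ring, cube
octamer, ion + water shells) constructed analytically so that their
hydrogen-bond graphs are known by design, plus seeded random clusters.
These are first-class library code: the same generators seed basin-hopping
runs and the test suite.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

from .forcefield import ClusterConfig, SpeciesSpec, get_species, water
from .optimize import random_initial_cluster

__all__ = ["orient_water", "water_dimer", "water_trimer_ring", "water_cube",
           "ion_water_shell", "water_bridging_ion", "generate_fixture"]


def _kabsch_vectors(body_dirs: np.ndarray, target_dirs: np.ndarray) -> Rotation:
    """Proper rotation best mapping body-frame unit vectors onto targets."""
    H = target_dirs.T @ body_dirs
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return Rotation.from_matrix(U @ np.diag([1.0, 1.0, d]) @ Vt)


def orient_water(
    o_position: np.ndarray,
    oh_targets: list[np.ndarray],
    species: SpeciesSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pose (translation, rotvec) putting a water's O at ``o_position`` with
    its O-H bond(s) pointing along the given unit direction(s).

    With one target the second OH direction is left free (chosen to tilt
    away from the first); with two targets both bonds are matched in a
    least-squares sense (the H-O-H angle is rigid at 104.52 deg, so
    targets subtending a different angle are split symmetrically).
    """
    sp = species or water()
    body = sp.body_positions
    o_b, h1_b, h2_b = body[0], body[1], body[2]
    u1 = (h1_b - o_b) / np.linalg.norm(h1_b - o_b)
    u2 = (h2_b - o_b) / np.linalg.norm(h2_b - o_b)
    targets = [np.asarray(t, float) / np.linalg.norm(t) for t in oh_targets]
    if len(targets) == 1:
        d1 = targets[0]
        # free OH: any direction at the water angle from d1
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, d1)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        perp = np.cross(d1, ref)
        perp /= np.linalg.norm(perp)
        ang = math.radians(104.52)
        d2 = math.cos(ang) * d1 + math.sin(ang) * np.cross(perp, d1)
        targets = [d1, d2]
    R = _kabsch_vectors(np.array([u1, u2]), np.array(targets))
    t = np.asarray(o_position, float) - R.apply(o_b)
    return t, R.as_rotvec()


def water_dimer(
    oo_distance: float = 2.9, species: SpeciesSpec | None = None
) -> ClusterConfig:
    """Linear hydrogen-bonded dimer: molecule 0 donates one OH along +x to
    the acceptor oxygen of molecule 1."""
    sp = species or water()
    t0, p0 = orient_water(np.zeros(3), [np.array([1.0, 0.0, 0.0])], sp)
    # acceptor: O at (d, 0, 0) with both hydrogens pointing away from the
    # donor (body bisector -z mapped near +x, tilted off-axis)
    q = Rotation.from_rotvec([0.0, math.radians(-65.0), 0.0])
    t1 = np.array([oo_distance, 0.0, 0.0]) - q.apply(sp.body_positions[0])
    return ClusterConfig((sp, sp), np.array([t0, t1]), np.array([p0, q.as_rotvec()]))


def water_trimer_ring(
    oo_distance: float = 2.8, species: SpeciesSpec | None = None
) -> ClusterConfig:
    """Symmetric trimeric ring: each water donates one OH to the next
    (0 -> 1 -> 2 -> 0), free hydrogens pointing up out of the ring plane."""
    sp = species or water()
    r = oo_distance / math.sqrt(3.0)
    o_pos = [
        np.array([r * math.cos(2 * math.pi * k / 3), r * math.sin(2 * math.pi * k / 3), 0.0])
        for k in range(3)
    ]
    T, P = [], []
    for k in range(3):
        d1 = o_pos[(k + 1) % 3] - o_pos[k]
        d1 = d1 / np.linalg.norm(d1)
        # free OH tilted upward, leaning outward from the ring centre
        out = o_pos[k] / np.linalg.norm(o_pos[k])
        d2 = 0.35 * out + np.array([0.0, 0.0, 1.0])
        d2 /= np.linalg.norm(d2)
        sol = _best_two_target_pose(o_pos[k], d1, d2, sp)
        T.append(sol[0])
        P.append(sol[1])
    return ClusterConfig((sp,) * 3, np.array(T), np.array(P))


def _best_two_target_pose(o_pos, d_donate, d_free, sp):
    """Pose matching the donated OH exactly and the free OH approximately.

    The rigid H-O-H angle cannot hit arbitrary target pairs; the donated
    direction is what the H-bond criterion cares about, so match it
    exactly and rotate the free OH as close to its target as the geometry
    allows (rotation about the donated axis).
    """
    body = sp.body_positions
    o_b = body[0]
    u1 = (body[1] - o_b) / np.linalg.norm(body[1] - o_b)
    u2 = (body[2] - o_b) / np.linalg.norm(body[2] - o_b)
    from ._rotation import minimal_rotation_between

    R0 = minimal_rotation_between(u1, d_donate)
    # spin about the donated axis to bring the free OH closest to d_free
    w = R0.apply(u2)
    axis = d_donate
    # components perpendicular to axis
    w_perp = w - np.dot(w, axis) * axis
    f_perp = d_free - np.dot(d_free, axis) * axis
    if np.linalg.norm(w_perp) > 1e-12 and np.linalg.norm(f_perp) > 1e-12:
        w_perp /= np.linalg.norm(w_perp)
        f_perp /= np.linalg.norm(f_perp)
        ang = math.atan2(np.dot(np.cross(w_perp, f_perp), axis), np.dot(w_perp, f_perp))
        R = Rotation.from_rotvec(ang * axis) * R0
    else:
        R = R0
    t = np.asarray(o_pos, float) - R.apply(o_b)
    return t, R.as_rotvec()


# cube-edge H-bond orientation: a Hamiltonian cycle (out-degree 1 each)
# plus a perfect matching of the remaining four edges
_CUBE_CYCLE = [(0, 4), (4, 6), (6, 2), (2, 3), (3, 7), (7, 5), (5, 1), (1, 0)]
_CUBE_EXTRA = [(0, 2), (1, 3), (4, 5), (6, 7)]


def water_cube(edge: float = 2.8, species: SpeciesSpec | None = None) -> ClusterConfig:
    """Cubic water octamer: oxygens at cube corners, H bonds along all 12
    edges (each water donates 1 or 2), four free OH pointing outward.

    Corner index encodes coordinates: bit k of the index is the k-th
    coordinate (0 or 1) scaled by ``edge``.
    """
    sp = species or water()
    corners = np.array(
        [[(i >> 0) & 1, (i >> 1) & 1, (i >> 2) & 1] for i in range(8)], float
    ) * edge
    centre = corners.mean(axis=0)
    donations: dict[int, list[int]] = {i: [] for i in range(8)}
    for a, b in _CUBE_CYCLE + _CUBE_EXTRA:
        donations[a].append(b)
    T, P = [], []
    for i in range(8):
        targets = [
            (corners[j] - corners[i]) / np.linalg.norm(corners[j] - corners[i])
            for j in donations[i]
        ]
        if len(targets) == 2:
            t, p = orient_water(corners[i], targets, sp)
        else:
            out = corners[i] - centre
            d_free = out / np.linalg.norm(out)
            t, p = _best_two_target_pose(corners[i], targets[0], d_free, sp)
        T.append(t)
        P.append(p)
    return ClusterConfig((sp,) * 8, np.array(T), np.array(P))


def ion_water_shell(
    ion: str | SpeciesSpec,
    n_waters: int,
    shell_radius: float = 3.4,
    species: SpeciesSpec | None = None,
) -> ClusterConfig:
    """Ion at the origin with waters on a golden-spiral sphere, each
    donating one OH towards the ion centre."""
    ion_sp = get_species(ion) if isinstance(ion, str) else ion
    sp = species or water()
    golden = math.pi * (3.0 - math.sqrt(5.0))
    T = [np.zeros(3)]
    P = [np.zeros(3)]
    for k in range(n_waters):
        z = 1.0 - 2.0 * (k + 0.5) / n_waters
        r = math.sqrt(max(1.0 - z * z, 0.0))
        th = golden * k
        pos = shell_radius * np.array([r * math.cos(th), r * math.sin(th), z])
        t, p = orient_water(pos, [-pos / np.linalg.norm(pos)], sp)
        T.append(t)
        P.append(p)
    return ClusterConfig((ion_sp,) + (sp,) * n_waters, np.array(T), np.array(P))


def water_bridging_ion(ion: str = "sulfite") -> ClusterConfig:
    """One water donating both hydrogens to two different ion oxygens."""
    ion_sp = get_species(ion)
    sp = water()
    body = ion_sp.body_positions
    o1, o2 = body[1], body[2]  # two ion oxygens (ion pose = identity)
    mid = 0.5 * (o1 + o2)
    n = mid / np.linalg.norm(mid)
    o_pos = mid + 2.1 * n
    d1 = (o1 - o_pos) / np.linalg.norm(o1 - o_pos)
    d2 = (o2 - o_pos) / np.linalg.norm(o2 - o_pos)
    t, p = orient_water(o_pos, [d1, d2], sp)
    return ClusterConfig(
        (ion_sp, sp), np.array([np.zeros(3), t]), np.array([np.zeros(3), p])
    )


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> ClusterConfig:
    """Dispatch by fixture kind: dimer | trimer_ring | cube | ion_shell |
    bridging | random."""
    params = dict(params or {})
    if kind == "dimer":
        return water_dimer(**params)
    if kind == "trimer_ring":
        return water_trimer_ring(**params)
    if kind == "cube":
        return water_cube(**params)
    if kind == "ion_shell":
        return ion_water_shell(**params)
    if kind == "bridging":
        return water_bridging_ion(**params)
    if kind == "random":
        ion = params.pop("ion", None)
        n_waters = params.pop("n_waters", 4)
        species = []
        if ion:
            species.append(get_species(ion))
        species.extend([water()] * n_waters)
        return random_initial_cluster(tuple(species), np.random.default_rng(seed), **params)
    raise ValueError(f"unknown fixture kind {kind!r}")
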