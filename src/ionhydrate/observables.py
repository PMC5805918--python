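"""Boltzmann-weighted ensemble observables over a minima database.

Minima are weighted by w_i = exp(-beta dU_i) / Z with dU_i the energy of
minimum i above the putative global minimum and beta = 1/(k_B T); the
default analysis temperature is 130 K.  Three windows are in use in
different analyses and the :class:`WeightingScheme` makes the choice
explicit: all unique minima (energy-per-water curves), the k lowest
(displacement ratio and ion coordination, k = 1000), or an energy cutoff
above the GM (dangling-OH suppression, 5 kcal/mol).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .constants import ATOMIC_MASSES, K_BOLTZMANN
from .forcefield import ClusterConfig
from .optimize import MinimaDatabase, MinimumRecord

__all__ = [
    "WeightingScheme",
    "boltzmann_weights",
    "mean_energy_per_water",
    "displacement_ratio",
    "weighted_statistic",
]


@dataclass(frozen=True)
class WeightingScheme:
    """Temperature + window for Boltzmann weighting.

    ``window`` is one of "all", "k_lowest" (uses ``k``), or "cutoff"
    (uses ``cutoff`` in kcal/mol above the GM).
    """

    temperature: float = 130.0
    window: str = "all"
    k: int = 1000
    cutoff: float = 5.0

    @property
    def beta(self) -> float:
        return 1.0 / (K_BOLTZMANN * self.temperature)

    def select(self, db: MinimaDatabase) -> list[MinimumRecord]:
        recs = db.records
        if not recs:
            raise ValueError("empty minima database")
        if self.window == "all":
            return list(recs)
        if self.window == "k_lowest":
            return recs[: self.k]
        if self.window == "cutoff":
            e0 = recs[0].energy
            return [r for r in recs if r.energy - e0 <= self.cutoff]
        raise ValueError(f"unknown window {self.window!r}")


def boltzmann_weights(
    db: MinimaDatabase, scheme: WeightingScheme | None = None
) -> tuple[np.ndarray, list[MinimumRecord]]:
    """Normalized weights over the scheme's window (log-domain safe).

    Returns ``(weights, records)`` with weights summing to 1 and records
    the window members in database (ascending energy) order.
    """
    scheme = scheme or WeightingScheme()
    recs = scheme.select(db)
    du = np.array([r.energy for r in recs])
    du -= du.min()
    logw = -scheme.beta * du
    w = np.exp(logw - logsumexp(logw))
    return w, recs


def mean_energy_per_water(
    db: MinimaDatabase, scheme: WeightingScheme | None = None
) -> float:
    """Boltzmann-weighted mean interaction energy per water (kcal/mol)."""
    w, recs = boltzmann_weights(db, scheme)
    n_waters = recs[0].config.n_waters
    if n_waters == 0:
        raise ValueError("cluster contains no waters")
    u = np.array([r.energy for r in recs])
    return float(np.dot(w, u) / n_waters)


def _water_com(config: ClusterConfig) -> np.ndarray:
    idx = [i for i, sp in enumerate(config.species_list) if sp.net_charge == 0.0]
    m = np.array([config.species_list[i].mass for i in idx])
    T = config.translations[idx]
    return (m[:, None] * T).sum(axis=0) / m.sum()


def radius_of_gyration(config: ClusterConfig, include_ion: bool = True) -> float:
    """Mass-weighted radius of gyration over all massive sites.

    ``include_ion=False`` restricts both the COM and the sum to water
    molecules (the alternative reading of the cluster radius).
    """
    positions = config.site_positions()
    pts, ms = [], []
    for i, sp in enumerate(config.species_list):
        if not include_ion and sp.net_charge != 0.0:
            continue
        for j, s in enumerate(sp.sites):
            if s.mass > 0:
                pts.append(positions[i][j])
                ms.append(s.mass)
    pts = np.array(pts)
    ms = np.array(ms)
    com = (ms[:, None] * pts).sum(axis=0) / ms.sum()
    r2 = ((pts - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.dot(ms, r2) / ms.sum()))


def displacement_ratio(config: ClusterConfig, include_ion_in_rgyr: bool = True) -> float:
    """Ion displacement ratio r' = |COM(ion) - COM(waters)| / r_gyr.

    Dimensionless and invariant under uniform scaling of all coordinates.
    """
    ion = config.ion_index
    if ion is None:
        raise ValueError("cluster has no ion")
    if config.n_waters < 1:
        raise ValueError("cluster has no waters")
    r = float(np.linalg.norm(config.translations[ion] - _water_com(config)))
    rg = radius_of_gyration(config, include_ion=include_ion_in_rgyr)
    if rg <= 0:
        raise ValueError("zero radius of gyration")
    return r / rg


def weighted_statistic(
    db: MinimaDatabase,
    per_minimum_fn: Callable[[MinimumRecord], float],
    scheme: WeightingScheme | None = None,
) -> float:
    """Generic Boltzmann-weighted mean of a per-minimum statistic."""
    w, recs = boltzmann_weights(db, scheme)
    vals = np.array([per_minimum_fn(r) for r in recs], dtype=float)
    return float(np.dot(w, vals))
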