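"""End-to-end orchestration: parallel-style basin-hopping runs, database
merging, structural observables tables, optional landscape connection.

A :class:`RunConfig` plus its seed reproduces a run exactly: per-run seeds
are spawned deterministically from the master seed, runs are independent
(no shared mutable state) and joined only at the merge.
"""
from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forcefield import get_species, water
from .hbond import HBondCriterion, count_dangling, count_ion_hbonds, detect_hbonds, \
    ion_coordination, ring_census
from .observables import WeightingScheme, displacement_ratio, mean_energy_per_water, \
    weighted_statistic
from .optimize import BasinHoppingConfig, MinimaDatabase, random_initial_cluster, \
    run_basin_hopping
from .io import write_xyz

__all__ = ["RunConfig", "pipeline_run", "run_parallel_bh", "observables_table"]


@dataclass
class RunConfig:
    """Serializable description of a full optimize -> analyze run."""

    ion: str | None = "sulfite"
    n_waters: int = 8
    n_runs: int = 2
    n_steps: int = 5000
    seed: int = 0
    parameter_set: str = "canonical"
    kT: float = 1.0
    block_size: int = 100
    translate_step: float = 1.0
    hbond_d_ha: float = 2.5
    hbond_angle_min: float = 120.0
    temperature: float = 130.0
    out_dir: str = "run_output"
    n_save_xyz: int = 20

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def species_list(self) -> tuple:
        species = []
        if self.ion and self.ion != "none":
            species.append(get_species(self.ion))
        species.extend([water(self.parameter_set)] * self.n_waters)
        return tuple(species)


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_parallel_bh(config: RunConfig) -> tuple[MinimaDatabase, list[dict]]:
    """Run ``n_runs`` independent seeded BH runs and merge the databases.

    Returns (merged database, per-run status records incl. each run's own
    lowest energy — the input for the GM-agreement statistic).
    """
    seeds = _spawn_seeds(config.seed, config.n_runs)
    merged = MinimaDatabase()
    statuses = []
    species = config.species_list()
    crit = HBondCriterion(config.hbond_d_ha, config.hbond_angle_min)
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        status = {"run": r, "seed": seed, "ok": False, "gm_energy": None,
                  "n_minima": 0}
        try:
            initial = random_initial_cluster(species, rng)
            bh = BasinHoppingConfig(
                n_steps=config.n_steps, seed=seed, kT=config.kT,
                block_size=config.block_size,
                translate_step=config.translate_step, hbond_criterion=crit,
            )
            db = run_basin_hopping(initial, bh)
            status.update(ok=True, gm_energy=db.global_minimum.energy,
                          n_minima=len(db))
            merged.merge(db)
        except Exception as exc:  # partial-failure tolerant
            status["error"] = f"{type(exc).__name__}: {exc}"
        statuses.append(status)
    return merged, statuses


def gm_agreement(merged: MinimaDatabase, statuses: list[dict],
                 tol: float = 1e-4) -> int:
    """How many runs found the merged database's global minimum."""
    if not len(merged):
        return 0
    gm = merged.global_minimum.energy
    return sum(
        1 for s in statuses
        if s["ok"] and s["gm_energy"] is not None and abs(s["gm_energy"] - gm) <= tol
    )


def observables_table(
    db: MinimaDatabase,
    criterion: HBondCriterion | None = None,
    temperature: float = 130.0,
) -> pd.DataFrame:
    """One-row observables summary of a minima database.

    Boltzmann windows follow the per-figure conventions: energy per water
    over all unique minima; dangling OH over the 5 kcal/mol window;
    ion statistics and displacement ratio over the 1000 lowest minima.
    """
    crit = criterion or HBondCriterion()
    cache: dict[int, object] = {}

    def graph(rec):
        key = id(rec)
        if key not in cache:
            cache[key] = detect_hbonds(rec.config, crit)
        return cache[key]

    gm = db.global_minimum.config
    has_ion = gm.ion_index is not None
    all_w = WeightingScheme(temperature, "all")
    cut_w = WeightingScheme(temperature, "cutoff", cutoff=5.0)
    k_w = WeightingScheme(temperature, "k_lowest", k=1000)
    row = {
        "n_waters": gm.n_waters,
        "ion": gm.species_list[gm.ion_index].name if has_ion else "none",
        "n_minima": len(db),
        "gm_energy": db.global_minimum.energy,
        "u_per_water": mean_energy_per_water(db, all_w),
        "n_dangling": weighted_statistic(db, lambda r: count_dangling(graph(r)), cut_w),
        "criterion_d_ha": crit.d_ha,
        "criterion_angle_min": crit.angle_min,
        "temperature": temperature,
    }
    ring3 = weighted_statistic(
        db, lambda r: ring_census(graph(r), 8).get(3, 0), cut_w
    )
    ring4 = weighted_statistic(
        db, lambda r: ring_census(graph(r), 8).get(4, 0), cut_w
    )
    row["rings_trimer"] = ring3
    row["rings_tetramer"] = ring4
    if has_ion:
        row["n_ion_hbonds"] = weighted_statistic(
            db, lambda r: count_ion_hbonds(graph(r))[0], k_w
        )
        row["ion_coordination"] = weighted_statistic(
            db, lambda r: ion_coordination(graph(r)), k_w
        )
        row["displacement_ratio"] = weighted_statistic(
            db, lambda r: displacement_ratio(r.config), k_w
        )
    return pd.DataFrame([row])


def pipeline_run(config: RunConfig) -> Path:
    """Run the full pipeline and write results under ``config.out_dir``.

    Writes: config.yaml, manifest.json (per-run status, GM agreement),
    minima index CSV, per-minimum XYZ files for the lowest structures, and
    the observables CSV.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    merged, statuses = run_parallel_bh(config)
    crit = HBondCriterion(config.hbond_d_ha, config.hbond_angle_min)

    index_rows = []
    for i, rec in enumerate(merged.records):
        index_rows.append(
            {"id": i, "energy": rec.energy, "hit_count": rec.hit_count,
             "first_found_step": rec.first_found_step}
        )
        if i < config.n_save_xyz:
            rec.config.energy = rec.energy
            write_xyz(out / "minima" / f"min{i:04d}.xyz", rec.config)
    pd.DataFrame(index_rows).to_csv(out / "minima_index.csv", index=False)
    if len(merged):
        observables_table(merged, crit, config.temperature).to_csv(
            out / "observables.csv", index=False
        )
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "runs": statuses,
        "n_minima_merged": len(merged),
        "gm_energy": merged.global_minimum.energy if len(merged) else None,
        "gm_agreement": gm_agreement(merged, statuses),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
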