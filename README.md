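# ionhydrate

Global optimization and energy-landscape analysis for micro-hydrated
XO₃-type anions — sulfite SO₃²⁻(H₂O)_N and chlorate ClO₃⁻(H₂O)_N — in
rigid-body TIP4P water.

The package is for computational chemists studying how small inorganic
ions pattern the hydrogen-bond network of gas-phase water clusters
(kosmotrope/chaotrope behaviour, solvation-shell build-up, atmospheric
nucleation precursors). It provides:

- **Force field** (`forcefield`, `energy`): rigid C₃ᵥ pyramidal ions and
  four-site TIP4P water; total interaction energy as a sum of Coulomb and
  Lennard-Jones terms over all inter-molecular site pairs,

  U = Σ_{i<j} 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶] + k_C q_i q_j / r_ij,

  with analytic gradients in rigid-body coordinates (COM translations +
  rotation vectors).
- **Basin-hopping** (`optimize`): Monte-Carlo minimization with a quench
  after every move and Metropolis acceptance on quenched energies; moves
  run in blocks of 100 of one class — random translations, random
  rotations (±π), and Takeuchi-style hydrogen-bond cycle inversions —
  feeding a deduplicated minima database.
- **Hydrogen-bond networks** (`hbond`): directed donor→acceptor graphs
  under a geometric criterion (H···O ≤ 2.5 Å, O–H···O ≥ 120°, both
  configurable), dangling-OH counts, per-oxygen ion coordination, and a
  minimal-cycle-basis ring census.
- **Ensemble observables** (`observables`): Boltzmann weighting
  w_i ∝ exp(−ΔU_i/k_BT) at T = 130 K over configurable windows (all
  minima / k lowest / energy cutoff), energy per water ⟨U⟩/N, and the ion
  displacement ratio r′ = |COM(ion) − COM(waters)| / r_gyr.
- **Energy landscapes** (`landscape`): slerp-interpolated bands, doubly
  nudged elastic band transition-state searches, hybrid
  eigenvector-following refinement (gradient-only curvature), min-max
  pathway extraction, and disconnectivity trees.
- **I/O and pipeline** (`io`, `fixtures`, `pipeline`, `cli`): XYZ
  read/write with rigid-pose re-fitting, deterministic structural
  fixtures, and an `ionhydrate` command-line front end
  (`optimize | analyze | landscape | pathway | fixtures | report`).

## Worked example

```python
import numpy as np
from ionhydrate import (BasinHoppingConfig, run_basin_hopping,
                        chlorate, water, detect_hbonds, ring_census,
                        mean_energy_per_water)
from ionhydrate.optimize import random_initial_cluster, refine_database

species = (chlorate(),) + (water(),) * 8
init = random_initial_cluster(species, np.random.default_rng(101))
db = run_basin_hopping(init, BasinHoppingConfig(n_steps=10000, seed=101))
db = refine_database(db)
gm = db.global_minimum
print(f"GM energy: {gm.energy:.4f} kcal/mol over {len(db)} minima")
g = detect_hbonds(gm.config)
print("rings:", ring_census(g), " dangling OH:", len(g.dangling_oh))
print(f"<U>/N at 130 K: {mean_energy_per_water(db):.3f} kcal/mol")
```

Output from this exact run:

```
GM energy: -117.7009 kcal/mol over 3042 minima
rings: {4: 3, 3: 5}  dangling OH: 0
<U>/N at 130 K: -14.707 kcal/mol
```

The chlorate octahydrate global minimum is a double-stacked-cube oxygen
framework (three tetrameric + five trimeric rings in the minimal cycle
basis, the ion oxygens replacing four water vertices) with every water
OH engaged — the ion suppresses the dangling hydrogens a pure-water
octamer would show. The energy per water is far below the ~−10 kcal/mol
bulk TIP4P limit because the ion–water attraction is shared among only
eight waters.

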