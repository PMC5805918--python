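"""Physical constants and atomic masses (single source of truth).

Energies are kcal/mol, distances Angstrom, charges elementary charges
throughout the package.
"""

#: Coulomb constant in kcal * A / (mol * e^2).
K_COULOMB = 332.0637

#: Boltzmann constant in kcal / (mol * K).
K_BOLTZMANN = 0.0019872

#: Standard atomic masses (u); pseudoatoms (e.g. the TIP4P lone-pair site)
#: are massless and must not appear here.
ATOMIC_MASSES = {
    "H": 1.008,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
}

#: Hard floor on inter-site separations; below this the configuration is
#: treated as an unphysical overlap rather than evaluated.
OVERLAP_FLOOR = 1e-6
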