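"""Rigid molecular species and cluster configurations.

A species is an immutable body-frame description of one rigid molecule:
site coordinates (Angstrom), Lennard-Jones parameters (kcal/mol, Angstrom)
and partial charges (e).  Built-in species are TIP4P water and the
pyramidal C3v anions sulfite (SO3^2-) and chlorate (ClO3^-).

Body-frame conventions: the centre of mass is at the origin; for the
pyramidal ions the C3 axis is +z (apex atom above the oxygen plane); for
water the C2 axis is +z with the hydrogens below the oxygen.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._rotation import rotation_matrices, wrap_rotvec
from .constants import ATOMIC_MASSES

__all__ = [
    "SiteSpec",
    "SpeciesSpec",
    "Pose",
    "ClusterConfig",
    "build_tip4p_species",
    "build_pyramidal_species",
    "water",
    "sulfite",
    "chlorate",
    "lab_frame_sites",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for impossible rigid-body geometries."""


@dataclass(frozen=True)
class SiteSpec:
    """One interaction site in the body frame.

    ``epsilon``/``sigma`` are LJ parameters (kcal/mol, Angstrom); a site with
    either equal to zero carries no LJ interaction.  ``mass`` is zero for
    pseudoatoms (e.g. the TIP4P lone-pair site).
    """

    label: str
    body_position: tuple[float, float, float]
    epsilon: float = 0.0
    sigma: float = 0.0
    charge: float = 0.0
    mass: float = 0.0

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma < 0:
            raise ValueError("LJ parameters must be non-negative")


@dataclass(frozen=True)
class SpeciesSpec:
    """Immutable rigid species: ordered sites in a canonical body frame."""

    name: str
    sites: tuple[SiteSpec, ...]
    net_charge: float = 0.0
    #: Allowed |sum(site charges) - net_charge|.  1e-6 by default; species
    #: whose published charges are rounded (sulfite's Bader charges sum to
    #: -1.999 e at 3 d.p.) declare a looser tolerance.
    charge_tolerance: float = 1e-6

    def __post_init__(self):
        total = sum(s.charge for s in self.sites)
        if abs(total - self.net_charge) > self.charge_tolerance:
            raise ValueError(
                f"site charges of {self.name} sum to {total}, "
                f"declared net charge {self.net_charge}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def body_positions(self) -> np.ndarray:
        return np.array([s.body_position for s in self.sites])

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.sites])

    @property
    def mass(self) -> float:
        return float(sum(s.mass for s in self.sites))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sites)

    def centre_of_mass(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.body_positions).sum(axis=0) / m.sum()


@dataclass(frozen=True)
class Pose:
    """Rigid-body pose: COM translation (Angstrom) + rotation vector."""

    translation: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class ClusterConfig:
    """A cluster state: one pose per molecule over declared species.

    ``translations`` (M, 3) hold centre-of-mass positions, ``orientations``
    (M, 3) rotation vectors.  ``energy`` is an optional cache of the total
    interaction energy in kcal/mol.
    """

    species_list: tuple[SpeciesSpec, ...]
    translations: np.ndarray
    orientations: np.ndarray
    energy: float | None = None

    def __post_init__(self):
        self.species_list = tuple(self.species_list)
        self.translations = np.array(self.translations, dtype=float).reshape(-1, 3)
        self.orientations = np.array(self.orientations, dtype=float).reshape(-1, 3)
        M = len(self.species_list)
        if self.translations.shape != (M, 3) or self.orientations.shape != (M, 3):
            raise ValueError("poses and species list must have equal length")
        n_ions = sum(1 for s in self.species_list if s.net_charge != 0)
        if n_ions > 1:
            raise ValueError("at most one ion per cluster is supported")

    # -- structural queries -------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.species_list)

    @property
    def ion_index(self) -> int | None:
        for i, s in enumerate(self.species_list):
            if s.net_charge != 0:
                return i
        return None

    @property
    def n_waters(self) -> int:
        return sum(1 for s in self.species_list if s.net_charge == 0)

    # -- coordinate packing -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """Flat coordinate vector (6M,): [t0, p0, t1, p1, ...]."""
        return np.concatenate(
            [np.concatenate([t, p]) for t, p in zip(self.translations, self.orientations)]
        )

    def with_coords(self, x: np.ndarray, energy: float | None = None) -> "ClusterConfig":
        x = np.asarray(x, dtype=float).reshape(-1, 6)
        return ClusterConfig(self.species_list, x[:, :3].copy(), x[:, 3:].copy(), energy)

    def copy(self) -> "ClusterConfig":
        return ClusterConfig(
            self.species_list,
            self.translations.copy(),
            self.orientations.copy(),
            self.energy,
        )

    def wrapped(self) -> "ClusterConfig":
        """Same configuration with orientations wrapped to |p| <= pi."""
        return ClusterConfig(
            self.species_list,
            self.translations.copy(),
            wrap_rotvec(self.orientations),
            self.energy,
        )

    # -- geometry -----------------------------------------------------------
    def site_positions(self) -> list[np.ndarray]:
        """Lab-frame site positions, one (n_sites, 3) array per molecule."""
        R = rotation_matrices(self.orientations)
        out = []
        for m, sp in enumerate(self.species_list):
            out.append(sp.body_positions @ R[m].T + self.translations[m])
        return out

    def molecule_com(self) -> np.ndarray:
        """Centres of mass (== translations by the body-frame convention)."""
        return self.translations.copy()

    def total_mass(self) -> float:
        return sum(sp.mass for sp in self.species_list)

    def centre_of_mass(self) -> np.ndarray:
        m = np.array([sp.mass for sp in self.species_list])
        return (m[:, None] * self.translations).sum(axis=0) / m.sum()


def lab_frame_sites(cluster: ClusterConfig) -> list[np.ndarray]:
    """Per-molecule lab-frame site positions (R(p) . body + t), stable order."""
    return cluster.site_positions()


# ---------------------------------------------------------------------------
# Built-in species
# ---------------------------------------------------------------------------

def build_tip4p_species(
    parameter_set: str = "canonical",
    oh_length: float = 0.9572,
    om_offset: float = 0.15,
    hoh_angle: float = 104.52,
) -> SpeciesSpec:
    """TIP4P water: LJ oxygen, two +0.52 e hydrogens, massless -1.04 e
    lone-pair (M) site on the H-O-H bisector.

    ``parameter_set`` selects the oxygen LJ parameters: "canonical" uses the
    standard TIP4P values (eps 0.1550 kcal/mol, sigma 3.15365 A);
    "as_printed" uses eps 0.648 kcal/mol, sigma 3.2 A.
    """
    if parameter_set == "canonical":
        eps_o, sig_o = 0.1550, 3.15365
    elif parameter_set == "as_printed":
        eps_o, sig_o = 0.648, 3.2
    else:
        raise ValueError(f"unknown parameter set {parameter_set!r}")

    half = math.radians(hoh_angle) / 2.0
    m_o, m_h = ATOMIC_MASSES["O"], ATOMIC_MASSES["H"]
    # O at origin, C2 bisector along -z (hydrogens below the oxygen)
    o = np.zeros(3)
    h1 = np.array([oh_length * math.sin(half), 0.0, -oh_length * math.cos(half)])
    h2 = np.array([-h1[0], 0.0, h1[2]])
    lp = np.array([0.0, 0.0, -om_offset])
    com = (m_o * o + m_h * (h1 + h2)) / (m_o + 2 * m_h)
    sites = (
        SiteSpec("O", tuple(o - com), epsilon=eps_o, sigma=sig_o, charge=0.0, mass=m_o),
        SiteSpec("H", tuple(h1 - com), charge=0.52, mass=m_h),
        SiteSpec("H", tuple(h2 - com), charge=0.52, mass=m_h),
        SiteSpec("LP", tuple(lp - com), charge=-1.04, mass=0.0),
    )
    return SpeciesSpec("water", sites, net_charge=0.0)


def pyramid_apex_height(bond_length: float, bond_angle_deg: float) -> float:
    """Apex height h of a C3v pyramid from bond length L and O-X-O angle.

    h^2 = L^2 (cos(theta) + 1/2) / 1.5; theta = 120 deg is the planar limit.
    """
    c = math.cos(math.radians(bond_angle_deg))
    val = bond_length**2 * (c + 0.5) / 1.5
    if val < 0:
        raise GeometryError(
            f"bond angle {bond_angle_deg} deg >= 120 deg: no C3v pyramid exists"
        )
    return math.sqrt(val)


def build_pyramidal_species(
    name: str,
    apex_label: str,
    bond_length: float,
    bond_angle: float,
    apex_site: SiteSpec,
    oxygen_site: SiteSpec,
    apex_height: float | str = "derive",
    height_tolerance: float = 0.02,
) -> SpeciesSpec:
    """C3v pyramidal ion XO3: apex atom on +z, three oxygens below.

    ``apex_site``/``oxygen_site`` supply LJ parameters, charges and masses;
    their body_position fields are ignored.  ``apex_height="derive"``
    computes the height from (L, theta); a supplied height inconsistent with
    (L, theta) beyond ``height_tolerance`` triggers a warning, not an error.
    """
    if bond_length <= 0:
        raise GeometryError("bond length must be positive")
    if not 0 < bond_angle < 120:
        raise GeometryError("bond angle must lie in (0, 120) degrees")
    h_derived = pyramid_apex_height(bond_length, bond_angle)
    if apex_height == "derive":
        h = h_derived
    else:
        h = float(apex_height)
        if abs(h - h_derived) > height_tolerance:
            import warnings

            warnings.warn(
                f"{name}: supplied apex height {h:.3f} A differs from the "
                f"(L, theta)-derived {h_derived:.3f} A",
                stacklevel=2,
            )
    rho = math.sqrt(max(bond_length**2 - h**2, 0.0))
    m_apex, m_o = apex_site.mass, oxygen_site.mass
    apex = np.array([0.0, 0.0, h])
    oxys = [
        np.array(
            [rho * math.cos(2 * math.pi * k / 3), rho * math.sin(2 * math.pi * k / 3), 0.0]
        )
        for k in range(3)
    ]
    com = (m_apex * apex + m_o * sum(oxys)) / (m_apex + 3 * m_o)
    sites = [replace(apex_site, label=apex_label, body_position=tuple(apex - com))]
    for o in oxys:
        sites.append(replace(oxygen_site, body_position=tuple(o - com)))
    net = apex_site.charge + 3 * oxygen_site.charge
    net_nominal = round(net)
    tol = max(1e-6, abs(net - net_nominal) * 1.5)
    return SpeciesSpec(name, tuple(sites), net_charge=float(net_nominal),
                       charge_tolerance=tol)


def water(parameter_set: str = "canonical") -> SpeciesSpec:
    """Built-in TIP4P water."""
    return build_tip4p_species(parameter_set=parameter_set)


def sulfite(
    apex_height: float | str = "derive",
    bond_length: float = 1.9,
    bond_angle: float = 106.0,
) -> SpeciesSpec:
    """Built-in SO3^2-: MP4-derived LJ parameters and Bader charges.

    The default S-O bond length of 1.9 A follows the published model
    description; note that physical sulfite has S-O ~= 1.53 A, and the
    published value is suspected to be a transcription artifact.  Pass
    ``bond_length=1.53`` for the physically consistent geometry (which
    also reproduces the published hydration-landscape topology: trimeric
    water rings in the low-lying SO3^2-(H2O)8 minima).
    """
    return build_pyramidal_species(
        "sulfite",
        "S",
        bond_length=bond_length,
        bond_angle=bond_angle,
        apex_site=SiteSpec("S", (0, 0, 0), epsilon=0.25, sigma=3.6, charge=0.281,
                           mass=ATOMIC_MASSES["S"]),
        oxygen_site=SiteSpec("O", (0, 0, 0), epsilon=0.25, sigma=3.2, charge=-0.760,
                             mass=ATOMIC_MASSES["O"]),
        apex_height=apex_height,
    )


def chlorate(apex_height: float | str = "derive") -> SpeciesSpec:
    """Built-in ClO3^-: L = 1.48 A, O-Cl-O = 105.8 deg."""
    return build_pyramidal_species(
        "chlorate",
        "Cl",
        bond_length=1.48,
        bond_angle=105.8,
        apex_site=SiteSpec("Cl", (0, 0, 0), epsilon=0.040, sigma=4.86, charge=0.452,
                           mass=ATOMIC_MASSES["Cl"]),
        oxygen_site=SiteSpec("O", (0, 0, 0), epsilon=0.076, sigma=3.10, charge=-0.484,
                             mass=ATOMIC_MASSES["O"]),
        apex_height=apex_height,
    )


_BUILTIN = {"water": water, "sulfite": sulfite, "chlorate": chlorate}


def get_species(name: str, **kwargs) -> SpeciesSpec:
    """Look up a built-in species by name."""
    try:
        return _BUILTIN[name](**kwargs)
    except KeyError:
        raise KeyError(f"unknown species {name!r}; known: {sorted(_BUILTIN)}") from None


def make_cluster(
    ion: str | SpeciesSpec | None,
    n_waters: int,
    translations: np.ndarray,
    orientations: np.ndarray,
    parameter_set: str = "canonical",
) -> ClusterConfig:
    """Assemble a ClusterConfig with the ion (if any) as molecule 0."""
    species: list[SpeciesSpec] = []
    if ion is not None and ion != "none":
        species.append(get_species(ion) if isinstance(ion, str) else ion)
    species.extend([water(parameter_set)] * n_waters)
    return ClusterConfig(tuple(species), translations, orientations)


# -- serialization ----------------------------------------------------------

def species_to_dict(sp: SpeciesSpec) -> dict:
    return {
        "name": sp.name,
        "net_charge": sp.net_charge,
        "charge_tolerance": sp.charge_tolerance,
        "sites": [
            {
                "label": s.label,
                "body_position": [float(x) for x in s.body_position],
                "epsilon": float(s.epsilon),
                "sigma": float(s.sigma),
                "charge": float(s.charge),
                "mass": float(s.mass),
            }
            for s in sp.sites
        ],
    }


def species_from_dict(d: dict) -> SpeciesSpec:
    sites = tuple(
        SiteSpec(
            s["label"],
            tuple(s["body_position"]),
            epsilon=s.get("epsilon", 0.0),
            sigma=s.get("sigma", 0.0),
            charge=s.get("charge", 0.0),
            mass=s.get("mass", 0.0),
        )
        for s in d["sites"]
    )
    return SpeciesSpec(
        d["name"], sites, net_charge=d.get("net_charge", 0.0),
        charge_tolerance=d.get("charge_tolerance", 1e-6),
    )
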