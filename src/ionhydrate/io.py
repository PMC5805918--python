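"""XYZ reading/writing and configuration serialization.

Clusters are exchanged as standard XYZ: a site-count line, a comment line
(carrying the energy as ``E = <value> kcal/mol`` when known), then one
``label x y z`` line per site.  Multi-frame files concatenate frames.
Pseudoatom sites (the TIP4P lone pair) are written with a configurable
label (default ``LP``) and round-tripped; files without them (bare O/H/H
waters) are also accepted.

On read, molecules are reassembled from site order (an S or Cl starts an
ion, an O followed by two H starts a water) and each molecule's rigid-body
pose is re-fitted to the species body frame by least-squares rotation
(Kabsch); the fit residual is checked against a rigidity tolerance.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .forcefield import (
    ClusterConfig,
    SpeciesSpec,
    chlorate,
    species_from_dict,
    species_to_dict,
    sulfite,
    water,
)

__all__ = ["read_xyz", "write_xyz", "XYZFormatError", "pose_fit",
           "save_species", "load_species"]

_ENERGY_RE = re.compile(r"E\s*=\s*(-?\d+\.?\d*(?:[eE][+-]?\d+)?)")


class XYZFormatError(ValueError):
    """Malformed XYZ content."""


def write_xyz(
    path: str | Path,
    configs: ClusterConfig | list[ClusterConfig],
    lp_label: str = "LP",
    mode: str = "w",
) -> None:
    """Write one or more cluster frames to an XYZ file."""
    if isinstance(configs, ClusterConfig):
        configs = [configs]
    lines = []
    for cfg in configs:
        positions = cfg.site_positions()
        n = sum(sp.n_sites for sp in cfg.species_list)
        comment = (
            f"E = {cfg.energy:.10f} kcal/mol" if cfg.energy is not None else ""
        )
        lines.append(f"{n}\n{comment}\n")
        for m, sp in enumerate(cfg.species_list):
            for j, site in enumerate(sp.sites):
                label = lp_label if site.label == "LP" else site.label
                x, y, z = positions[m][j]
                lines.append(f"{label} {x: .10f} {y: .10f} {z: .10f}\n")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, mode) as fh:
        fh.writelines(lines)


def pose_fit(
    body: np.ndarray, lab: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit lab ~= R . body + t.

    Returns (translation, rotvec, RMS residual); proper rotation only.
    """
    bc = body.mean(axis=0)
    lc = lab.mean(axis=0)
    H = (lab - lc).T @ (body - bc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = lc - R @ bc
    resid = lab - (body @ R.T + t)
    rms = float(np.sqrt((resid**2).sum() / len(body)))
    return t, Rotation.from_matrix(R).as_rotvec(), rms


def _segment_molecules(labels: list[str], lp_label: str):
    """Split a flat site list into molecules: (kind, site index list)."""
    out = []
    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        if lab in ("S", "Cl"):
            if i + 3 >= n or any(labels[i + k] != "O" for k in (1, 2, 3)):
                raise XYZFormatError(
                    f"ion apex {lab} at site {i} not followed by three O"
                )
            out.append(("sulfite" if lab == "S" else "chlorate", list(range(i, i + 4))))
            i += 4
        elif lab == "O":
            if i + 2 >= n or labels[i + 1] != "H" or labels[i + 2] != "H":
                raise XYZFormatError(f"water O at site {i} not followed by two H")
            idx = list(range(i, i + 3))
            i += 3
            if i < n and labels[i] == lp_label:
                idx.append(i)
                i += 1
            out.append(("water", idx))
        else:
            raise XYZFormatError(f"unexpected site label {lab!r} at index {i}")
    return out


def read_xyz(
    path: str | Path,
    lp_label: str = "LP",
    parameter_set: str = "canonical",
    rigidity_tolerance: float = 0.05,
    species_overrides: dict[str, SpeciesSpec] | None = None,
) -> list[ClusterConfig]:
    """Read all frames of an XYZ file into ClusterConfig objects.

    Returns a list of configurations with re-fitted rigid-body poses and
    energies parsed from the comment lines where present.  A molecule
    whose pose-fit RMS residual exceeds ``rigidity_tolerance`` (A) raises
    XYZFormatError — the file is not rigid under the declared body frames.
    """
    overrides = species_overrides or {}
    builders = {
        "water": overrides.get("water", water(parameter_set)),
        "sulfite": overrides.get("sulfite", sulfite()),
        "chlorate": overrides.get("chlorate", chlorate()),
    }
    text = Path(path).read_text().splitlines()
    frames = []
    ln = 0
    while ln < len(text):
        if not text[ln].strip():
            ln += 1
            continue
        try:
            n = int(text[ln].split()[0])
        except ValueError as exc:
            raise XYZFormatError(f"line {ln + 1}: expected site count") from exc
        if ln + 1 + n >= len(text) + 1 and n > 0:
            raise XYZFormatError("truncated frame")
        comment = text[ln + 1] if ln + 1 < len(text) else ""
        m = _ENERGY_RE.search(comment)
        energy = float(m.group(1)) if m else None
        labels, coords = [], []
        for k in range(n):
            parts = text[ln + 2 + k].split()
            if len(parts) < 4:
                raise XYZFormatError(f"line {ln + 3 + k}: malformed site line")
            labels.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        coords = np.array(coords)
        species_list, T, P = [], [], []
        for kind, idx in _segment_molecules(labels, lp_label):
            sp = builders[kind]
            body = sp.body_positions
            if len(idx) < sp.n_sites:
                body = body[: len(idx)]  # bare water without the LP site
            t, p, rms = pose_fit(body, coords[idx])
            if rms > rigidity_tolerance:
                raise XYZFormatError(
                    f"molecule at sites {idx}: pose-fit residual {rms:.4f} A "
                    f"exceeds rigidity tolerance {rigidity_tolerance} A"
                )
            species_list.append(sp)
            T.append(t)
            P.append(p)
        frames.append(
            ClusterConfig(tuple(species_list), np.array(T), np.array(P), energy)
        )
        ln += 2 + n
    if not frames:
        raise XYZFormatError(f"no frames found in {path}")
    return frames


# ---------------------------------------------------------------------------
# species / config serialization
# ---------------------------------------------------------------------------

def save_species(path: str | Path, sp: SpeciesSpec) -> None:
    Path(path).write_text(yaml.safe_dump(species_to_dict(sp), sort_keys=False))


def load_species(path: str | Path) -> SpeciesSpec:
    return species_from_dict(yaml.safe_load(Path(path).read_text()))
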