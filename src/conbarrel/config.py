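"""Global defaults and the key-value configuration file.

All lengths are in nanometres internally; Ångström appears only in PDB
output. The two lattice constants ``a`` (Cα spacing along a strand) and
``b`` (interstrand spacing) are the only numbers the closed-form barrel
theory needs; the defaults reproduce the canonical tilt angles 36°/55°
and the diameter coefficients 0.19/0.27 nm per strand simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Defaults:
    """Tunable global parameters, overridable from a YAML config file."""

    ca_spacing: float = 0.345          # a, nm, Cα-Cα along a beta strand
    interstrand_spacing: float = 0.483  # b, nm, strand-to-strand in a sheet
    pleat_amplitude: float = 0.05      # nm, radial in/out alternation
    handedness: str = "right"
    membrane_thickness: float = 5.0    # nm
    dry_gap_window: tuple[float, float] = (0.6, 1.0)    # nm, no lipid
    lipid_gap_window: tuple[float, float] = (1.0, 1.4)  # nm, GM1 alkyl chains
    lattice_margin: float = 0.4        # nm, unit-to-unit clearance
    lattice_margin_gm1: float = 1.0    # nm, when GM1 occupies 3-fold sites
    helix_ring_clearance: float = 0.5  # nm, helix ring radius - outer barrel R

    def replace(self, **kwargs) -> "Defaults":
        return replace(self, **kwargs)


DEFAULTS = Defaults()


def load_config(path: str | Path | None) -> Defaults:
    """Read a flat ``key: value`` YAML file and overlay it on the defaults.

    Unknown keys raise ``ValueError`` so typos do not silently do nothing.
    """
    if path is None:
        return DEFAULTS
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a key-value mapping")
    known = {f.name for f in fields(Defaults)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    for key in ("dry_gap_window", "lipid_gap_window"):
        if key in data:
            data[key] = tuple(float(x) for x in data[key])
    return DEFAULTS.replace(**data)
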