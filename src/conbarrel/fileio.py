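"""PDB output, flattened barrel maps, and JSON geometry reports.

Coordinates are nm internally and Å in PDB files. Each peptide is one
chain of Cα ATOM records; occupancy encodes side-chain facing (1.00
outward, 0.50 inward), the B-factor column encodes the segment id
(S1a=1, S1b=2, S2=3, S3=4, loop=0), and lattice units become MODEL /
ENDMDL blocks. Only the minimal ATOM/TER/MODEL subset is read back.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np

from .assembly import (ConcentricAssembly, compose, outer_radius,
                       protrusion_report)
from .geometry import derive_geometry
from .lattice import LatticeLayout
from .topology import SegmentScheme
from .util import round_half_away

__all__ = [
    "write_pdb",
    "read_ca_pdb",
    "write_flat_map",
    "build_report",
    "write_report",
    "read_report",
]

log = logging.getLogger("conbarrel")

_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_SEGMENT_ID = {"S1A": 1.0, "S1B": 2.0, "S2": 3.0, "S3": 4.0}


def _atom_line(serial: int, resname: str, chain: str, resseq: int,
               xyz_nm, occupancy: float, bfactor: float,
               segid: str = "") -> str:
    x, y, z = (10.0 * float(v) for v in xyz_nm)  # nm -> Å
    return (f"ATOM  {serial % 100000:5d}  CA  {resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occupancy:6.2f}{bfactor:6.2f}      {segid:<4s} C  ")


def _assembly_lines(assembly: ConcentricAssembly, serial_start: int = 1,
                    ) -> tuple[list[str], int]:
    coords = assembly.residue_coordinates()
    if not coords:
        raise ValueError("empty assembly: nothing to write")
    scheme = assembly.scheme
    lines: list[str] = []
    serial = serial_start
    n_sub = assembly.preset.subunit_count
    overflow = n_sub > len(_CHAIN_IDS)
    if overflow:
        log.warning(
            "%d chains exceed the %d chain ids; falling back to segment ids",
            n_sub, len(_CHAIN_IDS))
    for k in range(n_sub):
        chain = " " if overflow else _CHAIN_IDS[k]
        segid = f"P{k:03d}" if overflow else ""
        for r in range(1, len(scheme.sequence) + 1):
            rec = assembly.assignment.of(k, r)
            occ = 0.50 if rec.facing == "inward" else 1.00
            bf = _SEGMENT_ID.get(scheme.segment_of(r), 0.0)
            if rec.component is None:
                bf = 0.0  # loop
            lines.append(_atom_line(
                serial, _THREE[scheme.one_letter(r)], chain, r,
                coords[(k, r)], occ, bf, segid))
            serial += 1
        lines.append(f"TER   {serial % 100000:5d}      "
                     f"{_THREE[scheme.one_letter(len(scheme.sequence))]:>3s} "
                     f"{chain}{len(scheme.sequence):4d}")
        serial += 1
    return lines, serial


def write_pdb(obj, path) -> Path:
    """Write an assembly, or a lattice of assemblies, as a Cα-trace PDB."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, LatticeLayout):
        if obj.unit is None:
            raise ValueError("lattice has no unit preset to instantiate")
        base = compose(obj.unit)
        for i, (cx, cy) in enumerate(obj.centers, start=1):
            shifted = _translated_assembly(base, (cx, cy))
            lines.append(f"MODEL     {i:4d}")
            unit_lines, _ = _assembly_lines(shifted)
            lines.extend(unit_lines)
            lines.append("ENDMDL")
    else:
        unit_lines, _ = _assembly_lines(obj)
        lines.extend(unit_lines)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _translated_assembly(assembly: ConcentricAssembly,
                         xy) -> ConcentricAssembly:
    import copy
    shift = np.array([xy[0], xy[1], 0.0])
    out = copy.copy(assembly)
    out.barrels = [
        type(b)(key=b.key, role=b.role, model=b.model.translated(shift),
                radius=b.radius, transmembrane=b.transmembrane,
                concentric=b.concentric, lipid_interface=b.lipid_interface)
        for b in assembly.barrels
    ]
    if assembly.helix_ring is not None:
        hr = copy.copy(assembly.helix_ring)
        hr.coords = {k: c + shift for k, c in assembly.helix_ring.coords.items()}
        out.helix_ring = hr
    return out


def read_ca_pdb(path, model: int = 1, segment_id: float | None = None,
                ) -> np.ndarray:
    """Cα coordinates (nm) from the minimal ATOM/TER/MODEL subset.

    ``segment_id`` filters on the B-factor segment encoding (e.g. 4.0 for
    the S3 barrel). Atoms are returned in file order, so chains remain
    contiguous strand traces.
    """
    coords = []
    current_model = 1
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            current_model = int(line.split()[1])
        elif line.startswith("ATOM") and current_model == model:
            if line[12:16].strip() != "CA":
                continue
            if segment_id is not None:
                if abs(float(line[60:66]) - segment_id) > 1e-6:
                    continue
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
    return np.asarray(coords) / 10.0  # Å -> nm


# ---------------------------------------------------------------------------
# flattened maps


def write_flat_map(assembly: ConcentricAssembly, component_key: str,
                   strands: list[int] | None = None) -> str:
    """Text grid of one barrel: columns = strands (azimuthal order),
    rows = axial levels. Inward-facing residues are marked ``*``; the
    rows straddling the P2 dyad plane (z = 0) are annotated."""
    comp = assembly.component(component_key)
    spec = comp.model.spec
    recs = [r for r in assembly.assignment.records
            if r.component == component_key]
    if not recs:
        raise ValueError(f"no residues threaded onto {component_key}")
    from .geometry import _staggers
    stag = _staggers(spec)
    t = np.concatenate([[0], np.cumsum(stag[:-1])])
    sel = sorted(set(r.strand for r in recs)) if strands is None else strands
    L = spec.residues_per_strand

    grid: dict[tuple[int, int], str] = {}
    rows: set[int] = set()
    for r in recs:
        if r.strand not in sel:
            continue
        if spec.sense == "antiparallel" and r.strand % 2 == 1:
            slot = L - 1 - r.position
        else:
            slot = r.position
        row = int(t[r.strand]) + slot
        mark = "*" if r.facing == "inward" else " "
        grid[(row, r.strand)] = (
            assembly.scheme.one_letter(r.residue) + mark)
        rows.add(row)
    lo, hi = min(rows), max(rows)
    mid = (lo + hi) / 2.0
    header = "level " + " ".join(f"s{j:<2d}" for j in sel)
    lines = [header]
    for row in range(hi, lo - 1, -1):  # top of the barrel first
        cells = " ".join(f"{grid.get((row, j), '. '):<3s}"[:3] for j in sel)
        note = "  <-- P2 plane" if abs(row - mid) <= 0.5 else ""
        lines.append(f"{row:5d} {cells}{note}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# geometry reports


def build_report(assembly: ConcentricAssembly) -> dict:
    """Geometry report of an assembly; serializes losslessly to JSON."""
    preset = assembly.preset
    components = {}
    for pb in preset.barrels:
        geo = derive_geometry(pb.spec)
        components[pb.key] = {
            "role": pb.role,
            "n_strands": pb.spec.n_strands,
            "shear": pb.spec.shear,
            "s_over_n": pb.spec.shear / pb.spec.n_strands,
            "sense": pb.spec.sense,
            "tilt_deg": geo.tilt,
            "tilt_deg_printed": round_half_away(geo.tilt, 0),
            "radius_nm": geo.radius,
            "diameter_nm": geo.diameter,
            "height_nm": geo.height,
        }
    gaps = [{
        "inner": e.inner, "outer": e.outer,
        "gap_nm": e.gap,
        "gap_nm_printed": round_half_away(e.gap, 1),
        "constraint": e.constraint,
        "window_nm": list(e.window) if e.window else None,
        "passed": e.passed,
    } for e in assembly.gap_report.entries]
    report = {
        "preset": preset.name,
        "kind": preset.kind,
        "peptide_count": preset.subunit_count,
        "components": components,
        "gaps": gaps,
        "secondary_structure_pct": assembly.assignment.fractions(),
        "units": {"length": "nm", "angle": "deg"},
    }
    if preset.helix_ring is not None:
        report["helix_ring"] = {
            "count": preset.helix_ring.count,
            "tilt_deg": preset.helix_ring.tilt,
            "residues": list(preset.helix_ring.residues),
        }
    if assembly.membrane_thickness is not None:
        report["membrane_thickness_nm"] = assembly.membrane_thickness
        report["protrusion_nm"] = protrusion_report(assembly)
    return report


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
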