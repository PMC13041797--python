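"""Compose concentric barrels, tandem pore stacks and helix rings.

An assembly is a set of co-axial components in one frame: the barrel axis
is +z, the membrane (when present) is the slab |z| ≤ thickness/2, and P2
dyads lie in the z = 0 plane. Gap constraints between adjacent barrel
walls follow the modelling rule used throughout: 0.6–1.0 nm for dry
protein-protein interfaces, 1.0–1.4 nm when GM1 alkyl chains pack between
the walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS, Defaults
from .geometry import (BackboneModel, BarrelSpec, check_symmetry,
                       derive_geometry, generate_backbone)
from .topology import (AQUEOUS_S1S2, INNER_S3, OUTER_S1S2, PORE_S1,
                       PORE_S1_HAIRPIN, DEFAULT_SCHEME, ModelPreset,
                       ResidueAssignment, SegmentScheme, thread)
from .util import round_half_away

__all__ = [
    "PlacedBarrel",
    "HelixRing",
    "GapEntry",
    "GapReport",
    "ConcentricAssembly",
    "compose",
    "stack_tandem",
    "place_helix_ring",
    "protrusion_report",
    "peptide_count",
    "CompositionError",
]


class CompositionError(ValueError):
    pass


@dataclass
class PlacedBarrel:
    key: str               # matches the threading component keys
    role: str
    model: BackboneModel
    radius: float          # mean backbone cylinder, nm
    transmembrane: bool = False
    concentric: bool = True   # participates in the radial gap report
    lipid_interface: bool = False


@dataclass
class HelixRing:
    """Ideal α-helix Cα traces on a ring, mirrored per P2 on both faces."""

    count: int
    ring_radius: float
    tilt: float                       # degrees from the membrane normal
    residues: tuple[int, int]
    coords: dict[int, np.ndarray]     # helix index -> (n_res, 3) nm


@dataclass(frozen=True)
class GapEntry:
    inner: str
    outer: str
    gap: float                 # R_outer - R_inner of mean backbone cylinders
    constraint: str            # dry | lipid | open
    window: tuple[float, float] | None
    passed: bool


@dataclass
class GapReport:
    entries: list[GapEntry]

    def entry(self, inner: str, outer: str) -> GapEntry:
        for e in self.entries:
            if e.inner == inner and e.outer == outer:
                return e
        raise KeyError(f"no gap entry {inner} -> {outer}")

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries)


@dataclass
class ConcentricAssembly:
    preset: ModelPreset
    scheme: SegmentScheme
    assignment: ResidueAssignment
    barrels: list[PlacedBarrel]            # inner -> outer
    helix_ring: HelixRing | None
    tandem_stacks: list[tuple[str, str]]
    membrane_thickness: float | None
    gap_report: GapReport

    def component(self, key: str) -> PlacedBarrel:
        for b in self.barrels:
            if b.key == key:
                return b
        raise KeyError(f"assembly has no component {key}")

    def residue_coordinates(self) -> dict[tuple[int, int], np.ndarray]:
        """Cα position of every (subunit, residue), loops interpolated."""
        coords: dict[tuple[int, int], np.ndarray] = {}
        comp_by_key = {b.key: b for b in self.barrels}
        for rec in self.assignment.records:
            if rec.component is None:
                continue
            if rec.component == "helix_ring":
                coords[(rec.subunit, rec.residue)] = (
                    self.helix_ring.coords[rec.strand][rec.position])
            else:
                comp = comp_by_key.get(rec.component)
                if comp is None:
                    continue
                coords[(rec.subunit, rec.residue)] = comp.model.atom(
                    rec.strand, rec.position)
        _interpolate_loops(coords, self.preset.subunit_count,
                           len(self.scheme.sequence))
        return coords


def _interpolate_loops(coords, n_subunits: int, n_res: int) -> None:
    for k in range(n_subunits):
        known = sorted(r for (kk, r) in coords if kk == k)
        if not known:
            continue
        for r in range(1, n_res + 1):
            if (k, r) in coords:
                continue
            prev = max((x for x in known if x < r), default=None)
            nxt = min((x for x in known if x > r), default=None)
            if prev is None:
                coords[(k, r)] = np.array(coords[(k, nxt)])
            elif nxt is None:
                coords[(k, r)] = np.array(coords[(k, prev)])
            else:
                t = (r - prev) / (nxt - prev)
                coords[(k, r)] = ((1 - t) * coords[(k, prev)]
                                  + t * coords[(k, nxt)])


# ---------------------------------------------------------------------------
# building blocks


def stack_tandem(pore_barrel: BackboneModel,
                 ) -> tuple[BackboneModel, BackboneModel]:
    """Two copies of a parallel pore barrel stacked end-on along the axis.

    The copies are related by the P2 flip, so the N-terminal ends of both
    barrels meet at the assembly midplane with an axial contact gap of one
    inter-residue rise (a·cos α).
    """
    spec = pore_barrel.spec
    if spec is None or spec.sense != "parallel":
        raise CompositionError(
            "tandem stacks are built from parallel S1 barrels")
    geo = derive_geometry(spec)
    contact = spec.ca_spacing * math.cos(math.radians(geo.tilt))
    z = pore_barrel.coords[:, 2]
    # lift the barrel so its N-terminal end sits contact/2 above the midplane
    shift = contact / 2.0 - z.min()
    top = pore_barrel.translated([0.0, 0.0, shift])
    bottom = top.flipped_p2()
    return top, bottom


def place_helix_ring(count: int, ring_radius: float, tilt: float,
                     residues: tuple[int, int],
                     z_surface: float = 0.0,
                     rise: float = 0.15, helix_radius: float = 0.23,
                     twist: float = 100.0) -> HelixRing:
    """Ideal α-helices (3.6 res/turn) evenly spaced on a ring.

    Helices with even index sit on the +z face, odd index on the -z face
    (P2 images), with axes tilted ``tilt`` degrees from the membrane
    normal, tangentially to the ring, and midpoints at ±``z_surface``.
    """
    if ring_radius < 0:
        raise ValueError(f"ring radius must be >= 0, got {ring_radius}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    lo, hi = residues
    n_res = hi - lo + 1
    i = np.arange(n_res)
    local = np.column_stack([
        helix_radius * np.cos(np.radians(twist * i)),
        helix_radius * np.sin(np.radians(twist * i)),
        rise * i,
    ])
    local -= local.mean(axis=0)
    t = math.radians(tilt)
    tilt_rot = np.array([[1, 0, 0],
                         [0, math.cos(t), -math.sin(t)],
                         [0, math.sin(t), math.cos(t)]])
    local = local @ tilt_rot.T

    def top_helix(phi: float) -> np.ndarray:
        rot = np.array([[math.cos(phi), -math.sin(phi), 0],
                        [math.sin(phi), math.cos(phi), 0],
                        [0, 0, 1]])
        return local @ rot.T + np.array([
            ring_radius * math.cos(phi), ring_radius * math.sin(phi),
            z_surface])

    coords: dict[int, np.ndarray] = {}
    if count:
        step = 2.0 * math.pi / count
        psi = step / 2.0  # dyad azimuth relating the two faces
        u = np.array([math.cos(psi), math.sin(psi), 0.0])
        dyad = 2.0 * np.outer(u, u) - np.eye(3)
        for k in range(count):
            if k % 2 == 0:   # +z face at the subunit azimuth
                coords[k] = top_helix(k * step)
            else:            # -z face: exact dyad image of a +z-type helix
                coords[k] = top_helix(2.0 * psi - k * step) @ dyad.T
    return HelixRing(count=count, ring_radius=ring_radius, tilt=tilt,
                     residues=residues, coords=coords)


# ---------------------------------------------------------------------------
# composition


def _centered(model: BackboneModel) -> BackboneModel:
    return model.translated([0.0, 0.0, -model.coords[:, 2].mean()])


def _gap_window(constraint: str, defaults: Defaults):
    if constraint == "dry":
        return defaults.dry_gap_window
    if constraint == "lipid":
        return defaults.lipid_gap_window
    return None


def compose(preset: ModelPreset,
            scheme: SegmentScheme = DEFAULT_SCHEME,
            defaults: Defaults = DEFAULTS) -> ConcentricAssembly:
    """Build the full coordinate model of a preset and its gap report.

    All barrels share the +z axis; nested barrels are azimuthally
    interleaved by half an inter-strand angle so side-chain slots of
    facing walls alternate. Gap-window failures are flagged in the report,
    not fatal.
    """
    assignment = thread(preset, scheme)
    placed: list[PlacedBarrel] = []
    tandem: list[tuple[str, str]] = []
    membrane = defaults.membrane_thickness if preset.kind != "soluble_oligomer" else None

    phase = 0.0
    for pb in preset.barrels:
        geo = derive_geometry(pb.spec)
        spec = pb.spec.replace(azimuthal_phase=phase
                               + 180.0 / pb.spec.n_strands)
        phase = spec.azimuthal_phase
        if pb.role in (PORE_S1, PORE_S1_HAIRPIN):
            base = generate_backbone(spec)
            if pb.role == PORE_S1:
                top, bottom = stack_tandem(base)
            else:
                contact = spec.ca_spacing * math.cos(math.radians(geo.tilt))
                shift = contact / 2.0 - base.coords[:, 2].min()
                top = base.translated([0, 0, shift])
                bottom = top.flipped_p2()
            for tag, mdl in (("top", top), ("bottom", bottom)):
                placed.append(PlacedBarrel(
                    key=f"{pb.role}_{tag}", role=pb.role, model=mdl,
                    radius=geo.radius, lipid_interface=pb.lipid_interface))
            tandem.append((f"{pb.role}_top", f"{pb.role}_bottom"))
        elif pb.role == AQUEOUS_S1S2:
            base = _centered(generate_backbone(spec))
            half = membrane / 2.0 if membrane else 0.0
            top = base.translated([0, 0, half + geo.height / 2.0])
            bottom = top.flipped_p2()
            placed.append(PlacedBarrel(
                key=f"{pb.role}_top", role=pb.role, model=top,
                radius=geo.radius, concentric=False))
            placed.append(PlacedBarrel(
                key=f"{pb.role}_bottom", role=pb.role, model=bottom,
                radius=geo.radius, concentric=False))
        else:
            model = _centered(generate_backbone(spec))
            placed.append(PlacedBarrel(
                key=pb.key, role=pb.role, model=model, radius=geo.radius,
                transmembrane=(pb.role == INNER_S3
                               and preset.kind in ("TMO", "channel",
                                                   "plugged_channel")
                               and pb.key == INNER_S3),
                lipid_interface=pb.lipid_interface))

    placed.sort(key=lambda b: b.radius)

    helix_ring = None
    if preset.helix_ring is not None:
        outer_tm = max((b for b in placed if b.concentric),
                       key=lambda b: b.radius)
        ring_radius = outer_tm.radius + defaults.helix_ring_clearance
        helix_ring = place_helix_ring(
            preset.helix_ring.count, ring_radius, preset.helix_ring.tilt,
            preset.helix_ring.residues,
            z_surface=(membrane or 0.0) / 2.0)

    # gap report over concentric neighbours; tandem twins counted once
    ordered, seen_radius = [], set()
    for b in placed:
        if not b.concentric:
            continue
        tag = (b.role, round(b.radius, 6))
        if tag in seen_radius:
            continue
        seen_radius.add(tag)
        ordered.append(b)
    if any(o.radius <= i.radius for i, o in zip(ordered, ordered[1:])):
        raise CompositionError("barrel radii must strictly increase")
    entries = []
    for inner, outer in zip(ordered, ordered[1:]):
        plug_boundary = inner.key.startswith("plug_") != \
            outer.key.startswith("plug_")
        if plug_boundary:
            constraint = "open"
        elif inner.lipid_interface or outer.lipid_interface:
            constraint = "lipid"
        else:
            constraint = "dry"
        gap = outer.radius - inner.radius
        window = _gap_window(constraint, defaults)
        passed = (window is None
                  or window[0] <= round_half_away(gap, 1) <= window[1])
        entries.append(GapEntry(inner=inner.key, outer=outer.key, gap=gap,
                                constraint=constraint, window=window,
                                passed=passed))

    return ConcentricAssembly(
        preset=preset, scheme=scheme, assignment=assignment,
        barrels=placed, helix_ring=helix_ring, tandem_stacks=tandem,
        membrane_thickness=membrane, gap_report=GapReport(entries))


# ---------------------------------------------------------------------------
# reports


def protrusion_report(assembly: ConcentricAssembly) -> dict[str, float]:
    """Height of soluble structure above each membrane face, nm."""
    if assembly.membrane_thickness is None:
        raise ValueError("no membrane frame: assembly is soluble-only")
    half = assembly.membrane_thickness / 2.0
    zs = [b.model.coords[:, 2] for b in assembly.barrels
          if not b.transmembrane]
    if assembly.helix_ring is not None:
        zs.extend(c[:, 2] for c in assembly.helix_ring.coords.values())
    if not zs:
        return {"top": 0.0, "bottom": 0.0}
    z = np.concatenate(zs)
    return {"top": float(max(0.0, z.max() - half)),
            "bottom": float(max(0.0, -z.min() - half))}


def peptide_count(obj) -> int:
    """Total distinct peptides in an assembly (or preset)."""
    preset = obj.preset if hasattr(obj, "preset") else obj
    return preset.subunit_count


def assembly_symmetry(assembly: ConcentricAssembly,
                      check_p2: bool = True) -> dict[str, float]:
    """check_symmetry per component set at n_fold = subunit_count/2.

    Axially paired components (tandem pore stacks, TMO aqueous domains,
    the helix ring) are evaluated as the union of both copies — the P2
    dyad exchanges the two faces, so neither copy is symmetric alone.
    """
    n_fold = max(1, assembly.preset.subunit_count // 2)
    paired: dict[str, list[PlacedBarrel]] = {}
    singles: list[PlacedBarrel] = []
    for b in assembly.barrels:
        if b.key.endswith(("_top", "_bottom")):
            paired.setdefault(b.role, []).append(b)
        else:
            singles.append(b)

    out: dict[str, float] = {}
    for b in singles:
        nf = math.gcd(b.model.n_strands
                      if b.model.spec.sense == "parallel"
                      else b.model.n_strands // 2, n_fold)
        out[b.key] = check_symmetry(b.model, max(nf, 1), check_p2=check_p2)
    for role, pair in paired.items():
        pts = np.vstack([b.model.coords for b in pair])
        union = BackboneModel(
            coords=pts,
            strand_index=np.concatenate(
                [b.model.strand_index + i * pair[0].model.n_strands
                 for i, b in enumerate(pair)]),
            residue_index=np.concatenate(
                [b.model.residue_index for b in pair]),
            facing_inward=np.concatenate(
                [b.model.facing_inward for b in pair]),
            provenance="union",
        )
        spec = pair[0].model.spec
        nf = math.gcd(spec.n_strands if spec.sense == "parallel"
                      else spec.n_strands // 2, n_fold)
        out[role] = check_symmetry(union, max(nf, 1), check_p2=check_p2)
    if assembly.helix_ring is not None and assembly.helix_ring.count:
        pts = np.vstack(list(assembly.helix_ring.coords.values()))
        n = len(pts)
        ring = BackboneModel(
            coords=pts, strand_index=np.zeros(n, dtype=int),
            residue_index=np.arange(n), facing_inward=np.zeros(n, bool),
            provenance="union")
        nf = math.gcd(assembly.helix_ring.count // 2, n_fold)
        out["helix_ring"] = check_symmetry(ring, max(nf, 1),
                                           check_p2=check_p2)
    return out


def outer_radius(assembly: ConcentricAssembly) -> float:
    """Radial extent of the assembly including surface helices, nm."""
    r = max(b.radius for b in assembly.barrels)
    r += assembly.barrels[0].model.spec.pleat_amplitude
    if assembly.helix_ring is not None:
        r = max(r, assembly.helix_ring.ring_radius
                + 2 * 0.23)  # helix backbone radius allowance
    return r
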