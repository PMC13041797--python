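"""Aβ42 segments, the model-preset catalog, and residue threading.

The 42-residue amyloid-β peptide is divided into the standard segments
used throughout the concentric-barrel models:

    S1a = 1–7, S1b = 8–14   hydrophilic N-terminal third (charged pore face)
    S2  = 15–27             amphipathic middle (surface helix in channels)
    S3  = 28–42             hydrophobic C-terminal third (the core β-barrel)

Each preset assembles idealized barrels from these segments: soluble
oligomers bury an antiparallel S3 barrel inside an outer S1-S2 barrel;
transmembrane channels expose the S3 barrel to lipid and line its pore
with S1 barrels while S2 forms amphipathic surface helices. Presets whose
subunits all share one conformation come in two families: S/N = 1
(α ≈ 36°, tall/narrow) and S/N = 2 (α ≈ 55°, short/wide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from Bio.SeqUtils import molecular_weight

from .config import DEFAULTS, Defaults
from .geometry import BarrelSpec, derive_geometry, generate_backbone
from .util import round_half_away

__all__ = [
    "AB42_SEQUENCE",
    "SegmentScheme",
    "BarrelRole",
    "PresetBarrel",
    "HelixRingSpec",
    "ModelPreset",
    "ResidueRecord",
    "ResidueAssignment",
    "catalog",
    "get_preset",
    "thread",
    "glycine_pleat_check",
    "monomer_mass",
    "peptides_for_mass",
]

#: Human amyloid-β 1-42, one-letter code, Asp1 ... Ala42.
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SegmentScheme:
    """Named inclusive residue intervals partitioning the peptide."""

    sequence: str = AB42_SEQUENCE
    s1a: tuple[int, int] = (1, 7)
    s1b: tuple[int, int] = (8, 14)
    s2: tuple[int, int] = (15, 27)
    s3: tuple[int, int] = (28, 42)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        ranges = [self.s1a, self.s1b, self.s2, self.s3]
        if any(c not in _CANONICAL for c in self.sequence):
            bad = sorted(set(self.sequence) - _CANONICAL)
            raise ValueError(f"non-canonical residues {bad} in sequence")
        expect = 1
        for lo, hi in ranges:
            if lo != expect or hi < lo:
                raise ValueError(
                    f"segment ranges must tile 1..{n} contiguously; "
                    f"got {ranges}")
            expect = hi + 1
        if expect != n + 1:
            raise ValueError(f"segments cover 1..{expect - 1}, not 1..{n}")

    @property
    def s1(self) -> tuple[int, int]:
        return (self.s1a[0], self.s1b[1])

    def segment_of(self, residue: int) -> str:
        for name in ("s1a", "s1b", "s2", "s3"):
            lo, hi = getattr(self, name)
            if lo <= residue <= hi:
                return name.upper()
        raise ValueError(f"residue {residue} outside 1..{len(self.sequence)}")

    def one_letter(self, residue: int) -> str:
        return self.sequence[residue - 1]


DEFAULT_SCHEME = SegmentScheme()


# ---------------------------------------------------------------------------
# presets

#: Barrel roles within an assembly.
BarrelRole = str
INNER_S3 = "inner_S3"
OUTER_S1S2 = "outer_S1S2"
PORE_S1 = "pore_S1"                  # parallel, continuous S1 strands
PORE_S1_HAIRPIN = "pore_S1_hairpin"  # antiparallel S1a-S1b hairpins
AQUEOUS_S1S2 = "aqueous_S1S2"        # TMO surface domains, one per face


@dataclass(frozen=True)
class PresetBarrel:
    role: BarrelRole
    spec: BarrelSpec
    lipid_interface: bool = False  # GM1 alkyl chains outside this barrel's wall
    inferred_shear: bool = False   # shear set by the gap rule, not stated; see methods
    key: str = ""                  # unique component key (defaults to role)

    def __post_init__(self) -> None:
        if not self.key:
            object.__setattr__(self, "key", self.role)


@dataclass(frozen=True)
class HelixRingSpec:
    count: int                     # total helices (half per membrane face)
    tilt: float                    # degrees from the membrane normal
    residues: tuple[int, int]      # inclusive range forming the helix


@dataclass(frozen=True)
class ModelPreset:
    """A fully specified concentric-barrel model."""

    name: str
    kind: str                      # soluble_oligomer | TMO | channel | plugged_channel
    subunit_count: int
    barrels: tuple[PresetBarrel, ...]
    helix_ring: HelixRingSpec | None = None
    ss_override: dict | None = None   # {"beta": [(lo,hi),...], "helix": [...]}
    notes: str = ""

    def barrel(self, key: str) -> PresetBarrel:
        for b in self.barrels:
            if b.key == key:
                return b
        raise KeyError(f"preset {self.name} has no {key} barrel")


def _s3_spec(n: int, sn_ratio: int, length: int = 15) -> BarrelSpec:
    # registration: S/N=1 S3 barrels carry the Val36-Val36 dyad (staggers
    # (3,-1)); S/N=2 barrels align Gly33/Gly37 on one pleat (staggers (2,2))
    return BarrelSpec(
        n_strands=n,
        shear=sn_ratio * n,
        sense="antiparallel",
        residues_per_strand=length,
        stagger_asymmetry=2 if sn_ratio == 1 else 0,
        inward_parity=1,   # odd-numbered residues (28+odd index) face inward
    )


def _radius(n: int, s: int) -> float:
    return math.hypot(s * DEFAULTS.ca_spacing,
                      n * DEFAULTS.interstrand_spacing) / (2 * math.pi)


def _realizable_shears(n: int, sense: str = "antiparallel") -> list[int]:
    step = n if sense == "parallel" else (n // 2 if n % 2 == 0 else n)
    return [s for s in range(0, 3 * n + 1, step)]


def _best_outer_shear(n_outer: int, inner_radius: float,
                      target_gap: float) -> int:
    """Realizable shear bringing the inter-wall gap closest to target."""
    best, best_err = None, None
    for s in _realizable_shears(n_outer):
        gap = _radius(n_outer, s) - inner_radius
        err = abs(gap - target_gap)
        if best is None or err < best_err:
            best, best_err = s, err
    return best


def _outer_spec(n_sub: int, inner: BarrelSpec, target_gap: float = 0.8,
                ) -> BarrelSpec:
    n = 2 * n_sub  # one S1 + one S2 strand per subunit
    s = _best_outer_shear(n, _radius(inner.n_strands, inner.shear),
                          target_gap)
    return BarrelSpec(
        n_strands=n, shear=s, sense="antiparallel",
        residues_per_strand=14,
        inward_parity=1,  # even-numbered residues (Y10, V12 ...) face the core
    )


def _pore_parallel(n_sub: int) -> BarrelSpec:
    # two tandem parallel S1 barrels, S/N = 2, half the subunits each
    n = n_sub // 2
    return BarrelSpec(
        n_strands=n, shear=2 * n, sense="parallel",
        residues_per_strand=14,
        inward_parity=0,  # odd-numbered (D1, E3, R5 ...) line the pore
    )


def _pore_hairpin(n_sub: int, shear: int) -> BarrelSpec:
    # two tandem antiparallel S1a-S1b hairpin barrels, one hairpin = 2 strands;
    # half the subunits contribute to each barrel
    parity = tuple(0 if j % 2 == 0 else 1 for j in range(n_sub))
    return BarrelSpec(
        n_strands=n_sub, shear=shear, sense="antiparallel",
        residues_per_strand=7,
        inward_parity=parity,  # odd-numbered residues pore-facing in S1a & S1b
    )


def _aqueous_spec(n_sub: int) -> BarrelSpec:
    # TMO surface domain: the S1-S2 hairpins of the subunits exiting one
    # membrane face form a small antiparallel barrel stacked on that face
    return BarrelSpec(
        n_strands=n_sub, shear=n_sub, sense="antiparallel",
        residues_per_strand=14, inward_parity=1,
    )


def _soluble(name: str, n_sub: int, sn_ratio: int, *, lipid_gap: bool = False,
             inferred_shear: bool = False, notes: str = "") -> ModelPreset:
    inner = _s3_spec(n_sub, sn_ratio)
    target = 1.2 if lipid_gap else 0.8
    outer = _outer_spec(n_sub, inner, target_gap=target)
    return ModelPreset(
        name=name, kind="soluble_oligomer", subunit_count=n_sub,
        barrels=(
            PresetBarrel(INNER_S3, inner),
            PresetBarrel(OUTER_S1S2, outer, lipid_interface=lipid_gap,
                         inferred_shear=inferred_shear),
        ),
        notes=notes,
    )


def _tmo(name: str, n_sub: int, sn_ratio: int = 1) -> ModelPreset:
    return ModelPreset(
        name=name, kind="TMO", subunit_count=n_sub,
        barrels=(
            PresetBarrel(INNER_S3, _s3_spec(n_sub, sn_ratio)),
            PresetBarrel(AQUEOUS_S1S2, _aqueous_spec(n_sub),
                         inferred_shear=True),
        ),
        notes="aqueous S1-S2 barrels stacked on each membrane face",
    )


def _channel(name: str, n_sub: int, sn_ratio: int, *,
             hairpin_pore: bool = False, pore_shear: int | None = None,
             gm1: bool = False, helix_range: tuple[int, int] = (15, 27),
             ss_override: dict | None = None,
             inferred_shear: bool = False) -> ModelPreset:
    if hairpin_pore:
        pore = PresetBarrel(
            PORE_S1_HAIRPIN, _pore_hairpin(n_sub, pore_shear),
            lipid_interface=gm1, inferred_shear=inferred_shear)
    else:
        pore = PresetBarrel(PORE_S1, _pore_parallel(n_sub),
                            lipid_interface=gm1)
    return ModelPreset(
        name=name, kind="channel", subunit_count=n_sub,
        barrels=(pore, PresetBarrel(INNER_S3, _s3_spec(n_sub, sn_ratio))),
        helix_ring=HelixRingSpec(count=n_sub, tilt=55.0,
                                 residues=helix_range),
        ss_override=ss_override,
    )


def _build_catalog() -> dict[str, ModelPreset]:
    presets: dict[str, ModelPreset] = {}

    def add(p: ModelPreset) -> None:
        presets[p.name] = p

    # soluble oligomers (beaded-annular-protofibril bead sizes)
    add(_soluble("soluble_hexamer_small", 6, 1))
    add(_soluble("soluble_hexamer_large", 6, 2,
                 notes="GM1 alkyl chains inside the S3 barrel"))
    add(_soluble("soluble_octamer", 8, 1, inferred_shear=True))
    add(_soluble("soluble_dodecamer", 12, 1, inferred_shear=True,
                 notes="GM1 alkyl chains inside the S3 barrel"))
    add(_soluble("soluble_hexadecamer", 16, 1, inferred_shear=True))
    add(_soluble("soluble_octadecamer", 18, 1, lipid_gap=True,
                 inferred_shear=True,
                 notes="36-stranded outer barrel cannot sit closer than "
                       "~1.1 nm; interface modelled lipid-filled"))

    # transmembrane oligomers (no open pore)
    for n in (6, 12, 18):
        add(_tmo(f"tmo_{n}", n))

    # channels: S3 transmembrane barrel, S1 pore lining, S2 surface helices
    for n in (12, 18, 24, 36):
        add(_channel(f"channel_{n}_1con1", n, 1,
                     gm1=(n == 36),
                     helix_range=(17, 24) if n == 24 else (15, 27),
                     ss_override=(
                         {"beta": [(2, 13), (31, 41)], "helix": [(17, 24)]}
                         if n == 24 else None)))
    add(_channel("channel_12_1con2", 12, 2))
    add(_channel("channel_18_1con2", 18, 2, gm1=True))
    add(_channel("channel_24_1con2", 24, 2, hairpin_pore=True, pore_shear=12,
                 gm1=True, inferred_shear=True))
    add(_channel("channel_36_1con2", 36, 2, hairpin_pore=True, pore_shear=36,
                 gm1=True))

    # plugged channel: the large 36mer channel surrounding a soluble dodecamer
    chan = presets["channel_36_1con2"]
    plug = presets["soluble_dodecamer"]
    plug_barrels = tuple(replace(b, key=f"plug_{b.role}")
                         for b in plug.barrels)
    add(ModelPreset(
        name="plugged_48", kind="plugged_channel", subunit_count=48,
        barrels=plug_barrels + chan.barrels,
        helix_ring=chan.helix_ring,
        notes="36mer channel (outer) + soluble dodecamer plug (inner)",
    ))
    return presets


_CATALOG: dict[str, ModelPreset] | None = None


def catalog() -> list[ModelPreset]:
    """All built-in model presets."""
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = _build_catalog()
    return list(_CATALOG.values())


def get_preset(name: str) -> ModelPreset:
    catalog()
    try:
        return _CATALOG[name]
    except KeyError:
        valid = ", ".join(sorted(_CATALOG))
        raise KeyError(f"unknown preset {name!r}; valid presets: {valid}")


# ---------------------------------------------------------------------------
# threading


@dataclass(frozen=True)
class ResidueRecord:
    subunit: int
    residue: int           # 1-based position in the peptide
    secondary: str         # beta | helix | loop
    component: str | None  # barrel role, "helix_ring", or None for loops
    strand: int | None     # strand (or helix) index within the component
    position: int | None   # chain position within the strand/helix
    facing: str            # inward | outward | n/a


@dataclass
class ResidueAssignment:
    """Total, exclusive residue-to-structure assignment for one preset."""

    preset: ModelPreset
    scheme: SegmentScheme
    records: list[ResidueRecord]

    def of(self, subunit: int, residue: int) -> ResidueRecord:
        n_res = len(self.scheme.sequence)
        return self.records[subunit * n_res + (residue - 1)]

    def fractions(self) -> dict[str, int]:
        """Integer percentages of β/helix/loop, largest-remainder rounded."""
        counts = {"beta": 0, "helix": 0, "loop": 0}
        for rec in self.records:
            counts[rec.secondary] += 1
        total = sum(counts.values())
        raw = {k: 100.0 * v / total for k, v in counts.items()}
        floors = {k: int(math.floor(v)) for k, v in raw.items()}
        short = 100 - sum(floors.values())
        order = sorted(raw, key=lambda k: raw[k] - floors[k], reverse=True)
        for k in order[:short]:
            floors[k] += 1
        return floors


def _in_any(residue: int, ranges) -> bool:
    return any(lo <= residue <= hi for lo, hi in ranges)


def _beta_ranges(preset: ModelPreset, scheme: SegmentScheme):
    if preset.ss_override and "beta" in preset.ss_override:
        return preset.ss_override["beta"]
    ranges = []
    roles = {b.role for b in preset.barrels}
    if roles & {PORE_S1, OUTER_S1S2, AQUEOUS_S1S2, PORE_S1_HAIRPIN}:
        ranges.append(scheme.s1)
    if OUTER_S1S2 in roles or AQUEOUS_S1S2 in roles:
        ranges.append(scheme.s2)
    if INNER_S3 in roles:
        ranges.append(scheme.s3)
    return ranges


def _helix_ranges(preset: ModelPreset, scheme: SegmentScheme):
    if preset.ss_override and "helix" in preset.ss_override:
        return preset.ss_override["helix"]
    if preset.helix_ring is not None:
        return [preset.helix_ring.residues]
    return []


def _facing(residue: int, odd_inward: bool) -> str:
    inward = (residue % 2 == 1) == odd_inward
    return "inward" if inward else "outward"


def thread(preset: ModelPreset,
           scheme: SegmentScheme = DEFAULT_SCHEME) -> ResidueAssignment:
    """Assign every residue of every subunit to its structural slot.

    Channel presets put S3 on the transmembrane barrel, S2 on the surface
    helix ring and S1 on the pore barrels; soluble presets put S1+S2 on the
    outer barrel and S3 on the inner one. β-strand facing alternates with
    residue parity (odd-numbered S3 and pore residues inward).
    """
    n_res = len(scheme.sequence)
    beta = _beta_ranges(preset, scheme)
    helix = _helix_ranges(preset, scheme)

    records: list[ResidueRecord] = []
    for k in range(preset.subunit_count):
        for r in range(1, n_res + 1):
            if _in_any(r, helix):
                ss = "helix"
            elif _in_any(r, beta):
                ss = "beta"
            else:
                ss = "loop"
            comp, strand, pos, facing = _locate(preset, scheme, k, r)
            records.append(ResidueRecord(
                subunit=k, residue=r, secondary=ss, component=comp,
                strand=strand, position=pos, facing=facing))
    return ResidueAssignment(preset=preset, scheme=scheme, records=records)


def _locate(preset: ModelPreset, scheme: SegmentScheme, k: int, r: int):
    """(component key, strand, chain position, facing) of residue ``r``."""
    if preset.kind == "plugged_channel":
        plug_subunits = preset.barrel(f"plug_{INNER_S3}").spec.n_strands
        if k < plug_subunits:
            return _locate_soluble(preset, scheme, k, r, prefix="plug_")
        return _locate_channel(preset, scheme, k - plug_subunits, r)
    if preset.kind == "channel":
        return _locate_channel(preset, scheme, k, r)
    if preset.kind == "TMO":
        return _locate_tmo(preset, scheme, k, r)
    return _locate_soluble(preset, scheme, k, r)


def _locate_soluble(preset, scheme, k, r, prefix=""):
    s1_lo, s1_hi = scheme.s1
    s2_lo, s2_hi = scheme.s2
    s3_lo, s3_hi = scheme.s3
    if s3_lo <= r <= s3_hi:
        return (prefix + INNER_S3, k, r - s3_lo,
                _facing(r, odd_inward=True))
    if s1_lo <= r <= s1_hi:  # S1 strand = even strand 2k of the outer barrel
        return (prefix + OUTER_S1S2, 2 * k, r - s1_lo,
                _facing(r, odd_inward=False))
    return (prefix + OUTER_S1S2, 2 * k + 1, r - s2_lo,
            _facing(r, odd_inward=False))


def _locate_tmo(preset, scheme, k, r):
    s1_lo, s1_hi = scheme.s1
    s2_lo, s2_hi = scheme.s2
    s3_lo, s3_hi = scheme.s3
    n_sub = preset.subunit_count
    if s3_lo <= r <= s3_hi:
        return INNER_S3, k, r - s3_lo, _facing(r, odd_inward=True)
    # S1-S2 hairpins: even subunits exit the top face, odd the bottom;
    # each face barrel holds n_sub strands (2 per contributing subunit)
    pair = k // 2
    face = k % 2  # 0 = top barrel (strand block), 1 = bottom
    strand_base = 2 * pair
    if s1_lo <= r <= s1_hi:
        return (f"{AQUEOUS_S1S2}_{'top' if face == 0 else 'bottom'}",
                strand_base, r - s1_lo, _facing(r, odd_inward=False))
    return (f"{AQUEOUS_S1S2}_{'top' if face == 0 else 'bottom'}",
            strand_base + 1, r - s2_lo, _facing(r, odd_inward=False))


def _locate_channel(preset, scheme, k, r):
    s1_lo, s1_hi = scheme.s1
    s1a_lo, s1a_hi = scheme.s1a
    s1b_lo, s1b_hi = scheme.s1b
    s3_lo, s3_hi = scheme.s3
    helix_rng = preset.helix_ring.residues if preset.helix_ring else None
    hairpin = any(b.role == PORE_S1_HAIRPIN for b in preset.barrels)

    if s3_lo <= r <= s3_hi:
        return INNER_S3, k, r - s3_lo, _facing(r, odd_inward=True)
    if helix_rng and helix_rng[0] <= r <= helix_rng[1]:
        return "helix_ring", k, r - helix_rng[0], "n/a"
    face = "top" if k % 2 == 0 else "bottom"
    if hairpin:
        pair = k // 2
        if s1a_lo <= r <= s1a_hi:
            return (f"{PORE_S1_HAIRPIN}_{face}", 2 * pair, r - s1a_lo,
                    _facing(r, odd_inward=True))
        if s1b_lo <= r <= s1b_hi:
            return (f"{PORE_S1_HAIRPIN}_{face}", 2 * pair + 1, r - s1b_lo,
                    _facing(r, odd_inward=True))
    else:
        if s1_lo <= r <= s1_hi:
            return (f"{PORE_S1}_{face}", k // 2, r - s1_lo,
                    _facing(r, odd_inward=True))
    return None, None, None, "n/a"


# ---------------------------------------------------------------------------
# glycine pleat


def glycine_pleat_check(preset: ModelPreset,
                        assignment: "ResidueAssignment | None" = None,
                        residues: tuple[int, int] = (33, 37),
                        ) -> tuple[bool, dict]:
    """Do Gly33 and Gly37 of adjacent S3 strands share one pleat band?

    True when both face inward and their axial offset across an adjacent
    antiparallel strand pair is at most half a Cα spacing — the side-chain
    free groove that lets a GM1 alkyl chain pack along the S/N=2 barrel
    wall. S/N=1 barrels register Val36 against Val36 instead, leaving the
    glycines two pleats apart.
    """
    scheme = assignment.scheme if assignment is not None else DEFAULT_SCHEME
    try:
        pb = preset.barrel(INNER_S3)
    except KeyError:
        return False, {"note": "preset has no S3 barrel"}
    spec = pb.spec
    if spec.n_strands < 2:
        return False, {"note": "insufficient strands"}
    model = generate_backbone(spec)
    s3_lo = scheme.s3[0]
    ra, rb = residues
    ia, ib = ra - s3_lo, rb - s3_lo
    half_a = spec.ca_spacing / 2.0

    offsets = {}
    aligned = True
    for j in range(spec.n_strands):
        jn = (j + 1) % spec.n_strands
        dz = min(
            abs(model.atom(j, ia)[2] - model.atom(jn, ib)[2]),
            abs(model.atom(j, ib)[2] - model.atom(jn, ia)[2]),
        )
        offsets[(j, jn)] = dz
        aligned &= dz <= half_a
    inward = (_facing(ra, odd_inward=True) == "inward"
              and _facing(rb, odd_inward=True) == "inward")
    return bool(aligned and inward), {
        "axial_offsets_nm": offsets,
        "both_inward": inward,
        "threshold_nm": half_a,
    }


# ---------------------------------------------------------------------------
# mass accounting


def monomer_mass(scheme: SegmentScheme = DEFAULT_SCHEME) -> float:
    """Average molecular mass of the peptide, Da."""
    if not scheme.sequence:
        raise ValueError("empty sequence")
    return float(molecular_weight(scheme.sequence, seq_type="protein"))


def peptides_for_mass(total_mass_kda: float,
                      scheme: SegmentScheme = DEFAULT_SCHEME) -> int:
    """Peptides in an assembly of the given total mass (kDa)."""
    if total_mass_kda <= 0:
        raise ValueError(f"total mass must be positive, got {total_mass_kda}")
    return int(round_half_away(total_mass_kda * 1000.0 / monomer_mass(scheme)))
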