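"""Hexagonal lattices of assemblies and peptide-conserving transitions.

Membrane-embedded oligomers and channels can tile the bilayer: compact
units pack on a centered hexagonal (triangular) lattice, while hexamers
occupy the vertices of a honeycomb whose cell centres hold small
six-fold pores. Lateral membrane tension is proposed to drive merge and
split transitions between lattice states — two hexamer oligomers fusing
into a dodecamer, channels doubling in size, or large channels shedding
an inner lipoprotein — with the total peptide count strictly conserved
at every step. The :class:`TransitionLedger` book-keeps such sequences
and enforces conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS, Defaults
from .topology import ModelPreset, get_preset

__all__ = [
    "LatticeLayout",
    "TransitionStep",
    "TransitionLedger",
    "ConservationError",
    "centered_hex_lattice",
    "honeycomb_lattice",
    "apply_transition",
    "gating_sequence",
    "lattice_collapse_sequence",
]


# ---------------------------------------------------------------------------
# layouts


@dataclass
class LatticeLayout:
    """2D placement of identical assembly units in the membrane plane."""

    unit: ModelPreset | None
    style: str                      # centered_hex | honeycomb
    centers: np.ndarray             # (n, 2) nm
    spacing: float                  # nearest-centre distance, nm
    unit_orientations: np.ndarray   # (n,) degrees
    symmetry_sites: dict[str, int] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.centers)

    def peptide_count(self) -> int:
        return self.n_units * (self.unit.subunit_count if self.unit else 0)


def _unit_radius(unit: ModelPreset | None, defaults: Defaults) -> float:
    if unit is None:
        return 1.0
    from .assembly import compose, outer_radius  # local: avoid cycle at import
    return outer_radius(compose(unit, defaults=defaults))


def centered_hex_lattice(unit: ModelPreset | str | None, rings: int,
                         defaults: Defaults = DEFAULTS) -> LatticeLayout:
    """A central unit plus ``rings`` concentric hexagonal rings.

    Ring r holds 6r units, so the layout has 1 + 3·r·(r+1) units in
    total; e.g. two rings of 24mer channels give the nineteen-channel
    patch seen by AFM.
    """
    if rings < 0:
        raise ValueError(f"rings must be >= 0, got {rings}")
    if isinstance(unit, str):
        unit = get_preset(unit)
    spacing = 2.0 * _unit_radius(unit, defaults) + defaults.lattice_margin
    pts = [(0.0, 0.0)]
    for r in range(1, rings + 1):
        # walk the hexagon ring: start at a corner, take r steps per edge
        corners = [
            (r * math.cos(math.pi / 3 * i), r * math.sin(math.pi / 3 * i))
            for i in range(6)
        ]
        for i in range(6):
            cx, cy = corners[i]
            nx, ny = corners[(i + 1) % 6]
            for step in range(r):
                t = step / r
                pts.append((cx + (nx - cx) * t, cy + (ny - cy) * t))
    centers = np.asarray(pts) * spacing
    return LatticeLayout(
        unit=unit, style="centered_hex", centers=centers, spacing=spacing,
        unit_orientations=np.zeros(len(centers)),
        symmetry_sites={"sixfold": 1, "twofold": 3 * rings * (rings + 1)},
    )


def honeycomb_lattice(unit: ModelPreset | str | None, cells: int,
                      defaults: Defaults = DEFAULTS) -> LatticeLayout:
    """Hexamer units on honeycomb vertices around small six-fold pores.

    ``cells`` hexagonal cells are laid out in centred-hexagonal order
    (1 cell = 6 units around one pore; 7 cells = the 24-unit patch).
    Units on the two honeycomb sublattices alternate orientation by 30°
    to realize the two-fold contact sites between neighbours.
    """
    if cells < 0:
        raise ValueError(f"cells must be >= 0, got {cells}")
    if isinstance(unit, str):
        unit = get_preset(unit)
    if unit is not None and unit.subunit_count != 6:
        raise ValueError(
            "honeycomb lattices are built from hexamer-class units; "
            f"{unit.name} has {unit.subunit_count} subunits")
    edge = 2.0 * _unit_radius(unit, defaults) + defaults.lattice_margin
    if cells == 0:
        return LatticeLayout(
            unit=unit, style="honeycomb", centers=np.zeros((0, 2)),
            spacing=edge, unit_orientations=np.zeros(0),
            symmetry_sites={"sixfold": 0, "threefold": 0, "twofold": 0})

    # cell centres on a triangular lattice, in centred-hex (spiral) order
    cell_centers = [(0, 0)]
    r = 1
    while len(cell_centers) < cells:
        ring = []
        corners = [(r * math.cos(math.pi / 3 * i + math.pi / 6),
                    r * math.sin(math.pi / 3 * i + math.pi / 6))
                   for i in range(6)]
        for i in range(6):
            cx, cy = corners[i]
            nx, ny = corners[(i + 1) % 6]
            for step in range(r):
                t = step / r
                ring.append((cx + (nx - cx) * t, cy + (ny - cy) * t))
        cell_centers.extend(ring)
        r += 1
    cell_centers = np.asarray(cell_centers[:cells]) * (edge * math.sqrt(3))

    verts: dict[tuple[int, int], np.ndarray] = {}
    edges: set[frozenset] = set()
    for cc in cell_centers:
        cell_verts = []
        for i in range(6):
            v = cc + edge * np.array([math.cos(math.pi / 3 * i),
                                      math.sin(math.pi / 3 * i)])
            key = (round(v[0] / edge * 1000), round(v[1] / edge * 1000))
            verts[key] = v
            cell_verts.append(key)
        for i in range(6):
            edges.add(frozenset((cell_verts[i], cell_verts[(i + 1) % 6])))
    centers = np.array(list(verts.values()))
    # sublattice from vertex parity: orientation alternates 30°
    orients = np.array([
        0.0 if round(math.atan2(c[1], c[0]) / math.pi * 3) % 2 == 0 else 30.0
        for c in centers - centers.mean(axis=0)]) if len(centers) else \
        np.zeros(0)
    return LatticeLayout(
        unit=unit, style="honeycomb", centers=centers, spacing=edge,
        unit_orientations=orients,
        symmetry_sites={"sixfold": int(cells), "threefold": len(centers),
                        "twofold": len(edges)},
    )


# ---------------------------------------------------------------------------
# transition ledger


class ConservationError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionStep:
    operation: str                       # merge | split | extrude
    consumed: tuple[tuple[str, int, int], ...]   # (label, size, count)
    produced: tuple[tuple[str, int, int], ...]


@dataclass
class TransitionLedger:
    """Ordered lattice states; peptides strictly conserved step to step."""

    initial: dict[str, tuple[int, int]]  # label -> (size, count)
    steps: list[TransitionStep] = field(default_factory=list)

    @staticmethod
    def _total(state: dict[str, tuple[int, int]]) -> int:
        return sum(size * count for size, count in state.values())

    @property
    def total_peptides(self) -> int:
        return self._total(self.initial)

    def states(self) -> list[dict[str, tuple[int, int]]]:
        out = [dict(self.initial)]
        state = dict(self.initial)
        for step in self.steps:
            state = _apply(state, step)
            out.append(state)
        return out

    @property
    def current(self) -> dict[str, tuple[int, int]]:
        return self.states()[-1]


def _apply(state: dict[str, tuple[int, int]],
           step: TransitionStep) -> dict[str, tuple[int, int]]:
    new = dict(state)
    for label, size, count in step.consumed:
        if label not in new:
            raise ConservationError(f"no units {label!r} in current state")
        s, c = new[label]
        if s != size or c < count:
            raise ConservationError(
                f"state has {c} x {label}({s}); step consumes "
                f"{count} x {label}({size})")
        if c == count:
            del new[label]
        else:
            new[label] = (s, c - count)
    for label, size, count in step.produced:
        if label in new:
            s, c = new[label]
            if s != size:
                raise ConservationError(
                    f"label {label!r} reused with size {size} != {s}")
            new[label] = (s, c + count)
        else:
            new[label] = (size, count)
    before = TransitionLedger._total(state)
    after = TransitionLedger._total(new)
    if before != after:
        raise ConservationError(
            f"peptides not conserved: {before} -> {after} "
            f"(imbalance {after - before:+d})")
    return new


def apply_transition(ledger: TransitionLedger,
                     step: TransitionStep) -> TransitionLedger:
    """Append ``step``, re-verifying the conservation invariant."""
    _apply(ledger.current, step)  # raises on violation
    ledger.steps.append(step)
    return ledger


def merge_step(label: str, size: int, count: int, new_label: str,
               ) -> TransitionStep:
    """Pairwise merger: ``count`` units of ``size`` -> count/2 of 2·size."""
    if count % 2:
        raise ConservationError(f"cannot pairwise-merge {count} units")
    return TransitionStep(
        operation="merge",
        consumed=((label, size, count),),
        produced=((new_label, 2 * size, count // 2),),
    )


def split_step(label: str, size: int, count: int,
               parts: tuple[tuple[str, int, int], ...]) -> TransitionStep:
    return TransitionStep(operation="split",
                          consumed=((label, size, count),), produced=parts)


def gating_sequence() -> TransitionLedger:
    """The canonical mechanosensitive gating cascade of a 288-peptide patch.

    48 hexamer TMOs merge stepwise into 24 dodecamers, twelve 24mers and
    six 48mers; finally the 48mers split, the inward-facing third of the
    subunits combining into a 96mer lipoprotein and the outward-facing
    two thirds into the surrounding 192mer channel.
    """
    ledger = TransitionLedger(initial={"hexamer_tmo": (6, 48)})
    apply_transition(ledger, merge_step("hexamer_tmo", 6, 48, "dodecamer"))
    apply_transition(ledger, merge_step("dodecamer", 12, 24, "24mer"))
    apply_transition(ledger, merge_step("24mer", 24, 12, "48mer"))
    apply_transition(ledger, split_step(
        "48mer", 48, 6,
        (("192mer_channel", 192, 1), ("96mer_lipoprotein", 96, 1))))
    return ledger


def lattice_collapse_sequence() -> TransitionLedger:
    """Collapse of a nineteen-24mer patch into a giant channel.

    The outer ring of twelve 24mers (288 peptides) splits and merges into
    a 168mer channel plus a 120mer soluble barrel around the seven-24mer
    core. The 168/120 split is book-kept as printed; it is a distinct
    arithmetic from the 2/3–1/3 rule of :func:`gating_sequence`.
    """
    ledger = TransitionLedger(initial={"24mer": (24, 19)})
    apply_transition(ledger, split_step(
        "24mer", 24, 12,
        (("168mer_channel", 168, 1), ("120mer_barrel", 120, 1))))
    return ledger
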