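"""Closed-form β-barrel geometry and idealized symmetric Cα backbones.

A closed β-barrel of N strands is a β-sheet rolled onto a cylinder. The
register offset accumulated once around the barrel is the shear number S;
together with the two sheet lattice constants — Cα spacing ``a`` along a
strand and interstrand spacing ``b`` — it fixes everything else:

    tan(α) = S·a / (N·b)                      strand tilt vs barrel axis
    2πR    = sqrt((S·a)² + (N·b)²)            backbone-cylinder radius
    height = L·a·cos(α)                       axial extent of L residues

For barrels built from identical subunits, symmetry restricts S/N to a few
rational values; S/N = 1 gives α ≈ 36° and diameter ≈ 0.19·N nm, S/N = 2
gives α ≈ 55° and ≈ 0.27·N nm with the default lattice constants.

This module generates ideal Cα traces on that cylinder (with the ±pleat of
a β-sheet as a small radial alternation), measures their cyclic and P2
(dyad) symmetry, and solves the inverse problem of recovering (N, S, α, D)
from an unlabelled Cα point cloud.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial import cKDTree

from .config import DEFAULTS

__all__ = [
    "BarrelSpec",
    "BarrelGeometry",
    "BackboneModel",
    "BarrelFit",
    "BarrelError",
    "NotABarrelError",
    "derive_geometry",
    "generate_backbone",
    "check_symmetry",
    "fit_barrel_parameters",
]


class BarrelError(ValueError):
    """Invalid barrel specification or unrealizable shear."""


class NotABarrelError(ValueError):
    """A point cloud passed to the inverse fit is not a closed barrel."""


@dataclass(frozen=True)
class BarrelSpec:
    """Defining parameters of one idealized β-barrel.

    ``stagger_asymmetry`` selects the antiparallel registration: adjacent
    interfaces get integer staggers (S/N + Δ, S/N − Δ) so every pair of
    interfaces averages S/N. Δ=0 puts the dyad between the central residue
    pair of antiparallel neighbours; Δ=2 shifts the registration by one
    residue pair (e.g. the Val36–Val36 dyad of the S/N=1 Aβ42 S3 barrel).

    ``inward_parity`` states which chain-position parity (0- or 1-based
    alternation along each strand) faces the barrel axis; it may be a
    single int or one int per strand (hairpin barrels alternate it).
    """

    n_strands: int
    shear: int
    sense: str = "antiparallel"
    residues_per_strand: int = 14
    ca_spacing: float = DEFAULTS.ca_spacing
    interstrand_spacing: float = DEFAULTS.interstrand_spacing
    pleat_amplitude: float = DEFAULTS.pleat_amplitude
    azimuthal_phase: float = 0.0  # degrees
    handedness: str = DEFAULTS.handedness
    stagger_asymmetry: int = 0
    inward_parity: int | tuple[int, ...] = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_strands < 4:
            raise BarrelError(f"N must be >= 4, got N={self.n_strands}")
        if self.residues_per_strand < 3:
            raise BarrelError(
                f"L must be >= 3, got L={self.residues_per_strand}")
        if self.shear < 0:
            raise BarrelError(f"S must be >= 0, got S={self.shear}")
        if self.ca_spacing <= 0 or self.interstrand_spacing <= 0:
            raise BarrelError(
                "lattice spacings a and b must be positive "
                f"(a={self.ca_spacing}, b={self.interstrand_spacing})")
        if self.sense not in ("parallel", "antiparallel"):
            raise BarrelError(f"unknown sense {self.sense!r}")
        if self.sense == "antiparallel" and self.n_strands % 2:
            raise BarrelError(
                f"antiparallel sense requires even N, got N={self.n_strands}")
        if self.handedness not in ("right", "left"):
            raise BarrelError(f"unknown handedness {self.handedness!r}")
        if not isinstance(self.inward_parity, int):
            if len(self.inward_parity) != self.n_strands:
                raise BarrelError(
                    "per-strand inward_parity needs one entry per strand")

    def strand_parity(self, j: int) -> int:
        if isinstance(self.inward_parity, int):
            return self.inward_parity % 2
        return self.inward_parity[j] % 2

    def replace(self, **kwargs) -> "BarrelSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BarrelGeometry:
    """Derived closed-form quantities of a barrel (degrees and nm)."""

    tilt: float            # α
    radius: float          # R of the mean backbone cylinder
    diameter: float        # D = 2R
    height: float          # L·a·cos α
    rise_per_strand: float  # axial offset of one interstrand step, b·sin α


def derive_geometry(spec: BarrelSpec) -> BarrelGeometry:
    """Evaluate the shear-tilt-diameter relations for ``spec``.

    Pure closed form; no coordinates are generated.
    """
    spec.validate()
    a, b = spec.ca_spacing, spec.interstrand_spacing
    n, s = spec.n_strands, spec.shear
    alpha = math.atan2(s * a, n * b)
    radius = math.hypot(s * a, n * b) / (2.0 * math.pi)
    height = spec.residues_per_strand * a * math.cos(alpha)
    return BarrelGeometry(
        tilt=math.degrees(alpha),
        radius=radius,
        diameter=2.0 * radius,
        height=height,
        rise_per_strand=b * math.sin(alpha),
    )


# ---------------------------------------------------------------------------
# backbone generation


def _staggers(spec: BarrelSpec) -> np.ndarray:
    """Integer per-interface residue staggers summing to S around the barrel.

    Symmetric barrels need a stagger pattern whose period divides 2, so the
    cyclic N/2-fold (antiparallel) or N-fold (parallel) symmetry survives.
    """
    n, s = spec.n_strands, spec.shear
    if spec.sense == "parallel":
        if s % n:
            near = round(s / n) * n
            raise BarrelError(
                f"shear S={s} is not realizable for a parallel {n}-stranded "
                f"barrel with uniform integer staggers; nearest realizable "
                f"S = {near}")
        return np.full(n, s // n, dtype=int)
    # antiparallel: pairs of interfaces must carry an integer total 2S/N
    if (2 * s) % n:
        step = n // 2 if n % 2 == 0 else n
        near = round(s / step) * step
        raise BarrelError(
            f"shear S={s} is not realizable for an antiparallel {n}-stranded "
            f"barrel with period-2 integer staggers; nearest realizable "
            f"S = {near}")
    pair_total = (2 * s) // n
    hi = math.ceil(pair_total / 2) + spec.stagger_asymmetry
    lo = pair_total - hi
    out = np.empty(n, dtype=int)
    out[0::2] = hi  # larger stagger on even-indexed interfaces
    out[1::2] = lo
    return out


@dataclass
class BackboneModel:
    """Ordered idealized Cα coordinates with per-residue metadata.

    Atoms are ordered by (strand, position along the chain); for
    antiparallel barrels odd strands run in the opposite axial direction,
    so chain position and axial level differ there. ``facing`` is True for
    residues whose side-chain points at the barrel axis.
    """

    coords: np.ndarray                 # (N*L, 3) nm
    strand_index: np.ndarray           # (N*L,) int
    residue_index: np.ndarray          # (N*L,) int, position along the chain
    facing_inward: np.ndarray          # (N*L,) bool
    axis_origin: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    spec: BarrelSpec | None = None
    provenance: str = "generated"

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_strands(self) -> int:
        return int(self.strand_index.max()) + 1

    def strand(self, j: int) -> np.ndarray:
        """Coordinates of strand ``j`` ordered by chain position."""
        mask = self.strand_index == j
        order = np.argsort(self.residue_index[mask])
        return self.coords[mask][order]

    def atom(self, strand: int, residue: int) -> np.ndarray:
        mask = (self.strand_index == strand) & (self.residue_index == residue)
        idx = np.nonzero(mask)[0]
        if len(idx) != 1:
            raise KeyError(f"no atom (strand={strand}, residue={residue})")
        return self.coords[idx[0]]

    def radial_distances(self) -> np.ndarray:
        rel = self.coords - self.axis_origin
        axial = rel @ self.axis_direction
        return np.linalg.norm(
            rel - np.outer(axial, self.axis_direction), axis=1)

    def translated(self, shift: Sequence[float]) -> "BackboneModel":
        shift = np.asarray(shift, dtype=float)
        return replace(self, coords=self.coords + shift,
                       axis_origin=self.axis_origin + shift)

    def transformed(self, rot: np.ndarray) -> "BackboneModel":
        """Apply a rotation matrix about the coordinate origin."""
        return replace(
            self,
            coords=self.coords @ rot.T,
            axis_origin=rot @ self.axis_origin,
            axis_direction=rot @ self.axis_direction,
        )

    def flipped_p2(self, azimuth_deg: float = 0.0) -> "BackboneModel":
        """180° rotation about an in-plane axis through the origin."""
        phi = math.radians(azimuth_deg)
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        rot = 2.0 * np.outer(u, u) - np.eye(3)
        return self.transformed(rot)


def generate_backbone(spec: BarrelSpec) -> BackboneModel:
    """Roll the flat β-sheet lattice of ``spec`` onto its cylinder.

    The flat lattice has strand direction u tilted α from the axis, strand
    separation b along the perpendicular, and integer residue staggers from
    :func:`_staggers`; closure around the barrel is exact by construction
    because tan α = S·a/(N·b). The pleat is a ±``pleat_amplitude`` radial
    alternation, excluded from the definition of R.
    """
    spec.validate()
    geo = derive_geometry(spec)
    n, L = spec.n_strands, spec.residues_per_strand
    a, b = spec.ca_spacing, spec.interstrand_spacing
    alpha = math.radians(geo.tilt)
    sin_a, cos_a = math.sin(alpha), math.cos(alpha)
    circumference = 2.0 * math.pi * geo.radius

    stag = _staggers(spec)
    t = np.concatenate([[0], np.cumsum(stag[:-1])])  # strand slot origins

    strand_idx = np.repeat(np.arange(n), L)
    res_idx = np.tile(np.arange(L), n)
    if spec.sense == "antiparallel":
        odd = strand_idx % 2 == 1
        slot = np.where(odd, L - 1 - res_idx, res_idx)
    else:
        slot = res_idx

    along = t[strand_idx] + slot            # position along u, units of a
    x_flat = along * a * sin_a + strand_idx * b * cos_a
    z = along * a * cos_a - strand_idx * b * sin_a
    z = z - 0.5 * (z.min() + z.max())       # centre so P2 dyads sit at z=0

    theta = 2.0 * math.pi * x_flat / circumference
    theta = theta + math.radians(spec.azimuthal_phase)
    if spec.handedness == "left":
        theta = -theta

    parity = np.array([spec.strand_parity(j) for j in range(n)])
    inward = (res_idx % 2) == parity[strand_idx]
    radius = geo.radius + np.where(inward, -1.0, 1.0) * spec.pleat_amplitude

    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), z])
    return BackboneModel(
        coords=coords,
        strand_index=strand_idx,
        residue_index=res_idx,
        facing_inward=inward,
        spec=spec,
        provenance="generated",
    )


# ---------------------------------------------------------------------------
# symmetry measurement


def _axis_frame(model: BackboneModel) -> np.ndarray:
    """Coordinates expressed in a frame whose z axis is the model axis."""
    d = model.axis_direction / np.linalg.norm(model.axis_direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    frame = np.column_stack([e1, e2, d])
    return (model.coords - model.axis_origin) @ frame


def _max_nearest(tree: cKDTree, pts: np.ndarray) -> float:
    dist, _ = tree.query(pts, k=1)
    return float(dist.max())


def check_symmetry(
    model: BackboneModel,
    n_fold: int,
    check_p2: bool = False,
) -> float:
    """Maximum distance from any Cα to its nearest image under the symmetry.

    Applies (i) rotation by 360°/``n_fold`` about the model axis and, if
    ``check_p2``, (ii) 180° rotations about the ``n_fold`` in-plane dyad
    axes. The common dyad azimuth is not assumed known: it is located by a
    scan plus local refinement, so ideal barrels score ~0 regardless of
    their azimuthal phase.
    """
    if n_fold < 1:
        raise ValueError(f"n_fold must be >= 1, got {n_fold}")
    pts = _axis_frame(model)
    tree = cKDTree(pts)

    ang = 2.0 * math.pi / n_fold
    rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                    [math.sin(ang), math.cos(ang), 0.0],
                    [0.0, 0.0, 1.0]])
    deviation = _max_nearest(tree, pts @ rot.T)
    if not check_p2:
        return deviation

    def p2_dev(phi: float) -> float:
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        flip = 2.0 * np.outer(u, u) - np.eye(3)
        return _max_nearest(tree, pts @ flip.T)

    # dyad azimuths repeat every pi/n_fold; scan one period, refine the best
    period = math.pi / n_fold
    grid = np.linspace(0.0, period, 90, endpoint=False)
    vals = [p2_dev(phi) for phi in grid]
    best = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        p2_dev, bracket=None,
        bounds=(best - period / 60, best + period / 60), method="bounded",
        options={"xatol": 1e-12})
    phi0 = float(res.x) if res.fun < min(vals) else float(best)
    for k in range(n_fold):
        deviation = max(deviation, p2_dev(phi0 + k * math.pi / n_fold))
    return deviation


# ---------------------------------------------------------------------------
# inverse fit


@dataclass(frozen=True)
class BarrelFit:
    """Result of recovering barrel parameters from a Cα point cloud."""

    n_strands: int
    shear: int
    tilt: float        # degrees
    diameter: float    # nm
    radius: float
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    low_confidence: bool
    radial_spread: float


def _cylinder_residual(direction: np.ndarray, pts: np.ndarray):
    """Circle fit (Kåsa) of the points projected along ``direction``."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    uv = np.column_stack([pts @ e1, pts @ e2])
    uv0 = uv - uv.mean(axis=0)
    A = np.column_stack([2 * uv0, np.ones(len(uv0))])
    y = (uv0 ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    center2 = sol[:2]
    radius = math.sqrt(max(sol[2] + center2 @ center2, 0.0))
    r = np.linalg.norm(uv0 - center2, axis=1)
    rms = float(np.sqrt(np.mean((r - radius) ** 2)))
    center3 = ((center2 + uv.mean(axis=0)) @
               np.vstack([e1, e2])) + (pts.mean(axis=0) @ d) * d
    return rms, radius, center3, d, r


def _estimate_axis(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cylinder axis by minimizing the radial scatter of a circle fit."""
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)

    def objective(ang):
        th, ph = ang
        d = np.array([math.sin(th) * math.cos(ph),
                      math.sin(th) * math.sin(ph),
                      math.cos(th)])
        return _cylinder_residual(d, pts)[0]

    best = None
    for d0 in vt:  # all three principal directions as starts
        th0 = math.acos(np.clip(d0[2], -1.0, 1.0))
        ph0 = math.atan2(d0[1], d0[0])
        res = minimize(objective, x0=[th0, ph0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    th, ph = best.x
    d = np.array([math.sin(th) * math.cos(ph),
                  math.sin(th) * math.sin(ph),
                  math.cos(th)])
    _, _, center, _, _ = _cylinder_residual(d, pts)
    return d, center


def fit_barrel_parameters(
    coords: Sequence[Sequence[float]] | np.ndarray,
    ca_spacing: float = DEFAULTS.ca_spacing,
    interstrand_spacing: float = DEFAULTS.interstrand_spacing,
    pleat_amplitude: float = DEFAULTS.pleat_amplitude,
) -> BarrelFit:
    """Recover (N, S, α, D) from an ordered Cα trace of a closed barrel.

    The axis is found by least-squares cylinder fitting. Strands are then
    segmented by the axial direction of consecutive steps: within a strand
    every step advances by ±a·cos α along the axis with a consistent sign,
    the sign flips at each antiparallel hairpin turn, and parallel-barrel
    strand breaks appear as long (> 3·a) jumps. α comes from the mean
    strand-direction angle to the axis, S from round(N·b·tan α / a). A
    radial scatter above 3× the pleat amplitude sets ``low_confidence``
    rather than failing.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 6:
        raise NotABarrelError(
            "need at least 6 Cα coordinates of shape (n, 3)")

    # degenerate clouds (collinear / coplanar-thin) cannot be barrels
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-6 * max(svals[0], 1e-12):
        raise NotABarrelError("points are collinear; not a barrel")

    axis_dir, axis_origin = _estimate_axis(pts)
    _, _, _, _, radii = _cylinder_residual(axis_dir, pts)

    steps = np.diff(pts, axis=0)
    long_jump = np.linalg.norm(steps, axis=1) > 3.0 * ca_spacing
    # within a strand every step advances axially with one sign; the sign
    # flips at antiparallel turns. A 3-step moving majority vote absorbs
    # isolated noise-flipped steps; long jumps (parallel-barrel strand
    # breaks) are unconditional separators.
    sign = np.where(steps @ axis_dir >= 0.0, 1, -1)
    if len(sign) >= 3:
        padded = np.concatenate([sign[:1], sign, sign[-1:]])
        sign = np.sign(padded[:-2] + padded[1:-1] + padded[2:]).astype(int)
    ranges = []
    start = 0
    for i in range(1, len(steps)):
        if long_jump[i] or sign[i] != sign[i - 1]:
            ranges.append((start, i + 1))
            start = i + 1 if long_jump[i] else i
    ranges.append((start, len(pts)))
    ranges = [(i, j) for i, j in ranges if j - i >= 3]
    strands = [pts[i:j] for i, j in ranges]
    if len(strands) < 2:
        raise NotABarrelError(
            f"only {len(strands)} strand(s) detected; not a barrel")

    # Mean-cylinder radius from consecutive intrastrand pairs: adjacent
    # residues sit on opposite pleats, so each pair mean is exactly R for
    # an ideal trace — immune to the in/out population imbalance that
    # biases a plain average. Under noise, subtract the convexity bias
    # E|r+ε| - r ≈ σ²/(2R), with σ² taken from the radial spread in
    # excess of the pleat.
    # trim one atom per strand end: turn-adjacent atoms can belong to the
    # neighbouring strand (same pleat sign) and would skew the pairs
    pair_means = np.concatenate([
        0.5 * (radii[i + 1:j - 2] + radii[i + 2:j - 1])
        for i, j in ranges if j - i >= 4] or [np.empty(0)])
    radius = float(pair_means.mean()) if len(pair_means) else float(
        radii.mean())
    spread = float(np.sqrt(np.mean((radii - radius) ** 2)))
    noise_var = max(spread ** 2 - pleat_amplitude ** 2, 0.0)
    radius -= noise_var / (2.0 * radius)

    # strands are helical arcs, so a straight-line fit to one strand leans
    # toward the axis; the closure relation (2πR)² = (S·a)² + (N·b)² gives
    # the tilt from the well-determined radius instead, exactly for ideal
    # traces: sin α = S·a / (2πR)
    n = len(strands)
    circ = 2.0 * math.pi * radius
    s_len = math.sqrt(max(circ ** 2 - (n * interstrand_spacing) ** 2, 0.0))
    alpha = math.asin(min(s_len / circ, 1.0))
    shear = int(round(s_len / ca_spacing))
    return BarrelFit(
        n_strands=n,
        shear=shear,
        tilt=math.degrees(alpha),
        diameter=2.0 * radius,
        radius=radius,
        axis_origin=axis_origin,
        axis_direction=axis_dir,
        low_confidence=spread > 3.0 * pleat_amplitude,
        radial_spread=spread,
    )
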