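# Methods

## Model

All models in this package are assemblies of idealized β-barrels sharing
one axis (+z), plus optional α-helix rings and axial (tandem) stacks. A
barrel is fully specified by its strand count `N`, shear number `S`
(total residue register offset around the closed barrel), strand sense
(parallel or antiparallel), strands of `L` residues, and two sheet
lattice constants: the Cα spacing along a strand `a` and the interstrand
spacing `b`. The closed forms

    tan α = S·a/(N·b),   2πR = sqrt((S·a)² + (N·b)²),   height = L·a·cos α

determine the strand tilt α, the backbone-cylinder radius R (diameter
D = 2R) and the axial extent. With the defaults `a = 0.345 nm`,
`b = 0.483 nm`, the two identical-subunit families give α = 35.5° ≈ 36°
and D/N = 0.189 ≈ 0.19 nm (S/N = 1) versus α = 55.0° and D/N = 0.268 ≈
0.27 nm (S/N = 2). These two constants are the only geometric knobs; the
defaults were chosen because they reproduce both the canonical tilt
angles and both diameter coefficients simultaneously, and they are
configurable through the YAML config file.

Backbones are generated by building the flat sheet lattice — strand
direction tilted α from the axis, strands separated by `b`, integer
per-interface residue staggers — and rolling it onto the cylinder of
radius R. Closure is exact by construction because the tilt relation
makes one full circuit of N interfaces advance exactly the circumference
with zero net axial offset. The β pleat is realized as a ±0.05 nm radial
alternation (inward-facing residues at R − 0.05, outward at R + 0.05);
it is book-keeping for side-chain facing and is excluded from the
definition of R.

One consequence worth stating plainly: exact closure forces the axial
step per residue to `a·cos α`, so chord distances between consecutive
Cα on the pleated cylinder come out ≈ 2–4% longer than `a` (0.358 nm for
the small hexamer barrel). The generated spacing is uniform to 1e-9 nm;
it cannot simultaneously equal `a` exactly. For schematic Cα models at
this resolution the discrepancy is irrelevant, and the tests pin the
uniformity plus a 0.02 nm agreement with `a`.

### Stagger patterns and registration

Symmetric barrels need stagger patterns of period ≤ 2, which restricts
realizable shears to multiples of N/2 (antiparallel) or N (parallel);
other shears raise an error naming the nearest realizable value.
Antiparallel interfaces carry per-pair staggers `(S/N + Δ, S/N − Δ)`
with the larger value on even-indexed interfaces. The asymmetry Δ
selects the inter-strand registration — a genuine structural degree of
freedom (which residue pairs face each other across an interface):

* Δ = 2 for S/N = 1 S3 barrels: the perpendicular dyads pass between the
  Val36 pairs of adjacent strands, the registration reported for small
  Aβ42 oligomer cores;
* Δ = 0 otherwise: for S/N = 2 S3 barrels this aligns Gly33 of one
  strand with Gly37 of its antiparallel neighbour on one pleat band —
  the side-chain-free axial groove ("glycine pleat") that accommodates a
  GM1 alkyl chain along the barrel wall. The pleat check declares the
  glycines co-banded when both face inward and their axial offset is at
  most a/2; this criterion reproduces the S/N = 2 (true) versus
  S/N = 1 (false) contrast.

Barrels are right-handed by default; handedness is a flag, mirror-image
output, untested against any external reference.

## Preset catalog

Soluble oligomers (6, 8, 12, 16, 18 subunits) are an antiparallel S3
barrel (strand per subunit, residues 28–42) inside an outer barrel of
S1 (1–14) and S2 (15–27) strands (two per subunit). Channels put S3 in
the membrane, S2 into surface helix rings (ideal α-helices: 0.15 nm
rise/residue, 0.23 nm Cα radius, 100°/residue, axes tilted 55° from the
membrane normal, half per face as P2 images), and S1 into two tandem
pore barrels whose N-terminal Asp1 ends meet at the membrane midplane
separated by one inter-residue rise. Small channels use parallel
continuous-S1 pore barrels (S/N = 2); the large (S/N = 2) 24mer and
36mer use two antiparallel S1a-S1b hairpin barrels. Transmembrane
oligomers (TMOs) stack small antiparallel S1-S2 barrels on each membrane
face; the plugged 48mer nests a soluble dodecamer inside the large 36mer
channel.

Inter-wall gaps (difference of mean backbone-cylinder radii, the reading
that reproduces the printed ~0.8 nm hexamer value) are constrained to
0.6–1.0 nm for dry interfaces and 1.0–1.4 nm where GM1 alkyl chains pack
between the walls; windows are evaluated at the one-decimal precision at
which they are stated. Where a preset's outer shear is not fixed by the
text, it is chosen as the realizable shear bringing the gap closest to
the window target (0.8 nm dry, 1.2 nm lipid); this rule reproduces the
two published hexamer shears (18 and 24) exactly and is applied
unchanged to the presets whose shears are not stated anywhere, which
are marked `inferred_shear`.
Three catalog entries deserve honesty notes: the soluble octadecamer's
36-stranded outer barrel cannot sit closer than ~1.07 nm to its core
(the lattice circumference alone forbids it), so that interface is
modelled lipid-filled; and the S/N = 1 12mer/18mer channel variants —
catalogued for completeness — fail the dry window (0.33/0.49 nm), which
is flagged in their gap reports rather than hidden, consistent with the
observation that small channels need S/N = 2 to accommodate their pore
lining.

Secondary-structure fractions are reported per assembly with
largest-remainder rounding so β + helix + loop = 100. The small 24mer
channel uses its published explicit ranges (β 2–13 and 31–41, helix
17–24), giving 55% β and 19% helix; other presets derive ranges from
their segment scheme. Loop residues are placed by linear interpolation
between flanking structured residues — schematic, like everything at Cα
resolution here.

Protrusion above the membrane (default thickness 5.0 nm) is the extent
of non-transmembrane atoms beyond ±2.5 nm. TMO aqueous barrels protrude
≈ 3.8 nm, in the 2–5 nm range reported by AFM for large soluble domains;
channel presets protrude < 1 nm (pore-stack tops and surface helices),
matching the low end of the 1–3 nm AFM estimates for channel forms.

## Inverse fit

`fit_barrel_parameters` recovers (N, S, α, D) from an ordered Cα trace.
The axis minimizes the radial scatter of an algebraic circle fit
(Nelder-Mead over the direction sphere, started from all three principal
axes). Strands are runs of consistent axial step sign — each in-strand
step advances ±a·cos α along the axis; the sign flips at antiparallel
turns — smoothed by a 3-step majority vote, with > 3a jumps as hard
breaks (parallel barrels). A plain distance threshold cannot do this
job: antiparallel interface gaps (≈ sqrt(b² + (s·a)²)) overlap the
intrastrand scale. The radius is the mean of consecutive intrastrand
radius pairs (adjacent residues sit on opposite pleats, so each pair
mean is exactly R, immune to in/out population imbalance), with
strand-end atoms trimmed and a σ²/(2R) convexity debias under noise.
The tilt then comes from the closure relation sin α = S·a/(2πR) — not
from straight-line strand fits, which are biased because strands are
helical arcs that can wrap beyond 180° on small barrels — and
S = round(N·b·tan α/a). Radial scatter above 3× the pleat amplitude
sets a low-confidence flag.

Under the synthetic noise condition (σ = 0.05 nm per coordinate), the
fit recovers (N, S) exactly in ≥ 99 of 100 seeded replicates for the
hexamer and 24mer core barrels, and noiselessly it is exact to machine
precision for every catalog barrel. Per-replicate tilt scatter scales
with atom count: ≈ 0.1° for the 336-atom (12, 24) barrel, ≈ 0.75° for
the 90-atom hexamer core.

## Symmetry metric

`check_symmetry` reports the maximum distance from any atom to its
nearest image under rotation by 360°/n_fold, and optionally under 180°
rotations about the n_fold in-plane dyads. The dyad azimuth is located
by a 90-point scan plus bounded refinement, so the metric does not need
the construction phase. Ideal presets score < 2e-8 nm; the tests accept
< 1e-6. Tandem stacks, TMO face domains and helix rings are evaluated as
two-copy unions because the dyad exchanges the faces.

## Lattices and transitions

Centered hexagonal layouts place 1 + 3r(r + 1) units (unit spacing = two
outer radii + a 0.4 nm margin; 1.0 nm where GM1 occupies three-fold
sites); honeycomb layouts put hexamers on the deduplicated vertices of
hexagon cells in centred order (1 cell = 6 units, 7 cells = 24) with
30° alternation between sublattices. The transition ledger stores states
as {label: (subunit size, count)} and re-verifies total peptide count at
every applied step; the canonical gating cascade (48 hexamers → 24
dodecamers → 12 24mers → 6 48mers → 192mer channel + 96mer lipoprotein)
holds 288 peptides in all five states. The nineteen-24mer collapse
(outer twelve 24mers → 168mer channel + 120mer barrel) is a separate
preset ledger; its 168/120 arithmetic is distinct from the 2/3–1/3 rule
of the gating cascade, and both are kept as printed without
reconciliation.

## Synthetic fixtures: what they do and do not show

`make_fixture` perturbs ideal barrels with seeded isotropic Gaussian
coordinate noise (default σ = 0.05 nm, chosen as a plausible
Cα-coordinate uncertainty for low-resolution model traces and as the
scale of the pleat itself — noise that visibly blurs the pleat without
destroying the lattice). Fixtures emulate measurement noise only: real
Aβ42 assemblies would add strand twist and coning, irregular staggers,
partial disorder of S1, and genuine polymorphism. Passing the recovery
and symmetry tests therefore demonstrates the correctness and noise
tolerance of the geometric machinery, not that experimental Aβ42
densities will fit these idealized barrels. Stability claims requiring
molecular dynamics are out of scope; the geometric invariant suite
(symmetry, round-trip, monotonicity, conservation, lattice counts)
stands in for them.

## Numerical conventions

Lengths are nm internally and Å only in PDB output (occupancy 0.50 =
inward, 1.00 = outward; B-factor = segment id S1a/S1b/S2/S3 = 1–4, loop
0; chains A–Z, a–z, 0–9, then a segment-id fallback with a warning).
All "printed value" comparisons round half away from zero at the
printed precision, via a single routine (`conbarrel.util.round_half_away`).
Degenerate inputs fail loudly: collinear point clouds and single-strand
traces are "not a barrel", unrealizable shears name the nearest
realizable value, soluble assemblies have no membrane frame to protrude
from, and conservation violations report their imbalance.

## Problem sizes

The test suite and the acceptance script run the models at their natural
sizes — barrels of 6–72 strands (up to ~1500 atoms per assembly),
100-replicate noise simulations, lattices up to 5 rings — which a single
CPU completes in well under a minute each; nothing is down-scaled from
the sizes the models themselves specify.
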