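# conbarrel

Model-building toolkit for **concentric β-barrel models of amyloid-β 42
(Aβ42) oligomers, transmembrane channels and membrane lattices** — the
structural hypothesis that soluble Aβ42 oligomers and channels are built
from coaxial β-barrels: a hydrophobic C-terminal (S3) barrel at the core,
shielded by an outer barrel of the N-terminal/middle segments (S1, S2) in
solution, or lined by S1 pore barrels and capped by S2 surface helices in
membranes.

It is written for structural modellers who want the barrel arithmetic,
idealized Cα scaffolds and book-keeping behind such models to be explicit,
testable and reproducible, rather than buried in an interactive session.

## The geometry at the core

A closed β-barrel of `N` strands with shear number `S` (the residue
register offset accumulated once around the barrel) on a sheet lattice
with Cα spacing `a = 0.345 nm` and interstrand spacing `b = 0.483 nm`
satisfies

```
tan α = S·a / (N·b)          strand tilt from the barrel axis
2πR   = sqrt((S·a)² + (N·b)²)   backbone-cylinder radius, D = 2R
height = L·a·cos α            axial extent of L-residue strands
```

Identical-subunit ("1Con") models admit only a few S/N ratios: S/N = 1
gives α ≈ 36° and D ≈ 0.19·N nm (tall, narrow); S/N = 2 gives α ≈ 55° and
D ≈ 0.27·N nm (short, wide). The package generates ideal pleated Cα
backbones on these cylinders with N/2-fold radial and P2 (perpendicular
dyad) symmetry, threads the 42-residue Aβ42 sequence onto preset
architectures (hexamer → octadecamer soluble oligomers, transmembrane
oligomers, 12- to 36-subunit channels, a 48mer plugged channel), checks
the 0.6–1.0 nm (dry) / 1.0–1.4 nm (GM1 lipid) inter-wall gap constraints,
lays assemblies out on hexagonal membrane lattices, and book-keeps
peptide-conserving merge/split transitions such as the mechanosensitive
gating cascade of a 288-peptide patch. An inverse fit recovers
`(N, S, α, D)` from an unlabelled Cα trace, exactly for ideal input and
reliably at 0.05 nm coordinate noise.

## Worked example

```
$ conbarrel build soluble_hexamer_small
inner_S3               N=  6 S=  6 alpha=36 deg D=1.13 nm
outer_S1S2             N= 12 S= 18 alpha=47 deg D=2.70 nm
gap inner_S3 -> outer_S1S2: 0.8 nm (dry, pass)
secondary structure: beta 100% helix 0% loop 0%
```

The soluble hexamer is a 6-stranded antiparallel S3 barrel (S/N = 1, so
α rounds to 36° and D = 1.13 nm ≈ 0.19 × 6) inside a 12-stranded S1-S2
barrel whose shear (S = 18, S/N = 1.5) places its wall 0.8 nm outside the
core — inside the 0.6–1.0 nm window a dry protein–protein interface
allows. The small 24mer channel preset reports the measured secondary
structure split (55% β, 19% helix) and the tilted S2 surface-helix ring:

```
$ conbarrel build channel_24_1con1
pore_S1                N= 12 S= 24 alpha=55 deg D=3.22 nm
inner_S3               N= 24 S= 24 alpha=36 deg D=4.53 nm
gap pore_S1_top -> inner_S3: 0.7 nm (dry, pass)
secondary structure: beta 55% helix 19% loop 26%
```

Other entry points: `conbarrel build <preset> --pdb out.pdb --report
out.json --map inner_S3` (Cα-trace PDB, JSON geometry report, flattened
barrel map), `conbarrel lattice channel_24_1con1 --rings 2` (the
nineteen-channel hexagonal patch), `conbarrel gate` (the 288-peptide
merge/split ledger), `conbarrel fit model.pdb --segment 4` (inverse
barrel fit on the S3 atoms), and `conbarrel fixture <preset>` (seeded
noisy test barrels). The same operations are available as a library:

```python
from conbarrel import BarrelSpec, derive_geometry
derive_geometry(BarrelSpec(n_strands=6, shear=12)).tilt  # 55.008
```

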