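# Methods

## Features

Four features are measured per residue: backbone torsions φ (C(i−1)–N–Cα–C)
and ψ (N–Cα–C–N(i+1)), the first side-chain torsion χ1 (N–Cα–Cβ–Xγ, with the
standard lowest-numbered γ branch: CG1 for ILE/VAL, OG1 for THR, OG for SER,
SG for CYS), and the distal-block length dBlock. All angles follow the IUPAC
sign convention (cis = 0°, trans = 180°) and are reported on [0°, 360°):
negative Ramachandran-convention values are shifted by +360°. The boundary
−180° is treated as identical to 180°. Dihedrals are computed with the
cross-product/atan2 formula; the test suite checks it against an independent
oracle that constructs quadruples of known torsion by explicit Rodrigues
rotation about the central bond (agreement to 1e−6°), and checks mirror
antisymmetry and rigid-motion invariance.

φ is undefined at chain starts, ψ at chain ends, χ1 and dBlock for GLY/ALA
or when a required atom is absent from the model. Undefined features are
flagged missing and excluded from binning — never imputed. Chain
connectivity is decided by the C(i)–N(i+1) distance (< 2.0 Å), so chain
breaks suppress torsions across gaps instead of producing nonsense values
over missing residues.

## The block table

The distal block of each of the 18 side-chain-bearing residue types is a
configurable, ordered list of heavy atoms with standard atomic masses
(C 12.011, N 14.007, O 15.999, S 32.06 u); dBlock is the distance from Cα to
the block's mass-weighted center. Hydrogens are excluded throughout, because
deposited structures rarely contain them. The shipped defaults use the
chemically terminal rigid group of each side chain:

| residue | block | residue | block |
|---|---|---|---|
| ARG | NE, CZ, NH1, NH2 | LYS | CE, NZ |
| ASN | CG, OD1, ND2 | MET | SD, CE |
| ASP | CG, OD1, OD2 | PHE | CG..CZ ring (6) |
| CYS | SG | PRO | CG, CD |
| GLN | CD, OE1, NE2 | SER | OG |
| GLU | CD, OE1, OE2 | THR | OG1, CG2 |
| HIS | imidazole ring (5) | TRP | benzo ring (6) |
| ILE | CD1 | TYR | OH |
| LEU | CD1, CD2 | VAL | CG1, CG2 |

The exact block partition is not uniquely fixed by the statistic's published
descriptions, so the table is treated as calibrated configuration: with the
defaults above, ideal-geometry conformers reproduce the reference modal
lengths — LYS all-trans 5.75 Å (target 5.7), ILE (χ1=300°, χ2=180°) 3.88 Å,
PHE (300°, 90°) 3.78 Å, TYR (300°, 90°) 6.45 Å (target 6.43) — all within
0.02–0.05 Å, far inside the ±0.15 Å calibration tolerance. The table can be
exported/edited as JSON and passed to the CLI.

## Structure reading and selection

PDB files are read through gemmi; only the first MODEL is used, and HETATM
records (ligands, waters, modified residues such as MSE) are excluded.
Selection policy is explicit configuration, never inferred from the file:
`chains="first"` keeps the first chain (the convention for large
crystallographic sets, avoiding NCS duplication), `chains="all"` keeps every
chain (the choice for small EM sets, where NCS copies are retained to gain
statistics). For atoms with alternate conformations the altloc occurring
first in file order is kept — "first conformation", not highest occupancy.
Non-standard residues are dropped and counted; insertion codes and original
residue numbering are preserved. Record extraction conserves counts: one
record per selected residue, incomplete residues included with missing
flags and logged.

## Synthetic conformer generation

The builder places atoms by sequential internal-coordinate (NeRF) placement
from a standard stereochemistry parameter set (Engh–Huber-type bond lengths
and angles, stored as editable data in `templates.py`). The Cβ improper
torsion (dihedral C–N–Cα–Cβ = 240°) fixes the L configuration, and the
branched-atom offsets (±120°) match ideal L-amino-acid reference geometry.
Aromatic and other sp2 groups are rigid planar templates expressed as
successive in-plane placements, so no ring-closure solving is needed; the
implied closing bonds (e.g. CE2–CZ of PHE) land within ~0.05 Å of their
nominal lengths, and PRO uses a fixed ring template (no free χ). Every
requested torsion is realized exactly; writing to PDB quantizes coordinates
to 3 decimals, which perturbs re-measured torsions by well under the 0.05°
round-trip tolerance asserted in the tests.

Residues are built inside a GLY–X–GLY tripeptide (ω = 180°) so φ and ψ are
defined; the flanking glycines' own free torsions are fixed arbitrary
constants. Ensembles draw a mixture component by weight, add independent
Gaussian noise (σ in degrees, per angle) to all torsions, and reject
conformers in which any heavy-atom pair separated by ≥3 bonds comes closer
than 2.0 Å; clashing draws are redrawn up to 100 times before the generator
fails loudly. Everything is reproducible from the spec's single seed. The
generator's default study conditions used across the tests — host backbone
(φR, ψR) = (−62°, −41°), torsion noise σ = 5°, rotameric components at
{60°, 180°, 300°}, ensembles of 10⁴ samples for mode-recovery checks and
(1.5–3)·10³ per set for comparison checks — emulate a well-populated rotamer
class at high resolution.

What the synthetic stage deliberately does not emulate: experimental
coordinate error and map-driven modeling bias, backbone-dependent rotamer
preferences, correlations between χ angles, crystal/particle environment,
B-factors and occupancy, and real datasets' heterogeneous residue context.
Passing tests therefore demonstrate that the measurement and comparison
machinery is correct and well-calibrated on ground-truth geometry — not
that any particular experimental dataset shows a given bias.

## Binning, normalization and peak calling

Densities use half-open bins [edge, edge + w) anchored at 0, with w = 5° for
angles (72 bins over [0°, 360°)) and w = 0.05 Å for dBlock; bin centers are
therefore reproducible across datasets (2.5° and 0.025 Å offsets). The pdf
is count/(N·w), so densities integrate to 1; the npdf of a two-set
comparison divides *both* pdfs by the reference set's peak density (the
reference npdf has max exactly 1 in floating point, asserted exactly). 2D
histograms are normalized by their own modal cell; ties go to the
lowest-index cell.

Peaks are strict local maxima (plateaus reported at their leftmost bin) with
prominence — height above the highest saddle toward a higher point or the
profile edge — of at least 5 % of the global maximum (configurable). The
global maximum is always reported, so monotone and flat profiles yield
exactly one peak. Exceedance calls ("set B above set A") require B's npdf to
strictly exceed A's over at least 2 consecutive dBlock bins; interval masses
split partial bins proportionally. No significance testing is attempted:
the comparison is descriptive, and npdf differences at sparsely populated
bins should be read with the usual caution.

## Pipeline and outputs

`run_profile` maps two manifests (CSV of path, id, method, resolution) to
record tables, per-residue-type npdf tables for all four features, 2D
histogram tables for both sets, a JSON comparison report, and a log line per
structure (processed or skipped with reason). Identical configuration and
inputs give byte-identical tables. Plots (3D (φ, ψ, χ1) scatter colored by
χ1, χ1-colored Ramachandran maps, npdf overlays, (φ, dBlock) ratio maps) are
regenerable from the tables and are not part of the numeric contract. All
five feature pairs (φ, χ1), (ψ, χ1), (φ, ψ), (φ, dBlock), (ψ, dBlock) go
through the same generic 2D path; (φ, dBlock) is the default.

## Numerical choices and limitations

- Bin-edge membership relies on numpy's histogram edge semantics; exact
  multiples of the bin width land in the bin they open.
- dBlock is invariant to χ1 by construction (rotation about Cα–Cβ passes
  through Cα), so block-length ranges over rotamer grids are governed by
  χ2+ only.
- Ring-flip symmetry of PHE/TYR/ASP/GLU χ2 is not folded; symmetric rotamers
  appear as distinct angles.
- χ2–χ4 angles are measured only inside the builder's ground truth, not
  extracted from structures; block orientation is out of scope.
- The clash filter is a hard-sphere heuristic meant to keep synthetic
  ensembles physical, not an energy model.
- mmCIF input, structure download/culling and density-map handling are out
  of scope; PDB text files are the only input dialect.
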