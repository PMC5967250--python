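# distalblock

Statistical characterization of protein side-chain conformations by the
**distal-block length** together with backbone and side-chain torsion angles,
for comparing two sets of atomic structures (for example a high-resolution
crystallographic reference set against models built into cryo-EM density
maps, where side chains are the hardest part of the model to place).

## The statistic

A side chain is partitioned into rigid groups; the group farthest from the
backbone is its *distal block* (the guanidinium of ARG, the CE–NZ tip of LYS,
the phenyl ring of PHE, the hydroxyl oxygen of TYR, ...). The block length

&nbsp;&nbsp;&nbsp;&nbsp;d<sub>Block</sub> = | **r**(Cα) − **r**(mass center of the distal block) |

is a one-number summary that separates folded from extended side-chain
conformations while remaining measurable with good statistics even from
modest datasets. Alongside d<sub>Block</sub> the package measures the
backbone torsions φ, ψ and the first side-chain torsion χ1, all reported on
[0°, 360°) (φ = φ<sub>R</sub> + 360° for negative Ramachandran-convention
values, so the α-helical φ<sub>R</sub> = −62° appears as 298°).

Per residue type, feature values are binned (5° for angles, 0.05 Å for
d<sub>Block</sub>) into probability density functions. Two sets are compared
through *normalized* pdfs (npdf): both curves are divided by the peak density
of the reference set, so the reference peaks at exactly 1 and the other curve
reads directly as a peak-relative probability. 2D (φ, d<sub>Block</sub>)
histograms are normalized by their own modal cell, making each cell a
population ratio with respect to the most popular conformation. The package
reports peak positions, interval masses, population ratios, and the
contiguous d<sub>Block</sub> ranges where the scrutinized set's npdf exceeds
the reference's — the construct used to call a bias toward shorter side
chains.

Because real reference datasets are large external downloads, the package
ships a first-class synthetic-data stage: an internal-coordinate (NeRF-style)
builder that places side chains in GLY–X–GLY tripeptides at *exact*
user-specified torsions from standard covalent geometry, samples
torsion-mixture ensembles with Gaussian noise and a steric clash filter, and
writes valid PDB files next to a ground-truth table. The shipped block table
is calibrated so that ideal conformers reproduce the modal block lengths
observed in high-resolution structure sets (LYS 5.7 Å, ILE 3.88 Å,
PHE 3.78 Å, TYR 6.43 Å).

## Worked example

```python
from distalblock import (build_residue, block_length, default_block_table,
                         Component, SyntheticSpec, sample_ensemble,
                         extract_records, records_to_frame)
from distalblock.profiles import compare_sets

table = default_block_table()

# ideal conformers at the most common rotamers
for res_type, chis in [("LYS", [180]*4), ("ILE", [300, 180]),
                       ("PHE", [300, 90]), ("TYR", [300, 90])]:
    res = build_residue(res_type, -62, -41, chis)
    print(f"{res_type} dBlock = {block_length(res, table):.2f} A")

# two synthetic LYS sets: A all-trans; B with 40% folded (chi3 = 60)
trans, folded = (180, 180, 180, 180), (180, 180, 60, 180)
spec_a = SyntheticSpec("LYS", [Component(-62, -41, trans, 1.0, 5.0)], 5000, seed=1)
spec_b = SyntheticSpec("LYS", [Component(-62, -41, trans, 0.6, 5.0),
                               Component(-62, -41, folded, 0.4, 5.0)], 5000, seed=2)
frames = []
for spec in (spec_a, spec_b):
    structures, truth = sample_ensemble(spec, table)
    frames.append(records_to_frame(
        [r for s in structures for r in extract_records([s], table)]))
report = compare_sets(frames[0], frames[1], "LYS")
fc = report.features["dblock"]
print("set A peaks:", [(p.center, round(p.height, 2)) for p in fc.peaks_a])
print("set B peaks:", [(p.center, round(p.height, 2)) for p in fc.peaks_b])
for e in report.exceedance:
    print(f"B above A on {e.lo:.2f}-{e.hi:.2f} A: "
          f"mass A={e.mass_a:.3f}, B={e.mass_b:.3f}")
```

prints

```
LYS dBlock = 5.75 A
ILE dBlock = 3.88 A
PHE dBlock = 3.78 A
TYR dBlock = 6.45 A
set A peaks: [(5.725, 1.0)]
set B peaks: [(5.725, 0.58), (5.175000000000001, 0.18)]
B above A on 4.95-5.35 A: mass A=0.000, B=0.416
```

The ideal conformers land on the calibrated modal lengths. In the two-set
comparison, set A's single extended component peaks at the 5.725 Å bin
(height 1, it is the reference); set B keeps that peak at height 0.58 —
extended conformations are rarer — and gains a second peak one bin from the
folded component's ideal length (5.16 Å). The exceedance interval
4.95–5.35 Å is where B's npdf runs above A's: it contains 41.6 % of B's
observations and essentially none of A's, exactly the injected 40 % folded
fraction plus noise.

## Command line

```sh
distalblock simulate --spec spec.json --outdir sim       # ensembles + manifest
distalblock extract  --manifest m.csv --out records.csv  # PDB -> feature table
distalblock profile  --records records.csv --outdir out  # single-set tables
distalblock compare  --manifest-a a.csv --manifest-b b.csv --outdir out
distalblock plot     --bundle out                        # npdf / 2D histogram / scatter images
```

Record tables, npdf tables and histogram tables are plain CSV; the
comparison report is JSON; exit codes are 0 (ok), 1 (some structures
skipped), 2 (fatal). Selection policies (first chain vs all chains, first
altloc) are explicit flags, and a custom block table can be supplied as JSON
via `--block-table`.

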