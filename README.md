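# flexalign

Flexible, non-sequential protein structure alignment of Cα traces.

`flexalign` aligns two protein chains by enumerating **aligned fragment
pairs** (AFPs) — gapless correspondences of `l ≥ 8` consecutive residues
whose optimal-superposition RMSD is at most `ε = 2 Å` — and greedily chaining
a mutually non-overlapping subset of them into **rigid regions** separated by
**hinges**. A hinge is introduced whenever joining a fragment would push a
region's joint RMSD above the threshold `D_c = 3 Å`, so each region keeps a
single rigid-body transform. The general precedence relation permits
non-sequential placements, which lets the aligner recover circular
permutations that defeat sequential methods.

Key components:

- `flexalign.geometry` — Kabsch superposition and a constant-size RMSD
  accumulator that updates in O(1) per added residue pair, making fragment
  enumeration cubic instead of quartic.
- `flexalign.afp_extraction` — maximal-AFP enumeration via per-diagonal
  prefix statistics.
- `flexalign.chaining` — the greedy chaining engine with gap, RMSD-ramp, and
  hinge penalties, K restarts from the highest-weight seeds, and
  overlap-trimming of candidate fragments.
- `flexalign.sequential_chaining` — a faster endpoint-sweep variant for
  purely sequential alignment, with score-based (rather than dominance-based)
  pruning and two connection-cost flavors: `whole_region` (default; joins are
  judged against the entire terminal rigid region, guaranteeing region RMSD
  ≤ `D_c`) and `last_segment` (cheaper but lets slowly drifting
  chains accumulate large region RMSD).
- `flexalign.alignment_io_eval` — reference-alignment parsing plus the
  agreement (identically aligned pairs / reference length) and coverage
  (aligned pairs / smaller protein) metrics.
- `flexalign.synthetic_fixtures` — seeded generators for structure pairs with
  known ground truth (rigid copies, hinged conformers, circular permutations,
  drift chains) used throughout the test suite.

## Command line

Structures are given as `path:chain` (chain mandatory). Exit codes:
0 success, 1 I/O error, 2 usage error, 3 no significant similarity.

```sh
# generate a synthetic benchmark pair with known truth
flexalign synth --fixture ONE-HINGE --out-dir demo/

# flexible alignment with default parameters
flexalign align demo/A.pdb:A demo/B.pdb:B --mode flexible \
    --out demo/aln.tsv --superposed demo/superposed.pdb

# score it against the ground truth
flexalign eval --alignment demo/aln.tsv --reference demo/truth.txt \
    demo/A.pdb:A demo/B.pdb:B
```

`align` options mirror the scoring parameters: `--min-afp-len`, `--epsilon`,
`--dc`, `--alpha`, `--hinge-penalty`, `--gap-penalty`, `--max-hinges`,
`--restarts`, `--prune-factor`, plus `--mode {flexible,rigid,sequential}`
and `--region-cost-mode {whole_region,last_segment}` for sequential mode.
A flat `key=value` config file can be passed with `--config`; explicit flags
win over config values.

The alignment TSV starts with a `#JSON` header line carrying per-region
rotation/translation, region RMSDs, hinge count, total score, and the full
parameter set; the rows list equivalenced residues by internal index and
author residue number. Superposed output uses one PDB `MODEL` per rigid
region (a flexible alignment has no single global transform), with the
region id in the B-factor column.

## Scoring notes

The AFP weight is `W = l · (1 + α (ε − rmsd)/ε)`. The connection cost of a
join with joint RMSD `r` is 0 for `r ≤ ε`, ramps linearly to the full hinge
penalty `M_r` over `ε < r ≤ D_c`, and introduces a hinge at cost `M_r` above
`D_c` (at most `H` hinges). A gap penalty `M_g · |ΔA − ΔB|` applies to
sequential placements; across a non-sequential jump the diagonal offset is
meaningless and no gap is charged. These functional forms are documented
reconstructions: they satisfy the qualitative constraints of the method
(penalty proportional to RMSD excess, maximal at the hinge threshold,
α-weighted RMSD bonus) but the original coefficients are not published.
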