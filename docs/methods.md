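# Methods

## Scope and model

`mcwound` implements two deterministic rule pipelines around the type II
metacaspases of *Arabidopsis*: a geometric screen that classifies
predicted enzyme–propeptide complexes as plausible cleavage pairs, and a
set-algebra classifier that partitions differentially expressed genes
(DEGs) by metacaspase dependence. Neither involves statistical fitting:
all thresholds are fixed constants of the procedure, exposed as
configuration.

## Structure screen

**Inputs.** One PDB file per enzyme–substrate pair, two chains, no
hydrogens required. Reading and writing go through gemmi; waters are
dropped, only altloc `' '`/`'A'` atoms are kept, and elements missing
from columns 77–78 are inferred from atom names. Residue numbering is
taken from the file as-is. Linker excision (`excise_linker`) removes the
inter-domain linker from an enzyme sequence before it is submitted for
structure prediction, so the catalytic site cannot be occluded by it;
linker ranges are inputs, as they differ per enzyme and are not derivable
here.

**Clash count.** Inter-chain heavy-atom pairs with vdW overlap
`(r_i + r_j) − d ≥ 0.4 Å` (the MolProbity convention). The filter
consumes the raw count (threshold: more than 50 rejects); a normalised
per-1000-atom score is reported alongside for users who prefer the
clashscore convention. Intra-chain contacts are ignored — the question
is whether the substrate collides with the enzyme. The KD-tree-
accelerated count is exactly equal to brute-force enumeration; a 1e-9
tolerance on the overlap comparison keeps mathematically-exact boundary
contacts (two carbons at 3.0 Å) on the clash side despite float
rounding.

**SASA and buried area.** Shrake–Rupley quadrature with a golden-spiral
point set (default 960 points/atom, probe 1.4 Å), radii from a packaged
Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å;
unknown → 1.70), hydrogens excluded by default. Single-sphere accuracy
at 960 points is well within 1% of `4π(r+probe)²`; error falls roughly
4× per quadrature doubling on the two-sphere closed-form case. Points
are fixed in the model's coordinate frame, so results are bit-for-bit
deterministic; rotation invariance consequently holds only to quadrature
tolerance (~2%, tested). Buried interface area is
`(SASA(E)+SASA(S)−SASA(complex))/2`, halved to match the convention of
reporting one interface's area (a `halve_bsa` switch exposes the
unhalved value); tiny negative quadrature residue clamps to zero.

**Catalytic geometry and P1 ranking.** Minimum distance from the
designated catalytic atom (default SG of the chain's Cys, residue
number configurable per enzyme) to any substrate heavy atom, plus all
substrate Arg/Lys residues ranked by SG→main-chain-O distance (ties by
residue number). "Carbonyl oxygen" is the main-chain O: Arg/Lys side
chains have none. Ranking refines candidate ordering within a pair; it
is not an accept/reject filter because no numeric cutoff exists for it.

**Filter semantics.** Reject if clashes > 50, else if BSA < 500 Å², else
if min distance ≥ 4.5 Å; boundaries are strict exactly as stated. All
three metrics are always computed — only the verdict short-circuits — so
rejected pairs still carry full metrics for downstream inspection.

## DEG classifier

Significance is `log2FC > cutoff` (strict; `< −cutoff` for the repressed
direction) and `padj < 0.05`, with cutoff 2 by default and 3 for
high-stringency analyses. Missing `padj` (DESeq2 independent filtering)
and absence from a table both mean "not significant". Dependence on an
MC is defined set-theoretically — significant in WT, not in the mutant —
with no fold-change-ratio test. The Venn partition over
(WT, m4, m9) membership is exhaustive and mutually exclusive by
construction. Pep1+ status defaults to the WT Pep1 contrast alone;
`pep_plus_mode: pep1_or_propep1` unions in the Propep1+wound contrast,
since published analyses describe "Pep1 or Propep1 inducible" without a
fully specified algebra — both modes are provided rather than the
ambiguity resolved. Genes significant in a mutant in the opposite
direction are not treated specially beyond the one-sided thresholds.
Reported percentages use half-up integer rounding (128/377 → 34%), with
full precision retained in the JSON.

## Synthetic data

The generators define the test conditions for both pipelines.

*Complex fixtures* are geometric scaffolds, not proteins: a carbon
cluster (or slab) enzyme carrying a CYS/SG atom, and a peptide-like
substrate strand with main-chain O atoms and optional ARG/LYS residues.
The verdict suite uses two facing 9×9 carbon slabs 3 Å apart in-plane:
at a 3.5 Å gap the facing pairs touch without clashing (overlap
3.4−3.5 < 0.4 Å) and bury ≈ 950 Å²; at 1.0 Å they produce 180 clashes;
at 100 Å they bury nothing; moving SG from the interface (3.3 Å from
the central substrate atom) to 5 Å behind the slab flips the distance
filter. Slab size grows automatically (bounded attempts) if a designed
verdict fails oracle validation. Ground truth always comes from
independent oracles — O(n²) clash enumeration, an exhaustive
min-distance scan, and a separately written plain-loop Shrake–Rupley at
4× density (3840 points) — never from the production path. A 0.01 Å
coordinate jitter keeps seeds meaningful without approaching any filter
margin.

*DE tables* plant effects directly: induced genes draw
log2FC ~ N(4, 0.25²) with padj = 1e-6; nulls draw N(0, 0.2²) with
padj = 0.99. These mirror a clean DESeq2 outcome, far from the 2/0.05
calling thresholds on both sides, so planted-class recovery is exact by
construction whenever `mean − 3·sd > cutoff` (property-tested across
seeds). Defaults: 10 genes per (class × Pep1-status) combination and
1000 nulls, sized so the whole suite runs in seconds. Count-level
realism (dispersion, library size, borderline p-values, genes dropped by
independent filtering) is deliberately not simulated — the adjustment
pipeline is consumed, not modelled — so passing tests demonstrate the
correctness of the set algebra and thresholds, not robustness to noisy
calls near the significance boundary.

## Numerical and design choices

* Quadrature points fixed in the model frame → exact determinism,
  approximate rotation invariance.
* Clash/overlap and screen boundaries use strict inequalities as
  printed; the 1e-9 overlap tolerance is the only softening, and it acts
  at exact mathematical equality only.
* Candidate-site ties break by ascending residue number.
* PDB serials above 99,999 restart at 1 with a warning (never reached by
  generated fixtures).
* One named RNG per generator call, seeded from its parameters; no
  global state. Every CLI command is a pure function of (inputs,
  config) and reruns are byte-identical.
* Degenerate inputs: excising an entire sequence, empty atom sets,
  same-chain roles and ambiguous catalytic atoms raise typed errors;
  an empty gene partition reports null percentages rather than NaN.

## Limitations

* Fixtures exercise geometry, not chemistry: no secondary structure,
  rotamers, hydrogens or physically realistic packing.
* The screen evaluates exactly one model per pair; reconciling multiple
  predicted models, prediction confidence (pLDDT/PAE) and docking are
  out of scope.
* Interface energetics (ΔG-style measures) are not computed; BSA is the
  only interface-extent proxy.
* The classifier consumes adjusted p-values; it cannot detect problems
  upstream in the count model that produced them.
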