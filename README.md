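# mcwound

Tools for studying how the *Arabidopsis thaliana* type II metacaspases
AtMC4–AtMC9 shape the wound response, at two levels:

1. **Structure-based substrate screening.** Given a predicted
   enzyme–propeptide complex (one metacaspase chain, one candidate Propep
   chain, PDB format), decide whether it is a plausible cleavage pair and
   rank its candidate cleavage sites. Metacaspases cleave after Arg/Lys
   (the P1 residue), so a well-poised complex places the catalytic
   cysteine's thiol sulfur (SG; Cys139 in AtMC4) next to an Arg/Lys
   main-chain carbonyl.
2. **Transcriptome dependence classification.** Given per-contrast
   differential-expression tables (gene, log2FC, adjusted *p*) for WT,
   *atmc4-1* and *atmc9-1* plants under wounding and elicitor treatments,
   partition the induced genes by which metacaspase they require and by
   Pep1 responsiveness.

## The screen

A complex passes three filters, applied in order with strict boundaries:

1. **Clash filter** — at most 50 inter-chain van der Waals clashes
   (heavy-atom pairs with overlap `(r_i + r_j) − d_ij ≥ 0.4 Å`); a model
   whose chains interpenetrate is a prediction artefact, not a complex.
2. **Interface filter** — buried interface area
   `BSA = [SASA(E) + SASA(S) − SASA(E·S)] / 2 ≥ 500 Å²`; smaller
   interfaces are loosely bound. SASA is a Shrake–Rupley estimate
   (probe 1.4 Å, 960 quadrature points per atom).
3. **Distance filter** — the catalytic SG must lie `< 4.5 Å` from the
   nearest substrate heavy atom.

Surviving pairs are annotated with all substrate Arg/Lys residues ranked
by SG→carbonyl-oxygen distance, the shortest being the best candidate
P1 site. A batch of complexes named `ENZYME__SUBSTRATE.pdb` becomes an
enzymes × substrates prediction matrix.

## The classifier

For each gene, significance in a contrast means `log2FC > c` (or
`< −c` for repressed genes) **and** `padj < 0.05`, with `c = 2` by
default (3 for high-stringency runs). Comparing the WT, *atmc4-1* (m4)
and *atmc9-1* (m9) significant sets of the same treatment assigns each
gene to one of the 2³ Venn cells: MC4-specific (WT ∧ m9 ∧ ¬m4),
MC9-specific, co-dependent (WT only), MC-independent (all three),
MC9-repressed (m9 only), and so on. WT-induced genes are Pep1+ if also
significant in the WT Pep1-infiltration contrast, and AtMC4-dependent
genes map onto marker groups: Group 1 (MC4-specific ∧ Pep1+),
Group 2 (co-dependent ∧ Pep1+), Groups 3/4 (their Pep1− counterparts).

## Worked example

Real inputs (AlphaFold complexes, DESeq2 tables) are large; the package
generates oracle-validated synthetic stand-ins:

```sh
mcwound simulate structures --seed 1 --out demo/fixtures
mcwound screen demo/fixtures --out demo/screen
cat demo/screen/matrix.tsv
```

```
INFO mcwound: pair ENZ__fail-clash: clashes=180 bsa=1102.6 min_dist=3.31 verdict=rejected
INFO mcwound: pair ENZ__fail-distance: clashes=0 bsa=945.3 min_dist=8.51 verdict=rejected
INFO mcwound: pair ENZ__fail-interface: clashes=0 bsa=0.0 min_dist=105.01 verdict=rejected
INFO mcwound: pair ENZ__pass: clashes=0 bsa=945.7 min_dist=3.31 verdict=predicted-substrate
enzyme  fail-clash      fail-distance   fail-interface  pass
ENZ     rejected        rejected        rejected        predicted-substrate
```

Each fixture was designed to fail exactly one filter (or none): the
`fail-clash` model interpenetrates (180 clashes > 50), `fail-interface`
is 100 Å away (BSA 0 < 500 Å²), `fail-distance` buries a large interface
(945 Å² ≥ 500) but hides its SG 8.5 Å away (≥ 4.5), and `pass` clears all
three with a LYS carbonyl 3.76 Å from SG as the best P1 candidate
(`metrics.json` carries the full per-pair metrics and ranked sites).

The classifier runs the same way from a manifest of contrast TSVs:

```sh
mcwound simulate degs --seed 1 --out demo/degs
mcwound classify demo/degs/manifest.yaml --out demo/partition
```

`summary.json` then reports per-class counts (10 genes were planted per
class × Pep1-status combination, all recovered) and the Pep1+ share of
AtMC4-dependent genes.

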