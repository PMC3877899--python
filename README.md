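# pufamap

Rule-based mapping of polyunsaturated fatty acid (PUFA) biosynthesis in
diatoms: which desaturase/elongase genes a genome carries, where their
products act, and which route the cell can use to make eicosapentaenoic
acid (EPA, C20:5n3).

The package is aimed at algal lipid and metabolic-engineering groups working
with secondary-plastid microalgae such as the oleaginous diatom
*Fistulifera* sp. JPCC DA0580, where EPA content matters both as an ω3
product and as a biodiesel quality constraint.

## What it computes

**Enzyme annotation.** Membrane desaturases carry three conserved
histidine boxes coordinating the catalytic di-iron centre; the box
sequences are family-diagnostic (Δ12, ω3, Δ6, Δ5; the Δ6-elongase carries a
single motif, e.g. `QLSFLHVYHH`). Scanning matches literal box templates
with exact anchor residues (every H, plus a leading Q/W) and a small
mismatch budget elsewhere; boxes must occur in order. Front-end desaturases
(Δ6, Δ5) are flagged by a glutamine-initiated third box and an N-terminal
cytochrome-b5 `HPGG` core.

**Localization.** A deterministic decision tree over external-predictor
conclusions (TargetP, HECTAR, SignalP, Mitoprot, TMHMM), consumed as a
normalized table:

1. signal peptide present → ER if the C-terminus is `(K/D)(D/E)EL`,
   chloroplast if the +1 residue after the cleavage site is F/W/Y/L
   (bipartite plastid signal), otherwise ER;
2. else mitochondrion if both general predictors agree, or Mitoprot > 0.9,
   or Mitoprot > 0.8 with one supporting call;
3. else peroxisome if the C-terminal tripeptide is a PTS1
   (`[S/A/C][K/R/H][L/M]` or `SSL`);
4. else ER for transmembrane proteins; 5. else cytoplasm.

**Pathway inference.** A compartment-labelled desaturation/elongation graph
(plastid C16 track; ER C18/C20 ω6 track; ER ω3 branch; terminal plastid
ω3-desaturation of C20:4n6 fed from the ER). Edges activate only where an
enzyme of the required family is localized; reachability and simple-path
enumeration then classify every stearate→EPA route as ω6, ω3 or mixed.

**Expression screen.** RPKM = 10⁹·count/(exon length · mapped reads), log2
fold changes vs. the 48 h reference, differential-expression flags at
|log2 FC| ≥ 1, and log2 display bins (3: 8–16 … 10: ≥1024).

**FAME profiles.** Peak-area → percent-of-total normalization, PUFA
fraction (≥2 double bonds), and strict trend classification over a culture
time course, with the strain's measured 48/96/144 h composition built in.

A synthetic-data module generates proteins with planted targeting signals
and box complements, matching predictor bundles with a controllable noise
rate, count tables with planted fold changes, and peak tables realizing a
target composition — so the whole chain is testable without downloads.

## Worked example

```sh
$ pufamap pathway
EPA routes: 1 (ω6)
  C18:0 -> C18:1n9 -> C18:2n6 -> C18:3n6 -> C20:3n6 -> C20:4n6 -> C20:5n3
reachable species: C16:0, C16:1, C16:2, C18:0, C18:1n9, C18:2n6, C18:3n6, C20:3n6, C20:4n6, C20:5n3
```

With the strain's enzyme placements (ω3-desaturases chloroplast-only, the
other C18/C20 enzymes in the ER) there is exactly one way to reach EPA: the
ω6 route, finished by the plastid ω3-desaturase acting on imported
C20:4n6. None of the ω3-branch intermediates (C18:3n3, C18:4n3, C20:4n3)
is reachable — the graph-level counterpart of their absence from the
measured fatty-acid profile. C16:3 is likewise unreachable because the
plastid C16:2→C16:3 step has no placed enzyme and stays inactive.

```sh
$ pufamap fame --fixture
C20:5n3: 17.0 -> 8.3 -> 6.6 (DECREASING)
C16:1: 36.3 -> 42.4 -> 45.9 (INCREASING)
C16:0: 29.8 -> 37.3 -> 36.5 (NON_MONOTONE)
PUFA% at 48h: 17.0
...
```

EPA falls from 17.0% to 6.6% of total FAMEs over the culture while the
dominant C16 species rise — the compositional trend the expression screen's
overall down-regulation of ER desaturases/elongases accounts for.

Other stages: `pufamap annotate` (family calls from FASTA), `pufamap
localize` (compartments from FASTA + predictor TSV), `pufamap expression`
(RPKM/fold-change table from counts), `pufamap synth ...` (synthetic
inputs with ground truth), and `pufamap run` for the full chain.

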