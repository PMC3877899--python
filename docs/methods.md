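# Methods

## Motif grammar and matching

Family assignment rests on literal box templates rather than position-weight
matrices or profile HMMs: the diagnostic histidine boxes of the Δ12, ω3, Δ6
and Δ5 desaturases and the single Δ6-elongase motif are short, highly
conserved strings, and the per-slot alternatives bundled here cover the
variants seen across diatom orthologs. A window matches a template iff its
anchor residues — every histidine, plus a leading glutamine or tryptophan
when the template starts with one — are identical and at most
`motif_mismatch_budget` (default 1) of the remaining positions differ.
Anchors are held exact because they coordinate the di-iron centre (or, for
the glutamine of front-end third boxes, define the family signature);
the one-mismatch budget admits close homologs without letting families
bleed into one another (the closest cross-family pair of box strings
differs at two non-anchor positions).

Box order is enforced (box1 < box2 < box3 along the sequence, non-
overlapping); classification picks the family with a complete in-order
complement, breaking ties by fewest total mismatches and then by a fixed
family order. Overlapping candidate hits for one slot are resolved
leftmost-first. The scanner is property-tested against an independent
brute-force oracle on random sequences up to 300 residues.

Two auxiliary flags have no quantitative definition in the source
literature and are therefore configurable conventions:

* cytochrome-b5 fusion — presence of the heme-binding core `HPGG` within
  the first 120 residues (the fused b5 domain of front-end desaturases is
  N-terminal; 120 residues comfortably covers it while excluding chance
  hits elsewhere);
* serine/threonine richness after a signal peptide — S+T fraction ≥ 0.30
  (inclusive) over the 20 residues following the cleavage site; windows
  shorter than 5 residues are treated as undefined rather than guessed.

Δ9-desaturase box strings are strain-specific and none are bundled; Δ9
classification requires a user-supplied template file (`--templates`), and
the synthetic module ships a clearly-labelled synthetic Δ9 triple purely so
the closed-loop tests can exercise that path.

## Localization cascade

The decision tree follows the order signal peptide → mitochondrion →
peroxisome → transmembrane fallback → cytoplasm, and is total and
deterministic. Design points that were genuinely open:

* Precedence when a protein has both a predicted cleavage site and strong
  mitochondrial evidence is unstated in the underlying protocol; the signal
  branch wins here, and the conflict is recorded in the evidence trail
  (`MITO_CONFLICT_WITH_SIGNAL`).
* A cleavage site with neither an ER-retention tetrapeptide nor an
  aromatic/leucine +1 residue is assigned ER via the secretory pathway,
  with a distinct evidence token (`SIGNAL_NO_MOTIF`).
* Mitoprot thresholds are strict inequalities (>0.9, >0.8) exactly as the
  rule is written, and agreement of TargetP and HECTAR alone suffices
  regardless of the Mitoprot score, because the two criteria are stated
  independently. Boundary sweeps in the tests pin both thresholds.
* HMMTOP helix counts are carried through I/O but do not enter the cascade;
  only the TMHMM count drives the transmembrane fallback.

Every call carries the ordered list of fired rules, with the final token
being the rule that fixed the compartment, so assignments are auditable
row by row.

## Pathway model

The network has 14 species and 13 reaction edges; stoichiometry (elongase:
+2 carbons, desaturase: +1 double bond) is asserted at edge construction.
Decisions:

* The terminal plastid ω3-desaturation of C20:4n6 carries
  `requires_transport`, operationalizing the hypothesis that the ER-made
  precursor is finished in the chloroplast; transport is allowed by
  default and can be gated off for what-if analyses.
* The plastid C16:2 → C16:3 step is marked `uncertain` (no diatom has a
  predicted chloroplast Δ6-desaturase) and stays inactive unless
  `activate_uncertain_edges` is set.
* The Δ9-elongation/Δ8-desaturation bypass reported in other diatoms is
  available behind `include_alternative_route` and off by default, since no
  Δ9-elongase/Δ8-desaturase genes are reported for this strain.
* C16 species are kept plastid-confined; no exchange edges are modeled
  beyond the transport flag (no kinetic or flux information is available,
  so none is attempted).

Route classification: a stearate→EPA path is ω3 if it passes through
C18:3n3, ω6 if it carries no n3 intermediate before the terminal
desaturation, and mixed otherwise. C18:1n9 (an n9 species) lies on the ω6
route and deliberately does not affect the classification.

## Expression screen

RPKM is computed from supplied counts, exon lengths and library sizes; read
alignment and exon-model assembly are upstream of this package. Zero RPKM
on either side of a ratio yields UNDEFINED rather than a regularized value
— no pseudocount is applied by default (one can be configured) so that
zero-expression genes are visibly excluded from the DE screen instead of
silently imputed. The DE cutoff |log2 FC| ≥ 1 is inclusive. Display bins
use half-open intervals [2^k, 2^(k+1)) with floor(log2) clamped to [3, 10];
this is the simplest reading consistent with the published bin legend,
whose boundary convention is ambiguous.

## Synthetic data: what it emulates, and what it does not

Proteins are drawn over a background alphabet that excludes H/Q/W (box and
b5 anchors), S/T (the richness test) and L/M (the final residue of every
admissible retention signal and PTS1), so no rule motif can arise by
chance; this is checked over 10⁴ background draws plus full scans of a
subsample. Targeting features are planted explicitly: an 18-residue signal
peptide, a +1 aromatic/leucine and a 50% S/T 20-mer for plastid proteins;
a retention tetrapeptide or a transmembrane-only bundle for ER proteins;
a PTS1 for peroxisomal proteins. Predictor bundles are emulated at the
interface level — categorical conclusions, not the predictors' internals —
and noise corrupts fields independently at a configurable rate
(correlated predictor failure is not modeled; nothing is available to
calibrate it). Consequently, passing the closed-loop tests shows the rules
and generators are mutually consistent and the decision boundaries are
where they should be; it does not certify accuracy on real predictor
output, whose errors are correlated and version-dependent.

Count tables: reference expected RPKM is log-uniform over [10, 1000] by
default, exon lengths uniform over 1000–2000 bp, libraries 10⁶ mapped reads
per time point. Counts are Gamma-Poisson with variance μ + φμ²; the default
dispersion φ = 5·10⁻⁴ is at the technical-replicate scale (~2% extra CV),
appropriate because the emulated experiment sequenced one library per time
point. At φ = 0 the generator emits the exact real-valued expected counts,
so planted fold changes are recovered exactly; integer counts are drawn
only when φ > 0. Fold-change recovery claims are evaluated with reference
RPKM ≥ 50 — below that, Poisson counting noise alone exceeds the quoted
recovery bands regardless of implementation. Peak tables multiply target-
proportional areas by lognormal noise with a given CV (mean-one
parameterization), so CV = 0 inverts normalization exactly for complete
compositions; partial compositions renormalize to 100.

## Problem sizes and numerical conventions

The test suite uses 50 seeds per compartment and 10–25 per family for
closed-loop recovery, 200–300 genes for fold-change recovery, 100
replicates for peak-noise calibration, and randomized scanner-vs-oracle
comparisons capped at 300-residue sequences; the whole suite runs in
seconds. Trend classification treats steps within 0.05 percentage points
as flat, matching the precision of the bundled composition values.
Coordinates are 1-based and inclusive throughout; a cleavage position is
the last residue of the signal peptide.

## Known limitations

* Exact reproduction of per-gene localization calls from the original
  study requires the original predictor runs (tool versions and organism
  modes are unrecorded); the normalized predictor table sidesteps the
  tools but cannot reconstruct their outputs.
* Minor ω6 species percentages are carried as presence-only entries; their
  published quantification is not included, so their trends are not
  classified numerically.
* The pathway stage is purely topological — activation and reachability —
  with no flux or kinetic content.
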