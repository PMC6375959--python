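# Methods

`algscreen` re-implements, as a tested library, the analysis chain of an
"in-vivo enrichment" screen: gastropods (sea hare SH, sea snail SS) are fed a
single brown alga, and their gut microbiota are compared between wild (W) and
reared (R) individuals through 16S rRNA amplicon profiles and a
degenerate-primer clone-library survey of PL7-family alginate lyase (ALG)
genes. Real sequencing data are replaced by a synthetic-data generator with
the statistical structure the analysis assumes, so every stage is testable
offline; the published 50-phylotype occurrence table ships as a fixture and
its set algebra is reproduced exactly.

## Synthetic communities and reads

A community is a log-normal relative-abundance vector over `n_taxa` taxa
(default 50), normalized to 1 within 1e-12. Defaults `mu=0, sigma=1.5`
produce realistic steep rank-abundance curves. Rearing is modeled as a
multiplicative shift: a planted set of "degrader" taxa (default 5) is
multiplied by `enrichment_factor` (default 5) and all others by
`depletion_factor` (default 0.3); after renormalization, taxa below an
**extinction floor** of 1e-3 are removed and the vector is renormalized
again. The floor is what produces the reared richness decrease: at the
stated depletion, taxa whose shifted relative abundance falls below roughly
one organism per thousand are treated as unable to sustain a population on
the new diet, which removes about 5–15 of 50 taxa per shift. A much smaller
floor (e.g. 1e-4) removes essentially nothing under these abundances and
the richness signal disappears.

Individuals are log-normal jitters of a per-host template: wild individuals
with `wild_sigma=0.5`, reared with `reared_sigma=0.15`. The asymmetry encodes
the biology being emulated — wild animals forage on mixed algae and vary
more from one another, while a single controlled diet converges the
microbiota — and it is what makes reared-vs-wild dispersion comparisons
meaningful. Both sigmas are ordinary parameters of `simulate_study`.

Marker genes: every taxon carries a 16S-like marker (~310 nt; universal
primer cores at both ends, a variable body mutated from a common ancestor at
`marker_rate=0.05` per site) and, for degrader taxa always and others with
probability 0.3, an ALG-like gene. ALG genes embed an amplifiable region
framed by concrete codings of the two conserved strand motifs the degenerate
primers target (A3: `YARSELRE`; A4: `YFKAGSY`), around a synonymously
re-coded core from a packaged synthetic PL7-like protein family
(`data/pl7_reference_synthetic.faa`: 16 constructed proteins, one root core
with 30% substitution divergence, fixed seed — labelled synthetic, not
database entries). Point mutations that would create a stop codon in the
amplicon frame are re-drawn to a non-stop codon, as real purifying selection
would, so planted genes survive the stop-codon filter. The family is
colinear (substitution-only evolution, no indel model), matching the
generator's point-mutation contract; consequences for trimming are noted
below. Reads are whole markers drawn multinomially at a fixed depth with
substitution-only sequencing error (default 0.2%/base); no fragmentation,
quality scores, paired ends, chimeras, or homopolymer errors are modeled.

What passing tests therefore do and do not show: they demonstrate that the
pipeline recovers planted enrichment, richness loss and convergence under
log-normal communities with substitution-only, colinear marker evolution.
They do not exercise chimeras, indels, length heterogeneity, amplification
bias, or taxa whose markers are not separable at the clustering thresholds.

## In-silico PCR

Primers are IUPAC strings plus inosine (`I`). Inosine is treated as a
universal-pairing residue: it matches any template base and contributes a
factor of 1 to pool degeneracy (an `N` contributes 4). Matching is ungapped
with a configurable mismatch budget (default 0); a forward primer's site is
its literal sequence on the plus strand, a reverse primer's its reverse
complement. Amplification pairs every forward site with every downstream
reverse site and keeps primer-inclusive spans inside the size window
(default 300–650 bp, the gel-purification window); all products are
reported (no PCR-kinetics preference for short products). Primer design
back-translates a gap-free aligned protein window, emitting the minimal
IUPAC cover per codon position with `I` substituted where the cover would be
`N` at a codon third position (configurable — the printed primers carry `I`
at some non-third positions, and the original placement rule is not
recoverable); pools exceeding a degeneracy cap are split by codon family,
emulating the two-forward-primer mixture.

## Filtering

Cloned amplicons are translated in all six frames (standard code, partial
codons dropped); frames containing a stop codon are excluded; surviving
frames are screened by best local alignment (BLOSUM62, gap open 10 /
extend 1) against the packaged reference protein family, kept when identity
≥ 0.35 over ≥ 50% of the query. These thresholds play the role of a
hit-existence criterion against a comprehensive database and are
deliberately permissive; both are configurable. Survivors are trimmed to a
common length (95 aa for ALG, 280 nt for 16S) through a multiple alignment
(mafft when lengths differ; the identity alignment otherwise): the window of
exactly `target_len` alignment columns maximizing the number of sequences
with no gap inside it is chosen, ties leftmost, and shorter sequences are
excluded. An explicit objective replaces the original manual trimming, which
is not reproducible. Note that this window rule requires a largely colinear
alignment; data with pervasive scattered indels can leave no gap-free window.

## Phylotypes

Reads are dereplicated (multiplicity descending, ties lexicographic — the
clustering result is therefore invariant to input read order) and clustered
greedily: each unique sequence joins the first centroid with identity at or
above the threshold (0.97 nt for 16S, 0.90 aa for ALG), else founds a new
centroid. Identity is matching columns over alignment columns excluding
terminal gaps; for equal-length inputs this is one minus the Hamming
fraction, computed vectorized. Representatives come from reads observed at
least twice; phylotypes containing only singletons are retained but flagged,
with a switch to drop them (the stricter reading of the representative
rule). Occurrence sets (which sample types a phylotype appears in) are
summarized by set algebra: per-type counts, pairwise intersections,
type-specific counts, and the reared-only tally.

## Diversity and tests

Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, which is
defined when doubletons are absent. Shannon entropy is reported in nats
(configurable base); the published index ranges are consistent with nats.
Rarefaction is multivariate-hypergeometric subsampling (without
replacement) to a common depth, default 4,000 reads, with per-sample
substreams keyed to the sample name so row order is irrelevant. The
Mann-Whitney U test uses midranks; p-values are exact by enumeration of all
C(n1+n2, n1) labelings when the larger group has ≤ 8 observations and the
pooled data are tie-free (two-sided p counts labelings at least as far from
n1·n2/2 as observed), otherwise a tie- and continuity-corrected normal
approximation. Per-phylotype differential tests run on relative abundances
with no multiple-testing correction by default (matching the original
analysis); Benjamini–Hochberg is available behind a flag.

## Trees, UniFrac, ordination

Pairwise distances between aligned representatives are p-distances with
pairwise gap exclusion. Neighbor joining follows Saitou–Nei with
deterministic tie-breaking by label order; negative branch estimates are
clamped to zero with the deficit moved to the sibling so the joined pair's
path length is preserved. On additive matrices the generating tree's path
lengths are recovered exactly.

UniFrac is computed by postorder accumulation of per-branch leaf masses,
with correctness defined (and tested exhaustively on small trees) by the
naive branch-partition formula. Unweighted UniFrac is unique branch length
over observed branch length; weighted UniFrac is the branch-wise L1
difference of relative abundances, by default normalized by the
abundance-weighted tree width so values lie in [0, 1] (a `normalized=False`
raw variant exists). Root placement matters for unweighted and normalized
weighted UniFrac — this is why UniFrac is defined on rooted trees — so the
pipeline fixes a midpoint-rooting convention; only the raw weighted form is
rooting-invariant (complementary branch masses contribute equal L1 terms),
and the tests verify exactly that plus the stability of the midpoint
convention. PCoA is classical metric scaling (double-center −D²/2,
eigendecomposition, coordinates scaled by the square roots of positive
eigenvalues, explained variance over positive eigenvalues, axis signs fixed
by the first non-zero loading).

16S diversity and UniFrac consume rarefied tables; the ALG clone-library
branch uses full clone counts — clone libraries are small and equal-effort
by design.

## Problem sizes

The replicate-level recovery study runs 50 taxa, 5 planted degraders
(enrichment ×5, depletion ×0.3), 5 wild + 5 reared samples at 2,000 reads
each, over 20 replicate seeds — about 20,000 reads clustered per replicate.
These sizes exercise every stage at the scale of the original study's
per-sample data while keeping a full 20-replicate run in the low minutes on
one CPU.

## Known limitations

- The reference screen stands in for a live protein-database homology
  search; its thresholds are declared, not inferred from the original
  analysis, which names no cutoff.
- Substitution-only evolution and error; no indel, chimera or
  amplification-bias models. The trimming window rule assumes colinear
  alignments.
- The exact-test cutoff (larger group ≤ 8) covers the study's group sizes;
  larger groups fall back to the normal approximation.
- Synthetic effect sizes are free parameters of the generator, not
  calibrated to the original study, which reports no per-taxon truth.
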