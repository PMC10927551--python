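# Methods

## Scope and design

`paleokaryo` is organised as an analysis project: the library under
`src/paleokaryo/` holds every computation; the numbered drivers under
`analysis/` are thin narratives over it; `paleokaryo.studies` fixes the
study conditions so that tests, drivers and the acceptance script measure
the same quantities the same way.

Module map: `simulate` (karyotype-evolution generator and all synthetic
inputs), `homology` (reciprocal best hits, enrichment, AC grouping,
anchoring), `retention` (profiles, OR, ohnolog calling, Ward clustering,
orthology, asymmetry, fusion detection), `treecompat` (1R/2R gene-tree
classification), `fates` (expression fates, ACR context), `io` +
`pipeline` + `cli` (formats, orchestration, command line).

## The generator

A genome is an ordered map chromosome → gene list; genes carry a
`family_id` naming their ancestral gene.  No sequence is simulated —
homology is identity of family, and similarity scores are drawn, not
aligned.  Operators:

- **WGD** (×2 or ×3): every chromosome and gene copy replicated, tagged
  with a subgenome letter.  *Allopolyploid* mode adds an immediate extra
  loss round (default 15%) on the non-reference subgenome: the mechanism of
  biased fractionation is not modelled, only its observable retention
  asymmetry.
- **Fusion / fission**: end-to-end concatenation and order-preserving
  splits.  Random scenario fusions are constrained to chromosomes of
  disjoint AC origin; fusing the two copies of one AC would amount to
  rediploidization and would contaminate the fission control with genuine
  ohnolog pairs.
- **Attrition**: per gene, independent loss, translocation (uniform over
  other chromosomes) and small-scale duplication (50% same chromosome, 50%
  uniform elsewhere — needed so fission controls can exceed OR 0).
  Arriving genes append to the end of the target; every downstream
  statistic is order-free, so insertion position is immaterial.  Emptied
  chromosomes are kept and flagged so truth records stay valid.
- **Speciation**: independent copies under independent attrition;
  chromosome names persist, so cross-species orthology is name identity.

Truth is carried two ways.  Chromosome descent is tracked as ordered
*zones* — contiguous blocks of genes tagged (AC, WGD-copy chain) — which
survive fusion (concatenation), fission (split by cumulative count) and
attrition (in-place decrements) exactly; translocated/duplicated arrivals
fall outside the zones and are deliberately not counted as descent.  Gene
ancestry is encoded in identifiers (one suffix token per WGD copy or
small-scale duplicate, era-stamped), so the true topology of any gene
family is transcribed by merging each leaf's token stream with its
lineage's chronological event list into a trie; unary nodes collapse, a ×3
WGD yields a true trifurcation.  Optional estimation error applies one
random NNI per tree with probability *e*.

Hit tables emulate all-vs-all protein search output (12-column tabular):
one symmetric bit-score ~ Normal(μ=200, σ=10) per true cross-genome
same-family pair, e-value = min(1, exp(−score/2)) — a deterministic
monotone map; only the ordering matters for best-hit logic — plus
unidirectional spurious rows between random non-family pairs
(count ~ Binomial(n_true, offtarget_rate), scores centred at μ/3).

The expression generator constructs tissue domain sets that realise each
planted fate exactly, then emits TPM = 50 in-domain and 0.5 outside with a
multiplicative noise factor clipped to [0.5, 2], so noise can never cross
the TPM > 5 threshold; arguments violating that separation are rejected.
The regulatory-landscape generator lays genes every 50 kb (10-kb bodies,
three exons, random strand) and plants each ACR wholly inside one category
window, so truth labels are unambiguous by construction.

## Inference choices

- **Enrichment test**: for homologue pairs counted per chromosome pair,
  the 2×2 table [[n_ab, n_a−n_ab], [n_b−n_ab, N−n_a−n_b+n_ab]] is tested
  by Pearson chi-squared without continuity correction; any expected cell
  < 5 falls back to Fisher's exact test.  All pairs tested in one call
  form a single Benjamini–Hochberg family; enriched = observed > expected
  and q < 0.05.
- **AC grouping**: connected components of the ingroup homology graph,
  split along outgroup linkage groups — each linkage group with homologous
  ingroup chromosomes seeds one AC group.  A chromosome linked to several
  linkage groups (a fusion product) is listed in each group and flagged;
  collapsing it into one group would silently merge distinct ACs, and
  assigning it to a single "majority" AC fails when the two segments are
  of equal size.  This treats the outgroup karyotype as the proxy for
  ancestral linkage; where one true AC corresponds to several outgroup
  chromosomes (pre-WGD fusions in the outgroup's own lineage), the method
  reports per-linkage-group units — a documented limitation.
- **Anchoring**: rule 1 (own linkage group names the AC, confirmed by ≥1
  ingroup homologue) or rule 2 (≥5 distinct ingroup homologues, all on one
  AC's chromosomes); a conflict between the rules leaves the gene
  unanchored with the reason logged.
- **RBH tie-breaks**: equal bit-scores resolved by lower e-value, then
  lexicographic subject id, making results independent of row order.
- **Ohnolog calling**: strict OR > 0.15; chromosomes retaining < 20
  anchored genes are excluded before pairing.  "Mutually ohnologous" sets
  are reported both as connected components (the headline — robust to one
  stochastically missing edge) and as maximal cliques; disagreements are
  logged.  Profiles of fusion products are computed from the whole
  chromosome (content-based), not per segment.
- **Ward clustering**: own implementation of the Lance–Williams Ward
  update on the raw 1−OR dissimilarities (the 'Ward.D' flavour; no
  squaring), deterministic label-order tie-breaks, inversions reported and
  never repaired.  Verified against an independent full-recompute oracle.
- **Orthology**: mutual best cross-species OR above threshold → 1:1; a
  chromosome whose top two partners lie within 10% relative of each other
  (both above threshold) → ambiguous 1:2/2:1; else unassigned.
- **Tree classification**: trees are rooted on the outgroup; reference
  leaves map to groups A–D by chromosome; a tree whose backbone is not
  ((A,B),(C,D))-compatible after removing test leaves is unusable rather
  than partially scored.  For each maximal test clade the smallest
  ancestor with backbone context decides: context within one group → 2R
  (hence 1R); within one pair → 1R only; context spanning the whole
  backbone, or outgroup leaves on the climb → neither.  In a polytomy, a
  clean group clade beside the test clade counts as its sister (the
  permissive reading), flagged.  Branch lengths and support values are
  ignored.  A tree's per-tree call is the conjunction over its test
  clades (conservative).
- **Fates**: strict TPM > 5 after quantile normalization (mean-of-sorted
  reference, ties averaged over their span); pairs with a silent copy are
  excluded with a reason.  The three fates partition all non-empty domain
  pairs (proved by enumeration in the tests); specialization is strong
  when narrow/broad < 0.40.
- **ACR context**: precedence promoter > proximal > exonic > distal;
  promoter [TSS−1000, TSS+500], proximal [TSS−5000, TSS+1000] minus
  promoters, strand-aware, ≥1 bp overlap; exonic uses exon records of
  protein-coding genes only.  Each ACR is assigned the gene with the
  nearest TSS, without a distance cap (signed distance from the ACR
  midpoint, positive downstream); per-gene class comparisons use
  Bonferroni-adjusted two-sided Wilcoxon rank-sum tests.

## Study conditions

The canned studies (in `paleokaryo.studies`) fix the simulated conditions:
fission control on 300-gene ACs with ssd 0.05 and translocation 0.02
(1,000 split pairs); ohnolog floor from 500 single-WGD pairs at per-copy
retention 0.4 with the 20-gene floor; gnathostome recovery from 17 pre-WGD
chromosomes × 300 genes through 1R, 8 random post-1R fusions, 2R and 30%
per-copy loss in two descendants (outgroup loss 5%); triplication
multiplicity from 16 ACs × 300 genes through ×2 then ×3 WGDs with 20%
loss; ortholog-vs-ohnolog ordering from five replicates of
WGD → 25% shared (rediploidization) loss → speciation with 15% independent
loss.  Problem sizes were chosen to match the scale of the anchored AC
gene sets (hundreds of genes per AC) while keeping every study inside a
few seconds.

The demo pipeline history includes an attrition round between the WGDs and
before speciation.  This is not incidental: with no rediploidization-era
divergence, ohnologous and orthologous chromosomes have identically
distributed retention profiles and orthology assignment is legitimately
ambiguous.

The post-WGD mirror-fusion null draws random disjoint fusion matchings
(products do not re-fuse) and measures how often two fusions join the two
WGD copies of the same two pre-WGD chromosomes.  The construction of the
published karyotype-scale null is not fully specified; the implemented
default is validated exhaustively on the 2-AC case (2/3) and reported as
such.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the inference relies on
— shared ancestral gene content degraded by independent loss,
translocation and duplication noise, fusion/fission rearrangement, noisy
reciprocal similarity, planted fates and regulatory contexts — but not:
sequence-level evolution (alignment error, rate variation, saturation),
selection on retained duplicates, missing or mis-assembled real
annotations, expression measurement noise beyond a bounded multiplicative
factor, or genome-size and gene-density heterogeneity.  Passing recovery
tests therefore demonstrates the correctness and internal consistency of
the statistics, not their field performance on real assemblies.  Gene-tree
estimation is deliberately out of scope: trees are transcribed from truth
(optionally perturbed by NNI), never inferred.

## Numerical notes

Seeds control every random draw; child seeds are spawned from a master
generator, and identical configuration + seed reproduces outputs
byte-for-byte (asserted for the pipeline's JSON summary).  OR is exact
rational arithmetic over integer counts; undefined OR (a profile retaining
zero genes) raises rather than returning 0.  Ward merge heights follow the
recurrence exactly; degenerate zero-distance pairs merge first under the
label-order tie-break.  Empty OR matrices (< 2 qualifying chromosomes) are
flagged results, not errors.
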