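# Methods

## Problem and scope

Small RNA-seq of human airway epithelial cultures shows that, for some
miRNA loci, the most abundant mature sequence does not start at the
database-annotated 5' position. For miR-34b and miR-449c the database entry
carries one supplemental 5' uridine relative to the dominant form, which
shifts the seed register (positions 2–7/2–8) by one base and therefore the
target repertoire. `isoforge` implements the computational side of
characterizing such 5'-isomiRs end to end:

1. anchor mature sequences on their hairpins (`annotation_io`);
2. quantify reads by 5'-start offset and call canonical reassignments
   (`isomir_quant`);
3. scan transcripts for seed-complementary sites in either register with a
   free-energy filter and classify canonical/isomiR site sharing
   (`target_scan`);
4. compute signed hypergeometric word-enrichment landscapes over ranked
   gene lists (`word_enrichment`);
5. apply down-regulation filters and Venn-style overlap counts to
   per-condition expression tables (`expression_filter`);
6. generate every input with a ground-truth ledger (`synthetic_data`).

Wet-lab procedures, colorspace read mapping, and negative-binomial
differential-expression modelling are out of scope; edgeR-style outputs are
consumed, not re-derived.

## Offset quantification and reassignment

Reads are adapter-trimmed, collapsed mature fragments, so mapping is exact
full-length substring matching against hairpins — no mismatches or clipping.
A read matching several hairpins contributes its full count to each; per-
locus percentages are ratios and are unaffected by the shared constant. The
5' offset of a hit is its start minus the annotated mature start; only the
five classes {−2, −1, 0, +1, +2} are tabulated, and reads outside the window
are excluded from both the numerator and the denominator of the
percentages. Negative offsets are 5'-extended variants. CPM uses the total
mapped read count of the library as denominator.

A locus is flagged for reannotation when (i) its windowed abundance is at
least 20 CPM (detection threshold), (ii) the dominant offset is non-zero,
and (iii) the dominant form carries at least 50% of the windowed reads. At
an exact 50/50 tie between the annotated start and an alternative, the
alternative is flagged ("at least half the reads" reads inclusively);
remaining ties prefer the smaller |offset|, then the 5'-extended form. The
proposed canonical sequence shifts the 5' end by the dominant offset and
keeps the annotated 3' end, so for a U-prefixed reference with dominant +1
the proposal is exactly the reference minus its 5' uridine.

3'-end heterogeneity is ignored for offset classification (any 3' end is
accepted) but the per-miRNA *canonical fraction* — used for cross-library
concordance (R²) — requires full-sequence equality with the reference, and
is reported only for loci with ≥ 30 assigned reads.

## Site scanning and the energy model

A 6mer site is an exact occurrence of the reverse complement of seed
positions 2–7; 7mer-m8 adds Watson–Crick pairing to position 8, 7mer-A1 an
adenine opposite position 1, and 8mer both. Every requested type a position
satisfies is reported (8mer ⊂ 7mer-m8 ∩ 7mer-A1); deduplication happens at
the gene level in `predict_targets` only. Wobble (G·U) pairs are allowed in
duplex extension but never inside the seed core.

Each site is annotated with a seed-anchored duplex ΔG: pairing is extended
outward from the hexamer core in both directions while Watson–Crick or G·U
pairing holds (contiguous, no bulges — full hybridization folding is out of
scope), and the nearest-neighbor sum is

ΔG = ΔG_init + Σ stacks + terminal AU/GU penalties.

Parameters ship as a versioned YAML table
(`nn-rna-turner2004-derived-v1`): duplex initiation +4.10 kcal/mol,
terminal A-U/G-U penalty +0.50 per helix end, and all 36 ordered
Watson–Crick/wobble dinucleotide steps. The values were measured from
two-base-pair duplex energies evaluated with ViennaRNA's Turner-2004 rule
set; the Watson–Crick entries agree with the published Turner 2004 stack
table to 0.1 kcal/mol. The model is pluggable: any `EnergyModel` with the
same key convention can be substituted. The default retention cutoff is
ΔG ≤ −20 kcal/mol; at that stringency a bare seed match (≈ −10 to −15
kcal/mol) is discarded and retention requires pairing well beyond the seed.
The cutoff is an explicit parameter (`cutoff=None` disables the filter),
and the site-sharing analyses below scan unfiltered so that seed-core
architecture is classified independently of 3'-pairing context.

### Site sharing and the one-base register shift

For a 5'-isomiR built by prepending U to canonical sequence X, the isomiR
seed hexamer equals X positions 1–6, so the complement of the isomiR seed
heptamer *contains* the canonical seed hexamer complement. Two consequences
are built into the design:

- A canonical site and an isomiR site are classified **shared** only when
  they overlap such that their union pairs canonical positions 1–8 (the
  canonical cluster pairs position 8 and the isomiR cluster covers the base
  opposite canonical position 1). Bare-hexamer overlaps created by the
  register shift alone are not shared sites.
- A planted isomiR-only core is exclusive to the isomiR register at
  7mer-m8/7mer-A1/8mer stringency; under bare 6mer scanning the embedded
  canonical hexamer is necessarily also found. Likewise, contiguously
  extending an isomiR duplex 3'-ward creates the canonical m8 pairing, so
  "isomiR-only" is a seed-level, not an energy-level, notion.

## Word-enrichment landscapes

For a ranked gene list (default ordering: increasing log2 fold change, ties
broken by input order) and word length k (default 6, the seed hexamer), the
landscape at prefix size n is the hypergeometric tail probability of the
word count observed in the first n genes' UTRs, drawing the prefix's total
word tokens from the pooled totals (occurrence-counted, overlap-counted —
the Sylamer-style statistic; a presence/absence mode over genes is
available). Scores are signed −log10 p: positive when the observed count
exceeds its expectation (enrichment), negative for depletion; a word absent
from all UTRs scores 0, as does the full-list prefix. Landscape scores are
exploratory and are not multiplicity-adjusted; `bh_adjust`
(Benjamini–Hochberg step-up, via statsmodels) is provided for tabular
outputs. Control words are reproducible random samples excluding the focal
seeds.

## Expression filtering, overlaps, clustering

A gene is down-regulated in a condition iff log2 FC ≤ −0.9 versus the
control and its average log2 CPM across all samples (edgeR's logCPM
convention; the averaging set is a design choice) exceeds 3. Overlap counts
intersect each variant's predicted-target set with its condition's
down-regulated set and report the pairwise common counts (the Venn logic).
For clustering, rows are centered and scaled per gene (unit variance,
ddof = 1, matching R's `scale`), distance is 1 − Pearson r, and
agglomeration uses complete linkage by default with average linkage
available — the source analyses describe both, and neither is asserted
beyond determinism. Fold changes for synthetic tables are plain column
differences of log2 CPM; real edgeR outputs can be imported in their place.

## Synthetic data: what is emulated, what is not

Generators are pure functions of `SimConfig` (same seed ⇒ byte-identical
outputs) and every planted truth is ledgered.

- **Read libraries**: multinomial draws over (miRNA, offset) categories.
  Default study conditions: the miR-34b-like locus at offsets
  {0: 0.08, +1: 0.92} and the miR-449c-like locus at {0: 0.25, +1: 0.75}
  relative to the U-extended database entry; spike-in presets mix two
  variant pairs (1:1 and 9:1) into a complex background. Depths are
  2×10⁵ (library presets) and 2×10⁴ (two-miRNA mixture checks, ≈10⁴ reads
  per locus) — desk-scale stand-ins for the deposited libraries that keep
  binomial noise far below the 3-SD assertion bands. The error model is
  substitution-only (default 0, bounded at 5%): indels would move 5' starts
  and corrupt the offset ground truth. No ligation/cloning bias and no
  platform-specific error profile is modelled; passing tests therefore demonstrate correctness of
  the quantification arithmetic, not robustness to adapter artifacts.
- **Transcriptomes**: background is rejection-sampled to contain no
  unplanted occurrence of either register's seed complement, and assembled
  UTRs are re-verified across junctions, so site-count assertions are exact
  rather than statistical. Planted cores are bare seed cores (see above) at
  ledgered positions with ≥ 2 nt spacing; the RRAS-like preset plants three
  canonical-only cores plus one shared core in a 400-nt UTR.
- **Expression tables**: per-gene log-normal baseline (log2 CPM ≈
  N(5, 2)), per-condition noise SD 0.1, planted log2 effects of −2.0 on
  variant-specific target sets (canonical sets larger than isomiR sets,
  with partial overlaps). Planted targets' baselines are drawn from the
  expressed range (≥ 4.5 log2 CPM), since they emulate predicted-target
  genes that are detectable in the assay; genes repressed in several
  conditions can still drop below the average-CPM floor, which is the main
  source of sub-100% recovery.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; GFF3 (1-based
  inclusive) converts at the boundary. T/U are interchangeable on input.
- A mature sequence occurring more than once in its hairpin is an error
  (offset origin undefined), resolved by explicit GFF3 coordinates.
- Empty offset profiles (no windowed reads) carry empty percentage maps and
  CPM 0 and are never flagged.
- Percentage sums are validated to 100 ± 1e−9; scaled rows to mean 0 and
  unit variance ± 1e−9; zero-variance genes are rejected by name.
- Hypergeometric tails come from `scipy.stats.hypergeom`; tail probabilities
  are floored at the smallest positive float before taking log10.
- ΔG values are rounded to 10 decimals to keep equality checks stable.

## Known limitations

- Mapping is exact-match only; a substitution error anywhere in a read
  makes it unmapped rather than mismatched, which slightly deflates library
  size at non-zero error rates.
- The energy model scores only contiguous seed-anchored helices; sites
  whose stability depends on bulged 3' pairing are under-scored, so the
  −20 kcal/mol default is conservative for such sites.
- The landscape statistic implements neither low-complexity masking nor
  composition corrections; on real UTRs, repeat-rich words need external
  masking before interpretation.
- Replicate concordance on synthetic libraries is near 1 by construction
  (shared ground truth, binomial noise only); it validates the pipeline's
  arithmetic, not biological reproducibility.
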