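# isoforge

Characterization of 5'-isomiRs — mature miRNA variants whose 5' start is
shifted relative to the database annotation — from small RNA-seq, with
seed-shift-aware target prediction and downstream expression analysis.

A one-base 5' shift moves the seed region (nucleotides 2–8) by one base and
can redefine a miRNA's target repertoire. For the miR-34/449 family, the
database entries for miR-34b and miR-449c carry one supplemental 5' uridine
relative to the dominant sequenced form: the abundant form shares the
family seed `GGCAGU` (positions 2–7), while the U-extended variant reads
`AGGCAG`. `isoforge` provides the full computational pipeline for this kind
of analysis:

- **`annotation_io`** — hairpin/mature FASTA and miRBase-dialect GFF3
  parsing; anchors each mature on its hairpin (0-based internal
  coordinates).
- **`isomir_quant`** — exact-match read mapping, per-miRNA read counts by
  5'-start offset (−2…+2) with percentages and CPM, canonical-fraction
  tables, and reannotation calls: a locus is flagged when an alternative 5'
  form carries ≥ 50% of its reads at ≥ 20 CPM.
- **`target_scan`** — MicroCible-style seed-complementarity scanner:
  6mer / 7mer-m8 / 7mer-A1 / 8mer site taxonomy, nearest-neighbor duplex
  ΔG with a configurable cutoff (default ≤ −20 kcal/mol), and
  classification of sites as canonical-only / isomiR-only / shared between
  the two seed registers.
- **`word_enrichment`** — signed −log₁₀ hypergeometric enrichment
  landscapes of seed-complementary words over prefixes of a ranked gene
  list (Sylamer-style), control-word panels, Benjamini–Hochberg adjustment.
- **`expression_filter`** — down-regulation selection (log₂FC ≤ −0.9 and
  average log₂CPM > 3), Venn-style overlaps of predicted targets with
  down-regulated sets, correlation-distance hierarchical clustering.
- **`synthetic_data`** — generators for every input (hairpins, read
  mixtures, spike-ins, transcriptomes with planted site architectures,
  expression tables with planted repression) with ground-truth ledgers.

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

Quantify a simulated airway-culture library in which the two focal loci
carry 92/8 and 75/25 variant mixtures, then call reassignments:

```sh
python analysis/01_simulate_libraries.py --seed 17
python analysis/02_quantify_isomirs.py  --seed 17
```

```
[haec] 2 miRNA(s) flagged for reannotation:
    mir000: offset +1 carries 92.1% of reads at 50250 CPM
    mir001: offset +1 carries 75.0% of reads at 50595 CPM
[replicates] canonical-fraction R^2 = 1.000 over 20 miRNAs
```

`mir000`/`mir001` emulate miR-34b/miR-449c: ~92% and ~75% of their reads
start one base downstream (+1) of the annotated position, well above the
50%/20 CPM thresholds, so both database entries are flagged and the
dominant (U-less) sequence is proposed as canonical. The replicate R² is
the concordance of per-miRNA canonical fractions between two simulated
libraries.

The remaining drivers exercise the other stages:

```sh
python analysis/03_scan_targets.py        --seed 17   # site scanning + sharing
python analysis/04_enrichment_landscape.py --seed 17  # word landscapes + plot
python analysis/05_filter_overlap.py      --seed 17   # filters, Venn, clustering
```

`03` scans a synthetic RRAS-like 3'UTR and reports
`3 canonical-only site(s) + 1 shared site(s)` — three sites read only by
the canonical seed register plus one site whose core pairs canonical
positions 1–8 and is recognized by both registers. `04` prints the
landscape peak (`peak score 100.4 at prefix 100`) sitting exactly at the
planted down-regulation boundary, with control words near zero. `05`
recovers the planted target sets (e.g. `60/60 planted recovered`) and
prints the pairwise Venn counts.

All outputs land in `results/` as TSV/JSON/BED.

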