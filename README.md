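# ppa-scout

Detection and quantification of **premature intronic
cleavage-and-polyadenylation (pPA)** from bulk RNA-Seq read evidence,
plus a seeded synthetic-cohort generator with ground truth.

A pPA event truncates a transcript at a cryptic poly(A) signal (PAS)
inside an intron. Both pPA and intron retention (IR) leave intronic
reads, so the caller runs a three-tier cascade per sample:

1. **Triage** — classify intronic coverage as `NO_READS`, `ISOLATED`, or
   `SUSTAINED` (a covered stretch of >= 100 nt reaching depth >= 5, both
   configurable).
2. **IR test** — split the intron at the PAS into the truncation-specific
   region A (5' of the cleavage boundary, in transcription direction) and
   the remainder B; test the observed A/B read counts against the uniform
   IR null with a two-cell chi-square goodness-of-fit (df = 1, reject at
   p < 0.05).
3. **Continuity** — require coverage across region A with at most 4
   gaps, each strictly shorter than 75 nt (uncovered region ends count
   as gaps).

Samples passing all three tiers are `PPA_POSITIVE`; the others are
`CONSISTENT_WITH_IR`, `FAILS_CONTINUITY`, or `NEGATIVE`. Relative
truncated:full-length expression is quantified as length-corrected read
densities over declared isoform-unique regions, and matched-cohort
sequencing depth is compared via upper-quartile normalization and median
fold change.

## Layout

| module | contents |
|---|---|
| `ppa_scout.genemodel` | intervals, gene/isoform model, intron split at the PAS, read-through stop finder, BED12/GFF3 + TOML loading |
| `ppa_scout.coverage` | blocked reads (`BlockedRead`/`ReadSet`), splice-aware per-base coverage, BEDGRAPH/BED12 I/O, covered-stretch and gap analytics, optional SAM adapter |
| `ppa_scout.detect` | the cascade: tier-1 triage, read-to-region assignment, chi-square IR test, continuity filter, final call |
| `ppa_scout.quantify` | unique-region counts, density ratios, upper-quartile normalization, median fold change |
| `ppa_scout.simdata` | transcript-mixture read simulator with planted classes (negative / isolated noise / IR / pPA / gapped pPA) and a truth manifest |
| `ppa_scout.report` | per-group tier funnel summary and pipeline orchestration |
| `ppa_scout.cli` | `ppa-scout` command-line interface |

All coordinates are 0-based half-open (BED convention); GFF3 input is
converted at the boundary. Minus-strand genes are fully supported — the
"start of the intron" is always transcription-directional.

## CLI

```sh
# simulate the default 16 tumor + 16 normal synthetic cohort
ppa-scout simulate --out cohort/ --seed 1

# classify one sample (BED12 reads and/or BEDGRAPH coverage)
ppa-scout classify --model model.toml --reads cohort/tumor01.bed12 --out result.tsv

# unique-region quantification
ppa-scout quantify --model model.toml --reads cohort/tumor01.bed12 --out quant.tsv

# matched-group depth comparison (genes x samples TSV + pairing TSV)
ppa-scout depth-compare --matrix expr.tsv --pairs pairs.tsv --gene MYGENE --out depth.json

# full pipeline: simulate -> classify -> quantify -> summary
ppa-scout run --out artifacts/ --seed 1
```

`model.toml` names the annotation (BED12 with one record per isoform, or
GFF3) and declares the target intron, PAS position (first hexamer base,
transcription direction), optional cleavage offset, and per-isoform
unique regions:

```toml
annotation = "model.bed12"
gene_id = "DEMO1"
strand = "+"
pas_position = 2194
cleavage_offset = 0

[target_intron]
chrom = "chr1"
start = 1200
end = 5200

[unique_regions]
pPA = [[1200, 2200]]
FL_alpha = [[6000, 7000]]
FL_beta = [[7500, 8200]]
```

## Notes and caveats

- The chi-square test is applied per sample at alpha = 0.05 with no
  multiple-testing adjustment across the cohort.
- Reads are counted per region by the midpoint of their intronic
  footprint (boundary ties go to region A); per-base counting is
  available via `DetectionParams(count_mode="bases")` and is the
  fallback when only a BEDGRAPH is supplied.
- Duplicate reads are not collapsed and no mapping-quality filter is
  applied by default.
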