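# rxagsp

Relative expression analysis with gene-set pairs (RXA-GSP): a screening
toolkit for prognostic gene-set pairs in survival cohorts.

Given two biologically pre-defined candidate gene lists — a "poor-prognosis"
set and a "good-prognosis" set — the screen:

1. enumerates every gene-set pair (one subset of at least two genes from
   each list);
2. scores each patient with a rank-free, within-sample index: the median
   log-expression of the poor-side genes minus the median of the good-side
   genes (a positive index predicts poor outcome).  Because the index is a
   within-sample difference, it is invariant to per-sample normalization
   shifts and merges across platforms without preprocessing;
3. evaluates every pair in every cohort: sign-dichotomization, two-group
   log-rank test, and a Cox proportional-hazards fit (Efron ties);
4. combines per-cohort evidence with the Liptak–Stouffer weighted
   inverse-normal method (weights = cohort sample sizes) and selects pairs
   that (i) survive Bonferroni control over all enumerated pairs, (ii) split
   every cohort into groups of at least 20% each, and (iii) show hazard
   ratio > 1 with log-rank p < 0.05 in every cohort;
5. validates a winner on a held-out cohort against an empirical null built
   from size-matched random gene-set pairs;
6. tests clinical associations of the resulting grouping (exact r×2
   Fisher/Freeman–Halton test, Spearman rank correlation, Welch t-test);
7. scans promoter FASTA sequences with a position weight matrix at a
   fraction-of-maximum score threshold (both strands, duplicate hits from
   overlapping transcripts collapsed).

A seeded synthetic-cohort generator (`rxagsp.simulate`) produces
multi-cohort expression + right-censored survival data with a planted
index–hazard link, so the whole pipeline is testable without any external
downloads.

## Command line

One subcommand per pipeline stage:

```sh
# synthetic multi-cohort data with a planted pair
rxagsp simulate --seed 17 --n-cohorts 3 --n-samples 300 --out sim/

# enumerate, screen all cohorts, meta-analyze, select
rxagsp screen \
  --expr sim/cohort1_expr.tsv --clinical sim/cohort1_clinical.tsv \
  --expr sim/cohort2_expr.tsv --clinical sim/cohort2_clinical.tsv \
  --expr sim/cohort3_expr.tsv --clinical sim/cohort3_clinical.tsv \
  --poor sim/poor_candidates.txt --good sim/good_candidates.txt \
  --out screen/

# held-out validation of one pair (index + log-rank, optional KM plot)
rxagsp validate --expr sim/cohort3_expr.tsv --clinical sim/cohort3_clinical.tsv \
  --m-plus P1,P2,P3,P4,P5 --m-minus G1,G2 --out val/

# empirical p against size-matched random gene-set pairs
rxagsp empirical --expr sim/cohort3_expr.tsv --clinical sim/cohort3_clinical.tsv \
  --m-plus P1,P2,P3,P4,P5 --m-minus G1,G2 --n 1000 --seed 17 --out empirical.tsv

# clinical covariates vs the two prognosis groups (exact tests)
rxagsp assoc --clinical sim/cohort3_clinical.tsv --groups val/index.tsv --out assoc.tsv

# promoter motif scan (BED6 output); default motif ACYGGTTT at 85% of max
rxagsp scan-motif --fasta promoters.fa --threshold 0.85 --out hits.bed
```

All formats are plain text: expression matrices are TSV (genes/probes in
rows, samples in columns; probe-level input is collapsed per gene to the
probe with the highest across-sample variance via `--probe-map`); clinical
tables are TSV with `sample_id`, `time_years`, `event`, then covariates;
gene lists are one symbol per line; PWMs are TRANSFAC-like or 4-column
text.  Output tables carry provenance headers (version, config hash, seed).

## Layout

```
src/rxagsp/
  io.py         expression/clinical/gene-list IO, probe collapsing
  core.py       pair enumeration and the prognostic index
  survival.py   log-rank, Cox (fast 1-D + lifelines multivariate), screen
  meta.py       Liptak–Stouffer combination, Bonferroni, selection criteria
  empirical.py  resampling empirical null
  assoc.py      exact r×2 Fisher, Spearman, Welch tests
  motif.py      PWM construction and promoter scanning
  simulate.py   seeded synthetic cohorts with planted effects
  cli.py        click-based subcommands
```
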