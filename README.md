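# tracksuite

Integrative analysis of *collections* of genomic tracks: a tested library and
CLI for base-pair-level co-occurrence statistics over suites of BED tracks,
structure-preserving Monte Carlo null models, and the GSuite collection
format. Everything runs on local or synthetic data — no downloads required.

## What it does

* **Track model** — BED3+ tracks anchored to a `chrom.sizes` genome
  definition; 0-based half-open coordinates; points as 1 bp segments;
  sorted/merged normalization; exact bp set operations and contingency
  tables whose cells sum to the genome size N.
* **GSuite format** — a tabular text format for suites of tracks:
  `##key: value` headers, an optional `#uri<TAB>title<TAB>...` column
  declaration, tab-separated metadata columns. A plain file of one URI per
  line is a valid GSuite. Parse / write / validate / filter round-trip
  exactly.
* **Pairwise statistics (T)** — Jaccard, Forbes (observed over
  independence-expected co-coverage; 1 at independence), and the
  tetrachoric latent correlation (ML with thresholds fixed at the marginal
  coverage fractions). Jaccard is size-confounded when ranking; the docs and
  tests demonstrate this.
* **Suite statistics** — per-track Q (aggregate of T against the rest of
  the suite), whole-suite R, cross-suite matrices, binned
  occurrence/co-occurrence with ranked bins, and the higher-order coverage
  depth count (bp covered by ≥ k tracks, computed by a boundary sweep).
* **Null models** — three sampler categories: per-track randomization
  preserving segment-length and gap multisets per chromosome; pooled
  re-dealing of segments within a suite (± count preservation, ±
  replacement); across-suite randomization (pool elements or permute whole
  tracks).
* **Monte Carlo testing** — add-one p-values (k+1)/(m+1),
  Benjamini–Hochberg adjustment, and ready-made tests for the five
  analytical questions (suite coherence, query-vs-suite, cross-suite cells,
  binned variation). Every result records its multiplicity class
  (trivial / contrasting / integrative / higher-order), derived from the
  scope of the statistic and the sampler.
* **Synthetic data** — a block-latent-Gaussian suite generator whose model
  is exactly the tetrachoric assumption, with known per-track ρ, planted
  pairs and planted bins, so every statistic is testable against ground
  truth.

## CLI

All commands are under a single `gsuite` entry point; every analysis writes
TSV results plus a JSON run manifest (inputs, digests, seed, version), and
all randomness flows from an explicit seed.

```sh
# make a genome and a synthetic suite with known structure
printf 'chr1\t100000\n' > genome.chrom.sizes
gsuite simulate --genome genome.chrom.sizes --model shared-signal \
    --n-tracks 5 --rho 0.8,0.5,0.2,0,0 --seed 1 --out demo/

gsuite validate demo/suite.gsuite --genome genome.chrom.sizes

# q1: which tracks are most representative / atypical?
gsuite analyze q1 --suite demo/suite.gsuite --genome genome.chrom.sizes \
    --stat forbes --with-tests --mc-samples 99 --mc-seed 7 --out q1/

# q2: rank the suite against a separate query track
gsuite analyze q2 --suite demo/suite.gsuite --genome genome.chrom.sizes \
    --query demo/track00.bed --stat tetrachoric --out q2/

# q4/q5: binned occurrence / co-occurrence
gsuite analyze q4 --suite demo/suite.gsuite --genome genome.chrom.sizes \
    --bin-width 5000 --out q4/

# low-level: one pairwise statistic, one null draw
gsuite stats pairwise demo/track00.bed demo/track01.bed \
    --genome genome.chrom.sizes --stat jaccard
gsuite sample-null --suite demo/suite.gsuite --genome genome.chrom.sizes \
    --null pertrack --mc-seed 3 --out null/
```

Questions q1–q5 take, respectively: one suite; suite + query BED; two
suites (`--suite2`); suite + bins (`--bins BED` or `--bin-width INT`) for
occurrence and co-occurrence.

## Conventions

* Coordinates are BED-style 0-based half-open everywhere; strand is ignored
  (statistics are defined on covered base pairs).
* Intervals outside chromosome bounds are errors, never clipped.
* Forbes and tetrachoric are errors on degenerate margins (empty or
  genome-covering tracks); Jaccard of two empty tracks is 0 with a warning.
* Default statistic for ranking analyses is Forbes; tetrachoric is
  recommended for suites with heterogeneous track sizes; Jaccard rankings
  follow track size and should be avoided for ranking.
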