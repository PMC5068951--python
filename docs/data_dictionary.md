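# Data dictionary

File formats read and written by the pipeline. All tables are
tab-separated with a header row; gene/mutant identifiers are free-form
strings.

## Barcode catalog (`catalog.tsv`)

| column      | type   | description                                  |
|-------------|--------|----------------------------------------------|
| `mutant_id` | str    | unique strain identifier                     |
| `uptag_seq` | str    | uptag barcode, uniform length (default 20 nt)|
| `dntag_seq` | str    | dntag barcode, uniform length                |

## Sample sheet (`sample_sheet.tsv`)

One row per sequencing unit (one tag library of one biological sample).

| column      | type | description                                              |
|-------------|------|----------------------------------------------------------|
| `sample_id` | str  | unique unit id                                           |
| `index_seq` | str  | 3–4 nt sample index at the read start; unique and prefix-free within a file |
| `tag_class` | str  | `up` or `dn`                                             |
| `condition` | str  | `control` or a treatment/compound label                  |
| `batch`     | str  | experimental batch; (condition, batch) pairs the two tag units of one sample |
| `fastq`     | str  | optional; FASTQ file containing the unit (default `batch<batch>.fastq`) |

## Count table (`counts.tsv`)

Mutants × samples integer matrix; row order follows the catalog, column
order the sample sheet. Column labels are `condition.batch` after tag
combination (`sum`, `uptag-only`, `dntag-only`) or raw `sample_id`s
(`keep-separate`).

## QC tables

`qc_files.tsv` (per FASTQ file): `total_reads`, `assigned`,
`unassigned_index`, `unassigned_barcode`, `ambiguous`; the four categories
sum to `total_reads`. `qc_samples.tsv` (per demultiplexed unit): `total`,
`assigned`, `unassigned_barcode`, `ambiguous`.

## Screen manifest (`screen_manifest.tsv`)

| column      | type  | description                                   |
|-------------|-------|-----------------------------------------------|
| `screen_id` | str   | unique screen identifier                      |
| `compound`  | str   | compound; screens sharing it are replicates   |
| `doublings` | float | pool doublings d for the GI denominator       |
| `control`   | str   | control column name in the count table        |
| `treatment` | str   | treatment column name                         |
| `dose`, `batch`, `t0` | any | optional metadata; `t0` (0-h column) is recorded but unused |

## Score table (`scores_<screen_id>.tsv`)

| column      | type  | description                                   |
|-------------|-------|-----------------------------------------------|
| `mutant_id` | str   | strain                                        |
| `gi`        | float | growth-inhibition score; NaN = data missing   |
| `z`         | float | robust Z: (GI − median) / NIQR                |
| `fdr`       | float | tail-area FDR in [0, 1], non-increasing in abs z |

## Hit tables (`hits_<compound>.tsv`, `rescreen_<compound>.tsv`)

| column                  | type  | description                         |
|-------------------------|-------|-------------------------------------|
| `mutant_id`             | str   | strain                              |
| `mean_gi`               | float | mean GI across assayed screens      |
| `n_screens_assayed`     | int   | screens with a score                |
| `n_screens_significant` | int   | screens passing FDR and direction   |
| `supporting_screens`    | str   | comma-joined significant screen ids |
| `expressivity`          | str   | `high` / `medium` / `low` from mean GI |

## Enrichment table (`enrichment_<compound>.tsv`)

`term`, `k` (hits in term), `n` (hit-list size), `K` (term size in
background), `N` (background size), `fold_enrichment` (raw),
`fold_rounded` (nearest integer), `list_frequency` (k/n),
`background_frequency` (K/N), `p_value` (upper-tail hypergeometric),
`q_value` (Benjamini–Hochberg), `significant` (q ≤ α), `genes`
(comma-joined hits in the term). Rows sorted by p.

## Other artifacts

- `overlap.json`: per compound pair — `both`, `<a>_only`, `<b>_only`,
  `neither`, `universe`, `p_value` (two-sided Fisher).
- `dendrogram.newick` + `gi_matrix_ordered.tsv`: average-linkage tree and
  the GI matrix in leaf order.
- `manifest.json`: config snapshot, input SHA-256 checksums, seed,
  timestamps, completed stages.
- Gene sets: standard GMT (term, description, members...).
- Growth curves: `time_hr` column plus one OD600 column per dose.
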