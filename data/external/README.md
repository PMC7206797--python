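# External published-dataset inputs (not distributed)

Two of the acceptance-style tests reproduce summary numbers from the
published sorted-microglia TMT study whose design this pipeline targets.
The underlying supplementary tables are not redistributed here; to run
those tests, place the following files in this directory:

- `table_s1_log2.tsv` — the published log2-transformed protein abundance
  table (supplementary quantitative data), reshaped to the generic wide
  format: columns `accession`, `symbol`, optional `confidence`, then one
  column per TMT channel/sample.
- `design.csv` — two columns `sample,group` assigning each of the 10
  samples to `MACS` or `FACS`.
- `markers_proteome.tsv` — the proteome-derived cell-type marker list
  (two columns `symbol`, `cell_type`).
- `markers_transcriptome.tsv` — the transcriptome-derived cell-type
  marker list (same format).

Without these files the corresponding tests report a failure stating
which inputs are missing; every other test is self-contained.
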