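# Supplementary score-table exports (not distributed)

Place TSV exports of the published screen tables here to enable the
data-dependent acceptance targets (see the top-level README):

- `s1_table.tsv`: primary-screen scores — columns `pool_id`, `gene`, `zscore`
- `s2_table.tsv`: counter-screen scores — same columns; scrambled-control
  rows carry gene `SCRAMBLED`
- `s3_table.tsv`: expression — columns `gene`, `fpkm_minus_dox`,
  `fpkm_plus_dox`

These files are third-party supplementary material and are therefore not
shipped with the repository.
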