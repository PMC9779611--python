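# Supplementary data (not redistributed)

Place the published supplementary annotation spreadsheet here as
`SupSpreadsheet1.xlsx` (or a TSV export named `SupSpreadsheet1.tsv`) to
enable the database-count acceptance checks (targets t1-t9) and
`tests/test_acceptance.py::test_criterion_1_supplementary_counts`.
A PROSITE-format `disintegrin_blocks.prosite` file placed alongside it is
used to re-scan the sequence set for target t1; otherwise the
spreadsheet's own disintegrin-motif column is used.
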