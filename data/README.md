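Place the study's per-child source-data workbook here as
`supplementary_data_1.xlsx` (or a CSV with the same per-child columns) to let
`mathstrat.pipeline.load_supplementary_source_data` and the printed-statistic
checks in `tests/test_acceptance.py` recompute the published behavioral and
brain-behavior statistics. Nothing else in the package requires this file.
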