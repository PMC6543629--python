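# data/

Plate-structure files shipped with the package (plain text, derived from the
published experimental design):

* `dataset1_layout.csv` — the 96-well layout of 16 replicate two-fold six-step
  dilution sets (rows A–H, two six-well blocks per row; D = 0..5 within each
  block).
* `table3_groups.csv` — the concentration grouping of the 16 sets
  (100/50/12/3 ng, expected fold-dilutions 1/2/8/32 relative to 100 ng) used by
  the dilution-accuracy analysis.

The measured datasets themselves (per-well fluorescence readings and Cq calls)
are distributed by the journal as supplementary spreadsheets and are NOT
included here. To run the dataset-bound checks, convert them with

    python scripts/convert_supplementary.py <dataset1.xlsx> <dataset2.xlsx> data/

which writes `dataset1_fluorescence.csv` (well,cycle,rfu) and
`dataset2_cq.csv` (well,cq) into this directory.
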