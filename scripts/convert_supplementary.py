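#!/usr/bin/env python
"""One-shot converter: journal supplementary spreadsheets -> long-format CSVs.

Usage:
    python scripts/convert_supplementary.py DATASET1.xlsx DATASET2.xlsx data/

DATASET1 holds per-well, per-cycle baseline-subtracted fluorescence (one column
per well, one row per cycle, a 'Cycle' column); DATASET2 holds per-well Cq
values ('Well' and 'Cq' columns). Legacy .xls files must first be re-saved as
.xlsx (the reader here is openpyxl). Output:

    data/dataset1_fluorescence.csv   well,cycle,rfu
    data/dataset2_cq.csv             well,cq

Column headers are matched case-insensitively; well columns are anything that
parses as a plate coordinate (A1..H12).
"""

import re
import sys
from pathlib import Path

import pandas as pd

WELL = re.compile(r"^[A-Ha-h]\d{1,2}$")


def convert_fluorescence(src: Path, out: Path) -> None:
    df = pd.read_excel(src)
    cols = {str(c).strip(): c for c in df.columns}
    cycle_col = next((cols[c] for c in cols if c.lower() == "cycle"), None)
    if cycle_col is None:
        raise SystemExit(f"{src}: no 'Cycle' column found")
    well_cols = [c for c in df.columns if WELL.match(str(c).strip())]
    if not well_cols:
        raise SystemExit(f"{src}: no well columns (A1..H12) found")
    long = df.melt(id_vars=[cycle_col], value_vars=well_cols,
                   var_name="well", value_name="rfu")
    long = long.rename(columns={cycle_col: "cycle"})
    long["well"] = long["well"].astype(str).str.strip().str.upper()
    long[["well", "cycle", "rfu"]].to_csv(out, index=False)
    print(f"wrote {out} ({len(long)} readings, {len(well_cols)} wells)")


def convert_cq(src: Path, out: Path) -> None:
    df = pd.read_excel(src)
    lower = {str(c).strip().lower(): c for c in df.columns}
    if "well" not in lower or "cq" not in lower:
        raise SystemExit(f"{src}: need 'Well' and 'Cq' columns")
    tab = df[[lower["well"], lower["cq"]]].dropna()
    tab.columns = ["well", "cq"]
    tab["well"] = tab["well"].astype(str).str.strip().str.upper()
    tab.to_csv(out, index=False)
    print(f"wrote {out} ({len(tab)} wells)")


def main() -> None:
    if len(sys.argv) != 4:
        raise SystemExit(__doc__)
    d1, d2, outdir = map(Path, sys.argv[1:])
    outdir.mkdir(parents=True, exist_ok=True)
    convert_fluorescence(d1, outdir / "dataset1_fluorescence.csv")
    convert_cq(d2, outdir / "dataset2_cq.csv")


if __name__ == "__main__":
    main()
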