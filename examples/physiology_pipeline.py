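"""End-to-end file pipeline: simulate physiology, score it, write a report.

Generates a physiology-level cohort (raw bedside variables whose MSOFA panels
are known by construction), round-trips it through CSV, scores every snapshot
with both instruments and writes the four report tables.  The same pipeline
runs from the shell as:

    msofa simulate --out cohort.csv --seed 1
    msofa score    --input cohort.csv --out scores.csv
    msofa evaluate --input scores.csv --out report/
"""

import tempfile
from pathlib import Path

from msofa import (
    RunConfig,
    default_calibration,
    generate_physiology_cohort,
    read_cohort_csv,
    run_report,
    write_cohort_csv,
)

workdir = Path(tempfile.mkdtemp(prefix="msofa_demo_"))
records = generate_physiology_cohort(default_calibration(seed=1))

cohort_csv = workdir / "cohort.csv"
write_cohort_csv(records, cohort_csv, seed=1)
records_back = read_cohort_csv(cohort_csv)
assert records_back == records  # CSV round trip is lossless

paths = run_report(records_back, RunConfig(out_dir=workdir / "report", seed=1))
print(f"cohort of {len(records)} patients written to {cohort_csv}")
print("report files:", ", ".join(p.name for p in paths.values()))
print()
print((workdir / "report" / "report.txt").read_text())
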