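"""Preparing a mixed table: binning, coverage diagnostics, regrouping.

Builds a small CSV with a numeric column and a sparse categorical column,
then walks through the preprocessing steps the selection pipeline expects:
quantile binning, a sample-coverage report, and category regrouping.
"""

import tempfile
from pathlib import Path

import numpy as np

from casmi import BinningSpec, coverage_report, discretize, read_table, regroup

rng = np.random.default_rng(5)
n = 120
rows = ["age,clinic,outcome"]
clinics = [f"c{i}" for i in range(400)]  # far too many categories for n=120
for i in range(n):
    rows.append(f"{rng.normal(50, 12):.1f},{rng.choice(clinics)},{rng.integers(0, 2)}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "clinic.csv"
    path.write_text("\n".join(rows) + "\n")
    table = read_table(path, outcome="outcome")

table = discretize(table, BinningSpec("age", bin_count=4))  # quantile bins
print("coverage before regrouping:")
print(coverage_report(table).round(3), "\n")

# merge the sparse clinic codes into regions to restore coverage
mapping = {c: f"region{int(c[1:]) // 100}" for c in clinics}
table = regroup(table, "clinic", mapping)
print("coverage after regrouping clinics into regions:")
print(coverage_report(table).round(3))

print(
    "\nA coverage below 0.5 means most of the column's population mass is"
    "\nunseen: associations estimated from it would not generalize, and the"
    "\nselection score would (rightly) suppress it."
)
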