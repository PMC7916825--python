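"""Rank metabolic pathways from flat input files.

Builds a small two-condition experiment on disk (intensity CSV,
annotation CSV, pathway definitions CSV), then runs the SVD
activity-level scorer through the config-driven workflow and prints the
top of the ranked table.  Low p-values mean the pathway's features move
together between conditions more than label-reshuffled data would allow.
"""

import tempfile
from pathlib import Path

import pandas as pd

from metsetrank import RunConfig, run_analysis, generate_base

workdir = Path(tempfile.mkdtemp(prefix="metsetrank_"))

# a small synthetic experiment written out as the three input files
ds = generate_base(seed=7, n_background=30)
raw = (ds.matrix.values * 0.5 + 12).apply(lambda c: 10 ** (c / 2))
raw.to_csv(workdir / "intensity.csv", index_label="feature_id")
ds.annotations.records.to_csv(workdir / "annotations.csv", index=False)
pd.DataFrame(
    [
        (ms.set_id, ms.name, member, ms.member_kind)
        for ms in ds.database
        for member in ms.members
    ],
    columns=["set_id", "set_name", "member", "member_kind"],
).to_csv(workdir / "sets.csv", index=False)

config = RunConfig(
    intensity_path=str(workdir / "intensity.csv"),
    annotation_path=str(workdir / "annotations.csv"),
    sets_path=str(workdir / "sets.csv"),
    case="case",
    control="control",
    design={g: list(s) for g, s in ds.matrix.design.items()},
    output_path=str(workdir / "ranked.csv"),
    method="mplage",
    n_perm=1000,
    seed=1,
)
out = run_analysis(config)
table = pd.read_csv(out)

print(f"ranked table written to {out}")
print(table.head(10).to_string(index=False))
print(
    "\nThe seven planted pathways (Two..Eighty) carry a real between-group"
    "\nshift; larger ones rank higher because more coordinated features"
    "\nsharpen the activity-level signal against the permutation null."
)
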