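"""Score feature-keyed metabolite sets (molecular families / Mass2Motifs).

Set membership from fragmentation-based grouping arrives as feature ids,
not formulae.  This example converts a GNPS-style membership table into
feature-keyed sets with the adapter and scores them against a small
intensity matrix — no annotation table needed.
"""

import warnings

import numpy as np
import pandas as pd

from metsetrank import IntensityMatrix, map_database, run_mplage
from metsetrank.set_sources import build_database, gnps_to_set_records

warnings.filterwarnings("ignore", category=RuntimeWarning)

rng = np.random.default_rng(3)
design = {"high_plant": [f"hp{i}" for i in range(4)],
          "low_plant": [f"lp{i}" for i in range(4)]}
features = [f"spec_{i}" for i in range(60)]

# motif 1 (features 0-14) responds to the diet contrast; motif 2 does not
values = rng.standard_normal((60, 8))
values[:15, :4] += 2.5
matrix = IntensityMatrix(
    pd.DataFrame(values, index=features,
                 columns=design["high_plant"] + design["low_plant"]),
    design,
)

membership = pd.DataFrame(
    {
        "motif": ["motif_1"] * 15 + ["motif_2"] * 20 + ["motif_3"] * 25,
        "feature": features,
    }
)
records = gnps_to_set_records(membership, "motif", "feature",
                              source_tag="mass2motif")
db = build_database(records, source_tag="mass2motif", min_set_size=10)
mapping = map_database(db, None, matrix)

table = run_mplage(matrix, db, mapping, ("high_plant", "low_plant"),
                   n_perm=1000, seed=3)
print(table[["set_id", "n_features", "t_statistic", "p_value"]]
      .to_string(index=False))
print(
    "\nmotif_1 carries a coordinated intensity shift between the groups"
    "\nand gets a small p-value; the other motifs behave like noise."
)
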