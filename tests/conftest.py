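import numpy as np
import pandas as pd
import pytest

from metsetrank.data_model import AnnotationTable, IntensityMatrix

DESIGN = {
    "case": ["c1", "c2", "c3", "c4"],
    "control": ["k1", "k2", "k3", "k4"],
}
COMPARISON = ("case", "control")


@pytest.fixture
def design():
    return {g: list(s) for g, s in DESIGN.items()}


@pytest.fixture
def small_matrix(design):
    """6 features x 8 samples; f1/f2 share a formula, f6 has missing cells."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(1e4, 1e6, size=(6, 8))
    vals[5, [0, 1]] = 0.0  # missing in part of the case group
    df = pd.DataFrame(
        vals,
        index=[f"f{i}" for i in range(1, 7)],
        columns=DESIGN["case"] + DESIGN["control"],
    )
    return IntensityMatrix(df, design)


@pytest.fixture
def annotations():
    return AnnotationTable(
        pd.DataFrame(
            {
                "feature_id": ["f1", "f2", "f3", "f4", "f5", "f6"],
                "formula": [
                    "C6H12O6", "C6H12O6", "C5H9NO4", "C3H7NO2",
                    "C4H6O4", "C10H16N5O13P3",
                ],
                "adduct": ["M+H", "M-H", "M+H", "M+Na", "M+H", "M-H"],
            }
        )
    )


@pytest.fixture
def set_file(tmp_path):
    rows = [
        ("glycolysis", "Glycolysis", "C6H12O6", "formula"),
        ("glycolysis", "Glycolysis", "C3H7NO2", "formula"),
        ("glycolysis", "Glycolysis", "C4H6O4", "formula"),
        ("tca", "TCA cycle", "C4H6O4", "formula"),
        ("tca", "TCA cycle", "C5H9NO4", "formula"),
        ("motif_1", "Motif 1", "f1", "feature"),
        ("motif_1", "Motif 1", "f5", "feature"),
        ("motif_1", "Motif 1", "ghost", "feature"),
        ("lonely", "Single member", "C2H4O2", "formula"),
    ]
    path = tmp_path / "sets.csv"
    path.write_text(
        "set_id,set_name,member,member_kind\n"
        + "\n".join(",".join(r) for r in rows)
        + "\n"
    )
    return path
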