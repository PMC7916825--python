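"""Core data containers and peak-intensity preprocessing.

The central object is :class:`IntensityMatrix`: an LC-MS feature x sample
table of peak intensities together with an experimental design that assigns
every sample to exactly one factor group.  Missing measurements are encoded
as zero on input (the convention of most peak-picking exports); imputation
replaces them group-wise, and an optional normalisation step moves the
matrix to log space and standardises each feature row.

:class:`AnnotationTable` carries the feature -> molecular-formula relation
used to map features into metabolite sets.  Only protonated (M+H) and
deprotonated (M-H) adducts are retained, which limits false-positive
compound identifications from other ion forms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: adducts retained when mapping features to formulae
ALLOWED_ADDUCTS = frozenset({"M+H", "M-H"})

#: default intensity used when a whole factor group is missing a feature
DEFAULT_MIN_INTENSITY = 5000.0


class DesignError(ValueError):
    """Raised when the experimental design is inconsistent with the data."""


class InputError(ValueError):
    """Raised for malformed input tables (negative intensities, bad rows)."""


@dataclass
class IntensityMatrix:
    """A features x samples peak-intensity matrix with a factor design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    design
        Mapping of factor-group label to the list of sample ids in that
        group.  Every sample column must belong to exactly one group.
    """

    values: pd.DataFrame
    design: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.design = {g: list(s) for g, s in self.design.items()}
        assigned: list[str] = []
        for group, samples in self.design.items():
            if len(samples) == 0:
                raise DesignError(f"factor group {group!r} has no samples")
            assigned.extend(samples)
        if len(assigned) != len(set(assigned)):
            dupes = sorted({s for s in assigned if assigned.count(s) > 1})
            raise DesignError(f"samples in more than one group: {dupes}")
        missing = [s for s in assigned if s not in self.values.columns]
        if missing:
            raise DesignError(f"design samples absent from matrix: {missing}")

    # -- convenience ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_of(self, sample_id: str) -> str:
        for group, samples in self.design.items():
            if sample_id in samples:
                return group
        raise DesignError(f"sample {sample_id!r} not in any factor group")

    def group_columns(self, group: str) -> list[str]:
        try:
            return list(self.design[group])
        except KeyError:
            raise DesignError(f"unknown factor group {group!r}") from None

    def validate_comparison(self, comparison: tuple[str, str]) -> None:
        """Check a (case, control) contrast is statistically usable."""
        case, control = comparison
        for group in (case, control):
            if group not in self.design:
                raise DesignError(f"unknown factor group {group!r}")
            if len(self.design[group]) < 2:
                raise DesignError(
                    f"group {group!r} has fewer than 2 samples; "
                    "statistical comparison needs >=2 per group"
                )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), dict(self.design))


@dataclass
class AnnotationTable:
    """Feature -> molecular formula annotations, adduct-filtered on load.

    One feature maps to at most one formula; one formula may annotate many
    features (isomers/isobars are indistinguishable at the formula level).
    """

    records: pd.DataFrame  # columns: feature_id, formula, adduct

    REQUIRED = ("feature_id", "formula", "adduct")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise InputError(f"annotation table missing column {col!r}")
        df = df.copy()
        df["formula"] = df["formula"].astype(str).str.strip()
        df["adduct"] = df["adduct"].astype(str).str.strip()
        kept = df[df["adduct"].isin(ALLOWED_ADDUCTS)].reset_index(drop=True)
        n_dropped = len(df) - len(kept)
        if n_dropped:
            logger.info("dropped %d annotations with disallowed adducts", n_dropped)
        dup = kept["feature_id"][kept["feature_id"].duplicated()]
        if not dup.empty:
            raise InputError(
                f"features annotated more than once: {sorted(set(dup))[:5]}"
            )
        self.records = kept

    def features_for(self, formula: str) -> list[str]:
        formula = formula.strip()
        hit = self.records[self.records["formula"] == formula]
        return list(hit["feature_id"])

    @property
    def formula_of(self) -> dict[str, str]:
        return dict(zip(self.records["feature_id"], self.records["formula"]))


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def impute_missing(
    m: IntensityMatrix, min_intensity: float = DEFAULT_MIN_INTENSITY
) -> IntensityMatrix:
    """Impute zero (missing) intensities group-wise.

    Within each feature x factor-group block: if every sample is zero the
    whole block is set to ``min_intensity``; if only some are zero, each
    zero is replaced by the mean of the non-zero samples of that group.
    Non-zero values are never altered, so the operation is idempotent.
    """
    if min_intensity <= 0:
        raise InputError("min_intensity must be positive")
    vals = m.values.to_numpy(dtype=float, copy=True)
    if np.isnan(vals).any():
        vals = np.nan_to_num(vals, nan=0.0)  # NA == missing == 0
    if (vals < 0).any():
        raise InputError("negative intensities in input matrix")
    col_index = {s: i for i, s in enumerate(m.values.columns)}
    for group, samples in m.design.items():
        idx = [col_index[s] for s in samples]
        block = vals[:, idx]
        zero = block == 0.0
        all_zero = zero.all(axis=1)
        block[all_zero, :] = min_intensity
        some = ~all_zero & zero.any(axis=1)
        if some.any():
            nz_sum = np.where(zero, 0.0, block).sum(axis=1)
            nz_cnt = (~zero).sum(axis=1)
            with np.errstate(invalid="ignore"):
                nz_mean = nz_sum / np.maximum(nz_cnt, 1)
            rows = np.where(some)[0]
            for r in rows:
                block[r, zero[r]] = nz_mean[r]
        vals[:, idx] = block
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(out, m.design)


def normalise(
    m: IntensityMatrix,
    *,
    within_group: bool = False,
    ddof: int = 1,
) -> IntensityMatrix:
    """Log-transform then standardise each feature row.

    Natural-log intensities are standardised to zero mean and unit
    variance across all samples (the PLAGE-style row standardisation the
    activity decomposition expects).  ``within_group=True`` standardises
    each feature within each factor group instead; note that this centres
    every group to zero and therefore removes all between-group signal —
    it is only meaningful for workflows that compare shapes, not levels.

    A zero-variance block is centred only (scaling skipped, warning
    emitted) — never NaN.
    """
    vals = m.values.to_numpy(dtype=float, copy=True)
    if (vals <= 0).any():
        raise InputError("normalise requires a fully imputed (positive) matrix")
    vals = np.log(vals)

    col_index = {s: i for i, s in enumerate(m.values.columns)}
    blocks = (
        [[col_index[s] for s in samples] for samples in m.design.values()]
        if within_group
        else [list(range(vals.shape[1]))]
    )
    for idx in blocks:
        block = vals[:, idx]
        mean = block.mean(axis=1, keepdims=True)
        centred = block - mean
        if block.shape[1] > ddof:
            sd = block.std(axis=1, ddof=ddof, keepdims=True)
        else:
            sd = np.zeros((block.shape[0], 1))
        flat = sd[:, 0] == 0.0
        if flat.any():
            warnings.warn(
                f"{int(flat.sum())} zero-variance feature block(s); "
                "centred without scaling",
                RuntimeWarning,
                stacklevel=2,
            )
        sd = np.where(sd == 0.0, 1.0, sd)
        vals[:, idx] = centred / sd
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(out, m.design)


def standardise_rows(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardise each row over all columns (helper, no log step)."""
    arr = values.to_numpy(dtype=float, copy=True)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    sd = np.where(sd == 0.0, 1.0, sd)
    return pd.DataFrame(
        (arr - mean) / sd, index=values.index, columns=values.columns
    )


def build_set_matrix(
    m: IntensityMatrix,
    ann: AnnotationTable,
    member_formulae: Sequence[str],
) -> pd.DataFrame:
    """Row-submatrix of features whose annotated formula is a set member.

    All features sharing a member formula are included (formula-level
    mapping keeps isomer coverage).  Row order follows the input matrix, so
    the result is deterministic.  An empty result is a skip signal for the
    caller, not an error.
    """
    wanted = {f.strip() for f in member_formulae}
    formula_of = ann.formula_of
    rows = [
        fid
        for fid in m.values.index
        if formula_of.get(fid) in wanted
    ]
    return m.values.loc[rows]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_intensity_csv(
    path, design: Mapping[str, Sequence[str]], delimiter: str = ","
) -> IntensityMatrix:
    """Read a delimited intensity table (first column = feature id).

    Blank/NA cells are coerced to 0 (the missing-value convention).
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce").fillna(0.0)
    return IntensityMatrix(df, design)


def read_annotations_csv(path, delimiter: str = ",") -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, sep=delimiter, dtype=str))


def read_design_yaml(path) -> tuple[dict[str, list[str]], tuple[str, str]]:
    """Read a design config: group -> samples, plus the declared contrast.

    Expected keys: ``groups`` (mapping label -> list of sample ids) and
    ``comparison`` (two-element list [case, control]).
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        groups = {str(g): [str(s) for s in ss] for g, ss in cfg["groups"].items()}
        case, control = cfg["comparison"]
    except (KeyError, TypeError, ValueError) as exc:
        raise InputError(f"malformed design config {path}: {exc}") from exc
    return groups, (str(case), str(control))
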