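"""Metabolite-set definitions and feature -> set mapping.

A metabolite set is any user-defined grouping of LC-MS features: a
metabolic pathway (members given as molecular formulae), a molecular
family from spectral networking, or a Mass2Motif substructure (members
given directly as feature ids).  Sets are loaded from flat delimited
files so that database exports (KEGG / Reactome / GNPS) and synthetic
fixtures go through one code path.

Set file columns: ``set_id, set_name, member, member_kind`` where
``member_kind`` is ``formula`` or ``feature``.  A set must be keyed
entirely one way or the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .data_model import AnnotationTable, InputError, IntensityMatrix

logger = logging.getLogger(__name__)

SOURCE_TAGS = ("pathway", "molecular_family", "mass2motif", "custom")


@dataclass
class MetaboliteSet:
    set_id: str
    name: str
    members: tuple[str, ...]
    member_kind: str  # "formula" | "feature"
    source: str = "custom"

    def __post_init__(self) -> None:
        if self.member_kind not in ("formula", "feature"):
            raise InputError(
                f"set {self.set_id!r}: member_kind must be formula|feature"
            )
        members = tuple(str(m).strip() for m in self.members)
        if not members:
            raise InputError(f"set {self.set_id!r} has no members")
        if len(set(members)) != len(members):
            raise InputError(f"set {self.set_id!r} has duplicate members")
        self.members = members

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SetDatabase:
    """Collection of metabolite sets with load provenance."""

    sets: dict[str, MetaboliteSet]
    source_name: str = "custom"
    version: str = ""
    min_set_size: int = 1
    n_filtered: int = 0

    def __post_init__(self) -> None:
        # deterministic iteration order by set_id
        self.sets = {sid: self.sets[sid] for sid in sorted(self.sets)}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> MetaboliteSet:
        return self.sets[set_id]


def load_sets(
    path,
    source_tag: str = "custom",
    min_set_size: int = 2,
    delimiter: str = ",",
    version: str = "",
) -> SetDatabase:
    """Load set definitions from a flat file.

    Sets smaller than ``min_set_size`` are dropped and counted in the
    database metadata.  Duplicate set ids and mixed member kinds within a
    set are errors; malformed rows are reported with their line numbers.
    """
    if min_set_size < 1:
        raise InputError("min_set_size must be >= 1")
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = ("set_id", "set_name", "member", "member_kind")
    for col in required:
        if col not in df.columns:
            raise InputError(f"set file {path} missing column {col!r}")
    bad = df.index[df[list(required)].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise InputError(f"malformed rows in {path} at lines {lines}")
    return build_database(
        df, source_tag=source_tag, min_set_size=min_set_size, version=version
    )


def build_database(
    records: pd.DataFrame,
    source_tag: str = "custom",
    min_set_size: int = 2,
    version: str = "",
) -> SetDatabase:
    """Assemble a :class:`SetDatabase` from long-format member records."""
    sets: dict[str, MetaboliteSet] = {}
    n_filtered = 0
    grouped = records.groupby("set_id", sort=True)
    for set_id, grp in grouped:
        kinds = set(grp["member_kind"])
        if len(kinds) != 1:
            raise InputError(f"set {set_id!r} mixes member kinds {sorted(kinds)}")
        names = set(grp["set_name"])
        members = list(dict.fromkeys(m.strip() for m in grp["member"]))
        if len(members) < len(grp):
            raise InputError(f"set {set_id!r} has duplicate members")
        ms = MetaboliteSet(
            set_id=str(set_id),
            name=sorted(names)[0],
            members=tuple(members),
            member_kind=kinds.pop(),
            source=source_tag,
        )
        if ms.size < min_set_size:
            n_filtered += 1
            continue
        if set_id in sets:  # pragma: no cover - groupby precludes this
            raise InputError(f"duplicate set_id {set_id!r}")
        sets[str(set_id)] = ms
    return SetDatabase(
        sets,
        source_name=source_tag,
        version=version,
        min_set_size=min_set_size,
        n_filtered=n_filtered,
    )


def database_from_sets(sets: Iterable[MetaboliteSet], **kw) -> SetDatabase:
    sets = list(sets)
    d = {s.set_id: s for s in sets}
    if len(d) != len(sets):
        raise InputError("duplicate set_id")
    return SetDatabase(d, **kw)


def map_database(
    db: SetDatabase,
    ann: AnnotationTable | None,
    m: IntensityMatrix,
) -> dict[str, list[str]]:
    """Resolve every set to the feature ids it covers in the matrix.

    Formula-keyed sets resolve through the annotation table (every feature
    sharing a member formula is included); feature-keyed sets resolve
    directly, restricted to features present in the matrix.  Empty mappings
    are data, not errors — downstream code reports them as unscoreable.
    """
    present = set(m.values.index)
    order = {fid: i for i, fid in enumerate(m.values.index)}
    formula_features: dict[str, list[str]] = {}
    if ann is not None:
        for fid, formula in ann.formula_of.items():
            if fid in present:
                formula_features.setdefault(formula, []).append(fid)
    mapping: dict[str, list[str]] = {}
    for ms in db:
        if ms.member_kind == "formula":
            feats: list[str] = []
            for formula in ms.members:
                feats.extend(formula_features.get(formula, ()))
        else:
            feats = [f for f in ms.members if f in present]
        # deterministic: matrix row order, no duplicates
        mapping[ms.set_id] = sorted(set(feats), key=order.__getitem__)
    return mapping


def coverage(
    db: SetDatabase,
    mapping: Mapping[str, list[str]],
    ann: AnnotationTable | None = None,
) -> dict[str, float]:
    """Fraction of each set's declared members hit by >=1 mapped feature.

    For formula-keyed sets the unit is the member formula (several mapped
    features sharing a formula count once); feature-keyed sets count
    members directly.
    """
    formula_of = ann.formula_of if ann is not None else {}
    out: dict[str, float] = {}
    for ms in db:
        feats = mapping.get(ms.set_id, [])
        if ms.member_kind == "feature":
            hit = len(set(feats) & set(ms.members))
        else:
            covered = {formula_of.get(f) for f in feats}
            hit = len(covered & set(ms.members))
        out[ms.set_id] = hit / ms.size
    return out


def gnps_to_set_records(
    membership: pd.DataFrame,
    set_col: str,
    feature_col: str,
    source_tag: str = "molecular_family",
) -> pd.DataFrame:
    """Adapter: GNPS-style cluster/motif membership table -> set records.

    ``membership`` needs one row per (set, feature) pair, e.g. the
    componentindex/cluster-index columns of an FBMN node table or a
    motif-feature table from MS2LDA.  Returns a long-format DataFrame
    consumable by :func:`build_database` (feature-keyed sets).
    """
    df = membership[[set_col, feature_col]].dropna().astype(str)
    out = pd.DataFrame(
        {
            "set_id": df[set_col],
            "set_name": df[set_col],
            "member": df[feature_col],
            "member_kind": "feature",
        }
    )
    return out.drop_duplicates(["set_id", "member"]).reset_index(drop=True)
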