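"""Feature tables, taxonomy lineages, sample metadata and comparison designs.

The three tabular inputs are plain TSV:

* feature table — first header cell ``feature_id``, remaining header cells
  sample ids, one row per feature (taxon, OTU, KO or pathway);
* sample metadata — required columns ``sample_id``, ``group``, ``project``,
  optional ``phenotype``, ``intervention``, ``role``;
* taxonomy — ``feature_id<TAB>lineage`` with rank-prefixed lineage strings
  in either the QIIME/greengenes (``k__X; p__Y``) or the MetaPhlAn
  (``k__X|p__Y``) dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip(RANKS, ("k", "p", "c", "o", "f", "g", "s")))

UNCLASSIFIED = "Unclassified"


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class FeatureTable:
    """Features x samples abundance matrix.

    ``data`` holds features on rows and samples on columns. ``units`` is
    ``"counts"`` for raw library counts and ``"relative"`` for proportions
    (each column summing to at most 1). ``rank`` optionally records the
    taxonomic rank the rows live at after collapsing.
    """

    data: pd.DataFrame
    units: str = "counts"
    rank: str | None = None

    def __post_init__(self) -> None:
        if self.units not in ("counts", "relative"):
            raise ValidationError(f"unknown units {self.units!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            raise ValidationError("negative abundance values")
        if self.units == "relative":
            sums = values.sum(axis=0)
            if (sums > 1 + 1e-6).any():
                bad = self.data.columns[sums > 1 + 1e-6].tolist()
                raise ValidationError(
                    f"relative-abundance columns sum above 1: {bad}"
                )
        if self.rank is not None and self.rank not in RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, units: str | None = None) -> "FeatureTable":
        return FeatureTable(data=data, units=units or self.units, rank=self.rank)

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return replace(self, data=self.data.loc[:, ids])


@dataclass
class Lineage:
    """Ordered seven-rank lineage; empty string marks an unannotated level."""

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(RANKS):
            raise ValidationError(
                f"lineage needs {len(RANKS)} levels, got {len(self.levels)}"
            )

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        return self.levels[RANKS.index(rank)]

    def format(self, sep: str = "; ") -> str:
        return sep.join(
            f"{RANK_PREFIXES[r]}__{v}" for r, v in zip(RANKS, self.levels)
        )


def parse_lineage(text: str) -> Lineage:
    """Parse a rank-prefixed lineage string in either common dialect.

    Accepts ``k__Bacteria; p__Firmicutes; ...`` (QIIME/greengenes) and
    ``k__Bacteria|p__Firmicutes|...`` (MetaPhlAn); the separator is
    auto-detected. Missing trailing levels are filled with empty strings.
    """
    sep = "|" if "|" in text else ";"
    levels = [""] * len(RANKS)
    for chunk in text.split(sep):
        chunk = chunk.strip()
        if not chunk:
            continue
        if len(chunk) >= 3 and chunk[1:3] == "__":
            prefix, value = chunk[0], chunk[3:]
        else:
            raise ValidationError(f"unparseable lineage chunk {chunk!r}")
        for rank, pfx in RANK_PREFIXES.items():
            if prefix == pfx:
                levels[RANKS.index(rank)] = value.strip()
                break
        else:
            raise ValidationError(f"unknown rank prefix {prefix!r} in {text!r}")
    return Lineage(tuple(levels))


@dataclass
class TaxonomyMap:
    """feature_id -> :class:`Lineage`."""

    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def get(self, feature_id: str) -> Lineage | None:
        return self.lineages.get(feature_id)

    def level(self, feature_id: str, rank: str) -> str:
        lin = self.lineages.get(feature_id)
        return lin.at(rank) if lin is not None else ""


@dataclass
class SampleMetadata:
    """Per-sample labels defining groups, projects and strata.

    Backed by a DataFrame indexed by sample id with columns ``group``,
    ``project``, ``phenotype``, ``intervention``, ``role``.
    """

    frame: pd.DataFrame

    REQUIRED = ("group", "project")
    OPTIONAL = ("phenotype", "intervention", "role")

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in self.frame.columns:
                self.frame[col] = ""
        self.frame = self.frame.fillna("")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def samples_in_group(self, project: str, group: str) -> list[str]:
        mask = (self.frame["project"] == project) & (self.frame["group"] == group)
        return self.frame.index[mask].tolist()

    def groups_for(self, samples: Iterable[str]) -> pd.Series:
        return self.frame.loc[list(samples), "group"]

    def projects(self) -> list[str]:
        return sorted(self.frame["project"].unique().tolist())

    def align_table(self, table: FeatureTable) -> tuple[FeatureTable, "SampleMetadata"]:
        """Intersect table samples with metadata samples (case-sensitive).

        Samples absent from the metadata are dropped from the table with a
        logged warning rather than raising.
        """
        known = [s for s in table.sample_ids if s in self.frame.index]
        dropped = [s for s in table.sample_ids if s not in self.frame.index]
        if dropped:
            logger.warning(
                "dropping %d samples absent from metadata: %s", len(dropped), dropped
            )
        if not known:
            raise ValidationError("no table sample is present in the metadata")
        return table.subset_samples(known), SampleMetadata(self.frame.loc[known].copy())


@dataclass(frozen=True)
class ComparisonDesign:
    """One case-vs-control contrast within one project."""

    comparison_id: str
    project: str
    case_group: str
    control_group: str
    phenotype: str = ""
    intervention: str = ""

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ValidationError("case and control groups must differ")


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(
    path: str | Path,
    units: str = "counts",
    extract_taxonomy: bool = False,
) -> FeatureTable | tuple[FeatureTable, TaxonomyMap]:
    """Read a features x samples TSV.

    First column holds feature ids; the header row holds sample ids. When
    ``extract_taxonomy`` is true (MetaPhlAn-style tables whose id column is
    a lineage string), lineages are parsed out of the ids, the deepest
    annotated level becomes the feature id, and a :class:`TaxonomyMap` is
    returned alongside the table.
    """
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric abundance value in {path}: {exc}") from exc
    if not extract_taxonomy:
        return FeatureTable(frame, units=units)

    taxonomy = TaxonomyMap()
    new_ids = []
    for raw in frame.index:
        lineage = parse_lineage(raw)
        annotated = [v for v in lineage.levels if v]
        fid = annotated[-1] if annotated else raw
        taxonomy.lineages[fid] = lineage
        new_ids.append(fid)
    frame.index = pd.Index(new_ids, name="feature_id")
    return FeatureTable(frame, units=units), taxonomy


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError("taxonomy TSV needs feature_id and lineage columns")
    tax = TaxonomyMap()
    for fid, lineage in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        tax.lineages[str(fid)] = parse_lineage(str(lineage))
    return tax


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = [(fid, lin.format()) for fid, lin in tax.lineages.items()]
    pd.DataFrame(rows, columns=["feature_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if "sample_id" not in frame.columns:
        raise ValidationError("metadata TSV needs a sample_id column")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomic collapsing and design enumeration


def collapse_to_rank(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum features sharing a lineage value at ``rank``.

    Features with an empty (or missing) annotation at the rank are pooled
    into a single ``Unclassified`` row. Column totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    labels = [
        tax.level(fid, rank) or UNCLASSIFIED for fid in table.feature_ids
    ]
    collapsed = table.data.groupby(pd.Index(labels, name="feature_id"), sort=True).sum()
    return FeatureTable(collapsed, units=table.units, rank=rank)


def enumerate_comparisons(
    meta: SampleMetadata, case_label: str, control_label: str
) -> list[ComparisonDesign]:
    """One case-vs-control design per project containing both group labels.

    Projects are visited in sorted order so the result is deterministic;
    an empty list (with a warning) is returned when no project qualifies.
    """
    designs: list[ComparisonDesign] = []
    for project in meta.projects():
        sub = meta.frame[meta.frame["project"] == project]
        groups = set(sub["group"])
        if case_label not in groups or control_label not in groups:
            continue
        pheno = _single_label(sub, "phenotype")
        interv = _single_label(sub, "intervention")
        designs.append(
            ComparisonDesign(
                comparison_id=f"{project}:{case_label}_vs_{control_label}",
                project=project,
                case_group=case_label,
                control_group=control_label,
                phenotype=pheno,
                intervention=interv,
            )
        )
    if not designs:
        logger.warning(
            "no project contains both groups %r and %r", case_label, control_label
        )
    return designs


def enumerate_all_case_control(meta: SampleMetadata) -> list[ComparisonDesign]:
    """Designs from explicit case/control roles, one per project.

    Projects whose metadata labels samples with ``role`` in
    {case, control} yield one design per (case group, control group) pair
    present; projects without role labels are skipped.
    """
    designs: list[ComparisonDesign] = []
    for project in meta.projects():
        sub = meta.frame[meta.frame["project"] == project]
        cases = sorted(sub.loc[sub["role"] == "case", "group"].unique())
        controls = sorted(sub.loc[sub["role"] == "control", "group"].unique())
        for case in cases:
            for control in controls:
                if case == control:
                    continue
                designs.append(
                    ComparisonDesign(
                        comparison_id=f"{project}:{case}_vs_{control}",
                        project=project,
                        case_group=case,
                        control_group=control,
                        phenotype=_single_label(sub, "phenotype"),
                        intervention=_single_label(sub, "intervention"),
                    )
                )
    return designs


def _single_label(sub: pd.DataFrame, column: str) -> str:
    vals = [v for v in sub[column].unique() if v]
    return vals[0] if len(vals) == 1 else ""


def design_samples(
    design: ComparisonDesign, meta: SampleMetadata
) -> tuple[list[str], list[str]]:
    """(case sample ids, control sample ids) for a design; each side >= 2."""
    case = meta.samples_in_group(design.project, design.case_group)
    control = meta.samples_in_group(design.project, design.control_group)
    if len(case) < 2 or len(control) < 2:
        raise ValidationError(
            f"{design.comparison_id}: each side needs >=2 samples "
            f"(case {len(case)}, control {len(control)})"
        )
    return case, control
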