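"""Core domain containers and tabular I/O.

The pipeline works on three aligned tables: a samples x genera abundance
matrix (counts or relative abundances), per-sample metadata carrying the
colorectal disease label (CRC, AA or NC) plus clinical covariates, and a
per-genus trait annotation table (gram stain, oxygen requirement,
beneficial/harmful role, CRC-association direction).  Everything is stored
in plain pandas objects wrapped with validated dataclasses so downstream
stages can rely on the invariants instead of re-checking them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DISEASE_LABELS = ("CRC", "AA", "NC")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

GRAM_VALUES = frozenset({"positive", "negative", "unknown"})
OXYGEN_VALUES = frozenset(
    {"obligate_anaerobe", "facultative_anaerobe", "aerobe", "unknown"}
)
ROLE_VALUES = frozenset({"beneficial", "harmful", "neutral", "unknown"})
CRC_ASSOC_VALUES = frozenset({"positive", "negative", "related", "none"})
BIOFILM_VALUES = frozenset({"yes", "no", "unknown"})

UNKNOWN_TRAITS = {
    "gram": "unknown",
    "oxygen": "unknown",
    "role": "unknown",
    "crc_assoc": "none",
    "biofilm": "unknown",
}


class FormatError(ValueError):
    """Malformed input file (duplicate ids, ragged rows, bad header)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant (negative value, ...)."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited lineage string into rank -> name.

    Accepts both greengenes-style prefixed fields (``k__Bacteria;p__...``)
    and bare names (``Bacteria;Firmicutes;...``); names are stored bare.
    Missing trailing ranks are left empty.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    out: dict[str, str] = {}
    for rank, part in zip(TAXONOMY_RANKS, parts):
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        out[rank] = part
    for rank in TAXONOMY_RANKS[len(parts):]:
        out[rank] = ""
    return out


def format_lineage(ranks: Mapping[str, str]) -> str:
    return ";".join(ranks.get(r, "") for r in TAXONOMY_RANKS)


@dataclass
class AbundanceTable:
    """Samples x taxa non-negative abundance matrix with taxonomy.

    ``data`` has sample ids as the index and taxon (genus) ids as columns.
    ``taxonomy`` maps each taxon id to its ordered ranks (domain .. genus);
    taxa without a known lineage map to empty rank names.  ``is_relative``
    marks tables whose rows sum to one (total-sum scaling applied).
    """

    data: pd.DataFrame
    taxonomy: dict[str, dict[str, str]] = field(default_factory=dict)
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.data.index = self.data.index.rename("sample_id")
        self.data.columns = self.data.columns.rename(None)
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate taxon ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                "negative abundance at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(
                    f"is_relative set but row {bad!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - 1.0))]:.6g}"
                )
        # taxonomy keys must cover all taxa; fill unknowns rather than fail
        for taxon in self.data.columns:
            if taxon not in self.taxonomy:
                self.taxonomy[taxon] = {r: "" for r in TAXONOMY_RANKS}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.data.copy(),
            {t: dict(r) for t, r in self.taxonomy.items()},
            self.is_relative,
        )

    def phylum_of(self, taxon: str) -> str:
        return self.taxonomy.get(taxon, {}).get("phylum", "")


@dataclass
class SampleMetadata:
    """One sample's disease label and clinical covariates."""

    sample_id: str
    disease: str
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.disease not in DISEASE_LABELS:
            raise ValidationError(
                f"disease for {self.sample_id!r} must be one of "
                f"{DISEASE_LABELS}, got {self.disease!r}"
            )


def metadata_frame(meta: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Collect SampleMetadata records into a DataFrame indexed by sample id."""
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in metadata")
    rows = [{"disease": m.disease, **m.covariates} for m in meta]
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))


class TaxonTraitTable:
    """Per-genus trait annotations; lookups of unlisted taxa return unknowns.

    Fields per taxon: gram (positive/negative/unknown), oxygen
    (obligate_anaerobe/facultative_anaerobe/aerobe/unknown), role
    (beneficial/harmful/neutral/unknown), crc_assoc
    (positive/negative/related/none), biofilm (yes/no/unknown).
    """

    _FIELDS = {
        "gram": GRAM_VALUES,
        "oxygen": OXYGEN_VALUES,
        "role": ROLE_VALUES,
        "crc_assoc": CRC_ASSOC_VALUES,
        "biofilm": BIOFILM_VALUES,
    }

    def __init__(self, records: Mapping[str, Mapping[str, str]] | None = None):
        self._records: dict[str, dict[str, str]] = {}
        for taxon, rec in (records or {}).items():
            self._records[taxon] = self._validate(taxon, rec)

    def _validate(self, taxon: str, rec: Mapping[str, str]) -> dict[str, str]:
        out = dict(UNKNOWN_TRAITS)
        for key, value in rec.items():
            if key not in self._FIELDS:
                raise ValidationError(f"unknown trait field {key!r} for {taxon!r}")
            if value not in self._FIELDS[key]:
                raise ValidationError(
                    f"trait {key}={value!r} for {taxon!r} not in {sorted(self._FIELDS[key])}"
                )
            out[key] = value
        return out

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._records

    def __len__(self) -> int:
        return len(self._records)

    @property
    def taxa(self) -> list[str]:
        return list(self._records)

    def lookup(self, taxon: str) -> dict[str, str]:
        return dict(self._records.get(taxon, UNKNOWN_TRAITS))

    def taxa_with(self, field_name: str, values: str | Iterable[str]) -> set[str]:
        if isinstance(values, str):
            values = {values}
        values = set(values)
        return {t for t, rec in self._records.items() if rec[field_name] in values}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self._records, orient="index").rename_axis(
            "taxon_id"
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonTraitTable":
        return cls(frame.to_dict(orient="index"))


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance(
    path,
    orientation: str = "samples_rows",
    sep: str | None = None,
    taxonomy_path=None,
) -> AbundanceTable:
    """Read a genus abundance table from TSV/CSV.

    ``orientation`` is resolved explicitly: ``samples_rows`` (default) or
    ``samples_cols``; it is never guessed from the data.  An optional
    two-column taxonomy file maps taxon ids to semicolon-delimited lineages.
    """
    if orientation not in ("samples_rows", "samples_cols"):
        raise ValueError(f"orientation must be samples_rows|samples_cols, got {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if orientation == "samples_cols":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance body in {path}: {exc}") from exc

    taxonomy: dict[str, dict[str, str]] = {}
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep=sep, index_col=0, header=0)
        lineage_col = tax.columns[0]
        taxonomy = {
            str(taxon): parse_lineage(lineage)
            for taxon, lineage in tax[lineage_col].items()
        }

    sums = frame.to_numpy(dtype=float).sum(axis=1)
    is_relative = bool(len(frame) and np.allclose(sums, 1.0, atol=1e-9))
    return AbundanceTable(frame, taxonomy, is_relative=is_relative)


def write_abundance(table: AbundanceTable, path, sep: str = "\t", taxonomy_path=None) -> None:
    frame = table.data.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep, float_format="%.10g")
    if taxonomy_path is not None:
        lines = pd.DataFrame(
            {"lineage": [format_lineage(table.taxonomy[t]) for t in table.taxon_ids]},
            index=pd.Index(table.taxon_ids, name="taxon_id"),
        )
        lines.to_csv(taxonomy_path, sep=sep)


def read_metadata(path, sep: str | None = None) -> list[SampleMetadata]:
    if sep is None:
        sep = "\t" if str(path).endswith(".tsv") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if "disease" not in frame.columns:
        raise FormatError(f"metadata {path} lacks a 'disease' column")
    out = []
    for sample_id, row in frame.iterrows():
        cov = {k: v for k, v in row.items() if k != "disease"}
        out.append(SampleMetadata(str(sample_id), str(row["disease"]), cov))
    return out


def write_metadata(meta: Sequence[SampleMetadata], path, sep: str = ",") -> None:
    metadata_frame(meta).to_csv(path, sep=sep)


def read_traits(path, sep: str | None = None) -> TaxonTraitTable:
    if sep is None:
        sep = "\t" if str(path).endswith(".tsv") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0).astype(str)
    return TaxonTraitTable.from_frame(frame)


def write_traits(traits: TaxonTraitTable, path, sep: str = ",") -> None:
    traits.to_frame().to_csv(path, sep=sep)


def join_metadata(table: AbundanceTable, meta: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Align metadata to an abundance table; mismatched ids are an error.

    A silent inner join would drop samples and corrupt downstream disease
    ratios, so any asymmetric difference of sample ids raises.
    """
    frame = metadata_frame(meta)
    missing = set(table.sample_ids) - set(frame.index)
    extra = set(frame.index) - set(table.sample_ids)
    if missing or extra:
        raise ValidationError(
            f"metadata/abundance sample mismatch: missing={sorted(missing)[:5]} "
            f"extra={sorted(extra)[:5]}"
        )
    return frame.loc[table.sample_ids]


# ---------------------------------------------------------------------------
# basic abundance operations


def normalize_tss(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: divide each sample row by its total.

    Idempotent; rows with zero total are degenerate samples and raise.
    """
    values = table.values()
    sums = values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise ValidationError(f"all-zero samples cannot be normalized: {bad}")
    frame = pd.DataFrame(
        values / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(
        frame, {t: dict(r) for t, r in table.taxonomy.items()}, is_relative=True
    )


def top_taxa(
    table: AbundanceTable,
    n: int,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank taxa by mean relative abundance within each group.

    Returns a tidy frame (group, taxon, mean_fraction, rank) whose last row
    per group aggregates the remainder as ``Other``; fractions per group sum
    to one.  Ties are broken by taxon id so output is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = table if table.is_relative else normalize_tss(table)
    labels = pd.Series(
        ["all"] * rel.shape[0] if groups is None else list(groups),
        index=rel.data.index,
    )
    records = []
    for group, sub in rel.data.groupby(labels, sort=True):
        means = sub.mean(axis=0)
        order = sorted(means.index, key=lambda t: (-means[t], t))
        kept = order[: min(n, len(order))]
        for rank, taxon in enumerate(kept, start=1):
            records.append(
                {"group": group, "taxon": taxon, "mean_fraction": means[taxon], "rank": rank}
            )
        other = float(means.drop(kept).sum())
        records.append(
            {"group": group, "taxon": "Other", "mean_fraction": other, "rank": len(kept) + 1}
        )
    return pd.DataFrame.from_records(records)


def as_dataclass_dict(obj) -> dict:
    return dataclasses.asdict(obj)
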