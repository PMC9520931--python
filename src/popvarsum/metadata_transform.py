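"""Per-donor metadata: multimap container, ethnicity derivation, GDM meta files.

Source metadata arrives as delimited tables keyed by donor id.  Each donor's
rows from every table are merged into a single multimap (the same key may
appear several times, e.g. one ``platform`` entry per sequencing run), and a
few interoperability attributes are derived — chiefly ``ethnicity``, which is
assigned from the 1KGP-style population code so that cohorts from different
sources can be selected with a common vocabulary.

The on-disk form is the GDM metadata file: a two-column TSV of
``key<TAB>value`` lines, one per multimap entry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import MetadataConflictError, UnknownPopulationError

__all__ = [
    "EthnicityRow",
    "ethnicity_map",
    "map_population_to_ethnicity",
    "DonorMetadata",
    "build_donor_metadata",
    "write_meta_file",
    "read_meta_file",
]


class EthnicityRow(NamedTuple):
    population_name: str
    in_diaspora: bool
    super_population: str
    ethnicity: str


def _load_ethnicity_map() -> dict[str, EthnicityRow]:
    text = (
        importlib.resources.files("popvarsum.data") / "population_ethnicity.tsv"
    ).read_text()
    rows = {}
    lines = text.strip().splitlines()
    for line in lines[1:]:
        code, name, diaspora, superpop, eth = line.split("\t")
        rows[code.upper()] = EthnicityRow(name, diaspora == "yes", superpop, eth)
    return rows


_ETHNICITY_MAP: dict[str, EthnicityRow] | None = None


def ethnicity_map() -> dict[str, EthnicityRow]:
    """The full population-code table: code -> (name, diaspora, super
    population, ethnicity)."""
    global _ETHNICITY_MAP
    if _ETHNICITY_MAP is None:
        _ETHNICITY_MAP = _load_ethnicity_map()
    return _ETHNICITY_MAP


def map_population_to_ethnicity(pop_code: str) -> tuple[str, str, bool]:
    """Resolve a population code (case-insensitive) to
    ``(ethnicity, super_population, in_diaspora)``."""
    table = ethnicity_map()
    row = table.get(str(pop_code).upper())
    if row is None:
        raise UnknownPopulationError(
            f"unknown population code {pop_code!r}; known codes: "
            + ", ".join(sorted(table))
        )
    return row.ethnicity, row.super_population, row.in_diaspora


@dataclass
class DonorMetadata:
    """Multimap of metadata entries for one donor.

    ``entries`` preserves repeated keys; ordering is normalized to
    (key, value) sort order so that equality and file round-trips are
    well defined.
    """

    donor_id: str
    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, key: str, value) -> None:
        self.entries.append((str(key), str(value)))

    def get(self, key: str) -> list[str]:
        return [v for k, v in self.entries if k == key]

    def single(self, key: str, default: str | None = None) -> str | None:
        vals = sorted(set(self.get(key)))
        if not vals:
            return default
        if len(vals) > 1:
            raise MetadataConflictError(
                f"attribute {key!r} of donor {self.donor_id} has multiple values: {vals}"
            )
        return vals[0]

    def sorted_entries(self) -> list[tuple[str, str]]:
        return sorted(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DonorMetadata)
            and self.donor_id == other.donor_id
            and self.sorted_entries() == other.sorted_entries()
        )


def _normalize_value(key: str, value: str) -> str:
    # Donor ids and population codes keep their case; everything else is
    # lower-cased so the query layer can compare values uniformly.
    if key in ("donor_id", "population", "super_population"):
        return str(value)
    return str(value).lower()


def build_donor_metadata(
    metadata_tables: Iterable[pd.DataFrame],
    donor_id: str,
    technical: dict | None = None,
    donor_column: str = "donor_id",
    default_health_status: str = "true",
) -> DonorMetadata:
    """Merge every table's rows for one donor into a DonorMetadata multimap.

    Keys are lower-cased column names.  A key holding different values in
    two tables raises :class:`MetadataConflictError` (identical values are
    deduplicated; genuinely multi-valued keys must come from repeated rows
    of a single table, which are preserved as repeated entries).  The
    ``ethnicity`` and ``super_population`` attributes are derived from
    ``population`` when present; ``health_status`` defaults to the
    control-cohort value when no table provides it.  ``technical`` entries
    are appended under ``manually_curated__``-prefixed keys.
    """
    meta = DonorMetadata(donor_id=donor_id)
    seen_in_any = False
    per_key_sources: dict[str, dict[int, set[str]]] = {}
    for t_idx, table in enumerate(metadata_tables):
        if donor_column not in table.columns:
            continue
        rows = table[table[donor_column].astype(str) == str(donor_id)]
        if rows.empty:
            continue
        seen_in_any = True
        for _, row in rows.iterrows():
            for col in table.columns:
                if col == donor_column or pd.isna(row[col]):
                    continue
                key = str(col).strip().lower()
                value = _normalize_value(key, row[col])
                per_key_sources.setdefault(key, {}).setdefault(t_idx, set()).add(value)
    if not seen_in_any:
        raise MetadataConflictError(
            f"donor {donor_id!r} appears in no metadata table"
        )
    for key, by_table in per_key_sources.items():
        value_sets = list(by_table.values())
        if len(by_table) > 1 and len(set(frozenset(s) for s in value_sets)) > 1:
            raise MetadataConflictError(
                f"attribute {key!r} of donor {donor_id} conflicts across tables: "
                + "; ".join(sorted(str(sorted(s)) for s in value_sets))
            )
        for value in sorted(value_sets[0]):
            meta.add(key, value)

    pops = meta.get("population")
    if pops:
        ethnicity, superpop, in_diaspora = map_population_to_ethnicity(pops[0])
        if not meta.get("ethnicity"):
            meta.add("ethnicity", ethnicity.lower())
        if not meta.get("super_population"):
            meta.add("super_population", superpop)
        if not meta.get("in_diaspora"):
            meta.add("in_diaspora", "yes" if in_diaspora else "no")
    if not meta.get("health_status"):
        meta.add("health_status", default_health_status)
    for key, value in (technical or {}).items():
        k = str(key)
        if not k.startswith("manually_curated__"):
            k = "manually_curated__" + k
        meta.add(k, _normalize_value(k, value))
    meta.entries = meta.sorted_entries()
    return meta


def write_meta_file(meta: DonorMetadata, path) -> None:
    """Write a GDM metadata file: ``key<TAB>value`` lines sorted by key then
    value; repeated keys become repeated lines."""
    with open(path, "w") as fh:
        for key, value in meta.sorted_entries():
            fh.write(f"{key}\t{value}\n")


def read_meta_file(path, donor_id: str | None = None) -> DonorMetadata:
    """Reload a GDM metadata file written by :func:`write_meta_file`.

    The donor id defaults to the file stem (``<donor>.gdm.meta``).
    """
    import os

    if donor_id is None:
        base = os.path.basename(str(path))
        donor_id = base.split(".gdm")[0]
    meta = DonorMetadata(donor_id=donor_id)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("\t")
            meta.add(key, value)
    meta.entries = meta.sorted_entries()
    return meta
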