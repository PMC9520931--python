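"""Population selection, grouping, variant frequency, ranking and export.

A *population* is the donor set satisfying a :class:`PopulationFilter`:
metadata constraints (attribute -> allowed values) combined with
region-data constraints — variants that must be present or absent, pairs
or lists of variants that must sit on the same or on opposite chromosome
copies, or the presence of any variant in a region.  The filter is
evaluated per eligible source and the per-source populations are unioned
with duplicate elimination.

Frequencies follow the allele-counting contract: a donor carries a
variant on 0, 1 or 2 chromosome copies; the cohort occurrence is the sum
of per-donor occurrences, and the denominator is the total number of
chromosome copies the cohort carries at the locus, which on the sex
chromosomes depends on donor gender and on the pseudoautosomal intervals
of the assembly in use (see :mod:`popvarsum.assembly`).

Every answer that reports donor counts passes through the privacy guard,
which refuses responses exposing a group smaller than the configured
minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assembly import AssemblyModel, chrom_sort_key, normalize_chrom
from .datastore import (
    CAP_DIFF_COPY,
    CAP_IN_REGION,
    CAP_SAME_COPY,
    CAP_VARIANT_ID,
    CAP_WITH,
    CAP_WITHOUT,
    VariantStore,
)
from .errors import (
    PopvarsumError,
    PrivacyRefusal,
    UnknownAttributeError,
    UnresolvableVariantError,
)
from .metadata_transform import DonorMetadata, write_meta_file

__all__ = [
    "VariantSpec",
    "RegionSpec",
    "PopulationFilter",
    "FrequencyRow",
    "GroupCountCube",
    "QueryEngine",
    "privacy_guard",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSpec:
    """One variant, addressed by coordinates, by external id, or by gene
    name (the latter meaning: any variant in the gene's region)."""

    chrom: str | None = None
    left: int | None = None
    ref: str | None = None
    alt: str | None = None
    id: str | None = None
    gene: str | None = None

    def __post_init__(self):
        by_coords = self.chrom is not None and self.left is not None
        modes = sum([by_coords, self.id is not None, self.gene is not None])
        if modes != 1:
            raise PopvarsumError(
                "VariantSpec needs exactly one addressing mode: "
                "coordinates (chrom, left, ref, alt), id, or gene"
            )
        if by_coords and (self.ref is None or self.alt is None):
            raise PopvarsumError("coordinate-addressed VariantSpec needs ref and alt")

    @property
    def key(self):
        return (normalize_chrom(self.chrom), self.left, self.ref, self.alt)


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, either explicit (0-based half-open) or a gene name."""

    chrom: str | None = None
    start: int | None = None
    stop: int | None = None
    gene: str | None = None

    def __post_init__(self):
        explicit = self.chrom is not None and self.start is not None and self.stop is not None
        if explicit == (self.gene is not None):
            raise PopvarsumError("RegionSpec is either (chrom, start, stop) or a gene name")
        if explicit and not self.start < self.stop:
            raise PopvarsumError(f"empty region [{self.start}, {self.stop})")


@dataclass(frozen=True)
class PopulationFilter:
    """Conjunction of metadata constraints and variant/region constraints."""

    meta: dict = field(default_factory=dict)
    with_variants: tuple = ()
    without_variants: tuple = ()
    on_same_chrom_copy: tuple = ()
    on_diff_chrom_copy: tuple | None = None
    in_region: RegionSpec | None = None
    assembly: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "with_variants", tuple(self.with_variants))
        object.__setattr__(self, "without_variants", tuple(self.without_variants))
        object.__setattr__(self, "on_same_chrom_copy", tuple(self.on_same_chrom_copy))
        if self.on_diff_chrom_copy is not None:
            pair = tuple(self.on_diff_chrom_copy)
            if len(pair) != 2:
                raise PopvarsumError("on_diff_chrom_copy takes exactly two variants")
            object.__setattr__(self, "on_diff_chrom_copy", pair)
        overlap = set(self.with_variants) & set(self.without_variants)
        if overlap:
            raise PopvarsumError(f"variants both required and excluded: {overlap}")

    def required_capabilities(self) -> set[str]:
        caps = {f"meta:{a}" for a in self.meta}
        specs = list(self.with_variants) + list(self.without_variants)
        specs += list(self.on_same_chrom_copy) + list(self.on_diff_chrom_copy or ())
        if self.with_variants:
            caps.add(CAP_WITH)
        if self.without_variants:
            caps.add(CAP_WITHOUT)
        if self.on_same_chrom_copy:
            caps.add(CAP_SAME_COPY)
        if self.on_diff_chrom_copy:
            caps.add(CAP_DIFF_COPY)
        if self.in_region is not None or any(s.gene for s in specs):
            caps.add(CAP_IN_REGION)
        if any(s.id for s in specs):
            caps.add(CAP_VARIANT_ID)
        return caps


@dataclass(frozen=True)
class FrequencyRow:
    """One group of a variant-frequency cube."""

    key: tuple
    occurrence: int
    population_size: int
    positive_donors: int
    total_alleles: int
    frequency: float | None

    def to_dict(self, group_by):
        return {
            "key": list(self.key),
            "group_by": list(group_by),
            "OCCURRENCE_OF_TARGET_VARIANT": self.occurrence,
            "POPULATION_SIZE": self.population_size,
            "positive_donors": self.positive_donors,
            "total_alleles": self.total_alleles,
            "frequency": self.frequency,
        }


@dataclass(frozen=True)
class GroupCountCube:
    """Donor counts per combination of metadata attribute values."""

    group_by: tuple
    rows: tuple  # of (key tuple, count)

    def as_dict(self) -> dict:
        return {tuple(k): c for k, c in self.rows}

    def to_json_dict(self) -> dict:
        return {
            "group_by": list(self.group_by),
            "rows": [{"key": list(k), "count": c} for k, c in self.rows],
        }


def privacy_guard(result, min_donors: int):
    """Refuse any response reporting a positive donor count below
    ``min_donors``; otherwise return the result unchanged."""
    counts = []
    if isinstance(result, GroupCountCube):
        counts = [c for _, c in result.rows]
    elif isinstance(result, (list, tuple)):
        for item in result:
            if isinstance(item, FrequencyRow):
                counts.append(item.population_size)
            elif isinstance(item, dict):
                counts.extend(
                    v for k, v in item.items()
                    if k in ("donor_count", "POPULATION_SIZE", "population_size")
                )
            elif isinstance(item, int):
                counts.append(item)
    elif isinstance(result, int):
        counts = [result]
    for c in counts:
        if 0 < c < min_donors:
            raise PrivacyRefusal(c, min_donors)
    return result


class QueryEngine:
    """Endpoint semantics over a :class:`VariantStore`.

    Parameters
    ----------
    store:
        The loaded store.
    assembly:
        AssemblyModel (or bundled assembly name) governing ploidy.
    min_donors:
        Privacy threshold; 1 disables the guard for local use.
    """

    def __init__(self, store: VariantStore, assembly, min_donors: int = 1):
        self.store = store
        if isinstance(assembly, str):
            assembly = AssemblyModel.named(assembly)
        self.assembly = assembly
        self.min_donors = int(min_donors)
        self._region_cache: dict[str, pd.DataFrame] = {}
        self._view_cache: dict[str, pd.DataFrame] = {}

    # -- caches --------------------------------------------------------

    def _region(self, source: str) -> pd.DataFrame:
        if source not in self._region_cache:
            self._region_cache[source] = self.store.region_frame(source)
        return self._region_cache[source]

    def _view(self, source: str) -> pd.DataFrame:
        if source not in self._view_cache:
            self._view_cache[source] = self.store.meta_view(source)
        return self._view_cache[source]

    # -- resolution ----------------------------------------------------

    def resolve_region(self, region: RegionSpec) -> tuple[str, int, int]:
        if region.gene is not None:
            return self.store.gene_region(region.gene)
        return normalize_chrom(region.chrom), int(region.start), int(region.stop)

    def resolve_variant(self, spec: VariantSpec, sources=None) -> tuple[str, int, str, str]:
        """Resolve a coordinate- or id-addressed variant to its
        (chrom, left, ref, alt) key."""
        if spec.gene is not None:
            raise UnresolvableVariantError(
                "a gene-addressed spec denotes a region, not a single variant"
            )
        if spec.id is None:
            return spec.key
        names = [d.name for d in (sources or self.store.sources(kind="variation"))]
        for name in names:
            df = self._region(name)
            if "vid" not in df.columns:
                continue
            hit = df[df["vid"] == spec.id]
            if len(hit):
                r = hit.iloc[0]
                return (str(r["chrom"]), int(r["left"]), str(r["ref"]), str(r["alt"]))
        raise UnresolvableVariantError(f"variant id {spec.id!r} not found in any source")

    # -- population selection -------------------------------------------

    def _phased_donors(self, source: str) -> set[str]:
        view = self._view(source)
        col = "manually_curated__phased"
        if col not in view.columns:
            return set(view["donor_id"])
        return set(view.loc[view[col] != "false", "donor_id"])

    def _donors_with_variant(self, region: pd.DataFrame, key) -> pd.DataFrame:
        chrom, left, ref, alt = key
        return region[
            (region["chrom"] == chrom)
            & (region["left"] == left)
            & (region["ref"] == ref)
            & (region["alt"] == alt)
        ]

    def _select_in_source(self, source, filter: PopulationFilter) -> set[str]:
        view = self._view(source.name)
        donors = set(view["donor_id"])
        for attr, allowed in filter.meta.items():
            allowed_l = {str(a).lower() for a in allowed}
            if attr in view.columns:
                match = view[view[attr].astype(str).str.lower().isin(allowed_l)]
                donors &= set(match["donor_id"])
            else:  # multi-valued attribute: fall back to the long table
                rows = self.store.conn.execute(
                    "SELECT DISTINCT donor_id FROM metadata_long "
                    "WHERE source=? AND key=?",
                    (source.name, attr),
                ).fetchall()
                hit = set()
                for (d,) in rows:
                    vals = {
                        v.lower()
                        for k, v in self.store.donor_meta_entries(source.name, d)
                        if k == attr
                    }
                    if vals & allowed_l:
                        hit.add(d)
                donors &= hit
        region = self._region(source.name)

        def donors_of(spec: VariantSpec) -> set[str]:
            if spec.gene is not None:
                chrom, start, stop = self.store.gene_region(spec.gene)
                rows = region[
                    (region["chrom"] == chrom)
                    & (region["left"] >= start)
                    & (region["left"] < stop)
                ]
                return set(rows["donor_id"])
            return set(self._donors_with_variant(region, self.resolve_variant(spec))["donor_id"])

        for spec in filter.with_variants:
            donors &= donors_of(spec)
        for spec in filter.without_variants:
            donors -= donors_of(spec)

        if filter.on_same_chrom_copy:
            donors &= self._phased_donors(source.name)
            keys = [self.resolve_variant(s) for s in filter.on_same_chrom_copy]
            per_copy = []
            for c in ("al1", "al2"):
                ok = donors
                for key in keys:
                    rows = self._donors_with_variant(region, key)
                    ok = ok & set(rows.loc[rows[c] == 1, "donor_id"])
                per_copy.append(ok)
            donors = per_copy[0] | per_copy[1]
        if filter.on_diff_chrom_copy is not None:
            donors &= self._phased_donors(source.name)
            k1, k2 = (self.resolve_variant(s) for s in filter.on_diff_chrom_copy)
            r1 = self._donors_with_variant(region, k1).set_index("donor_id")
            r2 = self._donors_with_variant(region, k2).set_index("donor_id")
            both = set(r1.index) & set(r2.index) & donors
            donors = {
                d
                for d in both
                if (r1.at[d, "al1"] and r2.at[d, "al2"])
                or (r1.at[d, "al2"] and r2.at[d, "al1"])
            }
        if filter.in_region is not None:
            chrom, start, stop = self.resolve_region(filter.in_region)
            rows = region[
                (region["chrom"] == chrom)
                & (region["left"] >= start)
                & (region["left"] < stop)
            ]
            donors &= set(rows["donor_id"])
        return donors

    def select_population(self, filter: PopulationFilter) -> list[str]:
        """Donors satisfying every constraint, unioned over eligible
        sources with duplicate elimination."""
        sources = self.store.eligible_sources(filter)
        logger.info("eligible sources: %s", [s.name for s in sources])
        pop: set[str] = set()
        for src in sources:
            pop |= self._select_in_source(src, filter)
        return sorted(pop)

    def _population_table(self, filter: PopulationFilter) -> pd.DataFrame:
        """One row per selected donor with the flattened metadata attributes
        (first loaded source wins for donors present in several)."""
        sources = self.store.eligible_sources(filter)
        pop = set()
        frames = []
        for src in sources:
            selected = self._select_in_source(src, filter)
            view = self._view(src.name)
            frames.append(view[view["donor_id"].isin(selected)])
            pop |= selected
        table = pd.concat(frames, ignore_index=True)
        table = table.drop_duplicates(subset=["donor_id"], keep="first")
        return table.reset_index(drop=True)

    # -- allele totals ---------------------------------------------------

    def total_alleles(self, genders, chrom: str, pos: int) -> int:
        """Total chromosome copies carried at (chrom, pos) by donors with
        the given genders; donors of unknown gender are excluded on sex
        chromosomes (with a warning) and diploid elsewhere."""
        total = 0
        warned = False
        for g in genders:
            p = self.assembly.ploidy(chrom, pos, g)
            if p is None:
                if not warned:
                    logger.warning(
                        "donor(s) of unknown gender excluded from allele total at %s:%d",
                        chrom, pos,
                    )
                    warned = True
                continue
            total += p
        return total

    def _totals_by_class(self, genders) -> dict[str, int]:
        """Precomputed totals for each ploidy context of a donor set."""
        n_m = sum(1 for g in genders if str(g).lower() == "male")
        n_f = sum(1 for g in genders if str(g).lower() == "female")
        n_all = len(list(genders))
        return {
            "autosome": 2 * n_all,
            "MT": n_all,
            "X_par": 2 * n_all,
            "X_nonpar": 2 * n_f + n_m,
            "Y_par": 2 * n_m,
            "Y_nonpar": n_m,
        }

    def _ploidy_class(self, chrom: str, pos: int) -> str:
        c = normalize_chrom(chrom)
        if c == "MT":
            return "MT"
        if c == "X":
            return "X_par" if self.assembly.in_par(c, pos) else "X_nonpar"
        if c == "Y":
            return "Y_par" if self.assembly.in_par(c, pos) else "Y_nonpar"
        return "autosome"

    # -- endpoints -------------------------------------------------------

    def donor_grouping(self, filter: PopulationFilter, group_by) -> GroupCountCube:
        """Donor counts per combination of the ``group_by`` attribute values."""
        group_by = list(group_by)
        table = self._population_table(filter)
        self._check_groupable(group_by)
        keys = []
        for attr in group_by:
            if attr in table.columns:
                keys.append(table[attr].fillna(""))
            else:
                keys.append(pd.Series([""] * len(table)))
        if len(table):
            grouped = (
                pd.DataFrame({i: k for i, k in enumerate(keys)})
                .groupby(list(range(len(group_by))), dropna=False)
                .size()
            )
            rows = tuple(
                (tuple(k) if isinstance(k, tuple) else (k,), int(n))
                for k, n in sorted(grouped.items(), key=lambda kv: _key_str(kv[0]))
            )
        else:
            rows = ()
        cube = GroupCountCube(group_by=tuple(group_by), rows=rows)
        return privacy_guard(cube, self.min_donors)

    def _check_groupable(self, group_by) -> None:
        known = self.store.known_attributes()
        single_valued = set()
        for src in self.store.sources(kind="variation"):
            single_valued |= set(self._view(src.name).columns) - {"donor_id"}
        for attr in group_by:
            if attr not in known:
                raise UnknownAttributeError(
                    f"unknown attribute {attr!r}; valid attributes: " + ", ".join(known)
                )
            if attr not in single_valued:
                raise UnknownAttributeError(
                    f"attribute {attr!r} is multi-valued and cannot be grouped on"
                )

    def variant_grouping(
        self, filter: PopulationFilter, group_by, target: VariantSpec
    ) -> list[FrequencyRow]:
        """Frequency of ``target`` within each partition of the population."""
        group_by = list(group_by)
        self._check_groupable(group_by)
        key = self.resolve_variant(target, sources=self.store.eligible_sources(filter))
        chrom, left = key[0], key[1]
        table = self._population_table(filter)
        if not len(table):
            raise PrivacyRefusal(0, max(self.min_donors, 1))

        occ = self._occurrences_for_key(filter, key)
        table = table.assign(
            _occ=table["donor_id"].map(occ).fillna(0).astype(int)
        )
        rows = []
        group_cols = [c for c in group_by]
        for attr in group_cols:
            if attr not in table.columns:
                table[attr] = ""
        grouped = table.groupby(group_cols, dropna=False) if group_cols else [((), table)]
        if group_cols:
            grouped = [
                (k if isinstance(k, tuple) else (k,), g) for k, g in grouped
            ]
        for gkey, g in sorted(grouped, key=lambda kg: _key_str(kg[0])):
            genders = g["gender"] if "gender" in g.columns else [None] * len(g)
            total = self.total_alleles(genders, chrom, left)
            occurrence = int(g["_occ"].sum())
            rows.append(
                FrequencyRow(
                    key=tuple("" if pd.isna(x) else x for x in gkey),
                    occurrence=occurrence,
                    population_size=int(len(g)),
                    positive_donors=int((g["_occ"] > 0).sum()),
                    total_alleles=int(total),
                    frequency=(occurrence / total) if total > 0 else None,
                )
            )
        return privacy_guard(rows, self.min_donors)

    def _occurrences_for_key(self, filter, key) -> dict[str, int]:
        occ: dict[str, int] = {}
        for src in self.store.eligible_sources(filter):
            rows = self._donors_with_variant(self._region(src.name), key)
            for _, r in rows.iterrows():
                occ.setdefault(str(r["donor_id"]), int(r["al1"]) + int(r["al2"]))
        return occ

    def _variant_summary(
        self, filter: PopulationFilter, region: RegionSpec | None
    ) -> pd.DataFrame:
        """Per-variant donor_count / occurrence / total_alleles / frequency
        over the selected population."""
        table = self._population_table(filter)
        if not len(table):
            raise PrivacyRefusal(0, max(self.min_donors, 1))
        pop = set(table["donor_id"])
        frames = []
        for src in self.store.eligible_sources(filter):
            df = self._region(src.name)
            df = df[df["donor_id"].isin(pop)]
            frames.append(df[["donor_id", "chrom", "left", "right", "ref", "alt", "al1", "al2"]])
        rows = pd.concat(frames, ignore_index=True).drop_duplicates(
            subset=["donor_id", "chrom", "left", "right", "ref", "alt"]
        )
        if region is not None:
            chrom, start, stop = self.resolve_region(region)
            rows = rows[
                (rows["chrom"] == chrom) & (rows["left"] >= start) & (rows["left"] < stop)
            ]
        if not len(rows):
            return pd.DataFrame(
                columns=[
                    "chrom", "left", "right", "ref", "alt",
                    "donor_count", "occurrence", "total_alleles", "frequency",
                ]
            )
        rows = rows.assign(_occ=rows["al1"].astype(int) + rows["al2"].astype(int))
        agg = (
            rows.groupby(["chrom", "left", "right", "ref", "alt"], dropna=False)
            .agg(donor_count=("donor_id", "nunique"), occurrence=("_occ", "sum"))
            .reset_index()
        )
        totals = self._totals_by_class(list(table["gender"]) if "gender" in table else [])
        agg["total_alleles"] = [
            totals[self._ploidy_class(c, int(l))] for c, l in zip(agg["chrom"], agg["left"])
        ]
        agg["frequency"] = [
            (o / t) if t > 0 else None for o, t in zip(agg["occurrence"], agg["total_alleles"])
        ]
        return agg

    def rank_variants(
        self,
        filter: PopulationFilter,
        region: RegionSpec | None = None,
        order: str = "most_common",
        limit: int = 10,
    ) -> list[dict]:
        """The most common or rarest variants of the population, each with
        donor count, occurrence, total alleles and frequency.  Ties break
        deterministically on (chromosome natural order, left, ref, alt)."""
        if limit < 1:
            raise PopvarsumError("limit must be >= 1")
        if order not in ("most_common", "rarest"):
            raise PopvarsumError("order must be 'most_common' or 'rarest'")
        agg = self._variant_summary(filter, region)
        records = agg.to_dict("records")
        reverse = order == "most_common"
        records.sort(
            key=lambda r: (
                -(r["frequency"] or 0.0) if reverse else (r["frequency"] or 0.0),
                chrom_sort_key(r["chrom"]),
                r["left"],
                r["ref"],
                r["alt"],
            )
        )
        out = [
            {
                "chrom": r["chrom"], "left": int(r["left"]), "right": int(r["right"]),
                "ref": r["ref"], "alt": r["alt"],
                "donor_count": int(r["donor_count"]), "occurrence": int(r["occurrence"]),
                "total_alleles": int(r["total_alleles"]), "frequency": r["frequency"],
            }
            for r in records[: int(limit)]
        ]
        return privacy_guard(out, self.min_donors)

    def variants_in_region(self, filter: PopulationFilter, region: RegionSpec) -> list[dict]:
        """Distinct variants whose left coordinate falls in the region,
        with occurrence and donor counts over the population."""
        agg = self._variant_summary(filter, region)
        records = agg.to_dict("records")
        records.sort(key=lambda r: (chrom_sort_key(r["chrom"]), r["left"], r["ref"], r["alt"]))
        out = [
            {
                "chrom": r["chrom"], "left": int(r["left"]), "right": int(r["right"]),
                "ref": r["ref"], "alt": r["alt"],
                "donor_count": int(r["donor_count"]), "occurrence": int(r["occurrence"]),
                "total_alleles": int(r["total_alleles"]), "frequency": r["frequency"],
            }
            for r in records
        ]
        return privacy_guard(out, self.min_donors)

    def annotate(self, query) -> list[dict]:
        """Gene annotations overlapping a region or a variant's span.

        A variant is its ``[left, right)`` interval; an insertion is a
        zero-length point that must fall strictly inside a gene to count.
        """
        ann = self.store.annotation_frame()
        if isinstance(query, VariantSpec):
            chrom, left, ref, alt = self.resolve_variant(query)
            right = left + len(ref or "")
        else:
            chrom, left, right = self.resolve_region(query)
        ann = ann[ann["chrom"] == chrom]
        if left == right:  # insertion point
            hit = ann[(ann["start"] < left) & (left < ann["stop"])]
        else:
            hit = ann[(ann["start"] < right) & (left < ann["stop"])]
        out = [
            {"gene_name": r["gene_name"], "chrom": r["chrom"],
             "start": int(r["start"]), "stop": int(r["stop"])}
            for _, r in hit.sort_values(["start", "gene_name"]).iterrows()
        ]
        return out

    def export_donors(self, filter: PopulationFilter, out_dir) -> list[str]:
        """Write one ``.gdm``/``.gdm.meta`` pair per selected donor.

        Reloading the export yields the same answers for this population.
        """
        pop = self.select_population(filter)
        if len(pop) == 0 or 0 < len(pop) < self.min_donors:
            raise PrivacyRefusal(len(pop), self.min_donors)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sources = self.store.eligible_sources(filter)
        columns = None
        for src in sources:
            cols = list(src.columns)
            if columns is None or len(cols) > len(columns):
                columns = cols
        for donor in pop:
            frames = []
            entries = set()
            for src in sources:
                df = self._region(src.name)
                sub = df[df["donor_id"] == donor]
                frames.append(sub)
                entries.update(self.store.donor_meta_entries(src.name, donor))
            rows = pd.concat(frames, ignore_index=True).drop_duplicates(
                subset=["chrom", "left", "right", "ref", "alt"]
            )
            rows = rows.sort_values(
                by=["chrom", "left", "right", "ref", "alt"],
                key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            )
            with open(out_dir / f"{donor}.gdm", "w") as fh:
                for _, r in rows.iterrows():
                    fh.write("\t".join(str(r[c]) for c in columns) + "\n")
            meta = DonorMetadata(donor_id=donor, entries=sorted(entries))
            write_meta_file(meta, out_dir / f"{donor}.gdm.meta")
        # schema sidecar so the export can be reloaded as a dataset
        schema_cols = [
            {"chrom": "chr", "vid": "id", "al1": "AL1", "al2": "AL2"}.get(c, c)
            for c in columns
        ]
        with open(out_dir / "schema.yaml", "w") as fh:
            fh.write(f"source: export\nassembly: {sources[0].assembly}\ncolumns:\n")
            for c in schema_cols:
                fh.write(f"  - {c}\n")
        return pop


def _key_str(key) -> tuple:
    if not isinstance(key, tuple):
        key = (key,)
    return tuple("" if k is None or (isinstance(k, float) and pd.isna(k)) else str(k) for k in key)
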