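"""Embedded relational store for GDM datasets and gene annotations.

The store mirrors the relational layout the summarization engine needs:
one region table per variation source (donor_id plus the normalized
variant columns and the AL1/AL2 chromatid flags), a long key/value
metadata table shared by all sources, and one flattened per-source
metadata view holding the single-valued attributes used for filtering
and grouping.  SQLite is the engine; the query semantics, not the
engine, are the contract.

Each source declares a capability descriptor — the set of metadata
attributes and region-filter categories it can answer.  A request is
only routed to sources whose capability set covers every category the
request's filter references; chromatid-constrained filters, for
instance, are only answerable by sources whose rows carry AL1/AL2.
"""

from __future__ import annotations

import difflib
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assembly import normalize_chrom
from .errors import (
    NoEligibleSourceError,
    PopvarsumError,
    SchemaMismatchError,
    UnknownAttributeError,
    UnknownGeneError,
)
from .metadata_transform import read_meta_file

__all__ = ["SourceDescriptor", "VariantStore"]

# region-filter capability categories
CAP_WITH = "region:with_variant"
CAP_WITHOUT = "region:without_variant"
CAP_IN_REGION = "region:in_region"
CAP_SAME_COPY = "region:same_chrom_copy"
CAP_DIFF_COPY = "region:diff_chrom_copy"
CAP_VARIANT_ID = "region:variant_id"


@dataclass(frozen=True)
class SourceDescriptor:
    """What a loaded source is and what it can filter on."""

    name: str
    assembly: str
    kind: str  # "variation" | "annotation"
    capabilities: frozenset[str] = field(default_factory=frozenset)
    columns: tuple[str, ...] = ()

    def supports(self, categories) -> bool:
        return set(categories) <= set(self.capabilities)


_COLMAP = {"chr": "chrom", "id": "vid"}  # schema name -> store column name


class VariantStore:
    """SQLite-backed store of variation sources and annotation sources."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS sources ("
            "name TEXT PRIMARY KEY, assembly TEXT, kind TEXT,"
            "capabilities TEXT, columns TEXT)"
        )
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS metadata_long ("
            "source TEXT, donor_id TEXT, key TEXT, value TEXT)"
        )
        self.conn.commit()

    def close(self):
        self.conn.close()

    # -- descriptors ---------------------------------------------------

    def sources(self, kind: str | None = None) -> list[SourceDescriptor]:
        rows = self.conn.execute(
            "SELECT name, assembly, kind, capabilities, columns FROM sources"
        ).fetchall()
        out = [
            SourceDescriptor(
                name=r[0], assembly=r[1], kind=r[2],
                capabilities=frozenset(json.loads(r[3])),
                columns=tuple(json.loads(r[4])),
            )
            for r in rows
        ]
        if kind is not None:
            out = [d for d in out if d.kind == kind]
        return sorted(out, key=lambda d: d.name)

    def source(self, name: str) -> SourceDescriptor:
        for d in self.sources():
            if d.name == name:
                return d
        raise PopvarsumError(f"no source named {name!r}")

    def _register(self, desc: SourceDescriptor) -> None:
        if any(d.name == desc.name for d in self.sources()):
            raise PopvarsumError(f"source {desc.name!r} already loaded; no silent overwrite")
        self.conn.execute(
            "INSERT INTO sources VALUES (?,?,?,?,?)",
            (
                desc.name, desc.assembly, desc.kind,
                json.dumps(sorted(desc.capabilities)), json.dumps(list(desc.columns)),
            ),
        )

    # -- loading -------------------------------------------------------

    def load_gdm_dataset(
        self, gdm_dir, source_name: str, schema: list[str] | None = None,
        assembly: str | None = None,
    ) -> SourceDescriptor:
        """Load every ``.gdm``/``.gdm.meta`` pair under ``gdm_dir``.

        ``schema`` is the ordered region-file column list; it defaults to
        the ``schema.yaml`` sidecar written by the transformation step.
        Loading an empty directory, or reusing a source name, is an error.
        """
        if any(d.name == source_name for d in self.sources()):
            raise PopvarsumError(f"source {source_name!r} already loaded; no silent overwrite")
        gdm_dir = Path(gdm_dir)
        meta_files = sorted(gdm_dir.glob("*.gdm.meta"))
        if not meta_files:
            raise PopvarsumError(f"no .gdm.meta files found in {gdm_dir}")
        sidecar = gdm_dir / "schema.yaml"
        if schema is None:
            if not sidecar.exists():
                raise SchemaMismatchError(f"no schema given and no schema.yaml in {gdm_dir}")
            doc = yaml.safe_load(sidecar.read_text())
            schema = list(doc["columns"])
            assembly = assembly or doc.get("assembly")
        if assembly is None:
            assembly = "unknown"
        table_cols = [_COLMAP.get(c.lower(), c.lower()) for c in schema]
        if len(set(table_cols)) != len(table_cols):
            raise SchemaMismatchError(f"duplicate columns in schema: {schema}")

        frames = []
        metas = {}
        for mf in meta_files:
            donor = mf.name[: -len(".gdm.meta")]
            metas[donor] = read_meta_file(mf, donor_id=donor)
            rf = gdm_dir / f"{donor}.gdm"
            if not rf.exists():
                raise PopvarsumError(f"metadata without region file for donor {donor}")
            try:
                df = pd.read_csv(
                    rf, sep="\t", header=None, names=table_cols,
                    dtype={"ref": str, "alt": str, "chrom": str},
                    keep_default_na=False, na_values=[],
                )
            except pd.errors.EmptyDataError:
                df = pd.DataFrame({c: [] for c in table_cols})
            except (pd.errors.ParserError, ValueError) as exc:
                raise SchemaMismatchError(f"{rf} does not match schema {schema}: {exc}")
            if len(df.columns) != len(table_cols):
                raise SchemaMismatchError(f"{rf}: expected {len(table_cols)} columns")
            df.insert(0, "donor_id", donor)
            frames.append(df)
        region = pd.concat(frames, ignore_index=True)
        if len(region):
            region["chrom"] = region["chrom"].map(normalize_chrom)
            for c in ("left", "right", "length"):
                if c in region.columns:
                    region[c] = region[c].astype(int)
            for c in ("al1", "al2"):
                if c in region.columns:
                    region[c] = region[c].astype(int)
            dup = region.duplicated(subset=["donor_id", "chrom", "left", "right", "ref", "alt"])
            if dup.any():
                raise SchemaMismatchError(
                    f"duplicate (donor, variant) rows in {gdm_dir}: "
                    f"{region[dup].iloc[0].to_dict()}"
                )

        # metadata: long table plus flattened single-valued view
        long_rows = []
        for donor, meta in metas.items():
            for k, v in meta.sorted_entries():
                long_rows.append((source_name, donor, k, v))
        self.conn.executemany("INSERT INTO metadata_long VALUES (?,?,?,?)", long_rows)

        all_keys = sorted({k for _, _, k, _ in long_rows})
        multi = {
            k for k in all_keys
            if any(len(set(m.get(k))) > 1 for m in metas.values())
        }
        single_keys = [k for k in all_keys if k not in multi]
        view_rows = []
        for donor, meta in metas.items():
            row = {"donor_id": donor}
            for k in single_keys:
                vals = meta.get(k)
                row[k] = vals[0] if vals else None
            view_rows.append(row)
        view = pd.DataFrame(view_rows, columns=["donor_id"] + single_keys)

        rtable = f"region_{source_name}"
        region.to_sql(rtable, self.conn, index=False)
        self.conn.execute(
            f'CREATE INDEX "idx_{rtable}_coord" ON "{rtable}" (chrom, left, right)'
        )
        self.conn.execute(f'CREATE INDEX "idx_{rtable}_donor" ON "{rtable}" (donor_id)')
        view.to_sql(f"metaview_{source_name}", self.conn, index=False)

        caps = {f"meta:{k}" for k in all_keys}
        caps |= {CAP_WITH, CAP_WITHOUT, CAP_IN_REGION}
        if "al1" in region.columns and "al2" in region.columns:
            caps |= {CAP_SAME_COPY, CAP_DIFF_COPY}
        if "vid" in region.columns:
            caps.add(CAP_VARIANT_ID)
        desc = SourceDescriptor(
            name=source_name, assembly=str(assembly).lower(), kind="variation",
            capabilities=frozenset(caps), columns=tuple(table_cols),
        )
        self._register(desc)
        self.conn.commit()
        return desc

    def load_annotations(self, gtf_path, source_name: str, assembly: str = "unknown") -> SourceDescriptor:
        """Load gene annotations from a GTF file (``gene`` features only)."""
        import pyranges as pr

        if any(d.name == source_name for d in self.sources()):
            raise PopvarsumError(f"source {source_name!r} already loaded; no silent overwrite")
        df = pr.read_gtf(str(gtf_path)).df
        genes = df[df["Feature"] == "gene"].copy()
        if "gene_name" not in genes.columns:
            raise SchemaMismatchError(f"{gtf_path}: GTF gene features lack gene_name")
        out = pd.DataFrame(
            {
                "gene_name": genes["gene_name"].astype(str),
                "chrom": genes["Chromosome"].astype(str).map(normalize_chrom),
                "start": genes["Start"].astype(int),  # pyranges is already 0-based
                "stop": genes["End"].astype(int),
            }
        )
        out.to_sql(f"annotation_{source_name}", self.conn, index=False)
        desc = SourceDescriptor(
            name=source_name, assembly=str(assembly).lower(), kind="annotation",
            capabilities=frozenset({"annotation:gene"}),
            columns=("gene_name", "chrom", "start", "stop"),
        )
        self._register(desc)
        self.conn.commit()
        return desc

    # -- access --------------------------------------------------------

    def region_frame(self, source_name: str) -> pd.DataFrame:
        self.source(source_name)  # existence check
        return pd.read_sql_query(
            f'SELECT * FROM "region_{source_name}"', self.conn,
        ).fillna({"ref": "", "alt": "", "vid": ""})

    def meta_view(self, source_name: str) -> pd.DataFrame:
        self.source(source_name)
        return pd.read_sql_query(f'SELECT * FROM "metaview_{source_name}"', self.conn)

    def donor_meta_entries(self, source_name: str, donor_id: str) -> list[tuple[str, str]]:
        rows = self.conn.execute(
            "SELECT key, value FROM metadata_long WHERE source=? AND donor_id=? "
            "ORDER BY key, value",
            (source_name, donor_id),
        ).fetchall()
        return [(k, v) for k, v in rows]

    def known_attributes(self) -> list[str]:
        rows = self.conn.execute("SELECT DISTINCT key FROM metadata_long").fetchall()
        return sorted(r[0] for r in rows)

    def distinct_values(self, attribute: str) -> list[tuple[str, int]]:
        """Distinct values of a metadata attribute with donor counts, across
        all sources; a donor present in several sources is counted once."""
        known = self.known_attributes()
        if attribute not in known:
            raise UnknownAttributeError(
                f"unknown attribute {attribute!r}; valid attributes: " + ", ".join(known)
            )
        rows = self.conn.execute(
            "SELECT value, COUNT(DISTINCT donor_id) FROM metadata_long "
            "WHERE key=? GROUP BY value ORDER BY value",
            (attribute,),
        ).fetchall()
        return [(v, int(n)) for v, n in rows]

    # -- eligibility -----------------------------------------------------

    def eligible_sources(self, filter) -> list[SourceDescriptor]:
        """Variation sources whose capability set covers every category the
        filter references (and whose assembly matches, when requested)."""
        required = set(filter.required_capabilities())
        candidates = self.sources(kind="variation")
        if getattr(filter, "assembly", None):
            candidates = [d for d in candidates if d.assembly == filter.assembly.lower()]
        eligible = [d for d in candidates if d.supports(required)]
        if not eligible:
            if candidates:
                best = min(
                    (required - set(d.capabilities) for d in candidates), key=len
                )
                missing = best or {"assembly:" + str(getattr(filter, "assembly", ""))}
            else:
                missing = {"assembly:" + str(getattr(filter, "assembly", "any"))}
            raise NoEligibleSourceError(missing)
        return eligible

    # -- gene resolution -------------------------------------------------

    def gene_region(self, gene_name: str) -> tuple[str, int, int]:
        """Resolve a gene name to its (chrom, start, stop) interval using the
        loaded annotation sources."""
        annotations = self.sources(kind="annotation")
        if not annotations:
            raise PopvarsumError("no annotation source loaded")
        names = []
        for ann in annotations:
            rows = self.conn.execute(
                f'SELECT chrom, start, stop FROM "annotation_{ann.name}" WHERE gene_name=?',
                (gene_name,),
            ).fetchall()
            if rows:
                chrom, start, stop = rows[0]
                return str(chrom), int(start), int(stop)
            names.extend(
                r[0]
                for r in self.conn.execute(
                    f'SELECT DISTINCT gene_name FROM "annotation_{ann.name}"'
                ).fetchall()
            )
        raise UnknownGeneError(gene_name, difflib.get_close_matches(gene_name, names, n=3))

    def annotation_frame(self) -> pd.DataFrame:
        annotations = self.sources(kind="annotation")
        if not annotations:
            raise PopvarsumError("no annotation source loaded")
        frames = [
            pd.read_sql_query(f'SELECT * FROM "annotation_{a.name}"', self.conn)
            for a in annotations
        ]
        return pd.concat(frames, ignore_index=True)
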