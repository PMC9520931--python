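"""Request-body validation and endpoint dispatch.

The eight endpoints share one request-body schema, so a body written for
the ranking endpoints becomes valid for donor grouping by adding
``group_by``, and for variant grouping by further adding
``target_variant``.  Validation happens up front (with field paths in
the error) before any computation; responses are plain JSON-serializable
dictionaries with a frozen shape: data cubes as
``{"group_by": [...], "rows": [{"key": [...], ...}]}``, rankings and
listings as ``{"columns": [...], "rows": [...]}``.
"""

from __future__ import annotations

from typing import Any

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import genescore
from .errors import PopvarsumError
from .popquery import PopulationFilter, QueryEngine, RegionSpec, VariantSpec

__all__ = ["RequestBody", "dispatch", "ENDPOINTS"]

ENDPOINTS = (
    "donor_grouping",
    "variant_grouping",
    "most_common_variants",
    "rarest_variants",
    "values",
    "annotate",
    "variants_in_region",
    "download_donors",
)


class VariantSpecModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str | None = None
    left: int | None = None
    ref: str | None = None
    alt: str | None = None
    id: str | None = None
    gene: str | None = None

    def to_spec(self) -> VariantSpec:
        return VariantSpec(**self.model_dump())


class RegionSpecModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str | None = None
    start: int | None = None
    stop: int | None = None
    gene: str | None = None

    def to_spec(self) -> RegionSpec:
        return RegionSpec(**self.model_dump())


class HavingVariants(BaseModel):
    model_config = ConfigDict(extra="forbid")
    with_: list[VariantSpecModel] = Field(default_factory=list, alias="with")
    without: list[VariantSpecModel] = Field(default_factory=list)
    on_same_chrom_copy: list[VariantSpecModel] = Field(default_factory=list)
    on_diff_chrom_copy: list[VariantSpecModel] = Field(default_factory=list)


class RequestBody(BaseModel):
    """The shared request schema of all endpoints."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    meta: dict[str, list[str]] = Field(default_factory=dict)
    variants: HavingVariants = Field(default_factory=HavingVariants)
    in_region: RegionSpecModel | None = None
    assembly: str | None = None
    group_by: list[str] = Field(default_factory=list)
    target_variant: VariantSpecModel | None = None
    region: RegionSpecModel | None = None
    limit: int = 10
    attribute: str | None = None

    def to_filter(self) -> PopulationFilter:
        return PopulationFilter(
            meta=self.meta,
            with_variants=tuple(v.to_spec() for v in self.variants.with_),
            without_variants=tuple(v.to_spec() for v in self.variants.without),
            on_same_chrom_copy=tuple(v.to_spec() for v in self.variants.on_same_chrom_copy),
            on_diff_chrom_copy=(
                tuple(v.to_spec() for v in self.variants.on_diff_chrom_copy)
                if self.variants.on_diff_chrom_copy
                else None
            ),
            in_region=self.in_region.to_spec() if self.in_region else None,
            assembly=self.assembly,
        )


def dispatch(engine: QueryEngine, endpoint: str, body: dict, out_dir=None) -> dict[str, Any]:
    """Validate ``body`` and route it to the endpoint implementation."""
    if endpoint not in ENDPOINTS:
        raise PopvarsumError(
            f"unknown endpoint {endpoint!r}; expected one of: " + ", ".join(ENDPOINTS)
        )
    try:
        req = RequestBody.model_validate(body)
    except ValidationError as exc:
        raise PopvarsumError(f"invalid request body: {exc}") from exc

    if endpoint == "values":
        if not req.attribute:
            raise PopvarsumError("values requires 'attribute'")
        vals = engine.store.distinct_values(req.attribute)
        return {
            "attribute": req.attribute,
            "values": [{"value": v, "count": n} for v, n in vals],
        }

    if endpoint == "annotate":
        query = req.target_variant.to_spec() if req.target_variant else None
        if query is None and req.region is not None:
            query = req.region.to_spec()
        if query is None:
            raise PopvarsumError("annotate requires 'target_variant' or 'region'")
        return {"annotations": engine.annotate(query)}

    flt = req.to_filter()

    if endpoint == "donor_grouping":
        if not req.group_by:
            raise PopvarsumError("donor_grouping requires 'group_by'")
        return engine.donor_grouping(flt, req.group_by).to_json_dict()

    if endpoint == "variant_grouping":
        if req.target_variant is None:
            raise PopvarsumError("variant_grouping requires 'target_variant'")
        rows = engine.variant_grouping(flt, req.group_by, req.target_variant.to_spec())
        return {
            "group_by": list(req.group_by),
            "rows": [r.to_dict(req.group_by) for r in rows],
        }

    if endpoint in ("most_common_variants", "rarest_variants"):
        order = "most_common" if endpoint == "most_common_variants" else "rarest"
        region = req.region.to_spec() if req.region else None
        rows = engine.rank_variants(flt, region=region, order=order, limit=req.limit)
        return {
            "columns": list(rows[0].keys()) if rows else [],
            "rows": rows,
        }

    if endpoint == "variants_in_region":
        if req.region is None:
            raise PopvarsumError("variants_in_region requires 'region'")
        rows = engine.variants_in_region(flt, req.region.to_spec())
        return {"columns": list(rows[0].keys()) if rows else [], "rows": rows}

    # download_donors
    if out_dir is None:
        raise PopvarsumError("download_donors requires an output directory")
    donors = engine.export_donors(flt, out_dir)
    return {"exported_donors": donors, "out_dir": str(out_dir)}


def diff_genes(engine: QueryEngine, tumor_body: dict, healthy_body: dict, genes: list[str]) -> dict:
    """Differential gene scoring between two cohort request bodies."""
    tumor = RequestBody.model_validate(tumor_body).to_filter()
    healthy = RequestBody.model_validate(healthy_body).to_filter()
    results = genescore.differential_gene_ranking(engine, tumor, healthy, genes)
    return {
        "columns": [
            "gene", "S_tumor", "S_healthy", "norm_tumor", "norm_healthy", "diff",
        ],
        "rows": [
            {
                "gene": r.gene,
                "S_tumor": r.score_tumor,
                "S_healthy": r.score_healthy,
                "norm_tumor": r.normalized_tumor,
                "norm_healthy": r.normalized_healthy,
                "diff": r.diff,
            }
            for r in results
        ],
    }
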