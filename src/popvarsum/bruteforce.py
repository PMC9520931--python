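"""Naive full-scan reference implementations, used as cross-checks.

Everything here recomputes the endpoint answers donor by donor and
variant by variant, reading the GDM files directly and using explicit
Python loops — no SQL, no pandas, no shared query code.  The point is
independence: the optimized engine in :mod:`popvarsum.popquery` must
agree with these scans exactly (counts) or to floating-point round-off
(frequencies) on any dataset small enough to scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .popquery import PopulationFilter, RegionSpec, VariantSpec

__all__ = ["NaiveDataset", "load_naive"]


@dataclass
class NaiveDataset:
    """Plain in-memory image of one GDM dataset."""

    meta: dict = field(default_factory=dict)  # donor -> {key: [values]}
    rows: dict = field(default_factory=dict)  # donor -> [row dicts]
    genes: dict = field(default_factory=dict)  # name -> (chrom, start, stop)
    par: dict = field(default_factory=dict)  # chrom -> [(start, end)]

    # -- helpers -------------------------------------------------------

    def meta_value(self, donor: str, key: str):
        vals = self.meta.get(donor, {}).get(key, [])
        return vals[0] if vals else None

    def donor_rows(self, donor: str):
        return self.rows.get(donor, [])

    def find_rows(self, donor, chrom, left, ref, alt):
        return [
            r for r in self.donor_rows(donor)
            if r["chr"] == chrom and r["left"] == left
            and r["ref"] == ref and r["alt"] == alt
        ]

    def resolve(self, spec: VariantSpec):
        if spec.id is not None:
            for rows in self.rows.values():
                for r in rows:
                    if r.get("id") == spec.id:
                        return (r["chr"], r["left"], r["ref"], r["alt"])
            raise KeyError(spec.id)
        return (spec.chrom, spec.left, spec.ref, spec.alt)

    def resolve_region(self, region: RegionSpec):
        if region.gene is not None:
            return self.genes[region.gene]
        return (region.chrom, region.start, region.stop)

    # -- ploidy (independent if-chain) ---------------------------------

    def in_par(self, chrom, pos):
        for s, e in self.par.get(chrom, []):
            if s <= pos < e:
                return True
        return False

    def ploidy(self, donor, chrom, pos):
        gender = self.meta_value(donor, "gender")
        if chrom == "MT":
            return 1
        if chrom not in ("X", "Y"):
            return 2
        if chrom == "X":
            if self.in_par("X", pos):
                return 2
            if gender == "female":
                return 2
            if gender == "male":
                return 1
            return None
        # Y
        if gender == "male":
            return 2 if self.in_par("Y", pos) else 1
        if gender == "female":
            return 0
        return None

    def total_alleles(self, donors, chrom, pos):
        total = 0
        for d in donors:
            p = self.ploidy(d, chrom, pos)
            if p is not None:
                total += p
        return total

    # -- population selection ------------------------------------------

    def matches(self, donor: str, flt: PopulationFilter) -> bool:
        for attr, allowed in flt.meta.items():
            allowed_l = {str(a).lower() for a in allowed}
            vals = {v.lower() for v in self.meta.get(donor, {}).get(attr, [])}
            if not vals & allowed_l:
                return False

        def has(spec):
            if spec.gene is not None:
                chrom, start, stop = self.genes[spec.gene]
                return any(
                    r["chr"] == chrom and start <= r["left"] < stop
                    for r in self.donor_rows(donor)
                )
            key = self.resolve(spec)
            return bool(self.find_rows(donor, *key))

        for spec in flt.with_variants:
            if not has(spec):
                return False
        for spec in flt.without_variants:
            if has(spec):
                return False
        phased = self.meta_value(donor, "manually_curated__phased") != "false"
        if flt.on_same_chrom_copy:
            if not phased:
                return False
            keys = [self.resolve(s) for s in flt.on_same_chrom_copy]
            ok = False
            for copy in ("AL1", "AL2"):
                if all(
                    any(r[copy] == 1 for r in self.find_rows(donor, *k)) for k in keys
                ):
                    ok = True
            if not ok:
                return False
        if flt.on_diff_chrom_copy is not None:
            if not phased:
                return False
            k1, k2 = (self.resolve(s) for s in flt.on_diff_chrom_copy)
            r1 = self.find_rows(donor, *k1)
            r2 = self.find_rows(donor, *k2)
            if not r1 or not r2:
                return False
            a, b = r1[0], r2[0]
            if not ((a["AL1"] and b["AL2"]) or (a["AL2"] and b["AL1"])):
                return False
        if flt.in_region is not None:
            chrom, start, stop = self.resolve_region(flt.in_region)
            if not any(
                r["chr"] == chrom and start <= r["left"] < stop
                for r in self.donor_rows(donor)
            ):
                return False
        return True

    def select(self, flt: PopulationFilter):
        return sorted(d for d in self.meta if self.matches(d, flt))

    # -- endpoint answers ----------------------------------------------

    def donor_grouping(self, flt, group_by):
        counts = {}
        for d in self.select(flt):
            key = tuple(self.meta_value(d, a) or "" for a in group_by)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def occurrence(self, donor, key) -> int:
        rows = self.find_rows(donor, *key)
        return rows[0]["AL1"] + rows[0]["AL2"] if rows else 0

    def variant_grouping(self, flt, group_by, target: VariantSpec):
        key = self.resolve(target)
        chrom, left = key[0], key[1]
        groups = {}
        for d in self.select(flt):
            gkey = tuple(self.meta_value(d, a) or "" for a in group_by)
            groups.setdefault(gkey, []).append(d)
        out = {}
        for gkey, donors in groups.items():
            occ = sum(self.occurrence(d, key) for d in donors)
            total = self.total_alleles(donors, chrom, left)
            out[gkey] = {
                "occurrence": occ,
                "population_size": len(donors),
                "positive_donors": sum(1 for d in donors if self.occurrence(d, key) > 0),
                "total_alleles": total,
                "frequency": occ / total if total else None,
            }
        return out

    def variant_table(self, flt, region=None):
        """All variants of the population with donor counts, occurrences,
        totals and frequency — the common core of ranking and listing."""
        donors = self.select(flt)
        bounds = self.resolve_region(region) if region is not None else None
        per_variant = {}
        for d in donors:
            for r in self.donor_rows(d):
                if bounds is not None:
                    chrom, start, stop = bounds
                    if r["chr"] != chrom or not start <= r["left"] < stop:
                        continue
                k = (r["chr"], r["left"], r["right"], r["ref"], r["alt"])
                entry = per_variant.setdefault(k, {"donors": set(), "occ": 0})
                entry["donors"].add(d)
                entry["occ"] += r["AL1"] + r["AL2"]
        out = {}
        for k, entry in per_variant.items():
            total = self.total_alleles(donors, k[0], k[1])
            out[k] = {
                "donor_count": len(entry["donors"]),
                "occurrence": entry["occ"],
                "total_alleles": total,
                "frequency": entry["occ"] / total if total else None,
            }
        return out

    def annotate(self, chrom, left, right):
        hits = []
        for name, (gchrom, start, stop) in self.genes.items():
            if gchrom != chrom:
                continue
            if left == right:
                if start < left < stop:
                    hits.append(name)
            elif start < right and left < stop:
                hits.append(name)
        return sorted(hits)

    def gene_score(self, flt, gene):
        donors = self.select(flt)
        table = self.variant_table(flt, RegionSpec(gene=gene))
        return sum(v["occurrence"] for v in table.values()) / len(donors)


def load_naive(gdm_dir, genes=None, par=None) -> NaiveDataset:
    """Read a GDM directory (and optional gene/PAR descriptions) into a
    NaiveDataset using plain file iteration."""
    gdm_dir = Path(gdm_dir)
    doc = yaml.safe_load((gdm_dir / "schema.yaml").read_text())
    columns = list(doc["columns"])
    ds = NaiveDataset(genes=dict(genes or {}), par=dict(par or {}))
    for meta_path in sorted(gdm_dir.glob("*.gdm.meta")):
        donor = meta_path.name[: -len(".gdm.meta")]
        mm: dict[str, list[str]] = {}
        for line in meta_path.read_text().splitlines():
            if not line:
                continue
            k, _, v = line.partition("\t")
            mm.setdefault(k, []).append(v)
        ds.meta[donor] = mm
        rows = []
        region_path = gdm_dir / f"{donor}.gdm"
        for line in region_path.read_text().splitlines():
            fields = line.split("\t")
            row = dict(zip(columns, fields))
            row["chr"] = row["chr"]
            for c in ("left", "right", "AL1", "AL2", "length"):
                if c in row:
                    row[c] = int(row[c])
            rows.append(row)
        ds.rows[donor] = rows
    return ds
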