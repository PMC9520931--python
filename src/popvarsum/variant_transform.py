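"""VCF -> per-donor GDM region files: the variant rewriting rules.

A multi-sample, per-chromosome VCF describes each variant once, with a
genotype column per donor.  The GDM representation inverts this: one region
file per donor holding only the variants that donor actually carries, as
0-based half-open intervals.  Getting there requires rewriting every VCF
record:

* multi-allelic records are split into independent bi-allelic records,
  one per alternative allele, preserving ALT order;
* coordinates move from 1-based to 0-based half-open;
* bases shared between the reference and alternative alleles — including
  the padding base VCF needs to anchor indels and structural variants —
  are removed, and the coordinates adjusted;
* the stop coordinate is start plus the substituted length for SNPs/MNPs,
  equal to start for insertions, and start plus the deleted length for
  deletions;
* the genotype is decoded into two chromatid flags AL1/AL2 recording which
  chromosome copy carries the alternative allele (the input being phased,
  "left copy" is consistent across variants of a chromosome within a donor).

The per-row schema is: chr, left, right, strand (always '+'), AL1, AL2,
ref, alt, mut_type, length, followed by any retained INFO-derived columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .assembly import chrom_sort_key, normalize_chrom
from .errors import MalformedVariantError, MetadataConflictError
from .metadata_transform import build_donor_metadata, write_meta_file

__all__ = [
    "RawVcfVariant",
    "NormalizedVariant",
    "GenotypeCall",
    "GDM_FIXED_COLUMNS",
    "split_multiallelic",
    "normalize_alleles",
    "classify_variant",
    "normalize_variant",
    "genotype_to_copies",
    "transform_dataset",
]

logger = logging.getLogger(__name__)

GDM_FIXED_COLUMNS = [
    "chr", "left", "right", "strand", "AL1", "AL2",
    "ref", "alt", "mut_type", "length",
]

_GT_SPLIT = re.compile(r"[|/]")


class SkippedVariantError(MalformedVariantError):
    """An allele the transformation cannot interpret (e.g. a breakend);
    the dataset pipeline skips it with a warning rather than failing."""


@dataclass
class RawVcfVariant:
    """One VCF data line, possibly multi-allelic."""

    chrom: str
    pos: int  # 1-based
    id: str | None
    ref: str
    alts: list[str]
    info: dict = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.pos < 1:
            raise MalformedVariantError(f"pos must be >= 1, got {self.pos}")
        if not self.alts:
            raise MalformedVariantError("variant has no alternative alleles")
        if not self.ref:
            raise MalformedVariantError("empty REF allele")


@dataclass(frozen=True)
class NormalizedVariant:
    """One bi-allelic variant as a GDM region: 0-based half-open, trimmed."""

    chrom: str
    left: int
    right: int
    ref: str
    alt: str
    mut_type: str
    length: int
    strand: str = "+"
    variant_id: str | None = None
    extra: tuple = ()

    @property
    def key(self):
        return (self.chrom, self.left, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """Chromatid decoding of one genotype for one alternative allele."""

    al1: int
    al2: int
    occurrence: int
    phased: bool = True
    missing: bool = False


def split_multiallelic(v: RawVcfVariant) -> list[tuple[RawVcfVariant, int]]:
    """Split a (possibly multi-allelic) record into bi-allelic records.

    Returns one ``(record, alt_index)`` pair per alternative allele, in ALT
    column order; ``alt_index`` is 1-based as in the genotype encoding.
    Position, REF, INFO and genotypes are carried over unchanged.
    """
    v.validate()
    out = []
    for i, alt in enumerate(v.alts, start=1):
        out.append(
            (
                RawVcfVariant(
                    chrom=v.chrom, pos=v.pos, id=v.id, ref=v.ref, alts=[alt],
                    info=v.info, genotypes=v.genotypes,
                ),
                i,
            )
        )
    return out


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, int, str, str]:
    """Trim shared bases and convert to 0-based half-open coordinates.

    The longest shared prefix is removed first, then the longest shared
    suffix (left-aligned canonical form); this also strips the indel/SV
    padding base.  Returns ``(left, right, ref', alt')`` where
    ``right - left == len(ref')``.
    """
    if not ref:
        raise MalformedVariantError("empty REF allele")
    if ref == alt:
        raise MalformedVariantError(f"REF equals ALT ({ref!r})")
    prefix = 0
    limit = min(len(ref), len(alt))
    while prefix < limit and ref[prefix] == alt[prefix]:
        prefix += 1
    r, a = ref[prefix:], alt[prefix:]
    suffix = 0
    limit = min(len(r), len(a))
    while suffix < limit and r[-1 - suffix] == a[-1 - suffix]:
        suffix += 1
    if suffix:
        r, a = r[:-suffix], a[:-suffix]
    left = pos - 1 + prefix
    right = left + len(r)
    return left, right, r, a


def classify_variant(
    ref_trimmed: str, alt_trimmed: str, info: dict | None = None, pos: int | None = None
) -> tuple[str, int]:
    """Assign the mutation type and length of a trimmed allele pair.

    Equal single-base alleles are SNPs, equal multi-base alleles MNPs; an
    empty reference is an insertion and an empty alternative a deletion.
    A record whose INFO carries SVTYPE is a structural variant typed
    ``SV:<SVTYPE>``; its length is END - POS when END is available, else
    \\|SVLEN\\| (an SV with neither is rejected).  Length is the trimmed
    reference length for SNP/MNP/DEL and the trimmed alternative length
    for INS.  Unequal non-empty alleles (complex substitutions) are typed
    DELINS with the replaced reference span as length.
    """
    info = info or {}
    if "SVTYPE" in info:
        svtype = info["SVTYPE"]
        end = info.get("END")
        svlen = info.get("SVLEN")
        if end is not None and pos is not None:
            length = int(end) - int(pos)
        elif svlen is not None:
            sl = svlen[0] if isinstance(svlen, (tuple, list)) else svlen
            length = abs(int(sl))
        else:
            raise MalformedVariantError(
                f"structural variant of type {svtype} lacks both END and SVLEN"
            )
        return f"SV:{svtype}", length
    if not ref_trimmed and not alt_trimmed:
        raise MalformedVariantError("both alleles empty after trimming")
    if not ref_trimmed:
        return "INS", len(alt_trimmed)
    if not alt_trimmed:
        return "DEL", len(ref_trimmed)
    if len(ref_trimmed) == len(alt_trimmed):
        return ("SNP", 1) if len(ref_trimmed) == 1 else ("MNP", len(ref_trimmed))
    return "DELINS", len(ref_trimmed)


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") and alt.endswith(">")


def _is_breakend(alt: str) -> bool:
    return "[" in alt or "]" in alt or alt in (".", "*") or alt.startswith(".") or alt.endswith(".")


def normalize_variant(
    chrom: str,
    pos: int,
    variant_id: str | None,
    ref: str,
    alt: str,
    info: dict | None = None,
    extra: tuple = (),
) -> NormalizedVariant:
    """Rewrite one bi-allelic VCF allele into a GDM region row.

    Sequence alleles go through allele trimming and type classification.
    Symbolic alleles (``<DEL>``, ``<CN2>``, ...) are structural variants:
    the padding base empties the reference, ``left`` is the 0-based
    position after it, and ``right = left + length`` from END/SVLEN.
    Breakends and symbolic alleles without usable END/SVLEN raise
    :class:`SkippedVariantError`.
    """
    info = info or {}
    chrom = normalize_chrom(chrom)
    if _is_breakend(alt):
        raise SkippedVariantError(f"uninterpretable breakend allele {alt!r} at {chrom}:{pos}")
    if _is_symbolic(alt):
        svtype = info.get("SVTYPE") or alt.strip("<>").split(":")[0]
        end = info.get("END")
        svlen = info.get("SVLEN")
        if end is None and svlen is None:
            raise SkippedVariantError(
                f"symbolic allele {alt!r} at {chrom}:{pos} has neither END nor SVLEN"
            )
        mut_type, length = classify_variant("", alt, {**info, "SVTYPE": svtype}, pos=pos)
        left = pos  # padding base at pos-1 (0-based) removed
        return NormalizedVariant(
            chrom=chrom, left=left, right=left + max(length, 0), ref="", alt=alt,
            mut_type=mut_type, length=length, variant_id=variant_id, extra=extra,
        )
    left, right, r, a = normalize_alleles(pos, ref, alt)
    mut_type, length = classify_variant(r, a, info if "SVTYPE" in info else None, pos=pos)
    if mut_type.startswith("SV:"):
        right = left + length
        r = ""
    return NormalizedVariant(
        chrom=chrom, left=left, right=right, ref=r, alt=a,
        mut_type=mut_type, length=length, variant_id=variant_id, extra=extra,
    )


def genotype_to_copies(gt: str, alt_index: int, n_alts: int | None = None) -> GenotypeCall:
    """Decode a GT string into chromatid flags for one alternative allele.

    ``al1``/``al2`` flag whether the left/right chromosome copy carries the
    allele with 1-based index ``alt_index``.  Haploid genotypes fill only
    ``al1``.  A fully missing genotype yields occurrence 0 with
    ``missing=True``.  Unphased heterozygous calls are canonicalized to
    ``AL1=1, AL2=0`` and flagged ``phased=False`` — occurrence is preserved
    but no chromatid claim is made.
    """
    if alt_index < 1:
        raise MalformedVariantError(f"alt_index must be >= 1, got {alt_index}")
    gt = gt.strip()
    if not gt:
        raise MalformedVariantError("empty GT string")
    phased = "/" not in gt
    parts = _GT_SPLIT.split(gt)
    if len(parts) > 2:
        raise MalformedVariantError(f"unsupported ploidy in GT {gt!r}")
    alleles: list[int | None] = []
    for p in parts:
        if p == ".":
            alleles.append(None)
        else:
            try:
                idx = int(p)
            except ValueError:
                raise MalformedVariantError(f"unparseable GT {gt!r}") from None
            if idx < 0 or (n_alts is not None and idx > n_alts):
                raise MalformedVariantError(
                    f"allele index {idx} out of range in GT {gt!r} ({n_alts} alts)"
                )
            alleles.append(idx)
    missing = all(a is None for a in alleles)
    al1 = 1 if alleles[0] == alt_index else 0
    al2 = 1 if len(alleles) == 2 and alleles[1] == alt_index else 0
    if not phased and al1 + al2 == 1:
        al1, al2 = 1, 0
    return GenotypeCall(al1=al1, al2=al2, occurrence=al1 + al2, phased=phased, missing=missing)


# ---------------------------------------------------------------------------
# Dataset-level transformation
# ---------------------------------------------------------------------------


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_metadata_tables(metadata_tables):
    tables = []
    for t in metadata_tables:
        if isinstance(t, pd.DataFrame):
            tables.append(t)
        else:
            sep = "," if str(t).endswith(".csv") else "\t"
            tables.append(pd.read_csv(t, sep=sep, dtype=str))
    return tables


def transform_dataset(
    vcf_paths,
    metadata_tables,
    out_dir,
    *,
    source: str = "local",
    assembly: str = "grch38",
    on_missing_donor: str = "fail",
    keep_info: tuple[str, ...] = (),
    donor_column: str = "donor_id",
    default_health_status: str = "true",
) -> dict:
    """Convert per-chromosome multi-sample VCFs into per-donor GDM file pairs.

    Writes ``<donor>.gdm`` (TSV region rows, no header, sorted by chromosome
    natural order, left, right, ref, alt) and ``<donor>.gdm.meta`` for every
    donor, plus ``schema.yaml`` naming the columns and ``manifest.json``
    summarising the run.  A donor carrying no variant still gets an (empty)
    region file.  Re-running on byte-identical inputs is a no-op: input
    checksums are recorded in the manifest and compared on entry.

    ``on_missing_donor`` controls what happens when a VCF donor has no
    metadata row: ``"fail"`` raises, ``"skip"`` drops the donor.
    """
    if on_missing_donor not in ("fail", "skip"):
        raise ValueError("on_missing_donor must be 'fail' or 'skip'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_paths = [str(p) for p in vcf_paths]
    snapshot_paths = sorted(vcf_paths) + sorted(
        str(t) for t in metadata_tables if not isinstance(t, pd.DataFrame)
    )
    input_hashes = {os.path.basename(p): _md5(p) for p in snapshot_paths}

    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)
        if previous.get("input_hashes") == input_hashes:
            logger.info("inputs unchanged; transformation skipped")
            previous["skipped"] = True
            return previous

    tables = _read_metadata_tables(metadata_tables)
    known_donors = set()
    for t in tables:
        if donor_column in t.columns:
            known_donors.update(t[donor_column].astype(str))

    columns = GDM_FIXED_COLUMNS + ["id"] + list(keep_info)
    rows_by_donor: dict[str, list] = {}
    unphased_donors: set[str] = set()
    donors: list[str] | None = None
    n_input_records = 0
    n_split = 0
    n_skipped = 0
    n_missing_gt = 0

    for path in sorted(vcf_paths):
        vcf = VCF(path)
        samples = list(vcf.samples)
        if donors is None:
            donors = samples
            missing = [d for d in donors if d not in known_donors]
            if missing:
                if on_missing_donor == "fail":
                    raise MetadataConflictError(
                        f"donors missing from metadata: {', '.join(sorted(missing))}"
                    )
                logger.warning("skipping %d donors without metadata", len(missing))
            kept_idx = [i for i, d in enumerate(donors) if d in known_donors]
            for d in donors:
                if d in known_donors:
                    rows_by_donor.setdefault(d, [])
        elif samples != donors:
            raise MalformedVariantError(
                f"VCF {path} has a different donor column set than the first file"
            )
        for rec in vcf:
            n_input_records += 1
            info = dict(rec.INFO)
            extra_vals = tuple(str(info.get(k, "")) for k in keep_info)
            genotypes = rec.genotypes  # [a, b, phased] or [a, phased]
            alts = rec.ALT or []
            for alt_index, alt in enumerate(alts, start=1):
                try:
                    nv = normalize_variant(
                        rec.CHROM, rec.POS, rec.ID, rec.REF, alt, info, extra_vals
                    )
                except SkippedVariantError as exc:
                    logger.warning("skipped allele: %s", exc)
                    n_skipped += 1
                    continue
                n_split += 1
                tail = (
                    nv.ref, nv.alt, nv.mut_type, nv.length,
                    nv.variant_id or "",
                ) + extra_vals
                for i in kept_idx:
                    g = genotypes[i]
                    phased = bool(g[-1])
                    calls = g[:-1]
                    if alt_index == 1 and calls[0] == -1:
                        n_missing_gt += 1
                    al1 = 1 if calls[0] == alt_index else 0
                    al2 = 1 if len(calls) == 2 and calls[1] == alt_index else 0
                    if al1 + al2 == 0:
                        continue
                    if not phased and len(calls) == 2:
                        unphased_donors.add(donors[i])
                        if al1 + al2 == 1:
                            al1, al2 = 1, 0
                    rows_by_donor[donors[i]].append(
                        (nv.chrom, nv.left, nv.right, nv.strand, al1, al2) + tail
                    )

    if donors is None:
        raise MalformedVariantError("no VCF files given")

    rows_written = 0
    for donor in sorted(rows_by_donor):
        rows = sorted(
            rows_by_donor[donor],
            key=lambda r: (chrom_sort_key(r[0]), r[1], r[2], r[6], r[7]),
        )
        with open(out_dir / f"{donor}.gdm", "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
        rows_written += len(rows)
        mutated_chroms = sorted({r[0] for r in rows}, key=chrom_sort_key)
        technical = {
            "pipeline": "popvarsum vcf-to-gdm transformation",
            "phased": "false" if donor in unphased_donors else "true",
        }
        meta = build_donor_metadata(
            tables, donor, technical=technical, donor_column=donor_column,
            default_health_status=default_health_status,
        )
        if not meta.get("assembly"):
            meta.add("assembly", assembly.lower())
        if not meta.get("source"):
            meta.add("source", source.lower())
        for c in mutated_chroms:
            meta.add("manually_curated__chromosome", c)
        meta.entries = meta.sorted_entries()
        write_meta_file(meta, out_dir / f"{donor}.gdm.meta")

    with open(out_dir / "schema.yaml", "w") as fh:
        fh.write("# GDM region file column schema (0-based half-open coordinates)\n")
        fh.write(f"source: {source}\nassembly: {assembly.lower()}\ncolumns:\n")
        for c in columns:
            fh.write(f"  - {c}\n")

    manifest = {
        "source": source,
        "assembly": assembly.lower(),
        "input_hashes": input_hashes,
        "files_processed": len(vcf_paths),
        "file_pairs": len(rows_by_donor),
        "donors": sorted(rows_by_donor),
        "rows_written": rows_written,
        "n_input_records": n_input_records,
        "n_split_records": n_split,
        "n_skipped_symbolic": n_skipped,
        "n_missing_genotypes": n_missing_gt,
        "unphased_donors": sorted(unphased_donors),
        "skipped": False,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
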