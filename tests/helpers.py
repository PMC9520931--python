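"""Shared test utilities: independent oracles and fixture builders.

The oracles here deliberately avoid the package's own code paths:
allele trimming is re-derived by exhaustive search, VCF genotypes are
re-read with pysam (the implementation uses cyvcf2), and occurrence
matrices are rebuilt with plain loops.
"""

from __future__ import annotations

import os
from pathlib import Path

import pysam
import yaml


def trim_oracle(pos: int, ref: str, alt: str):
    """Exhaustive-search trimming oracle.

    Enumerates every (prefix, suffix) removal pair, keeps the valid ones,
    and picks the largest prefix first, then the largest suffix — the
    left-aligned canonical form.  Returns (left, right, ref', alt') in
    0-based half-open coordinates.
    """
    best_p = max(
        p for p in range(min(len(ref), len(alt)) + 1) if ref[:p] == alt[:p]
    )
    r, a = ref[best_p:], alt[best_p:]
    best_s = max(
        s for s in range(min(len(r), len(a)) + 1) if s == 0 or r[-s:] == a[-s:]
    )
    if best_s:
        r, a = r[:-best_s], a[:-best_s]
    left = pos - 1 + best_p
    return left, left + len(r), r, a


def normalize_key_oracle(chrom: str, pos: int, ref: str, alt: str, info=None):
    """Normalized (chrom, left, ref', alt') key of one split VCF allele,
    computed with the exhaustive trimming oracle; symbolic alleles follow
    the padding-base rule with coordinates from END."""
    chrom = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if alt.startswith("<"):
        return (chrom, pos, "", alt)
    left, _right, r, a = trim_oracle(pos, ref, alt)
    return (chrom, left, r, a)


def vcf_occurrence_matrix(vcf_paths) -> set[tuple[str, tuple, int]]:
    """(donor, normalized key, occurrence) triples parsed directly from
    the VCFs with pysam, splitting multi-allelic records."""
    triples = set()
    for path in vcf_paths:
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            info = dict(rec.info)
            for ai, alt in enumerate(rec.alts or (), start=1):
                key = normalize_key_oracle(rec.chrom, rec.pos, rec.ref, alt, info)
                for donor, sample in rec.samples.items():
                    gt = sample["GT"]
                    occ = sum(1 for g in gt if g == ai)
                    if occ:
                        triples.add((donor, key, occ))
    return triples


def gdm_occurrence_matrix(gdm_dir) -> set[tuple[str, tuple, int]]:
    """(donor, normalized key, occurrence) triples re-read from the GDM
    output files with plain text parsing."""
    gdm_dir = Path(gdm_dir)
    columns = yaml.safe_load((gdm_dir / "schema.yaml").read_text())["columns"]
    i = {c: k for k, c in enumerate(columns)}
    triples = set()
    for f in sorted(gdm_dir.glob("*.gdm")):
        donor = f.name[: -len(".gdm")]
        for line in f.read_text().splitlines():
            v = line.split("\t")
            key = (v[i["chr"]], int(v[i["left"]]), v[i["ref"]], v[i["alt"]])
            occ = int(v[i["AL1"]]) + int(v[i["AL2"]])
            triples.add((donor, key, occ))
    return triples


def truth_matrix_normalized(truth) -> set[tuple[str, tuple, int]]:
    """The TruthSet occurrence matrix re-keyed with the trimming oracle so
    it is comparable with GDM outputs."""
    out = set()
    for donor, row in truth.occurrence.items():
        for raw_key, occ in row.items():
            chrom, pos, ref, alt = raw_key.split(":")
            out.add((donor, normalize_key_oracle(chrom, int(pos), ref, alt), occ))
    return out


def build_cohort(tmp_path, config, source="kg_synth", keep_info=()):
    """Generate a cohort, transform it, load it, and wire up the engine
    plus the naive full-scan dataset.  Returns a dict of the pieces."""
    from popvarsum.bruteforce import load_naive
    from popvarsum.datastore import VariantStore
    from popvarsum.popquery import QueryEngine
    from popvarsum.synthio import synth_assembly, synth_cohort
    from popvarsum.variant_transform import transform_dataset

    raw = Path(tmp_path) / "raw"
    gdm = Path(tmp_path) / "gdm"
    truth = synth_cohort(config, raw)
    vcfs = sorted(
        str(p) for p in raw.iterdir()
        if p.name.endswith(".vcf") or p.name.endswith(".vcf.gz")
    )
    tables = [str(raw / "donors.tsv"), str(raw / "platforms.tsv")]
    manifest = transform_dataset(
        vcfs, tables, gdm, source=source, assembly=config.assembly_name,
        keep_info=keep_info,
    )
    store = VariantStore()
    store.load_gdm_dataset(gdm, source)
    store.load_annotations(raw / "genes.gtf", "genes", assembly=config.assembly_name)
    assembly = synth_assembly(config)
    engine = QueryEngine(store, assembly)
    genes = {g["name"]: (g["chrom"], g["start"], g["stop"]) for g in truth.genes}
    naive = load_naive(gdm, genes=genes, par=assembly.par)
    return {
        "truth": truth,
        "raw": raw,
        "gdm": gdm,
        "vcfs": vcfs,
        "manifest": manifest,
        "store": store,
        "engine": engine,
        "naive": naive,
        "assembly": assembly,
        "config": config,
    }
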