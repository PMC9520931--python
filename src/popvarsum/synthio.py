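"""Seeded synthetic cohorts: phased multi-sample VCFs with known ground truth.

The generator emulates the shape of a population-variation release: one
multi-sample VCF per chromosome with phased GT-only genotypes, a donor
metadata table (plus a second, multi-valued table to exercise repeatable
keys), a gene annotation GTF, and an assembly description with
pseudoautosomal intervals.  Sex chromosomes are generated with realistic
ploidy: males are haploid on non-PAR X and on Y, females carry no Y, and
the mitochondrial chromosome is haploid for everyone.

Allele frequencies are drawn from a rare-skewed Beta(0.2, 2) spectrum by
default.  Every random draw flows from a single seed, and the emitted
TruthSet records the exact donor-by-variant occurrence matrix, per-variant
allele counts, donor labels and gene intervals, so downstream modules can
be verified against construction rather than against themselves.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .assembly import AssemblyModel
from .errors import InfeasibleConfigError, UnknownGeneError

__all__ = [
    "SynthConfig",
    "TruthSet",
    "synth_cohort",
    "plant_differential_gene",
    "gene_layout",
    "synth_assembly",
]

_BASES = "ACGT"


class SynthConfig(BaseModel):
    """Configuration of a synthetic cohort; the seed fixes all randomness."""

    n_donors: int = Field(default=100, ge=1)
    chromosomes: list[str] = ["1", "2"]
    chrom_length: int = Field(default=100_000, ge=1000)
    n_variants_per_chrom: int = Field(default=100, ge=1)
    af_alpha: float = Field(default=0.2, gt=0)
    af_beta: float = Field(default=2.0, gt=0)
    frac_multiallelic: float = Field(default=0.10, ge=0, le=1)
    frac_indel: float = Field(default=0.15, ge=0, le=1)
    frac_sv: float = Field(default=0.05, ge=0, le=1)
    male_fraction: float = Field(default=0.5, ge=0, le=1)
    unknown_gender_fraction: float = Field(default=0.0, ge=0, le=1)
    populations: list[str] = ["CEU", "TSI", "YRI", "LWK", "MXL", "GIH", "CHB", "KHV"]
    tumor_fraction: float = Field(default=0.0, ge=0, le=1)
    disease: str = "skin cutaneous melanoma"
    phased: bool = True
    missing_rate: float = Field(default=0.0, ge=0, le=1)
    n_genes_per_chrom: int = Field(default=4, ge=0)
    assembly_name: str = "synth1"
    par_fraction: float = Field(default=0.05, ge=0, le=0.4)
    planted_gene: str | None = None
    burden_ratio: float = Field(default=1.0, gt=0)
    gzip_vcf: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check_fractions(self):
        if self.frac_multiallelic + self.frac_indel + self.frac_sv > 1:
            raise ValueError("variant-type fractions sum to more than 1")
        return self


@dataclass
class TruthSet:
    """Ground truth of a generated cohort, consistent with the emitted
    files by construction."""

    donors: dict[str, dict]  # donor_id -> labels
    variants: list[dict]  # per split (bi-allelic) alt
    occurrence: dict[str, dict[str, int]]  # donor -> variant key -> 1 or 2
    allele_counts: dict[str, dict]  # variant key -> occurrence/total/frequency
    genes: list[dict]
    planted_gene: str | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "donors": self.donors,
                    "variants": self.variants,
                    "occurrence": self.occurrence,
                    "allele_counts": self.allele_counts,
                    "genes": self.genes,
                    "planted_gene": self.planted_gene,
                    "config": self.config,
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)

    def occurrence_matrix(self) -> set[tuple[str, str, int]]:
        """(donor, variant key, occurrence) triples with occurrence >= 1."""
        return {
            (d, k, o)
            for d, row in self.occurrence.items()
            for k, o in row.items()
        }


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Raw (pre-normalization) key of one split VCF allele."""
    return f"{chrom}:{pos}:{ref}:{alt}"


def synth_assembly(config: SynthConfig) -> AssemblyModel:
    """The assembly implied by a config: every chromosome has the same
    length; X and Y carry a PAR at each end covering ``par_fraction`` of
    the chromosome."""
    L = config.chrom_length
    par_len = int(L * config.par_fraction)
    par = {}
    for c in ("X", "Y"):
        if c in config.chromosomes and par_len > 0:
            par[c] = [(0, par_len), (L - par_len, L)]
    return AssemblyModel(
        name=config.assembly_name,
        chromosomes={c: L for c in config.chromosomes},
        par=par,
    )


def gene_layout(config: SynthConfig) -> list[dict]:
    """Deterministic non-overlapping gene intervals (0-based half-open):
    ``n_genes_per_chrom`` equal blocks separated by intergenic gaps."""
    genes = []
    n = config.n_genes_per_chrom
    L = config.chrom_length
    for chrom in config.chromosomes:
        for k in range(n):
            start = L * (2 * k + 1) // (2 * n + 1)
            stop = L * (2 * k + 2) // (2 * n + 1)
            genes.append(
                {"name": f"GENE_{chrom}_{k + 1}", "chrom": chrom, "start": start, "stop": stop}
            )
    return genes


def plant_differential_gene(config: SynthConfig, gene: str, burden_ratio: float) -> SynthConfig:
    """Return a config whose tumor-cohort allele probabilities inside
    ``gene`` are scaled by ``burden_ratio`` (capped at 0.95)."""
    names = [g["name"] for g in gene_layout(config)]
    if gene not in names:
        raise UnknownGeneError(gene, near_matches=names[:5])
    return config.model_copy(update={"planted_gene": gene, "burden_ratio": burden_ratio})


def _draw_alleles(rng, probs: np.ndarray) -> np.ndarray:
    """Vector draw of one chromosome copy per donor: returns the 1-based
    alt index carried (0 = reference).  ``probs`` has shape (n_donors,
    n_alts)."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    out = np.zeros(probs.shape[0], dtype=int)
    for j in range(probs.shape[1] - 1, -1, -1):
        out = np.where(u < cum[:, j], j + 1, out)
    return out


def synth_cohort(config: SynthConfig, out_dir) -> TruthSet:
    """Generate the cohort files under ``out_dir`` and return the TruthSet.

    Emits one ``chr<label>.vcf``(.gz) per chromosome, ``donors.tsv`` and
    ``platforms.tsv`` metadata tables, ``genes.gtf``, ``assembly.yaml`` and
    ``truth.json``.
    """
    if "Y" in config.chromosomes and config.male_fraction == 0:
        raise InfeasibleConfigError("Y-chromosome variants require at least some males")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    assembly = synth_assembly(config)
    genes = gene_layout(config)
    planted = None
    if config.planted_gene is not None:
        planted = next(g for g in genes if g["name"] == config.planted_gene)

    # --- donors -------------------------------------------------------
    donor_ids = [f"D{i:04d}" for i in range(config.n_donors)]
    u = rng.random(config.n_donors)
    genders = np.where(u < config.male_fraction, "male", "female")
    genders = np.where(
        rng.random(config.n_donors) < config.unknown_gender_fraction, "unknown", genders
    )
    if "Y" in config.chromosomes and not (genders == "male").any():
        raise InfeasibleConfigError("Y-chromosome variants require at least one male donor")
    populations = rng.choice(config.populations, size=config.n_donors)
    tumor = rng.random(config.n_donors) < config.tumor_fraction
    donors = {
        d: {
            "gender": str(genders[i]),
            "population": str(populations[i]),
            "health_status": "false" if tumor[i] else "true",
            "disease": config.disease if tumor[i] else "",
        }
        for i, d in enumerate(donor_ids)
    }

    # generation-time ploidy per donor for a (chrom, pos); unknown gender
    # is generated female-like, the query layer decides how to count it
    def gen_ploidy(chrom: str, pos: int) -> np.ndarray:
        if chrom == "MT":
            return np.ones(config.n_donors, dtype=int)
        if chrom == "X":
            if assembly.in_par("X", pos):
                return np.full(config.n_donors, 2)
            return np.where(genders == "male", 1, 2)
        if chrom == "Y":
            p = 2 if assembly.in_par("Y", pos) else 1
            return np.where(genders == "male", p, 0)
        return np.full(config.n_donors, 2)

    occurrence: dict[str, dict[str, int]] = {d: {} for d in donor_ids}
    allele_counts: dict[str, dict] = {}
    variants_truth: list[dict] = []
    rs_counter = 1

    # ---- phase 1: variant descriptors (positions, alleles, frequencies) ---
    descs: dict[str, list[dict]] = {}
    for chrom in config.chromosomes:
        L = config.chrom_length
        n_var = config.n_variants_per_chrom
        positions = np.sort(
            rng.choice(np.arange(10, L - 300), size=n_var, replace=False)
        )
        type_u = rng.random(n_var)
        chrom_descs = []
        for vi in range(n_var):
            pos = int(positions[vi])  # 1-based VCF position
            tu = type_u[vi]
            info_str = "."
            end = None
            if tu < config.frac_sv:
                ref = _BASES[rng.integers(4)]
                alts = ["<DEL>"]
                end = min(pos + int(rng.integers(50, 200)), L - 1)
                info_str = f"SVTYPE=DEL;END={end}"
            elif tu < config.frac_sv + config.frac_indel:
                b = _BASES[rng.integers(4)]
                seq = "".join(_BASES[j] for j in rng.integers(0, 4, size=int(rng.integers(1, 4))))
                if rng.random() < 0.5:
                    ref, alts = b, [b + seq]  # insertion
                else:
                    ref, alts = b + seq, [b]  # deletion
            elif tu < config.frac_sv + config.frac_indel + config.frac_multiallelic:
                ref = _BASES[rng.integers(4)]
                others = [x for x in _BASES if x != ref]
                pick = rng.permutation(3)[:2]
                alts = [others[pick[0]], others[pick[1]]]
            else:
                ref = _BASES[rng.integers(4)]
                alts = [x for x in _BASES if x != ref][rng.integers(3)]
                alts = [alts]

            probs = rng.beta(config.af_alpha, config.af_beta, size=len(alts))
            if probs.sum() > 0.9:
                probs = probs * (0.9 / probs.sum())
            chrom_descs.append(
                {"pos": pos, "ref": ref, "alts": alts, "probs": probs,
                 "info_str": info_str, "end": end}
            )
        descs[chrom] = chrom_descs

    # ---- phase 2: planted-gene scaling --------------------------------
    # Planting must construct the study condition, not merely nudge it:
    # the factor applied to the gene's allele probabilities (for tumor
    # donors) is chosen so that the gene's expected tumor burden is
    # burden_ratio times the strongest other gene's, within the 0.95
    # per-copy probability cap.
    plant_factor = 1.0
    if planted is not None and config.burden_ratio != 1.0:
        tumor_ploidy = {
            chrom: {
                d["pos"]: int(gen_ploidy(chrom, d["pos"])[tumor].sum())
                for d in descs[chrom]
            }
            for chrom in config.chromosomes
        }

        def in_gene(g, chrom, pos):
            return chrom == g["chrom"] and g["start"] <= pos - 1 < g["stop"]

        def expected_burden(g, factor=1.0):
            total = 0.0
            for chrom in config.chromosomes:
                for d in descs[chrom]:
                    if not in_gene(g, chrom, d["pos"]):
                        continue
                    p = np.minimum(np.asarray(d["probs"]) * factor, 0.95)
                    total += float(p.sum()) * tumor_ploidy[chrom][d["pos"]]
            return total

        others = max(
            (expected_burden(g) for g in genes if g["name"] != planted["name"]),
            default=0.0,
        )
        target = config.burden_ratio * others
        if expected_burden(planted, 1e9) < target:
            raise InfeasibleConfigError(
                f"cannot plant {planted['name']} at {config.burden_ratio}x: "
                "too few variants in the gene even at saturated frequencies"
            )
        lo, hi = 1.0, 1e9
        for _ in range(60):
            mid = (lo * hi) ** 0.5
            if expected_burden(planted, mid) >= target:
                hi = mid
            else:
                lo = mid
        plant_factor = hi

    # ---- phase 3: genotypes, VCF emission, truth ----------------------
    for chrom in config.chromosomes:
        L = config.chrom_length
        lines = []
        for desc in descs[chrom]:
            pos = desc["pos"]
            ref, alts, probs = desc["ref"], desc["alts"], desc["probs"]
            info_str, end = desc["info_str"], desc["end"]

            # per-donor probability matrix (planted gene inflates tumor donors)
            pmat = np.tile(probs, (config.n_donors, 1))
            if (
                planted is not None
                and plant_factor != 1.0
                and chrom == planted["chrom"]
                and planted["start"] <= pos - 1 < planted["stop"]
            ):
                pmat[tumor] = np.minimum(pmat[tumor] * plant_factor, 0.95)

            ploidy = gen_ploidy(chrom, pos)
            copy1 = _draw_alleles(rng, pmat)
            copy2 = _draw_alleles(rng, pmat)
            miss = rng.random(config.n_donors) < config.missing_rate
            copy1 = np.where(ploidy >= 1, copy1, 0)
            copy2 = np.where(ploidy == 2, copy2, 0)

            vid = f"rs{rs_counter}"
            rs_counter += 1

            gts = []
            sep = "|" if config.phased else "/"
            for i in range(config.n_donors):
                if ploidy[i] == 0 or miss[i]:
                    gts.append(".")
                elif ploidy[i] == 1:
                    gts.append(str(copy1[i]))
                else:
                    gts.append(f"{copy1[i]}{sep}{copy2[i]}")

            lines.append(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{','.join(alts)}\t.\tPASS\t{info_str}\tGT\t"
                + "\t".join(gts)
            )

            for ai, alt in enumerate(alts, start=1):
                key = variant_key(chrom, pos, ref, alt)
                eff1 = np.where(miss | (ploidy < 1), 0, (copy1 == ai).astype(int))
                eff2 = np.where(miss | (ploidy < 2), 0, (copy2 == ai).astype(int))
                occ = eff1 + eff2
                total = int(np.where(miss, 0, ploidy).sum())
                for i, d in enumerate(donor_ids):
                    if occ[i]:
                        occurrence[d][key] = int(occ[i])
                allele_counts[key] = {
                    "occurrence": int(occ.sum()),
                    "total_alleles": total,
                    "frequency": (int(occ.sum()) / total) if total else None,
                    "p": float(probs[ai - 1]),
                }
                variants_truth.append(
                    {
                        "chrom": chrom, "pos": pos, "id": vid, "ref": ref, "alt": alt,
                        "alt_index": ai, "p": float(probs[ai - 1]),
                        "type": "SV" if alt.startswith("<") else "SEQ",
                        **({"end": end} if end is not None else {}),
                    }
                )

        header = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom},length={L}>",
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
            '##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Difference in length">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(donor_ids),
        ]
        text = "\n".join(header + lines) + "\n"
        if config.gzip_vcf:
            with gzip.open(out_dir / f"chr{chrom}.vcf.gz", "wt") as fh:
                fh.write(text)
        else:
            with open(out_dir / f"chr{chrom}.vcf", "w") as fh:
                fh.write(text)

    # --- metadata tables ---------------------------------------------
    with open(out_dir / "donors.tsv", "w") as fh:
        fh.write("donor_id\tgender\tpopulation\thealth_status\tdisease\tdna_source\n")
        for d in donor_ids:
            row = donors[d]
            fh.write(
                f"{d}\t{row['gender']}\t{row['population']}\t{row['health_status']}"
                f"\t{row['disease']}\tblood\n"
            )
    platforms = ["illumina hiseq 2000", "illumina hiseq 2500", "illumina novaseq 6000"]
    with open(out_dir / "platforms.tsv", "w") as fh:
        fh.write("donor_id\tplatform\n")
        for i, d in enumerate(donor_ids):
            fh.write(f"{d}\t{platforms[i % 3]}\n")
            if i % 5 == 0:  # some donors sequenced on two platforms
                fh.write(f"{d}\t{platforms[(i + 1) % 3]}\n")

    # --- annotations and assembly ------------------------------------
    with open(out_dir / "genes.gtf", "w") as fh:
        for g in genes:
            fh.write(
                f"{g['chrom']}\tsynth\tgene\t{g['start'] + 1}\t{g['stop']}\t.\t+\t.\t"
                f'gene_id "{g["name"]}"; gene_name "{g["name"]}";\n'
            )
    with open(out_dir / "assembly.yaml", "w") as fh:
        fh.write(f"name: {assembly.name}\nchromosomes:\n")
        for c, ln in assembly.chromosomes.items():
            fh.write(f'  "{c}": {ln}\n')
        fh.write("par:\n")
        for c, ivs in assembly.par.items():
            fh.write(f"  {c}:\n")
            for s, e in ivs:
                fh.write(f"    - [{s}, {e}]\n")

    # realized tumor burden per gene (sum of occurrences among tumor donors)
    genes_by_chrom: dict[str, list[dict]] = {}
    for g in genes:
        g["tumor_burden"] = 0
        genes_by_chrom.setdefault(g["chrom"], []).append(g)
    for i, d in enumerate(donor_ids):
        if not tumor[i]:
            continue
        for raw, occ in occurrence[d].items():
            chrom, pos = raw.split(":")[:2]
            for g in genes_by_chrom.get(chrom, ()):
                if g["start"] <= int(pos) - 1 < g["stop"]:
                    g["tumor_burden"] += occ

    truth = TruthSet(
        donors=donors,
        variants=variants_truth,
        occurrence={d: row for d, row in occurrence.items() if row},
        allele_counts=allele_counts,
        genes=genes,
        planted_gene=config.planted_gene,
        config=json.loads(config.model_dump_json()),
    )
    truth.to_json(out_dir / "truth.json")
    return truth
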