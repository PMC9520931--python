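# popvarsum

Population variant summarization over per-donor genomic datasets: a
toolkit for turning multi-sample VCF releases into a queryable cohort
store and asking fine-grained questions about arbitrary donor
populations — who carries what, on which chromosome copy, and how often.

It is aimed at researchers who want gnomAD-style aggregate answers but
over populations *they* define: "female donors of white or asian
ethnicity carrying variant X but not variant Y, with both constraints on
the same chromatid", rather than pre-computed whole-cohort statistics.

## What it does

**VCF → GDM transformation.** A chromosome-wise, multi-sample VCF is
rewritten into one region file + one metadata file per donor (the GDM
file pair). Multi-allelic records are split into bi-allelic ones;
coordinates become 0-based half-open; bases shared between REF and ALT
(including the indel/SV padding base) are trimmed away; each row carries
AL1/AL2 flags telling which chromosome copy holds the alternative
allele, decoded from the phased genotype. Stop coordinates follow the
per-type rules: SNP/MNP span the substituted bases, insertions are
zero-length points, deletions span the removed reference sequence.

**Metadata distribution.** Source metadata tables are distributed into
per-donor key/value multimaps. An `ethnicity` attribute is derived from
the 1KGP-style population code via a shipped 26-code mapping table
(5 super populations, 4 ethnicity labels), enabling cross-source cohort
selection.

**Embedded store + query engine.** GDM datasets load into a SQLite-backed
store, one region table per source plus a flattened metadata view. Each
source declares its filtering capabilities; a query runs only on sources
that support every category it references (e.g. chromatid constraints
need AL1/AL2). Eight endpoint semantics are provided: donor grouping,
variant frequency grouping, most-common / rarest variant ranking,
distinct metadata values, gene annotation, variants-in-region listing,
and cohort export — each guarded by a configurable minimum-donor privacy
threshold.

Frequencies use sex-aware allele totals: for a donor set the denominator
at a locus is the sum of per-donor ploidies — 2 on autosomes, 1 on MT,
and on X/Y whatever the donor's gender and the assembly's
pseudoautosomal regions imply (PAR intervals for hg19 and GRCh38 ship as
editable YAML).

**Differential gene scoring.** For a cohort *c* and gene *G*:

```
S(G, c) = Σ_{v ∈ variants(G, c)} count_c(v) / size(c)
```

where `count_c(v)` sums each donor's 0–2 copies. Scores are
rank-normalized per cohort (top gene = 1.0, others proportional), and
genes are ranked by the difference of normalized scores between a tumor
and a healthy cohort — a cohort-level simplification of per-donor
mutational-profile methods.

**Synthetic cohorts.** A seeded generator emits phased multi-sample
VCFs (with X/Y/MT ploidy by gender, multi-allelic sites, indels, SVs,
missing calls), metadata tables, gene GTFs and a ground-truth occurrence
matrix, so the whole pipeline is testable without any data download.

## Worked example

```python
import os
from popvarsum import (SynthConfig, synth_cohort, transform_dataset,
                       VariantStore, QueryEngine)
from popvarsum.synthio import synth_assembly
from popvarsum.interface import dispatch

cfg = SynthConfig(n_donors=100, chromosomes=["1", "X"],
                  n_variants_per_chrom=200, seed=11)
synth_cohort(cfg, "work/raw")
vcfs = sorted(f"work/raw/{f}" for f in os.listdir("work/raw") if f.endswith(".vcf"))
manifest = transform_dataset(
    vcfs, ["work/raw/donors.tsv", "work/raw/platforms.tsv"],
    "work/gdm", source="kg_synth", assembly="synth1")

store = VariantStore()
store.load_gdm_dataset("work/gdm", "kg_synth")
store.load_annotations("work/raw/genes.gtf", "genes", assembly="synth1")
engine = QueryEngine(store, synth_assembly(cfg))

dispatch(engine, "donor_grouping",
         {"meta": {"ethnicity": ["white", "asian"]},
          "group_by": ["ethnicity", "gender"]})
```

The transformation reports `file pairs: 100 | region rows: 5649 |
split variants: 448` — 100 donors each got a GDM pair, and the 400 VCF
records (some multi-allelic) became 448 bi-allelic variants. The
grouping returns a data cube:

```json
{"group_by": ["ethnicity", "gender"],
 "rows": [{"key": ["asian", "female"], "count": 16},
          {"key": ["asian", "male"],   "count": 24},
          {"key": ["white", "female"], "count": 12},
          {"key": ["white", "male"],   "count": 17}]}
```

Asking for the frequency of the most common X-chromosome variant by
gender shows the sex-aware denominators at work — 43 females contribute
86 alleles but 57 males only 57 at this non-PAR locus:

```json
{"group_by": ["gender"],
 "rows": [
   {"key": ["female"], "OCCURRENCE_OF_TARGET_VARIANT": 71,
    "POPULATION_SIZE": 43, "total_alleles": 86, "frequency": 0.8256},
   {"key": ["male"],   "OCCURRENCE_OF_TARGET_VARIANT": 47,
    "POPULATION_SIZE": 57, "total_alleles": 57, "frequency": 0.8246}]}
```

The same flows are available from the shell:

```bash
popvarsum synth --config synth.yaml --out raw/
popvarsum transform --vcf-dir raw/ --meta-dir raw/ --assembly synth1 --out gdm/
popvarsum load --gdm-dir gdm/ --source kg_synth --db store.db
popvarsum load-annotations --gtf raw/genes.gtf --source genes --db store.db
popvarsum query donor_grouping --body body.json --db store.db --assembly raw/assembly.yaml
popvarsum diff-genes --tumor tumor.json --healthy healthy.json \
    --genes genes.txt --db store.db --assembly raw/assembly.yaml
```

## Layout

- `src/popvarsum/variant_transform.py` — VCF→GDM rewriting rules
- `src/popvarsum/metadata_transform.py` — metadata multimaps, ethnicity mapping
- `src/popvarsum/datastore.py` — embedded store, capability descriptors
- `src/popvarsum/popquery.py` — population selection, grouping, frequency, ranking, export
- `src/popvarsum/genescore.py` — cohort gene scores and differential ranking
- `src/popvarsum/synthio.py` — seeded synthetic cohorts with ground truth
- `src/popvarsum/bruteforce.py` — naive full-scan reference implementations
- `src/popvarsum/assembly.py` + `data/` — PAR-aware ploidy model, mapping tables
- `src/popvarsum/interface.py`, `cli.py` — request validation, dispatch, CLI

See `docs/methods.md` for the modelling choices and their rationale.
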