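# Methods

This note documents the model and the design choices behind popvarsum:
what the transformation and query semantics are, which parameters
matter, what the synthetic cohorts do and do not emulate, and where the
design was genuinely open.

## Variant rewriting

A VCF record is a 1-based, padded, possibly multi-allelic description of
one site across all donors. The per-donor region representation needs
independent bi-allelic intervals, so every record is rewritten:

1. **Splitting.** One output per alternative allele, in ALT-column
   order; the 1-based allele index is kept so genotypes can be decoded
   per allele.
2. **Trimming.** The longest shared prefix of REF/ALT is removed first,
   then the longest shared suffix. Prefix-first trimming yields the
   left-aligned canonical form and also removes the padding base VCF
   uses to anchor indels and structural variants. After trimming, the
   residual alleles never share a first or last character (one may be
   empty).
3. **Coordinates.** `left` is the 0-based position of the residual
   reference span; `right = left + len(ref')`. Insertions therefore
   have `left == right` (a point between two bases), deletions span the
   removed sequence, SNP/MNP span the substituted bases.
4. **Type and length.** SNP (1 bp), MNP (equal lengths > 1), INS
   (`length = len(alt')`), DEL (`length = len(ref')`). Unequal non-empty
   residues — which a VCF can legally encode — are typed DELINS with the
   replaced reference span as length. Symbolic alleles (`<DEL>`,
   `<CN2>`, ...) are structural variants: `length = END − POS` when END
   is present, else `|SVLEN|`; `left = POS` (after the padding base) and
   `right = left + length`; the reference is emptied. A symbolic allele
   with neither END nor SVLEN, and any breakend, is skipped with a
   warning and counted in the manifest — the interval it denotes cannot
   be reconstructed.
5. **Genotype decoding.** `AL1`/`AL2` flag whether the left/right
   chromosome copy carries the allele; occurrence = AL1 + AL2 ∈ {0,1,2}.
   Haploid calls fill AL1 only. The strand column is constant `'+'`.

Only rows with occurrence ≥ 1 are stored; absence is implicit. Output
rows are sorted by (chromosome natural order, left, right, ref, alt) so
repeated runs are byte-identical, and the transformation manifest
records input checksums so a re-run on unchanged inputs is a no-op.

**Unphased and missing genotypes.** The intended inputs are phased.
When an unphased diploid call appears, occurrence is preserved,
heterozygous calls are canonicalized to AL1=1/AL2=0, and the donor is
marked `manually_curated__phased=false`; the query engine excludes such
donors from same-copy/opposite-copy constraints, since their chromatid
assignment would be fabricated. A fully missing genotype (`.`) counts
as occurrence 0 and is tallied in a per-dataset missingness report.
These two policies are this package's choices; reasonable alternatives
exist (e.g. dropping unphased donors entirely).

## Metadata

Each donor's metadata is a multimap: repeated keys represent genuinely
multi-valued attributes (a donor sequenced on two platforms has two
`platform` entries). Keys are lower-cased; values are lower-cased except
donor ids and population codes. A single-valued key that disagrees
across source tables is a hard error — silent precedence would corrupt
the one thing a metadata repository must guarantee. `ethnicity`,
`super_population` and `in_diaspora` are derived from the population
code through the shipped 26-code table (5 super populations, 4 ethnicity
labels); `health_status` defaults to `true` because the intended donors
are control-population individuals, and is configurable for disease
datasets. The `in_diaspora` flag is stored but no query consumes it.

## Store and eligibility

The store keeps one region table per source, a long key/value metadata
table, and a per-source flattened view of the single-valued attributes.
Multi-valued keys are filterable (via the long table) but not groupable:
a donor with two platform values has no unique group assignment.

Every source advertises a capability set — `meta:<attribute>` for each
metadata key plus region categories (variant presence/absence, region
presence, variant-by-id, same/opposite chromatid). A filter is answered
by exactly the sources whose capabilities form a superset of the
categories it references; chromatid capabilities are only advertised
when AL1/AL2 columns exist. When several sources answer, per-source
donor sets are unioned with duplicate elimination, so loading the same
cohort under two names changes no count.

## Allele totals and frequency

Frequency = occurrence / total alleles, where total alleles sums
per-donor ploidy at the locus:

| context | female | male |
|---|---|---|
| autosome | 2 | 2 |
| MT | 1 | 1 |
| X in PAR | 2 | 2 |
| X outside PAR | 2 | 1 |
| Y in PAR | 0 | 2 |
| Y outside PAR | 0 | 1 |

PAR intervals are data, not code: `data/par_hg19.yaml` and
`data/par_grch38.yaml` carry the GRC-published PAR1/PAR2 intervals in
0-based half-open form, and synthetic assemblies define their own.
Donors of unknown gender are excluded from sex-chromosome totals (with
a warning) and counted normally elsewhere. Y-in-PAR ploidy 2 for males
is a documented convention — counting PAR copies on the Y rather than
attributing them to X. Donors with a missing genotype at the target
site still contribute their full ploidy to the denominator; whether to
exclude them is a judgment call, and excluding them would overstate
the frequency of well-genotyped variants. A group whose total is zero
(e.g. a Y locus in an all-female group) reports frequency `null`,
never 0 — zero would assert absence.

Rankings sort by frequency (descending for most-common, ascending for
rarest) with the fully deterministic tie-break (chromosome natural
order, left, ref, alt). Region membership of a variant is judged by its
left coordinate, so a deletion straddling a region boundary belongs to
the region containing its start. For annotation overlap a variant is
its `[left, right)` span; an insertion is a zero-length point that must
fall strictly inside a gene to be annotated to it.

All query coordinates are 0-based half-open, matching the store; the
CLI's `--one-based` flag converts request bodies on entry.

## Privacy guard

Any response reporting a positive donor count below the configured
minimum is refused with a distinct error. The default threshold is 1
(guard off) for local use: the refusal semantics matter for a shared
deployment, not a laptop. Counts of zero are never refused — an empty
group reveals only absence.

## Gene scores

`S(G, c)` divides the cohort's total occurrence of the gene's variants
by cohort size; rank normalization divides by the per-cohort maximum,
so the top gene scores 1.0 and the rest scale proportionally ("rank"
here means anchoring the top, not using rank positions — division by
the maximum is the only reading that is both proportional and anchored
at 1.0). The differential ranking orders genes by the difference of
normalized scores between cohorts; it is antisymmetric under swapping
cohorts and bounded in [−1, 1]. Variants are counted once per
(chromosome, left, ref, alt) key; overlapping genes both count a shared
variant. Normalization is computed over the supplied candidate list —
scores against a larger gene universe would scale differently.

## Synthetic cohorts

The generator emulates the *shape* of a population release: phased
multi-sample per-chromosome VCFs, GT-only FORMAT, multi-allelic sites,
indels, symbolic deletions with END, missing calls, metadata tables
(one single-valued, one multi-valued), a gene GTF, and an assembly with
PAR intervals. Allele frequencies are drawn per alternative allele from
Beta(0.2, 2) — a rare-skewed spectrum resembling population data —
and genotypes are independent per chromosome copy, Bernoulli(p), with
ploidy by gender and PAR status (males haploid on non-PAR X and Y,
females without Y, everyone haploid on MT).

It deliberately does **not** emulate linkage disequilibrium, pedigree
structure, mutation-rate heterogeneity, or sequencing error. Passing
tests therefore demonstrate the correctness of the bookkeeping —
splitting, trimming, chromatid assignment, ploidy-aware counting, query
algebra — on realistic file shapes, not robustness to real-data
artefacts such as half-calls, genotype-quality filtering, or reference
errors.

**Planted differential genes.** `plant_differential_gene` constructs
the scenario the recovery experiments assume: the planted gene's
*expected* tumor-cohort burden equals `burden_ratio` times the
strongest other gene's. The per-variant allele probabilities of tumor
donors inside the gene are scaled by a common factor found by
bisection, with each probability capped at 0.95 per copy. When the cap
makes the target unreachable (a frequency draw where another gene is
already near saturation), the generator raises an infeasibility error
rather than planting a weaker signal; replicate experiments then move
to the next seed. Recovery experiments use 40 donors (half tumor), one
chromosome with 150 sites, and 5 genes — small enough that 100
replicates run in seconds per replicate, large enough that each gene
holds a dozen variant sites.

## Numerical and degenerate-input choices

- Trimming is pure string comparison; no floating point enters until
  frequency division, and oracle comparisons allow 1e-12 there.
- An empty `.gdm` file (a donor carrying nothing) is valid and loads as
  zero rows; the donor still exists for metadata queries.
- Grouping keys with a missing attribute value group under the empty
  string rather than being dropped.
- `rank_normalize` of all-zero scores returns all zeros (no division).
- Duplicate (donor, variant) rows, schema/column mismatches, unknown
  attributes, unknown genes (with near-match suggestions), unknown
  population codes, and reuse of a source name are all hard errors.

## Problem sizes used by the checks

The bundled verification runs use a 500-donor cohort with 1,000 sites
on each of chromosomes 1, 2, X, Y and MT (~5,400 split variants,
~300,000 occurrence triples) for the round-trip, oracle-equivalence,
allele-total and chromatid checks, and 100 seeded replicates of the
40-donor planted-gene experiment. These sizes keep a full from-scratch
run of `scripts/acceptance.py` around one minute on a single CPU while
leaving none of the checks trivially small.

## Known limitations

- Breakends and symbolic alleles without END/SVLEN are dropped (with
  counts), so datasets dominated by complex SVs lose information.
- MAF-format input, assembly liftover, and VCF re-export are out of
  scope; the GDM pair is the only output format.
- The embedded SQLite store targets desk-scale cohorts (≤ a few
  thousand donors); whole-genome-scale ranking would need the
  pre-computation strategies a server deployment would add.
- The HTTP façade is not included; the CLI and `dispatch()` provide the
  same endpoint semantics for scripting.
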