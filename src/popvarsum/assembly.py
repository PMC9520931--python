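"""Assembly model: chromosome inventory, pseudoautosomal regions, ploidy.

Allele frequencies over a cohort need a denominator — the total number of
chromosome copies the cohort carries at a locus.  On autosomes that is two
per donor, but on the sex chromosomes it depends on the donor's gender and
on whether the locus falls inside a pseudoautosomal region (PAR), where
males carry two copies as well.  The mitochondrial genome is treated as
haploid for every donor, matching the 0..2 per-donor occurrence contract.

PAR coordinates are shipped as editable YAML data files (one per supported
assembly) rather than hard-coded, so a non-human or synthetic assembly can
be described the same way.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import PopvarsumError

__all__ = ["AssemblyModel", "normalize_chrom", "chrom_sort_key"]

_SEX_ORDER = {"X": 0, "Y": 1, "MT": 2}


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip any ``chr`` prefix, upper-case
    sex/mito labels, and map ``M`` to ``MT`` (1KGP and GENCODE dialects
    differ on all three points)."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    cu = c.upper()
    if cu == "M":
        return "MT"
    if cu in ("X", "Y", "MT"):
        return cu
    return c


def chrom_sort_key(label: str):
    """Natural chromosome order: 1..22 numerically, then X, Y, MT, then
    anything else lexicographically."""
    c = normalize_chrom(label)
    if c.isdigit():
        return (0, int(c), "")
    if c in _SEX_ORDER:
        return (1, _SEX_ORDER[c], "")
    return (2, 0, c)


@dataclass(frozen=True)
class AssemblyModel:
    """Chromosome inventory plus PAR intervals governing per-donor ploidy.

    Parameters
    ----------
    name:
        Assembly identifier (e.g. ``hg19``, ``grch38``).
    chromosomes:
        Mapping of normalized chromosome label to length in bp.
    par:
        Mapping of sex-chromosome label to a list of 0-based half-open
        ``(start, end)`` pseudoautosomal intervals.
    """

    name: str
    chromosomes: dict[str, int]
    par: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, ivs in self.par.items():
            ordered = sorted(ivs)
            for (s1, e1), (s2, _) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise PopvarsumError(
                        f"overlapping PAR intervals on {chrom} in assembly {self.name}"
                    )
            for s, e in ivs:
                if not 0 <= s < e:
                    raise PopvarsumError(f"invalid PAR interval [{s}, {e}) on {chrom}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "AssemblyModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def named(cls, name: str) -> "AssemblyModel":
        """Load one of the bundled assemblies (``hg19`` or ``grch38``)."""
        resource = importlib.resources.files("popvarsum.data") / f"par_{name.lower()}.yaml"
        if not resource.is_file():
            raise PopvarsumError(f"no bundled assembly named {name!r}")
        doc = yaml.safe_load(resource.read_text())
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc) -> "AssemblyModel":
        chroms = {normalize_chrom(k): int(v) for k, v in doc["chromosomes"].items()}
        par = {
            normalize_chrom(k): [(int(s), int(e)) for s, e in v]
            for k, v in (doc.get("par") or {}).items()
        }
        return cls(name=str(doc["name"]), chromosomes=chroms, par=par)

    # -- queries -------------------------------------------------------

    def in_par(self, chrom: str, pos: int) -> bool:
        for s, e in self.par.get(normalize_chrom(chrom), ()):
            if s <= pos < e:
                return True
        return False

    def ploidy(self, chrom: str, pos: int, gender: str | None) -> int | None:
        """Number of chromosome copies a donor carries at ``(chrom, pos)``.

        Autosomes are diploid for everyone and MT is haploid for everyone.
        X: 2 inside a PAR; outside, 2 for females and 1 for males.
        Y: inside a PAR 2 for males and 0 for females; outside, 1 for males
        and 0 for females.  Unknown gender on a sex chromosome returns
        ``None`` — callers exclude such donors from allele totals.
        """
        c = normalize_chrom(chrom)
        g = gender.lower() if gender else None
        if c == "MT":
            return 1
        if c == "X":
            if self.in_par(c, pos):
                return 2
            if g == "female":
                return 2
            if g == "male":
                return 1
            return None
        if c == "Y":
            if g == "male":
                return 2 if self.in_par(c, pos) else 1
            if g == "female":
                return 0
            return None
        return 2

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.chromosomes
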