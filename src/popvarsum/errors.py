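"""Exception hierarchy for popvarsum."""


class PopvarsumError(Exception):
    """Base class for all package-specific errors."""


class MalformedVariantError(PopvarsumError):
    """A VCF record violates the preconditions of the transformation rules."""


class UnknownPopulationError(PopvarsumError):
    """A population code is not present in the ethnicity mapping table."""


class MetadataConflictError(PopvarsumError):
    """Two metadata tables disagree on a single-valued attribute."""


class UnknownAttributeError(PopvarsumError):
    """A metadata attribute is not known to the store."""


class SchemaMismatchError(PopvarsumError):
    """A GDM file does not conform to the declared column schema."""


class NoEligibleSourceError(PopvarsumError):
    """No loaded source supports every filter category of a request."""

    def __init__(self, missing_categories):
        self.missing_categories = sorted(missing_categories)
        super().__init__(
            "no eligible source: no loaded source supports "
            + ", ".join(self.missing_categories)
        )


class UnresolvableVariantError(PopvarsumError):
    """A variant id or gene name cannot be resolved against loaded data."""


class UnknownGeneError(PopvarsumError):
    """A gene name is absent from every annotation source."""

    def __init__(self, gene, near_matches=()):
        self.gene = gene
        self.near_matches = list(near_matches)
        msg = f"unknown gene {gene!r}"
        if self.near_matches:
            msg += "; did you mean: " + ", ".join(self.near_matches)
        super().__init__(msg)


class PrivacyRefusal(PopvarsumError):
    """The response would expose a donor group smaller than the configured
    minimum and is therefore refused."""

    def __init__(self, count, min_donors):
        self.count = count
        self.min_donors = min_donors
        super().__init__(
            f"refused: response involves a group of {count} donor(s), "
            f"below the privacy threshold of {min_donors}"
        )


class InfeasibleConfigError(PopvarsumError):
    """A synthetic-cohort configuration cannot be realised."""
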