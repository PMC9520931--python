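import pytest

from popvarsum.synthio import SynthConfig

from helpers import build_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """60 donors across autosomes and all sex/mito chromosomes, with
    multi-allelic sites, indels, SVs and some missing genotypes."""
    config = SynthConfig(
        n_donors=60,
        chromosomes=["1", "2", "X", "Y", "MT"],
        n_variants_per_chrom=40,
        frac_multiallelic=0.15,
        frac_indel=0.2,
        frac_sv=0.05,
        missing_rate=0.02,
        tumor_fraction=0.3,
        seed=101,
    )
    return build_cohort(tmp_path_factory.mktemp("small"), config)


@pytest.fixture(scope="session")
def phased_cohort(tmp_path_factory):
    """Fully phased cohort with common variants, for chromatid queries."""
    config = SynthConfig(
        n_donors=80,
        chromosomes=["1"],
        n_variants_per_chrom=30,
        af_alpha=2.0,
        af_beta=2.0,
        frac_multiallelic=0.0,
        frac_indel=0.0,
        frac_sv=0.0,
        seed=202,
    )
    return build_cohort(tmp_path_factory.mktemp("phased"), config)
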