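import pytest

from ampmux import (build_default_locus, find_discriminating_positions,
                    planted_guide)
from ampmux.decode import control_profile_from_reads
from ampmux.simulate import EditedGenotype, simulate_amplicon_reads


@pytest.fixture(scope="session")
def default_locus():
    """Default eight-allele locus: one amplicon-identical pair, one
    repeat-length-only pair."""
    return build_default_locus(1)


@pytest.fixture(scope="session")
def resolvable_locus():
    """Variant locus in which every allele pair is SNP-separated."""
    return build_default_locus(1, identical_pair=False,
                               repeat_only_pair=False)


@pytest.fixture(scope="session")
def default_guide(default_locus):
    return planted_guide(default_locus)


@pytest.fixture(scope="session")
def resolvable_guide(resolvable_locus):
    return planted_guide(resolvable_locus)


@pytest.fixture(scope="session")
def default_snps(default_locus):
    return find_discriminating_positions(default_locus)


@pytest.fixture(scope="session")
def resolvable_snps(resolvable_locus):
    return find_discriminating_positions(resolvable_locus)


def wt_genotype(model, line_id="control"):
    return EditedGenotype(line_id, [], {a.id: a.seq for a in model.alleles},
                          {}, 0)


@pytest.fixture(scope="session")
def control_reads(resolvable_locus):
    """Error-free control reads from the resolvable locus."""
    return list(simulate_amplicon_reads(wt_genotype(resolvable_locus),
                                        resolvable_locus, depth=200,
                                        error_rate=0.0, seed=7))


@pytest.fixture(scope="session")
def control_profile(control_reads, resolvable_locus, resolvable_snps):
    return control_profile_from_reads(control_reads, resolvable_locus,
                                      snps=resolvable_snps)
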