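import pytest

import tandemcut as tc

TARGET_FAMILIES = ("A1", "A2", "B", "D")


@pytest.fixture(scope="session")
def default_fixture() -> tc.FixtureResult:
    """The default planted family: 12 A copies over two loci, 8 B,
    5 pseudogene D, 6 non-target copies upstream of the A locus."""
    return tc.generate_family(tc.FixtureConfig(seed=17))


@pytest.fixture(scope="session")
def design_result(default_fixture) -> tc.DesignResult:
    """Full design pipeline run on the default fixture."""
    return tc.run_design(
        default_fixture.genome,
        default_fixture.genes,
        default_fixture.expression,
        tc.RunConfig(target_families=TARGET_FAMILIES),
    )


def make_genome(**chroms: str) -> dict[str, tc.GenomeSequence]:
    return {cid: tc.GenomeSequence(cid, seq.upper()) for cid, seq in chroms.items()}
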