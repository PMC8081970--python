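import pytest

from mrtools import AssociationRecord, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged interleukin/MS instrument sets."""
    return load_table1_fixture()


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.05,
    p_value=0.0455,
    eaf=0.3,
    chromosome="1",
    position=1000,
    trait_id="trait",
):
    """Association record with sane defaults (p consistent with beta/se)."""
    return AssociationRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        p_value=p_value,
        eaf=eaf,
        chromosome=chromosome,
        position=position,
        trait_id=trait_id,
    )
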