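"""Allele harmonization: alignment, strand flips, palindrome handling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtools import (
    HarmonizationError,
    HarmonizationWarning,
    InstrumentSet,
    harmonize_pair,
    harmonize_set,
    wald_ratio,
)

from conftest import make_record


class TestHarmonizePair:
    def test_matching_alleles_unchanged(self):
        exp = make_record(effect_allele="C", other_allele="T", eaf=0.31, beta=0.46, se=0.05,
                          p_value=2.4e-20)
        out = make_record(effect_allele="C", other_allele="T", eaf=0.31, beta=-0.04, se=0.02,
                          p_value=0.0455, trait_id="MS")
        pair = harmonize_pair(exp, out)
        assert pair.action == "unchanged"
        assert pair.x == 0.46 and pair.y == -0.04
        assert pair.effect_allele == "C" and not pair.palindromic

    def test_swapped_alleles_sign_flip(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.5, se=0.05, p_value=1e-22)
        out = make_record(effect_allele="G", other_allele="A", beta=0.2, se=0.1,
                          p_value=0.0455, eaf=0.7)
        pair = harmonize_pair(exp, out)
        assert pair.action == "sign_flipped"
        assert pair.y == pytest.approx(-0.2)
        assert pair.eaf_outcome == pytest.approx(0.3)

    def test_opposite_strand_same_orientation(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.5, se=0.05, p_value=1e-22)
        out = make_record(effect_allele="T", other_allele="C", beta=0.2, se=0.1, p_value=0.0455)
        pair = harmonize_pair(exp, out)
        assert pair.action == "strand_flipped"
        assert pair.y == pytest.approx(0.2)

    def test_opposite_strand_swapped_orientation(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.5, se=0.05, p_value=1e-22)
        out = make_record(effect_allele="C", other_allele="T", beta=0.2, se=0.1,
                          p_value=0.0455, eaf=0.7)
        pair = harmonize_pair(exp, out)
        assert pair.action == "strand_flipped_and_sign_flipped"
        assert pair.y == pytest.approx(-0.2)

    def test_ambiguous_palindrome_dropped(self):
        exp = make_record(effect_allele="A", other_allele="T", eaf=0.52, beta=0.3, se=0.05,
                          p_value=2e-9)
        out = make_record(effect_allele="A", other_allele="T", eaf=0.5, beta=0.1, se=0.1,
                          p_value=0.317)
        pair = harmonize_pair(exp, out)
        assert pair.action == "dropped" and pair.palindromic
        assert not pair.kept

    def test_drop_rule_boundary_is_strict(self):
        # MAF exactly 0.45 is retained, anything above dropped
        exp = make_record(effect_allele="A", other_allele="T", eaf=0.45, beta=0.3, se=0.05,
                          p_value=2e-9)
        out = make_record(effect_allele="A", other_allele="T", eaf=0.44, beta=0.1, se=0.1,
                          p_value=0.317)
        assert harmonize_pair(exp, out).kept
        exp46 = make_record(effect_allele="A", other_allele="T", eaf=0.46, beta=0.3, se=0.05,
                            p_value=2e-9)
        assert not harmonize_pair(exp46, out).kept

    def test_palindrome_orientation_from_eaf(self):
        exp = make_record(effect_allele="C", other_allele="G", eaf=0.2, beta=0.3, se=0.05,
                          p_value=2e-9)
        same = make_record(effect_allele="C", other_allele="G", eaf=0.22, beta=0.1, se=0.1,
                           p_value=0.317)
        assert harmonize_pair(exp, same).action == "unchanged"
        # Outcome coded for the other allele: EAF on the opposite side of 0.5
        opposite = make_record(effect_allele="C", other_allele="G", eaf=0.78, beta=0.1, se=0.1,
                               p_value=0.317)
        flipped = harmonize_pair(exp, opposite)
        assert flipped.action == "sign_flipped"
        assert flipped.y == pytest.approx(-0.1)

    def test_palindrome_without_eaf_raises(self):
        exp = make_record(effect_allele="A", other_allele="T", eaf=None, beta=0.3, se=0.05,
                          p_value=2e-9)
        out = make_record(effect_allele="A", other_allele="T", eaf=0.3, beta=0.1, se=0.1,
                          p_value=0.317)
        with pytest.raises(HarmonizationError, match="EAF"):
            harmonize_pair(exp, out)

    def test_variant_id_mismatch_raises(self):
        with pytest.raises(HarmonizationError, match="mismatch"):
            harmonize_pair(make_record(variant_id="rs1"), make_record(variant_id="rs2"))

    def test_irreconcilable_alleles_raise(self):
        exp = make_record(effect_allele="A", other_allele="G")
        out = make_record(effect_allele="A", other_allele="C")
        with pytest.raises(HarmonizationError, match="irreconcilable"):
            harmonize_pair(exp, out)

    def test_missing_other_allele_matches_on_effect_allele_with_warning(self):
        exp = make_record(effect_allele="A", other_allele=None)
        out = make_record(effect_allele="A", other_allele=None, beta=-0.05, se=0.05, p_value=0.317)
        with pytest.warns(HarmonizationWarning):
            pair = harmonize_pair(exp, out)
        assert pair.action == "unchanged" and pair.y == -0.05


class TestHarmonizeSet:
    def test_fixture_il18_both_kept(self, table1):
        result = harmonize_set(table1["IL-18"])
        assert len(result.pairs) == 2
        assert not result.dropped
        assert [p.variant_id for p in result.pairs] == ["rs2250417", "rs7577696"]

    def test_all_ambiguous_gives_empty_set_with_log(self):
        exp = make_record(effect_allele="A", other_allele="T", eaf=0.5, beta=0.3, se=0.05,
                          p_value=2e-9)
        out = make_record(effect_allele="A", other_allele="T", eaf=0.5, beta=0.1, se=0.1,
                          p_value=0.317)
        result = harmonize_set(InstrumentSet("X", [exp], [out]))
        assert result.pairs == []
        assert len(result.dropped) == 1
        assert any("dropped" in line for line in result.log)

    def test_missing_outcome_record_logged(self):
        result = harmonize_set(InstrumentSet("X", [make_record()], [None]))
        assert result.pairs == [] and any("no outcome" in line for line in result.log)

    def test_idempotence(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.5, se=0.05, p_value=1e-22)
        out = make_record(effect_allele="G", other_allele="A", beta=0.2, se=0.1,
                          p_value=0.0455, eaf=0.7)
        first = harmonize_pair(exp, out)
        # feed the aligned outcome back in: nothing more should change
        aligned_out = make_record(effect_allele="A", other_allele="G", beta=first.y, se=0.1,
                                  p_value=0.0455, eaf=first.eaf_outcome)
        second = harmonize_pair(exp, aligned_out)
        assert second.action == "unchanged"
        assert second.y == first.y and second.x == first.x


@pytest.mark.filterwarnings("ignore::mrtools.errors.ValueWarning")
@settings(derandomize=True, max_examples=100)
@given(
    beta_x=st.floats(0.05, 1.0),
    beta_y=st.floats(-0.5, 0.5),
    eaf=st.floats(0.05, 0.95),
    swap_exposure=st.booleans(),
)
def test_sign_symmetry_of_exposure_coding(beta_x, beta_y, eaf, swap_exposure):
    """Recoding the exposure allele flips x and y together: Wald ratio invariant."""
    exp = make_record(effect_allele="A", other_allele="G", beta=beta_x, se=0.05,
                      p_value=0.5, eaf=eaf)
    out = make_record(effect_allele="A", other_allele="G", beta=beta_y, se=0.05,
                      p_value=0.5, eaf=eaf)
    base = wald_ratio(harmonize_pair(exp, out))
    if swap_exposure:
        exp = exp.flip_coding()
    pair = harmonize_pair(exp, out)
    est = wald_ratio(pair)
    assert est.ratio == pytest.approx(base.ratio, rel=1e-12)
    assert est.se == pytest.approx(base.se, rel=1e-12)
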