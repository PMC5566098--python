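"""Count correction, completion, renormalisation and exclusion filters."""

import itertools

import pytest

from foramcensus import qc
from foramcensus.flags import assign_ocean_flag
from foramcensus.samples import (MODIFIED, NA, NO_COORDINATES,
                                 NONSTANDARD_DEVICE, SUM_DEVIATES,
                                 TAXONOMICALLY_INCORRECT, TOO_FEW_COUNTED,
                                 TOO_MANY_UNIDENTIFIED)
from foramcensus.taxonomy import counting_sum

from conftest import build_sample


@pytest.mark.parametrize("n,expected", [(40, 0.02), (1, 0.0005), (30, 0.015)])
def test_rounding_error_formula(n, expected):
    assert qc.rounding_error(n) == pytest.approx(expected)


def test_rounding_error_requires_categories():
    with pytest.raises(ValueError):
        qc.rounding_error(0)


def test_total_count_corrected_to_category_sum(scheme):
    sample = build_sample("a", counts={"g_bulloides": 200.0,
                                       "n_incompta": 112.0}, count=300)
    qc.correct_total_count(sample, scheme)
    assert sample.metadata.count == 312.0
    assert sample.has_error(MODIFIED)


def test_consistent_total_untouched(scheme):
    sample = build_sample("a", counts={"g_bulloides": 200.0,
                                       "n_incompta": 100.0}, count=300)
    qc.correct_total_count(sample, scheme)
    assert sample.metadata.count == 300.0
    assert not sample.has_error(MODIFIED)


def test_all_na_counts_leave_total_alone(scheme):
    sample = build_sample("a", counts={"g_bulloides": NA}, count=300)
    qc.correct_total_count(sample, scheme)
    assert sample.metadata.count == 300.0


def _complete_sample(scheme, given_sum, unidentified, n_given=40):
    species = [c.code for c in scheme.categories
               if c.kind == "species"][:n_given]
    values = {c: given_sum / n_given for c in species}
    values[scheme.unidentified] = unidentified
    sample = build_sample("a", values=values)
    for c in (c.code for c in scheme.categories if c.kind == "species"):
        sample.relative.setdefault(c, NA)
    return sample


def test_complete_sample_filled_with_zeros(scheme):
    # 41 given categories (40 species + unidentified): allowance 0.0205
    sample = _complete_sample(scheme, 0.995, 0.0)
    qc.complete_with_zeros(sample, scheme)
    species = [c.code for c in scheme.categories if c.kind == "species"]
    assert all(sample.relative[c] is not NA for c in species)
    assert sample.has_error(MODIFIED)


def test_incomplete_sum_not_filled(scheme):
    sample = _complete_sample(scheme, 0.95, 0.0)
    qc.complete_with_zeros(sample, scheme)
    assert any(v is NA for v in sample.relative.values())


def test_nonzero_unidentified_never_filled(scheme):
    sample = _complete_sample(scheme, 0.995, 0.01)
    qc.complete_with_zeros(sample, scheme)
    assert any(v is NA for v in sample.relative.values())
    assert not sample.has_error(MODIFIED)


def test_renormalisation_rescales_small_deviations(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.66,
                                       "n_incompta": 0.33})
    bits = qc.renormalize_or_flag(sample, scheme)
    assert bits == 0
    assert counting_sum(sample.relative, scheme) == pytest.approx(1.0,
                                                                  abs=1e-9)
    assert sample.has_error(MODIFIED)


def test_renormalisation_flags_large_deviations(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.60,
                                       "n_incompta": 0.30})
    bits = qc.renormalize_or_flag(sample, scheme)
    assert bits == SUM_DEVIATES
    assert sample.relative["g_bulloides"] == 0.60  # left untouched


def test_renormalisation_identity_on_exact_sum(scheme):
    sample = build_sample("a")
    qc.renormalize_or_flag(sample, scheme)
    assert not sample.has_error(MODIFIED)


def test_zero_sum_is_degenerate(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.0})
    assert qc.renormalize_or_flag(sample, scheme) == SUM_DEVIATES


def test_morphotypes_scaled_but_not_summed(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.57, "n_incompta": 0.4,
                                       "t_quinqueloba_d": 0.09})
    qc.renormalize_or_flag(sample, scheme)
    assert counting_sum(sample.relative, scheme) == pytest.approx(1.0)
    # the morphotype does not enter the sum but is rescaled alongside
    assert sample.relative["t_quinqueloba_d"] == pytest.approx(0.09 / 0.97)


@pytest.mark.parametrize("count,flagged", [(149, True), (150, False),
                                           (300, False)])
def test_low_count_filter_is_strict(count, flagged):
    sample = build_sample("a", count=count)
    bits = qc.filter_low_count(sample)
    assert bool(bits & TOO_FEW_COUNTED) is flagged


def test_low_count_default_minimum_never_triggers():
    sample = build_sample("a", count=None, count_min=300)
    assert qc.filter_low_count(sample) == 0
    sample = build_sample("a", count=None, count_min=100)
    assert qc.filter_low_count(sample) == TOO_FEW_COUNTED


@pytest.mark.parametrize("unid,flagged", [(0.051, True), (0.05, False),
                                          (NA, False)])
def test_unidentified_filter_is_strict(scheme, unid, flagged):
    sample = build_sample("a", values={"g_bulloides": 0.95,
                                       "unidentified": unid})
    bits = qc.filter_unidentified(sample, scheme)
    assert bool(bits & TOO_MANY_UNIDENTIFIED) is flagged


def _ocean(lat, lon):
    return assign_ocean_flag(lat, lon)


def test_pacific_ruber_pink_above_threshold_flagged(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.98,
                                       "g_ruber_pink": 0.02},
                          ocean_flag=_ocean(10.0, -150.0))
    bits = qc.apply_endemism_rules(sample, scheme)
    assert bits == TAXONOMICALLY_INCORRECT
    assert sample.relative["g_ruber_pink"] == 0.02  # flagged, not moved


def test_pacific_ruber_pink_trace_folded_into_unidentified(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.995,
                                       "g_ruber_pink": 0.005,
                                       "unidentified": 0.0},
                          ocean_flag=_ocean(10.0, -150.0))
    before = counting_sum(sample.relative, scheme)
    bits = qc.apply_endemism_rules(sample, scheme)
    assert bits == 0
    assert sample.relative["g_ruber_pink"] is NA
    assert sample.relative["unidentified"] == pytest.approx(0.005)
    assert counting_sum(sample.relative, scheme) == pytest.approx(before,
                                                                  abs=1e-12)
    assert sample.has_error(MODIFIED)


def test_indopacific_lumped_ruber_resolved_into_white(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.6,
                                       "ruber_pink_white": 0.4},
                          ocean_flag=_ocean(-10.0, 80.0))
    qc.apply_endemism_rules(sample, scheme)
    assert sample.relative["ruber_pink_white"] is NA
    assert sample.relative["g_ruber_white"] == pytest.approx(0.4)


def test_atlantic_indopacific_endemics_flagged(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.98,
                                       "g_hexagonus": 0.02},
                          ocean_flag=_ocean(45.0, -30.0))
    assert qc.apply_endemism_rules(sample, scheme) == TAXONOMICALLY_INCORRECT


def test_atlantic_trace_endemics_merged(scheme):
    sample = build_sample("a", values={"g_bulloides": 0.99,
                                       "g_adamsi": 0.01,
                                       "unidentified": 0.0},
                          ocean_flag=_ocean(45.0, -30.0))
    qc.apply_endemism_rules(sample, scheme)
    assert sample.relative["g_adamsi"] is NA
    assert sample.relative["unidentified"] == pytest.approx(0.01)


def test_unresolvable_basin_skips_endemism(scheme):
    sample = build_sample("a", values={"g_ruber_pink": 0.05}, ocean_flag=0)
    assert qc.apply_endemism_rules(sample, scheme) == 0


def test_missing_coordinates_flagged():
    sample = build_sample("a", lat=None)
    assert qc.filter_other(sample) & NO_COORDINATES


def test_nonstandard_or_missing_device_flagged():
    assert qc.filter_other(build_sample("a", device="other")) \
        & NONSTANDARD_DEVICE
    assert qc.filter_other(build_sample("a", device=None)) \
        & NONSTANDARD_DEVICE
    assert qc.filter_other(build_sample("a", device="Mini")) == 0


def test_filters_commute(scheme):
    def filters():
        return [
            lambda s: qc.filter_low_count(s),
            lambda s: qc.filter_unidentified(s, scheme),
            lambda s: qc.apply_endemism_rules(s, scheme),
            lambda s: qc.filter_other(s),
        ]

    def run(order):
        sample = build_sample(
            "a", values={"g_bulloides": 0.90, "g_ruber_pink": 0.02,
                         "unidentified": 0.08},
            count=120, device="Dredge", ocean_flag=_ocean(10.0, -150.0))
        for k in order:
            filters()[k](sample)
        return sample.metadata.error_flag

    flags = {run(order) for order in itertools.permutations(range(4))}
    assert len(flags) == 1
    assert flags.pop() == (TOO_FEW_COUNTED | TOO_MANY_UNIDENTIFIED
                           | TAXONOMICALLY_INCORRECT | NONSTANDARD_DEVICE)
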