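"""Master scheme structure, synonym resolution and category merges."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foramcensus.samples import MODIFIED, NA, CensusSample, SampleMetadata
from foramcensus.taxonomy import (UNKNOWN, apply_merge_rules, counting_sum,
                                  mark_unrecorded, resolve_label,
                                  resolve_synonym)

# the curated synonym table: historical name -> harmonised category
SYNONYM_ROWS = [
    ("Globigerina digitata", "b_digitata"),
    ("Globigerinella digitata", "b_digitata"),
    ("Globigerinita pumilio", "b_pumilio"),
    ("Dentagloborotalia anfracta", "d_anfracta"),
    ("Globorotalia anfracta", "d_anfracta"),
    ("Globigerina calida", "g_calida"),
    ("Globigerinella aequilateralis", "g_siphonifera"),
    ("Globigerinita bradyi", "g_uvula"),
    ("Globoturborotalita tenella", "g_tenellus"),
    ("Globorotalia inflata", "g_inflata"),
    ("Globorotalia menardii flexuosa", "g_menardii"),
    ("Globorotalia tumida flexuosa", "g_tumida"),
    ("Globoquadrina hexagona", "g_hexagonus"),
    ("Globigerina rubescens", "g_rubescens"),
    ("Hastigerina digitata", "h_digitata"),
    ("Globigerina pachyderma", "n_pachyderma"),
    ("Neogloboquadrina pachyderma sinistral", "n_pachyderma"),
    ("Globoquadrina dutertrei", "n_dutertrei"),
    ("Neogloboquadrina pachyderma dextral", "n_incompta"),
    ("Globigerinita iota", "t_iota"),
    ("Globigerinoides sacculifer", "t_sacculifer"),
    ("Globigerinoides trilobus", "t_sacculifer"),
    ("Globigerina humilis", "t_humilis"),
    ("Turborotalia cristata", "t_humilis"),
    ("Turborotalia humilis", "t_humilis"),
    ("Globigerina quinqueloba", "t_quinqueloba"),
    ("Turborotalia quinqueloba", "t_quinqueloba"),
]


def test_master_scheme_category_counts(scheme):
    counts = scheme.kind_counts()
    assert counts["species"] == 47
    assert counts["multi_species"] == 3
    assert counts["morphotype"] == 6


def test_morphotypes_have_species_parents(scheme):
    for cat in scheme.categories:
        if cat.kind == "morphotype":
            assert scheme.by_code[cat.parent].kind == "species"


def test_six_species_never_recorded(scheme):
    unrecorded = [c.code for c in scheme.categories
                  if c.kind == "species" and not c.recorded_anywhere]
    assert len(unrecorded) == 6


@pytest.mark.parametrize("raw,code", SYNONYM_ROWS)
def test_synonym_rows_resolve(scheme, raw, code):
    assert resolve_synonym(raw, scheme) == code


def test_resolution_is_idempotent(scheme):
    code = resolve_synonym("Globigerinoides sacculifer", scheme)
    assert code == "t_sacculifer"
    assert resolve_synonym(code, scheme) == code


def test_category_names_resolve_to_themselves(scheme):
    assert resolve_synonym("Trilobatus sacculifer", scheme) == "t_sacculifer"
    assert resolve_synonym("Globigerinoides ruber (pink)",
                           scheme) == "g_ruber_pink"
    assert resolve_synonym("globigerinoides ruber pink",
                           scheme) == "g_ruber_pink"


def test_unknown_label_never_guessed(scheme):
    assert resolve_synonym("Foo bar", scheme) == UNKNOWN
    with pytest.raises(ValueError):
        resolve_synonym("", scheme)


def test_dataset_interpretation_precedes_synonymy(scheme):
    # the undifferentiated pachyderma category reads as intergrades in the
    # compilation known to have used it that way, as N. pachyderma elsewhere
    assert resolve_label("Globigerina pachyderma", scheme,
                         "CLIMAP") == "pd_intergrades"
    assert resolve_label("Globigerina pachyderma", scheme,
                         "BUFD") == "n_pachyderma"


def _sample(values):
    return CensusSample(metadata=SampleMetadata(sample_id="x"),
                        original=dict(values), relative=dict(values))


@pytest.mark.parametrize("values,dataset,expected", [
    ({"pd_intergrades": 0.05, "n_incompta": 0.10}, "MARGO",
     {"n_incompta": 0.15}),
    ({"g_flexuosa": 0.02, "g_menardii": 0.03}, "BUFD",
     {"g_menardii": 0.05}),
    ({"g_crassula": 0.01, "other_identified": 0.02}, "MARGO",
     {"unidentified": 0.03}),
    ({"g_puncticulata": 0.04, "g_inflata": 0.10}, "Munz",
     {"g_inflata": 0.14}),
])
def test_merge_rules_move_abundances(scheme, values, dataset, expected):
    sample = apply_merge_rules(_sample(values), dataset, scheme)
    for code, value in expected.items():
        assert sample.relative[code] == pytest.approx(value, abs=1e-12)
    assert sample.has_error(MODIFIED)
    assert counting_sum(sample.relative, scheme) == pytest.approx(
        sum(v for v in values.values()), abs=1e-12)


def test_merge_rules_two_step_chain(scheme):
    # interpretation of the raw label, then merge into N. incompta
    sample = _sample({"raw:globigerina pachyderma": 0.07, "n_incompta": 0.01})
    apply_merge_rules(sample, "CLIMAP", scheme)
    assert sample.relative["n_incompta"] == pytest.approx(0.08)
    assert "pd_intergrades" not in sample.relative


def test_merge_rules_noop_leaves_sample_untouched(scheme):
    sample = _sample({"g_bulloides": 0.5})
    apply_merge_rules(sample, "MARGO", scheme)
    assert sample.relative == {"g_bulloides": 0.5}
    assert not sample.has_error(MODIFIED)
    assert sample.metadata.comment == ""


def test_merge_with_not_available_target(scheme):
    # numeric + NA = numeric: NA is absence of information, not zero
    sample = _sample({"pd_intergrades": 0.05, "n_incompta": NA})
    apply_merge_rules(sample, "MARGO", scheme)
    assert sample.relative["n_incompta"] == pytest.approx(0.05)


def test_mark_unrecorded_adds_na_not_zero(scheme):
    species = [c.code for c in scheme.categories if c.kind == "species"]
    reported = set(species[:23]) | {scheme.unidentified}
    sample = _sample({c: 1.0 / 23 for c in species[:23]})
    mark_unrecorded(sample, reported, scheme)
    na_species = [c for c in species if sample.relative.get(c, None) is NA
                  and c not in reported]
    assert len(na_species) == 24
    # reported numeric values never become NA
    assert all(sample.relative[c] is not NA for c in species[:23])


def test_lumped_category_constituents_marked_unavailable(scheme):
    reported = {"ruber_pink_white", scheme.unidentified}
    sample = _sample({"ruber_pink_white": 0.4})
    mark_unrecorded(sample, reported, scheme)
    assert sample.relative["g_ruber_pink"] is NA
    assert sample.relative["g_ruber_white"] is NA
    assert sample.relative["ruber_pink_white"] == 0.4


@settings(max_examples=50, derandomize=True)
@given(st.dictionaries(
    st.sampled_from(["pd_intergrades", "g_flexuosa", "g_crassula",
                     "other_identified", "n_incompta", "g_menardii",
                     "g_bulloides", "unidentified"]),
    st.floats(0.0, 1.0, allow_nan=False), min_size=1),
    st.sampled_from(["CLIMAP", "BUFD", "ATL947", "MARGO", "Munz", "other"]))
def test_merges_conserve_total_abundance(scheme, values, dataset):
    sample = _sample(values)
    before = counting_sum(sample.relative, scheme)
    apply_merge_rules(sample, dataset, scheme)
    assert counting_sum(sample.relative, scheme) == pytest.approx(
        before, abs=1e-12)
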