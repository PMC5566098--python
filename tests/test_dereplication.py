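"""Duplicate detection, classification and merge precedence."""

import random

import pytest

from foramcensus.dereplication import (basic_similarity, classify_pair,
                                       dereplicate_stage, find_duplicates,
                                       merge_cluster, name_distance,
                                       resolve_position)
from foramcensus.samples import DUPLICATE, NA

from conftest import build_sample

MINUTE = 1.0 / 60.0


@pytest.mark.parametrize("a,b,expected", [
    ("MD95-2042", "MD95-2042", 0),
    ("M8_12-1", "M8/12-1", 1),
    ("A", "", 1),
    ("ELT44.27-PC", "E44-27B", 6),       # frozen from a DP oracle
    ("A260210A", "AII-15-602-10A", 7),   # frozen from a DP oracle
])
def test_name_distance(a, b, expected):
    assert name_distance(a, b) == expected


def test_identical_assemblages_pass_basic(scheme):
    a = build_sample("a", count=300)
    b = build_sample("b", count=300)
    verdict = basic_similarity(a, b, scheme)
    assert verdict.passes_basic
    assert verdict.max_category_deviation == 0.0
    assert verdict.total_count_deviation == 0.0


def test_category_deviation_criterion_strict(scheme):
    a = build_sample("a")
    b = build_sample("b", values={"g_bulloides": 0.52, "g_ruber_white": 0.28,
                                  "n_incompta": 0.2})
    assert not basic_similarity(a, b, scheme).passes_basic


def test_total_count_criterion(scheme):
    # totals 300 vs 310: deviation 10/305 exceeds 3% of the pair average
    a = build_sample("a", count=300)
    b = build_sample("b", count=310)
    verdict = basic_similarity(a, b, scheme)
    assert verdict.total_count_deviation == pytest.approx(10 / 305)
    assert not verdict.passes_basic


def test_total_criterion_vacuous_without_counts(scheme):
    a = build_sample("a", count=300)
    b = build_sample("b", count=None)
    assert basic_similarity(a, b, scheme).passes_basic


def test_no_shared_categories_fails(scheme):
    a = build_sample("a", values={"g_bulloides": 1.0, "n_incompta": NA})
    b = build_sample("b", values={"g_bulloides": NA, "n_incompta": 1.0})
    verdict = basic_similarity(a, b, scheme)
    assert verdict.categories_compared == 0
    assert not verdict.passes_basic


def test_morphotypes_ignored_in_similarity(scheme):
    a = build_sample("a", values={"g_bulloides": 1.0,
                                  "t_quinqueloba_d": 0.5})
    b = build_sample("b", values={"g_bulloides": 1.0,
                                  "t_quinqueloba_d": 0.1})
    assert basic_similarity(a, b, scheme).passes_basic


def test_classification_order(scheme):
    a = build_sample("a", name="CORE-1", lat=0.0, lon=0.0, count=300)
    # same name, ~1 km away: plain
    b = build_sample("b", name="CORE-1", lat=0.009, lon=0.0, count=300)
    assert classify_pair(a, b, scheme) == "plain"
    # same name, far away: incorrect position
    c = build_sample("c", name="CORE-1", lat=8.0, lon=0.0, count=300)
    assert classify_pair(a, c, scheme) == "incorrect_position"
    # different name, ~0.3 km away: different name
    d = build_sample("d", name="CORE-2", lat=0.0027, lon=0.0, count=300)
    assert classify_pair(a, d, scheme) == "different_name"
    # different name, far away: manual candidate only
    e = build_sample("e", name="CORE-2", lat=1.0, lon=0.0, count=300)
    assert classify_pair(a, e, scheme) is None


def test_classification_requires_basic_similarity(scheme):
    a = build_sample("a", name="CORE-1")
    b = build_sample("b", name="CORE-1", values={"g_bulloides": 0.55,
                                                 "g_ruber_white": 0.25,
                                                 "n_incompta": 0.2})
    assert classify_pair(a, b, scheme) is None


def test_missing_position_still_matches_by_name(scheme):
    a = build_sample("a", name="CORE-1", lat=None)
    b = build_sample("b", name="CORE-1")
    assert classify_pair(a, b, scheme) == "incorrect_position"


def test_transitive_closure_forms_one_cluster(scheme):
    corpus = [build_sample(f"s{i}", name="CORE-1", lat=0.004 * i, lon=0.0)
              for i in range(3)]
    clusters = find_duplicates(corpus, "plain", scheme)
    assert len(clusters) == 1
    assert clusters[0].members == ["s0", "s1", "s2"]


def test_detection_permutation_invariant(scheme):
    corpus = [build_sample(f"s{i}", name=f"CORE-{i // 2}",
                           lat=0.004 * (i % 2), lon=float(i // 2))
              for i in range(8)]
    expected = [c.members for c in find_duplicates(corpus, "plain", scheme)]
    rng = random.Random(11)
    for _ in range(5):
        shuffled = corpus[:]
        rng.shuffle(shuffled)
        got = [c.members for c in find_duplicates(shuffled, "plain", scheme)]
        assert got == expected


def test_stage_is_idempotent(scheme):
    corpus = [build_sample("a", name="CORE-1"),
              build_sample("b", name="CORE-1")]
    corpus, clusters = dereplicate_stage(corpus, "plain", scheme)
    assert len(clusters) == 1 and len(corpus) == 1
    corpus, clusters = dereplicate_stage(corpus, "plain", scheme)
    assert clusters == [] and len(corpus) == 1


def test_merge_keeps_assemblage_with_most_taxa(scheme):
    species = [c.code for c in scheme.categories if c.kind == "species"]
    rich = {c: 1.0 / 35 for c in species[:35]}
    poor = {c: 1.0 / 28 for c in species[:28]}
    a = build_sample("a", name="X", values=poor, year=1980)
    b = build_sample("b", name="X", values=rich, year=2000)
    merged, discarded = merge_cluster([a, b], "plain", scheme)
    assert merged is b
    assert len([v for v in merged.relative.values() if v is not NA]) == 35
    assert discarded == [a]
    assert a.has_error(DUPLICATE)


def test_merge_prefers_most_precise_position(scheme):
    a = build_sample("a", name="X", lat=10.5, lon=20.0, lat_precision=1,
                     lon_precision=1)
    b = build_sample("b", name="X", lat=10.5, lon=20.0, lat_precision=4,
                     lon_precision=4)
    merged, _ = merge_cluster([a, b], "plain", scheme)
    assert (merged.lat_precision, merged.lon_precision) == (4, 4)


def test_merge_carries_over_existing_metadata(scheme):
    a = build_sample("a", name="X", device=None, year=1990)
    b = build_sample("b", name="X", device="Gravity", year=2000)
    a.metadata.database_flag = 1
    b.metadata.database_flag = 4
    merged, _ = merge_cluster([a, b], "plain", scheme)
    assert merged.metadata.device == "Gravity"
    assert merged.metadata.database_flag == 5  # provenance OR'd


def test_merge_conflicts_resolved_to_older_publication(scheme):
    a = build_sample("a", name="X", device="Gravity", year=2000)
    b = build_sample("b", name="X", device="Piston", year=1980)
    merged, _ = merge_cluster([a, b], "plain", scheme)
    assert merged.metadata.device == "Piston"


def test_merge_depth_prefers_complete_bounds(scheme):
    a = build_sample("a", name="X", sample_depth_average=2.0, year=1980)
    b = build_sample("b", name="X", sample_depth_upper=0.0,
                     sample_depth_lower=4.0, sample_depth_average=2.0,
                     year=2000)
    merged, _ = merge_cluster([a, b], "plain", scheme)
    assert merged.metadata.sample_depth_upper == 0.0
    assert merged.metadata.sample_depth_lower == 4.0


def test_resolve_position_accepts_minutes_repair(scheme):
    # 10 deg 30' recorded as 10.30 in one member, correctly as 10.5 in the
    # other: the repair moves the bad member ~22 km and closes the pair
    a = build_sample("a", name="X", lat=10.30, lon=20.0, lat_precision=2)
    b = build_sample("b", name="X", lat=10.5, lon=20.0)
    lat, lon, _latp, _lonp, method = resolve_position([a, b])
    assert method == "transform"
    assert lat == pytest.approx(10.5)


def test_resolve_position_rejects_small_repairs(scheme):
    # all candidate repairs move the members less than 3.7 km
    a = build_sample("a", name="X", lat=10.02, lon=20.0,
                     water_depth=2950.0, year=1990)
    b = build_sample("b", name="X", lat=12.00, lon=20.0,
                     water_depth=2950.0, year=2000)

    def bathymetry(lat, lon):
        return 3000.0 if lat < 11 else 120.0

    lat, _lon, _p, _q, method = resolve_position([a, b],
                                                 bathymetry=bathymetry)
    assert method == "bathymetry"
    assert lat == pytest.approx(10.02)  # member a matches the seafloor depth


def test_resolve_position_falls_back_to_oldest(scheme):
    a = build_sample("a", name="X", lat=10.02, lon=20.0, year=2001)
    b = build_sample("b", name="X", lat=12.00, lon=20.0, year=1975)
    lat, _lon, _p, _q, method = resolve_position([a, b])
    assert method == "oldest"
    assert lat == pytest.approx(12.00)
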