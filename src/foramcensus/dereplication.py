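"""Duplicate detection and information-maximising merging.

Census compilations clone one another, so the same physical sample can occur
many times under slightly different names, positions and rounded abundances.
Detection is deliberately conservative: a pair must first pass the basic
faunal-similarity criteria (per-category deviation of the relative
abundances below 1%, ignoring categories without information, and total
counted individuals within 3% of the pair average), and is then classified
by name and geography:

* plain duplicate — identical name, less than 2.621 km apart;
* incorrect-position duplicate — identical name, any distance;
* different-name duplicate — less than 0.5242 km apart.

Stages run sequentially (incorrect-position only after all plain duplicates
are treated), clusters are the transitive closure of pairwise matches, and
merging keeps the assemblage with the most counted taxa, the most precise
position and the most complete metadata, with conflicts resolved in favour
of the older publication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np

from .flags import assign_ocean_flag
from .geo import (DIFFERENT_NAME_DISTANCE_KM, PLAIN_DISTANCE_KM,
                  TRANSFORM_DISTANCE_KM, decimal_places, distance_km,
                  enumerate_transform_combinations)
from .samples import DUPLICATE, MODIFIED, NA, CensusSample
from .taxonomy import TaxonomyScheme, numeric_category_count

DEFAULT_CRITERIA = {
    "category_deviation": 0.01,   # max per-category deviation (fraction)
    "total_deviation": 0.03,      # max total-count deviation (of pair mean)
    "plain_km": PLAIN_DISTANCE_KM,
    "different_name_km": DIFFERENT_NAME_DISTANCE_KM,
    "transform_km": TRANSFORM_DISTANCE_KM,
}

STAGES = ("plain", "incorrect_position", "different_name")


@dataclass
class SimilarityVerdict:
    max_category_deviation: float | None
    total_count_deviation: float | None
    categories_compared: int
    passes_basic: bool


@dataclass
class DuplicateCluster:
    members: list  # sample ids, sorted
    type: str      # plain | incorrect_position | different_name | manual
    evidence: dict = field(default_factory=dict)
    resolution: str = ""  # id of the merged (retained) sample


def name_distance(a: str, b: str) -> int:
    """Levenshtein edit distance between two (uppercased) sample names."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _total_deviation(a: CensusSample, b: CensusSample) -> float | None:
    ca, cb = a.metadata.count, b.metadata.count
    if ca is None or cb is None:
        return None
    mean = (ca + cb) / 2.0
    if mean == 0:
        return None
    return abs(ca - cb) / mean


def basic_similarity(a: CensusSample, b: CensusSample,
                     scheme: TaxonomyScheme,
                     category_deviation: float = 0.01,
                     total_deviation: float = 0.03,
                     **_ignored) -> SimilarityVerdict:
    """Apply the basic faunal-similarity criteria to a sample pair.

    Deviations are computed on corrected relative abundances over categories
    numeric in BOTH samples (no-information categories are ignored),
    morphotypes excluded.  The total-count criterion applies only when both
    totals are known.
    """
    maxdev = None
    compared = 0
    for code in set(a.relative) | set(b.relative):
        if scheme.is_morphotype(code):
            continue
        va = a.relative.get(code, NA)
        vb = b.relative.get(code, NA)
        if va is NA or vb is NA:
            continue
        compared += 1
        dev = abs(va - vb)
        if maxdev is None or dev > maxdev:
            maxdev = dev
    tdev = _total_deviation(a, b)
    passes = (compared > 0 and maxdev is not None
              and maxdev < category_deviation
              and (tdev is None or tdev <= total_deviation))
    return SimilarityVerdict(maxdev, tdev, compared, passes)


def _position(sample: CensusSample):
    lat = sample.metadata.latitude
    lon = sample.metadata.longitude
    if lat is None or lon is None:
        return None
    return (lat, lon)


def classify_pair(a: CensusSample, b: CensusSample, scheme: TaxonomyScheme,
                  criteria: dict | None = None) -> str | None:
    """Duplicate type of a basic-similar pair, or None (manual candidate).

    Criteria are evaluated sequentially, first match wins: plain (same name,
    close), incorrect position (same name, any distance), different name
    (close).  Without positions only the name criterion is evaluable.
    """
    crit = {**DEFAULT_CRITERIA, **(criteria or {})}
    if not basic_similarity(a, b, scheme, crit["category_deviation"],
                            crit["total_deviation"]).passes_basic:
        return None
    nd = name_distance(a.metadata.sample_name, b.metadata.sample_name)
    pa, pb = _position(a), _position(b)
    dist = distance_km(pa, pb) if pa and pb else None
    if nd == 0:
        if dist is not None and dist < crit["plain_km"]:
            return "plain"
        return "incorrect_position"
    if dist is not None and dist < crit["different_name_km"]:
        return "different_name"
    return None


# -- corpus-scale candidate search -------------------------------------------


def _abundance_matrix(samples, scheme):
    codes = scheme.counting_categories()
    A = np.full((len(samples), len(codes)), np.nan)
    for i, s in enumerate(samples):
        for j, code in enumerate(codes):
            v = s.relative.get(code, NA)
            if v is not NA:
                A[i, j] = v
    return A


def _faunal_candidate_pairs(samples, scheme, category_deviation,
                            chunk: int = 128):
    """Index pairs (i < j) passing the per-category faunal criterion."""
    n = len(samples)
    if n < 2:
        return []
    A = _abundance_matrix(samples, scheme)
    pairs = []
    for i0 in range(0, n, chunk):
        B = A[i0:i0 + chunk]
        diff = np.abs(B[:, None, :] - A[None, :, :])
        missing = np.isnan(diff)
        maxdev = np.where(missing, -1.0, diff).max(axis=2)
        shared = (~missing).sum(axis=2)
        ok = (shared > 0) & (maxdev >= 0.0) & (maxdev < category_deviation)
        for bi, j in zip(*np.nonzero(ok)):
            i = i0 + int(bi)
            if i < j:
                pairs.append((i, int(j)))
    return pairs


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def find_duplicates(corpus, stage_type: str, scheme: TaxonomyScheme,
                    criteria: dict | None = None) -> list:
    """All maximal duplicate clusters of one type in a corpus.

    Clusters are the transitive closure of pairwise matches; ordering is
    deterministic (members and clusters sorted by sample id), so detection is
    invariant under permutation of the input.
    """
    crit = {**DEFAULT_CRITERIA, **(criteria or {})}
    samples = sorted(corpus, key=lambda s: s.sample_id)
    cand = _faunal_candidate_pairs(samples, scheme,
                                   crit["category_deviation"])
    uf = _UnionFind(range(len(samples)))
    evidence = {}
    matched = set()
    for i, j in cand:
        a, b = samples[i], samples[j]
        tdev = _total_deviation(a, b)
        if tdev is not None and tdev > crit["total_deviation"]:
            continue
        if classify_pair(a, b, scheme, crit) != stage_type:
            continue
        uf.union(i, j)
        matched.update((i, j))
        pa, pb = _position(a), _position(b)
        evidence[(a.sample_id, b.sample_id)] = {
            "distance_km": distance_km(pa, pb) if pa and pb else None,
            "name_distance": name_distance(a.metadata.sample_name,
                                           b.metadata.sample_name),
        }
    groups = {}
    for i in matched:
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for root in sorted(groups):
        members = sorted(samples[i].sample_id for i in groups[root])
        ev = {f"{x}|{y}": v for (x, y), v in evidence.items()
              if x in members and y in members}
        clusters.append(DuplicateCluster(members, stage_type, ev))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


# -- merging ------------------------------------------------------------------


def _year_key(sample: CensusSample) -> int:
    y = sample.metadata.year
    return y if y is not None else 10 ** 6  # missing year treated as newest


def resolve_position(cluster_samples, bathymetry=None,
                     criteria: dict | None = None, audit=None):
    """Correct position of an incorrect-position cluster.

    First tries the minutes-as-decimals repair: a combination of coordinate
    repairs is accepted iff it moves a member more than 3.7 km from its
    recorded position *and* brings the pair within the plain-duplicate
    distance.  Failing that, the member whose stated water depth best matches
    the bathymetry provider's depth at its position wins; with no provider,
    the position of the oldest publication is kept.

    Returns ``(latitude, longitude, lat_precision, lon_precision, method)``.
    """
    crit = {**DEFAULT_CRITERIA, **(criteria or {})}
    ordered = sorted(cluster_samples, key=lambda s: s.sample_id)
    for a, b in itertools.combinations(ordered, 2):
        pa, pb = _position(a), _position(b)
        if pa is None or pb is None:
            continue
        for mask, ca, cb in enumerate_transform_combinations(pa, pb)[1:]:
            disp = max(distance_km(pa, ca), distance_km(pb, cb))
            if disp <= crit["transform_km"]:
                continue
            if distance_km(ca, cb) >= crit["plain_km"]:
                continue
            a_touched = any(i < 2 for i in mask)
            b_touched = any(i >= 2 for i in mask)
            if a_touched and not b_touched:
                keeper, pos = b, cb
            elif b_touched and not a_touched:
                keeper, pos = a, ca
            else:
                keeper, pos = a, ca
            if audit is not None:
                audit.record(keeper.sample_id, "resolve_position",
                             "latitude,longitude", (pa, pb), pos,
                             "minutes-as-decimals repair accepted")
            if not (a_touched and b_touched):
                return (pos[0], pos[1], keeper.lat_precision,
                        keeper.lon_precision, "transform")
            return (pos[0], pos[1], decimal_places(pos[0]),
                    decimal_places(pos[1]), "transform")
    if bathymetry is not None:
        scored = []
        for s in ordered:
            pos = _position(s)
            wd = s.metadata.water_depth
            if pos is None or wd is None:
                continue
            depth = bathymetry(pos[0], pos[1])
            if depth is None:
                continue
            scored.append((abs(wd - depth), _year_key(s), s.sample_id, s))
        if scored:
            best = min(scored)[3]
            return (best.metadata.latitude, best.metadata.longitude,
                    best.lat_precision, best.lon_precision, "bathymetry")
    oldest = min(ordered, key=lambda s: (_year_key(s), s.sample_id))
    if audit is not None:
        audit.record(oldest.sample_id, "resolve_position",
                     "latitude,longitude", None,
                     _position(oldest), "unresolved: kept oldest publication")
    return (oldest.metadata.latitude, oldest.metadata.longitude,
            oldest.lat_precision, oldest.lon_precision, "oldest")


_CARRYOVER_FIELDS = ("device", "water_depth", "author", "journal", "year",
                     "publication_doi", "resource_doi", "count_min")


def _depth_score(sample: CensusSample) -> int:
    m = sample.metadata
    have = [m.sample_depth_upper is not None, m.sample_depth_lower is not None,
            m.sample_depth_average is not None]
    if have[0] and have[1]:
        return 0  # complete bounds (average derivable)
    if have[2]:
        return 1  # average only
    if have[0] or have[1]:
        return 2
    return 3


def merge_cluster(cluster_samples, ctype: str, scheme: TaxonomyScheme,
                  bathymetry=None, basin_provider=None,
                  criteria: dict | None = None,
                  audit=None) -> tuple:
    """Merge a duplicate cluster into the most informative single record.

    The member with the highest number of counted taxa donates the assemblage
    (ties: older publication, then smaller sample id) and is mutated in
    place; the others are flagged as duplicates.  Position precedence is
    highest precision (incorrect-position clusters go through
    ``resolve_position``), depth metadata prefers complete bounds over an
    average only, all other metadata prefers existing information, and
    conflicts fall to the older publication.  The Database flag of the merged
    record is the bitwise OR over all members.

    Returns ``(merged_sample, discarded_samples)``.
    """
    members = sorted(cluster_samples, key=lambda s: s.sample_id)
    donor = min(members, key=lambda s: (
        -numeric_category_count(s.relative, scheme), _year_key(s),
        s.sample_id))
    others = [s for s in members if s is not donor]
    by_age = sorted(members, key=lambda s: (_year_key(s), s.sample_id))

    # position
    if ctype == "incorrect_position":
        lat, lon, latp, lonp, method = resolve_position(
            members, bathymetry, criteria, audit)
    else:
        pos_member = min(members, key=lambda s: (
            -(s.lat_precision + s.lon_precision), _year_key(s), s.sample_id))
        lat, lon = pos_member.metadata.latitude, pos_member.metadata.longitude
        latp, lonp = pos_member.lat_precision, pos_member.lon_precision
        method = "precision"
    donor.metadata.latitude, donor.metadata.longitude = lat, lon
    donor.lat_precision, donor.lon_precision = latp, lonp
    donor.metadata.ocean_flag = assign_ocean_flag(lat, lon, basin_provider)

    # sediment depth: most complete wins, ties to the older publication
    depth_member = min(members, key=lambda s: (
        _depth_score(s), _year_key(s), s.sample_id))
    donor.metadata.sample_depth_upper = depth_member.metadata.sample_depth_upper
    donor.metadata.sample_depth_lower = depth_member.metadata.sample_depth_lower
    donor.metadata.sample_depth_average = (
        depth_member.metadata.sample_depth_average)

    # other metadata: presence beats absence; conflicts -> older publication
    for fname in _CARRYOVER_FIELDS:
        for s in by_age:
            value = getattr(s.metadata, fname)
            if value not in (None, ""):
                setattr(donor.metadata, fname, value)
                break

    for s in others:
        donor.metadata.database_flag |= s.metadata.database_flag
        s.set_error(DUPLICATE)
        s.add_comment(f"duplicate ({ctype}) of {donor.sample_id}")
    donor.set_error(MODIFIED)
    trail = ", ".join(
        f"{s.sample_id}" + (f" [{s.metadata.resource_doi}]"
                            if s.metadata.resource_doi else "")
        for s in others)
    donor.add_comment(f"merged {ctype} duplicates: {trail} "
                      f"(position: {method})")
    if audit is not None:
        audit.record(donor.sample_id, "merge_cluster", ctype,
                     [s.sample_id for s in members], donor.sample_id, "")
    return donor, others


def dereplicate_stage(corpus, stage_type: str, scheme: TaxonomyScheme,
                      bathymetry=None, basin_provider=None,
                      criteria: dict | None = None, audit=None):
    """Run one detection stage on a corpus, merging every cluster found.

    Returns ``(new_corpus, clusters)``; discarded members stay flagged in
    their original objects (callers keep them in the full record list).
    """
    clusters = find_duplicates(corpus, stage_type, scheme, criteria)
    if not clusters:
        return list(corpus), []
    by_id = {s.sample_id: s for s in corpus}
    removed = set()
    for cluster in clusters:
        members = [by_id[i] for i in cluster.members]
        merged, others = merge_cluster(members, stage_type, scheme,
                                       bathymetry, basin_provider, criteria,
                                       audit)
        cluster.resolution = merged.sample_id
        removed.update(s.sample_id for s in others)
    new_corpus = [s for s in corpus if s.sample_id not in removed]
    return new_corpus, clusters


def sequential_dereplicate(step_batches, scheme: TaxonomyScheme,
                           bathymetry=None, basin_provider=None,
                           criteria: dict | None = None, audit=None):
    """Fold datasets together in cloning order, dereplicating at each step.

    ``step_batches`` is an ordered list of ``(step_name, samples)`` where each
    batch has already been individually processed (QC plus internal
    dereplication).  At every step after the first, the three stages run in
    sequence against the accumulated corpus.  Returns ``(corpus, all_records,
    ledger, clusters)`` where the ledger rows mirror the cumulative/stepwise
    bookkeeping of the curation protocol.
    """
    corpus: list[CensusSample] = []
    all_records: list[CensusSample] = []
    ledger = []
    clusters_found = []
    for step_index, (step_name, samples) in enumerate(step_batches):
        all_records.extend(samples)
        corpus.extend(s for s in samples if s.passing)
        counts = {stage: 0 for stage in STAGES}
        if step_index > 0:
            for stage in STAGES:
                corpus, clusters = dereplicate_stage(
                    corpus, stage, scheme, bathymetry, basin_provider,
                    criteria, audit)
                counts[stage] = sum(len(c.members) - 1 for c in clusters)
                for c in clusters:
                    c.evidence["step"] = step_name
                clusters_found.extend(clusters)
        ledger.append({
            "step": step_name,
            "total": len(all_records),
            "included": len(corpus),
            "excluded": len(all_records) - len(corpus),
            "duplicates": sum(counts.values()),
            "plain": counts["plain"],
            "position": counts["incorrect_position"],
            "name": counts["different_name"],
        })
    return corpus, all_records, ledger, clusters_found


# -- manual review -------------------------------------------------------------


def manual_review_candidates(corpus, scheme: TaxonomyScheme,
                             criteria: dict | None = None) -> list:
    """Remaining basic-similar pairs after all automatic stages.

    These pairs (typically differing in both name and position beyond the
    automatic thresholds) are never merged automatically; they are emitted
    for inspection by the compiler, sorted by faunal similarity.
    """
    crit = {**DEFAULT_CRITERIA, **(criteria or {})}
    samples = sorted(corpus, key=lambda s: s.sample_id)
    out = []
    for i, j in _faunal_candidate_pairs(samples, scheme,
                                        crit["category_deviation"]):
        a, b = samples[i], samples[j]
        verdict = basic_similarity(a, b, scheme, crit["category_deviation"],
                                   crit["total_deviation"])
        if not verdict.passes_basic:
            continue
        pa, pb = _position(a), _position(b)
        out.append({
            "sample_a": a.sample_id,
            "sample_b": b.sample_id,
            "max_category_deviation": verdict.max_category_deviation,
            "total_count_deviation": verdict.total_count_deviation,
            "name_distance": name_distance(a.metadata.sample_name,
                                           b.metadata.sample_name),
            "distance_km": distance_km(pa, pb) if pa and pb else None,
        })
    out.sort(key=lambda r: (r["max_category_deviation"], r["sample_a"],
                            r["sample_b"]))
    return out


def write_review_file(candidates, path) -> None:
    cols = ("sample_a", "sample_b", "max_category_deviation",
            "total_count_deviation", "name_distance", "distance_km",
            "verdict")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [str(c["sample_a"]), str(c["sample_b"]),
                   f"{c['max_category_deviation']:.6f}",
                   "" if c["total_count_deviation"] is None
                   else f"{c['total_count_deviation']:.6f}",
                   str(c["name_distance"]),
                   "" if c["distance_km"] is None
                   else f"{c['distance_km']:.3f}",
                   ""]
            fh.write("\t".join(row) + "\n")


def read_decisions(path) -> dict:
    """Read a reviewed candidates file: pair -> 'merge' or 'keep'."""
    decisions = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            verdict = row.get("verdict", "").strip().lower()
            if verdict in ("merge", "keep"):
                decisions[(row["sample_a"], row["sample_b"])] = verdict
    return decisions


def apply_manual_decisions(corpus, decisions: dict, scheme: TaxonomyScheme,
                           bathymetry=None, basin_provider=None,
                           criteria: dict | None = None, audit=None):
    """Merge the pairs a compiler marked 'merge' (duplicate type: manual)."""
    by_id = {s.sample_id: s for s in corpus}
    merge_pairs = [pair for pair, verdict in sorted(decisions.items())
                   if verdict == "merge"
                   and pair[0] in by_id and pair[1] in by_id]
    if not merge_pairs:
        return list(corpus), []
    ids = sorted({i for pair in merge_pairs for i in pair})
    uf = _UnionFind(ids)
    for a, b in merge_pairs:
        uf.union(a, b)
    groups = {}
    for i in ids:
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    removed = set()
    for root in sorted(groups):
        members = sorted(groups[root])
        cluster = DuplicateCluster(members, "manual")
        merged, others = merge_cluster([by_id[i] for i in members], "manual",
                                       scheme, bathymetry, basin_provider,
                                       criteria, audit)
        cluster.resolution = merged.sample_id
        removed.update(s.sample_id for s in others)
        clusters.append(cluster)
    return [s for s in corpus if s.sample_id not in removed], clusters
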