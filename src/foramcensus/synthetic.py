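"""Synthetic multi-dataset corpora with a ground-truth ledger.

Emulates the statistical shape of overlapping census compilations: a pool of
base samples with skewed (Dirichlet) assemblage compositions and
minute-aligned ship positions, cloned across datasets with the corruptions
observed in real compilations — values rounded to the 0.1% granularity,
name punctuation mutations, minutes-as-decimals coordinate errors and small
position jitter — plus planted QC violations and near-duplicate negative
controls.  Every planted fact is recorded in a ledger so that recall, false
merges and the per-step bookkeeping of the pipeline can be checked exactly.

The defaults are the study conditions the package is validated under:
five datasets of 200 samples with 15% overlap.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dereplication import basic_similarity
from .flags import database_scheme
from .metadata import DEFAULT_COUNT_MIN
from .samples import (NA, CensusSample, SampleMetadata, SourceDataset)
from .taxonomy import TaxonomyScheme

#: species treated as endemic by the QC rules; zeroed in clean assemblages so
#: that planted endemism violations are the only ones
_ENDEMIC_CODES = ("g_ruber_pink", "g_conglomerata", "g_hexagonus", "g_adamsi")

_DEVICES = ("Piston", "Gravity", "Box", "Multi", "Grab")

_DATABASE_LABELS = ("CLIMAP", "BUFD", "ATL947", "MARGO North Atlantic",
                    "MARGO South Atlantic", "MARGO Indo-Pacific",
                    "MARGO Pacific", "MARGO Mediterranean")

_VIOLATION_KINDS = ("sum_deviation", "low_count", "unidentified_excess",
                    "endemic", "missing_coords", "bad_device")


@dataclass
class CorpusConfig:
    """Study conditions of a synthetic corpus; the seed fully determines it."""

    n_datasets: int = 5
    samples_per_dataset: int = 200
    overlap_fraction: float = 0.15
    dirichlet_alpha: float = 0.3
    rounding_decimals: int = 3          # 0.1% granularity of published values
    total_count_jitter: float = 0.02    # clone total jitter (< 3% criterion)
    name_mutation_prob: float = 0.25    # share of clones planted different-name
    coordinate_corruption_prob: float = 0.25  # share planted incorrect-position
    position_jitter_km: float = 0.9     # plain-clone jitter (< 2.621 km)
    qc_violation_rate: float = 0.03     # share of fresh samples per dataset
    negative_control_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("overlap_fraction", "name_mutation_prob",
                     "coordinate_corruption_prob", "qc_violation_rate",
                     "negative_control_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.overlap_fraction > 0 and self.n_datasets < 2:
            raise ValueError("overlap requires at least two datasets")


@dataclass
class TruthLedger:
    """Everything that was planted, keyed for exact comparison."""

    origin: dict = field(default_factory=dict)      # sample id -> base id
    clusters: list = field(default_factory=list)    # {members, type, step}
    violations: list = field(default_factory=list)  # {sample_id, bits}
    negatives: list = field(default_factory=list)   # {members, kind}

    def expected_step_counts(self) -> dict:
        """Planted duplicates by detection type per sequential step."""
        out: dict = {}
        for c in self.clusters:
            step = out.setdefault(c["step"], {"plain": 0,
                                              "incorrect_position": 0,
                                              "different_name": 0})
            step[c["type"]] += len(c["members"]) - 1
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"origin": self.origin, "clusters": self.clusters,
                       "violations": self.violations,
                       "negatives": self.negatives}, fh, indent=1,
                      sort_keys=True)


@dataclass
class _Base:
    """Internal ground-truth state of one physical sample."""

    base_id: str
    name: str
    lat: float   # true position, minute-aligned
    lon: float
    water_depth: float
    fractions: dict  # true (unrounded) assemblage over species codes
    total: int
    dataset_index: int


def synthetic_seafloor(lat: float, lon: float) -> float:
    """Analytic bathymetry (m, positive down) for provider-based tests."""
    return max(50.0, 2500.0 + 1500.0 * math.sin(math.radians(lat) * 4.0)
               + 1000.0 * math.cos(math.radians(lon) * 3.0))


def _minute_aligned(rng, lo_deg: int, hi_deg: int,
                    minute_lo: int = 0, minute_hi: int = 59) -> float:
    deg = int(rng.integers(lo_deg, hi_deg + 1))
    minute = int(rng.integers(minute_lo, minute_hi + 1))
    sign = -1.0 if deg < 0 else 1.0
    return sign * (abs(deg) + minute / 60.0)


def _lat_minutes(lat: float) -> int:
    return int(round((abs(lat) - math.floor(abs(lat))) * 60.0))


class _Generator:
    def __init__(self, config: CorpusConfig, scheme: TaxonomyScheme):
        config.validate()
        self.config = config
        self.scheme = scheme
        self.rng = np.random.default_rng(config.seed)
        self.species = [c.code for c in scheme.categories
                        if c.kind == "species" and c.recorded_anywhere]
        self.reported = set(self.species) | {scheme.unidentified}
        self.ledger = TruthLedger()
        self.counter = 0
        self.bases: list[_Base] = []

    # -- primitive builders ------------------------------------------------

    def _next_name(self) -> str:
        self.counter += 1
        return f"SYN-{self.counter:04d}"

    def _assemblage(self) -> dict:
        alpha = np.full(len(self.species), self.config.dirichlet_alpha)
        values = self.rng.dirichlet(alpha)
        fractions = dict(zip(self.species, values))
        for code in _ENDEMIC_CODES:
            fractions[code] = 0.0
        total = sum(fractions.values())
        return {c: v / total for c, v in fractions.items()}

    def _new_base(self, d: int) -> _Base:
        lat = _minute_aligned(self.rng, -64, 64)
        lon = _minute_aligned(self.rng, -179, 179)
        return _Base(
            base_id="", name=self._next_name(), lat=lat, lon=lon,
            water_depth=round(synthetic_seafloor(lat, lon)),
            fractions=self._assemblage(),
            total=int(self.rng.integers(280, 421)), dataset_index=d)

    def _sample(self, ds_id: str, index: int, d: int, raw: bool, name: str,
                lat, lon, fractions: dict, total: int | None,
                water_depth, device: str = "",
                lat_precision: int = 4, lon_precision: int = 4,
                ) -> CensusSample:
        sid = f"{ds_id}:{index:05d}"
        unid_frac = fractions.get("__unidentified__", 0.0)
        fracs = {c: v for c, v in fractions.items()
                 if c != "__unidentified__"}
        if raw:
            values = {c: float(round(f * total)) for c, f in fracs.items()}
            values[self.scheme.unidentified] = float(round(unid_frac * total))
            count = sum(values.values())
        else:
            dec = self.config.rounding_decimals
            values = {c: round(f, dec) for c, f in fracs.items()}
            values[self.scheme.unidentified] = round(unid_frac, dec)
            count = None
        meta = SampleMetadata(
            sample_name=name.upper(), sample_id=sid,
            device=device or _DEVICES[index % len(_DEVICES)],
            latitude=None if lat is None else round(lat, lat_precision),
            longitude=None if lon is None else round(lon, lon_precision),
            water_depth=water_depth,
            author=f"Synthetic compilation {d}",
            journal="Synthetic Data Repository", year=1980 + 5 * d,
            resource_doi=f"10.0000/synthetic.{d}",
            database_flag=0, type=1 if raw else 0,
            count_min=DEFAULT_COUNT_MIN, count=count)
        return CensusSample(
            metadata=meta, original=dict(values),
            counts=dict(values) if raw else None, relative={},
            dataset_id=ds_id, lat_precision=lat_precision,
            lon_precision=lon_precision)

    # -- planting ----------------------------------------------------------

    def _plant_violation(self, ds_id, index, d, raw, kind) -> CensusSample:
        from . import samples as S
        base = self._new_base(d)
        fractions = dict(base.fractions)
        lat, lon, device = base.lat, base.lon, ""
        expected = 0
        if kind == "sum_deviation":
            if raw:
                kind = "low_count"  # raw counts always sum consistently
            else:
                fractions = {c: v * 1.12 for c, v in fractions.items()}
                expected = S.SUM_DEVIATES
        if kind == "low_count":
            base.total = 120
            expected = S.TOO_FEW_COUNTED
            if not raw:
                # relative-only record whose study counted too few
                pass
        elif kind == "unidentified_excess":
            fractions = {c: v * 0.90 for c, v in fractions.items()}
            fractions["__unidentified__"] = 0.10
            expected = S.TOO_MANY_UNIDENTIFIED
        elif kind == "endemic":
            lat = _minute_aligned(self.rng, 0, 20)
            lon = -150.0 + float(self.rng.integers(0, 10))
            fractions = {c: v * 0.97 for c, v in fractions.items()}
            fractions["g_ruber_pink"] = 0.03
            expected = S.TAXONOMICALLY_INCORRECT
        elif kind == "missing_coords":
            lat = lon = None
            expected = S.NO_COORDINATES
        elif kind == "bad_device":
            device = "Dredge"
            expected = S.NONSTANDARD_DEVICE
        sample = self._sample(ds_id, index, d, raw, base.name, lat, lon,
                              fractions, base.total,
                              base.water_depth, device)
        if kind == "low_count" and not raw:
            sample.metadata.count_min = 120
            sample.metadata.count = None
        self.ledger.origin[sample.sample_id] = sample.sample_id
        self.ledger.violations.append(
            {"sample_id": sample.sample_id, "kind": kind, "bits": expected})
        return sample

    def _clone(self, ds_id, index, d, raw, base: _Base) -> CensusSample:
        cfg = self.config
        u = self.rng.random()
        lat, lon = base.lat, base.lon
        latp = lonp = 4
        name = base.name
        minutes = _lat_minutes(base.lat)
        if u < cfg.coordinate_corruption_prob and 6 <= minutes <= 54:
            ctype = "incorrect_position"
            sign = -1.0 if base.lat < 0 else 1.0
            lat = sign * (math.floor(abs(base.lat)) + minutes / 100.0)
            latp = 2
        elif u < (cfg.coordinate_corruption_prob + cfg.name_mutation_prob):
            ctype = "different_name"
            name = base.name.replace("-", "_")
            lat = base.lat + float(self.rng.uniform(-0.002, 0.002))
        else:
            ctype = "plain"
            jitter_deg = cfg.position_jitter_km / 111.195
            lat = base.lat + float(self.rng.uniform(-jitter_deg, jitter_deg))
        total = int(round(base.total
                          * (1.0 + float(self.rng.uniform(
                              -cfg.total_count_jitter,
                              cfg.total_count_jitter)))))
        sample = self._sample(ds_id, index, d, raw, name, lat, lon,
                              dict(base.fractions), total, base.water_depth,
                              lat_precision=latp, lon_precision=lonp)
        self.ledger.origin[sample.sample_id] = base.base_id
        self.ledger.clusters.append({
            "members": sorted([base.base_id, sample.sample_id]),
            "base": base.base_id, "clone": sample.sample_id,
            "type": ctype, "step": ds_id})
        return sample

    def _plant_negative(self, ds_id, index, d, raw, base: _Base,
                        kind: str) -> CensusSample:
        fractions = dict(base.fractions)
        name, lat = base.name, base.lat
        if kind == "recount":
            # same site, deviating recount: top category shifted by >= 2x
            # the 1% faunal criterion
            top, second = sorted(fractions, key=fractions.get)[-2:]
            shift = 0.025
            fractions[top] += shift
            fractions[second] -= shift
            if fractions[second] < 0:
                fractions[top] += fractions[second]
                fractions[second] = 0.0
        else:  # far twin: same fauna, unrelated name, >= 2x every distance
            name = self._next_name()
            lat = base.lat + 0.1
        sample = self._sample(ds_id, index, d, raw, name, lat, base.lon,
                              fractions, base.total, base.water_depth)
        self.ledger.origin[sample.sample_id] = sample.sample_id
        self.ledger.negatives.append(
            {"members": sorted([base.base_id, sample.sample_id]),
             "kind": kind})
        return sample

    # -- assembly ----------------------------------------------------------

    def generate(self):
        cfg = self.config
        datasets = []
        eligible: list[_Base] = []
        pending_negatives: list[tuple] = []
        for d in range(cfg.n_datasets):
            ds_id = f"SYN{d}"
            raw = d % 2 == 0
            samples = []
            index = 0

            n_clones = (round(cfg.overlap_fraction * cfg.samples_per_dataset)
                        if d > 0 else 0)
            n_clones = min(n_clones, len(eligible))
            if n_clones:
                chosen = self.rng.choice(len(eligible), size=n_clones,
                                         replace=False)
                for k in sorted(int(c) for c in chosen):
                    samples.append(self._clone(ds_id, index, d, raw,
                                               eligible[k]))
                    index += 1

            for base, kind in pending_negatives:
                samples.append(self._plant_negative(ds_id, index, d, raw,
                                                    base, kind))
                index += 1
            pending_negatives = []

            n_fresh = cfg.samples_per_dataset - index
            n_violations = round(cfg.qc_violation_rate * n_fresh)
            n_negatives = (round(cfg.negative_control_rate * n_fresh)
                           if d + 1 < cfg.n_datasets else 0)
            for v in range(n_violations):
                kind = _VIOLATION_KINDS[v % len(_VIOLATION_KINDS)]
                samples.append(self._plant_violation(ds_id, index, d, raw,
                                                     kind))
                index += 1
            for v in range(n_negatives):
                base = self._new_base(d)
                base.base_id = f"{ds_id}:{index:05d}"
                sample = self._sample(ds_id, index, d, raw, base.name,
                                      base.lat, base.lon, base.fractions,
                                      base.total, base.water_depth)
                self.ledger.origin[sample.sample_id] = sample.sample_id
                samples.append(sample)
                index += 1
                kind = "recount" if v % 2 == 0 else "far_twin"
                pending_negatives.append((base, kind))
            while index < cfg.samples_per_dataset:
                base = self._new_base(d)
                base.base_id = f"{ds_id}:{index:05d}"
                sample = self._sample(ds_id, index, d, raw, base.name,
                                      base.lat, base.lon, base.fractions,
                                      base.total, base.water_depth)
                self.ledger.origin[sample.sample_id] = sample.sample_id
                samples.append(sample)
                eligible.append(base)
                index += 1

            datasets.append(SourceDataset(
                dataset_id=ds_id, samples=samples,
                database_label=(_DATABASE_LABELS[d]
                                if d < len(_DATABASE_LABELS) else None),
                data_type="raw" if raw else "relative",
                relative_unit="fraction",
                reported_categories=set(self.reported)))
        for ds in datasets:
            if ds.database_label:
                bit = database_scheme().encode([ds.database_label])
                for s in ds.samples:
                    s.metadata.database_flag = bit
        self._validate_plants(datasets)
        return datasets, self.ledger


    def _validate_plants(self, datasets) -> None:
        """Planted within-threshold clones must satisfy basic similarity."""
        by_id = {s.sample_id: s for ds in datasets for s in ds.samples}
        for cluster in self.ledger.clusters:
            pair = []
            for sid in cluster["members"]:
                s = by_id[sid]
                probe = CensusSample(metadata=s.metadata,
                                     relative=_probe_relative(s, self.scheme))
                pair.append(probe)
            verdict = basic_similarity(pair[0], pair[1], self.scheme)
            if not verdict.passes_basic:
                raise AssertionError(
                    f"planted clone pair {cluster['members']} fails the "
                    f"basic similarity criteria: {verdict}")


def _probe_relative(sample: CensusSample, scheme) -> dict:
    if sample.counts is not None:
        total = sum(v for v in sample.counts.values() if v is not NA) or 1.0
        return {c: (NA if v is NA else v / total)
                for c, v in sample.counts.items()}
    return dict(sample.original)


def generate_corpus(config: CorpusConfig | None = None,
                    scheme: TaxonomyScheme | None = None):
    """Generate a synthetic corpus: ``(list of SourceDataset, TruthLedger)``.

    Deterministic in ``config.seed``; with ``overlap_fraction == 0`` the
    ledger contains no planted clusters.
    """
    config = config or CorpusConfig()
    scheme = scheme or TaxonomyScheme.load()
    return _Generator(config, scheme).generate()


# -- file emission (CLI) -------------------------------------------------------


def write_corpus(datasets, ledger, scheme: TaxonomyScheme, out_dir) -> None:
    """Write source tables, schema configs and the truth ledger to a folder."""
    os.makedirs(out_dir, exist_ok=True)
    display = {c.code: c.name or c.code for c in scheme.categories}
    display[scheme.unidentified] = "unidentified"
    for ds in datasets:
        codes = sorted(ds.reported_categories)
        meta_cols = ["Sample_name", "Latitude", "Longitude", "Device",
                     "Water_depth", "Year", "Author", "Resource_doi"]
        if ds.data_type == "raw":
            meta_cols.append("Total")
        path = os.path.join(out_dir, f"{ds.dataset_id}.tsv")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(meta_cols
                               + [display[c] for c in codes]) + "\n")
            for s in ds.samples:
                m = s.metadata
                row = [m.sample_name,
                       "" if m.latitude is None
                       else f"{m.latitude:.{s.lat_precision}f}",
                       "" if m.longitude is None
                       else f"{m.longitude:.{s.lon_precision}f}",
                       m.device or "", f"{m.water_depth:g}",
                       str(m.year), m.author, m.resource_doi]
                if ds.data_type == "raw":
                    row.append("" if m.count is None else f"{m.count:g}")
                for c in codes:
                    v = s.original.get(c, NA)
                    row.append("" if v is NA else f"{v:g}")
                fh.write("\t".join(row) + "\n")
        schema = {
            "dataset_id": ds.dataset_id,
            "database": ds.database_label,
            "type": ds.data_type,
            "relative_unit": ds.relative_unit,
            "columns": {
                "sample_name": "Sample_name", "latitude": "Latitude",
                "longitude": "Longitude", "device": "Device",
                "water_depth": "Water_depth", "year": "Year",
                "author": "Author", "resource_doi": "Resource_doi",
                **({"count": "Total"} if ds.data_type == "raw" else {}),
            },
        }
        with open(os.path.join(out_dir, f"{ds.dataset_id}.schema.yml"),
                  "w", encoding="utf-8") as fh:
            yaml.safe_dump(schema, fh, sort_keys=True)
    ledger.to_json(os.path.join(out_dir, "truth_ledger.json"))
    pipeline_config = {
        "datasets": [{"id": ds.dataset_id,
                      "path": f"{ds.dataset_id}.tsv",
                      "schema": f"{ds.dataset_id}.schema.yml"}
                     for ds in datasets],
        "output_dir": "out",
    }
    with open(os.path.join(out_dir, "pipeline.yml"), "w",
              encoding="utf-8") as fh:
        yaml.safe_dump(pipeline_config, fh, sort_keys=True)
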