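"""Core containers for census samples.

A census sample couples standardised metadata with up to three abundance
blocks keyed by taxon code: the original values as published (mapped onto the
master taxonomy only), corrected absolute counts (raw-count sources only) and
corrected relative proportions.  Throughout the package ``None`` is the
"not available" sentinel and is strictly distinct from an observed zero.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

#: not-available sentinel (distinct from 0.0)
NA = None

#: Error-flag bit values (see the shipped ``flags_error.tsv`` scheme).
MODIFIED = 1
DUPLICATE = 8
TAXONOMICALLY_INCORRECT = 16
TOO_MANY_UNIDENTIFIED = 32
SUM_DEVIATES = 64
TOO_FEW_COUNTED = 128
NONSTANDARD_DEVICE = 256
NO_COORDINATES = 512

#: A record passes all selection criteria iff its Error flag is at most 1
#: (i.e. at worst "modified").
PASSING_MAX_ERROR = 1


@dataclass
class SampleMetadata:
    """The 21 standardised metadata fields of one sample."""

    sample_name: str = ""
    sample_id: str = ""
    error_flag: int = 0
    device: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    water_depth: float | None = None
    ocean_flag: int = 0
    sample_depth_upper: float | None = None
    sample_depth_lower: float | None = None
    sample_depth_average: float | None = None
    author: str = ""
    journal: str = ""
    year: int | None = None
    publication_doi: str = ""
    resource_doi: str = ""
    comment: str = ""
    database_flag: int = 0
    type: int = 0  # 0 relative abundances, 1 raw counts
    count_min: int | None = None
    count: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CensusSample:
    """One sample: metadata plus the three abundance blocks.

    Abundance dicts map taxon code -> value, where value is a non-negative
    number or ``None`` (not available).  ``counts`` is ``None`` altogether
    for sources that only published relative abundances.
    """

    metadata: SampleMetadata = field(default_factory=SampleMetadata)
    original: dict = field(default_factory=dict)
    counts: dict | None = None
    relative: dict = field(default_factory=dict)
    dataset_id: str = ""
    lat_precision: int = 4
    lon_precision: int = 4

    @property
    def sample_id(self) -> str:
        return self.metadata.sample_id

    def set_error(self, bit_value: int) -> None:
        self.metadata.error_flag |= bit_value

    def has_error(self, bit_value: int) -> bool:
        return bool(self.metadata.error_flag & bit_value)

    @property
    def passing(self) -> bool:
        return self.metadata.error_flag <= PASSING_MAX_ERROR

    def add_comment(self, text: str) -> None:
        if self.metadata.comment:
            self.metadata.comment += "; " + text
        else:
            self.metadata.comment = text

    def copy(self) -> "CensusSample":
        return copy.deepcopy(self)


@dataclass
class SourceDataset:
    """An ordered collection of samples with shared provenance."""

    dataset_id: str = ""
    samples: list = field(default_factory=list)
    database_label: str | None = None
    data_type: str = "relative"  # "raw" or "relative"
    relative_unit: str = "auto"  # "fraction", "percent" or "auto"
    reported_categories: set = field(default_factory=set)
    unmapped_columns: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)
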