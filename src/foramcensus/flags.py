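"""Binary flag schemes (Error / Database / Ocean) and basin assignment.

Each scheme assigns one power of two per named state so that any combination
of states is expressible as a single integer, e.g. a Database flag of 7
records simultaneous membership in the first three constituent compilations
(1 + 2 + 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources


@dataclass(frozen=True)
class FlagBit:
    bit: int  # 1-based index
    value: int  # 2 ** (bit - 1)
    label: str


class FlagScheme:
    def __init__(self, name: str, bits):
        self.name = name
        self.bits = list(bits)
        values = [b.value for b in self.bits]
        for b in self.bits:
            if b.value != 2 ** (b.bit - 1):
                raise ValueError(f"bit {b.bit} has value {b.value}")
        if len(set(values)) != len(values):
            raise ValueError("duplicate bit values")
        self.by_label = {b.label: b for b in self.bits}
        self.max_value = sum(values)

    def __len__(self) -> int:
        return len(self.bits)

    def encode(self, labels) -> int:
        """Sum of the power-of-two values of the given bit labels."""
        value = 0
        for label in labels:
            if label not in self.by_label:
                raise KeyError(
                    f"unknown {self.name} flag label: {label!r}")
            value |= self.by_label[label].value
        return value

    def decode(self, value: int) -> set:
        """Set of bit labels contained in ``value`` (inverse of encode)."""
        if value < 0 or value > self.max_value:
            stray = value & ~self.max_value if value >= 0 else value
            raise ValueError(
                f"value {value} has bits outside the {self.name} scheme "
                f"(stray bits: {stray})")
        return {b.label for b in self.bits if value & b.value}

    @classmethod
    def from_tsv(cls, name: str, path) -> "FlagScheme":
        bits = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                bits.append(FlagBit(int(row["bit"]), int(row["value"]),
                                    row["label"]))
        return cls(name, bits)


@lru_cache(maxsize=None)
def error_scheme() -> FlagScheme:
    return FlagScheme.from_tsv(
        "Error", resources.files("foramcensus") / "data" / "flags_error.tsv")


@lru_cache(maxsize=None)
def database_scheme() -> FlagScheme:
    return FlagScheme.from_tsv(
        "Database",
        resources.files("foramcensus") / "data" / "flags_database.tsv")


@lru_cache(maxsize=None)
def ocean_scheme() -> FlagScheme:
    return FlagScheme.from_tsv(
        "Ocean", resources.files("foramcensus") / "data" / "flags_ocean.tsv")


def encode_flag(labels, scheme: FlagScheme) -> int:
    return scheme.encode(labels)


def decode_flag(value: int, scheme: FlagScheme) -> set:
    return scheme.decode(value)


# -- basin assignment ---------------------------------------------------------


def fallback_basin_labels(latitude: float, longitude: float) -> set:
    """Coarse longitude/latitude boxes standing in for a gridded basin mask.

    Deliberately crude: the QC logic only needs the Atlantic+Mediterranean
    versus Pacific+Indian+Red Sea dichotomy, plus hemispheric sub-basin bits
    for regional subsetting.  Marginal seas do not set their parent-basin
    bit; a user-supplied mask provider may adopt richer semantics.
    """
    if latitude is None or longitude is None:
        return set()
    labels = {"All oceans"}
    if 30.0 <= latitude <= 47.0 and -6.0 <= longitude <= 36.5:
        labels.add("Mediterranean Sea")
        return labels
    if 10.0 <= latitude <= 30.0 and 32.0 <= longitude <= 43.5:
        labels.add("Red Sea")
        return labels
    if latitude <= -60.0:
        labels.add("Southern Ocean")
        return labels
    if latitude >= 66.0:
        labels.add("Arctic Ocean")
        return labels
    if -70.0 <= longitude < 20.0:
        labels.add("Atlantic")
        labels.add("North Atlantic" if latitude >= 0 else "South Atlantic")
    elif 20.0 <= longitude < 146.0 and latitude <= 30.0:
        labels.add("Indian Ocean")
    else:
        labels.add("Pacific")
        labels.add("North Pacific" if latitude >= 0 else "South Pacific")
    return labels


def assign_ocean_flag(latitude, longitude, basin_provider=None,
                      scheme: FlagScheme | None = None) -> int:
    """Ocean flag for a position via a pluggable basin provider.

    The provider maps (lat, lon) to a set of Ocean bit labels; a missing
    position or an empty provider answer yields flag 0.
    """
    scheme = scheme or ocean_scheme()
    provider = basin_provider or fallback_basin_labels
    if latitude is None or longitude is None:
        return 0
    labels = provider(latitude, longitude)
    if not labels:
        return 0
    return scheme.encode(labels)


def grid_basin_provider(path):
    """Basin provider backed by a delimited lattice with nearest-cell lookup.

    The file is tab-delimited with a header ``latitude<TAB>longitude<TAB>
    labels`` where ``labels`` is a comma-separated list of Ocean bit labels
    for that grid cell.  Lookup returns the labels of the nearest cell.
    """
    import numpy as np

    lats, lons, labels = [], [], []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            lat, lon, cell = line.rstrip("\n").split("\t")
            lats.append(float(lat))
            lons.append(float(lon))
            labels.append({x.strip() for x in cell.split(",") if x.strip()})
    grid_lat = np.asarray(lats)
    grid_lon = np.asarray(lons)

    def provider(latitude: float, longitude: float) -> set:
        if latitude is None or longitude is None:
            return set()
        dlon = np.abs(grid_lon - longitude)
        dlon = np.minimum(dlon, 360.0 - dlon)  # wrap the antimeridian
        coslat = math.cos(math.radians(latitude))
        d2 = (grid_lat - latitude) ** 2 + (dlon * coslat) ** 2
        return set(labels[int(np.argmin(d2))])

    return provider


#: Ocean bits feeding the endemism rules, by group.
_ATLANTIC_LABELS = {"Atlantic", "Mediterranean Sea"}
_INDOPACIFIC_LABELS = {"Pacific", "Indian Ocean", "Red Sea"}


def basin_group(ocean_flag: int, scheme: FlagScheme | None = None):
    """Resolve an Ocean flag to the endemism dichotomy.

    Returns ``"atlantic"`` (Atlantic or Mediterranean), ``"indopacific"``
    (Pacific, Indian Ocean or Red Sea) or ``None`` when unresolvable.
    """
    scheme = scheme or ocean_scheme()
    try:
        labels = scheme.decode(ocean_flag)
    except ValueError:
        return None
    if labels & _ATLANTIC_LABELS:
        return "atlantic"
    if labels & _INDOPACIFIC_LABELS:
        return "indopacific"
    return None
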