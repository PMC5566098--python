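"""Standardisation of sample metadata.

Brings heterogeneous source metadata onto the common 21-field layout:
uppercased sample names, sampling devices mapped to a fixed vocabulary,
sediment depths in metres with the upper/lower/average relationship
enforced, and a default minimum count of 300 individuals (the common
counting standard) where no study-specific value is given.
"""

from __future__ import annotations

import math

from .samples import SampleMetadata

#: Devices considered standard for surface-sediment census work.  Anything
#: else (including plankton tows, dredges, unknown or missing devices) is
#: later flagged by the device filter.
STANDARD_DEVICES = ("Piston", "Gravity", "Trigger", "Grab", "Giant Box",
                    "Box", "Multi", "Mini", "CTD")

#: Default minimum number of counted individuals when a study states none.
DEFAULT_COUNT_MIN = 300

# keyword -> standard category; order matters ("giant box" before "box",
# "multi" before "mini" is irrelevant but kept explicit)
_DEVICE_KEYWORDS = (
    ("giant box", "Giant Box"),
    ("giant_box", "Giant Box"),
    ("boxcore", "Box"),
    ("box", "Box"),
    ("piston", "Piston"),
    ("gravity", "Gravity"),
    ("trigger", "Trigger"),
    ("grab", "Grab"),
    ("multi", "Multi"),
    ("mini", "Mini"),
    ("ctd", "CTD"),
    ("kasten", "Box"),
)


def standardize_device(raw) -> str | None:
    """Map a free-text device description onto the standard vocabulary.

    Never invents a category: unmapped non-empty descriptions become
    ``"other"``; empty/missing stays ``None``.
    """
    if raw is None or str(raw).strip() == "":
        return None
    text = str(raw).strip()
    if text in STANDARD_DEVICES or text == "other":
        return text
    low = text.lower()
    for keyword, category in _DEVICE_KEYWORDS:
        if keyword in low:
            return category
    return "other"


def _to_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if not text or text.upper() in ("NA", "NAN", "N/A"):
        return None
    try:
        return float(text)
    except ValueError:
        return None


def _to_int(value) -> int | None:
    f = _to_float(value)
    if f is None:
        return None
    return int(round(f))


def parse_coordinate(value) -> tuple:
    """Parse a coordinate cell, returning (value, decimal places).

    The printed number of decimal places is the coordinate's precision; it is
    preserved so that positional merge precedence and the minutes-as-decimals
    repair can operate on what was actually recorded.
    """
    if value is None:
        return None, 0
    text = str(value).strip()
    f = _to_float(text)
    if f is None:
        return None, 0
    if "e" in text.lower():
        return f, 6
    if "." in text:
        return f, len(text.split(".", 1)[1])
    return f, 0


def standardize_metadata(record: dict, depth_unit: str = "m",
                         default_type: int = 0) -> SampleMetadata:
    """Standardise one raw metadata record.

    ``record`` maps canonical field names to raw cell values.  The operation
    is idempotent: feeding a standardised record back yields the same result.
    Unparseable coordinates are kept missing (the record is flagged later,
    never dropped here).
    """
    scale = 0.01 if depth_unit == "cm" else 1.0

    name = str(record.get("sample_name") or "").strip().upper()
    lat, _ = parse_coordinate(record.get("latitude"))
    lon, _ = parse_coordinate(record.get("longitude"))
    if lat is not None and not -90.0 <= lat <= 90.0:
        lat = None
    if lon is not None and not -180.0 <= lon <= 180.0:
        lon = None

    upper = _to_float(record.get("sample_depth_upper"))
    lower = _to_float(record.get("sample_depth_lower"))
    average = _to_float(record.get("sample_depth_average"))
    if upper is not None:
        upper *= scale
    if lower is not None:
        lower *= scale
    if average is not None:
        average *= scale
    # a lower bound of zero can only be a misplaced upper bound
    if lower == 0.0 and upper is None:
        upper, lower = 0.0, None
    if upper is not None and lower is not None:
        average = (upper + lower) / 2.0

    count_min = _to_int(record.get("count_min"))
    if count_min is None:
        count_min = DEFAULT_COUNT_MIN

    return SampleMetadata(
        sample_name=name,
        sample_id=str(record.get("sample_id") or name),
        error_flag=_to_int(record.get("error_flag")) or 0,
        device=standardize_device(record.get("device")),
        latitude=lat,
        longitude=lon,
        water_depth=_to_float(record.get("water_depth")),
        ocean_flag=_to_int(record.get("ocean_flag")) or 0,
        sample_depth_upper=upper,
        sample_depth_lower=lower,
        sample_depth_average=average,
        author=str(record.get("author") or "").strip(),
        journal=str(record.get("journal") or "").strip(),
        year=_to_int(record.get("year")),
        publication_doi=str(record.get("publication_doi") or "").strip(),
        resource_doi=str(record.get("resource_doi") or "").strip(),
        comment=str(record.get("comment") or "").strip(),
        database_flag=_to_int(record.get("database_flag")) or 0,
        type=_to_int(record.get("type")) if record.get("type") is not None
        else default_type,
        count_min=count_min,
        count=_to_float(record.get("count")),
    )
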