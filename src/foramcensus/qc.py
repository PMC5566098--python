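"""Count standardisation, correction and single-sample exclusion filters.

Samples are never dropped here: quality problems set bits of the Error flag
and a record is excluded downstream iff its flag exceeds 1 ("modified" is the
only bit compatible with retention).  All threshold comparisons are strict as
printed in the curation protocol (>1%, >5%, <150, deviation by more than 5%),
and every value-altering correction sets the 'modified' bit and leaves an
audit entry, so filters commute and the exclusion set is order-independent.
"""

from __future__ import annotations

from .flags import basin_group
from .samples import (MODIFIED, NA, NO_COORDINATES, NONSTANDARD_DEVICE,
                      SUM_DEVIATES, TAXONOMICALLY_INCORRECT, TOO_FEW_COUNTED,
                      TOO_MANY_UNIDENTIFIED, CensusSample)
from .metadata import STANDARD_DEVICES
from .taxonomy import TaxonomyScheme, counting_sum, numeric_category_count

#: Curation thresholds, exposed for configuration; defaults are the
#: protocol's values.
DEFAULT_THRESHOLDS = {
    "sum_deviation": 0.05,       # tolerated |sum - 1| before exclusion
    "min_count": 150,            # minimum counted individuals
    "max_unidentified": 0.05,    # tolerated 'unidentified' proportion
    "endemic": 0.01,             # tolerated out-of-range endemic abundance
    "rounding_unit": 0.001,      # assumed rounding of individual categories
}


def rounding_error(n: int, rounding_unit: float = 0.001) -> float:
    """Expected total rounding error of a sample with n given categories.

    Individual categories are assumed rounded to 0.1%, so the expected
    deviation of the sum is n * 0.001 / 2.
    """
    if n <= 0:
        raise ValueError("need at least one given category")
    return n * rounding_unit / 2.0


def correct_total_count(sample: CensusSample, scheme: TaxonomyScheme,
                        audit=None) -> CensusSample:
    """Set the stated total count to the category sum when they disagree."""
    if sample.counts is None:
        return sample
    n = numeric_category_count(sample.counts, scheme)
    if n == 0:
        return sample
    total = counting_sum(sample.counts, scheme)
    stated = sample.metadata.count
    if stated is None or abs(stated - total) > 1e-9:
        if stated is not None:
            sample.set_error(MODIFIED)
            sample.add_comment(
                f"total count corrected from {stated:g} to {total:g}")
        if audit is not None:
            audit.record(sample.sample_id, "correct_total_count", "count",
                         stated, total, "total = sum of categories")
        sample.metadata.count = total
    return sample


def derive_relative(sample: CensusSample, scheme: TaxonomyScheme) -> CensusSample:
    """Compute relative proportions from corrected absolute counts."""
    if sample.counts is None:
        return sample
    total = sample.metadata.count
    if not total:
        return sample
    sample.relative = {
        code: (NA if v is NA else v / total)
        for code, v in sample.counts.items()
    }
    return sample


def standardize_relative(sample: CensusSample, scheme: TaxonomyScheme,
                         unit: str = "auto") -> CensusSample:
    """Bring published relative abundances onto the 0–1 range.

    ``unit`` is "fraction", "percent" or "auto" (percent assumed when the
    category sum exceeds 2 — far beyond any rounding slack of a fraction).
    """
    if sample.counts is not None:
        return sample
    values = dict(sample.original)
    if unit == "percent" or (unit == "auto"
                             and counting_sum(values, scheme) > 2.0):
        values = {c: (NA if v is NA else v / 100.0)
                  for c, v in values.items()}
    sample.relative = values
    return sample


def complete_with_zeros(sample: CensusSample, scheme: TaxonomyScheme,
                        audit=None,
                        rounding_unit: float = 0.001) -> CensusSample:
    """Fill unreported species with zeros in demonstrably complete samples.

    Applies only when the study explicitly reports 'unidentified' as zero and
    the given categories already sum to within the expected rounding error of
    one: then the assemblage is complete and every not-available species
    category can only have been absent.
    """
    unid = sample.relative.get(scheme.unidentified, NA)
    if unid is NA or unid != 0.0:
        return sample
    n = numeric_category_count(sample.relative, scheme)
    if n == 0:
        return sample
    total = counting_sum(sample.relative, scheme)
    if total <= 1.0 - rounding_error(n, rounding_unit):
        return sample
    filled = []
    for cat in scheme.categories:
        if cat.kind != "species":
            continue
        if sample.relative.get(cat.code, NA) is NA:
            sample.relative[cat.code] = 0.0
            if sample.counts is not None:
                sample.counts[cat.code] = 0.0
            filled.append(cat.code)
    if filled:
        sample.set_error(MODIFIED)
        sample.add_comment(
            f"{len(filled)} unreported categories completed with zeros")
        if audit is not None:
            audit.record(sample.sample_id, "complete_with_zeros",
                         ",".join(filled), NA, 0.0,
                         "complete sample: unidentified = 0 and sum within "
                         "rounding error of 1")
    return sample


def renormalize_or_flag(sample: CensusSample, scheme: TaxonomyScheme,
                        audit=None, sum_deviation: float = 0.05) -> int:
    """Rescale relative abundances to sum to 1, or flag the sample.

    Samples whose category sum deviates from 1 by more than 5% are flagged
    (Error bit 'sum deviates') and left untouched.  Morphotype columns do not
    enter the sum but are rescaled alongside to stay consistent with their
    parent categories.
    """
    total = counting_sum(sample.relative, scheme)
    if total == 0.0 or abs(total - 1.0) > sum_deviation:
        sample.set_error(SUM_DEVIATES)
        return SUM_DEVIATES
    if abs(total - 1.0) > 1e-12:
        factor = 1.0 / total
        sample.relative = {c: (NA if v is NA else v * factor)
                           for c, v in sample.relative.items()}
        sample.set_error(MODIFIED)
        sample.add_comment(f"relative abundances renormalized (sum {total:.6f})")
        if audit is not None:
            audit.record(sample.sample_id, "renormalize", "relative",
                         total, 1.0, "rescaled to unit sum")
    return 0


def filter_low_count(sample: CensusSample,
                     min_count: int = 150) -> int:
    """Flag samples with fewer than 150 counted individuals.

    Relative-only samples without an explicit count fall back on the study's
    minimum count; the 300-individual default never triggers the filter.
    """
    count = sample.metadata.count
    if count is None:
        count = sample.metadata.count_min
    if count is not None and count < min_count:
        sample.set_error(TOO_FEW_COUNTED)
        return TOO_FEW_COUNTED
    return 0


def filter_unidentified(sample: CensusSample, scheme: TaxonomyScheme,
                        max_unidentified: float = 0.05) -> int:
    """Flag samples with more than 5% unidentified individuals."""
    unid = sample.relative.get(scheme.unidentified, NA)
    if unid is not NA and unid > max_unidentified:
        sample.set_error(TOO_MANY_UNIDENTIFIED)
        return TOO_MANY_UNIDENTIFIED
    return 0


#: species endemic to the Atlantic/Mediterranean
ATLANTIC_ENDEMICS = ("g_ruber_pink",)
#: species endemic to the Indopacific (Pacific, Indian Ocean, Red Sea)
INDOPACIFIC_ENDEMICS = ("g_conglomerata", "g_hexagonus", "g_adamsi")


def _move_to(sample: CensusSample, source: str, target: str, scheme,
             audit=None, stage: str = "endemism") -> None:
    """Move a category's abundance onto another, in both corrected blocks."""
    for block, label in ((sample.relative, "relative"),
                         (sample.counts, "counts")):
        if block is None or block.get(source) is NA or source not in block:
            continue
        value = block[source]
        before = block.get(target, NA)
        block[target] = value if before is NA else before + value
        block[source] = NA
        if audit is not None:
            audit.record(sample.sample_id, stage,
                         f"{label}:{source}->{target}", before,
                         block[target], "")
    sample.set_error(MODIFIED)
    sample.add_comment(f"{source} resolved into {target}")


def apply_endemism_rules(sample: CensusSample, scheme: TaxonomyScheme,
                         audit=None, endemic: float = 0.01) -> int:
    """Enforce the known basin endemism of modern planktonic foraminifera.

    G. ruber pink is endemic to the Atlantic/Mediterranean; G. conglomerata,
    G. hexagonus and G. adamsi to the Indopacific.  Out-of-range abundances
    above 1% flag the sample as taxonomically incorrect; traces at or below
    1% are folded into 'unidentified'.  Lumped ruber pink+white reported in
    the Indopacific can only contain white and is resolved accordingly.
    """
    group = basin_group(sample.metadata.ocean_flag)
    if group is None:
        return 0
    bits = 0
    if group == "indopacific":
        wrong = ATLANTIC_ENDEMICS
        pw = sample.relative.get("ruber_pink_white", NA)
        if pw is not NA:
            _move_to(sample, "ruber_pink_white", "g_ruber_white", scheme,
                     audit)
    else:
        wrong = INDOPACIFIC_ENDEMICS
    for code in wrong:
        value = sample.relative.get(code, NA)
        if value is NA:
            continue
        if value > endemic:
            sample.set_error(TAXONOMICALLY_INCORRECT)
            sample.add_comment(f"{code} out of known range ({value:.4f})")
            bits |= TAXONOMICALLY_INCORRECT
        elif value > 0.0:
            _move_to(sample, code, scheme.unidentified, scheme, audit)
    return bits


def filter_other(sample: CensusSample) -> int:
    """Flag records without coordinates or with a non-standard device."""
    bits = 0
    if sample.metadata.latitude is None or sample.metadata.longitude is None:
        sample.set_error(NO_COORDINATES)
        bits |= NO_COORDINATES
    if sample.metadata.device not in STANDARD_DEVICES:
        sample.set_error(NONSTANDARD_DEVICE)
        bits |= NONSTANDARD_DEVICE
    return bits
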