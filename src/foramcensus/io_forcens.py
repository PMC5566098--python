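"""Reading heterogeneous source tables and writing the synthesis layout.

The output is a UTF-8 tab-delimited file with two header rows (variable
names, variable units), 21 metadata columns, and three blocks of abundance
columns in fixed master-taxonomy order: the original values (taxonomically
reformatted only), the corrected absolute counts where available, and the
corrected relative proportions.  Each block ends with the six morphotype
columns.  A not-available entry is an empty cell; zero is written as "0" —
the distinction is load-bearing and preserved round-trip.
"""

from __future__ import annotations

import yaml

from .flags import assign_ocean_flag, database_scheme
from .metadata import _to_float, parse_coordinate, standardize_metadata
from .samples import NA, PASSING_MAX_ERROR, CensusSample, SourceDataset
from .taxonomy import RAW_PREFIX, UNKNOWN, TaxonomyScheme, resolve_label

#: (variable name, unit) of the 21 metadata columns, in file order.
METADATA_COLUMNS = (
    ("Sample_name", "NA"),
    ("Sample_ID", "NA"),
    ("Error_flag", "NA"),
    ("Device", "NA"),
    ("Latitude", "decimal degrees"),
    ("Longitude", "decimal degrees"),
    ("Water_depth", "meter"),
    ("Ocean_flag", "NA"),
    ("Sample_depth_upper", "meters"),
    ("Sample_depth_lower", "meters"),
    ("Sample_depth_average", "meters"),
    ("Author", "NA"),
    ("Journal", "NA"),
    ("Year", "date"),
    ("Publication_doi", "doi"),
    ("Resource_doi", "doi"),
    ("Comment", "NA"),
    ("Database_flag", "NA"),
    ("Type", "NA"),
    ("Count_min", "individuals"),
    ("Count", "individuals"),
)

_FIELD_OF_COLUMN = {
    "Sample_name": "sample_name", "Sample_ID": "sample_id",
    "Error_flag": "error_flag", "Device": "device", "Latitude": "latitude",
    "Longitude": "longitude", "Water_depth": "water_depth",
    "Ocean_flag": "ocean_flag", "Sample_depth_upper": "sample_depth_upper",
    "Sample_depth_lower": "sample_depth_lower",
    "Sample_depth_average": "sample_depth_average", "Author": "author",
    "Journal": "journal", "Year": "year",
    "Publication_doi": "publication_doi", "Resource_doi": "resource_doi",
    "Comment": "comment", "Database_flag": "database_flag", "Type": "type",
    "Count_min": "count_min", "Count": "count",
}

_INT_FIELDS = {"error_flag", "ocean_flag", "database_flag", "type", "year",
               "count_min"}
_STR_FIELDS = {"sample_name", "sample_id", "device", "author", "journal",
               "publication_doi", "resource_doi", "comment"}


def _fmt_number(value) -> str:
    if value is NA:
        return ""
    f = float(value)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _fmt_text(value) -> str:
    if value is None:
        return ""
    return str(value).replace("\t", " ").replace("\n", " ")


def _metadata_cells(sample: CensusSample) -> list:
    m = sample.metadata
    cells = []
    for name, _unit in METADATA_COLUMNS:
        field = _FIELD_OF_COLUMN[name]
        value = getattr(m, field)
        if field == "latitude" and value is not None:
            cells.append(f"{value:.{sample.lat_precision}f}")
        elif field == "longitude" and value is not None:
            cells.append(f"{value:.{sample.lon_precision}f}")
        elif field in _STR_FIELDS:
            cells.append(_fmt_text(value))
        elif value is None:
            cells.append("")
        elif field in _INT_FIELDS:
            cells.append(str(int(value)))
        else:
            cells.append(_fmt_number(value))
    return cells


def write_forcens(records, path, scheme: TaxonomyScheme,
                  variant: str = "full") -> None:
    """Write a corpus in the synthesis layout.

    ``variant="full"`` keeps every record (including flagged and merged-away
    ones) with all three abundance blocks; ``variant="passing_only"`` keeps
    records passing all selection criteria (Error flag <= 1) and only their
    relative abundances.
    """
    if variant not in ("full", "passing_only"):
        raise ValueError(f"unknown variant {variant!r}")
    categories = scheme.output_categories()
    display = {c.code: c.name or c.code for c in scheme.categories}
    display[scheme.unidentified] = "unidentified"

    if variant == "passing_only":
        records = [r for r in records
                   if r.metadata.error_flag <= PASSING_MAX_ERROR]
        blocks = [("relative proportion", "relative")]
    else:
        blocks = [("original", "original"), ("individuals", "counts"),
                  ("relative proportion", "relative")]

    names = [n for n, _ in METADATA_COLUMNS]
    units = [u for _, u in METADATA_COLUMNS]
    for unit, _attr in blocks:
        names.extend(display.get(c, c) for c in categories)
        units.extend(unit for _ in categories)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(names) + "\n")
        fh.write("\t".join(units) + "\n")
        for sample in sorted(records, key=lambda s: s.sample_id):
            cells = _metadata_cells(sample)
            for _unit, attr in blocks:
                block = getattr(sample, attr)
                if block is None:
                    cells.extend("" for _ in categories)
                else:
                    cells.extend(_fmt_number(block.get(c, NA))
                                 for c in categories)
            fh.write("\t".join(cells) + "\n")


def read_forcens(path, scheme: TaxonomyScheme) -> list:
    """Read a full-variant synthesis file back into samples."""
    categories = scheme.output_categories()
    ncat = len(categories)
    nmeta = len(METADATA_COLUMNS)
    samples = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # names
        fh.readline()  # units
        for line in fh:
            if not line.strip("\n"):
                continue
            cells = line.rstrip("\n").split("\t")
            record = {}
            for (name, _unit), cell in zip(METADATA_COLUMNS, cells):
                field = _FIELD_OF_COLUMN[name]
                if field == "device":
                    record[field] = cell or None  # device is nullable
                elif field in _STR_FIELDS:
                    record[field] = cell
                elif cell == "":
                    record[field] = None
                elif field in _INT_FIELDS:
                    record[field] = int(cell)
                else:
                    record[field] = float(cell)
            meta_kwargs = dict(record)
            for key in ("count_min", "error_flag", "ocean_flag",
                        "database_flag", "type"):
                if meta_kwargs.get(key) is None:
                    meta_kwargs[key] = 0 if key != "count_min" else None
            from .samples import SampleMetadata
            meta = SampleMetadata(**meta_kwargs)
            _, latp = parse_coordinate(cells[4])
            _, lonp = parse_coordinate(cells[5])

            def _block(offset):
                vals = cells[nmeta + offset * ncat:
                             nmeta + (offset + 1) * ncat]
                return {c: (NA if v == "" else float(v))
                        for c, v in zip(categories, vals)}

            original = _block(0)
            counts = _block(1)
            relative = _block(2)
            if meta.type != 1 and all(v is NA for v in counts.values()):
                counts = None
            samples.append(CensusSample(
                metadata=meta, original=original, counts=counts,
                relative=relative, lat_precision=latp, lon_precision=lonp))
    return samples


# -- source ingestion -----------------------------------------------------------


def load_schema(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def read_source(path, schema: dict, scheme: TaxonomyScheme) -> SourceDataset:
    """Read one source table under a per-dataset schema config.

    The schema declares the dataset id, its data type (raw counts versus
    relative abundances), the metadata column mapping and, optionally, an
    explicit taxon-column list; all unmapped columns default to taxon columns
    keyed by their header label.  Labels are resolved through the
    dataset-aware synonym machinery; unresolvable labels are preserved under
    a raw key and reported in ``unmapped_columns``.  Non-numeric abundance
    cells become not-available.
    """
    import pandas as pd

    dataset_id = schema.get("dataset_id") or "dataset"
    columns = schema.get("columns") or {}
    if "sample_name" not in columns and ("latitude" not in columns
                                         or "longitude" not in columns):
        raise ValueError(
            "schema must map 'sample_name' or both coordinate columns")
    data_type = schema.get("type", "relative")
    if data_type not in ("raw", "relative"):
        raise ValueError(f"unknown data type {data_type!r}")
    delimiter = schema.get("delimiter", "\t")
    frame = pd.read_csv(path, sep=delimiter, dtype=str,
                        keep_default_na=False)

    meta_columns = set(columns.values())
    taxa = schema.get("taxa")
    if taxa is None:
        taxa = {col: col for col in frame.columns if col not in meta_columns}
    resolution = {}
    unmapped = []
    for col, label in taxa.items():
        code = resolve_label(label, scheme, dataset_id)
        if code == UNKNOWN:
            code = RAW_PREFIX + label.strip().lower()
            unmapped.append(col)
        resolution[col] = code

    database_label = schema.get("database")
    db_flag = (database_scheme().encode([database_label])
               if database_label else 0)

    samples = []
    seen_ids = set()
    for idx, row in frame.iterrows():
        record = {field: row[col] for field, col in columns.items()
                  if col in frame.columns}
        record.setdefault("database_flag", db_flag)
        meta = standardize_metadata(
            record, depth_unit=schema.get("depth_unit", "m"),
            default_type=1 if data_type == "raw" else 0)
        meta.database_flag = db_flag
        # sample ids must be unique across datasets: a name is not an id
        explicit = columns.get("sample_id") in frame.columns
        if (not explicit or not str(row[columns["sample_id"]]).strip()
                or meta.sample_id in seen_ids):
            meta.sample_id = f"{dataset_id}:{idx:05d}"
        seen_ids.add(meta.sample_id)
        _, latp = parse_coordinate(record.get("latitude"))
        _, lonp = parse_coordinate(record.get("longitude"))

        original = {}
        for col, code in resolution.items():
            value = _to_float(row[col]) if col in frame.columns else None
            if code in original and original[code] is not NA:
                if value is not None:
                    original[code] += value
            else:
                original[code] = NA if value is None else value
        sample = CensusSample(
            metadata=meta, original=original,
            counts=dict(original) if data_type == "raw" else None,
            relative={}, dataset_id=dataset_id,
            lat_precision=latp, lon_precision=lonp)
        samples.append(sample)

    reported = schema.get("reported_categories")
    if reported is None:
        reported = {code for code in resolution.values()
                    if not code.startswith(RAW_PREFIX)}
    return SourceDataset(
        dataset_id=dataset_id, samples=samples,
        database_label=database_label, data_type=data_type,
        relative_unit=schema.get("relative_unit", "auto"),
        reported_categories=set(reported), unmapped_columns=unmapped)


def write_step_ledger(rows, path) -> None:
    """Write the sequential-merging bookkeeping table."""
    cols = ("step", "total", "included", "excluded", "duplicates", "plain",
            "position", "name")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_dataset_ledger(rows, path) -> None:
    """Write the per-dataset individual-processing bookkeeping table."""
    cols = ("dataset", "total", "included", "excluded", "numerical",
            "taxonomic", "other", "duplicates")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
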