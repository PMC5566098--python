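"""Master taxonomy, synonym resolution and dataset-specific category merges.

The master scheme comprises 47 species categories, three multi-species
(lumped) categories and six morphotype categories whose abundances are
already contained in their parent species.  Historical category names are
resolved against a manually curated synonym table; categories that a given
compilation used but that have no place in the harmonised scheme (e.g.
"P/D intergrades") are carried as *legacy* categories and folded into master
categories by dataset-specific merge rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .samples import MODIFIED, NA, CensusSample

#: sentinel returned when a label cannot be resolved
UNKNOWN = "unknown"

#: prefix used to key unresolved raw labels inside abundance dicts
RAW_PREFIX = "raw:"


def normalize_name(text: str) -> str:
    """Case-fold, drop decoration characters and collapse whitespace."""
    text = text.strip().lower()
    for ch in "()*'\"":
        text = text.replace(ch, "")
    text = text.replace("_", " ")
    return " ".join(text.split())


@dataclass(frozen=True)
class TaxonCategory:
    code: str
    kind: str  # species | multi_species | morphotype | special | legacy
    genus: str = ""
    species: str = ""
    parent: str | None = None
    recorded_anywhere: bool = True

    @property
    def name(self) -> str:
        return f"{self.genus} {self.species}".strip()


@dataclass(frozen=True)
class MergeRule:
    source: str  # taxon code, or a raw label for interpretation rules
    target: str
    datasets: frozenset  # dataset ids, or frozenset({"ALL"})
    source_kind: str = "code"  # "code" | "label"
    rationale: str = ""

    def applies_to(self, dataset_id: str) -> bool:
        if "ALL" in self.datasets:
            return True
        return any(dataset_id == d or dataset_id.startswith(d + " ")
                   for d in self.datasets)


class TaxonomyScheme:
    """Ordered master category list plus synonym map and merge rules."""

    def __init__(self, categories, synonyms, merge_rules,
                 unidentified: str = "unidentified"):
        self.categories: list[TaxonCategory] = list(categories)
        self.by_code = {c.code: c for c in self.categories}
        self.synonyms: dict[str, str] = dict(synonyms)
        self.merge_rules: list[MergeRule] = list(merge_rules)
        self.unidentified = unidentified
        self._name_index = {normalize_name(c.name): c.code
                            for c in self.categories if c.name}
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        codes = [c.code for c in self.categories]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate taxon codes in scheme")
        for c in self.categories:
            if c.kind == "morphotype":
                parent = self.by_code.get(c.parent or "")
                if parent is None or parent.kind != "species":
                    raise ValueError(
                        f"morphotype {c.code} lacks a species parent")
        for syn, code in self.synonyms.items():
            if code not in self.by_code:
                raise ValueError(f"synonym {syn!r} maps to unknown {code!r}")
        for rule in self.merge_rules:
            if rule.target not in self.by_code:
                raise ValueError(f"merge rule target {rule.target!r} unknown")
            if rule.source == rule.target:
                raise ValueError("merge rule source equals target")
        if self.unidentified not in self.by_code:
            raise ValueError("scheme lacks an 'unidentified' sink category")

    def kind_counts(self) -> dict:
        counts: dict[str, int] = {}
        for c in self.categories:
            counts[c.kind] = counts.get(c.kind, 0) + 1
        return counts

    def is_morphotype(self, code: str) -> bool:
        cat = self.by_code.get(code)
        return cat is not None and cat.kind == "morphotype"

    def output_categories(self) -> list[str]:
        """Column order of the data blocks: species, multi-species and the
        unidentified sink, with the six morphotype columns at the end."""
        species = [c.code for c in self.categories if c.kind == "species"]
        multi = [c.code for c in self.categories if c.kind == "multi_species"]
        morpho = [c.code for c in self.categories if c.kind == "morphotype"]
        return species + multi + [self.unidentified] + morpho

    def counting_categories(self) -> list[str]:
        """Categories that enter sums and totals (morphotypes excluded:
        their individuals are already contained in the parent species)."""
        return [c for c in self.output_categories()
                if not self.is_morphotype(c)]

    def multi_species_constituents(self) -> dict:
        return {
            "menardii_tumida": ("g_menardii", "g_tumida"),
            "ruber_pink_white": ("g_ruber_pink", "g_ruber_white"),
            "humilis_pumilio": ("t_humilis", "b_pumilio"),
        }

    # -- loading -----------------------------------------------------------

    @classmethod
    def load(cls, taxonomy_path=None, synonyms_path=None,
             merge_rules_path=None) -> "TaxonomyScheme":
        """Load the shipped master scheme, optionally overriding any table."""
        data = resources.files("foramcensus") / "data"
        categories = []
        with open(taxonomy_path or data / "taxonomy.tsv",
                  encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                categories.append(TaxonCategory(
                    code=row["code"], kind=row["kind"],
                    genus=row.get("genus", ""), species=row.get("species", ""),
                    parent=row.get("parent") or None,
                    recorded_anywhere=row.get("recorded", "1") == "1"))
        synonyms = {}
        with open(synonyms_path or data / "synonyms.tsv",
                  encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                key = normalize_name(row["synonym"])
                if key in synonyms and synonyms[key] != row["code"]:
                    raise ValueError(f"synonym {key!r} maps to two codes")
                synonyms[key] = row["code"]
        rules = []
        with open(merge_rules_path or data / "merge_rules.tsv",
                  encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                rules.append(MergeRule(
                    source=row["source"], target=row["target"],
                    datasets=frozenset(
                        d.strip() for d in row["datasets"].split(",")),
                    source_kind=row.get("source_kind", "code"),
                    rationale=row.get("rationale", "")))
        return cls(categories, synonyms, rules)


# -- operations -------------------------------------------------------------


def resolve_synonym(raw_label: str, scheme: TaxonomyScheme) -> str:
    """Resolve a raw category label to a master taxon code.

    Returns the code when the normalised label matches a category name or a
    curated synonym, the code itself, or the sentinel ``"unknown"``.  Never
    guesses: an unknown label signals that the synonym table must be extended
    by the curator.
    """
    if not raw_label:
        raise ValueError("empty taxon label")
    if raw_label in scheme.by_code:
        return raw_label
    key = normalize_name(raw_label)
    if key in scheme.synonyms:
        return scheme.synonyms[key]
    if key in scheme._name_index:
        return scheme._name_index[key]
    return UNKNOWN


def resolve_label(raw_label: str, scheme: TaxonomyScheme,
                  dataset_id: str) -> str:
    """Dataset-aware label resolution.

    Interpretation rules (merge rules whose source is a raw label) take
    precedence over the global synonym table: e.g. an undifferentiated
    "Globigerina pachyderma" column in a compilation known to have used it
    for pachyderma/dutertrei intergrades is read as the intergrade category,
    not as N. pachyderma.
    """
    key = normalize_name(raw_label)
    for rule in scheme.merge_rules:
        if (rule.source_kind == "label" and rule.applies_to(dataset_id)
                and normalize_name(rule.source) == key):
            return rule.target
    return resolve_synonym(raw_label, scheme)


def _merge_value(sample: CensusSample, block: dict, source: str, target: str,
                 stage: str, rule: str, audit=None) -> bool:
    """Move ``source``'s abundance onto ``target`` inside one block.

    Numeric + not-available = numeric: NA carries no information and never
    acts as zero.  Returns True when a numeric value actually moved.
    """
    if source not in block:
        return False
    value = block.pop(source)
    if value is NA:
        return False
    before = block.get(target, NA)
    block[target] = value if before is NA else before + value
    if audit is not None:
        audit.record(sample.sample_id, stage, f"{source}->{target}",
                     before, block[target], rule)
    return True


def apply_merge_rules(sample: CensusSample, dataset_id: str,
                      scheme: TaxonomyScheme, audit=None) -> CensusSample:
    """Apply the dataset-specific merge rules to all abundance blocks.

    Rules are applied in their shipped order so that two-step chains (label
    interpretation followed by a category merge) compose.  The sum of numeric
    abundances is conserved; any actual move sets the 'modified' bit and is
    appended to the sample comment.
    """
    blocks = [b for b in (sample.original, sample.counts, sample.relative)
              if b is not None]
    moved_rules = []
    for rule in scheme.merge_rules:
        if not rule.applies_to(dataset_id):
            continue
        if rule.source_kind == "label":
            source_key = RAW_PREFIX + normalize_name(rule.source)
        else:
            source_key = rule.source
        moved = False
        for block in blocks:
            moved |= _merge_value(sample, block, source_key, rule.target,
                                  "merge_rules", rule.rationale, audit)
        if moved:
            moved_rules.append((source_key, rule.target))
    if moved_rules:
        sample.set_error(MODIFIED)
        detail = ", ".join(f"{s}->{t}" for s, t in moved_rules)
        sample.add_comment(f"category merge: {detail}")
    return sample


def mark_unrecorded(sample: CensusSample, reported_categories: set,
                    scheme: TaxonomyScheme) -> CensusSample:
    """Mark master categories a study did not report as not-available.

    Categories absent from the study's reported list get the NA sentinel —
    explicitly distinct from zero, since the study may simply not have
    counted them.  Reported numeric values are never converted to NA.
    """
    for code in scheme.output_categories():
        if code in reported_categories:
            continue
        for block in (sample.original, sample.counts, sample.relative):
            if block is None:
                continue
            if block.get(code) is NA:
                block[code] = NA  # explicit sentinel, keyed
    return sample


def counting_sum(values: dict, scheme: TaxonomyScheme) -> float:
    """Sum of numeric abundances over non-morphotype categories."""
    total = 0.0
    for code, v in values.items():
        if v is NA or scheme.is_morphotype(code):
            continue
        total += v
    return total


def numeric_category_count(values: dict, scheme: TaxonomyScheme) -> int:
    """Number of non-morphotype categories carrying a numeric value."""
    return sum(1 for code, v in values.items()
               if v is not NA and not scheme.is_morphotype(code))
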