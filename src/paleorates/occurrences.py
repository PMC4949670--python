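"""Read, filter, group and age-randomize fossil occurrence tables.

The input is a genus-level occurrence download (one row per fossil find,
with a taxon name, a min-max age interval in Ma and a preservation /
plant-organ column).  The output of the pipeline is a set of replicate
"resolved" datasets in which every occurrence age has been drawn uniformly
from its dating interval, grouped per genus and ready for inference.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GROUPS = ("spore_bearing", "nonflowering_seed", "angiosperm", "other")
ORGAN_CLASSES = ("macrofossil", "microfossil", "unknown")

# canonical single-table output column order
CANONICAL_COLUMNS = ("genus", "group", "extant", "min_age", "max_age", "organ_class")
REPLICATE_COLUMNS = ("genus", "group", "extant", "age")

_GENUS_RE = re.compile(r"^[A-Z][a-zA-Z]+$")
_OPEN_NOMENCLATURE = {"sp", "sp.", "spp", "spp.", "indet", "indet.", "aff.",
                      "aff", "cf", "cf.", "?"}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence: a taxon observed in a min-max age interval."""

    occurrence_id: str
    taxon_name: str
    genus: str
    min_age: float
    max_age: float
    rank: str = "genus_sp"          # "species" | "genus_sp"
    group: str = "other"
    organ_class: str = "unknown"
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.genus:
            raise ValueError("genus must be non-empty")
        if not (self.max_age >= self.min_age >= 0):
            raise ValueError(
                f"invalid age interval for {self.taxon_name!r}: "
                f"[{self.min_age}, {self.max_age}]")


@dataclass(frozen=True)
class TaxonSeries:
    """One genus with a vector of resolved occurrence ages (one replicate)."""

    genus: str
    group: str
    ages: np.ndarray
    extant: bool

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        if ages.size == 0:
            raise ValueError(f"{self.genus}: ages must be non-empty")
        if np.any(ages < 0):
            raise ValueError(f"{self.genus}: negative occurrence age")
        object.__setattr__(self, "ages", ages)


def default_dialect() -> dict:
    """The packaged column map for PBDB-style downloads."""
    ref = resources.files("paleorates.data") / "pbdb_columns.yaml"
    return yaml.safe_load(ref.read_text())


def packaged_group_map() -> dict:
    """The packaged supra-generic taxon -> group table."""
    ref = resources.files("paleorates.data") / "group_map.yaml"
    return yaml.safe_load(ref.read_text())


def packaged_extant_genera() -> frozenset[str]:
    """The packaged (user-editable) list of extant genera."""
    ref = resources.files("paleorates.data") / "extant_genera.txt"
    lines = ref.read_text().splitlines()
    return frozenset(x.strip() for x in lines
                     if x.strip() and not x.startswith("#"))


def parse_genus(taxon_name: str) -> tuple[str | None, str]:
    """Extract (genus, rank) from a reported taxon name.

    "Psilophyton sp." -> ("Psilophyton", "genus_sp"); "Quercus alba" ->
    ("Quercus", "species"); a bare genus name counts as genus-level.
    Returns (None, "") when no genus can be parsed.
    """
    tokens = taxon_name.replace('"', " ").split()
    tokens = [t for t in tokens if t.lower() not in _OPEN_NOMENCLATURE or t[0].isupper()]
    if not tokens:
        return None, ""
    genus = tokens[0].strip("?")
    if not _GENUS_RE.match(genus):
        return None, ""
    rest = [t for t in taxon_name.split()[1:] if t.lower() not in _OPEN_NOMENCLATURE]
    rank = "species" if rest else "genus_sp"
    return genus, rank


def _pick_column(df: pd.DataFrame, candidates) -> str | None:
    if isinstance(candidates, str):
        candidates = [candidates]
    for c in candidates:
        if c in df.columns:
            return c
    return None


def classify_organ(value, keyword_table: dict) -> str:
    """Map a preservation / plant-organ field to macro/microfossil/unknown."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    text = str(value).strip().lower()
    if not text:
        return "unknown"
    for kw in keyword_table.get("microfossil", ()):
        if kw in text:
            return "microfossil"
    for kw in keyword_table.get("macrofossil", ()):
        if kw in text:
            return "macrofossil"
    return "unknown"


def read_occurrence_table(path, dialect: dict | None = None) -> list[OccurrenceRecord]:
    """Read an occurrence CSV/TSV into validated records.

    ``dialect`` maps logical fields to column-name candidates (see the
    packaged ``pbdb_columns.yaml``).  Rows without a parsable genus or ages,
    or with ``min_age > max_age``, are reported and dropped; a missing
    mandatory column raises ``KeyError``.
    """
    dialect = dialect or default_dialect()
    sep = dialect.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, comment=None, skip_blank_lines=True)
    name_col = _pick_column(df, dialect["taxon_name"])
    min_col = _pick_column(df, dialect["min_age"])
    max_col = _pick_column(df, dialect["max_age"])
    missing = [k for k, c in
               (("taxon_name", name_col), ("min_age", min_col), ("max_age", max_col))
               if c is None]
    if missing:
        raise KeyError(f"mandatory column(s) not found in {path}: {missing}")
    id_col = _pick_column(df, dialect.get("occurrence_id", []))
    rank_col = _pick_column(df, dialect.get("rank", []))
    organ_col = _pick_column(df, dialect.get("organ", []))
    tax_cols = [c for c in dialect.get("taxonomy", []) if c in df.columns]
    keyword_table = dialect.get("organ_keywords", {})

    records: list[OccurrenceRecord] = []
    n_dropped = 0
    for i, row in df.iterrows():
        name = (row[name_col] or "").strip() if isinstance(row[name_col], str) else ""
        genus, parsed_rank = parse_genus(name) if name else (None, "")
        try:
            min_age = float(row[min_col])
            max_age = float(row[max_col])
        except (TypeError, ValueError):
            min_age = max_age = float("nan")
        if genus is None or not np.isfinite(min_age) or not np.isfinite(max_age):
            logger.debug("dropping row %s: unparsable genus or ages (%r)", i, name)
            n_dropped += 1
            continue
        if min_age > max_age or min_age < 0:
            logger.warning("dropping row %s (%s): invalid interval [%s, %s]",
                           i, name, min_age, max_age)
            n_dropped += 1
            continue
        rank = parsed_rank
        if rank_col is not None and isinstance(row[rank_col], str):
            declared = row[rank_col].strip().lower()
            if declared == "genus":
                rank = "genus_sp"
            elif declared == "species":
                rank = "species"
        records.append(OccurrenceRecord(
            occurrence_id=str(row[id_col]) if id_col else str(i),
            taxon_name=name,
            genus=genus,
            rank=rank,
            min_age=min_age,
            max_age=max_age,
            organ_class=classify_organ(row[organ_col] if organ_col else None,
                                       keyword_table),
            taxonomy=tuple(str(row[c]).strip() for c in tax_cols
                           if isinstance(row[c], str) and row[c].strip()),
        ))
    logger.info("read %d records from %s (%d rows dropped)",
                len(records), path, n_dropped)
    return records


def filter_macrofossil_genus(records: list[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Keep only macrofossil records; genus-level ("sp.") records are retained.

    Microfossils (pollen and spores) and records of unknown organ class are
    removed; counts are reported through the module logger.  The operation
    is idempotent.
    """
    kept = [r for r in records if r.organ_class == "macrofossil"]
    n_micro = sum(r.organ_class == "microfossil" for r in records)
    n_unknown = sum(r.organ_class == "unknown" for r in records)
    logger.info("macrofossil filter: %d in, %d kept, %d microfossil removed, "
                "%d unknown removed", len(records), len(kept), n_micro, n_unknown)
    return kept


def assign_groups(records: list[OccurrenceRecord], group_map: dict,
                  default: str | None = None) -> list[OccurrenceRecord]:
    """Label each record with its vegetation group from its supra-generic taxonomy.

    The first taxonomy field (most to least inclusive) with an entry in
    ``group_map`` wins; unmatched records get ``default`` or "other" and are
    reported.  Pure function of the taxonomy fields and the map.
    """
    lower_map = {str(k).lower(): v for k, v in group_map.items()}
    for v in lower_map.values():
        if v not in GROUPS:
            raise ValueError(f"group_map value {v!r} not one of {GROUPS}")
    out = []
    unmatched: set[str] = set()
    for r in records:
        group = None
        for t in r.taxonomy:
            hit = lower_map.get(t.lower())
            if hit is not None:
                group = hit
                break
        if group is None:
            group = default or "other"
            unmatched.add(" / ".join(r.taxonomy) if r.taxonomy else "<no taxonomy>")
        out.append(replace(r, group=group))
    if unmatched:
        logger.info("assign_groups: %d unmatched taxonomy label sets -> %r",
                    len(unmatched), sorted(unmatched)[:20])
    return out


def resample_replicates(records: list[OccurrenceRecord], n_reps: int, seed: int,
                        extant_genera: frozenset[str] | set[str] = frozenset(),
                        ) -> list[list[TaxonSeries]]:
    """Draw ``n_reps`` datasets with occurrence ages resolved uniformly.

    Each occurrence age is drawn independently and uniformly from its
    ``[min_age, max_age]`` interval; occurrences are then grouped by genus.
    Replicates differ only in the resolved ages and are deterministic for a
    given seed.  A genus carrying conflicting group labels is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    by_genus: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        by_genus.setdefault(r.genus, []).append(r)
    conflicts = [g for g, rs in by_genus.items()
                 if len({r.group for r in rs}) > 1]
    if conflicts:
        raise ValueError(f"genera with conflicting group labels: {sorted(conflicts)}")
    rng = np.random.default_rng(seed)
    lo = np.array([r.min_age for r in records])
    hi = np.array([r.max_age for r in records])
    idx_by_genus: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        idx_by_genus.setdefault(r.genus, []).append(i)
    idx_by_genus = {g: np.array(v) for g, v in idx_by_genus.items()}
    datasets = []
    for _ in range(n_reps):
        ages = rng.uniform(lo, hi)
        dataset = [
            TaxonSeries(genus=g,
                        group=by_genus[g][0].group,
                        ages=ages[idx_by_genus[g]],
                        extant=g in extant_genera)
            for g in by_genus
        ]
        datasets.append(dataset)
    return datasets


def dataset_summary(records: list[OccurrenceRecord],
                    extant_genera: frozenset[str] | set[str] = frozenset(),
                    ) -> pd.Series:
    """Headline statistics of an occurrence dataset.

    Reports occurrence and genus counts, extinct/extant genus counts,
    per-group occurrence shares and the mean and SD of the dating-interval
    widths ``max_age - min_age`` (population SD).
    """
    n = len(records)
    genera = sorted({r.genus for r in records})
    widths = np.array([r.max_age - r.min_age for r in records])
    n_extant = sum(g in extant_genera for g in genera)
    out = {
        "n_occurrences": n,
        "n_genera": len(genera),
        "n_extant_genera": n_extant,
        "n_extinct_genera": len(genera) - n_extant,
        "mean_interval_width": float(widths.mean()) if n else float("nan"),
        "sd_interval_width": float(widths.std()) if n else float("nan"),
    }
    for grp in GROUPS:
        out[f"share_{grp}"] = (sum(r.group == grp for r in records) / n) if n else 0.0
        out[f"genera_{grp}"] = len({r.genus for r in records if r.group == grp})
    return pd.Series(out)


# ---------------------------------------------------------------------------
# canonical table I/O

def records_to_frame(records: list[OccurrenceRecord],
                     extant_genera: frozenset[str] | set[str] = frozenset(),
                     ) -> pd.DataFrame:
    """Canonical occurrence table (fixed column order)."""
    return pd.DataFrame({
        "genus": [r.genus for r in records],
        "group": [r.group for r in records],
        "extant": [r.genus in extant_genera for r in records],
        "min_age": [r.min_age for r in records],
        "max_age": [r.max_age for r in records],
        "organ_class": [r.organ_class for r in records],
    }, columns=list(CANONICAL_COLUMNS))


def write_canonical(records, path, extant_genera=frozenset()) -> None:
    records_to_frame(records, extant_genera).to_csv(path, index=False)


def read_canonical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CANONICAL_COLUMNS) - set(df.columns)
    if missing:
        raise KeyError(f"canonical table missing columns: {sorted(missing)}")
    return df


def frame_to_records(df: pd.DataFrame) -> list[OccurrenceRecord]:
    """Records from a canonical table (inverse of ``records_to_frame``)."""
    return [OccurrenceRecord(occurrence_id=str(i), taxon_name=row.genus,
                             genus=row.genus, rank="genus_sp", group=row.group,
                             organ_class=row.organ_class,
                             min_age=float(row.min_age), max_age=float(row.max_age))
            for i, row in enumerate(df.itertuples(index=False))]


def dataset_to_frame(dataset: list[TaxonSeries]) -> pd.DataFrame:
    """Per-replicate resolved-age table (genus, group, extant, age)."""
    rows = [(t.genus, t.group, t.extant, a) for t in dataset for a in t.ages]
    return pd.DataFrame(rows, columns=list(REPLICATE_COLUMNS))


def write_replicate(dataset: list[TaxonSeries], path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def frame_to_dataset(df: pd.DataFrame) -> list[TaxonSeries]:
    out = []
    for (genus, group, extant), sub in df.groupby(["genus", "group", "extant"],
                                                  sort=True):
        out.append(TaxonSeries(genus=genus, group=group,
                               ages=sub["age"].to_numpy(dtype=float),
                               extant=bool(extant)))
    return out


def read_replicate(path) -> list[TaxonSeries]:
    df = pd.read_csv(path)
    missing = set(REPLICATE_COLUMNS) - set(df.columns)
    if missing:
        raise KeyError(f"replicate table missing columns: {sorted(missing)}")
    return frame_to_dataset(df)
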