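"""Reading and normalizing occurrence exports and species trait tables.

Occurrence data arrive as Darwin-Core-style delimited text (one row per
observation event, with a scientific name, taxon rank, order, event
timestamp and optionally a biogeographic realm). The steps applied here
mirror standard cleaning for community-science mammal data: subspecies are
recoded to their parent species (first two name tokens), hybrid and
unparseable names are dropped with a count, observations of domestic
species are excluded against a configurable list, and the retained records
are aggregated into one profile per species joined to an EltonTraits-like
trait table. Every record is accounted for: raw = domestic-excluded +
invalid-dropped + retained.
"""

from __future__ import annotations

import importlib.resources
import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "SpeciesProfile",
    "IngestReport",
    "DEFAULT_DIALECT",
    "default_domestic_list",
    "read_occurrences",
    "normalize_binomial",
    "rollup_subspecies",
    "filter_domestic",
    "read_trait_table",
    "build_species_profiles",
    "count_by_realm",
    "profiles_to_frame",
    "ingest",
]

REALMS = ("Australian", "Ethiopic", "Nearctic", "Neotropical", "Oriental", "Palearctic", "Marine")
IUCN_LEVELS = ("DD", "LC", "NT", "VU", "EN", "CR", "NE")
TROPHIC_LEVELS = ("herbivore", "insectivore", "carnivore", "omnivore")
STRATA_LEVELS = ("ground", "aerial", "arboreal", "scansorial", "marine")

# column-name mapping for a GBIF/iNaturalist Darwin Core export
DEFAULT_DIALECT = {
    "sep": ",",
    "scientific_name": "species",
    "taxon_rank": "taxonRank",
    "order": "order",
    "timestamp": "eventDate",
    "realm": "realm",
    "quality_grade": "qualityGrade",
}

_TIME_RE = re.compile(r"[T ](\d{1,2}):(\d{2})(?::(\d{2}(?:\.\d+)?))?")


@dataclass
class OccurrenceRecord:
    scientific_name: str
    taxon_rank: str  # species | subspecies | other
    order_name: str
    event_date: str  # calendar date as recorded (date part only)
    hour: float | None  # local clock hour fraction in [0, 24), None if absent
    realm: str | None = None
    quality_grade: str = ""


@dataclass
class SpeciesProfile:
    species: str
    order_name: str = ""
    n_obs: int = 0
    diurnal: int | None = None
    nocturnal: int | None = None
    crepuscular: int | None = None
    trophic: frozenset = frozenset()
    strata: frozenset = frozenset()
    body_mass: float | None = None  # grams
    biomass: float | None = None  # grams, species total
    population: float | None = None  # individuals
    range_area: float | None = None
    realms: frozenset = frozenset()
    iucn: str = "NE"
    in_nearctic: int = 0
    has_traits: bool = True


@dataclass
class IngestReport:
    n_raw: int = 0
    n_domestic_excluded: int = 0
    n_invalid_name: int = 0
    n_no_time: int = 0
    n_retained: int = 0
    n_species: int = 0
    n_species_no_traits: int = 0
    domestic_species_used: list[str] = field(default_factory=list)

    def check(self) -> None:
        if self.n_raw != self.n_domestic_excluded + self.n_invalid_name + self.n_retained:
            raise AssertionError(
                "record accounting violated: "
                f"{self.n_raw} != {self.n_domestic_excluded} + {self.n_invalid_name} + {self.n_retained}"
            )

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def default_domestic_list() -> frozenset[str]:
    """The shipped stand-in list of 13 domestic mammal binomials."""
    text = importlib.resources.files("obsbias.data").joinpath("domestic_mammals.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def _parse_timestamp(value) -> tuple[str, float | None]:
    """Split an event timestamp into (date string, clock-hour fraction).

    The hour is read verbatim from the local clock string; no timezone
    conversion. Date-only values yield hour None.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "", None
    s = str(value).strip()
    m = _TIME_RE.search(s)
    if not m:
        return s, None
    hh = int(m.group(1))
    mm = int(m.group(2))
    ss = float(m.group(3) or 0.0)
    hour = hh + mm / 60.0 + ss / 3600.0
    if not (0.0 <= hour < 24.0):
        return s[: m.start()], None
    return s[: m.start()], hour


def read_occurrences(path, dialect: dict | None = None) -> list[OccurrenceRecord]:
    """Read a delimited occurrence export into records.

    ``dialect`` maps logical fields to the file's column names (see
    ``DEFAULT_DIALECT``); ``scientific_name`` and ``timestamp`` are
    required, the rest optional. Rows with an unparseable timestamp keep
    their date and lose the hour.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=d.get("sep", ","), dtype=str)
    if df.empty:
        raise ValueError(f"occurrence file {path} contains no rows")
    for key in ("scientific_name", "timestamp"):
        if d[key] not in df.columns:
            raise ValueError(
                f"required column {d[key]!r} (field {key!r}) missing from {path}; "
                f"available: {list(df.columns)}"
            )
    has = {k: d.get(k) in df.columns for k in ("taxon_rank", "order", "realm", "quality_grade")}
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        name = str(row[d["scientific_name"]] or "").strip()
        date, hour = _parse_timestamp(row[d["timestamp"]])
        if has["taxon_rank"]:
            rank = str(row[d["taxon_rank"]] or "").strip().lower()
            if rank not in ("species", "subspecies"):
                rank = rank or ("subspecies" if len(name.split()) >= 3 else "species")
        else:
            rank = "subspecies" if len(name.split()) >= 3 else "species"
        realm = str(row[d["realm"]]).strip() if has["realm"] and pd.notna(row[d["realm"]]) else None
        records.append(
            OccurrenceRecord(
                scientific_name=name,
                taxon_rank=rank if rank in ("species", "subspecies") else "other",
                order_name=str(row[d["order"]] or "").strip() if has["order"] else "",
                event_date=date,
                hour=hour,
                realm=realm,
                quality_grade=str(row[d["quality_grade"]] or "") if has["quality_grade"] else "",
            )
        )
    return records


def normalize_binomial(name: str) -> str | None:
    """Genus + species from a possibly decorated scientific name.

    Case-folds, strips authorship tails by keeping the first two word
    tokens, and rejects hybrids (names containing a multiplication sign
    or a standalone ``x``) and mononomials by returning None.
    """
    s = re.sub(r"\s+", " ", str(name)).strip()
    if not s or "×" in s:
        return None
    tokens = s.split(" ")
    if len(tokens) >= 2 and tokens[1].lower() == "x":
        return None
    # drop leading hybrid marker or authorship parentheses outright
    tokens = [t for t in tokens if t]
    if len(tokens) < 2:
        return None
    genus, epithet = tokens[0], tokens[1]
    if not epithet[0].isalpha() or not genus[0].isalpha():
        return None
    return f"{genus[0].upper()}{genus[1:].lower()} {epithet.lower()}"


def rollup_subspecies(records: list[OccurrenceRecord]) -> tuple[list[OccurrenceRecord], int]:
    """Recode subspecies as their parent species (first two name tokens).

    Returns the normalized records plus the count of rows dropped because
    their name could not be reduced to a binomial (mononomials, hybrids).
    Idempotent: applying it twice changes nothing.
    """
    out = []
    dropped = 0
    for rec in records:
        binom = normalize_binomial(rec.scientific_name)
        if binom is None:
            dropped += 1
            continue
        out.append(
            OccurrenceRecord(
                scientific_name=binom,
                taxon_rank="species",
                order_name=rec.order_name,
                event_date=rec.event_date,
                hour=rec.hour,
                realm=rec.realm,
                quality_grade=rec.quality_grade,
            )
        )
    return out, dropped


def filter_domestic(
    records: list[OccurrenceRecord],
    domestic_list: frozenset[str] | set[str] | None = None,
) -> tuple[list[OccurrenceRecord], IngestReport]:
    """Remove observations of domestic species.

    ``domestic_list`` holds binomials; None loads the shipped default.
    The report counts exclusions and lists the species actually hit.
    """
    if domestic_list is None:
        domestic_list = default_domestic_list()
    domestic_list = frozenset(domestic_list)
    kept, hit = [], set()
    for rec in records:
        if rec.scientific_name in domestic_list:
            hit.add(rec.scientific_name)
        else:
            kept.append(rec)
    report = IngestReport(
        n_raw=len(records),
        n_domestic_excluded=len(records) - len(kept),
        n_no_time=sum(1 for r in kept if r.hour is None),
        n_retained=len(kept),
        domestic_species_used=sorted(hit),
    )
    return kept, report


def _parse_multiset(value, allowed: tuple[str, ...]) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return frozenset()
    items = {t.strip() for t in re.split(r"[;|,]", str(value)) if t.strip()}
    bad = {t for t in items if t not in allowed}
    if bad:
        raise ValueError(f"unrecognized categories {sorted(bad)}; allowed: {allowed}")
    return frozenset(items)


def read_trait_table(path) -> pd.DataFrame:
    """Read the species trait CSV (one row per binomial).

    Multi-valued cells (trophic, strata, realms) are
    semicolon-separated. Duplicate species rows are an error.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError(f"trait table {path} lacks a 'species' column")
    dupes = df["species"][df["species"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate trait rows for species: {dupes[:10]}")
    return df


def _num(row, col) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    v = float(row[col])
    return v if v > 0 else None


def build_species_profiles(
    records: list[OccurrenceRecord],
    trait_table: pd.DataFrame,
) -> tuple[list[SpeciesProfile], IngestReport]:
    """Aggregate retained records per species and join traits.

    Species present in the records but absent from the trait table keep a
    profile with empty trait fields (``has_traits=False``) so their
    observations still count in totals; the join statistics land in the
    returned report.
    """
    counts: dict[str, int] = {}
    orders: dict[str, str] = {}
    realms_seen: dict[str, set] = {}
    for rec in records:
        counts[rec.scientific_name] = counts.get(rec.scientific_name, 0) + 1
        if rec.order_name and rec.scientific_name not in orders:
            orders[rec.scientific_name] = rec.order_name
        if rec.realm:
            realms_seen.setdefault(rec.scientific_name, set()).add(rec.realm)

    traits = trait_table.set_index("species")
    dupes = traits.index[traits.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate trait rows for species: {dupes[:10]}")

    profiles = []
    n_missing = 0
    for species in sorted(counts):
        base = SpeciesProfile(
            species=species,
            order_name=orders.get(species, ""),
            n_obs=counts[species],
            realms=frozenset(realms_seen.get(species, set())),
        )
        if species in traits.index:
            row = traits.loc[species]
            base.order_name = str(row.get("order_name", base.order_name) or base.order_name)
            for flag in ("diurnal", "nocturnal", "crepuscular"):
                if flag in row and pd.notna(row[flag]):
                    setattr(base, flag, int(row[flag]))
            base.trophic = _parse_multiset(row.get("trophic"), TROPHIC_LEVELS)
            base.strata = _parse_multiset(row.get("strata"), STRATA_LEVELS)
            base.body_mass = _num(row, "body_mass_g")
            base.biomass = _num(row, "biomass_g")
            base.population = _num(row, "population")
            base.range_area = _num(row, "range_area")
            table_realms = _parse_multiset(row.get("realms"), REALMS)
            base.realms = base.realms | table_realms
            iucn = str(row.get("iucn", "NE") or "NE").strip().upper()
            base.iucn = iucn if iucn in IUCN_LEVELS else "NE"
        else:
            n_missing += 1
            base.has_traits = False
        base.in_nearctic = int("Nearctic" in base.realms)
        profiles.append(base)

    report = IngestReport(
        n_raw=len(records),
        n_retained=len(records),
        n_no_time=sum(1 for r in records if r.hour is None),
        n_species=len(profiles),
        n_species_no_traits=n_missing,
    )
    return profiles, report


def count_by_realm(profiles: list[SpeciesProfile]) -> dict[str, int]:
    """Total observations per biogeographic realm.

    A species belonging to several realms contributes its full count to
    each, so realm totals may sum to more than the overall total.
    """
    totals: dict[str, int] = {}
    for p in profiles:
        for realm in p.realms:
            totals[realm] = totals.get(realm, 0) + p.n_obs
    return totals


def profiles_to_frame(profiles: list[SpeciesProfile]) -> pd.DataFrame:
    """Flatten profiles into the per-species analysis table."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "species": p.species,
                "order_name": p.order_name,
                "n_obs": p.n_obs,
                "diurnal": p.diurnal,
                "nocturnal": p.nocturnal,
                "crepuscular": p.crepuscular,
                "trophic": ";".join(sorted(p.trophic)),
                "strata": ";".join(sorted(p.strata)),
                "body_mass_g": p.body_mass,
                "biomass_g": p.biomass,
                "population": p.population,
                "range_area": p.range_area,
                "realms": ";".join(sorted(p.realms)),
                "iucn": p.iucn,
                "in_nearctic": p.in_nearctic,
                "has_traits": p.has_traits,
            }
        )
    return pd.DataFrame(rows)


def ingest(
    occurrence_path,
    trait_path,
    dialect: dict | None = None,
    domestic_list: frozenset[str] | None = None,
) -> tuple[list[OccurrenceRecord], list[SpeciesProfile], IngestReport]:
    """Full ingest stage: read, roll up, filter, profile.

    Returns the retained records, the species profiles, and a reconciled
    report (raw = domestic + invalid + retained, asserted).
    """
    raw = read_occurrences(occurrence_path, dialect)
    rolled, n_invalid = rollup_subspecies(raw)
    kept, report = filter_domestic(rolled, domestic_list)
    traits = read_trait_table(trait_path)
    profiles, join_report = build_species_profiles(kept, traits)
    report.n_raw = len(raw)
    report.n_invalid_name = n_invalid
    report.n_species = join_report.n_species
    report.n_species_no_traits = join_report.n_species_no_traits
    report.check()
    return kept, profiles, report
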