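"""Peptide-marker reference databases and contaminant lists.

A reference database maps species (and their ZooMS taxon / family / order
lineage) to monoisotopic collagen peptide-marker masses, partitioned by
geographic region because continental faunas share markers and mixing
them degrades identification. The package ships a small synthetic fixture
database for tests and demos; real curated marker tables are drop-in CSV
replacements with the same schema.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("Eurasia", "Africa", "NewWorld", "Other")
REFERENCE_COLUMNS = ("species", "zooms_taxon", "family", "order", "marker_id", "mass", "region")
CONTAMINANT_COLUMNS = ("name", "mass")
MASS_RANGE_DA = (800.0, 4000.0)


class SchemaError(ValueError):
    """Raised when a reference or contaminant table has a malformed schema."""


@dataclass(frozen=True)
class MarkerRecord:
    """One reference peptide-marker mass with its taxonomic lineage."""

    species: str
    zooms_taxon: str
    family: str
    order: str
    marker_id: str
    mass_da: float
    region: str = "Other"


@dataclass
class ReferenceDB:
    records: list[MarkerRecord] = field(default_factory=list)
    region_label: str = "all"

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.species)
        return list(seen)

    def markers_of(self, species: str) -> list[MarkerRecord]:
        return [rec for rec in self.records if rec.species == species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "zooms_taxon": [r.zooms_taxon for r in self.records],
                "family": [r.family for r in self.records],
                "order": [r.order for r in self.records],
                "marker_id": [r.marker_id for r in self.records],
                "mass": [r.mass_da for r in self.records],
                "region": [r.region for r in self.records],
            }
        )


@dataclass(frozen=True)
class ContaminantRecord:
    """A known non-sample peptide mass (keratins, trypsin autolysis, ...)."""

    name: str
    mass_da: float


def _normalize_text(value: object) -> str:
    text = "" if value is None or (isinstance(value, float) and pd.isna(value)) else str(value)
    text = re.sub(r"\s+", " ", text).strip()
    text = text.strip(" ,;")
    return text


def load_reference_csv(path: str | Path, delimiter: str = ",") -> ReferenceDB:
    """Load a marker table (``species,zooms_taxon,family,order,marker_id,mass,region``).

    ``zooms_taxon`` and ``region`` may be absent (filled by
    :func:`clean_reference_table` / treated as ``Other``); the remaining
    columns are required.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"species", "family", "order", "marker_id", "mass"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    records: list[MarkerRecord] = []
    for idx, row in table.iterrows():
        raw_mass = _normalize_text(row["mass"])
        # multiple masses in one cell are legal here; split in clean_reference_table
        for part in re.split(r"[;|]", raw_mass):
            part = part.strip()
            if not part:
                continue
            try:
                mass = float(part)
            except ValueError as exc:
                raise SchemaError(f"{path}: row {idx}: non-numeric mass {part!r}") from exc
            records.append(
                MarkerRecord(
                    species=_normalize_text(row["species"]),
                    zooms_taxon=_normalize_text(row.get("zooms_taxon", "")),
                    family=_normalize_text(row["family"]),
                    order=_normalize_text(row["order"]),
                    marker_id=_normalize_text(row["marker_id"]),
                    mass_da=mass,
                    region=_normalize_text(row.get("region", "")) or "Other",
                )
            )
    return ReferenceDB(records=records, region_label="all")


def clean_reference_table(db: ReferenceDB, taxon_map: dict[str, str] | None = None) -> ReferenceDB:
    """Normalize punctuation/whitespace, split multi-mass cells, fill taxa.

    ``taxon_map`` maps species names to their ZooMS taxon (e.g. several
    cervid species collapsing into one compound taxon); species without a
    mapping or an explicit ``zooms_taxon`` keep their own name. Records
    with masses outside the plausible peptide range or duplicate
    (species, marker, mass) triples are dropped with a log line.
    Idempotent.
    """
    taxon_map = taxon_map or {}
    lo, hi = MASS_RANGE_DA
    seen: set[tuple[str, str, float]] = set()
    cleaned: list[MarkerRecord] = []
    for rec in db.records:
        species = _normalize_text(rec.species)
        if not species:
            logger.warning("dropping record with empty species (marker %s)", rec.marker_id)
            continue
        if not (lo <= rec.mass_da <= hi):
            logger.warning("dropping %s marker %s: mass %.2f outside [%g, %g]", species, rec.marker_id, rec.mass_da, lo, hi)
            continue
        key = (species, _normalize_text(rec.marker_id), round(rec.mass_da, 4))
        if key in seen:
            logger.warning("dropping duplicate record %s", key)
            continue
        seen.add(key)
        taxon = _normalize_text(rec.zooms_taxon) or taxon_map.get(species, species)
        region = _normalize_text(rec.region)
        cleaned.append(
            MarkerRecord(
                species=species,
                zooms_taxon=taxon,
                family=_normalize_text(rec.family),
                order=_normalize_text(rec.order),
                marker_id=_normalize_text(rec.marker_id),
                mass_da=float(rec.mass_da),
                region=region if region in REGIONS else "Other",
            )
        )
    return ReferenceDB(records=cleaned, region_label=db.region_label)


def partition_by_region(db: ReferenceDB, region: str) -> ReferenceDB:
    """Restrict a database to one geographic region."""
    canonical = {r.lower(): r for r in REGIONS}
    key = region.strip().lower().replace(" ", "").replace("_", "")
    key = {"newworld": "newworld"}.get(key, key)
    if key not in canonical:
        raise ValueError(f"unknown region {region!r}; valid regions: {', '.join(REGIONS)}")
    label = canonical[key]
    records = [rec for rec in db.records if rec.region == label]
    if not records:
        logger.warning("region %s has no records", label)
    return ReferenceDB(records=records, region_label=label)


def load_contaminants(path: str | Path, delimiter: str = ",") -> list[ContaminantRecord]:
    """Load a ``name,mass`` contaminant list (duplicate names allowed)."""
    path = Path(path)
    table = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    table.columns = [c.strip().lower() for c in table.columns]
    missing = set(CONTAMINANT_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    out: list[ContaminantRecord] = []
    for idx, row in table.iterrows():
        try:
            mass = float(row["mass"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {idx}: non-numeric mass {row['mass']!r}") from exc
        if mass <= 0:
            raise SchemaError(f"{path}: row {idx}: non-positive mass {mass}")
        out.append(ContaminantRecord(name=_normalize_text(row["name"]), mass_da=mass))
    if not out:
        logger.warning("contaminant list %s is empty", path)
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("zoomsid").joinpath("data", name)))


def fixture_reference_db(region: str | None = None) -> ReferenceDB:
    """The shipped synthetic fixture marker database (cleaned).

    The species, compound ZooMS taxa and marker letters follow standard
    ZooMS usage, but the marker masses are synthetic stand-ins chosen for
    testing, not curated biological values.
    """
    db = clean_reference_table(load_reference_csv(_data_path("reference_markers_synthetic.csv")))
    if region is not None:
        db = partition_by_region(db, region)
    return db


def fixture_contaminants() -> list[ContaminantRecord]:
    """The shipped synthetic contaminant list (names real, masses stand-ins)."""
    return load_contaminants(_data_path("contaminants_synthetic.csv"))
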