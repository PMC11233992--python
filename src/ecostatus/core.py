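"""Domain types and CSV I/O for species-by-sample abundance data.

Abundance is expressed as individuals per cubic meter (ind·m⁻³), so values
are non-negative reals rather than integers.  A sample optionally carries a
replicate-unit incidence matrix (presence/absence across tows or depth
layers) used by incidence-based richness estimation.
"""
from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ecostatus")

WARM = "warm"
COLD = "cold"
SEASONS = (WARM, COLD)

GOOD = "good"
NON_GOOD = "non_good"
UNKNOWN = "unknown"
LABELS = (GOOD, NON_GOOD, UNKNOWN)


class ValidationError(ValueError):
    """An input table or metadata file violates the format contract."""


def assign_season(date: _dt.date) -> str:
    """Assign the hydrological season of a sampling date.

    May through October is the warm season; November through April the
    cold season.  The two seasons partition the calendar year.
    """
    return WARM if 5 <= date.month <= 10 else COLD


@dataclass
class IncidenceMatrix:
    """Presence/absence of species across sampling units (tows, layers).

    Rows are units, columns species; ``presence[u, s]`` is True when
    species ``s`` was detected in unit ``u``.
    """

    units: list[str]
    species: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.units), len(self.species)):
            raise ValidationError(
                f"incidence shape {self.presence.shape} does not match "
                f"{len(self.units)} units x {len(self.species)} species"
            )

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class AbundanceSample:
    """One sample's species abundances (ind·m⁻³) plus its metadata."""

    sample_id: str
    counts: dict[str, float]
    station: str = ""
    period: str = ""
    date: _dt.date | None = None
    season: str | None = None
    incidence: IncidenceMatrix | None = None

    def __post_init__(self) -> None:
        for sp, v in self.counts.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}, species {sp!r}: "
                    f"abundance {v!r} is negative or not finite"
                )
        if self.season is None and self.date is not None:
            self.season = assign_season(self.date)
        if self.season is not None and self.season not in SEASONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown season {self.season!r} "
                f"(expected one of {SEASONS})"
            )

    @property
    def positive_counts(self) -> dict[str, float]:
        return {sp: v for sp, v in self.counts.items() if v > 0}

    @property
    def richness(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)

    @property
    def total_abundance(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class SampleSet:
    """An ordered collection of samples with an optional status labelling."""

    samples: list[AbundanceSample]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        for sid, lab in self.labels.items():
            if lab not in LABELS:
                raise ValidationError(
                    f"sample {sid!r}: unknown label {lab!r} (expected one of {LABELS})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> AbundanceSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_universe(self) -> list[str]:
        """Sorted union of species ids over all samples."""
        universe: set[str] = set()
        for s in self.samples:
            universe.update(s.counts)
        return sorted(universe)

    def label_of(self, sample_id: str) -> str:
        return self.labels.get(sample_id, UNKNOWN)

    def subset(self, sample_ids: Iterable[str]) -> "SampleSet":
        wanted = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in wanted]
        labels = {k: v for k, v in self.labels.items() if k in wanted}
        return SampleSet(samples=samples, labels=labels)

    def filter_season(self, season: str | None) -> "SampleSet":
        """Samples of one season; ``None`` or ``"annual"`` keeps all."""
        if season in (None, "annual"):
            return self
        if season not in SEASONS:
            raise ValidationError(f"unknown season {season!r}")
        return self.subset(s.sample_id for s in self.samples if s.season == season)

    def pooled_richness(self, label: str | None = None) -> int:
        """Number of species with a positive count in any (labelled) sample."""
        pool: set[str] = set()
        for s in self.samples:
            if label is None or self.label_of(s.sample_id) == label:
                pool.update(s.positive_counts)
        return len(pool)

    def to_wide_frame(self) -> pd.DataFrame:
        """Species x samples abundance matrix (absent species as 0)."""
        universe = self.species_universe
        data = {
            s.sample_id: [float(s.counts.get(sp, 0.0)) for sp in universe]
            for s in self.samples
        }
        return pd.DataFrame(data, index=pd.Index(universe, name="species_id"))

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "station": s.station,
                    "period": s.period,
                    "date": s.date.isoformat() if s.date else "",
                    "season": s.season or "",
                    "label": self.label_of(s.sample_id),
                }
            )
        return pd.DataFrame(rows)


def _parse_date(token: str) -> _dt.date | None:
    token = (token or "").strip()
    if not token:
        return None
    return _dt.date.fromisoformat(token)


def _read_metadata(path: str | Path) -> dict[str, dict]:
    meta = pd.read_csv(path, dtype=str).fillna("")
    if "sample_id" not in meta.columns:
        raise ValidationError(f"metadata {path}: missing 'sample_id' column")
    out: dict[str, dict] = {}
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        season = row.get("season", "") or None
        if season is not None and season not in SEASONS:
            raise ValidationError(
                f"metadata {path}: sample {sid!r} has unknown season {season!r}"
            )
        out[sid] = {
            "station": row.get("station", ""),
            "period": row.get("period", ""),
            "date": _parse_date(row.get("date", "")),
            "season": season,
            "label": (row.get("label", "") or UNKNOWN),
        }
    return out


def read_abundance_table(
    path: str | Path,
    layout: str = "wide",
    metadata_path: str | Path | None = None,
) -> SampleSet:
    """Read a species-by-sample abundance table from CSV.

    ``wide`` layout: first column is ``species_id``, remaining columns are
    sample ids, cells are abundances.  ``long`` layout: columns
    ``sample_id, species_id, abundance``.  Species absent from a sample
    are zero.  An optional metadata CSV keyed by ``sample_id`` supplies
    station, period, date (ISO 8601), season and label; an explicit
    season overrides the one derived from the date.
    """
    if layout not in ("wide", "long"):
        raise ValidationError(f"unknown layout {layout!r}")
    meta = _read_metadata(metadata_path) if metadata_path else {}

    counts_by_sample: dict[str, dict[str, float]] = {}
    if layout == "wide":
        df = pd.read_csv(path)
        species_col = df.columns[0]
        species = df[species_col].astype(str).tolist()
        if len(species) != len(set(species)):
            raise ValidationError(f"{path}: duplicate species ids in wide table")
        for sid in df.columns[1:]:
            col = pd.to_numeric(df[sid], errors="raise")
            for sp, v in zip(species, col):
                v = float(v)
                if v < 0:
                    raise ValidationError(
                        f"{path}: negative abundance {v} for sample {sid!r}, "
                        f"species {sp!r}"
                    )
            counts_by_sample[str(sid)] = dict(zip(species, (float(v) for v in col)))
    else:
        df = pd.read_csv(path)
        required = {"sample_id", "species_id", "abundance"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"{path}: long layout needs columns {sorted(required)}"
            )
        seen: set[tuple[str, str]] = set()
        for i, row in df.iterrows():
            sid, sp = str(row["sample_id"]), str(row["species_id"])
            v = float(row["abundance"])
            if (sid, sp) in seen:
                raise ValidationError(
                    f"{path} row {i}: duplicate entry for sample {sid!r}, "
                    f"species {sp!r}"
                )
            seen.add((sid, sp))
            if v < 0:
                raise ValidationError(
                    f"{path} row {i}: negative abundance {v} for sample "
                    f"{sid!r}, species {sp!r}"
                )
            counts_by_sample.setdefault(sid, {})[sp] = v

    samples = []
    labels: dict[str, str] = {}
    for sid, counts in counts_by_sample.items():
        m = meta.get(sid, {})
        samples.append(
            AbundanceSample(
                sample_id=sid,
                counts=counts,
                station=m.get("station", ""),
                period=m.get("period", ""),
                date=m.get("date"),
                season=m.get("season"),
            )
        )
        lab = m.get("label", UNKNOWN)
        if lab != UNKNOWN:
            if lab not in LABELS:
                raise ValidationError(f"sample {sid!r}: unknown label {lab!r}")
            labels[sid] = lab
    return SampleSet(samples=samples, labels=labels)


def write_sample_set(
    sample_set: SampleSet,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a SampleSet as a wide CSV (plus optional metadata CSV)."""
    wide = sample_set.to_wide_frame()
    wide.to_csv(path)
    if metadata_path is not None:
        sample_set.metadata_frame().to_csv(metadata_path, index=False)


def write_table(records, path: str | Path) -> None:
    """Write rectangular records (DataFrame or list of dicts) as CSV.

    Floats are written at full precision so that a read round-trips
    exactly.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, index=False)
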