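"""Compound registry: platform detections, concentrations and coverage math.

The registry models a serum-metabolome reference list: each record is a
compound with optional HMDB accession, the analytical platforms that detected
it, and one or more concentration entries.  Coverage arithmetic (percent of a
configured denominator, inclusion–exclusion unions, multi-platform overlap
with synonym resolution) lives here too.

The denominator of coverage percentages is configuration, not a constant: the
reference list grows as instruments improve.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PLATFORMS",
    "ConcentrationEntry",
    "CompoundRecord",
    "PlatformCoverage",
    "load_registry",
    "coverage_percent",
    "union_count",
    "overlap_sets",
    "min_concentration",
    "convert_units",
    "round_half_up",
    "canonical_names",
]

#: Recognized platform tags.
PLATFORMS = frozenset(
    {
        "NMR",
        "GCMS_global",
        "GCMS_targeted",
        "LCMSMS_mediator",
        "TLC_GCFID",
        "DFI_MSMS",
        "literature",
    }
)

_HMDB_RE = re.compile(r"^HMDB\d+$")

#: Exact power-of-ten unit scales relative to µM.
_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "mM": 1e3}


@dataclass(frozen=True)
class ConcentrationEntry:
    """One concentration measurement: mean ± sd in a unit, tagged by cohort
    (healthy, transplant, literature, ...) and optionally by platform."""

    mean: float
    sd: Optional[float] = None
    unit: str = "uM"
    cohort: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if self.unit not in _UNIT_TO_UM:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.mean < 0:
            raise ValueError("concentration mean must be non-negative")
        if self.sd is not None and self.sd < 0:
            raise ValueError("concentration sd must be non-negative")

    @property
    def mean_uM(self) -> float:
        return convert_units(self.mean, self.unit, "uM")


@dataclass
class CompoundRecord:
    """A registry compound with platform detections and concentrations."""

    name: str
    synonyms: tuple[str, ...] = ()
    hmdb_id: Optional[str] = None
    compound_class: str = ""
    platform_detections: frozenset[str] = frozenset()
    status: str = "confirmed"
    concentrations: tuple[ConcentrationEntry, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("record needs a non-empty name")
        if self.hmdb_id is not None and not _HMDB_RE.match(self.hmdb_id):
            raise ValueError(f"malformed HMDB accession {self.hmdb_id!r}")
        unknown = set(self.platform_detections) - PLATFORMS
        if unknown:
            raise ValueError(f"unknown platform tags {sorted(unknown)}")


@dataclass(frozen=True)
class PlatformCoverage:
    platform: str
    detected_count: int
    denominator: int
    percent: float


_MANDATORY_COLUMNS = {"name", "platform"}


def load_registry(path) -> tuple[list[CompoundRecord], list[dict]]:
    """Load a registry CSV (columns: name, synonyms, hmdb_id, class, platform,
    status, mean, sd, unit, cohort); one record per row.

    Malformed rows are collected into an error report (list of dicts with the
    row number, the offending row and the reason), never silently dropped.
    """
    records: list[CompoundRecord] = []
    errors: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        missing = _MANDATORY_COLUMNS - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValueError, KeyError) as exc:
                errors.append({"line": lineno, "row": dict(row), "error": str(exc)})
    return records, errors


def _record_from_row(row: Mapping[str, str]) -> CompoundRecord:
    def opt(key: str) -> Optional[str]:
        val = (row.get(key) or "").strip()
        return val or None

    concentrations: tuple[ConcentrationEntry, ...] = ()
    if opt("mean") is not None:
        sd = opt("sd")
        concentrations = (
            ConcentrationEntry(
                mean=float(row["mean"]),
                sd=None if sd in (None, "NA", "ND") else float(sd),
                unit=opt("unit") or "uM",
                cohort=opt("cohort") or "",
                platform=opt("platform") or "",
            ),
        )
    synonyms = tuple(
        s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()
    )
    return CompoundRecord(
        name=row["name"].strip(),
        synonyms=synonyms,
        hmdb_id=opt("hmdb_id"),
        compound_class=opt("class") or "",
        platform_detections=frozenset({row["platform"].strip()}),
        status=opt("status") or "confirmed",
        concentrations=concentrations,
    )


def coverage_percent(detected: int, denominator: int, platform: str = "") -> PlatformCoverage:
    """Fraction of the reference metabolome a platform measures, as a percent.

    The percent is kept at full precision; formatting to the printed number of
    decimals is a presentation step (:func:`round_half_up`).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= detected <= denominator:
        raise ValueError("detected count must lie in [0, denominator]")
    return PlatformCoverage(
        platform=platform,
        detected_count=detected,
        denominator=denominator,
        percent=100.0 * detected / denominator,
    )


def union_count(size_a: int, size_b: int, overlap: int) -> int:
    """Inclusion–exclusion: |A ∪ B| = |A| + |B| − |A ∩ B|."""
    if overlap > min(size_a, size_b) or overlap < 0:
        raise ValueError("overlap cannot exceed either set size")
    return size_a + size_b - overlap


def canonical_names(record: CompoundRecord, synonyms: Mapping[str, str]) -> set[str]:
    """Canonical lower-case name set for a record.

    Combined labels ("L-Isoleucine+L-Leucine") expand into their components;
    each candidate then passes through the synonym map.  A record detecting a
    combined analyte therefore counts as detecting every component.
    """
    names: set[str] = set()
    for raw in (record.name, *record.synonyms):
        for part in raw.split("+"):
            key = part.strip().lower()
            if key:
                names.add(synonyms.get(key, key))
    return names


def overlap_sets(
    registry: Sequence[CompoundRecord],
    platforms: Iterable[str],
    synonyms: Optional[Mapping[str, str]] = None,
) -> set[str]:
    """Canonical names detected by *every* platform in ``platforms``.

    Matching is case-insensitive with synonym expansion; monotone decreasing
    in the platform set.
    """
    wanted = set(platforms)
    unknown = wanted - PLATFORMS
    if unknown:
        raise ValueError(f"unknown platform tags {sorted(unknown)}")
    syn = dict(synonyms or {})
    per_platform: dict[str, set[str]] = {p: set() for p in wanted}
    for rec in registry:
        names = None
        for p in rec.platform_detections & wanted:
            if names is None:
                names = canonical_names(rec, syn)
            per_platform[p] |= names
    if not per_platform:
        return set()
    result: Optional[set[str]] = None
    for names in per_platform.values():
        result = names if result is None else result & names
    return result or set()


def min_concentration(
    records: Sequence[CompoundRecord],
    class_filter: Optional[str] = None,
) -> tuple[CompoundRecord, ConcentrationEntry]:
    """The record with the smallest mean concentration after unit
    normalization to µM (ties broken by name); e.g. a platform's effective
    lower limit of quantification."""
    best: Optional[tuple[float, str, CompoundRecord, ConcentrationEntry]] = None
    for rec in records:
        if class_filter is not None and rec.compound_class != class_filter:
            continue
        for entry in rec.concentrations:
            key = (entry.mean_uM, rec.name)
            if best is None or key < (best[0], best[1]):
                best = (entry.mean_uM, rec.name, rec, entry)
    if best is None:
        raise ValueError("no records with concentrations")
    return best[2], best[3]


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact power-of-ten conversion between nM, µM and mM."""
    try:
        scale = _UNIT_TO_UM[from_unit] / _UNIT_TO_UM[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown unit {exc.args[0]!r}") from None
    return value * scale


def round_half_up(value: float, digits: int = 1) -> float:
    """Round half away from zero to ``digits`` decimals (display rounding)."""
    factor = 10.0**digits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
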