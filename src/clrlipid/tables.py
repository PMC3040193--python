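"""Packaged reference tables and helpers built on them.

The ``data/`` directory ships verbatim CSV transcriptions of the printed
serum-metabolome reference tables (NMR panel, GC-MS lists, targeted
fatty-acid panel, oxylipin/endocannabinoid panels, the TLC/GC-FID chain-level
lipid table, the direct-flow-injection kit panels, and summary count tables).
A manifest records each file's row count and SHA-256 checksum; loaders verify
both so silent edits to the transcriptions are caught.

Helpers here turn the tables into package objects: acyl profiles for the
chain-level lipid classes, the default simulation chain pool, and a
multi-platform compound registry.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Optional

import pandas as pd

from .chains import AcylChain, parse_chain, get_class
from .reconstruct import AcylProfile
from .registry import CompoundRecord, ConcentrationEntry

__all__ = [
    "FixtureIntegrityError",
    "fixture_tables",
    "load_table",
    "load_synonyms",
    "default_chain_pool",
    "acyl_profile_from_lipomics",
    "registry_from_tables",
]

_DATA_PACKAGE = "clrlipid.data"

TABLE_FILES = {
    "table03": "table03_nmr.csv",
    "table04": "table04_gcms_global.csv",
    "table05": "table05_ffa_targeted.csv",
    "table06": "table06_gcms_quantified.csv",
    "table07": "table07_oxylipins_n6.csv",
    "table08": "table08_oxylipins_n3.csv",
    "table09": "table09_oxylipins_c18.csv",
    "table10": "table10_acyl_amides_glycerols.csv",
    "table11": "table11_lipomics.csv",
    "table12": "table12_dfi.csv",
    "table13": "table13_dfi_lipids.csv",
    "table14": "table14_lysopc_comparison.csv",
    "platform_counts": "platform_counts.csv",
    "lipid_class_counts": "lipid_class_counts.csv",
    "dfi_panel_counts": "dfi_panel_counts.csv",
    "gcms_counts": "gcms_counts.csv",
    "synonyms": "synonyms.csv",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged table does not match its manifest (edited or corrupted)."""


def _read_bytes(filename: str) -> bytes:
    return resources.files(_DATA_PACKAGE).joinpath(filename).read_bytes()


def _manifest() -> dict:
    return json.loads(_read_bytes("manifest.json"))


def load_table(name: str, *, verify: bool = True) -> pd.DataFrame:
    """Load one packaged table by short name (e.g. ``"table11"``), verifying
    its checksum and row count against the manifest."""
    filename = TABLE_FILES[name]
    blob = _read_bytes(filename)
    if verify:
        entry = _manifest()[filename]
        digest = hashlib.sha256(blob).hexdigest()
        if digest != entry["sha256"]:
            raise FixtureIntegrityError(f"{filename}: checksum mismatch")
    import io

    df = pd.read_csv(io.BytesIO(blob), dtype=str, keep_default_na=False)
    if verify and len(df) != entry["rows"]:
        raise FixtureIntegrityError(
            f"{filename}: {len(df)} rows, manifest records {entry['rows']}"
        )
    return df


def fixture_tables(*, verify: bool = True) -> dict[str, pd.DataFrame]:
    """All packaged tables as a name → DataFrame bundle."""
    return {name: load_table(name, verify=verify) for name in TABLE_FILES}


def load_synonyms() -> dict[str, str]:
    """The packaged synonym map (lower-case name → canonical name)."""
    df = load_table("synonyms")
    return dict(zip(df["name"].str.lower(), df["canonical"].str.lower()))


def _num(cell: str) -> Optional[float]:
    cell = (cell or "").strip()
    if cell in ("", "ND", "NA"):
        return None
    return float(cell)


_LIPOMICS_COLUMNS = {"CE": "ce", "FFA": "ffa", "LysoPC": "lysopc"}


def acyl_profile_from_lipomics(class_name: str) -> AcylProfile:
    """Acyl profile of one chain-level lipid class (CE, FFA or LysoPC) from
    the packaged TLC/GC-FID table; the class total is the sum of the chain
    means (k = 1 for these classes, so chain and class amounts coincide)."""
    col = _LIPOMICS_COLUMNS[class_name]
    df = load_table("table11")
    entries: dict[AcylChain, float] = {}
    for _, row in df.iterrows():
        mean = _num(row[f"{col}_mean"])
        if mean is not None:
            entries[parse_chain(row["chain"])] = mean
    total = sum(entries.values())
    return AcylProfile(class_spec=get_class(class_name), entries=entries, class_total=total)


def default_chain_pool() -> list[AcylChain]:
    """The default 26-chain pool for simulations.

    Chain-level profiling of adult serum resolves on the order of 26 unique
    acyl chains per sample.  The pool used here is the set of chains from the
    packaged TLC/GC-FID table carrying a complete free-fatty-acid mean ± SD
    (27 quantified FFA means minus the one trace chain whose SD is not
    reported), a deterministic rule that lands exactly on 26 chains.
    """
    df = load_table("table11")
    pool = [
        parse_chain(row["chain"])
        for _, row in df.iterrows()
        if _num(row["ffa_mean"]) is not None and _num(row["ffa_sd"]) is not None
    ]
    assert len(pool) == 26, "packaged table no longer yields the 26-chain pool"
    return pool


def _mean_sd(cell: str) -> tuple[Optional[float], Optional[float]]:
    """Split a ``mean±sd`` cell; returns (None, None) for ND/NA/"<x" cells."""
    cell = (cell or "").strip()
    if not cell or cell in ("ND", "NA") or cell.startswith("<"):
        return None, None
    for sep in ("±", "+/-", "+/−"):
        if sep in cell:
            mean, sd = cell.split(sep, 1)
            return float(mean), float(sd)
    return float(cell), None


def registry_from_tables() -> list[CompoundRecord]:
    """Build the multi-platform compound registry from the packaged tables.

    One record per table row, tagged with the platform that produced it:
    NMR panel → ``NMR``; global and targeted GC-MS lists → ``GCMS_global`` /
    ``GCMS_targeted``; oxylipin, endocannabinoid and acyl-glycine panels →
    ``LCMSMS_mediator``; chain-level lipid table rows → ``TLC_GCFID``; kit
    panels → ``DFI_MSMS``.  Name resolution across platforms is the job of
    :func:`clrlipid.registry.overlap_sets` with the packaged synonyms.
    """
    records: list[CompoundRecord] = []

    for _, row in load_table("table03").iterrows():
        if row["healthy_mean"] == "ND" and row["transplant_mean"] == "ND":
            continue  # defensive; every row is detected in at least one cohort
        concs = []
        for cohort in ("healthy", "transplant"):
            mean = _num(row[f"{cohort}_mean"])
            if mean is not None:
                concs.append(
                    ConcentrationEntry(
                        mean=mean,
                        sd=_num(row[f"{cohort}_sd"]),
                        unit="uM",
                        cohort=cohort,
                        platform="NMR",
                    )
                )
        records.append(
            CompoundRecord(
                name=row["name"],
                platform_detections=frozenset({"NMR"}),
                concentrations=tuple(concs),
            )
        )

    for _, row in load_table("table04").iterrows():
        records.append(
            CompoundRecord(
                name=row["name"],
                compound_class=row["category"],
                platform_detections=frozenset({"GCMS_global"}),
            )
        )

    for _, row in load_table("table05").iterrows():
        records.append(
            CompoundRecord(
                name=row["name"],
                synonyms=(row["abbreviation"],),
                hmdb_id=row["hmdb_id"],
                compound_class=row["class"],
                platform_detections=frozenset({"GCMS_targeted"}),
                concentrations=(
                    ConcentrationEntry(
                        mean=float(row["mean"]),
                        sd=float(row["sd"]),
                        unit="uM",
                        cohort="Pennington",
                        platform="GCMS_targeted",
                    ),
                ),
            )
        )

    for table in ("table07", "table08", "table09", "table10"):
        for _, row in load_table(table).iterrows():
            mean, sd = _mean_sd(row["pennington"])
            concs = (
                (
                    ConcentrationEntry(
                        mean=mean,
                        sd=sd,
                        unit="nM",
                        cohort="Pennington",
                        platform="LCMSMS_mediator",
                    ),
                )
                if mean is not None
                else ()
            )
            records.append(
                CompoundRecord(
                    name=row["abbreviation"],
                    hmdb_id=row["hmdb_id"],
                    compound_class=row["class"],
                    platform_detections=frozenset({"LCMSMS_mediator"}),
                    concentrations=concs,
                )
            )

    for class_name, col in _LIPOMICS_COLUMNS.items():
        for _, row in load_table("table11").iterrows():
            mean = _num(row[f"{col}_mean"])
            if mean is None:
                continue
            records.append(
                CompoundRecord(
                    name=f"{class_name} {row['chain']}",
                    compound_class=class_name,
                    platform_detections=frozenset({"TLC_GCFID"}),
                    concentrations=(
                        ConcentrationEntry(
                            mean=mean,
                            sd=_num(row[f"{col}_sd"]),
                            unit="uM",
                            cohort="healthy",
                            platform="TLC_GCFID",
                        ),
                    ),
                )
            )

    for table, class_key in (("table12", "group"), ("table13", "group")):
        for _, row in load_table(table).iterrows():
            records.append(
                CompoundRecord(
                    name=row["name"],
                    compound_class=row[class_key],
                    platform_detections=frozenset({"DFI_MSMS"}),
                    concentrations=(
                        ConcentrationEntry(
                            mean=float(row["mean"]),
                            sd=_num(row["sd"]),
                            unit="uM",
                            cohort="healthy",
                            platform="DFI_MSMS",
                        ),
                    ),
                )
            )

    return records
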