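"""Tab-separated input/output for acyl profiles and reconstruction results.

Acyl-profile TSV: header ``class\tchain\tamount`` with one row per chain.
Class totals (µM) come either from comment lines of the form
``# total_uM = <value>`` (applying to the class of the rows that follow) or
``# total_uM <class> = <value>``, or from a separate totals TSV with columns
``class\ttotal_uM``.  Machine-readable columns spell the unit ``uM``;
decimals use ``.`` and encoding is UTF-8.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .chains import BUILTIN_CLASSES, LipidClassSpec, parse_chain, sum_composition_of
from .grouping import GroupedDesignation
from .reconstruct import AcylProfile, ReconstructedSpecies

__all__ = [
    "read_acyl_profiles",
    "read_class_totals",
    "write_species_tsv",
    "write_grouped_tsv",
    "write_mixture_tsv",
]

_TOTAL_RE = re.compile(r"^#\s*total_uM\s*(?P<cls>\S+)?\s*=\s*(?P<val>[0-9.eE+-]+)\s*$")


def read_class_totals(path) -> dict[str, float]:
    """Read a class-totals TSV (columns ``class``, ``total_uM``)."""
    df = pd.read_csv(path, sep="\t", dtype={"class": str})
    if not {"class", "total_uM"} <= set(df.columns):
        raise ValueError(f"{path}: totals file needs columns class, total_uM")
    return dict(zip(df["class"], df["total_uM"].astype(float)))


def read_acyl_profiles(
    path,
    totals: Optional[dict[str, float]] = None,
    class_specs: Optional[dict[str, LipidClassSpec]] = None,
) -> dict[str, AcylProfile]:
    """Read acyl profiles from TSV, one :class:`AcylProfile` per class.

    Raises ValueError naming any class that lacks a total (from a comment
    line or the ``totals`` mapping).
    """
    specs = dict(BUILTIN_CLASSES)
    if class_specs:
        specs.update(class_specs)
    totals = dict(totals or {})

    rows: list[tuple[str, str, float]] = []
    pending_total: Optional[float] = None
    text = Path(path).read_text(encoding="utf-8")
    header: Optional[list[str]] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        m = _TOTAL_RE.match(line)
        if m:
            if m.group("cls"):
                totals[m.group("cls")] = float(m.group("val"))
            else:
                pending_total = float(m.group("val"))
            continue
        if line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            if header[:3] != ["class", "chain", "amount"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header 'class\\tchain\\tamount'"
                )
            continue
        cls, chain, amount = fields[0], fields[1], float(fields[2])
        if pending_total is not None and cls not in totals:
            totals[cls] = pending_total
            pending_total = None
        rows.append((cls, chain, amount))

    profiles: dict[str, AcylProfile] = {}
    by_class: dict[str, dict] = {}
    for cls, chain, amount in rows:
        by_class.setdefault(cls, {})[parse_chain(chain)] = amount
    for cls, entries in by_class.items():
        if cls not in specs:
            raise ValueError(f"{path}: unknown lipid class {cls!r}")
        if cls not in totals:
            raise ValueError(f"{path}: class {cls!r} lacks a total_uM value")
        profiles[cls] = AcylProfile(
            class_spec=specs[cls], entries=entries, class_total=totals[cls]
        )
    return profiles


def write_species_tsv(path, species: Sequence[ReconstructedSpecies]) -> None:
    """Write reconstructed species: class, composition (chains joined by
    ``/``), sum_composition, most_probable_uM, upper_limit_uM, status."""
    rows = [
        {
            "class": r.composition.class_name,
            "composition": r.composition.canonical,
            "sum_composition": sum_composition_of(r.composition).label,
            "most_probable_uM": r.most_probable,
            "upper_limit_uM": r.upper_limit,
            "status": r.status,
        }
        for r in species
    ]
    pd.DataFrame(
        rows,
        columns=[
            "class",
            "composition",
            "sum_composition",
            "most_probable_uM",
            "upper_limit_uM",
            "status",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_grouped_tsv(path, groups: Sequence[GroupedDesignation]) -> None:
    rows = [
        {
            "class": g.designation.class_name,
            "designation": g.designation.label,
            "total_mp_uM": g.total_most_probable,
            "total_ul_uM": g.total_upper_limit,
            "n_members": g.n_members,
            "members": ";".join(m.canonical for m in g.member_compositions),
        }
        for g in groups
    ]
    pd.DataFrame(
        rows,
        columns=["class", "designation", "total_mp_uM", "total_ul_uM", "n_members", "members"],
    ).to_csv(path, sep="\t", index=False)


def write_mixture_tsv(path, mixture) -> None:
    """Write a ground-truth mixture: class, composition, concentration_uM."""
    rows = [
        {
            "class": comp.class_name,
            "composition": comp.canonical,
            "concentration_uM": conc,
        }
        for comp, conc in sorted(
            mixture.species_concentrations.items(), key=lambda kv: kv[0].canonical
        )
    ]
    pd.DataFrame(rows, columns=["class", "composition", "concentration_uM"]).to_csv(
        path, sep="\t", index=False
    )
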