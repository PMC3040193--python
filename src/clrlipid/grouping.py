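"""Sum-composition regrouping and targeted-panel alignment.

Chain-resolved species are collapsed onto shotgun-style sum-composition
designations (e.g. the diacyl species PC(C18:0/C20:4n6) and PC(C16:0/C22:4n6)
both land in PC(38:4)), which is the granularity reported by direct-infusion
targeted kits.  Panel labels use their own dialect ("LysoPC a C18:1",
"SM (OH) C22:1") with acyl/ether markers and an optional hydroxyl tag; a small
grammar parses them so kit rows can be paired with reconstruction groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chains import (
    AcylChain,
    SpeciesComposition,
    SumComposition,
    sum_composition_of,
)
from .reconstruct import ReconstructedSpecies, enumerate_species
from .chains import LipidClassSpec

logger = logging.getLogger(__name__)

__all__ = [
    "GroupedDesignation",
    "group_species",
    "expand_designation",
    "PanelLabel",
    "parse_panel_label",
    "match_platforms",
]


@dataclass(frozen=True)
class GroupedDesignation:
    """All member species sharing one sum-composition designation, with the
    summed most-probable and upper-limit totals (µM)."""

    designation: SumComposition
    member_compositions: tuple[SpeciesComposition, ...]
    total_most_probable: float
    total_upper_limit: float

    @property
    def n_members(self) -> int:
        return len(self.member_compositions)


def group_species(
    species: Sequence[ReconstructedSpecies],
    *,
    include_plasmalogen_in_acyl: bool = False,
) -> list[GroupedDesignation]:
    """Partition reconstructed species by sum composition and sum their totals.

    All species must share a class.  With ``include_plasmalogen_in_acyl`` the
    plasmalogen-containing members are folded into the acyl ("a") designation
    of the same totals instead of a separate ether ("e") one.  Output is
    ordered by (bond type, total carbons, total double bonds).
    """
    if not species:
        return []
    classes = {r.composition.class_name for r in species}
    if len(classes) > 1:
        raise ValueError(f"species from multiple classes: {sorted(classes)}")
    buckets: dict[SumComposition, list[ReconstructedSpecies]] = {}
    for rec in species:
        key = sum_composition_of(
            rec.composition, plasmalogen_as_acyl=include_plasmalogen_in_acyl
        )
        buckets.setdefault(key, []).append(rec)
    out = [
        GroupedDesignation(
            designation=key,
            member_compositions=tuple(r.composition for r in members),
            total_most_probable=sum(r.most_probable for r in members),
            total_upper_limit=sum(r.upper_limit for r in members),
        )
        for key, members in buckets.items()
    ]
    out.sort(
        key=lambda g: (
            g.designation.bond_type,
            g.designation.total_carbons,
            g.designation.total_double_bonds,
        )
    )
    return out


def expand_designation(
    designation: SumComposition,
    chain_pool: Sequence[AcylChain],
    *,
    acyl_positions: Optional[int] = None,
) -> list[SpeciesComposition]:
    """All chain multisets from the pool matching a designation's totals.

    ``acyl_positions`` defaults to the built-in k of the designation's class.
    An infeasible designation yields an empty list.
    """
    from .chains import BUILTIN_CLASSES

    if acyl_positions is None:
        spec = BUILTIN_CLASSES.get(designation.class_name)
        if spec is None:
            raise ValueError(
                f"unknown class {designation.class_name!r}: pass acyl_positions"
            )
        k = spec.acyl_positions
    else:
        k = acyl_positions
    spec = LipidClassSpec(designation.class_name, k)
    members = []
    for comp in enumerate_species(spec, chain_pool, mode="multiset"):
        if sum_composition_of(comp) == designation:
            members.append(comp)
    return members


_PANEL_RE = re.compile(
    r"^(?P<cls>[A-Za-z]+)"
    r"(?:\s+\(OH\))?"
    r"(?:\s+(?P<bond>aa?|ae|e))?"
    r"\s+C(?P<carbons>\d+):(?P<bonds>\d+)$"
)


@dataclass(frozen=True)
class PanelLabel:
    """A parsed targeted-panel designation such as ``LysoPC a C18:1``."""

    class_name: str
    bond_type: str  # "a" or "e"
    hydroxyl: bool
    total_carbons: int
    total_double_bonds: int

    def as_sum_composition(self) -> SumComposition:
        return SumComposition(
            self.class_name, self.bond_type, self.total_carbons, self.total_double_bonds
        )


def parse_panel_label(text: str) -> PanelLabel:
    """Parse the targeted-kit label dialect ("LysoPC a C18:1", "SM (OH) C22:1",
    "PC ae C36:2").  Raises ValueError on unrecognized labels."""
    token = text.strip()
    m = _PANEL_RE.match(token)
    if m is None:
        raise ValueError(f"cannot parse panel label {token!r}")
    bond = m.group("bond") or "a"
    return PanelLabel(
        class_name=m.group("cls"),
        bond_type="e" if "e" in bond else "a",
        hydroxyl="(OH)" in token,
        total_carbons=int(m.group("carbons")),
        total_double_bonds=int(m.group("bonds")),
    )


def match_platforms(
    groups: Sequence[GroupedDesignation],
    panel: Sequence,
) -> pd.DataFrame:
    """Pair reconstruction groups with targeted-panel rows of equal
    class/bond-type/carbons/double-bonds.

    ``panel`` rows need ``name``, ``mean`` and ``sd`` attributes (e.g.
    :class:`clrlipid.registry.CompoundRecord` with one concentration, or any
    namedtuple).  Unparsable panel names are logged and skipped.  Returns a
    table with columns designation, panel_mean_uM, panel_sd_uM, clr_total_uM,
    status in {matched, panel_only, clr_only}.
    """
    by_designation = {g.designation: g for g in groups}
    rows = []
    seen: set[SumComposition] = set()
    for rec in panel:
        name = getattr(rec, "name")
        try:
            label = parse_panel_label(name)
        except ValueError:
            logger.warning("skipping unparsable panel label %r", name)
            continue
        key = label.as_sum_composition()
        group = by_designation.get(key)
        if group is not None:
            seen.add(key)
        rows.append(
            {
                "designation": key.label,
                "panel_mean_uM": getattr(rec, "mean", None),
                "panel_sd_uM": getattr(rec, "sd", None),
                "clr_total_uM": None if group is None else group.total_most_probable,
                "status": "matched" if group is not None else "panel_only",
            }
        )
    for g in groups:
        if g.designation not in seen:
            rows.append(
                {
                    "designation": g.designation.label,
                    "panel_mean_uM": None,
                    "panel_sd_uM": None,
                    "clr_total_uM": g.total_most_probable,
                    "status": "clr_only",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["designation", "panel_mean_uM", "panel_sd_uM", "clr_total_uM", "status"],
    )
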