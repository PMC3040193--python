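"""Acyl-chain shorthand and lipid-class data model.

Fatty-acid chains are written in the GC-FID shorthand dialect used throughout
this package: an optional ``C`` prefix (or ``dm`` for plasmalogen /
dimethylacetal-derived chains), a ``carbons:double_bonds`` core, an optional
omega-series tag (``n3``, ``n6``, ``n7``, ``n9``, ...) and an optional trailing
geometry descriptor that is preserved verbatim (``t`` for trans, CLA-style
positional annotations, ...).  Examples: ``C16:0``, ``C18:1n9``, ``C16:1n7t``,
``dm18:1n9``, ``C18:2(9c/t,11t)-CLA``.

Omega tags and geometry descriptors are identity-bearing: ``C18:1n7`` and
``C18:1n9`` are distinct chains even though they collapse to the same sum
composition.  Positional double-bond isomers are not modelled beyond the
verbatim descriptor.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping, Optional

__all__ = [
    "ChainParseError",
    "AcylChain",
    "parse_chain",
    "LipidClassSpec",
    "BUILTIN_CLASSES",
    "get_class",
    "SpeciesComposition",
    "SumComposition",
    "sum_composition_of",
]


class ChainParseError(ValueError):
    """Raised when a chain-shorthand token cannot be interpreted."""


_CHAIN_RE = re.compile(
    r"^(?P<prefix>dm|C)?(?P<carbons>\d+):(?P<bonds>\d+)(?P<omega>n\d+)?(?P<rest>.*)$"
)


@total_ordering
@dataclass(frozen=True)
class AcylChain:
    """One fatty-acid chain: carbon count, unsaturation, series and linkage."""

    carbons: int
    double_bonds: int
    omega_series: Optional[int] = None
    linkage: str = "acyl"  # "acyl" or "plasmalogen"
    geometry_note: str = ""

    def __post_init__(self) -> None:
        if self.linkage not in ("acyl", "plasmalogen"):
            raise ChainParseError(f"unknown linkage {self.linkage!r}")
        if self.double_bonds < 0:
            raise ChainParseError("double bond count cannot be negative")
        if self.double_bonds > self.carbons:
            raise ChainParseError(
                f"C{self.carbons}:{self.double_bonds}: more double bonds than carbons"
            )
        if self.carbons < 2:
            raise ChainParseError(f"chain needs at least 2 carbons, got {self.carbons}")

    @property
    def canonical(self) -> str:
        prefix = "dm" if self.linkage == "plasmalogen" else "C"
        omega = f"n{self.omega_series}" if self.omega_series is not None else ""
        return f"{prefix}{self.carbons}:{self.double_bonds}{omega}{self.geometry_note}"

    def __str__(self) -> str:
        return self.canonical

    def __lt__(self, other: "AcylChain") -> bool:
        return self.canonical < other.canonical


def parse_chain(text: str) -> AcylChain:
    """Parse a chain-shorthand token such as ``C20:4n6`` or ``dm16:0``.

    The leading ``C`` is optional; ``dm`` marks plasmalogen linkage.  Anything
    after the omega tag (e.g. ``t``, ``(9c/t,11t)-CLA``) is kept verbatim in
    :attr:`AcylChain.geometry_note`.
    """
    token = text.strip()
    if not token:
        raise ChainParseError("empty chain token")
    m = _CHAIN_RE.match(token)
    if m is None:
        raise ChainParseError(f"cannot parse chain token {token!r}: no 'x:y' core")
    omega = m.group("omega")
    try:
        return AcylChain(
            carbons=int(m.group("carbons")),
            double_bonds=int(m.group("bonds")),
            omega_series=int(omega[1:]) if omega else None,
            linkage="plasmalogen" if m.group("prefix") == "dm" else "acyl",
            geometry_note=m.group("rest") or "",
        )
    except ChainParseError as exc:
        raise ChainParseError(f"{token!r}: {exc}") from None


@dataclass(frozen=True)
class LipidClassSpec:
    """A lipid class: its name, number of acyl positions k, and whether
    sn-position permutations are distinguishable structures."""

    name: str
    acyl_positions: int
    positional: bool = False

    def __post_init__(self) -> None:
        if self.acyl_positions < 1:
            raise ValueError("a lipid class needs at least one acyl position")


#: The seven classes resolved by TLC class separation of serum lipids.
BUILTIN_CLASSES: dict[str, LipidClassSpec] = {
    "CE": LipidClassSpec("CE", 1),
    "FFA": LipidClassSpec("FFA", 1),
    "LysoPC": LipidClassSpec("LysoPC", 1),
    "PC": LipidClassSpec("PC", 2, positional=True),
    "PE": LipidClassSpec("PE", 2, positional=True),
    "DG": LipidClassSpec("DG", 2, positional=True),
    "TG": LipidClassSpec("TG", 3, positional=True),
}


def get_class(name: str) -> LipidClassSpec:
    """Look up a built-in lipid class by name (case-sensitive)."""
    try:
        return BUILTIN_CLASSES[name]
    except KeyError:
        raise KeyError(
            f"unknown lipid class {name!r}; built-ins are {sorted(BUILTIN_CLASSES)}"
        ) from None


@total_ordering
@dataclass(frozen=True)
class SpeciesComposition:
    """An intact lipid species: a class and a multiset of k acyl chains.

    ``chains`` is stored sorted by canonical string unless ``ordered`` is set,
    in which case the tuple represents one sn-resolved structure and the order
    is significant.
    """

    class_name: str
    chains: tuple[AcylChain, ...]
    ordered: bool = False

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a species needs at least one chain")
        if not self.ordered:
            object.__setattr__(self, "chains", tuple(sorted(self.chains)))

    @property
    def k(self) -> int:
        return len(self.chains)

    @property
    def chain_counts(self) -> Counter[AcylChain]:
        return Counter(self.chains)

    @property
    def canonical(self) -> str:
        return "/".join(c.canonical for c in self.chains)

    def __str__(self) -> str:
        return f"{self.class_name}({self.canonical})"

    def __lt__(self, other: "SpeciesComposition") -> bool:
        return (self.class_name, self.canonical) < (other.class_name, other.canonical)


@dataclass(frozen=True)
class SumComposition:
    """Shotgun-style designation: class, acyl/ether bond type, total carbons
    and total double bonds, e.g. PC(38:4)."""

    class_name: str
    bond_type: str  # "a" diacyl/acyl, "e" ether/plasmalogen
    total_carbons: int
    total_double_bonds: int

    def __post_init__(self) -> None:
        if self.bond_type not in ("a", "e"):
            raise ValueError("bond_type must be 'a' or 'e'")

    @property
    def label(self) -> str:
        ether = "e" if self.bond_type == "e" else ""
        return f"{self.class_name}({ether}{self.total_carbons}:{self.total_double_bonds})"

    def __str__(self) -> str:
        return self.label


def sum_composition_of(
    comp: SpeciesComposition, *, plasmalogen_as_acyl: bool = False
) -> SumComposition:
    """Collapse a species to its sum composition (totals over the multiset).

    Any plasmalogen chain marks the designation ``bond_type="e"`` unless
    ``plasmalogen_as_acyl`` groups it under the acyl ("a") designation.
    """
    has_ether = any(c.linkage == "plasmalogen" for c in comp.chains)
    return SumComposition(
        class_name=comp.class_name,
        bond_type="e" if (has_ether and not plasmalogen_as_acyl) else "a",
        total_carbons=sum(c.carbons for c in comp.chains),
        total_double_bonds=sum(c.double_bonds for c in comp.chains),
    )
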