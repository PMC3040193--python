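"""Literature-value parsing and platform agreement classification.

Reference tables print literature concentrations in several coexisting
dialects: ``60.0±20.0`` (mean ± sd), ``54; (8–80)`` (mean with a range),
``21.0–150.0`` (range only) and NA markers.  These are parsed into a common
:class:`LiteratureValue`, and a measured mean is classified against it by the
one-standard-deviation rule: agreement means the measured value falls within
one sd of the literature mean (or inside the printed range when only a range
is given).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .registry import CompoundRecord, canonical_names

__all__ = [
    "LiteratureValue",
    "parse_literature_value",
    "classify_agreement",
    "concordance_table",
]

_NA_MARKERS = {"na", "nd", "not available", ""}

# numbers like 60, 60.0, .5  (no exponents occur in the printed dialects)
_NUM = r"[0-9]*\.?[0-9]+"
# ± appears as "±", "+/-" or "+/−" (with a unicode minus); ranges use "–" or "-"
_PM = r"(?:±|\+/[-−])"
_DASH = r"[–\-]"

_MEAN_SD_RE = re.compile(rf"^(?P<mean>{_NUM})\s*{_PM}\s*(?P<sd>{_NUM})$")
_MEAN_RANGE_RE = re.compile(
    rf"^(?P<mean>{_NUM})\s*;?\s*\(\s*(?P<lo>{_NUM})\s*{_DASH}\s*(?P<hi>{_NUM})\s*\)$"
)
_RANGE_RE = re.compile(rf"^(?P<lo>{_NUM})\s*{_DASH}\s*(?P<hi>{_NUM})$")
_MEAN_ONLY_RE = re.compile(rf"^(?P<mean>{_NUM})$")


@dataclass(frozen=True)
class LiteratureValue:
    """A parsed literature concentration: mean and/or range, plus the verbatim
    source string."""

    mean: Optional[float] = None
    sd: Optional[float] = None
    range_low: Optional[float] = None
    range_high: Optional[float] = None
    raw: str = ""

    def __post_init__(self) -> None:
        if (self.range_low is None) != (self.range_high is None):
            raise ValueError("range needs both endpoints")
        if self.range_low is not None and self.range_low > self.range_high:
            raise ValueError("range_low must not exceed range_high")

    @property
    def is_missing(self) -> bool:
        return self.mean is None and self.range_low is None

    def format(self) -> str:
        """Canonical rendering of the value in its own dialect."""
        if self.is_missing:
            return "NA"
        if self.mean is not None and self.sd is not None:
            return f"{self.mean:g}±{self.sd:g}"
        if self.mean is not None and self.range_low is not None:
            return f"{self.mean:g}; ({self.range_low:g}–{self.range_high:g})"
        if self.mean is not None:
            return f"{self.mean:g}"
        return f"{self.range_low:g}–{self.range_high:g}"


def parse_literature_value(text: str) -> LiteratureValue:
    """Parse one literature-value cell; raises ValueError (carrying the raw
    string) on unrecognized patterns."""
    raw = (text or "").strip()
    if raw.lower() in _NA_MARKERS:
        return LiteratureValue(raw=raw)
    m = _MEAN_SD_RE.match(raw)
    if m:
        return LiteratureValue(mean=float(m["mean"]), sd=float(m["sd"]), raw=raw)
    m = _MEAN_RANGE_RE.match(raw)
    if m:
        return LiteratureValue(
            mean=float(m["mean"]),
            range_low=float(m["lo"]),
            range_high=float(m["hi"]),
            raw=raw,
        )
    m = _RANGE_RE.match(raw)
    if m:
        lo, hi = float(m["lo"]), float(m["hi"])
        # a bare "a-b" with a > b cannot be a range; reject rather than guess
        if lo > hi:
            raise ValueError(f"unrecognized literature value {raw!r}")
        return LiteratureValue(range_low=lo, range_high=hi, raw=raw)
    m = _MEAN_ONLY_RE.match(raw)
    if m:
        return LiteratureValue(mean=float(m["mean"]), raw=raw)
    raise ValueError(f"unrecognized literature value {raw!r}")


def classify_agreement(measured_mean: float, reference: LiteratureValue) -> str:
    """Classify a measured mean against a literature value.

    With an sd: agree iff |measured − mean| ≤ sd, otherwise higher/lower by
    the sign of the difference.  With a range (printed ranges are used even
    when a mean is also present, since they need not equal mean ± sd): agree
    iff inside [low, high].  With a bare mean: agree only on equality.  With
    nothing: undetermined.
    """
    if measured_mean < 0:
        raise ValueError("measured mean must be non-negative")
    if reference.mean is not None and reference.sd is not None:
        if abs(measured_mean - reference.mean) <= reference.sd:
            return "agree"
        return "higher" if measured_mean > reference.mean else "lower"
    if reference.range_low is not None:
        if reference.range_low <= measured_mean <= reference.range_high:
            return "agree"
        return "higher" if measured_mean > reference.range_high else "lower"
    if reference.mean is not None:
        if measured_mean == reference.mean:
            return "agree"
        return "higher" if measured_mean > reference.mean else "lower"
    return "undetermined"


def concordance_table(
    registry: Sequence[CompoundRecord],
    platform_a: str,
    platform_b: str,
    synonyms: Optional[Mapping[str, str]] = None,
    merge_rules: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Pair concentrations of compounds measured by two platforms.

    Combined analytes that one platform cannot resolve (e.g. a kit reporting
    leucine and isoleucine as one value) are handled by ``merge_rules``
    mapping the combined name to its components: the other platform's
    component means are summed (sds added in quadrature) before comparison.
    Returns columns name, mean_a, sd_a, mean_b, sd_b, ratio_a_b, agreement,
    where agreement classifies mean_a against mean_b ± sd_b.
    """
    syn = dict(synonyms or {})
    merge = {k.lower(): tuple(v) for k, v in (merge_rules or {}).items()}

    def entries_by_name(platform: str) -> dict[str, tuple[float, Optional[float]]]:
        out: dict[str, tuple[float, Optional[float]]] = {}
        for rec in registry:
            if platform not in rec.platform_detections:
                continue
            for entry in rec.concentrations:
                key = rec.name.strip().lower()
                key = syn.get(key, key)
                out.setdefault(key, (entry.mean_uM, entry.sd))
        return out

    def resolve(
        name: str, table: Mapping[str, tuple[float, Optional[float]]]
    ) -> Optional[tuple[float, Optional[float]]]:
        key = syn.get(name.lower(), name.lower())
        if key in table:
            return table[key]
        components = merge.get(name.lower())
        if components:
            parts = [resolve(c, table) for c in components]
            if any(p is None for p in parts):
                return None
            mean = sum(p[0] for p in parts)
            sds = [p[1] for p in parts]
            sd = None if any(s is None for s in sds) else sum(s**2 for s in sds) ** 0.5
            return mean, sd
        return None

    a_entries = entries_by_name(platform_a)
    b_entries = entries_by_name(platform_b)

    # names as reported by platform b (the reference side), plus merge-rule
    # combined names so an unresolved kit analyte still finds its partners
    rows = []
    seen: set[str] = set()
    for rec in registry:
        if platform_b not in rec.platform_detections or not rec.concentrations:
            continue
        name = rec.name.strip()
        if name.lower() in seen:
            continue
        seen.add(name.lower())
        b_val = resolve(name, b_entries)
        a_val = resolve(name, a_entries)
        if a_val is None and "+" in name:
            # sum the components on side a for a combined side-b analyte
            components = [p.strip() for p in name.split("+")]
            a_val = resolve(name, a_entries) or _sum_components(
                components, a_entries, syn
            )
        if a_val is None or b_val is None:
            continue
        mean_a, sd_a = a_val
        mean_b, sd_b = b_val
        rows.append(
            {
                "name": name,
                "mean_a": mean_a,
                "sd_a": sd_a,
                "mean_b": mean_b,
                "sd_b": sd_b,
                "ratio_a_b": mean_a / mean_b if mean_b else float("nan"),
                "agreement": classify_agreement(
                    mean_a, LiteratureValue(mean=mean_b, sd=sd_b)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "mean_a", "sd_a", "mean_b", "sd_b", "ratio_a_b", "agreement"],
    )


def _sum_components(components, table, syn):
    parts = []
    for comp in components:
        key = syn.get(comp.lower(), comp.lower())
        if key not in table:
            return None
        parts.append(table[key])
    mean = sum(p[0] for p in parts)
    sds = [p[1] for p in parts]
    sd = None if any(s is None for s in sds) else sum(s**2 for s in sds) ** 0.5
    return mean, sd
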