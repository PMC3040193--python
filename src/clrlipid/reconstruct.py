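"""Combinatorial lipid reconstruction.

Given the fractional abundance f_i of each fatty-acid chain within one lipid
class (measured after class separation and hydrolysis) and the total class
concentration C, the intact species of a class with k acyl positions are
enumerated combinatorially and two concentration estimates are attached to
each species S with chain multiplicities n_i:

* most probable   MP(S) = C * (k! / prod n_i!) * prod f_i**n_i
  — the multinomial expectation under independent random assembly of chains;
* upper limit     UL(S) = C * min(1, min_i k*f_i / n_i)
  — the concentration at which the scarcest chain of S is exhausted, i.e. the
  maximum consistent with chain balance when no competing species consumes
  that chain.

The upper limit has an equivalent linear-programming formulation (maximise
x_S subject to the chain-balance equalities sum_S n_i(S) x_S = k*f_i*C and
x >= 0) which is kept as an independent oracle in
:func:`upper_limit_lp`.

Fractional abundances are on the acyl-chain mole basis: a class at total
concentration C carries k*C chain equivalents, so chain balance reads
sum_S n_i(S) x_S = k * f_i * C for every chain i.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .chains import AcylChain, LipidClassSpec, SpeciesComposition

__all__ = [
    "ProfileError",
    "AcylProfile",
    "ReconstructedSpecies",
    "ReconstructionOptions",
    "normalize_profile",
    "enumerate_species",
    "most_probable",
    "upper_limit",
    "upper_limit_lp",
    "reconstruct_class",
]


class ProfileError(ValueError):
    """Invalid acyl profile (negative, all-zero, or inconsistent entries)."""


@dataclass(frozen=True)
class AcylProfile:
    """Per-class chain abundances plus the total class concentration.

    ``entries`` maps each chain to either a chain amount (µM, acyl-chain
    basis) or an already-normalized fractional abundance f_i; ``class_total``
    is the class concentration C in µM.
    """

    class_spec: LipidClassSpec
    entries: Mapping[AcylChain, float]
    class_total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        if self.class_total < 0:
            raise ProfileError("class total must be non-negative")
        for chain, amount in self.entries.items():
            if amount < 0:
                raise ProfileError(f"negative amount for chain {chain}")

    @property
    def chains(self) -> tuple[AcylChain, ...]:
        return tuple(sorted(self.entries))

    def is_normalized(self, tol: float = 1e-9) -> bool:
        total = sum(self.entries.values())
        return math.isclose(total, 1.0, rel_tol=tol, abs_tol=tol)


def normalize_profile(profile: AcylProfile, *, tol: float = 1e-9) -> AcylProfile:
    """Rescale entries so the fractional abundances sum to one.

    Idempotent; the class total is untouched.  Raises :class:`ProfileError`
    when every entry is zero.
    """
    total = sum(profile.entries.values())
    if total <= 0:
        raise ProfileError("profile has no positive chain amounts")
    if math.isclose(total, 1.0, rel_tol=tol, abs_tol=tol):
        return profile
    return replace(
        profile, entries={c: a / total for c, a in profile.entries.items()}
    )


def enumerate_species(
    class_spec: LipidClassSpec,
    chains: Sequence[AcylChain],
    *,
    mode: str = "multiset",
) -> list[SpeciesComposition]:
    """Enumerate the candidate species of a class over a chain pool.

    ``multiset`` mode returns one composition per distinct multiset of size k
    (C(n+k-1, k) of them); ``ordered`` mode returns every sn-resolved tuple
    (n**k of them).  Output is in lexicographic canonical order.
    """
    if not chains:
        raise ValueError("chain pool is empty")
    if len(set(chains)) != len(chains):
        raise ValueError("chain pool contains duplicates")
    pool = sorted(chains)
    k = class_spec.acyl_positions
    if mode == "multiset":
        combos = itertools.combinations_with_replacement(pool, k)
        return [SpeciesComposition(class_spec.name, tup) for tup in combos]
    if mode == "ordered":
        return [
            SpeciesComposition(class_spec.name, tup, ordered=True)
            for tup in itertools.product(pool, repeat=k)
        ]
    raise ValueError(f"unknown enumeration mode {mode!r}")


def _check_membership(profile: AcylProfile, comp: SpeciesComposition) -> None:
    if comp.class_name != profile.class_spec.name:
        raise ProfileError(
            f"species class {comp.class_name!r} does not match profile class "
            f"{profile.class_spec.name!r}"
        )
    for chain in comp.chain_counts:
        if chain not in profile.entries:
            raise ProfileError(f"chain {chain} absent from profile")


def most_probable(profile: AcylProfile, comp: SpeciesComposition) -> float:
    """Most-probable concentration of one species (µM).

    For a multiset composition this is the multinomial term
    C * (k!/prod n_i!) * prod f_i**n_i; for an ordered (sn-resolved)
    structure it is C * prod f_i over the tuple, so the ordered structures of
    one multiset sum to its multiset value.
    """
    _check_membership(profile, comp)
    f = profile.entries
    C = profile.class_total
    if comp.ordered:
        p = 1.0
        for chain in comp.chains:
            p *= f[chain]
        return C * p
    k = comp.k
    coeff = math.factorial(k)
    p = 1.0
    for chain, n in comp.chain_counts.items():
        coeff //= math.factorial(n)
        p *= f[chain] ** n
    return C * coeff * p


def upper_limit(profile: AcylProfile, comp: SpeciesComposition) -> float:
    """Upper-limit concentration of one species (µM): the level at which its
    scarcest chain is exhausted, capped at the class total."""
    _check_membership(profile, comp)
    k = comp.k
    C = profile.class_total
    ratio = min(k * profile.entries[chain] / n for chain, n in comp.chain_counts.items())
    return C * min(1.0, ratio)


def upper_limit_lp(profile: AcylProfile, comp: SpeciesComposition) -> float:
    """Upper limit via the chain-balance linear program (independent oracle).

    Maximises the target species' concentration over all non-negative species
    mixtures satisfying sum_S n_i(S) x_S = k*f_i*C for every profiled chain i.
    """
    _check_membership(profile, comp)
    k = profile.class_spec.acyl_positions
    C = profile.class_total
    chains = profile.chains
    species = enumerate_species(profile.class_spec, chains, mode="multiset")
    index = {s.canonical: j for j, s in enumerate(species)}
    target = SpeciesComposition(comp.class_name, comp.chains)  # multiset view
    if target.canonical not in index:
        raise ProfileError(f"target {target} not enumerable from the profile chains")

    a_eq = np.zeros((len(chains), len(species)))
    for j, s in enumerate(species):
        for i, chain in enumerate(chains):
            a_eq[i, j] = s.chain_counts.get(chain, 0)
    b_eq = np.array([k * profile.entries[c] * C for c in chains])
    cost = np.zeros(len(species))
    cost[index[target.canonical]] = -1.0
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise ProfileError(f"chain-balance LP infeasible: {res.message}")
    return float(-res.fun)


@dataclass(frozen=True)
class ReconstructedSpecies:
    """One reconstructed species with its concentration estimates (µM)."""

    composition: SpeciesComposition
    most_probable: float
    upper_limit: float
    status: str = "probable"


@dataclass(frozen=True)
class ReconstructionOptions:
    """Knobs for :func:`reconstruct_class`.

    ``report_mode`` selects multiset (one record per distinct composition,
    default) or ordered (sn-resolved) reporting.  ``top_n``/``min_mp``
    truncate the sorted output; truncation is applied last.
    ``keep_zero_chains`` retains zero-abundance chains, which generate only
    zero-MP species but remain addressable for upper-limit queries.
    """

    report_mode: str = "multiset"
    top_n: Optional[int] = None
    min_mp: Optional[float] = None
    normalization_tolerance: float = 1e-9
    keep_zero_chains: bool = False

    def __post_init__(self) -> None:
        if self.report_mode not in ("multiset", "ordered"):
            raise ValueError(f"unknown report_mode {self.report_mode!r}")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def reconstruct_class(
    profile: AcylProfile,
    options: ReconstructionOptions | None = None,
) -> list[ReconstructedSpecies]:
    """Normalize, enumerate and estimate MP/UL for every species of a class.

    Results are sorted by descending MP with lexicographic tie-breaking, then
    truncated per the options.  Upper limits are always computed on the
    multiset view of a composition (sn position does not change which chain
    runs out first).
    """
    opts = options or ReconstructionOptions()
    profile = normalize_profile(profile, tol=opts.normalization_tolerance)
    if not opts.keep_zero_chains:
        entries = {c: f for c, f in profile.entries.items() if f > 0}
        profile = replace(profile, entries=entries)
    species = enumerate_species(
        profile.class_spec, profile.chains, mode=opts.report_mode
    )
    out = [
        ReconstructedSpecies(
            composition=comp,
            most_probable=most_probable(profile, comp),
            upper_limit=upper_limit(profile, comp),
        )
        for comp in species
    ]
    out.sort(key=lambda r: (-r.most_probable, r.composition.canonical))
    if opts.min_mp is not None:
        out = [r for r in out if r.most_probable >= opts.min_mp]
    if opts.top_n is not None:
        out = out[: opts.top_n]
    return out
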