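"""Ground-truth lipid mixtures and the forward model of chain profiling.

A :class:`TrueMixture` is a known composition of intact species; hydrolysing
it and measuring the freed chains corresponds to :func:`derive_profile`,
which computes the chain fractional abundances

    f_i = sum_S n_i(S) * x_S / (k * sum_S x_S)

and the class total.  Reconstruction from the derived profile can then be
validated against the known truth (upper limits must dominate the true
species concentrations; a mixture that is itself the multinomial mixture of
its profile is recovered exactly by the most-probable estimate).

All randomness flows through a single seed; no global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chains import AcylChain, LipidClassSpec, SpeciesComposition
from .reconstruct import AcylProfile, enumerate_species, most_probable

__all__ = ["TrueMixture", "simulate_mixture", "derive_profile", "multinomial_mixture"]


@dataclass(frozen=True)
class TrueMixture:
    """Known species concentrations (µM) for one lipid class."""

    class_spec: LipidClassSpec
    species_concentrations: Mapping[SpeciesComposition, float]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "species_concentrations", dict(self.species_concentrations)
        )
        if not self.species_concentrations:
            raise ValueError("mixture has no species")
        for comp, conc in self.species_concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {comp}")
            if comp.k != self.class_spec.acyl_positions:
                raise ValueError(f"{comp} does not fit class {self.class_spec.name}")

    @property
    def total(self) -> float:
        return sum(self.species_concentrations.values())


def simulate_mixture(
    class_spec: LipidClassSpec,
    chains: Sequence[AcylChain],
    n_species: int,
    total: float,
    seed: int,
    abundance_model: str = "lognormal",
) -> TrueMixture:
    """Draw a reproducible random mixture of ``n_species`` distinct species.

    Species are sampled without replacement from the full multiset
    enumeration; abundances come from the named model (``lognormal`` with
    sigma=1, or flat ``dirichlet``) and are scaled to ``total``.
    """
    candidates = enumerate_species(class_spec, chains, mode="multiset")
    if n_species < 1 or n_species > len(candidates):
        raise ValueError(
            f"n_species must be in [1, {len(candidates)}], got {n_species}"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(candidates), size=n_species, replace=False)
    if abundance_model == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_species)
    elif abundance_model == "dirichlet":
        weights = rng.dirichlet(np.ones(n_species))
    else:
        raise ValueError(f"unknown abundance model {abundance_model!r}")
    weights = weights / weights.sum() * total
    return TrueMixture(
        class_spec=class_spec,
        species_concentrations={
            candidates[i]: float(w) for i, w in zip(chosen_idx, weights)
        },
        seed=seed,
    )


def derive_profile(mixture: TrueMixture) -> AcylProfile:
    """Forward model of class-separated hydrolysis + chain quantification:
    the acyl profile a chain-level assay would measure on the mixture."""
    k = mixture.class_spec.acyl_positions
    total = mixture.total
    if total <= 0:
        raise ValueError("mixture total must be positive")
    chain_amounts: dict[AcylChain, float] = {}
    for comp, conc in mixture.species_concentrations.items():
        for chain, n in comp.chain_counts.items():
            chain_amounts[chain] = chain_amounts.get(chain, 0.0) + n * conc
    entries = {c: amt / (k * total) for c, amt in chain_amounts.items()}
    return AcylProfile(
        class_spec=mixture.class_spec, entries=entries, class_total=total
    )


def multinomial_mixture(profile: AcylProfile) -> TrueMixture:
    """The mixture whose species concentrations are exactly the multinomial
    most-probable values of ``profile`` — a fixed point of reconstruction."""
    from .reconstruct import normalize_profile

    profile = normalize_profile(profile)
    species = enumerate_species(profile.class_spec, profile.chains, mode="multiset")
    return TrueMixture(
        class_spec=profile.class_spec,
        species_concentrations={
            comp: most_probable(profile, comp) for comp in species
        },
    )
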