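"""Reconstruction engine: normalization, enumeration, MP/UL and the LP oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clrlipid import (
    AcylProfile,
    ProfileError,
    ReconstructionOptions,
    acyl_profile_from_lipomics,
    enumerate_species,
    get_class,
    most_probable,
    normalize_profile,
    parse_chain,
    reconstruct_class,
    upper_limit,
    upper_limit_lp,
    SpeciesComposition,
)
from conftest import random_profile

A, B, C3 = (parse_chain(t) for t in ("C16:0", "C18:0", "C20:4n6"))


class TestNormalize:
    def test_proportions(self):
        prof = AcylProfile(get_class("PC"), {A: 30.0, B: 10.0}, 100.0)
        norm = normalize_profile(prof)
        assert norm.entries[A] == pytest.approx(0.75)
        assert norm.entries[B] == pytest.approx(0.25)
        assert norm.class_total == 100.0

    def test_idempotent(self):
        prof = AcylProfile(get_class("PC"), {A: 0.75, B: 0.25}, 100.0)
        assert normalize_profile(prof) is prof

    def test_ffa_column_fractions(self):
        """Fractions of the chain-level FFA table sum to 1 and f(C16:0) equals
        the printed mean over the hand-summed column total."""
        prof = acyl_profile_from_lipomics("FFA")
        norm = normalize_profile(prof)
        assert sum(norm.entries.values()) == pytest.approx(1.0, rel=1e-12)
        hand_total = sum(prof.entries.values())
        assert norm.entries[parse_chain("C16:0")] == pytest.approx(
            66.01 / hand_total, rel=1e-12
        )

    def test_rejects_all_zero(self):
        with pytest.raises(ProfileError):
            normalize_profile(AcylProfile(get_class("PC"), {A: 0.0, B: 0.0}, 10.0))

    def test_rejects_negative(self):
        with pytest.raises(ProfileError):
            AcylProfile(get_class("PC"), {A: -1.0}, 10.0)


class TestEnumerate:
    def test_two_chain_diacyl(self):
        out = enumerate_species(get_class("PC"), [A, B])
        assert [s.canonical for s in out] == [
            "C16:0/C16:0",
            "C16:0/C18:0",
            "C18:0/C18:0",
        ]

    @pytest.mark.parametrize("cls, expected", [("PC", 351), ("TG", 3276)])
    def test_counts_match_brute_force(self, chain_pool, cls, expected):
        spec = get_class(cls)
        out = enumerate_species(spec, chain_pool)
        brute = set(
            itertools.combinations_with_replacement(
                sorted(chain_pool), spec.acyl_positions
            )
        )
        assert len(out) == len(brute) == expected

    def test_ordered_count(self):
        out = enumerate_species(get_class("PC"), [A, B, C3], mode="ordered")
        assert len(out) == 3**2
        assert len(set(out)) == 9

    def test_duplicate_chains_rejected(self):
        with pytest.raises(ValueError):
            enumerate_species(get_class("PC"), [A, A])


class TestMostProbable:
    def test_single_position_class(self):
        prof = AcylProfile(get_class("FFA"), {A: 0.6, B: 0.4}, 10.0)
        assert most_probable(prof, SpeciesComposition("FFA", (A,))) == pytest.approx(6.0)

    def test_even_split_matches_ordered_sum(self):
        """Multiset MP equals the sum over its ordered structures (oracle)."""
        prof = AcylProfile(get_class("PC"), {A: 0.5, B: 0.5}, 100.0)
        ab = SpeciesComposition("PC", (A, B))
        aa = SpeciesComposition("PC", (A, A))
        assert most_probable(prof, ab) == pytest.approx(50.0)
        assert most_probable(prof, aa) == pytest.approx(25.0)
        # explicit ordered-tuple oracle
        from collections import Counter

        for comp in (ab, aa):
            ordered_sum = sum(
                100.0 * prof.entries[x] * prof.entries[y]
                for x, y in itertools.product([A, B], repeat=2)
                if Counter((x, y)) == comp.chain_counts
            )
            assert most_probable(prof, comp) == pytest.approx(ordered_sum)

    def test_degenerate_profile(self):
        prof = AcylProfile(get_class("TG"), {A: 1.0}, 7.0)
        assert most_probable(prof, SpeciesComposition("TG", (A, A, A))) == pytest.approx(7.0)

    def test_missing_chain_rejected(self):
        prof = AcylProfile(get_class("PC"), {A: 1.0}, 7.0)
        with pytest.raises(ProfileError):
            most_probable(prof, SpeciesComposition("PC", (A, B)))


class TestUpperLimit:
    def test_no_limiting_chain(self):
        prof = AcylProfile(get_class("PC"), {A: 1.0}, 50.0)
        assert upper_limit(prof, SpeciesComposition("PC", (A, A))) == pytest.approx(50.0)

    def test_skewed_profile(self, toy_profile):
        aa = SpeciesComposition("PC", (A, A))
        ab = SpeciesComposition("PC", (A, B))
        bb = SpeciesComposition("PC", (B, B))
        assert upper_limit(toy_profile, aa) == pytest.approx(10.0)
        assert upper_limit(toy_profile, ab) == pytest.approx(20.0)
        assert upper_limit(toy_profile, bb) == pytest.approx(90.0)

    def test_triacyl_mixed_multiplicity(self):
        prof = AcylProfile(get_class("TG"), {A: 0.5, B: 0.5}, 10.0)
        aab = SpeciesComposition("TG", (A, A, B))
        assert upper_limit(prof, aab) == pytest.approx(7.5)

    def test_lp_hand_solved_case(self):
        prof = AcylProfile(get_class("PC"), {A: 0.5, B: 0.5}, 100.0)
        aa = SpeciesComposition("PC", (A, A))
        assert upper_limit_lp(prof, aa) == pytest.approx(50.0, rel=1e-6)

    def test_lp_equality_forced_for_k1(self):
        prof = AcylProfile(get_class("FFA"), {A: 0.6, B: 0.4}, 10.0)
        sp = SpeciesComposition("FFA", (A,))
        assert upper_limit_lp(prof, sp) == pytest.approx(6.0, rel=1e-9)

    @pytest.mark.parametrize("k_cls, n_chains", [("PC", 4), ("TG", 4), ("PC", 6)])
    def test_lp_matches_closed_form_random(self, chain_pool, k_cls, n_chains):
        """LP optimum equals the limiting-chain closed form on random profiles."""
        rng = np.random.default_rng(11)
        spec = get_class(k_cls)
        chains = chain_pool[:n_chains]
        for _ in range(25):
            prof = random_profile(rng, spec, chains)
            prof = normalize_profile(prof)
            for comp in enumerate_species(spec, chains):
                closed = upper_limit(prof, comp)
                lp = upper_limit_lp(prof, comp)
                assert lp == pytest.approx(closed, rel=1e-6, abs=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    total=st.floats(0.1, 1000.0),
    k_name=st.sampled_from(["FFA", "PC", "TG"]),
)
def test_bound_dominance_property(weights, total, k_name):
    """0 <= MP(S) <= UL(S) <= C for every enumerated species."""
    spec = get_class(k_name)
    chains = [parse_chain(f"C{12 + 2 * i}:0") for i in range(len(weights))]
    prof = normalize_profile(AcylProfile(spec, dict(zip(chains, weights)), total))
    for comp in enumerate_species(spec, chains):
        mp = most_probable(prof, comp)
        ul = upper_limit(prof, comp)
        assert 0.0 <= mp <= ul * (1 + 1e-12)
        assert ul <= total * (1 + 1e-12)


class TestReconstructClass:
    def test_identity_on_single_chain_class(self):
        prof = acyl_profile_from_lipomics("FFA")
        out = reconstruct_class(prof)
        assert len(out) == 27
        by_chain = {r.composition.chains[0]: r for r in out}
        for chain, amount in prof.entries.items():
            assert by_chain[chain].most_probable == pytest.approx(amount, rel=1e-12)
            assert by_chain[chain].status == "probable"

    def test_mp_sums_to_class_total(self, chain_pool):
        rng = np.random.default_rng(5)
        prof = random_profile(rng, get_class("PC"), chain_pool)
        out = reconstruct_class(prof)
        assert len(out) == 351
        assert sum(r.most_probable for r in out) == pytest.approx(
            prof.class_total, rel=1e-9
        )

    def test_chain_mass_balance(self, chain_pool):
        rng = np.random.default_rng(6)
        spec = get_class("TG")
        chains = chain_pool[:8]
        prof = normalize_profile(random_profile(rng, spec, chains))
        out = reconstruct_class(prof)
        for chain in chains:
            consumed = sum(
                r.composition.chain_counts.get(chain, 0) * r.most_probable for r in out
            )
            expected = spec.acyl_positions * prof.entries[chain] * prof.class_total
            assert consumed == pytest.approx(expected, rel=1e-9)

    def test_ordered_structures_sum_to_multiset(self):
        prof = normalize_profile(
            AcylProfile(get_class("PC"), {A: 0.2, B: 0.3, C3: 0.5}, 60.0)
        )
        multi = reconstruct_class(prof)
        ordered = reconstruct_class(
            prof, ReconstructionOptions(report_mode="ordered")
        )
        totals: dict[str, float] = {}
        for r in ordered:
            key = SpeciesComposition("PC", r.composition.chains).canonical
            totals[key] = totals.get(key, 0.0) + r.most_probable
        for r in multi:
            assert totals[r.composition.canonical] == pytest.approx(
                r.most_probable, rel=1e-12
            )

    def test_sorted_descending_and_truncation(self, chain_pool):
        rng = np.random.default_rng(9)
        prof = random_profile(rng, get_class("TG"), chain_pool)
        full = reconstruct_class(prof)
        mps = [r.most_probable for r in full]
        assert mps == sorted(mps, reverse=True)
        top = reconstruct_class(prof, ReconstructionOptions(top_n=289))
        assert len(top) == 289
        assert [r.composition for r in top] == [r.composition for r in full[:289]]

    def test_zero_chains_dropped_by_default(self):
        prof = AcylProfile(get_class("PC"), {A: 1.0, B: 0.0}, 10.0)
        out = reconstruct_class(prof)
        assert len(out) == 1
        kept = reconstruct_class(prof, ReconstructionOptions(keep_zero_chains=True))
        assert len(kept) == 3
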