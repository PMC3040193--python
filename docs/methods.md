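# Methods

## The reconstruction model

Chain-level lipid profiling (TLC class separation, hydrolysis, GC-FID
quantification of the freed fatty acids) yields, per lipid class, the total
class concentration C (µM) and chain fractional abundances f_i.  Fractions
are taken on the acyl-chain mole basis: a class at concentration C carries
k·C chain equivalents, where k is the number of acyl positions (1 for
cholesterol esters, free fatty acids and lysophosphatidylcholines; 2 for
phosphatidylcholines, phosphatidylethanolamines and diacylglycerols; 3 for
triacylglycerols).  This basis is what makes the chain-balance identities
close exactly:  Σ_S n_i(S)·x_S = k·f_i·C for any species mixture x
consistent with the profile.

**Most probable.**  Under the assumption that chains occupy the k positions
independently with probabilities f_i, the concentration of the multiset
species S with multiplicities n_i is the multinomial term

    MP(S) = C · (k!/Π n_i!) · Π f_i^{n_i}.

Two exact identities follow and are enforced as tests: Σ_S MP(S) = C (total
probability) and Σ_S n_i(S)·MP(S) = k·f_i·C for every chain (mass balance),
both at 1e-9 relative tolerance.  The independence assumption is a modeling
choice, not a fact about biosynthesis — positional preferences (e.g.
saturated chains favouring sn-1) are real and are exactly what this method
cannot see; MP is therefore reported as "probable", never "confirmed".

**Upper limit.**  The maximum concentration of S consistent with chain
balance is reached when no competing species consumes S's scarcest chain:

    UL(S) = C · min(1, min_{i in S} k·f_i / n_i).

This closed form equals the optimum of the linear program max x_S subject to
the chain-balance equalities and x ≥ 0: the cap from each chain i is
k·f_i·C/n_i, and any leftover chain amounts can always be absorbed by
homo-species (x_{ii...i} = r_i/k), so the binding cap is attained.  The LP
(solved with scipy's HiGHS backend) is retained in `upper_limit_lp` purely
as an independent oracle; agreement within 1e-6 relative is checked on 1000
random profiles (the looser tolerance acknowledges that LP solvers are
iterative; measured agreement is at machine precision).

**Multiset vs ordered reporting.**  The default reports one record per
distinct chain multiset.  An ordered (sn-resolved) mode assigns each tuple
C·Π f_i, so the ordered structures of one multiset sum exactly to its
multiset MP; published species tallies that count sn-permutations separately
correspond to this mode.  Upper limits are always computed on the multiset
view — position does not change which chain is exhausted first.

## Parameters and defaults

- `class_total` (µM): required input; profiles without a total are rejected
  rather than defaulted, because chain amounts alone cannot distinguish a
  concentrated small class from a dilute large one.
- `normalization_tolerance` (1e-9 relative): profiles whose entries already
  sum to 1 are passed through unchanged (idempotence).
- Truncation (`top_n`, `min_mp`): disabled by default.  Published tallies
  truncated the triacylglycerol list to the most abundant species without
  stating the rule, so both a count rule and an abundance floor are
  provided and neither is applied silently.
- Zero-abundance chains are dropped before enumeration (they generate only
  zero-MP species); `keep_zero_chains=True` retains them for upper-limit
  queries.
- Sorting is by descending MP with lexicographic canonical-string
  tie-breaking — deterministic across runs and platforms.

## Chain and label grammars

Chain shorthand: optional `C` prefix (or `dm` for plasmalogen /
dimethylacetal-derived chains), `carbons:double_bonds`, optional omega tag
`n<digit>` (n3/n5/n6/n7/n9 all occur in the packaged tables), and a verbatim
trailing descriptor (`t`, `(9c/t,11t)-CLA`).  Omega series and geometry are
identity-bearing: C18:1n7 ≠ C18:1n9 as species, though both collapse to the
same 18:1 sum composition.  The `dm` prefix is treated as ether/plasmalogen
linkage; a plasmalogen chain marks its sum composition as bond type "e", and
folding such species into acyl ("a") designations is an explicit flag
(`include_plasmalogen_in_acyl`), since targeted-kit comparisons have been
printed both ways.  CLA-style positional descriptors are preserved, not
interpreted: double-bond positional isomerism is outside the model.

Panel labels (`LysoPC a C18:1`, `SM (OH) C22:1`, `PC ae C36:2`) use a
separate grammar; the acyl/ether marker and hydroxyl tag are carried as
designation attributes.

## Registry, coverage and concordance conventions

- The coverage denominator (default 4229 = 665 literature + 3564
  experimental compounds) is configuration, not a constant; percentages are
  kept at full precision with half-up display rounding as a separate step.
- Name matching is case-insensitive with a packaged synonym table
  (hexose↔D-glucose, one kit label misspelling, DL-/L-carnitine,
  N-acetyl-glycine↔acetylglycine).  Combined analytes written with `+`
  expand to their components, so a kit reporting leucine+isoleucine as one
  value counts as detecting both; concordance comparisons sum the resolved
  platform's component means (sds combined in quadrature).
- Literature agreement uses the one-standard-deviation rule: within mean±sd
  when an sd is printed.  When a printed range accompanies a mean, the range
  is the agreement interval — ranges in the source tables are not guaranteed
  to equal mean±sd.  A bare mean agrees only on equality; no information
  yields "undetermined".
- Known internal inconsistencies of the source tables (a 50-row panel
  described as 49 compounds; an agreement tally of 35+7+2 over 43; pairwise
  overlap counts that our transcriptions put at 31 rather than 29) are kept
  as documented soft checks, not test assertions.  The three-way
  NMR ∩ GC-MS ∩ kit overlap of 15 (14 amino acids + hexose/glucose) does
  reproduce exactly and is asserted.

## Synthetic mixtures

`simulate_mixture` draws n distinct species uniformly without replacement
from the full enumeration and assigns abundances from a lognormal(σ=1) or
flat Dirichlet model scaled to the class total; all draws flow through one
seed (numpy Generator), with no global random state.  `derive_profile` is
the exact forward model of hydrolysis: f_i = Σ_S n_i(S)·x_S / (k·Σ x_S).
The default chain pool has 26 chains, matching the typical per-sample count
of unique quantified acyl chains in adult serum; the pool is defined
deterministically as the chains of the packaged chain-level table that carry
a complete free-fatty-acid mean ± SD.  What the simulation emulates is the
combinatorial structure of the problem — it does not model instrument noise,
chain-dependent response factors, hydrolysis bias or detection limits, so
passing tests certify the estimator's mathematical properties (conservation,
bounds, recovery of multinomially assembled mixtures), not quantitative
accuracy on real chromatograms.  In particular, upper-limit dominance over
simulated truth holds by construction for any feasible mixture, while
most-probable recovery is exact only when the truth actually is the
multinomial mixture of its own profile.

## Numerical choices and problem sizes

Conservation checks use 1e-9 relative tolerance (sums of products of
double-precision fractions), LP-vs-closed-form 1e-6.  Acceptance
measurements use 30 random profiles for the conservation identities
(classes of 1–3 positions, up to 32 chains), 1000 random profiles of 2–6
chains for the LP cross-check, 500 simulated mixtures of 3–12 chains for
upper-limit dominance and 15 fixed-point mixtures for exact recovery —
sizes chosen to probe every class and pool size generously while keeping a
full run in seconds on one CPU.

## Known limitations

- Positional (sn) preference, double-bond position and stereochemistry are
  outside the model; two platforms can disagree legitimately where those
  matter.
- MP assumes independent assembly; classes with strong positional or
  pairing preferences will be systematically mis-ranked even though the
  aggregate identities still hold.
- The registry's overlap arithmetic is only as good as name normalization;
  the packaged synonym table covers the cases appearing in the bundled
  tables, not general chemical nomenclature.
- Mass computation and full systematic lipid nomenclature are non-goals.
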