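# Methods

## Model

`webstab` treats a mass-balanced food-web snapshot as the equilibrium
X\* of generalized Lotka–Volterra dynamics

dX_i/dt = X_i (r_i − Σ_j a_ij X_j),

augmented by a detritus balance

dX_d/dt = R_d + Σ_j (1−ac_j)·F_j + Σ_i m_i X_i − Σ_j a_dj X_d X_j,

where the pool gains the unassimilated fraction (1−ac) of *all* feeding
(detritivory included), the carcasses of non-predation mortality m_i X_i,
and a constant allochthonous import R_d, and loses what detritivores eat.
Because R_d is density-independent it never enters the Jacobian; it is
reported in the detritus budget only.

Equilibrium feeding rates come from the mass-balance identities: each
consumer's total consumption is F\*_j = (P/B)_j·B_j/e_j, split among prey
by biomass-weighted preference ω_ij·B_i (or taken directly as diet
fractions when the input is an Ecopath diet matrix — both modes are
supported because preferences are the model-native form while fractions
are the common export). Each living group's total mortality (P/B) then
splits into predation M_i/B_i and non-predation m_i ≥ 0; a web where
predation exceeds production is rejected as unbalanced.

### Interaction strengths

Living pairs: α_ij = −F\*_ij/B_j (top-down), α_ji = e_j·F\*_ij/B_i
(bottom-up). The *detritus variant* adds the aggregate effect of each
living group A on the pool,

α_DA = −F\*_DA/B_A + m_A + Σ_K (1−ac_K)·F\*_AK/B_A,

i.e. detritivory, carcass production, and egestion by A's predators K;
for a group that eats no detritus the first term vanishes and the entry
is non-negative. The *grazing variant* keeps only the feeding terms. The
effect of detritus on its consumers is the ordinary bottom-up term in
both variants.

Note the aggregate detritus row is *not* the exact partial derivative of
the detritus balance: differentiation also yields A's own egestion
response (1−ac_A)·F\*_A/B_A, which the three-term aggregate attributes to
A's prey instead. The package implements the aggregate form as its
default (it is the form in which these interaction types are defined) and
exposes the exact derivative behind `full_derivative=True` for
sensitivity analysis; the finite-difference oracle checks both: the
living–living block and detritus column against the default build, the
detritus row against the full-derivative build.

### Sign conventions

The non-predation mortality rate is stored as a magnitude m_i ≥ 0 and
signs are applied at use sites (−s·m_i on the diagonal, +m_i in detritus
gains). This avoids carrying a negative-rate convention through the data
model.

## Stability index

The diagonal is α_ii = −s·m_i for living groups with one dimensionless
strength s shared by all groups. The index S is the minimal s for which
the leading eigenvalue's real part is negative, computed by
order-of-magnitude bracket expansion from s = 1 followed by bisection to
relative width 1e-4 (configurable); |λ_max| at the returned s is reported
alongside the bracket. λ_max within ±1e-10 of zero counts as unstable, so
marginal cases push the index up by at most one tolerance step. Matrices
here are small (≲ 25 groups), so a dense nonsymmetric eigensolver is
used throughout.

Two policies exist for the detritus diagonal, which has no mortality rate
to scale: 0 (default — self-limitation is a property of living
populations) or donor control, −Σ_j F\*_Dj/B_D (the derivative of the
consumption term of the detritus balance).

Structurally decoupled compartments — an entire off-diagonal row or
column of zeros with a zero diagonal, e.g. a detritus pool nobody eats —
make the matrix block-triangular and contribute exact zero eigenvalues
that no diagonal scaling can move. `leading_real_part` splits these off
(exact linear algebra, not an approximation) so such webs are assessed on
their coupled part rather than reported non-stabilizable. Genuine
non-stabilizability (e.g. a destabilizing feedback through groups with
m_i = 0) is detected by a search cap (default 1e6) and raised as an
error.

## Loop weights

A loop of length k is a closed chain of k distinct groups traversed
through nonzero matrix entries; its weight is the geometric mean of the
absolute entry values. The two traversal directions pass through
different entries and are distinct loops; both are enumerated (networkx
simple-cycle search with a length bound, validated against exhaustive
permutation search on small webs), and the tabular report keeps the
heavier direction per group set, labeling it basal-node-first with the
count of negative entries as an orientation flag. MLW defaults to the
length-3 maximum — in energetically derived webs the heaviest feedbacks
are 3-link omnivorous loops, and 2-link predator–prey loops are pure
negative feedback — with an all-lengths option. Category means over a
multi-period table pool every loop × period cell, which is the
convention that reproduces the packaged case-study summary.

## Empirical indicators

BCBP_t is the geometric-mean predator/prey biomass ratio over a pair set;
the default set is every direct trophic link (detritus links included)
because the index is meant to be computable from biomass data alone, and
loop-specific presets (e.g. only the heaviest loop's pairs) can be passed
explicitly. R² is the squared Pearson correlation of untransformed
values. The trend report flags the period at which the identity of the
heaviest loop changes (a structural regime shift) and scores each
indicator's concordance with the required-s trend.

## Synthetic webs

The generator emulates balanced Ecopath outputs for a small lake-like
ecosystem: one detritus pool, a producer layer and (by default) three
consumer layers in cascade order, a biomass pyramid (ratio 0.15 per layer
around a base of 100 mass·area⁻¹, lognormal-ish jitter ±50%), conversion
efficiencies U(0.1, 0.3), unassimilated fraction 0.2, facultative
detritivory (probability 0.5 per consumer, at least one detritivore), and
extra feeding links at connectance 0.3. Balance is guaranteed by
construction, processing layers from the top down: unpreyed groups draw
P/B from a per-layer range declining with trophic level (producers
20–60 yr⁻¹ down to 0.3–1.2 yr⁻¹ at the top); preyed groups set
P/B = (specific predation)·(1 + margin) with margin U(0.05, 1), i.e.
ecotrophic efficiency between 0.5 and 0.95, the consumed fraction typical
of balanced webs. Non-predation mortality is therefore strictly positive
everywhere and interaction strengths land in the ~0.01–1 yr⁻¹ range of
energetically derived community matrices.

Randomness is split over two streams. `structure_seed` draws the
*system*: topology, diet preferences, efficiencies, mortality margins and
top-layer rates. `seed` draws the *snapshot*: standing biomasses (rates
of preyed groups rebalance to them). With `structure_seed` fixed and
`seed` varying, the generator yields repeated survey snapshots of one
parameterized ecosystem — the setting in which the stability index is
actually used, and the design under which the required-s ~ MLW
correlation is tested (mean within-system Pearson r over 10 systems × 20
snapshots). Across structurally unrelated webs that correlation is
confounded and near zero: a web's overall mortality scale inflates the
detritus-row entries (hence MLW) while simultaneously strengthening the
diagonal damping available per unit s — a limitation worth remembering
when comparing S or MLW between different ecosystems rather than through
time.

What the generator does not emulate: multiple detritus pools, fishery
removals (all non-predation loss is "other mortality"), import diets,
seasonal forcing, and empirical diet rewiring between periods. Passing
tests on synthetic webs therefore demonstrate internal consistency of the
estimators and their oracles, not fidelity to any particular lake.

## Dynamical oracle

The ODE system is reconstructed independently of the matrix builder:
per-capita rates a_ij = F\*_ij/(X\*_i·X\*_j), intrinsic rates solved so
the snapshot is an equilibrium (residual < 1e-9 relative by
construction), and the detritus import set to close the budget. Central
finite differences (relative step 1e-6, cross-validated at 10× the step)
recover the Jacobian; the living–living block must match the energetic
entries to 1e-6 at matrix scale. The imposed diagonal −s·m_i is a
matrix-level assumption, not part of the reconstructed energetics, so the
base system's diagonal is excluded from comparisons; simulation-based
stability checks add an explicit self-limitation term
−s·m_i·X_i·(X_i/X\*_i − 1), which vanishes at equilibrium and contributes
exactly −s·m_i to the Jacobian diagonal. Integration uses a
stiff-capable solver (LSODA) with states clipped at zero and clips
reported.

## Case-study fixture

The packaged fixture carries the published loop-weight table of the
Baiyangdian Lake detritus food web — 40 three-link loops × 5 snapshot
years, the per-year maximum loop weight and required s rows — plus the
12-group roster with root categories. The meiofauna abbreviation is
normalized to `Meio` (the source table prints two spellings for the same
group). The per-year biomass/diet/Ecopath source tables are published
only as a supplement; `load_period_tables` ingests user-converted CSV
versions for a full-pipeline rerun, and the test suite exercises that
ingestion path on synthetic stand-ins.

## Numerical and design choices, summarized

- Balance tolerances 1e-9 relative; stability search tolerance 1e-4
  relative on s, cap 1e6; marginal-eigenvalue band ±1e-10 treated as
  unstable.
- Group order is input order everywhere, so matrices, loop labels and
  exports are reproducible; matrix CSVs round-trip bit-exactly.
- BCBP is computed as the product of per-pair ratios^(1/k), making the
  single-pair case identical to the plain biomass ratio.
- Uniform s across groups; per-group s is out of scope. A single detritus
  pool; webs with several are rejected.
- Problem sizes in the shipped tests: webs of 5–14 groups, ensembles of
  100 webs for oracle sweeps and 10 × 20 webs for the correlation
  property — small enough that the full suite runs in seconds while every
  estimator is exercised against an independent oracle.
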