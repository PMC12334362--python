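# webstab

Food-web interaction strengths and local stability from mass-balance
(Ecopath-style) outputs, with explicit species–detritus interactions.

## The problem

Judging whether a lake (or any) food web is locally stable requires the
community matrix — the Jacobian **α** of the multi-species dynamics at
equilibrium, whose entry α<sub>ij</sub> is the effect of group *j* on group
*i*'s growth rate (yr⁻¹). Measuring these interaction strengths directly is
rarely feasible, but they can be estimated from the energy flows that a
balanced Ecopath model already provides: biomass *B*, production/biomass
ratio *P/B*, conversion efficiency *e*, diet composition, and the
unassimilated fraction *ac*. Most such estimates ignore the detritus pool,
even where the detrital pathway carries as much energy as the grazing
pathway. `webstab` builds the Jacobian in both conventions and quantifies
the stability consequences.

## The method

From each feeding rate F\*<sub>ij</sub> (prey *i* → predator *j*,
partitioned from total consumption F\*<sub>j</sub> = (P/B)<sub>j</sub>·B<sub>j</sub>/e<sub>j</sub>
by biomass-weighted preference or by diet fractions):

- top-down: α<sub>ij</sub> = −F\*<sub>ij</sub>/B<sub>j</sub>
- bottom-up: α<sub>ji</sub> = e<sub>j</sub>·F\*<sub>ij</sub>/B<sub>i</sub>

The **detritus variant** adds the three species–detritus interaction
types. A living group feeds the pool through its predators' egestion and
its own non-predation mortality *m*, and (if a detritivore) depletes it by
feeding, so its aggregate effect on detritus is

α<sub>DA</sub> = −F\*<sub>DA</sub>/B<sub>A</sub> + m<sub>A</sub> + Σ<sub>K</sub>(1−ac<sub>K</sub>)·F\*<sub>AK</sub>/B<sub>A</sub>

The **grazing variant** keeps only the feeding links. On either matrix:

- **Required diagonal strength S**: the diagonal is α<sub>ii</sub> = −s·m<sub>i</sub>;
  the minimal uniform *s* making every eigenvalue's real part negative is a
  comparative stability index (smaller = more stable), found by
  order-of-magnitude bracketing plus bisection.
- **Loop-weight analysis**: every closed chain of *k* matrix entries has
  weight |α<sub>i₁i₂</sub>·…·α<sub>iₖi₁</sub>|<sup>1/k</sup>; the maximum
  3-link (omnivorous) loop weight (MLW) approximates the self-limitation
  needed for stability and names the critical interaction.
- **BCBP**: the geometric-mean predator/prey biomass ratio over a set of
  trophic pairs — a biomass-only early-warning proxy for *S*.

## Worked example

```python
from webstab import CommunityStability
from webstab.synth import SynthParams, generate_synthetic_web

web = generate_synthetic_web(SynthParams(seed=1))   # a balanced 12-group web
res = CommunityStability(web, variant="detritus").fit()
print(res.summary())
```

```
Community stability results
===========================
period:                synthetic-1
groups:                12 (9 consumers, 1 detritus pool)
matrix variant:        detritus
required s:            0.205675
lambda_max at s*:      -4.73703e-07 /yr
search bracket:        [0.205661, 0.205675]
eigenvalue solves:     19
max loop weight (k=3): 0.162652
heaviest loop:         C1_2 > Detritus > C2_1
3-link loops:          11
trophic levels:        1 - 3.018
BCBP (all links):      0.0680651
```

Reading: this web needs intraspecific interaction at about 21% of each
group's non-predation mortality rate to be locally stable (required s =
0.206, with the leading eigenvalue just below zero there); the feedback
that carries the heaviest 3-link loop runs through the detritus pool. A
smaller required s — or a lighter maximum loop — would mean a more stable
web. `res.loop_records` lists all 3-link loops with root category and
weight, and `webstab.fit_periods` assembles multi-period indicator series
(required s, MLW, heaviest-loop identity, BCBP, named biomass ratios) with
trend and regime-shift diagnostics.

The published loop-weight table of the Baiyangdian Lake case study (40
three-link loops × 5 snapshot years, with the per-year maximum loop weight
and required *s*) ships as a fixture:

```python
from webstab import byd_fixture, rsquared
fx = byd_fixture()
rsquared(fx.max_loop_weight.to_numpy(), fx.required_s.to_numpy())
# 0.7303807437605144
```

From a shell, the same pipeline runs as `webstab matrix | stability |
loops | report | synth` on CSV/JSON inputs (see `webstab --help`).

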