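# shoalforage

Bout-based models of social foraging in fish shoals: agent simulation,
trajectory analysis, and simulation-based model fitting.

Groups of zebrafish searching for scattered food flakes perform a
stereotyped maneuver when consuming one — a burst of speed followed by a
sharp, high-curvature turn — and neighbors are attracted to the location of
that maneuver. `shoalforage` implements a modeling framework built around
this observation, for researchers in collective animal behavior who want to
simulate, fit, and score social foraging strategies against trajectory
data.

## The model

Each fish is a correlated random walker over discrete swimming **bouts**:
at every time step it draws a step length *L* and a turning angle *θ* from
its empirical (or moment-matched surrogate) bout distributions — defaults
*L* = 2.85 ± 1.7 BL with *θ*-SD 50° for groups of three, 3.1 ± 1.9 BL and
46° for groups of six, in a circular arena of radius 32 BL (body lengths).
Individual foraging: a fish that has a flake within its detection range
*D_f* orients at it with probability `exp(-d_f / D_f)`. Social strategies
add responses to neighbors within the neighbor detection range *D_n*,
applied in a strict per-tick hierarchy:

1. orient to the nearest flake within *D_f* (probability `exp(-d_f/D_f)`);
2. else orient to the nearest location where a neighbor consumed a flake in
   the last τ = 5 ticks, with probability `exp(-d_n/D_n)` (**Att_feed**);
3. else attract to the neighbors' center of mass (**Att**), align with
   their mean heading (**Align**), or both in inner/outer half-zones of
   *D_n* (**Att+Align**), firing with probability `exp(-d_com/D_n)`;
4. else take a random bout.

The seven model variants (IND, Att_feed, Att, Align, Att_feed+Align,
Att+Align, Att_feed+Att+Align) differ only in which of steps 2–3 are
enabled; IND uses neither (*D_n* = 0).

Group-level observables follow the field's standard definitions:
consumption curves `log T_k(n) = n·b_k + a_k` (the consumption-rate slope
*b_k* and first-detection intercept *a_k* fitted by least squares);
polarity `P = ⟨‖(1/N) Σ_i d̂_i‖⟩_t`; cohesion *D_nn* (mean nearest-neighbor
distance); and income equality `1 − I_Theil / log k` from the Theil index
of per-fish consumption counts, ranging from 0 (one fish ate everything) to
1 (full equality). Models are fitted to an observed group by grid search
over (*D_f*, *D_n*), combining a kernel-density likelihood of the observed
consumption-time sequence with normalized errors of polarity and *D_nn*.

## Worked example

Compare independent and social foraging on a single cluster of 18 flakes
(50 repetitions each, groups of three, *D_f* = 3 BL):

```python
import numpy as np
from shoalforage import (SimulationConfig, generate_clustered_field,
                         run_ensemble, fit_consumption_curve,
                         group_polarity_and_cohesion, theil_equality)

field = generate_clustered_field(n_clusters=1, n_flakes=18, seed=7)

for label, model, dn in [("independent", "ind", 0.0),
                         ("social", "att_feed_align", 15.0)]:
    cfg = SimulationConfig(k=3, model=model, df=3.0, dn=dn, seed=7)
    recs = run_ensemble(cfg, field, reps=50, record_trajectory=True)
    mean_times = np.mean([r.consumption_times_s() for r in recs], axis=0)
    fit = fit_consumption_curve(mean_times)
    pol = np.mean([group_polarity_and_cohesion(r).polarity for r in recs])
    eq = np.mean([theil_equality(r.per_agent_counts()).equality for r in recs])
    print(f"{label:>11}: b = {fit.slope:.3f} log-s/flake, "
          f"T(18) = {mean_times[-1]:6.1f} s, polarity = {pol:.2f}, "
          f"equality = {eq:.2f}")
```

Output:

```
independent: b = 0.048 log-s/flake, T(18) =  113.3 s, polarity = 0.54, equality = 0.30
     social: b = 0.022 log-s/flake, T(18) =   74.6 s, polarity = 0.77, equality = 0.64
```

Attraction to neighbors' consumption locations (plus alignment) roughly
halves the consumption-rate slope *b* and the time to finish all 18 flakes,
raises group polarity, and distributes the food far more equally among the
three fish — the central qualitative findings this framework reproduces.

A command-line layer exposes the same operations
(`shoalforage gen-env | gen-synthetic | simulate | stats |
analyze-behavior | fit`); see `shoalforage --help`.

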