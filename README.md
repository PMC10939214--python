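# arenasim

Trophic mass-balance and foraging-arena food-web modelling for
predator–prey–fishery systems, built around the question of how growing
marine-mammal populations, shrinking fisheries, and ocean-productivity
swings jointly reshape the mortality of their prey — the setting is the
northeast Pacific shelf, where recovering pinnipeds and resident killer
whales feed on declining salmon stocks.

The package couples four pieces:

1. **Static mass balance.**  For every functional group *i* the
   production balance
   `(P/B)·B·EE = Y + Σ_j DC_ij·(Q/B)_j·B_j + E + BA·B`
   closes the budget between production, catch `Y`, predation (diet
   fractions `DC` times predator consumption), net migration `E` and
   biomass accumulation `BA`; the ecotrophic efficiency `EE` is the
   modelled share of production, `1 − EE` the unexplained mortality.
   Each group supplies three of {B, P/B, Q/B, EE} and a single linear
   solve fills the fourth, along with the full mortality ledger
   `Z = F + Σ M2 + M0 + BA`.
2. **Monthly time dynamics.**  `dB_i/dt = g_i Σ Q_ji − Σ Q_ij −
   (M0_i + F_i(t))·B_i`, with consumption on each link following the
   foraging-arena form `Q = a·v·B_prey·B_pred / (2v + a·B_pred)`.
   Calibrating `v = x·M2(base)` makes the balanced base an equilibrium
   and caps each link's predation mortality at `x` times its base value —
   the vulnerability multiplier `x` is how far a predator sits below its
   carrying capacity.  Split species (salmon, herring) run as monthly
   age-structured stanzas with von Bertalanffy growth and
   survivorship-distributed biomass.
3. **Time-series fitting.**  A weighted log-scale sum of squares against
   reference biomass and mortality series, minimized by deterministic
   coordinate descent over per-predator vulnerability blocks and over 42
   annual producer-productivity anomaly nodes, plus sign-agreement /
   correlation comparison of the fitted anomaly against climate indices
   (NPGO/PDO/ENSO-style).
4. **Synthetic data.**  Seeded generators for balanced webs, fishing
   declines, census-forced predator growth, noisy observation series and
   climate-like indices with known ground truth, so the whole pipeline is
   testable end to end.

A transcription of the published 1979 northeast Pacific parameter table
(74 functional groups, 242,623 km²) ships as a packaged model bundle;
its diet matrix is a documented synthetic placeholder and the model is
flagged accordingly.

## Worked example

Generate a small synthetic scenario with known truth and run the full
analysis — balance, two fitting cycles (vulnerabilities, then the annual
productivity anomaly), simulation, and mortality decomposition:

```sh
arenasim synth --preset small --seed 1 --out demo/scenario
arenasim pipeline \
    --model demo/scenario/model \
    --timeseries demo/scenario/timeseries.csv \
    --forcings demo/scenario/forcings \
    --groups "salmon A adults,salmon A smolts" \
    --budget 150 --budget-ppa 300 --cycles 2 \
    --out demo/out
```

prints

```
[balance] balanced=True
[fit] SS baseline: 10.3157
[fit] SS vulnerabilities (cycle 1): 7.3498
[fit] SS production anomaly (cycle 1): 4.4341
[fit] SS vulnerabilities (cycle 2): 4.1277
[fit] SS production anomaly (cycle 2): 3.3686
[decompose] salmon A adults: M2 trend 1.777
[decompose] salmon A smolts: M2 trend 1.659
[done] artifacts in demo/out
```

Reading: the static model balances (all EE within [0, 1]); the fit
objective drops monotonically across the staged searches, from 10.32
for the uncalibrated model to 3.37 after the second anomaly pass; and
over the 42 simulated years the predation mortality (M2) on the adult
and smolt salmon stanzas ends at 1.8× and 1.7× its 1979 value — the
growing forced predators, not fishing, carry the mortality trend.
`demo/out/` holds the solved balance (`solution/`), annual trajectories
and per-predator mortality ledgers (`run/`), the fitted vulnerabilities
and anomaly (`fit_report.json`), per-year mortality decompositions, and
a machine-readable `summary.json`.

The same stages are available as library calls (`solve_mass_balance`,
`run_simulation`, `fit_pipeline`, `mortality_decomposition`) for use
from Python; see the module docstrings and `docs/methods.md` for the
model description, parameter defaults and numerical choices.

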