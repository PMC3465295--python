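# leatherback

Bioenergetics and population-level resource requirements of Pacific
leatherback sea turtles (*Dermochelys coriacea*).

Leatherbacks are obligate consumers of gelatinous zooplankton. Because
jellyfish are ~95% water and energy-poor (~0.2 kJ g⁻¹ wet mass), a
leatherback must process enormous quantities of prey to grow from a 46 g
hatchling to a ~319 kg adult. This package couples a growth curve fitted to
captive feeding trials with a food-conversion allometry to estimate
individual jellyfish intake across ontogeny, scales the individual to the
Pacific population through a stage-structured mortality model, and
propagates parameter uncertainty by Monte Carlo. The outputs — individual
lifetime consumption, population consumption and biomass, and the
consumption-to-biomass ratio Q/B — are the quantities a conservation or
ecosystem modeller needs to weigh leatherback resource requirements against
jellyfish availability.

## Model

Mass-at-age follows the von Bertalanffy growth function (mass form)

    W(t) = W∞ (1 − e^{−k (t − t₀)})^b,

with `W∞ = 319 kg` (range 267–379), `k = 0.299 yr⁻¹` (SEM 0.001),
`b = 2.86` (SEM 0.014) from the length–mass relation `W = a L^b`
(`a = 2.14×10⁻⁴`), and `t₀` anchored so that `W(0)` equals the 0.046 kg
hatchling mass. Gross food-conversion efficiency declines with mass
following the Pauly allometry

    K₁(W) = 1 − (W / W∞)^β,        β = 0.0328 (SEM 0.001),

fitted as a through-origin regression of `log(1 − K₁)` on `log(W / W∞)`
from weekly feeding records. Individual intake at age is then

    F(t) = (dW/dt) / K₁(W(t)),

in units of the experimental gelatin diet; multiplying wet mass by 10
converts to jellyfish equivalents (the diet is ~2.0 kJ g⁻¹ WM vs ~0.2 for
jellyfish). At `W → W∞` the ratio resolves to the maintenance limit
`k W∞ / β` (≈80 kg jellyfish day⁻¹).

Cohort abundance declines exponentially within each life stage,
`N(t) = R e^{−Z (t − t_R)}`, with annual hatchling production from the
nesting-ecology table (128,031 hatchlings yr⁻¹ at the mean), 25% first-year
survival, 1,268 annual recruits to the adult stage at 16 yr, and
instantaneous mortalities `Z = 1.38 / 0.216 / 0.229 yr⁻¹` for hatchlings /
juveniles / adults. Population consumption `Q(t) = N·F` and biomass
`B(t) = N·W` integrate over age to the annual totals, and `Q/B` is their
ratio. Monte Carlo resampling of (β, b, k, W∞) over 10,000 runs yields 95%
envelopes by excluding the 2.5% tails.

## Worked example

```python
from leatherback import (default_growth_params, ConversionParams,
                         cumulative_consumption, pacific_schedule,
                         build_grid, integrate_totals, q_over_b,
                         total_population)

gp = default_growth_params()      # W∞=319, k=0.299, b=2.86, t₀=-0.155
cp = ConversionParams()           # β=0.0328, ×10 jellyfish factor

print(cumulative_consumption(0, 40, gp, cp))   # 1010.97  t per individual, lifetime
print(cumulative_consumption(0, 16, gp, cp))   # 314.85   t to maturity

sched = pacific_schedule("mean")
pop = total_population(sched, annual_nesters=1361)
print(pop.total, pop.by_stage["adult"])        # 294165.4  6190.2 turtles

grid = build_grid(sched, gp, cp)
tot = integrate_totals(grid, cp)
print(tot.consumption_t_per_yr)                # 2224347.5 t jellyfish / yr
print(tot.biomass_t)                           # 21569.9   t standing biomass
print(q_over_b(grid).q_over_b)                 # 103.1     yr⁻¹
```

A single turtle therefore eats about a thousand tonnes of jellyfish in a
40-year life; the Pacific population of ~294,000 turtles (of which ~6,200
are adults) consumes ~2.2 million tonnes per year — roughly 100 times its
own standing biomass, or about a quarter of its body mass in jellyfish per
animal per day.

The same pipeline is exposed on the command line:

```sh
leatherback population-totals --level mean --bands 2-7,16-40 \
    --scenario-adults 180000 --density-t-per-km2 105
leatherback montecarlo --draws 10000 --seed 42 --target consumption --out env.csv
```

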