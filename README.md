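# nbudget

Plant–soil–atmosphere nitrogen budgeting for factorial field trials.

Agronomists comparing cropping patterns (e.g. flat planting vs ridge
planting under biodegradable or conventional plastic mulch) and nitrogen
fertilizer rates need to close the nitrogen books for each treatment:
how much N went in, where it ended up, and how much is unaccounted for.
`nbudget` implements that accounting as a tested Python library, from
the raw field measurements up to the treatment statistics:

* **Soil inorganic-N stocks** — per-layer nitrate/ammonium stocks
  `NR = γ·h·N/10` (bulk density γ in g·cm⁻³, thickness h in cm,
  concentration N in mg·kg⁻¹ → kg N·ha⁻¹), summed over a 0–60 cm
  profile.
* **Static-chamber N₂O flux** — `F = ρ·H·(dc/dt)·273/(273+T)·60` with
  ρ = 2×14/22.4 = 1.25 kg·m⁻³ (an N₂O-N mass basis), OLS headspace
  slope with r² quality flagging, ridge/furrow area-weighted averaging,
  and the trapezoidal seasonal total
  `f = Σ (Fᵢ₊₁+Fᵢ)/2 · tᵢ · 24·10⁻⁵` kg·ha⁻¹ over campaign dates.
* **Plant N accumulation** — organ N content (%) × dry matter, summed
  over leaves + stems and over cuts, with seasonal hay yield.
* **The apparent nitrogen ledger** —
  `N_balance = (rate + initial soil N) − (soil residue + plant N + N₂O)`
  and the apparent nitrogen loss rate `ANLR = N_balance/rate × 100 %`
  (undefined at zero rate), with deficit / near-equilibrium / surplus
  classification.
* **Factorial statistics** — crossed fixed-effects ANOVA (rate ×
  pattern × year), Shapiro–Wilk / Levene prechecks, and protected LSD
  post hoc comparisons with a compact letter display.
* **A synthetic trial generator** — a full 3-pattern × 4-rate ×
  3-replicate, two-year experiment with designed pattern effects,
  dose–responses and seasonal flux curves plus a noise-free truth
  table, so every stage runs and is testable with no external data.

## Worked example

The package ships a reference component table from a published two-year
alfalfa ridge–furrow trial (12 treatments × 2 years). Running it through
the ledger:

```python
from nbudget import budget_table, budgets_from_components, load_reference_components

report = budget_table(budgets_from_components(load_reference_components()))
print(report.query("pattern == 'PM' and n_rate == 160")
            [["year", "n_balance_kg_ha", "anlr_pct", "category"]])
```

prints

```
    year  n_balance_kg_ha anlr_pct          category
20  2023             9.73     6.08  near_equilibrium
21  2024             1.84     1.15  near_equilibrium
```

i.e. ridge planting with conventional plastic mulch at 160 kg N·ha⁻¹
leaves a surplus of only 9.73 and 1.84 kg N·ha⁻¹ in the two seasons
(6.08 % and 1.15 % of the applied N), while the same pattern at
240 kg·ha⁻¹ strands >100 kg·ha⁻¹ in the system and unfertilized plots
mine 80–115 kg·ha⁻¹ from the soil pool. See `examples/` for narrative
scripts covering each capability (soil stocks, chamber flux, the
synthetic trial, the statistics layer) and `nbudget --help` for the
command-line pipeline (`simulate`, `soil-stocks`, `plant`, `flux`,
`emissions`, `budget`, `stats`, `run-all`).

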