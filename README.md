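# paraflux

Constraint-based analysis of the *Paracoccus denitrificans* Pd1222
genome-scale metabolic model: a flux-balance-analysis (FBA) core, the
yield-prediction and maintenance-estimation protocols used to validate the
model against chemostat and batch physiology, and synthetic stoichiometric
networks that let every protocol be exercised and tested without the
full-size model.

## The problem

*P. denitrificans* is the classic model denitrifier: it grows aerobically
or with nitrate as terminal electron acceptor, co-consumes methanol and
mannitol, fixes the CO₂ from C1 oxidation through the Calvin cycle, and
catabolizes a broad portfolio of carbon sources. A genome-scale metabolic
model (GSMM) compiles its reaction network into a stoichiometric matrix
**S** with flux bounds; FBA predicts behavior by linear programming:

```
maximize  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub
```

where the objective is usually the biomass pseudo-reaction, whose flux is
the specific growth rate µ (h⁻¹). Observed substrate consumption follows
Pirt's partition

```
q_s = m_s + µ / Y^max
```

with `q_s` the specific uptake (mmol g-DW⁻¹ h⁻¹), `m_s` the maintenance
consumption and `Y^max` the maximal yield (g-DW mol⁻¹). The package
implements the protocols that connect these two descriptions:

* **maximal theoretical yield** — uptake fixed to 1, non-growth ATP
  hydrolysis fixed to 0, biomass maximized (`Y^max = 1000·µ_opt`);
* **batch / denitrifying yield** — µ fixed to its measured value,
  maintenance ATP fixed (default 5.5 mmol g-DW⁻¹ h⁻¹), carbon uptake
  minimized; the anoxic variant closes O₂ and opens nitrate;
* **ATP yield** — mol ATP per mol substrate at zero growth;
* **scenario comparison** — yields under alternative reaction sets (e.g.
  quinone- vs NAD-linked formate dehydrogenase);
* **mixture-ratio scan** — a single pseudo-reaction supplies two
  substrates at a fixed molar ratio, its flux is minimized at fixed µ and
  maintenance, and the *forced* flux range of a target reaction (RuBisCO)
  is recorded; the activation threshold is the smallest ratio at which the
  minimal flux becomes nonzero;
* **maintenance estimation** — `m_ATP = Σᵢ yieldᵢ·m_sᵢ` from Pirt
  intercepts and ATP-yield coefficients, plus OLS fitting of Pirt's
  equation with standard errors;
* **leak check** — a sound model must not grow with every organic uptake
  closed (guards against artifacts like obligatory AMP import).

Because FBA optima are degenerate, no protocol ever reads a single flux
off one solve: reaction activity is always decided by a flux-variability
range over the optimal face.

## Worked example

```python
import numpy as np
import paraflux as pf

# a two-route respiratory network: 10 vs 6 ATP per substrate
model = pf.toy_respiratory({"high_po": 10.0, "low_po": 6.0})
medium = pf.MediumSpec.inorganic(model)

print(pf.atp_yield(model, "EX_S", medium))
# 10.0                        best route wins: mol ATP per mol substrate

ymax = pf.max_theoretical_yield(model, "EX_S", medium)
print(ymax.yield_g_per_mol)
# 500.0                       g-DW per mol at zero maintenance

batch = pf.batch_yield(model, "EX_S", mu=0.2, m_atp=5.5, medium=medium)
print(round(batch.yield_g_per_mol, 1), round(batch.uptake, 3))
# 210.5 0.95                  maintenance lowers the yield below Y^max

# forced activation of CO2 fixation on a two-substrate mixture
ds, oracle_thr = pf.toy_dual_substrate()
scan = pf.ratio_scan(ds, "meoh", "mann", list(np.arange(0, 5.01, 0.05)),
                     mu=0.3, m_atp=7.5, target="FIX",
                     medium=pf.MediumSpec.inorganic(ds))
print(round(scan.threshold, 2), round(oracle_thr, 2))
# 2.51 2.5                    scan agrees with the brute-force oracle
```

The same protocols run unchanged on the deposited GSMM (load it with
`paraflux.deposit.load_deposit`), or from the shell:

```
paraflux model-stats   --model deposit/Paracoccus_denitrificans.xml
paraflux predict-yield --model deposit/Paracoccus_denitrificans.xml --substrate mannitol
paraflux fit-pirt      --data chemostat_points.tsv
```

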