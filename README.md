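# nitrikin

Octyne-partitioned soil nitrification kinetics: simulate shaken-slurry
incubation assays, split nitrification rates into archaeal (AOA) and
bacterial (AOB) components, fit Michaelis–Menten and Haldane
substrate-inhibition models, select between them, and compare kinetic
parameters across ecosystems with Bayesian posterior contrasts.

## Who this is for

Soil microbial ecologists and biogeochemists analyzing nitrification
kinetics assays in which 1-octyne (a selective inhibitor of the bacterial
ammonia monooxygenase) separates AOA from AOB activity: activity with
octyne is archaeal, and the bacterial share is the difference from the
uninhibited bottle. The central scientific question the toolchain answers
is whether a guild's substrate–rate curve saturates (Michaelis–Menten,
V = Vmax·S/(Km+S)) or is inhibited at high ammonium (Haldane,
V = Vmax·S/(Km+S+S²/Ki)) — inhibition of AOB but not AOA is a candidate
mechanism for ammonium-driven niche differentiation between the guilds.

## Worked example

Simulate one ecosystem under the standard design (8 NH₄⁺ levels from 0.01
to 15 mM, paired ±octyne bottles, 4 field replicates, 5% concentration
noise), partition the rates, and run the model comparison:

```python
from nitrikin import (
    IncubationDesign, NoiseModel, default_truths, simulate_incubation,
    partition_records, fit_kinetics, select_model,
)

truths = [t for t in default_truths() if t.ecosystem_id == "Biologically-based"]
records = simulate_incubation(truths, IncubationDesign(),
                              NoiseModel(conc_cv=0.05, seed=1))
obs = [o for o in partition_records(records) if o.taxon == "AOB"]
fit_mm = fit_kinetics(obs, "MM")
fit_h = fit_kinetics(obs, "Haldane")
comp = select_model("Biologically-based", "AOB", fit_mm, fit_h)
print(f"Haldane fit: Vmax={fit_h.vmax:.2f}, Km={fit_h.km * 1000:.1f} uM, "
      f"Ki={fit_h.ki:.1f} mM")
print(f"AIC {comp.aic_mm:.1f} (MM) vs {comp.aic_haldane:.1f} (Haldane), "
      f"F={comp.f_stat:.2f}, p={comp.p_value:.4f} -> {comp.selected}")
```

prints

```
Haldane fit: Vmax=5.48, Km=18.0 uM, Ki=36.7 mM
AIC 80.1 (MM) vs 67.6 (Haldane), F=16.63, p=0.0003 -> Haldane
```

The bacterial population was generated with Haldane kinetics
(Vmax 5.29 mg N kg⁻¹ day⁻¹, Km 9.18 μM, Ki 52.2 mM); with one seed's
noise the fit recovers Vmax within 4%, and the selection procedure
correctly prefers the substrate-inhibition model — smaller AIC *and* a
significant extra-sum-of-squares F-test (the rule requires both, at
p < 0.1). Ki, which only shapes the curve's gentle decline beyond 10 mM,
is estimated far less precisely — exactly why cross-ecosystem comparisons
of these parameters carry their standard errors into the Bayesian stage.

## The analysis

Numbered drivers under `analysis/` reproduce the full study flow on
synthetic data; each writes its tables under `results/analysis/`:

1. `01_simulate_incubations.py` — 8 ecosystems × 4 replicates × 8 levels
   × paired bottles from the bundled reference truths.
2. `02_partition_rates.py` — rates per kg dry soil per day, octyne
   partition, negative-rate and detection flags.
3. `03_fit_and_select.py` — both models per (ecosystem, taxon), AIC +
   nested F-test selection. On the default seed the procedure recovers
   the generating model for all 16 populations: substrate inhibition for
   5 AOB populations vs 1 AOA.
4. `04_bayesian_contrasts.py` — plugin-mode posterior contrasts of Vmax:
   compact letter display across the managed systems and 0N vs +N
   fertilization contrasts, 13,002 draws per group.
5. `05_vmax_covariate_regressions.py` — OLS of fitted Vmax on soil pH and
   log10 amoA abundance (synthetic field covariates).

The same stages are scriptable through the CLI
(`nitrikin simulate|rates|fit|select|bayes|regress|run`), configured by a
YAML file; `nitrikin run --config c.yaml --seed 1 --out DIR` executes the
whole pipeline and writes byte-reproducible artifacts plus a log and a
config snapshot.

See `docs/methods.md` for the models, conventions (AIC form, thinning
rule, letter-display construction) and the simulator's scope.

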