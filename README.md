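# pdqsp

Quantitative systems pharmacology of anti-PD-1 / anti-PD-L1 antibody
treatment in the CT26 syngeneic mouse tumor model.

Checkpoint-inhibitor responses in syngeneic mice are highly variable:
some animals clear their tumors, litter-mates on the same regimen
progress. `pdqsp` is a tested re-implementation of a mechanistic
framework for asking *where that variability comes from*: a
tumor–immune ODE model whose CD8+ T-cell influx and activation are
controlled by competitive PD-1:PD-L1/antibody binding, embedded in a
population (nonlinear mixed-effects) analysis over virtual mouse
cohorts. It is aimed at modelers in preclinical pharmacometrics / QSP
who want a transparent, scriptable version of this class of analysis.

## The model in brief

Two-compartment linear PK per antibody; a tumor compartment with viable
and damaged tumor cells and a 21-state CD8+ T-cell life cycle
(inactive -> active -> 7 proliferation stages with doubling per transit
-> CTLs with a ten-kill capacity ladder -> exhausted). Free PD-1, PD-L1
and antibody species equilibrate in the tumor interstitium; the
complexes-per-cell readout x inhibits both the inactive-cell influx

    f_influx(x) = max(0, Emax/(1+EC50/x_ref) − Emax/(1+EC50/x)) + ks_IVt

(exact cancellation at the untreated anchor x_ref = 6.6 complexes/cell)
and the activation rate Emax_act − Emax_act/(1+EC50/x). Tumor volume
grows logistically (rate k_pfr, capacity k_limit in mm³), CTL kills and
anti-PD-L1 ADCC move cells into a damaged pool that apoptoses at a
constant rate. Individual mice vary log-normally in k_pfr, k_limit and
the proliferation half-life, with an exponential study-site covariate
on the first two and combined-2 residual error
(sd = sqrt(a² + b²·f²)) on observed volumes.

Population estimation is a deterministic alternating MAP / Laplace-EM
scheme with a FOCE-style polish, floor-censoring-aware likelihood and
REML-style error-term correction (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from pdqsp import default_parameters
from pdqsp.model import calibrate_binding_anchor
from pdqsp.pk import parse_regimen
from pdqsp.simulate import simulate_individual, percent_change_vs_control

p = calibrate_binding_anchor(default_parameters(), 8e6)
ctrl = simulate_individual(p, t_end=30.0)
reg = parse_regimen("Q3Dx3 start 7", 10.0, "IV", "antiPDL1", p=p)
trt = simulate_individual(p, reg, t_end=30.0)
day17 = lambda tr: float(tr.volume_at(17.0))   # 10 d after first dose
print(f"control volume day 17: {day17(ctrl):.1f} mm^3")
print(f"anti-PD-L1 volume day 17: {day17(trt):.1f} mm^3")
print(f"change vs control: {percent_change_vs_control(day17(trt), day17(ctrl)):.1f}%")
print(f"CTL expansion: x{np.interp(17, trt.t, trt.ctl)/np.interp(17, ctrl.t, ctrl.ctl):.0f}")
```

prints

```
control volume day 17: 116.3 mm^3
anti-PD-L1 volume day 17: 23.6 mm^3
change vs control: -79.7%
CTL expansion: x603560
```

— ten days into a 10 mg/kg Q3Dx3 anti-PD-L1 course the simulated tumor
is ~80% smaller than control, driven by a massive binding-released CTL
influx plus ADCC. The same call with `"antiPD1"` gives a weaker (−36%)
effect, and with `constant_influx=True` the anti-PD-1 effect all but
vanishes — activation of resident T cells alone cannot explain the
anti-tumor response.

A command-line pipeline wraps the library:

```bash
qsp all --config config.yaml --seed 7 --out results/
```

with stages `simulate | generate | fit | sensitivity | analyze`
(cohort CSVs, fit JSON, sensitivity tables, responder classification,
expression sweeps; every stage writes a manifest with the config hash
and seed).

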