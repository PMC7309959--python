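# ra223cea

A cost-effectiveness model of **radium-223 dichloride plus best supportive
care (BSC) versus BSC alone** in chemotherapy-naive metastatic
castration-resistant prostate cancer (mCRPC), from the Spanish National
Health System perspective.

The package is aimed at health economists and methodologists who want a
tested, scriptable re-implementation of a published partitioned-survival
cohort model: every input is a config field, every stage (survival
extrapolation, state occupancy, QALY/cost accrual, ICER, tornado, PSA/CEAC)
is a library function, and a synthetic patient-level data generator makes the
curve-fitting stage reproducible without access to trial data.

## The model in brief

A cohort moves weekly through five states — progression-free without a
symptomatic skeletal event (SSE), progression-free with SSE, progressed
without SSE, progressed with SSE, dead — over a 10-year horizon.  Occupancy
is derived from three lognormal survival curves per arm (overall survival,
progression-free survival, time to first SSE; time in weeks,
`S(t) = 1 - Phi((ln t - mu)/sigma)` with `sigma = exp(shape)`), using the
partitioned-survival construction

    PF_noSSE(t) = min(S_PFS, S_SSE, S_OS)(t),   dead(t) = 1 - S_OS(t), ...

Utilities (EQ-5D) weight state time into QALYs; nine cost categories accrue
per cycle; and the headline statistic is the incremental cost-effectiveness
ratio

    ICER = (C_Ra223 - C_BSC) / (QALY_Ra223 - QALY_BSC)   [EUR per QALY]

computed from unrounded increments, with net monetary benefit
`NMB(lambda) = lambda * dQALY - dCost` supporting the acceptability curve.
Uncertainty is explored one-way (tornado ranking by ICER spread) and
probabilistically (1000 draws, beta for probabilities/utilities, gamma for
resource use/costs, moment-matched to the published ranges).

See `docs/methods.md` for assumptions, calibrated fields and limitations.

## Worked example

The packaged base case runs with zero inputs:

```python
import ra223cea as r

config = r.load_config(None)          # packaged base case
result = r.evaluate_base(config)      # both arms, 520 weekly cycles

print(f"radium-223: {result.reference.qalys:.2f} QALYs, "
      f"{result.reference.total_cost:,.0f} EUR")
print(f"BSC:        {result.comparator.qalys:.2f} QALYs, "
      f"{result.comparator.total_cost:,.0f} EUR")
print(f"ICER: {result.icer:,.0f} EUR/QALY")
```

prints

```
radium-223: 1.01 QALYs, 64,387 EUR
BSC:        0.69 QALYs, 54,770 EUR
ICER: 30,051 EUR/QALY
```

i.e. radium-223 gains 0.32 QALYs (0.41 life-years) for an extra 9,618 EUR —
about 30,000 EUR per QALY gained, in the middle of the willingness-to-pay
range usually cited for Spain.  The same pipeline is available from the
shell:

```
cea run  --out results/           # base case: CEA table + cost breakdown
cea owsa --out results/ --top-k 10
cea psa  --out results/ --n 1000 --seed 1
cea simulate --out results/ --n 395 --seed 1
cea scenario --out results/ --curve OS radium223 exponential 135 0 ...
```

Every command writes a `manifest.json` recording the config digest, the seed,
and the list of calibrated (non-published, assumed) parameters in force.

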