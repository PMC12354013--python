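# acylnmr

Continuous NMR-based enzyme kinetics for lysine acylation of the histone
H4 tail.  The package is aimed at enzymologists and NMR spectroscopists
who monitor acyltransferase reactions (e.g. the p300 lysine
acetyltransferase and its activated autoinhibitory-loop truncation
p300Δ) by serial ¹H,¹³C-HSQC experiments: it simulates multi-site
acylation kinetics, synthesizes and reduces 2D HSQC time series to
progress curves, fits and selects among exponential growth models, and
predicts/calls MALDI-TOF acylation-state ladders.

## The model

Five lysines (K5, K8, K12, K16, K20) on the H4(1–25)W tail acquire an
acyl mark independently, each with first-order rate constant *kᵢ*
(min⁻¹), so site *i* is modified by time *t* with probability
*pᵢ(t) = 1 − e^(−kᵢ t)*.  The aggregate acyllysine NMR signal is
proportional to Σᵢ *pᵢ(t)*; the number of marks per molecule follows a
Poisson-binomial distribution, which is what a MALDI mass ladder reads
out.  Progress curves are fit to three nested growth models:

1. mono-exponential: *I(t) = I_max (1 − e^(−kt))*
2. bi-exponential: *I(t) = A₁(1 − e^(−k₁t)) + A₂(1 − e^(−k₂t))*
3. lagged mono-exponential:
   *I(t) = A (1 − e^(−kt)) / (1 + e^(−α(t − t₀))) + C*

With two rate classes of multiplicities (3, 2) the five-site aggregate
is *exactly* bi-exponential with a 60 %/40 % amplitude split — the
analytic identity behind interpreting fitted amplitude fractions as site
counts.  A selection ladder formalizes the escalation from model 1:
residual randomness is judged by a Wald–Wolfowitz runs test, an
early-lag score flags lag phases, and AICc breaks ties.

## Worked example

```python
from acylnmr import (SiteRateProfile, AcquisitionSchedule, aggregate_curve,
                     ProgressCurveFitter, amplitude_fraction, rate_ratio)

# 3 fast + 2 slow sites, serial 3.6-min experiments after a 5-min deadtime
profile = SiteRateProfile.two_class(k_fast=0.0473, k_slow=0.0156)
curve = aggregate_curve(profile, AcquisitionSchedule())

fit = ProgressCurveFitter(model="bi").fit(curve.times, curve.intensities)
print(f"k1={fit.params_.k1:.4f} k2={fit.params_.k2:.4f} min^-1")
print(f"fast amplitude fraction={amplitude_fraction(fit.params_)[0]:.1%}")
print(f"rate ratio={rate_ratio(fit.params_):.2f}")
```

prints

```
k1=0.0473 k2=0.0156 min^-1
fast amplitude fraction=60.0%
rate ratio=3.03
```

i.e. the bi-exponential fit recovers both generating rate constants, the
60 % fast-amplitude fraction identifying the 3-lysine fast class, and a
~3-fold fast/slow rate separation.

The same pipeline is available from the shell:

```sh
acylnmr simulate --acyl acetyl --enzyme p300d --out curve.tsv
acylnmr fit --curve curve.tsv --model bi --out fit.json
acylnmr spectra --acyl acetyl --out-dir series/   # synthetic HSQC series
acylnmr extract --series-dir series/ --window ac --out extracted.tsv
acylnmr select --curve extracted.tsv --out selection.json
acylnmr maldi --acyl acetyl --time 60 --out peaks.txt
```

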