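# sadpower

**Power analysis for tests of neutrality on species abundance data.**

Species abundance distributions (SADs) are famously forgiving: data sets
that are statistically consistent with Hubbell's standard neutral model
(SNM) may nevertheless have been produced by strongly non-neutral
community dynamics.  `sadpower` quantifies exactly how forgiving.  It
simulates communities with explicit non-neutral processes — density-
dependent mortality, Ricker-type competition acting on fecundity, and
intrinsic species fitness differences — coupled by immigration to a
log-series or perfectly even metacommunity, subjects each simulated data
set to an exact maximum-likelihood test of the neutral null, and reports
the *statistical power*: the probability that neutrality is (correctly)
rejected.  The answer tells a field ecologist what sample size, or what
strength of non-neutral interaction, is needed before a SAD can reveal
non-neutrality at all.

## The model and the test

A local community of fixed size `J` evolves by zero-sum birth-death
dynamics; a fraction `m` of recruits immigrate from a metacommunity with
relative abundances `P_i` (log-series with biodiversity number θ, or
`S_T` equally common species).  Three alternative models each add one
non-neutrality parameter: `γ` (excess intraspecific mortality, model HL),
`c` (Ricker fecundity penalty, model PC), `k` (variance of intrinsic
fitness, model IF); at `γ = c = k = 0` the local dynamics are neutral.

The neutral null is tested by parametric bootstrap with the maximized
Etienne-formula likelihood as statistic: with `I = m(J−1)/(1−m)`,

    P(D | θ, m, J) = J!/(∏ nᵢ ∏ Φⱼ!) · θ^S/(I)_J · Σ_A K(D,A) I^A/(θ)_A

is maximized over `(θ, m)` for the data and for `u` urn-sampled null
replicates at the fitted parameters; the p-value is the fraction of null
maximized likelihoods below the data's.  Power is the rejection fraction
over many simulated data sets, with Jeffreys 95% binomial intervals.
Details, numerics and design choices are in [docs/methods.md](docs/methods.md).

## Worked example

Draw one neutral sample, test it, then measure the power of the test
against a strongly competitive HL community of the same size:

```python
import numpy as np
from sadpower import ModelSpec, bootstrap_test, estimate_power, urn_sample

rng = np.random.default_rng(1)

# one SNM sample at theta=50, m=0.1, J=200
D = urn_sample(50.0, 0.1, 200, rng)
res = bootstrap_test(D, u=200, rng=rng)
print(f"S={D.S}  theta_hat={res.fit_test.theta_hat:.1f} "
      f"m_hat={res.fit_test.m_hat:.3f}  p={res.p_value:.3f}")

# power against HL with gamma=1 (independent stochastic niches)
spec = ModelSpec(model="hl", J=200, m=1e-4, theta=50.0, strength=1.0)
est = estimate_power(spec, n_datasets=100, u=200, rng=np.random.default_rng(2))
print(f"power={est.power:.2f}  95% CI=({est.ci_low:.2f}, {est.ci_high:.2f})")
```

```
S=37  theta_hat=41.4 m_hat=0.123  p=0.670
power=1.00  95% CI=(0.98, 1.00)
```

The neutral sample is not rejected (`p = 0.67`, far above 0.05), and its
fitted parameters recover the generating values.  Against the `γ = 1`
community — independent stochastic niches, the most detectable form of
competition — the test rejects every one of the 100 data sets even at
this small `J`.  The same machinery runs from the
shell (`sadpower urn`, `sadpower test-neutrality`, `sadpower power
--config sweep.yaml`, `sadpower fit-summary`, ...); every command writes a
JSON manifest with its full configuration and seed.

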