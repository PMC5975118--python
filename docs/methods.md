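# Methods

## The facilitation–depression map

The synapse is modelled per spike, not in continuous time. The state is
(C, P, R): dimensionless presynaptic calcium, release probability, and the
fraction of release sites ready to release. Between spikes, calcium decays
exponentially with time constant `tau_ca` and the pool relaxes toward 1 at
a calcium-dependent rate `k(C) = k_min + (k_max - k_min) C / (C + K_r)`; at
each spike calcium jumps by `delta` and the release of a fraction `P` of
the ready pool sets the recovery initial condition to `(1 - P) R`. The
release probability is a Hill function of calcium with coefficient 4
(synaptotagmin-1 cooperativity), saturating at `p_max`. The observable is
the normalized peak response `Pr = P * R`, with `R` the pre-release pool.

Both facilitation (calcium raises `P` and speeds recovery) and depression
(release empties the pool) are present; with the fitted constants the
synapse is depression-dominated at all stimulation rates.

**The pool exponent.** The spike-to-spike pool update multiplies the
recovery factor `exp(-k_min T)` by a calcium-ratio factor raised to
`delta_k = k_max - k_min`. Integrating the recovery ODE exactly gives the
exponent `delta_k * tau_ca` instead; the two differ measurably (the
`delta_k` form leaves a residual factor `(K_r / (K_r + C))^delta_k` of
about 0.89 even when calcium decays instantly). The `delta_k` form is the
default because the constants were fitted to data under that form and it
is the form whose consequences this package sets out to reproduce; every
map routine accepts `exponent="dimensional"` for the ODE-consistent
variant. The closed-form pool fixed point
`R_bar(T) = (1 - e^(-k_min T)) / (1 - (1 - p_max) e^(-k_min T))` assumes
recovery at exactly `k_min`, so it matches the map's fixed point to 1e-3
only under the dimensional exponent (verified in the tests); under the
default exponent it is a lower bound.

**Units.** Internal time is ms and rates are 1/ms; the interfaces accept
Hz and convert with `lambda[1/ms] = f[Hz] / 1000`.

## Conditions, and how muscarine enters the dynamics

Fitted constants: `K = 0.2`, `k_min = 0.0017/ms`, `k_max = 0.0517/ms`,
`K_r = 0.1`, `tau_ca = 1.5 ms`, and per condition `p_max = 0.85`,
`delta = 1` (control), `p_max = 0.27`, `delta = 0.17` (muscarine). The
muscarine condition models mAChR activation as reduced calcium influx
(`delta`) and reduced maximal release probability.

The Hill half-activation constants were fitted on a calcium axis scaled
by the per-spike influx: the measured first-pulse response under *each*
condition equals its `p_max` (that is how `p_max` was obtained by
variance–mean analysis), which requires the release Hill function to
saturate on the condition's own influx. Feeding the muscarine `delta`
literally through the control-scaled Hill functions would instead give a
first-pulse response of `0.093`, a stationary mean at 0.1 Hz of `0.09`
(measured: about 0.3), and no high-frequency entropy maximum at all.
`parameters.dynamics_parameters` therefore rescales the map to the
influx-normalized axis — unit calcium jumps, fitted `K`, `K_r` unchanged —
which is the identity under control and makes every reported muscarine
result reproducible. All sweeps use it; `delta` remains on the preset as
the fitted influx ratio and scales absolute calcium concentrations.

## Stimulation protocol and synthetic data

Spike trains are synthetic: i.i.d. exponential ISIs at a chosen mean rate
(Poisson drive, the in-vivo-like case) or fixed-period trains (the
protocol of the underlying paired recordings). Stationary quantities use
2^14 samples per frequency after discarding a 100-spike transient from
the rest state (C=0, P=0, R=1); the collapse to the attractor takes only
a few spikes, so 100 is a conservative margin. Every experiment derives
one independent sub-stream per grid frequency from a single root seed
(`numpy` `SeedSequence` spawning), making sweeps bit-reproducible and
element-wise extensible.

What the generator does *not* emulate: refractoriness or burstiness of
real PV basket-cell trains (ISIs are exactly exponential), spike-timing
jitter, recorded in-vivo trains, and any postsynaptic membrane dynamics.
Passing tests therefore validate the model pipeline, not the biological
variability of real trains.

## Stationary laws

*Calcium.* The spike-sampled recurrence `C_n = C_{n-1} e^(-T_n/tau_ca) +
Delta_n` has the exact stationary law `Gamma(lambda*tau_ca + 1, scale 1)`
when the influxes `Delta_n` are i.i.d. exponential with unit mean: the
decay factor is Beta(lambda*tau_ca, 1)-distributed, beta-thinning a
Gamma(lambda*tau_ca + 1) variable yields Gamma(lambda*tau_ca), and the
Exp(1) influx restores the shape. With a *constant* influx the chain is
supported on [delta, inf) and no gamma law can hold exactly; the
simulator therefore defaults to exponential influx for this analysis
(`influx="constant"` is available for comparison). The deterministic map
driving the response analyses keeps its constant influx.

*Stochastic fixed point.* For `tau_ca` much smaller than the mean ISI,
the response at a spike is approximated by the map's fixed point at the
preceding interval; `T ~ Exp(lambda)` pushed through `R_bar(T)` gives

    f(x) = (lambda (1-a) / k_min) (1-x)^(lambda/k_min - 1) (1 - a x)^-(1 + lambda/k_min)

with `a = 1 - p_max`, and the response law is its scaling onto
`[0, p_max]`. The mean involves the Gauss hypergeometric function 2F1,
evaluated with `scipy.special.hyp2f1` (the argument `a < 1` is well
inside its convergence disc) and cross-checked against quadrature to
1e-6; at `a = 0` it reduces to `k_min / (k_min + lambda)`. Densities are
evaluated in log space because the `(1-x)` factor diverges at the right
endpoint whenever `lambda < k_min`; the quadrature oracle absorbs that
integrable singularity into an algebraic weight.

Quantile–quantile comparisons report two statistics: identity-line R²
(same law, same scale) and the squared Pearson correlation of the
quantile pairs (same shape up to affine transform — the usual reading of
a straight quantile plot). The map-vs-law comparison satisfies only the
second: after a very short ISI the map's pool is floored at
`(1 - P) R_prev` while the law's tail reaches zero, so the quantile
pairs are affine (linearity r² > 0.99 for mean ISI ≥ 50 ms) but offset.
Below a 10 ms mean ISI the approximation visibly breaks down, and the
tests assert that degradation rather than hiding it.

## Response model and information measures

Release across `n_sites` independent sites is binomial in `Pr`; each
released vesicle contributes a truncated-normal quantal amplitude (mean
`mu = 0.5`, s.d. `sigma = 0.1`, support `(0, 2 mu)`), sampled exactly by
inverse-CDF transform and summed per spike. The site count is not
constrained by the source data; the default `n_sites = 10` is a typical
anatomical estimate for this connection, it is recorded in every
experiment's metadata, and all MI comparisons between conditions are made
at the same `n_sites` (the absolute MI level scales with it, the
control-vs-muscarine ordering does not). Failures (zero amplitude) are
part of the response law — the mixture has an atom at zero — and are
included in histograms by default; a zero response cannot itself encode
the preceding interval, and `include_failures=False` quantifies how much
of the measured MI the atom carries.

Scalar entropies and MI use histograms, in bits. Response and ISI axes
are binned by the Freedman–Diaconis rule (`nbins = range / (2 Iqr
n^(-1/3))`, ceiling; square-root fallback with a warning when the IQR
degenerates). Pr distributions use a fixed partition — 100 even bins on
[0, 1] — held constant across conditions and rates so entropies are
comparable; 100 bins resolves the muscarine support (27 occupied bins)
while keeping at least ~160 expected counts per occupied bin at 2^14
samples. The argmax location of the entropy curve is insensitive to the
bin count (checked from 20 to 400 bins). MI is computed from the joint
table with marginals obtained by summing it, which makes the histogram
estimate exactly symmetric and nonnegative. The conditional-entropy form
`H(S) - H(S|t_k)` for the sum-of-history MI is computed as
`H(S) + H(t_k) - H(S, t_k)` for the same reason.

Multivariate MI between a response and the *ordered* tuple of its k
preceding ISIs uses the Kozachenko–Leonenko entropy estimator and the
KSG (variant 1) MI estimator, max-norm, k = 4 neighbors, in nats. Every
coordinate is standardized to unit variance first (the true MI is
invariant; comparable scales keep the joint neighborhood informative
about both blocks) and ties are broken by a uniform jitter of 1e-10
times the coordinate scale. Tuple depth is capped at 8 for the 2^14
sample size. The rise-then-fall of the tuple-MI curve with depth mixes
true history dependence with the estimator's dimensionality bias; the
comparisons drawn from it (control peaks at depth 2; muscarine's rise
extends over three to four preceding ISIs; muscarine below control at
matched rate) are qualitative orderings, not absolute MI values.

## Sweep protocol and numerical choices

Default grids: a 60-point logarithmic grid over 0.1–100 Hz for
physiological sweeps, and a linear high band (50–1000 Hz) for the
high-frequency entropy structure. Local maxima of the entropy curve are
detected with a prominence threshold of 0.05 bits (about five times the
sampling noise of a 2^14-sample histogram entropy) and refined by a
3-point quadratic fit around the grid argmax, falling back to the grid
point at band edges or for non-concave triples. The reproduction script
scans the high band at 25 Hz steps, selects the most prominent interior
peak, and resolves it with a 5 Hz pass. Fixed-point iteration uses
tolerance 1e-10 with a 10^4-iteration cap (convergence takes under ~40
iterations across T in [1, 5000] ms for both parameter sets).

## Known discrepancies and limitations

* The low-frequency entropy maximum computed under this protocol lies at
  ≈ 2 Hz, where the stationary Pr distribution is flattest — a fixed
  partition pins the entropy maximum to the flattest distribution by
  construction. Published descriptions place the flat distribution near
  1.8 Hz but read the entropy maximum at ≈ 4 Hz; those two statements
  cannot both hold for this estimator, and this package reports the
  computed ≈ 2 Hz.
* The high-frequency entropy maximum of the muscarine curve sits on a
  very flat bump (≈ 0.005 bits of curvature across 300–400 Hz at 2^14
  samples), so its refined location wanders by ±30 Hz across seeds.
* The MI-vs-rate peak location is reported by the curve itself; published
  summaries place it variously between 0.1–2 Hz and 3–5 Hz, and the peak
  ratio to the high-rate baseline depends on the unconstrained `n_sites`,
  so only the control ≫ muscarine ordering is asserted.
* The stochastic fixed-point density family is also tabulated with a
  baseline recovery of 0.0013/ms (a variant that appears in one published
  rendering of the family); everything else uses the fitted 0.0017/ms.
* No receptor desensitization, postsynaptic conductance noise, membrane
  dynamics, network oscillations, or parameter refitting: the fitted
  constants are taken as given.
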