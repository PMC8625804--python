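# Methods

## Signal model

A melt curve is modeled, and simulated, as a sum of two-state helix-to-coil
transitions on top of a dye background:

```
F(T) = bg(T) + A · Σᵢ wᵢ / (1 + exp((T − Tmᵢ)/sᵢ)) + ε(T)
bg(T) = b₀·exp(−r·(T − T_lo)) + b₁·(T − T_lo)
```

with total melt amplitude `A` (RFU), per-domain melting temperatures `Tmᵢ`,
logistic width parameters `sᵢ` (°C; the −dF/dT peak has FWHM ≈ 3.5 s),
weights `wᵢ` summing to 1, an exponential-plus-linear background and
i.i.d. Gaussian noise `ε`. The logistic was chosen over nearest-neighbor
thermodynamics deliberately: the analysis consumes only curve *shape*, and
the logistic has closed-form derivatives — −dF/dT peaks exactly at Tm and
the normalized curve passes through ½ there — so every pipeline stage can be
checked against analytic values.

A heterozygote melt is a fraction-weighted mixture of duplex species:
wildtype homoduplex at Tm, variant homoduplex at Tm + `hom_delta`, and
heteroduplexes at Tm + `het_delta`. Heteroduplexes carry a mismatch and are
destabilized, so `het_delta` is negative, typically −1 to −3 °C; `hom_delta`
is a small shift (default −0.3 °C). A 1:1 mix of hemizygous and wildtype DNA
re-annealed after PCR gives fractions ≈ (0.25, 0.25, 0.5), the default. This
mixing step (the *artificial heterozygote*) is what makes hemizygous male
variants detectable: an unmixed hemizygote forms only homoduplexes, whose
melt can be nearly indistinguishable from wildtype.

## Simulator defaults (the conditions the tests probe)

| parameter | default | meaning |
|---|---|---|
| grid | 65–95 °C, 0.04 °C step | 25 readings/°C acquisition density |
| amplitude | 1000 RFU | total melt drop |
| background | (200, −2, 0) | intercept RFU, RFU/°C, 1/°C |
| noise_sd | 5 RFU (0.5 % of amplitude) | per-point Gaussian noise |
| transition | Tm 80 °C, s = 1 °C | single reference domain |
| mixture | (0.25, 0.25, 0.5), het −2 °C, hom −0.3 °C | artificial heterozygote |

Cohorts are all-male (controls `role=control`, variants `role=test` with
`mixed=True`), mirroring the hemizygous-mixing protocol; `n_wildtype_tests`
adds wildtype draws in the test role for specificity estimation.

What the simulator does **not** emulate: correlated (drift-like) instrument
noise, well-to-well temperature calibration offsets, dye-saturation
nonlinearity, inter-run chemistry effects, and sequence-dependent multi-state
melting. Passing tests therefore demonstrate that the *algorithm* recovers
known structure under realistic point noise — not that any instrument will
achieve the same error rates on real DNA, where Tm offsets between runs and
plate-position effects are often the dominant error source.

## Derivatives and domain detection

−dF/dT and its slope are evaluated analytically from a Savitzky–Golay local
cubic fit (never by finite-differencing the smoothed output). The default
window of 75 grid points (≈ 3 °C at 0.04 °C spacing) is an engineering
balance measured on the simulator: it cuts derivative noise ≈ 20-fold
(σ ≈ 1.7 RFU/°C at 0.5 % noise against a 250 RFU/°C peak), attenuates the
sharpest physiological transition (s = 0.5 °C) by only ~6 %, and, being a
symmetric filter, leaves peak positions unbiased. Narrower windows
oversegment noisy curves long before they help resolution: two domains 4 °C
apart are still cleanly resolved at 3 °C.

A domain must satisfy two *relative* criteria (raw RFU scales are
instrument-dependent, so both are fractions of the curve's global −dF/dT
maximum):

* **height ≥ 0.10** — small shoulders below a tenth of the main peak are
  noise, not domains;
* **prominence ≥ 0.10** — the peak must rise that far above its connecting
  saddle. Height alone cannot reject noise: on the flank of a tall
  transition the underlying signal already exceeds 10 % of the maximum, so
  any noise wiggle there clears a height threshold, while its prominence
  stays at the noise scale. A real domain rises from the inter-domain
  valley, so its prominence is comparable to its height.

Domain boundaries are the nearest *prominent* local minima of −dF/dT on
each side (grid ends if none) — the same prominence filter applied to the
inverted curve, so a noise dimple near a peak's top cannot pinch a domain.
Domains narrower than `min_domain_width` (0.5 °C) are dissolved into their
nearest neighbor, which absorbs their span only when the spans touch
(absorbing a distant spike would stretch a real domain across dead
baseline). With all filters applied, domain counts for 1–4 transitions
≥ 4 °C apart are recovered exactly on noise-free curves and in ≥ 99 % of
draws at 0.5 % noise.

The melting region of a domain pads its boundaries by `region_pad`
(default 2 °C) on each side, clipped to the grid. Tm is the −dF/dT peak
temperature, so its resolution is one grid step noise-free; under noise the
argmax is unbiased but scatters, so Tm accuracy statements are about the
seed-averaged estimate.

## Normalization

Within a region, a line is fitted by least squares to the leading
`baseline_frac` (default 10 %, ≥ 5 points) of the region — the fully helical
upper baseline U(T) — and to the trailing fraction — the fully melted lower
baseline L(T). The normalized curve is q = (F − L)/(U − L), followed by the
affine map v = (q − q̄_trail)/(q̄_lead − q̄_trail) that anchors the
leading/trailing window means at exactly 1 and 0. The anchoring matters:
with noisy baselines the pointwise quotient alone leaves the window means
off by O(noise), whereas the anchored version satisfies the 1/0 identity to
machine precision on any input, and it changes nothing else (it is affine).
Linear backgrounds are absorbed exactly; values are clipped to
[−0.05, 1.05]. Baselines that cross inside the region (e.g. a region placed
mid-transition, or a non-melting trace) raise `DegenerateBaselines` rather
than returning nonsense.

## Reference band and calling

The reference for each scope is the per-temperature **median** and sample
standard deviation (ddof = 1) of ≥ 2 normalized control curves (warning
below 3). Control values are sorted per temperature before computing both,
which makes the band bit-identical under any reordering of the controls. A
`center="mean"` option exists for comparison, but the median is the default
because a single outlying control then shifts the reference by at most one
rank.

z-scores divide the sample−median difference by the SD floored at the
region's 10th-percentile SD (and 1e-6 absolute): the baseline windows have
near-zero spread *by construction* of the normalization, and unfloored
division there would manufacture calls out of rounding noise.

A sample is a **variant** when |z| > k for at least m consecutive grid
points in any scope; k = 2, m = 10 (≈ 0.4 °C) by default. The run-length
requirement suppresses single-point excursions; both knobs are monotone
(raising either never creates a variant call). Measured on simulated
cohorts at defaults, wildtype draws from the control distribution are called
normal ≈ 97–98 % of the time; the residual false-positive mode is a
baseline-fit tilt that holds a mild deviation over many points, which is
also why m trades directly against sensitivity to subtle variants.

## Two-step analysis, stratification, preparations

`analyze_experiment` first treats the whole amplicon as one region, then
analyzes each domain separately. Domains are detected **once, on the median
of all control curves** — the median suppresses noise √n-fold and, more
importantly, gives every sample identical scopes, so per-domain results are
comparable across the run (per-sample domain tallies are still reported as a
diagnostic). With `stratify_by_sex`, male/female test samples are compared
against same-sex control bands; a stratum with < 2 controls falls back to
the pooled band with a warning (or raises, with
`stratum_fallback=False`). With `combine_preparations`, samples sharing a
`preparation_group` — the unmixed and mixed preparations of one individual —
are OR-combined: the individual is a variant if *either* preparation
deviates, which is the point of running both.

## Numerical choices and degenerate inputs

* Resampling: linear interpolation onto the intersection of spans, no
  extrapolation; curves already on the target grid are returned untouched
  (bit-equal), making the operation idempotent. Duplicate temperatures in an
  export are an error (a malformed file), not averaged away.
* Grids are uniform to 1e-9 °C; derivative code refuses non-uniform grids.
* A curve whose −dF/dT has no positive values is rejected (not a melt
  curve); a curve with no above-threshold peak yields an empty domain list
  plus a warning, not an exception.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the specs; identical seeds give bit-identical curves, cohorts, and report
  files.

## Problem sizes used by the test suite and acceptance script

Sensitivity is estimated over 20 seeded cohorts of 16 controls + 50
artificial heterozygotes with heteroduplex ΔTm ~ U[−3, −1] °C at 0.5 %
noise; specificity over 10 cohorts × 5 wildtype test draws; oracle
equivalence over 100 random multi-domain curves; Tm recovery over 100 seeds
per slope. These sizes give stable estimates (binomial SE < 1 % on the
sensitivity) while the whole suite runs in well under a minute.

## Known limitations

* Binary calls only: no genotype clustering into more than two classes and
  no allele-fraction estimation; calls are screening results that need
  sequencing confirmation.
* The 10 % height/prominence thresholds are relative to the global −dF/dT
  maximum, so a genuinely tiny domain (< 10 % of the tallest) is invisible
  by design.
* Difference-band calling has no statistical p-value; k and m are
  calibration knobs, and the wildtype false-positive rate (~2–3 % per sample
  at defaults) scales with the number of scopes analyzed.
* No correction for inter-run Tm drift; controls must come from the same run
  as the test samples.
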