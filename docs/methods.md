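# Methods

## The impedance model

Tissue impedance over a frequency sweep is modelled with a single
distributed circuit element (DCE), the Cole-type form

    Z(ω) = R∞ + R / (1 + (iτω)^ψ),   ω = 2πf

- `R∞` (Ω): resistance at the high-frequency limit, where current crosses
  membranes freely and flows through both apoplast and symplast.
- `R` (Ω): difference between the DC resistance and `R∞`; the arc
  amplitude.
- `τ` (s): relaxation time of the membrane/electrolyte polarisation; the
  −Im(Z) peak sits at `ωτ = 1` when `ψ = 1`.
- `ψ` (dimensionless, 0 < ψ ≤ 1): distribution coefficient; `ψ = 1` is an
  ideal RC semicircle, smaller values depress the arc, reflecting a
  distribution of relaxation times in heterogeneous tissue.

The complex power uses the principal branch. Because the base is a
positive real multiple of `i`, `(iτω)^ψ = (τω)^ψ e^{iψπ/2}` with no branch
ambiguity, and Im(Z) ≤ 0 over the whole sweep — the capacitive sign
convention used throughout (Nyquist plots display −Im(Z)).

Closed forms used as test anchors: at `ωτ = 1`, `Re(Z) = R∞ + R/2` for
every `ψ`, and `Im(Z) = −(R/2)·tan(ψπ/4)`; for `ψ = 1` the locus is the
semicircle centred at `(R∞ + R/2, 0)` with radius `R/2`.

## Two-pathway resistances

At low frequency the electrical double layer blocks membrane crossing and
current is confined to the apoplast: `Re = R∞ + R`. The intracellular
pathway is `Ri = R∞ (1 + R∞/R)`. These definitions satisfy the parallel
identity `1/Re + 1/Ri = 1/R∞` exactly, which the suite asserts at 1e-12
relative tolerance. Lumped values are geometry-normalised to specific
resistances `r = (A/l)·R` (Ω·m), with the default geometry a 10 mm cube
measured across opposite faces (`A = 1e-4 m²`, `l = 1e-2 m`).

## Fitting the arc

Complex nonlinear least squares on the stacked residual
`[Re(Z_model) − Z_re, Im(Z_model) − Z_im]`, each point weighted by
`1/|Z_model|` under the default *modulus* weighting (spectra span orders
of magnitude across the sweep; modulus weighting keeps both ends
informative). *Unit* weighting is selectable, and is what the brute-force
grid oracle in the tests uses so both sides minimise the same objective.

`R∞`, `R` and `τ` are optimised in log10 space — they are positive scale
parameters — and `ψ` directly, inside the default box
`R∞, R ∈ [1e-6, 1e12] Ω`, `τ ∈ [1e-9, 1e3] s`, `ψ ∈ [0.3, 1]`. The wide
resistance box accommodates the extreme `rᵢ/rₑ` ratios of sapwood
(10⁻⁶–10⁻⁷), which put `R∞` six to seven orders of magnitude below the
arc amplitude. The optimiser is scipy's Trust Region Reflective
`least_squares` with `xtol = ftol = 1e-15`, giving machine-precision
recovery on noiseless input.

Initialisation reads the sweep: `R∞₀ = min(Z_re)`,
`R₀ = max(Z_re) − min(Z_re)` (floored at `1e-6·R∞₀`), `τ₀ = 1/(2πf_peak)`
from the −Im(Z) peak, `ψ₀ = 0.8`. A sweep whose −Im(Z) has no interior
peak is flagged `NO_ARC`; the fit is still attempted and the flag
propagates. If the first solve fails, up to five restarts are made from
log-uniformly jittered (×0.3–×3) copies of the guess, seeded
deterministically from the sample id; persistent failure returns
`converged=False` with diagnostics rather than raising. Parameters landing
within 1e-6 of a bound (in optimisation coordinates) raise
`EDGE_OF_BOUNDS`.

## LT50 from the freeze response

Specific extracellular resistance rises sigmoidally as freezing exposure
temperature falls, tracking electrolyte leakage from injured membranes.
The four-parameter logistic

    y(x) = A / (1 + e^{B(C − x)}) + D

is fitted to `rₑ` versus temperature; `A` and `D` set the asymptotes,
`B` (per °C) the steepness, and the inflection `C` (°C) is reported as the
LT50. Initialisation is data-driven (`D₀ = min ȳ`, `A₀ = max ȳ − min ȳ`,
`C₀` at the half-transition, `B₀ = ±4·slope/A₀`); both signs of `B` are
attempted because the orientation is not assumed, the lower-residual fit
wins, and exact ties break toward `B < 0` (resistance rising toward cold,
the physically usual direction). The exponent is clamped to ±700 so
extreme arguments saturate instead of overflowing.

A single series is fitted on per-temperature replicate means. The pipeline
defaults to *per-replicate* fitting — each replicate's series is fitted
separately and the cell's LT50 is the mean of the replicate inflections
with its standard error, mirroring how replicated freezing experiments
report means ± SE — with pooled-mean fitting selectable. Constant series
are flagged `DEGENERATE` (no inflection exists); an inflection outside the
observed temperature range is flagged `EXTRAPOLATED`; fits with
`r² < 0.8` are reported but flagged `LOW_CONFIDENCE` (the threshold is a
reporting convention of this package, not a literature value). An optional
temperature window restricts the fit range for series that show a second
transition at very deep frost.

At least five distinct temperatures are required per fit: four parameters
leave no residual degree of freedom below that.

## Synthetic study

The generator reproduces the factorial design of the underlying freezing
experiment: 2 species × 2 cooling rates (2 and 10 °C/min) × 6 moisture
levels (200, 150, 100, 80, 30, 10% of oven-dry mass) × 2 durations
(0.5, 1 h) = 48 cells, each at 8 temperatures (−10 … −80 °C) with 3
replicate sweeps of 40 log-spaced frequencies over 80 Hz – 1 MHz.

Ground truth per cell: `rₑ(T)` follows the logistic with its inflection at
the cell's planted LT50 — by default the published mean from the packaged
reference table, so recovery tests face the real spread of effect sizes.
Sigmoid shape defaults are `D = 10 Ω·m`, `A = 40 Ω·m` (a 5:1 ratio between
the frozen and unfrozen plateaus) and `B = −0.25 /°C`; the source
experiment reports no fitted amplitudes, so these are order-of-magnitude
choices fixed once, sized so the transition spans several grid
temperatures. `rₑ(T)` is back-converted to arc parameters through the
two-pathway identity with `Ri = (rᵢ/rₑ)·Re`, ratio default `3e-7` (the
geometric middle of the observed 10⁻⁶–10⁻⁷ band). `τ(T)` is log-linear
from 1e-4 s at −10 °C to 1e-2 s at −80 °C (relaxation slows as tissue
freezes; the trend is reported, the magnitudes are package choices), and
`ψ = 0.8` throughout.

Noise is proportional Gaussian, independent per frequency point and per
real/imaginary component, default σ = 2% — the simplest model consistent
with an LCR bridge's relative accuracy, since no instrument noise
characterisation exists for the source data. Seeding is one master seed
plus a stable CRC32 hash of (cell, temperature, replicate), so regeneration
is byte-identical and independent of generation order or parallelism.

What the generator does *not* emulate: electrode polarisation at the
low-frequency end, drift within a sweep, the second resistance transition
some tissues show near −70 °C, inductive tails, or any temperature
dependence of `ψ`. Passing recovery tests therefore demonstrates that the
analysis chain is correct and well-conditioned under the stated noise
model — not that real spectra are this clean.

## Problem sizes and numerical checks

The test suite and the acceptance script use: 20 random parameter draws
for zero-noise arc recovery (tolerance 1e-6 relative); 200 seeded 1%-noise
replicates for the noisy medians; a 50-points-per-decade grid-search
oracle over a ±0.25-decade bound box on 5 noisy spectra (the fitter's
residual must never exceed the lattice optimum); 100 simulations of the
5-replicate, 2%-noise sigmoid recovery; and the full 48-cell study at
zero and 2% noise. These sizes make the whole verification run in about a
minute on one CPU while keeping Monte-Carlo standard errors well below
the asserted tolerances.

## Known limitations

- Single-arc model only: tissues with two resolvable dispersions need a
  multi-element circuit, which is out of scope.
- `R∞` (hence `Ri`) is weakly identified when it is many orders of
  magnitude below the arc amplitude and noise is present; `Re`, which
  drives the LT50, is unaffected. The fitted-ratio property is therefore
  asserted on noiseless spectra.
- The duration-effect percentage is computed on LT50 magnitudes with the
  0.5 h value as baseline; other conventions exist, so every summary
  carries its formula string.
- LT50 here is an impedance-inflection proxy for half-lethal injury; no
  survival-fraction calibration is performed.
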