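# frosteis

Freeze-injury analysis of woody plant tissue from electrical impedance
spectroscopy (EIS).

When sapwood freezes, ice formation and cell dehydration injure cell
membranes; symplastic electrolytes leak into the apoplast and the tissue's
electrical properties change. `frosteis` turns measured impedance sweeps
into a physiological damage threshold — the semi-lethal temperature
**LT50** — through three stages:

1. **Arc fitting.** Each frequency sweep (80 Hz – 1 MHz) is fitted with the
   single distributed-circuit-element (Cole-type) model

   `Z(ω) = R∞ + R / (1 + (iτω)^ψ)`

   with high-frequency resistance `R∞` (Ω), arc amplitude `R` (Ω, the
   difference between the DC resistance and `R∞`), relaxation time `τ` (s)
   and distribution coefficient `ψ ∈ (0, 1]`, by complex nonlinear least
   squares on the stacked real/imaginary residual (modulus weighting by
   default).

2. **Resistance extraction.** The lumped two-pathway resistances follow as
   `Re = R∞ + R` (extracellular) and `Ri = R∞(1 + R∞/R)` (intracellular),
   which satisfy `1/Re + 1/Ri = 1/R∞` exactly; both are normalised by the
   sample geometry, `r = (A/l)·R`, to specific resistances in Ω·m.

3. **LT50 estimation.** Per experimental condition, specific extracellular
   resistance versus freezing-exposure temperature is fitted with the
   four-parameter logistic `y = A / (1 + e^{B(C − x)}) + D`; the inflection
   temperature `C` is the LT50.

A packaged reference table (48 published LT50 means ± SE for pine and
poplar sapwood across 2 cooling rates × 6 moisture levels × 2 freezing
durations) feeds the study-level summaries, and a seeded synthetic
generator (`frosteis.simulate`) reproduces the full factorial experiment
with known ground truth so the entire chain is verifiable by parameter
recovery.

## Worked example

```python
import numpy as np
import frosteis as fe

truth = fe.DCEParameters(r_inf=100.0, r_arc=900.0, tau=1e-3, psi=0.8)
f = np.logspace(np.log10(80.0), 6.0, 40)
z = fe.dce_impedance(truth, f)
rng = np.random.default_rng(42)
spec = fe.ImpedanceSpectrum(
    frequencies=f,
    z_real=z.real * (1 + rng.normal(0, 0.01, len(f))),
    z_imag=z.imag * (1 + rng.normal(0, 0.01, len(f))),
    meta=fe.SampleMeta(sample_id="demo-cube", temperature=-40.0),
)
result = fe.fit_dce(spec)
lumped = fe.lumped_resistances(result.params, spec.meta)
print(result.params)
print(lumped.re_ohm, lumped.re_specific)
```

At 1% measurement noise this recovers `R∞ ≈ 100.11 Ω`, `R ≈ 904.6 Ω`,
`τ ≈ 1.011 ms`, `ψ ≈ 0.799` and reports `Re ≈ 1004.7 Ω`, i.e.
`rₑ ≈ 10.05 Ω·m` for the default 10 mm cube geometry — within about half a
percent of the planted values. The extracellular resistance is the quantity
that carries the freeze-injury signal downstream.

The scripts in `examples/` run one capability each (single-spectrum fit,
LT50 estimation, factorial simulation + recovery, reference-table
summaries) and print what the numbers mean; `examples/04` reports, from the
packaged table, a 19.98 °C LT50 gap between the wettest (200%) and driest
(10%) pine samples and a maximum duration effect of 52.52%.

A thin CLI mirrors the pipeline for shell use:

```sh
frosteis simulate-study --out study --sigma 0.02 --seed 1
frosteis run-all --manifest study/manifest.csv --out results
```

## Layout

- `src/frosteis/spectra.py` — spectrum container, CSV dialect, metadata
- `src/frosteis/dce.py` — arc model, fitter, resistance identities
- `src/frosteis/lt50.py` — logistic fit and LT50 estimation
- `src/frosteis/fixtures.py` — packaged reference LT50 table
- `src/frosteis/simulate.py` — seeded synthetic factorial study
- `src/frosteis/pipeline.py` — orchestration and summaries
- `src/frosteis/cli.py` — command-line interface
- `docs/methods.md` — model assumptions, defaults, and design notes
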