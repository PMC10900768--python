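"""Seeded synthetic factorial freezing study.

The measured study design is 2 species x 2 cooling rates x 6 moisture
levels x 2 freezing durations = 48 condition cells, each exposed at 8
temperatures (-10 .. -80 deg C) with replicated impedance sweeps over
80 Hz .. 1 MHz.  This module regenerates that design synthetically with a
known ground truth so the whole analysis chain — arc fitting, resistance
extraction, sigmoid LT50 estimation, summaries — can be scored by
parameter recovery instead of requiring the (undeposited) raw spectra.

Ground truth per cell is a logistic trajectory of specific extracellular
resistance r_e(T) whose inflection equals a planted LT50 (by default the
cell's published value), back-converted at every temperature to single-DCE
parameters via the lumped-resistance identities; spectra are the exact
forward model plus proportional Gaussian noise.  All randomness derives
from one master seed and a stable per-spectrum hash, so regeneration is
byte-identical and independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dce import DCEParameters, dce_impedance
from .errors import ConfigurationError
from .fixtures import (
    COOLING_RATE_C_PER_MIN,
    DURATIONS_H,
    MC_LEVELS_PCT,
    lookup_lt50,
)
from .lt50 import sigmoid
from .spectra import (
    DEFAULT_CROSS_AREA_M2,
    DEFAULT_LENGTH_M,
    ImpedanceSpectrum,
    SampleMeta,
    write_spectrum,
)

__all__ = [
    "CellKey",
    "StudyDesign",
    "TruthTrajectory",
    "NoiseModel",
    "StudyDataset",
    "make_truth",
    "simulate_spectrum",
    "simulate_study",
    "write_study",
]


class CellKey(NamedTuple):
    """One condition cell of the factorial design."""

    species: str
    cooling_rate_label: str
    mc_pct: float
    duration_h: float


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout and measurement grid of the freezing experiment."""

    species: tuple[str, ...] = ("Pi", "Po")
    cooling_rate_labels: tuple[str, ...] = ("Slow", "Fast")
    mc_levels_pct: tuple[float, ...] = MC_LEVELS_PCT
    durations_h: tuple[float, ...] = DURATIONS_H
    temperatures_c: tuple[float, ...] = (-10, -20, -30, -40, -50, -60, -70, -80)
    replicates: int = 3
    n_frequencies: int = 40
    freq_range_hz: tuple[float, float] = (80.0, 1.0e6)
    cross_area_m2: float = DEFAULT_CROSS_AREA_M2
    length_m: float = DEFAULT_LENGTH_M

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        if np.any(np.diff(t) >= 0):
            raise ConfigurationError("temperature grid must be strictly decreasing")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.n_frequencies < 8:
            raise ConfigurationError("need at least 8 frequency points")

    @property
    def cells(self) -> list[CellKey]:
        return [
            CellKey(sp, rate, mc, dur)
            for sp in self.species
            for rate in self.cooling_rate_labels
            for mc in self.mc_levels_pct
            for dur in self.durations_h
        ]

    @property
    def frequencies_hz(self) -> np.ndarray:
        lo, hi = self.freq_range_hz
        return np.logspace(np.log10(lo), np.log10(hi), self.n_frequencies)

    @property
    def geometry_factor(self) -> float:
        """A / l in metres: converts ohm to ohm * m."""
        return self.cross_area_m2 / self.length_m


@dataclass(frozen=True)
class TruthTrajectory:
    """Ground truth for one cell.

    r_e(T) follows the logistic with inflection ``true_lt50_c`` between the
    plateaus; tau(T) is log-linear between its values at the warmest and
    coldest grid temperatures (relaxation slows as tissue freezes); psi is
    constant; the intracellular path is ``ri_over_re`` of the extracellular
    one, as observed for sapwood (1e-6 .. 1e-7).
    """

    true_lt50_c: float
    re_plateau_low: float = 10.0      # ohm * m, unfrozen asymptote (D)
    re_plateau_high: float = 50.0     # ohm * m, fully injured asymptote (A + D)
    slope_b: float = -0.25            # per deg C; negative: r_e rises as T falls
    ri_over_re: float = 3.0e-7
    tau_warm_s: float = 1.0e-4
    tau_cold_s: float = 1.0e-2
    psi_value: float = 0.8
    t_warm_c: float = -10.0
    t_cold_c: float = -80.0

    def __post_init__(self) -> None:
        if not (self.re_plateau_high > self.re_plateau_low > 0):
            raise ConfigurationError("need re_plateau_high > re_plateau_low > 0")
        if not (1e-8 <= self.ri_over_re <= 1e-1):
            raise ConfigurationError("ri_over_re outside the plausible band [1e-8, 1e-1]")
        if not (0 < self.psi_value <= 1):
            raise ConfigurationError("psi_value must lie in (0, 1]")
        if self.tau_cold_s <= self.tau_warm_s:
            raise ConfigurationError("tau must increase toward colder temperatures")

    @property
    def sigmoid_params(self) -> tuple[float, float, float, float]:
        a = self.re_plateau_high - self.re_plateau_low
        return (a, self.slope_b, self.true_lt50_c, self.re_plateau_low)

    def re_specific(self, temperature_c: float) -> float:
        """Planted specific extracellular resistance at T, ohm * m."""
        return float(sigmoid(temperature_c, self.sigmoid_params))

    def tau(self, temperature_c: float) -> float:
        """Relaxation time at T, s (log-linear in temperature)."""
        frac = (temperature_c - self.t_warm_c) / (self.t_cold_c - self.t_warm_c)
        return float(10.0 ** (
            np.log10(self.tau_warm_s)
            + frac * (np.log10(self.tau_cold_s) - np.log10(self.tau_warm_s))
        ))

    def dce_parameters(self, temperature_c: float, geometry_factor: float) -> DCEParameters:
        """Back-convert r_e(T) to the four arc parameters.

        Re = r_e * l / A; Ri = ri_over_re * Re; R_inf solves the two-pathway
        identity 1/Re + 1/Ri = 1/R_inf; r_arc = Re - R_inf.
        """
        re_ohm = self.re_specific(temperature_c) / geometry_factor
        ri_ohm = self.ri_over_re * re_ohm
        r_inf = 1.0 / (1.0 / re_ohm + 1.0 / ri_ohm)
        return DCEParameters(
            r_inf=r_inf,
            r_arc=re_ohm - r_inf,
            tau=self.tau(temperature_c),
            psi=self.psi_value,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Proportional Gaussian noise, independent per point and component."""

    sigma_prop: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_prop < 0:
            raise ConfigurationError("sigma_prop must be >= 0")


def make_truth(
    design: StudyDesign,
    source: str = "table2",
    configured_lt50: dict[CellKey, float] | float | None = None,
    **trajectory_overrides,
) -> dict[CellKey, TruthTrajectory]:
    """Ground-truth trajectory for every cell of the design.

    ``source='table2'`` plants each cell's LT50 at its published mean, so
    recovery tests face the real spread of effect sizes; with
    ``source='configured'`` the LT50 comes from ``configured_lt50`` (one
    value or a per-cell mapping).  Extra keyword arguments override
    :class:`TruthTrajectory` defaults for every cell.
    """
    if source not in ("table2", "configured"):
        raise ConfigurationError(f"unknown truth source {source!r}")
    t_grid = np.asarray(design.temperatures_c, dtype=float)
    truth: dict[CellKey, TruthTrajectory] = {}
    for cell in design.cells:
        if source == "table2":
            lt50 = lookup_lt50(cell.species, cell.cooling_rate_label,
                               cell.mc_pct, cell.duration_h).lt50_mean
        elif isinstance(configured_lt50, dict):
            lt50 = configured_lt50[cell]
        elif configured_lt50 is not None:
            lt50 = float(configured_lt50)
        else:
            raise ConfigurationError("source='configured' needs configured_lt50")
        if not (t_grid.min() < lt50 < t_grid.max()):
            raise ConfigurationError(
                f"planted LT50 {lt50} deg C outside the temperature grid "
                f"({t_grid.min()} .. {t_grid.max()})"
            )
        kwargs = {"t_warm_c": float(t_grid.max()), "t_cold_c": float(t_grid.min())}
        kwargs.update(trajectory_overrides)
        truth[cell] = TruthTrajectory(true_lt50_c=lt50, **kwargs)
    return truth


def _sample_id(cell: CellKey, temperature_c: float, replicate: int) -> str:
    return (
        f"{cell.species}-{cell.cooling_rate_label}-mc{cell.mc_pct:g}"
        f"-d{cell.duration_h:g}h-T{temperature_c:g}-r{replicate}"
    )


def _spectrum_rng(seed: int, cell: CellKey, temperature_c: float,
                  replicate: int) -> np.random.Generator:
    # stable per-spectrum stream: order of generation never matters
    tag = f"{_sample_id(cell, temperature_c, replicate)}"
    return np.random.default_rng(
        np.random.SeedSequence((seed, zlib.crc32(tag.encode("utf-8"))))
    )


def simulate_spectrum(
    truth: TruthTrajectory,
    cell: CellKey,
    temperature_c: float,
    design: StudyDesign,
    noise: NoiseModel,
    replicate: int = 1,
) -> ImpedanceSpectrum:
    """One noisy sweep for (cell, temperature, replicate).

    The real and imaginary parts are each scaled by an independent
    (1 + N(0, sigma_prop)) factor per frequency point; sigma_prop = 0
    returns the exact forward model.  The draw depends only on
    (noise.seed, cell, temperature, replicate).
    """
    params = truth.dce_parameters(temperature_c, design.geometry_factor)
    f = design.frequencies_hz
    z = dce_impedance(params, f)
    zr, zi = z.real.copy(), z.imag.copy()
    if noise.sigma_prop > 0:
        rng = _spectrum_rng(noise.seed, cell, temperature_c, replicate)
        eps = rng.normal(0.0, noise.sigma_prop, size=(2, len(f)))
        zr *= 1.0 + eps[0]
        zi *= 1.0 + eps[1]
    meta = SampleMeta(
        sample_id=_sample_id(cell, temperature_c, replicate),
        species=cell.species,
        moisture_content=cell.mc_pct,
        cooling_rate=COOLING_RATE_C_PER_MIN.get(cell.cooling_rate_label, 2.0),
        duration=cell.duration_h,
        temperature=temperature_c,
        cross_area=design.cross_area_m2,
        length=design.length_m,
        replicate=replicate,
    )
    return ImpedanceSpectrum(frequencies=f, z_real=zr, z_imag=zi, meta=meta)


@dataclass(frozen=True)
class StudyDataset:
    """All spectra of one simulated study plus the truth table."""

    design: StudyDesign
    spectra: tuple[ImpedanceSpectrum, ...]
    truth_table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.spectra)


def simulate_study(
    design: StudyDesign,
    truth: dict[CellKey, TruthTrajectory],
    noise: NoiseModel,
) -> StudyDataset:
    """Generate the full factorial dataset.

    Emits ``len(design.cells) * len(temperatures) * replicates`` spectra
    and a truth table (one row per cell: planted LT50 and trajectory
    parameters) for recovery scoring.
    """
    spectra = []
    rows = []
    for cell in design.cells:
        tr = truth[cell]
        rows.append({
            "species": cell.species,
            "cooling_rate_label": cell.cooling_rate_label,
            "mc_pct": cell.mc_pct,
            "duration_h": cell.duration_h,
            "true_lt50_c": tr.true_lt50_c,
            "re_plateau_low": tr.re_plateau_low,
            "re_plateau_high": tr.re_plateau_high,
            "slope_b": tr.slope_b,
            "ri_over_re": tr.ri_over_re,
            "tau_warm_s": tr.tau_warm_s,
            "tau_cold_s": tr.tau_cold_s,
            "psi_value": tr.psi_value,
        })
        for t in design.temperatures_c:
            for rep in range(1, design.replicates + 1):
                spectra.append(
                    simulate_spectrum(tr, cell, float(t), design, noise, rep)
                )
    return StudyDataset(
        design=design, spectra=tuple(spectra), truth_table=pd.DataFrame(rows)
    )


def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write every spectrum CSV plus manifest.csv and truth.csv.

    Returns the manifest path; spectrum paths in the manifest are relative
    to the manifest's directory.
    """
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for spec in dataset.spectra:
        name = f"{spec.meta.sample_id}.csv"
        write_spectrum(spec, spectra_dir / name)
        manifest_rows.append({"sample_id": spec.meta.sample_id,
                              "path": f"spectra/{name}"})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    dataset.truth_table.to_csv(out_dir / "truth.csv", index=False)
    return manifest
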