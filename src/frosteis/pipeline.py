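"""Spectra -> DCE fits -> r_e(T) series -> LT50 table -> summaries.

The orchestration layer: fit every spectrum, derive specific resistances,
group samples into per-cell freeze-response series, estimate LT50 per
condition cell, and compute the two study-level summaries — the
duration effect (how much warmer the LT50 is after 1 h than after 0.5 h
of freezing) and the moisture-content extreme difference (LT50 gap
between the wettest and driest samples of a group).

Percentage change for the duration effect is computed on LT50 magnitudes
with the short duration as the baseline:

    pct = 100 * (|LT50_0.5h| - |LT50_1h|) / |LT50_0.5h|

The formula string is carried in the report so downstream readers never
have to guess the convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dce
from .errors import ConfigurationError, FrosteisError
from .fixtures import COOLING_RATE_C_PER_MIN
from .lt50 import FreezeResponseSeries, estimate_lt50
from .spectra import ImpedanceSpectrum, SampleMeta, read_spectrum

__all__ = [
    "RunConfig",
    "SummaryReport",
    "DurationEffect",
    "fit_all_spectra",
    "estimate_lt50_table",
    "duration_effect",
    "mc_extreme_difference",
    "summarize",
    "read_result_table",
    "run_pipeline",
    "analyze_dataset",
]

DURATION_EFFECT_FORMULA = "100 * (|LT50_0.5h| - |LT50_1h|) / |LT50_0.5h|"


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    # shortest round-trip repr keeps the full float64 value, so written
    # tables re-read exactly (pair with read_result_table)
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline result CSV with bit-exact float round-trip."""
    return pd.read_csv(path, float_precision="round_trip")

_LABEL_BY_RATE = {v: k for k, v in COOLING_RATE_C_PER_MIN.items()}


def _rate_label(rate_c_per_min: float) -> str:
    return _LABEL_BY_RATE.get(rate_c_per_min, f"{rate_c_per_min:g}C/min")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    manifest: str
    output_dir: str
    weighting: str = "modulus"
    max_restarts: int = 5
    per_replicate: bool = True
    temperature_window: tuple[float, float] | None = None
    min_temperatures: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "temperature_window" in raw and raw["temperature_window"] is not None:
            raw["temperature_window"] = tuple(raw["temperature_window"])
        return cls(**raw)


def fit_all_spectra(
    spectra: list[ImpedanceSpectrum],
    weighting: str = "modulus",
    max_restarts: int = 5,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Fit the single-DCE model to every spectrum.

    Returns the fit report: one row per sample with the four arc
    parameters, the lumped and specific resistances, and diagnostics.
    """
    rows = []
    for spec in spectra:
        meta = spec.meta
        if meta is None:
            meta = SampleMeta(sample_id=f"sample-{len(rows)}")
        result = dce.fit_dce(spec, weighting=weighting, max_restarts=max_restarts)
        lumped = dce.lumped_resistances(result.params, meta)
        if log is not None and not result.converged:
            log.append(f"fit did not converge: {meta.sample_id}")
        if log is not None and result.quality_flags:
            log.append(
                f"fit flags {sorted(result.quality_flags)}: {meta.sample_id}"
            )
        rows.append({
            "sample_id": meta.sample_id,
            "species": meta.species,
            "cooling_rate": meta.cooling_rate,
            "cooling_rate_label": _rate_label(meta.cooling_rate),
            "mc_pct": meta.moisture_content,
            "duration_h": meta.duration,
            "temperature_c": meta.temperature,
            "replicate": meta.replicate,
            "r_inf": result.params.r_inf,
            "r_arc": result.params.r_arc,
            "tau": result.params.tau,
            "psi": result.params.psi,
            "re_ohm": lumped.re_ohm,
            "ri_ohm": lumped.ri_ohm,
            "re_specific": lumped.re_specific,
            "ri_specific": lumped.ri_specific,
            "residual_norm": result.residual_norm,
            "converged": result.converged,
            "flags": ";".join(sorted(result.quality_flags)),
        })
    return pd.DataFrame(rows)


_CELL_COLS = ["species", "cooling_rate_label", "mc_pct", "duration_h"]


def estimate_lt50_table(
    fit_report: pd.DataFrame,
    per_replicate: bool = True,
    temperature_window: tuple[float, float] | None = None,
    min_temperatures: int = 5,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """LT50 per condition cell from a fit report.

    In per-replicate mode (default) each replicate's r_e(T) series is
    fitted separately and the cell's LT50 is the mean of the replicate
    inflections with its standard error — mirroring how a replicated
    experiment reports means +/- SE.  In pooled mode one sigmoid is fitted
    to the per-temperature means and the SE column is NaN.  Cells with
    fewer usable temperatures than ``min_temperatures`` are skipped with a
    logged reason.
    """
    rows = []
    for cell, grp in fit_report.groupby(_CELL_COLS, sort=True):
        cell_d = dict(zip(_CELL_COLS, cell))
        n_temps = grp["temperature_c"].nunique()
        if n_temps < min_temperatures:
            if log is not None:
                log.append(
                    f"cell {cell}: skipped, only {n_temps} usable temperatures"
                )
            continue
        condition = tuple(cell)
        estimates = []
        if per_replicate and grp["replicate"].nunique() > 1:
            for _, rep_grp in grp.groupby("replicate"):
                if rep_grp["temperature_c"].nunique() < min_temperatures:
                    continue
                series = FreezeResponseSeries(
                    condition=condition,
                    temperatures_c=rep_grp["temperature_c"].to_numpy(),
                    re_specific=rep_grp["re_specific"].to_numpy(),
                    replicates=rep_grp["replicate"].to_numpy(),
                )
                estimates.append(estimate_lt50(series, temperature_window))
        else:
            series = FreezeResponseSeries(
                condition=condition,
                temperatures_c=grp["temperature_c"].to_numpy(),
                re_specific=grp["re_specific"].to_numpy(),
                replicates=grp["replicate"].to_numpy(),
            )
            estimates.append(estimate_lt50(series, temperature_window))

        good = [e for e in estimates if e.converged]
        if not good:
            if log is not None:
                log.append(f"cell {cell}: no converged sigmoid fit")
            continue
        c_vals = np.array([e.lt50_c for e in good])
        se = (
            float(np.std(c_vals, ddof=1) / math.sqrt(len(c_vals)))
            if len(c_vals) > 1 else float("nan")
        )
        flags = sorted(set().union(*(e.quality_flags for e in good)))
        rows.append({
            **cell_d,
            "lt50_c": float(np.mean(c_vals)),
            "lt50_se_c": se,
            "fit_r2": float(np.mean([e.r_squared for e in good])),
            "n_fits": len(good),
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)


def _as_lt50_frame(table) -> pd.DataFrame:
    """Accept a DataFrame or a list of LT50Record."""
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame([
        {
            "species": r.species,
            "cooling_rate_label": r.cooling_rate_label,
            "mc_pct": r.moisture_content,
            "duration_h": r.duration,
            "lt50_c": r.lt50_mean,
            "lt50_se_c": r.lt50_se,
        }
        for r in table
    ])


@dataclass(frozen=True)
class DurationEffect:
    """Per-condition % change of LT50 magnitude between freezing durations."""

    species: str
    per_condition: pd.DataFrame = field(repr=False)
    mean_pct: float = float("nan")
    max_pct: float = float("nan")
    formula: str = DURATION_EFFECT_FORMULA


def duration_effect(table, species: str,
                    log: list[str] | None = None) -> DurationEffect:
    """Duration effect of one species across all (rate, MC) pairs.

    For each pair with both durations present, the percentage by which the
    1 h LT50 magnitude falls short of the 0.5 h one (positive when the
    longer freeze kills at a warmer temperature).  Pairs missing a duration
    partner are skipped with a warning.
    """
    df = _as_lt50_frame(table)
    df = df[df["species"] == species]
    short, long_ = sorted(df["duration_h"].unique())[:2] if df["duration_h"].nunique() >= 2 else (0.5, 1.0)
    rows = []
    for (rate, mc), grp in df.groupby(["cooling_rate_label", "mc_pct"]):
        by_dur = {d: g["lt50_c"].iloc[0] for d, g in grp.groupby("duration_h")}
        if short not in by_dur or long_ not in by_dur:
            if log is not None:
                log.append(
                    f"duration_effect {species} ({rate}, {mc}%): missing a "
                    "duration partner, pair skipped"
                )
            continue
        l_short, l_long = abs(by_dur[short]), abs(by_dur[long_])
        rows.append({
            "species": species,
            "cooling_rate_label": rate,
            "mc_pct": mc,
            "lt50_short_c": by_dur[short],
            "lt50_long_c": by_dur[long_],
            "pct_change": 100.0 * (l_short - l_long) / l_short,
        })
    per_condition = pd.DataFrame(rows)
    if per_condition.empty:
        return DurationEffect(species=species, per_condition=per_condition)
    return DurationEffect(
        species=species,
        per_condition=per_condition,
        mean_pct=float(per_condition["pct_change"].mean()),
        max_pct=float(per_condition["pct_change"].max()),
    )


def mc_extreme_difference(
    table, species: str, cooling_rate_label: str, duration_h: float
) -> float:
    """|LT50(highest MC) - LT50(lowest MC)| for one (species, rate, duration).

    The extremes are the largest and smallest moisture-content levels
    present in the table for that group (200% and 10% in the full design).
    """
    df = _as_lt50_frame(table)
    grp = df[
        (df["species"] == species)
        & (df["cooling_rate_label"] == cooling_rate_label)
        & (df["duration_h"] == duration_h)
    ]
    if grp.empty:
        raise KeyError(
            f"no LT50 rows for ({species}, {cooling_rate_label}, {duration_h} h)"
        )
    mc_hi, mc_lo = grp["mc_pct"].max(), grp["mc_pct"].min()
    lt_hi = grp.loc[grp["mc_pct"] == mc_hi, "lt50_c"].iloc[0]
    lt_lo = grp.loc[grp["mc_pct"] == mc_lo, "lt50_c"].iloc[0]
    return float(abs(lt_hi - lt_lo))


@dataclass(frozen=True)
class SummaryReport:
    """Study-level summaries, all pure functions of the LT50 table."""

    lt50_table: pd.DataFrame = field(repr=False)
    duration_effects: dict[str, DurationEffect] = field(repr=False, default_factory=dict)
    mc_extremes: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    formula: str = DURATION_EFFECT_FORMULA


def summarize(lt50_table, log: list[str] | None = None) -> SummaryReport:
    """Duration effects per species and MC-extreme differences per group."""
    df = _as_lt50_frame(lt50_table)
    effects = {
        sp: duration_effect(df, sp, log=log) for sp in sorted(df["species"].unique())
    }
    rows = []
    for (sp, rate, dur), _ in df.groupby(
        ["species", "cooling_rate_label", "duration_h"]
    ):
        rows.append({
            "species": sp,
            "cooling_rate_label": rate,
            "duration_h": dur,
            "mc_extreme_diff_c": mc_extreme_difference(df, sp, rate, dur),
        })
    return SummaryReport(
        lt50_table=df,
        duration_effects=effects,
        mc_extremes=pd.DataFrame(rows),
    )


def analyze_dataset(
    spectra: list[ImpedanceSpectrum],
    weighting: str = "modulus",
    max_restarts: int = 5,
    per_replicate: bool = True,
    temperature_window: tuple[float, float] | None = None,
    min_temperatures: int = 5,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SummaryReport]:
    """In-memory pipeline: spectra -> (fit report, LT50 table, summary)."""
    fit_report = fit_all_spectra(
        spectra, weighting=weighting, max_restarts=max_restarts, log=log
    )
    lt50_table = estimate_lt50_table(
        fit_report,
        per_replicate=per_replicate,
        temperature_window=temperature_window,
        min_temperatures=min_temperatures,
        log=log,
    )
    report = summarize(lt50_table, log=log)
    return fit_report, lt50_table, report


def _load_manifest(manifest_path: Path, log: list[str]) -> list[ImpedanceSpectrum]:
    mdf = pd.read_csv(manifest_path)
    if "path" not in mdf.columns:
        raise ConfigurationError(f"{manifest_path}: manifest needs a 'path' column")
    if mdf.empty:
        raise ConfigurationError(f"{manifest_path}: empty manifest")
    base = manifest_path.parent
    spectra = []
    for _, row in mdf.iterrows():
        p = base / str(row["path"])
        try:
            spectra.append(read_spectrum(p))
        except FrosteisError as exc:
            log.append(f"excluded {row['path']}: {exc}")
    return spectra


def _write_summary_csv(report: SummaryReport, path: Path) -> None:
    rows = []
    for sp, eff in report.duration_effects.items():
        for _, r in eff.per_condition.iterrows():
            rows.append({
                "statistic": "duration_effect_pct",
                "species": sp,
                "cooling_rate_label": r["cooling_rate_label"],
                "mc_pct": r["mc_pct"],
                "duration_h": "",
                "value": r["pct_change"],
                "formula": eff.formula,
            })
        rows.append({
            "statistic": "duration_effect_mean_pct", "species": sp,
            "cooling_rate_label": "", "mc_pct": "", "duration_h": "",
            "value": eff.mean_pct, "formula": eff.formula,
        })
        rows.append({
            "statistic": "duration_effect_max_pct", "species": sp,
            "cooling_rate_label": "", "mc_pct": "", "duration_h": "",
            "value": eff.max_pct, "formula": eff.formula,
        })
    for _, r in report.mc_extremes.iterrows():
        rows.append({
            "statistic": "mc_extreme_diff_c",
            "species": r["species"],
            "cooling_rate_label": r["cooling_rate_label"],
            "mc_pct": "",
            "duration_h": r["duration_h"],
            "value": r["mc_extreme_diff_c"],
            "formula": "|LT50(highest MC) - LT50(lowest MC)|",
        })
    _to_csv(pd.DataFrame(rows), path)


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Run the whole chain from a manifest of spectrum CSVs.

    Writes ``fit_report.csv``, ``lt50.csv``, ``summary.csv`` and
    ``run.log`` into the output directory.  Corrupted spectrum files and
    cells with too few temperatures are logged and excluded; the run
    continues.  Outputs are deterministic functions of the inputs and
    configuration (the log carries no timestamps), so a rerun is
    byte-identical.
    """
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise ConfigurationError(f"manifest not found: {manifest_path}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"manifest: {manifest_path.name}",
                      f"weighting: {config.weighting}",
                      f"per_replicate: {config.per_replicate}"]

    spectra = _load_manifest(manifest_path, log)
    if not spectra:
        raise ConfigurationError("no usable spectra in manifest")
    log.append(f"spectra loaded: {len(spectra)}")

    fit_report, lt50_table, report = analyze_dataset(
        spectra,
        weighting=config.weighting,
        max_restarts=config.max_restarts,
        per_replicate=config.per_replicate,
        temperature_window=config.temperature_window,
        min_temperatures=config.min_temperatures,
        log=log,
    )
    log.append(f"cells estimated: {len(lt50_table)}")

    _to_csv(fit_report, out / "fit_report.csv")
    _to_csv(lt50_table, out / "lt50.csv")
    _write_summary_csv(report, out / "summary.csv")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    return report
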