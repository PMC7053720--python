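"""File formats, configuration and the end-to-end pipeline.

Patient files are one CSV per subject with mandatory header
``time_min,plasma_mg_l,taps_per_min``; a blank cell means the quantity was
not sampled at that time (plasma stops at 3 h, tapping runs to 4 h).
Results files are one row per patient with the nine estimates and fit
diagnostics.  Configuration is a TOML file with sections mirroring the
module structure (``pk``, ``pd``, ``network``, ``synth``, ``estimation``);
unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bg_network import (
    FrequencyCurve,
    NetworkConfig,
    default_frequency_curve,
    steady_state_frequency_curve,
    default_synapses,
)
from .cohort_analysis import compare_groups
from .errors import FormatError, InputError
from .estimation import RestartRanges, fit_pd
from .fitresult import FitResult
from .pharmacokinetics import DEFAULT_PK_GUESS, DoseEvent, fit_pk
from .series import SampledSeries
from .synthetic_data import PatientRecord, generate_cohort

__all__ = [
    "RunConfig",
    "load_config",
    "read_patient_csv",
    "write_patient_csv",
    "fit_patient",
    "write_fit_results",
    "read_fit_results",
    "run_pipeline",
]

logger = logging.getLogger("levotap")

_PATIENT_COLUMNS = ("time_min", "plasma_mg_l", "taps_per_min")

_RESULT_COLUMNS = (
    "id", "group", "k12", "k21", "ketot", "ke3", "D0", "T", "Dmax",
    "Dc50", "ND", "cost_pk", "cost_pd", "r2_LD", "r2_tapping",
    "best_restart", "seed",
)


@dataclass(frozen=True)
class PKConfig:
    V1_l: float = 30.0
    V2_l: float = 30.0
    ka_per_min: float = 0.035
    initial_guess: tuple[float, float, float] = DEFAULT_PK_GUESS


@dataclass(frozen=True)
class PDConfig:
    internal_grid_min: float = 1.0
    v3_l: float = 30.0  # inert: the link model has unit gain, V3 drops out


@dataclass(frozen=True)
class SynthConfig:
    n_stable: int = 13
    n_fluctuating: int = 13
    plasma_cv: float = 0.08
    tapping_sd: float = 7.0


@dataclass(frozen=True)
class EstimationConfig:
    n_restarts: int = 10
    maxiter: int = 1000
    cost_max_weight: float = 10.0
    n_hops: int = 2
    axis_rounds: int = 0
    ke3_profile: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; every field has a shipped default."""

    seed: int = 0
    input_dir: str | None = None
    output_dir: str = "levotap-out"
    dose_mg: float = 100.0
    pk: PKConfig = field(default_factory=PKConfig)
    pd: PDConfig = field(default_factory=PDConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)


_SECTION_TYPES = {
    "pk": PKConfig, "pd": PDConfig, "network": NetworkConfig,
    "synth": SynthConfig, "estimation": EstimationConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration, rejecting unknown keys."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    for key, value in raw.items():
        if key not in top_fields:
            raise FormatError(f"unknown configuration key {key!r}")
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - valid
            if bad:
                raise FormatError(
                    f"unknown key(s) in [{key}]: {sorted(bad)}")
            if "initial_guess" in value:
                value["initial_guess"] = tuple(value["initial_guess"])
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def read_patient_csv(path: str | Path, group: str = "unknown",
                     dose: DoseEvent = DoseEvent()) -> PatientRecord:
    """Parse one patient CSV (blank cells = quantity not sampled there)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in _PATIENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    for col in _PATIENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() \
            & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise FormatError(
                f"{path.name}: non-numeric value in column {col!r}, "
                f"row {row}")
        df[col] = coerced
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise FormatError(f"{path.name}: blank time_min cell")
    plasma_mask = df["plasma_mg_l"].notna().to_numpy()
    tap_mask = df["taps_per_min"].notna().to_numpy()
    if plasma_mask.sum() == 0 or tap_mask.sum() == 0:
        raise FormatError(f"{path.name}: a series is entirely blank")
    return PatientRecord(
        id=path.stem,
        group=group,
        dose=dose,
        plasma=SampledSeries(t[plasma_mask],
                             df["plasma_mg_l"].to_numpy(float)[plasma_mask]),
        tapping=SampledSeries(t[tap_mask],
                              df["taps_per_min"].to_numpy(float)[tap_mask]),
    )


def write_patient_csv(record: PatientRecord, path: str | Path) -> None:
    """Write one patient record in the standard dialect."""
    times = np.union1d(record.plasma.times, record.tapping.times)
    plasma = {t: v for t, v in zip(record.plasma.times, record.plasma.values)}
    taps = {t: v for t, v in zip(record.tapping.times, record.tapping.values)}
    df = pd.DataFrame({
        "time_min": times,
        "plasma_mg_l": [plasma.get(t, np.nan) for t in times],
        "taps_per_min": [taps.get(t, np.nan) for t in times],
    })
    df.to_csv(path, index=False)


def fit_patient(
    record: PatientRecord,
    curve: FrequencyCurve | None = None,
    config: RunConfig = RunConfig(),
    seed: int = 0,
) -> dict:
    """Two-stage fit of one patient; returns one results-table row."""
    if curve is None:
        curve = default_frequency_curve()
    pk_fit = fit_pk(
        record.plasma, config.pk.initial_guess, record.dose,
        V1=config.pk.V1_l, V2=config.pk.V2_l, ka=config.pk.ka_per_min,
        maxiter=config.estimation.maxiter,
    )
    pd_fit = fit_pd(
        record.tapping, pk_fit.parameters, curve,
        n_restarts=config.estimation.n_restarts, seed=seed,
        dose=record.dose, maxiter=config.estimation.maxiter,
        k=config.estimation.cost_max_weight,
        n_hops=config.estimation.n_hops,
        axis_rounds=config.estimation.axis_rounds,
        ke3_profile=config.estimation.ke3_profile,
    )
    pk, pdp = pk_fit.parameters, pd_fit.parameters
    return {
        "id": record.id, "group": record.group,
        "k12": pk.k12, "k21": pk.k21, "ketot": pk.ketot,
        "ke3": pdp.ke3, "D0": pdp.D0, "T": pdp.T, "Dmax": pdp.Dmax,
        "Dc50": pdp.Dc50, "ND": pdp.ND,
        "cost_pk": pk_fit.cost, "cost_pd": pd_fit.cost,
        "r2_LD": pk_fit.r2, "r2_tapping": pd_fit.r2,
        "best_restart": pd_fit.best_restart, "seed": seed,
    }


def write_fit_results(rows: list[dict], path: str | Path) -> None:
    """Results CSV: one row per patient, stable column order."""
    if not rows:
        raise InputError("no fit results to write")
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_fit_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Fit every patient, then compare the groups.

    Patients come from ``config.input_dir`` (one CSV each; files whose name
    starts with ``S``/``F`` are labelled stable/fluctuating) or, if no input
    directory is set, from the synthetic-cohort generator.  A failure on one
    patient is recorded and the pipeline continues with the rest.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curve = steady_state_frequency_curve(config.network,
                                         default_synapses(config.network),
                                         warn_nonmonotone=False)
    if config.input_dir is not None:
        records = []
        errors: list[dict] = []
        for f in sorted(Path(config.input_dir).glob("*.csv")):
            if f.stem == "ground_truth":
                continue
            group = {"S": "stable", "F": "fluctuating"}.get(
                f.stem[:1].upper(), "unknown")
            try:
                records.append(read_patient_csv(
                    f, group=group, dose=DoseEvent(config.dose_mg)))
            except Exception as exc:  # fault isolation per file
                logger.warning("skipping %s: %s", f.name, exc)
                errors.append({"id": f.stem, "error": str(exc)})
    else:
        records = generate_cohort(config.synth.n_stable,
                                  config.synth.n_fluctuating,
                                  master_seed=config.seed, curve=curve)
        errors = []

    seeds = np.random.SeedSequence(config.seed).generate_state(len(records))
    rows = []
    for record, s in zip(records, seeds):
        try:
            rows.append(fit_patient(record, curve, config,
                                    seed=int(s % (1 << 31))))
        except Exception as exc:
            logger.warning("fit failed for %s: %s", record.id, exc)
            errors.append({"id": record.id, "error": str(exc)})
    results_path = out_dir / "results.csv"
    write_fit_results(rows, results_path)
    results = pd.DataFrame(rows)

    stats = None
    stats_path = None
    by_group = results.groupby("group")
    if {"stable", "fluctuating"} <= set(results["group"]) and \
            all(len(g) >= 3 for _, g in by_group):
        stats = compare_groups(by_group.get_group("stable"),
                               by_group.get_group("fluctuating"))
        stats_path = out_dir / "stats.csv"
        stats.to_csv(stats_path, index=False)
    else:
        logger.info("group comparison skipped: need two groups of >= 3")

    return {
        "results": results,
        "stats": stats,
        "results_path": results_path,
        "stats_path": stats_path,
        "errors": errors,
    }
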