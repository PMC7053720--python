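"""Synthetic patients with the clinical sampling schedule and ground truth.

The clinical records this package was designed for are not public, so this
module generates replacements with the same structure: one 100 mg oral
levodopa dose; plasma sampled pre-dose, every 15 minutes up to 90 minutes,
then half-hourly to 3 hours; tapping sampled on the same grid extended to 4
hours.  Two response archetypes are provided, separated in the effect-site
removal rate and the Hill coefficient (both higher in fluctuating
responders): *stable* patients keep an elevated tapping rate through the
4-hour window, *fluctuating* patients return to baseline.

Every synthetic patient carries its generating (ground-truth) parameters,
which is what makes parameter-recovery testing of the estimator possible.
Observation noise: multiplicative Gaussian on plasma (default CV 8%),
additive Gaussian on tapping (default SD 7 taps/min), clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bg_network import FrequencyCurve, default_frequency_curve
from .errors import InputError
from .estimation import predict_tapping
from .pharmacodynamics import PDParameters, dopaminergic_response
from .pharmacokinetics import DoseEvent, PKParameters, plasma_closed_form
from .series import SampledSeries

__all__ = [
    "PLASMA_SCHEDULE_MIN",
    "TAPPING_SCHEDULE_MIN",
    "Archetype",
    "STABLE_ARCHETYPE",
    "FLUCTUATING_ARCHETYPE",
    "PatientRecord",
    "sample_parameters",
    "generate_patient",
    "generate_cohort",
]

#: Clinical plasma sampling grid (minutes): pre-dose, q15min to 90, q30min to 180.
PLASMA_SCHEDULE_MIN = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0, 150.0, 180.0)

#: Tapping sampling grid: the plasma grid extended to the 4-hour window.
TAPPING_SCHEDULE_MIN = PLASMA_SCHEDULE_MIN + (210.0, 240.0)


@dataclass(frozen=True)
class Archetype:
    """Per-parameter sampling intervals and noise model for one responder type.

    All parameter draws are independent and log-uniform within their
    intervals.  The fluctuating intervals for ``ke3`` and ``ND`` lie
    strictly above the stable ones, encoding faster effect-site washout and
    a steeper, more all-or-nothing concentration-effect relationship.
    """

    label: str
    k12: tuple[float, float] = (0.3, 0.8)     # l/min
    k21: tuple[float, float] = (0.3, 1.0)     # l/min
    ketot: tuple[float, float] = (0.4, 0.7)   # l/min
    ke3: tuple[float, float] = (0.004, 0.01)  # 1/min
    T: tuple[float, float] = (5.0, 30.0)      # min
    D0: tuple[float, float] = (0.3, 0.8)
    Dmax: tuple[float, float] = (1.0, 2.0)
    Dc50: tuple[float, float] = (0.3, 0.6)    # mg/l
    ND: tuple[float, float] = (1.5, 4.0)
    plasma_cv: float = 0.08
    tapping_sd: float = 7.0                   # taps/min


STABLE_ARCHETYPE = Archetype(label="stable")

FLUCTUATING_ARCHETYPE = Archetype(
    label="fluctuating",
    ke3=(0.05, 0.15),
    ND=(6.0, 12.0),
    Dc50=(0.55, 1.0),   # above the plasma tail, so the steep Hill shuts off
)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: dose event, plasma and tapping series, group label.

    ``ground_truth`` is present exactly when the record is synthetic.
    """

    id: str
    group: str                       # "stable" | "fluctuating" | "unknown"
    dose: DoseEvent
    plasma: SampledSeries
    tapping: SampledSeries
    ground_truth: tuple[PKParameters, PDParameters] | None = None


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameters(
    archetype: Archetype, seed: int | np.random.Generator
) -> tuple[PKParameters, PDParameters]:
    """Draw one ground-truth parameter set from the archetype's intervals."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pk = PKParameters(
        k12=_loguniform(rng, *archetype.k12),
        k21=_loguniform(rng, *archetype.k21),
        ketot=_loguniform(rng, *archetype.ketot),
    )
    pd = PDParameters(
        ke3=_loguniform(rng, *archetype.ke3),
        T=_loguniform(rng, *archetype.T),
        D0=_loguniform(rng, *archetype.D0),
        Dmax=_loguniform(rng, *archetype.Dmax),
        Dc50=_loguniform(rng, *archetype.Dc50),
        ND=_loguniform(rng, *archetype.ND),
    )
    return pk, pd


def generate_patient(
    archetype: Archetype,
    seed: int | np.random.Generator,
    patient_id: str | None = None,
    dose: DoseEvent = DoseEvent(),
    curve: FrequencyCurve | None = None,
    noise: bool = True,
) -> PatientRecord:
    """One synthetic patient on the clinical sampling schedule.

    Samples ground-truth parameters, runs the full forward pipeline, then
    adds observation noise (disable with ``noise=False`` to place the
    observations exactly on the model curves).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if curve is None:
        curve = default_frequency_curve()
    pk, pd = sample_parameters(archetype, rng)
    t_plasma = np.asarray(PLASMA_SCHEDULE_MIN)
    t_tap = np.asarray(TAPPING_SCHEDULE_MIN)
    c1 = plasma_closed_form(pk, dose, t_plasma)
    tapping = predict_tapping(pd, pk, curve, t_tap, dose=dose)
    plasma_vals = c1.values.copy()
    tap_vals = tapping.values.copy()
    if noise:
        plasma_vals = plasma_vals * (1.0 + archetype.plasma_cv
                                     * rng.standard_normal(t_plasma.size))
        tap_vals = tap_vals + archetype.tapping_sd \
            * rng.standard_normal(t_tap.size)
    plasma_vals = np.clip(plasma_vals, 0.0, None)
    tap_vals = np.clip(tap_vals, 0.0, None)
    if patient_id is None:
        patient_id = f"{archetype.label}-{rng.integers(1 << 31)}"
    return PatientRecord(
        id=patient_id,
        group=archetype.label,
        dose=dose,
        plasma=SampledSeries(t_plasma, plasma_vals),
        tapping=SampledSeries(t_tap, tap_vals),
        ground_truth=(pk, pd),
    )


def generate_cohort(
    n_stable: int = 13,
    n_fluctuating: int = 13,
    master_seed: int = 0,
    curve: FrequencyCurve | None = None,
    noise: bool = True,
) -> list[PatientRecord]:
    """A full synthetic cohort with deterministic per-patient seeds."""
    if n_stable < 1 or n_fluctuating < 1:
        raise InputError("cohort needs at least one patient per group")
    if curve is None:
        curve = default_frequency_curve()
    children = np.random.SeedSequence(master_seed).spawn(
        n_stable + n_fluctuating)
    cohort: list[PatientRecord] = []
    for i in range(n_stable):
        cohort.append(generate_patient(
            STABLE_ARCHETYPE, np.random.default_rng(children[i]),
            patient_id=f"S{i + 1:02d}", curve=curve, noise=noise))
    for i in range(n_fluctuating):
        cohort.append(generate_patient(
            FLUCTUATING_ARCHETYPE,
            np.random.default_rng(children[n_stable + i]),
            patient_id=f"F{i + 1:02d}", curve=curve, noise=noise))
    return cohort
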