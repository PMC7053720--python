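"""Dopamine-gated Hebbian learning on cortico-striatal synapses.

A training session presents noisy go-cues to the network and lets it choose
between the two channels.  Choosing the cued channel earns a reward — a
phasic burst that transiently doubles the current dopaminergic input — and
the Go synapses update; choosing wrong (or timing out) earns a punishment —
a transient dip that nulls the dopaminergic input — and the NoGo synapses
update.  The update itself is a threshold-Hebb rule,

    dw = gamma * pre * (post - theta),

evaluated at the end of the phasic period: the synapse potentiates when the
post-synaptic striatal unit is above the threshold ``theta`` and depresses
when it is below.  The same signless rule produces the reward/punishment
asymmetry: during a burst the winning Go unit is strongly active (Go
potentiation), during a dip the NoGo units are disinhibited both directly
and through the cholinergic unit (NoGo potentiation).  When dopamine is low
— late after a dose, especially with fast effect-site removal — rewards are
feeble and punishments fierce, which is the mechanism of aberrant learning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _fastloop as fl
from .bg_network import (
    FrequencyCurve,
    NetworkConfig,
    SynapseSet,
    default_network_config,
    frequency_from_D_series,
    steady_state_frequency_curve,
)
from .errors import InputError
from .pharmacodynamics import PDParameters, dopaminergic_response
from .pharmacokinetics import DoseEvent, PKParameters, plasma_closed_form
from .series import SampledSeries

__all__ = [
    "TrainingProtocol",
    "hebbian_update",
    "run_training_session",
    "simulate_training_experiment",
    "synapse_presets",
    "PRESET_LEVELS",
    "DEFAULT_PRESET_SEED",
]

#: Recognized preset training depths (epochs): poor skill to very high skill.
PRESET_LEVELS = (60, 80, 100, 150, 200)

#: Seed of the shipped moderate-skill (100-epoch) preset.
DEFAULT_PRESET_SEED = 20200303

#: Dopaminergic input under which the skill presets are trained; a healthy
#: mid-range tone so that rewards and punishments both occur.
PRESET_TRAINING_D = 1.5

#: Standard preset protocol: easier discrimination than a therapy session
#: and gentle learning rates, so skill accrues gradually over hundreds of
#: epochs and the preset weight sets stay within the network's calibrated
#: operating neighbourhood.
PRESET_NOISE_SD = 0.45
PRESET_GAMMA = 0.002
PRESET_GAMMA_NOGO = 0.02


@dataclass(frozen=True)
class TrainingProtocol:
    """Settings of one reward/punishment training session.

    ``reward_factor`` and ``punishment_factor`` multiply the current
    dopaminergic input during the phasic period (defaults: transient
    doubling and nulling).  ``noise_sd`` is the standard deviation of the
    additive stimulus noise that makes the action choice difficult.
    """

    n_epochs: int = 50
    noise_sd: float = 0.8
    reward_factor: float = 2.0
    punishment_factor: float = 0.0
    phasic_duration: float = 300.0   # ms
    gamma: float = 0.01              # Go-pathway learning rate (burst-scaled)
    gamma_nogo: float = 0.16         # NoGo-pathway learning rate (dip-driven)
    burst_ref: float = 3.0           # phasic D at which the Go rate equals gamma
    theta: float = 0.35              # Hebb threshold on post-synaptic activity
    session_time: float = 90.0       # minutes post-dose
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise InputError("n_epochs must be >= 1")
        for name in ("noise_sd", "reward_factor", "punishment_factor",
                     "phasic_duration", "gamma", "gamma_nogo"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if not 0.0 < self.theta < 1.0:
            raise InputError("theta must lie in (0, 1)")


def hebbian_update(pre: float, post: float, gamma: float, theta: float) -> float:
    """Threshold-Hebb weight increment ``gamma * pre * (post - theta)``.

    The caller clips the resulting weight to ``[0, wmax]``.
    """
    return gamma * pre * (post - theta)


def run_training_session(
    config: NetworkConfig,
    synapses: SynapseSet,
    protocol: TrainingProtocol,
    D_at_session: float,
) -> tuple[SynapseSet, list[dict]]:
    """Train the cortico-striatal weights for one session.

    Each epoch: the network settles, a noisy stimulus is presented with a
    randomly cued channel, the network selects whichever motor unit crosses
    the threshold first (timeout counts as an error), the phasic dopamine
    change is applied for ``phasic_duration`` ms, and the Hebb rule updates
    the Go synapses after a reward or the NoGo synapses after a punishment.
    Returns the new weights and a per-epoch log.
    """
    rng = np.random.default_rng(protocol.rng_seed)
    P = config.param_vector()
    dt = config.dt
    wGo = list(synapses.wGo)
    wNoGo = list(synapses.wNoGo)
    timeout_steps = int(config.selection_timeout / dt)
    settle_steps = int(config.settle_ms / dt)
    phasic_steps = int(protocol.phasic_duration / dt)
    log: list[dict] = []
    D = float(D_at_session)
    for epoch in range(protocol.n_epochs):
        cue = int(rng.integers(0, 2))
        noise = rng.normal(0.0, protocol.noise_sd, size=2)
        s = [noise[0], noise[1]]
        s[cue] += config.stim
        W = np.array([*wGo, *wNoGo])
        y = np.zeros(fl.N_STATE)
        fl.integrate(y, P, W, 0.0, 0.0, D, settle_steps)
        choice, _steps = fl.run_selection(y, P, W, s[0], s[1], D,
                                          -1, timeout_steps)
        correct = choice == cue
        phasic_D = D * (protocol.reward_factor if correct
                        else protocol.punishment_factor)
        fl.integrate(y, P, W, s[0], s[1], phasic_D, phasic_steps)
        # credit assignment: the pathway of the performed action updates —
        # the chosen channel's Go after a reward, its NoGo after a
        # punishment; a timeout blames the cued channel's NoGo
        i = int(choice) if choice >= 0 else cue
        pre = y[7 * i + 1]                       # motor cortex activity
        if correct:
            # bursts enhance Go plasticity in proportion to their size, so
            # rewards earned at a low drug level barely teach
            gamma_eff = protocol.gamma * phasic_D / protocol.burst_ref
            post = y[7 * i + 2]                  # Go unit
            wGo[i] = float(np.clip(
                wGo[i] + hebbian_update(pre, post, gamma_eff,
                                        protocol.theta),
                0.0, config.wmax))
        else:
            # the dip always disinhibits NoGo fully; its strength needs no
            # extra scaling
            post = y[7 * i + 3]                  # NoGo unit
            wNoGo[i] = float(np.clip(
                wNoGo[i] + hebbian_update(pre, post, protocol.gamma_nogo,
                                          protocol.theta),
                0.0, config.wmax))
        log.append({
            "epoch": epoch,
            "cue": cue,
            "choice": int(choice),
            "outcome": "reward" if correct else "punishment",
            "wGo": tuple(wGo),
            "wNoGo": tuple(wNoGo),
        })
    return SynapseSet(tuple(wGo), tuple(wNoGo), wmax=config.wmax), log


def simulate_training_experiment(
    pk: PKParameters,
    pd: PDParameters,
    protocol: TrainingProtocol,
    config: NetworkConfig | None = None,
    synapses: SynapseSet | None = None,
    dose: DoseEvent = DoseEvent(),
    times: np.ndarray | None = None,
) -> dict:
    """Train a fitted patient at ``protocol.session_time`` minutes post-dose.

    Computes the dopaminergic input trajectory from the patient's kinetic
    and dynamic parameters, evaluates ``D`` at the session time, runs the
    training session, then regenerates the tapping trajectory with the
    updated synapses (recomputing the steady-state curve).  Returns a dict
    with the untrained and trained trajectories, both synapse sets, the
    session log and ``D_at_session``.
    """
    from .bg_network import default_synapses

    config = config if config is not None else default_network_config()
    synapses = synapses if synapses is not None else default_synapses(config)
    if times is None:
        times = np.arange(0.0, 241.0, 5.0)
    t_dense = np.arange(0.0, max(float(times[-1]), protocol.session_time) + 1.0)
    c1 = plasma_closed_form(pk, dose, t_dense)
    D_series = dopaminergic_response(c1, pd)
    D_at_session = float(np.interp(protocol.session_time,
                                   D_series.times, D_series.values))
    curve_before = steady_state_frequency_curve(config, synapses,
                                                warn_nonmonotone=False)
    trained, log = run_training_session(config, synapses, protocol,
                                        D_at_session)
    curve_after = steady_state_frequency_curve(config, trained,
                                               warn_nonmonotone=False)
    D_at = SampledSeries(times, np.interp(times, D_series.times,
                                          D_series.values))
    return {
        "untrained": frequency_from_D_series(curve_before, D_at),
        "trained": frequency_from_D_series(curve_after, D_at),
        "synapses_before": synapses,
        "synapses_after": trained,
        "log": log,
        "D_at_session": D_at_session,
        "baseline_frequency": float(curve_before(pd.D0)),
    }


def synapse_presets(
    level: int,
    seed: int = DEFAULT_PRESET_SEED,
    config: NetworkConfig | None = None,
) -> SynapseSet:
    """Skill presets: weights after training a naive network for ``level`` epochs.

    Levels 60/80 stand for poor skill, 100 for the moderate skill typical of
    a PD patient (the shipped default), 150/200 for high skill.  The preset
    is produced deterministically by training the naive weight set under a
    fixed standard protocol at a healthy dopaminergic tone.
    """
    if level not in PRESET_LEVELS:
        raise InputError(
            f"unknown preset level {level!r}; recognized: {PRESET_LEVELS}"
        )
    config = config if config is not None else default_network_config()
    protocol = TrainingProtocol(n_epochs=int(level), rng_seed=seed,
                                noise_sd=PRESET_NOISE_SD,
                                gamma=PRESET_GAMMA,
                                gamma_nogo=PRESET_GAMMA_NOGO)
    trained, _log = run_training_session(
        config, SynapseSet.naive(config), protocol, PRESET_TRAINING_D)
    return trained
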