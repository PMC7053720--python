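"""Container for the outcome of a parameter fit."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Result of a (possibly multi-restart) derivative-free fit.

    Attributes
    ----------
    parameters
        The estimated parameter object (``PKParameters`` or ``PDParameters``).
    cost
        Final value of the minimized objective (sum of squared errors for the
        kinetic fit, the weighted tapping cost for the dynamic fit).
    r2
        Coefficient of determination of the fitted curve against the data.
    n_restarts, best_restart
        Number of optimizer restarts and the index of the winning one.
    seed
        Seed that generated the random restarts (``None`` for the
        single-guess kinetic fit).
    converged
        Per-restart convergence flags from the simplex optimizer.
    restart_log
        One dict per restart: initial guess, final cost, iterations.
    """

    parameters: Any
    cost: float
    r2: float
    n_restarts: int = 1
    best_restart: int = 0
    seed: int | None = None
    converged: Sequence[bool] = field(default_factory=lambda: [True])
    restart_log: list[dict] = field(default_factory=list)

    @property
    def any_converged(self) -> bool:
        return any(self.converged)
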