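"""Stochastic lattice simulator of facilitated diffusion — the internal oracle.

The closed-form model in :mod:`searchkin.kinetics` rests on scaling
estimates (rounds ~ M/<n>, each covered site revisited ~<n> times).  This
module checks those estimates against an explicit discrete simulation:

* the DNA is a ring of ``M`` sites (periodic, so there are no edge effects
  the analytic model does not describe);
* the walker performs an unbiased +-1 step every ``tau_res`` seconds;
* after each step it dissociates with a fixed probability, which makes the
  dwell per 1D round geometric with mean ``tau_1D``; it then re-lands
  uniformly after one 3D excursion of duration ``tau_3d``;
* every arrival at the target site (by a step, or by landing on it)
  triggers an independent S->R attempt with the per-visit probability
  ``P_f``; the trial ends at the first success.

``SimConfig.from_model`` maps a parameter point of the analytic model onto
these simulation inputs (``tau_res = 1/k_res``, dissociation probability
``tau_res/tau_1D``, attempt probability ``P_f``), so the simulated mean
recognition time can be compared directly with ``tau_R``.

The inner loop is numba-compiled; a fixed seed reproduces the event
sequence bit-for-bit (single-threaded Mersenne-Twister draws in a fixed
order: step direction, attempt-on-target, dissociation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .errors import InvalidParameterError, NoAbsorptionError
from .kinetics import KineticsBreakdown, LandscapeParameters, ModelParameters, total_recognition_time

__all__ = ["SimConfig", "SimResult", "simulate_search"]


@dataclass(frozen=True)
class SimConfig:
    """Inputs of one simulation campaign.

    ``start_position`` is the landing site of the first round; ``None``
    draws it uniformly (the default, matching uncorrelated rounds).
    """

    genome_length: int
    target_position: int
    per_step_time: float
    dissociation_probability_per_step: float
    transition_probability_per_visit: float
    tau_3d: float = 0.0
    n_trials: int = 10_000
    rng_seed: int = 1
    start_position: int | None = None

    def __post_init__(self) -> None:
        if self.genome_length < 2:
            raise InvalidParameterError(
                f"genome_length must be >= 2, got {self.genome_length!r}")
        if not (0 <= self.target_position < self.genome_length):
            raise InvalidParameterError(
                f"target_position {self.target_position!r} outside "
                f"[0, {self.genome_length})")
        if self.per_step_time <= 0:
            raise InvalidParameterError("per_step_time must be > 0")
        for name in ("dissociation_probability_per_step",
                     "transition_probability_per_visit"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v!r}")
        if self.tau_3d < 0:
            raise InvalidParameterError("tau_3d must be >= 0")
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")
        if self.start_position is not None and not (
                0 <= self.start_position < self.genome_length):
            raise InvalidParameterError(
                f"start_position {self.start_position!r} outside the ring")

    @classmethod
    def from_model(cls, landscape: LandscapeParameters,
                   params: ModelParameters, *, genome_length: int | None = None,
                   target_position: int = 0, n_trials: int = 10_000,
                   rng_seed: int = 1) -> "SimConfig":
        """Map an analytic parameter point onto simulation inputs.

        ``genome_length`` defaults to ``params.genome_length`` (must be a
        desk-scale integer; the analytic model is the one meant for
        genome-scale M).
        """
        m = int(genome_length if genome_length is not None
                else params.genome_length)
        b: KineticsBreakdown = total_recognition_time(
            landscape, replace(params, genome_length=m))
        tau_res = 1.0 / b.k_res
        return cls(
            genome_length=m, target_position=target_position,
            per_step_time=tau_res,
            dissociation_probability_per_step=min(1.0, tau_res / b.tau_1d),
            transition_probability_per_visit=b.p_f,
            tau_3d=params.tau_3d, n_trials=n_trials, rng_seed=rng_seed)


@dataclass(frozen=True)
class SimResult:
    """Summary of a simulation campaign.

    ``times`` holds the per-trial recognition times (seconds) so callers
    can build their own distribution summaries.
    """

    mean_time: float
    sd_time: float
    median_time: float
    mean_rounds: float
    mean_steps: float
    n_trials: int
    times: np.ndarray
    #: per-trial total step counts
    steps: np.ndarray
    #: per-trial number of 3D excursions (completed 1D rounds)
    rounds_3d: np.ndarray
    #: per-trial step count of the final, success-truncated 1D round;
    #: (steps - final_round_steps) / rounds_3d is an unbiased estimate of
    #: the geometric dwell per completed round
    final_round_steps: np.ndarray

    @property
    def sem_time(self) -> float:
        """Standard error of the mean recognition time."""
        return self.sd_time / np.sqrt(self.n_trials)

    def as_dict(self) -> dict:
        return {
            "mean_tau_r": self.mean_time, "sd": self.sd_time,
            "median": self.median_time, "sem": self.sem_time,
            "n_rounds_mean": self.mean_rounds,
            "n_steps_mean": self.mean_steps, "n_trials": self.n_trials,
        }


@njit(cache=True)
def _run_trials(m, target, p_off, p_visit, n_trials, seed, start):
    # start < 0 means: land uniformly.  Returns per-trial (total steps,
    # number of 3D rounds, steps of the final - truncated - 1D round).
    np.random.seed(seed)
    steps_out = np.empty(n_trials, dtype=np.int64)
    n3d_out = np.empty(n_trials, dtype=np.int64)
    final_out = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        if start >= 0:
            pos = start
        else:
            pos = int(np.random.random() * m)
        steps = 0
        n3d = 0
        round_steps = 0
        done = pos == target and np.random.random() < p_visit
        while not done:
            # one sliding step of tau_res
            if np.random.random() < 0.5:
                pos += 1
                if pos == m:
                    pos = 0
            else:
                pos -= 1
                if pos < 0:
                    pos = m - 1
            steps += 1
            round_steps += 1
            if pos == target and np.random.random() < p_visit:
                break
            # dissociation check comes after the step
            if p_off > 0.0 and np.random.random() < p_off:
                pos = int(np.random.random() * m)
                n3d += 1
                round_steps = 0
                if pos == target and np.random.random() < p_visit:
                    break
        steps_out[t] = steps
        n3d_out[t] = n3d
        final_out[t] = round_steps
    return steps_out, n3d_out, final_out


def simulate_search(config: SimConfig) -> SimResult:
    """Run the lattice simulation and summarize the recognition times.

    Raises
    ------
    NoAbsorptionError
        If the per-visit transition probability is zero (the walk would
        never terminate).
    """
    if config.transition_probability_per_visit <= 0.0:
        raise NoAbsorptionError(
            "transition_probability_per_visit is 0: the target can never "
            "be recognized and the simulation would not terminate")
    start = -1 if config.start_position is None else int(config.start_position)
    steps, n3d, final_steps = _run_trials(
        config.genome_length, config.target_position,
        config.dissociation_probability_per_step,
        config.transition_probability_per_visit,
        config.n_trials, config.rng_seed, start)
    times = steps * config.per_step_time + n3d * config.tau_3d
    return SimResult(
        mean_time=float(times.mean()),
        sd_time=float(times.std(ddof=1)) if config.n_trials > 1 else 0.0,
        median_time=float(np.median(times)),
        mean_rounds=float(n3d.mean() + 1.0),
        mean_steps=float(steps.mean()),
        n_trials=config.n_trials,
        times=times,
        steps=steps,
        rounds_3d=n3d,
        final_round_steps=final_steps)
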