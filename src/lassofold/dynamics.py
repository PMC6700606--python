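"""Langevin dynamics engine.

Integrates any energy/force provider (EFM or Go model) with the BAOAB
splitting scheme (velocity half-kick, half-drift, Ornstein-Uhlenbeck
collision, half-drift, half-kick), which gives accurate configurational
sampling at the working time step of 5e-4.  The friction coefficient is
gamma = m / tau_frict; initial velocities are Maxwell-Boltzmann at the run
temperature.  Identical seeds produce bit-identical trajectories on one
platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import baoab_chunk_for
from .chain import ChainConfiguration, ModelParameters
from .efm import BondOverstretchedError, IntegrationDivergedError

__all__ = ["TrajectoryRecord", "run_trajectory"]

#: default observable sampling interval, in integration steps (1 tau_MD)
DEFAULT_SAMPLE_EVERY = 2000


@dataclass
class TrajectoryRecord:
    """Sampled observables (and optionally frames) of one trajectory."""

    sample_times: np.ndarray
    traces: dict
    frames: list = None
    seed: int = 0
    run_length: float = 0.0
    diverged: bool = False

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, float)
        for k, v in self.traces.items():
            v = np.asarray(v, float)
            if len(v) != len(self.sample_times):
                raise ValueError(f"trace {k!r} not aligned with sample_times")
            self.traces[k] = v
        if len(self.sample_times) and self.run_length < self.sample_times[-1]:
            raise ValueError("run_length shorter than last sample time")

    def trace(self, name: str) -> np.ndarray:
        if name not in self.traces:
            raise KeyError(f"missing trace: {name!r}")
        return self.traces[name]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time": self.sample_times, **self.traces})


def run_trajectory(
    model,
    conf0: ChainConfiguration,
    n_steps: int,
    seed: int,
    sample_every: int = DEFAULT_SAMPLE_EVERY,
    observers: dict | None = None,
    params: ModelParameters | None = None,
    record_frames: bool = False,
    allow_divergence: bool = False,
    warmup_tau: float = 1.0,
    warmup_factor: int = 5,
) -> TrajectoryRecord:
    """Run Langevin dynamics and sample observables.

    Parameters
    ----------
    model : energy/force provider
        Object exposing ``force_func`` (jitted kernel), ``force_args`` and
        ``params``; see :class:`~lassofold.efm.EFMModel`.
    conf0 : initial configuration
    n_steps : total number of integration steps
    seed : RNG seed for initial velocities and the thermostat noise
    sample_every : steps between observable samples (also the frame stride)
    observers : dict of name -> f(positions) -> float
        Evaluated at t = 0 and every ``sample_every`` steps.  The total
        potential energy is always recorded under ``"energy"``.
    record_frames : keep the sampled configurations
    allow_divergence : bool
        If True, a blown-up integration (overstretched bond or non-finite
        coordinates) truncates the record at the last valid sample instead
        of raising; the record is flagged ``diverged``.
    warmup_tau, warmup_factor : soft launch
        The first ``warmup_tau`` time units are integrated with the time
        step reduced by ``warmup_factor`` (same trajectory time, finer
        steps).  Stretched starting states are nearly collinear, where the
        angular-force denominators are close to singular; the finer initial
        step absorbs that transient.  Set ``warmup_tau=0`` to disable.

    Raises
    ------
    BondOverstretchedError, IntegrationDivergedError
        With the offending step index in the message (unless
        ``allow_divergence``).
    """
    params = params or model.params
    observers = observers or {}
    rng = np.random.default_rng(seed)
    n = conf0.n_beads
    dt, mass, kT = params.dt, params.mass, params.temperature
    gamma = params.gamma

    pos = np.ascontiguousarray(conf0.positions, float).copy()
    vel = (
        rng.normal(scale=np.sqrt(kT / mass), size=(n, 3))
        if kT > 0
        else np.zeros((n, 3))
    )

    chunk = baoab_chunk_for(model.force_func)
    args = model.force_args
    energy, forces, status = model.force_func(pos, args)
    if status != 0:
        raise BondOverstretchedError("bond overstretched in initial configuration")

    times, energies, kinetics = [], [], []
    obs_values = {k: [] for k in observers}
    frames = [] if record_frames else None

    def _sample(t):
        times.append(t)
        energies.append(energy)
        kinetics.append(0.5 * mass * float(np.sum(vel * vel)))
        for k, fn in observers.items():
            obs_values[k].append(float(fn(pos)))
        if record_frames:
            frames.append(pos.copy())

    _sample(0.0)
    done = 0
    diverged = False
    while done < n_steps:
        m = min(sample_every, n_steps - done)
        if done * dt < warmup_tau and warmup_factor > 1:
            dt_eff, m_eff = dt / warmup_factor, m * warmup_factor
        else:
            dt_eff, m_eff = dt, m
        normals = rng.standard_normal((m_eff, n, 3))
        energy, status, at = chunk(
            pos, vel, forces, args, dt_eff, gamma, kT, mass, normals
        )
        at = at // warmup_factor if dt_eff != dt else at
        if status == 2 or status == 1 or not np.all(np.isfinite(pos)):
            if allow_divergence:
                import warnings

                warnings.warn(
                    f"trajectory diverged at step {done + at}; "
                    "record truncated at last valid sample",
                    stacklevel=2,
                )
                diverged = True
                break
            if status == 2:
                raise BondOverstretchedError(
                    f"bond overstretched at step {done + at}"
                )
            raise IntegrationDivergedError(
                f"integration diverged at step {done + at}"
            )
        done += m
        _sample(done * dt)

    traces = {"energy": np.asarray(energies), "kinetic": np.asarray(kinetics)}
    traces.update({k: np.asarray(v) for k, v in obs_values.items()})
    return TrajectoryRecord(
        sample_times=np.asarray(times),
        traces=traces,
        frames=frames,
        seed=seed,
        run_length=n_steps * dt,
        diverged=diverged,
    )
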