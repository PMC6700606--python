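"""Stochastic force-field optimization: SFFO and its evolutionary MFFO extension.

The elastic folder model leaves the per-angle stiffness vector
K = (k_bend_1..k_bend_{N-2}, k_tor_1..k_tor_{N-3}) free; these routines tune
it to maximize the probability of folding within short trajectories.

Single force-field optimization (SFFO) is a Metropolis search: one paired
coefficient group is perturbed by a Gaussian step (SD 2.5), the mutated
force field is scored by the average minimum mean-square displacement
<F(tau_min)> over n short test trajectories started from fresh random
stretched configurations, and the mutation is accepted with probability
min{1, exp(<F>_old - <F>_new)}.

Multiple force-field optimization (MFFO) runs a population of N_K force
fields through m SFFO steps per cycle, ranks them by a folding-probability
proxy Pi_f (an exponential moving average, smoothing alpha, of the
per-step Fermi-switched fraction of test runs below the MSD threshold F0),
keeps the N_win best verbatim, and rebuilds the rest by uniform crossover
from the winners plus N_low freshly randomized parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import msd_from_native
from .chain import ChainConfiguration, ModelParameters, ReferenceGeometry
from .chain import generate_stretched_configuration
from .dynamics import run_trajectory
from .efm import BridgeParameters, EFMModel, ForceField
from .topology import fermi_switch

__all__ = [
    "OptimizerConfig",
    "OptimizerEntry",
    "FoldingObjective",
    "mutate_forcefield",
    "evaluate_forcefield",
    "metropolis_accept",
    "ema_update",
    "sffo_step",
    "rank_and_crossover",
    "mffo_run",
]


@dataclass
class OptimizerConfig:
    """Optimization hyperparameters (defaults: the full-protein settings)."""

    n_test: int = 16              # test trajectories per mutation
    tau_run: float = 3.5e3       # test-trajectory length, tau_MD
    delta_k_sd: float = 2.5      # mutation SD
    F0: float = 0.9              # MSD threshold of the folding proxy
    w: float = 0.2               # Fermi switching width of the proxy
    alpha: float = 0.03          # EMA smoothing (decay time ~33 steps)
    m_cycle: int = 50            # SFFO steps per ranking cycle
    N_K: int = 16                # population size
    N_win: int = 6               # winners kept verbatim
    N_low: int = 4               # randomly generated parents for crossover
    random_k_range: tuple = (30.0, 60.0)
    k_floor: float = 1.0         # positive stiffness floor
    init_k_choices: tuple = (20.0, 40.0, 60.0, 80.0)
    sample_every: int = 2000     # MSD sampling stride (steps) in test runs

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.N_win > self.N_K or self.N_low < 0:
            raise ValueError("invalid population sizes")


@dataclass
class OptimizerEntry:
    """One population member: force field plus its bookkeeping."""

    ff: ForceField
    mean_F: float | None = None   # <F(tau_min)> from the entry's last test
    Pi_f: float | None = None     # EMA folding-probability proxy
    accepted: int = 0


class FoldingObjective:
    """Scores a force field by short folding test runs of the EFM.

    Bundles the reference geometry, native coordinates, model parameters and
    bridge setting; :meth:`evaluate` runs ``n_test`` Langevin trajectories
    from fresh random stretched configurations and reduces each to
    F(tau_min), the minimum of its sampled MSD-from-native trace.
    """

    def __init__(
        self,
        ref: ReferenceGeometry,
        native: ChainConfiguration,
        params: ModelParameters | None = None,
        bridges: BridgeParameters | None = None,
    ):
        self.ref = ref
        self.native = native
        self.params = params or ModelParameters()
        self.bridges = bridges

    def evaluate(self, ff: ForceField, config: OptimizerConfig, seed) -> tuple:
        """(mean_F, pi_f, per-trajectory F(tau_min) values)."""
        rng = np.random.default_rng(seed)
        model = EFMModel(self.ref, ff, self.params, self.bridges)
        n_steps = int(round(config.tau_run / self.params.dt))
        native_pos = self.native.positions
        f_mins = []
        for _ in range(config.n_test):
            conf0 = generate_stretched_configuration(
                self.native.n_beads, int(rng.integers(2**31)), self.params
            )
            traj = run_trajectory(
                model,
                conf0,
                n_steps=n_steps,
                seed=int(rng.integers(2**31)),
                sample_every=config.sample_every,
                observers={"F": lambda pos: msd_from_native(pos, native_pos)},
                allow_divergence=True,
            )
            f_mins.append(float(np.min(traj.trace("F"))))
        f_mins = np.asarray(f_mins)
        mean_F = float(f_mins.mean())
        pi_f = float(np.mean(fermi_switch(config.F0 - f_mins, config.w)))
        return mean_F, pi_f, f_mins


def mutate_forcefield(K: ForceField, config: OptimizerConfig, seed) -> ForceField:
    """Perturb exactly one paired coefficient group by delta_k ~ N(0, sd^2).

    Both members of the pair receive the same increment; results are clipped
    at the positive stiffness floor.
    """
    rng = np.random.default_rng(seed)
    coeffs = K.coefficients.copy()
    group = K.pairing[int(rng.integers(len(K.pairing)))]
    dk = rng.normal(scale=config.delta_k_sd)
    coeffs[group] = np.maximum(coeffs[group] + dk, config.k_floor)
    return ForceField.from_coefficients(coeffs, K.n_beads, K.pairing)


def evaluate_forcefield(
    ff: ForceField, objective: FoldingObjective, config: OptimizerConfig, seed
):
    """Module-level convenience wrapper around :meth:`FoldingObjective.evaluate`."""
    return objective.evaluate(ff, config, seed)


def metropolis_accept(mean_F_old: float, mean_F_new: float, seed_or_rng) -> bool:
    """Accept with probability min{1, exp(<F>_old - <F>_new)}."""
    if not (np.isfinite(mean_F_old) and np.isfinite(mean_F_new)):
        raise ValueError("means must be finite")
    if mean_F_new <= mean_F_old:
        return True
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return bool(rng.random() < np.exp(mean_F_old - mean_F_new))


def ema_update(Pi_prev: float, pi_new: float, alpha: float) -> float:
    """Exponential moving average Pi = alpha pi_new + (1 - alpha) Pi_prev."""
    return alpha * pi_new + (1.0 - alpha) * Pi_prev


def sffo_step(
    entry: OptimizerEntry,
    objective: FoldingObjective,
    config: OptimizerConfig,
    seed,
) -> OptimizerEntry:
    """One SFFO iteration: mutate, test, Metropolis-accept, update the EMA.

    The incumbent's stored <F> (from when it was last tested) enters the
    Metropolis comparison without re-testing.  The folding proxy pi_f
    measured for the tested (possibly rejected) mutant feeds the entry's
    EMA either way: a single mutation perturbs the folding propensity only
    slightly, so the measurement remains informative about the entry.
    """
    rng = np.random.default_rng(seed)
    if entry.mean_F is None:
        raise ValueError("entry must be evaluated before stepping")
    mutant = mutate_forcefield(entry.ff, config, int(rng.integers(2**31)))
    mean_F_new, pi_f, _ = objective.evaluate(
        mutant, config, int(rng.integers(2**31))
    )
    accept = metropolis_accept(entry.mean_F, mean_F_new, rng)
    if accept:
        entry = replace(
            entry, ff=mutant, mean_F=mean_F_new, accepted=entry.accepted + 1
        )
    entry.Pi_f = (
        pi_f if entry.Pi_f is None else ema_update(entry.Pi_f, pi_f, config.alpha)
    )
    return entry


def _random_forcefield(n_beads: int, config: OptimizerConfig, rng) -> ForceField:
    """Pairing-consistent force field with groups uniform in random_k_range."""
    lo, hi = config.random_k_range
    from .efm import paired_groups

    pairing = paired_groups(n_beads)
    coeffs = np.empty(2 * n_beads - 5)
    for g in pairing:
        coeffs[g] = rng.uniform(lo, hi)
    return ForceField.from_coefficients(coeffs, n_beads, pairing)


def rank_and_crossover(
    entries: list, config: OptimizerConfig, seed, n_beads: int | None = None
) -> list:
    """Select winners by decreasing Pi_f and rebuild the rest by crossover.

    The top N_win entries survive verbatim (ties broken by entry index).
    Each remaining slot is filled by a hybrid: every paired coefficient
    group is copied from a uniformly chosen parent among the winners plus
    N_low freshly randomized force fields.  Hybrids carry no Pi_f history.
    """
    rng = np.random.default_rng(seed)
    if any(e.Pi_f is None for e in entries):
        raise ValueError("all entries need Pi_f values before ranking")
    n_beads = n_beads or entries[0].ff.n_beads
    order = sorted(range(len(entries)), key=lambda i: (-entries[i].Pi_f, i))
    winners = [entries[i] for i in order[: config.N_win]]
    new_pop = [
        OptimizerEntry(w.ff.copy(), w.mean_F, w.Pi_f, w.accepted) for w in winners
    ]
    parents = [w.ff for w in winners] + [
        _random_forcefield(n_beads, config, rng) for _ in range(config.N_low)
    ]
    pairing = entries[0].ff.pairing
    for _ in range(config.N_K - config.N_win):
        coeffs = np.empty(2 * n_beads - 5)
        for g in pairing:
            p = parents[int(rng.integers(len(parents)))]
            coeffs[g] = p.coefficients[g]
        hybrid = ForceField.from_coefficients(coeffs, n_beads, pairing)
        new_pop.append(OptimizerEntry(hybrid, mean_F=None, Pi_f=None))
    return new_pop


def initial_population(n_beads: int, config: OptimizerConfig) -> list:
    """Homogeneous (k_bend, k_tor) combinations of the initial stiffness grid."""
    combos = [
        (kb, kt) for kb in config.init_k_choices for kt in config.init_k_choices
    ]
    entries = []
    for i in range(config.N_K):
        # spread evenly over the grid when the population is smaller than it
        if config.N_K >= len(combos):
            kb, kt = combos[i % len(combos)]
        else:
            kb, kt = combos[round(i * (len(combos) - 1) / max(config.N_K - 1, 1))]
        entries.append(OptimizerEntry(ForceField.homogeneous(n_beads, kb, kt)))
    return entries


def save_checkpoint(path, entries, cycle, master_seed):
    """Write the full optimizer state of one cycle as JSON."""
    import json

    state = {
        "cycle": cycle,
        "master_seed": master_seed,
        "population": [
            {
                "k_bend": e.ff.k_bend.tolist(),
                "k1_tor": e.ff.k1_tor.tolist(),
                "mean_F": e.mean_F,
                "Pi_f": e.Pi_f,
                "accepted": e.accepted,
            }
            for e in entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(state, fh)


def load_checkpoint(path):
    """Rebuild an optimizer population from a checkpoint file."""
    import json

    with open(path) as fh:
        state = json.load(fh)
    entries = [
        OptimizerEntry(
            ForceField(p["k_bend"], p["k1_tor"]),
            mean_F=p["mean_F"],
            Pi_f=p["Pi_f"],
            accepted=p["accepted"],
        )
        for p in state["population"]
    ]
    return entries, state["cycle"], state["master_seed"]


def mffo_run(
    objective: FoldingObjective,
    config: OptimizerConfig,
    cycles: int,
    master_seed: int,
    crossover: bool = True,
    population: list | None = None,
    progress: bool = False,
    checkpoint_dir=None,
) -> tuple:
    """Full MFFO optimization.

    Each cycle advances every population entry through ``m_cycle``
    independent SFFO steps (fresh entries are first scored once to seed
    their <F> and Pi_f), then ranks by Pi_f and applies crossover.  With
    ``crossover=False`` (equivalent to N_win = N_K) the run degenerates to
    N_K independent SFFO optimizations at identical budget.

    Returns ``(best ForceField, history)`` where history holds one record
    per cycle with the best and mean Pi_f and the acceptance counts.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    n_beads = objective.native.n_beads
    entries = population or initial_population(n_beads, config)
    history = []
    for cycle in range(cycles):
        accepted0 = [e.accepted for e in entries]
        for idx, entry in enumerate(entries):
            rng = np.random.default_rng([master_seed, cycle, idx])
            if entry.mean_F is None:
                mean_F, pi_f, _ = objective.evaluate(
                    entry.ff, config, int(rng.integers(2**31))
                )
                entry.mean_F = mean_F
                if entry.Pi_f is None:
                    entry.Pi_f = pi_f
            for _step in range(config.m_cycle):
                entry = sffo_step(
                    entry, objective, config, int(rng.integers(2**31))
                )
            entries[idx] = entry
        pis = np.array([e.Pi_f for e in entries])
        history.append(
            {
                "cycle": cycle,
                "best_Pi_f": float(pis.max()),
                "mean_Pi_f": float(pis.mean()),
                "accepted": [e.accepted - a0 for e, a0 in zip(entries, accepted0)],
            }
        )
        if progress:
            print(
                f"cycle {cycle}: best Pi_f = {pis.max():.3f}, "
                f"mean = {pis.mean():.3f}"
            )
        if checkpoint_dir is not None:
            import pathlib

            d = pathlib.Path(checkpoint_dir)
            d.mkdir(parents=True, exist_ok=True)
            save_checkpoint(d / f"cycle_{cycle:04d}.json", entries, cycle, master_seed)
        if crossover and cycle < cycles - 1:
            entries = rank_and_crossover(
                entries, config, [master_seed, cycle, 10**6], n_beads
            )
    best = max(entries, key=lambda e: e.Pi_f)
    return best.ff.copy(), history
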