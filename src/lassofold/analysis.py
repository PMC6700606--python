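"""Folding-trajectory analysis.

Success criterion, mean-square displacement from the native structure,
native-contact fraction, folding landscapes F = -log f, transition times and
folding-pathway classification.

A trajectory is considered successfully folded once both the RMSD from the
native structure drops below 0.9 sigma and the lasso variable L exceeds 0.9;
the RMSD alone misses false positives with non-native topology.  Three
transition times characterize each successful run: the bridge formation time
t_b (first sustained closure of the cysteine pair), the topology formation
time t_k (first sustained L > 0.9) and the folding time t_f (first sustained
visit to the native basin).  Their ordering, together with bridge-distance
fluctuations, separates three mechanisms: *threading* (bridge closes first,
the tail then pierces the closed loop), *bridge reopening* (bridge closes
first but reopens widely before the topology forms) and *open-loop* (the
lasso topology forms before the bridge closes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainConfiguration
from .dynamics import TrajectoryRecord

__all__ = [
    "kabsch_superpose",
    "msd_from_native",
    "native_contact_fraction",
    "is_folded",
    "TransitionTimes",
    "transition_times",
    "classify_pathway",
    "Landscape",
    "folding_landscape",
    "pathway_statistics",
]

#: success thresholds: RMSD < 0.9 sigma and L > 0.9
RMSD_THRESHOLD = 0.9
L_THRESHOLD = 0.9
#: persistence window for transition times, tau_MD units
PERSISTENCE = 10.0


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Least-squares rotation via SVD (Kabsch), with the determinant correction
    that excludes reflections.  Returns the transformed copy of ``mobile``.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return (R @ P0.T).T + qc


def msd_from_native(conf, native, superpose: bool = True) -> float:
    """Mean-square displacement F from the native configuration.

    F = (1/N sigma^2) sum_i |r_i - r_i^0|^2, after optimal rigid-body
    superposition by default (trajectories start in arbitrary orientations,
    and sqrt(F) is then the conventional RMSD in sigma units).
    """
    p = conf.positions if isinstance(conf, ChainConfiguration) else np.asarray(conf)
    q = (
        native.positions
        if isinstance(native, ChainConfiguration)
        else np.asarray(native)
    )
    if p.shape != q.shape:
        raise ValueError("configuration sizes differ")
    if superpose:
        p = kabsch_superpose(p, q)
    return float(np.mean(np.sum((p - q) ** 2, axis=1)))


def native_contact_fraction(conf, contacts, factor: float = 1.2) -> float:
    """Fraction Q of native contacts formed.

    ``contacts`` is an iterable of (i, j, r_native[, ...]) bead-index tuples;
    a contact counts as formed when r_ij < factor * r_native.
    """
    contacts = list(contacts)
    if not contacts:
        raise ValueError("contact list is empty")
    p = conf.positions if isinstance(conf, ChainConfiguration) else np.asarray(conf)
    formed = 0
    for c in contacts:
        i, j, r0 = int(c[0]), int(c[1]), float(c[2])
        if np.linalg.norm(p[i] - p[j]) < factor * r0:
            formed += 1
    return formed / len(contacts)


def is_folded(F: float, L: float) -> bool:
    """Native-basin test: sqrt(F) < 0.9 and L > 0.9."""
    return bool(np.sqrt(F) < RMSD_THRESHOLD and L > L_THRESHOLD)


@dataclass
class TransitionTimes:
    """First sustained times of bridge closure, topology formation, folding."""

    t_b: float | None = None
    t_k: float | None = None
    t_f: float | None = None

    def __post_init__(self):
        for name in ("t_b", "t_k", "t_f"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.t_f is not None and self.t_k is None:
            raise ValueError("t_f present requires t_k present")

    @property
    def successful(self) -> bool:
        return self.t_f is not None


def _first_sustained(times: np.ndarray, cond: np.ndarray, persistence: float):
    """First time from which ``cond`` holds continuously for ``persistence``.

    The window [t_i, t_i + persistence] must lie within the trace.
    """
    n = len(times)
    i = 0
    while i < n:
        if not cond[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cond[j + 1]:
            j += 1
        if times[j] - times[i] >= persistence:
            return float(times[i])
        i = j + 1
    return None


def transition_times(
    traj: TrajectoryRecord,
    bridge_threshold: float,
    persistence: float = PERSISTENCE,
) -> TransitionTimes:
    """Transition times from the d_b1, L and F traces of a trajectory.

    Each time is the first sample time from which its condition --
    d_b1 < bridge_threshold for t_b, L > 0.9 for t_k, the native-basin test
    for t_f -- holds continuously for the persistence window (default
    10 tau_MD).
    """
    t = traj.sample_times
    d = traj.trace("d_b1")
    L = traj.trace("L")
    F = traj.trace("F")
    t_b = _first_sustained(t, d < bridge_threshold, persistence)
    t_k = _first_sustained(t, L > L_THRESHOLD, persistence)
    folded = (np.sqrt(F) < RMSD_THRESHOLD) & (L > L_THRESHOLD)
    t_f = _first_sustained(t, folded, persistence) if t_k is not None else None
    return TransitionTimes(t_b=t_b, t_k=t_k, t_f=t_f)


def classify_pathway(
    traj: TrajectoryRecord,
    times: TransitionTimes,
    reopening_threshold: float,
) -> str:
    """Mechanism label of a successful trajectory.

    * ``open-loop``: the topology forms before the bridge (t_k < t_b, or the
      bridge never closed by t_k);
    * ``threading``: the bridge closed first and stayed below the reopening
      threshold until the topology formed;
    * ``reopening``: the bridge closed first but fluctuated beyond the
      reopening threshold in [t_b, t_k].

    The classifier compares t_k with t_b only; t_f may precede t_b inside
    the native basin (the bridge contact can occur slightly later than the
    arrival in the basin) without affecting the label.
    """
    if not times.successful:
        raise ValueError("not a successful trajectory (t_f absent)")
    t_k = times.t_k
    if times.t_b is None or t_k < times.t_b:
        return "open-loop"
    if times.t_b <= t_k:
        t = traj.sample_times
        d = traj.trace("d_b1")
        win = (t >= times.t_b) & (t <= t_k)
        if np.any(d[win] > reopening_threshold):
            return "reopening"
        return "threading"
    return "unresolved"


@dataclass
class Landscape:
    """2-D folding landscape F = -log f over two reaction variables."""

    var_x: str
    var_y: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_samples: int

    @property
    def surface(self) -> np.ndarray:
        """F = -log f with probability-normalized f; empty bins are masked."""
        f = self.counts / self.n_samples
        with np.errstate(divide="ignore"):
            F = -np.log(f)
        return np.ma.masked_where(self.counts == 0, F)


def folding_landscape(
    records,
    var_x: str,
    var_y: str,
    bins=40,
    successful_only: bool = False,
    bridge_threshold: float | None = None,
    ranges=None,
) -> Landscape:
    """Pooled 2-D histogram landscape over an ensemble of trajectories.

    With ``successful_only`` the pool is restricted to trajectories that
    reach the native basin (the "successful folding landscape" F_s), which
    requires ``bridge_threshold`` for the transition-time computation.
    """
    records = list(records)
    if successful_only:
        if bridge_threshold is None:
            raise ValueError("successful_only requires bridge_threshold")
        records = [
            r
            for r in records
            if transition_times(r, bridge_threshold).successful
        ]
    if not records:
        raise ValueError("empty trajectory selection")
    xs = np.concatenate([r.trace(var_x) for r in records])
    ys = np.concatenate([r.trace(var_y) for r in records])
    counts, xe, ye = np.histogram2d(xs, ys, bins=bins, range=ranges)
    return Landscape(var_x, var_y, xe, ye, counts, n_samples=len(xs))


def pathway_statistics(
    records,
    bridge_threshold: float,
    reopening_threshold: float,
    persistence: float = PERSISTENCE,
) -> dict:
    """Folding probability and pathway distribution of an ensemble.

    Returns P_f = n_f / n_tot and the per-mechanism probabilities (class
    counts over the total number of trajectories), which sum to P_f together
    with the unresolved fraction, plus the per-trajectory details.
    """
    records = list(records)
    if not records:
        raise ValueError("empty ensemble")
    labels = []
    details = []
    for r in records:
        times = transition_times(r, bridge_threshold, persistence)
        if times.successful:
            lab = classify_pathway(r, times, reopening_threshold)
        else:
            lab = None
        labels.append(lab)
        details.append((times, lab))
    n = len(records)
    n_f = sum(1 for lab in labels if lab is not None)
    out = {
        "n_total": n,
        "n_folded": n_f,
        "P_f": n_f / n,
        "P_threading": labels.count("threading") / n,
        "P_reopening": labels.count("reopening") / n,
        "P_open_loop": labels.count("open-loop") / n,
        "P_unresolved": labels.count("unresolved") / n,
        "details": details,
    }
    return out
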