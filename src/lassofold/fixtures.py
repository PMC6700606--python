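"""Deterministic synthetic test systems.

Three generators support desk-scale experiments and testing of every other
module without any external structure file:

* :func:`make_mini_lasso` -- a small chain whose native state is a complex
  lasso: a near-circular covalent loop whose ends play the role of the
  bridge-forming cysteines, threaded once (L1) or twice in opposite
  directions through a hairpin (L2) by its tail.  The returned reference
  geometry and topology spec make it a drop-in stand-in for a real lasso
  protein at a fraction of the cost.
* :func:`make_hopf_pair` -- two discretized circles, linked or unlinked, the
  textbook oracle for the Gauss linking number.
* :func:`make_trace` -- exact piecewise synthetic observable traces for
  analyzer unit tests.

All generators are bit-reproducible from their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainConfiguration, extract_reference_geometry
from .dynamics import TrajectoryRecord
from .topology import (
    TopologySpec,
    linking_from_configuration,
    native_signature_from_structure,
)

__all__ = ["MiniLassoParams", "make_mini_lasso", "make_hopf_pair", "make_trace"]


@dataclass
class MiniLassoParams:
    n_loop: int = 12
    n_tail: int = 10
    lasso_class: str = "L2"
    bead_spacing: float = 1.0
    seed: int = 0
    jitter_sd: float = 0.02

    def __post_init__(self):
        if self.n_loop < 8:
            raise ValueError("n_loop must be >= 8")
        if self.n_tail < 4:
            raise ValueError("n_tail must be >= 4")
        if self.lasso_class not in ("L1", "L2"):
            raise ValueError("lasso_class must be 'L1' or 'L2'")


def _loop_radius(n_loop: int, gap: float = 1.2, bond: float = 1.0) -> float:
    """Radius such that n_loop-1 chords of ``bond`` plus one of ``gap`` close."""
    from scipy.optimize import brentq

    def f(R):
        return (
            (n_loop - 1) * 2 * np.arcsin(bond / (2 * R))
            + 2 * np.arcsin(gap / (2 * R))
            - 2 * np.pi
        )

    return brentq(f, max(gap, bond) / 2 + 1e-9, 10.0 * n_loop)


def _chord_walk(w, chord):
    """Place points along a polyline at constant chord distance.

    Walks the path, placing each next point where the sphere of radius
    ``chord`` around the previous point last intersects the remaining path.
    Returns the points (including the start) and the leftover distance from
    the last placed point to the path end.
    """
    pts = [w[0]]
    seg_i, t = 0, 0.0  # current position: segment index and fraction
    while True:
        cur = pts[-1]
        placed = False
        j, tj = seg_i, t
        while j < len(w) - 1:
            a = w[j] + tj * (w[j + 1] - w[j])
            b = w[j + 1]
            # solve |a + u (b - a) - cur| = chord for the largest u in (0, 1]
            d = b - a
            f = a - cur
            A = d @ d
            B = 2 * f @ d
            C = f @ f - chord * chord
            disc = B * B - 4 * A * C
            if disc >= 0 and A > 0:
                u = (-B + np.sqrt(disc)) / (2 * A)
                if 0 < u <= 1.0:
                    pts.append(a + u * d)
                    seg_i, t = j, tj + u * (1.0 - tj)
                    placed = True
                    break
            j += 1
            tj = 0.0
        if not placed:
            leftover = float(np.linalg.norm(w[-1] - pts[-1]))
            return np.asarray(pts), leftover


def _resample_polyline(waypoints, target_spacing: float = 0.97):
    """Resample a waypoint path at near-uniform chord (bond) spacing.

    The chord length is tuned within +-15% of the target so that the walk
    lands exactly on the final waypoint; intermediate bonds are then all
    equal to the tuned chord.
    """
    w = np.asarray(waypoints, float)
    arclen = float(np.linalg.norm(np.diff(w, axis=0), axis=1).sum())
    nb = max(2, int(round(arclen / target_spacing)))
    lo, hi = 0.80 * target_spacing, 1.20 * target_spacing
    best = None
    for _ in range(50):
        chord = 0.5 * (lo + hi)
        pts, leftover = _chord_walk(w, chord)
        placed = len(pts) - 1  # chords placed; final bond is the leftover
        if placed > nb - 1:
            lo = chord  # chord too small
        elif placed < nb - 1:
            hi = chord  # chord too large
        else:
            best = pts
            if abs(leftover - chord) < 1e-9:
                break
            if leftover > chord:
                lo = chord
            else:
                hi = chord
    if best is None:
        best, _ = _chord_walk(w, target_spacing)
    return np.vstack([best, w[-1]])


def make_mini_lasso(params: MiniLassoParams | None = None, **kw):
    """Build a synthetic mini-lasso native structure.

    Returns ``(conf, ref, spec)``: the native chain configuration, its
    reference geometry (bridge pair = the two loop-end "cysteines" at 1.2
    sigma separation) and a topology spec whose native signature is computed
    from the generated geometry.

    Chain layout: threading tail first (a hairpin through the loop for L2, a
    single strand for L1), then a connector routed outside the loop rim,
    then the covalent loop.  Strand beads carry a small deterministic zigzag
    plus seeded Gaussian jitter so that no dihedral is degenerate.
    """
    params = params or MiniLassoParams(**kw)
    n_loop, n_tail = params.n_loop, params.n_tail
    rng = np.random.default_rng(params.seed)
    gap = 1.2

    R = _loop_radius(n_loop, gap=gap, bond=params.bead_spacing)
    g_gap = 2 * np.arcsin(gap / (2 * R))
    g_bond = 2 * np.arcsin(params.bead_spacing / (2 * R))
    # clockwise ordering (normal of the fan triangulation points -z), so the
    # native linking number of the downward-threading strand is positive
    angles = g_gap / 2 + g_bond * np.arange(n_loop)
    loop_pts = np.column_stack(
        [R * np.cos(-angles), R * np.sin(-angles), np.zeros(n_loop)]
    )

    zig = lambda k, amp=0.08: amp * (-1.0) ** k  # noqa: E731

    if params.lasso_class == "L2":
        n_a = n_tail // 2
        n_b = n_tail - n_a
        # turn depth below the loop plane: deep enough that the reduced-tail
        # plane crossings sit far from the segment ends (sharp L switches)
        depth = 1.5 if n_a >= 4 else 0.5
        z_a = (n_a - 1.0 - depth) - np.arange(n_a)  # descend to -depth
        z_b = -depth + np.arange(n_b)               # ascend from -depth
        strand_a = np.column_stack(
            [np.full(n_a, -0.5), [zig(k) for k in range(n_a)], z_a]
        )
        strand_b = np.column_stack(
            [np.full(n_b, +0.5), [zig(k + 1) for k in range(n_b)], z_b]
        )
        tail_pts = np.vstack([strand_a, strand_b])
        top_b = strand_b[-1]
        turn_pos_1based = n_a  # bottom of strand A
        tail_ids = [1, turn_pos_1based, n_tail]
        split = 1
    else:  # L1: single strand straight through the loop
        depth = 1.5 if n_tail >= 6 else 0.5
        z_s = (n_tail - 1.0 - depth) - np.arange(n_tail)
        tail_pts = np.column_stack(
            [np.zeros(n_tail), [zig(k) for k in range(n_tail)], z_s]
        )
        top_b = None
        tail_ids = [1, (n_tail + 1) // 2, n_tail]
        split = None

    l1 = loop_pts[0]
    if params.lasso_class == "L2":
        # over the rim: from the top of strand B horizontally outward, then
        # down outside the loop radius to l_1
        mid_z = float(np.clip(0.5 * (top_b[2] + 0.2), 0.7, 1.6))
        way = [top_b, top_b + np.array([1.3, -0.3, 0.2]),
               np.array([R + 0.9, -0.3, mid_z]),
               np.array([R + 0.9, l1[1], 0.7]), l1]
    else:
        # under the rim: from the strand bottom outward, below, and up to l_1
        bot = tail_pts[-1]
        way = [bot, np.array([R * 0.6, 0.3, -1.2]),
               np.array([R + 0.8, 0.4, -1.0]), np.array([R + 0.8, l1[1], -0.3]), l1]
    connector = _resample_polyline(way)[1:-1]
    connector = connector + np.column_stack(
        [np.zeros(len(connector)),
         [zig(k, 0.06) for k in range(len(connector))],
         np.zeros(len(connector))]
    )

    pts = np.vstack([tail_pts, connector, loop_pts])
    pts = pts + rng.normal(scale=params.jitter_sd, size=pts.shape)

    n_total = len(pts)
    conf = ChainConfiguration(pts, np.arange(1, n_total + 1))

    # no steric clash among non-bonded beads
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    iu = np.triu_indices(n_total, k=2)
    if d[iu].min() <= 0.9:
        raise ValueError("infeasible mini-lasso geometry: steric clash")

    c1_id = n_total - n_loop + 1
    c2_id = n_total
    ref = extract_reference_geometry(conf, bridge_pairs=[(c1_id, c2_id)])

    loop_sel = np.round(np.linspace(0, n_loop - 1, 5)).astype(int)
    spec = TopologySpec(
        loop_residues=(c1_id + loop_sel).tolist(),
        tail_residues=tail_ids,
        tail_split_index=split,
        native_signature=[(0, 1)],  # placeholder, replaced below
    )
    sig = native_signature_from_structure(conf, spec)
    expected = 2 if params.lasso_class == "L2" else 1
    if len(sig) != expected:
        raise ValueError(
            f"infeasible mini-lasso geometry: {len(sig)} piercings, "
            f"expected {expected}"
        )
    spec.native_signature = sig
    return conf, ref, spec


def make_hopf_pair(radius: float = 1.0, separation: float = 1.0, n_vertices: int = 64):
    """Two discretized circles: a Hopf link for 0 < separation < radius.

    Circle 1 lies in the xy-plane at the origin; circle 2 in the xz-plane
    centered at (separation, 0, 0).  Both are returned as (n_vertices, 3)
    open vertex lists (close them when integrating).
    """
    if n_vertices < 8:
        raise ValueError("need at least 8 vertices")
    t = 2 * np.pi * np.arange(n_vertices) / n_vertices
    c1 = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)])
    c2 = np.column_stack(
        [separation + radius * np.cos(t), np.zeros_like(t), radius * np.sin(t)]
    )
    return c1, c2


def make_trace(segments, sample_interval: float = 1.0, seed: int = 0):
    """Exact piecewise traces for analyzer tests.

    ``segments`` is a list of ``(t0, t1, values)`` with ``values`` a mapping
    from trace name (e.g. ``"d_b1"``, ``"L"``, ``"F"``) to either a constant
    or a ``(v_start, v_end)`` pair interpolated linearly over the segment.
    Segments must tile [0, tau_run] without gaps or overlaps.
    """
    if not segments:
        raise ValueError("empty trace specification")
    segs = sorted(segments, key=lambda s: s[0])
    for (a0, a1, _), (b0, _b1, _v) in zip(segs, segs[1:]):
        if a1 > b0 + 1e-12:
            raise ValueError("overlapping trace segments")
        if a1 < b0 - 1e-12:
            raise ValueError("gap between trace segments")
    t_end = segs[-1][1]
    times = np.arange(0.0, t_end + 1e-9, sample_interval)
    names = sorted(set().union(*(v.keys() for _0, _1, v in segs)))
    traces = {k: np.empty_like(times) for k in names}
    for i, t in enumerate(times):
        for t0, t1, values in segs:
            # half-open segments [t0, t1); the final segment owns its end
            last = t1 == t_end
            if t0 - 1e-12 <= t < t1 - 1e-12 or (last and t <= t1 + 1e-12):
                for k in names:
                    v = values[k]
                    if np.iterable(v):
                        v0, v1 = v
                        frac = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
                        traces[k][i] = v0 + frac * (v1 - v0)
                    else:
                        traces[k][i] = v
                break
    return TrajectoryRecord(
        sample_times=times, traces=traces, seed=seed, run_length=float(t_end)
    )


def native_linking(conf, spec) -> float:
    """Convenience: G of a native fixture (sign follows the generator)."""
    return linking_from_configuration(conf, spec)
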