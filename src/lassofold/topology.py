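"""Complex-lasso topology descriptors on reduced structures.

A complex lasso is a covalent loop -- the backbone stretch between two
bridge-forming cysteines, sealed by the disulfide bond -- whose spanning
surface is pierced by another part of the chain.  Monitoring this along a
trajectory needs descriptors that are cheap and specific to the native
topology, so the structure is *reduced* to a handful of representative
residues: the loop becomes an M_l-vertex polygon fan-triangulated into
M_l - 2 triangles, the threading tail an M_t-vertex polyline.

Two descriptors are computed on the reduced geometry:

* the lasso variable ``L`` in [0, 1]: a product of smooth (Fermi-switched)
  indicator scores, one per required native piercing event, rising to ~1
  when every native piercing of the loop surface is present with the right
  direction;
* the Gauss linking number ``G``: the double line integral of the mutual
  winding of the loop polyline (integrated between the two cysteines) and
  the tail.  For an L2 lasso the tail is split at the hairpin turn and its
  second part integrated with reversed orientation, so the two opposite
  piercings add instead of cancelling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chain import ChainConfiguration

__all__ = [
    "TopologySpec",
    "reduce_structure",
    "triangulate_loop",
    "segment_triangle_crossing",
    "lasso_variable",
    "gauss_linking_number",
    "polyline_linking",
    "segment_pair_linking",
    "native_signature_from_structure",
]

#: default Fermi switching width for geometric margins, sigma units
DEFAULT_SWITCH_WIDTH = 0.2


def fermi_switch(z, w: float = DEFAULT_SWITCH_WIDTH):
    """Smooth step [1 + exp(-z/w)]^-1: 0 for z << 0, 1 for z >> 0."""
    from scipy.special import expit

    return expit(np.asarray(z, float) / w)


@dataclass
class TopologySpec:
    """Reduced-structure selection and native piercing signature.

    ``loop_residues`` are ordered residue ids whose first and last entries
    are the bridge cysteines; ``tail_residues`` the reduced threading tail.
    ``tail_split_index`` (position within ``tail_residues``) separates the
    two oppositely oriented tail parts of an L2 hairpin; None means a single
    part (L1).  ``native_signature`` lists the required piercing events as
    (tail_part, direction) pairs, direction being the crossing sign with
    respect to the loop-orientation normal.
    """

    loop_residues: np.ndarray
    tail_residues: np.ndarray
    tail_split_index: int | None = None
    native_signature: list = field(default_factory=list)
    switch_width: float = DEFAULT_SWITCH_WIDTH

    def __post_init__(self):
        self.loop_residues = np.asarray(self.loop_residues, int)
        self.tail_residues = np.asarray(self.tail_residues, int)
        if len(self.loop_residues) < 3:
            raise ValueError("need at least 3 loop residues")
        if len(self.tail_residues) < 2:
            raise ValueError("need at least 2 tail residues")
        if set(self.loop_residues) & set(self.tail_residues):
            raise ValueError("loop and tail residue sets must be disjoint")
        self.native_signature = [
            (int(p), int(d)) for p, d in self.native_signature
        ]

    @property
    def n_tail_parts(self) -> int:
        return 1 if self.tail_split_index is None else 2

    def to_json(self) -> str:
        return json.dumps(
            {
                "loop_residues": self.loop_residues.tolist(),
                "tail_residues": self.tail_residues.tolist(),
                "tail_split_index": self.tail_split_index,
                "native_signature": self.native_signature,
                "switch_width": self.switch_width,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TopologySpec":
        d = json.loads(text)
        return cls(
            d["loop_residues"],
            d["tail_residues"],
            d.get("tail_split_index"),
            d.get("native_signature", []),
            d.get("switch_width", DEFAULT_SWITCH_WIDTH),
        )


#: default reduction for 2GMF: loop = bridge cysteines 88/121 plus three
#: roughly equidistant interior residues; tail = the threading hairpin,
#: split at its turn.  The L2 hairpin pierces once per part, in opposite
#: directions; recompute the signature on the actual native structure with
#: :func:`native_signature_from_structure` before production use.
TWO_GMF_SPEC = dict(
    loop_residues=[88, 96, 105, 113, 121],
    tail_residues=[43, 48, 53],
    tail_split_index=1,
    native_signature=[(0, 1), (1, -1)],
)


# ---------------------------------------------------------------------------
# structure reduction
# ---------------------------------------------------------------------------

def reduce_structure(conf: ChainConfiguration, spec: TopologySpec):
    """Reduced loop polyline and tail part polylines, in sigma units.

    Tail parts follow the chain order; for an L2 split both parts include
    the turn residue.  Orientation handling (reversal of part 2) is done by
    the descriptor functions, not here.
    """
    loop = np.array([conf.positions[conf.index_of(r)] for r in spec.loop_residues])
    tail = np.array([conf.positions[conf.index_of(r)] for r in spec.tail_residues])
    if spec.tail_split_index is None:
        parts = [tail]
    else:
        s = spec.tail_split_index
        if not 0 < s < len(tail) - 1:
            raise ValueError("tail_split_index must be interior")
        parts = [tail[: s + 1], tail[s:]]
    return loop, parts


def triangulate_loop(loop: np.ndarray) -> np.ndarray:
    """Fan triangulation from the first loop vertex: (M_l - 2, 3, 3) array."""
    m = len(loop)
    tris = np.empty((m - 2, 3, 3))
    for i in range(1, m - 1):
        tris[i - 1] = (loop[0], loop[i], loop[i + 1])
    return tris


# ---------------------------------------------------------------------------
# segment / triangle crossings
# ---------------------------------------------------------------------------

def segment_triangle_crossing(p0, p1, triangle, w: float = DEFAULT_SWITCH_WIDTH):
    """Signed crossing of the open segment p0->p1 through a triangle.

    Returns ``(hard, soft)``: ``hard`` is +1/-1 for a strict interior
    crossing (sign = crossing direction versus the triangle normal, which is
    fixed by the vertex order), 0 otherwise; ``soft`` in [0, 1] is a product
    of Fermi switches of width ``w`` on the in-plane edge margins and the
    along-segment margins, all in sigma units.  Degenerate triangles yield
    (0, 0.0) with a warning.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    A, B, C = (np.asarray(v, float) for v in triangle)
    nvec = np.cross(B - A, C - A)
    nn = np.linalg.norm(nvec)
    if nn < 1e-12:
        warnings.warn("degenerate (zero-area) triangle", stacklevel=2)
        return 0, 0.0
    nhat = nvec / nn

    d0 = float(np.dot(p0 - A, nhat))
    d1 = float(np.dot(p1 - A, nhat))
    denom = d0 - d1
    if abs(denom) < 1e-12:  # segment parallel to the plane
        return 0, 0.0
    t = d0 / denom
    X = p0 + t * (p1 - p0)
    seg_len = float(np.linalg.norm(p1 - p0))

    # along-segment margins (distance of the plane intersection from the ends)
    m_t0 = t * seg_len
    m_t1 = (1.0 - t) * seg_len

    # in-plane signed distances to the three edges (positive inside)
    margins = []
    verts = (A, B, C)
    for k in range(3):
        va, vb = verts[k], verts[(k + 1) % 3]
        e = vb - va
        inward = np.cross(nhat, e)
        inward /= np.linalg.norm(inward)
        margins.append(float(np.dot(X - va, inward)))

    # crossing direction vs normal: sign of (segment direction . normal)
    sign = 1 if (d1 - d0) > 0 else -1

    hard = 0
    if 0.0 < t < 1.0 and all(m > 0 for m in margins):
        hard = sign

    soft = float(
        fermi_switch(m_t0, w)
        * fermi_switch(m_t1, w)
        * np.prod([fermi_switch(m, w) for m in margins])
    )
    return hard, soft


def _all_crossings(loop, parts, w):
    """All (part, segment, triangle, hard, soft, sign) crossing candidates."""
    tris = triangulate_loop(loop)
    out = []
    for pi, part in enumerate(parts):
        for si in range(len(part) - 1):
            for ti, tri in enumerate(tris):
                hard, soft = segment_triangle_crossing(part[si], part[si + 1], tri, w)
                # candidate sign even without a hard crossing
                A = tri[0]
                nvec = np.cross(tri[1] - tri[0], tri[2] - tri[0])
                nn = np.linalg.norm(nvec)
                if nn < 1e-12:
                    continue
                s = float(np.dot(part[si + 1] - part[si], nvec / nn))
                sign = 1 if s > 0 else (-1 if s < 0 else 0)
                out.append((pi, si, ti, hard, soft, sign))
    return out


def lasso_variable(conf: ChainConfiguration, spec: TopologySpec) -> float:
    """Continuous lasso variable L in [0, 1].

    L is the product, over the required native piercing events, of the best
    soft crossing score realizing that event (same tail part, same crossing
    direction).  The fan triangles tile one loop surface, so a segment's
    score is the sum of its per-triangle soft scores (clipped at 1): a
    piercing near an interior fan diagonal collects ~0.5 from each adjacent
    triangle instead of being spuriously penalized.  Surplus non-native
    crossings do not reduce L.
    """
    if not spec.native_signature:
        raise ValueError("native_signature is empty")
    loop, parts = reduce_structure(conf, spec)
    cands = _all_crossings(loop, parts, spec.switch_width)
    L = 1.0
    for part, direction in spec.native_signature:
        # per-segment sum over the triangle fan, then best segment
        seg_scores = {}
        for pi, si, _ti, _hard, soft, sign in cands:
            if pi == part and sign == direction:
                seg_scores[si] = seg_scores.get(si, 0.0) + soft
        best = min(1.0, max(seg_scores.values())) if seg_scores else 0.0
        L *= best
    return float(L)


def hard_piercing_events(conf: ChainConfiguration, spec: TopologySpec) -> list:
    """Hard (binary) piercing events as (tail_part, direction) pairs.

    A tail segment crossing several fan triangles of the same loop counts
    once per triangle crossed; for a simple (convex, planar-ish) reduced
    loop each true piercing registers exactly one triangle.
    """
    loop, parts = reduce_structure(conf, spec)
    events = []
    for pi, _si, _ti, hard, _soft, _sign in _all_crossings(
        loop, parts, spec.switch_width
    ):
        if hard != 0:
            events.append((pi, hard))
    return events


def native_signature_from_structure(
    conf: ChainConfiguration, spec: TopologySpec
) -> list:
    """Signature of the native structure, for storing into a TopologySpec."""
    return hard_piercing_events(conf, spec)


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

def segment_pair_linking(a1, a2, b1, b2) -> float:
    """Analytic Gauss integral of one segment pair (solid-angle formula).

    Exact value of (1/4pi) int int (r1-r2).(dr1 x dr2)/|r1-r2|^3 over the
    straight segments a1->a2 and b1->b2.  Near-degenerate geometries
    (coincident endpoints across the two segments) are regularized with a
    1e-9 offset.
    """
    p = [np.asarray(a1, float), np.asarray(a2, float),
         np.asarray(b1, float), np.asarray(b2, float)]
    # regularize coincident endpoints across the two curves
    for i in (0, 1):
        for j in (2, 3):
            if np.linalg.norm(p[i] - p[j]) < 1e-12:
                warnings.warn(
                    "coincident segment endpoints; regularized with 1e-9 offset",
                    stacklevel=2,
                )
                p[j] = p[j] + 1e-9

    r12 = p[1] - p[0]
    r34 = p[3] - p[2]
    r13 = p[2] - p[0]
    r14 = p[3] - p[0]
    r23 = p[2] - p[1]
    r24 = p[3] - p[1]

    def _unit(v):
        nv = np.linalg.norm(v)
        return v / nv if nv > 1e-14 else None

    n1 = _unit(np.cross(r13, r14))
    n2 = _unit(np.cross(r14, r24))
    n3 = _unit(np.cross(r24, r23))
    n4 = _unit(np.cross(r23, r13))
    if n1 is None or n2 is None or n3 is None or n4 is None:
        # segments (nearly) coplanar with a connecting vector: integral -> 0
        return 0.0

    def _asin(x):
        return float(np.arcsin(np.clip(x, -1.0, 1.0)))

    omega = (
        _asin(np.dot(n1, n2))
        + _asin(np.dot(n2, n3))
        + _asin(np.dot(n3, n4))
        + _asin(np.dot(n4, n1))
    )
    s = np.dot(np.cross(r34, r12), r13)
    sign = 1.0 if s > 0 else (-1.0 if s < 0 else 0.0)
    return sign * omega / (4.0 * np.pi)


def polyline_linking(curve1, curve2, closed1=False, closed2=False) -> float:
    """Gauss linking integral between two polylines (sum over segment pairs)."""
    c1 = np.asarray(curve1, float)
    c2 = np.asarray(curve2, float)
    if closed1:
        c1 = np.vstack([c1, c1[:1]])
    if closed2:
        c2 = np.vstack([c2, c2[:1]])
    g = 0.0
    for i in range(len(c1) - 1):
        for j in range(len(c2) - 1):
            g += segment_pair_linking(c1[i], c1[i + 1], c2[j], c2[j + 1])
    return g


def gauss_linking_number(loop, tail_parts, orientations=None) -> float:
    """Open-curve Gauss linking number of the reduced lasso geometry.

    ``loop`` is the reduced covalent-loop polyline whose ends are the bridge
    cysteines (the integration runs between them, so G responds to the loop
    opening and closing).  ``tail_parts`` is a list of tail polylines;
    ``orientations`` gives the integration direction of each part (default:
    +1 for the first, -1 for the second, so the two opposite piercings of an
    L2 hairpin add up).
    """
    if orientations is None:
        orientations = [1] + [-1] * (len(tail_parts) - 1)
    g = 0.0
    for part, o in zip(tail_parts, orientations):
        part = np.asarray(part, float)
        if o < 0:
            part = part[::-1]
        g += polyline_linking(loop, part)
    return g


def linking_from_configuration(conf: ChainConfiguration, spec: TopologySpec) -> float:
    """G evaluated on the reduced structure of a configuration."""
    loop, parts = reduce_structure(conf, spec)
    return gauss_linking_number(loop, parts)
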