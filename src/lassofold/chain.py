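"""Calpha chain configurations, reference geometry and initial-state generation.

The protein is represented by one bead per residue, placed at the Calpha
position.  All coordinates are handled in reduced units with the length unit
``sigma`` = 3.8 A, the typical separation between consecutive Calpha atoms.
The reference (native) structure is summarised by its internal coordinates --
bond lengths, bending angles and torsion angles -- which parameterise the
structure-based angular potentials, together with the cysteine bridge pairs
and their native distances.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

#: length unit in Angstrom (consecutive-Calpha spacing)
SIGMA_ANGSTROM = 3.8

__all__ = [
    "SIGMA_ANGSTROM",
    "ChainConfiguration",
    "ReferenceGeometry",
    "ModelParameters",
    "ChainError",
    "parse_calpha_chain",
    "extract_reference_geometry",
    "generate_stretched_configuration",
    "build_chain_from_internal",
    "bending_angles",
    "torsion_angles",
    "write_xyz",
    "read_xyz",
    "write_calpha_pdb",
]


class ChainError(ValueError):
    """Raised for malformed or unusable chain input."""


@dataclass
class ChainConfiguration:
    """Ordered Calpha bead positions in units of sigma.

    Parameters
    ----------
    positions : (N, 3) float array
        Bead coordinates in sigma units.
    residue_ids : (N,) int array
        Original PDB residue numbers (or 1..N for synthetic chains); used so
        that biological indices (e.g. cysteines 88 and 121 of 2GMF) address
        the right beads even when some residues are unresolved.
    chain_label : str
        Chain identifier.
    """

    positions: np.ndarray
    residue_ids: np.ndarray = None
    chain_label: str = "A"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ChainError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ChainError("positions contain non-finite values")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.positions) + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.residue_ids) != len(self.positions):
            raise ChainError("residue_ids length mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def index_of(self, residue_id: int) -> int:
        """Array index of a PDB residue number."""
        hits = np.flatnonzero(self.residue_ids == residue_id)
        if len(hits) == 0:
            raise ChainError(f"unknown residue id {residue_id}")
        return int(hits[0])

    def end_to_end_distance(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def copy(self) -> "ChainConfiguration":
        return ChainConfiguration(
            self.positions.copy(), self.residue_ids.copy(), self.chain_label
        )


@dataclass
class ReferenceGeometry:
    """Native internal coordinates and bridge definitions of a chain."""

    theta0: np.ndarray            # (N-2,) native bending angles, radians in [0, pi]
    phi0: np.ndarray              # (N-3,) native torsion angles, radians in (-pi, pi]
    bond_lengths: np.ndarray      # (N-1,) native bond lengths, sigma units
    bridge_pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bridge_ref_dist: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residue_ids: np.ndarray = None

    def __post_init__(self):
        self.theta0 = np.asarray(self.theta0, dtype=float)
        self.phi0 = np.asarray(self.phi0, dtype=float)
        self.bond_lengths = np.asarray(self.bond_lengths, dtype=float)
        self.bridge_pairs = np.asarray(self.bridge_pairs, dtype=int).reshape(-1, 2)
        self.bridge_ref_dist = np.asarray(self.bridge_ref_dist, dtype=float)

    @property
    def n_beads(self) -> int:
        return len(self.bond_lengths) + 1

    @property
    def n_bridges(self) -> int:
        return len(self.bridge_pairs)

    def to_json(self) -> str:
        payload = {
            "theta0": self.theta0.tolist(),
            "phi0": self.phi0.tolist(),
            "bond_lengths": self.bond_lengths.tolist(),
            "bridges": self.bridge_pairs.tolist(),
            "bridge_ref_dist": self.bridge_ref_dist.tolist(),
        }
        if self.residue_ids is not None:
            payload["residue_ids"] = np.asarray(self.residue_ids).tolist()
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceGeometry":
        d = json.loads(text)
        return cls(
            theta0=d["theta0"],
            phi0=d["phi0"],
            bond_lengths=d["bond_lengths"],
            bridge_pairs=d.get("bridges", []),
            bridge_ref_dist=d.get("bridge_ref_dist", []),
            residue_ids=np.asarray(d["residue_ids"]) if "residue_ids" in d else None,
        )


@dataclass
class ModelParameters:
    """Reduced-unit model and integration parameters.

    Defaults follow the standard coarse-grained bead-spring settings: FENE
    strength 30 and maximum extension 1.5 sigma, Langevin friction time 1.0
    and integration step 5e-4 (all in reduced units with m = epsilon = 1).
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    mass: float = 1.0
    k_fene: float = 30.0
    R0: float = 1.5
    dt: float = 5.0e-4
    tau_frict: float = 1.0
    temperature: float = 0.1
    #: cap on the per-bead *angular* force magnitude; far above ordinary
    #: force scales, it only bounds the 1/sin(theta) spikes of
    #: near-collinear transients (bond/steric walls are never capped)
    angular_force_cap: float = 1.0e4

    def __post_init__(self):
        if self.R0 <= self.sigma:
            raise ValueError("R0 must exceed sigma")
        if self.dt <= 0 or self.tau_frict <= 0:
            raise ValueError("dt and tau_frict must be positive")

    @property
    def gamma(self) -> float:
        """Langevin friction coefficient m / tau_frict."""
        return self.mass / self.tau_frict


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def bending_angles(positions: np.ndarray) -> np.ndarray:
    """Interior angles in [0, pi] at each internal bead.

    theta_i is the angle at bead i+1 between the bond vectors to beads i and
    i+2; a collinear triple gives theta = pi.
    """
    p = np.asarray(positions, float)
    u = p[:-2] - p[1:-1]
    v = p[2:] - p[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


def torsion_angles(positions: np.ndarray, check_degenerate: bool = True) -> np.ndarray:
    """Signed dihedral angles in (-pi, pi] for each consecutive quadruplet.

    Right-handed (IUPAC) convention: a planar trans zig-zag has |phi| = pi.
    Raises ``ChainError`` for collinear quadruplets when ``check_degenerate``.
    """
    p = np.asarray(positions, float)
    b1 = p[1:-2] - p[:-3]
    b2 = p[2:-1] - p[1:-2]
    b3 = p[3:] - p[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
    if check_degenerate:
        scale = (np.linalg.norm(b1, axis=1) * nb2) ** 2
        bad = (np.einsum("ij,ij->i", n1, n1) < 1e-16 * scale) | (
            np.einsum("ij,ij->i", n2, n2) < 1e-16 * scale
        )
        if np.any(bad):
            raise ChainError(
                f"degenerate dihedral at quadruplet(s) {np.flatnonzero(bad).tolist()}"
            )
    phi = np.arctan2(y, x)
    # map -pi -> pi so the range is (-pi, pi]
    phi[phi <= -np.pi + 1e-15] = np.pi
    return phi


# ---------------------------------------------------------------------------
# parsing and reference extraction
# ---------------------------------------------------------------------------

def parse_calpha_chain(pdb_text, chain_label: str = "A") -> ChainConfiguration:
    """Extract the Calpha trace of one chain from PDB-format text.

    One bead per resolved residue, ordered by residue number; coordinates are
    converted from Angstrom to sigma units.  For duplicate CA records
    (altlocs) the first occurrence is kept, with a warning.

    Parameters
    ----------
    pdb_text : str or file-like
        PDB ATOM records.
    chain_label : str
        Chain identifier to extract.
    """
    if hasattr(pdb_text, "read"):
        text = pdb_text.read()
    else:
        text = pdb_text

    chains_seen = set()
    coords, resids = [], []
    seen = set()
    for line in io.StringIO(text):
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        name = line[12:16].strip()
        ch = line[21].strip()
        chains_seen.add(ch)
        if name != "CA" or ch != chain_label.strip():
            continue
        resid = int(line[22:26])
        if resid in seen:
            warnings.warn(
                f"duplicate CA for residue {resid}; keeping first altloc",
                stacklevel=2,
            )
            continue
        seen.add(resid)
        coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        resids.append(resid)

    if chain_label.strip() not in chains_seen:
        raise ChainError(f"chain not found: {chain_label!r}")
    if not coords:
        raise ChainError(f"empty chain: no CA atoms in chain {chain_label!r}")

    order = np.argsort(resids, kind="stable")
    pos = np.asarray(coords, float)[order] / SIGMA_ANGSTROM
    rid = np.asarray(resids, int)[order]
    return ChainConfiguration(pos, rid, chain_label)


def extract_reference_geometry(
    conf: ChainConfiguration, bridge_pairs=()
) -> ReferenceGeometry:
    """Internal coordinates and bridge distances of a reference structure.

    ``bridge_pairs`` are given as pairs of *residue ids* (PDB numbering);
    they are stored as array indices in the returned geometry.
    """
    if conf.n_beads < 4:
        raise ChainError("need at least 4 beads")
    theta0 = bending_angles(conf.positions)
    phi0 = torsion_angles(conf.positions)

    idx_pairs, dists = [], []
    for c1, c2 in bridge_pairs:
        try:
            i, j = conf.index_of(int(c1)), conf.index_of(int(c2))
        except ChainError as exc:
            raise ChainError(f"unknown bridge residue: {exc}") from None
        if i == j:
            raise ChainError("bridge pair must index distinct residues")
        idx_pairs.append((i, j))
        dists.append(np.linalg.norm(conf.positions[i] - conf.positions[j]))

    return ReferenceGeometry(
        theta0=theta0,
        phi0=phi0,
        bond_lengths=conf.bond_lengths(),
        bridge_pairs=np.asarray(idx_pairs, int).reshape(-1, 2),
        bridge_ref_dist=np.asarray(dists, float),
        residue_ids=conf.residue_ids.copy(),
    )


def build_chain_from_internal(
    bond_lengths, theta0, phi0, residue_ids=None
) -> ChainConfiguration:
    """Rebuild Cartesian coordinates from internal coordinates (NeRF-style).

    The first three beads are placed canonically in the xy-plane; subsequent
    beads follow from (bond length, bending angle, torsion angle).  Up to a
    rigid-body motion this inverts :func:`extract_reference_geometry`.
    """
    b = np.asarray(bond_lengths, float)
    th = np.asarray(theta0, float)
    ph = np.asarray(phi0, float)
    n = len(b) + 1
    if n < 4 or len(th) != n - 2 or len(ph) != n - 3:
        raise ChainError("inconsistent internal-coordinate lengths")

    pos = np.zeros((n, 3))
    pos[1] = [b[0], 0.0, 0.0]
    # third bead in the xy-plane, interior angle th[0] at bead 1
    pos[2] = pos[1] + b[1] * np.array(
        [-np.cos(th[0]), np.sin(th[0]), 0.0]
    )
    for i in range(3, n):
        a, bb, c = pos[i - 3], pos[i - 2], pos[i - 1]
        r, theta, phi = b[i - 1], th[i - 2], ph[i - 3]
        bc = c - bb
        bc /= np.linalg.norm(bc)
        ab = bb - a
        nvec = np.cross(ab, bc)
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            raise ChainError("degenerate internal geometry (collinear triple)")
        nvec /= nn
        m = np.cross(nvec, bc)
        d = np.array(
            [
                -r * np.cos(theta),
                r * np.sin(theta) * np.cos(phi),
                r * np.sin(theta) * np.sin(phi),
            ]
        )
        pos[i] = c + d[0] * bc + d[1] * m + d[2] * nvec
    return ChainConfiguration(pos, residue_ids)


# ---------------------------------------------------------------------------
# stretched initial states
# ---------------------------------------------------------------------------

def generate_stretched_configuration(
    N: int,
    seed: int,
    params: ModelParameters | None = None,
    transverse_sd: float = 0.05,
    n_relax: int = 100,
) -> ChainConfiguration:
    """Random stretched chain with end-to-end distance close to N sigma.

    Beads are laid along a uniformly random direction at unit spacing with
    small Gaussian transverse perturbations, then relaxed for ``n_relax``
    steepest-descent steps on the bonded terms (FENE plus bonded WCA) to
    remove residual strain.  Deterministic for a given (N, seed).
    """
    if N < 4:
        raise ChainError("need at least 4 beads")
    params = params or ModelParameters()
    rng = np.random.default_rng(seed)

    # uniformly random direction on the sphere
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    # orthonormal transverse frame
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    t = np.arange(N)[:, None] * u[None, :]
    noise = rng.normal(scale=transverse_sd, size=(N, 2))
    pos = t + noise[:, :1] * e1[None, :] + noise[:, 1:] * e2[None, :]

    # steepest descent on bonded terms: FENE + WCA between bonded neighbours
    # (step below the stability limit of the ~1e3 eps/sigma^2 bond stiffness)
    step = 4e-4
    for _ in range(n_relax):
        d = np.diff(pos, axis=0)
        r = np.linalg.norm(d, axis=1)
        r = np.minimum(r, 0.99 * params.R0)
        # FENE tension (pull towards r=0) plus WCA repulsion
        f_fene = -params.k_fene * r / (1.0 - (r / params.R0) ** 2)
        inv = params.sigma / r
        f_wca = np.where(
            r < 2 ** (1 / 6) * params.sigma,
            24.0 * params.epsilon * (2.0 * inv**12 - inv**6) / r,
            0.0,
        )
        fmag = f_fene + f_wca
        fvec = (fmag / r)[:, None] * d
        forces = np.zeros_like(pos)
        forces[1:] += fvec
        forces[:-1] -= fvec
        pos += step * forces

    conf = ChainConfiguration(pos - pos.mean(axis=0))
    return conf


# ---------------------------------------------------------------------------
# trajectory file I/O
# ---------------------------------------------------------------------------

def write_xyz(path_or_file, frames, comment: str = "") -> None:
    """Write one or more configurations as multi-frame XYZ (sigma units)."""
    if hasattr(frames, "positions"):
        frames = [frames]
    own = not hasattr(path_or_file, "write")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        for fr in frames:
            p = fr.positions if hasattr(fr, "positions") else np.asarray(fr)
            fh.write(f"{len(p)}\n{comment}\n")
            for x, y, z in p:
                fh.write(f"CA {x:.8f} {y:.8f} {z:.8f}\n")
    finally:
        if own:
            fh.close()


def write_calpha_pdb(path_or_file, conf: "ChainConfiguration") -> None:
    """Write a configuration as CA-only PDB ATOM records (Angstrom)."""
    own = not hasattr(path_or_file, "write")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        for k, (rid, (x, y, z)) in enumerate(
            zip(conf.residue_ids, conf.positions * SIGMA_ANGSTROM), start=1
        ):
            fh.write(
                f"ATOM  {k:5d}  CA  GLY {conf.chain_label[:1]}{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def read_xyz(path_or_file) -> list:
    """Read a multi-frame XYZ file back into position arrays."""
    own = not hasattr(path_or_file, "read")
    fh = open(path_or_file) if own else path_or_file
    try:
        frames = []
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            p = np.array(
                [[float(v) for v in fh.readline().split()[1:4]] for _ in range(n)]
            )
            frames.append(p)
        return frames
    finally:
        if own:
            fh.close()
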