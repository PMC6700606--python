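"""Elastic folder model energetics.

The elastic folder model (EFM) drives folding exclusively through
structure-based bending and torsion potentials whose minima sit at the
reference (native) internal angles:

    U_tot = U_steric + U_bonds + U_angular + U_bridges

* sterics: Weeks-Chandler-Andersen (purely repulsive LJ) of diameter sigma;
* bonds: FENE springs, which together with the WCA term give the standard
  bead-spring bond of ~0.96 sigma;
* angular: U_bend = k (theta - theta0)^2 per bending angle and
  U_tor = k1 [1 - cos(phi - phi0)] + (k1/3) [1 - cos 3(phi - phi0)] per
  torsion angle, zero and minimal at the native angles;
* bridges: truncated force-shifted LJ wells between cysteine pairs that form
  disulfide bridges in the native state, switched on in oxidizing conditions.

Per-angle stiffnesses form the force-field vector K that the evolutionary
optimizer tunes; neighbouring coefficients can be constrained pairwise to
reduce the search dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chain import ChainConfiguration, ModelParameters, ReferenceGeometry

TWO_1_6 = 2.0 ** (1.0 / 6.0)

__all__ = [
    "wca_energy",
    "fene_energy",
    "bending_energy",
    "torsion_energy",
    "bridge_pair_energy",
    "ForceField",
    "BridgeParameters",
    "EFMModel",
    "BondOverstretchedError",
    "IntegrationDivergedError",
]


class BondOverstretchedError(RuntimeError):
    """A FENE bond reached its maximal extension (integrator blow-up)."""


class IntegrationDivergedError(RuntimeError):
    """Coordinates became non-finite during integration."""


# ---------------------------------------------------------------------------
# scalar pair/angle potentials (reference forms; kernels mirror these)
# ---------------------------------------------------------------------------

def lj_energy(r, epsilon=1.0, sigma=1.0):
    """Plain Lennard-Jones 4 eps [(s/r)^12 - (s/r)^6]."""
    s6 = (sigma / np.asarray(r, float)) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6)


def wca_energy(r, epsilon=1.0, sigma=1.0):
    """Purely repulsive WCA potential: LJ + eps below 2^(1/6) sigma, else 0."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    out = np.where(r < TWO_1_6 * sigma, lj_energy(r, epsilon, sigma) + epsilon, 0.0)
    return out if out.ndim else float(out)


def fene_energy(r, k_fene=30.0, R0=1.5):
    """FENE bond energy -(k/2) R0^2 ln[1 - (r/R0)^2]; diverges at r = R0."""
    r = np.asarray(r, float)
    if np.any(r >= R0):
        raise BondOverstretchedError("bond overstretched: r >= R0")
    out = -0.5 * k_fene * R0 * R0 * np.log(1.0 - (r / R0) ** 2)
    return out if out.ndim else float(out)


def bending_energy(theta, theta0, k):
    """Harmonic bending k (theta - theta0)^2 (no 1/2 factor)."""
    d = np.asarray(theta, float) - theta0
    out = k * d * d
    return out if out.ndim else float(out)


def torsion_energy(phi, phi0, k1):
    """Torsion potential, minimal and zero at phi = phi0.

    U = k1 [1 - cos(phi - phi0)] + (k1/3) [1 - cos 3(phi - phi0)], with the
    second-harmonic amplitude locked to k3 = k1/3.
    """
    d = np.asarray(phi, float) - phi0
    out = k1 * (1.0 - np.cos(d)) + (k1 / 3.0) * (1.0 - np.cos(3.0 * d))
    return out if out.ndim else float(out)


def bridge_pair_energy(r, epsilon_b, sigma_b, r_cut):
    """Truncated, force-shifted LJ well for a cysteine bridge pair.

    U(r) = LJ(r) - LJ(rc) - (r - rc) LJ'(rc) for r < rc, else 0; both the
    energy and its derivative vanish at the cutoff.
    """
    r = np.asarray(r, float)

    def _du(x):
        s6 = (sigma_b / x) ** 6
        return -24.0 * epsilon_b * (2.0 * s6 * s6 - s6) / x

    u = (
        lj_energy(r, epsilon_b, sigma_b)
        - lj_energy(r_cut, epsilon_b, sigma_b)
        - (r - r_cut) * _du(r_cut)
    )
    out = np.where(r < r_cut, u, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# force-field container with pairing constraints
# ---------------------------------------------------------------------------

def paired_groups(n_beads: int) -> list:
    """Neighbour-pairing of the stiffness vector K = (k_bend, k_tor).

    Bending coefficients 0..N-3 and torsion coefficients N-2..2N-6 are paired
    (0,1), (2,3), ... within each block; an odd leftover forms a singleton.
    Returned as lists of indices into the concatenated coefficient vector.
    """
    nb, nt = n_beads - 2, n_beads - 3
    groups = []
    for off, m in ((0, nb), (nb, nt)):
        i = 0
        while i < m:
            groups.append(list(range(off + i, off + min(i + 2, m))))
            i += 2
    return groups


@dataclass
class ForceField:
    """Per-angle stiffness coefficients of the EFM.

    ``k_bend`` has N-2 entries, ``k1_tor`` N-3; the third-harmonic torsion
    amplitude is always k1/3 and is not stored.  ``pairing`` groups indices
    of the concatenated vector that are constrained to be equal.
    """

    k_bend: np.ndarray
    k1_tor: np.ndarray
    pairing: list = None

    def __post_init__(self):
        self.k_bend = np.asarray(self.k_bend, dtype=float)
        self.k1_tor = np.asarray(self.k1_tor, dtype=float)
        if np.any(self.k_bend <= 0) or np.any(self.k1_tor <= 0):
            raise ValueError("stiffness coefficients must be positive")
        if self.pairing is None:
            self.pairing = paired_groups(self.n_beads)

    @property
    def n_beads(self) -> int:
        return len(self.k_bend) + 2

    @property
    def coefficients(self) -> np.ndarray:
        """Concatenated vector K = (k_bend, k1_tor) of length 2N-5."""
        return np.concatenate([self.k_bend, self.k1_tor])

    @classmethod
    def from_coefficients(cls, coeffs, n_beads, pairing=None) -> "ForceField":
        coeffs = np.asarray(coeffs, float)
        nb = n_beads - 2
        return cls(coeffs[:nb].copy(), coeffs[nb:].copy(), pairing)

    @classmethod
    def homogeneous(cls, n_beads: int, k_bend: float = 36.5, k_tor: float = 38.5):
        """Homogeneous-stiffness force field (the HM uses 36.5 / 38.5)."""
        return cls(
            np.full(n_beads - 2, float(k_bend)), np.full(n_beads - 3, float(k_tor))
        )

    def satisfies_pairing(self, atol: float = 0.0) -> bool:
        k = self.coefficients
        return all(
            np.allclose(k[g], k[g[0]], atol=atol, rtol=0.0) for g in self.pairing
        )

    def copy(self) -> "ForceField":
        return ForceField(self.k_bend.copy(), self.k1_tor.copy(), self.pairing)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "k_bend": self.k_bend.tolist(),
                "k1_tor": self.k1_tor.tolist(),
                "pairing": self.pairing,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ForceField":
        import json

        d = json.loads(text)
        return cls(d["k_bend"], d["k1_tor"], d.get("pairing"))


@dataclass
class BridgeParameters:
    """Cysteine-bridge well parameters.

    The LJ length sigma_b of each pair is fixed so the well minimum sits at
    the native pair distance; ``enabled`` models oxidizing (True) versus
    reducing (False) conditions.
    """

    pairs: np.ndarray
    epsilon_b: np.ndarray
    sigma_b: np.ndarray
    r_cut: np.ndarray
    enabled: bool = True

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, int).reshape(-1, 2)
        n = len(self.pairs)
        self.epsilon_b = np.broadcast_to(
            np.asarray(self.epsilon_b, float), (n,)
        ).copy()
        self.sigma_b = np.broadcast_to(np.asarray(self.sigma_b, float), (n,)).copy()
        self.r_cut = np.broadcast_to(np.asarray(self.r_cut, float), (n,)).copy()
        if np.any(self.r_cut <= TWO_1_6 * self.sigma_b):
            raise ValueError("r_cut must exceed the well minimum")

    @classmethod
    def from_reference(
        cls,
        ref: ReferenceGeometry,
        kBT: float,
        epsilon_b: float | None = None,
        rc_factor: float = 2.5,
        enabled: bool = True,
    ) -> "BridgeParameters":
        """Bridge wells at the native pair distances.

        The well depth defaults to 10 kBT (deep enough that thermal
        fluctuations rarely break a formed bridge); the cutoff is
        ``rc_factor * sigma_b``.
        """
        sigma_b = ref.bridge_ref_dist / TWO_1_6
        eps = 10.0 * kBT if epsilon_b is None else epsilon_b
        return cls(
            pairs=ref.bridge_pairs,
            epsilon_b=np.full(len(sigma_b), eps),
            sigma_b=sigma_b,
            r_cut=rc_factor * sigma_b,
            enabled=enabled,
        )

    @property
    def n_bridges(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class EFMModel:
    """EFM energy/force provider for a given reference and force field.

    Parameters
    ----------
    ref : ReferenceGeometry
    ff : ForceField
    params : ModelParameters
    bridges : BridgeParameters or None
        None means no bridge interactions at all (equivalent to reducing
        conditions); a disabled BridgeParameters behaves identically.
    exclude_bonded_wca : bool
        If True, bonded neighbours are excluded from the WCA sum.  Default
        False: the steric diameter equals the bond length and the WCA-FENE
        balance sets the ~0.96 sigma equilibrium bond.
    """

    def __init__(
        self,
        ref: ReferenceGeometry,
        ff: ForceField,
        params: ModelParameters | None = None,
        bridges: BridgeParameters | None = None,
        exclude_bonded_wca: bool = False,
    ):
        self.ref = ref
        self.ff = ff
        self.params = params or ModelParameters()
        self.bridges = bridges
        self.exclude_bonded_wca = exclude_bonded_wca
        if ff.n_beads != ref.n_beads:
            raise ValueError("force field / reference size mismatch")
        self._rebuild_args()

    @property
    def n_beads(self) -> int:
        return self.ref.n_beads

    def _rebuild_args(self):
        p = self.params
        br = self.bridges
        if br is not None and br.enabled and br.n_bridges > 0:
            bp_i = br.pairs[:, 0].astype(np.int64)
            bp_j = br.pairs[:, 1].astype(np.int64)
            b_eps, b_sig, b_rc = br.epsilon_b, br.sigma_b, br.r_cut
            on = 1
        else:
            bp_i = np.zeros(0, np.int64)
            bp_j = np.zeros(0, np.int64)
            b_eps = b_sig = b_rc = np.zeros(0)
            on = 0
        self._args = (
            self.ref.theta0,
            self.ref.phi0,
            self.ff.k_bend,
            self.ff.k1_tor,
            self.ff.k1_tor / 3.0,
            p.k_fene,
            p.R0,
            p.epsilon,
            p.sigma,
            2 if self.exclude_bonded_wca else 1,
            bp_i,
            bp_j,
            b_eps,
            b_sig,
            b_rc,
            on,
            p.angular_force_cap,
        )

    # force provider protocol used by the Langevin engine
    force_func = staticmethod(_kernels.efm_energy_forces)

    @property
    def force_args(self):
        return self._args

    def with_forcefield(self, ff: ForceField) -> "EFMModel":
        return EFMModel(
            self.ref, ff, self.params, self.bridges, self.exclude_bonded_wca
        )

    def energy_forces(self, conf) -> tuple:
        """Total energy and per-bead forces (exact negative gradient)."""
        pos = conf.positions if isinstance(conf, ChainConfiguration) else conf
        pos = np.ascontiguousarray(pos, float)
        e, f, status = _kernels.efm_energy_forces(pos, self._args)
        if status == 2:
            raise BondOverstretchedError("bond overstretched")
        return e, f

    def energy(self, conf) -> float:
        return self.energy_forces(conf)[0]

    def minimize(self, conf, tol: float = 1e-15):
        """Quench a configuration to the nearest local energy minimum."""
        from scipy.optimize import minimize as _min

        pos0 = (
            conf.positions if isinstance(conf, ChainConfiguration) else conf
        ).copy()
        shape = pos0.shape

        def fun(x):
            # overstretched trial points (line-search overshoot) get a large
            # finite penalty so the search backs off instead of aborting
            try:
                e, f = self.energy_forces(x.reshape(shape))
            except BondOverstretchedError:
                return 1e12, np.zeros_like(x)
            return e, -f.ravel()

        res = _min(fun, pos0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": tol, "gtol": 1e-12})
        return ChainConfiguration(res.x.reshape(shape))
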