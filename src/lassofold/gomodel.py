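"""Calpha Go model with 12-10 native-contact potentials.

Structure-based model of Clementi type: residue pairs in contact in the
native state attract through U(r) = E_ij [5 (r0/r)^12 - 6 (r0/r)^10],
minimal at the native pair distance r0; all other non-local pairs feel a
12-power excluded volume.  Backbone stiffness uses the same bending/torsion
forms as the elastic folder model with homogeneous coefficients
(k_bend = 40.0, k1 = 1.0, k3 = 0.5).  Oxidizing conditions are modeled by
rescaling the contact amplitude of natively bridged cysteine pairs to
10 kBT, so that a formed bridge is rarely broken by thermal fluctuations.

Contacts are read from a whitespace-separated two-column (i j, 1-based
residue ids) contact file, or derived from a Calpha distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chain import (
    SIGMA_ANGSTROM,
    ChainConfiguration,
    ModelParameters,
    bending_angles,
    torsion_angles,
)
from .efm import BondOverstretchedError

__all__ = ["GoForceField", "GoModel", "build_go_forcefield", "contact_energy_12_10"]

#: default contact amplitude in energy units
DEFAULT_CONTACT_E = 1.0
#: default Calpha-Calpha contact cutoff in Angstrom
DEFAULT_CUTOFF_ANGSTROM = 7.5
#: excluded-volume diameter for non-contact pairs, in Angstrom
DEFAULT_EV_ANGSTROM = 4.0


def contact_energy_12_10(r, r0, E):
    """12-10 contact potential E [5 (r0/r)^12 - 6 (r0/r)^10], minimal at r0."""
    q = r0 / np.asarray(r, float)
    out = E * (5.0 * q**12 - 6.0 * q**10)
    return out if out.ndim else float(out)


@dataclass
class GoForceField:
    """Native-contact list plus homogeneous angular stiffnesses."""

    contacts: np.ndarray          # (n_c, 2) int array of bead indices, i < j
    contact_r0: np.ndarray        # (n_c,) native distances, sigma units
    contact_E: np.ndarray         # (n_c,) amplitudes, energy units
    k_bend_homog: float = 40.0
    k1_tor_homog: float = 1.0
    k3_tor_homog: float = 0.5
    sigma_ev: float = DEFAULT_EV_ANGSTROM / SIGMA_ANGSTROM
    eps_ev: float = 1.0

    def __post_init__(self):
        self.contacts = np.asarray(self.contacts, int).reshape(-1, 2)
        self.contact_r0 = np.asarray(self.contact_r0, float)
        self.contact_E = np.asarray(self.contact_E, float)
        ij = np.abs(self.contacts[:, 0] - self.contacts[:, 1])
        if len(ij) and ij.min() < 3:
            raise ValueError("contacts must satisfy |i-j| >= 3")
        if np.any(self.contact_E <= 0):
            raise ValueError("contact amplitudes must be positive")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def contact_list(self) -> list:
        """Contacts as (i, j, r0, E) tuples (bead indices)."""
        return [
            (int(i), int(j), float(r), float(E))
            for (i, j), r, E in zip(self.contacts, self.contact_r0, self.contact_E)
        ]


def _contacts_from_cutoff(conf: ChainConfiguration, cutoff_angstrom: float):
    """All |i-j| >= 3 pairs closer than the cutoff in the native structure."""
    pos = conf.positions
    n = len(pos)
    cut = cutoff_angstrom / SIGMA_ANGSTROM
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    ii, jj = np.triu_indices(n, k=3)
    keep = d[ii, jj] < cut
    return np.column_stack([ii[keep], jj[keep]]), d[ii[keep], jj[keep]]


def _contacts_from_file(conf: ChainConfiguration, path) -> tuple:
    """Parse a two-column (i j, 1-based residue id) contact file."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.split("#")[0].strip()
            if not s:
                continue
            fields = s.split()
            try:
                ri, rj = int(fields[0]), int(fields[1])
            except (ValueError, IndexError):
                raise ValueError(
                    f"malformed contact file {path}: line {ln}: {line.rstrip()!r}"
                ) from None
            pairs.append((conf.index_of(ri), conf.index_of(rj)))
    pairs = np.asarray(pairs, int).reshape(-1, 2)
    pairs.sort(axis=1)
    r0 = np.linalg.norm(
        conf.positions[pairs[:, 0]] - conf.positions[pairs[:, 1]], axis=1
    )
    return pairs, r0


def build_go_forcefield(
    conf: ChainConfiguration,
    contact_source=None,
    oxidizing: bool = False,
    kBT: float = 0.7,
    cysteine_pairs=(),
    contact_E: float = DEFAULT_CONTACT_E,
    cutoff_angstrom: float = DEFAULT_CUTOFF_ANGSTROM,
) -> GoForceField:
    """Construct a Go force field from a native structure.

    Parameters
    ----------
    conf : native ChainConfiguration
    contact_source : path or None
        A two-column contact file (1-based residue ids); None derives
        contacts from a ``cutoff_angstrom`` Calpha cutoff with |i-j| >= 3.
    oxidizing : bool
        If True, the contact amplitude of each natively bridged cysteine
        pair is set to 10 kBT (the pair is added if absent from the map).
    cysteine_pairs : iterable of (residue_id, residue_id)
        The bridge-forming cysteines, in PDB numbering.
    """
    if contact_source is None:
        pairs, r0 = _contacts_from_cutoff(conf, cutoff_angstrom)
    else:
        pairs, r0 = _contacts_from_file(conf, contact_source)
    E = np.full(len(pairs), float(contact_E))

    if oxidizing:
        for c1, c2 in cysteine_pairs:
            i, j = sorted((conf.index_of(c1), conf.index_of(c2)))
            hit = np.flatnonzero((pairs[:, 0] == i) & (pairs[:, 1] == j))
            if len(hit):
                E[hit] = 10.0 * kBT
            else:
                pairs = np.vstack([pairs, [i, j]])
                r0 = np.append(
                    r0, np.linalg.norm(conf.positions[i] - conf.positions[j])
                )
                E = np.append(E, 10.0 * kBT)

    return GoForceField(pairs, r0, E)


class GoModel:
    """Go-model energy/force provider bound to a native structure."""

    def __init__(
        self,
        native: ChainConfiguration,
        goff: GoForceField,
        params: ModelParameters | None = None,
    ):
        self.native = native
        self.goff = goff
        self.params = params or ModelParameters(temperature=0.7)
        self.theta0 = bending_angles(native.positions)
        self.phi0 = torsion_angles(native.positions)
        self._rebuild_args()

    @property
    def n_beads(self) -> int:
        return self.native.n_beads

    def _rebuild_args(self):
        n = self.n_beads
        g = self.goff
        p = self.params
        is_contact = np.zeros(n * n, dtype=np.bool_)
        for i, j in g.contacts:
            is_contact[i * n + j] = True
            is_contact[j * n + i] = True
        self._args = (
            self.theta0,
            self.phi0,
            np.full(n - 2, g.k_bend_homog),
            np.full(n - 3, g.k1_tor_homog),
            np.full(n - 3, g.k3_tor_homog),
            p.k_fene,
            p.R0,
            p.epsilon,
            p.sigma,
            g.contacts[:, 0].astype(np.int64),
            g.contacts[:, 1].astype(np.int64),
            g.contact_r0,
            g.contact_E,
            g.eps_ev,
            g.sigma_ev,
            is_contact,
            p.angular_force_cap,
        )

    force_func = staticmethod(_kernels.go_energy_forces)

    @property
    def force_args(self):
        return self._args

    def energy_forces(self, conf) -> tuple:
        pos = conf.positions if isinstance(conf, ChainConfiguration) else conf
        pos = np.ascontiguousarray(pos, float)
        e, f, status = _kernels.go_energy_forces(pos, self._args)
        if status == 2:
            raise BondOverstretchedError("bond overstretched")
        return e, f

    def energy(self, conf) -> float:
        return self.energy_forces(conf)[0]
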