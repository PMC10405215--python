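"""Two-chain bead-spring system builder and geometric observables.

Two oppositely charged homopolymers (default 60 beads each) in a periodic
cubic box (default edge 100 sigma).  A fraction f of the beads carry unit
charges, placed maximally evenly along the backbone; the two chains carry
opposite signs so the pair is net neutral.  Initial conformations are
self-avoiding random walks at large center-of-mass separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["ChainSystem", "charge_indices", "build_pair", "radius_of_gyration", "fixture_dimer"]


@dataclass
class ChainSystem:
    """Topology + coordinates of (up to) two bead-spring chains.

    ``positions`` is (n_total, 3) in sigma units inside a cubic box;
    ``charges`` holds signed unit charges; ``bonds`` is an (n_bonds, 2) int
    array of consecutive-bead pairs.
    """

    positions: np.ndarray
    charges: np.ndarray
    bonds: np.ndarray
    n_chain1: int
    box: float = 100.0
    f: float = 0.0
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)

    @property
    def n_total(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chain2(self) -> int:
        return self.n_total - self.n_chain1

    @property
    def chain1(self) -> slice:
        return slice(0, self.n_chain1)

    @property
    def chain2(self) -> slice:
        return slice(self.n_chain1, self.n_total)

    def to_xyz(self, path, comment: str = "") -> None:
        """Write the current coordinates as an XYZ frame ('C' for charged
        beads, 'N' for neutral) for quick visualization."""
        with open(path, "a") as fh:
            fh.write(f"{self.n_total}\n{comment}\n")
            for q, (x, y, z) in zip(self.charges, self.positions):
                name = "C" if q != 0 else "N"
                fh.write(f"{name} {x:.5f} {y:.5f} {z:.5f}\n")

    def com_separation(self) -> float:
        """Minimum-image distance between the two chain centers of mass."""
        d = self.positions[self.chain1].mean(axis=0) - self.positions[self.chain2].mean(axis=0)
        d -= self.box * np.round(d / self.box)
        return float(np.linalg.norm(d))


def charge_indices(f: float, n: int) -> np.ndarray:
    """Maximally even charge placement: bead indices floor((k + 1/2)/f) for
    k = 0..round(f*n)-1.  f = 0.5 gives every 2nd bead, f = 0.1 every 10th."""
    if not (0.0 < f <= 1.0):
        raise ConfigurationError(f"charge fraction f must be in (0, 1], got {f}")
    n_charges = int(round(f * n))
    if n_charges < 1:
        raise ConfigurationError(f"f={f} with N={n} places no charges")
    idx = np.floor((np.arange(n_charges) + 0.5) / f).astype(np.int64)
    if idx[-1] >= n:
        idx[-1] = n - 1
    return idx


def _saw_chain(n: int, bond_length: float, min_dist: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk: fixed step length, rejecting any nonbonded
    pair closer than ``min_dist``."""
    pos = np.zeros((n, 3))
    i = 1
    attempts = 0
    while i < n:
        step = rng.normal(size=3)
        step *= bond_length / np.linalg.norm(step)
        cand = pos[i - 1] + step
        if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) >= min_dist:
            pos[i] = cand
            i += 1
            attempts = 0
        else:
            attempts += 1
            if attempts > 1000:  # back up and retry
                i = max(1, i - 5)
                attempts = 0
    return pos


def build_pair(
    f: float,
    seed: int = 0,
    box: float = 100.0,
    n_beads_per_chain: int = 60,
    separation: float = 30.0,
    bond_length: float = 0.7,
    min_dist: float = 1.0,
) -> ChainSystem:
    """Construct the standard two-chain system: chain 1 carries +1 charges,
    chain 2 the mirror -1 pattern, centers of mass ``separation`` apart."""
    n = n_beads_per_chain
    idx = charge_indices(f, n)
    rng = np.random.default_rng(seed)

    center = box / 2.0
    c1 = _saw_chain(n, bond_length, min_dist, rng)
    c1 = c1 - c1.mean(axis=0) + np.array([center - separation / 2.0, center, center])
    # rebuild chain 2 until it does not overlap chain 1 at the requested
    # separation (random walks can extend several sigma from their COM)
    for _ in range(200):
        c2 = _saw_chain(n, bond_length, min_dist, rng)
        c2 = c2 - c2.mean(axis=0) + np.array([center + separation / 2.0, center, center])
        cross = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
        if cross.min() >= min_dist:
            break
    else:
        raise ConfigurationError(
            f"could not place two non-overlapping chains at separation {separation}"
        )

    positions = np.vstack([c1, c2])
    charges = np.zeros(2 * n)
    charges[idx] = 1.0
    charges[idx + n] = -1.0
    bonds = np.vstack(
        [
            np.column_stack([np.arange(n - 1), np.arange(1, n)]),
            np.column_stack([n + np.arange(n - 1), n + np.arange(1, n)]),
        ]
    )
    return ChainSystem(positions=positions, charges=charges, bonds=bonds, n_chain1=n, box=box, f=f)


def radius_of_gyration(system_or_traj, n_chain1: int | None = None) -> float:
    """Standard Rg per chain, averaged over chains (and over frames when a
    trajectory array of shape (n_frames, n_beads, 3) is given)."""
    if isinstance(system_or_traj, ChainSystem):
        frames = system_or_traj.positions[None, :, :]
        n1 = system_or_traj.n_chain1
    else:
        frames = np.asarray(system_or_traj, dtype=float)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        n1 = n_chain1 if n_chain1 is not None else frames.shape[1]
    chains = [frames[:, :n1, :]]
    if n1 < frames.shape[1]:
        chains.append(frames[:, n1:, :])
    rgs = []
    for c in chains:
        com = c.mean(axis=1, keepdims=True)
        rgs.append(np.sqrt(((c - com) ** 2).sum(axis=2).mean(axis=1)))
    return float(np.mean(rgs))


def fixture_dimer(
    r: float,
    qi: float = 0.0,
    qj: float = 0.0,
    box: float = 100.0,
    bonded: bool = False,
) -> ChainSystem:
    """Minimal two-particle system (one bead per 'chain') for unit tests of
    potentials, sampling and the PMF machinery."""
    if r <= 0:
        raise ConfigurationError("dimer separation must be positive")
    center = box / 2.0
    positions = np.array(
        [[center - r / 2.0, center, center], [center + r / 2.0, center, center]]
    )
    bonds = np.array([[0, 1]]) if bonded else np.zeros((0, 2), dtype=np.int64)
    return ChainSystem(
        positions=positions,
        charges=np.array([qi, qj], dtype=float),
        bonds=bonds,
        n_chain1=1,
        box=box,
        f=0.0,
    )
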