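"""Synthetic multi-state ground truths, sampled ensembles and eNOE-like restraints.

The generator emulates the situation the correlation analysis is designed
for: a protein in conformational exchange between discrete states.  A
ground-truth model is a compact self-avoiding Calpha chain (state A) plus a
smooth displacement field moving a contiguous segment into state B, with
state populations, isotropic thermal noise for sampled bundles, and
distance restraints obtained by population-weighted r^-6 averaging over
the true states within an NOE-like contact range (the Calpha-Calpha
equivalent of the 5 A proton-proton NOE reach).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble, StateModel
from .restraints import AtomRef, DistanceRestraint, RestraintSet

__all__ = [
    "SyntheticModel",
    "make_two_state_model",
    "sample_ensemble",
    "restraints_from_model",
]

BOND_LENGTH = 3.8  # A, consecutive-Calpha spacing
MIN_SEPARATION = 4.0  # A, self-avoidance floor for non-neighbours
NOE_RANGE = 5.0  # A, range of a single proton-proton NOE
# Calpha-Calpha contact range equivalent to a proton-level NOE: side chains
# extend several Angstrom from the backbone, so a 5 A H-H contact reaches
# Calpha pairs up to ~9 A apart; this also reproduces paper-like restraint
# densities (~10 per residue) on a Calpha chain
CONTACT_CUTOFF = 9.0


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticModel:
    """Ground-truth multi-state chain.

    ``state_displacements`` holds one (L, 3) displacement field per state
    (zero outside ``mobile_segment``); populations sum to 1.
    """

    base_coords: np.ndarray
    state_displacements: np.ndarray
    populations: np.ndarray
    noise_sigma: float
    mobile_segment: np.ndarray
    residue_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.base_coords = np.asarray(self.base_coords, dtype=float)
        self.state_displacements = np.asarray(self.state_displacements, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-12:
            raise SyntheticError("state populations must sum to 1")
        L = self.base_coords.shape[0]
        fixed = np.setdiff1d(np.arange(L), self.mobile_segment)
        if self.state_displacements[:, fixed, :].any():
            raise SyntheticError("displacements must vanish outside the mobile segment")
        if not self.residue_names:
            self.residue_names = ["ALA"] * L

    @property
    def length(self) -> int:
        return self.base_coords.shape[0]

    @property
    def n_states(self) -> int:
        return self.state_displacements.shape[0]

    @property
    def sequence(self) -> list[str]:
        return list(self.residue_names)

    def state_coords(self) -> np.ndarray:
        """(n_states, L, 3) ground-truth coordinates of every state."""
        return self.base_coords[None, :, :] + self.state_displacements


def _compact_chain(
    length: int,
    rng: np.random.Generator,
    bond: float = BOND_LENGTH,
    min_sep: float = MIN_SEPARATION,
    radius: float | None = None,
    max_restarts: int = 500,
    max_tries: int = 100,
) -> np.ndarray:
    """Grow a compact self-avoiding chain inside a sphere by rejection."""
    if radius is None:
        radius = max(2.0 * bond, 3.3 * length ** (1.0 / 3.0))
    for _ in range(max_restarts):
        pts = [np.zeros(3)]
        failed = False
        for _ in range(length - 1):
            for _ in range(max_tries):
                v = rng.normal(size=3)
                v *= bond / np.linalg.norm(v)
                cand = pts[-1] + v
                if np.linalg.norm(cand) > radius:
                    continue
                if len(pts) > 1:
                    d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                pts.append(cand)
                break
            else:
                failed = True
                break
        if not failed:
            chain = np.array(pts)
            return chain - chain.mean(axis=0)
    raise SyntheticError(f"failed to grow a self-avoiding chain of length {length}")


def make_two_state_model(
    length: int = 30,
    displacement: float = 4.5,
    mobile_fraction: float = 0.5,
    noise_sigma: float = 0.3,
    populations: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> SyntheticModel:
    """Two-state ground truth: a compact chain whose central segment swings
    between two positions.

    State B displaces a contiguous segment of ``round(mobile_fraction * L)``
    residues along a random direction with a smooth sine envelope peaking at
    ``displacement`` (A).  The displaced state is re-drawn until it is free
    of steric clashes.  Deterministic per seed.
    """
    if length < 8:
        raise SyntheticError("length must be >= 8")
    if displacement < 0:
        raise SyntheticError("displacement must be >= 0")
    if not 0 < mobile_fraction <= 1:
        raise SyntheticError("mobile_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    base = _compact_chain(length, rng)
    m = max(2, int(round(mobile_fraction * length)))
    m = min(m, length)
    start = (length - m) // 2
    segment = np.arange(start, start + m)
    envelope = np.sin(np.pi * (np.arange(m) + 1) / (m + 1))
    disp_b = np.zeros((length, 3))
    if displacement > 0:
        fixed = np.setdiff1d(np.arange(length), segment)
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            field_ = displacement * envelope[:, None] * u[None, :]
            cand = base.copy()
            cand[segment] += field_
            # displaced state must stay self-avoiding (slightly relaxed floor)
            diff = cand[:, None, :] - cand[None, :, :]
            d = np.sqrt((diff ** 2).sum(-1))
            iu = np.triu_indices(length, k=2)
            if d[iu].min() >= min(MIN_SEPARATION - 0.8, 3.2):
                disp_b[segment] = field_
                break
        else:
            raise SyntheticError("could not place a clash-free displaced state")
    displacements = np.stack([np.zeros((length, 3)), disp_b])
    return SyntheticModel(
        base_coords=base,
        state_displacements=displacements,
        populations=np.asarray(populations, dtype=float),
        noise_sigma=float(noise_sigma),
        mobile_segment=segment,
    )


def _ca_state_model(coords: np.ndarray, residue_names: list[str], state_index: int) -> StateModel:
    L = coords.shape[0]
    return StateModel(
        ["A"] * L,
        np.arange(1, L + 1),
        residue_names,
        ["CA"] * L,
        coords,
        state_index=state_index,
    )


def sample_ensemble(model: SyntheticModel, n_conformers: int = 20, seed: int = 0) -> Ensemble:
    """Sample a bundle: each conformer holds one noisy copy of every state.

    Isotropic Gaussian noise of ``model.noise_sigma`` is added independently
    to every bead, emulating random thermal motion.
    """
    rng = np.random.default_rng(seed)
    states = model.state_coords()
    conformers = []
    for _ in range(n_conformers):
        conf = []
        for s in range(model.n_states):
            noisy = states[s] + rng.normal(0.0, model.noise_sigma, size=states[s].shape)
            conf.append(_ca_state_model(noisy, model.sequence, s + 1))
        conformers.append(conf)
    return Ensemble(conformers)


def ground_truth_average_distances(model: SyntheticModel) -> np.ndarray:
    """Population-weighted r^-6 averaged Calpha distance matrix of the truth.

    Generalizes the equal-population ensemble average to weights p_i;
    reduces exactly to the plain average at equal populations.
    """
    states = model.state_coords()
    diff = states[:, :, None, :] - states[:, None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))  # (S, L, L)
    L = d.shape[1]
    d[:, np.arange(L), np.arange(L)] = 1.0  # avoid 0^-6 on the diagonal
    inv6 = (d ** -6.0 * model.populations[:, None, None]).sum(axis=0)
    avg = inv6 ** (-1.0 / 6.0)
    np.fill_diagonal(avg, 0.0)
    return avg


def restraints_from_model(
    model: SyntheticModel,
    contact_cutoff: float = CONTACT_CUTOFF,
    fraction: float = 1.0,
    corrupt: list[tuple[int, float]] | None = None,
    seed: int = 0,
    slack: float = 0.02,
    upper_only: bool = False,
) -> RestraintSet:
    """eNOE-like distance restraints from the ground truth.

    Every residue pair (contact) whose population-weighted r^-6 averaged
    Calpha distance is within ``contact_cutoff`` yields an *exact* eNOE:
    an upper limit at the averaged distance plus ``slack`` and a matching
    lower limit at the distance minus ``slack`` (the accuracy of exact
    NOEs; ``upper_only`` drops the lower limits).  ``fraction`` uniformly
    subsamples the contacts; ``corrupt`` entries ``(index, scale)`` rescale
    the distance of the contact at ``index`` in the subsampled contact
    list, moving both of its bounds (emulating a misassigned or inaccurate
    eNOE).
    """
    if not 0 < fraction <= 1:
        raise SyntheticError("fraction must be in (0, 1]")
    avg = ground_truth_average_distances(model)
    L = model.length
    contacts = [(i, j, float(avg[i, j])) for i in range(L) for j in range(i + 1, L) if avg[i, j] <= contact_cutoff]
    if fraction < 1:
        rng = np.random.default_rng(seed)
        keep = max(1, int(round(fraction * len(contacts))))
        idx = np.sort(rng.choice(len(contacts), size=keep, replace=False))
        contacts = [contacts[i] for i in idx]
    if corrupt:
        for index, scale in corrupt:
            if not 0 <= index < len(contacts):
                raise SyntheticError(f"corruption index {index} out of range 0..{len(contacts) - 1}")
            i, j, d = contacts[index]
            contacts[index] = (i, j, d * scale)
    restraints = []
    for i, j, d in contacts:
        a = AtomRef(i + 1, model.residue_names[i], "CA")
        b = AtomRef(j + 1, model.residue_names[j], "CA")
        restraints.append(DistanceRestraint(a, b, d + slack, "upper"))
        if not upper_only and d - slack > 0:
            restraints.append(DistanceRestraint(a, b, d - slack, "lower"))
    return RestraintSet(restraints)
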