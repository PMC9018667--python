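"""Toy multi-state structure-calculation backend.

A coarse-grained Cartesian stand-in for a torsion-angle-dynamics engine:
each conformer is an N-state set of Calpha bead chains fitted by seeded
random initialization plus monotone gradient descent to the objective

* distance-restraint term: weighted squared violations of upper/lower
  limits evaluated on the r^-6 average over the N states,
* harmonic chain-connectivity term toward the consecutive-bead spacing,
* per-state steric repulsion below a minimum non-neighbour distance,
* flat-bottom bundling between corresponding beads of different states
  (zero inside half the bottom width, harmonic outside) keeping the states
  together unless the data pull them apart.

With a grouping scheme the states are split into two groups whose members
are bundled strongly within a group and weakly across groups, emulating
population-scan calculations.  Many conformers are minimized in parallel
from independent random starts and the lowest-objective ones are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensemble import Ensemble, StateModel
from .restraints import RestraintSet

__all__ = ["BackendConfig", "GroupingScheme", "RefineError", "calculate", "rank_and_select"]


class RefineError(ValueError):
    pass


@dataclass(frozen=True)
class BackendConfig:
    """Effort and force-field parameters of the toy backend.

    Defaults follow established multi-state calculation practice: many
    conformers calculated, the best few kept, weak 1.2 A flat-bottom
    bundling between states.
    """

    n_states: int = 2
    n_conformers_calculated: int = 500
    n_conformers_kept: int = 20
    n_steps: int = 2000
    bundling_width: float = 1.2  # A, full bottom width of the flat-bottom well
    bundling_weight: float = 0.02  # "weak" relative to the restraint weight
    bundling_huber_delta: float = 0.5  # A, excess beyond which the well becomes linear
    group_bundling_weight: float = 5.0  # strong intra-group bundling
    chain_bond_length: float = 3.8  # A
    bond_weight: float = 10.0
    steric_min: float = 4.0  # A, between non-neighbour beads of one state
    steric_weight: float = 1.0
    sidechain_relaxation: float = 1.5  # A, bound slack for non-CA restrained atoms
    init_jitter: float = 0.5  # A, floor of the per-conformer start diversity
    state_jitter: float = 0.5  # A, initial spread between states of one conformer
    convergence_tol: float = 1e-6  # relative objective decrease per check interval
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers_kept > self.n_conformers_calculated:
            raise RefineError("cannot keep more conformers than calculated")
        if min(self.n_states, self.n_conformers_calculated, self.n_conformers_kept, self.n_steps) < 1:
            raise RefineError("counts must be >= 1")
        if min(self.bundling_width, self.chain_bond_length, self.steric_min) <= 0:
            raise RefineError("widths and lengths must be positive")


@dataclass(frozen=True)
class GroupingScheme:
    """Partition of the state indices (1-based) into two controlled groups."""

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]

    @classmethod
    def split(cls, n_states: int, k: int) -> "GroupingScheme":
        if not 1 <= k <= n_states - 1:
            raise RefineError(f"group A size {k} must be in 1..{n_states - 1}")
        return cls(tuple(range(1, k + 1)), tuple(range(k + 1, n_states + 1)))

    def validate(self, n_states: int) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b or a & b or a | b != set(range(1, n_states + 1)):
            raise RefineError("groups must be a non-empty disjoint cover of the states")


@dataclass
class _Problem:
    ia: np.ndarray  # (R,) bead index of atom a
    ib: np.ndarray
    bounds: np.ndarray  # (R,)
    upper: np.ndarray  # (R,) bool
    weights: np.ndarray  # (R,)
    bundle_w: np.ndarray  # (N, N) pairwise bundling weights, zero diagonal
    inc: np.ndarray | None = None  # (L, R) signed incidence of restrained pairs

    def with_incidence(self, L: int) -> "_Problem":
        inc = np.zeros((L, self.ia.size))
        for r, (i, j) in enumerate(zip(self.ia, self.ib)):
            inc[i, r] += 1.0
            inc[j, r] -= 1.0
        self.inc = inc
        return self


def _map_restraints(rset: RestraintSet, length: int, cfg: BackendConfig) -> tuple[np.ndarray, ...]:
    ia, ib, bounds, upper, weights = [], [], [], [], []
    for r in rset.restraints:
        for ref in (r.atom_a, r.atom_b):
            if not 1 <= ref.residue_index <= length:
                raise RefineError(f"restraint references residue outside the sequence: {ref}")
        i, j = r.atom_a.residue_index - 1, r.atom_b.residue_index - 1
        if i == j:
            raise RefineError(f"restraint collapses onto one bead after coarse-graining: {r}")
        b = r.bound
        # non-Calpha atoms are mapped to their residue's bead; relax the bound
        # to absorb the side-chain offset
        if r.atom_a.atom_name != "CA" or r.atom_b.atom_name != "CA":
            b = b + cfg.sidechain_relaxation if r.rtype == "upper" else max(b - cfg.sidechain_relaxation, 0.1)
        ia.append(i)
        ib.append(j)
        bounds.append(b)
        upper.append(r.rtype == "upper")
        weights.append(rset.weights[r.rtype])
    return (
        np.asarray(ia, dtype=int),
        np.asarray(ib, dtype=int),
        np.asarray(bounds, dtype=float),
        np.asarray(upper, dtype=bool),
        np.asarray(weights, dtype=float),
    )


def _bundle_weights(cfg: BackendConfig, grouping: GroupingScheme | None) -> np.ndarray:
    N = cfg.n_states
    W = np.full((N, N), cfg.bundling_weight)
    if grouping is not None:
        grouping.validate(N)
        group = np.zeros(N, dtype=int)
        for s in grouping.group_b:
            group[s - 1] = 1
        same = group[:, None] == group[None, :]
        W = np.where(same, cfg.group_bundling_weight, cfg.bundling_weight)
    np.fill_diagonal(W, 0.0)
    # per-partner normalization: the aggregate pull on one state from all
    # others stays at the nominal weight regardless of the state count
    return W / max(N - 1, 1)


def _objective(X: np.ndarray, prob: _Problem, cfg: BackendConfig) -> tuple[np.ndarray, np.ndarray]:
    """Objective and gradient, vectorized over a batch of conformers.

    ``X`` has shape (C, N, L, 3); returns per-conformer objectives (C,) and
    the gradient with the same shape as ``X``.
    """
    C, N, L, _ = X.shape
    f = np.zeros(C)
    G = np.zeros_like(X)

    # chain connectivity
    bond_vec = X[:, :, 1:] - X[:, :, :-1]
    bond_d = np.linalg.norm(bond_vec, axis=-1)
    e = bond_d - cfg.chain_bond_length
    f += cfg.bond_weight * (e ** 2).sum(axis=(1, 2))
    coef = (2.0 * cfg.bond_weight * e / np.maximum(bond_d, 1e-9))[..., None] * bond_vec
    G[:, :, 1:] += coef
    G[:, :, :-1] -= coef

    # steric repulsion within each state (non-neighbour beads); pairwise
    # distances via the Gram-matrix identity and forces via matmul to avoid
    # the (.., L, L, 3) displacement tensor
    B = C * N
    Xb = X.reshape(B, L, 3)
    sq = (Xb ** 2).sum(-1)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * (Xb @ Xb.transpose(0, 2, 1))
    np.maximum(d2, 1e-12, out=d2)
    d = np.sqrt(d2)
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    mask = (sep >= 2) & (d < cfg.steric_min)
    pen = np.where(mask, cfg.steric_min - d, 0.0)
    f += 0.5 * cfg.steric_weight * (pen ** 2).reshape(C, N, L, L).sum(axis=(1, 2, 3))
    # factor 2: the (j, i) copy of each pair also depends on bead i
    coef = np.where(mask, -2.0 * cfg.steric_weight * pen / d, 0.0)
    # grad_i = sum_j coef_ij (x_i - x_j) = rowsum_i * x_i - coef @ x
    Gst = coef.sum(axis=2)[..., None] * Xb - coef @ Xb
    G += Gst.reshape(C, N, L, 3)

    # flat-bottom bundling between corresponding beads of state pairs:
    # quadratic just outside the bottom, linear (Huber) far outside, so that
    # thermal drift is damped but a large data-driven state separation is
    # not quadratically taxed
    if N > 1 and prob.bundle_w.any():
        sdiff = X[:, :, None, :, :] - X[:, None, :, :, :]  # (C, N, N, L, 3)
        sd = np.linalg.norm(sdiff, axis=-1)
        excess = np.maximum(sd - 0.5 * cfg.bundling_width, 0.0)
        delta = cfg.bundling_huber_delta
        e_quad = np.minimum(excess, delta)
        energy = e_quad ** 2 + 2.0 * delta * (excess - e_quad)
        W = prob.bundle_w[None, :, :, None]
        f += 0.5 * (W * energy).sum(axis=(1, 2, 3))
        coef = np.where(excess > 0, 2.0 * W * e_quad / np.maximum(sd, 1e-9), 0.0)
        G += (coef[..., None] * sdiff).sum(axis=2)

    # distance restraints on the r^-6 state-averaged distances
    if prob.ia.size:
        rvec = X[:, :, prob.ia, :] - X[:, :, prob.ib, :]  # (C, N, R, 3)
        rd = np.maximum(np.linalg.norm(rvec, axis=-1), 1e-3)
        inv6 = rd ** -6.0
        S = inv6.mean(axis=1)  # (C, R)
        dstar = S ** (-1.0 / 6.0)
        viol = np.where(prob.upper[None, :], dstar - prob.bounds[None, :], prob.bounds[None, :] - dstar)
        viol = np.maximum(viol, 0.0)
        f += (prob.weights[None, :] * viol ** 2).sum(axis=1)
        dE_dstar = 2.0 * prob.weights[None, :] * viol * np.where(prob.upper[None, :], 1.0, -1.0)
        dE_dstar = np.where(viol > 0, dE_dstar, 0.0)
        # d(dstar)/d(d_s) = dstar^7 * d_s^-7 / N
        dcoef = dE_dstar[:, None, :] * (dstar[:, None, :] ** 7) * rd ** -7.0 / N  # (C, N, R)
        gvec = (dcoef / rd)[..., None] * rvec  # force along the pair axis
        G += np.moveaxis(np.tensordot(prob.inc, gvec, axes=(1, 2)), 0, 2)

    return f, G


def _distance_bounds(prob: _Problem, L: int, cfg: BackendConfig) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper distance-bound matrices of the restraint network.

    Bonds fix consecutive beads; restraints set pair bounds; unknown pairs
    default to the steric floor below and the shortest path through the
    bound graph above (triangle inequality smoothing).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    upper = np.full((L, L), np.inf)
    lower = np.full((L, L), cfg.steric_min)
    idx = np.arange(L - 1)
    upper[idx, idx + 1] = upper[idx + 1, idx] = cfg.chain_bond_length
    lower[idx, idx + 1] = lower[idx + 1, idx] = cfg.chain_bond_length
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    for i, j, b, up in zip(prob.ia, prob.ib, prob.bounds, prob.upper):
        if up:
            upper[i, j] = upper[j, i] = min(upper[i, j], b)
        else:
            lower[i, j] = lower[j, i] = max(lower[i, j], b)
    graph = csr_matrix(np.where(np.isfinite(upper), upper, 0.0))
    upper = shortest_path(graph, directed=False)
    upper = np.maximum(upper, lower)
    return lower, upper


def _embed_distances(D: np.ndarray) -> np.ndarray:
    """Classical MDS: rank-3 embedding of a (approximate) distance matrix."""
    L = D.shape[0]
    J = np.eye(L) - np.ones((L, L)) / L
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    w3 = np.clip(w[-3:], 0.0, None)
    return v[:, -3:] * np.sqrt(w3)


def _init_conformers(
    C: int, N: int, L: int, cfg: BackendConfig, prob: _Problem, rng: np.random.Generator
) -> np.ndarray:
    """Distance-geometry embedding with uncertainty-scaled diversity.

    All conformers start from the classical-MDS embedding of the
    triangle-smoothed upper-bound matrix (restrained pairs at their bound
    midpoints).  The per-conformer random displacement of each bead is
    scaled by that bead's positional uncertainty — a quarter of its mean
    distance-bound width — so a tightly determined network yields a tight
    starting pool while a sparse network yields genuinely diverse random
    folds.  A smaller per-state jitter breaks the symmetry between the
    states so restraint gradients can pull them apart.
    """
    lower, upper = _distance_bounds(prob, L, cfg)
    D = upper.copy()
    tight = (upper - lower) < 1.0
    D[tight] = 0.5 * (upper + lower)[tight]
    np.fill_diagonal(D, 0.0)
    embed = _embed_distances(D)
    width = upper - lower
    np.fill_diagonal(width, 0.0)
    bead_sigma = np.maximum(0.25 * width.mean(axis=1), 2.0 * cfg.init_jitter)  # (L,)
    X = np.broadcast_to(embed, (C, N, L, 3)).copy()
    X += rng.normal(size=(C, 1, L, 3)) * bead_sigma[:, None]  # conformer diversity
    X += rng.normal(0.0, cfg.state_jitter, size=(C, N, L, 3))  # state symmetry breaking
    return X


def calculate(
    restraints: RestraintSet,
    sequence: list[str],
    config: BackendConfig,
    grouping: GroupingScheme | None = None,
    return_trace: bool = False,
) -> Ensemble:
    """Run the toy multi-state structure calculation.

    Minimizes the objective by batched gradient descent with per-conformer
    adaptive step sizes (accepted steps never increase the objective) and a
    three-stage step-size annealing schedule.  Returns the
    ``n_conformers_kept`` lowest-objective conformers as an
    :class:`~mscorval.ensemble.Ensemble`; final objectives are stored in
    ``ensemble.meta["objectives"]`` (and the full descent trace under
    ``meta["trace"]`` when requested).
    """
    cfg = config
    L = len(sequence)
    if L < 2:
        raise RefineError("sequence must contain at least 2 residues")
    ia, ib, bounds, upper, weights = _map_restraints(restraints, L, cfg)
    prob = _Problem(ia, ib, bounds, upper, weights, _bundle_weights(cfg, grouping)).with_incidence(L)
    C, N = cfg.n_conformers_calculated, cfg.n_states
    rng = np.random.default_rng(cfg.seed)
    X = _init_conformers(C, N, L, cfg, prob, rng)

    stage_caps = (0.5, 0.15, 0.05)  # A, maximum per-bead displacement per stage
    lr = np.full(C, stage_caps[0])
    f, G = _objective(X, prob, cfg)
    trace = [f.copy()]
    check_every = 50
    f_check = f.copy()
    final_stage = 2 * cfg.n_steps // 3
    for step in range(cfg.n_steps):
        cap = stage_caps[min(3 * step // cfg.n_steps, 2)]
        lr = np.minimum(lr, cap)
        gmax = np.maximum(np.linalg.norm(G, axis=-1).max(axis=(1, 2)), 1e-12)
        prop = X - (lr / gmax)[:, None, None, None] * G
        f_new, G_new = _objective(prop, prob, cfg)
        accept = f_new <= f
        X[accept] = prop[accept]
        f = np.where(accept, f_new, f)
        G[accept] = G_new[accept]
        lr = np.where(accept, np.minimum(lr * 1.1, cap), np.maximum(lr * 0.5, 1e-6))
        if return_trace:
            trace.append(f.copy())
        # stop once every conformer has stalled in the final annealing stage
        if step >= final_stage and (step + 1) % check_every == 0:
            if np.max(f_check - f) < cfg.convergence_tol * (np.max(np.abs(f_check)) + 1e-9):
                break
            f_check = f.copy()

    conformers = [
        [_bead_state(X[c, s], sequence, s + 1) for s in range(N)] for c in range(C)
    ]
    ensemble = rank_and_select(conformers, f.tolist(), cfg.n_conformers_kept)
    ensemble.meta["config"] = cfg
    if return_trace:
        ensemble.meta["trace"] = np.array(trace)
    return ensemble


def _bead_state(coords: np.ndarray, sequence: list[str], state_index: int) -> StateModel:
    L = len(sequence)
    return StateModel(["A"] * L, np.arange(1, L + 1), list(sequence), ["CA"] * L, coords, state_index=state_index)


def rank_and_select(
    conformers: list[list[StateModel]],
    objectives: list[float],
    keep: int,
) -> Ensemble:
    """Keep the ``keep`` conformers with the lowest final objective, ordered
    by objective and, on ties, by calculation index."""
    if len(conformers) != len(objectives):
        raise RefineError("conformers and objectives differ in length")
    if keep > len(conformers):
        raise RefineError(f"cannot keep {keep} of {len(conformers)} conformers")
    order = sorted(range(len(conformers)), key=lambda i: (objectives[i], i))[:keep]
    ens = Ensemble([conformers[i] for i in order])
    ens.meta["objectives"] = [float(objectives[i]) for i in order]
    return ens
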