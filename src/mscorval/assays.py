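"""Validation assays for multi-state structure calculations.

Each assay drives a structure-calculation backend over a scan of
conditions, evaluates the resulting bundles for the distance target
function, ensemble RMSD and the structural correlation parameter mu, and
returns a tidy results table plus the condition optimum or ranking:

* ``states_scan``      -- optimal number of states (mu maximum vs target-function plateau)
* ``population_scan``  -- state populations via grouped ten-state calculations
* ``titration``        -- restraint-network density titration (RMSD fall, mu rise)
* ``loo_ranking``      -- leave-one-out restraint ranking (key vs suspect restraints)
* ``distance_profile`` -- correlation vs interresidual distance in equal-count bins
* ``convergence_scan`` -- minimizer effort grid judged by mu convergence
* ``compare_with_without`` -- paired runs differing by one restraint
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import refine
from .correlation import CorrelationMatrix, analyze
from .ensemble import Ensemble, StateModel
from .geometry import ensemble_rmsd
from .refine import BackendConfig, GroupingScheme
from .restraints import DistanceRestraint, RestraintSet, target_function

__all__ = [
    "ScanResult",
    "RestraintRanking",
    "AssayError",
    "states_scan",
    "population_scan",
    "titration",
    "loo_ranking",
    "distance_profile",
    "convergence_scan",
    "compare_with_without",
]

Backend = Callable[[RestraintSet, list[str], BackendConfig, GroupingScheme | None], Ensemble]


class AssayError(ValueError):
    pass


@dataclass
class ScanResult:
    """Per-replicate rows plus a per-condition summary (means and SDs)."""

    detail: pd.DataFrame
    summary: pd.DataFrame
    optimum: object = None

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)


@dataclass
class RestraintRanking:
    """Leave-one-out ranking sorted ascending by mu after removal."""

    table: pd.DataFrame
    baseline_mu: float
    top_set: list[DistanceRestraint]
    bottom_set: list[DistanceRestraint]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _run_backend(
    backend: Backend,
    restraints: RestraintSet,
    sequence: list[str],
    config: BackendConfig,
    grouping: GroupingScheme | None = None,
    context: str = "",
) -> Ensemble:
    try:
        return backend(restraints, sequence, config, grouping)
    except Exception as exc:  # re-raise with the scan condition attached
        raise AssayError(f"backend failed at condition [{context}]: {exc}") from exc


def _mu(ensemble: Ensemble, n_states: int, threshold: float, seed: int) -> float:
    return analyze(ensemble, n_states=n_states, threshold=threshold, seed=seed).mu


def _summarize(detail: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    agg = {}
    for col in detail.columns:
        if col in by or col == "replicate":
            continue
        if pd.api.types.is_numeric_dtype(detail[col]):
            agg[col] = ["mean", "std"]
    out = detail.groupby(by, dropna=False).agg(agg)
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    out["n_replicates"] = detail.groupby(by, dropna=False).size().values
    return out.reset_index()


def states_scan(
    restraints: RestraintSet,
    sequence: list[str],
    backend: Backend = refine.calculate,
    state_range: Iterable[int] = range(1, 10),
    replicates: int = 1,
    seed: int = 0,
    config: BackendConfig | None = None,
    threshold: float = 0.5,
) -> ScanResult:
    """Scan the number of modelled states.

    For each state count N the backend recalculates the bundle; the
    normalized target function (V_d per restraint) is reported for every N
    and mu (clustering into K = N states) only for N >= 2.  The optimum is
    the N maximizing the mean mu.
    """
    cfg = config or BackendConfig()
    states = list(state_range)
    if not states:
        raise AssayError("empty state range")
    seeds = _spawn_seeds(seed, len(states) * replicates)
    rows = []
    si = 0
    for n in states:
        for rep in range(replicates):
            s = seeds[si]
            si += 1
            c = replace(cfg, n_states=n, seed=s)
            ens = _run_backend(backend, restraints, sequence, c, context=f"n_states={n}")
            tf = target_function(ens, restraints)
            rows.append(
                {
                    "n_states": n,
                    "replicate": rep,
                    "target_function": tf.value,
                    "normalized_target_function": tf.value / max(len(restraints), 1),
                    "mu": _mu(ens, n, threshold, s) if n >= 2 else np.nan,
                    "ensemble_rmsd": ensemble_rmsd(ens) if ens.n_conformers * n >= 2 else np.nan,
                }
            )
    detail = pd.DataFrame(rows)
    summary = _summarize(detail, ["n_states"])
    mus = summary.set_index("n_states")["mu_mean"].dropna()
    optimum = int(mus.idxmax()) if len(mus) else None
    return ScanResult(detail, summary, optimum)


def _group_representatives(ensemble: Ensemble, grouping: GroupingScheme) -> Ensemble:
    """Reduce each N-state conformer to two entities: per group, the member
    state closest (RMSD without refitting; states share a frame) to the
    group's mean coordinates."""
    conformers = []
    for conf in ensemble.conformers:
        pair = []
        for gi, group in enumerate((grouping.group_a, grouping.group_b)):
            members = [conf[s - 1] for s in group]
            coords = np.array([m.coords for m in members])
            mean = coords.mean(axis=0)
            rmsds = np.sqrt(((coords - mean) ** 2).sum(-1).mean(-1))
            rep = members[int(np.argmin(rmsds))]
            pair.append(
                StateModel(
                    rep.chain_ids, rep.residue_indices, rep.residue_names, rep.atom_names, rep.coords, gi + 1
                )
            )
        conformers.append(pair)
    return Ensemble(conformers)


def population_scan(
    restraints: RestraintSet,
    sequence: list[str],
    backend: Backend = refine.calculate,
    total_states: int = 10,
    group_sizes: Iterable[int] | None = None,
    seed: int = 0,
    config: BackendConfig | None = None,
    threshold: float = 0.5,
) -> ScanResult:
    """Estimate two-state populations from grouped multi-state calculations.

    The ``total_states`` states are split into controlled groups A (size k)
    and B; intra-group bundling is strong, so a group behaves as one state
    with population k / total.  One representative per group feeds the
    correlation analysis, making each condition a two-state analysis.  The
    optimum is the group size maximizing mu.
    """
    cfg = config or BackendConfig()
    sizes = list(group_sizes) if group_sizes is not None else list(range(1, total_states))
    for k in sizes:
        if not 1 <= k <= total_states - 1:
            raise AssayError(f"group size {k} invalid for {total_states} states (empty group)")
    seeds = _spawn_seeds(seed, len(sizes))
    rows = []
    for k, s in zip(sizes, seeds):
        grouping = GroupingScheme.split(total_states, k)
        c = replace(cfg, n_states=total_states, seed=s)
        ens = _run_backend(backend, restraints, sequence, c, grouping, context=f"group_a={k}")
        tf = target_function(ens, restraints)
        reps = _group_representatives(ens, grouping)
        rows.append(
            {
                "group_a_size": k,
                "population_a": k / total_states,
                "replicate": 0,
                "target_function": tf.value,
                "normalized_target_function": tf.value / max(len(restraints), 1),
                "mu": _mu(reps, 2, threshold, s),
                "ensemble_rmsd": ensemble_rmsd(reps),
            }
        )
    detail = pd.DataFrame(rows)
    summary = _summarize(detail, ["group_a_size", "population_a"])
    optimum = int(summary.set_index("group_a_size")["mu_mean"].idxmax())
    tf_optimum = int(summary.set_index("group_a_size")["normalized_target_function_mean"].idxmin())
    res = ScanResult(detail, summary, optimum)
    res.tf_optimum = tf_optimum
    return res


def _subsample(rset: RestraintSet, fraction: float, rng: np.random.Generator) -> RestraintSet:
    n = len(rset)
    keep = int(round(fraction * n))
    if keep <= 0:
        return RestraintSet([], dict(rset.weights))
    if keep >= n:
        return rset.subset(range(n))
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    return rset.subset(idx)


def titration(
    restraints: RestraintSet,
    sequence: list[str],
    backend: Backend = refine.calculate,
    fractions: Sequence[float] = (0.03, 0.05, 0.1, 0.2, 0.4, 0.7, 0.9, 1.0),
    replicates: int = 10,
    seed: int = 0,
    config: BackendConfig | None = None,
    threshold: float = 0.5,
) -> ScanResult:
    """Restraint-network density titration.

    Each (fraction, replicate) draws a fresh uniform random subset of the
    restraints from a dedicated seeded generator, recalculates the bundle
    and records ensemble RMSD and mu.  Sparse networks fail to converge on
    the fold (high RMSD, no state separation); dense networks both fix the
    fold and separate the states.
    """
    cfg = config or BackendConfig()
    if replicates < 1:
        raise AssayError("replicates must be >= 1")
    import warnings

    ss = np.random.SeedSequence(seed)
    rows = []
    for fi, frac in enumerate(fractions):
        if not 0 < frac <= 1:
            raise AssayError(f"fraction {frac} outside (0, 1]")
        for rep in range(replicates):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(fi, rep))
            rng = np.random.default_rng(child)
            sub = _subsample(restraints, frac, rng)
            if len(sub) == 0:
                warnings.warn(f"fraction {frac} yields no restraints; condition skipped", stacklevel=2)
                continue
            s = int(rng.integers(0, 2**31 - 1))
            c = replace(cfg, seed=s)
            ens = _run_backend(backend, sub, sequence, c, context=f"fraction={frac}, rep={rep}")
            tf = target_function(ens, sub)
            rows.append(
                {
                    "fraction": frac,
                    "replicate": rep,
                    "n_restraints": len(sub),
                    "target_function": tf.value,
                    "normalized_target_function": tf.value / len(sub),
                    "mu": _mu(ens, cfg.n_states, threshold, s) if cfg.n_states >= 2 else np.nan,
                    "ensemble_rmsd": ensemble_rmsd(ens),
                }
            )
    detail = pd.DataFrame(rows)
    return ScanResult(detail, _summarize(detail, ["fraction"]))


def loo_ranking(
    restraints: RestraintSet,
    sequence: list[str],
    backend: Backend = refine.calculate,
    long_range_only: bool = True,
    min_separation: int = 5,
    set_size: int = 20,
    seed: int = 0,
    config: BackendConfig | None = None,
    threshold: float = 0.5,
    common_seed: bool = True,
) -> RestraintRanking:
    """Leave-one-out restraint ranking by structural correlation.

    Every in-scope distance (by default long-range: sequence separation >=
    ``min_separation``) is removed in turn -- a distance here is the atom
    pair, so an exact eNOE's upper and lower limit leave together -- the
    bundle is recalculated and mu recorded.  Distances whose removal
    *lowers* mu the most are key (state-defining) restraints; those whose
    removal *raises* mu above the full-set baseline are suspects (possible
    inaccuracy or misassignment).  ``common_seed`` reuses one backend seed
    across all runs so differences reflect the removed restraint rather
    than the random start.
    """
    cfg = config or BackendConfig()
    groups: dict[tuple, list[DistanceRestraint]] = {}
    for r in restraints:
        key = (r.atom_a.residue_index, r.atom_a.atom_name, r.atom_b.residue_index, r.atom_b.atom_name)
        groups.setdefault(key, []).append(r)
    scope = [
        rs
        for rs in groups.values()
        if (not long_range_only) or rs[0].sequence_separation >= min_separation
    ]
    if len(scope) < 2:
        raise AssayError("leave-one-out scope must contain at least 2 restraints")
    seeds = _spawn_seeds(seed, len(scope) + 1)
    base_seed = seeds[0]
    base_cfg = replace(cfg, seed=base_seed)
    base_ens = _run_backend(backend, restraints, sequence, base_cfg, context="baseline")
    baseline_mu = _mu(base_ens, cfg.n_states, threshold, base_seed)
    rows = []
    for i, group in enumerate(scope):
        s = base_seed if common_seed else seeds[i + 1]
        c = replace(cfg, seed=s)
        reduced = restraints
        for r in group:
            reduced = reduced.without(r)
        label = str(group[0])
        ens = _run_backend(backend, reduced, sequence, c, context=f"without {label}")
        rows.append({"restraint": label, "mu_without": _mu(ens, cfg.n_states, threshold, s), "_obj": group[0]})
    table = pd.DataFrame(rows).sort_values("mu_without", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    k = min(set_size, len(table) // 2)
    bottom = list(table["_obj"].iloc[:k])
    top = list(table["_obj"].iloc[len(table) - k :])
    table["baseline_mu"] = baseline_mu
    return RestraintRanking(table.drop(columns="_obj"), baseline_mu, top, bottom)


def distance_profile(
    ensemble: Ensemble,
    matrix: CorrelationMatrix,
    n_bins: int = 10,
    atom_mode: str = "CA",
) -> pd.DataFrame:
    """Correlation vs interresidual distance.

    All residue pairs are sorted by their ensemble-mean Calpha-Calpha
    distance and split into ``n_bins`` equal-count groups (remainders go to
    the last bins); each bin reports its mean distance and mean correlation.
    """
    if n_bins < 2:
        raise AssayError("n_bins must be >= 2")
    L = matrix.L
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    if len(pairs) < n_bins:
        raise AssayError(f"{len(pairs)} residue pairs cannot fill {n_bins} bins")
    coords = np.array([e.reference_coords(atom_mode) for e in ensemble.entities()])
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    mean_d = np.sqrt((diff ** 2).sum(-1)).mean(axis=0)
    ii, jj = np.array(pairs).T
    d = mean_d[ii, jj]
    a = matrix.A[ii, jj]
    order = np.argsort(d, kind="stable")
    n = len(pairs)
    base, extra = divmod(n, n_bins)
    sizes = [base] * (n_bins - extra) + [base + 1] * extra  # remainder to the last bins
    rows, pos = [], 0
    for b, size in enumerate(sizes):
        idx = order[pos : pos + size]
        pos += size
        rows.append(
            {
                "bin": b + 1,
                "n_pairs": size,
                "mean_distance": float(d[idx].mean()),
                "mean_correlation": float(a[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


def convergence_scan(
    restraints: RestraintSet,
    sequence: list[str],
    backend: Backend = refine.calculate,
    step_counts: Sequence[int] = (250, 500, 1000, 2000),
    conformer_counts: Sequence[int] = (50, 100, 200, 500),
    seed: int = 0,
    config: BackendConfig | None = None,
    threshold: float = 0.5,
    tolerance: float = 0.05,
) -> ScanResult:
    """Minimizer effort grid: mu per (step count, conformer count) cell.

    Flags the cheapest cell (smallest steps x conformers product) whose mu
    is within ``tolerance`` (relative) of the maximal-effort cell's mu.
    """
    cfg = config or BackendConfig()
    if not step_counts or not conformer_counts:
        raise AssayError("empty effort grid")
    seeds = _spawn_seeds(seed, len(step_counts) * len(conformer_counts))
    rows, si = [], 0
    for st in step_counts:
        for nc in conformer_counts:
            s = seeds[si]
            si += 1
            kept = min(cfg.n_conformers_kept, nc)
            c = replace(cfg, n_steps=st, n_conformers_calculated=nc, n_conformers_kept=kept, seed=s)
            ens = _run_backend(backend, restraints, sequence, c, context=f"steps={st}, conformers={nc}")
            tf = target_function(ens, restraints)
            rows.append(
                {
                    "n_steps": st,
                    "n_conformers": nc,
                    "replicate": 0,
                    "effort": st * nc,
                    "target_function": tf.value,
                    "normalized_target_function": tf.value / max(len(restraints), 1),
                    "mu": _mu(ens, cfg.n_states, threshold, s) if cfg.n_states >= 2 else np.nan,
                }
            )
    detail = pd.DataFrame(rows)
    summary = _summarize(detail, ["n_steps", "n_conformers"])
    ref_row = detail.loc[detail["effort"].idxmax()]
    ref_mu = ref_row["mu"]
    ok = detail[detail["mu"] >= ref_mu * (1 - tolerance)] if np.isfinite(ref_mu) else detail
    cell = ok.loc[ok["effort"].idxmin()] if len(ok) else ref_row
    optimum = (int(cell["n_steps"]), int(cell["n_conformers"]))
    return ScanResult(detail, summary, optimum)


@dataclass
class PairedComparison:
    target: DistanceRestraint
    mu_with: float
    mu_without: float
    target_function_with: float
    target_function_without: float


def compare_with_without(
    restraints: RestraintSet,
    target: DistanceRestraint,
    sequence: list[str],
    backend: Backend = refine.calculate,
    seed: int = 0,
    config: BackendConfig | None = None,
    threshold: float = 0.5,
) -> PairedComparison:
    """Two backend runs differing only in one restraint; reports the mean
    target function and mu of both bundles side by side."""
    cfg = config or BackendConfig()
    if target not in restraints.restraints:
        raise AssayError(f"target restraint not in set: {target}")
    s = _spawn_seeds(seed, 1)[0]
    c = replace(cfg, seed=s)
    with_ens = _run_backend(backend, restraints, sequence, c, context="with target")
    without_set = restraints.without(target)
    without_ens = _run_backend(backend, without_set, sequence, c, context="without target")
    return PairedComparison(
        target,
        mu_with=_mu(with_ens, cfg.n_states, threshold, s),
        mu_without=_mu(without_ens, cfg.n_states, threshold, s),
        target_function_with=target_function(with_ens, restraints).value,
        target_function_without=target_function(without_ens, without_set).value,
    )
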