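"""Distance restraints: parsing, r^-6 ensemble averaging and the target function.

The distance part of the structure-calculation target function is the
weighted sum of squared violations over the currently violated restraints,

    V_d = sum_c w_c sum_{(a,b) in I_c} (d*_ab - b_ab)^2 ,

with restraint classes c = u (experimental upper limit), l (experimental
lower limit) and v (steric lower limit).  For a conformer that models N
coexisting states the model distance entering V_d is the NOE-appropriate
r^-6 ensemble average over the states,

    d* = ( (1/N) sum_i d_i^-6 )^(-1/6) ,

which is dominated by the shortest per-state distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ensemble import Ensemble

__all__ = [
    "AtomRef",
    "DistanceRestraint",
    "RestraintSet",
    "TargetFunctionReport",
    "RestraintError",
    "read_restraints",
    "write_restraints",
    "ensemble_average_distance",
    "target_function",
]

RESTRAINT_TYPES = ("upper", "lower", "steric")


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRef:
    residue_index: int
    residue_name: str
    atom_name: str

    def __str__(self) -> str:  # e.g. "TRP11 H"
        return f"{self.residue_name}{self.residue_index} {self.atom_name}"


@dataclass(frozen=True)
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    bound: float
    rtype: str = "upper"

    def __post_init__(self) -> None:
        if self.bound <= 0:
            raise RestraintError(f"restraint bound must be positive, got {self.bound}")
        if self.rtype not in RESTRAINT_TYPES:
            raise RestraintError(f"unknown restraint type {self.rtype!r}")
        if self.atom_a == self.atom_b:
            raise RestraintError(f"restraint connects an atom to itself: {self.atom_a}")

    @property
    def sequence_separation(self) -> int:
        return abs(self.atom_a.residue_index - self.atom_b.residue_index)

    def __str__(self) -> str:
        return f"{self.atom_a} - {self.atom_b} {self.rtype} {self.bound:.2f} A"


@dataclass
class RestraintSet:
    """A list of distance restraints plus per-class weights w_c."""

    restraints: list[DistanceRestraint] = field(default_factory=list)
    weights: dict[str, float] = field(default_factory=lambda: {t: 1.0 for t in RESTRAINT_TYPES})

    def __post_init__(self) -> None:
        for t in RESTRAINT_TYPES:
            if t not in self.weights:
                raise RestraintError(f"missing weight for restraint type {t!r}")
            if self.weights[t] < 0:
                raise RestraintError("restraint weights must be >= 0")

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def subset(self, indices: Iterable[int]) -> "RestraintSet":
        idx = list(indices)
        return RestraintSet([self.restraints[i] for i in idx], dict(self.weights))

    def without(self, restraint: DistanceRestraint) -> "RestraintSet":
        if restraint not in self.restraints:
            raise RestraintError(f"restraint not in set: {restraint}")
        rest = list(self.restraints)
        rest.remove(restraint)
        return RestraintSet(rest, dict(self.weights))


@dataclass
class Violation:
    restraint: DistanceRestraint
    conformer_index: int
    model_distance: float
    violation: float


@dataclass
class TargetFunctionReport:
    """V_d (Angstrom^2), averaged over conformers, plus the violation list."""

    value: float
    per_conformer: np.ndarray
    violated: list[Violation]

    def to_rows(self) -> list[dict]:
        return [
            {
                "restraint": str(v.restraint),
                "conformer": v.conformer_index + 1,
                "bound": v.restraint.bound,
                "model_distance": v.model_distance,
                "violation": v.violation,
            }
            for v in self.violated
        ]


def read_restraints(path: str | Path, rtype: str = "upper", weights: dict[str, float] | None = None) -> RestraintSet:
    """Parse a CYANA-style .upl/.lol file.

    Each data line reads ``resnum resname atomname resnum resname atomname
    distance``; ``#`` comments and blank lines are ignored.  Extra trailing
    columns (e.g. CYANA weights) are ignored.
    """
    if rtype not in RESTRAINT_TYPES:
        raise RestraintError(f"unknown restraint type {rtype!r}")
    out: list[DistanceRestraint] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 7:
                raise RestraintError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}: {line!r}")
            try:
                ra, rb = int(fields[0]), int(fields[3])
                dist = float(fields[6])
            except ValueError as exc:
                raise RestraintError(f"{path}:{lineno}: malformed numeric field: {line!r}") from exc
            if dist <= 0:
                raise RestraintError(f"{path}:{lineno}: non-positive distance {dist}")
            out.append(
                DistanceRestraint(
                    AtomRef(ra, fields[1], fields[2]),
                    AtomRef(rb, fields[4], fields[5]),
                    dist,
                    rtype,
                )
            )
    rs = RestraintSet(out)
    if weights:
        rs.weights.update(weights)
    return rs


def write_restraints(rset: RestraintSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rset.restraints:
            a, b = r.atom_a, r.atom_b
            fh.write(
                f"{a.residue_index:>4d} {a.residue_name:<4s} {a.atom_name:<5s}"
                f"{b.residue_index:>4d} {b.residue_name:<4s} {b.atom_name:<5s}"
                f"{r.bound:8.2f}\n"
            )


def ensemble_average_distance(per_state_distances: Sequence[float], n_states: int | None = None) -> float:
    """r^-6 ensemble average over equally populated states.

    ``d* = (mean_i d_i^-6)^(-1/6)``; always within
    ``[min d_i, min d_i * N^(1/6)]``.
    """
    d = np.asarray(per_state_distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise RestraintError("need at least one per-state distance")
    if n_states is not None and d.size != n_states:
        raise RestraintError(f"got {d.size} distances for {n_states} states")
    if np.any(d <= 0):
        raise RestraintError("per-state distances must be positive")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


def _match_atoms(entity, ref: AtomRef, equivalent_protons: bool) -> list[int]:
    i = entity.atom_index(ref.residue_index, ref.atom_name)
    if i >= 0:
        return [i]
    if equivalent_protons:
        # CYANA-style pseudo-atom fallback: match all protons of the residue
        # whose names start with the stereo-stripped name (QB -> HB*, HB% -> HB*).
        base = ref.atom_name.replace("%", "").replace("*", "")
        if base.startswith("Q"):
            base = "H" + base[1:]
        idx = [
            j
            for j, (r, a) in enumerate(zip(entity.residue_indices, entity.atom_names))
            if int(r) == ref.residue_index and a.startswith(base) and a.startswith("H")
        ]
        if idx:
            return idx
    raise RestraintError(f"restrained atom not found in structure: {ref}")


def target_function(
    ensemble: Ensemble,
    rset: RestraintSet,
    equivalent_protons: bool = False,
) -> TargetFunctionReport:
    """Evaluate V_d on a multi-state ensemble.

    For each conformer, the model distance of every restraint is the r^-6
    average over its N states; upper limits are violated when d* exceeds the
    bound, lower and steric limits when d* falls below it.  The reported
    value is the mean of the per-conformer V_d over the bundle.

    With ``equivalent_protons`` enabled, a restraint naming an unresolvable
    proton is matched against all equivalent protons of the residue and the
    per-state effective distance is the r^-6 *sum* over the matched pairs
    (the NOE pseudo-atom convention).
    """
    if not rset.restraints:
        return TargetFunctionReport(0.0, np.zeros(ensemble.n_conformers), [])
    ref_entity = ensemble.conformers[0][0]
    matches = [
        (_match_atoms(ref_entity, r.atom_a, equivalent_protons), _match_atoms(ref_entity, r.atom_b, equivalent_protons))
        for r in rset.restraints
    ]
    n_conf = ensemble.n_conformers
    per_conformer = np.zeros(n_conf)
    violated: list[Violation] = []
    for ci, conf in enumerate(ensemble.conformers):
        v = 0.0
        for r, (ia, ib) in zip(rset.restraints, matches):
            inv6 = []
            for sm in conf:
                diffs = sm.coords[np.asarray(ia)][:, None, :] - sm.coords[np.asarray(ib)][None, :, :]
                dists = np.sqrt(np.sum(diffs ** 2, axis=-1)).ravel()
                if np.any(dists <= 0):
                    raise RestraintError(f"coincident restrained atoms for {r}")
                # r^-6 sum over equivalent pairs within a state, then averaged over states
                inv6.append(np.sum(dists ** -6.0))
            dstar = float(np.mean(inv6) ** (-1.0 / 6.0))
            if r.rtype == "upper":
                excess = dstar - r.bound
            else:
                excess = r.bound - dstar
            if excess > 0:
                w = rset.weights[r.rtype]
                v += w * excess ** 2
                violated.append(Violation(r, ci, dstar, excess))
        per_conformer[ci] = v
    return TargetFunctionReport(float(per_conformer.mean()), per_conformer, violated)
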