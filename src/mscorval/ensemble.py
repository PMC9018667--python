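"""Multi-state structure ensembles and multi-model PDB input/output.

A multi-state NMR bundle consists of M conformers, each of which jointly
models N coexisting conformational states.  Every state of every conformer
is one *entity* -- the unit on which distance statistics and structural
correlations are computed.  Two file layouts are supported:

* ``models`` dialect (default): the PDB file holds ``M x N`` consecutive
  MODEL blocks; blocks are grouped N at a time into conformers.
* ``chains`` dialect: the file holds M MODEL blocks, each containing N
  chains of identical composition, one chain per state.

Entity order is always conformer-major, state-minor and stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StateModel",
    "Ensemble",
    "EnsembleError",
    "read_ensemble",
    "write_ensemble",
]


class EnsembleError(ValueError):
    """Raised for malformed or inconsistent multi-state ensembles."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one entity.

    Coordinates are in Angstrom.  ``residue_index`` follows the (1-based)
    numbering of the source file.
    """

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise EnsembleError(f"non-finite or malformed position for atom {self.atom_name}")
        if self.residue_index < 1:
            raise EnsembleError(f"residue index must be >= 1, got {self.residue_index}")
        object.__setattr__(self, "position", pos)


class StateModel:
    """A single protein state: an ordered list of atoms.

    Internally stores parallel arrays for speed; ``atoms`` reconstructs
    :class:`AtomRecord` objects on demand.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        coords: np.ndarray,
        state_index: int = 1,
    ) -> None:
        self.chain_ids = list(chain_ids)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = list(residue_names)
        self.atom_names = list(atom_names)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.state_index = int(state_index)
        n = len(self.atom_names)
        if not (len(self.chain_ids) == len(self.residue_indices) == len(self.residue_names) == self.coords.shape[0] == n):
            raise EnsembleError("inconsistent atom array lengths")
        if n == 0:
            raise EnsembleError("empty state model")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleError("non-finite coordinates")
        if np.any(self.residue_indices < 1):
            raise EnsembleError("residue indices must be >= 1")
        # residue numbering must be non-decreasing within each chain
        for cid in dict.fromkeys(self.chain_ids):
            idx = self.residue_indices[[i for i, c in enumerate(self.chain_ids) if c == cid]]
            if np.any(np.diff(idx) < 0):
                raise EnsembleError(f"residue indices decrease along chain {cid!r}")

    @classmethod
    def from_atoms(cls, atoms: Sequence[AtomRecord], state_index: int = 1) -> "StateModel":
        return cls(
            [a.chain_id for a in atoms],
            [a.residue_index for a in atoms],
            [a.residue_name for a in atoms],
            [a.atom_name for a in atoms],
            np.array([a.position for a in atoms], dtype=float),
            state_index=state_index,
        )

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(c, int(r), rn, an, p)
            for c, r, rn, an, p in zip(
                self.chain_ids, self.residue_indices, self.residue_names, self.atom_names, self.coords
            )
        ]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, residue_index) keys in order of appearance."""
        return list(dict.fromkeys(zip(self.chain_ids, (int(i) for i in self.residue_indices))))

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def composition(self) -> list[tuple[str, int, str, str]]:
        return list(zip(self.chain_ids, (int(i) for i in self.residue_indices), self.residue_names, self.atom_names))

    def residue_composition(self) -> list[tuple[int, str, tuple[str, ...]]]:
        """Per-residue (index, name, atom names) summary used for homogeneity checks."""
        out: dict[tuple[str, int], list] = {}
        order: list[tuple[str, int]] = []
        names: dict[tuple[str, int], str] = {}
        for c, r, rn, an in zip(self.chain_ids, self.residue_indices, self.residue_names, self.atom_names):
            key = (c, int(r))
            if key not in out:
                out[key] = []
                order.append(key)
                names[key] = rn
            out[key].append(an)
        return [(key[1], names[key], tuple(out[key])) for key in order]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Index of the first atom matching (residue_index, atom_name); -1 if absent."""
        if not hasattr(self, "_atom_lookup"):
            lut: dict[tuple[int, str], int] = {}
            for i, (r, a) in enumerate(zip(self.residue_indices, self.atom_names)):
                lut.setdefault((int(r), a), i)
            self._atom_lookup = lut
        return self._atom_lookup.get((int(residue_index), atom_name), -1)

    def reference_coords(self, atom_mode: str = "CA") -> np.ndarray:
        """One reference point per residue: Calpha, Cbeta (Calpha for GLY), or heavy-atom centroid."""
        keys = self.residue_keys
        out = np.empty((len(keys), 3))
        groups: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chain_ids, self.residue_indices)):
            groups.setdefault((c, int(r)), []).append(i)
        for j, key in enumerate(keys):
            idx = groups[key]
            names = [self.atom_names[i] for i in idx]
            if atom_mode == "CA":
                if "CA" not in names:
                    raise EnsembleError(f"residue {key[1]} ({self.residue_names[idx[0]]}) has no CA atom")
                out[j] = self.coords[idx[names.index("CA")]]
            elif atom_mode == "CB":
                name = "CB" if "CB" in names else "CA"
                if name not in names:
                    raise EnsembleError(f"residue {key[1]} has neither CB nor CA atom")
                out[j] = self.coords[idx[names.index(name)]]
            elif atom_mode == "heavy_centroid":
                heavy = [i for i in idx if not self.atom_names[i].startswith("H")]
                if not heavy:
                    raise EnsembleError(f"residue {key[1]} has no heavy atoms")
                out[j] = self.coords[heavy].mean(axis=0)
            else:
                raise ValueError(f"unknown atom_mode {atom_mode!r}")
        return out

    def selection_coords(self, selection: str = "CA") -> np.ndarray:
        """Coordinates of a named atom selection (``CA`` or ``backbone``)."""
        if selection == "CA":
            mask = [a == "CA" for a in self.atom_names]
        elif selection == "backbone":
            mask = [a in ("N", "CA", "C", "O") for a in self.atom_names]
        else:
            raise ValueError(f"unknown atom selection {selection!r}")
        if not any(mask):
            raise EnsembleError(f"no atoms match selection {selection!r}")
        return self.coords[np.asarray(mask)]


class Ensemble:
    """M conformers x N states of one protein.

    ``conformers`` is an ordered list of conformers, each an ordered list of
    N :class:`StateModel`.  All M x N entities must share residue numbering,
    residue names and atom composition.
    """

    def __init__(self, conformers: Sequence[Sequence[StateModel]], meta: dict | None = None) -> None:
        conformers = [list(c) for c in conformers]
        if len(conformers) == 0 or any(len(c) == 0 for c in conformers):
            raise EnsembleError("ensemble must contain at least one conformer with at least one state")
        n_states = len(conformers[0])
        if any(len(c) != n_states for c in conformers):
            raise EnsembleError("all conformers must contain the same number of states")
        ref = conformers[0][0].residue_composition()
        for ci, conf in enumerate(conformers):
            for si, sm in enumerate(conf):
                comp = sm.residue_composition()
                if comp != ref:
                    msg = f"entity (conformer {ci + 1}, state {si + 1}) differs in composition"
                    for a, b in zip(ref, comp):
                        if a != b:
                            msg += f"; first mismatching residue: expected {a}, got {b}"
                            break
                    else:
                        msg += f"; residue counts {len(ref)} vs {len(comp)}"
                    raise EnsembleError(msg)
        self.conformers = conformers
        self.meta = dict(meta or {})

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def n_states(self) -> int:
        return len(self.conformers[0])

    @property
    def sequence_length(self) -> int:
        return self.conformers[0][0].n_residues

    @property
    def residue_indices(self) -> list[int]:
        return [k[1] for k in self.conformers[0][0].residue_keys]

    def entities(self) -> list[StateModel]:
        """All M x N entities in conformer-major, state-minor order."""
        return [sm for conf in self.conformers for sm in conf]

    def __len__(self) -> int:
        return self.n_conformers

    def __iter__(self) -> Iterator[list[StateModel]]:
        return iter(self.conformers)


def _state_from_gemmi_chains(chains: list[gemmi.Chain], state_index: int) -> StateModel:
    chain_ids: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for chain in chains:
        for res in chain:
            for atom in res:
                chain_ids.append(chain.name)
                res_idx.append(res.seqid.num)
                res_names.append(res.name)
                atom_names.append(atom.name)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not atom_names:
        raise EnsembleError("empty MODEL/chain in PDB file")
    return StateModel(chain_ids, res_idx, res_names, atom_names, np.array(coords), state_index=state_index)


def read_ensemble(path: str | Path, states_per_conformer: int, dialect: str = "models") -> Ensemble:
    """Read a multi-state ensemble from a multi-model PDB file.

    Parameters
    ----------
    states_per_conformer:
        Number of states N jointly modelled by each conformer.
    dialect:
        ``"models"``: consecutive MODEL blocks are grouped N at a time.
        ``"chains"``: each MODEL is one conformer holding N chains, one per state.
    """
    n = int(states_per_conformer)
    if n < 1:
        raise EnsembleError("states_per_conformer must be >= 1")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    models = list(st)
    if not models:
        raise EnsembleError(f"no MODEL records found in {path}")
    conformers: list[list[StateModel]] = []
    if dialect == "models":
        if len(models) % n != 0:
            raise EnsembleError(
                f"model count {len(models)} not divisible by {n} states per conformer in {path}"
            )
        for m0 in range(0, len(models), n):
            conformers.append(
                [_state_from_gemmi_chains(list(models[m0 + s]), s + 1) for s in range(n)]
            )
    elif dialect == "chains":
        for mi, model in enumerate(models):
            chains = list(model)
            if len(chains) != n:
                raise EnsembleError(
                    f"MODEL {mi + 1} holds {len(chains)} chains, expected {n} states per conformer"
                )
            conformers.append([_state_from_gemmi_chains([ch], s + 1) for s, ch in enumerate(chains)])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Ensemble(conformers)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (``models`` dialect).

    Coordinates are stored at the PDB format's 3-decimal precision, so a
    round trip reproduces them to within 5e-4 Angstrom.
    """
    st = gemmi.Structure()
    st.name = "mscorval ensemble"
    for i, entity in enumerate(ensemble.entities()):
        model = gemmi.Model(i + 1)
        chain = None
        res = None
        last = (None, None)
        for c, r, rn, an, xyz in zip(
            entity.chain_ids, entity.residue_indices, entity.residue_names, entity.atom_names, entity.coords
        ):
            if chain is None or c != chain.name:
                chain = gemmi.Chain(c)
                model.add_chain(chain)
                chain = model[-1]
                last = (None, None)
            if last != (c, int(r)):
                res = gemmi.Residue()
                res.name = rn
                res.seqid = gemmi.SeqId(int(r), " ")
                chain.add_residue(res)
                res = chain[-1]
                last = (c, int(r))
            atom = gemmi.Atom()
            atom.name = an
            atom.element = gemmi.Element(an[:1] if an[:1] != "H" else "H")
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
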