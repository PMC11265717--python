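"""Multistate structure combination.

Inverse-folding models encode inter-residue geometry with distance-based edge
features of limited range, so feeding several conformational states of one
protein to such a model as a single coordinate file requires the states to be
placed far enough apart that no spurious inter-state edges arise.  The
placement rule used here enforces, for every pair of states ``i, j``, the
centroid-separation inequality

    r_ij >= 2 * max(r_i_max, r_j_max) + r_min

where ``r_i_max`` is the maximum distance from state ``i``'s CA centroid to
any of its CA atoms and ``r_min`` defaults to 24 Angstrom.  The inequality
implies every inter-state CA-CA distance is at least ``r_min``:
``|ca_i - ca_j| >= r_ij - r_i_max - r_j_max >= r_min + 2*max(...) - r_i_max -
r_j_max >= r_min``.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from modesign.core import DesignProblem

DEFAULT_R_MIN = 24.0

#: Deterministic chain renaming order for combined files.
CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class StructureState:
    """CA-level coordinates for one conformational state.

    ``chains`` maps a chain id to ``(residue ids, residue names, coords)``
    with ``coords`` an ``(n, 3)`` float array in Angstrom.
    """

    state_id: str
    chains: Mapping[str, tuple[np.ndarray, list[str], np.ndarray]]

    def __post_init__(self) -> None:
        frozen = {}
        for cid, (resids, names, coords) in self.chains.items():
            resids = np.asarray(resids, int)
            coords = np.asarray(coords, float)
            if coords.ndim != 2 or coords.shape[1] != 3:
                raise ValueError(f"chain {cid!r}: coords must be (n, 3)")
            if len(np.unique(resids)) != len(resids):
                raise ValueError(f"chain {cid!r}: duplicate residue ids")
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"chain {cid!r}: non-finite coordinates")
            frozen[cid] = (resids, list(names), coords)
        self.chains = frozen

    def all_coords(self) -> np.ndarray:
        return np.concatenate([c for _, _, c in self.chains.values()])

    def translated(self, shift: np.ndarray) -> "StructureState":
        shift = np.asarray(shift, float)
        return StructureState(
            self.state_id,
            {
                cid: (resids.copy(), list(names), coords + shift)
                for cid, (resids, names, coords) in self.chains.items()
            },
        )


def bounding_radius(state: StructureState) -> float:
    """Maximum distance from the CA centroid to any CA atom (Angstrom)."""
    coords = state.all_coords()
    if coords.shape[0] == 0:
        raise ValueError(f"state {state.state_id!r} has no CA atoms")
    centroid = coords.mean(axis=0)
    return float(np.linalg.norm(coords - centroid, axis=1).max())


def place_states(
    states: Sequence[StructureState],
    r_min: float = DEFAULT_R_MIN,
) -> list[StructureState]:
    """Rigidly translate states onto a line so every pair satisfies the
    centroid-separation inequality.

    States are laid out along +x in input order with the exact minimal
    allowed separation between neighbors; for a collinear layout the
    adjacent inequalities imply the inequality for every pair.
    """
    if len(states) == 0:
        raise ValueError("no states to place")
    radii = [bounding_radius(s) for s in states]
    centroids_x = [0.0]
    for k in range(1, len(states)):
        sep = 2.0 * max(radii[k - 1], radii[k]) + r_min
        centroids_x.append(centroids_x[-1] + sep)
    placed = []
    for s, x in zip(states, centroids_x):
        centroid = s.all_coords().mean(axis=0)
        placed.append(s.translated(np.array([x, 0.0, 0.0]) - centroid))
    return placed


def min_interstate_ca_distance(states: Sequence[StructureState]) -> float:
    """Exhaustive minimum CA-CA distance over all state pairs."""
    if len(states) < 2:
        raise ValueError("need at least two states")
    best = np.inf
    coords = [s.all_coords() for s in states]
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            best = min(best, cdist(coords[i], coords[j]).min())
    return float(best)


def _chain_renaming(
    states: Sequence[StructureState],
) -> dict[tuple[str, str], str]:
    mapping: dict[tuple[str, str], str] = {}
    k = 0
    for s in states:
        for cid in s.chains:
            if k >= len(CHAIN_IDS):
                raise ValueError("more than 62 chains: chain-id space exhausted")
            mapping[(s.state_id, cid)] = CHAIN_IDS[k]
            k += 1
    return mapping


def write_combined_pdb(
    placed: Sequence[StructureState],
    problem: DesignProblem | None,
    path: str | Path,
) -> dict:
    """Write a single-model PDB of all placed states plus a sidecar JSON.

    Chains are re-lettered deterministically (A..Z, a..z, 0..9) while the
    original per-chain residue numbering is preserved.  The sidecar maps
    ``(state, original chain) -> combined chain`` and lists the tied position
    groups under the renaming; it is returned and written next to the PDB as
    ``<path>.ties.json``.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    renaming = _chain_renaming(placed)
    atoms = []
    for s in placed:
        for cid, (resids, names, coords) in s.chains.items():
            for resid, name, xyz in zip(resids, names, coords):
                atom = struc.Atom(
                    xyz,
                    chain_id=renaming[(s.state_id, cid)],
                    res_id=int(resid),
                    res_name=name,
                    atom_name="CA",
                    element="C",
                    occupancy=1.0,
                    b_factor=0.0,
                )
                atoms.append(atom)
    array = struc.array(atoms)
    pdb = PDBFile()
    pdb.set_structure(array)
    path = Path(path)
    pdb.write(str(path))

    sidecar: dict = {
        "chain_map": {
            f"{sid}/{cid}": new for (sid, cid), new in renaming.items()
        },
    }
    if problem is not None:
        groups = {}
        present = {
            (s.state_id, cid): set(int(r) for r in resids)
            for s in placed
            for cid, (resids, _, _) in s.chains.items()
        }
        for pos in problem.designable_positions:
            sites = []
            for sid in problem.states:
                for chain, resid in problem.tie_map.get(sid, {}).get(pos, ()):
                    if (sid, chain) in present and resid in present[(sid, chain)]:
                        sites.append([renaming[(sid, chain)], resid])
            groups[str(pos)] = sites
        sidecar["tie_groups"] = groups
    path.with_suffix(path.suffix + ".ties.json").write_text(
        json.dumps(sidecar, indent=1)
    )
    return sidecar


def read_structure_state(path: str | Path, state_id: str) -> StructureState:
    """Read the CA trace of a (possibly CA-minimal) PDB file as one state."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(model=1)
    ca = array[array.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no CA atoms found")
    chains: dict[str, tuple[np.ndarray, list[str], np.ndarray]] = {}
    for cid in np.unique(ca.chain_id):
        sel = ca[ca.chain_id == cid]
        chains[str(cid)] = (
            sel.res_id.astype(int),
            [str(r) for r in sel.res_name],
            sel.coord.astype(float),
        )
    return StructureState(state_id, chains)


__all__ = [
    "CHAIN_IDS",
    "DEFAULT_R_MIN",
    "StructureState",
    "bounding_radius",
    "min_interstate_ca_distance",
    "place_states",
    "read_structure_state",
    "write_combined_pdb",
]
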