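"""Design problems, sequence individuals, and populations.

A multistate design problem fixes a set of *designable positions* in a
reference numbering, a set of structural *states*, and a *tie map* recording
where each designable position appears in each state (a position may occur in
several chain copies of one state — e.g. both protomers of a homodimer — or be
absent from a state altogether).  Candidate sequences are strings over the 20
standard amino acids, one letter per designable position; their quality is a
real objective vector in minimization framing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the 20 standard amino acids.  Every logit table,
#: count matrix and probability row in the package uses this column order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letter -> column index into :data:`AMINO_ACIDS`-ordered tables.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}


class ProblemValidationError(ValueError):
    """Raised when a design-problem definition is internally inconsistent."""


def seq_to_indices(residues: str) -> np.ndarray:
    """Encode a residue string as an int array of alphabet indices."""
    try:
        return np.array([AA_INDEX[a] for a in residues], dtype=np.intp)
    except KeyError as exc:  # non-standard residue
        raise ProblemValidationError(
            f"non-standard residue {exc.args[0]!r}; the alphabet is fixed "
            f"to the 20 standard amino acids"
        ) from None


def indices_to_seq(idx: Iterable[int]) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)


# (chain id, 1-based residue index within that chain)
ChainSite = tuple[str, int]


@dataclass(frozen=True)
class DesignProblem:
    """A validated multistate sequence design problem.

    Parameters
    ----------
    states
        Ordered state identifiers.
    designable_positions
        Reference-numbering residue indices (1-based, from the input PDB).
    tie_map
        ``state -> {position -> tuple of (chain, residue index)}``.  A
        position present in several chain copies of a state lists one site per
        copy; a position absent from a state is simply missing from that
        state's mapping.
    wt_sequence
        Wild-type residues at the designable positions, in order.
    objective_labels
        Names of the objective dimensions, in minimization framing.
    """

    states: tuple[str, ...]
    designable_positions: tuple[int, ...]
    tie_map: Mapping[str, Mapping[int, tuple[ChainSite, ...]]]
    wt_sequence: str
    objective_labels: tuple[str, ...] = ()

    @property
    def n_positions(self) -> int:
        return len(self.designable_positions)

    @property
    def n_objectives(self) -> int:
        return len(self.objective_labels)

    def state_mask(self, state: str) -> np.ndarray:
        """Boolean mask over designable positions present in ``state``."""
        present = self.tie_map[state]
        return np.array([p in present for p in self.designable_positions])

    def position_chain_counts(self) -> np.ndarray:
        """Number of tied chain copies per position, summed over states.

        This is the number of per-chain score vectors available at each
        position; its maximum bounds the per-position effective dimension of
        the problem (e.g. 16 for a 14-state problem with two dimeric states).
        """
        counts = np.zeros(self.n_positions, dtype=int)
        for i, p in enumerate(self.designable_positions):
            counts[i] = sum(
                len(self.tie_map[s].get(p, ())) for s in self.states
            )
        return counts


@dataclass
class SequenceIndividual:
    """A candidate sequence plus (optionally) its objective vector."""

    residues: str
    objectives: np.ndarray | None = None

    def copy(self) -> "SequenceIndividual":
        obj = None if self.objectives is None else self.objectives.copy()
        return SequenceIndividual(self.residues, obj)


@dataclass
class Population:
    members: list[SequenceIndividual] = field(default_factory=list)
    generation: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def residues(self) -> list[str]:
        return [m.residues for m in self.members]

    def objectives(self) -> np.ndarray:
        """Stack member objective vectors into an (n, d) array."""
        if any(m.objectives is None for m in self.members):
            raise ValueError("population contains unscored members")
        return np.stack([m.objectives for m in self.members])


def make_problem(
    states: Sequence[str],
    designable_positions: Sequence[int],
    tie_map: Mapping[str, Mapping[int, Sequence[ChainSite]]],
    wt_sequence: str,
    objective_labels: Sequence[str] = (),
) -> DesignProblem:
    """Validate and freeze a design-problem definition.

    Positions absent from a state are recorded as absent, not errors; but
    every designable position must appear in at least one state.
    """
    states = tuple(states)
    positions = tuple(int(p) for p in designable_positions)
    if len(set(positions)) != len(positions):
        raise ProblemValidationError("duplicate designable position")
    if len(wt_sequence) != len(positions):
        raise ProblemValidationError(
            f"wild-type sequence length {len(wt_sequence)} does not match "
            f"{len(positions)} designable positions"
        )
    seq_to_indices(wt_sequence)  # reject non-standard residues
    if len(set(states)) != len(states):
        raise ProblemValidationError("duplicate state identifier")
    unknown = set(tie_map) - set(states)
    if unknown:
        raise ProblemValidationError(f"tie map references unknown states {unknown}")
    frozen: dict[str, dict[int, tuple[ChainSite, ...]]] = {}
    for s in states:
        entries = tie_map.get(s, {})
        bad = set(entries) - set(positions)
        if bad:
            raise ProblemValidationError(
                f"state {s!r} ties non-designable positions {sorted(bad)}"
            )
        frozen[s] = {
            int(p): tuple((str(c), int(r)) for c, r in sites)
            for p, sites in entries.items()
        }
    covered = set().union(*(frozen[s].keys() for s in states)) if states else set()
    missing = set(positions) - covered
    if missing:
        raise ProblemValidationError(
            f"designable positions {sorted(missing)} absent from every state"
        )
    return DesignProblem(
        states=states,
        designable_positions=positions,
        tie_map=frozen,
        wt_sequence=wt_sequence,
        objective_labels=tuple(objective_labels),
    )


def randomize_population(
    problem: DesignProblem,
    size: int,
    seed: int | np.random.Generator,
) -> Population:
    """Fully randomized initial population: every position of every member is
    drawn i.i.d. uniformly from the 20-letter alphabet."""
    if size < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(AMINO_ACIDS), size=(size, problem.n_positions))
    members = [SequenceIndividual(indices_to_seq(row)) for row in draws]
    return Population(members=members, generation=0)


def reconstruct_state_sequence(
    problem: DesignProblem,
    individual: SequenceIndividual,
    state: str,
    template_sequences: Mapping[str, str],
) -> dict[str, str]:
    """Write a candidate's residues into a state's per-chain template strings.

    Designable positions present in ``state`` are overwritten in every tied
    chain copy; all other residues are untouched.  Chains' residue indices are
    1-based into the template strings.
    """
    if state not in problem.tie_map:
        raise KeyError(f"unknown state {state!r}")
    out = {c: list(seq) for c, seq in template_sequences.items()}
    entries = problem.tie_map[state]
    for i, pos in enumerate(problem.designable_positions):
        for chain, resid in entries.get(pos, ()):
            if chain not in out:
                raise KeyError(
                    f"tie map references chain {chain!r} missing from templates"
                )
            if not 1 <= resid <= len(out[chain]):
                raise IndexError(
                    f"tie map residue {resid} outside chain {chain!r} "
                    f"(length {len(out[chain])})"
                )
            out[chain][resid - 1] = individual.residues[i]
    return {c: "".join(seq) for c, seq in out.items()}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def problem_to_json(problem: DesignProblem) -> str:
    payload = {
        "states": list(problem.states),
        "designable_positions": list(problem.designable_positions),
        "tie_map": {
            s: {str(p): [list(site) for site in sites] for p, sites in m.items()}
            for s, m in problem.tie_map.items()
        },
        "wt_sequence": problem.wt_sequence,
        "objectives": list(problem.objective_labels),
    }
    return json.dumps(payload, indent=1)


def problem_from_json(text: str) -> DesignProblem:
    payload = json.loads(text)
    tie_map = {
        s: {int(p): [tuple(site) for site in sites] for p, sites in m.items()}
        for s, m in payload["tie_map"].items()
    }
    return make_problem(
        payload["states"],
        payload["designable_positions"],
        tie_map,
        payload["wt_sequence"],
        payload.get("objectives", ()),
    )


def population_to_fasta(pop: Population, labels: Sequence[str] = ()) -> str:
    """FASTA serialization; objectives go into the description line as
    semicolon-separated ``label=value`` pairs."""
    lines = []
    for i, m in enumerate(pop.members):
        desc = f"member_{i}"
        if m.objectives is not None:
            labs = labels or [f"obj{j}" for j in range(len(m.objectives))]
            desc += " " + ";".join(
                f"{l}={v:.6g}" for l, v in zip(labs, m.objectives)
            )
        lines.append(f">{desc}\n{m.residues}")
    return "\n".join(lines) + "\n"


def population_from_fasta(text: str) -> Population:
    from io import StringIO

    from Bio import SeqIO

    members = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        obj = None
        desc = rec.description.split(maxsplit=1)
        if len(desc) == 2 and "=" in desc[1]:
            obj = np.array(
                [float(kv.split("=")[1]) for kv in desc[1].split(";")]
            )
        members.append(SequenceIndividual(str(rec.seq), obj))
    return Population(members=members)


def population_to_frame(pop: Population, labels: Sequence[str] = ()) -> pd.DataFrame:
    """One row per member: generation, sequence, and objective columns."""
    rows: list[dict] = []
    for i, m in enumerate(pop.members):
        row: dict = {"member": i, "generation": pop.generation,
                     "sequence": m.residues}
        if m.objectives is not None:
            labs = labels or [f"obj{j}" for j in range(len(m.objectives))]
            row.update(dict(zip(labs, m.objectives)))
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "AMINO_ACIDS",
    "AA_INDEX",
    "ChainSite",
    "DesignProblem",
    "Population",
    "ProblemValidationError",
    "SequenceIndividual",
    "indices_to_seq",
    "make_problem",
    "population_from_fasta",
    "population_to_fasta",
    "population_to_frame",
    "problem_from_json",
    "problem_to_json",
    "randomize_population",
    "reconstruct_state_sequence",
    "seq_to_indices",
]
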