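"""Synthetic data generators.

Every fixture is generated from a (spec, seed) pair only — no file or
network dependency.  The central generator builds a two-state toy logit model
with a planted wild-type sequence and a controllable mix of position classes:

* ``non_conflicting`` — both states prefer the wild-type residue;
* ``conflicting`` — each state prefers a different non-wild-type residue and
  the wild type is the runner-up in *both* states, so only the multistate
  compromise (equal-weight averaged logits) makes the wild type the argmax;
* ``neutral`` — uniform logits, no signal.

With the default gaps the planted wild type is the argmax of the averaged
logits at every position, with a per-position averaged-softmax probability of
about 0.8 (non-conflicting) / 0.92 (conflicting) at decoding temperature 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from modesign.core import (
    AA_INDEX,
    AMINO_ACIDS,
    DesignProblem,
    indices_to_seq,
    make_problem,
)
from modesign.scoring import ScorerBundle, StateLogitModel

N_AA = len(AMINO_ACIDS)


@dataclass
class ToyProblemSpec:
    """Specification of the two-state toy design problem.

    ``n_conflicting + n_non_conflicting + n_neutral`` positions are laid out
    in a seeded random order.  ``base_gap`` is the wild-type logit margin at
    non-conflicting positions; at conflicting positions the wild type sits at
    ``conflict_base`` while each state's preferred (non-wild-type) residue
    sits ``conflict_gap`` above it.
    """

    n_non_conflicting: int = 24
    n_conflicting: int = 12
    n_neutral: int = 0
    base_gap: float = 1.3
    conflict_base: float = 2.4
    conflict_gap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_non_conflicting, self.n_conflicting, self.n_neutral) < 0:
            raise ValueError("position class counts must be non-negative")
        if self.n_positions < 1:
            raise ValueError("need at least one position")
        if self.base_gap <= 0 or self.conflict_gap <= 0 or self.conflict_base <= 0:
            raise ValueError("logit gaps must be positive")

    @property
    def n_positions(self) -> int:
        return self.n_non_conflicting + self.n_conflicting + self.n_neutral


def make_two_state_toy(
    spec: ToyProblemSpec = ToyProblemSpec(),
) -> tuple[DesignProblem, StateLogitModel]:
    """Build the planted-wild-type two-state problem and its logit model.

    At conflicting positions state A prefers one alternative residue and
    state B another, with the wild type the runner-up in both, so
    single-state decoding drifts away from the wild type while equal-weight
    averaged decoding recovers it.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positions
    classes = np.array(
        ["non_conflicting"] * spec.n_non_conflicting
        + ["conflicting"] * spec.n_conflicting
        + ["neutral"] * spec.n_neutral
    )
    rng.shuffle(classes)
    wt_idx = rng.integers(0, N_AA, size=n)
    W1 = np.zeros((n, N_AA))
    W2 = np.zeros((n, N_AA))
    for i, cls in enumerate(classes):
        w = wt_idx[i]
        if cls == "non_conflicting":
            W1[i, w] = W2[i, w] = spec.base_gap
        elif cls == "conflicting":
            alt = rng.choice([a for a in range(N_AA) if a != w], 2, replace=False)
            W1[i, w] = W2[i, w] = spec.conflict_base
            W1[i, alt[0]] = spec.conflict_base + spec.conflict_gap
            W2[i, alt[1]] = spec.conflict_base + spec.conflict_gap
        # neutral: all-zero row (uniform softmax)
    positions = tuple(range(1, n + 1))
    tie_map = {
        "stateA": {p: (("A", p),) for p in positions},
        "stateB": {p: (("A", p),) for p in positions},
    }
    problem = make_problem(
        states=("stateA", "stateB"),
        designable_positions=positions,
        tie_map=tie_map,
        wt_sequence=indices_to_seq(wt_idx),
        objective_labels=("nll[stateA]", "nll[stateB]"),
    )
    model = StateLogitModel(
        states=("stateA", "stateB"),
        tables={"stateA": W1, "stateB": W2},
    )
    return problem, model


def ranking_profile_from_model(
    model: StateLogitModel, weights: np.ndarray | None = None
) -> np.ndarray:
    """Equal-weight (or caller-weighted) state-averaged logit table, used as
    the surrogate ranking profile for position selection."""
    if weights is None:
        weights = np.ones(len(model.states))
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    return np.einsum(
        "s,spa->pa", weights, np.stack([model.tables[s] for s in model.states])
    )


# ---------------------------------------------------------------------------
# enumerable known-front problem
# ---------------------------------------------------------------------------

#: Restricted alphabet of the enumerable problem (first four canonical letters).
FRONT_ALPHABET = AMINO_ACIDS[:4]


@dataclass
class KnownFrontProblem:
    problem: DesignProblem
    bundle: ScorerBundle
    pareto_objectives: np.ndarray
    pareto_sequences: list[str]
    tables: tuple[np.ndarray, np.ndarray]


def known_front_problem(n_positions: int = 4, seed: int = 0) -> KnownFrontProblem:
    """Biobjective additive toy problem with an exhaustively enumerated
    Pareto set.

    Per-position objective contributions for the four front-alphabet letters
    are seeded random draws; the sixteen remaining letters are placed strictly
    worse than every front-alphabet letter in both objectives, so any
    sequence using them is dominated and the Pareto set over the full
    20-letter space equals the enumerated set over the 4-letter space
    (at most 4**n_positions candidates).
    """
    if not 1 <= n_positions <= 8:
        raise ValueError("n_positions must be in 1..8 for enumerability")
    rng = np.random.default_rng(seed)
    T1 = np.empty((n_positions, N_AA))
    T2 = np.empty((n_positions, N_AA))
    k = len(FRONT_ALPHABET)
    T1[:, :k] = rng.uniform(0.0, 1.0, size=(n_positions, k))
    T2[:, :k] = rng.uniform(0.0, 1.0, size=(n_positions, k))
    # strictly dominated letters: worse than any front letter in both objectives
    T1[:, k:] = T1[:, :k].max(axis=1, keepdims=True) + rng.uniform(
        0.5, 1.5, size=(n_positions, N_AA - k)
    )
    T2[:, k:] = T2[:, :k].max(axis=1, keepdims=True) + rng.uniform(
        0.5, 1.5, size=(n_positions, N_AA - k)
    )

    def additive_scorer(table: np.ndarray):
        def score(ind) -> float:
            return float(
                sum(table[i, AA_INDEX[a]] for i, a in enumerate(ind.residues))
            )

        return score

    bundle = ScorerBundle(
        labels=("f1", "f2"),
        scorers=(additive_scorer(T1), additive_scorer(T2)),
    )

    # exhaustive enumeration over the 4-letter space
    seqs, F = [], []
    for combo in product(range(k), repeat=n_positions):
        idx = np.array(combo)
        seqs.append(indices_to_seq(idx))
        F.append(
            [T1[np.arange(n_positions), idx].sum(),
             T2[np.arange(n_positions), idx].sum()]
        )
    F = np.array(F)
    # brute-force Pareto filter
    keep = []
    for i in range(len(F)):
        dominated = np.any(
            np.all(F <= F[i], axis=1) & np.any(F < F[i], axis=1)
        )
        if not dominated:
            keep.append(i)
    positions = tuple(range(1, n_positions + 1))
    wt = seqs[int(np.argmin(F.sum(axis=1)))]
    problem = make_problem(
        states=("f1", "f2"),
        designable_positions=positions,
        tie_map={
            "f1": {p: (("A", p),) for p in positions},
            "f2": {p: (("A", p),) for p in positions},
        },
        wt_sequence=wt,
        objective_labels=("f1", "f2"),
    )
    return KnownFrontProblem(
        problem=problem,
        bundle=bundle,
        pareto_objectives=F[keep],
        pareto_sequences=[seqs[i] for i in keep],
        tables=(T1, T2),
    )


# ---------------------------------------------------------------------------
# toy structures and reference sets
# ---------------------------------------------------------------------------

def make_toy_structures(
    n_states: int,
    n_residues_per_state: int,
    seed: int | np.random.Generator = 0,
    scale: float = 6.0,
) -> list:
    """Random compact CA clouds (isotropic Gaussian, ``scale`` Angstrom
    standard deviation) with sequential residue numbering."""
    from modesign.assembly import StructureState

    if n_states < 1 or n_residues_per_state < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    states = []
    for k in range(n_states):
        coords = rng.normal(0.0, scale, size=(n_residues_per_state, 3))
        resids = np.arange(1, n_residues_per_state + 1)
        names = ["ALA"] * n_residues_per_state
        states.append(
            StructureState(f"state{k}", {"A": (resids, names, coords)})
        )
    return states


def make_reference_sets(
    problem: DesignProblem,
    n_pos_set: int,
    n_neg_set: int,
    pos_substitution_rate: float = 0.1,
    neg_substitution_rate: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Labeled reference sequence sets, aligned to the design region and
    gap-free.

    The positive set is sampled around the planted wild type with i.i.d.
    substitutions at ``pos_substitution_rate``; the negative set is sampled
    the same way around a random decoy profile.
    """
    if n_pos_set < 1 or n_neg_set < 1:
        raise ValueError("set sizes must be >= 1")
    rng = np.random.default_rng(seed)
    n = problem.n_positions
    wt_idx = np.array([AA_INDEX[a] for a in problem.wt_sequence])
    decoy_idx = rng.integers(0, N_AA, size=n)

    def sample_around(center: np.ndarray, rate: float, count: int) -> list[str]:
        out = []
        for _ in range(count):
            idx = center.copy()
            mask = rng.random(n) < rate
            idx[mask] = rng.integers(0, N_AA, size=int(mask.sum()))
            out.append(indices_to_seq(idx))
        return out

    return (
        sample_around(wt_idx, pos_substitution_rate, n_pos_set),
        sample_around(decoy_idx, neg_substitution_rate, n_neg_set),
    )


__all__ = [
    "FRONT_ALPHABET",
    "KnownFrontProblem",
    "ToyProblemSpec",
    "known_front_problem",
    "make_reference_sets",
    "make_toy_structures",
    "make_two_state_toy",
    "ranking_profile_from_model",
]
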