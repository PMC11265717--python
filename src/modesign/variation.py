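"""Crossover operators and the composite mutation operator.

The mutation operator factorizes into a position-selection strategy (random
Bernoulli thinning, or ranking by per-position pseudo-likelihood and taking
the least native-like positions) and a proposal strategy (uniform resetting
over the 20 amino acids, or redesign from the weighted average of per-state
logits decoded in random order at a sampling temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax

from modesign.core import (
    AMINO_ACIDS,
    SequenceIndividual,
    indices_to_seq,
    seq_to_indices,
)
from modesign.scoring import StateLogitModel, per_position_rank_scores

N_AA = len(AMINO_ACIDS)


@dataclass
class MutationConfig:
    """Composite mutation operator settings.

    ``mutation_rate`` is the per-position redesign probability mu in (0, 1];
    ``temperature`` scales the averaged logits before sampling (0.3 by
    default, balancing recovery against diversity); ``state_weights`` are
    non-negative per-state weights, normalized to sum 1 before use (default:
    equal weight 1.0 per state).
    """

    mutation_rate: float = 0.3
    selection_mode: str = "random"        # random | ranked
    proposal_mode: str = "conditional"    # uniform | conditional
    temperature: float = 0.3
    state_weights: Mapping[str, float] | None = None
    n_crossover_points: int = 2
    p_crossover: float = 0.9
    p_mutation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.selection_mode not in ("random", "ranked"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        if self.proposal_mode not in ("uniform", "conditional"):
            raise ValueError(f"unknown proposal mode {self.proposal_mode!r}")

    def normalized_weights(self, states: Sequence[str]) -> np.ndarray:
        if self.state_weights is None:
            w = np.ones(len(states))
        else:
            w = np.array([float(self.state_weights[s]) for s in states])
        if (w < 0).any():
            raise ValueError("state weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("state weights sum to zero")
        return w / total


# ---------------------------------------------------------------------------
# crossover
# ---------------------------------------------------------------------------

def n_point_crossover(
    a: SequenceIndividual,
    b: SequenceIndividual,
    n: int,
    rng: int | np.random.Generator,
) -> tuple[SequenceIndividual, SequenceIndividual]:
    """Classic n-point crossover: n distinct cut points among the L-1
    junctions, alternating segments exchanged; offspring are complementary."""
    rng = np.random.default_rng(rng)
    L = len(a.residues)
    if len(b.residues) != L:
        raise ValueError("parents must have equal length")
    if not 1 <= n <= L - 1:
        raise ValueError(f"n={n} out of range for L={L}")
    cuts = np.sort(rng.choice(L - 1, size=n, replace=False)) + 1
    # origin[i] True -> offspring 1 takes position i from parent a
    origin = np.ones(L, bool)
    flip = True
    prev = 0
    for c in list(cuts) + [L]:
        origin[prev:c] = flip
        flip = not flip
        prev = c
    sa, sb = np.array(list(a.residues)), np.array(list(b.residues))
    c1 = np.where(origin, sa, sb)
    c2 = np.where(origin, sb, sa)
    return SequenceIndividual("".join(c1)), SequenceIndividual("".join(c2))


def uniform_crossover(
    a: SequenceIndividual,
    b: SequenceIndividual,
    rng: int | np.random.Generator,
) -> tuple[SequenceIndividual, SequenceIndividual]:
    """Per-position independent fair choice between parents; the second
    offspring is complementary."""
    rng = np.random.default_rng(rng)
    L = len(a.residues)
    if len(b.residues) != L:
        raise ValueError("parents must have equal length")
    origin = rng.random(L) < 0.5
    sa, sb = np.array(list(a.residues)), np.array(list(b.residues))
    c1 = np.where(origin, sa, sb)
    c2 = np.where(origin, sb, sa)
    return SequenceIndividual("".join(c1)), SequenceIndividual("".join(c2))


# ---------------------------------------------------------------------------
# position selection
# ---------------------------------------------------------------------------

def select_positions_random(
    n_positions: int,
    mu: float,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Bernoulli(mu) thinning over positions; if the draw is empty, one
    position is picked uniformly so the returned set is never empty."""
    rng = np.random.default_rng(rng)
    if n_positions < 1:
        raise ValueError("need at least one position")
    chosen = np.nonzero(rng.random(n_positions) < mu)[0]
    if chosen.size == 0:
        chosen = np.array([rng.integers(n_positions)])
    return chosen


def select_positions_ranked(
    scores: np.ndarray,
    mu: float,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Take the k lowest-scored positions, k = max(1, Binomial(n, mu)); ties
    broken by lower index (stable sort)."""
    rng = np.random.default_rng(rng)
    scores = np.asarray(scores, float)
    if scores.ndim != 1 or scores.size < 1:
        raise ValueError("scores must be a non-empty vector")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite position score")
    k = max(1, int(rng.binomial(scores.size, mu)))
    order = np.argsort(scores, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# residue proposal
# ---------------------------------------------------------------------------

def propose_uniform(
    individual: SequenceIndividual,
    positions: np.ndarray,
    rng: int | np.random.Generator,
) -> SequenceIndividual:
    """Resample the selected positions i.i.d. uniformly over the alphabet
    (self-substitution allowed); all other positions untouched."""
    rng = np.random.default_rng(rng)
    positions = np.asarray(positions, int)
    if positions.size == 0:
        raise ValueError("no positions selected")
    idx = seq_to_indices(individual.residues)
    idx[positions] = rng.integers(0, N_AA, size=positions.size)
    return SequenceIndividual(indices_to_seq(idx))


def averaged_position_logits(
    model: StateLogitModel,
    position: int,
    weights: np.ndarray,
    context: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted average of the per-state logits at one position.

    Weights are renormalized over the states in which the position is present;
    a position absent from every state is an error.
    """
    rows, ws = [], []
    for s, w in zip(model.states, weights):
        if model.masks[s][position]:
            rows.append(model.logits(s, position, context))
            ws.append(w)
    if not rows:
        raise ValueError(f"position {position} absent from every state")
    ws = np.asarray(ws)
    if ws.sum() <= 0:
        # all weight on absent states: fall back to unweighted average
        ws = np.ones(len(rows))
    ws = ws / ws.sum()
    return np.einsum("s,sa->a", ws, np.stack(rows))


def propose_conditional(
    individual: SequenceIndividual,
    positions: np.ndarray,
    model: StateLogitModel,
    config: MutationConfig,
    rng: int | np.random.Generator,
) -> SequenceIndividual:
    """Redesign the selected positions from the weighted state-averaged
    logits, decoding in a uniformly random order.

    At each step the averaged logits are conditioned on the current sequence
    context (a no-op for context-free tables), divided by the sampling
    temperature, softmax-normalized and sampled.  Unselected positions are
    untouched.
    """
    rng = np.random.default_rng(rng)
    positions = np.asarray(positions, int)
    if positions.size == 0:
        raise ValueError("no positions selected")
    weights = config.normalized_weights(model.states)
    idx = seq_to_indices(individual.residues)
    order = rng.permutation(positions)
    for pos in order:
        logits = averaged_position_logits(model, int(pos), weights, context=idx)
        p = softmax(logits / config.temperature)
        idx[pos] = rng.choice(N_AA, p=p)
    return SequenceIndividual(indices_to_seq(idx))


def decode_single_pass(
    n_sequences: int,
    model: StateLogitModel,
    config: MutationConfig,
    rng: int | np.random.Generator,
) -> list[SequenceIndividual]:
    """Single-pass averaged-logit decoding of full sequences (the
    multistate-design baseline: every position redesigned once, no selection
    loop).  Decoding starts from a uniformly random sequence so that with
    context-dependent models the initial context carries no information."""
    rng = np.random.default_rng(rng)
    n_pos = model.n_positions
    out = []
    for _ in range(n_sequences):
        start = SequenceIndividual(
            indices_to_seq(rng.integers(0, N_AA, size=n_pos))
        )
        out.append(
            propose_conditional(start, np.arange(n_pos), model, config, rng)
        )
    return out


# ---------------------------------------------------------------------------
# operator bundle
# ---------------------------------------------------------------------------

@dataclass
class VariationBundle:
    """Everything the generation loop needs to produce offspring: the
    mutation configuration, the logit model backing conditional proposals,
    and the ranking profile backing ranked position selection."""

    config: MutationConfig = field(default_factory=MutationConfig)
    model: StateLogitModel | None = None
    ranking_profile: np.ndarray | None = None

    def mutate(
        self,
        individual: SequenceIndividual,
        rng: np.random.Generator,
    ) -> SequenceIndividual:
        cfg = self.config
        n_pos = len(individual.residues)
        if cfg.selection_mode == "random":
            positions = select_positions_random(n_pos, cfg.mutation_rate, rng)
        else:
            if self.ranking_profile is None:
                raise ValueError("ranked selection requires a ranking profile")
            scores = per_position_rank_scores(individual, self.ranking_profile)
            positions = select_positions_ranked(scores, cfg.mutation_rate, rng)
        if cfg.proposal_mode == "uniform":
            return propose_uniform(individual, positions, rng)
        if self.model is None:
            raise ValueError("conditional proposal requires a logit model")
        return propose_conditional(individual, positions, self.model, cfg, rng)

    def crossover(
        self,
        a: SequenceIndividual,
        b: SequenceIndividual,
        rng: np.random.Generator,
    ) -> tuple[SequenceIndividual, SequenceIndividual]:
        return n_point_crossover(a, b, self.config.n_crossover_points, rng)


__all__ = [
    "MutationConfig",
    "VariationBundle",
    "averaged_position_logits",
    "decode_single_pass",
    "n_point_crossover",
    "propose_conditional",
    "propose_uniform",
    "select_positions_random",
    "select_positions_ranked",
    "uniform_crossover",
]
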