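"""Objective-function contracts and desk-scale surrogate scorers.

The package's scorers emulate the three families of objectives used in
model-guided multistate design — per-state inverse-folding log-likelihoods, a
bounded folding-propensity composite, and language-model-style per-position
pseudo-likelihoods — but are driven by explicit per-state, per-position,
per-residue logit tables (:class:`StateLogitModel`) instead of neural-network
inference.  This keeps every score a pure, closed-form function of
(sequence, table), so unit tests have exact oracles, while the
:class:`ScorerBundle` contract accepts any external adapter with the same
``SequenceIndividual -> float`` signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_softmax, softmax

from modesign.core import (
    AMINO_ACIDS,
    DesignProblem,
    SequenceIndividual,
    seq_to_indices,
)

N_AA = len(AMINO_ACIDS)


@dataclass
class StateLogitModel:
    """Per-state, per-position, per-residue score tables.

    ``tables[state]`` is an ``(n_positions, 20)`` array of raw logits (not
    temperature-scaled, not softmax-normalized).  ``masks[state]`` marks the
    designable positions present in that state.  By default logits do not
    depend on sequence context; optional pairwise couplings
    ``couplings[state][i, j, a, b]`` add a context term
    ``sum_j J[i, j, :, seq_j]`` for richer fixtures.  ``chain_copies`` records
    how many tied chain copies of each state carry the designable region
    (e.g. 2 for a homodimer), which bounds the number of per-chain score
    vectors available at a position.
    """

    states: tuple[str, ...]
    tables: Mapping[str, np.ndarray]
    masks: Mapping[str, np.ndarray] = field(default_factory=dict)
    couplings: Mapping[str, np.ndarray] = field(default_factory=dict)
    chain_copies: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.tables = {s: np.asarray(t, dtype=float) for s, t in self.tables.items()}
        for s in self.states:
            t = self.tables[s]
            if t.ndim != 2 or t.shape[1] != N_AA:
                raise ValueError(f"state {s!r}: table must be (n_positions, 20)")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"state {s!r}: non-finite logits")
        self.masks = {
            s: np.asarray(
                self.masks.get(s, np.ones(self.tables[s].shape[0], bool)), bool
            )
            for s in self.states
        }
        self.chain_copies = {s: int(self.chain_copies.get(s, 1)) for s in self.states}

    @property
    def n_positions(self) -> int:
        return self.tables[self.states[0]].shape[0]

    def logits(self, state: str, position: int, context: np.ndarray | None = None
               ) -> np.ndarray:
        """Raw logits at one position, conditioned on a sequence context
        (index-encoded) when the model carries pairwise couplings."""
        row = self.tables[state][position].copy()
        J = self.couplings.get(state)
        if J is not None and context is not None:
            for j, aj in enumerate(context):
                if j != position and aj >= 0:
                    row += J[position, j, :, aj]
        return row

    def position_chain_vectors(self, position: int) -> tuple[np.ndarray, list[str]]:
        """Stack one 20-vector per (state, chain copy) present at ``position``.

        Returns the ``(n_vectors, 20)`` array and matching labels; used by the
        per-position effective-dimension analysis.
        """
        vecs, labels = [], []
        for s in self.states:
            if self.masks[s][position]:
                for c in range(self.chain_copies[s]):
                    vecs.append(self.tables[s][position])
                    labels.append(f"{s}/chain{c}")
        if not vecs:
            raise ValueError(f"position {position} absent from every state")
        return np.stack(vecs), labels


def state_loglikelihood_score(
    individual: SequenceIndividual,
    model: StateLogitModel,
    state: str,
) -> float:
    """Negative mean log-likelihood of a sequence under one state's logits.

    The score is averaged over the state's unmasked positions and is
    temperature-independent (softmax of the raw logits).  Lower is better, so
    the value is used directly as a minimization objective.
    """
    idx = seq_to_indices(individual.residues)
    mask = model.masks[state]
    if not mask.any():
        raise ValueError(f"state {state!r} has no designable positions")
    positions = np.nonzero(mask)[0]
    total = 0.0
    for i in positions:
        row = model.logits(state, int(i), context=idx)
        total += log_softmax(row)[idx[i]]
    return -total / len(positions)


@dataclass(frozen=True)
class CompositeParams:
    """Logistic-squashing parameters for the folding-propensity surrogate.

    The real composite score is the product of three structure-prediction
    confidence factors (mean pLDDT scaled to [0, 1], pTM, and a
    template-vs-prediction TM-score).  The surrogate mirrors that product
    structure with three logistic squashings of the state's mean
    log-likelihood; ``midpoints`` are the scores mapping to 0.5 (so a sequence
    scoring at all three midpoints gets 0.5**3 = 0.125) and ``widths`` set the
    squashing scale.
    """

    midpoints: tuple[float, float, float] = (3.0, 3.0, 3.0)
    widths: tuple[float, float, float] = (0.5, 0.7, 1.0)


def composite_fold_score(
    individual: SequenceIndividual,
    model: StateLogitModel,
    state: str,
    params: CompositeParams = CompositeParams(),
) -> float:
    """Bounded [0, 1] folding-propensity surrogate; higher is better.

    A product of three logistic factors, each a monotone decreasing function
    of the state's negative mean log-likelihood, so any sequence strictly
    better under :func:`state_loglikelihood_score` scores at least as high.
    As an objective the value is negated (minimization framing), with the
    origin as the natural hypervolume reference point of the negated score.
    """
    nll = state_loglikelihood_score(individual, model, state)
    value = 1.0
    for m, w in zip(params.midpoints, params.widths):
        value *= 1.0 / (1.0 + np.exp((nll - m) / w))
    return float(value)


def per_position_rank_scores(
    individual: SequenceIndividual,
    profile: np.ndarray,
) -> np.ndarray:
    """Per-position log-probability of the current residue under a ranking
    profile (an ``(n_positions, 20)`` logit table, single pass, no masking).

    The mean of the returned vector is the sequence-level pseudo-likelihood
    score; positions with low values are the least native-like and are the
    ones a ranked mutation operator redesigns first.
    """
    profile = np.asarray(profile, float)
    idx = seq_to_indices(individual.residues)
    if profile.shape[0] != idx.size:
        raise ValueError("profile does not cover all designable positions")
    logp = log_softmax(profile, axis=1)
    return logp[np.arange(idx.size), idx]


def mean_rank_score(individual: SequenceIndividual, profile: np.ndarray) -> float:
    return float(per_position_rank_scores(individual, profile).mean())


@dataclass
class ScorerBundle:
    """Ordered objective scorers, each mapping an individual to a real value
    in minimization framing."""

    labels: tuple[str, ...]
    scorers: tuple[Callable[[SequenceIndividual], float], ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.scorers = tuple(self.scorers)
        if len(self.labels) != len(self.scorers):
            raise ValueError("labels and scorers must align")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("scorer labels must be unique")

    def __len__(self) -> int:
        return len(self.scorers)


def assemble_objectives(
    individual: SequenceIndividual,
    bundle: ScorerBundle,
) -> np.ndarray:
    """Evaluate every scorer in the bundle; errors name the offending scorer."""
    if len(bundle) == 0:
        raise ValueError("empty scorer bundle")
    values = np.empty(len(bundle))
    for k, (label, scorer) in enumerate(zip(bundle.labels, bundle.scorers)):
        v = float(scorer(individual))
        if not np.isfinite(v):
            raise ValueError(f"scorer {label!r} returned non-finite value {v}")
        values[k] = v
    return values


def loglikelihood_bundle(model: StateLogitModel) -> ScorerBundle:
    """One negative-log-likelihood objective per state (minimization)."""
    return ScorerBundle(
        labels=tuple(f"nll[{s}]" for s in model.states),
        scorers=tuple(
            (lambda ind, s=s: state_loglikelihood_score(ind, model, s))
            for s in model.states
        ),
    )


def composite_bundle(
    model: StateLogitModel,
    params: CompositeParams = CompositeParams(),
) -> ScorerBundle:
    """One negated composite folding-propensity objective per state."""
    return ScorerBundle(
        labels=tuple(f"-composite[{s}]" for s in model.states),
        scorers=tuple(
            (lambda ind, s=s: -composite_fold_score(ind, model, s, params))
            for s in model.states
        ),
    )


def with_rank_objective(bundle: ScorerBundle, profile: np.ndarray) -> ScorerBundle:
    """Append the negated mean pseudo-likelihood as an extra objective."""
    return ScorerBundle(
        labels=bundle.labels + ("-mean_rank_score",),
        scorers=bundle.scorers + ((lambda ind: -mean_rank_score(ind, profile)),),
    )


def state_weight_sweep(
    position: int,
    model: StateLogitModel,
    temperature: float,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Residue probabilities at one position as a function of the relative
    weight of the first state of a two-state model.

    For each relative weight ``w`` the decoded distribution is
    ``softmax((w * W_1[i] + (1 - w) * W_2[i]) / T)``; rows sum to 1.
    """
    if len(model.states) != 2:
        raise ValueError("state-weight sweep requires a two-state model")
    s1, s2 = model.states
    rows = []
    for w in grid:
        mixed = w * model.tables[s1][position] + (1 - w) * model.tables[s2][position]
        rows.append(softmax(mixed / temperature))
    return pd.DataFrame(rows, index=list(grid), columns=list(AMINO_ACIDS))


# ---------------------------------------------------------------------------
# logit-table I/O
# ---------------------------------------------------------------------------

def logit_table_to_csv(table: np.ndarray, positions: Sequence[int]) -> str:
    """CSV text: rows = designable positions, columns = the 20 residues."""
    df = pd.DataFrame(table, index=list(positions), columns=list(AMINO_ACIDS))
    df.index.name = "position"
    return df.to_csv()


def logit_table_from_csv(text: str) -> tuple[np.ndarray, list[int]]:
    from io import StringIO

    df = pd.read_csv(StringIO(text), index_col=0)
    if list(df.columns) != list(AMINO_ACIDS):
        raise ValueError("logit CSV columns must be the 20 residues in "
                         "canonical order")
    return df.to_numpy(float), [int(i) for i in df.index]


def model_from_problem(
    problem: DesignProblem,
    tables: Mapping[str, np.ndarray],
    couplings: Mapping[str, np.ndarray] | None = None,
) -> StateLogitModel:
    """Build a logit model whose masks and chain multiplicities follow a
    problem's tie map."""
    masks = {s: problem.state_mask(s) for s in problem.states}
    copies = {}
    for s in problem.states:
        sites = problem.tie_map[s]
        copies[s] = max((len(v) for v in sites.values()), default=1)
    return StateLogitModel(
        states=problem.states,
        tables=dict(tables),
        masks=masks,
        couplings=dict(couplings or {}),
        chain_copies=copies,
    )


__all__ = [
    "CompositeParams",
    "ScorerBundle",
    "StateLogitModel",
    "assemble_objectives",
    "composite_bundle",
    "composite_fold_score",
    "loglikelihood_bundle",
    "logit_table_from_csv",
    "logit_table_to_csv",
    "mean_rank_score",
    "model_from_problem",
    "per_position_rank_scores",
    "state_loglikelihood_score",
    "state_weight_sweep",
    "with_rank_objective",
]
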