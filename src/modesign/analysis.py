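"""Sequence-population and objective-space diagnostics.

Covers native recovery, per-position entropy, BLOSUM62 similarity and its
spectral embedding, exact and Monte-Carlo hypervolume, post hoc
non-dominated-sorting baselines, percentile similarity to reference sequence
sets, net charge, consensus selection, objective-space effective
dimensionality, per-position logit-correlation effective dimension, and the
interface double-difference energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from modesign.core import AMINO_ACIDS, DesignProblem, Population
from modesign.engine import non_dominated_sort

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# recovery, entropy, charge, consensus
# ---------------------------------------------------------------------------

def native_recovery(
    pop: Population, problem: DesignProblem
) -> tuple[np.ndarray, float]:
    """Per-member fraction of designable positions identical to the wild
    type, and the population mean."""
    wt = np.array(list(problem.wt_sequence))
    fracs = []
    for m in pop.members:
        if len(m.residues) != len(wt):
            raise ValueError("sequence length does not match the problem")
        fracs.append(float((np.array(list(m.residues)) == wt).mean()))
    fracs = np.array(fracs)
    return fracs, float(fracs.mean())


def per_position_recovery(pop: Population, problem: DesignProblem) -> np.ndarray:
    """Fraction of the population carrying the wild-type residue, per
    position."""
    wt = np.array(list(problem.wt_sequence))
    mat = np.array([list(m.residues) for m in pop.members])
    return (mat == wt).mean(axis=0)


def position_count_matrix(sequences: Sequence[str]) -> np.ndarray:
    """(n_positions, 20) letter counts in canonical alphabet order — the
    count matrix consumed by standard sequence-logo tools."""
    if len(sequences) == 0:
        raise ValueError("empty sequence set")
    mat = np.array([list(s) for s in sequences])
    counts = np.stack(
        [(mat == a).sum(axis=0) for a in AMINO_ACIDS], axis=1
    )
    return counts.astype(int)


def per_position_entropy(sequences: Sequence[str]) -> np.ndarray:
    """Shannon entropy (nats) of the empirical letter distribution at each
    position; bounded by ln 20."""
    counts = position_count_matrix(sequences)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    return -terms.sum(axis=1)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF as (sorted values, cumulative probabilities ending at
    1); right-continuous step function."""
    v = np.sort(np.asarray(values, float))
    p = np.arange(1, v.size + 1) / v.size
    return v, p


def net_charge_count(residues: str) -> int:
    """Number of K and R minus the number of D and E over the designable
    positions."""
    return sum(residues.count(a) for a in "KR") - sum(
        residues.count(a) for a in "DE"
    )


def representative_sequence(
    pop: Population, mode: str = "nearest_to_consensus"
) -> str:
    """Consensus (per-position modal letter, alphabetical ties) or the
    population member with the highest identity to the consensus
    (ties by population index)."""
    if len(pop) == 0:
        raise ValueError("empty population")
    counts = position_count_matrix(pop.residues())
    consensus = "".join(AMINO_ACIDS[i] for i in counts.argmax(axis=1))
    if mode == "consensus":
        return consensus
    if mode != "nearest_to_consensus":
        raise ValueError(f"unknown mode {mode!r}")
    cons = np.array(list(consensus))
    idents = [
        (np.array(list(m.residues)) == cons).mean() for m in pop.members
    ]
    return pop.members[int(np.argmax(idents))].residues


# ---------------------------------------------------------------------------
# similarity and embedding
# ---------------------------------------------------------------------------

def raw_similarity(a: str, b: str) -> float:
    """Mean per-position BLOSUM62 score between two aligned sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    try:
        return float(np.mean([_BLOSUM62[x, y] for x, y in zip(a, b)]))
    except IndexError:
        raise ValueError("letter outside the substitution matrix") from None


def normalized_similarity(a: str, b: str) -> float:
    """BLOSUM62 similarity normalized by the geometric mean of the two
    self-similarities, so that ``normalized_similarity(a, a) == 1`` and the
    measure is symmetric."""
    return raw_similarity(a, b) / np.sqrt(
        raw_similarity(a, a) * raw_similarity(b, b)
    )


def similarity_matrix(
    sequences: Sequence[str], normalized: bool = True
) -> np.ndarray:
    """Symmetric pairwise (normalized) BLOSUM62 similarity matrix."""
    # vectorized: encode sequences as indices into the BLOSUM62 submatrix
    idx = np.array([[AMINO_ACIDS.index(c) for c in s] for s in sequences])
    sub = np.array(
        [[_BLOSUM62[x, y] for y in AMINO_ACIDS] for x in AMINO_ACIDS]
    )
    n = len(sequences)
    S = np.empty((n, n))
    for i in range(n):
        S[i] = sub[idx[i][None, :], idx].mean(axis=1)
    S = (S + S.T) / 2.0
    if normalized:
        self_sim = np.sqrt(np.diag(S))
        S = S / np.outer(self_sim, self_sim)
    return S


def spectral_embedding(
    matrix: np.ndarray,
    n_components: int = 2,
    floor: float = 1e-6,
) -> np.ndarray:
    """Laplacian-eigenmaps coordinates from a precomputed affinity matrix.

    The similarity matrix is shifted by its global minimum plus a small
    positive floor so all edge weights are positive (a monotone transform of
    the affinities); the graph must be connected.
    """
    S = np.asarray(matrix, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("affinity matrix must be square")
    if np.abs(S - S.T).max() > 1e-9:
        raise ValueError("affinity matrix must be symmetric")
    A = S - S.min() + floor
    np.fill_diagonal(A, 0.0)
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components((A > 0).astype(int), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph disconnected: {n_comp} components with sizes "
            f"{sizes.tolist()}"
        )
    from sklearn.manifold import SpectralEmbedding

    emb = SpectralEmbedding(
        n_components=n_components, affinity="precomputed", random_state=0
    )
    return emb.fit_transform(A + np.eye(len(A)) * 0.0)


# ---------------------------------------------------------------------------
# hypervolume
# ---------------------------------------------------------------------------

@dataclass
class HypervolumeSpec:
    """Reference point and computation mode for hypervolume.

    ``exact`` uses dimension-recursive slicing (practical up to ~8
    objectives); ``monte_carlo`` samples the bounding orthant with a sample
    size chosen from a Bernoulli concentration bound so the relative error is
    at most ``epsilon`` with probability at least ``1 - delta``.
    """

    reference: np.ndarray
    mode: str = "exact"
    epsilon: float = 0.1
    delta: float = 0.05

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float)
        if self.mode not in ("exact", "monte_carlo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.epsilon <= 0 or not 0 < self.delta < 1:
            raise ValueError("need epsilon > 0 and delta in (0, 1)")


def _filter_contributing(points: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Keep points strictly dominating the reference point; others contribute
    zero volume."""
    P = np.asarray(points, float).reshape(-1, ref.size)
    return P[np.all(P < ref, axis=1)]


def hypervolume_exact(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact dominated hypervolume by recursive slicing along the last
    objective (minimization; the dominated region of p is the box [p, ref])."""
    ref = np.asarray(ref, float)
    P = _filter_contributing(points, ref)
    if P.shape[0] == 0:
        return 0.0
    return _hv_recurse(P, ref)


def _hv_recurse(P: np.ndarray, ref: np.ndarray) -> float:
    d = ref.size
    if d == 1:
        return float(ref[0] - P[:, 0].min())
    if d == 2:
        # sweep in x; the dominated area is a staircase
        order = np.lexsort((P[:, 1], P[:, 0]))
        area = 0.0
        best_y = ref[1]
        for i in order:
            x, y = P[i]
            if y < best_y:
                area += (ref[0] - x) * (best_y - y)
                best_y = y
        return float(area)
    zs = np.unique(P[:, -1])
    bounds = np.append(zs, ref[-1])
    total = 0.0
    for k, z in enumerate(zs):
        width = bounds[k + 1] - bounds[k]
        if width <= 0:
            continue
        slab = P[P[:, -1] <= z][:, :-1]
        total += _hv_recurse(slab, ref[:-1]) * width
    return float(total)


def hypervolume_monte_carlo(
    points: np.ndarray,
    ref: np.ndarray,
    epsilon: float = 0.1,
    delta: float = 0.05,
    rng: int | np.random.Generator = 0,
    pilot: int = 2000,
) -> float:
    """(epsilon, delta) multiplicative-error Monte-Carlo hypervolume.

    Uniform rejection sampling in the box [componentwise min of the points,
    reference].  A pilot estimate of the dominated fraction p sizes the main
    sample via the Chernoff bound ``n >= 3 ln(2/delta) / (epsilon^2 p)``
    (with a conservative lower confidence bound for p); the final estimate
    pools pilot and main samples.
    """
    rng = np.random.default_rng(rng)
    ref = np.asarray(ref, float)
    P = _filter_contributing(points, ref)
    if P.shape[0] == 0:
        return 0.0
    lo = P.min(axis=0)
    box_vol = float(np.prod(ref - lo))

    def dominated_count(n: int, chunk: int = 1_000_000) -> int:
        total = 0
        left = n
        while left > 0:
            m = min(left, chunk)
            X = rng.uniform(lo, ref, size=(m, ref.size))
            hit = np.zeros(m, dtype=bool)
            for p in P:
                hit |= np.all(X >= p, axis=1)
            total += int(hit.sum())
            left -= m
        return total

    n0 = pilot
    hits = dominated_count(n0)
    while hits == 0 and n0 < 10_000_000:
        extra = n0
        hits += dominated_count(extra)
        n0 += extra
    p_hat = max(hits / n0, 1e-12)
    # one-sided lower confidence bound on p at level delta/2
    p_lo = max(p_hat - np.sqrt(np.log(4 / delta) / (2 * n0)), p_hat / 2)
    n_main = int(np.ceil(3.0 * np.log(2.0 / delta) / (epsilon**2 * p_lo)))
    n_main = min(max(n_main - n0, 0), 20_000_000)
    if n_main > 0:
        hits += dominated_count(n_main)
    return box_vol * hits / (n0 + n_main)


def hypervolume(
    points: np.ndarray,
    spec: HypervolumeSpec,
    rng: int | np.random.Generator = 0,
) -> float:
    """Dominated hypervolume of a point set w.r.t. a reference point; an
    empty point set has hypervolume 0."""
    points = np.asarray(points, float)
    if points.size == 0:
        return 0.0
    if spec.mode == "exact":
        if spec.reference.size > 8:
            raise ValueError(
                "exact mode is limited to <= 8 objectives; use monte_carlo"
            )
        return hypervolume_exact(points, spec.reference)
    return hypervolume_monte_carlo(
        points, spec.reference, spec.epsilon, spec.delta, rng
    )


# ---------------------------------------------------------------------------
# post hoc sorting baseline
# ---------------------------------------------------------------------------

@dataclass
class PosthocBaseline:
    front_indices: list[int]
    front_entropies: np.ndarray
    baseline_entropies: np.ndarray


def posthoc_front_baseline(
    sequences: Sequence[str],
    objectives: np.ndarray,
    n_resamples: int = 100,
    rng: int | np.random.Generator = 0,
) -> PosthocBaseline:
    """Entropy of the post hoc non-dominated subset of a scored population,
    against pooled entropies of equally-sized random subsamples (without
    replacement, repeated ``n_resamples`` times)."""
    rng = np.random.default_rng(rng)
    front = non_dominated_sort(np.asarray(objectives, float)).fronts[0]
    front_seqs = [sequences[i] for i in front]
    front_H = per_position_entropy(front_seqs)
    pooled = []
    n = len(sequences)
    for _ in range(n_resamples):
        pick = rng.choice(n, size=len(front), replace=False)
        pooled.append(per_position_entropy([sequences[i] for i in pick]))
    return PosthocBaseline(
        front_indices=list(front),
        front_entropies=front_H,
        baseline_entropies=np.concatenate(pooled),
    )


# ---------------------------------------------------------------------------
# reference-set comparison
# ---------------------------------------------------------------------------

def percentile_similarity_to_set(
    query: str,
    refs: Sequence[str],
    q: float = 95.0,
) -> float:
    """q-th percentile (linear interpolation) of normalized BLOSUM62
    similarity between a query and each sequence of a gap-free, pre-aligned
    reference set."""
    if len(refs) == 0:
        raise ValueError("empty reference set")
    sims = np.array([normalized_similarity(query, r) for r in refs])
    return float(np.percentile(sims, q, method="linear"))


# ---------------------------------------------------------------------------
# effective dimensionality
# ---------------------------------------------------------------------------

def effective_dimension_pca(
    points: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Explained-variance ratios and the number of principal components with
    eigenvalues above the largest consecutive spectral gap."""
    X = np.asarray(points, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(X, X.mean(axis=0)):
        return np.zeros(min(X.shape)), 0
    from sklearn.decomposition import PCA

    pca = PCA()
    pca.fit(X)
    eig = pca.explained_variance_
    if eig.sum() <= 0 or not np.any(eig > 0):
        return np.zeros_like(eig), 0
    ratios = eig / eig.sum()
    gaps = eig[:-1] - eig[1:]
    if gaps.size == 0:
        return ratios, 1
    return ratios, int(np.argmax(gaps)) + 1


def logit_effective_dimension(
    vectors: np.ndarray,
    threshold: float = 0.8,
    labels: Sequence[str] | None = None,
) -> int:
    """Cluster count from single-linkage clustering of the Pearson
    correlation matrix over per-chain logit vectors at one position.

    Clusters merge while the maximum inter-cluster correlation is at least
    ``threshold`` (equivalently: single linkage on distance ``1 - r`` cut at
    ``1 - threshold``).
    """
    V = np.asarray(vectors, float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need at least 2 logit vectors")
    stds = V.std(axis=1)
    if np.any(stds == 0):
        k = int(np.nonzero(stds == 0)[0][0])
        name = labels[k] if labels is not None else f"vector {k}"
        raise ValueError(f"constant logit vector ({name}): correlation undefined")
    corr = np.corrcoef(V)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="single")
    clusters = fcluster(Z, t=1.0 - threshold, criterion="distance")
    return int(clusters.max())


# ---------------------------------------------------------------------------
# interface energetics
# ---------------------------------------------------------------------------

def interface_ddE(
    energy: Callable[[object], float],
    complex_mut: object,
    parts_mut: Sequence[object],
    complex_wt: object,
    parts_wt: Sequence[object],
) -> float:
    """Interface double-difference energy

    ``ddE = (E_mut[C:P] - E_mut[C] - E_mut[P]) - (E_wt[C:P] - E_wt[C] - E_wt[P])``

    against a pluggable energy function (e.g. a full potential or an
    electrostatics-only variant).  Energy failures propagate with the input's
    label.
    """

    def _e(label: str, x: object) -> float:
        try:
            return float(energy(x))
        except Exception as exc:
            raise RuntimeError(f"energy evaluation failed on {label}: {exc}")

    e_mut = _e("complex_mut", complex_mut) - sum(
        _e(f"parts_mut[{i}]", p) for i, p in enumerate(parts_mut)
    )
    e_wt = _e("complex_wt", complex_wt) - sum(
        _e(f"parts_wt[{i}]", p) for i, p in enumerate(parts_wt)
    )
    return e_mut - e_wt


__all__ = [
    "HypervolumeSpec",
    "PosthocBaseline",
    "ecdf",
    "effective_dimension_pca",
    "hypervolume",
    "hypervolume_exact",
    "hypervolume_monte_carlo",
    "interface_ddE",
    "logit_effective_dimension",
    "native_recovery",
    "net_charge_count",
    "normalized_similarity",
    "per_position_entropy",
    "per_position_recovery",
    "percentile_similarity_to_set",
    "position_count_matrix",
    "posthoc_front_baseline",
    "raw_similarity",
    "representative_sequence",
    "similarity_matrix",
    "spectral_embedding",
]
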