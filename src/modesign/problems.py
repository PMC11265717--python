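"""Shipped multistate design-problem definitions.

Three benchmark problems are defined here with their real state/chain
topology and designable-position lists:

* **RfaH** — the fold-switching transcription factor whose C-terminal domain
  interconverts between an all-alpha state (packed against the N-terminal
  domain) and a dissociated all-beta state; designable positions are CTD
  residues 119-154 (two states, one chain each).
* **PapD** — the P pilus chaperone, whose multi-specific interface is
  redesigned against three binding states: PapD-PapE, PapD-PapK, and the PapD
  homodimer (designable positions tied across both protomers of the dimer).
* **CaM** — calmodulin across 14 conformational/binding states; designable
  positions are residues 6-145 excluding the 16 Ca2+-coordinating residues.
  Two of the 14 states contain two CaM copies (the domain-swapped
  CaM2:calcineurin2 complex 2F2P and the 2:2 CaM:SK2-CaMBD complex 1G4Y), so
  up to 16 tied chain copies carry a designable position.

The wild-type residue identities are SYNTHETIC placeholders (seeded random
sequences): the topology and position lists are the real benchmark
definitions, but the native sequences are not bundled.  Dimensionality-type
analyses (objective-vector length, per-position chain-copy counts) depend
only on the topology.
"""

from __future__ import annotations

import numpy as np

from modesign.core import DesignProblem, indices_to_seq, make_problem

_WT_SEED = 20240101  # synthetic placeholder wild types only


def _synthetic_wt(n: int, salt: int) -> str:
    rng = np.random.default_rng(_WT_SEED + salt)
    return indices_to_seq(rng.integers(0, 20, size=n))


def rfah_problem() -> DesignProblem:
    """Two-state RfaH problem: CTD residues 119-154 designable, tied across
    the alpha-state and beta-state structures (one chain each).  Wild-type
    residues are a synthetic placeholder."""
    positions = tuple(range(119, 155))
    tie_map = {
        "rfah_alpha": {p: (("A", p - 118),) for p in positions},
        "rfah_beta": {p: (("A", p - 118),) for p in positions},
    }
    return make_problem(
        states=("rfah_alpha", "rfah_beta"),
        designable_positions=positions,
        tie_map=tie_map,
        wt_sequence=_synthetic_wt(len(positions), 1),
        objective_labels=("nll[rfah_alpha]", "nll[rfah_beta]"),
    )


#: PapD interface designable positions.
PAPD_POSITIONS: tuple[int, ...] = (
    1, 3, 4, 5, 6, 7, 8, 31, 91, 104, 105, 106, 107, 108, 109, 110, 112,
    152, 154, 163, 164, 166, 170, 194, 200,
)


def papd_problem() -> DesignProblem:
    """Three-state PapD interface problem (PapD-PapE, PapD-PapK, PapD
    homodimer); in the homodimer state each designable position is tied
    across both protomers.  Wild-type residues are a synthetic placeholder."""
    positions = PAPD_POSITIONS
    sites = {p: i + 1 for i, p in enumerate(positions)}
    tie_map = {
        "papd_pape": {p: (("A", sites[p]),) for p in positions},
        "papd_papk": {p: (("A", sites[p]),) for p in positions},
        "papd_papd": {p: (("A", sites[p]), ("B", sites[p])) for p in positions},
    }
    return make_problem(
        states=("papd_pape", "papd_papk", "papd_papd"),
        designable_positions=positions,
        tie_map=tie_map,
        wt_sequence=_synthetic_wt(len(positions), 2),
        objective_labels=(
            "nll[papd_pape]", "nll[papd_papk]", "nll[papd_papd]",
        ),
    )


#: The 14 CaM states by PDB id of the underlying structure; the two dimeric
#: states carry two CaM copies each.
CAM_STATES: tuple[str, ...] = (
    "1CFD", "1CFF", "1CKK", "1CLL", "1CM1", "1G4Y", "1NIW",
    "1NWD", "2F2P", "2N8J", "2WEL", "3EWT", "3EWV", "4DJC",
)
CAM_DIMER_STATES: frozenset[str] = frozenset({"2F2P", "1G4Y"})

#: Ca2+-coordinating residues excluded from design.
CAM_EXCLUDED: tuple[int, ...] = (
    20, 22, 24, 31, 56, 58, 60, 67, 93, 95, 97, 104, 129, 131, 133, 140,
)


def cam_problem() -> DesignProblem:
    """Fourteen-state CaM problem: residues 6-145 designable except the 16
    Ca2+-binding residues; dimeric states tie each position across both CaM
    copies (up to 16 chain copies per position).  Wild-type residues are a
    synthetic placeholder."""
    positions = tuple(
        p for p in range(6, 146) if p not in set(CAM_EXCLUDED)
    )
    sites = {p: i + 1 for i, p in enumerate(positions)}
    tie_map: dict[str, dict[int, tuple]] = {}
    for s in CAM_STATES:
        if s in CAM_DIMER_STATES:
            tie_map[s] = {
                p: (("A", sites[p]), ("B", sites[p])) for p in positions
            }
        else:
            tie_map[s] = {p: (("A", sites[p]),) for p in positions}
    return make_problem(
        states=CAM_STATES,
        designable_positions=positions,
        tie_map=tie_map,
        wt_sequence=_synthetic_wt(len(positions), 3),
        objective_labels=tuple(f"nll[{s}]" for s in CAM_STATES),
    )


__all__ = [
    "CAM_DIMER_STATES",
    "CAM_EXCLUDED",
    "CAM_STATES",
    "PAPD_POSITIONS",
    "cam_problem",
    "papd_problem",
    "rfah_problem",
]
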