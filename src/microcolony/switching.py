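"""Stochastic state-switching test.

Each root-to-leaf lineage path is binarized against the global ATP threshold
into a HIGH/LOW symbol sequence, a 2-state HMM is fitted to the pooled
sequences by Baum-Welch, and each transition probability is compared with a
shuffle null: every sequence's symbols are permuted in time (destroying
temporal order, preserving per-sequence symbol counts), the HMM is refitted,
and the observed edge is called *significantly small* below the null 5th
percentile or *significantly large* above the 95th percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _hmm
from .lineage import HIGH, LOW, BinaryClassification, LineageTree

__all__ = [
    "StateSequence",
    "HMMFitResult",
    "binarize_lineages",
    "baum_welch_fit",
    "transition_randomization_test",
    "SIG_LARGE",
    "SIG_SMALL",
    "NOT_SIG",
]

SIG_LARGE = "significantly_large"
SIG_SMALL = "significantly_small"
NOT_SIG = "not_significant"

STATE_NAMES = (LOW, HIGH)  # canonical order: state 0 = LOW, state 1 = HIGH


@dataclass
class StateSequence:
    """Binary HIGH/LOW symbol sequence along one root-to-leaf lineage path."""

    lineage_id: str
    states: list[str]

    def to_ints(self) -> np.ndarray:
        return np.array([1 if s == HIGH else 0 for s in self.states], dtype=np.int8)


@dataclass
class HMMFitResult:
    """Canonically ordered 2-state HMM parameters plus shuffle-null verdicts."""

    transition: np.ndarray          # 2x2 row-stochastic, states (LOW, HIGH)
    emission: np.ndarray            # 2x2, columns (LOW, HIGH) symbols
    initial: np.ndarray             # length 2
    log_likelihood: float
    edge_significance: dict = field(default_factory=dict)
    null_p5: np.ndarray | None = None
    null_p95: np.ndarray | None = None
    n_shuffles: int = 0

    def edge_table(self):
        """Rows (edge, observed, p5, p95, verdict) for reporting."""
        rows = []
        for i, si in enumerate(STATE_NAMES):
            for j, sj in enumerate(STATE_NAMES):
                rows.append(
                    {
                        "edge": f"{si}->{sj}",
                        "observed": float(self.transition[i, j]),
                        "p5": None if self.null_p5 is None else float(self.null_p5[i, j]),
                        "p95": None if self.null_p95 is None else float(self.null_p95[i, j]),
                        "verdict": self.edge_significance.get((si, sj), ""),
                    }
                )
        return rows


class NoSequencesError(ValueError):
    """Tree yields no usable state sequences."""


def binarize_lineages(
    tree: LineageTree, classification: BinaryClassification
) -> list[StateSequence]:
    """One HIGH/LOW sequence per root-to-leaf path, placeholders skipped.

    Sequences shorter than 2 symbols carry no transition information and are
    dropped with a warning.
    """
    if not tree.cells:
        raise NoSequencesError("empty tree")
    sequences = []
    n_dropped = 0
    for path in tree.root_to_leaf_paths():
        symbols: list[str] = []
        for cid in path:
            for o in tree.cells[cid].observations:
                if o.placeholder:
                    continue
                cls = classification.per_observation_class.get((cid, o.frame))
                if cls is None:
                    raise ValueError(
                        f"classification missing for cell {cid} frame {o.frame}"
                    )
                symbols.append(cls)
        if len(symbols) >= 2:
            sequences.append(StateSequence(lineage_id=path[-1], states=symbols))
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} sequences shorter than 2 symbols",
                      stacklevel=2)
    if not sequences:
        raise NoSequencesError("no sequences of length >= 2")
    return sequences


def _check_degenerate(seqs_int: list[np.ndarray]) -> None:
    allsym = np.concatenate(seqs_int)
    if np.all(allsym == allsym[0]):
        warnings.warn(
            "all symbols identical: transition row for the unvisited state "
            "is unidentifiable",
            stacklevel=3,
        )


def baum_welch_fit(
    sequences: list[StateSequence],
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    n_restarts: int = 5,
) -> HMMFitResult:
    """Fit one pooled 2-state HMM by Baum-Welch (best of random restarts).

    States are canonically ordered by their HIGH-emission probability
    (state 0 = LOW-emitting, state 1 = HIGH-emitting) so that transition
    entries are comparable across fits and against the shuffle null.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    seqs_int = [s.to_ints() for s in sequences]
    _check_degenerate(seqs_int)
    obs, mask = _hmm.pack_sequences(seqs_int)
    A, B, pi, ll = _hmm.fit_best_of_restarts(
        obs[None], mask, np.random.SeedSequence(seed),
        n_restarts=n_restarts, max_iter=max_iter, tol=tol,
    )
    return HMMFitResult(
        transition=A[0], emission=B[0], initial=pi[0], log_likelihood=float(ll[0])
    )


def transition_randomization_test(
    sequences: list[StateSequence],
    n_shuffles: int = 4000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_restarts: int = 5,
    batch_size: int = 500,
) -> HMMFitResult:
    """Shuffle-null significance of every transition probability.

    For each replicate, every sequence's symbols are independently permuted
    in time (per-sequence symbol counts preserved exactly), the HMM is
    refitted, and the canonical transition matrix recorded.  Observed edges
    below the null 5th percentile are ``significantly_small``; above the
    95th percentile ``significantly_large``.
    """
    if n_shuffles < 100:
        warnings.warn("n_shuffles < 100: percentile estimates unstable",
                      stacklevel=2)
    if not sequences or max(len(s.states) for s in sequences) < 2:
        raise ValueError("need at least one sequence of length >= 2")

    root = np.random.SeedSequence(seed)
    fit_seed, shuffle_seed, null_fit_seed = root.spawn(3)
    observed = baum_welch_fit(
        sequences, tol=tol, max_iter=max_iter,
        seed=fit_seed.generate_state(1)[0] % 2**31, n_restarts=n_restarts,
    )

    seqs_int = [s.to_ints() for s in sequences]
    obs, mask = _hmm.pack_sequences(seqs_int)
    lengths = [len(s) for s in seqs_int]
    rng = np.random.default_rng(shuffle_seed)

    null_A = np.empty((n_shuffles, 2, 2))
    null_seeds = null_fit_seed.spawn((n_shuffles + batch_size - 1) // batch_size)
    done = 0
    b_idx = 0
    while done < n_shuffles:
        b = min(batch_size, n_shuffles - done)
        shuffled = np.zeros((b, *obs.shape), dtype=np.int8)
        for r in range(b):
            for s_i, L in enumerate(lengths):
                shuffled[r, s_i, :L] = rng.permutation(obs[s_i, :L])
        A, _, _, _ = _hmm.fit_best_of_restarts(
            shuffled, mask, null_seeds[b_idx],
            n_restarts=n_restarts, max_iter=max_iter, tol=tol, n_datasets=b,
        )
        null_A[done : done + b] = A
        done += b
        b_idx += 1

    p5 = np.percentile(null_A, 5, axis=0)
    p95 = np.percentile(null_A, 95, axis=0)
    verdicts = {}
    for i, si in enumerate(STATE_NAMES):
        for j, sj in enumerate(STATE_NAMES):
            a = observed.transition[i, j]
            if a < p5[i, j]:
                verdicts[(si, sj)] = SIG_SMALL
            elif a > p95[i, j]:
                verdicts[(si, sj)] = SIG_LARGE
            else:
                verdicts[(si, sj)] = NOT_SIG
    observed.edge_significance = verdicts
    observed.null_p5 = p5
    observed.null_p95 = p95
    observed.n_shuffles = int(n_shuffles)
    return observed
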