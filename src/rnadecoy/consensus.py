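"""Iterative consensus folding and alignment of a homolog group.

A simplified iterative-refinement loop: every pair of sequences is aligned with a
three-state pair hidden Markov model whose match emissions are informed by
the structural match score; base-pair proclivities for each sequence
("extrinsic information") are estimated from the other sequences' pair
probabilities through the alignment posteriors, and folding is repeated with
those proclivities as multiplicative bonuses. After the configured number of
iterations a multiple sequence alignment is built progressively from
consistency-transformed posteriors over a neighbor-joining guide tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .core import PairProbabilityMatrix, SecondaryStructure, SequenceGroup, SequenceRecord
from .foldengine import EnergyModel, ensemble_free_energy, mea_structure, partition_probabilities

__all__ = [
    "MatchScoreParams",
    "PairHmmParams",
    "AlignmentPosterior",
    "MultipleAlignment",
    "TurboResult",
    "match_score",
    "match_score_matrix",
    "pairwise_posteriors",
    "extrinsic_information",
    "consistency_transform",
    "run_turbo",
]


@dataclass(frozen=True)
class MatchScoreParams:
    """Weights of the pairing-status match score.

    a1 rewards conserved pairing direction (both upstream-paired or both
    downstream-paired), a2 rewards conserved unpairedness, a3 is a constant
    offset. Defaults follow the published grid-search optimum.
    """

    a1: float = 1.0
    a2: float = 0.8
    a3: float = 0.5


@dataclass(frozen=True)
class PairHmmParams:
    """Pair-HMM parameters for posterior alignment.

    gap_open: probability of moving from match into either insert state;
    gap_extend: probability of staying in an insert state;
    match_odds_same / match_odds_diff: emission odds ratios (relative to
    background) for identical and differing nucleotides.
    """

    gap_open: float = 0.05
    gap_extend: float = 0.4
    match_odds_same: float = 3.0
    match_odds_diff: float = 0.5

    def log_transitions(self) -> tuple[float, float, float, float]:
        mm = math.log(1.0 - 2.0 * self.gap_open)
        mg = math.log(self.gap_open)
        gm = math.log(1.0 - self.gap_extend)
        gg = math.log(self.gap_extend)
        return mm, mg, gm, gg


@dataclass
class AlignmentPosterior:
    """Posterior probability pi[i, k] that position i of one sequence aligns
    to position k of the other."""

    pi: np.ndarray
    log_likelihood: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.pi < -1e-12) or np.any(self.pi > 1 + 1e-6):
            raise ValueError("posterior entries must lie in [0, 1]")
        if np.any(self.pi.sum(axis=1) > 1 + 1e-6) or np.any(self.pi.sum(axis=0) > 1 + 1e-6):
            raise ValueError("posterior row/column sums must not exceed 1")

    @property
    def transpose(self) -> "AlignmentPosterior":
        return AlignmentPosterior(self.pi.T.copy(), self.log_likelihood)


class MultipleAlignment:
    """A gapped multiple alignment with column/position maps.

    ``rows[m]`` is the gapped string of sequence m; stripping gaps recovers
    the input sequence exactly. ``col_of(m)`` maps each ungapped position to
    its column; ``pos_of(m)`` maps each column to a position or -1 for a gap.
    """

    GAP = "-"

    def __init__(self, rows: Sequence[str], ids: Optional[Sequence[str]] = None):
        rows = list(rows)
        if not rows:
            raise ValueError("alignment needs at least one row")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError("alignment rows must have equal length")
        self.rows = rows
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(rows))]
        self._pos_of = []
        self._col_of = []
        for r in rows:
            pos_of = np.full(width, -1, dtype=np.int64)
            col_of = []
            p = 0
            for c, ch in enumerate(r):
                if ch != self.GAP:
                    pos_of[c] = p
                    col_of.append(c)
                    p += 1
            self._pos_of.append(pos_of)
            self._col_of.append(np.asarray(col_of, dtype=np.int64))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def pos_of(self, m: int) -> np.ndarray:
        return self._pos_of[m]

    def col_of(self, m: int) -> np.ndarray:
        return self._col_of[m]

    def ungapped(self, m: int) -> str:
        return self.rows[m].replace(self.GAP, "")


@dataclass
class TurboResult:
    """Everything the feature extractor consumes from one consensus run."""

    group: SequenceGroup
    initial_probs: list[PairProbabilityMatrix]
    final_probs: list[PairProbabilityMatrix]
    msa: MultipleAlignment
    free_energies: list[float]
    mea: list[SecondaryStructure]
    posteriors: dict = field(default_factory=dict)


def match_score(i_marginals, k_marginals, params: MatchScoreParams = MatchScoreParams()) -> float:
    """Pairing-status similarity of two (possibly gapped) aligned positions.

    Each argument is a (P<, P>, Po) triple; a gap is the all-zero triple.
    """
    pu_m, pd_m, po_m = i_marginals
    pu_n, pd_n, po_n = k_marginals
    return params.a1 * (pu_m * pu_n + pd_m * pd_n) + params.a2 * (po_m * po_n) + params.a3


def match_score_matrix(marg_m: np.ndarray, marg_n: np.ndarray,
                       params: MatchScoreParams = MatchScoreParams()) -> np.ndarray:
    """All-against-all match scores from (L, 3) marginal arrays."""
    pairing = marg_m[:, :2] @ marg_n[:, :2].T
    unpair = np.outer(marg_m[:, 2], marg_n[:, 2])
    return params.a1 * pairing + params.a2 * unpair + params.a3


def _substitution_log_odds(m: str, n: str, hmm: PairHmmParams) -> np.ndarray:
    a = np.frombuffer(m.encode(), dtype=np.uint8)
    b = np.frombuffer(n.encode(), dtype=np.uint8)
    same = a[:, None] == b[None, :]
    return np.where(same, math.log(hmm.match_odds_same), math.log(hmm.match_odds_diff))


def pairwise_posteriors(m: SequenceRecord, n: SequenceRecord,
                        m_probs: Optional[PairProbabilityMatrix] = None,
                        n_probs: Optional[PairProbabilityMatrix] = None,
                        params: MatchScoreParams = MatchScoreParams(),
                        beta: float = 1.0,
                        hmm: PairHmmParams = PairHmmParams()) -> AlignmentPosterior:
    """Forward-backward alignment posteriors of a three-state pair HMM.

    The match emission log-odds is a base-substitution term plus
    ``beta * log(match_score)``; with ``beta = 0`` (or without probability
    matrices) the alignment is sequence-only.
    """
    ls = _substitution_log_odds(m.residues, n.residues, hmm)
    if beta != 0.0 and m_probs is not None and n_probs is not None:
        ms = match_score_matrix(m_probs.marginals(), n_probs.marginals(), params)
        ls = ls + beta * np.log(ms)
    mm, mg, gm, gg = hmm.log_transitions()
    pi, logz = _kernels.hmm_forward_backward(np.ascontiguousarray(ls), mm, mg, gm, gg)
    if not np.isfinite(logz):
        raise ValueError("zero-likelihood alignment")
    return AlignmentPosterior(np.clip(pi, 0.0, 1.0), float(logz))


def extrinsic_information(target: int, group_probs: Sequence[PairProbabilityMatrix],
                          posteriors: dict) -> np.ndarray:
    """Pair proclivities for one sequence from the rest of the group.

    E(i, j) = mean over other sequences n of
    sum_{k<l} pi(i, k) * pi(j, l) * P^n(k, l), mapped through the pairwise
    alignment posteriors pi between the target and n. A single-sequence
    group yields the all-zero matrix.
    """
    S = len(group_probs)
    L = group_probs[target].length
    E = np.zeros((L, L))
    if S < 2:
        return E
    for n in range(S):
        if n == target:
            continue
        pi = _get_pi(posteriors, target, n)
        upper = pi @ np.triu(group_probs[n].P, 1) @ pi.T
        E += np.triu(upper, 1)
    E /= (S - 1)
    E = E + E.T
    return np.clip(E, 0.0, None)


def _get_pi(posteriors: dict, m: int, n: int) -> np.ndarray:
    if (m, n) in posteriors:
        return posteriors[(m, n)].pi
    return posteriors[(n, m)].pi.T


def consistency_transform(posteriors: dict, n_seqs: int) -> dict:
    """One round of triplet consistency:
    pi'_mn = (pi_mn + mean_h pi_mh @ pi_hn) / 2 over intermediates h != m, n."""
    out = {}
    for (m, n) in posteriors:
        pi = posteriors[(m, n)].pi
        inter = [h for h in range(n_seqs) if h not in (m, n)]
        if not inter:
            out[(m, n)] = AlignmentPosterior(pi.copy())
            continue
        acc = np.zeros_like(pi)
        for h in inter:
            acc += _get_pi(posteriors, m, h) @ _get_pi(posteriors, h, n)
        new = 0.5 * (pi + acc / len(inter))
        out[(m, n)] = AlignmentPosterior(np.clip(new, 0.0, 1.0))
    return out


def _expected_identity(m: SequenceRecord, n: SequenceRecord, pi: np.ndarray) -> float:
    a = np.frombuffer(m.residues.encode(), dtype=np.uint8)
    b = np.frombuffer(n.residues.encode(), dtype=np.uint8)
    same = (a[:, None] == b[None, :]).astype(float)
    return float((pi * same).sum() / min(len(m), len(n)))


def _nj_merge_order(dist: np.ndarray, ids: Sequence[str]) -> list[tuple[int, int]]:
    """Neighbor-joining join sequence over cluster indices.

    Returns joins as (cluster_a, cluster_b); new clusters are numbered after
    the leaves. Ties break lexicographically on the smallest member id so a
    run is reproducible regardless of float noise.
    """
    S = dist.shape[0]
    if S == 1:
        return []
    active = list(range(S))
    names = {i: ids[i] for i in range(S)}
    D = {(i, j): dist[i, j] for i in range(S) for j in range(S) if i < j}

    def d(i, j):
        return D[(i, j)] if i < j else D[(j, i)]

    joins: list[tuple[int, int]] = []
    nxt = S
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for bj in range(ai + 1, r):
                i, j = active[ai], active[bj]
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                key = (round(q, 12), min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        for k in active:
            if k not in (i, j):
                D[(min(k, nxt), max(k, nxt))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        joins.append((i, j))
        names[nxt] = min(names[i], names[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    if len(active) == 2:
        joins.append((active[0], active[1]))
    return joins


def _merge_profiles(prof_a: dict, prof_b: dict, posteriors: dict) -> dict:
    """Align two profiles (maps seq-index -> per-column position or -1) by
    maximizing summed posterior match probability (gaps score zero)."""
    la = len(next(iter(prof_a.values())))
    lb = len(next(iter(prof_b.values())))
    S = np.zeros((la, lb))
    for m, pos_a in prof_a.items():
        for n, pos_b in prof_b.items():
            pi = _get_pi(posteriors, m, n)
            pad = np.zeros((pi.shape[0] + 1, pi.shape[1] + 1))
            pad[:-1, :-1] = pi
            S += pad[np.asarray(pos_a)[:, None], np.asarray(pos_b)[None, :]]
    choice = _kernels.nw_profile(S)
    # traceback: 0 diagonal, 1 consume A, 2 consume B
    cols: list[tuple[int, int]] = []
    x, y = la, lb
    while x > 0 or y > 0:
        c = choice[x, y]
        if c == 0:
            cols.append((x - 1, y - 1))
            x, y = x - 1, y - 1
        elif c == 1:
            cols.append((x - 1, -1))
            x -= 1
        else:
            cols.append((-1, y - 1))
            y -= 1
    cols.reverse()
    merged: dict = {}
    for m, pos_a in prof_a.items():
        merged[m] = [pos_a[cx] if cx >= 0 else -1 for cx, _ in cols]
    for n, pos_b in prof_b.items():
        merged[n] = [pos_b[cy] if cy >= 0 else -1 for _, cy in cols]
    return merged


def _progressive_msa(group: SequenceGroup, posteriors: dict) -> MultipleAlignment:
    S = len(group)
    if S == 1:
        return MultipleAlignment([group.members[0].residues], group.ids)
    dist = np.zeros((S, S))
    for m in range(S):
        for n in range(m + 1, S):
            ident = _expected_identity(group.members[m], group.members[n],
                                       _get_pi(posteriors, m, n))
            dist[m, n] = dist[n, m] = 1.0 - ident
    joins = _nj_merge_order(dist, group.ids)
    profiles: dict[int, dict] = {
        i: {i: list(range(len(group.members[i])))} for i in range(S)
    }
    nxt = S
    for a, b in joins:
        profiles[nxt] = _merge_profiles(profiles.pop(a), profiles.pop(b), posteriors)
        nxt += 1
    final = profiles[nxt - 1]
    rows = []
    for m in range(S):
        seq = group.members[m].residues
        rows.append("".join(seq[p] if p >= 0 else MultipleAlignment.GAP for p in final[m]))
    return MultipleAlignment(rows, group.ids)


def run_turbo(group: SequenceGroup, model: EnergyModel = EnergyModel(),
              iterations: int = 3,
              params: MatchScoreParams = MatchScoreParams(),
              gamma: float = 50.0, beta: float = 1.0,
              hmm: PairHmmParams = PairHmmParams()) -> TurboResult:
    """Run the full iterative consensus loop on a group.

    Iteration 0 folds each sequence on its own and aligns pairs from sequence
    alone; each later iteration recomputes extrinsic information, refolds
    with it, recomputes match scores and realigns. Deterministic throughout.
    """
    S = len(group)
    initial = [partition_probabilities(s, model) for s in group.members]
    probs = list(initial)
    posteriors: dict = {}
    if S > 1:
        for m in range(S):
            for n in range(m + 1, S):
                posteriors[(m, n)] = pairwise_posteriors(
                    group.members[m], group.members[n], beta=0.0, hmm=hmm)
        for _ in range(iterations):
            new_probs = []
            for m in range(S):
                E = extrinsic_information(m, probs, posteriors)
                new_probs.append(partition_probabilities(group.members[m], model,
                                                         extrinsic=E, gamma=gamma))
            probs = new_probs
            for m in range(S):
                for n in range(m + 1, S):
                    posteriors[(m, n)] = pairwise_posteriors(
                        group.members[m], group.members[n],
                        probs[m], probs[n], params, beta, hmm)
        aln_post = consistency_transform(posteriors, S)
    else:
        aln_post = {}
    msa = _progressive_msa(group, aln_post)
    free_energies = [ensemble_free_energy(s, model) for s in group.members]
    mea = [mea_structure(p, min_hairpin=model.min_hairpin) for p in probs]
    return TurboResult(group=group, initial_probs=initial, final_probs=probs,
                       msa=msa, free_energies=free_energies, mea=mea,
                       posteriors=aln_post)
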