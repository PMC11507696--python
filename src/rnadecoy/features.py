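"""Per-sequence classification features from a consensus-folding run.

Six features per sequence: the Kullback-Leibler divergence of its pairing/
unpairing-score histogram from the rest of the group, the Z-score of its
folding free energy, the mean sequence Shannon entropy of its alignment
columns, the structural Shannon entropy before and after consensus folding,
and the difference of the two. Decoys tend to have a histogram unlike the
group's (high KL), an atypical free energy, noisier alignment columns, and a
larger drop in structural entropy because consensus folding forces them
toward the family structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import MultipleAlignment, TurboResult
from .core import PairProbabilityMatrix

__all__ = [
    "N_HISTOGRAM_BINS",
    "PsUsScores",
    "PsUsHistogram",
    "FeatureVector",
    "FEATURE_NAMES",
    "ps_us_scores",
    "build_histogram",
    "kl_score",
    "z_score",
    "sequence_entropy",
    "structural_entropy",
    "feature_vector",
    "feature_table",
]

#: Bins per axis of the PS-US histogram.
BINS_PER_AXIS = 30
#: Triangular bin count: PS + US <= 1 keeps only x + y <= 29.
N_HISTOGRAM_BINS = BINS_PER_AXIS * (BINS_PER_AXIS + 1) // 2

FEATURE_NAMES = ("kl_score", "z_score", "seq_entropy",
                 "ss_initial", "ss_final", "ss_delta")

# flat index of triangular bin (x, y), x + y <= 29
_TRI_INDEX = {}
for _x in range(BINS_PER_AXIS):
    for _y in range(BINS_PER_AXIS - _x):
        _TRI_INDEX[(_x, _y)] = len(_TRI_INDEX)


@dataclass
class PsUsScores:
    """Per-column pairing score PS(i) and unpairing score US(i) for one
    sequence, with the columns where that sequence has a gap flagged."""

    ps: np.ndarray
    us: np.ndarray
    gap_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ps + self.us > 1 + 1e-9):
            raise ValueError("PS(i) + US(i) must not exceed 1")


@dataclass
class PsUsHistogram:
    """Normalized triangular 2-D histogram of (PS, US) over columns."""

    bins: np.ndarray

    def __post_init__(self) -> None:
        if self.bins.shape != (N_HISTOGRAM_BINS,):
            raise ValueError(f"histogram must have {N_HISTOGRAM_BINS} bins")
        if np.any(self.bins < 0):
            raise ValueError("histogram values must be nonnegative")
        total = self.bins.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("histogram must be normalized (or all zero)")

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    kl_score: float
    z_score: float
    seq_entropy: float
    ss_initial: float
    ss_final: float
    ss_delta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.kl_score, self.z_score, self.seq_entropy,
                         self.ss_initial, self.ss_final, self.ss_delta])


def _column_marginals(target: int, msa: MultipleAlignment,
                      probs: Sequence[PairProbabilityMatrix]) -> np.ndarray:
    """(n_columns, 3) pairing-status marginals of one sequence mapped onto
    alignment columns; gap columns get the all-zero triple."""
    marg = probs[target].marginals()
    pos = msa.pos_of(target)
    out = np.zeros((msa.n_columns, 3))
    valid = pos >= 0
    out[valid] = marg[pos[valid]]
    return out


def ps_us_scores(target: int, msa: MultipleAlignment,
                 probs: Sequence[PairProbabilityMatrix]) -> PsUsScores:
    """Column-wise pairing and unpairing conservation scores.

    PS(i) averages, over the other sequences, the product of upstream-pairing
    probabilities plus the product of downstream-pairing probabilities at
    column i; US(i) does the same for unpaired probabilities. A gap column of
    any sequence contributes zero.
    """
    S = msa.n_sequences
    if S < 2:
        raise ValueError("PS/US need at least two sequences")
    cols = [_column_marginals(m, msa, probs) for m in range(S)]
    tgt = cols[target]
    ps = np.zeros(msa.n_columns)
    us = np.zeros(msa.n_columns)
    for n in range(S):
        if n == target:
            continue
        ps += tgt[:, 0] * cols[n][:, 0] + tgt[:, 1] * cols[n][:, 1]
        us += tgt[:, 2] * cols[n][:, 2]
    ps /= (S - 1)
    us /= (S - 1)
    gap_mask = msa.pos_of(target) < 0
    ps[gap_mask] = 0.0
    us[gap_mask] = 0.0
    return PsUsScores(ps=ps, us=us, gap_mask=gap_mask)


def build_histogram(scores: PsUsScores) -> PsUsHistogram:
    """Bin each non-gap column into the triangular (PS, US) grid.

    Bin width is 1/30 per axis; a score of exactly 1.0 clamps into the last
    bin, and counts are normalized by the total number of counted columns.
    """
    bins = np.zeros(N_HISTOGRAM_BINS)
    count = 0
    for ps, us, gap in zip(scores.ps, scores.us, scores.gap_mask):
        if gap:
            continue
        x = min(int(ps * BINS_PER_AXIS), BINS_PER_AXIS - 1)
        y = min(int(us * BINS_PER_AXIS), BINS_PER_AXIS - 1)
        y = min(y, BINS_PER_AXIS - 1 - x)  # float noise can cross the diagonal
        bins[_TRI_INDEX[(x, y)]] += 1
        count += 1
    if count == 0:
        warnings.warn("all columns are gaps; histogram left all-zero")
        return PsUsHistogram(bins=bins)
    return PsUsHistogram(bins=bins / count)


def kl_score(target_hist: PsUsHistogram,
             other_hists: Sequence[PsUsHistogram]) -> float:
    """KL divergence of the target histogram from the mean of the others.

    Both distributions receive a pseudocount of 1/465 per bin (then are
    renormalized) before computing sum q log(q / r) with the natural log.
    """
    if not other_hists:
        raise ValueError("need at least one other histogram")
    q = target_hist.bins.copy()
    r = np.mean([h.bins for h in other_hists], axis=0)
    pseudo = 1.0 / N_HISTOGRAM_BINS
    q = q + pseudo
    r = r + pseudo
    q /= q.sum()
    r /= r.sum()
    return float(np.sum(q * np.log(q / r)))


def z_score(target_dg: float, other_dgs: Sequence[float]) -> float:
    """How atypical the target's folding free energy is within the group.

    (dG(m) - mean over others) / population std over others; 0 with a warning
    when the others have zero spread.
    """
    others = np.asarray(other_dgs, dtype=float)
    if others.size < 2:
        raise ValueError("need at least two other free energies")
    sigma = others.std()
    if sigma == 0:
        warnings.warn("zero free-energy spread; Z-score defined as 0")
        return 0.0
    return float((target_dg - others.mean()) / sigma)


def sequence_entropy(target: int, msa: MultipleAlignment) -> float:
    """Mean per-column log10 frequency of the target's own symbol.

    The symbol alphabet is {A, C, G, U, gap}; for each column the frequency
    of the target's symbol among all sequences enters as p * log10(p),
    averaged over columns. 0 when all rows are identical; always in
    [-log10(5), 0].
    """
    A = msa.n_columns
    total = 0.0
    for c in range(A):
        col = [row[c] for row in msa.rows]
        p = col.count(msa.rows[target][c]) / len(col)
        total += p * np.log10(p)
    return total / A


def structural_entropy(probs: PairProbabilityMatrix) -> float:
    """Shannon entropy of the base-pair probability distribution.

    -(1/N) * sum_{i<j} P(i,j) log10 P(i,j) with 0 log 0 = 0; low values mean
    a well-defined single structure.
    """
    upper = np.triu(probs.P, 1)
    nz = upper[upper > 0]
    return float(-(nz * np.log10(nz)).sum() / probs.length)


def feature_vector(target: int, result: TurboResult) -> FeatureVector:
    """Assemble the six classification features for one group member."""
    S = len(result.group)
    if S < 3:
        raise ValueError("feature vector needs a group of at least 3 sequences")
    hists = [build_histogram(ps_us_scores(m, result.msa, result.final_probs))
             for m in range(S)]
    kl = kl_score(hists[target], [h for m, h in enumerate(hists) if m != target])
    z = z_score(result.free_energies[target],
                [fe for m, fe in enumerate(result.free_energies) if m != target])
    se = sequence_entropy(target, result.msa)
    ss0 = structural_entropy(result.initial_probs[target])
    ss1 = structural_entropy(result.final_probs[target])
    return FeatureVector(kl_score=kl, z_score=z, seq_entropy=se,
                         ss_initial=ss0, ss_final=ss1, ss_delta=ss0 - ss1)


def histogram_table(result: TurboResult) -> "pandas.DataFrame":
    """The full 465-bin PS/US histogram of every member, one row per
    sequence (id + bin_0..bin_464).

    Supports classifying directly on the raw histogram for comparison
    experiments; the six-feature summary remains the default input because
    a 465-dimensional block tends to mask the scalar features.
    """
    import pandas as pd

    S = len(result.group)
    rows = []
    for m in range(S):
        hist = build_histogram(ps_us_scores(m, result.msa, result.final_probs))
        rows.append({"id": result.group.ids[m],
                     **{f"bin_{b}": v for b, v in enumerate(hist.bins)}})
    return pd.DataFrame(rows)


def feature_table(result: TurboResult) -> "pandas.DataFrame":
    """Feature vectors for every member of a group, one row per sequence."""
    import pandas as pd

    S = len(result.group)
    hists = [build_histogram(ps_us_scores(m, result.msa, result.final_probs))
             for m in range(S)]
    rows = []
    for target in range(S):
        kl = kl_score(hists[target],
                      [h for m, h in enumerate(hists) if m != target])
        z = z_score(result.free_energies[target],
                    [fe for m, fe in enumerate(result.free_energies) if m != target])
        se = sequence_entropy(target, result.msa)
        ss0 = structural_entropy(result.initial_probs[target])
        ss1 = structural_entropy(result.final_probs[target])
        rows.append({"id": result.group.ids[target], "kl_score": kl, "z_score": z,
                     "seq_entropy": se, "ss_initial": ss0, "ss_final": ss1,
                     "ss_delta": ss0 - ss1})
    return pd.DataFrame(rows)
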