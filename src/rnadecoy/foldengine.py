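"""Thermodynamic folding engine with a simplified per-pair energy model.

Computes exact base-pair probabilities over the Boltzmann ensemble of
pseudoknot-free secondary structures via inside/outside dynamic programming,
plus the ensemble free energy, maximum-expected-accuracy (MEA) structures and
structure-accuracy scores. The energy model assigns one stability term per
canonical pair (A-U, C-G, G-U) and an optional helix-stacking bonus when a
pair sits directly inside another; it deliberately trades the full
nearest-neighbor parameterization for a transparent, exactly testable model.
A brute-force enumerator over all legal structures serves as the oracle for
the dynamic programs on short sequences.

Energies are in kcal/mol-equivalents; ``temperature_scale`` (beta = 1/RT)
converts them to Boltzmann exponents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from . import _kernels
from .core import (
    CANONICAL_PAIRS,
    PairProbabilityMatrix,
    SecondaryStructure,
    SequenceRecord,
)

__all__ = [
    "EnergyModel",
    "PairProbabilityMatrix",
    "partition_probabilities",
    "brute_force_probabilities",
    "enumerate_structures",
    "structure_weight",
    "ensemble_free_energy",
    "mea_structure",
    "score_structure",
]

#: Default per-pair stabilities, ordered GC > AU > GU as in real helices.
DEFAULT_PAIR_ENERGIES = {"CG": -3.0, "GC": -3.0, "AU": -2.0, "UA": -2.0,
                         "GU": -1.0, "UG": -1.0}

#: RT at 37 degrees C in kcal/mol.
RT_37 = 0.6163


@dataclass(frozen=True)
class EnergyModel:
    """Simplified RNA stability model.

    pair_energies: free-energy contribution of each canonical pair type
        (more negative = more stable); non-canonical pairs are disallowed.
    stack_energy: extra contribution when pair (i, j) directly encloses
        pair (i+1, j-1), rewarding contiguous helices. 0 disables stacking.
    min_hairpin: minimum number of unpaired residues enclosed by a pair.
    temperature_scale: beta = 1/RT converting energies to exponents.
    """

    pair_energies: tuple = tuple(sorted(DEFAULT_PAIR_ENERGIES.items()))
    stack_energy: float = -1.0
    min_hairpin: int = 3
    temperature_scale: float = 1.0 / RT_37

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.temperature_scale <= 0:
            raise ValueError("temperature_scale must be positive")
        for pair, _ in self.pair_energies:
            if pair not in CANONICAL_PAIRS:
                raise ValueError(f"non-canonical pair in energy model: {pair}")

    @property
    def energies(self) -> dict:
        return dict(self.pair_energies)

    def pair_weight(self, a: str, b: str) -> float:
        """Unscaled Boltzmann weight of pairing residues a and b (0 if illegal)."""
        e = self.energies.get(a + b)
        if e is None:
            return 0.0
        return math.exp(-self.temperature_scale * e)

    @property
    def stack_bonus(self) -> float:
        return math.exp(-self.temperature_scale * self.stack_energy)


def _weight_matrix(seq: str, model: EnergyModel,
                   extrinsic: Optional[np.ndarray], gamma: float,
                   scale: float) -> np.ndarray:
    """Scaled pair-weight matrix; w[i, j] = 0 where pair (i, j) is illegal."""
    n = len(seq)
    w = np.zeros((n, n))
    inv_c2 = 1.0 / (scale * scale)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            base = model.pair_weight(seq[i], seq[j])
            if base == 0.0:
                continue
            bonus = 1.0
            if extrinsic is not None:
                bonus = 1.0 + gamma * extrinsic[i, j]
            w[i, j] = base * bonus * inv_c2
            w[j, i] = w[i, j]
    return w


def _scale_factor(n: int, model: EnergyModel) -> float:
    # Keeps Q in float64 range: u**n and stacked-helix products both bounded.
    return math.exp(min(1.1 * model.temperature_scale, 500.0 / max(n, 1)))


def _inside(seq: SequenceRecord, model: EnergyModel,
            extrinsic: Optional[np.ndarray], gamma: float):
    n = len(seq)
    if extrinsic is not None:
        extrinsic = np.asarray(extrinsic, dtype=float)
        if extrinsic.shape != (n, n):
            raise ValueError("extrinsic matrix shape must match sequence length")
        if np.any(extrinsic < -1e-12):
            raise ValueError("extrinsic bonuses must be nonnegative")
    c = _scale_factor(n, model)
    w = _weight_matrix(seq.residues, model, extrinsic, gamma, c)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite pair weights")
    Q, Qb = _kernels.inside_kernel(w, 1.0 / c, model.stack_bonus, model.min_hairpin)
    return w, c, Q, Qb


def partition_probabilities(seq: SequenceRecord, model: EnergyModel = EnergyModel(),
                            extrinsic: Optional[np.ndarray] = None,
                            gamma: float = 50.0) -> PairProbabilityMatrix:
    """Exact base-pair probabilities under the model.

    When an ``extrinsic`` pair-bonus matrix is supplied (proclivities inferred
    from other sequences in a group), each pair's Boltzmann weight is
    multiplied by ``1 + gamma * extrinsic[i, j]``.
    """
    w, c, Q, Qb = _inside(seq, model, extrinsic, gamma)
    P = _kernels.outside_kernel(w, model.stack_bonus, model.min_hairpin, Q, Qb)
    return PairProbabilityMatrix(P)


def ensemble_free_energy(seq: SequenceRecord, model: EnergyModel = EnergyModel()) -> float:
    """-(1/beta) ln Q over the full ensemble (0 when only the empty structure exists)."""
    n = len(seq)
    _, c, Q, _ = _inside(seq, model, None, 0.0)
    ln_q = math.log(Q[0, n]) + n * math.log(c)
    return -ln_q / model.temperature_scale


def enumerate_structures(length: int, pairable, min_hairpin: int = 3,
                         max_length: int = 20) -> Iterator[frozenset]:
    """Yield every pseudoknot-free structure (as a frozenset of pairs).

    ``pairable(i, j)`` says whether positions may pair. Exponential; refuses
    sequences longer than ``max_length``.
    """
    if length > max_length:
        raise ValueError(f"brute-force enumeration capped at {max_length} nt")

    def rec(i: int, j: int) -> list[frozenset]:
        if i >= j:
            return [frozenset()]
        out = list(rec(i + 1, j))
        for k in range(i + min_hairpin + 1, j):
            if not pairable(i, k):
                continue
            for left in rec(i + 1, k):
                for right in rec(k + 1, j):
                    out.append(left | right | {(i, k)})
        return out

    yield from rec(0, length)


def structure_weight(pairs: frozenset, seq: str, model: EnergyModel) -> float:
    """Unscaled Boltzmann weight of one structure (pair terms plus stacks)."""
    w = 1.0
    for i, j in pairs:
        w *= model.pair_weight(seq[i], seq[j])
    for i, j in pairs:
        if (i + 1, j - 1) in pairs:
            w *= model.stack_bonus
    return w


def brute_force_probabilities(seq: SequenceRecord, model: EnergyModel = EnergyModel(),
                              max_length: int = 20) -> PairProbabilityMatrix:
    """Oracle: exhaustive Boltzmann-weighted enumeration of all structures."""
    n = len(seq)
    s = seq.residues

    def pairable(i: int, j: int) -> bool:
        return model.pair_weight(s[i], s[j]) > 0.0

    P = np.zeros((n, n))
    Z = 0.0
    for pairs in enumerate_structures(n, pairable, model.min_hairpin, max_length):
        wt = structure_weight(pairs, s, model)
        Z += wt
        for i, j in pairs:
            P[i, j] += wt
            P[j, i] += wt
    P /= Z
    return PairProbabilityMatrix(P)


def mea_structure(probs: PairProbabilityMatrix, gamma_mea: float = 1.0,
                  min_hairpin: int = 3) -> SecondaryStructure:
    """Maximum-expected-accuracy structure.

    Maximizes sum(2 * gamma_mea * P(i,j)) over chosen pairs plus sum(Po(i))
    over unpaired positions, by dynamic programming over pseudoknot-free
    structures. Deterministic tie-break: prefer unpaired, then the smaller
    partner index.
    """
    if gamma_mea <= 0:
        raise ValueError("gamma_mea must be positive")
    n = probs.length
    Po = probs.p_unpaired
    _, choice = _kernels.mea_kernel(probs.P, Po, gamma_mea, min_hairpin)
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        k = choice[i, j]
        if k < 0:
            stack.append((i + 1, j))
        else:
            pairs.add((i, int(k)))
            stack.append((i + 1, int(k)))
            stack.append((int(k) + 1, j))
    return SecondaryStructure(pairs=frozenset(pairs), length=n)


def score_structure(predicted: SecondaryStructure,
                    accepted: SecondaryStructure) -> tuple[float, float]:
    """Sensitivity and PPV of a predicted structure against an accepted one.

    sensitivity = |predicted ∩ accepted| / |accepted|,
    ppv = |predicted ∩ accepted| / |predicted|;
    by convention each is 1.0 when its denominator is zero.
    """
    if predicted.length != accepted.length:
        raise ValueError("structures are over sequences of different lengths")
    common = len(predicted.pairs & accepted.pairs)
    sens = common / len(accepted.pairs) if accepted.pairs else 1.0
    ppv = common / len(predicted.pairs) if predicted.pairs else 1.0
    return sens, ppv
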