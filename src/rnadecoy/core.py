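"""Core domain types shared across the package.

The atomic unit of analysis is a :class:`SequenceRecord` (an RNA sequence);
groups of putative homologs are :class:`SequenceGroup`; secondary structures
are pseudoknot-free sets of canonical base pairs; base-pair probabilities and
their pairing-status marginals live in :class:`PairProbabilityMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

VALID_RESIDUES = frozenset("ACGU")

#: Canonical (Watson-Crick plus wobble) base pairs.
CANONICAL_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

#: Ground-truth tags a group member may carry.
LABEL_HOMOLOG = "homolog"
LABEL_DECOY = "decoy"
LABEL_UNKNOWN = "unknown"


def normalize_residues(raw: str) -> str:
    """Uppercase, map T->U, and validate an RNA (or DNA) sequence string."""
    seq = raw.strip().upper().replace("T", "U")
    bad = set(seq) - VALID_RESIDUES
    if not seq:
        raise ValueError("empty sequence")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence with a unique identifier.

    Residues are normalized on construction: T is accepted and mapped to U,
    case is folded to upper, and any character outside {A,C,G,U} is rejected.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceGroup:
    """An ordered set of putative homologous sequences with optional truth tags."""

    members: list[SequenceRecord]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sequence ids in group: {sorted(dupes)}")
        if self.labels is not None and len(self.labels) != len(self.members):
            raise ValueError("labels length must match members length")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.members)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def label_of(self, index: int) -> str:
        if self.labels is None:
            return LABEL_UNKNOWN
        return self.labels[index]


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free RNA secondary structure: a set of (i, j) pairs, i < j.

    Indices are 0-based internally. Invariants enforced: each index in at most
    one pair, no pseudoknots (crossing pairs), and hairpin loops enclosing at
    least ``min_hairpin`` unpaired residues (checked with the conventional 3).
    """

    pairs: frozenset[tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if j - i - 1 < 3:
                raise ValueError(f"pair ({i},{j}) closes a hairpin shorter than 3")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair: ({i},{j})")
            seen.update((i, j))
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for k, l in plist[a + 1:]:
                if i < k < j < l:
                    raise ValueError(f"pseudoknot: ({i},{j}) crosses ({k},{l})")

    def __len__(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> np.ndarray:
        """-1 for unpaired positions, else the 0-based partner index."""
        partner = np.full(self.length, -1, dtype=np.int64)
        for i, j in self.pairs:
            partner[i] = j
            partner[j] = i
        return partner

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in sorted(self.pairs):
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    @classmethod
    def from_dot_bracket(cls, db: str) -> "SecondaryStructure":
        stack: list[int] = []
        pairs: set[tuple[int, int]] = set()
        for idx, ch in enumerate(db):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {idx + 1}")
                pairs.add((stack.pop(), idx))
            elif ch != ".":
                raise ValueError(f"unsupported dot-bracket character {ch!r}")
        if stack:
            raise ValueError("unbalanced '(' in dot-bracket string")
        return cls(pairs=frozenset(pairs), length=len(db))


class PairProbabilityMatrix:
    """Base-pair probabilities for one sequence plus pairing-status marginals.

    ``P[i, j]`` is the probability that positions i and j (0-based) are paired.
    Derived per-position marginals describe the three pairing statuses used by
    the match score: paired with a downstream (3') partner, paired with an
    upstream (5') partner, or unpaired.
    """

    def __init__(self, P: np.ndarray, atol: float = 1e-6):
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("probability matrix must be square")
        if not np.allclose(P, P.T, atol=1e-9):
            raise ValueError("probability matrix must be symmetric")
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-9):
            raise ValueError("pair probabilities must lie in [0, 1]")
        if np.any(np.diag(P) != 0):
            raise ValueError("P(i,i) must be zero")
        total = P.sum(axis=1)
        if np.any(total > 1 + atol):
            worst = int(np.argmax(total))
            raise ValueError(
                f"pairing marginal exceeds 1 at position {worst + 1}: {total[worst]:.6f}"
            )
        self.P = np.clip(P, 0.0, 1.0)

    @property
    def length(self) -> int:
        return self.P.shape[0]

    @property
    def p_downstream(self) -> np.ndarray:
        """P>(i): probability the partner of i is 3' of i."""
        return np.triu(self.P, 1).sum(axis=1)

    @property
    def p_upstream(self) -> np.ndarray:
        """P<(i): probability the partner of i is 5' of i."""
        return np.tril(self.P, -1).sum(axis=1)

    @property
    def p_unpaired(self) -> np.ndarray:
        """Po(i) = 1 - P>(i) - P<(i)."""
        return np.clip(1.0 - self.P.sum(axis=1), 0.0, 1.0)

    def marginals(self) -> np.ndarray:
        """(length, 3) array of (P<, P>, Po) per position."""
        return np.stack([self.p_upstream, self.p_downstream, self.p_unpaired], axis=1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairProbabilityMatrix) and np.array_equal(self.P, other.P)
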