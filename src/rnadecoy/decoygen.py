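"""Decoy (contaminant) sequence generation.

Two kinds of decoys mirror the two realistic contamination modes: a member
of a different RNA family (wrong structure, wrong sequence), and a partial
shuffle of a true family member (right composition and near-family identity,
but a disrupted structure). A shuffled decoy keeps a fraction of positions
fixed equal to the family's mean pairwise identity, so by construction it
aligns to the family at least as well as a typical homolog does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import MultipleAlignment
from .core import LABEL_DECOY, SequenceGroup, SequenceRecord

__all__ = ["ShuffleSpec", "mean_pairwise_identity", "shuffle_decoy", "cross_family_decoy"]


@dataclass(frozen=True)
class ShuffleSpec:
    """How much of a sequence to shuffle.

    keep_fraction: fraction of positions held fixed; when derived from a
    family it equals the family's mean pairwise sequence identity.
    """

    keep_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in [0, 1]")


def mean_pairwise_identity(msa: MultipleAlignment) -> float:
    """Mean over all sequence pairs of matching non-gap columns divided by
    columns where at least one of the two sequences is non-gap."""
    S = msa.n_sequences
    if S < 2:
        raise ValueError("pairwise identity needs at least two sequences")
    rows = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    gap = ord(MultipleAlignment.GAP)
    total = 0.0
    n_pairs = 0
    for m in range(S):
        for n in range(m + 1, S):
            a, b = rows[m], rows[n]
            covered = (a != gap) | (b != gap)
            match = (a == b) & (a != gap)
            total += match.sum() / covered.sum()
            n_pairs += 1
    return total / n_pairs


def shuffle_decoy(seq: SequenceRecord, spec: ShuffleSpec) -> SequenceRecord:
    """Shuffle a random subset of positions of a homolog to make a decoy.

    round((1 - keep_fraction) * L) positions are chosen uniformly without
    replacement and their residues are permuted uniformly at random among
    themselves; all other positions are untouched. The residue multiset and
    length are preserved, and identity to the original is at least
    keep_fraction for every seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(seq)
    n_shuffle = int(np.floor((1.0 - spec.keep_fraction) * L + 0.5))
    residues = np.array(list(seq.residues))
    if n_shuffle > 0:
        idx = rng.choice(L, size=n_shuffle, replace=False)
        residues[idx] = residues[rng.permutation(idx)]
    return SequenceRecord(id=seq.id + "_shuffled", residues="".join(residues))


def cross_family_decoy(donor_families: list[SequenceGroup], exclude: int,
                       seed: int = 0) -> tuple[SequenceRecord, str]:
    """Draw a decoy uniformly from a random family other than ``exclude``.

    ``exclude`` indexes into ``donor_families``; pass -1 to allow all.
    Returns the sequence and a provenance label "decoy:family<index>".
    """
    rng = np.random.default_rng(seed)
    eligible = [i for i in range(len(donor_families)) if i != exclude]
    if not eligible:
        raise ValueError("no eligible donor family")
    fam = int(rng.choice(eligible))
    member = int(rng.integers(len(donor_families[fam])))
    rec = donor_families[fam].members[member]
    return rec, f"{LABEL_DECOY}:family{fam}"
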