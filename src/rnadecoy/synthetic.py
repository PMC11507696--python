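"""Synthetic RNA families with conserved secondary structure.

Generates Rfam-like families for training and testing without external
data: a random nested consensus structure, a seed sequence compatible with
it, and members evolved by point mutations that are compensatory at paired
positions (both partners switch to another canonical pair) with high
probability, so the consensus structure is conserved while sequence
identity decays to a target level. Groups then mix family members with
cross-family or shuffled decoys, mirroring a realistic contamination
scenario, and corpora keep train and test families disjoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .consensus import MultipleAlignment
from .core import (
    LABEL_DECOY,
    LABEL_HOMOLOG,
    SecondaryStructure,
    SequenceGroup,
    SequenceRecord,
)
from .decoygen import ShuffleSpec, cross_family_decoy, mean_pairwise_identity, shuffle_decoy

__all__ = [
    "FamilySpec",
    "GroupSpec",
    "random_consensus_structure",
    "generate_family",
    "build_group",
    "build_corpus",
]

_BASES = np.array(list("ACGU"))
_PAIR_TYPES = ["GC", "CG", "AU", "UA", "GU", "UG"]
_PAIR_WEIGHTS = np.array([0.3, 0.3, 0.15, 0.15, 0.05, 0.05])
# Loop composition is A-rich, as in natural RNAs; it also limits spurious
# helices competing with the designed consensus.
_LOOP_WEIGHTS = np.array([0.5, 0.25, 0.1, 0.15])


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic family.

    length/target_identity of None are drawn from the default ranges
    (40-120 nt, 0.5-0.8 mean pairwise identity) that emulate small
    structured-RNA families.
    """

    seed: int
    n_members: int = 24
    length: Optional[int] = None
    target_identity: Optional[float] = None
    name: str = "fam"
    consensus_structure: Optional[SecondaryStructure] = None


@dataclass(frozen=True)
class GroupSpec:
    """Recipe for one classification group: homologs plus decoys."""

    seed: int
    n_homologs: int = 10
    n_decoys: int = 1
    decoy_kind: str = "mixed"  # cross_family | shuffled | mixed

    def __post_init__(self) -> None:
        if not 5 <= self.n_homologs <= 20:
            raise ValueError("n_homologs must be in 5..20")
        if not 0 <= self.n_decoys <= 3:
            raise ValueError("n_decoys must be in 0..3")
        if self.decoy_kind not in ("cross_family", "shuffled", "mixed"):
            raise ValueError(f"unknown decoy kind {self.decoy_kind!r}")


def random_consensus_structure(length: int, seed: int) -> SecondaryStructure:
    """A random nested structure with >= 2 helices of >= 3 stacked pairs,
    hairpin loops >= 3, and 30-60% of residues in pairs."""
    if length < 10:
        raise ValueError("length must be at least 10")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(rng.uniform(0.35, 0.55) * length / 2.0))
    n_helices = int(rng.integers(2, 5))
    n_helices = max(2, min(n_helices, n_pairs // 3))
    while 2 * n_pairs + 3 * n_helices > length:
        n_pairs -= 1
        n_helices = max(2, min(n_helices, n_pairs // 3))
    stems = [3] * n_helices
    for _ in range(n_pairs - 3 * n_helices):
        stems[int(rng.integers(n_helices))] += 1
    nest = n_helices >= 3 and rng.random() < 0.4
    if nest:
        outer, inner = stems[0], stems[1:]
    else:
        outer, inner = None, stems
    # unpaired budget: hairpin loops of 3 plus randomly spread slack
    loops = [3] * len(inner)
    n_linkers = len(inner) + 1
    linkers = [0] * n_linkers
    slack = length - 2 * n_pairs - sum(loops)
    for _ in range(slack):
        k = int(rng.integers(len(loops) + n_linkers))
        if k < len(loops):
            loops[k] += 1
        else:
            linkers[k - len(loops)] += 1
    parts = []
    for h in range(len(inner)):
        parts.append("." * linkers[h])
        parts.append("(" * inner[h] + "." * loops[h] + ")" * inner[h])
    parts.append("." * linkers[-1])
    db = "".join(parts)
    if outer is not None:
        # wrap the interior, moving the flanking linkers outside the helix
        lead, tail = linkers[0], linkers[-1]
        core = db[lead:len(db) - tail if tail else len(db)]
        db = "." * lead + "(" * outer + core + ")" * outer + "." * tail
    assert len(db) == length, (len(db), length)
    return SecondaryStructure.from_dot_bracket(db)


def _seed_sequence(structure: SecondaryStructure, rng: np.random.Generator) -> list[str]:
    seq = [""] * structure.length
    paired = set()
    for i, j in structure.pairs:
        pt = _PAIR_TYPES[rng.choice(len(_PAIR_TYPES), p=_PAIR_WEIGHTS)]
        seq[i], seq[j] = pt[0], pt[1]
        paired.update((i, j))
    for i in range(structure.length):
        if i not in paired:
            seq[i] = str(rng.choice(_BASES, p=_LOOP_WEIGHTS))
    return seq


def _consensus_overlap(residues: str, structure: SecondaryStructure) -> float:
    from .foldengine import mea_structure, partition_probabilities

    rec = SequenceRecord(id="cand", residues=residues)
    mea = mea_structure(partition_probabilities(rec))
    common = len(mea.pairs & structure.pairs)
    return common / len(structure.pairs) if structure.pairs else 1.0


def _mutation_fraction(target_identity: float) -> float:
    # Two members mutated independently from the seed at fraction f match at
    # roughly (1-f)^2 + f^2/3 of positions; invert that for f.
    inner = 1.0 - (4.0 / 3.0) * (1.0 - target_identity)
    return 0.75 * (1.0 - math.sqrt(max(inner, 0.0)))


def _evolve(seed_seq: list[str], structure: SecondaryStructure, frac: float,
            compensatory_p: float, rng: np.random.Generator) -> str:
    seq = list(seed_seq)
    L = len(seq)
    partner = structure.partner_array()
    budget = int(round(frac * L))
    order = rng.permutation(L)
    done: set[int] = set()
    for i in order:
        if budget <= 0:
            break
        i = int(i)
        if i in done:
            continue
        j = int(partner[i])
        if j >= 0 and rng.random() < compensatory_p:
            budget -= 2  # both partners change
            a, b = (i, j) if i < j else (j, i)
            current = seq[a] + seq[b]
            options = [p for p in _PAIR_TYPES if p != current]
            pt = options[int(rng.integers(len(options)))]
            seq[a], seq[b] = pt[0], pt[1]
            done.update((i, j))
        else:
            budget -= 1
            options = [c for c in "ACGU" if c != seq[i]]
            seq[i] = options[int(rng.integers(3))]
            done.add(i)
    return "".join(seq)


def generate_family(spec: FamilySpec, compensatory_p: float = 0.9,
                    seed_tries: int = 15, member_tries: int = 8,
                    fold_fidelity: float = 0.7) -> SequenceGroup:
    """Generate one family of structure-sharing members.

    The seed sequence is redrawn (up to ``seed_tries`` times, keeping the
    best) until its own thermodynamic MEA fold recovers the consensus
    structure, and each member is evolved from the seed by point mutations
    that are compensatory at paired positions with probability
    ``compensatory_p``. Candidate members whose fold drifts off the
    consensus are redrawn up to ``member_tries`` times (best kept) —
    emulating the purifying selection that keeps real family structures
    conserved despite sequence divergence.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.length if spec.length is not None else int(rng.integers(40, 121))
    target = (spec.target_identity if spec.target_identity is not None
              else float(rng.uniform(0.5, 0.8)))
    structure = spec.consensus_structure
    if structure is None:
        structure = random_consensus_structure(length, int(rng.integers(2 ** 31)))
    best_seed, best_ov = None, -1.0
    for _ in range(seed_tries):
        cand = _seed_sequence(structure, rng)
        ov = _consensus_overlap("".join(cand), structure)
        if ov > best_ov:
            best_seed, best_ov = cand, ov
        if ov >= 0.9:
            break
    seed_seq = best_seed
    frac = _mutation_fraction(target)
    members = []
    for k in range(spec.n_members):
        best_res, best_ov = None, -1.0
        for _ in range(member_tries):
            residues = _evolve(seed_seq, structure, frac, compensatory_p, rng)
            ov = _consensus_overlap(residues, structure)
            if ov > best_ov:
                best_res, best_ov = residues, ov
            if ov >= fold_fidelity:
                break
        members.append(SequenceRecord(id=f"{spec.name}_m{k}", residues=best_res))
    return SequenceGroup(members=members)


def family_alignment(family: SequenceGroup) -> MultipleAlignment:
    """The trivial ungapped alignment of an indel-free synthetic family."""
    return MultipleAlignment([m.residues for m in family], family.ids)


def family_identity(family: SequenceGroup) -> float:
    return mean_pairwise_identity(family_alignment(family))


def build_group(families: Sequence[SequenceGroup], spec: GroupSpec,
                home_family: Optional[int] = None) -> tuple[SequenceGroup, int]:
    """Assemble one labeled group: homologs from one family plus decoys.

    Shuffled decoys keep a fraction of positions equal to the home family's
    mean pairwise identity; cross-family decoys are drawn from the other
    families. Member order is shuffled. Returns (group, home_family_index).
    """
    rng = np.random.default_rng(spec.seed)
    eligible = [i for i, f in enumerate(families) if len(f) >= spec.n_homologs]
    if not eligible:
        raise ValueError("no family large enough for the requested group")
    if home_family is None:
        home_family = int(rng.choice(eligible))
    elif len(families[home_family]) < spec.n_homologs:
        raise ValueError("home family too small")
    if spec.n_decoys > 0 and spec.decoy_kind != "shuffled" and len(families) < 2:
        raise ValueError("cross-family decoys need at least 2 families")
    family = families[home_family]
    picks = rng.choice(len(family), size=spec.n_homologs, replace=False)
    members = [family.members[int(p)] for p in picks]
    labels = [LABEL_HOMOLOG] * spec.n_homologs
    keep = family_identity(family)
    for d in range(spec.n_decoys):
        kind = spec.decoy_kind
        if kind == "mixed":
            kind = "shuffled" if rng.random() < 0.5 else "cross_family"
        if kind == "shuffled":
            src = family.members[int(rng.integers(len(family)))]
            rec = shuffle_decoy(src, ShuffleSpec(keep_fraction=keep,
                                                 seed=int(rng.integers(2 ** 31))))
            rec = SequenceRecord(id=f"{rec.id}_d{d}", residues=rec.residues)
            labels.append(f"{LABEL_DECOY}:shuffled")
        else:
            rec, label = cross_family_decoy(list(families), home_family,
                                            seed=int(rng.integers(2 ** 31)))
            rec = SequenceRecord(id=f"{rec.id}_d{d}", residues=rec.residues)
            labels.append(label)
        members.append(rec)
    order = rng.permutation(len(members))
    group = SequenceGroup(members=[members[int(i)] for i in order],
                          labels=[labels[int(i)] for i in order])
    return group, home_family


@dataclass
class Corpus:
    """Labeled train/test groups built from disjoint family sets."""

    train_groups: list[SequenceGroup]
    test_groups: list[SequenceGroup]
    train_families: list[SequenceGroup]
    test_families: list[SequenceGroup]
    train_group_families: list[int] = field(default_factory=list)
    test_group_families: list[int] = field(default_factory=list)


def build_corpus(n_families: int = 13, groups_per_condition: int = 60,
                 seed: int = 0, n_train_families: Optional[int] = None,
                 length_range: tuple[int, int] = (40, 121),
                 identity_range: tuple[float, float] = (0.5, 0.8)) -> Corpus:
    """Build a full training/testing corpus with disjoint families.

    Defaults give the desk-scale corpus: 8 training families providing
    ``groups_per_condition`` groups for each of 1, 2 and 3 mixed-kind decoys
    plus half that many no-decoy groups (60/60/60/30 = 210), and 5 testing
    families providing ``groups_per_condition // 6`` groups per decoy count
    for cross-family and shuffled decoys separately plus the same number
    with no decoys (70 in total).
    """
    if n_families < 4:
        raise ValueError("need at least 4 families")
    if n_train_families is None:
        # same 8:5 split ratio as the default corpus
        n_train_families = min(n_families - 1, max(2, round(n_families * 8 / 13)))
    if not 1 <= n_train_families < n_families:
        raise ValueError("n_train_families must leave at least one test family")
    rng = np.random.default_rng(seed)
    families = []
    for k in range(n_families):
        fs = FamilySpec(seed=int(rng.integers(2 ** 31)), name=f"fam{k}",
                        length=int(rng.integers(*length_range)),
                        target_identity=float(rng.uniform(*identity_range)))
        families.append(generate_family(fs))
    train_fams = families[:n_train_families]
    test_fams = families[n_train_families:]

    def _groups(fams, plan):
        groups, fam_idx = [], []
        for n_decoys, kind, count in plan:
            for _ in range(count):
                gs = GroupSpec(seed=int(rng.integers(2 ** 31)),
                               n_homologs=int(rng.integers(5, 21)),
                               n_decoys=n_decoys, decoy_kind=kind)
                g, fi = build_group(fams, gs)
                groups.append(g)
                fam_idx.append(fi)
        return groups, fam_idx

    train_plan = [(1, "mixed", groups_per_condition),
                  (2, "mixed", groups_per_condition),
                  (3, "mixed", groups_per_condition),
                  (0, "mixed", groups_per_condition // 2)]
    per_test = max(1, groups_per_condition // 6)
    test_plan = ([(d, "cross_family", per_test) for d in (1, 2, 3)]
                 + [(d, "shuffled", per_test) for d in (1, 2, 3)]
                 + [(0, "mixed", per_test)])
    train_groups, train_gf = _groups(train_fams, train_plan)
    test_groups, test_gf = _groups(test_fams, test_plan)
    return Corpus(train_groups=train_groups, test_groups=test_groups,
                  train_families=train_fams, test_families=test_fams,
                  train_group_families=train_gf, test_group_families=test_gf)
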