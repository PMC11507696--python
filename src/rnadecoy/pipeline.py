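"""End-to-end orchestration: groups -> consensus run -> features -> model.

Thin glue shared by the command-line interface, the test suite and the
reproduction script; the science lives in the other modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import BoostModel, RocCurve, roc, train
from .consensus import MatchScoreParams, MultipleAlignment, TurboResult, run_turbo
from .core import SequenceGroup
from .features import FEATURE_NAMES, feature_table
from .foldengine import EnergyModel, ensemble_free_energy, mea_structure
from .synthetic import Corpus


@dataclass(frozen=True)
class RunConfig:
    """Pipeline knobs with their documented defaults."""

    iterations: int = 3
    a1: float = 1.0
    a2: float = 0.8
    a3: float = 0.5
    gamma: float = 50.0
    beta: float = 1.0
    threshold: float = 0.4971
    seed: int = 0

    @property
    def match_params(self) -> MatchScoreParams:
        return MatchScoreParams(a1=self.a1, a2=self.a2, a3=self.a3)


def group_features(group: SequenceGroup, config: RunConfig = RunConfig(),
                   model: EnergyModel = EnergyModel()) -> pd.DataFrame:
    """Run the consensus loop on one group and extract per-sequence features."""
    result = run_turbo(group, model=model, iterations=config.iterations,
                       params=config.match_params, gamma=config.gamma,
                       beta=config.beta)
    table = feature_table(result)
    if group.labels is not None:
        table["label"] = list(group.labels)
    return table


def corpus_features(groups: Sequence[SequenceGroup],
                    config: RunConfig = RunConfig(),
                    model: EnergyModel = EnergyModel()) -> pd.DataFrame:
    """Feature rows for every sequence of every group (adds group_id)."""
    frames = []
    for gi, group in enumerate(groups):
        table = group_features(group, config, model)
        table.insert(0, "group_id", gi)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def result_from_external(group: SequenceGroup, msa: MultipleAlignment,
                         initial_probs, final_probs,
                         model: EnergyModel = EnergyModel()) -> TurboResult:
    """Assemble a TurboResult from externally computed probability matrices
    and an alignment (the post-processing path for an external folding
    engine); free energies fall back to the internal ensemble values."""
    fes = [ensemble_free_energy(s, model) for s in group.members]
    mea = [mea_structure(p, min_hairpin=model.min_hairpin) for p in final_probs]
    return TurboResult(group=group, initial_probs=list(initial_probs),
                       final_probs=list(final_probs), msa=msa,
                       free_energies=fes, mea=mea)


def consensus_pull_trial(seed: int, n_homologs: int = 8,
                         config: RunConfig = RunConfig(),
                         energy_model: EnergyModel = EnergyModel()) -> tuple[float, float]:
    """One seeded trial of the consensus-pull experiment.

    Builds a synthetic family, groups ``n_homologs`` members with one decoy
    shuffled at the family's mean identity, runs the consensus loop, and
    returns the decoy's MEA-structure overlap with the family consensus
    (fraction of consensus pairs recovered) before and after iteration.
    """
    from .core import SequenceRecord
    from .decoygen import ShuffleSpec, shuffle_decoy
    from .synthetic import FamilySpec, family_identity, generate_family, random_consensus_structure

    rng = np.random.default_rng(seed)
    length = int(rng.integers(40, 121))
    identity = float(rng.uniform(0.5, 0.8))
    consensus = random_consensus_structure(length, int(rng.integers(2 ** 31)))
    fam = generate_family(FamilySpec(seed=int(rng.integers(2 ** 31)),
                                     n_members=n_homologs + 2, length=length,
                                     target_identity=identity,
                                     consensus_structure=consensus))
    keep = family_identity(fam)
    homologs = fam.members[:n_homologs]
    decoy = shuffle_decoy(fam.members[n_homologs + 1],
                          ShuffleSpec(keep_fraction=keep, seed=int(rng.integers(2 ** 31))))
    group = SequenceGroup(members=homologs + [decoy])
    result = run_turbo(group, model=energy_model, iterations=config.iterations,
                       params=config.match_params, gamma=config.gamma,
                       beta=config.beta)
    d = n_homologs
    from .foldengine import score_structure
    before = score_structure(mea_structure(result.initial_probs[d],
                                           min_hairpin=energy_model.min_hairpin), consensus)[0]
    after = score_structure(mea_structure(result.final_probs[d],
                                          min_hairpin=energy_model.min_hairpin), consensus)[0]
    return before, after


@dataclass
class Evaluation:
    model: BoostModel
    roc: RocCurve
    auc: float
    sensitivity_at_5fpr: float
    train_table: pd.DataFrame
    test_table: pd.DataFrame


def benchmark_corpus(corpus: Corpus, config: RunConfig = RunConfig(),
                     model_params: Optional[dict] = None,
                     energy_model: EnergyModel = EnergyModel()) -> dict:
    """Full benchmark on one corpus: features once, then the all-feature
    model and the KL-score-only ablation, scored on the held-out families."""
    train_table = corpus_features(corpus.train_groups, config, energy_model)
    test_table = corpus_features(corpus.test_groups, config, energy_model)
    params = dict(model_params or {})
    out = {"train_table": train_table, "test_table": test_table}
    for tag, cols in (("all", list(FEATURE_NAMES)), ("kl_only", ["kl_score"])):
        clf = train(train_table[cols].to_numpy(),
                    train_table["label"].to_numpy(), seed=config.seed, **params)
        scores = clf.predict_probability(test_table[cols].to_numpy())
        curve = roc(scores, test_table["label"].to_numpy())
        out[f"auc_{tag}"] = curve.auc
        out[f"sensitivity_at_5fpr_{tag}"] = curve.sensitivity_at(0.05)
        out[f"model_{tag}"] = clf
    return out


def evaluate_corpus(corpus: Corpus, config: RunConfig = RunConfig(),
                    model_params: Optional[dict] = None,
                    energy_model: EnergyModel = EnergyModel(),
                    feature_subset: Sequence[str] = FEATURE_NAMES) -> Evaluation:
    """Train on the corpus training groups and score the test groups.

    Train/test families are disjoint by construction of the corpus.
    """
    train_table = corpus_features(corpus.train_groups, config, energy_model)
    test_table = corpus_features(corpus.test_groups, config, energy_model)
    params = dict(model_params or {})
    clf = train(train_table[list(feature_subset)].to_numpy(),
                train_table["label"].to_numpy(), seed=config.seed, **params)
    scores = clf.predict_probability(test_table[list(feature_subset)].to_numpy())
    curve = roc(scores, test_table["label"].to_numpy())
    test_table = test_table.assign(decoy_probability=scores)
    return Evaluation(model=clf, roc=curve, auc=curve.auc,
                      sensitivity_at_5fpr=curve.sensitivity_at(0.05),
                      train_table=train_table, test_table=test_table)
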