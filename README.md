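# rnadecoy

Detect non-homologous contaminant sequences ("decoys") in sets of putative
RNA homologs.

## The problem

Conserved secondary structure is what defines most structured-RNA families,
and predicting that structure from a set of homologs is far more accurate
than from any single sequence. But assembling the homolog set is itself
error-prone: early in the curation of a family, candidate members come from
sequence scans, synteny, or manual inspection, and some of them are not
homologs at all. Such contaminants are hard to spot precisely because RNA
sequence alone carries little signal — a decoy can align as well as a true
member while folding into an entirely different structure. `rnadecoy` flags
these sequences so they can be removed before the family (and downstream
covariance models) are contaminated.

## The method

For a group of S putative homologs the pipeline:

1. **Folds** every sequence: exact base-pair probabilities P(i,j) over the
   pseudoknot-free Boltzmann ensemble, under a simplified per-pair energy
   model (inside–outside dynamic programming; a brute-force enumerator
   serves as its test oracle). Precomputed probability matrices from an
   external folding engine can be supplied instead.
2. **Iterates toward a consensus** (3 iterations by default): all sequence
   pairs are aligned by a pair-HMM whose match emissions include the
   structural *match score*

   p(i,k) = a₁(P<ᵐP<ⁿ + P>ᵐP>ⁿ) + a₂(PoᵐPoⁿ) + a₃,  (a₁,a₂,a₃)=(1.0,0.8,0.5)

   where P<, P>, Po are the probabilities of position i being paired
   upstream, paired downstream, or unpaired. Each sequence is then refolded
   with *extrinsic information* — pair proclivities E(i,j) inferred from the
   other sequences' probabilities through the alignment posteriors — and a
   final multiple alignment is built progressively from
   consistency-transformed posteriors.
3. **Extracts six features** per sequence m:
   - **KL score**: Kullback–Leibler divergence of the sequence's triangular
     465-bin histogram of per-column pairing/unpairing conservation scores
     (PS, US) from the mean histogram of the other sequences;
   - **Z-score** of its folding free energy against the others;
   - **mean sequence Shannon entropy** of its alignment columns;
   - **structural Shannon entropy** before and after the consensus
     iteration, and the **difference** of the two.
4. **Classifies** each sequence with an AdaBoost ensemble of decision
   stumps, producing a decoy probability; a threshold (re-derivable from the
   ROC at a 5% false-positive rate) yields the verdict.

Training and evaluation use synthetic Rfam-like families: groups of 5–20
homologs sharing a conserved structure at 0.5–0.8 mean pairwise identity,
contaminated with 1–3 decoys drawn from other families or made by partially
shuffling a member while keeping a fraction of positions equal to the
family's mean identity. Train and test families never overlap.

## Worked example

```sh
python examples/detect_decoys.py
```

trains on a small synthetic corpus (28 groups) and classifies one held-out
test group:

```
        id  kl_score  z_score  decoy_probability verdict         truth
  fam5_m22     0.143   -0.178              0.480 homolog       homolog
   fam5_m3     0.120   -0.400              0.469 homolog       homolog
   ...
fam4_m3_d0     0.332   11.261              0.555   decoy decoy:family0
   fam5_m8     0.153   -0.327              0.470 homolog       homolog
```

The contaminant (a member of a different family, `fam4_m3_d0`) has the
largest KL score — its pairing-status histogram disagrees with the group —
and an extreme free-energy Z-score; the classifier assigns it the highest
decoy probability and it alone crosses the threshold.

`examples/consensus_folding.py` shows the underlying consensus effect: over
the iterations every sequence is pulled toward the family structure
(homologs from ~0.7 to ~1.0 overlap with the consensus; a shuffled decoy
from 0.0 to ~0.2), which is exactly why before/after comparisons carry
signal about who belongs.

A command-line interface mirrors the library:

```sh
rnadecoy simulate --seed 1 --out corpus/        # synthetic train/test corpus
rnadecoy features group.fasta --out feats.tsv   # six features per sequence
rnadecoy train feats.tsv --model model.joblib   # fit the classifier
rnadecoy classify group.fasta --model model.joblib --out report.tsv
rnadecoy evaluate scored.tsv --out roc.tsv      # ROC / AUC summary
```

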