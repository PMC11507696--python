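"""Fold a single RNA: base-pair probabilities, free energy, MEA structure.

The folding engine computes exact Boltzmann-ensemble pair probabilities
under a simple per-pair energy model (GC > AU > GU, with a helix-stacking
bonus), then extracts the maximum-expected-accuracy structure.
"""

from rnadecoy import EnergyModel, SequenceRecord, ensemble_free_energy, mea_structure, partition_probabilities

seq = SequenceRecord("demo", "GGGCGAAAAGCGCCCAAAGGGCGAAAAGCCC")
model = EnergyModel()

probs = partition_probabilities(seq, model)
structure = mea_structure(probs, min_hairpin=model.min_hairpin)
dg = ensemble_free_energy(seq, model)

print(f"sequence      {seq.residues}")
print(f"MEA structure {structure.to_dot_bracket()}")
print(f"ensemble free energy: {dg:.2f} kcal/mol-equivalents")
print("strongest pairs (P > 0.5):")
for i, j in sorted(structure.pairs):
    if probs.P[i, j] > 0.5:
        print(f"  {i + 1:3d} - {j + 1:3d}   P = {probs.P[i, j]:.3f}")
# The dot-bracket line shows the most-credible structure; each listed pair's
# P is its probability over the whole thermodynamic ensemble.
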