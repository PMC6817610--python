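"""Learn chromatin states from simulated mark tracks and profile them.

Simulates four marks over 20,000 200-bp bins from a known 3-state hidden
Markov chain, binarizes each mark against its Poisson background
(p <= 1e-4), trains the Bernoulli-emission HMM with 3 restarts, segments
the genome by maximum posterior, and computes fold enrichment over the
"promoter" feature intervals derived from the generating path.
"""

import numpy as np

from omicsforge import chromatin as ch, synthetic

tracks, features, truth = synthetic.simulate_chromatin(n_bins=20000, seed=7)
binary = ch.binarize(tracks, p_threshold=1e-4)
model, traces = ch.learn_model(binary, n_states=3, seed=7, n_restarts=3)
seg = ch.segment(model, binary, rule="posterior_max")

E_true = np.array(truth.hmm_emissions)
perm = ch.match_states(model.emissions, E_true)
mae = np.abs(model.emissions[perm] - E_true).mean()
print(f"marks: {binary.marks}")
print(f"final log-likelihoods per restart: {[round(t[-1], 1) for t in traces]}")
print(f"emission mean absolute error vs truth: {mae:.4f}")

table = ch.overlap_enrichment(seg, features, marks=binary)
print("\nfold enrichment (states x promoter feature + marks):")
print(table.fold.to_string(float_format=lambda v: f"{v:.2f}"))
# The state matching the generating "active" state is strongly enriched in
# the promoter intervals (they are, by construction, that state's bins);
# fold = 1 would mean no association beyond genome-wide expectation.
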