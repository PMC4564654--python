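"""Probe a trained network with the three test conditions.

Trains briefly, then evaluates the fixed five-sequence test sets: in-scale
sequences outlining I-V-I / I-IV-I progressions, in-scale sequences with no
implied harmony, and sequences containing out-of-scale tones. All sequences
are nominally in C major; percent correct counts how often the C-major
output unit wins.
"""

import tonalnet as tn

corpus = tn.augment_by_transposition(
    tn.generate_corpus(tn.CorpusSpec(n_major=106, n_minor=14, seed=1))
)
state = tn.init_network(seed=1)
cfg = tn.TrainingConfig(n_epochs=1200, learning_rate=3e-4, checkpoint_interval=1200, seed=1)
(checkpoint,) = tn.train(state, corpus, cfg)

print(f"{'condition':<28} {'% correct':>10} {'C-major activation':>20}")
for test_set in tn.build_test_sets():
    pc = tn.percent_correct(checkpoint.state, test_set)
    act = tn.normalized_correct_key_activation(checkpoint.state, test_set)
    print(f"{test_set.condition.value:<28} {pc:>10.1f} {act:>20.3f}")
print(
    "\nactivation is the C-major output rescaled from (-1, 1) to (0, 1), "
    "averaged over the five sequences"
)
for test_set in tn.build_test_sets():
    example = test_set.sequences[0]
    key = tn.identify_key(checkpoint.state, example)
    print(f"{example.id}: chromas {example.chromas} -> identified as {key}")
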