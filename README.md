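# tonalnet

A connectionist simulation of how listeners acquire a musical *tonal
schema* — the internalized knowledge of a culture's pitch-structure
regularities that lets them hear a melody as being "in a key" — by mere
exposure to melodies.

The package is for researchers in music cognition and computational
modeling who want a fully reproducible, inspectable implementation of the
classic finding that **sensitivity to scale membership emerges before
sensitivity to implied harmony** when a learning network is exposed to
Western tonal music, mirroring the developmental trajectory of musically
westernized children.

## The model

A multilayer perceptron maps a monophonic, isochronous sequence of tone
chromas (pitch classes, C = 0 … B = 11) to one of 24 keys (12 tonics × 
{major, minor}):

- **Input** (2,232 units): 186 serial positions × 12 chromas; position *p*
  of a melody lights exactly one unit, positions beyond the melody's length
  stay zero, so temporal order is part of the code.
- **Hidden layers**: 45 and 30 units.
- **Output** (24 units): one per key; the teacher signal is the 24-bit
  one-hot code of the notated key.
- **Activation**: hyperbolic tangent sigmoid
  *f(x) = (eˣ − e⁻ˣ)/(eˣ + e⁻ˣ)* on every hidden and output unit; for
  readout, outputs are binarized (1 if positive, else 0) or read by argmax.
- **Learning**: plain online backpropagation (stochastic gradient descent
  on squared error between raw outputs and the teacher signal), every
  training melody presented once per epoch.

Training material is a synthetic songbook-style corpus: 315 major-key and
41 minor-key base melodies of 17–186 tones, sampled from tonal profiles
with ≥95% in-scale content, then transposed to all 12 same-mode keys —
4,272 items per epoch, with no learnability bias toward any key within a
mode.

At regular checkpoints the frozen network is probed with three fixed sets
of five nine-tone sequences, all nominally in C major:

| condition | content |
|---|---|
| in-scale / regular harmony | C-major triad arpeggios outlining I–V–I or I–IV–I |
| in-scale / irregular harmony | C-major scale tones, no three consecutive tones forming a triad |
| out-of-scale / irregular harmony | sequences containing chromatic, out-of-scale tones |

Percent correct (how often the C-major unit wins) and the normalized
C-major activation per condition, traced over checkpoints across multiple
runs, are analyzed with a two-way (condition × epoch) repeated-measures
ANOVA, per-epoch simple main effects on a pooled error term, and
Bonferroni pairwise contrasts.

## Worked example

`examples/03_test_conditions.py` trains one network for 1,200 epochs on a
1,440-item corpus and probes it:

```
condition                     % correct   C-major activation
in_scale_regular                   60.0                0.715
in_scale_irregular                 20.0                0.603
out_of_scale_irregular              0.0                0.507
```

The network already separates in-scale from out-of-scale sequences (scale
sensitivity) and identifies C major most reliably when the sequence
arpeggiates a regular progression (emerging harmony sensitivity); the
C-major unit's rescaled activation shows the same ordering. The other
examples cover corpus generation (`01`), single-network training with
agreement-rate checkpoints (`02`), and the full multi-run study with the
repeated-measures analysis (`04`).

A thin CLI wraps the same library surface:

```bash
tonalnet generate-corpus --n-major 315 --n-minor 41 --seed 0 --augment --out corpus.jsonl
tonalnet train --corpus corpus.jsonl --out rundir/
tonalnet evaluate --run rundir/ --out trajectories.csv
tonalnet experiment --config cfg.yaml --out expdir/
```

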