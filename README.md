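# dhsig — dendrographic-hologram EEG signatures

`dhsig` computes topological signatures of multichannel EEG recordings by
encoding hierarchical-clustering dendrograms as 2-adic numbers:

1. **Events.** Each electrode's signal is cut into 1-s windows; every
   (electrode, window) vector is one *event* (19 channels x 500 windows =
   9500 events for a 500-s recording at 500 Hz).
2. **Universal dendrogram.** All events are joined into one binary tree by
   Ward linkage on pairwise Euclidean distances.
3. **2-adic codes.** Each root-to-leaf path becomes a binary digit string
   `a_0..a_k` (root digit in the 2^0 place) with branch value
   `V_i = sum a_j * 2^j`; the tree's *maximal 2-adic ball* is
   `floor(log2(max V_i))`.
4. **PUDHS.** With a global natural parameter `z`, the threshold is
   `T = 2^(max_ball - z)` and PUDHS is the number of branches with
   `V_i < T` — equivalently, the number of sub-dendrograms dissected by the
   threshold line.
5. **PBDHS.** The series is alternatively cut into short *block*
   dendrograms (1/3/5/10 windows each). Every block gets two counts: `E`
   below a per-block threshold (`z1`) and `E1` below a series-wide
   threshold (`z2`). Histograms `F`/`F1` of these counts over bins `1..m`
   are sampled at `h` random bin centres `p`/`p1`, and
   `PBDHS = max((F(p)+1)(F1(p1)+1)) / mean((F(p)+1)(F1(p1)+1))`.
   A randomized search scans `(z1, z2, p, p1)` to maximize summed pairwise
   group AUC.
6. **Evaluation.** Mann-Whitney ROC/AUC, a random-regrouping chance
   control, and a Welch band-power baseline.

A synthetic EEG generator (band-limited noise oscillators with a tunable
inter-channel coupling, drift and noise) makes the whole pipeline testable
with no data downloads.

## Frozen conventions

The branch values depend on two conventions that the data alone does not
fix; both are frozen for reproducibility:

- digit orientation: `a_0` (the 2^0 place) is the digit at the **root**
  split, so two branches are 2-adically close exactly when their common
  root-branch is long;
- child labelling: at every internal node the child subtree containing the
  smallest leaf id takes digit 0.

Event rows are ordered window-major (window 0: all electrodes, window 1:
all electrodes, ...), making each block a contiguous row slice. `V_i` are
arbitrary-precision integers and all threshold comparisons are exact
integer arithmetic; the `V_i = 0` branch counts as below every threshold.

## CLI

```bash
# synthesize a labeled cohort (EDF + manifest.csv)
dhsig synth --config examples/synth.yaml --out cohort/ --seed 1

# per-subject PUDHS table (z = 4; --scan sweeps z = 1..8)
dhsig pudhs --manifest cohort/manifest.csv --z 4 --total-s 500 --out pudhs.csv

# block-signature search over (z1, z2, p, p1)
dhsig pbdhs --manifest cohort/manifest.csv --block-windows 10 \
    --z1-range 1 8 --z2-range 1 8 --h 10 --reps 10000 --seed 7 --out pbdhs/

# pairwise ROC curves from any score table
dhsig roc --table pudhs.csv --score-col pudhs --out roc/

# Welch band power per subject x channel x band
dhsig bandpower --manifest cohort/manifest.csv --out bandpower.csv

# one-shot pipeline from a YAML config (synth -> pudhs -> roc)
dhsig run --config run.yaml --out bundle/
```

A `synth`/`run` YAML describes groups of subjects:

```yaml
synth:
  seed: 3
  groups:
    - {label: a, n_subjects: 10, duration: 30, coupling: 0.9}
    - {label: b, n_subjects: 10, duration: 30, coupling: 0.1}
pudhs: {z: 4, total_s: 30}
```

Inputs may be EDF (16-bit, annotation channels dropped by label) or CSV
(rows = channels); recordings at other sampling rates are polyphase
resampled to 500 Hz unless `--no-resample` is given.

## Notes

- A full 9500-leaf universal dendrogram takes ~45 M pairwise distances
  (~360 MB condensed) and about half a minute to build and code.
- PUDHS is bounded by the number of events (9500 in the standard regime);
  the package enforces this bound.
- Block histogram bins whose count `E` is 0 fall outside the 1-based bin
  support and are tracked, not binned.
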