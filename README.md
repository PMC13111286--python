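# qhandpd

A dual-track hybrid quantum–classical classifier for Parkinson's disease
(PD) screening from handwriting exams, with a synthetic exam generator that
makes the entire pipeline testable end to end on a laptop.

In a spiral/meander exam a subject traces a printed template curve; PD-related
tremor shows up as oscillation of the pen trace around the template.  The
public HandPD corpus couples each exam image with structured clinical data
(age, sex, handedness) and handwriting-derived statistics: the root-mean-square
template–trace deviation (RMS), mean relative tremor (MRT), and the standard
deviation of the point-wise deviations.  `qhandpd` classifies such exams with
two cooperating tracks:

- **Image track (TVSFE).**  Preprocessing removes the near-gray printed
  template: a pixel *i* is whitened iff
  `|R(i)−G(i)| < 45 ∧ |R(i)−B(i)| < 45 ∧ |G(i)−B(i)| < 45`,
  then the image is resized to 512×512 and scaled to [0, 1].  A 7×7
  convolutional stem feeds a stack of CDAB blocks (ghost convolution +
  coordinate attention/squeeze-and-excite in early stages, triplet attention
  in late stages, residual skip), global average pooling and a dense head
  produce a layer- and L2-normalised 256-dim embedding `v`.  That unit vector
  is amplitude-embedded into 8 qubits, `|ψ⟩ = Σ_i v_i |i⟩`, passed through
  strongly entangling layers (per-qubit `RZ·RY·RZ` rotations and a CNOT
  ring), and read out as the 8 Pauli-Z expectations `⟨Z_q⟩ ∈ [−1, 1]`.
- **Structured track (VQFMN).**  The six structured features are imputed,
  min–max mapped to [0, π], encoded one per qubit as `RY(x_j)|0⟩`, passed
  through strongly entangling layers and read out as 6 Pauli-Z expectations.
- **Fusion.**  Both readouts are layer-normalised, concatenated and passed
  through a small dense head with a 2-class softmax.  Training uses focal
  loss `−α(1−p_t)^γ log p_t` with γ = 3, Adam at 1e-4, batch size 4,
  ReduceLROnPlateau and early stopping.  Evaluation offers stratified
  (patient-grouped) 5-fold cross-validation and a percentile bootstrap CI
  over pooled per-sample predictions (10,000 resamples).

Circuits are simulated exactly (statevector, no shot noise) on the package's
own reverse-mode autodiff engine, so gradients flow through both circuits and
the CNN in one backward pass.  No GPU or external deep-learning framework is
required.

## Worked example

```python
import numpy as np
from qhandpd import (generate_dataset, read_exam_directory,
                     preprocess_manifest, split_holdout, build_model,
                     reduced_config, TrainingConfig, train, evaluate)

generate_dataset(n_control=40, n_pd=40, draws_per_subject=4,
                 seed=7, out_dir="exams/")
full = preprocess_manifest(read_exam_directory("exams/"), side=128)
train_set, val_set = split_holdout(full, val_fraction=0.2, seed=7)
model = build_model(reduced_config(), seed=7)
model, history = train(model, train_set, val_set,
                       TrainingConfig(max_epochs=8, seed=7))
print(evaluate(model, val_set).as_dict())
```

which trains the reduced (128×128, two-stage) model on 320 synthetic exams
and prints

```
{'accuracy': 1.0, 'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
```

— the synthetic tremor signal (6 px sinusoidal wobble plus the derived RMS
contrast) is strong enough that the held-out split is classified perfectly
after three epochs.  The same pipeline is exposed on the command line:

```bash
qhandpd simulate --n-control 40 --n-pd 40 --seed 7 --out exams/
qhandpd cv --data exams/ --k 5 --seed 7
qhandpd explain --data exams/ --mode sensitivity --seed 7
```

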