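# mebci

EEG simulation-to-classification toolkit for the microexpression-assisted
BCI paradigm. It implements the full chain:

1. **`mebci.neural_mass`** — three parallel Wendling-type neural-mass
   populations tuned to the low (4–12 Hz), medium (12–30 Hz) and high
   (>30 Hz) EEG bands; fixed-step RK4 integration with seeded Gaussian
   exogenous drive; band-energy weights estimated from reference recordings.
2. **`mebci.forward`** — equivalent-dipole forward problem through an
   isotropic three-shell head: procedural icosphere meshes, a geometric
   10-20 montage (30 channels, CPz reference / AFz ground), the analytic
   concentric-sphere Legendre-series solution (with an independent
   homogeneous-sphere closed-form oracle), and a constant-collocation BEM
   solver with deflation and the isolated-skull correction.
3. **`mebci.gan`** — a conditional GAN converter (generator and
   discriminator exactly per the published layer tables; RMSprop with
   clipping and decay; binary cross-entropy; 100 ms window slicing) that
   maps simulated scalp EEG plus a one-hot class label toward the statistics
   of real template windows. The network kernel (`mebci.nn`) is plain numpy
   with hand-written backprop, verified against numerical gradients.
4. **`mebci.pipeline`** — detrend + 2–55 Hz zero-phase Butterworth
   preprocessing, one-vs-rest CSP (log-variance features), a bank of
   standard classifiers with stratified 5-fold validation, session-disjoint
   testing, confusion matrices, and the augmented-vs-real comparison with a
   two-sample t-test.
5. **`mebci.synthetic`** — surrogate "real" recordings following the
   experimental protocol (8 subjects × 4 classes × 4 sessions × 6 trials,
   3 s countdown + 4 s task + 2 s rest, 30 channels, 1000 Hz) with
   class-specific dipoles and band-energy profiles, subject jitter, and
   1/f + white sensor noise at a configurable SNR.
6. **`mebci.edf` / `mebci.config` / `mebci.cli`** — minimal EDF+ I/O with
   class annotations, YAML run configuration with reproducibility
   manifests, and the command-line interface.

## CLI

```sh
mebci --seed 7 simulate --out source.tsv          # mixed NMM source potential
mebci forward --out leadfield.tsv                 # BEM lead field, 4 class dipoles
mebci --seed 1 make-synthetic --subjects 2 --out synthetic/
mebci --seed 1 train-gan --real synthetic/S1 --sim simdir/ --out converter.h5
mebci convert --converter converter.h5 --sim simdir/ --out converted/
mebci --seed 1 augment-eval --real synthetic/S1 --sim simdir/ --out report/
```

Every command accepts `--config <yaml>` (per-stage blocks; defaults carry
the published parameter tables) and writes a `manifest.json` with the
config hash and seeds.

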