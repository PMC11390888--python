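# retinacode

Bayesian decoding of natural images from retinal ganglion cell (RGC) spike
trains, with a synthetic retina so the whole stack is testable without
recorded data.

The package implements:

- **Synthetic stimuli** (`retinacode.synthetic_stimulus`) — grayscale
  textures with power-law (`1/f^alpha`) spectra standing in for natural
  photographs, discretized 2D Brownian fixational-drift trajectories
  (default diffusion 10 µm²/frame at 120 Hz), and rendered flashed or
  per-frame-jittered stimulus movies.
- **A synthetic retina** (`retinacode.retina_simulator`) — jittered
  hexagonal mosaics of ON/OFF parasol and midget cells with ground-truth
  encoder parameters (difference-of-Gaussians spatial filters, biphasic
  temporal kernels, refractory feedback, neighbor coupling) and Bernoulli
  spike generation per 1 ms bin, either as a coupled network or conditioned
  on provided spike trains.
- **Encoding models** (`retinacode.encoding_models`) — the coupled Bernoulli
  GLM (stimulus + feedback + coupling filters + bias through a sigmoid), its
  uncoupled variant, and a Poisson benchmark; raised-cosine temporal bases
  and tensor B-spline spatial bases; fitting by coordinate descent over the
  rank-1 space/time factorization with FISTA, an L1 penalty on spatial
  weights and an L2,1 group penalty on coupling, plus held-out
  hyperparameter grid search.
- **Image priors** (`retinacode.priors`) — the exact `1/f²` Gaussian prior
  (value, gradient, closed-form prox), generic Fourier-diagonal Gaussian
  priors, and an MSE-trained spectral (Wiener) stand-in denoiser satisfying
  the plug-and-play denoiser contract.
- **Reconstruction** (`retinacode.reconstruction`) — plug-and-play MAP via
  half-quadratic splitting along a log-spaced rho schedule (10 iterations by
  default), exact MAP under the 1/F prior by gradient descent, the
  known-eye-trajectory variant, joint image/eye-trajectory estimation by
  particle-filter EM (sequential importance resampling, N = 10 particles,
  image updates every 5 frame transitions), and the noiseless
  linear-projection reconstruction with its closed-form constrained step.
- **Evaluation** (`retinacode.evaluation`) — valid-region masks (convex hull
  of receptive fields), masked shift-searched MS-SSIM, PSTHs,
  shift-predictor-corrected cross-correlograms, Gaussian spike-time
  perturbation, across-repeat shuffling, realized drift magnitude and
  eye-position error.
- **Experiments** (`retinacode.cli_config`, `retinacode.cli`) — YAML-driven,
  seeded, end-to-end experiment runner and the `retinacode` CLI.

## CLI

```bash
# render a jittered drift trial
retinacode simulate-stimulus --kind jitter --size 32 --seed 1 --out mov.h5

# build a mosaic + ground-truth encoder and simulate spikes
retinacode simulate-retina --stimulus mov.h5 --out spikes.h5

# fit an encoding model to the simulated data
retinacode fit --model lnbrc --stimulus mov.h5 --spikes spikes.h5 \
    --mosaic spikes.mosaic.csv --out fitted.h5

# reconstruct (modes: flash, zero, known, joint; priors: dcnn, one_over_f)
retinacode reconstruct --mode known --stimulus mov.h5 --spikes spikes.h5 \
    --encoder spikes.encoder.h5 --out recon.h5

# score a reconstruction over the valid region
retinacode evaluate --recon recon.h5 --stimulus mov.h5 --mosaic spikes.mosaic.csv

# or run a whole experiment from a YAML config
retinacode run --config experiment.yaml --out results/
```

A minimal `experiment.yaml`:

```yaml
image_size: 32
n_trials: 3
mode: known        # flash | zero | known | joint
prior: one_over_f  # dcnn | one_over_f | gaussian
diffusion_um2_per_frame: 10.0
```

## Conventions

- Time is discretized in 1 ms bins; display frames default to 120 Hz.
- Images are luminance in [0, 1] with background gray 0.5; the stimulus
  drive uses contrast (pixel minus background).
- Trajectories are (dy, dx) displacements in µm, with the pixel path rounded
  per frame (11 µm/pixel default).
- Drift diffusion D follows the MSD = 4·D·t convention (per-axis increment
  variance 2D per frame); a `per_axis` switch is available.
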