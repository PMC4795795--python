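# reachframes

Simulation and analysis of reference frames in a trajectory-computing
sensorimotor network.

## The problem

Neurons in reach-related posterior parietal cortex (PPC) encode targets in
reference frames that span the continuum between eye-centered and
hand-centered — and these frames shift toward eye-centered coordinates
during movement.  `reachframes` implements a population model that
explains both observations with a single mechanism: an *internal kinematic
model* that computes the desired hand trajectory in visual coordinates by
temporal interpolation,

    TH = TE − HE,        he(t) = TE − ψ(t)·TH,

where TE and HE are the target and initial hand positions in eye
coordinates, TH is their difference (the displacement vector), and ψ(t)
falls from 1 at movement onset to 0 at movement offset.  Implemented with
basis-function nodes, the network's internal representations are
eye-centered (TE ⊗ HE), dynamic hand-centered (ψ(t)·TH), and
eye-and-hand-centered (TE ⊗ ψ(t)·TH) — and when analyzed exactly as
electrophysiologists analyze real populations, they reproduce the
heterogeneous, drifting reference frames reported for PPC.

The package is for computational/systems neuroscientists who want to
simulate such populations, run the standard analysis battery on them (or
on their own unit-by-condition rate tables), and compare variants of the
network:

* Gaussian-tuned, gain-modulated unit models with alternating gain signs,
  population tiling over onset space, and additive Gaussian rate noise;
* the center-out tuning screen with the spike-variance-explained criterion
  (SVE = r²·a ≥ 10, peak at least s/2 inside the task range);
* the six-parameter reference-frame regression
  r = a·exp[−(TX−μ)²/2s²]·(1+g·HE)+c with TX = w·TE + (1−w)·TH, nested
  submodels at w = 0 and w = 1, F-tests at P < 0.01, and stepwise
  classification into eye / hand / intermediate / indeterminate;
* time-resolved re-screening and re-classification across movement;
* gradient (resultant-vector) analysis of 5×5 condition-response matrices
  with angle doubling, for pure and hybrid (25/50/25) populations.

## A worked example

```
python examples/03_reference_frame_distribution.py
```

runs the delay-period pipeline at a reduced tiling (N = 10 onsets per
dimension, seed 1) and prints:

```
      eye:  18 units included | eye  94.4%  hand   0.0%  intermediate   5.6%  indeterminate   0.0%
 eye_hand:  24 units included | eye  16.7%  hand   4.2%  intermediate  79.2%  indeterminate   0.0%
     hand:   4 units included | eye   0.0%  hand 100.0%  intermediate   0.0%  indeterminate   0.0%
```

Each row is one internal node of the network: of the units passing the
tuning screen, eye-node and hand-node units are classified in their own
pure frames, while eye-and-hand-node units are predominantly classified
*intermediate* — their best-fit weight w lies strictly between the
hand-centered (w = 0) and eye-centered (w = 1) frames.  That is the
heterogeneous reference-frame distribution observed in parietal reach
areas, emerging here from a fully systematic computation.

The other example scripts follow the same pattern: desired-trajectory
kinematics (`01`), unit tuning and screening (`02`), reference-frame drift
during movement (`04`), and gradient analysis across the whole task
(`05`).  A thin CLI wraps the experiment runner:

```
reachframes reproduce fig4_noisy --seed 1 --out results/fig4
reachframes analyze my_rates.csv --out fits.csv
```

`reproduce` accepts `fig4_noiseless`, `fig4_noisy`, `fig6`, `fig7_pure`,
`fig7_hybrid`, `fig8_variantA`, `fig8_variantB`, `fig8_variantE`; the
`analyze` command runs the regression/classification on an external
unit-by-condition CSV (columns `unit_id, node, u, v, gain_sign, E, H, T,
t, rate`).

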