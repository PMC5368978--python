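# redoxflim

Dual-mode (intensity + fluorescence-lifetime) quantification of cellular
oxidative stress from two-photon TCSPC FLIM images.

## The problem

Intensity-based imaging of redox probes in living tissue is confounded by
probe concentration, depth attenuation, and autofluorescence: a bright cell
is not necessarily a probe-positive cell.  Ru(II)-complex turn-on probes for
glutathione (GSH) and reactive oxygen species (H₂O₂, HOCl) solve this with a
second, concentration-independent channel — the fluorescence **lifetime**.
The unreacted probes and tissue autofluorescence decay within a few
nanoseconds, while the analyte-reacted probes emit from a long-lived
triplet state (τ ≈ 90–225 ns), so a long *slow decay lifetime* uniquely
identifies cells in which the probe actually reacted.

`redoxflim` implements the full quantification pipeline around this idea,
for people who analyse (or simulate) intravital FLIM of hepatocytes under
oxidative-stress challenge: TCSPC decay fitting, cell segmentation,
per-cell positivity calling, subpopulation modeling, and the optical
oxidative-stress index, plus a synthetic scene generator with planted
ground truth so that every stage can be validated without microscope data.

## The model

Each pixel (or cell ROI) of a TCSPC acquisition is a histogram of photon
arrival times within the laser period.  The decay is modeled as

```
F(t) = A (α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂)) + C,     α₁ + α₂ = 1,
```

with fast lifetime τ₁ (unreacted probe pooled with 2–3 ns tissue
autofluorescence), slow lifetime τ₂ (reacted probe), and baseline C.  At an
80 MHz repetition rate the inter-pulse period is T = 12.5 ns, far shorter
than the reacted-probe lifetimes, so each pulse's emission has not finished
when the next arrives.  The steady state of this pulse train is the
**incomplete-decay model**: every exponential acquires the geometric wrap
factor of its accumulated tails,

```
F_per(t) = A [ α₁ e^(−t/τ₁)/(1 − e^(−T/τ₁)) + α₂ e^(−t/τ₂)/(1 − e^(−T/τ₂)) ] + C,   t ∈ [0, T).
```

Bin contents are Poisson, so fits maximize the Poisson likelihood of the
per-bin integrals of `F_per` (class `IncompleteDecayModel`, results in
`DecayFitResult`).  Downstream, cells are segmented by Gaussian smoothing +
global Otsu threshold + a 30–70 px equivalent-diameter and roundness filter;
a cell is called probe-positive when its slow lifetime exceeds 100 ns;
per-cell intensity histograms of positive cells are fitted with 1- and
2-component Gaussian mixtures and the Akaike information criterion
(AIC = 2p − 2 log L, p = 3k − 1) selects the number of subpopulations; and
the optical oxidative-stress index is

```
OSI = mean per-cell ROS-probe intensity / mean per-cell GSH-probe intensity,
```

compared between groups with Student's t tests under Bonferroni correction.

## Worked example

Simulate a reacted P-GSH ROI decay (10⁷ photons in 256 bins over the
12.5 ns window) and refit it:

```python
import redoxflim as rf

acq = rf.AcquisitionSpec()                      # 80 MHz -> 12.5 ns window
probe = rf.load_probe("P-GSH")
decay = rf.DecayParams.mono(probe.tau_reacted)  # fully reacted probe
hist = rf.simulate_decay_histogram(decay, acq, n_photons=1e7, seed=1)
result = rf.fit_histogram(hist, acq, n_components=1, fix_offset=0.0)
print(result.summary())
```

```
Incomplete-decay bi-exponential fit (Poisson ML)
================================================
components        1
photons           9994784
converged         True
tau1 [ns]         222.7
tau2 [ns]         222.7  (s.e. 4.35)
alpha1 / alpha2   0.0000 / 1.0000
offset C [cts/bin]         0
amplitude [cts]   9.99478e+06
log-likelihood    -1686.9444
reduced chi-sq    0.7751
```

The 225 ns input lifetime is recovered as 222.7 ± 4.35 ns even though the
observation window is 18× shorter than the lifetime — the information lives
in the slight slope of the wrapped, quasi-flat decay, and the standard
error quantifies exactly how much of it survives.

A full in-silico experiment — parallel GSH/ROS scenes, segmentation, ROI
fitting, positivity, subpopulations, OSI — is one call (or
`redoxflim run --template injury --seed 7 --out run/` from the shell):

```python
from redoxflim.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(template="injury", seed=7, outdir="run"))
print(manifest["summary"])
```

For this seed the injury template yields 18/18 planted cells segmented,
72.2% GSH-positive cells (planted: 72.2%), a two-component GSH-intensity
mixture (AIC 198.5 for k=2 vs 213.4 for k=1) and OSI = 1.68; the matching
`template="treated"` run yields a single GSH population and OSI = 0.43 —
the treatment contrast the index is designed to detect.

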