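# livespot

Headless quantification of live-cell single-molecule fluorescence movies:
photobleach correction, cell segmentation, diffraction-limited spot
detection and tracking, intensity-trace extraction, two-channel
colocalization, and fluctuation-correlation analysis of translation
kinetics — plus a ground-truth synthetic movie simulator so the whole
pipeline can be validated end to end without any raw data.

## Who it is for

Labs imaging single mRNAs and nascent proteins in live cells (MS2/PP7
stem-loop mRNA labels, SunTag/frankenbody nascent-chain labels) who need a
scriptable, reproducible alternative to interactive point-and-click
analysis. Every stage is a library function with a thin CLI on top; every
run exports its full parameter set as metadata.

## The model at the core

A translation site's nascent-protein intensity I(t) fluctuates as
ribosomes load, elongate, and release. With Poisson initiation at rate
k_i and deterministic elongation at k_e codons/s over an effective
probe-to-termination length L_eff, the normalized fluctuation
autocorrelation

    G(tau) = <dI(t) dI(t+tau)> / <I>^2,   dI = I - <I>,

decays to zero over the mean transit time tau_c = L_eff / k_e, and its
amplitude scales inversely with the mean ribosome load:
G(0) = 1 / (k_i tau_c). Measuring tau_c and G(0) therefore yields

    k_e = L_eff / tau_c,        k_i = 1 / (G(0) * tau_c).

Spots are found with a scale-normalized Laplacian-of-Gaussian filter and
an automated threshold (hybrid of the count-curve elbow and plateau),
linked frame-to-frame by gated optimal assignment with memory, and
quantified by disk photometry with ring-median background subtraction.
Photobleaching is fitted as I(t) = A exp(-k_b t) + offset on region means
and corrected multiplicatively above the offset. See `docs/methods.md`
for the full model, parameter defaults, and numerical conventions.

## Worked example

Simulate the benchmark trace ensemble (80 spots, 360 frames at 5 s,
k_i = 0.04 1/s, k_e = 5 codons/s, L_eff = 1900 codons) and recover the
kinetic rates from the autocorrelation:

```python
from livespot.simulator import benchmark_params, simulate_translation_traces
from livespot.kinetics import autocorrelate, decorrelation_time, estimate_rates

params = benchmark_params(seed=1)
traces = simulate_translation_traces(params)          # (80 spots, 360 frames)
acf = autocorrelate(traces, dt_s=params.frame_interval_s)
tau = decorrelation_time(acf)
est = estimate_rates(acf, tau, L_eff_codons=params.effective_length)

print(f"G(0) raw / extrapolated : {acf.g0_raw:.4f} / {acf.g0_extrap:.4f}")
print(f"de-correlation time     : {tau:.0f} s")
print(f"elongation rate ke      : {est.ke_codons_per_s:.2f} codons/s")
print(f"initiation rate ki      : {est.ki_per_s:.4f} 1/s")
print(f"95% CI for ke           : ({est.ke_ci[0]:.2f}, {est.ke_ci[1]:.2f})")
```

Output:

```
G(0) raw / extrapolated : 0.0693 / 0.0694
de-correlation time     : 357 s
elongation rate ke      : 5.33 codons/s
initiation rate ki      : 0.0404 1/s
95% CI for ke           : (4.83, 5.80)
```

The recovered rates sit within a few percent of the simulated truth
(k_e = 5, k_i = 0.04); the de-correlation time estimates the 380-s mean
probe-to-stop transit time.

A full movie analysis runs from a YAML config:

```bash
livespot pipeline --config examples/benchmark.yaml --out run1 --seed 1
```

which writes `movie.tif`, `truth.csv`, `spots.csv`, `tracks.csv`,
`traces.csv`, `correlation.csv`, `kinetics.json` and `metadata.json`
(the complete parameter record) into `run1/`.

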