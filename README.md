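# sensillum

Analysis pipeline for pheromone-sensitive olfactory receptor neuron (ORN)
responses recorded from insect sensilla by tip-recording, plus a synthetic
recording generator with known ground truth so the whole pipeline is
testable end to end without any experimental data.

The pipeline quantifies the three components of the ORN pheromone response
(phasic burst, tonic spiking, late long-lasting response) from dual-channel
recordings (unfiltered DC + 150 Hz high-pass AC, 20 kHz):

1. **synth** — renders synthetic dual-channel recordings: a near-regular
   phasic burst, Poisson tonic and late long-lasting components, a negative
   difference-of-exponentials DC deflection, per-condition linear parameter
   drift, additive Gaussian noise; plus qPCR Ct tables. Ground truth is
   reported from the realized spike times, so recovery is checkable
   sample-exactly.
2. **sigio** — HDF5 recording containers (`/dc`, `/ac` + attributes),
   zero-phase Butterworth AC derivation, CSV/XLS feature-, slope- and
   raw-parameter tables (missing cells round-trip as `"NaN"`).
3. **features** — threshold spike detection on the AC trace (auto threshold
   = 5x MAD noise SD, refractory 1 ms) and the five per-stimulus response
   parameters: latency to the first spike after the DC response onset,
   F_6AP (mean instantaneous frequency of the first six spikes), sensillum
   potential amplitude (SPA), spike count in a 1 s or 100 ms early window,
   and the late-response count from 5 s after a stimulus to the next one.
4. **kinetics** — 10 ms PSTHs of the first second pooled across
   stimulations per animal; the cumulative histogram is fitted with
   `AP(t) = AP_max / (1 + exp((t - t_half)/k))`, k < 0.
5. **stats** — per-animal OLS slopes of each parameter over recording time,
   gated to exactly 0 when the slope's t test is not significant; group
   comparison via a fixed decision tree (Shapiro-Wilk + Levene -> one-way
   ANOVA/Tukey, log transform on normality failure for positive data,
   otherwise Kruskal-Wallis/Dunn), and one-way repeated-measures ANOVA for
   paired designs.
6. **qpcr** — relative expression by 2^-ddCt with two reference genes
   (technical means first, arithmetic-mean reference aggregation,
   configurable calibrator group) and ANOVA across zeitgeber times.

## CLI

```sh
sensillum simulate --design design.yaml --seed 1 --out sim/
sensillum inspect sim/ctrl_ZT1-3_00_day1.h5
sensillum extract --rec sim/ctrl_ZT1-3_00_day1.h5 --early-window 1000 --out features.csv
sensillum fit-kinetics --rec sim/ctrl_ZT1-3_00_day1.h5 --out fits.csv
sensillum slopes --features features.csv --out slopes.csv
sensillum compare --slopes slopes.csv --parameter f6ap --out stats.json
sensillum qpcr --ct ct.csv --target PLCb4 --refs RPS13,G3PDH --calibrator ZT1
```

A design YAML lists groups as `[condition, zt, n_animals]` plus schedule
fields (`stimulus_interval`, `recording_duration`, `first_stimulus`,
`paired`, ...) and per-group `params` for `GroundTruthParams`.

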