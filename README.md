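# ssdkit

Data-driven spatial filters for multichannel electrophysiology.

Intracranial recordings (ECoG grids, depth arrays) mix several neuronal
rhythms plus broadband 1/f background and line noise into every electrode.
`ssdkit` separates these rhythms with **spatio-spectral decomposition
(SSD)**: given a signal band of interest (say 8–12 Hz) and flanking noise
bands (6–7 and 13–14 Hz), it finds spatial filters **w** maximizing the
Rayleigh quotient

```
SNR(w) = (wᵀ C_S w) / (wᵀ C_N w)
```

where `C_S` and `C_N` are the covariance matrices of the band-pass-filtered
signal and flank ("noise") contributions. The maximizers solve the
generalized eigenvalue problem `C_S W = C_N W Λ`; the eigenvalues are the
achieved band-limited SNRs. Filters are then applied to the **broadband**
data, so harmonics of non-sinusoidal rhythms — which share the source's
spatial profile — are preserved in the component time series.

Around this core the package provides:

- **Spectral parameterization** — Welch spectra decomposed into an
  aperiodic component `b − χ·log₁₀ f` plus Gaussian peaks
  `aₙ·exp(−(f−μₙ)²/2σₙ²)` in log₁₀-power; the largest in-band peak height,
  `10·a` dB, is a 1/f-corrected SNR used to select oscillation bands and to
  retain components (default threshold 5 dB).
- **Spatial patterns** — `A = C_S W (WᵀC_S W)⁺`, the interpretable forward
  model of each component (`AᵀW = Id`), plus a spatial-spread statistic:
  the largest normalized pattern coefficient within 25 mm of the pattern
  maximum.
- **Waveform-shape analysis** — cycle-by-cycle segmentation with burst
  classification and signed peak-trough / rise-decay asymmetries
  (`(peak_time − trough_time)/period`; 0 for a symmetric waveform).
- **Spatial line-noise removal** — SSD components maximizing SNR at e.g.
  60 ± 1.75 Hz are subtracted linearly (`X_cleaned = X − Σ aⱼ sⱼ`),
  attenuating the artifact without the spectral notch and ringing of a
  band-stop filter.
- **A forward-model simulator** — bursty, optionally non-sinusoidal sources
  with Gaussian spatial profiles on an electrode grid, 1/f^χ channel noise
  and optional common line noise, with full ground truth for validation.

## Worked example

```python
import ssdkit as sk

# simulate a 180 s, 20-channel grid recording with three bursty alpha
# rhythms (9, 10.5, 11.5 Hz; the 10.5 Hz one arc-shaped) and a 16 Hz rhythm
rec, truth = sk.simulate_recording(duration=180, seed=0)

band = sk.make_band(10)               # signal (8,12), flanks (6,7)/(13,14)
model = sk.fit_ssd(rec, band)
cs = sk.score_components(model, rec)  # 1/f-corrected SNR per component
print(cs.table.head(4).round(2))
```

```
   component  eigenvalue  snr_db  peak_hz  retained
0          0      612.58   29.64     8.88      True
1          1      198.22   24.66    10.55      True
2          2       59.39   27.95    11.55      True
3          3        2.19    0.00      NaN     False
```

The three alpha sources appear as the top three components — eigenvalues
(band-limited SNR) drop off fast, and the fitted component peak frequencies
(8.88, 10.55, 11.55 Hz) recover the simulated rhythms. Only components
whose spectral peak exceeds the aperiodic fit by more than 5 dB are
retained. Waveform shape of the arc-shaped rhythm:

```python
j = int(cs.table.loc[1, "component"])          # the 10.5 Hz component
ct = sk.burst_mask(sk.segment_cycles(cs.series[:, j], rec.fs, 10.5))
print(sk.summarize_bursts(ct))
```

```
{'n_burst_cycles': 305, 'amplitude': 4.34, 'frequency_hz': 10.5,
 'peak_trough_asym': 0.22, 'rise_decay_asym': 0.01}
```

The positive peak-trough asymmetry (≈0.22, generator truth 0.3 before
band-limiting) identifies the non-sinusoidal, mu-like rhythm; e.g. an
asymmetry of 0.2 on a 100 ms cycle means 60 ms spent in the peak and 40 ms
in the trough.

The same workflow is available from the shell:

```
ssdkit simulate --duration 180 --seed 0 -o scene.bin
ssdkit fit scene.bin --band 8,12 --flanks 6,7,13,14 -o model.json
ssdkit components model.json scene.bin -o components.tsv
ssdkit denoise scene.bin --noise-hz 60 -o cleaned.bin
ssdkit run config.json -o results/
```

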