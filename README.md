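# hemophase

Non-invasive blood-glucose *trend* estimation from ordinary two-wavelength
photoplethysmography (PPG), built on a phase-delay metabolic index.

Conventional pulse oximetry treats the oxy- and deoxyhemoglobin pulsations as
synchronous. Under the modified Beer–Lambert law with a pulsating optical
path length, a perfectly synchronous model forces the deoxyhemoglobin
concentration pulsation to vanish — which contradicts the fact that tissue
consumes oxygen every beat. Admitting a small, slowly varying phase delay
Δθ(t) of the deoxyhemoglobin signal

    N_HbO2,AC(t) = A_HbO2(t) · sin ωt
    N_Hb,AC(t)   = A_Hb(t)   · sin(ωt − Δθ(t))

resolves the contradiction and yields a deoxyhemoglobin pulsation amplitude

    C_Hb,AC(t) = [A_HbO2(t) + A_Hb(t)] / L(t) · SaO2(t)·[1 − SaO2(t)]·|Δθ(t)|

proportional to per-beat oxygen consumption. Its dimensionless, path-free
core is the **metabolic index**

    MI(t) = SaO2(t) · [1 − SaO2(t)] · |Δθ(t)|,

with SaO2 = A_HbO2 / (A_HbO2 + A_Hb) from the cardiac-fundamental FFT
amplitudes and Δθ from the FFT phase difference at the same bin. Because
oxygen consumption rises with blood glucose, MI tracks glucose excursions. A
perfusion-amplitude correction

    α(t) = [(A_HbO2 + A_Hb) / (A_HbO2,0 + A_Hb,0)]^(1 − 1/n),   MI′ = α · MI

(default n = 0.5) compensates slow changes in pulsatile path length.

The package is for researchers in biomedical optics and physiological signal
processing who want a tested, reusable reference implementation: readers for
plain two-channel intensity CSVs, the MBLL inversion, the spectral
phase-delay pipeline, minute-level post-processing, glucose calibration and
agreement metrics (Pearson r, MARD, RMSE, Parkes consensus error grid for
type 1 diabetes), and a forward hemodynamic simulator that provides ground
truth for every inverse stage. No subject data ship with the package; every
fixture is synthesized.

## Worked example

Simulate a 90-minute oral-challenge session (glucose rising from 90 to
~155 mg/dL and decaying, coupled to Δθ at 0.1 rad per 40 mg/dL, CGM-like
reference with a 15-min sensor delay), process it, and evaluate:

```bash
$ cat sim.yaml
duration_s: 5400.0
$ hemophase simulate --config sim.yaml --out demo --seed 7 --delay-s 900
simulated 5400 s at 100 Hz into demo
$ hemophase process --ppg demo/ppg.csv --out demo/results.csv
INFO processed 1686 windows (1686 ok, 0 low-SNR, 0 rejected), filter order 3
wrote 1686 windows (1686 ok) to demo/results.csv
$ hemophase evaluate --results demo/results.csv --reference demo/glucose.csv --delay-s 900
n=75 pairs | r=0.992 | slope=5028 mg/dL per MI, intercept=64.47 mg/dL | MARD=2.3% | RMSE=2.9 mg/dL | zones [A: 100.0%]
```

Reading the numbers: 1686 four-beat analysis windows passed the quality
gates; the per-minute smoothed MI trend, interpolated onto the
delay-compensated reference timestamps, correlates with glucose at r = 0.992;
the fitted linear conversion maps MI ≈ 0.005–0.020 onto 90–165 mg/dL; and
every calibrated estimate lands in Parkes zone A (clinically benign error).
On clean synthetic data the agreement is limited only by measurement noise —
real skin, motion and physiology will do worse (see `docs/methods.md`).

The same flow works from Python:

```python
import hemophase as hp

params = hp.session_params(seed=7)
record, glucose, truth = hp.simulate_session(params, sensor_delay_s=900.0)
result = hp.process_record(record)            # per-window SaO2, Δθ, MI, MI′
series = result.minute_series()               # robust 1-min means + smoothing
report = hp.evaluate_session(series, glucose) # fit + r/MARD/RMSE/zones
print(report.summary())
```

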