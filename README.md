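# erpbci

**Predicting visual P300-speller aptitude from auditory-oddball ERPs — a
simulation and analysis pipeline.**

People with severe motor impairment can use a P300 matrix speller as a
communication channel, but the attainable performance ("BCI aptitude")
varies widely between users, and finding out by running full speller
sessions is exhausting for exactly the population that needs the system
most. A short passive auditory oddball session offers a way out: the
amplitudes of the event-related potentials it evokes — N1, P2, N2 and P300 —
correlate strongly with the number of errors the same person later makes
when spelling. `erpbci` implements that whole study design as reproducible,
tested code:

1. **synthetic cohorts** — virtual participants with per-component ERP
   amplitude/latency parameters, 1/f background EEG, ocular artifacts, and a
   *planted* rank correlation ρ between N2 strength and expected speller
   error count;
2. **signal processing** — zero-phase least-squares FIR band-pass
   (0.5–20 Hz), AMUSE blind source separation for blink removal, common
   average reference, epoching (0–800 ms) and baseline correction
   (−100–0 ms);
3. **ERP features** — condition averages, component peaks in the standard
   windows (N1 100–200, P2 200–250, N2 250–375, P3 250–700 ms), with
   sign-inverted amplitude reporting for channels posterior to Cz;
4. **speller simulation** — SWLDA (stepwise linear discriminant analysis:
   forward entry at p<0.1, backward removal at p≥0.15, 60-feature cap) on
   moving-average/decimated single-trial features, row/column score summing,
   per-session error counts;
5. **aptitude statistics** — Spearman rank correlations, signed-r²
   spatio-temporal maps (sign(ρ)·ρ²), peak-correlation tables with the
   p>0.1 readability mask, median-split group t-tests, and the accuracy
   estimate 100·required/(required+errors).

## Worked example

```python
from scipy.stats import spearmanr
from erpbci import (make_cohort, expected_errors, simulate_oddball_session,
                    preprocess_oddball, average_erp, component_peak_table,
                    MONTAGE_16)

cohort = make_cohort(n=11, planted_rho=-0.85, seed=7)
print(f"mean P3 latency {sum(p.comp_lat['P3'] for p in cohort)/11:.1f} ms")

amps, errs = [], []
for i, p in enumerate(cohort):
    rec = simulate_oddball_session(p, seed=100 + i)   # 300 tones, 60 deviants
    epochs = preprocess_oddball(rec)                  # filter, AMUSE, CAR, epoch
    table = component_peak_table(average_erp(epochs, "deviant"),
                                 epochs.time, MONTAGE_16)
    amps.append(table.amplitude[("N2", "Oz")])
    errs.append(expected_errors(p))
rho, p = spearmanr(amps, errs)
print(f"Oz N2 amplitude vs errors: rho = {rho:.2f} (p = {p:.3f})")
```

prints

```
mean P3 latency 336.6 ms
Oz N2 amplitude vs errors: rho = -0.62 (p = 0.043)
```

Eleven simulated participants: the cohort's mean P3 latency parameter sits
in the mid-300 ms range typical of motor-impaired users, and even at n = 11
with realistic single-session noise the planted negative coupling between
occipital N2 amplitude (posterior-inverted convention) and speller errors is
recovered as a significant negative rank correlation — larger N2, fewer
errors.

The full study design (three sessions per participant, SWLDA calibration and
40-selection speller task, correlation maps, peak tables, median split,
report) runs from one config:

```bash
erpbci all --seed 7 --outdir run1          # or --config study.yaml
erpbci report --outdir run1 --figures
```

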