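# foulfit

Pore-blocking (fouling) analysis for constant-pressure membrane filtration:
simulate permeate-flux decline under the four classical blocking mechanisms,
fit the linearized blocking laws to flux data, attribute the dominant
mechanism per filtration stage, and compute filtration-train performance
metrics. Built for downstream bioprocessing workflows — the packaged example
is a seven-stage crossflow train (0.45 µm microfiltration followed by
1000/500/300/100/50/10 kDa ultrafiltration) concentrating a fungal laccase
extract — but the models are generic to constant-TMP micro/ultrafiltration.

## The model

Flux decline at constant transmembrane pressure is described by the unified
blocking law with a crossflow removal term,

    −dJ/dt = K (J − J_R) J^(2−n)

where `J` is the permeate flux (L·m⁻²·h⁻¹), `J_R` the steady-state flux
sustained by crossflow back-transport, and the blocking index `n` selects
the mechanism: **2** complete pore blocking, **1.5** standard blocking
(pore filling), **1** intermediate blocking, **0** cake formation.
`J_R = 0` gives the dead-end family. Each mechanism has an exactly linear
transform — e.g. `ln J = −K_b·t + ln J_o` (dead-end complete), or
`(J_o−J)/t = K_bF·(v/t) − K_bF·J_R` (crossflow complete, with `v` the
cumulative permeate volume per membrane area) — so constants are estimated
by ordinary least squares, with the linearized R², the slope-sign validity
check and the flux-reconstruction RMSE as the attribution diagnostics.
Per-stage train performance is summarised by the volumetric and activity
concentration factors `VCF = V₀/V_r`, `ACF = Lac_r/Lac₀`, recovery
`R = ACF/VCF` and purification factor `PF = SA_r/SA₀`, and the
degree-of-fouling criterion `V_max = |ln f|/K_i` of the intermediate law.

See `docs/methods.md` for the full model account, estimator design and
limitations.

## Worked example

Simulate a crossflow stage under complete pore blocking, add 2% measurement
noise, and fit/attribute:

```python
import foulfit as ff

params = ff.BlockingParams("complete", Jo=400.0, K=2.0, JR=60.0,
                           family="crossflow")
series = ff.simulate_crossflow(params, ff.default_time_grid(60))
noisy = ff.add_noise(series, ff.NoiseSpec(cv=0.02, seed=42))

res = ff.BlockingLawModel(noisy, "complete", family="crossflow", jo=400.0).fit()
print(res.summary())
```

```
Blocking-law fit
======================================
stage             sim complete crossflow
family            crossflow
mechanism         complete (n=2)
n points          55
K                 2.0851 1/h
K (SI)            0.000579195 1/s
Jo                400 L/m2 h
JR                68.0094 L/m2 h
R2 (linearized)   0.975745
RMSE flux         3.91434 L/m2 h
slope sign valid  True
```

The fitted blocking constant (2.09 h⁻¹) and steady-state flux
(68 L·m⁻²·h⁻¹) recover the generating values (2.0, 60) to within the noise;
`slope sign valid` confirms the decline is compatible with the mechanism.
Ranking all four mechanisms picks the generator and rejects the others on
slope-sign/clamping grounds despite their respectable linearized R²:

```python
report = ff.rank_mechanisms(noisy, "crossflow", jo=400.0)
print(report.summary())
```

```
Mechanism ranking — stage sim complete crossflow (crossflow)
============================================================
* complete     R2= 0.97575  K=2.085 1/h  JR=68.01  rmse=3.914
  standard     R2= 0.95557  K=0.0418 1/(h^0.5 (L/m2)^0.5)  JR=0  rmse=12.19  [invalid]
  cake         R2= 0.91521  K=-1.52e-05 h m4/L2  JR=400  rmse=211.3  [invalid]
  intermediate R2= 0.82292  K=0.002341 m2/L  JR=0  rmse=80.81  [invalid]
```

Train performance for the packaged laccase example (volumes in mL,
activities in U/mL, protein in mg/mL; `R_pct` is percent recovery):

```sh
$ foulfit performance --demo
  stage   VCF  ACF  R_pct   PF  SA_feed  SA_retentate
     MF 16.67 4.78  28.70 1.37     2.71          3.71
UF 1000 10.44 2.04  19.55 1.49     2.08          3.08
 UF 500 28.33 0.80   2.81 1.79     1.36          2.42
 UF 300 26.67 0.89   3.32 0.89     1.63          1.44
 UF 100 24.33 4.98  20.46 6.97     1.36          9.46
  UF 50 23.00 5.34  23.21 3.20     1.18          3.79
  UF 10 21.33 5.65  26.49 4.04     0.92          3.71
```

Microfiltration concentrates 16.7-fold with 29% activity recovery; the
100 kDa stage delivers the best purification (PF ≈ 7.0), consistent with
laccases in the 50–70 kDa range being retained there.

The CLI also provides `simulate` (YAML config → `time,flux` CSV), `fit`,
`select` (mechanism ranking → JSON report) and `report` (full pipeline over
many stage CSVs).

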