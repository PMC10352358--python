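# fliopipe

Analysis pipeline for **fluorescence lifetime imaging ophthalmoscopy
(FLIO)**: per-pixel biexponential lifetime fitting of two-channel TCSPC
photon histograms, ETDRS-grid regional statistics, and a full cohort
comparison battery — together with a synthetic-data generator that
emulates a smoker / non-smoker study cohort so that every stage can be
exercised and validated without access to clinical raw data.

## Who this is for

FLIO measures the autofluorescence decay of the ocular fundus pixel by
pixel (473 nm pulsed excitation at 80 MHz; emission split into a short
spectral channel, SSC 498–560 nm, and a long one, LSC 560–720 nm; photon
arrival times histogrammed by time-correlated single photon counting
until the foveal-centre pixel has collected 1000 photons). Changes in
the fluorescence lifetime of retinal fluorophores track metabolic state,
which makes FLIO interesting for studying lifestyle exposures — such as
cigarette smoking — in structurally healthy eyes. This package is aimed
at researchers who want a transparent, scriptable re-implementation of
that analysis chain, plus a simulator for power analysis and method
validation.

## The model

Each pixel's decay is modelled as a biexponential

    f(t) = α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂)

with short and long lifetime components τ₁ ≤ τ₂ (ps). Because the laser
period (12.5 ns) is not long against τ₂, the model sums the contributions
of all preceding pulses (each component is multiplied by
1/(1 − e^(−T/τᵢ))), and the result is convolved with the instrument
response function before being compared with the measured counts.
Parameters are estimated per pixel by Poisson maximum likelihood — at
1000 photons per pixel most bins hold only a few counts, where Gaussian
least squares is biased. The headline summary statistic is the
amplitude-weighted mean lifetime

    τ_m = (α₁τ₁ + α₂τ₂) / (α₁ + α₂),

reported per region of the ETDRS macular grid (central subfield C within
1 mm diameter; inner and outer rings at 3 mm and 6 mm, each split into
nasal / superior / temporal / inferior quadrants; IR and OR are the
pooled rings). Group comparisons use unpaired t-tests (two groups) and
one-way ANOVA with Tukey HSD post hoc tests (non-smokers vs light vs
heavy smokers, split at the smokers' median pack-year), with
Kruskal–Wallis/Dunn routing when a Shapiro–Wilk screen rejects
normality; correlations are Pearson r with Cohen's magnitude labels.

## Worked example

```python
from fliopipe.simulate import default_population, generate_cohort, generate_regional_cohort
from fliopipe.stats import run_full_analysis

pop = default_population()                      # published group distributions
subjects = generate_cohort(pop, seed=1)         # 26 non-smokers + 28 smokers
regional = generate_regional_cohort(pop, subjects, seed=2)
tables = run_full_analysis(regional, subjects)

row = tables.flt[(tables.flt.channel == "SSC") & (tables.flt.region == "IR")
                 & (tables.flt.parameter == "tau_m")].iloc[0]
print(f"SSC inner ring tau_m: non-smokers {row.nonsmoker_mean:.1f} ps, "
      f"smokers {row.smoker_mean:.1f} ps, p = {row.p_two_group:.4f}")
print(f"pack-year split value: {tables.assignment.split_value:.2f}")
print(f"between-eye r range: {tables.inter_eye.r.min():.3f} - {tables.inter_eye.r.max():.3f}")
```

prints

```
SSC inner ring tau_m: non-smokers 214.4 ps, smokers 223.7 ps, p = 0.0255
pack-year split value: 7.38
between-eye r range: 0.824 - 0.943
```

Non-smokers' inner-ring mean lifetime in the short channel sits near the
configured population mean of 210 ps, the smokers' near 220 ps, and at
this cohort size the ~10 ps group difference reaches two-sided
significance; the smokers split into light/heavy subgroups near the
configured median pack-year of 7.11, and every between-eye correlation
exceeds 0.8, as expected for the configured inter-eye correlation of 0.9.

The same chain is available from the shell; `flio all --config run.toml`
writes the cohort CSV, regional summaries and all statistics tables, and
`flio simulate --mode full`, `flio fit`, `flio grid` run the photon-level
pipeline (histogram cubes in HDF5, lifetime maps as 32-bit TIFF,
pseudo-color PNG renders with the orange-to-blue lifetime scale).

## Layout

| module               | contents                                                          |
|----------------------|-------------------------------------------------------------------|
| `fliopipe.decay`     | biexponential model, τ_m, IRF convolution, SPCImage-style binning |
| `fliopipe.fitting`   | per-pixel Poisson ML fit, lifetime maps, brute-force grid oracle  |
| `fliopipe.grid`      | ETDRS masks and regional reduction                                |
| `fliopipe.simulate`  | cohort, ground-truth and photon-cube generators                   |
| `fliopipe.stats`     | group comparisons, correlations, full cohort battery              |
| `fliopipe.io` / `cli`| HDF5 / TIFF / CSV / TOML / PNG formats and the `flio` command     |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
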