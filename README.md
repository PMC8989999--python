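# acidhet

Single-cell analysis of phenotypic heterogeneity in the three inducible
acid-resistance (AR) systems of *Escherichia coli* — Gad (glutamate), Adi
(arginine) and Cad (lysine) — and comparative genomics of their antiporters
(GadC, AdiC, CadB) across bacteria.

The package is aimed at microbiologists quantifying division of labor in
stress responses from multi-color reporter micrographs: each antiporter is
chromosomally fused to a fluorophore (eGFP, mCerulean, mCherry), and per-cell
fluorescence across conditions (pH 7.6 / pH 5.8 + lysine / pH 4.4, several
time points) reveals which cells activate which AR system.

## What it computes

**Intensity chain** (per cell, per channel):

1. per-field background subtraction;
2. spectral crosstalk correction of the GFP channel for CFP bleed-through,
   RF′ = RF_gfp − f·RF_cfp, with *f* fitted by zero-intercept least squares
   (f = Σxy/Σx²) or supplied (0.456 in the reference calibration);
3. brightness normalization across fluorophores,
   nRF = RF·B_max/B_fluor (eGFP 33, mCerulean 16, mCherry 15);
4. the heterogeneity ("noise") statistic of a sample:
   **noise = σ(y)/μ(y), y = ln(x + 1)** — the coefficient of variation of
   log-transformed intensities, robust for skewed distributions and low
   expression.

**Population statistics**: ON/OFF calls against a non-fluorescent control
(threshold μ + k·σ, default k = 3), Pearson correlation between channels,
chi-square homogeneity tests of binned intensity histograms (tail pooling to
expected ≥ 5), moment skewness, and luminescence normalization to RLU
(counts s⁻¹ mL⁻¹ OD₆₀₀⁻¹).

**Imaging**: Otsu segmentation of rod-shaped cells, medial-axis shape
descriptors (length, width, curvature, angularity), and the rod-shape gates
(area ≥ 0.1 µm², length 1.2–5 µm, width 0.1–1 µm, curvature ≤ 0.15,
angularity ≤ 0.25).

**Comparative genomics**: filtering of protein BLAST hit tables with
per-component e-value cutoffs (e.g. e < 10⁻¹⁰⁰ for GadC, e < 10⁻¹²⁰ for
AdiC/CadB) and a ±10% length tolerance; species × component presence/absence
matrices; co-occurrence percentages; Jukes-Cantor distances
d = −((a−1)/a)·ln(1 − a·p/(a−1)); Saitou–Nei neighbor joining; Felsenstein
bootstrap supports; Newick and iTOL ring-annotation output.

**Synthetic data**: every input above can be generated with known ground
truth — correlated three-channel populations (Gaussian copula over normal or
lognormal marginals, additive bleed-through, per-field background),
micrographs of planted spherocylinders, presence tables, and alignments
evolved under the equal-rates substitution model on a known tree.

## Worked example

```python
import numpy as np
from acidhet import synthesize as syn, quantify as q, popstats as ps

channels = [
    syn.ChannelSpec("gfp", on_fraction=0.99, family="normal",
                    loc=300, scale=40, off_level=5),
    syn.ChannelSpec("cfp", on_fraction=0.477, family="normal",
                    loc=250, scale=35, off_level=5),
    syn.ChannelSpec("mcherry", on_fraction=0.83, family="lognormal",
                    loc=5.5, scale=0.6, off_level=5),
]
corr = np.array([[1.0, 0.45, 0.10], [0.45, 1.0, -0.07], [0.10, -0.07, 1.0]])
bleed = np.zeros((3, 3)); bleed[0, 1] = 0.456   # GFP receives CFP signal

spec = syn.PopulationSpec(channels=channels, correlation=corr, bleed=bleed,
                          background_mean=50.0, background_sd=5.0,
                          n_fields=4, cells_per_field=250, seed=42,
                          condition="pH 4.4", time_min=300)
cells = syn.simulate_population(spec)
bg = {f: {c.name: 50.0 for c in channels} for f in range(4)}
cells = q.process_cells(cells, {"gfp": "eGFP", "cfp": "mCerulean",
                                "mcherry": "mCherry"}, backgrounds=bg)
for ch in ("gfp", "cfp", "mcherry"):
    mean_rf, noise = q.compute_noise(cells[f"{ch}_nrf"])
    print(f"{ch:8s} mean nRF = {mean_rf:7.1f}   noise = {noise:.3f}   "
          f"skewness = {ps.skewness(cells[f'{ch}_nrf']):+.2f}")
```

prints

```
gfp      mean nRF =   297.8   noise = 0.076   skewness = -1.73
cfp      mean nRF =   256.0   noise = 0.724   skewness = +0.11
mcherry  mean nRF =   529.7   noise = 0.301   skewness = +1.77
```

The fully-ON GFP channel is homogeneous (noise 0.076). The CFP channel —
only 47.7% of cells ON — is strongly bimodal, which the log-CV statistic
reports as high noise (0.724). The mCherry channel (83% ON, lognormal ON
intensities) shows the intermediate noise and the positive skew
characteristic of a right-skewed activation pattern.

A pipeline run tying all stages together (`acid-het run --config run.yaml
--out out/`) writes per-condition summary tables, channel-pair correlations,
presence matrices with co-occurrence percentages, and bootstrapped NJ trees.

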