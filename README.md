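# serscyto

Multiplexed SERS nanotag cytometry: spectral unmixing, cell-line
classification, and embedding selection for five-plex integrin profiling of
single cancer cells.

## The problem

Surface-enhanced Raman scattering (SERS) nanotags let one laser shot read
several surface markers off a single cell at once: each nanotag carries a
Raman reporter dye with a distinct fingerprint spectrum and an antibody
against one integrin. A cell decorated with five nanotag colors yields one
composite spectrum, and the analysis problem is to (1) decompose that
spectrum into per-tag contributions, (2) use the resulting five-marker
profiles to tell cancer cell lines apart, and (3) visualize the profile
space. `serscyto` implements that computational workflow for the five-plex
panel in which DTDC, SiNC, BHQ3, QXL680 and QSY21 (strongest bands at 510,
684, 1094, 1140 and 1496 cm⁻¹) report integrins β5, α3, β1, β3 and β4 on
the breast-cancer lines MM231, MCF7 and SKBR3 — and ships a synthetic-data
generator so the whole pipeline runs and is tested without any instrument.

## The model

A measured cell spectrum is modelled as a linear combination of the five
pure-nanotag reference spectra,

    S_total = C₁S₁ + C₂S₂ + C₃S₃ + C₄S₄ + C₅S₅ + Δ,

and classical least squares (CLS) finds the weight factors C₁…C₅ that
minimise ‖Δ‖₂ — unconstrained (`ols`) or with Cᵢ ≥ 0 (`nnls`, the default,
since the weights represent physical signal fractions). The weight factors
are relative intensities against the pure-tag reference spectra and proxy
the abundance of each integrin on the cell. Downstream:

* **Classification** — a random forest (100 trees, unlimited depth) on the
  five weight factors; stratified 70/30 split, repeated over independent
  resplits; evaluation by confusion matrix, per-class precision/recall,
  per-class F1 = 2·PRE·REC/(PRE+REC), and the macro (unweighted) average F1.
* **Embedding selection** — t-SNE replicates per candidate perplexity; the
  replicate with the lowest final Kullback–Leibler divergence represents a
  perplexity, and the perplexity whose representative embedding minimises
  the Davies–Bouldin index, DBI = (1/k) Σᵢ maxⱼ≠ᵢ (σᵢ+σⱼ)/d(cᵢ,cⱼ), wins.
* **Preprocessing** — multi-segment iterative-polynomial baseline
  subtraction and boxcar smoothing on the 250–3000 cm⁻¹ / 7 cm⁻¹ grid.

## Worked example

```sh
python examples/01_unmix_mixture_panel.py
```

```
design 1:6:1:1:1  (reporter: designed -> recovered fraction)
  DTDC    0.10 -> 0.106
  SiNC    0.10 -> 0.088
  BHQ3    0.10 -> 0.110
  QXL680  0.60 -> 0.590
  QSY21   0.10 -> 0.107

pooled recovery over 40 (design, tag) pairs: r = 0.9978, p = 2.71e-46
```

Eight five-tag mixtures are simulated at designed ratios with 1.5% additive
noise and unmixed by non-negative CLS; each recovered fraction sits within a
couple of percent of its design, and the pooled Pearson r of 0.998 says the
deconvolution reproduces the designed proportions essentially perfectly at
this noise level. The other examples classify the three cell lines
(`02_classify_cell_lines.py`, mean macro F1 ≈ 0.98 on the default synthetic
population and a predicted-vs-training profile correlation of r ≈ 0.9998),
select a t-SNE perplexity (`03_select_tsne_perplexity.py`), and run the full
pipeline (`04_full_pipeline.py`).

The same stages are available from the shell:

```sh
serscyto run --config examples/config.yaml --seed 0 --out out/
```

writes the reference library, the mixture-recovery table and correlation,
the per-cell profile table, confusion matrices (counts and fractions), the
mixed-population prediction summary, the embedding audit trail, and a
machine-readable `summary.json`; individual subcommands (`simulate-refs`,
`simulate-cells`, `mixture-panel`, `preprocess`, `unmix`, `classify`,
`embed`) expose one stage each. Runs are byte-reproducible for a fixed
config and seed.

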