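# immetab

Quantitative analysis toolkit for T cell immunometabolism studies — built for
the question of how a microenvironmental metabolite (succinate, accumulated
by SDH-mutant pheochromocytoma/paraganglioma tumors) suppresses T cell
effector function. It covers the four measurement modalities such a study
chains together, each testable against synthetic data with known ground
truth:

* **Stable-isotope tracing** (`immetab.isotopes`): natural-abundance
  correction of GC-MS isotopologue spectra. For a derivatized fragment with
  elemental formula F and n tracer carbons, the forward model is a
  correction matrix **M** with column *j* = natural isotope distribution of
  F minus *j* heavy-fixed carbons, shifted by *j*; the mass isotopomer
  distribution (MID) solves **M**·x ≈ counts by non-negative least squares
  with renormalization. Fractional enrichment Σᵢ i·Mᵢ/n,
  internal-standard-normalized abundances, and metabolite ratios follow.
* **Extracellular-flux bioenergetics** (`immetab.flux`): ATP-coupled OCR
  (mean of the 3 cycles before oligomycin − mean of the 3 after), basal
  glycolysis (post-glucose − pre-glucose ECAR 3-means), their ratio, and
  mitochondrial/glycolytic/total ATP synthesis rates with every constant
  (P/O = 2.75, CO₂ acidification factor 0.61, ECAR→proton-efflux factor)
  exposed and configurable.
* **Gene-signature scoring** (`immetab.signature`): median-of-ratios size
  factors, log2 normalized counts, the per-sample geometric mean of log2
  normalized counts over an IFN-γ response gene set, per-gene relative
  abundances, and Wilcoxon/t group comparisons.
* **Cytokine quantitation** (`immetab.elisa`): four-parameter logistic
  standard curves y = d + (a−d)/(1+(x/c)^b), analytic inverse
  interpolation, and correction of concentrations to a reference live-cell
  input: corrected = raw × ref / (cells × viability).

`immetab.simulate` generates seeded, truth-labelled synthetic inputs for all
four stages (log-normal ion-count noise, Gaussian flux noise,
negative-binomial counts for an 18-vs-27 two-group cohort, 4PL plates);
`immetab.stats` holds the shared tests (paired t, one-way ANOVA with
Bonferroni post-tests, rank-sum); `immetab.pipeline` orchestrates everything
from one YAML config with byte-reproducible outputs.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import numpy as np
from immetab import simulate as sim, isotopes as iso, flux as fx, signature as sg
from immetab.io import spectra_from_table

# --- tracing: cells grown on fully 13C-labeled succinate ------------------
scen = sim.TracerScenario(noise_cv=0.01, seed=1)          # C4 fragment, true m+4 = 0.70
spectra, truth = sim.gen_isotopologue_spectra(scen, n_samples=3)
M = iso.build_correction_matrix(scen.fragment_formula, scen.n_tracer_positions)
for spec in spectra_from_table(spectra):
    mid = iso.correct_mid(spec, M)
    print(spec.sample_id, np.round(mid.fractions, 3), round(iso.fractional_enrichment(mid), 3))

# --- flux: one noisy stress-test well -------------------------------------
trace, _ = sim.gen_flux_trace(sim.FluxScenario(noise_sd=1.5, seed=1))
well = fx.traces_from_table(trace)[0]
print("ATP-coupled OCR:", round(fx.atp_coupled_ocr(well), 2))
print("basal glycolysis:", round(fx.basal_glycolysis(well), 2))
print("ATP rates:", {k: round(v, 1) for k, v in fx.atp_rates(well).items()})

# --- signature: 18 SDH-mutant vs 27 other tumors, 2-fold signature drop ---
cs = sim.CountScenario(seed=1)
matrix, groups, _ = sim.gen_count_matrix(cs)
log2 = sg.log2_normalized(matrix, sg.size_factors(matrix))
scores = sg.signature_score(log2, sg.GeneSignature(cs.signature_gene_ids), groups)
print(scores.groupby("group")["score"].mean().round(3).to_dict())
print(sg.compare_groups(scores)["p_value"])
```

prints

```
s000 [0.15  0.03  0.04  0.078 0.702] 0.788
s001 [0.15  0.029 0.04  0.08  0.7  ] 0.788
s002 [0.151 0.03  0.04  0.08  0.699] 0.787
ATP-coupled OCR: 65.52
basal glycolysis: 45.73
ATP rates: {'mito_atp': 360.3, 'glyco_atp': 5.0, 'total_atp': 365.4}
{'SDHB_D': 2.461, 'other': 3.625}
0.0055250857238493805
```

Reading it: the corrected MIDs recover the generator's truth
(0.15, 0.03, 0.04, 0.08, 0.70) to within the 1% ion-count noise, with the
fully labeled m+4 species modal — the signature of growth on a fully labeled
carbon source. The flux well recovers its generated phase structure
(coupled OCR ≈ 65, glycolysis ≈ 45); mito ATP = 65.5 × 2 × 2.75 ≈ 360
pmol/min, and the glycolytic rate is in ECAR-equivalent units until a medium
buffer factor is configured. The SDH-mutant group's signature score is lower
(2.46 vs 3.63) and the rank-sum test flags the difference (p ≈ 0.006) — the
18-vs-27 design reliably detects a 2-fold signature downshift.

The same stages run from the shell:

```sh
immetab simulate counts --seed 3 --out work/
immetab signature --counts work/counts.tsv --genes work/signature_genes.txt \
        --groups work/groups.tsv --out work/sig/
immetab run --config tests/data/pipeline_config.yaml --out work/full/
```

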