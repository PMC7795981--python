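# fermnir

Moving-window PCA monitoring of lactic-acid (yogurt) fermentation from
time-resolved near-infrared (NIR) absorbance spectra.

## The problem

Yogurt is made by inoculating milk with lactic-acid bacteria and fermenting
until the pH falls from ~6.7 to the casein isoelectric point (pH 4.6), at
which point the milk has coagulated into a gel. Industrial monitoring still
relies on discontinuous pH sampling. NIR spectroscopy offers a non-invasive
alternative: the spectra carry both the physical signature of coagulation (a
broadband scattering baseline rise as casein micelles aggregate) and chemical
signatures in the water absorbance bands (970, 1150, 1450, 1910 nm and their
neighbours), which act as a cumulative probe of the changing aqueous matrix.

`fermnir` implements the full chemometric analysis chain for such a run, for
process analysts and spectroscopists who want a tested, scriptable pipeline:

1. **Simulation** — a synthetic generator that emulates an 8-h fermentation
   monitored every 15 min on a 12000–4000 cm⁻¹ FT grid (16 cm⁻¹ step), with a
   logistic pH decline, a coagulation-driven scattering baseline, and
   stage-dependent Gaussian absorbance bands (no public dataset exists for
   this protocol, so the generator makes every downstream stage testable).
2. **Preprocessing** — truncation to the usable 950–1880 nm region and
   Savitzky–Golay smoothing (2nd-order polynomial, 25 points).
3. **Moving-window PCA (MWPCA)** — a window of `h_s = 5` consecutive spectra
   slides over the time axis; for each window submatrix `X_i` the first
   principal-component loading `p(i)` is computed, and compared with a
   reference loading `p(0)` through the **dissimilarity index**

   `A_i = 1 − p(i)ᵀ p(0)` (sign-aligned, so `A_i ∈ [0, 1]`),

   which is 0 when the window's dominant direction of spectral change matches
   the reference and 1 when it is orthogonal. With 33 spectra the run yields
   29 windows.
4. **Stage segmentation** — the sigmoidal `A_i` series splits the run into
   lag, coagulation, and gel-setting stages (rise-fraction thresholds at 10%
   and 90% of the `A` range by default, or manual breakpoints).
5. **Loading variance + band annotation** — per-stage, per-channel variance
   of the loadings localizes the absorbance bands driving each stage; peaks
   are matched against a shipped table of literature band assignments (water
   species, proton hydrates, protein, lactic acid, EPS).

## Worked example

```sh
fermnir pipeline --out-dir demo --seed 7
```

```
fermnir INFO: simulating spectra (seed=7)
fermnir INFO: preprocessed: 33 spectra, 301 channels (969.0-1811.6 nm)
fermnir INFO: MWPCA: 29 windows (h_s=5), 3 stages
fermnir INFO: run complete: demo/summary.json
wrote 12 artifacts to demo
```

`demo/summary.json` then contains (abridged):

```json
{
  "n_spectra": 33,
  "n_windows": 29,
  "dissimilarity_max": 0.9813,
  "stages": {
    "1": {"first_window": 1,  "last_window": 9},
    "2": {"first_window": 10, "last_window": 19},
    "3": {"first_window": 20, "last_window": 29}
  },
  "top_bands_per_stage": {
    "1": [{"detected_nm": 1090.75, "matched": "1090"},
          {"detected_nm": 996.81,  "matched": "998"}],
    "2": [{"detected_nm": 1361.66, "matched": "1361"}]
  }
}
```

Reading: the dominant direction of spectral change stays close to the
reference through the 9 lag-phase windows (`A` small), rotates sharply during
coagulation (windows 10–19, `A` rising to ~0.98), and stabilizes once the gel
is set. The lag-phase variance spectrum peaks at the early chemistry bands
(998, 1090 nm — lactic-acid production region), while the transition windows
are dominated by the 1361 nm proton-hydrate band and the broad scattering
baseline. `demo/` also holds the per-window loadings, the `A_i` table, the
per-stage variance spectra, and the annotated band lists as CSV.

The same analysis runs on real data: `fermnir run --spectra your.csv
--out-dir out` with a wide CSV (`wavelength_nm` column plus one column per
acquisition, labelled `t0`, `t15`, … in minutes).

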