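# Methods

## The monitoring statistic

A fermentation run is an `m × n` matrix `X` of absorbance spectra (rows:
acquisition times, columns: wavelength channels). A time window of `h_s`
consecutive spectra slides over the run; window `i` is the submatrix
`X_i = X[i … i+h_s−1]`, giving `m − h_s + 1` windows. For each window the
column means are subtracted and the first right singular vector of the
centred submatrix — the first principal-component loading `p(i)`, a unit
vector of per-wavelength weights — is taken as the window's dominant
direction of spectral change. With a reference loading `p(0)` (the first
window's, by default) the dissimilarity index is

    A_i = 1 − ⟨p(i), p(0)⟩,   p(i) sign-aligned so ⟨p(i), p(0)⟩ ≥ 0,

so `A_i ∈ [0, 1]`, exactly 0 at the reference and 1 for an orthogonal
direction. Because both centring and unit normalization are applied, the
statistic is invariant to positive rescaling of the spectra.

Stage boundaries are read off the `A_i` series. The default *rise-fraction*
rule assigns stage 1 to windows before `A` first exceeds
`A_min + f_lo (A_max − A_min)`, stage 3 from where it first exceeds
`A_min + f_hi (A_max − A_min)`, and stage 2 in between (`f_lo = 0.1`,
`f_hi = 0.9`). Manual breakpoints are accepted verbatim, e.g. `(10, 17)` on
29 windows for stages 1–10 / 11–17 / 18–29.

For each stage with at least two windows, the per-channel sample variance
(denominator `n − 1`) of the loading values localizes the wavelengths whose
weights move within that stage. Loadings are sign-aligned by chaining each to
its predecessor inside the stage before the variance is taken: the SVD sign
is arbitrary, and aligning against the reference loading instead becomes
ill-conditioned when a stage's loadings are nearly orthogonal to it
(`A ≈ 1`), where the alignment sign degenerates to noise. Variance peaks
(local maxima with prominence ≥ 5% of the spectrum maximum) are matched to a
shipped table of literature band assignments within ±5 nm; range entries
(e.g. 1026–1032 nm) match at distance zero anywhere inside the range, and
exact ties resolve to the lower wavelength with a tie flag.

### Choices where the design was open

* **Window axis.** Windows slide over time (consecutive spectra), not over
  wavelength: stage structure is a temporal phenomenon, and 33 spectra with
  `h_s = 5` give the canonical 29 windows.
* **Centring.** Column-mean centring within each window precedes the SVD; a
  `center=False` flag exists for sensitivity analysis.
* **Reference.** `p(0)` is the first window's loading; the index is
  configurable.
* **Only the first component** is used for `A_i`; per-window scores are kept
  optionally for diagnostics.
* **Savitzky–Golay derivatives** are taken with respect to channel index, not
  nm: the FT-style grid (even in wavenumber) is non-uniform in nm, and only
  the sign structure of the second derivative is consumed downstream (zero
  crossings that locate baseline-only wavelengths), for which the abscissa
  scale is immaterial.
* **Filter edges.** The filtered series keeps interior channels only — 12
  channels trimmed per side for the 25-point window — avoiding fabricated
  edge values; mirror padding is available but off by default. The analysis
  range is therefore slightly narrower than the truncation range.
* **Degenerate inputs.** A window with zero variance after centring raises an
  error naming the window; a constant `A` series yields a single stage with a
  warning; a single-window stage is rejected by name when a variance spectrum
  is requested.

## The synthetic fermentation

No public dataset exists for this acquisition protocol, so the generator
produces the study conditions directly: 33 spectra at 15-min intervals over
8 h (including t = 0) on a 12000–4000 cm⁻¹ grid at 16 cm⁻¹ (501 channels,
converted to a non-uniform ascending nm axis via λ = 10⁷/ν̃; a uniform nm
grid can be requested instead).

The model for each spectrum is

    A(λ, t) = [b₀ + b₁·λ̃] · (1 + s·g(t)) + Σ_k a_k(t)·G_k(λ) + ε,

with `λ̃` the normalized wavelength, `G_k` Gaussian bands specified by centre
and FWHM, and `ε ~ N(0, σ²)` i.i.d. detector noise.

* **pH.** `pH(t) = 4.6 + (6.7 − 4.6)/(1 + exp(r(t − t_mid)))` with
  `r = 1.5 h⁻¹`, `t_mid = 3.875 h`: endpoints are the canonical inoculation
  and casein-isoelectric values; the rate and midpoint give a lag phase, a
  rapid decline, and a slow-down, with the rapid phase centred where the
  observed stage-2 windows sit (the stage-2 interval 3 h 15 min – 4 h 30 min
  is centred on ~3.9 h).
* **Scattering baseline.** `g(t)` is an increasing logistic sharing the pH
  midpoint but steeper by a factor 4.5 (10–90% in ~40 min): acid coagulation
  of casein is a threshold-like event compared with the smooth pH decline.
  `s = 0.12` lifts the baseline by ~12% over the run — a clearly visible but
  not dominating drift.
* **Bands.** Four static water bands (970, 1150, 1450, 1910 nm) carry a mild
  growth component on top of a constant base. Early bands (998, 1090, 1361,
  1670, 1840 nm) accumulate during the lag phase along logistic drivers
  centred at ~1.9 h and ~2.6 h — rising, as produced species (lactic acid,
  solvated hydronium/proton hydrates, EPS-related features) accumulate. Late
  bands (1420, 1453 nm — hydration and adsorbed water in the set gel) rise
  along a slow driver centred at 5.5 h so the gel keeps maturing to the end
  of the run. Amplitudes (0.01–0.09 AU for dynamic bands, up to ~2 AU for
  the 1910 nm water band) and FWHMs are synthetic fixture choices.
* **Noise.** `σ = 1 × 10⁻⁴ AU`: the RMS noise of an FT-NIR instrument
  averaging 32 scans at 16 cm⁻¹ is of order 0.05–0.2 mAU. The band
  amplitudes and drivers are sized so that every window — including the
  weak-signal lag and plateau windows — is signal-dominated after smoothing.

Two structural choices matter for the shape of `A_i`. First, each dynamic
band group has its own logistic driver: if every term shared the scatter
driver the spectra would lie on a one-parameter curve, the loading would
never rotate, and `A` would stay near zero. Second, the early bands rise
rather than decay: a decaying early group is anti-correlated with the scatter
rise, so during the handoff the transient change direction swings *past*
orthogonality to the reference and `A` overshoots to ~1 before falling back —
a non-sigmoidal signature. With rising early bands the rotation stays inside
the wedge between the reference and scatter directions and `A` is monotone.

### What the generator does and does not emulate

It reproduces: the acquisition geometry and grid; a three-phase pH decline;
a coagulation-synchronized scattering baseline; stage-dependent water and
solute bands; i.i.d. detector noise; and, emergent from these, a sigmoidal
dissimilarity series whose rise brackets the transition and stage variance
spectra localized at the expected bands.

It does not emulate: wavelength-dependent scattering physics (no
Kubelka–Munk or Mie model), temperature drift, detector nonlinearity at
high absorbance (the >1900 nm noise that motivates truncation is not
generated — truncation is applied regardless), correlated (pink) noise,
band-shape changes (only amplitudes move), or biological replicate-to-
replicate variability. Passing tests therefore demonstrate that the analysis
chain recovers known structure of this model class, not that it is robust to
every artefact of real instruments.

## Numerical notes

* First PC via `numpy.linalg.svd` of the centred window; zero-variance
  windows are those with leading singular value ≤ 1e−12 relative to the
  window scale. The stored sign convention makes the largest-magnitude
  loading element positive; `A_i` additionally re-aligns against `p(0)`.
* `A_i` is clipped to `[0, 1]` against float round-off, and the reference
  window's value is set to exactly 0 (an identity).
* CSV round trips are exact: floats are written with `%.17g` and parsed with
  numpy's `strtod`.
* Savitzky–Golay filtering delegates to `scipy.signal.savgol_filter`
  (`delta = 1`, channel-index abscissa); the test suite checks it against a
  brute-force sliding least-squares polynomial fit.
* Problem sizes used by the test suite and the acceptance script — 33 × 501
  simulated matrices, 29 windows of 5 × 301, 100 replicate seeds — are the
  study conditions themselves; the full acceptance run completes in seconds.

## Known limitations

* The rise-fraction rule assumes a roughly monotone `A` series; strongly
  non-monotone series (e.g. transient process upsets) should use manual
  breakpoints.
* Band annotation is a nearest-neighbour literature look-up, not chemical
  identification; unmatched peaks are reported as such.
* `A_i` compresses all directional change into one scalar; processes that
  rotate the loading *back* toward the reference are invisible to it.
* The generator's parameter defaults constitute one plausible fermentation;
  they are not fitted to any measured dataset.
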