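# Methods

This note documents the models, estimators, numerical choices and known
limitations of `phasegraph`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and the synthetic generator

Each simulated channel is

    x_c(t) = b_c(t) + Σ_k a_k s_k(t; lag) + ε_c(t)

* `b_c`: unit-variance 1/f^α background, synthesised by inverse-FFT
  spectral shaping of Gaussian white noise (amplitude ∝ f^(−α/2), DC bin
  zeroed). The target spectrum is exact by construction; estimation error
  in recovery tests comes only from the spectral estimator.
* planted couplings: a shared narrowband carrier — white noise hard-masked
  in the FFT domain to the coupling band — injected into channel i at
  amplitude `a` (relative to the unit-RMS background), and into channel j
  after multiplying every positive-frequency component by exp(−i·lag). The
  lag is therefore a constant *phase* lag across the band, not a constant
  time lag; a narrowband carrier (rather than a pure tone) keeps the
  epoch-averaged coherency non-degenerate. Zero-lag couplings are legal
  configurations used to verify that the lagged estimator suppresses
  purely instantaneous coupling.
* `ε_c`: optional independent white noise.

Defaults state the nominal world of the analysis: 19 channels at 128 Hz,
α = 1 (the pink-noise regime reported for spontaneous neural activity),
five minutes duration. All randomness flows from one integer seed;
identical config + seed is bit-identical.

What the generator does **not** emulate: volume conduction / leadfield
mixing, non-stationarity, artifacts, or any physiologically realistic
network structure. A green recovery test therefore establishes estimator
correctness on the stated signal model, not fidelity to clinical EEG.

The packaged 84-region coordinate table is a constructed, anatomically
plausible stand-in (mirrored across hemispheres) and is labelled synthetic;
the 19-electrode table uses standard approximate MNI positions.

## Spectral estimation

* Preprocessing: polyphase resampling to 128 Hz, then zero-phase
  forward-backward 4th-order Butterworth band-pass 2–44 Hz. Output length
  is `floor(n·target/orig)`.
* Epochs: default 2 s, no overlap — 0.5 Hz resolution, which resolves the
  narrowest canonical band edges (e.g. 3.5 vs 4 Hz). A bin belongs to a
  band iff f_lo ≤ f ≤ f_hi; at 0.5 Hz resolution the canonical edges never
  collide.
* Power spectra: per-epoch Hann-tapered periodograms, averaged over epochs.
* Cross-spectra (and their phase-only counterparts) are computed from
  **untapered** epoch FFTs. Tapering correlates adjacent Fourier bins
  (neighbouring Hann bins of white noise correlate at −2/3), which would
  invalidate the independence assumption behind the asymptotic LPC
  threshold; with a rectangular window the per-bin coefficients of white
  noise are exactly independent. This was confirmed by the packaged
  Monte-Carlo calibration, which showed ~5× family-wise inflation with a
  Hann taper and nominal behaviour without.
* 1/f slope: OLS of log PS on log f, α reported as the negated
  coefficient (white ≈ 0, Brownian ≈ 2). The default fit range is
  [2, 43] Hz — clipped at the filter passband edge, since log power below
  the passband is numerically unstable; a wider printed range such as
  [1, 43] can be requested explicitly. Per-epoch fitting is averaged
  implicitly by fitting the epoch-averaged spectrum; at these epoch counts
  the difference from averaging per-epoch fits is negligible and the
  averaged-spectrum route has strictly lower variance.
* Group slope comparison: pooled log-log regression with group dummy and
  group × log f interaction; the interaction t (two-sided p) is the test.
  Sign convention: statistic > 0 ⇔ group B steeper (larger α).

## Lagged phase coherence

ρ_ij is the average over epochs and in-band bins of
`u_i(f,e) · conj(u_j(f,e))` with `u = X/|X|`; LPC = Im(ρ)²/(1 − Re(ρ)²).
The band-collapsed variant (one ρ per band, averaging phase-only
cross-spectra over bins before forming the statistic) is implemented;
per-bin variants exist in the literature but the band-collapsed form
matches epoch-averaged band cross-spectra. Degenerate case Re(ρ)² = 1
(perfect instantaneous coherence) returns 0 with a warning.

Properties enforced by tests: symmetry, range [0, 1), exact invariance to
amplitude scaling of any channel, suppression of zero-lag couplings.

### Significance threshold

Under independence, ρ̂ over N = n_epochs · n_bins unit phasors is
isotropic complex Gaussian with Var(Im ρ̂) = 1/(2N), hence
**2·N·LPC ~ χ²(1)** asymptotically. The threshold inverts this at the
Bonferroni-adjusted level α/n_pairs. (The simpler convention N·LPC ~ χ²(1)
is ~2× conservative; the factor-2-corrected form is used because the
Monte-Carlo calibration shows it holds the family-wise error at or below
nominal without the needless power loss.) Connectivity matrices are *not*
thresholded before graph metrics; thresholding is available separately.

## Graph metrics

* Lengths: L = 1/W (the standard toolbox convention; −log W rejected to
  stay commensurable with the literature this analysis style comes from).
* Distances: Dijkstra (scipy.sparse.csgraph) on L; unreachable pairs are
  infinite. Characteristic path length = mean over finite unordered
  off-diagonal pairs; NaN when no finite pair exists.
* Clustering: Onnela geometric-mean-of-triangles with global max
  normalisation ŵ = W/max W; k_i counts strictly positive weights, nodes
  with k_i < 2 score 0 (not undefined).
* Local efficiency: for node u with neighbours V,
  E_loc(u) = Σ_{j≠h∈V} (ŵ_uj ŵ_uh)^{1/3} / d_jh(V) / (k(k−1)), where
  d_jh(V) is the shortest path within the neighbourhood subgraph on
  lengths ŵ^(−1/3) — the weighted-toolbox formulation; max normalisation
  keeps values in [0, 1]. Local efficiency tracks clustering only loosely;
  the full formula is implemented, not a proportionality shortcut.
* Scale covariance (tested): W → cW multiplies strengths by c, divides
  distances by c, leaves clustering and local efficiency unchanged.

## Group statistics

* Physical distance: Euclidean in MNI mm.
* Edge-level regressions: OLS of a per-edge quantity on physical distance
  over unordered edges, infinite entries excluded with their count
  reported; group slope differences via the pooled dummy-interaction model.
* Fisher transform: z = atanh r, SE = 1/√(n−3); two independent
  correlations compared by the standard z statistic.
* Edgewise group map: the Fisher machinery needs a bounded, correlation-like
  quantity, so significance is computed on the connectivity weights
  (|w| < 1) with the groups' sample sizes, while the *direction* label
  (which group's functional distance is longer) comes from the distance
  matrices — distances themselves are unbounded and cannot be
  atanh-transformed. Bonferroni over edges. The three classes partition
  the edge set.
* Cross-frequency coupling: Pearson r between the unordered-edge vectors
  of two bands' functional-distance matrices, over edges finite in both;
  group differences via the Fisher z test with n = number of common finite
  edges. n is exposed as data (not hard-coded) because the appropriate
  effective sample size for spatially correlated edges is debatable.
* Mixed ANOVA: balanced split-plot sums of squares, group (between) ×
  band (within); group tested against subjects-within-groups, band and
  interaction against the band × subject residual. Implemented by hand so
  that `pingouin.mixed_anova` can serve as an independent oracle in the
  tests. Observational units are nodes (for node metrics) or edges — a
  documented choice isolated behind one function; treating nodes of one
  average network as independent units overstates degrees of freedom, as
  it does in the analysis tradition this mirrors. Per-band simple
  contrasts are one-tailed in the direction of the observed difference.
* Group reduction supports two conventions, selectable by flag: pooling
  epochs before cross-spectral averaging (`cross_spectra`, default) or
  averaging per-recording connectivity matrices (`networks`).

## Numerical and degenerate-input choices

* LPC values are clipped below 1 by one ulp; |ρ| may exceed 1 by ≤1e−9
  before an error is raised (floating-point accumulation).
* `fit_slope` refuses nonpositive power in the fit window rather than
  silently dropping bins.
* Empty bands at the current epoch resolution raise an error that names
  the minimum epoch length required.
* Unknown montages, config keys, and shape mismatches raise immediately.

## Known limitations

* No volume-conduction forward model: the generator cannot produce the
  inflated zero-lag coherence structure of real scalp data, so the
  suppression tests probe the estimator's algebra, not its field
  performance.
* The asymptotic threshold assumes white, independent epochs; strongly
  coloured narrowband signals make it approximate (the Monte-Carlo
  calibration covers the white null only).
* The ANOVA unit choice (nodes/edges of group-average networks) inherits
  the pseudo-replication of the underlying analysis style; p-values should
  be read as descriptive at desk scale.
* EDF ingestion is not provided (no EDF reader in the supported
  dependency set); recordings are CSV/TSV + JSON sidecar.
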