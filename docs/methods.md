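# Methods

This note documents the models, estimators, defaults and numerical choices
behind leukotrack, and what the synthetic cohorts do and do not establish
about real intravital data.

## Data model and units

Units are fixed package-wide: time in **minutes**, positions in
**micrometres**, speeds in µm min⁻¹, diffusivities in µm² min⁻¹. Readers
convert nothing; inputs are declared to be in these units. A `Track` is
one cell's strictly time-ordered positions (2D or 3D) with cohort labels
(disease, stage, epoch); a `TrackSet` adds acquisition metadata (frame
interval, dimensionality). The frame interval of a read file is inferred
as the modal time step, and dimensionality from the presence of a `z`
column. Duplicate (track, time) rows are treated as a broken export and
rejected rather than silently deduplicated.

Quality control before statistics keeps tracks with ≥ 5 points and no
time gap above 2 frame intervals. Imaging papers rarely state their
inclusion rules; these defaults are declared choices, set so that every
retained track supports at least 4 MSD lags, and both knobs are exposed.

## Motility statistics

- **Mean speed** = path length / elapsed time. This matches the "track
  mean speed" exported by spot-tracking software, not net displacement
  over time. Gaps contribute their true Δt to the denominator.
- **Straightness** = net displacement / path length, defined as 0 for a
  zero-length path (the 0/0 case of a cell that never moved).
- **Local displacement** over a window $W$: for every point with a
  partner observed at $t + W$ (matched within half a frame interval to
  survive export jitter), the distance between the two positions.
  Default $W$ = 15 min (5 frames) — long enough to average out
  localization noise, short compared with an epoch.
- **Distinct sites visited**: unique half-open grid cells (origin fixed
  at 0) containing at least one point; default grid 10 µm, roughly one
  cell diameter. Grid size and window are configuration, since published
  supplementary analyses seldom state their discretization.

## TA-MSD estimation and exponent fitting

The per-track estimator is the maximal overlapping-pairs time average:
all ordered point pairs separated by $\tau = k\,\Delta t$ contribute,
including pairs that span a gap whenever both endpoints exist. Lags run
up to a quarter of the track duration by default (`max_lag_fraction` =
0.25); longer lags have few pairs and dominate the variance. The
implementation maps times onto the frame grid and is tested for exact
agreement with an $O(n^2)$ brute-force double loop.

The ensemble curve is pair-count weighted — algebraically identical to
pooling every pair from every track — with an unweighted per-track mean
available (`weighting="track"`) as a sensitivity check. Lags with fewer
than 10 pooled pairs are dropped from ensemble fits (`min_pairs`).

$\alpha$ is the OLS slope of $\log \mathrm{MSD}$ on $\log \tau$ (natural
logs internally), with the regression standard error reported. Zero-MSD
lags (stationary stretches) are excluded with a warning, never clamped.
Regime thresholds: $\alpha < 0.9$ subdiffusive, $0.9 \le \alpha \le 1.1$
diffusive, $\alpha > 1.1$ superdiffusive. The published analyses report
regimes qualitatively; explicit, configurable thresholds make the calls
reproducible. An optional SE-aware mode additionally requires
$|\alpha - 1| > 2\,\mathrm{SE}(\alpha)$ to leave "diffusive".
Dimensionality enters closed-form comparisons only, never the fit.

## Synthetic generators

All generators share one master seed with counter-based substreams
(`SeedSequence([seed, stream, track_index])`): cohorts are bit-for-bit
reproducible across platforms, and track $i$'s trajectory is independent
of how many tracks are requested.

- **Brownian**: i.i.d. Gaussian increments, per-axis variance
  $2D\Delta t$; ensemble MSD $2dD\tau$.
- **Fractional Brownian motion**: per-axis fGn increments with the exact
  Toeplitz covariance implied by $\mathrm{E}[X(t)^2] = K t^{2H}$, sampled
  by circulant embedding (Davies–Harte): the $n \times n$ covariance is
  embedded in a $2^k \ge 2n$ circulant whose FFT eigenvalues are
  non-negative for fGn, so the construction is exact, not an
  approximation (a Cholesky fallback guards the never-observed negative
  eigenvalue case). Ensemble MSD $dK\tau^{2H}$, hence $\alpha = 2H$.
- **Persistent random walk**: per-axis stationary Ornstein–Uhlenbeck
  velocity with RMS speed $s$ and persistence time $P$. Each frame
  samples the exact joint Gaussian of (displacement, end velocity) —
  not an Euler step — so the Fürth relation
  $\mathrm{MSD}(\tau) = 2 d s^2 P\,(\tau - P(1 - e^{-\tau/P}))$
  holds at the 3-min frame interval with no step-size bias.
- **Ballistic**: constant speed along a fixed random heading; TA-MSD
  exactly $s^2\tau^2$, so the fitted $\alpha$ is 2 to machine precision.
- **Localization noise**: i.i.d. Gaussian jitter of sd $\sigma$ on every
  coordinate, raising the expected MSD by the constant $2d\sigma^2$ —
  the additivity used as a pipeline check.

The cohort generator reproduces the imaging design: 3-min frames over a
90-min pre-drug epoch, a 15-min injection gap represented as a pure time
offset (no frames acquired during it), then 180 min post-drug. A seeded
subset of $\lfloor$ mobilized_fraction $\cdot n \rfloor$ cells terminates
at drug time, modelling intravascular departure as track loss; survivors
continue from their final pre-drug position under the post-drug model.
Pre and post observations are distinct tracks sharing a cell id, since an
epoch is a cohort label of a track.

**What the synthetic cohorts do not emulate**: vessel/niche geometry and
spatial heterogeneity of the marrow, cell–cell interactions, proliferation
and death, drift of the imaging field, heteroscedastic or correlated
localization error, and mouse-level clustering (each track is
independent). Passing tests therefore establishes that the estimators and
tests are correct under their stated models — not that real marrow
trajectories follow those models. The demo scenarios' mobilized fractions
(0.15 and 0.3) and motion parameters are illustrative, chosen to make the
qualitative contrasts robust at modest cohort sizes; the study they are
shaped after does not quantify these, so they are not calibrated values.

## Statistics

Unpaired comparisons default to Student's pooled-variance *t* (Welch
behind a flag); all tests are two-sided; stars follow the figure-legend
convention (\* < 0.05 to \*\*\*\* < 0.0001); no multiple-testing
correction is applied, matching how such studies report, and all
comparisons are emitted so users can adjust externally. Epoch comparisons
are unpaired because pre- and post-drug tracks are distinct samplings of
the population. Paired *t* on after − before differences is used for
same-region intensity data; identical pairs throughout give the null
result (t = 0, p = 1), while a constant nonzero difference has no
variance to test against and raises an error. Cells are treated as
independent observations pooled across animals — the field's common
practice; a mouse-level blocking factor is out of scope, though labels
survive the pipeline for external modelling.

## Problem sizes and tolerances

Validation checks use cohorts large enough that Monte-Carlo error sits
well inside each tolerance: exponent recovery uses 500 tracks × 31 frames
(observed spread of the fitted ensemble $\alpha$ ≈ 0.01–0.05 against
bands of ±0.1); closed-form MSD agreement uses 1000 tracks with a 5%
band (31 frames for Brownian; 61 frames — the post-epoch length — for
the persistent walk, whose 9-min velocity correlation otherwise inflates
the time-average variance at 30-min lags); noise additivity uses 500
tracks with a 10% band on the $2d\sigma^2$ offset; the fGn covariance
check uses 20 000 realizations of a 10-step track with a 5%-of-variance
entrywise band. Exact identities (brute-force equivalence, power-law
slopes, *t* formulas) are asserted at 10⁻⁶ or tighter.

## Determinism and reproducibility

Reports are byte-for-byte reproducible for identical configurations: all
randomness flows from the configured seed, floats are written with
shortest-roundtrip (`repr`) formatting and read back with round-trip
parsing, JSON is key-sorted, and no timestamps enter outputs. Each run
directory carries a manifest with the effective configuration, package
version, seed, input SHA-256 hashes and per-stage track counts, so every
reported number can be recomputed from the manifest alone. Runs are
staged in a temporary directory and moved into place on success; a failed
run leaves no partial report.
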