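# Methods

`dirspec` estimates directed functional connectivity (dFC) in continuous
multichannel neural recordings (LFP, EEG, MEG virtual channels) and ships the
simulation and validation machinery needed to probe how those estimates break
under the confounds of real recordings: measurement noise, unequal
signal-to-noise ratios, volume conduction, common drive, short records, and
incompletely observed relay nodes.

## Spectral estimation

Cross-spectral density matrices are estimated by disjoint-segment averaging:
the record (or each trial) is cut into non-overlapping segments of `seg_len`
samples (default 2^8 ≈ 1.3 s at 200 Hz), each segment is demeaned, Hann
tapered (power-normalized), and the one-sided cross-periodograms are averaged.
Trials shorter than the default segment length are used whole, one taper per
trial. The estimator guarantees Hermitian matrices with non-negative diagonals
and the Cauchy–Schwarz bound per frequency; coherence is

    |R_yx(ω)|² = |f_yx(ω)|² / (f_xx(ω) f_yy(ω)) ∈ [0, 1].

The DC bin is excluded from every connectivity summary (peaks, detection
rules, thresholds). No overlap is used: overlapping Hann segments would
correlate the averaged periodograms and complicate the segment-count
arithmetic that the surrogate statistics rely on.

## Non-parametric directionality (NPD)

NPD decomposes coherence into reverse-lagged, zero-lag, and forward-lagged
components. The spectral matrix is MMSE pre-whitened, `Fw_ij = S_ij·(S_ii
S_jj)^(−1/2)`, which sets every autospectrum to 1 and leaves the coherence as
the squared magnitude of the whitened cross-spectrum. The inverse transform
of the (Hermitian-extended) whitened cross-spectrum is a real correlation
sequence ρ(τ) on lags −(seg_len/2 − 1) … +seg_len/2. The τ < 0, τ = 0 and
τ > 0 portions are transformed back to frequency, and the three
magnitude-squared spectra are rescaled at each frequency so they sum exactly
to the coherence. Scalar components are the lag-domain sums of ρ² (Parseval).

Numerical conventions:

- The single τ = 0 bin carries the instantaneous component.
- The discrete lag grid has one ambiguous bin at τ = seg_len/2, where +τ and
  −τ coincide (the lag-domain analogue of the Nyquist bin). Its energy is
  split evenly between forward and reverse. This makes two identities exact
  simultaneously: direction labels swap exactly under argument exchange
  (forward(i→j) ≡ reverse(j→i)), and the three scalar components sum to the
  full lag-domain energy.
- No window is applied to ρ(τ) before the component transforms.
- Frequencies with numerically zero coherence get all components set to 0 and
  are counted on the result (`n_undefined`).

Conditioned NPD partializes the spectral matrix on a reference channel Z
first, `f_ab|z = f_ab − f_az f_zb / f_zz` (single-predictor complex
regression), then runs the identical decomposition; additivity then holds
against the partial coherence. Conditioning on one reference at a time is
supported; multi-reference partialization is out of scope.

## Non-parametric Granger causality (NPG)

Wilson's iterative algorithm factorizes the spectral matrix into a
minimum-phase transfer function and innovation covariance, S(ω) = H(ω) Σ
H(ω)*, H(lag 0) = I; Geweke's frequency-domain formula then splits the target
power into intrinsic and causal parts:

    F_{x→y}(ω) = ln [ S_yy / (S_yy − (Σ_xx − Σ_yx²/Σ_yy) |H_yx(ω)|²) ].

Implementation choices that matter:

- Initialization with the (upper) Cholesky factor of the zero-lag covariance;
  convergence when the maximum relative change of ψ drops below 1e−9, with a
  cap of 500 sweeps.
- Channels are rescaled to equal mean power before iterating and the scaling
  is restored afterwards (H → D^{1/2} H D^{−1/2} preserves H(0) = I). Without
  this, a channel 40 dB noisier than the rest destabilizes the iteration.
- On near-singular input (coherence ≳ 0.95 over a band) the iteration reaches
  an accuracy floor and then drifts in a slow limit cycle; the factor with the
  best reconstruction residual seen during the run is returned.
- A causal factor restricted to seg_len/2 + 1 lags cannot exactly represent
  every estimated spectrum; sharp resonances leave an irreducible relative
  residual of order 1e−3…5e−2 at the worst frequency. Runs are accepted when
  the worst-frequency relative Frobenius residual of H Σ H* is below 0.1
  (`recon_tol`); the residual is always reported. On analytic (closed-form
  MVAR) spectra the same code reaches ~1e−9, which is what the oracle tests
  assert.
- Negative directional values (floating-point artifacts of the log ratio) are
  clipped to zero and counted; the instantaneous term is reported unclipped
  because it is genuinely negative (and uninterpretable) in strongly
  mixed data.

Pairwise NPG factorizes the 2×2 submatrix of each pair. Multivariate NPG
(mvNPG) factorizes the full channel set once and applies the same pairwise
formula with the full-system H and Σ. Because the full-system transfer
function carries only direct and relayed linear routes, lagged common drive
no longer produces a spurious pairwise edge (H between the two driven nodes
is ≈ 0), while serially relayed influence (X→Z→Y) *is* retained — mvNPG does
not discriminate direct from relayed routes, unlike conditioned NPD, which
removes them by partial regression. This asymmetry between the two
multivariate extensions is a finding the validation experiments reproduce,
not an implementation accident.

## Synthetic data: MVAR simulator and observation model

The generator produces order-P MVAR processes, X_t = c + Σ A_i X_{t−i} + ε_t,
ε ~ N(0, R), R = I by default. Node dynamics are an AR(2) resonator placed on
the diagonal: a complex pole pair at angle 2π f₀/fs and radius r (coefficients
a₁ = 2r cos ω₀ at lag 1, a₂ = −r² at lag 2, alternating sign). Directed
coupling is a single off-diagonal coefficient (default 0.5) at the edge's lag
(1–3). Defaults: fs = 200 Hz, f₀ = 55 Hz, T = 5×10⁴ samples (250 s),
burn-in max(500, 10·P·N) samples discarded from zero initial conditions.

The pole radius defaults to r = 0.74, fixed once by matching the magnitudes
the validation experiments are anchored to: a clear ~55 Hz spectral peak,
coherence above 0.5 on coupled pairs, and a forward NPD near 0.6 for a
directly coupled pair at coupling 0.5. For acyclic graphs the companion
eigenvalues are exactly the node poles; cyclic graphs (reciprocal or
recurrent coupling) push the companion radius toward 1 and make spectra
numerically singular, so the builder shrinks r geometrically until the
companion spectral radius is below 0.95. Random benchmark graphs draw
distinct directed edges uniformly with i.i.d. lags in [1, 3] and are redrawn
(bounded retries) if no stable scaling exists.

The observation model maps latent to recorded channels: Y = z(LX) + λγ, with
L a unit-diagonal mixing matrix (volume conduction), z(·) per-channel
standardization, γ unit white noise and λ per-channel noise scales. SNR is
accounted for in a narrow band (peak ± 5 Hz, i.e. 50–60 Hz for the default
model; 45–55 Hz grids are a config choice, never hard-coded) as 10·log10 of
the mean in-band signal power over mean in-band noise power. Because the
noise is white with a flat one-sided density 2λ²/fs, the λ achieving a target
narrowband SNR follows in closed form from the measured signal band power;
the round trip is within ±0.5 dB.

Mixing strength is specified as *target shared variance* v: the squared
zero-lag correlation that the symmetric matrix [[1, l], [l, 1]] would induce
on independent unit-variance channels, giving l = (1 − √(1−c²))/c with
c = √v in closed form. The published descriptions of the λ ↔ shared-variance
map are mutually inconsistent, so the observable quantity is made the
interface; on coupled channels the realized correlation differs from v, which
is documented rather than hidden.

## Surrogates and detection

Phase-randomization surrogates keep each channel's amplitude spectrum exactly
(DC and Nyquist untouched, independent uniform phases elsewhere, per
channel), nulling cross-channel dependence while preserving autospectra.
Confidence limits pool each surrogate realization into one number — by
default the maximum of the metric over frequency bins, giving family-wise
control across the spectrum and matching the single horizontal confidence
line practitioners draw per spectrum; the pooling is configurable. Thresholds
are empirical percentiles with the "lower" order-statistic convention (the
99.9th percentile of 1000 samples is the 2nd-largest sample), P = 0.001 at
the 99.9th percentile.

The graph-recovery benchmark detects an edge when ≥ 10% of the frequency bins
(DC excluded, full spectrum) of a directional spectrum exceed the pair's
99.99th-percentile surrogate limit, and scores predicted against true
adjacency at +1 per matching off-diagonal cell and −1 per mismatch, reported
as a percentage of the maximum (+6 on three nodes). In the data-length
benchmark each trial is a single tapered segment, so the segment length — and
with it the frequency resolution and the available lag range — varies with
the trial length; that coupling of trial length to estimator resolution is
the mechanism the benchmark probes.

## Calibration sweeps and logistic fits

Sweeps inject one confound over a grid, re-estimate connectivity, and record
the peak of each spectrum (DC excluded): symmetric SNR (−30…+30 dB), SNR
asymmetry ΔSNR_XY on a symmetric reciprocal two-node model with the quieter
channel clamped (+13 dB), shared variance (0…1), and reference-channel SNR in
serial / feedforward / recurrent triads. Sigmoidal responses are summarized
by least-squares fits of y = A/(1 + exp(−κ(x − x₀))) on the dB axis
(multi-start initialization; fits reported as reliable only when R² > 0.95;
κ in per-dB).

## What the generator does and does not emulate

The simulator reproduces the statistical structure the validation needs:
narrowband oscillators with lagged linear coupling, additive white
measurement noise, and instantaneous linear mixing. It does not emulate 1/f
background spectra, nonstationarity, nonlinearity, spike-field coupling, or
multi-source volume conduction with realistic lead fields. Tests passing on
these models show that the estimators recover linear lagged structure under
the stated confounds — not that they are unbiased on arbitrary real
recordings.

## Reproduction script sizes and known limitations

`scripts/acceptance.py` re-runs the validation suite at desk scale: surrogate
counts 100–200 (instead of 1000), SNR grids at 3–5 dB steps, 24 random
3-edge graphs, T = 5×10⁴ per condition. These sizes keep the full run under
~10 minutes on one CPU and leave the stochastic summaries within a few
percent of large-run values.

Known limitations, all traceable to the lost coefficient tables of the
reference models (the simulator reconstructs them from their described
structure):

- The mixing response of the reconstructed three-node model is steeper than
  the reference curves; at 45% target shared variance the forward NPD falls
  to ≈ 0.18 rather than ≈ 0.4.
- The recurrent (cyclic) triad carries a high loop gain at the stability
  margin, so cleaning the relay channel moves mvNPG by ≈ 0.6 rather than
  ≈ 0.1; the direction of the effect and the recurrent > serial ordering are
  robust.
- With max-statistic pooling, NPD and NPG cross their significance limits at
  nearly the same symmetric SNR (≈ −6 dB); separate onsets (−11.5 vs −7 dB)
  are not reproduced and depend on a pooling convention the reference does
  not state.
- The most negative ΔNPD on the asymmetry sweep is a noisy order statistic
  (−0.004…−0.05 across seeds; always negative, always more than an order of
  magnitude smaller than ΔNPG).
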