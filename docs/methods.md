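# Methods

## The measurement being modelled

A donor/acceptor dye pair on a surface-tethered E2~ubiquitin conjugate
reports the conjugate's conformation as an apparent FRET efficiency.  Three
long-lived conformational states are resolved: an open state (E ≈ 0.36), an
intermediate (E ≈ 0.57) and the closed, catalytically primed state
(E ≈ 0.71).  Two experiment types are supported:

* **Equilibrium** — the stable (isopeptide-linked) conjugate imaged at
  100 ms/frame for ~1 minute; the observable is the population distribution
  over states under different conditions (temperature, partner protein UEV,
  RING-domain dimer).
* **Real-time injection** — the reactive (thioester-linked) conjugate imaged
  at 1 s/frame while reaction components are injected; the observable is the
  per-molecule terminal event (ubiquitin transfer vs photobleaching), its
  dwell time from injection, and the FRET state it started from.

All efficiencies are *apparent*: the only correction applied is the
donor-into-acceptor leakage term α = 0.88 in E = I_A/(I_D + α·I_A).  No
gamma (detection-efficiency) or direct-excitation corrections are made, and
distances from the Förster relation (R0 = 60 Å) are indicative only.

## Synthetic-data generator

`simulate.SimulationConfig` defines a study condition; named presets cover
the conjugate alone at 12 °C and 22 °C, with UEV, with UEV + RING dimer, and
the two injection experiments (full reaction mix, UEV-only control).

Per molecule, the generator draws an initial state from the condition's
occupancy vector, independent exponential donor/acceptor photobleach times,
and (after the injection frame) an exponential transfer time whose rate
depends on the state: only the closed state reacts at the catalysed rate
(`reaction_rate_high`), while every state carries a small RING-independent
background rate (`reaction_rate_low`).  Signatures written into the traces:

* transfer — both channels drop to background in the same frame, never to
  return;
* acceptor bleach — acceptor drops while the donor *recovers* to the full
  excitation level (energy transfer has stopped);
* donor bleach — both channels drop (acceptor emission requires the donor);
* a configurable fraction of molecules is donor-only (under-labelled).

Intensities are generated by inverting the efficiency formula under the
constraint I_D + I_A = total: given state mean E,
I_D = T(1−αE)/(1−αE+E) and I_A = E·I_D/(1−αE), so that the analysis
formula returns the ground-truth mean exactly in the noise-free limit.  The
physical leakage model lives only in the movie renderer, which adds 12% of
the donor intensity to the acceptor-channel spot.  This split keeps
trace-level tests analytic while the imaging round trip exercises the
physical bookkeeping.

Key defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `total_intensity` | 1000 a.u. | arbitrary scale; absolute counts are not reported by the reference experiments |
| `noise_sigma` | 40 a.u./channel | per-frame FRET precision ≈ 0.03, matching visually clean TIRF traces; chosen so the fixed 3-frame minimum-dwell assignment rule has a false-transition rate well below the 1% true interconversion fraction |
| `frame_interval` | 0.1 s equilibrium / 1 s real-time | the two integration times used experimentally |
| `n_frames` | 600 (equilibrium), 300 (real-time) | ~1 min observation window; ~5 min injection recording |
| bleach rates | 0.002 / 0.004 s⁻¹ (equilibrium); 0.0002 / 0.004 s⁻¹ (real-time, donor/acceptor) | photobleaching is slow relative to the observation window and ≥5× slower than catalysed transfer; the acceptor bleaches faster than the donor |
| `interconversion_rate`, `dynamic_fraction` | 0.1 s⁻¹ within 1% of molecules | continuous-time Markov switching restricted to a small dynamic subpopulation, so ~1% of one-minute traces show a detectable switch |
| `reaction_rate_high` | 0.04 s⁻¹ | calibrated (competing-exponentials arithmetic, below) so the full reaction mix converts ~60% of conjugates within the recording |
| `reaction_rate_low` | 0.0007 s⁻¹ | background reaction independent of the RING ligase, calibrated to ~14% conversion in the UEV-only control |
| `donor_only_fraction` | 0.1 (real-time) | small under-labelled subpopulation that still reacts |

Calibration of the real-time rates is analytic and was fixed before any
recovery measurement: for a molecule with transfer rate k_r and total bleach
rate k_b observed for T seconds after injection, the probability of a
transfer-first event is (k_r/(k_r+k_b))·(1−exp(−(k_r+k_b)T)); averaging over
the occupancy vector and the donor-only subpopulation gives the expected
reacted fraction, solved to hit 60% / 14% at the study sample sizes.

Reproducibility: per-molecule RNG streams derive from
`SeedSequence([master_seed, molecule_index])`, so identical config + seed is
bit-identical regardless of molecule count ordering.  Noise is additive
Gaussian per channel by default (the reference experiments do not state a
noise model); Poisson shot noise is available behind `noise_model="poisson"`.
No photophysical blinking or oxygen-scavenger chemistry is modelled.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analyses assume — long-lived states, exponential
event times, step-like channel loss, leakage bookkeeping — but real traces
additionally contain baseline drift, blinking, non-Gaussian EMCCD noise and
heterogeneous brightness.  Recovery results on synthetic data validate the
*pipeline logic and estimators*, not instrument-specific robustness.

## Analysis choices

**Population histograms.** One sample per molecule: E is computed per frame
and then averaged over the first ten *valid* frames (frames after the
molecule's terminal event, found by the event classifier, are masked).
Averaging E per frame, rather than averaging intensities before the ratio,
is the default convention; the other convention can be assembled from the
primitives.  Molecules with fewer than 3 valid frames are dropped (their
sample variance would dominate); shorter-than-ten traces contribute the mean
over what they have.  Binning: 60 bins over [−0.1, 1.1], density normalised
to unit area; clamping of E to [0, 1] is off by default.

**Gaussian mixture.** Sample-space EM (scikit-learn) with 20 k-means++
restarts, tolerance 1e-6, variance floor (0.01)², deterministic for a fixed
seed; k selected by BIC over 1–3 unless fixed.  Components map to
low/intermediate/high strictly by ascending mean; when BIC selects k < 3,
components are attached to the nearest canonical state position and absent
states are reported as zero rather than forced.  A histogram-space
least-squares sum-of-Gaussians fit is provided as the cross-checking route;
the two agree on well-sampled synthetic data.

**State assignment.** Boundaries at midpoints between adjacent component
means, applied to a 5-frame median-filtered efficiency series; a label
change is accepted only when the new label persists ≥ 3 frames *and* the
unfiltered run mean lies on the new state's side of the boundary.  The
starting state is taken from the first sustained run, so a noisy opening
frame cannot masquerade as an initial state.  With the default noise this
keeps the false-transition rate per one-minute trace near 0.1–0.3%, an order
of magnitude below the true 1% interconversion signal.

**Cross-correlation.** Implemented literally as
G(τ) = Σ_t (I_D(t)−Ī_D)(I_A(t+τ)−Ī_A) / (N·mean(I_D·I_A)), with means over
the full trajectory.  The normalisation term is typeset ambiguously in the
field (mean of products vs product of means); mean of products is the
default and `denominator="product_of_means"` switches the convention.  A
brute-force double-loop evaluation is the test oracle (agreement to 1e-9).

**Event classification.** Per-channel noise is estimated robustly (scaled
median absolute first difference); a channel is lost when it stays below
background + 3σ for ≥ 3 frames and shows no sustained recovery.
"Simultaneous" means within one frame at the 1-s real-time integration.
Donor-only molecules are identified from the first five acceptor frames.
Events inside the injection interval are classified but excluded from rate
fits; conflicting signatures are flagged ambiguous and excluded likewise.
An intrinsic limitation, shared with the experimental analysis: donor
photobleach of a FRET pair produces the same simultaneous dual-loss
signature as transfer and is only separable kinetically, which is why the
slow donor-bleach rate matters for classification accuracy (~98% against
ground truth at the default conditions).

**Dwell-time fits.** Dwells are binned at two frames per bin and
A·exp(−kt) (or a two-term sum) is fitted by least squares with Poisson
weights iteratively reweighted by the model prediction — weighting by
observed counts alone biases the rate upward by ~10% at n = 500.  Standard
errors come from the fit covariance.  An unbinned MLE (1/mean for mono; a
Nelder-Mead mixture fit for bi) is computed alongside as a cross-check, and
mono-vs-bi selection under `model="auto"` uses the AIC of the unbinned
likelihoods.  Identical dwells degenerate to k = 1/mean with a warning.
Per-molecule rates (1/dwell) grouped by initial FRET state give the box-plot
summaries; initial states are labelled from the pre-event mean E against the
fitted (or canonical) component means.

**Imaging.** 0-based pixel coordinates, origin top-left.  Reference image =
mean of the first 5 frames; spot detection by local maxima above a robust
threshold with centroid refinement, brighter spot kept on collision;
donor-to-acceptor registration by nearest-neighbour matching after a coarse
median offset, least-squares translation (or affine) with one round of
3×-median residual rejection; extraction by aperture sums (radius 3 px)
minus the median of a local annulus (2 px gap, 2 px width).  No drift
correction or gain calibration is attempted.

## Problem sizes used by the packaged analyses

Equilibrium recovery runs use 3000 molecules × 600 frames; interconversion
detection 1000 molecules; the injection experiments use the study sample
sizes (270 reaction, 263 control); dwell-fit validation uses 500–2000 drawn
event times.  These sizes put every recovered quantity's sampling error
comfortably inside its check tolerance while keeping a full pipeline run in
the seconds range.

## Known limitations

* No hidden-Markov modelling of trajectories; state assignment is
  threshold-based and intended for long-lived states.
* No more than three mixture components; broader conformational ensembles
  would need a different population model.
* The classifier cannot distinguish donor photobleach from transfer on a
  per-event basis (see above); the separation is kinetic.
* The movie renderer uses an idealised Gaussian PSF, a pure translation
  between channels by default, and no EMCCD gain or blinking model.
* Absolute intensity scales and noise levels are free parameters of the
  generator, documented above, not measured quantities.
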