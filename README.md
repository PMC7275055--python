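# smfretkit

Simulation and analysis of single-molecule FRET (smFRET) trajectories from
prism-TIRF experiments on surface-immobilised molecules, built around the
workflow used to watch a RING-E3-catalysed ubiquitination reaction one
molecule at a time: an E2~ubiquitin conjugate carrying a Cy3B/AlexaFluor 647
FRET pair reports its conformation (open / intermediate / closed) as a FRET
efficiency, and single ubiquitin-transfer events appear as the simultaneous,
irreversible loss of both dye signals after reagent injection.

The package is aimed at single-molecule biophysicists who need a tested,
scriptable pipeline from raw donor/acceptor intensity traces (or dual-channel
TIFF movies) to state populations and reaction kinetics — plus a synthetic
trajectory generator with full ground-truth labels, so every stage of the
pipeline can be validated without any experimental download.

## What it computes

**Apparent FRET efficiency with leakage correction.** Per frame,

```
E = I_A / (I_D + α·I_A),        α = 0.88
```

where `I_D`, `I_A` are the raw donor and acceptor channel intensities and α
compensates for 12% bleed-through of donor emission into the acceptor
detection channel. The Förster relation `E(r) = 1 / (1 + (r/R0)^6)` with
`R0 = 60 Å` (Cy3B/AlexaFluor 647) converts efficiencies to inter-dye
distances.

**State populations.** One sample per molecule — the mean E over its first
ten valid frames — binned into a unit-area histogram and decomposed into up
to three Gaussian components (low ≈ 0.36, intermediate ≈ 0.57, high ≈ 0.71);
component weights give the fractional occupancy of the open, intermediate
and closed conformations.

**Dynamics.** Donor–acceptor cross-correlation

```
G(τ) = Σ_t (I_D(t) − Ī_D)(I_A(t+τ) − Ī_A) / (N · mean(I_D·I_A))
```

detects anticorrelated state switching (G(0) < 0) or confirms its absence,
and a hysteresis state-assignment with a 3-frame minimum dwell flags the
rare (~1%) trajectories that interconvert between FRET states.

**Real-time reaction kinetics.** After reagent injection, each molecule is
classified from its channel step signatures: ubiquitin transfer
(simultaneous dual loss, no recovery), acceptor photobleach (acceptor loss
with concomitant donor recovery), donor photobleach, donor-only transfer, or
unreacted. Dwell times from injection to event are fitted with mono- or
biexponential decays (AIC model selection, unbinned-MLE cross-check), rates
are grouped by the molecule's initial FRET state, and 15-s windowed
histograms build the time-resolved population contour.

## Worked example

Simulate an equilibrium experiment for the conjugate bound to its partner
protein and the RING dimer, then analyse it:

```
$ smfretkit simulate --preset plus_UEV_RNF4 --n-molecules 500 --seed 42 \
      --out conjugate_traces.tsv --truth-out truth.tsv
$ smfretkit equilibrium --traces conjugate_traces.tsv --outdir eq
fractions (%): {'low': 16.2, 'intermediate': 16.0, 'high': 67.7}
dynamic fraction: 1.00%
```

The three fitted Gaussian means land on the generating state efficiencies
(`eq/equilibrium.json` reports 0.361 / 0.572 / 0.710), the weights recover
the preset occupancies (15/15/70%) within sampling error — the closed,
catalytically primed conformation dominates when both binding partners are
present — and 1.0% of one-minute trajectories show an interconversion event.

A real-time injection experiment:

```
$ smfretkit simulate --preset thioester_reaction --n-molecules 270 --seed 7 \
      --out reaction_traces.tsv
$ smfretkit realtime --traces reaction_traces.tsv --outdir rt
reacted fractions (%): {'transfer_FRET': 53.7, 'transfer_donor_only': 4.1,
 'acceptor_photobleach': 29.3, 'donor_photobleach': 0.0, 'unreacted': 13.0,
 'ambiguous': 0.0, 'transfer_combined': 57.8, 'n_molecules': 270}
```

57.8% of conjugates undergo ubiquitin transfer (the preset is calibrated to
~60%); the fitted transfer rate from the FRET-loss dwell times is
0.043 ± 0.008 s⁻¹ against a configured closed-state rate of 0.04 s⁻¹, and the
per-state grouping shows transfer proceeding overwhelmingly from the
high-FRET (closed) state (137 high-state events vs 4 low-state background
events in `rt/realtime.json`).

The same analyses are available as library functions
(`smfretkit.equilibrium_analysis`, `smfretkit.realtime_analysis`), and
`smfretkit render` / `smfretkit extract` round-trip trace sets through
dual-channel TIFF movies (Gaussian spots, 12% donor leakage into the
acceptor half-image, aperture photometry with annulus background).

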