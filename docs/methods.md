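# Methods

This note documents the models, conventions and numerical choices behind
`nqbridge`, and what its synthetic data can and cannot establish.

## Scope and units

All analyses concern 1,4-naphthoquinone derivatives: the quinoid ring
(ring I, carbonyl-bearing), the fused benzene ring (ring II), and — in
the hydroxy-substituted compounds — one or two intramolecular O–H...O
bridges with O...O distances around 2.58–2.60 Å. Atom indices in every
public interface are 1-based and follow the conventional numbering
(C1–C10, O1–O4, bridge protons H1/H2). Internal units are Å,
femtoseconds, Å/fs, kcal/mol and cm⁻¹; energies read in hartree are
converted with 1 Eh = 627.5095 kcal/mol.

## HOMA

The Harmonic Oscillator Model of Aromaticity scores a carbocycle as

    HOMA = 1 − (α/n) Σᵢ (d_opt − dᵢ)²

with the CC parameterization α = 257.7 and d_opt = 1.388 Å: 1 for
perfect bond equalization, about 0 for a localized non-aromatic ring,
negative for strongly localized/antiaromatic rings such as ring I.
Only the CC parameterization ships; rings containing heteroatoms are
rejected rather than silently approximated, because mixing heteroatom
reference lengths changes the meaning of the index. Quasi-rings closed
by the O–H...O bridge are likewise out of scope. Results carry full
floating precision internally; the CLI prints 4 decimals (published
values in this family are usually quoted to 2).

## cSAR

The charge of the Substituent Active Region is cSAR(X) = q(X) +
q(C_ipso), the sum of the substituent's partial atomic charges plus its
ipso carbon. The formula is charge-scheme agnostic; tables record the
scheme (Hirshfeld is typical here) as metadata only. Unsubstituted
positions are treated as one-atom hydrogen substituents so that a
profile covers all ring positions 1–8.

## PT profiles

Relaxed-scan proton-transfer profiles (typical increment 0.05 Å) are
analyzed on the grid: local minima are interior points lower than both
neighbors (endpoints count against their single neighbor; plateaus
collapse to their leftmost index), the two lowest minima define the
wells, the barrier is the maximum strictly between them, and all
energies are re-referenced to the global minimum, so E_barrier ≥
E_min2 ≥ 0 whenever a second minimum exists. Grid extrema are reported
as-is by default — scan energetics are conventionally quoted on the scan
grid — which underestimates the true barrier; refining the grid
converges to it from below. A 3-point parabolic refinement is available
behind a flag. `r_min1` is always the left-hand (shorter O–H) well; for
the profiles these scans produce the molecular form sits there, making
it also the global minimum.

## Bridge dynamics

Per-frame possession assigns the proton to the closer oxygen; exact
ties go to the donor (deterministic, and of measure zero in real data).
Possession therefore satisfies donor + acceptor = 1 exactly, and
swapping the donor/acceptor roles maps p → 1 − p exactly.

PT events are sign changes of δ(t) = d(O_donor,H) − d(H,O_acceptor)
confirmed by a hysteresis band (default 0.05 Å, the scale of the scan
increment): a crossing only counts once |δ| exceeds the band on the new
side before recrossing, so barrier-top chatter is never counted.
Directions alternate by construction.

Synchrony between the two bridges' event trains uses greedy
nearest-time matching (smallest delay first, each event used once)
within a window of 500 fs — comfortably above the sub-0.1 ps delays
reported for coupled twin bridges. The match fraction is
n_matched/max(n₁, n₂); two empty trains match vacuously.

Trajectories may declare an equilibration window (0.7 ps is the usual
Car–Parrinello convention at a 1.452 fs sampling stride) which all
analyses drop.

## Velocity power spectra

Spectra use the Wiener–Khinchin route: FFT-based biased velocity
autocorrelation summed over the selected atoms and Cartesian
components, truncated at a 2 ps maximum lag, Hann-tapered, zero-padded
to the next power of two and cosine-transformed. The one-sided
intensity is normalized so its integral over wavenumber equals the mean
squared velocity of the selection (Parseval; exact up to clipping of
tiny negative leakage values). At the default stride the bin width is
~5.6 cm⁻¹ and the axis ends at the Nyquist wavenumber 1/(2·dt·c) ≈
11 486 cm⁻¹ for dt = 1.452 fs. Barycenters are intensity-weighted mean
wavenumbers over a window (default 2200–3400 cm⁻¹, bracketing both
anharmonically red-shifted ~2700 cm⁻¹ bands and harmonic-like ones);
they are invariant under intensity rescaling, so per-bridge
normalization conventions do not matter. Bridge comparison uses
per-proton spectra (H1 vs H2), not mass-weighted all-atom sums, because
the observable of interest is the inequivalence of the two O–H
oscillators. Velocities absent from a trajectory can be derived by
central finite differences behind an explicit flag; the sinc attenuation
this introduces at high wavenumber is symmetric across a band and does
not move barycenters at the bin-width level.

## Synthetic coupled-bridge generator

No trajectories for these compounds are public, so the generator
provides data with closed-form ground truth. Design: a Markov-switching
model rather than Langevin dynamics on a 2-D surface, precisely because
the 4-state continuous-time Markov chain over joint proton states
{DD, DA, AD, AA} has an analytic stationary distribution and the
injected oscillation frequency is exact — every recovery test compares
against algebra, not another simulation.

Per bridge, forward (D→A) and backward (A→D) hopping rates k_fwd and
k_rev are in ps⁻¹; a coupling knob γ ≥ 1 multiplies the rate of any
transition that creates a concordant joint state (DD or AA) and divides
the rate of any transition creating a discordant one, preserving the
detailed-balance structure. γ = 1 gives independent two-state bridges
with stationary donor fraction k_rev/(k_fwd + k_rev); γ → ∞ drives the
concordance probability π(DD) + π(AA) → 1. The proton of each bridge
sits on its current holder's side at d_eq = 1.00 Å from that oxygen,
plus a deterministic stretching oscillation A·cos(2πcν̃t + φ) (defaults
ν̃ = 2750 cm⁻¹, A = 0.05 Å) along the O...O axis (R_OO = 2.585 Å), plus
optional Gaussian positional jitter. Velocities are the analytic
oscillation derivative; when jitter is requested, velocity jitter of
standard deviation σ·2πcν̃ (the positional jitter oscillating at the
stretch frequency) is added. Defaults k_fwd = 0.8, k_rev = 1.6 ps⁻¹
give a 2:1 donor preference and roughly one transfer per picosecond —
the possession and event density regime of the symmetric parent
compound — and the stride/duration defaults (1.452 fs, 25 ps) mirror
typical Car–Parrinello production settings. The initial joint state is
drawn from the stationary law, so no burn-in bias enters possession
estimates; the chain itself is simulated exactly (Gillespie) and
sampled on the frame grid.

### What the generator does and does not emulate

It reproduces: twin-bridge geometry scale, stochastic hopping with
tunable bias, correlated (γ-skewed) joint dynamics, an O–H stretching
band at a controllable wavenumber, and the published sampling stride.
It does **not** model electronic structure, forces, anharmonic coupling
between hopping and stretching, O...O breathing, or the continuous
motion of a real proton through the barrier — state switches are
instantaneous between frames. Consequently, passing recovery tests
validates the *analysis* chain (possession counting, event detection,
spectral estimation), not any claim about real substituent chemistry.

A known structural limitation follows from memorylessness: from a
discordant state the chain cannot distinguish the lagging bridge
"completing" a joint transfer from the leading bridge reverting, so
both are accelerated by γ equally. Brief single-bridge
transfer-and-return excursions therefore keep a γ-independent share of
all transfer events, and the event-train match fraction saturates
around ~0.45 for these defaults at intermediate γ instead of rising
toward 1; only when γ is large enough that excursion lifetimes fall
below the sampling stride (γ ≈ 100 here) does the measured match
fraction climb. Possession-level synchrony (the concordance
probability) is monotone in γ and is the cleaner coupling diagnostic.

## Series reports

Across a substitution series the headline statistic is the
tie-corrected Spearman rank correlation among {quinoid HOMA, barrier,
second-minimum energy, ν(OH)}, computed over pairwise-complete records
(pairs with fewer than 3 usable records are flagged undefined). Rank
correlation is used because the series-level claims are monotone
association claims, and it is invariant under monotone transforms.
Mirror-image substitution patterns ("(M)" labels) are distinct records.

## Problem sizes

Default test and acceptance runs use 25 ps synthetic trajectories
(17 218 frames at 1.452 fs) for statistics, 5 ps for smoke/pipeline
checks, 10-seed sweeps for stochastic recovery properties, and 2 ps
autocorrelation lags for spectra. Possession recovery is judged within
3 binomial-style standard errors of the pooled sojourn count — a
deliberately conservative error model, since for exponential sojourns
the true estimator variance is smaller by a factor 4p(1−p) ≤ 1.
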