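# Methods

## Charge model

Per-residue charges at neutral pH are integers: D, E = −1; K, R = +1; all
other residues, and both termini, 0. Histidine defaults to 0 — its imidazole
pKa (~6) leaves it mostly neutral at pH 7 — but is configurable
(`ChargeParams.histidine_charge`) for users who prefer a fractional value.
Each annotated phosphorylation site adds `phospho_delta` = −2 elementary
charges, the phosphate's dominant (dianionic) state at neutral pH; the
monoanion/dianion equilibrium is not modelled. Sites annotated on residues
other than S/T/Y are kept, with a validation warning, and still contribute
−2: annotation tables are taken at face value rather than silently edited.
Integer charges keep every downstream quantity exactly reproducible; a
Henderson–Hasselbalch fractional mode was considered and deliberately left
out of scope.

## Sliding windows and terminal extrapolation

Profiles are computed over an odd window of length *W* (default 21, allowed
5–41) centered on the reported residue — centering is the only symmetric
choice and matches how per-residue profiles are indexed. The default of 21
balances responsiveness against smoothing: windows of 5–10 track local
composition too noisily for region calls, while 41 blurs genuine boundaries.
The first and last (*W*−1)/2 positions cannot host a full window; they copy
the value at the first/last full-window position (for *W* = 21, positions
1–10 copy position 11). Even window lengths are rejected (no center
residue), and sequences shorter than the window raise an error telling the
user to lower the window length — truncating the window silently would
change the statistic's meaning. Window sums are computed per window (not by
cumulative-sum differencing), so results are bit-identical to a brute-force
evaluation; the test suite asserts exact equality against an independent
O(L·W) oracle.

## Fold propensity

The score combines the windowed mean normalized hydropathy ⟨h⟩ with the
windowed mean net charge ⟨q⟩ through the linear boundary that separates
natively folded from natively unfolded proteins in mean-hydrophobicity vs
mean-net-charge space, applied per window:

FP(i) = slope·⟨h⟩(i) − |⟨q⟩(i)| − intercept,  slope = 2.785, intercept = 1.151.

Hydropathies are Kyte–Doolittle values normalized as (raw + 4.5)/9, which
maps the scale onto [0, 1] (I = 1, R = 0). Alternative scales load from a
two-column TSV with explicit normalization bounds, and the boundary
constants live in `FoldPropensityParams` so they can be re-fit. Useful
closed forms: a poly-I window scores 2.785 − 1.151 = +1.634, poly-R scores
−1 − 1.151 = −2.151, poly-G ≈ +0.118.

Two consequences of the functional form are intentional and documented
rather than bugs. First, the charge term is |⟨q⟩|: the boundary is symmetric
in charge sign, so phosphorylating a strongly *positive* window can
transiently raise FP as the window passes through neutrality before driving
it negative. Second, phosphorylation touches only the charge term — the
phosphate is assumed not to change the residue's hydropathy contribution.
FP depends only on window composition, not residue order within the window.

## Sawtooth smoothing

Positions with FP > 0 are labelled structured, FP ≤ 0 disordered (an exact
zero counts as disordered: the tool's purpose is flagging potential
disorder). Two rules then clean the labelling:

1. every maximal disordered run shorter than 10 residues is re-labelled by
   the sign of the mean raw FP over a window of up to 41 positions centered
   on the run's midpoint (left-of-center for even-length runs), truncated at
   the sequence ends — short IDR calls inside domains usually describe
   loops;
2. every maximal structured run shorter than 10 residues lying strictly
   between two disordered runs is re-labelled disordered, merging its
   neighbours into one longer IDR. Terminal structured runs are exempt
   (nothing disordered on one side); terminal disordered runs remain subject
   to rule 1.

The rules are applied in that order and repeated until the labelling stops
changing. Iteration is safe: any change flips an entire maximal run and
therefore merges runs, strictly decreasing the run count, so the procedure
terminates (in at most the initial number of runs, in practice 1–2 passes)
and cannot oscillate. The result is a fixed point, which makes smoothing
idempotent — re-segmenting a smoothed labelling changes nothing. A single
pass of each rule was considered and rejected: it leaves rare
non-idempotent configurations where a merge creates a new short disordered
run.

The sawtooth *envelope* is a display track only: within each region a
triangle rising from 0 at the region boundaries to +1 (structured) or −1
(disordered) at the midpoint. Even-length regions have no midpoint residue;
they use half-width n/2 so every position keeps the region's sign, and
single-position regions take the full ±1. Analysis code consumes the
RegionSet, never the envelope.

## IDR window charges and ΔNCPR

Inside each predicted disordered region of length ≥ *W*, every fully
contained window contributes its summed net charge; windows never straddle a
region boundary ("within predicted IDRs" is read strictly), and regions
shorter than the window contribute nothing. Histograms use integer bins over
±10 by default — ±10 summed over 21 residues is ±0.476 charge per residue —
with nearest-integer binning for fractional charges and out-of-range windows
tallied as `clipped` rather than dropped.

Both modification states are evaluated over the regions computed from the
*unmodified* profile, so the two histograms cover identical windows and
their difference isolates the charge change; the phospho-mode segmentation
is separately computable for users who want it.

ΔNCPR = (phospho_delta × sites in scope)/(residues in scope), hence in
[−2, 0] with defaults. The scope is `idr_only` by default, with
`whole_protein` available because either denominator is defensible; a
zero-residue scope returns missing (`None`), not zero. At set level the
headline statistic is the unweighted mean of per-protein ΔNCPR (each protein
one observation); the residue-pooled value is reported alongside since the
two differ when protein lengths vary.

## Synthetic generators

`BlockSpec`/`generate_protein` sample sequences block by block from
residue-composition multinomials — a hydrophobic folded-like block
(`STRUCTURED_COMPOSITION`, expected FP ≈ +1.1) and an RGG-like disordered
block (`RGG_LIKE_COMPOSITION`: G/S-rich, mildly positive, expected FP ≈
−0.3), emulating the RRM + RGG architecture typical of stress-granule
RNA-binding proteins. `BlockSpec.phospho_density` is the per-S/T/Y
probability of a site.

`SetSpec`/`generate_set` build whole sets: per protein, a structured block
of 80–150 residues and a disordered block of 250–400 residues (uniform
lengths), with the IDR composition drawn per protein. The
`near_neutral_positive_tail` target (core-like) jitters arginine content in
0.10–0.15 so pooled IDR window charges sit slightly positive; the `broad`
target (client-like) draws a net-charge bias in −0.10–+0.12 per residue for
a wider spread. `SetSpec.phospho_density` is defined per predicted-IDR
*residue*: after segmenting each generated protein, sites are planted on
S/T/Y within the predicted disordered regions with per-S/T/Y probability
q = p·L_IDR/n_STY, so the expected site count is p·L_IDR and the expected
IDR-scope ΔNCPR is exactly −2p. Planting inside *predicted* (rather than
designed) regions avoids the small bias that window-smoothed boundaries
would otherwise introduce into the denominator. Default densities of 0.017
and 0.0075 give ΔNCPR magnitudes of ≈ −0.034 and −0.015, the scale at which
phosphorylation is comparable to the NCPR differences known to modulate
condensate formation.

All randomness flows from one integer seed; protein *i* uses the substream
`default_rng([seed, i])`, so a set is a stable prefix of any larger set with
the same seed, and output is platform-independent.

What the generators do **not** emulate: real position-specific sequence
patterning (charge blockiness, pi-contacts, proline effects), evolutionary
covariation, kinase motif context for site placement, or incomplete/
condition-dependent site annotation. Tests passing on synthetic sets
demonstrate that the *machinery* (profiles, segmentation, window pooling,
ΔNCPR accounting) is correct and calibrated, not that any particular real
protein set has a given ΔNCPR — real-set values depend on the annotation
snapshot used as input.

## Degenerate inputs and numeric conventions

Non-canonical residues (X, B, Z, U, lowercase) are rejected by validation by
default; a permissive mode maps them to charge 0 and the hydropathy-scale
midpoint with a warning, because silent guessing would corrupt profiles.
Duplicate phospho rows deduplicate with a warning; rows referencing unknown
ids warn; out-of-range positions are errors. Exported tables print floats
with 4 decimals (configurable) for byte-reproducible diffs; the run manifest
records inputs, parameters and version.

## Problem sizes used in validation

The bundled checks run on synthetic data sized for quick, fully seeded
reproduction: 500 random tracks (length ≤ 200) for the window oracle,
150 random records for charge bookkeeping, and 200 proteins × 3 seeds per
planted density for ΔNCPR recovery, which bounds the standard error of the
recovered mean near 0.001 — comfortably resolving the −2p target.
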