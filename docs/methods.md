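# Methods

## The two-state conformational model

Active, dual-phosphorylated (2P) ERK2 interconverts between two global
conformers, L and R, with an exchange rate constant k_ex ≈ 300 s⁻¹.  The R
state is associated with a catalytically productive ATP-binding mode and
exists only in the activated kinase; unphosphorylated (0P) ERK2 populates L
exclusively.  The apoenzyme populations used as study conditions throughout
the package are R:L = 80:20 at 25 °C and 50:50 at 5 °C for 2P-ERK2, and
0:100 for 0P-ERK2 at both temperatures.  An ATP-competitive inhibitor is
described by the R population of its saturated 2P complex (`bound_p_R`):
R-state-selective compounds trap R completely (`bound_p_R = 1`),
exchange-retaining compounds leave the apo equilibrium untouched, and
intermediate compounds shift it partially (default `bound_p_R = 0.9`).

## HDX forward model

Amide exchange is simulated in the fast-ensemble limit.  Because k_ex
(hundreds per second) exceeds every observable exchange rate on the
labelling grid (slowest time point 30 s) by orders of magnitude, each
residue exchanges at the population-weighted rate

    k_obs = p_R · k_int / PF_R + p_L · k_int / PF_L,

where k_int is the residue's intrinsic (unstructured) rate and PF_R, PF_L
are per-state protection factors.  Peptide uptake is the sum of independent
single-exponential site contributions,

    D(t) = f_label · f_bx · Σ_i (1 − exp(−k_obs,i · t)),

with f_label = 0.9 (labelling in 90% D₂O) and a constant back-exchange
survival factor f_bx = 0.75, a typical value for a cooled LC setup, exposed
as a parameter.  The first residue of each peptide and all prolines carry
no observable amide, so LKICDFGL has 7 exchangeable sites, YRAPEIML 6, and
YTKSIDIW 7.  The labelling grid is the nine-point schedule 0.5, 1, 3, 8,
16, 30, 60, 90, 180 min.

Intrinsic rates come from a compact poly-alanine-referenced model with
acid-, base- and water-catalysed terms, nearest-neighbour side-chain
factors, and Arrhenius temperature scaling.  Near pD 7 the base term
dominates by ~7 orders of magnitude, so rates scale linearly with [OD⁻]
(tenfold per pD unit).  The D₂O ion product is held at pK = 15.05 over the
narrow temperature range of interest, and the N-terminal charge effect on
the second residue is neglected.  The analysis stages never invert this
model; it only supplies realistic rate magnitudes and heterogeneity.

### Regions and inhibitor effects

Peptide segments carry a region class that controls how an inhibitor
perturbs them:

- **Contact** regions (Gly loop, hinge, helices αC, αE, αL16) receive a
  steric protection multiplier (default ×20) from any bound ligand, in
  both phosphoforms; strands β7–β8 behave the same but only in 2P.
- **Allosteric** regions (DFG motif/β9, P+1 segment, helix αF) receive a
  class-dependent multiplier in the 2P form only: ×20 for R-selective,
  ×5 for intermediate, ×1 for exchange-retaining compounds.  This models
  the long-range rigidification that accompanies R-state trapping.
- 0P datasets keep p_R = 0 for every condition: the population-shift
  channel is absent in the unphosphorylated kinase.

The paper-facing quantities (population ratios, class memberships, the
time grid, the 90% labelling fraction) are fixed study conditions; the
remaining generator knobs are modelling choices with no experimental
counterpart.  Baseline protection factors are PF_R = 300 and PF_L = 30 in
allosteric regions (the R state is the more protected one; L resembles the
more dynamic 0P enzyme) and PF_R = PF_L = 50 elsewhere.  These magnitudes
are typical of folded-protein HDX and were chosen, together with the
multipliers above, so that the three inhibitor classes produce cleanly
separated uptake differences; they are not inferences about ERK2.
Segment sequences other than the three documented peptides (161–168
LKICDFGL, 191–198 YRAPEIML, 203–210 YTKSIDIW) are synthetic placeholders
of the correct length — they only feed intrinsic-rate magnitudes.

### In-exchange control and noise

The in-exchange control (quench added before labelling) is modelled as
exchange during a fixed 30-s handling window at a 100-fold reduced
effective rate, giving a small constant per-peptide offset that is added
to every measured time point and recorded in a dedicated control row
(time 0 sentinel with a flag column).  Measurement noise is additive
Gaussian on uptake (Da) and on NMR peak volumes; every random draw flows
from an explicit integer seed, and noiseless output is seed-independent.

## Uptake computation

Centroid masses are intensity-weighted mean neutral masses (m/z decharged
with the proton mass, 1.007276 Da), which makes uptake charge-independent.
Uptake is the labelled centroid minus the unlabelled centroid; negative
values are flagged with a warning but never clamped, because clamping
would bias the downstream difference statistic toward protection.  The
in-exchange control is subtracted from every time point; correction is
applied before replicate averaging (the two operations commute for a
constant control, so the order is a convention).  A noisy control that
reads below zero is treated as zero deuterium content.

Simulated isotope envelopes convolve a natural-abundance binomial over the
peptide's carbons (¹³C at 1.07%) with a binomial deuteration distribution
over its exchangeable amides.  All peaks are placed on a single grid
spaced by the H→D increment (1.006277 Da)/charge; the ~3 mDa difference
from the true ¹³C spacing is a deliberate simplification that keeps
centroid arithmetic exact (centroid shift = N·p·1.006277 Da identically).

## dAUC and classification

For a peptide segment, dAUC = Σ_t (uptake_apo − uptake_inhibitor)_t over
the nine time points, computed on corrected uptake, in Da·timepoints.  It
is linear in the curves, antisymmetric, and invariant to constant offsets.
Inhibitors are ranked per segment (rank 1 = most protected; ties get the
average rank) and classified on the DFG (161–168) and P+1 (191–198)
segments: dAUC is min–max normalized to [0, 1] per segment across the
panel (the VTX11e and GDC0994 references span the dynamic range), the two
normalized scores are averaged, and fixed thresholds assign R-selective
(≥ 0.6), exchange-retaining (≤ 0.4), or intermediate.  The explicit
threshold rule replaces visual clustering: it is deterministic and
scale-free (invariant to affine rescaling of all dAUC values).  If a
segment's dAUC values are all equal, normalization is degenerate; scores
default to 0.5 with a warning.  Both ranks and raw dAUC are exported;
classification uses the normalized values.

## Slow-exchange NMR

For methyl probes in slow exchange (Δω ≫ k_ex, enforced as a ratio > 10
at probe construction, evaluated at a 900-MHz ¹H field), the R and L
conformers give separate peaks with volumes proportional to populations,
so p_R = V_R/(V_R + V_L).  Volumes are used rather than heights or
lineshape fits.  Volumes below 5% of the larger peak (or of the apo
volume, when available) are treated as undetected, which makes the
estimator exact for pure states and guards against small negative noise
excursions; uncertainty is first-order propagation of independent volume
noise through the ratio.

Chemical shift perturbations combine both dimensions as
Δδ = sqrt(Δδ_H² + (0.25·Δδ_C)²); the 0.25 carbon weight is the
conventional methyl scaling and is exposed as a parameter.  A probe whose
bound peak falls below 5% of its apo volume is marked BROADENED for that
inhibitor.  Probes are categorized from the CSP matrix: broadened under
every inhibitor → broadened contact; point-biserial correlation of Δδ
with the R-selective indicator ≥ 0.8 → R-state reporter; analogously for
the tetrahydropyran left-side indicator → left-side reporter; probes with
a CSP dynamic range below 0.02 ppm, or with too few surviving peaks, are
left unclassified (this is where the probes broadened by all but the
amidopyrrole-scaffold compounds land, since only two complexes retain
their peaks).

The generator's CSP model displaces the ¹H position of an R-state
reporter by 0.12 ppm × (bound_p_R − p_R^apo)/(1 − p_R^apo), and of a
left-side reporter by 0.10 ppm for tetrahydropyran versus 0.02 ppm for
other substituents — large enough to dominate the 0.02-ppm flatness
floor, small enough to stay in the methyl shift range.

## Structural geometry

Coordinates are read from PDB or mmCIF (via gemmi) keeping author residue
numbering, dropping hydrogens, and retaining the highest-occupancy altloc
of each atom.  Superposition is the closed-form least-squares (Kabsch)
solution via SVD with the determinant sign correction, so the rotation is
always proper; the default selection is Cα of the ERK2 C-terminal domain
(residues 109–141, 205–245, 272–310), and a per-structure numbering
offset absorbs construct/tag shifts.  Per-residue RMSDs are computed after
the single global fit with no local refit, over the atom-name intersection
of the paired residues; the default ALL_HEAVY subset can be narrowed to
side-chain-only or Cα.  The halogen–π distance is measured from the
halogen atom to the unweighted centroid of the six tyrosine ring carbons,
the standard convention for quoted Cl–π contacts of ~3.3–3.5 Å.

The geometry checks against the deposited ERK2 entries (5UMO, 2ERK, 6OPK,
6GDQ) require those coordinate files under `data/structures/`; they are
not distributed with the package.  All algorithmic behaviour is verified
on constructed fixtures with closed-form answers, a brute-force rigid-fit
oracle, and an independent library cross-check.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on
— population-proportional peak volumes, population- and protection-driven
uptake differences, class-correlated CSPs, broadening patterns, seeded
noise — but not the messiness of real data: no EX1/bimodal envelopes, no
peptide overlap or misassignment, no peptide-to-peptide back-exchange
variation, no baseline or phase artefacts in spectra, no partial binding
saturation.  Passing tests therefore demonstrate that the analysis
correctly recovers known ground truth under the stated model, not that
the model captures every property of experimental HDX-MS or NMR data.

## Problem sizes and numerical choices

Default runs use 9 peptide segments (2 for classification), 21 conditions
(17 panel compounds, BVD523, ATG017, and the two references), 9 time
points, and 14 methyl probes; population summaries average 20 seeded
replicates at 2% volume noise, and the label-recovery property uses 200
seeded panels at 0.1 Da uptake noise.  Ties in ranking use average ranks;
time grids must match exactly (no interpolation) for dAUC; curve
comparisons use strict grids and peptide identity checks.  All
floating-point tolerances in tests reflect closed-form expectations
(1e-9–1e-6) except where sampling noise sets the scale.
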