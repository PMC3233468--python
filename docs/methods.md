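# Methods

This note documents the models, conventions and numerical choices behind
`remdens`, and what the synthetic-data validation does and does not show.

## Peptide model

The peptide is represented by its five backbone atoms N, H, CA, C, O per
residue (85 atoms for the 17 residues, numbered 12–28).  Side chains are
not modelled.  Conformations are built from internal coordinates by
sequential natural extension (NeRF) with fixed canonical bond geometry
(Engh–Huber-like values): N–CA 0.1458 nm, CA–C 0.1525 nm, C–N 0.1329 nm,
C=O 0.1231 nm, N–H 0.1010 nm; angles N–CA–C 111.2°, CA–C–N 116.2°,
C–N–CA 121.7°, CA–C–O 120.8°; ω fixed at trans.  The carbonyl O is placed
anti to the next amide N across the sp² carbonyl carbon and the amide H
anti to the preceding carbonyl O, so the peptide group is planar.  The
builder and the torsion extractor are exact inverses: round trips agree
to better than 1e-4 degrees (tested to ~1e-13).

Angles are degrees on the half-open interval [−180, 180); trans torsions
are therefore stored as −180.  φ of the first and ψ of the last residue
are undefined and carried as NaN markers, never zero-filled.

## Ramachandran regions

For φ < 0 the ψ axis is tiled exactly by three half-open intervals:
β [−180, −120), α [−120, 30), bridge [30, 90), β [90, 180).  Everything
with φ ≥ 0 is "other".  The source definitions use strict inequalities on
both sides, which leaves boundaries unassigned; half-open boxes make the
classifier total at measure-zero cost on continuous data.  "Other" is
exactly the φ ≥ 0 half-plane, which is why the three printed region rows
of a probability table sum to slightly less than one.  Region
probabilities are pooled counts over residues 13–27 excluding the
glycine at position 25 (14 residues).

Potentials of mean force are histogram-based only (no kernel density):
F(bin) = −RT ln(P(bin)/P_max) with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹, the most
populated bin at zero and empty bins masked.  Default Ramachandran bin
width is 10° (a standard choice; the sources do not state one).

## Secondary structure (rule set `mesostate-v1`)

Assignment uses (φ, ψ) only — no hydrogen-bond criterion, no DSSP.  Each
defined pair maps to a 60°×60° mesostate cell; the φ grid is offset by
30° (boundaries at ±30, ±90, ±150) and the ψ grid is aligned to multiples
of 60°.  This particular anchoring places the canonical helix (−63, −43),
PPII (−75, 145) and extended-β (−120, 130) values in the interior of
three distinct cells; with a fully aligned grid PPII and extended-β would
share a cell.  Labels: helix = run of ≥ 4 helical cells, strand = run of
≥ 2 extended cells, PPII = run of ≥ 2 PPII cells, turn = the two central
residues of a 4-residue window whose centre residues fall within ±40° of
the type-I′ turn pair (+60, +30)/(+90, 0) — matched by boxes rather than
grid cells because (+90, 0) sits exactly on a φ grid line.  Precedence is
H > E > P > T > C.

Ensemble totals are computed over residues whose torsion pair is defined
(the 15 interior residues): a dihedral-only method cannot assign chain
termini, and counting their forced coil padding would bias the coil total
upward by about 0.02.

A known, quantified bias: the random-coil state of the generator draws
every residue independently from the region mixture, and roughly 2.5% of
coil residues land in chance runs of ≥ 2 PPII or extended cells.  A
mixture generated with a 0.70 coil weight is therefore recovered at
≈ 0.68–0.69 with ≈ 0.015 going to PPII/strand.  This is a property of
i.i.d. coil sampling meeting run-length rules, not a classifier defect.

## Principal components and free-energy surfaces

PCA uses the 51 heavy backbone atoms (N, CA, C per residue — the only
backbone set of that size for 17 residues); H and O are excluded.  Frames
are iteratively superposed on the running mean structure (C-alpha Kabsch
fit, 2 refinement rounds plus a final pass against the stored mean so
that `transform` reproduces the covariance alignment exactly), the
153-coordinate covariance is diagonalised, and eigenvector signs are
fixed by making the largest-magnitude component positive so output is
deterministic.  Whether one fits one model per temperature or a pooled
model is an open choice; the default is per-ensemble, and a fitted model
can be applied to any topology-compatible ensemble.

2-D surfaces on (PC1, PC2) use 0.1 nm bins whose edges sit on integer
multiples of the bin width, so bin centres land on values like 2.05 or
−0.25 nm.  Minima are local minima over the 8-neighbourhood among bins
with occupancy ≥ 5 frames (scaled down for very small ensembles), merged
within 2 bins keeping the deeper, with depths relative to the global
minimum.  Depth ordering tracks state population only when the state
clouds have comparable widths resolved by the bin — clouds much narrower
than a bin alias against the grid edges.

## Clustering and hairpin analysis

Pairwise C-alpha RMSD uses a batched Kabsch evaluation via the singular
values of the 3×3 cross-covariance (eigendecomposition of HᵀH with a
determinant sign guard), accurate to ~1e-8 nm, which keeps the ~2×10⁶
pair evaluations of a 2,000-frame matrix around a few seconds.  The
default stride reduces 10,000-frame ensembles to ≤ 2,000 frames for the
pairwise matrix; full scale is available by setting stride 1.

Clusters are connected components of the sub-cutoff graph (cutoff
0.15 nm): chained frames merge even when their mutual RMSD exceeds the
cutoff.  Representatives are medoids (minimum mean intra-cluster RMSD) —
the sources say "representative conformation" without defining one.  The
hairpin population is the population of the cluster whose medoid is
nearest the template reference, provided that distance is below the
cutoff, else zero.

The two hairpin templates place extended-β dihedrals on the strand
residues, the canonical type-I′ pair on the two central turn residues and
extended values elsewhere.  The noise-free references are separated by
0.58 nm C-alpha RMSD (far above the cutoff, so the two hairpins are
mutually exclusive under clustering), and both close their turn hydrogen
bond at 0.19 nm donor-H–acceptor-O distance.

Distance free-energy profiles use 0.05 nm bins (unstated in the sources)
and the convention ΔF = −RT ln(P(bin)/P(reference)) with the reference at
the most populated bin, so the profile is ≥ 0 with minimum zero — the
same convention as the 2-D surfaces; "the zero point is set as zero" is
otherwise circular.  Errors are standard deviations over 4 equal
contiguous blocks evaluated against the full-series reference bin; bins
populated in fewer than two blocks report NaN.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral sphere mesh (default
960 points, probe 0.14 nm) and united-atom radii N 0.155 / C,CA 0.170 /
O 0.152 / H 0.110 nm.  Accuracy: isolated and two-sphere configurations
match the analytic spherical-cap solution within 1% at 960 points.  The
mesh is fixed in the laboratory frame, so SASA is exactly
translation-invariant but rotation-invariant only to the mesh resolution
(a few mesh points, ≈ 1% of an atom's area).  Because only backbone atoms
exist, absolute S_LVFFA values describe the backbone model and are not
comparable to full-peptide areas; only relative trends (compact versus
extended states) are meaningful.

## Synthetic ensembles

Frames are i.i.d. mixture draws — no energetics, solvent or kinetics, and
no Markovian time correlation, so block-error estimates on synthetic data
measure pure sampling noise.  Per state: dihedrals are a per-residue
library value plus wrapped-Gaussian jitter (default σ = 4°), or fresh
region-mixture draws for coil; coordinates are built and then jittered
with isotropic Gaussian noise.  Two noise regimes serve different
stages:

* **Cartesian σ = 0.02 nm** for clustering studies: same-state frame
  pairs stay below the 0.15 nm RMSD cutoff in ≥ 99% of cases, while
  dihedral noise on a 17-residue chain would be lever-arm amplified.
* **Cartesian σ = 0.002 nm with angular σ = 4°** for dihedral-space
  studies (secondary structure): 0.02 nm displacements on ~0.14 nm bonds
  would perturb torsions by ~10° and scramble mesostates.

The coil state samples every residue independently from the Ramachandran
region mixture (default weights α 0.26 / bridge 0.06 / β 0.62 /
other 0.06, a measured low-temperature column), which makes coil frames
mutually distant (> 0.15 nm for ≥ 99% of pairs) so connectivity
clustering cannot bridge coil into hairpin clusters.  True state labels
are stored in ensemble provenance for recovery tests and never read by
analysis stages.

Temperature-dependent mixtures vary weights linearly in T with
renormalisation; the linear law is a fixture convenience (no quantitative
temperature dependence is published), and a slope of −0.00165 K⁻¹ on the
β weight reproduces the published 0.62/0.58/0.55 series within 0.01.

What passing recovery tests shows: each stage measures what the generator
put in, at the published magnitudes, within binomial sampling error.
What it does not show: anything about force-field accuracy, real
conformational equilibria, or time correlation in genuine trajectories.

## Toy replica exchange

Each replica performs Metropolis dynamics (proposal σ 0.35 nm) on a 1-D
double well V(x) = h((x/a)² − 1)² with barrier h = 5 kJ/mol and minima at
±1 nm, plus an effective bath of n = 10,000 harmonic degrees of freedom
whose potential energy is redrawn from its exact equilibrium distribution
(RT/2 · χ²ₙ) at each exchange attempt — a composition of kernels that
each preserve the joint Boltzmann distribution.  Swaps follow
p = min(1, exp[(1/RTᵢ − 1/RTⱼ)(Eᵢ − Eⱼ)]) on alternating even/odd
neighbour pairs (the attempt schedule is unspecified in the sources).
The bath size is an effective heat-capacity scale chosen from the
analytic acceptance estimate (mean Δ ≈ −n·ΔT²/2T², σ_Δ ≈ √n·ΔT/T) so
that the 36-rung 273–370 K ladder exchanges at ≈ 0.6 per pair — well
above the 0.1 sufficiency rule.  The toy model is explicitly not the
solvated peptide system; only the exchange machinery and its diagnostics
are the point.

## Problem sizes and defaults

Recovery studies use 10,000-frame ensembles (or 10,000 × 14 dihedral
draws), stride-5 pairwise matrices (2,000 frames, ~2×10⁶ Kabsch fits),
50,000-step toy-REMD runs, and 960-point SASA meshes (256 in profile
scans).  At these sizes binomial standard errors are ≈ 0.002–0.006 on
recovered fractions, against stated tolerances of ±0.01 (±0.02 for
secondary-structure totals).

## Known limitations

* Backbone-only geometry: no side chains, hence no steric realism and no
  full-peptide SASA.
* i.i.d. frames: no kinetics, no autocorrelation, so convergence
  diagnostics exercise machinery rather than hard cases.
* The secondary-structure rule set is a reconstruction of a dihedral-only
  mesostate method with explicitly chosen run lengths, grid anchoring and
  turn boxes (version-tagged `mesostate-v1`); recovery tests are matched
  to this rule table rather than to any historical binary.
* FES minima coordinates depend on PCA sign/orientation conventions and
  are not comparable across implementations; only counts, depths and
  population ordering are.
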