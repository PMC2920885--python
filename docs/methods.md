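# Methods

This note records the models, conventions and numerical choices behind
`betaturn`, including decisions made where several defensible designs
existed.

## Geometric turn annotation

A β-turn window is four consecutive residues *i..i+3* with
|Cα(*i*) − Cα(*i*+3)| **strictly less than 7.0 Å** and no residue of
the window marked helical. The helix exclusion is evaluated on *all
four* residues (the literal reading of "four adjacent residues not in
an α-helix"); the helix mask is an input — from upstream secondary
structure labels or a fixture generator — never computed internally
from hydrogen bonding. Chains are split wherever consecutive Cα–Cα
distance reaches 4.5 Å, and no window spans a break. Overlapping
windows are all reported; about half of real β-turns are multiple
turns, so no deduplication is attempted.

Torsions follow the IUPAC sign convention, computed with the
atan2 formulation, range (−180°, 180°] with −180° canonicalised to
+180°. φ of the first and ψ of the last residue of a segment are
undefined and propagate as such (never as 0).

### Type classification

A window's type comes from (φ, ψ) of residues *i*+1 and *i*+2 against
the table of nine ideal quadruples. A specific type matches when each
of the four angles is within 30° circular deviation of its ideal,
allowing **exactly one** of the four to deviate up to 45°; ties go to
table row order (I, I′, II, II′, VIa1, VIa2, VIb, VIII); no match
falls through to the catch-all type IV. This 30°/45° tolerance is the
established convention of the turn-classification literature; the
window's assignment is deliberately dihedral-only — the classical
requirement of a cis-proline at *i*+2 for the VI types is dropped,
because the ω torsion is not part of this pipeline's inputs. All nine
tabulated quadruples round-trip to their own type under these rules
(verified exhaustively in the tests).

For the six label channels, types I′, II′, VIa1, VIa2 and VIb map to
the non-specific (NS) class; a residue in overlapping turns of
different types is positive in several type channels at once, and any
type-positive residue is turn-positive.

## Feature encoding

230 attributes per residue, frozen as layout `pssm9-ss5-cluster5/v1`:
window offsets −4..+4 of 20 scaled PSSM values each (180), then
offsets −2..+2 of 3 secondary-structure bits (15), then offsets −2..+2
of 7 dihedral-cluster bits (35). PSSM scaling is a single division by
ten, no clipping and no further standardisation. Window positions
beyond the chain termini contribute all-zero sub-blocks: zero is the
neutral element both for scaled log-odds and for one-hot blocks, and
padding with repeated terminal residues would fabricate evidence.
PSSM files may order their amino-acid columns differently by dialect;
the parser remaps every file to a canonical alphabetical order, so
differently ordered inputs encode identically.

## Upstream predictions and dihedral clusters

The classifiers consume per-residue H/E/C labels and a seven-state
dihedral-cluster label. These normally come from an external
predictor's output files (3-column TSV). For the self-contained path
the package clusters (φ, ψ) space itself: Lloyd iteration under the
**toroidal** metric (per-coordinate differences folded into ±180°)
with D²-weighted seeding, circular-mean centroid updates, and
farthest-point re-seeding of emptied clusters — plain random seeding
demonstrably merges well-separated clouds. Assignment is
nearest-centroid with ties to the lowest index; undefined terminal
torsions map to the most populous cluster, a frequency-weighted
neutral default. A fixed seven-centroid partition of the Ramachandran
torus (αR, β, PPII, bridge, αL, γL, ε) supplies cluster labels for
synthetic corpora without refitting.

## Classifiers

Six independent one-vs-rest binary SVMs (libsvm via scikit-learn),
RBF kernel, with the tuned (C, γ, w) defaults listed in the README;
w multiplies C for the positive class only. The decision threshold is
0 on the signed decision score — no probability calibration, since the
class weights already address imbalance. No per-fold re-tuning: the
defaults are frozen, overridable per call. Type channels are trained
one-vs-all-residues (not one-vs-other-turn-residues); the large w
values are consistent with that reading.

Cross-validation partitions *chains* into k (default 7) groups by a
seeded shuffle dealt round-robin, trains on k−1 groups, predicts the
held-out chains, filters per chain, and pools confusion counts over
folds (residue pooling, not fold averaging). ROC AUC per channel is
computed from the pooled raw decision scores *before* filtering;
thresholded metrics are computed *after* filtering.

## Filtering

Four rewrite rules in fixed order — tnt→ttt, ntn→nnn, nttn→nnnn,
ntttn→ttttt — each applied as one simultaneous-match pass (matches
located on the pre-pass string, all flips applied together, so scan
direction is irrelevant). Chain ends behave as virtual 'n' context;
rule 4 flips only in-chain positions, so a terminal three-run extends
inward. The four-rule cycle repeats to a **fixpoint**: a single cycle
is not idempotent (rule 4 can create a one-gap context that rule 1
would fill), and idempotence — re-filtering a filtered prediction must
change nothing — is a contract here. Convergence needs at most a few
cycles; a pass-count safeguard bounds it. Exhaustively over all t/n
strings up to length 12, every output turn run is at least four
residues, except a three-run flush at a terminus of a chain too short
to extend it.

All six channels are filtered independently; there is deliberately no
cross-channel reconciliation (no forcing of type-positive residues to
be turn-positive), preserving each classifier's output semantics.

## Evaluation statistics

From counts p (true positive), n (true negative), o (over-prediction),
u (under-prediction), t = p+n+o+u:
Q_total = 100(p+n)/t; sensitivity Q_obs = 100p/(p+u); specificity =
100n/(n+o); Q_pred = 100p/(p+o); MCC = (pn−ou)/√((p+o)(p+u)(n+o)(n+u));
S = 100(p+n−R)/(t−R) with R = ((p+o)(p+u)+(n+o)(n+u))/t, the expected
number of correct calls from a marginal-preserving random predictor.
Metrics with zero denominators are reported as undefined (`None` /
`NA`), never silently zero: "no positive predictions" and "all
positive predictions wrong" must stay distinguishable. Reports print
percentages to 1 d.p. and MCC/AUC to 2 d.p. ROC curves place one point
per distinct score threshold plus the (0,0) and (1,1) endpoints; AUC
uses the trapezium rule.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:
chains of 30–60 residues, a target of 25 % of residues inside turns
(matching the observed share in non-redundant chain sets), planted
type frequencies proportional to the observed distribution
(I : II : IV : VIII : NS ≈ 9.3 : 3.8 : 9.4 : 2.7 : 2.4), PSSM signal
shift of 5 log-odds units on the four turn-favouring columns (N, D, G,
P), and a 10 % upstream label-noise rate (three-state secondary
structure prediction is ~80–90 % accurate, so 0.1 is a realistic
per-residue error for a good predictor).

Backbones are built by NeRF internal-coordinate extension with
standard bond geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å;
angles 111.0°, 117.2°, 121.7°; ω fixed trans). The builder
round-trips: recomputed φ/ψ match the prescription to well under
0.5°. Flanks are extended (−120°, 120°), which keeps non-turn windows
near 10 Å end-separation; the flanking ψ of residue *i* matters
because the Cα(*i*)–Cα(*i*+3) distance depends on it, so it is part of
the plan, and the generator *validates* assignability: ground truth is
always produced by re-annotating the built coordinates, and generation
fails loudly if a planted turn is not recovered with its planted type.

Three planting details follow from ideal trans geometry. The VI types
require a cis peptide and are not plantable (end separations
8.6–10.4 Å trans); the NS class is planted as II′, its cleanest
trans-plantable member. The tabulated *average* type-IV angles land at
7.36 Å — just outside the cutoff — so catch-all windows are planted
with a compact conformation (−100°, 10°, −100°, 10°) that classifies
as IV robustly under the ±3° planting jitter (≤ 5° by contract).
Jitter keeps planted types stable: no specific type's tolerance region
is within 5° of another's.

Synthetic PSSMs draw integer background scores from a truncated normal
(sd 2.5) on [−7, 7] and add the signal shift on the designated columns
for turn residues; files are written in the PSI-BLAST ASCII dialect so
the parser is exercised on generated data. The upstream stand-in
corrupts true labels (turn residues 'C', flanks 'E'; clusters from the
fixed torus partition) by uniform substitution at the given rate. For
the zero-information control the corpus instead draws upstream labels
uniformly at random: substitution noise at *any* single rate leaves
residual (anti-)correlation with the truth that a kernel classifier
can exploit, which would contaminate the null condition.

What the generator does **not** emulate: sequence–structure
covariation, side-chain or proline-specific geometry, real
overlapping-turn statistics, helices, or PSSM column correlations.
Passing the end-to-end tests therefore demonstrates that the pipeline
learns a planted, recoverable signal under honest chain-level
cross-validation — not any particular accuracy on real proteins, which
depends on real PSSMs and a real upstream predictor.

## Problem sizes and thresholds

The end-to-end learnability checks use 49 chains (7 folds × 7) of
30–60 residues: large enough that the cross-validated turn-channel MCC
exceeds 0.8 with the default signal and sits within ±0.1 of zero for
the null corpus — both thresholds are fixture design choices.
Exhaustive filter checks cover all 2^L strings for L ≤ 12. The
assignment-boundary bisection runs 60 halvings over a one-parameter
backbone family whose end separation is monotone on the bracket,
locating the boundary to far better than the asserted ±0.01 Å.

## Known limitations

- Turn typing is dihedral-only; VI-type assignments on real structures
  may differ from cis-proline-aware annotators.
- The helix mask must be supplied; there is no internal DSSP-style
  assignment.
- The internal dihedral clustering is a stand-in for a real
  secondary-structure/dihedral predictor, not a re-implementation of
  one; production use should feed real predictor output via the TSV
  interface.
- Filtering can leave a three-residue turn at a terminus of a chain
  shorter than four residues' reach; this is the documented boundary
  behaviour, not an oversight.
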