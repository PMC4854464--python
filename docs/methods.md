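# Methods

This note documents the models, conventions and numerical choices behind
`enzgrad`, and what its synthetic tests do and do not establish about
real data.

## Residue representation

Every analysis operates on one point per residue: the unweighted mean of
the side-chain heavy-atom coordinates. Glycine, which has no side chain,
is represented by its Cα; the same fallback applies to any residue whose
side-chain atoms are absent from the coordinate record (disordered side
chains), which is logged rather than dropped — dropping sites would
silently misalign the rate vector, which is mapped to residues strictly
by order. Alternate locations resolve to the highest-occupancy conformer
(ties: first in file order); insertion codes are part of the residue key;
selenomethionine is read as methionine; other nonstandard residues are
excluded with a warning.

Biological assemblies deposited as multiple MODEL records are flattened
into a single model whose repeated chains get suffixed ids ("A", "A-2",
…). This matters: packing (WCN) and catalytic distance must see every
subunit copy, and catalytic annotations given per author chain are
propagated to all symmetry copies of that chain (a policy of this
package — annotation sources do not state how copies are handled).

## Per-residue metrics

**WCN** (Å⁻²): WCNᵢ = Σ_{j≠i} 1/r²ᵢⱼ over side-chain centers. Computed on
the full assembly by default; single-chain variants are explicit options.

**ASA/RSA**: accessible surface area by the Shrake–Rupley quadrature —
each heavy atom's van der Waals sphere (C 1.70, N 1.55, O 1.52, S 1.80,
Se 1.90 Å; default 1.70) is expanded by the 1.4 Å probe and covered with
a golden-angle Fibonacci lattice (960 points by default; the quadrature
error on an isolated sphere is well under 2%, and doubling the point
count moves per-residue areas by < 1%). A point is accessible iff it lies
outside every other expanded sphere; neighbor lookups use a k-d tree.
Per-residue ASA is the sum over the residue's atoms and is divided by the
residue type's maximum accessibility in an extended Gly-X-Gly tripeptide
(Tien et al. theoretical values, user-overridable) to give RSA. RSA > 1
is possible and deliberately not clipped (the normalization is a
reference, not a bound); the count of such sites is logged. Residues with
a covalent-range (< 2.1 Å) heavy-atom contact across chains — disulfide
bridges, inter-chain peptide linkages — get RSA 0: their burial is
chemical, not solvent-driven. A reader for the ACC column of DSSP output
allows substituting precomputed areas when bit-compatibility with
DSSP-based analyses is wanted; exact agreement between the built-in
quadrature and DSSP is not promised (different radii and algorithms).

**Interfaces**: a residue is an interface residue when its RSA computed
on the isolated chain exceeds its RSA in the assembly by at least 0.10.
The "10%" criterion is read as an absolute RSA difference: RSA is itself
a fraction, and a relative reading would flag noise at near-zero RSA. The
relative reading is implemented as an option. Metrics are always computed
on the full coordinate set; the interface-excluded analysis variant drops
rows only afterwards.

**Distance d** (Å): Euclidean distance from a residue's center to the
nearest catalytic residue's center; catalytic residues sit at exactly 0.

## Rates

Raw site-specific rate estimates (Rate4Site output or two-column tables;
positions must be consecutive from 1) are rescaled to a per-protein mean
of exactly 1. Normalization is idempotent and scale-invariant. Negative
raw scores are accepted with a warning. Rates map to residues by order,
and a length mismatch is a hard error — there is no safe way to guess an
alignment between a rate vector and a structure, so this package refuses
rather than truncates.

## Shells and smoothing

Shells are 5 Å wide — roughly the minimum distance between two side-chain
centers, so shell 1 contains residues in direct contact with the
catalytic site. Shell 0 is [0, 2.5] and shell k ≥ 1 is (5k−2.5, 5k+2.5];
the left-open/right-closed convention is fixed by requiring 27.5 Å to lie
in shell 5 (the boundary at which pooled rate gradients level off), and
shell 0 is closed at 0 so catalytic residues are included. Trend curves
against distance use a deterministic binned-mean smoother (default bin
2.5 Å, standard error reported for bins with ≥ 2 points) rather than a
spline/GAM smoother: the binned means are reproducible to the bit and
directly testable.

## Linear models

Per protein, ordinary least squares with intercept for seven formulas:
K ~ d, K ~ RSA, K ~ WCN, K ~ RSA + d, K ~ WCN + d, K ~ WCN + RSA, and
K ~ WCN + RSA + d. The purely structural pair (WCN + RSA) is included
because the gain ΔR² from adding d to it is the headline measure of the
functional constraint. Conventions: a constant response yields R² = 0
with zero slopes; a constant predictor is a rank error naming the
predictor; catalytic residues themselves (d = 0 rows) are included as
observations (excluding them is a sensitivity option a caller can apply
by filtering the table). Aggregation across proteins is unweighted — one
protein, one vote — matching per-protein fitting. Stratification labels:
active-site location from the mean RSA of catalytic residues (core
< 0.05, intermediate [0.05, 0.25), surface ≥ 0.25; the half-open
intermediate/surface boundary follows the textual definition) and size
classes from tertiles of the dataset's length distribution with ties to
the lower class.

## Active-site recovery

The optimized-distance scan fits, for every residue r, the one-predictor
model K ~ ‖·−r‖ over all residues and proposes the r with maximal R²
(ties: lowest residue index). The reference's own observation (distance
0) is included — exclusion changes R² negligibly for n ≫ 1. The slope is
recorded but its sign is not constrained: a rapidly evolving functional
site produces a *negative* gradient that is equally informative. For
simple regression the profile is computed as squared Pearson correlation
between K and each distance column, which makes the n-regression scan a
single matrix product. Predictions are scored by distance to the nearest
true catalytic residue: exact (0 Å), neighbor (≤ 7.5 Å, one shell), miss.
By side-chain geometry a wrong prediction is at least ~2.5 Å away, so the
distance distribution has a gap above 0.

Method comparison: a 2×2 success-within-7.5-Å table, unconditional
cross-product odds ratio (Haldane–Anscombe +0.5 only when a zero cell
exists; the conditional MLE is reported alongside), two-sided Fisher
exact p, and ROC/AUC from per-residue scores (scan: the residue's
reference-R²; control: its WCN) pooled across proteins against the true
catalytic labels, with AUC computed by the tie-corrected rank statistic.
Pooling residues across proteins (rather than averaging per-protein ROC
curves) is this package's construction.

## Synthetic generator

The generator emulates exactly the statistical structure the analysis
assumes: n residue centers uniform in a sphere with sequential-rejection
excluded volume (min separation 4 Å, default density 30% of the
exclusion-sphere volume ⇒ a ~20 Å globule for 300 sites); a planted
catalytic site of 3 residues chosen by burial (highest WCN), exposure
(lowest WCN) or at random; and raw rates β₀ + β_d·d + β_wcn·WCN +
β_rsa·RSA + ε, ε ~ N(0, σ²), floored at 10⁻⁶ (rates are non-negative)
and normalized to mean 1. Defaults — β₀ = 1.0, β_d = 0.03 Å⁻¹,
β_wcn = −0.4 Å², β_rsa = 0.3, σ = 0.3 — were chosen once so that, at the
default geometry, the model R² lands in the 0.2–0.45 range typical of
real per-enzyme fits, packed cores are conserved, exposed residues evolve
fast, and the floor binds only in the extreme conserved tail (~1% of
sites). Residue centers double as the only atom, so WCN and d are exact
by construction, while ASA uses one 3 Å pseudo-sphere per residue —
coarse, but it creates a genuine buried/surface axis. Every stage is
deterministic given the seed; sub-generators for placement, site choice
and noise derive from (seed, stage) so the stages are independently
reproducible.

What the generator does **not** emulate: real side-chain geometry and
chemistry, chain connectivity, multimeric assemblies and interfaces,
phylogenetic correlation in the rate estimates, or alignment error.
Passing tests therefore establish the correctness and statistical
behavior of the estimators under the assumed linear rate law — not that
real enzymes follow that law; the deposited-data reproduction path exists
for the latter.

## Study sizes and test design

Monte-Carlo checks use scales at which the tested property is
well-resolved: coefficient recovery on 50 proteins × 300 sites (each β
within 3 standard errors in ≥ 90% of seeds; the mean-bias/coverage check
uses a strong-signal configuration, β_wcn = −1.0, β_rsa = 1.2, so that 5%
of each |β| exceeds the Monte-Carlo standard error of the mean); the null
control (β_d = 0) on 50 proteins, where the mean ΔR² from adding d stays
below 0.02 (≈ the 1/n inflation expected from one extra regressor); and
noisy-gradient recovery on 50 proteins of 200 sites with the planted pure
gradient β_d = 0.04, σ = 0.2, where the scan must land within one shell
of the planted site in ≥ 80% of seeds. The bundled study script runs 40
proteins of 100–400 sites (log-uniform, echoing the right-skewed size
spread of curated enzyme sets) with an 8/28/4 buried/random/surface mix,
reflecting the strong interior bias of real catalytic sites.

## Known limitations

- The Shrake–Rupley areas use generic van der Waals radii; analyses that
  must match DSSP-derived RSA should pass DSSP areas through the
  provided reader.
- Rate-to-structure mapping is strictly positional; structures whose
  SEQRES/ATOM numbering disagrees with the rate file must be reconciled
  by the caller.
- mmCIF input, assembly prediction and structure download are out of
  scope; inputs are user-supplied PDB-format files.
- The interface machinery needs both assembly and per-chain areas and is
  skipped for monomers (all-false flags) and for DSSP pass-through.
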