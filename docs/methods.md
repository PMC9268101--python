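# Methods

`qsarligand` implements a ligand-based QSAR workflow for small-molecule
TLR7 antagonist design: formula-level 2D molecular descriptors, ordinary
least squares (OLS) multiple linear regression with genetic-algorithm
variable subset selection (GA-VSS), a complete internal/external validation
suite, a leverage-based applicability domain, a simplified grid-field
3D-QSAR with partial least squares (PLS), and the activity/cost arithmetic
used in design tables. This note records the models, their assumptions, the
parameters that matter, and the design choices made where the conventions
were genuinely open.

## The activity model

Activity is expressed as pIC50 = −log10(IC50/µM). The frozen published
five-descriptor model is

    pIC50 = −6.2155 + 0.1409·VE3sign_D/Dt + 4.1832·SpMin2_Bh(s)
            + 0.0366·P_VSA_logP_5 − 0.9329·Eig02_EA(dm)
            − 0.1016·CATS2D_09_AA

and is available as `model_core.published_tlr7_model()`. New models are fit
by OLS (`fit_mlr`), optionally after GA subset selection.

## 2D descriptors

All five descriptors are computed from their defining formulas on the
hydrogen-suppressed molecular graph (RDKit parses and perceives
aromaticity; aromatic bonds always carry order 1.5 so no result depends on
a Kekulé assignment).

**VE3sign_D/Dt.** The distance/detour ratio matrix holds, for every atom
pair, shortest topological distance divided by longest simple-path
distance (diagonal 0). The descriptor is (n/10)·log10|Σᵢ lᵢ| where lᵢ are
the coefficients of the eigenvector of the smallest (most negative)
eigenvalue; eigenvector sign is fixed by making the largest-magnitude
coefficient positive, and the coefficients are summed signed (the "sign"
variant). Two degenerate regimes return NaN with a warning: acyclic graphs
(the ratio matrix is J − I, whose non-Perron eigenvectors are exactly
orthogonal to the ones vector, so the coefficient sum is identically zero)
and vertex-transitive rings such as benzene (same orthogonality by
symmetry). Longest-path search is exponential in principle; an exhaustive
DFS with a default 60-heavy-atom cap handles drug-sized molecules in
milliseconds.

**SpMin2_Bh(s).** Second-smallest eigenvalue of the Burden matrix of the
hydrogen-filled graph with Kier–Hall intrinsic states on the diagonal:
I = ((2/N)²·δv + 1)/δ with δ the heavy-atom degree, δv the valence
electrons minus attached hydrogens and N the principal quantum number
(reference values: pyridine-type N 3.00, tertiary amine N 2.00, ether O
3.50; hydrogen gets I = 5). Off-diagonal entries are the bond order π_b
(+0.001 when an endpoint is terminal) for bonded pairs and 0.001
otherwise — deliberately the literal printed convention rather than the
classical 0.1·π_b Burden weighting; the spectra differ, and the literal
form is what the model definition states.

**P_VSA_logP_5.** Per-atom Ghose–Crippen logP contributions are obtained
from RDKit's Crippen atom typing with hydrogen contributions folded into
the bonded heavy atom (so per-atom values sum to whole-molecule logP).
Per-atom Van der Waals surface areas subtract one spherical cap per bonded
neighbour using Bondi radii and reference bond lengths from Cordero
covalent-radius sums, shortened by 0/0.1/0.2/0.3 Å for
single/aromatic/double/triple bonds; negative areas clamp to zero. The
descriptor sums VSA over atoms with logP in the left-open bin (0, 0.25].

**Eig02_EA(dm).** Second-largest eigenvalue (descending sort, the common
"Eig02" convention) of the bond-bond adjacency matrix with bond dipole
moments (Debye) on the diagonal. The dipole table
(`data/bond_dipoles.yaml`) is a documented stand-in assembled from
textbook group dipole moments — no open reference table exists for this
descriptor family — and unknown bond types contribute 0 with a warning.

**CATS2D_09_AA.** Count of unordered acceptor–acceptor pairs at
shortest-path distance exactly 9. Acceptors: any O unless positively
charged; any N unless positively charged, amide-type (bonded to a carbonyl
carbon) or pyrrole-type (aromatic with an attached H or three ring
neighbours).

All constants live in versioned YAML files under `qsarligand/data/`; they
are configuration, not code.

## Model building

The sorted-response split orders compounds by increasing activity, forces
the most- and least-active compounds into training, and assigns the rest
train, train, test cyclically with the test quota capped at
floor(0.3·n). For 54 compounds this yields 38 training / 16 test — the
split whose PRESS/RMSE algebra the published statistics satisfy
(RMSE_cv = √(4.31/38) ≈ 0.34, RMSE_ext = √(2.21/16) ≈ 0.37,
h* = 3·6/38 ≈ 0.474).

GA-VSS runs one genetic search per subset size (1..5 by default)
maximizing leave-one-out Q² computed with the exact OLS hat-matrix
identity (LOO residual = e/(1 − h)). Internals the source conventions do
not specify are package defaults: population 50, tournament selection of
size 3, uniform crossover probability 0.5, per-gene mutation 1/n, elitism
of one, and a mandatory seed. Subsets whose OLS coefficients fail a
per-coefficient t-test at α = 0.05 are discarded; ranking ties break by
fewer descriptors, then higher R². The canonical 10,000 generations per
size remains the config default; the test and acceptance runs use 25–50
generations, which is ample at desk scale (≤ 20 candidates) — the GA
matches an exhaustive-search oracle there.

The descriptor pre-filter drops near-constant columns (> 80% identical
values) and, from each pair with |Pearson r| > 0.95, the later column.

## Validation statistics

Fit block: R², adjusted R², RMSE, MAE, standard error of estimate
s = √(RSS/(n−k−1)), F = (R²/k)/((1−R²)/(n−k−1)), Lin's concordance
correlation coefficient, and Friedman's lack-of-fit
LOF = (RSS/n)/(1 − (k+1+d·k)/n)² with smoothing d = 0.5. The published
LOF value cannot pin d, so LOF is reported but never used as an acceptance
surface.

Internal validation: leave-one-out with explicit per-point refits (the
hat-matrix shortcut is kept as a tested identity, and used inside the GA
and Y-scrambling for speed); leave-many-out holds out 30% per iteration,
refits on the remainder and pools PRESS and TSS over iterations
(Q²_LMO = 1 − ΣPRESS/ΣTSS, deviations about the retained subset's mean) —
the pooled estimator is stable for small held-out blocks and converges to
the LOO value as the fraction shrinks to 1/n, which the mean-of-ratios
form does not; Y-scrambling permutes the response, refits, and reports
mean R², mean Q² and mean RMSE of the scrambled models.

External validation: PRESS_ext, RMSE_ext, MAE_ext, R²_ext,
Q²_F1 = 1 − PRESS/Σ(y_ext − ȳ_tr)², Q²_F2 = 1 − PRESS/Σ(y_ext − ȳ_ext)²
(never larger than Q²_F1), Q²_F3 = 1 − (PRESS/n_ext)/(TSS_tr/n_tr),
CCC_ext, and the origin-forced agreement metrics
r²m = r²(1 − √(r² − r0²)) computed in both regression directions, then
averaged (r²m_aver) and differenced (r²m_delta). Models carry their
training mean and TSS so these can be computed without the training
responses.

## Applicability domain

Leverage of a query descriptor vector x (intercept-augmented) is
h = xᵀ(XᵀX)⁻¹x; training leverages are the hat diagonal (trace k + 1).
The warning threshold is h* = 3(k+1)/n. Williams tables standardize
residuals by their own set's RMSE (training rows by training RMSE, test
rows by external RMSE — the plotting convention does not state a
denominator, and the set-wise choice keeps both clouds on a comparable σ
scale) and flag |r| > 2.5σ or h > h*. Insubria tables replace the residual
with the predicted value for compounds without activities and flag
h ≤ h* as in-domain.

## Grid-field 3D-QSAR

Pre-aligned molecules share one rectangular grid (1.4 Å spacing, 3 Å
margin around the union bounding box). Two probe energies per point and
molecule: a Lennard-Jones 6-12 steric field for a carbon probe of radius
1.73 Å (per-element well depths of AMBER/GAFF magnitude,
Lorentz–Berthelot combination, r*_ij = R_i + R_probe so the single-atom
minimum is −√(ε_i·ε_p)), and a Coulomb electrostatic field for a +1 point
charge with distance-dependent dielectric ε(r) = r, i.e.
E = 332.0637·q/r² kcal/mol. Both truncate at ±30 kcal/mol, the classic
field convention. Near-constant columns (SD < 0.05 kcal/mol) are dropped
with the mask recorded. PLS uses scikit-learn's NIPALS implementation
without scaling; at full-rank components it reproduces the OLS fit, the
property the tests use as the independent cross-check. Contour export maps
the PLS coefficient vector back through the drop mask to grid coordinates
(positive coefficients mark regions where larger field values raise
predicted activity).

Alignment is deliberately out of scope: the module requires pre-aligned
input and offers only rigid Kabsch superposition onto a user-supplied atom
map as a convenience. Partial charges default to Gasteiger (with hydrogen
charges folded into heavy atoms); the charge assignment is a pluggable
hook.

## Synthetic data

The generator emulates a 54-compound antagonist study set at desk scale:
valence-correct quinazoline/benzoxazole-like graphs assembled from five
two-slot scaffold templates and twenty substituents, activities linear in
the five computed descriptors plus Gaussian noise of σ = 0.30 log units
(the magnitude of the emulated training RMSE), a ≥ 3-order-of-magnitude
IC50 spread, and all four potency classes populated
(≤ 2 / 2–10 / 10–20 / > 20 µM).

Two calibrations are part of the generator's design. First, the published
coefficients act on a proprietary descriptor implementation whose scales
differ from ours, so applying them raw would put every compound far
outside the study's potency window; the linear predictor is therefore
rescaled to signal SD 0.75 log units (which against σ = 0.30 gives the
emulated R² ≈ 0.86 regime) and centred at pIC50 −0.9 (≈ 8 µM, the middle
of the study window). Second, on our scales the P_VSA term would carry
essentially all of the signal variance, making the other four descriptors
statistically invisible at this noise level — not the structure a genuine
five-descriptor model exhibits — so the per-term contribution variances
are equalised, keeping the published signs. The effective generating
coefficients and intercept are recorded in the returned truth dictionary
and in `truth.json`; noiseless runs recover them exactly.

Decoy descriptors for subset-selection experiments are smooth random
functions of the true descriptors plus noise, redrawn until every decoy's
|r| with every true column is below 0.95 so the pre-filter cannot remove
them trivially. The 3D toy system is a set of rigid point-charge
pseudo-molecules on one shared jittered-lattice frame (charges uniform in
±0.3 e), with activities linear in the electrostatic energies at three
designated grid points plus σ = 0.1 noise.

What the generator does *not* emulate: real conformational chemistry,
synthesizability, assay error structure, or the actual study compounds
(which are not machine-readable). Passing tests demonstrate that the
pipeline recovers planted statistical structure under the stated noise
conditions; they say nothing about prospective accuracy on real TLR7
chemistry, and the published headline statistics are consequently checked
as self-consistency identities, not reproduced.

## Numerical choices and degenerate inputs

- Symmetric eigenproblems use dense `eigh`; eigenvalue descriptors agree
  with independently constructed oracle matrices to 1e−8.
- VE3sign returns NaN (with a warning) when the eigenvector coefficient
  sum is below 1e−12; see above for when this provably happens.
- OLS refuses rank-deficient designs and names suspect columns; LOO
  refuses when any sub-fit is rank-deficient; LMO logs and skips
  degenerate subsamples.
- PLS with a response exactly orthogonal to every retained column has no
  extractable direction; the fit degrades gracefully to the mean predictor
  (R² = 0) instead of propagating NaNs.
- Splits break activity ties lexicographically by compound id, making
  every split reproducible from the table alone.
- All stochastic operations (GA, LMO, Y-scrambling, generators) take
  explicit seeds; one seeded generator per call, no global state.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 54-compound
synthetic sets, ≤ 20 candidate descriptors, GA populations of 30–50 with
25–50 generations, 200-iteration LMO/Y-scrambling (the 2000-iteration
canonical counts remain the API defaults), and 3D grids of a few thousand
points. At these sizes the full suite completes in well under a minute.

## Known limitations

- Bit-parity with the proprietary descriptor tool is not attainable or
  claimed: bond-dipole tables, radii sources and several sorting
  conventions are not published; this package's conventions are documented
  above and frozen in the data files.
- The detour matrix is exponential-time in pathological ring systems; the
  60-atom cap is a guard, not a performance guarantee for fused cage
  topologies.
- The 3D module does not generate conformers or optimise alignment.
- HypoGen-style hypothesis generation, docking, MD and ADMET prediction
  are out of scope; only the cost arithmetic and reliability banding of
  pharmacophore hypotheses are implemented.
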