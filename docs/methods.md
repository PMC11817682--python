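# Methods

## Model

`pocketsig` implements a linear map from the equilibrium population of a
receptor's intracellular-pocket conformations to its signaling efficacy
along two transducer pathways (G protein and β-arrestin-2). For ligand
*l* and pathway *p*,

    E_{l,p} = Σ_n β_{p,n} · f_{l,n}

where `f_{l,n}` is the fraction of ligand *l*'s structural ensemble
assigned to conformation *n* and the slopes `β` are the ordinary
least-squares solution. No intercept is fitted: fractions sum to one, so
an intercept would be confounded with a constant shift of all slopes.
Efficacies are maximal responses (E_max) in percent of the reference
full agonist, so slopes carry the same percent units and are read as the
intrinsic efficacy of each conformation.

The model assumes (i) the ensemble is an equilibrium sample, (ii)
efficacy is linear in conformational populations, and (iii) the
conformations defined by clustering are the functionally relevant
states. None of these is checked by the code; they are the modeling
commitments.

## Features and the configuration distance

Each frame is reduced to three vectors: torsion angles (ψ, ϕ, χ1, χ2 of
the intracellular residues; radians in [−π, π)), pairwise Cα distances
between 22 anchor residues (Å), and donor–acceptor distances of the
hydrogen-bonding polar N/O atoms found within 8.0 Å in a reference frame
(Å). Angles undefined for a residue type (χ1 for Gly/Ala; χ2 for
Ser/Thr/Cys/Val and smaller) or at chain termini are omitted, and the
realized angle list is stored so the feature count is explicit. χ
dihedrals follow the IUPAC heavy-atom definitions; for residues with
ambiguous terminal branches the lower-numbered branch atom is used.

The distance between two configurations is a convex combination

    d(i,j) = w_θ·d_θ + w_C·d_C + w_H·d_H ,  w_θ + w_C + w_H = 1

where each component is the root-mean-square of per-feature differences
(periodic smallest difference for torsions). RMS normalization makes the
three components commensurate despite very different dimensionalities
(hundreds of torsions vs. tens of distances), which the weighted sum
presupposes. Both choices are isolated behind `torsion_component` /
`vector_component` / `combined_distance` so either could be swapped.

## Two-stage conformation definition

1. Complete-linkage agglomerative clustering of the combined distance,
   cut to exactly `h` clusters (scipy). Each cluster is represented by
   its medoid — the member frame minimizing summed distance to the rest;
   medoids rather than mean structures because stage 2 needs a concrete
   frame, and ties resolve to the lowest frame index for determinism.
2. The medoid–medoid RMSD matrix is converted to a Gaussian similarity
   `S = exp(−D²/(2δ²))` and grouped into `c` conformations by spectral
   clustering with the pivoted-QR (`cluster_qr`) label assignment
   (scikit-learn) — deterministic, no k-means restarts.

When Cartesian coordinates are available the stage-2 RMSD is the Cα RMSD
after optimal (Kabsch) superposition over the intracellular residues.
Feature-table inputs carry no coordinates, so the default stage-2 metric
is the RMS difference of the Cα-pair-distance features of the medoids —
also in Å, rotation-invariant by construction, and measuring the same
intracellular-geometry change. The choice is the `medoid_metric`
parameter of `ConformationClusterer`.

Held-out ligands are excluded from clustering; their frames are assigned
afterwards to the conformation of the nearest cluster medoid under the
combined distance (ties → lowest conformation id). This matches the
intended use: predicting efficacy for a ligand with a known binding pose
but unknown pharmacology.

## Training and hyperparameter selection

Hyperparameters are the distance weights, `h`, the bandwidth `δ`, and
`c`. They are selected by grid search with a nested leave-one-out (LOO)
loss: within a training set, each ligand in turn is held out, the
conformation model and slopes are refit on the remainder, the held
ligand is predicted, and the loss is the mean squared error summed over
both pathways. The default grid mirrors the selected search space:
weight patterns {(w,w,1−2w), (w,1−2w,w), (1−2w,w,w)} for
w ∈ {0.1, 0.2, 0.25, 0.33}, h ∈ 2..40, δ ∈ {1,2,3}, c ∈ 2..h−1.
Patterns with a negative entry (the printed value w = 1 produces them)
are skipped with a logged notice. Ties resolve to the first point in
deterministic grid order (weights, then h, then δ, then c ascending);
losses within a small numerical tolerance (1e-9, absolute plus relative)
of the minimum count as tied, so that mathematically identical losses —
routine on noise-free data, where every hyperparameter point recovering
the same labeling yields the same fractions — are not separated by
floating-point dust.
The package default hyperparameters are the selected values
w = (0.25, 0.25, 0.5), h = 40, δ = 2, c = 14.

The outer LOO refits the grid search per fold. With 10 training ligands
and up to 14 conformations the regression is routinely rank-deficient;
the minimum-norm solution is returned and a warning logged, so
conformations unvisited in training get slope 0.

Reported per-ligand prediction SDs are taken across the n outer CV
models (each model also predicts the ligands it was trained on, via
their fraction rows). Slope means/SDs across CV models require a
conformation correspondence across folds: each fold's conformations are
matched to a reference model (fit on all ligands with the modal fold
hyperparameters) by nearest conformation-medoid under the combined
distance. Collisions are averaged; a reference conformation matched by
no fold is NaN in the summary.

## Efficacy response functions

For a structural feature x, the per-conformation density `p_c(x)` is a
normalized histogram (60 bins per domain by default) evaluated on a
1000-point midpoint grid. Torsional samples are triplicated at x ± 2π
before binning so the estimate is continuous across the periodic seam,
then renormalized so the rectangle-rule integral over [−π, π) is exactly
one. Non-periodic domains default to [min − 0.5 Å, max + 0.5 Å] of the
observed samples.

The ERF of a pathway is `r(x) = Σ_c β̄_c p_c(x)` with `β̄` the
across-CV-model mean slopes. ERFs can be negative and are not
normalized. Two sign-gated combinations rank features:

    a(x) = sign(r_G)·min(|r_G|, |r_β|)  where sign(r_G) = sign(r_β), else 0
    s(x) = sign(r_G)·min(|r_G|, |r_β|)  where sign(r_G) = −sign(r_β), else 0

`a` (general activation) is nonzero exactly where both pathways agree in
sign; `s` (selective activation) where they oppose, positive marking
G-protein-favoring and negative β-arrestin-favoring feature values. This
sign-gated minimum-magnitude form was chosen because it satisfies those
gating properties and is bounded by both ERFs; it is isolated behind
`general_activation`/`selective_activation` and configurable. Scores are
rectangle-rule integrals over the 1000-point grid (spacing × sum), exact
for constants; ranking is a stable descending sort by absolute score
with top-percentile truncation.

## Synthetic data

The generator emulates what the analysis assumes: each ligand's ensemble
is an i.i.d. mixture over a small set of true conformations — centers in
feature space plus wrapped-normal torsion noise and reflected-normal
distance noise — and efficacies are the planted linear model over the
*realized* fractions plus Gaussian observation noise, optionally with
replicate records to exercise the median-of-assays target. It does not
emulate time correlation, anharmonic within-state distributions, or
force-field physics, so passing tests demonstrate correctness of the
estimation machinery, not fidelity to real trajectories.

Presets (sizes chosen as desk-scale study conditions):

* `separable_small` — 3 conformations, 6 ligands × 200 frames, feature
  widths 8/6/6, noise 0.10 rad / 0.20 Å, noise-free efficacies. Centers
  are redrawn until the minimum between-center combined distance exceeds
  4× the within-conformation noise scale, so recovery is unambiguous.
* `noisy_medium` — 4 conformations, 8 ligands × 150 frames, wider noise,
  5% efficacy noise in triplicate.
* `paper_shaped` — 11 ligands (3 pooled replicate runs of 50 frames
  each), 14 conformations, 2 pathways, 5% efficacy noise in triplicate,
  feature widths 40/30/30. Occupancies mirror the study system
  qualitatively: most conformations shared between ligands, some ligands
  dominated by a single conformation, others spread.
* `grid_identifiability_dataset` — a dedicated construction where the
  true 4-conformation structure lives only in the Cα block and the
  torsion/H-bond blocks carry independent decoy partitions, sized (from
  the complete-linkage separation bounds in its docstring) so exactly
  one weight pattern separates; used to verify the grid search end to
  end.

The toy-structure builder assembles small peptide chains from ideal
internal coordinates with every requested ψ/ϕ/χ torsion set exactly,
giving closed-form ground truth for the featurizer without any external
structure file. It supports the 14 residue types listed in
`pocketsig.toys.SUPPORTED_RESIDUES`.

## Numerical choices

* Torsions are radians everywhere; wrapping is to [−π, π).
* All tie-breaks (medoids, nearest-medoid assignment, grid search,
  cluster relabeling) resolve to the lowest index — every stage is
  deterministic given its inputs.
* Cluster labels are canonicalized by order of first appearance so
  refits and permuted inputs produce comparable labelings.
* A complete-linkage cut that cannot realize exactly `h` clusters
  (tied merge heights) raises rather than silently returning fewer.
* `superpose_rmsd` applies the fitted Kabsch rotation and measures the
  residual directly, avoiding the cancellation error of the
  sum-of-squares shortcut (~1e-7) and keeping rigid-copy RMSD below 1e-8.
* PDB coordinates are promoted to float64 on read; the format's three
  decimal places bound round-trip feature agreement at about 5e-3.
* Sequence separation ≥ 2 is enforced between Cα pair members ("at least
  one residue in between"); for the 22 default anchors it excludes no
  pair (231 pairs).
* H-bond pairs exclude donor and acceptor within the same residue; the
  polar-atom convention (backbone N donor except proline, backbone O
  acceptor, standard polar side-chain N/O) may differ in pair count from
  other donor/acceptor definitions — the list is data, not hard-coded
  behavior, and any spec can be supplied.

## Problem sizes

Default test and acceptance runs use the preset sizes above: the
separable preset (1 200 frames) for recovery checks, ten noise seeds for
the noisy-LOO error, the 135-point grid for identifiability, and the
full 11 × 150-frame run for the end-to-end smoke test. These sizes were
chosen so each property is measured at unambiguous resolution.

## Known limitations

* The held-out accuracy achievable on `paper_shaped` is limited by the
  min-norm regression: a held-out ligand occupying conformations barely
  visited in training is predicted toward zero. This mirrors the real
  small-n/large-c regime of the problem rather than a software defect.
* Conformation indices are arbitrary (first-appearance order); ordering
  by decreasing average slope, where wanted, is a relabeling the caller
  applies to the slope summary.
* The spectral stage relies on scikit-learn's eigensolver; a fixed
  `random_state` makes it reproducible, and the QR assignment itself has
  no randomness.
* No trajectory-format readers beyond multi-model PDB are bundled;
  precomputed feature tables are the general interchange format.
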