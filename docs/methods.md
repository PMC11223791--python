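# Methods

`ppiddg` predicts the change in binding free energy (ΔΔG, kcal/mol) of a
protein–protein complex upon one or more point mutations. Sign convention
throughout: **ΔΔG > 0 means enhanced binding**, ΔΔG ≤ 0 reduced binding.
This note records the model, the conventions and numerical choices behind
each stage, what the synthetic data generator does and does not emulate,
and the known limitations.

## Model

For every variant the package builds a *pair* of inputs: the forward
direction (wild-type structure, WT→Mut substitution) and the hypothetical
reverse direction (mutant structure, Mut→WT substitution). A single
weight-shared sub-network *g* scores each direction:

    f = g(forward inputs),   r = g(reverse inputs)

and the reported prediction is `(f − r) / 2`. Training minimizes the
anti-symmetric loss per forward/reverse pair

    loss = log cosh((f − r)/2 − y) + |f + r|

where `y` is the experimental forward ΔΔG. The loss is zero exactly when
`f = y` and `r = −y`; the second term penalizes violations of the
thermodynamic identity ΔΔG(Mut→WT) = −ΔΔG(WT→Mut). Because the two
directions share every weight, swapping the direction inputs exchanges `f`
and `r`, so the reported value negates *exactly* under direction swap — an
architectural guarantee, not a learned property. log cosh is evaluated in
the stable form `|x| + log1p(e^(−2|x|)) − log 2`, exact to machine
precision and overflow-free for large `|x|`.

The reported combination `(f − r)/2` mirrors the first loss term; serving
`f` alone would discard the reverse direction's information and break exact
anti-symmetry of the served number.

### Sub-network branches

Each direction's sub-network combines three switchable branches; their
outputs are concatenated and passed through a dense head ending in a single
linear unit.

* **Graph branch.** The interface graph (below) is processed by a
  graph-convolutional network: each layer computes
  `H ← relu(Â H W + b)` with `Â = D^(−1/2) (A + I) D^(−1/2)`, where `A`
  sums the per-edge interaction-type counts (configurable to unweighted).
  Node states are mean-pooled and projected. Defaults: two layers of
  width 64, output 32. An empty interface yields a zero vector.
* **Signature branch.** The cutoff-scanning signature (below) is reshaped
  to (n_cutoffs × 36), passed through a same-padded 1-D convolution along
  the cutoff axis (kernel 3, 32 channels), then one transformer-encoder
  block (4 heads, pre-layer-norm, feed-forward width 64, residual
  connections), and mean-pooled over cutoffs. Both the convolution and the
  transformer can be switched off independently.
* **Dense branch.** The tabular feature vector through two relu layers of
  width 128, projected to 32.

Training uses Adam (lr 3e-3), batch size 32, 100 epochs by default, with a
seeded generator driving initialization (Glorot uniform) and data order, so
a config seed fully determines the trained model. The network runs on a
small in-repo reverse-mode autodiff core over numpy arrays (verified
against central finite differences in the test suite); only model
parameters carry gradients, data enters the graph as constants.

The epoch and width defaults were chosen as the smallest settings at which
training on the synthetic reference task converges stably (training-loss
plateau, anti-symmetry residual |mean(f+r)| of a few hundredths of a
kcal/mol); they are package choices, not tuned per dataset. The residual
bias fluctuates with the random seed at roughly the ±0.1 kcal/mol level on
this task size — exact anti-symmetry holds for the *served* `(f − r)/2`
under direction swap regardless, but `f + r` itself is only driven toward
zero by the loss, not constrained to it.

## Features

### Interface graph

Interface residues are those with ≥1 heavy atom within **5.0 Å
(inclusive)** of any atom of a *different* chain; for complexes with more
than two chains the interface is computed complex-wide. Nodes carry a
per-residue embedding vector from a pluggable provider:

* a file provider for precomputed protein-language-model embeddings
  (1024-dimensional per-residue vectors are the intended payload), or
* a deterministic stub that maps residue *type* to a pseudorandom
  unit-norm vector (pure function of residue letter and seed) — used for
  testing and synthetic work, where no language model is available.

Edges join cross-chain residue pairs having at least one detected contact;
the edge feature is the 10-slot count vector of interaction types
aggregated over atom pairs, plus the minimum atomic distance. Intra-chain
contacts never form edges.

### Contact typing

Ten interaction types are distinguished: van der Waals, aromatic,
hydrophobic, carbonyl–carbonyl, polar, ring, covalent, hydrogen bond,
halogen bond, metal complex. The built-in detector types every heavy-atom
pair within a 5.0 Å capture radius using geometric rules over a bundled
pharmacophore table (`data/pharmacophores.tsv`, one row per residue/atom
name) and element radius tables (`data/contact_rules.yaml`):

| type | rule (Å, inclusive unless noted) |
|---|---|
| covalent | d < r_cov(a)+r_cov(b)+0.2 (strict) |
| van der Waals | d ≤ r_vdw(a)+r_vdw(b)+0.5 |
| hydrogen bond | donor-class with acceptor-class, d ≤ 3.5 |
| hydrophobic | two hydrophobic-class carbons, d ≤ 4.5 |
| aromatic, ring | both atoms in aromatic ring systems, d ≤ 5.0 |
| polar | both atoms donor/acceptor/charged, d ≤ 4.0 |
| halogen bond | halogen with acceptor-class, d ≤ 4.0 |
| metal complex | metal HETATM with N/O/S, d ≤ 3.0 |
| carbonyl–carbonyl | two backbone carbonyl carbons, d ≤ 3.6 |

These thresholds are this package's choices (conventional values); a
full-featured external contact annotator can be substituted through the
importer (`import_contacts`), whose output is interchangeable downstream.
Ring membership comes from the pharmacophore table (His/Phe/Tyr/Trp
aromatic atoms), not geometric perception; hydrogen-bond geometry is
distance-only (no angle term); waters are excluded.

### Cutoff-scanning signatures

Around each mutation site, every unordered pair of heavy atoms in the
environment (atoms within the largest cutoff of any atom of the site
residue) contributes counts to its pharmacophore class pair at every cutoff
≥ the pair distance. Eight classes (hydrophobic, positive, negative,
H-acceptor, H-donor, aromatic, sulphur, neutral; multi-membership allowed)
give 36 unordered class pairs; the default schedule 2–10 Å in 2 Å steps
gives a 180-long cumulative count vector. Counts are cumulative rather
than per-shell and boundaries inclusive; the schedule is configurable. For
multi-mutation variants, per-site signatures are summed elementwise,
consistent with the additive prediction design.

### Network metrics

On the (unweighted, simple) interface graph: mean/max degree, mean
PageRank (damping 0.85, tolerance 1e-10), mean closeness, mean
eccentricity, mean clustering, diameter, radius, mean Kleinberg authority,
adjacency spectral energy (Σ|eigenvalues|), degree entropy, and counts of
articulation points ("central points") and degree-1 nodes ("end points").
Conventions for quantities whose upstream definition is open:

* *authority* is the L2-normalized, non-negative projection of the uniform
  vector onto the principal eigenspace of AᵀA — the HITS fixed point from
  a uniform start, well defined even for bipartite graphs where the
  principal eigenvector alone is not unique;
* *degree entropy* is the Shannon entropy (natural log) of the empirical
  distribution of degree values, hence 0 for regular graphs;
* path metrics are computed per connected component with unreachable pairs
  excluded; graph diameter/radius are the max/min over components;
  closeness uses the unscaled per-component form.

The wild-type→mutant difference of every scalar (including Δauthority) is
a tabular feature.

### Tabular features

Per direction: BLOSUM62 and PAM250 substitution scores (symmetric, from
Biopython's matrices); deltas of six physicochemical properties
(Kyte–Doolittle hydrophobicity, residue volume, formal charge, Grantham
polarity, residue mass, isoelectric point) from a curated table; relative
solvent accessibility, residue depth and secondary structure of the
site residue(s) in the direction's starting structure; the 20 contact-delta
counts (10 types × intra/cross-chain); the 13 network-metric deltas; and
optional imported columns (PSSM scores per position, an external
force-field ΔΔG per mutation) which are NaN sentinels when missing and
omitted from the schema when the source table is absent entirely.

Solvent accessibility is Shrake–Rupley with 92 golden-spiral sphere points
and a 1.4 Å probe over heavy atoms, normalized by theoretical maximum
per-residue areas. Residue depth is the mean distance of the residue's
atoms to the nearest solvent-exposed atom (atom SASA > 0). Secondary
structure is assigned from backbone φ/ψ windows (helix: φ∈[−145,−35],
ψ∈[−70,50]; strand: φ∈[−180,−40], ψ∈[90,180]∪[−180,−170]; else coil;
chain termini default to coil). These are deliberately self-contained
approximations of the usual DSSP/MSMS toolchain.

All tabular and signature columns are z-scored with statistics fitted on
training rows only (both directions pooled); constant columns pass through
unscaled with a warning.

## Structures and mutant models

PDB ATOM/HETATM records are read with author numbering and insertion codes
preserved; altloc conformers resolve to highest occupancy (ties: first in
file); hydrogens are ignored downstream; waters and hetero records stay
out of the residue index (metals still participate in contact typing).

Mutant structures: a user-supplied mutant PDB always takes precedence.
Otherwise a **naive mutant** is built: the residue is renamed, backbone
(N, CA, C, O) kept, CB kept when both residue types have one, remaining
side-chain atoms dropped, nothing else touched. This is an explicit
approximation standing in for template-based mutant modelling with
side-chain optimization; it under-represents gained interactions (a larger
mutant side chain has no modelled atoms) and captures losses better than
gains.

## Datasets, augmentation, cross-validation

Mutation tables use a documented SKEMPI-style dialect (`pdb, partner1,
partner2, mutations, ddg[, binding_site]`), with chain-aware mutation
grammar (`L45G` with a chain; `I D46A; I R48K` for multi-mutations).
Multi-mutation rows stay single records with several specs and are excluded
from single-mutation training by a filter. Reverse augmentation adds one
record per forward record with swapped identities and `y` negated exactly;
reverse records reuse the naive mutant as their starting structure.

Grouped cross-validation prevents leakage at the complex level
(leave-one-complex-out) or the binding-site-type level
(leave-one-binding-site-out); reverse records always co-fold with their
forward partner; folds are ordered by sorted group key, so splits are
deterministic.

## Synthetic data generator

`generate_synthetic_complex` builds two idealized parallel chains (N, CA,
C, O, CB and one gamma-level atom per residue, ~3.8 Å CA spacing, small
seeded jitter) with a configurable number of residue pairs inside the 5 Å
interface band; facing side chains meet at van-der-Waals range, never
covalent. `generate_synthetic_dataset` samples single mutations uniformly
over interface residues and target amino acids and labels them with a
declared linear ground truth over property deltas and contact-delta counts
(default coefficients: hydrophobicity 0.25, volume 0.012, charge 0.9,
cross-chain H-bond delta 0.35, cross-chain hydrophobic delta 0.15) plus
Gaussian noise (default sd 0.3 kcal/mol), giving labels with a realistic
spread of roughly ±2 kcal/mol and an exactly known signal for
parameter-recovery tests.

What the generator does **not** emulate: real side-chain geometry and
rotamers, residue-environment correlations, epistasis between mutations,
label noise heteroscedasticity, and the strong destabilizing skew of
curated experimental datasets. Passing the recovery tests therefore shows
that the pipeline and optimizer recover a known signal under the declared
conditions — not that the model attains any particular accuracy on real
complexes.

## Evaluation

Seven statistics: R² (1 − SS_res/SS_tot, may be negative), Pearson,
Spearman (average ranks), Kendall τ-b (tie-corrected), RMSE, MAE, and mean
signed error oriented as *prediction − truth*. Anti-symmetry diagnostics
report mean(f + r) over pairs and direction-stratified sub-reports split at
y ≤ 0 / y > 0. Permutation importance shuffles one feature column across
records (same permutation in both directions) and reports the Pearson
change. The ablation harness retrains with each branch disabled in turn
under identical seed and split.

## Problem sizes

The bundled reference task (tests and `scripts/acceptance.py`) uses 500
synthetic records over ~8 two-chain complexes of 10 residues per chain
(400 train / 100 test), 16-dimensional stub embeddings, and the default
model. These sizes were chosen as the smallest at which the recovery
statistics stabilize; everything scales to larger inputs through the same
interfaces.

## Known limitations

* The naive mutant builder models no gained side-chain atoms; contact
  deltas for size-increasing substitutions are asymmetric in quality.
* Contact typing is distance-only; no angular hydrogen-bond or π-stacking
  geometry, no water-mediated contacts, no small-molecule typing.
* The numpy training loop is single-threaded and per-example; it is sized
  for datasets of 10²–10⁴ records, not for full-scale benchmark training.
* Secondary structure from φ/ψ windows disagrees with DSSP near window
  boundaries.
* Stub embeddings encode residue identity only; with them, two sites with
  the same residue type share node features and differ only through graph
  topology and the other branches.
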