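# Methods

## Overview

`sparsemeld` determines protein folds from sparse, ambiguous, noisy NOESY
peak lists by sampling structure and data interpretation jointly. The
posterior `p(x|D) ∝ p(D|x)·p(x)` is sampled by Hamiltonian+temperature
replica-exchange Monte Carlo over a Cα-bead chain. The package covers the
full workflow: peak-list I/O, dataset curation, the restraint likelihood,
the sampler, ensemble analysis, and a synthetic-data generator that
serves as ground truth for every statistical claim the test suite makes.

## The likelihood p(D|x)

Every peak becomes a *restraint group*: one flat-bottom distance
restraint per candidate interpretation,

```
E(r) = ½·(k/100)·Δ²                    Δ ≤ Δ₀
     = ½·(k/100)·Δ₀² + (k/100)·Δ₀·(Δ−Δ₀)   Δ > Δ₀
Δ    = max(0, r − d_high, d_low − r)   [Å]
```

with `k` in kJ·mol⁻¹·nm⁻² (hence the factor 100 = Å²/nm²) and a linear
continuation beyond `Δ₀ = linear_onset` (default 2 Å) that bounds forces
on badly violated start states without affecting the quadratic regime.
The printed anchors — 0.435 / 1.75 / 3.5 kJ/mol at a 1 Å violation for
k = 87 / 350 / 700 — pin the functional form and the unit conventions.

Evaluating a conformation: each group is represented by its
minimum-energy member (ties to the lowest member index), groups are
ranked (ties by peak id), and the lowest `ceil(accuracy·N)` groups are
enforced. `ceil` rather than `floor` so any positive trust enforces at
least one peak. The selection is re-derived from the instantaneous
structure at every energy evaluation; during replica exchange a
configuration evaluated under another replica's force scalar gets that
replica's own selection — selection is part of the Hamiltonian, not of
the walker. Because selection is invariant under uniform scaling of all
force constants, the likelihood at force scalar α equals α times the
unscaled likelihood; the compiled kernels exploit this.

Torsion predictions (TALOS-like phi/psi tables) are mapped onto the Cα
chain as flat-bottom wells on the pseudo-dihedral of beads
(i−1, i, i+1, i+2): predictions classified as helical (phi ≈ −63°,
psi ≈ −42°) become wells at +50°, extended ones at 180°; unclassifiable
predictions contribute nothing. The same trust-fraction selection applies
(default 0.8). This mapping is the desk-scale stand-in for all-atom
dihedral restraints; its default force constant is 20 kJ·mol⁻¹·rad⁻².

Restraints written on heavy atoms or hydrogens are evaluated between Cα
beads with the upper bound padded by `ca_projection_pad` (default 3 Å)
to absorb side-chain extent; interpretations already on CA atoms get no
pad.

## The prior p(x)

A deliberately minimal Cα physics model; every term is a penalty well so
the prior energy is ≥ 0 and an ideal chain scores 0:

| term | form | default |
|---|---|---|
| virtual bond | harmonic at 3.8 Å | k = 100 kJ·mol⁻¹·Å⁻² |
| bond angle | flat bottom [85°, 180°] | k = 60 kJ·mol⁻¹·rad⁻² |
| excluded volume | soft sphere, pairs \|i−j\| ≥ 2 | radius 4 Å, k = 20 kJ·mol⁻¹·Å⁻² |
| chirality | ½·k·max(0, −sin θ)² per pseudo-dihedral θ | k = 3 kJ·mol⁻¹ |
| SS bias | optional flat-bottom wells on θ | from predictions |

Two terms deserve justification. *Chirality*: distance data cannot
distinguish a fold from its mirror image, while real Cα traces are
right-handed locally (L-amino acids); the sine-based penalty is zero for
θ ∈ [0°, 180°] and at ±180°, so helices are chirally selected while
strands are untouched. *Angle stiffness*: native Cα pseudo-angles occupy
roughly 85–150°; a much wider or softer well lets a restrained ensemble
shear globally by ~3 Å RMSD while keeping every upper bound satisfied,
because upper-bound-only data leaves soft collective modes that only
local geometry can stiffen. The full-scale analogue of this stiffness is
the all-atom force field.

The secondary-structure wells stand in for predicted secondary structure,
which the full protocol always enforces alongside the NOE data (torsion
predictions trusted at 80%, SS predictions at 60%). At Cα resolution the
distance data alone is thermodynamically underdetermined: diagnostics
with zero-temperature Monte Carlo from the native showed the
all-bounds-satisfied set is several Å wide without local structure
information, with it the posterior basin tightens to ~1.5–2.5 Å.

## The replica ladder

`build_ladder(n, t_min, t_max, plateau, q)`:

```
T(i) = t_min · (t_max/t_min)^(min(i, plateau)/plateau)
α(i) = 1                                   i ≤ plateau
     = (1 − (i − plateau)/(n − 1 − plateau))^q   otherwise
```

The full-scale protocol grid is 30 replicas, plateau 12, temperature
ranges {300, 350, 400}–550 K crossed with k ∈ {87, 350, 700}; the
preferred protocol is 400–550 K with k = 350. The ramp exponent `q` is
exposed (default 2) since only "nonlinear" scaling is prescribed.

The desk protocol (`protocols.desk_ladder`) uses 6 replicas, geometric
120→400 with plateau at n/2 and a linear α ramp. These are *model
temperatures* for the CG prior's energy scale, not physical Kelvin: the
prior is far softer than an all-atom force field, so its useful
temperature window sits lower. They were fixed from exchange-acceptance
and equilibration diagnostics on the synthetic hairpin before the
recovery benchmarks were run.

## Monte Carlo moves

A sweep is `2n` attempted Metropolis moves for an `n`-bead chain —
roughly one local and one collective attempt per bead. The symmetric move
mixture is: single-bead displacement (35%, Gaussian σ = 0.35 Å),
single-bead crankshaft (30%, ≤ 60°), internal-segment rotation about the
chord between two random beads (20%, ≤ 30° — the workhorse for compact
states, since both hinge bonds are preserved), and head/tail pivot (15%,
≤ 25°). Amplitudes were set once for ~20–40% acceptance across the
ladder. Exchange attempts alternate even/odd neighbour pairs every 5
sweeps (desk protocol) with the standard two-Hamiltonian acceptance rule.

The hot loop is compiled with numba (`_kernels.py`); the numpy reference
implementations remain the canonical semantics and the test suite asserts
bit-level agreement between the two paths. Runs are reproducible
bit-for-bit given the seed.

## Curation

The dataset family mirrors standard practice: the *4-residue* dataset
drops every peak with **any** interpretation between residues closer than
4 in sequence (short-range contacts are nearly always satisfiable, so
they soak up the trust budget and import noise); the *1-residue* dataset
drops only intra-residue interpretations; the *true* datasets keep only
interpretations satisfied in a reference structure; the *clustered*
dataset reduces true contacts to k representatives by k-means on sorted
residue-index pairs (10 restarts, medoid-style representative = member
nearest the cluster mean, so outputs are real contacts).

One desk-scale deviation: on a 20-residue target the 4-residue filter
removes the helical i,i+3 / i,i+4 contacts that carry most of the
information, leaving too little data to fold at all — the filter's
purpose (drop trivially satisfiable contacts) is served at this size by
`min_separation = 2`, which the desk pipeline uses for ambiguous data.
Both datasets remain first-class and tested.

Pseudoatom mapping collapses side-chain hydrogens onto their bonded heavy
atom with a +1 Å pad (absorbing methyl-hydrogen degeneracy); backbone
amide H maps to N and Hα to CA with no pad, since no degeneracy is
removed there. Carbon-bound hydrogens map by name (HD11 → CD1); polar
side-chain hydrogens need the sequence for residue-typed lookup (Lys
HZ → NZ, Ser HG → OG, …) and are otherwise left unchanged with a warning.

## Synthetic data

The generator emulates the statistical structure of expert-prepared
sparse-label datasets, with full ground-truth bookkeeping:

* **Topologies** — `helix_hairpin` (two ideal Cα helices, internal-
  coordinate construction, joined by a 3-residue turn), `two_domain`
  and `random_compact` (simulated-annealing collapse under the prior
  plus a radius-of-gyration squeeze).
* **Sparsity** — a seeded subset of residues is observable
  (`label_fraction`, default 0.85: amides make nearly every residue a
  probe in perdeuterated samples).
* **Peaks** — every labelled pair within `contact_cutoff` (default 8 Å
  at Cα, the proxy for the ~6 Å H–H criterion) yields a peak. The upper
  bound is intensity-calibrated: true distance × (1 + `calibration_slack`,
  default 0.1) rounded up to 0.1 Å, as synthetic NOE tables derived from
  a reference structure typically are. Spurious peaks get a plausible
  but wrong bound drawn uniformly.
* **Ambiguity** — each labelled residue draws a pseudo-shift cluster;
  a peak's interpretation list is every labelled pair whose shift pair
  matches its own. The cluster count is set so the mean list length ≈
  `ambiguity_target` (realized mean within 10% over seeds).
* **Noise** — with probability `p_missing` a peak loses its correct
  interpretation (and any other natively satisfied member, so truth
  bookkeeping stays exact); spurious peaks (fraction `p_spurious` of the
  final list) are seeded on far pairs and their ambiguity lists filtered
  to natively unsatisfied pairs, keeping them mechanistically realistic
  yet exactly identifiable by the reference filter.

What the generator does **not** emulate: real chemical-shift prediction,
peak intensities and overlap, spin diffusion, or the error modes of an
actual SS/torsion predictor (the generated predictions are error-free,
which makes the recovery benchmarks optimistic in that one respect).
Passing tests therefore demonstrate the machinery — joint selection +
H,T-REMD + clustering recovering a planted fold from degraded data — not
performance on experimental spectra.

## Analysis

RMSD is Kabsch (SVD with proper-rotation correction, explicit residual).
Clustering pools the second half of the lowest replicas (defaults: 5 at
full scale, 2 in the 6-replica desk protocol), builds the pairwise
superposed-RMSD matrix, applies average-linkage agglomerative clustering
and cuts the dendrogram at 1.5 Å (assigned data) or 2.0 Å (ambiguous
data). Cluster representatives are medoids, never coordinate averages.
`top1`/`top5` are the medoids of the most populated clusters. The
funneling diagnostic reports per-replica RMSD distributions and flags a
run funneled when medians are non-increasing down the ladder and the
bottom median is below 4 Å. Violation reports re-run the selection on a
fixed structure along an accuracy grid; the lowest-restraint-energy frame
provides a reference-free alternative to cluster population for picking
predictions.

## Problem sizes used in the benchmarks

The statistical benchmarks run a 20-residue helix-hairpin with 6 replicas
× 2000 sweeps × 5 seeds per condition (clean, ambiguous+spurious,
unrestrained control) — sizes chosen so the full battery completes in a
few minutes on one CPU while leaving clear margins on the tested
properties (clean top1 ≈ 1.5–2 Å; restrained vs unrestrained bottom
medians ≈ 2 Å vs ≈ 7 Å).

## Known limitations

* Cα resolution: no side-chain packing, no explicit hydrogens; distance
  bounds are projected with a fixed pad.
* The Monte Carlo sampler is not a dynamics engine; kinetic quantities
  are meaningless, only ensemble statistics are used.
* Desk-scale temperatures/force constants are calibrated to the CG
  prior's energy scale; the full-scale protocol grid is exposed but has
  no all-atom backend here.
* Normalisation `p(D)` is never computed; all sampling is from the
  unnormalised posterior.
* The external whitespace peak-list dialect is a best-effort adapter;
  archive-scale dataset reproduction is out of scope.
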