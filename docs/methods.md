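# Methods

## Model and procedure

The package evaluates disease phenotype networks (DPNs) by how well they
drive propagation-based gene prioritization. The pipeline has four stages.

**1. Alignment.** When two DPNs are compared or blended, both are first
restricted to their common disease identifiers (sorted order), since every
downstream operation assumes identical indexing. Identifiers are opaque
strings; nothing assumes 6-digit OMIM numbers, so Orphanet/DECIPHER-style
identifiers pass through unchanged.

**2. Normalization and calibration.** Asymmetric similarity exports
(`Sim(A→B) ≠ Sim(B→A)`) can either be kept asymmetric — per-disease scores
are then read along the row (`Form.ROW`) or column (`Form.COL`) — or
symmetrized by arithmetic mean. Four normalizations map raw scores into
[0, 1]: Lin and Sqrt rescale by self-similarities, Maxmin by the global
extremes (taken over the whole matrix, diagonal included), Tanimoto by
`S(A,A)+S(B,B)−S(A,B)`. Normalization is computed once on the stored
matrix; the row/column distinction is purely a read direction at prior
construction, never a second normalization. The logistic calibration
`L(x) = 1/(1+e^{cx+d})`, `d = ln 9999`, is applied last; when two networks
are blended, blending precedes calibration so that a single `c` is fitted
to the combined network.

**3. Validation.** Each disease–gene association is held out in turn; the
remaining genes of that disease are seeds (none for a monogenic disease),
candidates are all PPI genes minus the seeds, and the held-out gene's rank
among the candidates is recorded. The prior assigns 1 to seeds and, to any
other gene, the calibrated similarity between the query and the most
similar disease that gene is associated with (maximum, not sum — this keeps
the prior within [0, 1] and matches the most-similar-disease reading of
propagation priors). Propagation uses the symmetric degree normalization
`D^{-1/2} A D^{-1/2}`, which bounds the spectral radius by 1 and guarantees
contraction for α < 1.

**4. Reporting.** MRR (mean of `100·rank/n_candidates`), count of rank-1
targets, TPR@{5,10,30}, per-C tables for the sweep, a 2×2 concordance table
between two networks' rank-1 sets, and the relative network mean (average
per-disease row-sum ratio against a reference network — a scale diagnostic
that tracks how aggressive a calibration the network needs).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.9 | weight of network smoothing vs. prior; results are insensitive above ~0.5 |
| `tol` | 1e-9 | L1 threshold on successive propagation iterates |
| `max_iter` | 100 | iteration cap; reached before `tol` at α = 0.9 (see below) |
| `c` | swept, integers −25…−8 | logistic steepness; more negative ⇒ harsher suppression of weak similarities |
| `d` | ln 9999 (fixed) | pins `L(0) = 10⁻⁴` |
| `proportion` | — | weight of the primary network in a blend |
| seed prior | 1.0 | prior value of a known disease gene (configurable via `seed_value`) |

The default C grid (integers −25 to −8) brackets the region where the
optimum lands for [0, 1]-scaled networks of this kind; ties in the
top-ranking count resolve to the smallest |c| (least aggressive
calibration), then to the larger c, for determinism.

## Numerical choices and degenerate inputs

- **Convergence metric** is the L1 norm of successive iterates — the common
  strict reading; it is checked after each update and the `converged` flag
  reports it honestly. At α = 0.9 the iteration contracts by a factor ≤ 0.9
  per step, so pushing the L1 difference below 1e-9 needs roughly 200+
  updates; with the default 100-iteration cap the flag is therefore
  typically false while ranks are already stable (the remaining distance to
  the fixed point is ~10⁻⁵ in max-abs). The closed-form solve
  `(I − αW)F = (1−α)Y` is exposed separately and the two agree to
  tolerance-level precision when the cap is raised — the test suite and the
  acceptance script verify this with `max_iter=2000`.
- **Zero denominators** in Lin/Sqrt/Tanimoto (a disease with zero
  self-similarity, i.e. no annotated phenotype evidence) define the entry
  as 0 rather than erroring; Maxmin on a constant matrix raises a
  degenerate-input error.
- **Out-of-range values** after Lin/Sqrt/Tanimoto (cross-similarity above a
  self-similarity in noisy input) are clipped into [0, 1] with a warning.
- **Ties in ranking** use pessimistic competition rank: the target is
  placed after every competitor scoring ≥ its score, so tied ranks never
  flatter the method and runs are reproducible.
- **Pairwise-score files** may omit pairs and the diagonal; absent entries
  default to 0 (absent evidence). An absent diagonal then triggers the
  zero-denominator rule for the self-similarity-based normalizations, so
  such files should either include diagonals or use Maxmin. Dense files
  declared symmetric are rejected above an asymmetry of 1e-9 and
  sub-tolerance residuals are averaged away; no assumption is made that a
  dense file's diagonal equals 1.
- Duplicate PPI edges collapse to the maximum weight; unweighted edges get
  weight 1; self-loops are dropped.

## The synthetic generator

`SynthConfig` plants the regularity the method exploits: genes associated
with phenotypically similar diseases encode PPI-proximal proteins. A
preferential-attachment graph (500 genes, 3 edges per new node by default)
stands in for the scale-free PPI; 10 disease modules are anchored at random
nodes and take their 15-gene pools from breadth-first neighborhoods; each
of 100 diseases draws 1–3 causal genes from its module pool; pairwise
similarities are truncated normals with mean 0.6 (sd 0.1) within modules
and 0.1 (sd 0.05) between, clipped to [0, 1]. The diagonal is set to each
row's off-diagonal maximum so self-similarity dominates and Lin/Sqrt/
Tanimoto stay in [0, 1] without clipping. Optional additive noise
(`asym_noise`) breaks symmetry to emulate asymmetric exports.
`permute_labels` relabels the similarity matrix with a random permutation,
preserving the value distribution while destroying the disease–gene
alignment — the null for the recovery check.

What the generator does *not* emulate: the heavy-tailed, text-mining-driven
similarity distributions of real DPNs, annotation noise and
ascertainment bias in disease–gene catalogues, and the incompleteness of
real interactomes. Passing tests therefore demonstrate correctness of the
machinery and sensitivity to planted structure, not performance levels on
real data; absolute MRR/TPR values on synthetic instances are far better
than anything achievable on real catalogues.

## Design choices made where the design was open

- Seed genes receive prior 1 rather than their calibrated self-similarity:
  a direct association is certain evidence; configurable.
- Seeds are excluded from the candidate list in every validation run, for
  both monogenic and polygenic diseases (configurable through the
  `candidates` argument of `prioritize`).
- In the C sweep, best C maximizes the number of rank-1 targets (not MRR),
  because the top of the list is what a screening application consumes.
- The blend proportion applies to the primary (normalized) network; the
  reference network gets `1 − p`.
- Problem sizes in the test suite and acceptance script (50–500-gene
  graphs, 20–100 diseases, 10 generator seeds) were chosen as the smallest
  instances at which the planted-structure effect is decisively measurable.

## Known limitations

- Only one propagation variant (PRINCE-style label propagation) is
  implemented; no random-walk-with-restart comparison.
- No statistical significance testing between networks is provided — the
  concordance table is descriptive.
- The iterative solver's default cap (100) mirrors common practice but
  stops short of the L1 tolerance at α = 0.9; use
  `closed_form_propagate` or a higher `max_iter` when exact fixed points
  matter.
- Multi-PPI integration and construction of phenotype networks from raw
  annotations (MeSH/HPO text mining) are out of scope; DPNs are consumed
  as precomputed inputs.
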