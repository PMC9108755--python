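# Methods

This note documents the models, parameters and numerical choices behind
`psnvaria`, and what its synthetic benchmark does and does not show.

## Structure model

A conformer is a single protein chain read from PDB format: first model,
one chain (explicit, or inferred when unambiguous), standard amino acids
only, heavy atoms only. Selenomethionine is read as methionine; all
other modified residues, waters and HETATM groups (cofactors, ligands)
are excluded. When alternate locations are present, the altloc with the
highest summed occupancy within the residue is kept (first encountered
on a tie) together with all blank-altloc atoms. Output uses author
residue numbering; internal computation uses 0-based chain positions.

Conformers of one protein are required to be sequence-identical
(mutation- and gap-free); residue correspondence is therefore positional
and no structural aligner is involved. Backbone divergence is the
classic Kabsch superposition RMSD over all matched Cα atoms (SVD with a
determinant correction so reflections are never introduced). Published
RMSDs computed with aligners that trim to an aligned core can differ
slightly from this all-residue value.

## Network construction

Edge weights follow the normalized proximal-atom-count definition: all
heavy-atom pairs of residues at sequence separation ≥ 2 within a 4.5 Å
cutoff (inclusive — "within" is read as ≤) are counted, and the count is
divided by the largest count observed for that unordered amino-acid-type
pair over the input ensemble. Dividing by per-type maxima makes an edge
weight the *fraction of the strongest contact this residue-type pair can
make*, so weights are comparable across residue types.

Parameters (all configurable):

| parameter | default | meaning |
|---|---|---|
| cutoff | 4.5 Å | proximal-atom distance, inclusive |
| min_separation | 2 | smallest \|Δ seq index\| that may form an edge |
| normalization table | computed from input | per-type-pair maxima |

With the table computed from the input ensemble the maximum edge weight
is exactly 1 (the arg-max pair attains its own maximum). A table from a
larger corpus may be supplied; ratios above 1 are then allowed (with a
warning) rather than clipped, since clipping would hide a genuine
stronger-than-reference contact. Glycine participates through its
backbone heavy atoms; the definition counts all heavy atoms, not only
sidechain atoms.

## Spectral comparison

All spectral quantities come from the weighted graph Laplacian
L = D − W. Eigenvectors are unit-norm with a deterministic sign fix
(largest-magnitude component positive).

* **EDS** — Σ|a_ij − b_ij| / Σ max(a_ij, b_ij) over unordered pairs;
  defined as 0 when both networks are empty. Lives in [0, 1].
* **EWCS** — over the k lowest non-trivial eigenpairs (default: all),
  Σ w_m (1 − |cos θ_m|) / Σ w_m with w_m the mean of the two m-th
  eigenvalues and θ_m the angle between the m-th eigenvectors. Weighting
  by eigenvalue emphasizes modes that carry real connectivity.
* **CRS** — residues embedded by their components in the k lowest
  non-trivial eigenvectors of their own graph (default k = 5, capped at
  n − 1); a minimum-cost one-to-one assignment (Hungarian algorithm,
  Euclidean cost) between the two embeddings; CRS is the fraction of
  residues assigned to themselves.
* **NDS** = sqrt(EDS² + EWCS² + (1 − CRS)²) ∈ [0, √3].

Identical inputs short-circuit to exactly (EDS, EWCS, CRS, NDS) =
(0, 0, 1, 0) rather than accumulating eigensolver round-off; the same
fast path returns RMSD 0.0 for bitwise-identical coordinate sets.

Modes are paired by sorted index. When consecutive eigenvalues are
closer than 1e-9 the pairing within the degenerate subspace is
arbitrary and a warning is emitted. More broadly, eigenvector-based
scores are ill-conditioned whenever the spectrum is nearly degenerate —
an important consideration for the synthetic benchmark (below). The
three component formulas are isolated behind `netcompare`'s scoring
functions so alternative normalizations can be swapped in without
touching callers.

The Fiedler vector (eigenvector of the second-smallest eigenvalue) is
compared between conformers after a global sign alignment (flip one
vector if the dot product is negative); residues are ranked by absolute
component difference, ties broken by chain position, top 10 reported by
default. A near-zero second eigenvalue indicates a disconnected network
and triggers a warning, since the Fiedler vector then reflects component
membership rather than clustering.

## Sub-networks

Residues are classified two ways, each splitting the PSN into three
edge-disjoint sub-networks over the **full node set** (edges filtered,
nodes kept, so spectral comparison of sub-networks stays well-posed even
when two conformers disagree about a residue's class):

* **Burial** — relative solvent accessibility below 7% ⇒ buried (B),
  otherwise exposed (E); RSA exactly at the threshold counts exposed.
  SASA is computed with an in-package Shrake–Rupley sampler
  (960 near-uniform sphere points by golden-section spiral, 1.4 Å probe,
  Chothia-type heavy-atom radii: C 1.87, N 1.65, O 1.40, S 1.85 Å) and
  normalized by theoretical Ala-X-Ala maximal areas (Tien et al. 2013).
* **Secondary structure** — helix and strand letters (H, G, I, E, B)
  map to ordered (O), everything else to non-ordered (N). Labels are
  read from STRIDE/DSSP-style files when available; otherwise a
  dihedral-window fallback assigns O to runs of ≥ 3 consecutive residues
  with φ/ψ in canonical helix (φ ∈ [−90, −30], ψ ∈ [−77, −17]) or
  strand (φ ∈ [−170, −70], ψ ∈ [90, 180] ∪ [−180, −170]) windows.

The triple partitions the parent network exactly: edge counts and weight
mass are conserved, and the full-graph EDS numerator splits additively
over the three sub-networks when the two conformers' labels agree.

## Ensemble edge-weight variance

Across N conformers each edge position (union edge set; a missing edge
contributes weight 0 — edge loss *is* variability) gets the population
variance (1/N) of its weight. Per-edge values are sorted before
accumulation, which makes the profile exactly invariant to conformer
order and pins constant edges at variance 0 despite floating-point
non-associativity.

Highly variable edges are those whose variance strictly exceeds three
standard deviations of all edge variances; in descending order the first
five are red, the next ten yellow, remaining candidates blue. Ties are
broken by residue indices. Note the threshold is relative to the spread
of the variance distribution: a profile whose variances are all equal
and nonzero has spread zero, so every edge is (tied) candidate; a
constant ensemble (all variances zero) has none.

## Variability categories

Thresholds default to the arithmetic mean and population SD of each axis
over the pooled input scatter; a config block can pin external constants
instead (including a separate NDS extremity override, because published
mean + SD values and a published extremity do not always agree — the
package does not resolve that discrepancy, it exposes both). Categories
are evaluated in order R → N → B → F, first match wins, else M:

* quadrant membership at exactly the mean counts to the high side;
* the quadrant fraction cutoff is ≥ 0.60 (configurable);
* R requires no point beyond either extremity; N caps only NDS, B caps
  only RMSD; F has no extremity cap; M absorbs everything else,
  including extremity violators of R/N/B.

The rule set is total and deterministic: every finite point set receives
exactly one category, independent of point order.

## Synthetic conformer ensembles

The generator emulates a conformer ensemble with controlled ground
truth, not any real protein. The base conformer is a torsion-built ideal
α-helix (φ = −57°, ψ = −47°, ω = 180°, ideal bond geometry) of 30
residues (default) cycling through LEU/SER/VAL/THR with 1–3
pseudo-sidechain heavy atoms from fixed templates, coordinates rounded
to PDB precision so in-memory and re-parsed structures agree exactly.
Each residue's sidechain torsion carries a fixed golden-angle offset
(i · 137.5° mod 80° − 40°): a perfectly periodic chain produces a
near-degenerate Laplacian spectrum — precisely the regime where
eigenvector pairing is arbitrary — whereas real proteins are irregular,
so the base network is made spectrally non-degenerate by construction.

Modes map one-to-one onto the variability categories:

| mode | perturbation | ground truth |
|---|---|---|
| none | identical copies | R |
| sidechain_only | per-residue rotation about Cα–Cβ by U(−m, m) rad | B |
| backbone_hinge | rigid rotation of the C-terminal half about a mid-chain axis by U(−3m°, 3m°) | N |
| combined | both | F |

with magnitude m = 1.0 by default, 10 conformers per ensemble, and a
clash guard (regenerate on any non-bonded inter-residue distance
< 1.5 Å, at most 10 attempts). Defaults were chosen once so that the
pooled four-mode benchmark (40 ensembles, 1,800 pairs) reproduces the
qualitative scatter structure of crystal-structure ensembles: backbone
motion of a few tenths of an Å, sidechain-driven network change spanning
near-zero to saturated NDS.

What passing the benchmark shows: the pipeline separates
backbone-confined from network-confined variability and recovers the
generating regime through the category flowchart with thresholds
computed from the pooled scatter. What it does not show: behaviour on
real crystallographic detail (missing atoms, alternate conformations in
dense packing, ligand-induced allostery), absolute NDS scales of large
(~150-residue) proteins — the synthetic graphs are smaller and perturbed
harder, so NDS values run higher than typical published ensemble values
— or robustness of the secondary-structure fallback outside clean
helix/strand geometry.

Known saturation: once perturbations are large enough that the
correspondence term bottoms out, NDS plateaus near its ceiling and no
longer orders magnitudes; monotonicity of mean NDS in perturbation size
holds below that regime and is tested there.

## Numerical choices

* Inclusive distance test (≤ cutoff); integer contact counts make edge
  weights exact rationals.
* Eigendecomposition via LAPACK `eigh` on the dense symmetric Laplacian;
  retained pairs satisfy ‖Lv − λv‖ < 1e-8.
* Cosines clamped to ≤ 1 before (1 − |cos|) so round-off cannot produce
  negative EWCS contributions.
* Assignment via `scipy.optimize.linear_sum_assignment`.
* Kabsch handles degenerate (collinear/planar) inputs through the SVD
  convention with determinant correction.
* All randomness flows through `numpy.random.default_rng` seeded from
  the ensemble spec; identical specs produce byte-identical PDB output.

## Limitations

* No interaction-type-specific networks (H-bond/ionic subgraphs) or
  energy-weighted edges; proximity counts only.
* No support for gapped, mutated or multi-chain inputs by design — the
  comparison is defined on identical sequences.
* The EDS/EWCS/CRS normalizations are this package's documented
  reconstructions of the component contracts (direct edge difference;
  eigenvalue-weighted global term; assignment-based local term;
  identical networks score 0); other implementations of the same idea
  may scale components differently, so absolute NDS values should be
  compared only within one implementation.
* Sub-network classes are assigned per conformer; when two conformers
  disagree on a residue's class, each conformer's sub-network honours
  its own labels.
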