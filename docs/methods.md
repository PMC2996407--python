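# Methods

`motifhash` matches small residue motifs — ordered Cα positions with allowed
residue labels — against collections of protein structures, and assigns each
match a nonparametric significance. This note describes the model, its
parameters, the numerical choices, what the synthetic benchmark does and does
not show, and the known limitations.

## The two-phase matching model

**Preprocessing.** Each target (a chain, or a merged chain group for motifs
spanning chains) is reduced to its standard amino-acid residues with Cα
coordinates, side-chain centroids, a surface-depth estimate and per-target
label counts. All residue *n*-tuples (n = 3 by default) satisfying four
geometric constraints — called *reference sets* — are enumerated and stored
in an HDF5 table keyed by the sorted tuple of their one-letter labels:

1. each Cα within `d_maxmindist` = 16 Å of its nearest other Cα in the tuple;
2. all pairwise Cα distances strictly under `d_diameter` = 25 Å;
3. every residue within `d_maxdepth` = 3.1 Å of the molecular surface;
4. at least one residue within `d_maxmindepth` = 1.6 Å of the surface.

Tuples are stored once as unordered combinations; label order is resolved at
match time, which reproduces any-order storage at n!-fold less space. The
defaults are deliberately generous: they exist to guarantee that a typical
catalytic-site motif contains at least one valid reference set, not to filter
aggressively. Constraint 2 is the only strict inequality (the others are
inclusive bounds).

**Matching.** For a motif of m ≥ n points, all n-subsets passing the two
distance constraints (motifs carry no surface, so the depth clauses do not
apply) are candidate seeds. Seeds are ranked by ascending total frequency of
their induced label keys in the table — rare keys are more function-specific
— and the `max_seed_refsets` = 15 rarest are used. Every stored reference set
under a seed's keys yields one or more label-compatible correspondences; each
is grown one motif point at a time by depth-first search. At every step the
optimal rigid superposition is re-solved; a partial match whose RMSD exceeds
ε = 7 Å is pruned. Candidate residues for the next point are those within
`candidate_radius` (= ε by default) of the aligned motif position, found with
precomputed neighbor lists; residues added during augmentation are *not*
subject to the reference-set constraints. By default only the lowest-RMSD
complete match per target is kept; multiple matches and partial matches (at
least `min_partial_size` points, ranked by `size − rmsd_weight·rmsd`,
rmsd_weight = 1/Å) are options that disable significance.

Completeness is relative to the seeds: a match none of whose compatible
triples forms a valid reference set in both motif and target is unreachable.
The small-instance oracle test makes this caveat explicit by comparing
against exhaustive injection search restricted to seed-reachable matches.

**Augmentation order.** Remaining motif points are visited in ascending
distance from the seed triple's centroid (ties by point index). The leaf set
is order-independent when no pruning occurs; geometric proximity keeps
intermediate alignments stable when it does. Input order is available as an
option.

## Superposition

The minimum-RMSD proper rigid motion is obtained from the largest eigenvalue
of the 4×4 quaternion key matrix, found as the largest root of its quartic
characteristic polynomial by Newton iteration (started at the upper bound
(G_A+G_B)/2, tolerance 1e-11, ≤ 50 iterations) rather than a full eigen
decomposition; the rotation is the corresponding eigenvector, read off the
adjugate of K − λI. An SVD (Kabsch) fallback covers non-convergence and
degenerate eigenvectors, so correctness never depends on the fast path. The
reported RMSD is the deviation actually achieved by the returned rotation:
the textbook form sqrt((G_A+G_B−2λ)/k) cancels catastrophically near zero
(double precision floors it at ~1e-7 for Å-scale inputs), while the direct
form is exact to round-off at O(k) cost. Reflections are never returned;
mirror-image point sets therefore score a strictly positive RMSD.

## Neighbor queries

Fixed-radius queries about arbitrary points (aligned motif positions) use
per-residue neighbor lists precomputed at radius 2r (r = ε, so 14 Å): if the
residue nearest the query point is x away, members of its list closer than
r − x are accepted outright and those in [r − x, r + x] are distance-checked,
which is exhaustive because everything within r of the query lies within
r + x ≤ 2r of that residue. The single nearest-neighbor search uses a uniform
grid with cell size 2r and an expanding-ring scan with the standard
(ring−1)·cell lower bound for termination; the result is exact, and is
property-tested against brute force.

## Surface depth

The reference implementation of the surface constraints in the original
method family uses a molecular-surface mesh; this package instead ships a
neighbor-count exposure test: an atom is *exposed* when fewer than 6 heavy
atoms **from other residues** lie within r_atom + 2·probe = 1.8 + 2·1.4 =
4.6 Å; a residue's depth is the distance from its atom nearest to the exposed
set (0 if it has an exposed atom itself — depth is measured from the atom
closest to the surface). Counting only other-residue atoms makes isolated
residues fully exposed for any threshold; 6 is the coordination number of a
chain-like packing at 3.8 Å spacing, so the interior of a dense Cα lattice is
correctly buried. This is a declared substitute calibrated for the sparse
synthetic traces used in testing, **not** a reconstruction of a surface mesh:
on real all-atom structures it is conservative (many atoms count as buried),
so for real data either supply precomputed mesh-derived depths via the
sidecar file (`chain seqnum icode depth` per line) or disable the depth
clauses (`check_depth = False`). Depth is rigid-motion invariant by
construction.

## Significance

For one motif against a target collection, the per-target best complete-match
RMSDs form the *motif profile*. The profile is smoothed with a Gaussian
kernel at the Sheather–Jones solve-the-equation bandwidth (implemented from
the plug-in recipe with stage-one bandwidths 1.24·λ·n^(−1/7) and
1.23·λ·n^(−1/9), λ = min(sd, IQR/1.349); validated to ~1e-4 relative against
an independent reference implementation). Fewer than two distinct samples, a
degenerate functional estimate, or a root-finding failure fall back to
Silverman's rule, flagged in the output.

Because matches above ε are never reported, targets that found no match but
contain enough residues of the right labels (*missed matches*) could have
matched at a larger cutoff. Label feasibility is decided exactly as a
bipartite flow problem (each motif point needs a distinct residue with an
allowed label), not a greedy count. Missed matches carry a point weight at
infinity with each target weighing equally, so with n_matched = M and
n_missed = C the corrected p-value of a match at RMSD r is

    p(r) = W · F(r),   W = M / (M + C),

where F is the kernel CDF renormalized to [0, ∞) (each kernel divided by its
half-line mass). This keeps p(∞) = W exactly and p monotone in r; the price
is p(0) = 0 exactly (any positive RMSD accumulates kernel mass). Targets
whose label content cannot host the motif are excluded from both M and C.
Label-infeasible targets can be included in the denominator via the profile
options if a different normalization is wanted; the default excludes them.
Partial-match and multiple-match runs have no defined profile; significance
is refused rather than approximated.

Below ε/√m the reported p-values are provably unaffected by the ε cutoff —
a complete m-point match at RMSD r bounds every point deviation by r·√m, so
competitors excluded at ε cannot displace it. For a 6-residue motif at
ε = 7 Å the bound is 7/√6 ≈ 2.9 Å.

## Parallel matching

Targets are partitioned over worker processes; each opens the table
read-only and matches independently; the parent merges per-target results.
Seed ranking always uses the *full* target set of the run, never a worker's
share, and the XML writer sorts matches by (p-value, target id,
correspondence), so output bytes are identical for any worker count. A
worker failure aborts the run with the failing batch logged.

## Synthetic benchmark

`synth` generates protein-like targets: self-avoiding random Cα walks with
consecutive spacing 3.8 ± 0.05 Å, non-consecutive separation ≥ 4 Å,
persistence plus a weak inward pull for compactness, random labels from a
configurable composition (uniform by default), and synthetic side-chain
centroids at 1.5–3 Å offsets. Planting replaces the most compact m-residue
neighborhood's Cαs with a rigidly transformed copy of the motif geometry
plus isotropic Gaussian noise (σ = 0.25 Å per coordinate by default) and
draws labels from the allowed sets. Decoys are label-shuffled walks, so many
decoys *could* match by label content — exercising both the matcher's
negative path and the missed-match point weight.

The default benchmark is 200 targets of 30–50 residues, half planted. These
sizes keep the whole suite desk-scale: a 40-residue target has ~10⁴ triples,
and the full benchmark builds and matches in about a minute on one core.
Benchmark scoring (`score_benchmark`) builds the motif profile **from the
decoy partition** and scores every target against it. This is deliberate:
the significance model assumes the profile is dominated by background — in
realistic screens the family is well under 1 % of the database — and a
profile built over a 50 %-planted fixture would put half its mass at the
planted mode, making small p-values arithmetically impossible for family
members. Scoring against the known-negative background is the standard
simulation-study analogue of that regime.

What passing the benchmark shows: the geometric machinery (hashing, seeding,
augmentation, superposition) recovers planted instances essentially always
at < 1 Å, and the corrected p-value separates a tight low-RMSD mode from
label-matched decoys at α = 0.01 with sensitivity and specificity ≥ 0.95.
What it does not show: performance on real folds (the walks have no
secondary structure, rotamers, or realistic packing), robustness to missing
residues or conformational change, or calibration of absolute p-values
against a real database background.

## Numerical and design notes

- Altloc resolution keeps the highest occupancy, ties by identifier order;
  MSE is kept as methionine, other non-standard residues are dropped; the
  first MODEL of multi-model files is used.
- Author numbering (chain, residue number, insertion code) is the external
  residue identity everywhere (motif specs, XML); internal indices never
  leak.
- Glycine's side-chain centroid is its Cα; truncated side chains fall back
  to Cα with a per-residue flag.
- Table files refuse queries under different geometric parameters unless
  explicitly overridden — profiles computed under drifted parameters would
  be silently wrong otherwise.
- Matches are deduplicated by their correspondence as a set of pairs; the
  same match reached from several seeds reports the rarest seed's key.
- Centroid RMSD of a match is computed under an optimal superposition of
  the corresponded centroids (not the Cα alignment); it is the default
  tie-breaking criterion only when explicitly selected.
- Side-chain centroid selection, partial-match scoring weights and the
  augmentation order are declared package choices where the method family
  leaves them open.

## Known limitations

- The depth approximation is tuned for sparse synthetic traces; real
  structures should use sidecar depths from a surface program.
- Completeness is seed-relative (see above); pathological motifs may need a
  larger `max_seed_refsets`.
- Partial matches near the ε boundary can be pruned even when their
  completion would satisfy ε (subset RMSD may exceed superset RMSD by up to
  √((k+1)/k)); this affects only matches within ~15 % of the cutoff.
- No mmCIF input, no hydrogens, no biological-assembly generation.
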