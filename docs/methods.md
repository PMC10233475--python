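# Methods

This note documents the models and procedures implemented in `navpd`, their
assumptions, the parameters that matter, and the design decisions taken where
the underlying workflow left choices open.

## Contact definition and EC evaluation

A residue pair is in structural contact when the **minimum pairwise atom
distance** between the two residues is **strictly below 8 Å**; heavy atoms
only by default, since homology models and most deposited structures lack
hydrogens (a flag includes them). An EC score table predicts a contact when
the score is **strictly above 0.2** ("more than" ⇒ strict inequality at both
boundaries; both cutoffs are arguments). No sequence-separation filter is
applied by default (`min_seq_sep=0`); because coupling-analysis practice
often excludes |i−j| < 5, the flag exists and every results table states the
value used.

Evaluation metrics per scope (one domain, one domain pair, or all domain
pairs pooled): CA_Str = structural contacts, CA_DCA = predicted contacts,
N_Coin = their intersection, precision = 100·N_Coin/CA_DCA (undefined and
reported as NaN with a warning when CA_DCA = 0), and N_T10 = hits among the
ten highest-scoring records. Ties at the tenth score are resolved
deterministically by (score descending, pair lexicographic), then truncated
to exactly ten. Inter-domain scopes treat domain pairs as unordered.

## Candidate selection and tetramer assembly

The selection rule "lowest energy and highest contact consistency" is
operationalised as **Pareto-front selection**: successive non-dominated
fronts of (minimise energy, maximise precision) are peeled, each front
ordered by energy ascending with ties broken by precision descending then
model id, and the first *k* (default 2) are taken. When energies dominate
this reduces to energy ranking; a pure-energy mode is provided because the
exact trade-off between the two criteria is genuinely ambiguous when they
disagree. The selection is idempotent.

Assembly superposes each selected domain model onto the corresponding
template domain with the **Kabsch algorithm over Cα atoms matched by
domain-local residue number** (a full structural-alignment search is
unnecessary because the helices are index-aligned between candidates and
template; indels would sit in the loops, which are excluded from the fit when
unmatched but kept in the output). All combinations of the per-domain
selections are enumerated (2×2×2×2 = 16 by default); assembly ids concatenate
the member tags in D1–D4 order. Assembly energies are **external inputs** —
the package does not recompute force-field scores — and ranking is by energy
ascending with a reported flag when the energy winner also maximises
inter-domain contact precision.

## Pore geometry

**Gate diameter** of a frame: the larger of the cross-pore residue-pair
distances (default pairs D1:121–D3:356 and D2:225–D4:463, configurable).
The distance rule defaults to minimum-heavy-atom (the generic residue
distance); a Cα mode exists for sensitivity checks because the atom choice
is a convention, not a law. The frame is **closed** when the diameter is
strictly below the effective hydrated-Na⁺ diameter of 7.8 Å.

**Axis estimation**: the axis passes through the centroid of the gate
residues' Cα atoms; its direction is the principal axis of the Cα covariance
whose eigenvalue is most separated from the other two. For a (pseudo-)C4
bundle the two transverse eigenvalues are nearly degenerate while the
symmetry axis stands apart, so this choice is rotation-equivariant — unlike
"the eigenvector closest to z", which would silently depend on how the
structure happens to be oriented. The sign convention makes the
largest-magnitude component positive.

**Radius profile**: at each position along the axis (default step 0.5 Å),
the pore radius is the largest clearance of a sphere centred in the
perpendicular plane against the van der Waals surfaces of atoms within
±3 Å of the plane. The centre is optimised by a deterministic multi-start
coordinate descent (axis point plus eight 1 Å ring offsets; step halved from
1 Å down to 0.05 Å), negative clearances clamp to zero, and an empty slab
reports an upper-bound sentinel (default 15 Å) with a warning. The vdW table
is fixed (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, default 1.70 Å)
and recorded here because the choice is otherwise invisible in the output.
This is a straight-channel simplification of full channel-tracing tools:
it assumes the pore is reasonably aligned with the estimated axis and does
not follow curved centerlines.

## Trajectory metrics

RMSD series are mass-unweighted over an atom selection (default Cα), either
fitted (optimal superposition per frame before the RMSD — hence never larger
than the raw value) or "nofit" (raw coordinates, sensitive to drift). RMSF
uses an **iterated mean reference** (frames aligned to the first frame, mean
taken, frames re-aligned to the mean; two iterations), then per-atom
fluctuations about the time average are averaged within residues. Loop
exclusions (e.g. P-loop proxies) are configurable residue ranges per domain.

## Docking-pose clustering

Poses share the receptor frame, so pose–pose RMSD is computed **without
superposition**. Clustering is **energy-ordered greedy leader clustering**:
poses are visited from best to worst energy; a pose joins the first cluster
whose founding seed is within the 2 Å cutoff, otherwise it founds a new
cluster. This matches classic docking-package behaviour; it is documented
explicitly because leader and complete-linkage clustering produce different
memberships. Clusters are reported by size descending then minimum energy
(C1, C2, …); ties everywhere break on pose id, so the procedure is fully
deterministic. Independent runs are merged before clustering. No ligand
symmetry correction is applied to the RMSD.

## MM-GBSA bookkeeping

ΔG_bind ≈ ΔE_ele + ΔE_vdW + ΔG_GB + ΔG_surf − TΔS per frame; the entropy
term is omitted by default (the field exists so the full identity is
representable). Summaries report mean ± standard error (sample sd/√N) per
component and for the framewise total; by linearity the mean total equals
the total of the means, which the code asserts. The plain SEM ignores frame
autocorrelation; an optional block-averaging SEM (configurable block size)
is provided and labelled as such. Key binding residues are those with
decomposed interaction energy **strictly below −2.0 kcal/mol**, reported
most favourable first. Report tables round totals to 2 dp and leave
components at input precision.

## Synthetic study design

The generators define the study conditions; they are seeded, pure functions
of the spec (one explicit NumPy generator per call, derived from
`(seed, stream tag, scope)` — no global state), and every artifact
round-trips through the package's writers and readers.

- **Structure**: four domains of two idealised α-helices each (rise 1.5
  Å/residue, helix radius 2.3 Å, 100° twist, 15 residues per helix, six
  atoms per residue including one hydrogen), arranged C4-symmetrically
  about z with the inner helices lining the pore. The placement radius is
  solved by bracketing root-finding so the bottom inner-helix residues meet
  the requested gate diameter (default 3.5 Å ⇒ closed; 8.5 Å is used as the
  widened open control).
- **EC tables**: each true contact receives a high score U(0.25, 1) with
  probability equal to the designed true-positive rate (default 0.7); an
  equal-sized pool of non-contacts contributes high-scoring decoys with the
  complementary probability, making the expected precision of the >0.2
  prediction set equal to the designed rate. Sub-threshold scores are
  U(0, 0.2) plus Gaussian noise clipped to [0, 0.2] — clipping at the
  threshold, not only at zero, so the designed precision cannot leak.
- **Candidate ensembles**: 20 candidates per domain, perturbed by **rigid
  per-residue Gaussian displacements** at levels (0, 0.3, 0.6, 1.0, 1.5) Å
  cycled. Residue-level (rather than per-atom) noise preserves local
  geometry while residue–residue distances diffuse, so contact precision
  declines with perturbation instead of being inflated by the downward bias
  of a minimum over independently noised atoms. Pseudo-energies are
  −260 + 40·noise + N(0, 0.5), so the least-perturbed model is the planted
  optimum.
- **Trajectories**: 20 frames of per-atom jitter, 0.2 Å in helices and
  0.8 Å in the four turn residues per domain (loops fluctuate more), plus a
  0.15 Å/frame random-walk rigid drift that separates nofit from fitted
  RMSD.
- **Poses**: three planted clusters 12 Å apart (intra-cluster jitter 0.2 Å,
  far below the 2 Å cutoff) with energies ordered by cluster, plus three
  distant weak-binding outliers.
- **Energy frames**: 3000 frames (matching the 30 ns at 1 ps/10 sampling
  convention of end-point analyses) of Gaussian components about the
  published per-ligand component means with per-component sds
  (3.0, 2.0, 2.5, 0.5) kcal/mol — chosen as typical frame-level MM-GBSA
  fluctuation scales; the decomposition plants the four reported key
  residues below −2.0 kcal/mol on a weak U(−1.5, 0.5) background.

What the synthetic data does *not* emulate: real protein stereochemistry,
side-chain packing, membrane context, correlated (non-Gaussian) dynamics,
force-field energies, or realistic EC score distributions. Passing tests
therefore demonstrate the correctness and internal consistency of the
*computations* (metrics, selection logic, geometry, bookkeeping) under known
ground truth — not the accuracy of any physical model on real channels.

## Numerical choices and degenerate inputs

Kabsch superposition requires ≥3 non-collinear corresponding points
(checked via the second singular value) and always returns a proper
rotation. PDB coordinates round-trip at the format's 0.001 Å precision;
altloc handling keeps the highest-occupancy conformer (first on tie).
Duplicate EC pairs collapse keeping the maximum score. Contact/threshold
boundaries are strict everywhere. Empty selections, single-frame RMSF,
missing energies, zero-prediction precision and infeasible geometry targets
all raise (or warn, where a value can still be reported) rather than
returning silent defaults.

## Known limitations

Homology modelling, coupling inference, docking search, force-field and GB
solvation energies are out of scope — their outputs are inputs here. The
radius profile assumes a straight pore. Exact reproduction of published
contact counts for deposited structures is not attempted: it would require
the external structures and alignments; the package instead verifies the
arithmetic those tables imply and the behaviour of every computation on
ground-truthed synthetic data. Problem sizes in the analysis scripts
(30-residue domains, 20 candidates/domain, 20-frame trajectories, 30 poses,
3000 energy frames, 20-seed recovery suites) are the package's desk-scale
defaults chosen to keep the whole study reproducible in seconds.
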