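# Methods

`stepstone` models the structural evolution of a protein as a
continuous-time Markov process over a set of protein-like "stepping
stone" structures intermediate in topology between two natural folds.
Each stepping stone carries an "island" of sequences able to fold into
it; evolution inside an island is assumed fast, and the rare jumps
between islands set the pace of structural change.  The package
estimates those jump rates, fits an analytic detailed-balance rate
surface to them, and solves the resulting master equation.

## Secondary-structure grammar

A fold's topology class is coarse-grained to a string over {H, E, C}
(helix, strand, coil).  Legal strings obey: helices 4–15 residues,
strands 2–8, at least one coil between structured elements, and a total
structured content of 20–45 residues.  Elementary edits are: lengthen a
run by one residue into an adjacent coil, shorten a run by one terminal
residue, insert a minimal element (`C HHHH C` or `C EE C`) into an
all-coil window, and delete a minimal-length element.  Helix insertion
therefore needs a coil window of width ≥ 6, strand insertion ≥ 4 — the
minimal windows that keep a coil on both flanks.

The two bundled endpoints are the B1 domain of protein G (1PGB, element
pattern E7 E7 H15 E5 E5) and chain X of the 2GYC ribosome complex
(E5 H8 E4 H7 E2), both rendered at the shared length 56 (1PGB's true
length; the model requires equal lengths).  The coil gaps are laid out
so that no position is a helix in one endpoint and a strand in the
other.  This layout choice matters: a pathway step must strictly
decrease the per-position mismatch (Hamming) distance to the
destination, and a position with conflicting structured types cannot be
improved by any single legal edit, so conflicting layouts would make
every pathway infeasible.  With the bundled layout the greedy seeded
walk reaches the destination in ≈ 25–29 moves from an initial distance
of 29.

"More closely matches the target" is operationalized as a strict
decrease of Hamming distance over {H, E, C}; ties among equally
improving moves are broken uniformly at random with the caller's seed.
Element movement arises as compositions of shorten-on-one-side /
lengthen-on-the-other and delete+insert, not as a distinct move type.

A parsimonious pathway between two endpoints is an injective, type- and
order-preserving partial matching of their internal secondary-structure
elements, with the terminal strands always mapped to each other.
Between the bundled endpoints (internal elements E H E versus H E H)
there are exactly 7 such matchings.

## Stepping stones as contact maps

Downstream theory consumes only two structural descriptors per stepping
stone — the hydrogen-bond energy E_HB = −ε_HB · n_hb (ε_HB = 1 reduced
unit per bond by default) and the contact count N_c — plus the pairwise
shared-contact fraction.  Structures are therefore represented as
contact sets with hydrogen-bond counts, not 3D coordinates.  The
synthetic generator realizes an SS string deterministically (helix of
length ℓ: ℓ−4 H-bonds and the (i, i+3), (i, i+4) local contacts;
adjacent strands pair antiparallel in chain order, one H-bond and one
cross contact per aligned residue pair) and then adds uniformly random
long-range contacts (j − i ≥ 3, no duplicates, seeded) up to a requested
N_c.  Contact maps can also be read from PDB Cα coordinates with a
configurable cutoff (default 8 Å, strict `<`, separation ≥ 3 — the
standard coarse-grained convention).  What the generator does *not*
emulate: real β-sheet topology rules, loop geometry, or refinement —
so tests passing on synthetic stones validate the rate theory, not any
claim about real protein geometry.

## Energetics

A sequence S threaded on structure X has energy

    E(S, X) = Σ_{(i,j) ∈ contacts(X)} ε(s_i, s_j) + E_HB(X)

with a symmetric, pluggable 20×20 interaction matrix in reduced units
(k_B = 1).  The bundled default is derived from the Kyte–Doolittle
hydropathy scale, ε(a, b) = −h_a h_b / 10, so like residues attract:
a simple knowledge-based table giving designable, heterogeneous ground
states.  No solvent term is included.  All rate theory below depends
only on energy *differences* between structures for the same sequence,
which this surrogate carries through the contact-set difference and
ΔE_HB.

The compositional heterogeneity of a sequence is measured by the
multinomial permutation count N_perm = N! / Π_k n_k!, computed in log
space via log-gamma, with the exact single-mutation increment
Δ ln N_perm = ln n_old − ln(n_new + 1).

## Sequence design

Design moves are single-point substitutions (uniform site, uniform new
residue among the 20-letter alphabet) accepted with

    p = min{1, exp(−[ΔE − E_R Δln N_perm] / T)}

which minimizes energy while maximizing permutation entropy; the E_R
term (default 2 reduced units) prevents collapse to homopolymers.
Replica exchange across a temperature ladder replaces the original
virtual-move parallel tempering — the stationary distributions are
identical and the simpler sampler is exactly verifiable: the test suite
checks the sampled distribution against full Boltzmann enumeration on
2-letter toy systems.  Defaults: one sequence recorded per sweep after a
10% burn-in; a design temperature is selected by matching the designed
population's per-site Shannon-entropy histogram to a reference profile
(total-variation distance), the package's analogue of calibrating
against a natural sequence family; any user-supplied alignment profile
can serve as the reference.

## Jump rates

The committor indicator Λ_AB(S) = Θ(E(S, A) − E(S, B)) marks sequences
that already favor B; ties commit to neither (Θ(0) = 0, implemented
with a 1e-9 relative tolerance because exactly tied pairs would
otherwise flip on ~1e-12 incremental-float drift).  The jump rate per
mutation attempt is the equilibrium island-A average k_AB = ⟨Λ_AB⟩_A,
multiplied by a uniform mutation-rate prefactor μ (default 1).

Two estimators are provided:

- **direct**: a Metropolis chain in island A's own ensemble
  (weight ∝ exp(−[E_A − E_R ln N_perm]/T)) whose committor-indicator
  mean is k_AB; block means give standard errors.  This is the default
  at desk scale, where committed fractions are ~1e-4–1 and directly
  observable.
- **joint**: the rare-event machinery — a chain over the biased joint
  ensemble exp(−[E_A + E_B − E_R ln N_perm]/T), which concentrates
  samples near the committor surface, reweighted back to the
  single-structure ensemble by exp(+E_B/T) in log space (max-shifted),
  with block-bootstrap errors and an effective-sample-size flag
  (warning below ESS 100).  At length 56 the joint and single ensembles
  overlap poorly and the reweighting ESS collapses, which is why it is
  not the desk-scale default; on small systems it converges to the
  exact enumeration oracle and is verified against it.

The exact oracle enumerates all |alphabet|^length sequences (capped at
1e7 states) and computes the same Boltzmann-weighted averages,
including the permutation term; it exists only for verification.

Relative equilibrium probabilities follow from detailed balance,
P_B/P_A = k_AB/k_BA, propagated along a spanning tree of the measured
pair graph from a reference structure; cycle residuals of non-tree
edges report the internal consistency of a measured rate table.

## The analytic rate surface

Measured rates are summarized by the family

    ln k(A→B) = ln k_max − ln(1 + e^{α_HB ΔE_HB}) − ln(1 + e^{−α_c ΔN_c})
                + ln G(q_AB),
    G(q) = σ(α_q (q − q_mid)) / σ(α_q (1 − q_mid)),

with ΔE_HB = E_HB^B − E_HB^A, ΔN_c = N_c^B − N_c^A, q the symmetric
shared-contact fraction 2Q/(N_c^A + N_c^B), and σ the logistic
function.  The printed form this family realizes is: step-like in both
descriptor differences (rates saturate once a jump is clearly favorable
or clearly unfavorable), monotone — decreasing in ΔE_HB, increasing in
ΔN_c — and with sigmoid midpoints pinned at 0 so that the log rate
ratio factorizes *exactly*:

    ln k_AB − ln k_BA = −α_HB ΔE_HB + α_c ΔN_c.

G is symmetric in A↔B and normalized to G(1) = 1, so it cancels in
every ratio and leaves detailed balance intact.  Freeing the midpoints
is available by flag, at the cost of only approximate detailed balance
(reported as a residual).

Because the ratio identity makes (α_HB, α_c) exactly the antisymmetric
content of the data, the default fit is two-stage: (1) weighted plane
regression of ln k_AB − ln k_BA on (ΔE_HB, ΔN_c) through the origin
gives the α's; (2) ln k_max and the G(q) sigmoid are then fit on the
stacked per-direction ln k with the α's fixed.  The equilibrium model
built from the α's is thereby consistent with the measured fluxes by
construction.  The one-stage joint least squares (`RateSurfaceModel`,
scikit-learn estimator conventions) remains available and is used for
recovery tests.  All fits weight by inverse variance of ln k with an
additive variance floor of 0.25: without the floor, near-saturated
rates (k ≈ 1 measured to a fraction of a percent) would outweigh the
informative small rates by ~1e6 and model error, not measurement error,
would dominate the loss.  G(q) is only fit when the q values spread by
at least 0.02 (standard deviation); otherwise it is pinned to 1 with a
warning, since a sigmoid on a point mass is unidentifiable.

Equilibrium (designability) follows in closed form:

    P_X ∝ exp(−α_HB E_HB^X + α_c N_c^X),

increasing in both hydrogen-bond count and compactness.

## Markov network

The generator matrix K has off-diagonal K[A, B] = k(A→B) from the
fitted family (units of μ) and diagonals closing each row to zero.  The
stationary distribution is the null space of Kᵀ (normalized); for
family-built networks it must and does coincide with the closed form
above to 1e-10.  The master equation is propagated as
p(t) = p0 · expm(K t) (dense matrix exponential, adequate to ~2,000
states); probability is conserved to 1e-12 over horizons of several
hundred relaxation times (the slowest relaxation time is 1/|λ₂| from
the generator's spectrum; pushing t to ~1e6/|λ₂| accumulates ~1e-11
float drift, so the shipped consistency checks use ~500 relaxation
times).  Disconnected networks yield per-component distributions with
a warning.  For user-supplied raw rate tables the detailed-balance
violation max |π_A K_AB − π_B K_BA| is reported, never silently
repaired.

## Desk-scale experiment design

The end-to-end driver reproduces the pipeline at sizes that run on one
CPU in minutes; all depths are config-exposed.  Defaults: 12 stepping
stones sampled evenly along one realized 1PGB→2GYC pathway, each
realized with 12–24 extra random long-range contacts (so E_HB spans
~15 reduced units and N_c ~22–64 across the set); rates measured for
the 30 pairs within 3 path positions of each other (closer pairs have
moderate descriptor differences, keeping both directions' committed
fractions directly measurable — the regime where the flux-balance
study is meaningful); sampling temperature T = 2.0, E_R = 2.0, 1e5
committor samples per direction after 1e4 burn-in; design islands of
~90 sequences at T = 1.0.  With these conditions the measured
forward/backward total-rate ratios R_AB/R_BA = (k_AB/k_BA)(P_A/P_B)
concentrate at 1 (median within ~±20% across seeds), the package's
flux-balance consistency check.

## Numerical choices

- All randomness flows from `numpy.random.default_rng` seeds carried in
  the configs; every sampler and generator is reproducible bit-for-bit
  given its seed.
- Reweighting and normalization always happen in log space with
  max-shifts (`logsumexp`); probabilities are exponentiated last.
- Histogram free energies F(Q) = −T ln H(Q) are shifted to min 0;
  empty bins are NaN, an all-empty histogram is an error.
- The committor tie tolerance is 1e-9 relative (see above).
- DRMSD is the root-mean-square over all pairwise distance differences,
  with no superposition; it is rigid-motion invariant by construction.

## Known limitations

- Stepping stones are synthetic contact maps; no fold-topology rules,
  no backbone refinement, no census of realizable topologies.
- The contact energy plus constant H-bond term is a surrogate for a
  full geometric coarse-grained field; absolute energies are not
  comparable to any physical scale, only differences drive the model.
- Conformational refolding of designed sequences is out of scope; the
  committor shortcut *is* the model of the jump.
- The equilibrium model sees only (E_HB, N_c, q); structures identical
  in these descriptors but topologically different get identical rates,
  a stated approximation of the descriptor family.
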