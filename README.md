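# stepstone

Markovian rates for protein structural evolution over "stepping stone"
fold intermediates.

## The problem

How fast does a protein fold evolve into a different fold?  `stepstone`
models the structural evolutionary trajectory between two natural folds
as a continuous-time Markov process over a set of protein-like
intermediate structures ("stepping stones").  Each stepping stone
carries an "island" — the population of sequences that fold into it —
and evolution proceeds by rare jumps between islands: a lineage drifts
neutrally inside its island until it stumbles on a sequence that
already prefers a neighboring structure.  The package is for
computational biophysicists and molecular-evolution researchers who
want a fully seeded, testable implementation of this committor-based
rate theory on coarse-grained (contact-map) structures.

## The model

A structure X is a contact set (N_c contacts) plus a hydrogen-bond
energy E_HB = −ε_HB·n_hb.  A sequence S threaded on X has energy
E(S, X) = Σ_{(i,j)∈contacts} ε(s_i, s_j) + E_HB(X) with a 20×20
interaction matrix (k_B = 1, reduced units).  The committor indicator

    Λ_AB(S) = Θ(E(S, A) − E(S, B)),   Θ(0) = 0,

marks sequences already committed to B, and the jump rate per mutation
attempt is the island-A Boltzmann average k_AB = ⟨Λ_AB⟩_A.  Sequence
islands are designed by Metropolis Monte Carlo with acceptance
min{1, exp(−[ΔE − E_R Δln N_perm]/T)}, where N_perm = N!/Πn_k! keeps
compositions heterogeneous.  Measured rates are summarized by a
detailed-balance sigmoid family

    ln k(A→B) = ln k_max − ln(1+e^{α_HB ΔE_HB}) − ln(1+e^{−α_c ΔN_c}) + ln G(q),

whose log-ratio factorizes exactly as −α_HB ΔE_HB + α_c ΔN_c, giving
closed-form equilibrium probabilities (designabilities)

    P_X ∝ exp(−α_HB E_HB^X + α_c N_c^X)

and a solvable master equation dp/dt = p·K.  Secondary-structure edit
rules (helix 4–15, strand 2–8, ≥1 coil between elements, 20–45
structured residues) generate the intermediates between the two bundled
endpoint folds, the B1 domain of protein G (1PGB) and the 2GYC
ribosomal chain X.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
from stepstone.experiment import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(seed=1))
p = report["params"]
print("pathways:", report["n_pathways"])
print("pairs measured:", len(report["rates"]))
print(f"alpha_HB = {p.alpha_hb:.3f}, alpha_c = {p.alpha_c:.3f}")
pf = report["plane_fit"]
print(f"plane fit: c_HB = {pf.c_hb:.3f}, c_c = {pf.c_c:.3f}, R^2 = {pf.r_squared:.3f}")
print(f"median R_AB/R_BA = {report['ratio_table']['r_ratio'].median():.3f}")
```

prints (about 4 minutes on one CPU):

```
pathways: 7
pairs measured: 30
alpha_HB = 0.567, alpha_c = 0.209
plane fit: c_HB = -0.567, c_c = 0.209, R^2 = 0.893
median R_AB/R_BA = 0.921
```

Reading the numbers: there are exactly **7** parsimonious ways to match
the internal secondary-structure elements of 1PGB onto those of 2GYC
(terminal strands fixed).  Twelve stepping stones are sampled along one
realized pathway and the committor rates of the 30 nearby pairs are
measured in both directions.  The fitted decay constants say a jump
becomes e-fold slower per ~1.8 reduced units of hydrogen-bond energy
gained (α_HB ≈ 0.57) and e-fold faster per ~5 extra contacts
(α_c ≈ 0.21): compact, hydrogen-bond-rich structures are easier to jump
*into*.  The plane fit of the log rate *ratios* returns the same
coefficients (the detailed-balance consistency check), and the
forward/backward total-rate ratios R_AB/R_BA = (k_AB/k_BA)(P_A/P_B)
have median 0.92 ≈ 1: the measured fluxes balance under the fitted
equilibrium.  The most probable (most designable) stepping stone in
this run, with P ≈ 0.69, is the one with the most hydrogen bonds (28)
at high contact count — designability rewards both descriptors at once.

The same pipeline is scriptable from the shell:

```bash
stepstone run --config experiment.json --seed 1 --out results/
stepstone sspath enumerate --src 1pgb.txt --dst 2gyc.txt
stepstone fit --rates rates.tsv --out params.json
```

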