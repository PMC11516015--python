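# rxnet

Autonomous exploration of chemical reaction networks with Newton-trajectory
elementary-step searches, runnable entirely on built-in analytic toy
potential-energy surfaces — no quantum-chemistry engine required.

## The problem

Mapping the chemistry accessible from a set of reactants means discovering
*elementary steps*: transformations that connect a reactant valley to a
product valley on the potential-energy surface through a single first-order
saddle point (transition state, TS). Done by hand this requires chemical
intuition for every guess; done autonomously it becomes a pipeline that any
structure can be fed into:

1. **Reactive complex generation** — one or two reactants are aligned along
   a *trial reactive coordinate*: declared atom pairs to be bonded or
   cleaved (pair-driven scans) or two atom sets pushed onto one another
   (fragment-driven scans).
2. **Newton-trajectory scan** — a steepest-descent walk in which the
   gradient component along the reactive coordinate is replaced by an
   artificial force, driving the system uphill toward a saddle region while
   all other degrees of freedom relax (optionally with constrained BFGS
   micro-cycles). Scans stop on a gradient-call budget, on
   collision/conversion of the constrained coordinate (bond order ≥ 0.75
   formed, ≤ 0.15 broken), or on calculator failure.
3. **TS-guess extraction** — scan energies are smoothed with a repeated
   5-point Savitzky–Golay filter and the highest interior maximum is taken
   as the TS guess.
4. **TS refinement** — quasi-Newton saddle search with Bofill-mixed SR1/PSB
   Hessian updates and partitioned rational-function steps (or explicit
   eigenvector following); converged structures must have exactly one
   negative Hessian eigenvalue after projecting rigid-body modes.
5. **IRC validation** — damped steepest descent from the saddle into both
   valleys; the endpoint molecular graphs decide whether the step is new,
   fell back to the start, or connects the wrong species.
6. **Network bookkeeping** — structures are deduplicated into *compounds*
   by a permutation-invariant canonical graph key (+ charge and spin);
   validated steps are aggregated into *reactions* between compound
   multisets; barriers are stored in both the separated
   (ΔE‡ = E(T‡) − Σᵢ E(Aᵢ)) and complexed (ΔE‡ = E(T‡) − E([AB]))
   conventions, with the path retained as a cubic spline over arc length.

An engine/gear loop (compound gear → kinetics gear → step-trial gear →
scheduler → reaction gear) repeats these trials until the network is
quiescent or a budget is exhausted.

The electronic structure behind all of this is a generic single-point
calculator contract (energy, gradient, Hessian, bond orders, partial
charges). Two toy backends ship with the package: a pairwise Morse
potential with Pauling-style exponential bond orders (optionally augmented
with a Gaussian barrier so dissociations have a true saddle), and the
classic 2D Müller–Brown surface for optimizer validation. Real engines
could be docked behind the same contract.

## Who this is for

Method developers and students who want a transparent, fully testable
implementation of the reaction-network exploration machinery — the scan
algebra, the saddle refinement, the graph deduplication, the orchestration
— without the cost and noise of semiempirical or DFT engines.

## Worked example: dissociating toy H₂

```python
from rxnet import (MorseCalculator, barrier_params, Database, add_structure,
                   make_fixture, run_exploration, ExplorationOptions, GearConfig)

calc = MorseCalculator(barrier_params())   # Morse wells + dissociation barriers
db = Database()
add_structure(make_fixture("h2"), db)      # H2 at its 0.62 Å toy bond length
summary = run_exploration(db, calc, ExplorationOptions(),
                          GearConfig(probe_bimolecular=False))
print(f"trials={summary.n_trials} steps={summary.n_validated_steps} "
      f"reactions={summary.n_reactions} compounds={summary.n_compounds}")
(step,) = db.all("elementary_steps").values()
for key, value in step["barriers"].items():
    print(key, value)
```

prints

```
trials=1 steps=1 reactions=1 compounds=2
barrier_separated 0.07768755701271803
reaction_energy_separated 0.17000000000891427
barrier_complexed 0.07768755701271803
reaction_energy_complexed 0.05794953712725542
ts_energy -0.09231244298728197
negative_barrier False
```

The single enumerable trial (break the one H–H bond) is scanned, refined
and IRC-validated into one dissociation reaction. Two compounds result: H₂
and the H atom. The separated reaction energy equals the Morse well depth
D_e = 0.17 (exact to ~1e−11), the forward barrier is the Gaussian crest at
0.96 Å, and the complexed reaction energy is smaller because the IRC ends
in a weakly bound H···H pair rather than free atoms.

The same run from the shell:

```bash
rxnet init network.json h2.xyz --write-config config.yaml
# edit config.yaml: backend: morse_barrier
rxnet explore network.json --config config.yaml
rxnet report network.json
rxnet export network.json --graphml net.graphml --json net.json
```

## Scope and limitations

Spin is handled by a single minimal-spin rule (singlet/doublet by electron
parity); stereochemistry is not encoded in graph keys; barrierless steps
cannot be stored (every step needs a TS); conformer ensembles, microkinetic
gating beyond a simple barrier cutoff, and distributed job execution are
out of scope. See `docs/methods.md` for the full model description, the
numerical choices and their rationale.
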