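# dnacyclize

Sequence-dependent DNA cyclization: Jacobson–Stockmayer J-factors from rigid
base-pair Monte Carlo, with transient single-stranded hinges drawn from a
nonlinear-lattice model of DNA breathing.

## The problem

The J-factor (mol/L) measures how readily a linear DNA of N base pairs closes
into a ring.  For DNA shorter than its ~150 bp persistence length, a
uniformly stiff worm-like chain predicts essentially zero cyclization, yet
experiments on ultra-short fragments find J-factors up to six orders of
magnitude higher.  A physical resolution is that thermal "breathing" —
transient local strand separation — puts individual base pairs into a
single-stranded state whose persistence length is only a few base pairs;
these rare, sequence-dependent flexible hinges let a short duplex bend
sharply enough to loop.

`dnacyclize` implements both halves of that picture and their coupling, for
people who model DNA looping, protein-mediated loops, or mini-circle
mechanics:

- **Breathing lattice** (`dnacyclize.epbd`): a quasi-2D nonlinear lattice
  with Morse base-pairing, D(e^{-a(u_n-v_n)}-1)², and anharmonic
  dinucleotide stacking, sampled by Metropolis MCMC.  Output: the
  probability p_n that base pair n is stretched beyond 2.5 Å (locally
  melted).  A mismatched base pair (e.g. C:C) gets p = 1.
- **Rigid base-pair chain** (`dnacyclize.chain_mc`): chains built from
  tilt/roll/twist/shift/slide/rise steps with trinucleotide equilibrium
  geometry (intrinsic curvature) and Gaussian angular fluctuations — RMS
  4.84°/4.84°/4.09° for duplex steps, 30.08°/30.08°/27.96° for
  single-stranded ones.
- **Coupling and J-factor** (`dnacyclize.jfactor`): per chain, each base
  pair is declared single-stranded with probability p_n; closure is scored
  through the three-factor estimator

  J = (4π/N_A) · W(r≈0) · Γ_r(cos γ≈1) · Φ_{r,cos γ}(φ≈0)

  with nested gates r < 30 Å, cos γ > 0.86, cos φ > 0.86 on end-to-end
  distance, normal alignment, and torsional register.  With an all-zero
  profile the coupled model reduces exactly to the pure rigid-chain model.
- **Benchmarking** (`dnacyclize.bench`): fraction of sequences whose
  computed J is within k orders of magnitude of experiment, stratified at
  100 bp — plus fully synthetic panels for end-to-end testing
  (`dnacyclize.synthetic`).

## Worked example

An 84 bp ring (~0.6 persistence lengths) with a weak breathing background
(p = 0.05 per base pair), with and without a 3 bp bubble held permanently
open in the middle (the mismatch rule, p = 1):

```python
import numpy as np
from dnacyclize import (
    DNASequence, FlexibilityModel, OpeningProfile,
    estimate_jfactor, estimate_persistence_length,
)
from dnacyclize.synthetic import random_sequence, straight_step_table

fit = estimate_persistence_length(None, FlexibilityModel(),
                                  n_chains=4000, chain_length=600, seed=1)
print(f"duplex persistence length: {fit.lp_bp:.1f} bp "
      f"(95% CI {fit.ci_low:.1f}-{fit.ci_high:.1f})")

table = straight_step_table()
seq = random_sequence(84, gc=0.5, rng=np.random.default_rng(84), id="demo84")
breathing = OpeningProfile(np.full(84, 0.05), source="synthetic")

plain = estimate_jfactor(seq, table, profile=breathing,
                         n_chains=1_000_000, seed=5)
bubble = DNASequence(seq.id, seq.bases, mismatch_positions=frozenset({41, 42, 43}))
hinged = estimate_jfactor(bubble, table, profile=breathing,
                          n_chains=1_000_000, seed=5)

for name, est in (("plain", plain), ("bubble", hinged)):
    c = est.counts
    print(f"{name:7s} J = {est.j:.2E} mol/L  "
          f"counts r/gamma/phi = {c.n_r}/{c.n_gamma}/{c.n_phi}  ({est.mode})")
print(f"end-contact enhancement: {hinged.counts.n_r / plain.counts.n_r:.1f}x")
```

which prints:

```
duplex persistence length: 141.1 bp (95% CI 138.4-144.4)
plain   J = 0.00E+00 mol/L  counts r/gamma/phi = 252/1/0  (cso_epbd)
bubble  J = 2.46E-06 mol/L  counts r/gamma/phi = 2666/13/2  (cso_epbd)
end-contact enhancement: 10.6x
```

Reading the output: the chain model's duplex persistence length lands at the
small-angle value 2/(σ_tilt²+σ_roll²) ≈ 140 bp.  Without the bubble, only
252 of 10⁶ chains of this stiff 84 bp ring even bring their ends within
30 Å and none passes all three gates (J reported as 0 and flagged as
insufficient sampling).  Holding a 3 bp hinge open raises the end-contact
count by an order of magnitude and yields a measurable J.  Counts, mode,
seed and thresholds travel with every estimate.

The same pipeline is scriptable from the shell:

```sh
dnacyclize make-fixture --kind straight-table --out table.tsv
dnacyclize epbd-profile --seq seqs.fa --sweeps 50000 --seed 1 --out profile.tsv
dnacyclize jfactor --seq seqs.fa --table table.tsv --profile profile.tsv \
    --chains 1000000 --seed 1 --out j.json
dnacyclize benchmark --records panel.tsv --out-prefix bench
```

## Layout

```
src/dnacyclize/
  params_io.py   sequences (FASTA/plain), 64-row trinucleotide step tables,
                 opening profiles (TSV), constants, periodic ring extension
  epbd.py        lattice potential + Metropolis sampler -> opening profiles
  chain_mc.py    step sampling, frame composition, closure observables,
                 persistence length
  jfactor.py     nested closure counting, J-factor estimator, closed forms
  bench.py       within-k-orders curves, 100 bp strata
  synthetic.py   random sequences, toy step tables, synthetic profiles/panels
  cli.py         `dnacyclize` command group
docs/methods.md  models, parameters, numerical choices, limitations
```

Model equations, parameter defaults with units, and the reasoning behind
every numerical choice are documented in `docs/methods.md`.
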