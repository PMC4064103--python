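# hierfold

Hierarchical-folding prediction of pseudoknotted RNA secondary structure,
with the surrounding accuracy and robustness statistics.

Many functional RNA structures — H-type pseudoknots, kissing hairpins,
chains of interleaved helices — are out of reach for classic
pseudoknot-free minimum-free-energy (MFE) folding, while exact folding over
general pseudoknotted classes is computationally prohibitive.  The
*hierarchical folding hypothesis* offers a middle road: an RNA first forms
a pseudoknot-free structure G, then adds pairs (possibly crossing G) that
lower the free energy.  `hierfold` implements that programme for the
density-2 structure class:

* **HFold** — given a sequence S and a pseudoknot-free input structure G,
  find a pseudoknot-free layer G′ over the bases unpaired in G such that
  G ∪ G′ is the lowest-energy density-2 structure containing G;
* **HFold-PKonly** — the same minimisation with every pair of G′ required
  to cross a pair of G (pure pseudoknot detection);
* **Iterative HFold** — four methods (HFold; PKonly→HFold re-seeding;
  constrained-MFE + relaxed-stem trimming; the same after removing external
  unpaired bases) whose lowest-energy candidate is reported.  Unlike HFold,
  the iterative variant may *revise* the input structure;
* **SimFold-equivalent pseudoknot-free folding** — plain and constrained
  Zuker-style MFE over hairpin/stack/internal/multiloop terms;
* **seeding** — HotKnots-style hotspot stems and a suboptimal-structure
  surrogate, for the case where no input structure is available;
* **evaluation** — sensitivity / PPV / F-measure, bootstrap 95% percentile
  confidence intervals, two-sided permutation tests, and the α-sampled
  partial-information robustness experiment over G_big (the maximum
  pseudoknot-free subset of a reference structure).

## Energy model

Free energies are sums over loops.  Ordinary loops use nearest-neighbour
tables (hairpin e_H, stack e_S, internal e_int) and the multiloop linear
form `a + b·pairs + c·unpaired`.  Pseudoknotted structures decompose into
*pseudoloops* — chains of crossing *bands* — charged

```
P_x + P_b·(bands) + P_up·(unpaired) + P_ps·(closed subregions)
```

where the initiation P_x depends on context: exterior (P_s = −1.38),
inside a multiloop (P_sm = 10.07), inside another pseudoloop
(P_sp = 15.00); P_b = 2.46, P_up = 0.06, P_ps = 0.96 kcal/mol.  Stacked
pairs and internal loops that span a band are scaled by 0.89 and 0.74;
band-spanning multiloops use primed coefficients a′, b′, c′.  All
energies are fixed-point (hundredths of kcal/mol), so ties and the
scaling factors are exact and deterministic.  The package ships a compact
self-consistent parameter set (`hierfold/params/default.par`); the loader
ingests any file in the same documented sectioned format.

Correctness of the folding engines is defined by exhaustive oracles:
enumeration of every admissible added layer, scored by the shared
evaluator — the dynamic programs match the oracles exactly on hundreds of
random instances (see `tests/test_acceptance.py`).

## Worked example

```python
import random
import hierfold as hf

f = hf.generate_fixtures(1, (38, 38), rng=random.Random(42), kinds=("htype",))[0]
gbig, gsmall = hf.extract_gbig(f.reference)
rep = hf.iterative_hfold(f.sequence, gbig, report=True)
for r in rep.methods:
    print(f"{r.method_tag}: {hf.write_structure(r.structure, f.sequence.n)}  {r.energy:.2f}")
print(hf.accuracy(rep.winner.structure, f.reference))
```

prints

```
method1: ....(((...[[[[[..)))..]]]]]...........  -13.77
method2: ....(((...[[[[[..)))..]]]]]...........  -13.77
method3: ....(((...[[[[[..)))..]]]]]...........  -13.77
method4: ....(((...[[[[[..)))..]]]]]...........  -13.77
AccuracyRecord(sensitivity=1.0, ppv=1.0, f_measure=1.0)
```

The fixture is a 38-nt sequence with a planted H-type pseudoknot
(reference `....(((...[[[[[..)))..]]]]]...........`).  Given only G_big —
the five-pair stem, i.e. the pseudoknot-free part of the truth — every
method adds the crossing three-pair stem back, reaching the full
reference (F-measure 1.0) at −13.77 kcal/mol under the shipped parameter
set.

The same pipeline is available from the shell:

```bash
hierfold fixtures --count 3 --seed 5 --out-prefix fx
hierfold seed one.fa --mode hotspots --k 5
hierfold iterative-hfold one.fa --seed-mode hotspots --report
hierfold score '((..[[..))...]].' '((..[[..))...]].'
hierfold robustness manifest.tsv --replicates 100 --seed 1
```

## Layout

| module | contents |
|---|---|
| `hierfold.structures` | sequences, pairs, crossing/density-2 predicates, bands, dot-bracket / CT / BPSEQ / FASTA I/O |
| `hierfold.energy` | parameter loading, loop decomposition, structure evaluator |
| `hierfold.pkfree` | MFE and constrained pseudoknot-free folding, relaxed stems |
| `hierfold.engine` | HFold, HFold-PKonly, exhaustive oracles |
| `hierfold.iterative` | methods 1–4 and the lowest-energy orchestrator |
| `hierfold.seeding` | hotspot stems, suboptimal-structure surrogate |
| `hierfold.evaluation` | accuracy metrics, G_big/G_small, bootstrap, permutation, robustness driver |
| `hierfold.fixtures` | synthetic sequences with planted reference structures |
| `hierfold.cli` | `hierfold` command-line entry point |

See `docs/methods.md` for the model's assumptions, the operational
definition of the density-2 class, numerical conventions and known
limitations.
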