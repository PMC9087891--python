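# mscipost

Unidentifiability analysis and MCMC label-switching removal for
bidirectional-introgression (BDI) multispecies-coalescent (MSci) models.

## The problem

An MSci model is a species tree with episodic gene-flow edges: at a fixed
time τ two branches exchange migrants, and a lineage traced backwards
through a hybridization node takes the horizontal (cross-species) parent
path with probability φ and the vertical path with probability 1 − φ.
Divergence times (τ) and population sizes (θ) are measured in expected
substitutions per site; the pairwise coalescent rate in a population is
2/θ.

A BDI event between sister branches makes the model unidentifiable: the
parameter point Θ and its mirror

    φ'_X = 1 − φ_X,   φ'_Y = 1 − φ_Y,   θ'_X = θ_Y,   θ'_Y = θ_X

give *exactly* the same distribution of gene trees, f(G | Θ) = f(G | Θ′).
With m sister-BDI events and n nonsister-BDI events the posterior has
2^n unidentifiable model variants, each with 2^m within-model "towers";
two BDI events stacked between the same two species jointly admit four
transforms forming a Klein four-group. An MCMC sampler wandering between
towers switches the meaning of its columns mid-run ("label switching"),
so naive posterior means of φ drift toward 1/2 no matter what the data
say.

`mscipost` provides:

* **msci_model / towers** — a declarative text format for MSci models
  with explicit BDI pairing; validation, parameter counting, sister /
  nonsister classification on the condensed graph, and enumeration of
  all tower mappings;
* **relabel** — the three relabeling algorithms that remove label
  switching from MCMC sample tables: CoG0 and CoGN (iterative
  center-of-gravity, unweighted / variance-weighted) and β–γ (maximum
  likelihood beta fits for φ columns, gamma fits for θ columns,
  alternated with per-draw best-transform selection; the log likelihood
  never decreases). Implemented as scikit-learn style transformers
  (`CoGRelabeler`, `BetaGammaRelabeler`) with functional wrappers;
* **posterior** — sample-table I/O (bpp `mcmc.txt` dialect accepted),
  means, shortest-window 95% HPD intervals, autocorrelation-based ESS;
* **simulate** — a tower-structured posterior emulator with a Markov
  label-switching process and recorded true labels, a backwards-in-time
  coalescent gene-tree simulator for arbitrary MSci models, and the
  closed-form pairwise coalescent density used as the mirror-invariance
  oracle;
* **heuristics** — ABBA–BABA site-pattern counts, the D statistic and
  the hyde-style φ̂ estimator, for contrast with full-likelihood
  treatment.

## Worked example

```python
from mscipost import (parse_model, detect_bdi_events, enumerate_towers,
                      single_bdi_mapping, beta_gamma_relabel, summarize,
                      simulate_label_switching_samples)
from mscipost.simulate import single_bdi_tower_spec
from mscipost.towers import identity_mapping

model = parse_model("""
tree ((A,B)R;)
bdi X=A@0.00125 Y=B@0.00125
tau R=0.005
theta A=0.01 B=0.01 X=0.005 Y=0.02 R=0.01
phi X=0.7 Y=0.2
""")
towers = enumerate_towers(model)
print(f"{towers.n_variants} model variant(s), {towers.towers_per_variant} towers")

event = detect_bdi_events(model)[0]
mappings = [identity_mapping(), single_bdi_mapping(event)]
spec = single_bdi_tower_spec(n=100_000, seed=1)     # twin towers, phi means (0.7, 0.2)
table, z_true = simulate_label_switching_samples(spec, mappings)
print("raw mean phi_X:", round(table["phi_X"].mean(), 3))

result = beta_gamma_relabel(table, mappings)
print("processed mean phi_X:", round(result.table["phi_X"].mean(), 3))
print(summarize(result.table).table.round(4).to_string(index=False))
```

prints

```
1 model variant(s), 2 towers
raw mean phi_X: 0.515
processed mean phi_X: 0.7
   name   mean  hpd_lo  hpd_hi        ess      n
  phi_X 0.6999  0.4296  0.9426 96787.6263 100000
  phi_Y 0.2001  0.0103  0.4339 99100.0805 100000
theta_X 0.0100  0.0037  0.0170 97752.3593 100000
theta_Y 0.0020  0.0007  0.0034 99958.1606 100000
```

The raw φ_X mean (0.515) has collapsed toward the symmetric-mixture
value 1/2 because the emulated chain spends half its time in the mirror
tower; after β–γ relabeling the mean returns to the tower center 0.7 and
the marginals are unimodal, so the HPD intervals are meaningful again.

The same operations are available from a shell:

```sh
msci model count fig1.msci          # parameters: 9 (5 theta, 2 tau, 2 phi)
msci towers fig5b.msci              # 2 model variant(s) x 4 tower(s) = 8 total
msci relabel mcmc.tsv --algorithm bg \
    --map phiX=phi_X,phiY=phi_Y,thetaX=theta_X,thetaY=theta_Y \
    --out processed.tsv --labels-out z.tsv
msci summarize processed.tsv --out summary.tsv
msci simulate-genetrees fig1.msci --nseq A=2,B=2 --nloci 1000 --seed 1 --out trees.nwk
msci dstat quartet.fa
```

## Documentation

`docs/methods.md` describes the model conventions, the algorithms and
their numerical details, the synthetic-data generators and the design
choices and limitations.
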