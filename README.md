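# seqgauge

Gauge fixing for one-hot models of sequence–function relationships.

## The problem

Quantitative models of sequence–function relationships — protein fitness
landscapes, transcription-factor binding energies, enrichment scores from
deep mutational scanning — are usually written as linear models over
one-hot features:

    f(s; θ) = Σ_{s'} θ_{s'} x_{s'}(s)

where each feature is indexed by an *augmented sequence* `s'`: a length-`L`
pattern over the alphabet plus the wildcard `*`, matching every sequence
that agrees with it at its non-wildcard positions.  `"***"` is the constant
feature, `"*G*"` an additive feature, `"A*G"` a pairwise-interaction
feature, and so on up to order `L`.

These features are linearly dependent (summing an order-`K` feature over
all characters at one of its positions gives the order-`K−1` feature), so
the model has **gauge freedoms**: directions in parameter space along which
every prediction is unchanged.  Individual parameter values carry no
meaning until the gauge is fixed by restricting parameters to a *gauge
space* Θ that meets each equivalence class (*gauge orbit*) exactly once.

## What the package provides

* **Feature spaces** — alphabets, augmented-sequence features, one-hot
  embeddings and design matrices for constant, additive, pairwise,
  nearest-neighbor, all-order and custom hierarchical models; orthonormal
  bases of the gauge-freedom space (additive models have `L` freedoms,
  pairwise models `L + C(L,2)(2α−1)`).
* **The parametric gauge family** — for every penalization strength
  `λ ∈ [0, ∞]` and factorized position distribution `p`, a projector onto
  the corresponding gauge space, built as a Kronecker product of
  `(α+1)×(α+1)` per-position blocks in `η = λ/(1+λ)`.  Named members:
  trivial (`λ=0`), Euclidean (`λ=α`, uniform `p`), equitable (`λ=1`),
  hierarchical (`λ→∞`), zero-sum (hierarchical with uniform `p`), wild-type
  (`p` an indicator) and generalized wild-type (`p` with zeros).  For
  `0<λ<∞` the diagonal penalizer `Λ_{s's'} = p(s') λ^{o(s')}` whose
  constrained minimizer realizes the same gauge.
* **Arbitrary linear gauges** — projection along the gauge freedoms onto a
  gauge space given either by a basis or by a positive-definite penalizer
  `Λ`, via `P = Λ^{-1/2}(XΛ^{-1/2})⁺X`.
* **Hierarchical-gauge tools** — closed-form (enumeration-free) projection
  of additive/pairwise/other hierarchical models built from conditional
  means of the landscape; ANOVA-style variance decomposition by interaction
  order; truncation to the p-weighted best lower-order approximation
  (local additive models for regions of sequence space); the maximum gauge
  for additive models.
* **Synthetic landscapes** — random all-order landscapes, region-structured
  pairwise landscapes with disjoint high-activity regions, and a
  least-squares fitter.
* A `gauge` command-line tool (`simulate`, `fit`, `project`, `decompose`,
  `truncate`, `freedoms`, `orbit-check`) operating on TSV tables.

## Worked example

Simulate a random landscape on binary sequences of length 3, express it in
the zero-sum gauge, and decompose its variance by interaction order:

```python
import seqgauge as sg
from seqgauge.simulate import SimConfig

cfg = SimConfig(alphabet="01", length=3, preset="random_all_order", seed=7)
theta, table = sg.simulate_landscape(cfg)

p = sg.PositionDistribution.uniform(theta.spec.alphabet, 3)
zs = sg.project_hierarchical(theta, p)
print("constant:", round(zs.constant, 4))
for lab in ("0**", "1**", "*0*", "*1*"):
    print(f"theta[{lab}] = {zs[lab]: .4f}")
print(sg.variance_decomposition(zs, p).to_frame().round(4).to_string(index=False))
```

Output:

```
constant: -0.1138
theta[0**] = -0.1023
theta[1**] =  0.1023
theta[*0*] = -0.1727
theta[*1*] =  0.1727
 order  variance  fraction
     0    0.0000    0.0000
     1    0.0431    0.0898
     2    0.3208    0.6677
     3    0.1165    0.2426
```

The constant is the mean activity of all 8 sequences; additive parameters
come in equal-and-opposite pairs (the zero-sum property for a binary
alphabet) and measure the average effect of fixing one position; the
variance table shows how much of the landscape variance each interaction
order explains — here the landscape is dominated by pairwise epistasis.

The same analysis from the shell:

```sh
gauge simulate --preset random_all_order --alphabet 01 --length 3 --seed 7 \
      --out-params true.tsv --out-data data.tsv
gauge project --model true.tsv --gauge zero_sum --out zs.tsv
gauge decompose --model zs.tsv --out variance.tsv
```

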