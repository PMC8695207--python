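# herblike

Weighted herbicide-likeness scoring and physico-chemical descriptor
profiling for compound libraries.

Agrochemical discovery increasingly mines libraries assembled for other
purposes — antimalarial boxes, kinase sets — for molecules that might kill
plants. Whether such a molecule can work as a *herbicide* (reach its target
through soil, cuticle and membranes at field-relevant doses) is strongly
constrained by its physico-chemical profile. `herblike` implements a
weighted scoring system that quantifies how closely a compound's profile
resembles that of commercial herbicides, for triaging candidate libraries
before any wet work.

## The score

A compound is profiled by ten descriptors evaluated at pH 7.4: six
continuous — molar mass *M*, percentage of aromatic atoms, polar surface
area (PSA), log *D*₇.₄, log *S*, log *P* — and four discrete counts —
rotatable bonds, H-bond acceptors (HBA₇.₄), H-bond donors (HBD₇.₄) and net
formal charge.

Each continuous descriptor *x* is scored by its distance from the
reference-herbicide mean μ in units of the reference SD σ, with closed
band bounds (z = |x − μ|/σ):

| band | z ≤ 1 | 1 < z ≤ 2 | 2 < z ≤ 3 | z > 3 |
|---|---|---|---|---|
| standard score | 1.5 | 1.0 | 0.5 | −1.0 |
| log *P* score | 3.0 | 2.0 | 1.0 | −1.0 |

log *P* is weighted double inside three SD because it is the descriptor
that best separates soil-active from soil-inactive compounds.

Each discrete descriptor is scored by its integer offset from the
reference mode (offsets −2…+2 score 0.5/1.0/1.5/1.0/0.5; anything further
scores −1.0), except formal charge, which is weighted heavily and
penalises cations:

| charge offset | −2 | −1 | 0 | +1 | +2 | beyond |
|---|---|---|---|---|---|---|
| score | 1.0 | 2.0 | 3.0 | 2.0 | −3.0 | −1.0 |

The herbicide-likeness total is the plain sum of the ten scores; under the
default rules it ranges from −12 to a maximum of **18 points**. The
packaged reference model carries the published commercial-herbicide
statistics (n = 360): *M* 317±88, aromatic % 25±12, PSA 72±39,
log *D* 2.2±2.4, log *S* −3.5±1, log *P* 2.9±1.5; modes 5 (rotatable
bonds), 2 (HBA), 0 (HBD), 0 (charge).

Descriptors come from either a **table backend** (CSV/TSV with precomputed
values — the authoritative route) or a **computed backend** (RDKit from
SMILES, with a rule-based group-pKa ionisation model for the pH 7.4
fields; see `docs/methods.md` for its limits). The package also provides
the surrounding comparison statistics: per-descriptor two-sample t-tests,
Fisher's exact test on positive vs non-positive charge, charge CDFs,
central percentile intervals and score histograms, plus a seeded synthetic
library generator for testing and power studies.

## Worked example

```python
import pandas as pd
from herblike import HerbicideLikenessScorer, compute_descriptors

ds = compute_descriptors("CC(=O)Oc1ccccc1C(=O)O")   # aspirin
est = HerbicideLikenessScorer().fit()                # published reference
X = pd.DataFrame([ds.as_dict()])
print(est.score_samples(X))   # [10.5]
print(est.transform(X))
# [[ 1.   1.   1.5  1.   1.   2.  -1.   0.5  1.5  2. ]]
```

Aspirin totals 10.5 of 18: its mass, aromaticity, log *D*, log *S* sit in
their 2-SD bands (1.0 each), PSA and donor count are ideal (1.5 each),
log *P* lands in the 2-SD log *P* band (2.0), its two rotatable bonds are
three below the herbicide mode (catch-all, −1.0), four acceptors are two
above the mode (0.5), and the −1 charge of the anion at pH 7.4 scores 2.0.

The same pipeline from the shell, on the shipped six-compound worked
fixture:

```sh
herblike simulate --n 500 --seed 3 --out sim/       # synthetic library
herblike rank scored.csv --threshold 17 --out ranked/
```

Ranking the worked fixture with `--threshold 17` prints
`3 compounds scored >= 17` and writes `scores.csv` with the full
per-descriptor audit trail:

```
compound_id  rank  total
     HL-MAX     1   18.0
   HL-TIE-A     2   17.5
   HL-TIE-B     3   17.5
  HL-FAR3SD     4   14.0
    HL-CHG2     5   12.0
   HL-WORST     6  -12.0
```

`HL-MAX` sits at every reference mean and mode (the analytic maximum);
`HL-CHG2` differs only by a +2 formal charge, which swaps the +3.0 charge
score for −3.0 and drops the total to 12. Equal totals are ordered by
compound id.

Library-level statistics:

```python
from herblike import (generate_library, herbicide_like_spec,
                      antimalarial_like_spec, compare_descriptors,
                      fisher_charge_test)

herb = generate_library(herbicide_like_spec(n=200, seed=1))
anti = generate_library(antimalarial_like_spec(n=200, seed=2))
rows = compare_descriptors(herb, anti)          # nine t-test rows
fisher = fisher_charge_test(herb, anti)         # charge 2x2 exact test
```

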