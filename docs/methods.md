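# Methods

## The scoring model

Herbicide-likeness is a weighted desirability score over ten
physico-chemical descriptors evaluated at pH 7.4. The reference model
supplies, per continuous descriptor (molar mass, aromatic-atom
percentage, PSA, log D₇.₄, log S, log P), a mean μ and standard deviation
σ, and per discrete descriptor (rotatable bonds, HBA₇.₄, HBD₇.₄, formal
charge₇.₄) a mode. A continuous value x is banded by z = |x − μ|/σ with
closed upper bounds (z ≤ 1, ≤ 2, ≤ 3, > 3) and scored
1.5/1.0/0.5/−1.0, except log P which scores 3.0/2.0/1.0/−1.0; a discrete
value is scored by its offset from the mode (−2…+2 and a catch-all),
with the symmetric 0.5/1.0/1.5/1.0/0.5 pattern for the counts and the
asymmetric, heavily weighted 1.0/2.0/3.0/2.0/−3.0 pattern for formal
charge (a +2 cation is penalised harder than any other single cell). The
total is the plain sum; the default rule set has an analytic maximum of
18 and minimum of −12. The model assumes descriptors contribute
independently and additively — there is no interaction term — which is
what makes per-descriptor audit trails and re-weighting trivial.

Design choices where the rules as printed leave room:

* **Band boundary inclusivity.** "Within one SD" is read inclusively:
  a value exactly at k·σ receives the better band's score. Boundary
  comparisons carry a 1e-9 relative tolerance so that a value
  *constructed* at a boundary (μ + 1.0·σ in floating point) is not
  pushed into the worse band by a last-ulp rounding. The tolerance is
  nine orders of magnitude below any band width that occurs in practice.
* **HBA −1/−2 offsets.** The published acceptor row specifies no score
  below the mode. The default (`hba_na_policy="mirrored"`) mirrors the
  +1/+2 scores, consistent with the symmetry of every other count row; a
  `"strict"` policy scores those offsets with the catch-all −1.0
  instead. Both are selectable on the estimator, the functions and the
  CLI.
* **Charge non-monotonicity.** The +2-charge score (−3.0) is lower than
  the beyond-±2 catch-all (−1.0). This is implemented exactly as
  specified, without smoothing.
* **Exact totals.** Rule scores are half-point multiples; totals are
  summed with integer doubling so the breakdown-sum invariant holds
  exactly, with a rational-arithmetic fallback for user-supplied rules
  that are not half-point multiples.
* **Ranking ties** are broken by compound id (lexicographic), making
  ranked output deterministic; shortlist membership uses ≥ threshold.

## Reference statistics

`fit_reference` uses the arithmetic mean and the *sample* SD (n−1): the
reference libraries are samples of a larger compound universe. Modes are
the most frequent value with ties broken toward the smallest value, for
determinism. Values are sorted before reduction so fitting is
permutation-invariant bit-for-bit. The packaged `published_reference()`
carries the printed statistics of the 360-commercial-herbicide set
(provenance `"published-2021"`), deliberately *not* a refit, so scoring
against it requires no dataset and reproduces exactly.

## Descriptor backends

The **table backend** ingests precomputed descriptors from CSV/TSV and is
the authoritative path for reproducing published numbers: the original
descriptor values were produced by a commercial physico-chemical engine
(Marvin-class pKa/log D/log S models) whose numerics cannot be cloned.
Parsing is strict — duplicate ids and non-numeric cells are hard errors
with coordinates, rows with missing descriptor values are returned as
reasoned rejects, and counts must be integral (a "1.0" cell is accepted
as 1; "1.5" is rejected).

The **computed backend** is a best-effort profiler from SMILES built on
RDKit: molar mass, Crippen log P, topological PSA (the package's reading
of "polar surface area"), rotatable bonds, and aromatic percentage over
heavy atoms (hydrogens are never aromatic; an `aromatic_include_h` flag
adds them to the denominator for tools that count total atoms).
Multi-fragment inputs keep the largest covalent component. The pH 7.4
fields use a rule-based ionisation model: SMARTS-recognised groups with
representative literature pKa values (carboxylic/sulfonic/phosphonic
acids, tetrazole, phenol, thiol; aliphatic amines, amidines, guanidines,
anilines, pyridine-type nitrogens). A group is toggled by
Henderson–Hasselbalch at pH 7.4 (acid deprotonated iff pKa < 7.4, base
protonated iff its conjugate acid's pKa > 7.4); HBD/HBA and formal
charge are counted on the resulting major species. log D₇.₄ is
log P + log₁₀ f(neutral) under an independent-sites approximation —
exactly log P for molecules with no recognised ionisable group. log S is
the ESOL regression (0.16 − 0.63·clogP − 0.0062·M + 0.066·RB −
0.74·aromatic fraction). These are group-constant models, not
per-molecule pKa predictions: computed log D/log S/charge for molecules
with unusual electronics (strong electron-withdrawing substituents on an
acid, vinylogous acids, zwitterion-prone structures) can differ
materially from measured or engine-computed values. Setting
`ProviderConfig(ionization="none")` makes the backend refuse (raise)
rather than return neutral-species values for ionisable molecules.
Scoring never inspects which backend produced a descriptor set.

## Group statistics

Two-sample comparisons default to the pooled-variance Student's t-test
(the classic reading of "two-sample t-test"); Welch is selectable and the
choice is recorded in the output. Count descriptors are t-tested as-is,
matching conventional reporting despite their discreteness. The charge
comparison dichotomises at ≥ +1 (cation vs not) and uses the two-sided
Fisher's exact test, with the p-value defined by summing hypergeometric
probabilities of tables as or less probable than the observed one (the
scipy convention; verified in tests against exhaustive exact-rational
enumeration for all margins ≤ 12). Percentile intervals use linear
interpolation between order statistics (numpy's default), and score
histograms use half-point-aligned bins anchored at the rule set's
minimum, widened if data fall outside, so counts always sum to n. No
multiple-testing correction is applied across the nine descriptor rows;
the report is descriptive.

## Synthetic libraries

`generate_library` draws each continuous descriptor from a normal
distribution (molar mass, PSA and aromatic % clipped to their physical
ranges) and each count from an explicit categorical distribution, so the
generating mode is exact and controllable; draws use
`numpy.random.default_rng(seed)` and are byte-reproducible. The
`herbicide_like_spec` profile uses the published herbicide means/SDs and
count distributions peaked at the published modes with under 1% positive
charge mass (positively charged herbicides are rare); the
`antimalarial_like_spec` profile uses the published plate-active
antimalarial summaries (log P mean 4.2, lower PSA, more donors) with 35%
positive-charge mass. Probability vectors must sum to 1 within 1e−9 and
are renormalised exactly before sampling.

Limitations of the generator, hence of what passing tests demonstrate:
descriptors are sampled independently, whereas real descriptors are
correlated (log P with log S and log D, mass with rotatable bonds); no
SMILES structures are generated, so the computed backend is exercised
only by real molecules in the unit tests; and marginal normality is an
idealisation — real libraries are skewed and multimodal. Tests on
synthetic libraries therefore validate the statistical machinery
(fitting, scoring, ranking, group tests) under the model's own
assumptions, not the chemistry of any particular library.

Problem sizes used by the test-suite statistics were chosen as standard
for this kind of check: n = 500 for moment recovery (mean within
3σ/√n ≈ 0.13σ, SD within 20%), n = 1000 for exact mode recovery, n = 500
per arm for the score-separation comparison; all seeded.

## Known limitations

* The computed backend's pH 7.4 descriptors are approximations; treat
  computed scores as a screen, not as reproductions of engine-computed
  values. Published-number reproduction requires the original descriptor
  tables via the table backend.
* The score's weights are fixed by the rule tables; the package does not
  learn weights from data.
* Reference models are unimodal summaries; multimodal reference
  libraries are represented only by their most frequent value (ties to
  the smallest).
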