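# Methods

## Cohort model

Tumors are classified twice, independently. The **etiopathogenic group** is
phenotypic: *nevogenic* requires strictly more than 50 melanocytic nevi and
no solar elastosis; *CSD* requires strictly fewer than 20 nevi and
moderate-to-severe elastosis. Both inequalities are strict, so the boundary
counts (exactly 50 or 20 nevi) are unclassifiable, as is any patient
satisfying neither rule or missing a field (a reason code is attached). The
elastosis score has 11 histological degrees from 0 to 3+; we collapse them
into four bands by leading digit (0 → none, 1x → mild, 2x → moderate,
3x → severe) and, for integer-coded ordinals 0–10, by thresholds 0 / 1–3 /
4–6 / 7–10. The two group rules are mutually exclusive for every input by
construction (the rule thresholds are validated so the nevus intervals
cannot overlap).

The **molecular subtype** depends only on the driver-status columns: BRAF+,
RAS+ (any of NRAS/HRAS/KRAS), NF1+, or 3wt when none is mutated. A tumor
mutated in more than one driver class receives a concatenated overlap label
(e.g. `BRAF+NF1+`) and is excluded from the four mutually exclusive
subtypes. The triple overlap label is supported although absent from the
study cohort. The TERT promoter participates in prevalence tables but never
in subtyping, and may be missing (non-informative) per tumor.

Variant ingest keeps calls with VAF strictly above 0.05 in the pathogenic /
likely-pathogenic / predicted-pathogenic classes; calls on genes outside
the 21-gene panel (+TERTp) are rejected with a warning naming the record.
Pathogenicity is consumed as a label — no annotation is performed here.

### Fixture reconstruction from printed marginals

The study cohort is not deposited, but its per-gene mutated counts by group,
the three pairwise driver overlaps, and the group sizes (82/37) are printed.
`fixture_from_marginals` rebuilds a status matrix exact on all of them:

1. The overlap totals must be split between the groups; any split consistent
   with the per-group class marginals is admissible. We enumerate all splits
   (the counts are small) and keep the feasible one that maximises the
   minimum remaining single-driver count, ties broken lexicographically —
   deterministic, and infeasibility is reported naming the violated
   constraint. The subtype *totals* are invariant to this choice; the
   per-group subtype split is not printed precisely enough to pin down.
2. Overlap patients are materialised first, then single-driver patients,
   then wild-type padding; RAS patients consume the printed per-gene
   NRAS/HRAS/KRAS counts in panel order within each group.
3. Non-driver columns are filled group-wise by exact count with patients
   drawn at random (seeded), independently per gene — the study publishes
   no joint distribution beyond the driver overlaps, so co-occurrence is
   deliberately not modelled. Non-informative TERTp status (6 tumors, 3 per
   group) is assigned the same way before the mutated draws.

Consequently the fixture is exact on every printed marginal and overlap for
any seed; the seed moves only which padded patient carries which non-driver
mutation.

## Association statistics

The default 2×2 test is the two-sided Fisher exact test with the
probability-mass convention (sum the hypergeometric probabilities, at fixed
margins, of all tables no more probable than the observed one). The printed
cohort p-values match this test — e.g. counts 1/82 vs 4/37 give 0.032 —
and not the chi-square or Yates-corrected statistic, so Fisher is the
default and chi-square is available behind a flag. The implementation
delegates to `scipy.stats.fisher_exact`; the test suite checks it against an
independent enumeration oracle across random tables. Degenerate tables
(an empty margin) return p = 1 with a degeneracy flag. Display rounding is
half-up (1 decimal for percentages, 3 for p, `<0.001` below 0.0005).

Logistic models (univariate and joint) are maximum-likelihood fits via
statsmodels; complete or quasi-complete separation is detected by a
diverging coefficient (|β| > 15) and returned as a flagged result without a
numeric odds ratio. Rank-deficient joint designs raise, naming collinear
columns. No multiple-testing correction is applied across the prevalence
table (the published p-values are unadjusted).

## Pathway model

Pathways are signed directed graphs; cycles are rejected at parse time
rather than iterated to a fixed point, which keeps activities well defined
and bit-reproducible — feedback motifs are a documented limitation.
Receptors and effectors are inferred by degree (in-degree 0 / out-degree 0),
overridable by explicit role annotations. A circuit is, per effector, the
induced sub-DAG of the effector and its receptor-reachable ancestors; in a
DAG this equals the union of all simple receptor→effector paths, which the
tests verify against a brute-force path enumerator on graphs up to 12
nodes. Effectors with no incoming receptor path (isolated nodes) are
skipped with a warning.

Expression is mapped to (0, 1) by ranking **the whole matrix** (rank/(N+1),
ties averaged); a per-gene mode exists behind a flag. Multi-gene node values
are the arithmetic mean of member-gene rescaled values. Propagation follows
the standard effector-circuit recursion — receptors emit their own value;
any other node emits v(n) · (1 − ∏(1 − S(activators))) · ∏(1 − S(inhibitors))
— evaluated once per node in topological order with values clipped into the
open interval by ε = 1e-12. The cited mechanistic framework does not print
its equations, so this recursion and the mean rule are recorded as modelling
assumptions and isolated behind single functions for substitution. On a pure
activating chain the activity is exactly the product of node values;
activity is monotone in activator-path values and antitone in inhibitor
values (property-tested on random DAGs).

## Knockdown simulation

A tumor's in-silico knockdown multiplies the raw expression of each mutated
panel gene by 0.01. By default all mutated genes are knocked down, oncogenic
ones included — the study applies knockdowns to mutational profiles
wholesale, and whether activating mutations were exempted is unstated — with
an `lof_only` mode restricting to a supplied LoF gene set. TERTp has no
expression proxy and is skipped. Per bootstrap realisation, one normal
sample is drawn with replacement per tumor profile ("an equal number of
samples"), perturbed, and optionally matched by an equal number of
unperturbed normal columns; the assembled matrix is rank-rescaled
**jointly after perturbation** (the order matters and is fixed here), then
propagated. Knocking down an inhibitor raises its circuit's activity — the
mechanism by which LoF mutations yield upregulated circuits.

## Differential activation

Activities live in (0, 1) and are logit-transformed before linear modelling
(raw scale behind a flag). The per-circuit statistic is the two-group
moderated t: the residual variance s² (d residual df) is shrunk toward a
prior via s²ₚₒₛₜ = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) estimated by
closed-form moment matching on the log residual variances (digamma/trigamma
equations, trigamma inverted by Newton iteration); t = logFC/(se·√s²ₚₒₛₜ)
is referred to a t distribution on d + d₀ df. When the observed spread of
log-variances does not exceed its sampling noise, d₀ is infinite and all
variances collapse onto s₀². With shrinkage disabled the statistic equals
the classical pooled t exactly; with shrinkage it matches Bioconductor
limma's `lmFit`+`eBayes` to ~1e-6 (cross-checked in the test suite via
Rscript). The optional differential-expression log-odds (B-statistic) is
not computed; nothing downstream uses it.

The bootstrap repeats draw → knockdown → activities → moderated t → BH 50
times with fresh sample draws. Per circuit the 50 **BH-adjusted** p-values
are pooled by Fisher's method and compared to α = 0.05 without
re-adjustment (the alternative ordering — combine raw p, then adjust — is
available by flag); concordance is the fraction of iterations agreeing with
the majority fold-change sign, and selection requires combined p < α AND
concordance ≥ 0.70 (i.e. ≥35 of 50 iterations). Because iterations share
the cohort, the χ²₂ₖ reference is approximate and anti-conservative in
principle; the result metadata says so, and the null calibration below
bounds the realised false-positive rate. Ties in the majority sign resolve
to "up".

## Hallmark annotation

Hallmark scores (text-mining output, consumed as input) annotate a circuit
when strictly above the threshold — fixed 0.18 by default, which on the
original score table equals the 90th percentile; a recompute-the-percentile
mode (linear interpolation) serves synthetic tables. The radar table
reports, per comparison group and hallmark, the count of selected circuits
annotated to it and two normalisations: over all circuits annotated to that
hallmark (primary) and over the group's total selected circuits (the
approximate percentages of the radar visualisation) — the published text is
ambiguous between them, so both are emitted. Pathway-level dysregulation
pools a pathway's circuit p-values with the same Fisher combination.
Enrichment fits a logistic regression of hallmark membership on the
circuits' moderated-t ranking statistic (per comparison against normal
tissue), reporting the slope's Wald p with the same separation handling as
the cohort models.

## Synthetic data

The generators emulate: cohorts with per-gene Bernoulli mutations at the
published group frequencies (82/37 by default; genes independent within
group, since only marginals plus three driver overlaps are published);
log-normal normal-skin expression with gene-specific means (log-mean
N(2, 1), within-gene SD 0.5); random signed DAG pathways (10 nodes, edge
probability 0.35, 25% inhibiting edges) plus designed 4-node circuits for
planted effects; and exponential hallmark scores with scale 0.18/ln 10 so
that ~10% exceed the 0.18 cut. A planted effect is by definition a
constitutively active circuit restrained by a highly expressed inhibitor:
the planted gene and the designed circuit's scaffold genes are pinned at
log-mean 4.0 (two SD above average) so the knockdown produces a large,
detectable activity change. Every generator is a pure function of
(parameters, seed).

What the synthetic data does **not** model: transcriptome covariance,
germline variation, realistic pathway sizes or KEGG topology, and any
coupling between mutation status and expression beyond the knockdowns.
Passing tests therefore demonstrate the machinery's correctness and
operating characteristics, not biological conclusions about real cohorts —
in particular, the published mechanistic circuit counts depend on the
proprietary inputs and are not reproduced here.

## Reference experiments and problem sizes

Two standing experiments (in `melpath.experiments`) characterise the
pipeline at sizes chosen to run comfortably on one CPU:

* **Null calibration** — two all-wild-type groups of 15 profiles drawn from
  one normal pool of 30 samples, ~90 random pathways (≥200 circuits),
  B = 50. Selection requires both a small Fisher-combined p over
  BH-adjusted values and ≥70% sign concordance (probability ≈ 0.007 for a
  fair sign under the null), so the realised false-positive rate is
  essentially zero (0/218 at the default seed; the acceptance bound is 7%).
* **Planted recovery** — 20 independent replicates of the 8+8-profile
  planted-inhibitor scenario, B = 50 each; 20/20 recovered (selected,
  direction up) at the default seeds against an 80% requirement.

## Numerical choices

Rank ties averaged; activities and node values clipped to
[1e-12, 1 − 1e-12]; p-values floored at 1e-300 before log in Fisher's
combination; trigamma inversion by Newton with relative tolerance 1e-10;
logistic separation cut |β| > 15; percentage display rounding half-up.
Seeds everywhere derive from `numpy.random.SeedSequence`, with per-iteration
bootstrap seeds spawned from the stage seed and kept below 2³¹.
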