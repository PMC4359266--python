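# Methods

## The inference model

`ppibayes` predicts protein–protein interactions (PPIs) by naive Bayesian
integration of heterogeneous evidence against gold-standard interaction
sets. For a candidate pair with evidence values E₁…Eₙ, the posterior odds of
interaction are

    O_posterior = O_prior · LR(E₁, …, Eₙ),
    LR(E₁, …, Eₙ) = Π LR(Eᵢ)           (conditional independence),

where each channel's likelihood ratio is estimated per discretization bin
from the gold standards:

    LR(bin) = P(value ∈ bin | interacting) / P(value ∈ bin | non-interacting).

Bin probabilities are frequency estimates over the Gold Standard Positive
(GSP) and Gold Standard Negative (GSN) sets with add-pseudocount smoothing
(default pseudocount 1), which guarantees finite, strictly positive LRs for
any gold counts. Composite LRs are accumulated in log space to avoid
overflow with many channels; a pair with missing evidence in a channel
receives a factor of 1 there (missingness is never a bin). Because the prior
odds are a constant across pairs, ranking and thresholding operate on the
composite LR directly; `prior_odds` defaults to 1 and only enters
`posterior_odds`.

The global network keeps every candidate whose composite LR is **greater
than or equal to** the cutoff (inclusive; configurable) and appends the GSP
wholesale, flagged by edge provenance, so gold interactions are present
regardless of score. The default cutoff is 113, the conventional
proteome-scale operating point for this procedure; the model's headline
reliability statistic in that setting is an LR of 117. Both are surfaced as
configuration and neither is derived from the other. Analyses of small
synthetic universes set their own cutoff in their config (the demo uses 10),
since LR magnitudes scale with gold-set sizes and bin occupancy.

## Gold standards

- **GSP** — deduplicated union of the source interactomes over canonical
  pairs (lexicographically ordered 2-tuples; self-pairs dropped with a
  logged warning because real source files contain them).
- **GSN** — all membrane-only × nucleus-only protein pairs, exploiting
  compartment incompatibility. Proteins annotated to both compartments are
  removed before pairing and recorded; candidate negatives that appear in
  the GSP are removed and recorded. Proteins localized only elsewhere never
  enter the GSN.
- **STS** — the standard test set. Positives are a held-out fraction
  (default 20%) of the planted true interactome that the generator excludes
  from every source database, so the evaluation is leakage-free by
  construction; the fitted model records its training GSP and the evaluator
  aborts with an error naming the offending pairs if any test positive
  appears there. Negatives are sampled uniformly from pairs that are neither
  true edges nor training positives, defaulting to a balanced set (one
  negative per positive). Both choices are configuration, since the ratio is
  not canonical.

## Evidence channels

| channel | value | default binning |
|---|---|---|
| `rho` | Pearson correlation of expression profiles | 10 equal-frequency bins (quantiles of pooled gold values) |
| `ddi_hit` | # interacting domain pairs bridging the proteins | presence/absence {0, ≥1} |
| `interolog_count` | # organisms whose ortholog pair interacts | one bin per observed count |
| `ssbp_size` | size of smallest shared biological-process term | [2,5), [5,10), [10,25), [25,100), [100,∞) |

Pearson correlation uses sample (n−1) standard deviations and requires at
least 3 samples; a constant profile yields an undefined correlation,
recorded as missing. The domain channel counts bridging domain pairs but is
binned as presence/absence by default — the minimal reading of "enriched
domain pairs mediate interactions" — with the count retained for finer
binning if wanted. Ortholog maps are one-to-one (seed-ortholog style);
paralog clusters are out of scope. An interolog count of 0 (both proteins
mappable somewhere, no conserved interaction) is an observed value, distinct
from missing (no organism maps both). The smallest-shared-process size
counts all member proteins including the pair, so it is ≥ 2 whenever
defined; smaller means more specific shared function.

Values falling outside a channel's fitted bins (possible when scoring pairs
unseen during fitting) are clamped into the nearest edge bin.

## Evaluation

ROC curves sweep thresholds over the distinct scores in descending order;
all pairs tied at a score enter at one step, producing a diagonal segment,
and the trapezoidal area then equals the Mann–Whitney concordance
probability with ties counted ½ — the identity the test suite uses as an
independent oracle (alongside scikit-learn's implementation). Sensitivity
and specificity at the operating cutoff are TP/positives and
1 − FP/negatives. AUC is invariant under monotone transforms of the score,
so raw and log composite LRs give identical curves.

## Hub identification

Four conjunctive filters, each also reported separately so any combination
can be recovered:

1. **degree** ≥ threshold (default 300; inclusive boundary);
2. **cancer links** — neighbors in the cancer-related set, with a classical
   tier (default ≥ 300) and a relaxed novel tier (default ≥ 200);
3. **module membership** — connected components of the maximal k-core
   (default k = 5). k-cores are deterministic, order-independent and
   capture "dense-area" membership without the run-to-run variability of
   stochastic community detection;
4. **divergent expression** — SAM-style statistic
   d = (mean_tumor − mean_normal)/(s + s₀) with s the pooled two-sample
   standard error; s₀ defaults to the median of the per-gene s (the usual
   exchangeability fudge), so with s₀ = 0 the statistic reduces exactly to
   the pooled-variance two-sample t. Significance compares ordered observed
   statistics with their mean ordered values over seeded label permutations
   (default 200), calling genes whose departure exceeds delta (default 1.0).

A classical hub passes all four at the classical tier; a novel hub at the
novel tier; classical therefore implies novel. The default thresholds are
proteome-scale operating points; small-universe analyses scale them in their
config (the bundled demo uses degree 6, links 2/1, k = 3; the acceptance
run on a 500-protein universe uses degree 8, links 3/2, k = 4).

## The synthetic universe

The generator plants a true interactome (Bernoulli edges at `true_density`)
and emulates the surrounding data ecosystem:

- **sources** — each samples the training portion of the true edges at
  `source_coverage` and mixes in spurious non-true pairs so that
  `source_noise` of the file is false;
- **expression** — each true edge contributes a shared latent factor; a
  protein with true-degree k loads √(rho_signal/k) on each of its k factors
  plus √(1−rho_signal) idiosyncratic noise, giving unit variance and an
  expected edge correlation of rho_signal/√(k_i·k_j): exact for degree-1
  partners, attenuated for hubs, and identically 0 for non-interacting
  pairs. Half of the samples are "tumor": a planted fraction of proteins
  (default 10%) receives a mean shift there, feeding the SAM filter;
- **domains** — 1–3 domains per protein; each true edge plants one of its
  cross-domain pairs into the DDI list with probability `ddi_signal`, on top
  of uniform background domain pairs;
- **organisms** — up to six model organisms with ortholog coverage
  `ortholog_coverage`; each mirrors a true edge with probability
  `interolog_fidelity` and carries spurious edges at the `source_noise`
  fraction;
- **biological processes** — term sizes follow a truncated power law
  (exponent `bp_size_skew`, sizes 2 to n/5), membership is random and every
  protein belongs to at least one term. No edge signal is planted in the
  annotation, so the SSBP channel is exercised structurally but is
  uninformative on synthetic data (its fitted LRs sit near 1).

All randomness flows from one seeded root generator through deterministic
child streams, so identical configuration reproduces the universe — and
every downstream text output — byte for byte.

What the generator does **not** emulate: real database citation structure
and confidence scores, GO's DAG hierarchy (terms are flat sets), paralog
ambiguity in ortholog maps, expression batch effects, and the actual degree
distribution of curated interactomes (edges are independent Bernoulli, so
there are no scale-free hubs). Passing tests therefore demonstrate the
correctness and calibration of the machinery under controlled signal, not
performance on real curated data.

## Problem sizes and numerical choices

The test suite and the acceptance script exercise universes of 60–500
proteins — large enough for stable quantile bins and gold sets of hundreds
to thousands of pairs, small enough to run the whole suite in well under a
minute. The signal-recovery study uses 500 proteins with all signal knobs at
0.8 (held-out AUC ≥ 0.9) and a 20-seed zero-signal null (mean AUC 0.5 ±
0.05). Determinism is checked by running the CLI end-to-end twice and
comparing every output byte-wise.

Ties in ROC scores are grouped (see above); quantile bin edges are
deduplicated when gold values tie heavily; degenerate inputs raise early
with the offending field or protein named (invalid config fractions, empty
gold sides, one-class ROC input, absent query protein). Composite-LR
accumulation in log space bounds intermediate magnitudes; per-bin smoothing
keeps logs finite.

## Known limitations

- Conditional independence is assumed, not tested; correlated channels
  (e.g. co-expression and shared process on real data) would inflate
  composite LRs. Dependence-aware integration is a non-goal.
- The GSN construction presumes membrane/nucleus pairs do not interact;
  real exceptions (e.g. receptor-transcription-factor shuttling) make the
  GSN slightly impure, which biases LRs conservatively.
- k-core modules are one fixed notion of "dense area"; biological modules
  found by community detection may differ.
- SAM significance uses the mean ordered permutation statistic with a fixed
  delta; no false-discovery-rate calibration of delta is performed.
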