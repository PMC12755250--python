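# Methods

`dagclimb` learns a causal-structure hypothesis over standardized
continuous variables and quantifies it as a recursive linear structural
model. This note records the model, the algorithmic and numerical
choices, and what the synthetic test batteries do and do not establish.

## Model and score

Every variable is z-scored (mean 0, sample standard deviation with the
n−1 denominator) before any analysis, so all fitted coefficients are
standardized effects. A candidate structure is a DAG; each node X_i with
parent set Pa(X_i) is modeled as

    X_i = b0 + sum_{X_j in Pa(X_i)} b_j X_j + e_i,   e_i ~ N(0, sigma_i^2)

with mutually independent errors. The structure score is a
linear-Gaussian BIC: per node,

    BIC(X_i | Pa) = -(n/2) [ln(2*pi) + 1 + ln(RSS/n)] - ((k+2)/2) ln(n)

where RSS is the residual sum of squares of the node's OLS fit, n the
sample count and k the number of parents. The first term is the
maximized Gaussian log-likelihood; the penalty counts k slopes, the
intercept and the residual variance, hence k+2 parameters. Scores are
decomposable: the graph score is the sum of node scores, so a
single-edge change re-scores only the touched node(s). The score is
maximized (larger, i.e. less negative, is better), and adding a parent
that leaves RSS unchanged lowers the score by exactly (1/2) ln n.

Node regressions are solved by orthogonal decomposition
(`numpy.linalg.lstsq`), not the normal equations: aggregated factors can
be nearly collinear, and the normal equations square the condition
number. A residual variance below 1e−12 is treated as degenerate
(perfect collinearity) and raises an error by default; an opt-in clamp
exists for exploratory runs, because silently flooring the variance
would fabricate effectively unbounded scores.

## Search

Structure search is steepest-ascent hill climbing from the empty graph.
Each iteration enumerates every legal single-edge addition, removal and
reversal — "legal" meaning acyclic after the change and not blacklisted
— computes each move's score delta from the affected local scores
(cached by (node, parent-set) key), applies the best move if it improves
the score by more than epsilon (default 1e−9), and stops at a local
optimum or after 10·p² iterations (flagged in the trace).

Tie handling deserves a note. Markov-equivalent structures (same
skeleton and v-structures) receive exactly equal scores on any data, so
the first addition of an edge always ties with its reversed orientation.
Deltas within epsilon of the best are treated as ties, which also makes
the search invariant to input row order (float summation order cannot
flip the choice). Ties are resolved by a one-move lookahead: the tied
move whose successor graph offers the best follow-up delta wins, with
remaining ties falling back to the deterministic move ordering
(additions, removals, reversals; lexicographic within class). The
lookahead matters because equally scoring orientations can open
different equivalence classes one move later — a collider X→Z←Y is
reachable from the empty graph only if the first edge is oriented into
Z, and a purely lexicographic rule systematically walks into the wrong
class for such targets. With lookahead the climb attains the
exhaustive-search optimum on the full 3-node battery (all 25 DAGs
scoreable by brute force); without it, collider-containing problems are
missed at a measurable rate. No tabu list and no random restarts are
used.

Acyclicity of a candidate move is checked incrementally by reachability
from the would-be child; the DAG container also re-validates with Kahn's
algorithm on every construction (property-tested against networkx).

Expert knowledge enters as a blacklist. The default constraint set
forbids every edge out of the outcome variable (it is a sink) and every
edge from the genetic score into the aggregated parental factors —
nothing else, so genetic→outcome and parental→genetic edges remain
searchable. A reversal is legal only if the reversed direction is not
blacklisted and the result is acyclic.

## Effect quantification

Given a learned DAG, every node with parents is regressed on exactly its
parents. For a recursive linear model with independent errors and no
latent variables, these equation-wise OLS estimates are the
maximum-likelihood path coefficients; full-covariance ML fitting would
change standard errors only at O(k/n) and is not implemented. Standard
errors come from the classical OLS covariance and p-values from the t
distribution with n−k−1 degrees of freedom (exact at small n, converging
to the normal reference at study-scale n).

Paths into the outcome are enumerated breadth-first (shortest first,
lexicographic expansion), which in a DAG yields exactly the simple
directed paths. The total effect of a source on the target is the sum
over its paths of the product of edge coefficients; it is computed a
second time as the (target, source) entry of (I − B)⁻¹ − I, where B is
the direct-effect matrix (B[child, parent]). B is nilpotent under a
topological order, so the inverse always exists and the Neumann series
terminates at p terms. The two routes must agree to 1e−10 — a built-in
guard against path-bookkeeping bugs — and indirect = total − direct by
construction.

## Preprocessing

Multicollinearity among raw variables destabilizes score-based search,
so highly correlated variables are merged before searching. Variables
are clustered by average-linkage agglomeration on the dissimilarity
1 − |r| (Pearson), cutting the dendrogram at 1 − t so that merges happen
only while linkage distance stays at or below that height. The default
cutoff t = 0.7 is configurable; the cutoff, the linkage rule and the use
of |r| rather than signed r are package choices, standard for variable
clustering and monotone in the threshold. Each multi-variable cluster is
replaced by its first principal component (computed from the cluster's
correlation matrix, i.e. of the z-scored columns); the reported
variance-explained is the leading eigenvalue over the cluster size, and
for a two-variable cluster it equals (1 + |r|)/2 in closed form.
Eigenvector sign is arbitrary, so it is fixed by a positive loading sum
(ties broken by the first variable's loading), making factor scores
reproducible across platforms; flipping every input's sign flips the
factor exactly. Singleton clusters pass through unchanged with
variance-explained 1.

LMG relative importance (the average over all predictor orderings of a
predictor's incremental R²) is provided for screening. It is evaluated
through the subset reformulation — O(2^p) rather than O(p!) — and capped
at 12 predictors; no ordering-sampling fallback is provided, since the
screening step in this workflow operates on small factor sets. Shares
sum to the full-model R² by construction.

Missing data are handled once, at ingest: rows with any missing value
are dropped when a table is read, and every downstream constructor
rejects NaNs outright.

## Bootstrap stability and model comparison

Robustness of a learned structure is assessed by a nonparametric
bootstrap of the entire learn-and-fit procedure: B resamples (default
100) of n rows drawn with replacement, each re-standardized, re-searched
and re-fitted. Per directed edge the summary records its appearance
frequency (denominator B, counting failed resamples) and the
2.5th/97.5th percentiles of its coefficient across the resamples in
which the edge was present. Conditioning the interval on presence is a
deliberate convention — an absent edge has no coefficient — and carries
the usual selective-inference caveat for low-frequency edges. Reported
edges default to frequency ≥ 0.40 (boundary inclusive); an effect is
"consistent" when the full-data coefficient lies in the closed bootstrap
interval. Per-resample random streams derive from (master seed, resample
index), so summaries are bit-reproducible and independent of execution
order.

Two learned models are compared as directed edge sets (X→Y and Y→X are
distinct outcomes): shared and unique edges, the Jaccard overlap
|A∩B|/|A∪B|, and the share of each model's edges found in the other.

## Synthetic data

`simulate_sem` draws from an arbitrary recursive linear-Gaussian model
in topological order. For the built-in fixtures, noise variances are
auto-solved so every node has unit marginal variance, keeping
coefficients interpretable as standardized effects.

`make_study_like` emulates an eight-factor system patterned on a
parental-behavior / child-outcome cohort design: three inter-correlated
parental substance-use factors (Tobacco→Drug 0.45, Tobacco→Alcohol 0.25,
Drug→Alcohol 0.45), substance use feeding parental problem factors
(Alcohol→EmoIssues 0.55, Alcohol→Behavioral 0.25, EmoIssues→Behavioral
0.30, EmoIssues→Somatic 0.45), a child polygenic score weakly linked to
the parental side (Tobacco→PRS 0.05, giving the |r| ≈ 0.05
gene–environment correlation such scores show against parental
measures), and direct effects on the externalizing outcome of
Alcohol 0.33, EmoIssues 0.20, Behavioral 0.10 and PRS 0.07. The
outcome-edge coefficients are the quantities the recovery batteries
target; the upstream coefficients are fixture choices at plausible
strengths, not estimates of any particular dataset. The fixture
reproduces the qualitative structure of such cohorts — not their
sampling design, measurement error, or the construction of polygenic
scores — so passing recovery tests demonstrates correctness of the
machinery under the assumed linear-Gaussian model, not robustness to
real-data violations of it (non-normality, selection, latent
confounding).

`make_correlated_blocks` draws block-equicorrelated Gaussian tables
(Cholesky of the target correlation matrix, then column-wise
z-scoring) for exercising the clustering and aggregation steps.

## Test batteries and problem sizes

The end-to-end batteries run at sizes chosen to make their statistical
claims sharp while keeping the default suite fast: chain-recovery uses
100 seeds at n = 5000 (β = 0.8); the optimality battery uses 100 random
3-node problems at n = 300 against exhaustive enumeration of all 25
DAGs; effect recovery uses 20 replicates at n = 10 000 (direct effects
within ±0.03, totals within ±0.05); bootstrap batteries use B = 100 at
n = 5000 (strong edge) and n = 2000 (pure noise).

One noise-bootstrap subtlety: bootstrap edge frequencies condition on
the base sample's realized correlations, which at n = 2000 fluctuate
(sd ≈ 1/√n ≈ 0.022) against a BIC detection threshold of about
√(ln n / n) ≈ 0.062. A single unlucky base draw can therefore show one
recurrent spurious edge above any small cutoff even though the expected
spurious frequency is far below it. The suppression property is
accordingly asserted on the expectation: each edge's frequency averaged
over ten independent noise datasets stays below 0.2 (observed ≈ 0.1).

## Known limitations

- Greedy search returns one DAG from a local optimum's equivalence
  class; edges whose orientation is not forced by constraints or
  v-structures are reported in one arbitrary (deterministic) direction.
- Percentile bootstrap intervals are conditional on edge presence and
  undercover for edges near the selection boundary.
- LMG is exact-enumeration only (≤ 12 predictors).
- No latent variables, no residual covariances among exogenous factors,
  no nonlinearities, no missing-data likelihood; complete cases only.
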