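# Methods

## Model

An order-*o* Markov chain over a finite alphabet Δ has state space Ω = Δ^o,
the set of length-*o* contexts. Two contexts are equivalent when they induce
the same next-symbol distribution; the partition of Ω into these equivalence
classes is the *minimal partition*, and a chain together with its minimal
partition is a partition Markov model (PMM). Parts of the minimal partition
pool their counts, so the model has (|Δ|−1)·|P| free parameters instead of
(|Δ|−1)·|Δ|^o. A partition is *good* when every part groups only equivalent
contexts; the singleton partition is always good, which is what licenses the
bottom-up estimator.

Assumptions: the chain is stationary with a fixed, known order *o* and a
fixed alphabet; a single realization x₁ⁿ is observed; the first *o* symbols
serve only as the initial context (count mass is n − o).

## Scores and the merge distance

The modified log-likelihood of a partition is L(P) = Σ_{a,Γ} N(Γ,a)·
ln(N(Γ,a)/N(Γ)) with 0·ln 0 ≡ 0, computed with `scipy.special.xlogy`. The
EDC score subtracts γ((|Δ|−1)·|P|·α)·wₙ. γ is applied to the full scalar
product: the normalizer bracket γ((|Δ|−1)|P|α) − γ((|Δ|−1)(|P|−1)α) only
makes sense under that reading, and it collapses to (|Δ|−1)·α for γ =
identity, making δ independent of |P| in the default configuration.

The pair distance δ_P(i,j) = vₙ·[L(Γᵢ)+L(Γⱼ)−L(Γᵢ∪Γⱼ)] compares the
separate and pooled fits of two parts. The identity
EDC(P_ij) − EDC(P) = vₙ⁻¹ − [L(Γᵢ)+L(Γⱼ)−L(Γ_ij)] makes the threshold rule
exact: merging improves the score iff δ < 1. This equivalence is verified
exactly (boundary tolerance 1e−9) over thousands of random count tables in
the test suite.

### What δ is, and is not

δ is nonnegative, zero exactly when the two empirical rows coincide, and
symmetric. It is **not** a metric: the bracket equals
N_i·D(p̂_i‖p̂_ij) + N_j·D(p̂_j‖p̂_ij) — a count-weighted Jensen–Shannon-type
divergence, which behaves like a *squared* distance — and the triangle
inequality fails on concrete triples, including counts realized from genuine
chain samples evaluated over the true partition (the test suite constructs
such counterexamples; √δ fails as well). Nothing in the estimator relies on
the triangle inequality: the merge rule uses only pairwise comparisons
against the threshold 1, and the consistency of the selected partition rests
on the score comparison, not on metric axioms. The acceptance suite keeps a
faithful triangle-inequality check, which fails by construction and is left
failing deliberately.

## Penalty sequences

| family      | wₙ          | consistency | notes |
|-------------|-------------|-------------|-------|
| `log_n`     | ln n        | yes         | the BIC penalty |
| `loglog_n`  | ln ln n     | yes (boundary case) | lightest consistent penalty; requires n ≥ 16 so wₙ > 1 |
| `power`     | n^a, a∈(0,1)| yes         | heaviest; strong over-merging at small n |
| `power_log` | n^a·ln n    | yes         | |
| `custom`    | user callable | probed numerically | verdict on a 10³–10¹² grid, heuristic |

α defaults to 2, matching the genomic application configuration; users can
override it. Heavier penalties produce coarser partitions; on a shared
sample the fitted part count is non-decreasing along n^{1/2} → n^{1/3} →
ln n → ln ln n in ≈100% of seeded replicates (measured, not proved).

## Agglomeration details

The clustering scheme is stated in the literature only as "the agglomerative
algorithm", so the following choices are this package's own:

- **one merge per round**, always the globally smallest δ, recomputing all
  pairwise δ after each merge; vₙ uses the |P| of the current partition
  (the score comparison is between |P| and |P|−1 parts);
- **tie-break**: among equal δ, the pair whose (min member state of the
  first part, min member state of the second) is lexicographically smallest
  — fits are bit-for-bit deterministic;
- **stop** when the smallest δ ≥ 1 (no single merge improves the score);
- **unobserved contexts** (N(s) = 0) are excluded from clustering and
  reported separately: the likelihood terms and the MLE rows are undefined
  on them;
- display labels G1, G2, … are assigned by decreasing part size, then by
  smallest member state.

Greedy agglomeration is a heuristic for the EDC argmax. On small instances
(≤ 8 observed states) `exhaustive_best_partition` enumerates every set
partition and returns the exact argmax (refusing ties); on 50 seeded
well-separated instances the greedy fit attains the argmax score in all
cases tested.

## Simulator

`random_pmm` draws a generative PMM: contexts are assigned to parts
uniformly with each part guaranteed nonempty, and part rows are drawn from a
flat Dirichlet, redrawn as a set until all pairwise total-variation
distances reach `min_separation` (default 0.2 — distributions a practitioner
would call clearly distinct, and the separation used in the recovery
experiments). `sample_sequence` starts from a uniformly random context and
discards a 1000-step burn-in rather than sampling the stationary law
exactly; the theory is asymptotic and burn-in removes initialization bias at
negligible cost.

The simulator emulates a stationary, homogeneous PMM with a known order. It
does not emulate features of real genomes — codon structure, strand
asymmetry, repeats, selection, non-stationarity along the genome — so
passing recovery tests demonstrate correctness of the estimator under the
model's own assumptions, not that any genome is a PMM.

## Problem sizes and tolerances

Recovery experiments use |Δ| = 4, o = 2 (16 contexts), 3-part truths with
TV separation ≥ 0.2 at n = 200,000 (20 replicates) and 1-part truths at
n = 50,000 (10 replicates); both recover exactly in all replicates across
the seeds exercised. Property checks run on 500 random count tables
(counts 0–50, alphabets of 2 and 4 symbols, 3–6 parts). Floating
tolerances: 1e−9 absolute for the δ = 1 boundary and score comparisons,
1e−12 for the BIC-specialization identity. `max_admissible_order` guards
the ⌊log_|Δ| n⌋ computation against float underestimation of exact powers
with a 1e−12 nudge.

## Input handling

FASTA is read via Biopython; symbols are lower-cased. Characters outside the
alphabet either abort (`error`, default) or split the record at each run of
unknown characters (`split`), so no transition is ever counted across a
removed symbol — each segment is fitted as its own sequence. Multi-record
files are fitted record by record.

## Limitations

- The order *o* is user-chosen, bounded above by ⌊log_|Δ| n⌋; the package
  does not select it.
- Counts from split segments are not pooled into one model.
- `check_penalty_admissible` for custom sequences is a numeric probe, not a
  proof.
- Exhaustive search is limited to 8 observed states (Bell-number growth).
- The greedy fit may differ from the EDC argmax on poorly separated data;
  the merge trace makes any such divergence diagnosable.
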