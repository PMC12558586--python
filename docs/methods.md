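# Methods

This note documents the models, parameter choices, numerics and known
limitations of `regswitch`.

## Allele-aware motif scanning

Each TF is modeled by a position frequency matrix converted to log-odds:
`p[b,j] = (counts[b,j] + c·bg[b]) / (colsum_j + c)` with pseudocount
`c = 0.8` split in proportion to the background (a common JASPAR
convention), `pwm = log2(p / bg)`. The background defaults to uniform
(0.25 each): SNP windows of 13–19 nt are far too short to estimate
composition from, and a cohort-level background is not identifiable from
the inputs. Both are configurable.

Scores are discretized on a 1e-3-bit grid. Because a random w-mer's
score is a sum of w independent per-column scores, its exact null
distribution is the convolution of the per-column distributions (each
with ≤ 4 support points), computed in O(w · range) by shifted adds. The
survival function of that distribution converts any discretized score to
P(score ≥ s | background) with no sampling and no approximation beyond
the grid itself; the test suite checks bit-exact agreement with
enumeration of all 4^w words for w ≤ 6. The reverse strand is scored
with the reverse-complement matrix re-expressed against the
forward-strand background, with its own exact null, so strand symmetry
holds for any (possibly asymmetric) background.

A single scanner with one documented null replaces the two external
motif tools used upstream of this workflow historically; how those two
tools' hit sets were combined is not recoverable, and one reproducible
scanner is preferable to an unverifiable union/intersection guess.

**Perturbation calls.** Windows span SNP ± (w − 1), so every scored
placement overlaps the SNP; the two allele windows must differ at
exactly one position. A hit is a placement with p ≤ 1e-4 (FIMO's
conventional default; ties kept) on either strand. Gained = hits on the
risk window only; lost = non-risk only; both = unchanged_bound; neither
= unbound. This construction makes gain/loss attributable to the allele
by design: equalizing the alleles removes every call. Ambiguous bases
(N) score −∞. The threshold is configurable; note that under a uniform
background the smallest achievable p-value is 4^-w, so motifs narrower
than 7 columns can never produce a hit at 1e-4.

## Ontology, information content and similarity

The GO DAG (biological_process namespace; `is_a` plus, by default,
`part_of` edges) is read from OBO 1.2; obsolete terms are dropped and
alt_ids mapped to canonical ids. Annotations propagate by the true-path
rule; each distinct gene counts once per term. `IC(t) = −ln p(t)` with
p(t) the propagated annotation frequency. The IC corpus is the TF→GO
annotation set supplied to the run, keeping the artifact self-contained;
swapping in a full GOA corpus is a matter of pointing the annotation
input elsewhere.

Relevance/SimRel — one implementation serves both the redundancy
reduction and the contrast filter, since the two published metrics share
the same functional form —

    sim(t1,t2) = [2·IC(MICA) / (IC(t1) + IC(t2))] · (1 − p(MICA)),

where MICA is the common ancestor (including the terms themselves)
maximizing IC; the score is 0 when the only shared ancestry is the root
(IC = 0) or when both terms are the root. It is symmetric, lies in
[0,1], and `sim(t,t) = 1 − p(t)`.

**Redundancy reduction** is a deterministic greedy approximation of
REVIGO (whose exact clustering is not published in reproducible detail):
repeatedly merge the remaining pair with the highest similarity ≥ 0.5,
removing the lower-IC member (ties: lexicographically larger id), until
no pair reaches the cutoff. Survivors therefore have all pairwise
similarities below the cutoff, and the result is independent of input
order. The removed→representative map is applied to TF term sets
*before* switch pairing.

## Switch calculus and the filter cascade

Healthy-state TFs at a SNP = {lost ∪ unchanged_bound}; disease-state =
{gained ∪ unchanged_bound}. GO switch pairs are the cross product of the
exclusive healthy terms (H∖(D∪S)) and exclusive disease terms (D∖(H∪S)),
where S collects terms of shared TFs plus H∩D; S terms are tracked as
shared-state ("grey") but never pair. TF→GO sets use direct annotations
only — propagating to ancestors would place near-root terms in every set
and drown all switches; propagation is used only for IC.

Stage order is fixed: reduction (via the term map) → curated-list filter
(keep if either side is curated; disabled in sensitivity mode) →
contrast filter (keep similarity < 0.5, strict) → enrichment filter.
Each stage returns a subset of its input and the cascade is idempotent.
The enrichment filter keys on the **disease** term by default: the
DEG-derived enrichment reflects the disease state. The text this rule
descends from is ambiguous ("contained GO terms that were enriched"),
so the side is configurable (`disease`/`healthy`/`either`).

**Carrier rule.** A patient's SNP is active at dosage ≥ 1 (dominant
coding); configurable to ≥ 2. Missing or malformed genotypes count as
dosage 0 with a warning (absence of evidence of the risk allele).

## Enrichment

DEGs are the up-regulated genes (log2FC > 0.5 AND BH-adjusted p < 0.05,
both strict as printed in the thresholds' source conventions; an
absolute-value option exists but is off by default). The ORA universe is
exactly the genes present in the supplied expression table, never the
genome. Per term, P(X ≥ k) for X ~ Hypergeometric(N, K, n), BH-corrected
across tested terms; per-tissue significant sets (adjusted p < 0.01) are
unioned.

## Permutation framework

Two complementary nulls, all randomness from one seed:

* **Global null.** Random sets of non-disease regulatory SNPs,
  size-matched to the observed cohort SNP set, drawn without replacement
  within each of n_perm = 1000 draws (default). Per draw, the percentage
  of annotated terms gained (distinct disease-side terms across the
  set's switches) and lost; run both before and after the filter
  cascade. Summary: z = (rv − mean)/sd with the *sample* SD (ddof = 1),
  two-sided p = 2·Φ(−|z|), plus an empirical rank p ((r+1)/(n+1)) for
  robustness. A degenerate null (sd = 0) leaves z undefined and reports
  p = 1 iff the observation equals the null mean.
* **Patient-matched null.** Random cohorts sample, per patient, exactly
  as many pool SNPs as the patient's real active SNP count (patients
  with none contribute none). Per (term, direction), the proportion of
  patients gaining/losing the term yields a z per the same formula,
  BH-corrected across terms. This stage applies the full cascade minus
  the redundancy-reduction step, whose quadratic cost is not justified
  inside a permutation loop.

Per-SNP perturbation calls are independent of which set a SNP lands in,
so permutations reuse precomputed per-SNP switch records; a draw is pure
set algebra. Calibration is verified: with the observed set itself drawn
from the pool, the two-sided p is uniform (KS test over 200 replicate
toy runs, not rejected at α = 0.01).

## Stratification

Patients are rows of a (feature, direction) count matrix — the number of
active SNPs supporting each gained/lost GO term (or TF) — standardized
per column; zero-variance columns are excluded from scaling and listed.
k-means (k-means++, n_init = 10, fixed seed 17 recorded in outputs) runs
over k = 2..8; the chosen k maximizes silhouette (Euclidean) among
*admissible* solutions, ties to smaller k. A solution is inadmissible
when its smallest cluster holds fewer than max(2, 5% of patients): on
near-duplicate count profiles the raw silhouette is maximized by carving
single noisy patients into their own clusters (within-cluster distance
0 ⇒ silhouette → 1), and such micro-clusters carry no stratification
value. Inadmissible candidates remain in the diagnostics table with
their silhouette and inertia so the trade-off stays inspectable. Cluster
markers: per (cluster, feature), one-sided "cluster > rest" — t test if
the feature's pooled values pass Shapiro–Wilk at α = 0.05, else
Mann–Whitney U — BH-corrected over all pairs, significant at adjusted
p < 0.05; clusters under 3 members are skipped. PCA uses the top-2
components of the scaled matrix with the sign convention that each
component's largest-magnitude loading is positive; rank-1 matrices get a
zero second coordinate.

## Synthetic study generator

The generator emulates the real study's inputs at desk scale with
planted truth. Defaults: 10 TFs with near-degenerate motifs (dominant
base count 97 of 100) of width 7–10; 20 disease SNPs (4 clusters × 4
cluster-specific SNPs + 4 cohort-wide); 40 patients (20 UC + 20 CD)
assigned round-robin to clusters within label; a 31-term, 3-level
ontology (root, 5 branches, 25 leaves, one cross-link) with 2 leaf
annotations per TF; a 160-gene corpus (6 genes per annotated leaf plus
10 unannotated) driving two DEG tables whose planted enriched terms are
split across tissues so the union is exercised; and a 150-SNP null pool
of which ~60% perturb a random TF pair (a fully motif-neutral pool would
make every permutation statistic identically zero and the nulls
degenerate) and the rest are verified motif-neutral.

Each disease SNP embeds one TF's consensus ending at the SNP (last base
= non-risk allele ⇒ binding lost on the risk allele) and another TF's
consensus starting at it (first base = risk allele ⇒ gained); the
embeddings share only the SNP base. Filler sequence is redrawn
(rejection sampling, verified with the package scanner) until exactly
the planted calls hold, so planted truth is guaranteed by construction
rather than probabilistically. Genotype noise flips carrier status with
a configurable rate; the acceptance checks use 1%, the upper end of
SNP-array genotyping error — real arrays are typically below 0.5%.

Expected per-stage record counts are computed by a *self-contained*
re-implementation of the set algebra, similarity, reduction and
enrichment arithmetic inside the generator, independent of the pipeline
modules, and serve as the oracle for the cross-product law and the
filter cascade.

What the fixture does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, chromatin context, annotation noise, or motif
redundancy between TF families. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration, not predictive
accuracy on real cohorts.

## Problem sizes and determinism

Default analysis sizes (20 disease SNPs, 150-SNP pool, 40 patients,
n_perm 200 in the examples, 1000 by configuration default) keep a full
run around a second and the acceptance recomputation well under a
minute; they are desk-scale choices, and every size is configurable
upward. All outputs are sorted before writing; identical inputs, config
and seed give byte-identical files, and a stage whose manifest carries
the current config hash is skipped on re-run.

## Known limitations

* Sequence-only TF binding prediction: no chromatin accessibility or
  epigenetic weighting; motif hits overpredict in vivo binding.
* The REVIGO approximation is greedy and uses the run's own annotation
  corpus, not GOA background frequencies; exact replication of REVIGO
  output is not attempted.
* The normal-tail p-values of the permutation z-scores are an
  approximation; empirical rank p-values are emitted alongside.
* Indels, multi-allelic variants and genotype imputation are out of
  scope; multi-allelic records are skipped with a count.
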