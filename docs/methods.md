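# Methods

## The Cq generative model

`erenorm.simulate.generate_cq_dataset` draws quantification-cycle values
from an explicit model of an RT-qPCR experiment. For sample `s` in group
`g`, target `t` and replicate well `r`:

    Q_{s,t}    = FC_{g,t} · 2^{u_s} · 2^{b_{s,t}}
    Cq_{s,t,r} = c_t − log_{F_t}(Q_{s,t}) + ε_{s,t,r}

* `FC_{g,t}` — designed group fold change (default 1);
* `u_s ~ N(0, σ_content)` — a per-sample mRNA-content factor shared by all
  targets. This is the nuisance variation normalization exists to remove:
  a perfect reference set cancels it exactly;
* `b_{s,t} ~ N(0, σ_bio,t)` — target-specific biological variability,
  log-normal on the log2 scale so that geNorm's log-ratio statistics see
  Gaussian noise. A "stable" target is one with small σ_bio and no fold
  changes (threshold 0.25 log2 units for the inferred flag);
* `ε ~ N(0, σ_tech)` — independent per-well technical noise, in cycles.
  Technical replicates share `Q_{s,t}` and differ only through ε,
  mirroring replicate wells of one cDNA;
* `F_t` — per-cycle amplification factor (2.0 = 100% efficiency), `c_t`
  the baseline Cq at `Q = 1`.

What the generator does **not** emulate: amplification-curve shape (Cq
values are produced directly, not from fluorescence), inhibition,
pipetting outliers, inter-plate calibration and biological pooling
effects. Passing tests therefore demonstrate correctness of the analysis
chain on its stated model, not robustness to raw-signal artifacts.

`make_dilution_series` produces standard curves
`Cq(q) = top_cq − log_F(q / q_max)` over the four-fold ladder
16 → 0.0625 ng, the conventional design for efficiency estimation.

## Planted-repeat sequence sets

`generate_repeat_sequences` builds a random genome and transcript set
with planted copies of a random consensus. Copies are point-mutated at a
per-base substitution rate (no indels — the aligner's ungapped model is
exact for this process), placed in non-overlapping slots with a minimum
gap, about half reverse-complemented. Transcript copies are confined to
the final third of the transcript, emulating repeat instances in 3'
untranslated regions. Truth records carry 0-based half-open coordinates
and realized per-copy identity; per-copy identity is binomial, so the
mean identity of many copies concentrates at `100·(1 − rate)` percent.

## Quantification conventions

Replicates are collapsed by arithmetic mean **on the Cq scale** (the
near-Gaussian scale; replicate SD is retained as quality metadata).
Relative quantities are referenced per target to the minimum Cq,
`Q = F^(minCq − Cq)`, keeping `Q ∈ (0, 1]`; only ratios matter downstream,
so the reference point is irrelevant to the stability statistics.
Efficiency-corrected Cq values from per-well tools are accepted by
treating them as Cq with `F = 2`; per-target standard-curve efficiencies
and the fixed `F = 2` path are both supported, selected simply by what is
passed to `cq_to_relative_quantity`. Efficiencies outside 90–110% are
flagged. Missing cells are a hard error by default (the stability
analysis requires a complete matrix; silent imputation would corrupt M);
an explicit `missing="drop"` policy removes incomplete samples instead.

## geNorm statistics

Pairwise variation is the sample SD (n−1 denominator, as in the original
implementation) of the log2 ratio of two targets across samples; the
stability value M is its mean over partners; ranking proceeds by
stepwise exclusion of the argmax-M target, ties broken toward the later
input position (deterministic; the choice is arbitrary but documented).
The final two targets cannot be separated — with two targets both M
values equal their pairwise variation — and are reported as a tied top
pair in input order. Both the per-round M trajectory and each target's M
at exclusion are reported. Categories: M < 0.2 "very-high", M < 0.5
"high", otherwise "low". Normalization factors are geometric means of
the top-n targets; `V_{n/n+1}` is the SD of `log2(NF_n/NF_{n+1})` and the
optimal reference count is the smallest n with `V_{n/n+1}` below the
0.15 default cut-off (configurable), falling back to the full panel with
a flag when the curve never crosses it.

Numerical choices: log base 2 throughout (cycle-scale interpretability);
all log-ratio statistics are computed on within-sample quotients
additionally referenced to the first sample — algebraically a constant
shift that an SD ignores, but it makes per-sample and power-of-two
per-target rescalings cancel *bit-exactly* in IEEE-754 arithmetic.
`V_{n/n+1}` uses the identity
`log2(NF_n/NF_{n+1}) = (1/(n(n+1))) Σ_{i≤n} log2(Q_i/Q_{n+1})`, which
needs only within-sample target ratios; the direct NF-based formula is
used as the independent oracle in the tests. Exact invariance under
arbitrary (non-power-of-two) factors is impossible for any
implementation, because the scaled matrix itself is rounded; those
scalings are verified to 1e-9 with identical rankings.

## Rank aggregation

The consensus ordering minimizes `Φ(δ) = Σ_i d(δ, L_i)` where `d` is the
weighted Spearman footrule `Σ_t w̃_i(t)·|r_δ(t) − r_i(t)|`. Weight
convention: per list, raw M-values are min-max inverted,
`w̃ = (M_max − M)/(M_max − M_min)`, so the most stable target carries
weight 1 and a constant weight vector reduces to the unweighted footrule.
Published descriptions of weighted-footrule aggregation are ambiguous
about the exact variant (weights by element vs by position); the formula
above is this package's contract and is oracle-tested self-consistently
rather than claimed identical to any external tool.

Borda count (ascending mean rank; ties by ascending mean raw weight,
then input order) provides the baseline and the starting point. The
cross-entropy optimizer keeps an item×position probability matrix,
initialized as an equal blend of uniform and the Borda permutation;
each iteration samples `N = 100·n` permutations by sequential position
sampling without replacement, and relaxes the matrix toward the elite
fraction ρ = 0.1 with smoothing λ = 0.1 (standard cross-entropy practice,
sized for panels of ~20 targets). The incumbent best permutation is
re-injected into every pool, so `Φ(δ*) ≤ Φ(Borda)` always holds; the run
stops after 10 iterations without improvement or 100 iterations. A
single-target universe returns trivially with Φ = 0. Exhaustive search
(`brute_force_aggregate`, ≤ 8 targets, lexicographic tie-break) is the
oracle: on every tested universe of ≤ 6 targets the optimizer attains
the exhaustive minimum.

## Discovery

The screen is the classic repeat-library workflow: genomic copy number,
expressed-hit count per transcript collection (a transcript counts once
however many hit segments it contains — the unit of interest is the
expressed locus), and mean conservation rate of the hits, filtered with
strict inequalities at copies > 100, combined hits > 30, conservation >
85%. Conservation can be recomputed from transcript hits (default) or
genomic hits; the source is recorded in the output.

Search is a self-contained seeded aligner rather than an external BLAST
dependency: exact k-mer seeds (k = 11) define subject diagonals; on each
diagonal the best-scoring ungapped segment (match +1, mismatch −2,
Kadane's algorithm) becomes a hit; hits under 70% identity or 50 bp are
discarded; hits on one subject and strand overlapping a better hit by
more than half the shorter hit are merged (keeping the best identity).
The ungapped model is exact for the substitution-only mutation process
the generator emulates and deterministic at desk scale; end bases of a
copy that fall outside the max-scoring segment may be trimmed. For real
data an adapter ingests standard 12-column tabular hits from any
external aligner. The conserved region used as primer template is the
fixed-length consensus window maximizing summed per-position hit
identity (coverage × mean identity), earliest window on ties.

## Comparison and reporting

Fold changes of a gene of interest divide its quantity by the per-sample
normalization factor (geometric mean over the reference set) and compare
group summaries — geometric means by default, arithmetic by option (the
two orders of averaging replicate pools differ only in that choice). On
noiseless data the measured fold change obeys the ratio law
`FC_measured = FC_true(goi) / geomean_ref FC_true(ref)`, which is the
quantitative statement of normalization bias. Group stability is
compared with an equal-variance two-sample t-test on M-values; "spread"
is operationalized as the same t-test on absolute deviations from each
group's median (a Brown–Forsythe-style contrast), since plain variance
tests are fragile at panel sizes of ~10 per group. Only the two planned
contrasts are computed, so no multiple-testing correction is applied.

## The demonstration study

`erenorm.demo` packages a six-experiment design (developmental time
series 0 hpf–12 dpf with 3 pools per stage, 7 adult organs × 2 fish, two
morpholino injections and two compound treatments with 3 pools per arm;
2 technical replicates, σ_content = 0.5, σ_tech = 0.1 cycles) over a
20-assay panel — 10 ERE targets and 10 classic genes with their
published standard-curve efficiencies (91.2–109.5%). Designed biological
SDs encode the study structure: ERE targets 0.10–0.22 log2 units
(hatn10 lowest, sine3 the weakest ERE), classic genes 0.55–1.3 in the
developmental/organ settings and ~0.25 under the milder perturbations,
gapdh worst overall. Three classic references additionally shift between
the maternal and zygotic stages (gapdh 10×, bactin2 6×, elfa 5×;
geometric mean 6.69), chosen once from the ratio law so the designed
20-fold *zorba* contrast reads as ~3-fold under classic-gene
normalization; the organ panel gives the same three genes modest eye
enrichment (geometric mean 1.69) so the 1.25-fold *pax6a* eye/brain
contrast flips sign under classic normalization. These sizes keep the
whole six-experiment run and its report generation in the order of
seconds.

## Problem sizes and determinism

Every generator and the cross-entropy optimizer take explicit seeds;
given a seed, all outputs (including written report bytes) are
reproducible. The test suite and the acceptance script use desk-scale
sizes — 5×8 to 21×30 Cq matrices, 100-run recovery experiments, genomes
of 36–100 kb with 60–150 planted copies — chosen so the full pipeline
remains interactive while leaving comfortable statistical margins (e.g.
the mean identity of 150 planted copies has a standard error of ~0.1
percentage points).

## Known limitations

* The aligner is ungapped: indel-diverged repeat copies would be
  fragmented or missed; use the tabular adapter with an external aligner
  for real genomes.
* geNorm's last two targets are inherently tied; downstream consumers
  needing a total order receive the tied pair in input order.
* The cross-entropy optimizer guarantees improvement over Borda, not
  global optimality for large universes (it is oracle-verified optimal on
  small ones).
* The spread t-test on absolute deviations is approximate for very small
  groups; it is reported alongside medians and IQRs rather than instead
  of them.
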