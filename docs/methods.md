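# Methods

## The inference problem

Two rodent models carry reduced AHR activity — a knockout mouse and a rat
strain whose receptor variant confers striking dioxin resistance. Genes
under constitutive (ligand-free) AHR control should differ in baseline mRNA
abundance between AHR-active and AHR-less-active animals, and genes under
*core* control should do so in most tissues of both species. The pipeline
formalizes that chain: per-study differential abundance, cross-species
alignment, multi-study set statistics, and three lines of regulatory
corroboration (response-element motifs, ChIP binding, ontology coherence).

## Per-study model

Each study is a normalized log₂ matrix (genes × arrays) with a two-level
genotype factor. The gene-wise model is

    Y_gij = mu_g + alpha_gi + eps_gij,   eps_gij ~ N(0, sigma_g^2)

fit by least squares; the contrast of interest is
`M_g = mean(less_active) − mean(active)`, so genes up-regulated when the
receptor is less active carry **positive** M (the direction in which most
core-battery candidates move). Pooled within-group variances s²_g with
d_g = n₁ + n₂ − 2 degrees of freedom are shrunk toward a prior by the
standard empirical-Bayes scheme: s²_g is modelled as s₀²·F(d_g, d₀), the
prior (d₀, s₀²) is estimated by moment-matching the mean and excess
variance of log s²_g (digamma/trigamma corrections; the trigamma inverse is
solved by Newton iteration), and the posterior variance is

    s~2_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g).

When the log-variances show no excess dispersion the prior degrees of
freedom are infinite and every posterior variance equals s₀². The
moderated statistic t = M / sqrt(s̃²(1/n₁ + 1/n₂)) is referred to a t
distribution with d_g + d₀ df (normal at d₀ = ∞), two-sided, and adjusted
by Benjamini–Hochberg; significance means q < 0.05 unless stated.

Numerical choices: genes with zero pooled variance are floored at
machine-epsilon times the largest observed variance before moderation (an
all-zero-variance study is an error, with instructions to add
pseudo-variance); BH is delegated to `statsmodels.multipletests`.

### QC and stability

Arrays are screened by median Pearson correlation to the rest of the study
(default threshold 0.8; constant arrays are flagged outright). This
operationalizes the criterion actually acted on in practice — failure to
normalize with the cohort — rather than a clustering visualization. The
leave-one-out check removes one array of a group at a time, refits the
whole pipeline, and compares removals by Kolmogorov–Smirnov distance
between the per-removal **p-value** distributions. q-vectors are returned
too, but the KS distance is deliberately computed on p: BH q-values are a
running minimum whose null distribution collapses to a near-point mass, so
a KS distance between q-vectors saturates on location jitter alone and
carries no stability information.

## Homology alignment

Per-species gene→HID tables are cleaned by removing genes with no HID and,
by default, *every* member of a within-species many-to-one HID group
(`drop_all`). Keeping one representative would require an arbitrary probe
choice; the alternative `keep_first` policy exists behind a flag. The
analysis universe is the intersection of the cleaned per-study HID sets —
a single shared N is what makes the hypergeometric tests across studies
coherent.

## Set statistics

*Pairwise overlap.* For significant sets A, B on universe N:
expected = |A||B|/N, enrichment ratio = observed/expected (0 when the
overlap is empty), p = P[X ≥ observed] for X ~ Hypergeometric(N, |A|, |B|),
BH-adjusted across all study pairs in the run (10 pairs for 5 studies).
This arithmetic reproduces every printed (observed, expected, ratio)
triple it is checked against, e.g. (98, 36, 2.7) at sizes 1,187/316 on
N = 10,445.

*Multi-set bootstrap.* Under the null each significant set is a uniform
draw of its size from the universe. Rather than materializing sets, the
default path samples only the running intersection size — intersecting a
running intersection of size c with the next set of size nᵢ draws
Hypergeometric(N, c, nᵢ) — which is exact in distribution and handles 10⁶
replicates in seconds; direct set sampling remains available and is
checked against it (KS agreement). The reported p uses the strict
"greater than observed" counting rule, reported as `< 1/reps` when no
replicate exceeds; the conventional (#{≥ observed}+1)/(reps+1) pseudocount
estimate is also returned. The permutation mean converges to
N·∏(nᵢ/N).

*Core battery.* A gene (HID) enters the battery when significant in at
least `min_studies` (default 4) studies. Direction classes: `consistent`
(all significant M one sign), `species_divergent` (sign constant within
species, differing between), else `tissue_variable`. Rows are ordered by
decreasing mean |M| across all studies; using all studies rather than only
significant ones keeps the ordering stable when a gene just misses a
threshold in one tissue.

*Direction consistency.* One-sample, one-sided proportion test of the
share of signed observations in the expected direction against 0.5; both
the exact binomial tail and the continuity-corrected chi-square variant
are reported, with a one-sided exact (Clopper–Pearson) 95% interval.

## Motifs and conservation

Four AHRE patterns are compiled from a small grammar (exact bases, `N`,
`[X|Y]`, `{Nk}` gaps) into positional base classes: core GCGTG (5 bp),
extended TNGCGTG (7 bp), full [T|G]NGCGTG[A|C][G|C]A (10 bp), and the
gapped AHRE-II CATG{N6}C[T|A]TG (14 bp, positions 5–10 unconstrained).
Windows are [TSS−3000, TSS+3000), 0-based half-open. Both strands are
scanned by default (the core pentamer is not its own reverse complement,
so strand choice matters; a flag restricts it); overlapping matches all
count, and the {N6} gap is fixed-length. A hit's conservation score is the
arithmetic mean of the per-base track over the whole footprint, gap bases
included — the aggregation had to be fixed somewhere, and the mean keeps
scores in [0, 1] with a perfect-conservation hit scoring exactly 1.
Per-gene summaries expose both mean and max aggregation. Class
comparisons report, per motif and count threshold (1, 2, 3+), the fraction
of significant vs non-significant genes carrying at least that many hits.

## ChIP binding

Probes are assigned to every gene whose TSS±1 kb interval they overlap;
unassigned probes are dropped. Each probe's replicate log-ratios are
tested one-sample, one-sided against zero ("preferential binding"; the
original contrast's exact null is not recoverable, so this choice is
documented rather than asserted). Zero-variance probes: positive mean →
limit p = 0 with a warning; otherwise p = 1. Multiple probes per gene
collapse to the **minimum** p — a deliberately liberal rule; its
inflation of the per-gene null rate (one minus the product of per-probe
non-rejections) is visible in the synthetic calibration and is why
set-level *comparisons* of fractions, not their absolute values, carry the
signal. A gene is bound at p < 0.05 (flag-adjustable) and a set's binding
fraction is #{bound}/|set|. Fractions are reported per direction stratum
(up / down / non-significant) and as 2×2 row proportions against an
externally supplied ligand-responsive gene list; in the synthetic pipeline
that list is the planted bound-gene set, standing in for a treated
contrast.

## Ontology enrichment

Terms form a rooted DAG (child→parent edges); a term's gene set is the
union of its own and all descendants' direct annotations, so ancestor sets
always contain descendant sets. Terms annotating fewer than 5 universe
genes are excluded. Enrichment is the upper-tail hypergeometric
probability; the FDR at a term's p is estimated from `n_perm` (default
1000) random same-size gene sets: mean null count of terms at or below
that p, divided by the observed count, capped at 1. The default reporting
threshold is FDR < 0.01, with the stricter 0.001 available as a parameter
(both appear in practice and the tooling exposes the choice). Significant
terms are traced along parent links to their root(s); full root-ward paths
are available. This permutation scheme approximates the behaviour of the
classical web tooling for this task; it is not a clone of any tool.

## The synthetic generator

The generator emulates the study design at the *normalized-matrix* level:
five studies (rat liver/adipose/hypothalamus, mouse kidney/liver), n = 4
per genotype group, 2,000 genes, a 20-gene planted battery with a
1.0 log₂ shift (inside the fold-change range reported for constitutive
receptor targets) against i.i.d. Gaussian log₂ noise of sd 0.5, with a
configurable fraction (default 0.2) of battery genes flipping sign in the
second species to emulate species-clustered fold-change patterns. Group
sizes in the emulated studies ranged 3–6 and are configurable per study.
Homology tables map 90% of genes, with 5% many-to-one collisions.
Promoters are uniform-random ACGT with planted motif realizations at
recorded offsets/strands; conservation is Beta(1,3) background and
Beta(8,1) over planted footprints — arbitrary, chosen only to separate the
score distributions. Binding probes carry 3 replicates at shift 1.0, sd
1.0 for bound genes (the battery plus a 5% background). All randomness
derives from one seed through fixed `SeedSequence` spawn keys, one stream
per artifact, so outputs are byte-reproducible and any artifact can be
regenerated alone.

What it does **not** emulate: probe-level microarray structure and RMA
normalization (all analyses start post-normalization), batch effects,
gene–gene correlation (the models are gene-wise), RNA degradation, and
realistic promoter composition (no GC skew, repeats, or positional motif
preferences). Passing tests therefore demonstrate correctness of the
statistical machinery under its stated assumptions, not robustness to
real-data pathologies.

## Problem sizes and calibration findings

The test suite runs studies of 100–10,000 genes; the acceptance script
uses the published set sizes (1,187/318/316 on N = 10,445) for the overlap
and bootstrap arithmetic, a 10,000-gene null study for type-I calibration,
and the default synthetic conditions for battery recovery.

A power note on those defaults: with noise sd 0.5 and n = 4/4 the standard
error of M is 0.354, so a planted 1.0 log₂ effect has noncentrality ≈ 2.8,
while the BH cutoff at q < 0.05 with ~20 true among 2,000 genes sits near
p ≈ 5·10⁻⁴. Per-study power is then ~0.1–0.25 and the probability of
clearing 4 of 5 studies is negligible — the default-condition battery
sensitivity the acceptance script reports is honestly ≈ 0. Recovering a
battery at these group sizes needs effects ≳ 1.8 log₂ (or noise ≈ 0.25),
which is why the worked example and the recovery unit tests use a
well-powered configuration (effect 2.5, sd 0.4) to validate the machinery
itself.

## Known limitations

- The strict homology de-duplication discards real signal carried by
  duplicated probes; `keep_first` trades that for an arbitrary choice.
- The min-p probe collapse makes absolute binding fractions
  threshold-and-coverage dependent; only contrasts between strata are
  interpretable.
- The permutation FDR is a ratio estimator and noisy for terms observed
  near the significance boundary at small `n_perm`.
- Bootstrap support for more than three sets exists but mirrors no
  reference output; the three-set case is the validated one.
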