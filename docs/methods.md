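# Methods

## The methylation time course being modelled

The analysis targets the mouse germline reprogramming window: E6.5
epiblast; migrating PGCs at E9.5, E10.5, E11.5 (mixed-sex pools); gonadal
PGCs at E13.5 and E16.5 (sexed). Methylation erasure is two-phase. Bulk
sequence loses methylation early and passively: without maintenance
methyltransferase activity at the replication fork, each division converts
fully methylated CpG dyads into hemimethylated ones and dilutes the
methylated-cytosine fraction by half. Sequences carrying epigenetic memory
— imprinted DMRs (50% methylated, one parental allele), X-linked CGIs in
female cells (one inactive, methylated X), and germline-gene promoter CGIs
— are actively maintained through the migration phase and erased only
after gonadal entry. IAP retrotransposons, and sequence in their immediate
context, resist erasure altogether. Male PGCs remethylate de novo by
E16.5; females, in meiotic arrest, stay hypomethylated.

## Synthetic-data generator

The generator produces the study conditions the analysis assumes, not a
replica of a real genome.

**Genome.** Chromosomes are user-sized (default three 3 Mb autosomes plus
a 1 Mb X). CpG dyads are placed with geometric spacing, mean 100 bp in
bulk sequence and 10 bp inside CpG-island-like features (CGIs, DMRs,
germline and X-linked CGIs), so island features are CpG-dense as in real
genomes. Coordinates are 0-based half-open; a dyad is indexed by its
top-strand C, and call tables keep the two strands of a dyad as separate
rows (bottom-strand C at position + 1). Feature placement is globally
non-overlapping (stricter than the per-class requirement) by rejection
sampling; an impossible request fails with a sizing error naming the
class. A configurable number of promoters is placed 0–4 kb from an IAP
copy to emulate IAP-context protection.

**Trajectories.** Each feature class has a policy: initial fraction,
optional erasure stage (protected until then, 0 from then on), a
resistance flag, and a de novo exemption. Defaults: bulk/exon/intron 0.71
(epiblast-like), LINE1 0.80, ordinary CGIs 0.15, DMRs 0.5 and germline
promoter CGIs 0.75 erased at E13.5, X-linked CGIs 0.5 scaled by the
sample's sex composition (female 1×, mixed ½×, male 0 — a mixed pool
carries inactive X chromosomes from only its female half), IAPs 0.90 and
resistant. Unprotected classes follow exact passive halving,
initial × 2^−divisions. Cumulative divisions per stage are configuration
(default 2 per stage interval); the literature gives no exact PGC
cell-cycle counts. E16.5 male samples raise every non-exempt class to the
de novo target (default 0.5). Promoters and CGIs within the IAP protection
radius (default 2 kb) are pulled toward the IAP level in proportion to
1 − d/radius, which makes resistance decay smoothly with distance.

**Observation model.** Coverage per CpG strand is Poisson with half the
sample mean (matching the dispersion of shallow whole-genome bisulfite
data well enough for testing); methylated counts are binomial at the
apparent rate m + (1 − m)·ε, where ε is the bisulfite conversion-failure
rate (default 0.002). CHH cytosines have true methylation 0, so all CHH
signal is conversion failure — the basis of the conversion-efficiency
control. Replicates differ only by derived seeds; all generators are
byte-deterministic given a seed.

**What the generator does not emulate** — and therefore what passing
tests cannot show about real data: sequence-specific CpG density and
composition, per-CpG heterogeneity within a class (each CpG sits exactly
at its class level, so between-feature variance is purely sampling),
partially methylated domains, 5hmC (indistinguishable from 5mC in
bisulfite data anyway), mapping and PCR artefacts, and variably erased
CGIs as a distinct class: under the default profile the only E13.5
resistance is IAP-borne, so the VEC caller returns an empty set on default
output and is exercised on constructed matrices instead.

## Quantification choices

Within a probe or feature, methylation is read-count weighted:
100·Σmeth/(Σmeth + Σunmeth) over contained cytosines, both strands of a
dyad included. Across probes, the global figure is the unweighted mean of
non-missing probe percentages (a median variant is available; which one
underlies the published global values is not stated). Cells with fewer
than 10 informative counts (20 CHH observations for 1 kb conversion
probes) are missing, never 0. "100% conversion" means literally zero
methylated CHH counts in a qualifying probe, not a rounded percentage.
At ε = 0.002 and ~200 CHH observations per 1 kb probe, the expected
fully-converted fraction is (1 − ε)^200 ≈ e^−0.4 ≈ 0.67, comfortably
above the 60% benchmark for adequate conversion. CpG-density association
uses the Pearson product-moment correlation on per-probe CpG counts.

## Classification choices

Thresholds are strict as worded: "> 25%" and "< 2 kb". Classification
operates on per-stage replicate medians. X-linked CGIs in mixed-sex pools
sit at an expected 25% — exactly the selection boundary — so the late
demethylater rule recovers them reliably only in sexed (female) series;
this mirrors the elevated-but-intermediate epiblast observation. The VEC
definition has no principled numeric "variability" cutoff, so the caller
reports resistance/IAP logic plus a continuous per-feature methylation
range and a sex-bias sign rather than a binary "variable" call. Flanks in
the core-vs-flank contrast default to 2 kb per side, clipped at chromosome
ends. Overlap enrichment is a hypergeometric upper-tail test on a
selected-vs-background 2×2, with an undefined-ratio flag when the
background carries no sites.

## Dilution model

States are per-dyad {M, H, U}, hemimethylation pooled over strands (strand
detail lives in the hairpin module). One division is, in population
expectation over both daughters: an M dyad's daughters each inherit a
methylated template and are M with probability p_m, else H; an H dyad's
methylated-strand daughter behaves likewise while the other daughter is H
with probability p_d, else U; a U dyad's daughters are H with probability
p_d, else U. Active removal then strips each methylated cytosine
independently with probability p_a (M→H at 2p_a(1−p_a), M→U at p_a²,
H→U at p_a). Replication-then-removal ordering is a modelling choice; no
ordering is implied by the biology. The composite is a fixed 3×3
stochastic matrix, so the step is linear on the simplex, and with
p_m = p_d = p_a = 0 the methylated-cytosine fraction halves exactly per
division.

Fitting maximizes the multinomial log-likelihood of observed (M, H, U)
counts at successive timepoints, taking the first timepoint's empirical
distribution as the initial condition. A vectorised grid (default step
0.02 per free parameter) is scanned, then the optimum is polished with
bounded Nelder–Mead; the likelihood profile along p_m (maximized over the
other parameters) is reported. With 10⁴ dyads over 4 timepoints, p_m is
recovered within ±0.05 across seeds. p_m and p_a trade off only weakly at
these sizes, but nuisance parameters can be pinned via `fixed=` when the
experiment warrants it.

## Hairpin strand analysis

Passive loss predicts that within a hemimethylated molecule every
methylated CG sits on the parental template strand: the joint
(k_top, k_bottom) distribution has all mass on the axes. Strand-independent
active removal scatters meCGs over both strands, giving a symmetric joint;
a read with k hemimethylated dyads is single-strand-confined with
probability 2·(1/2)^k. Reads are compared to simulated passive and active
nulls by total-variation distance between normalized joints (the published
comparison is visual; TV is a simple, symmetric, bounded choice), and the
verdict is the nearer null, with exact ties reported indeterminate.
Molecules with no hemimethylated dyads land in cell (0, 0) and are
excluded from the confined-fraction denominator; missing positions are
dropped per read, never imputed.

## Expression dynamics

Profiles are standardized per gene (zero mean, unit variance across
samples), clustered by average linkage on correlation distance, and cut at
1 − similarity (default similarity 0.8); clusters below the minimum size
(default 2) are discarded and genes are pre-sorted by id so the outcome is
order-independent. The cluster count is data-dependent, not a contract.
The planted pluripotency-like cluster peaks at E11.5 and declines into
E16.5; the meiosis-like cluster rises from E13.5 with female gonadal
samples highest. Background genes carry constant per-gene baselines with
15% multiplicative noise — chosen so transcriptome complexity (band
occupancy over log10 expression) is stable across stages, the study's
design condition; note that with only 8 samples, random background
profiles frequently exceed 0.8 correlation by chance, so small spurious
clusters among background genes are expected and recovery is judged on
planted genes. Methylation–expression association uses Spearman rank
correlation (robust to the heavy right tail of expression); the de novo
gain comparison between up- and down-regulated genes uses a two-sided
permutation test on the group-mean difference.

## Problem sizes and tolerances

The default demo pipeline runs a 10 Mb genome with 8 samples at 20× mean
coverage (seconds to a few minutes on one CPU); the test suite uses
0.8–2.6 Mb genomes at 30–100× so binomial sampling error stays small
relative to the 25-percentage-point decision threshold. Stochastic
assertions use explicit sampling-error bounds (4–6 standard errors) with
fixed seeds. Dyad-state distributions are validated to sum to 1 within
1e−9; the halving law is asserted to 1e−12.

## Known limitations

Class-level (not per-CpG) truth understates biological variance;
conversion failure is the only error mode (no over-conversion of 5mC, no
mapping bias); the dilution model assumes homogeneous rates across sites
and divisions; the hairpin simulator draws dyad states independently
across positions, ignoring the spatial correlation real molecules show;
X-chromosome dosage is modelled at the methylation level only. These are
the places where conclusions drawn from synthetic runs transfer least
directly to real libraries.
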