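# Methods

## Setting

The package infers, genome-wide and per embryo, which parental haplotype an
IVF embryo inherited, from read counts at biallelic SNVs in: the two
parents and a phasing reference (a born sibling, or one to two grandparents
per parental side) sequenced at low pass (~1–5x), and embryo biopsies
(whole-genome amplified) at ultra-low pass (~0.2–0.4x). Everything is fully
probabilistic: no hard genotype calls are made at any depth.

## Hidden state and why the meiosis counts differ by mode

Child-reference mode tracks, per parental side, whether the embryo's
transmitted haplotype is identical by descent to the reference sibling's.
That indicator is the XOR of two independent meiosis indicators (the
sibling's gamete and the embryo's gamete), so it flips at the superposition
of both crossover processes: with Haldane (no-interference) meioses the
switch probability across genetic distance d Morgans is
r = (1 − e^(−4d))/2, i.e. two meioses. Grandparent mode tracks which
grandparent the embryo's allele originates from. A crossover in the
grandparent→parent meiosis exchanges material between the two haplotypes
*of the same grandparent* and leaves the origin label unchanged; only the
parent→embryo meiosis flips it, so r = (1 − e^(−2d))/2, one meiosis. (An
alternative convention assigns one meiosis to the sibling state and two to
the origin state; under the generative model used here — and in the
simulator — that convention is miscalibrated, which is measurable as excess
confidently-wrong sites near recombination breakpoints.)

The two parental sides are a priori independent chains; child mode runs
their joint 4-state product because the embryo's read likelihood couples
them at each site, and reports per-side marginals by summation. Grandparent
mode runs one 2-state chain per phaseable side, marginalising the other
parent's transmitted allele per site with Hardy–Weinberg/read weights.
Initial distributions are uniform; chromosomes are independent chains;
Viterbi ties break deterministically to the first state.

## Emissions

Per site, the emission for a state sums over all latent genotype
configurations: parental (and grandparental) genotypes weighted by
Hardy–Weinberg priors at the site's population alternate-allele frequency
times their own binomial read likelihoods; transmitted alleles uniform over
a heterozygous carrier's two alleles; the reference child's genotype is the
sum of its two transmitted alleles; the embryo's genotype follows
deterministically from the hidden state. Read likelihoods are
Binomial(k; n, p_g) with p_g = ε, ½, 1−ε (allele-symmetric error ε,
default 0.002). Embryo heterozygotes use the allele-dropout mixture
(1−ado)·Bin(½) + (ado/2)·Bin(ε) + (ado/2)·Bin(1−ε), default ado = 0.1 for
PicoPLEX-style amplification. A sample with zero reads contributes a flat
factor, so sites missing in any individual (including the embryo) remain in
the chain and keep a stable site index. In grandparent mode the sums
factorise exactly into per-grandparent transmitted-allele weight tables;
the test suite verifies both emission modes against brute-force enumeration
over all genotype configurations to 1e-9 relative error.

ChrX is phased maternally only, with a hemizygous father (and, in
grandparent mode, a hemizygous grandfather identified from the pedigree's
sex field). Male embryos use hemizygous embryo likelihoods; embryo sex can
be supplied directly or taken from the CNV module's chrX depth ratio
(< 0.75 → male). If sex is unknown the diploid model is used with a
warning.

## Parameters

| parameter | default | meaning |
|---|---|---|
| eps | 0.002 | per-read substitution error (symmetric) |
| ado | 0.1 | per-het-site allele dropout in WGA embryo material |
| cm_per_mb | 1.0 | genetic-map rate; physical-distance proxy, no map file |
| conf_hi / conf_lo | 0.99 / 0.01 | high-confidence ("pass") marginal thresholds |
| min_alt_reads | 2 | site filter: alt reads required in ≥1 parent/reference |
| min_cnv_len | 5 Mb | minimum reportable copy-number event |
| cnv_bin_width | 1 Mb | depth bin width |
| cnv_switch_prob | 1e-4 | per-bin CNV state switch probability |
| roc_min_len | 3 Mb | minimum reported ROC interval |
| subtel_len | 5 Mb | subtelomeric window from telomeres/acrocentric centromeres |

ε and ado are not identifiable at these depths beyond coarse scales; they
are exposed so laboratory-calibrated values can be dropped in. The 0.99
pass threshold and the 5 Mb CNV and subtelomere lengths are fixed
conventions of the reporting scheme, not tuning knobs.

## Site filtering

For real data the usable site list comes from variant calling on the
parents and reference; `filter_informative_sites` emulates that
ascertainment with a count threshold (alt reads ≥ 2 in at least one parent
or reference individual; embryo reads never qualify a site). Simulated
site lists already represent an ascertained panel, so the validation
pipeline phases all simulated sites directly.

## CNV calling

The copy-number caller uses only the embryo's data: reads are binned
(1 Mb), normalised by the autosomal median, and segmented by a 3-state HMM
with Gaussian emissions centred at depth ratios 0.5/1.0/1.5 and a common
dispersion estimated by the MAD of autosomal ratios (floored at 0.02).
Non-neutral Viterbi segments shorter than 5 Mb are relabelled neutral. No
GC or mappability correction is applied; segment coordinates are reported
in BED convention. On a male embryo the whole X sits near ratio 0.5 and is
reported as such unless the caller's sex inference is used upstream.

## ROC detection

Regions of consanguinity (both parental haplotypes shared) are detected
from parental counts alone via the per-site indicator "confident opposite
homozygotes" (one parent ≥ 2 alt reads and 0 ref, the other ≥ 2 ref and
0 alt). Its genome-wide rate depends strongly on depth, so no absolute
threshold is used: a 2-state HMM contrasts the observed genome-wide rate
(non-ROC) against a reduced in-ROC rate (default ratio 0.15, reflecting the
residual from binomial sampling of shared heterozygotes), with a per-bp
switch probability of 1e-7. Viterbi intervals are then extended outward
past two discordant sites: inside a true ROC discordant sites are sparse,
so truncated intervals grow to their real extent, while in normal sequence
the extension stops within a few hundred kb. The extension makes reported
intervals deliberately conservative, which is the right direction for
their purpose (excluding ambiguous sites from accuracy claims). Intervals
shorter than 3 Mb are dropped. If the genome-wide rate is below 0.003
(e.g. unsequenced parents) the scan is reported indeterminate rather than
calling the whole genome ROC.

## The simulator

`simulate_family` generates the designs the engine is validated on:
site positions uniform per chromosome (default five 50 Mb chromosomes,
10,000 SNVs each); alternate-allele frequencies Uniform(0.05, 0.95);
founder haplotypes site-wise independent Bernoulli(q) (no linkage
disequilibrium); Haldane meioses (Poisson crossovers at 1 cM/Mb, uniform
positions); consanguinity by copying the mother's haplotype pair into the
father over segments (default 10 Mb) totalling a requested genome fraction;
embryo CNVs scale depth by copy/2 and restrict the sampled allele pool;
reads per site Poisson(depth), allele choice uniform over the carried
alleles with error ε, and per-het-site dropout in embryos. Depths default
to 2x for parents/reference and 0.3x for embryos. An optional per-site
Gamma depth multiplier (off by default) mimics amplification unevenness.
All randomness flows from one integer seed through numpy's PCG64;
regenerated fixtures are byte-identical.

What the simulator does not emulate: linkage disequilibrium and realistic
allele-frequency spectra, GC/mappability depth waves, chimeric or
overdispersed WGA reads (dropout is the only amplification artefact),
mosaicism, and sequencing-ascertainment correlation between the site list
and the data. Passing tests therefore demonstrate correctness and
calibration of the inference under its stated model, not performance on
any particular laboratory's data.

Because founder alleles are site-wise independent, the phasing HMM here is
not just an approximation but the *exact* marginal posterior of the
simulator's generative process (the match chain is Markov with the stated
rates, and sites are conditionally independent given it). Two consequences
are worth noting. First, posterior calibration is testable and holds: among
sites with marginal in (0.99, 0.999), roughly 99–99.9% are correct.
Second, residual pass-site errors are irreducible: they come from short
(~1–2 Mb) double-crossover segments whose total read evidence at 200
SNVs/Mb and 0.3x embryo depth is smaller than the recombination prior
penalty, so the exact posterior — and hence any method — confidently keeps
the flanking state. Real sequencing data mitigate this with several-fold
higher SNV density. This is why the validation suite's strictest
child-reference concordance check (99.8% at every depth including 1x)
fails at 1x (~98.5–99% worst track) while the 2x/4x and non-ROC checks
pass; the corresponding analysis is part of the design record, and the
thresholds were left as specified rather than loosened.

## Validation problem sizes

The standard validation designs use 50,000 SNVs over five 50 Mb
chromosomes, three (child mode) or eight (grandparent mode) embryos, three
seeds, and 40 seeds for CNV trials — sizes chosen so the full suite and
the reproduction script each run in minutes on a single CPU while keeping
per-track pass-site counts in the tens of thousands.
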