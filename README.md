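# famphase

Family-based haplotype phasing and copy-number calling for sequencing-only
comprehensive preimplantation genetic testing (PGT).

In linkage-based PGT, embryos produced by IVF are tested for inherited
disease variants without a variant-specific assay: instead, the laboratory
determines *which parental haplotype* each embryo inherited around the locus
of interest, using a relative (an already born child, or grandparents) to
anchor which haplotype carries the pathogenic allele. `famphase` implements
this inference for an all-sequencing design: low-pass (~1-5x) whole-genome
sequencing of the parents and the phasing reference, and ultra-low-pass
(~0.2-0.4x) sequencing of whole-genome-amplified embryo biopsies. It is
aimed at method developers and analysts who need a transparent, fully
probabilistic engine for genome-wide embryo haplotyping, aneuploidy
screening from the same data, and simulation-based validation.

## The model

At each biallelic SNV the data are per-individual reference/alternate read
counts. A hidden Markov model runs along each chromosome over the hidden
transmission state of an embryo:

- **Child-reference mode** — the state is the pair
  (maternal match, paternal match), where "match" means the embryo inherited
  the haplotype *identical by descent* to the one the reference sibling
  received from that parent (4 states, jointly, because the embryo's reads
  couple the two sides).
- **Grandparent-reference mode** — per phaseable side, the state is which
  grandparent the embryo's transmitted haplotype originates from (2 states).

Emissions marginalise over everything unobserved. With genotype
g ∈ {0, 1, 2} counting alternate alleles, a sample with *n* reads of which
*k* are alternate contributes Binomial(k; n, p_g) with
p_g = ε, ½, 1−ε for g = 0, 1, 2 (per-read error ε). Embryo material is
whole-genome amplified, so heterozygous genotypes use an allele-dropout
mixture: (1−ado)·Bin(½) + (ado/2)·Bin(ε) + (ado/2)·Bin(1−ε). Founder
genotypes carry Hardy–Weinberg priors at the site's population alternate
allele frequency; transmitted alleles are uniform over a heterozygous
parent's two alleles. Transitions follow Haldane's map function on physical
distance d (in Morgans via a constant cM/Mb rate): the per-side switch
probability is r = (1 − e^(−2·m·d))/2 with m meioses — m = 2 for the
sibling-match state (either gamete may recombine) and m = 1 for the
grandparent-origin state (grandparent-to-parent crossovers move between
haplotypes of the *same* grandparent).

Outputs per embryo, per parental side, per SNV: the **marginal** posterior
probability of the match/origin state (forward–backward), the **binary
prediction** (Viterbi path), and a **pass** flag for high-confidence calls
(marginal > 0.99 or < 0.01). ChrX is phased maternally only. Two companion
components run alongside: a 3-state depth HMM that calls copy-number
gains/losses ≥ 5 Mb from the embryo's binned read depth alone (also used to
infer embryo sex from the chrX depth ratio), and a detector for **regions of
consanguinity** (ROCs) — stretches where the parents share both haplotypes
and phasing is intrinsically ambiguous — from the parents' read counts.

## Worked example

Simulate a child-reference family (5 × 50 Mb chromosomes, 10,000 SNVs each,
parents and reference child at 2x, three embryos at 0.3x), phase it, and
score against the simulator's truth:

```python
from famphase import FamilyPhasingModel, ModelParams, SimConfig, simulate_family
from famphase.evaluate import evaluate_family

sim = simulate_family(SimConfig(seed=42))          # 5 x 50 Mb, 10,000 SNVs each
model = FamilyPhasingModel(sim.table, sim.pedigree, params=ModelParams())
results = model.fit(filter_sites=False)
print(results.summary().round(3).to_string(index=False))

report = evaluate_family(results.tracks, sim.truth)
print(report.round(4).to_string(index=False))
```

```
 embryo     side  n_sites  n_embryo_covered  prop_pass  prop_match
embryo1 maternal    50000             12959      0.912       0.728
embryo1 paternal    50000             12959      0.944       0.441
embryo2 maternal    50000             12733      0.917       0.593
embryo2 paternal    50000             12733      0.941       0.628
embryo3 maternal    50000             12957      0.874       0.512
embryo3 paternal    50000             12957      0.922       0.491
 embryo     side  n_considered  concordance stratum  prop_pass
embryo1 maternal         45591       1.0000     all     0.9118
embryo1 paternal         47214       0.9983     all     0.9443
embryo2 maternal         45845       1.0000     all     0.9169
embryo2 paternal         47064       0.9983     all     0.9413
embryo3 maternal         43709       1.0000     all     0.8742
embryo3 paternal         46098       0.9983     all     0.9220
```

Each row is one embryo/side track. `prop_pass` is the fraction of SNVs with
a high-confidence call (87–94% here); `concordance` is the agreement of the
dichotomised marginals with the true transmitted haplotype at those pass
sites (99.8–100%). `prop_match` reflects how much of the genome the embryo
happens to share with the reference sibling (~50% in expectation).

The same workflow is available from the shell:

```
famphase simulate --config sim.yaml --out fam/
famphase phase --counts fam/counts.tsv --pedigree fam/pedigree.yaml --out phased/
famphase cnv --bins bins.tsv --out cnv.bed
famphase evaluate --tracks phased/ --truth fam/truth_labels.tsv --out report.tsv
```

`famphase phase` also accepts a VCF with per-sample AD fields in place of
the allele-count TSV.

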