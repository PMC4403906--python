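# Methods

## Model and scope

`hhdkit` targets the situation where a recessive lethal segregates in a
population with deep paternal half-sib structure and where genotypes exist
essentially only for (healthy, adult) males and selection candidates. Because
homozygotes die before genotyping, the allele is detectable only indirectly:
as a haplotype with missing homozygosity among the genotyped, and as depressed
outcomes in matings between carrier bulls and daughters of carrier sires.

The package assumes phased, imputed, biallelic genotypes as input (statistical
phasing and imputation are upstream, out of scope), a pedigree with reliable
sire and dam links, and service/calving records keyed to the same identifiers.

## Expected homozygosity from male ancestors

Cows are mostly ungenotyped, so an animal's haplotype-homozygosity probability
is reconstructed from its genotyped male ancestry plus the population
frequency:

* paternal allele: the sire transmits each of his two chromosomes with
  probability ½, so P(paternal = h) = c_sire/2;
* maternal allele: the dam inherited her paternal chromosome from the
  maternal grandsire (transmitting with probability ½ · c_MGS/2) and her
  maternal chromosome from an ungenotyped granddam, approximated by the
  population frequency f_h — hence P(maternal = h) = ½·c_MGS/2 + ½·f_h,
  degrading to f_h when the MGS is unknown or ungenotyped.

Animals whose sire is ungenotyped are not scored at all: without the sire the
paternal term would collapse to f_h and the expectation would lose most of its
information. Dam genotypes, when they exist, are deliberately not used by
default (the contract targets the male-ancestor data regime); this is the main
approximation of the expectation model.

## The deficit test

Given per-animal probabilities p_1…p_n, the homozygote count is a sum of
independent, non-identical Bernoulli trials — a Poisson-binomial variable.
The reported P is its exact lower tail P(X ≤ O), computed by convolving the
binomial PMFs of groups of equal p_i, truncated at O+1 terms (truncation is
exact for the lower tail). A pooled alternative, Binomial(n, mean p), is
provided for comparison; it is anti-conservative when the p_i are heterogeneous
and is never the default.

Numerical choices:

* Inside the scan, every (window, haplotype) pair is first screened with the
  instant pooled-binomial tail; the exact Poisson-binomial is recomputed
  whenever that screen falls below 10⁻³ (configurable). Decisions at the
  10⁻⁶ significance threshold therefore always rest on the exact test; the
  screen only skips exact evaluation for hypotheses three orders of magnitude
  away from it.
* P-values are clipped into (0, 1] at the smallest subnormal double.
* No multiple-testing correction is applied; significance is a fixed
  genome-wide threshold (default 10⁻⁶), as is conventional for these scans.

Windows are laid out per chromosome for each size in a ladder (default
{0.75, 1.5, 3, 5, 10} Mb, a geometric cover of the classic range), advancing
by half a window and clipping the terminal window at the last marker.
Haplotypes are counted over all 2N chromosomes; strings at ≤ 2% frequency are
dropped from testing but stay in the frequency denominator. Significant
windows merge into a region when they overlap and share ≥ 50% of carriers
(Jaccard, against the region's current lowest-P window); region bounds are the
union of merged windows. With only two simulated generations a founder
haplotype is largely unbroken, so merged regions can span most of a
chromosome; localisation sharpens with pedigree depth, not with window size.

`required_sample_size(f_h, alpha)` inverts P(0 homozygotes) < alpha. Under
random mating the sire/MGS expectation model averages to the same per-animal
probability f_h² as the Hardy-Weinberg model, so both models return the same
n; the function exists mainly for study design (e.g. f_h = 0.01 at
alpha = 10⁻³ needs 69,075 scored animals).

## Mating-outcome contrasts

Risk matings (carrier bull × daughter of a carrier sire) produce homozygotes
with probability 1/8 through the tracked path; the contrast group is
non-carrier bulls on the same dam background (daughters of carrier sires), so
dam-side confounding cancels. Matings to daughters of non-carrier sires are
excluded. Contrasts are differences in group proportions, in percentage
points; the P-value is the pooled two-proportion z test, identical to the
slope test of the covariate-free linear probability model. Hooks for
covariates exist but are off by default — with a contrast group this tightly
matched, the unadjusted estimate is the primary quantity.

"Insemination success" is per-service conception in the simulator; real
recording systems often measure non-return instead, which shifts baselines
but not the logic of the contrast. The analytic deficit for a fully penetrant
embryonic lethal at baseline b is b/8 — 6.25 points at b = 0.5 — plus a small
dam-side leakage term ≈ b·q0/4 because a cow can also inherit the allele from
her (untracked) dam; at q0 = 5% that adds ~0.6 points, which is why empirical
deficits tend to sit slightly above 6.25.

First-year survival uses the Kaplan-Meier product-limit estimator on live-born
calves, deaths as events, survivors censored at day 365. Calves leaving
recording within the year for other reasons (export) are *omitted* by default,
matching how such records are usually cleaned; right-censoring them instead is
available (`export_handling="censor"`) and is the statistically preferable
choice when exit dates are trustworthy. Group differences are reported at days
10 and 365 with the log-rank P.

The 5–32-day return-to-service window flags a repeat insemination at the next
oestrus, separating "conception never happened / embryo lost immediately"
from later abortion: a lethal acting at or before implantation raises the
share of first services followed by a return inside that window.

## Variant prioritisation

Filters encode two genotype-logic modes over sequence-derived genotypes
(alt-allele counts, missing = −1):

* `lethal_recessive`: (1) drop sites alt-homozygous in any healthy adult of
  the cohort; (2) keep sites heterozygous in ≥ k of m flagged carriers.
  k < m absorbs heterozygote under-calling in low-coverage data; with an
  under-call rate u, the retention probability of the true variant is
  P(Binomial(m, 1−u) ≥ k), which motivates k ≈ ⌈0.6·m⌉ at u ≈ 0.2 and makes
  larger sequenced cohorts (larger m) the lever for reliability.
* `affected_homozygote`: with known affected animals, keep sites
  alt-homozygous in every affected and in no other animal.

Missing genotypes are conservative in both directions: never heterozygous for
step 2, never alt-homozygous for step 1. Cross-population screening removes
candidates alt-homozygous in any unrelated cohort and only flags ones merely
segregating there. `hwe_deficit_test` gives the companion cohort-level check:
allele frequency q from genotype counts, expected homozygotes n·q², exact
binomial lower tail for the observed count. Carrier/variant concordance is
summarised as the squared correlation between carrier flags and dosage
(undefined, reported as missing, for constant vectors).

## Coding consequences

Edits are compact cDNA descriptions (`c.55C>T`,
`c.772_779delTTGAAAAGinsCATC`); stated deleted sequences are validated against
the reference before application. Translation uses the standard code and stops
at the first stop codon. Frameshift notation is the compact field style
`p.L258fs16`: first changed residue plus the count of codons from it through
the premature stop inclusive (strict HGVS counts the stop differently; a
`hgvs_style` toggle emits `p.L258fs*16`). In-silico PCR is exact string
matching of the forward primer and the reverse complement of the reverse
primer, no mismatch or thermodynamic model — sufficient for transcript-level
product-size checks.

The bundled GLUT2 reference (`build_glut2_reference`) is a **synthetic
stand-in**, not the RefSeq record: a programmatically constructed 1569-nt CDS
engineered to carry the documented properties of the bovine *SLC2A2*
frameshift allele — Pro19, Leu258, the octamer TTGAAAAG at c.772–779 whose
replacement by CATC (net −4 nt) frameshifts from residue 258 into a stop at
codon 273 (protein 522 → 272 aa, −48%), and a single 370 bp product for the
published exon-6/8 primer pair. Outside these anchored features the sequence
is filler codons and shares no other homology with the real gene. Note the
widely quoted cDNA anchor for this delins is c.771_778; with the deleted
octamer anchored there, codon 258 of the wild type would itself be a stop
codon, contradicting the protein-level arithmetic (Leu at 258, termination at
273). Only the c.772–779 anchor is internally consistent, and the stand-in
adopts it; the net −4 nt arithmetic is anchor-independent.

## The simulator

`simulate_population` grows two bred generations: G0 founder sires (genotyped)
over an unlimited pool of unrelated founder dams, G1 daughters and service
bulls, then an insemination campaign producing G2 calves whose sire and
maternal grandsire are both genotyped. Founder chromosomes are copies of a
small pool of ancestral haplotypes (default 30) with one focal haplotype at
frequency q0 carrying the causal allele in complete LD; meioses recombine with
Poisson counts per marker interval at 0.01 expected crossovers per Mb (a
~1 cM/Mb genetic map). Each service draws an independent bull, succeeds with
the baseline probability (default 0.5), and failure returns the cow to oestrus
18–24 days later, so early losses surface in the 5–32-day return window.
Lethality acts where configured: `embryonic` converts homozygous conceptions
to recorded insemination failures, `perinatal` marks them stillborn,
`juvenile` kills live-born homozygotes before day 365. Baseline nuisance rates
(2% stillbirth, 3% first-year mortality, 5% export) keep the record tables
realistic. The genotyped panel consists of founder sires plus all animals
alive and in-country at day 365 — exactly the survivorship that creates HHD.

What the simulator does *not* emulate: realistic LD decay and haplotype-block
structure (founder haplotypes are random strings), selection and genomic
evaluation, genotyping error on the array panel, dam genotypes, multi-breed
structure, or variable family sizes. Passing tests therefore demonstrate the
statistical machinery under the stated data regime, not robustness to array
artefacts or to incomplete LD between haplotype and mutation (ancestral
haplotypes without the mutation will dilute carrier definitions in real data).

Default desk-scale preset: 50 sires × 200 daughters × 2 generations on one
20 Mb chromosome with 700 markers (~20,000 genotyped animals), a miniature of
the national-scale scans this method is used for. Stochastic check sizes were
chosen for statistical power, not convenience: the acceptance script measures
the insemination deficit on ~800 sires × 500 daughters (≈ 680,000 services,
Monte-Carlo SE ≈ 0.6 points) and runs the end-to-end scan on 80 sires × 250
daughters (≈ 34,000 genotyped animals), where the expected homozygote count
stays above ~20 even under unlucky founder-frequency drift through the small
number of sires, keeping the deficit signal orders of magnitude beyond the
10⁻⁶ threshold for any seed.

## Known limitations

* The expectation model ignores genotyped dams and deeper ancestry; it is the
  male-ancestor reconstruction, not a full pedigree likelihood.
* Half-sib phase correction is a heuristic (relabel an offspring's strings
  when the maternal-labelled one matches the sire strictly better, ties
  untouched); it fixes label swaps, not within-string switch errors.
* The genomic-vs-pedigree relationship consistency screen sometimes applied
  before such scans has no agreed threshold and is not implemented.
* Region merging keys on the lowest-P window's carrier set; haplotypes in
  partial LD can produce several overlapping regions for one causal locus.
* In-silico PCR is exact-match only; primer mismatches or genomic (spliced)
  templates are out of scope.
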