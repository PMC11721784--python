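# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that matter when interpreting
output.

## Coordinates and formats

All genomic intervals are held internally as 0-based half-open; conversion
to and from the 1-based conventions of VCF and GFF3 happens only at the I/O
boundary (`io_formats`). Multi-allelic VCF records are split into biallelic
variants; spanning-deletion star alleles are dropped with a warning because
the loss-of-function classifier operates on biallelic events. Phasing is
ignored (0/1 and 1/0 are both heterozygous): the intended panels are
inbred, so heterozygous calls are most plausibly genotyping artefacts.

## ORF integrity and presence calling

A variant `(pos, ref, alt)` in CDS coordinates replaces the half-open slice
`[pos, pos+len(ref))` with `alt` — VCF-style left-anchored indel semantics.
Edits are applied in descending coordinate order so earlier edits never
shift later coordinates; overlapping edits are rejected.

Classification walks codons from position 0 of the edited sequence:

- no leading ATG → `START_LOST` (ATG is the only accepted start codon);
- first in-frame stop strictly before the reference terminal codon
  position → `PREMATURE_STOP`. Any truncation counts; there is no
  "last-few-percent-of-protein" exemption, because the absent alleles this
  models carry single truncating variants with no positional caveat;
- no stop reached by the end of the sequence → `STOP_LOST`;
- otherwise `FUNCTIONAL`.

Frameshifting indels are classified purely through their translated
consequence, so they surface as `PREMATURE_STOP` or `STOP_LOST`. The
classifier stops at the first decisive event; compensatory edits downstream
of an early stop-loss are not re-examined.

Under the default `strict` policy an accession with a heterozygous or
missing genotype at any of the gene's variant sites is `UNRESOLVED`;
unresolved accessions are excluded from frequency denominators rather than
counted absent (conservative: absence is never inflated by missing data).
The `any-functional` policy instead calls such accessions by their
reference-allele haplotype.

## Frequencies, bins and contrasts

Presence frequency is `100 · n_present / n_called` per gene × population.
Spectrum bins: exact 0 and exact 100 are their own classes; any other value
falls in a decade bin `[10k, 10(k+1))` labelled by its midpoint (5, 15, …,
95). Nearly-fixed uses a strict `> 90 %` rule by default while the
low/high feature contrast uses `< 10 %` vs `≥ 90 %`; both thresholds and
their strictness are parameters, because the two conventions legitimately
coexist in this literature.

Feature contrasts use the two-sided Wilcoxon rank-sum test (exact for
small tie-free samples via scipy), Benjamini–Hochberg adjusted across the
feature list within one contrast — not across populations. A feature
constant in both groups is reported with p = 1 and direction 0 rather than
a tie-corrected asymptotic value. GC content is (G+C)/(A+C+G+T) with N
excluded from the denominator. Expression evidence tiers: translated with
poly(A) → TL+, translated without → TL−, otherwise transcribed (any tissue
TPM strictly > 1) → TC, else TN.

## Branch events and the parsimony ancestor

Sequences are aligned to the reference and read in the reference frame;
indels in individual sequences do not shift codon indexing, which always
follows the reference's non-gap columns. Each substituted column is
classified by substituting that site alone into the parent codon (ancestral
background). Stop-codon gain/loss outranks the SYN/NONSYN label, and also
outranks `START_LOST` when a single change does both (e.g. ATG→TAG); a
stop-to-stop exchange is reported as synonymous. Codons hit at more than
one site are flagged `multi_hit`; the default counts per site, and a
`per-codon` mode classifies the joint codon change instead — the package
takes no position on which convention published counts used. Substituted
columns where the reference has a gap cannot be framed and are reported as
`UNFRAMED` with a missing codon index. Maximal runs of gap-vs-base columns
are single INS/DEL events.

The ancestor is reconstructed column-wise by Fitch parsimony on the ingroup
with gap as a fifth state. The Fitch root set equals the set of
most-parsimonious root states; ambiguity is resolved by the outgroup state
when it is in the set, then the reference state, then lexicographically
(unreachable on quartets). Maximum-likelihood reconstruction is out of
scope; an externally produced ancestor can be supplied and is used
verbatim.

TSD distances are reported 1-based in bp upstream of the first base of the
ATG (a motif abutting the start codon is 1 bp upstream); the convention is
stated because published distances rarely define it. Homology-hit
filtering keeps hits with E ≤ 1e-5, identity ≥ 60 % and query coverage
≥ 70 %, all bounds inclusive.

## Environmental association

The per-factor test is the two-sided equal-variance Student's t (not
Welch), with a BH-adjusted column reported alongside raw p; significance
statements default to raw p to match how such contrasts are usually
reported, with the adjusted column available for honesty.

The permutation test draws `k = n_absent` values without replacement from
the present group (`replace=True` is available), builds the null from the
subsample means, and compares the observed absent-group mean to the
empirical [2.5, 97.5] percentile interval; `statistic="diff"` centres both
on the present-group mean, which shifts the scale but never the call.

Calibration caveat: when the absent group is sampled *independently* of the
present group, this subsampling interval is mildly anti-conservative — the
null variance carries a finite-population factor (N−k)/(N−1) and is centred
on the present-sample mean, giving an asymptotic rejection rate of
2·Φ(−1.96·√((1−k/N)/(1+k/n))) ≈ 0.07 at N = 55, k = 5 under a true null,
≈ 0.08 with n_perm = 1000. Under the exchangeable null — absence labels
carrying no information about the factor, i.e. the absent values are
themselves a size-k subsample of the pool — the test is exactly calibrated
at 5 %. Both properties are exercised in the test suite.

The collinearity pre-filter greedily drops, while any pair of factors has
|Pearson r| above the threshold (0.7), the factor with the largest mean
absolute correlation to the remaining factors; ties break towards the
earliest factor in bio1→bio19 order, and zero-variance factors are dropped
first. Only this pre-filter is in scope; the ordination it feeds is not.

## Sweep scan

r² is D²/(p(1−p)q(1−q)) over haplotypes non-missing at both sites
(pairwise-complete); a site monomorphic in the pairwise-complete subset
makes the pair undefined and it is skipped. ω at a grid point is maximised
over 10 window extents geometrically spaced between `minwin` = 10 kb and
`maxwin` = 100 kb, symmetric about the point, each flank requiring ≥ 2
sites; this ladder is a documented simplification of the exhaustive
boundary maximisation of the original scanners. When the cross-flank sum
is exactly zero with a positive numerator, the capped sentinel 1e6 keeps
quantile machinery finite and rank-correct. The grid step is 10 kb; the
top-5 % threshold is the 0.95 quantile of finite ω values genome-wide per
population (not per chromosome), ties at the cut included; adjacent
selected grid points merge into one region (disable with `merge=False`).
Gene overlap is ≥ 1 bp under half-open semantics.

π is the per-site-averaged unbiased heterozygosity Σ 2p(1−p)·n/(n−1) / L
over the matrix columns; with only polymorphic sites in the matrix it is a
per-variant-site average, not a per-genomic-bp estimate.

## Synthetic data: what it emulates and what it does not

All generators derive per-scenario RNG substreams from one global seed by
stable hashing of the scenario name; the same (scenario, seed) regenerates
byte-identical outputs.

- **Catalog** (`gen_catalog_variants`): one chromosome of single-exon genes
  (40 codons by default, alternating strands to exercise both
  orientations). Absence counts per population are exact census values
  (`round(freq·n)`), not binomial draws, so frequency-recovery tests
  isolate classifier bugs from sampling noise. Each absent accession
  carries exactly one planted LoF variant of a uniformly drawn type
  (premature-stop SNP, start-loss SNP, 1-bp frameshift deletion, stop-loss
  SNP); every frameshift allele is verified LoF by direct translation at
  generation time, sliding the deletion site in the rare case a shifted
  frame stays open. Not emulated: linked variation, multi-exon structure,
  genotyping error, segregating non-LoF variation.
- **Sweep** (`gen_sweep_haplotypes`): 100 haplotypes over 200 kb, ~1
  polymorphic site per 250 bp (a realistic density for a selfing plant
  panel), background sites independent Bernoulli with frequency uniform on
  [0.1, 0.5]. Inside the sweep each haplotype gets one of two block
  patterns per flank, independently per flank — within-flank r² of 1,
  cross-flank r² near 0. The flank half-width defaults to 10 kb (one grid
  step): because each flank is a single indicator pattern, the cross-flank
  r² at the centre is one heavy-tailed draw rather than an average, and the
  block *edges* carry genuine LD contrast; a one-step footprint keeps the
  whole planted signature within one grid step of the centre, which is
  the resolution at which the scan is meant to localise. Not emulated:
  recombination gradients, allele-frequency skew of real sweeps, demography.
- **Environment** (`gen_env`): 19 iid Normal(0, sd) factors; the focal
  factor (bio17 by default) shifted by `effect` in the absent group. Real
  bioclimatic variables are strongly cross-correlated; only the focal-shift
  structure is emulated, so collinearity behaviour must be tested with
  purpose-built inputs.
- **Quartet** (`gen_ortholog_quartet`): fixed topology
  ((ingroup1,ingroup2),outgroup) with the reference ingroup1, 72 codons by
  default (the scale of an 8 kDa ORF). Every planted substitution occupies
  its own codon, indel blocks are codon-aligned and same-branch indels
  non-adjacent, so recovery is exact by construction; multi-hit behaviour
  must be tested separately.

Passing tests therefore demonstrate correctness of the algorithms under
clean, collision-free conditions — not robustness to alignment error,
genotyping noise or demographic confounding in real data.

## Numerical conventions and degenerate inputs

- Quantiles/percentiles use numpy's default linear interpolation.
- `p_empirical` can never be 0 (add-one rule); identical constant groups
  give p = 1.
- Empty FASTA, duplicate ids, inverted intervals, missing GT definitions
  and missing required table columns raise typed format errors naming the
  offender.
- An all-N sequence has undefined GC content (NaN, flagged missing).
- A region shorter than one grid step cannot be scanned; a scan with fewer
  than 20 finite ω values warns that a 5 % cut is poorly resolved.
- Pipeline manifests contain the package version, seed, every threshold
  used and per-stage row counts, and carry no timestamps, so a rerun with
  the same config and seed is byte-identical.

## Known limitations

- Single-transcript gene models only; splice-site LoF and isoform choice
  are out of scope.
- The ω ladder maximises over 10 window extents, not all boundaries, so
  absolute ω values are not comparable to exhaustive-maximisation scanners
  (ranks on a grid are).
- The permutation test's anti-conservativeness for independently sampled
  groups (above) is a property of the published procedure itself and is
  documented rather than corrected.
- The evolutionary-history module assumes the reference frame is the frame
  of interest for all sequences; genuinely frameshifted orthologs are
  reported relative to that frame, not re-framed.
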