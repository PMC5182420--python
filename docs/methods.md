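# Methods

This note documents the models, conventions and defaults behind `pelage`,
and what the synthetic studies do and do not demonstrate about real data.

## The mapping model

The target situation is a fully penetrant autosomal recessive trait
segregating in a closed population descended from a single founder
carrier. All affected individuals then carry two copies of the founder
haplotype around the causal locus (autozygosity), which a SNP chip sees as
a shared run of homozygous markers. The mapping statistic is **observed**
heterozygosity within the case group,

    He(marker) = (# heterozygous called cases) / (# called cases),

and a marker *qualifies* when `He = 0`. This is a per-genotype criterion,
deliberately not the allele-frequency ("expected") heterozygosity that
shares the symbol: the case group is small and inbred, and the biological
claim being tested is "every affected is homozygous here".

### Marker eligibility (chip QC)

A marker at which fewer than `min_called` cases have calls (default: all
of them) is treated as failing QC and is removed from the scan — it
neither qualifies nor interrupts a run. This mirrors how an "informative
SNP" set is defined before a run analysis: call-rate filtering happens
upstream of run-finding, so a sporadic missing call does not artificially
split a genuine autozygous segment. The alternative (ineligible markers
break runs) can be recovered by setting `min_called=1`, under which
almost every marker is eligible, or by pre-filtering the matrix.

### Runs and ranking

Runs are maximal stretches of consecutive eligible qualifying markers,
never crossing a chromosome boundary, with at least `min_run_snps`
markers (default 20 — a noise floor; short qualifying stretches abound in
any inbred cohort). Ranking is by SNP count descending, ties by bp span
descending, then genomic order. Span uses the inclusive convention
`end − start + 1`, recorded in the output header. An optional stricter
mode (`require_shared_allele`) additionally demands that all cases are
homozygous for the *same* allele, which true autozygosity implies; the
default is off because per-individual homozygosity is the weaker, safer
criterion, and the two modes can be compared on any dataset.

## The contrast model

The sequenced case is compared against a panel of control genomes. A
record survives when the case genotype is homozygous for an alternate
allele and, in the default `allele_absent` mode, no panel sample carries
that allele at all. `genotype_absent` mode (tolerate panel heterozygotes,
the behaviour of genotype-level contrast tools) is provided because the
two readings genuinely differ; `allele_absent` is the default as the
stricter filter for a recessive causal allele that should be absent from
unaffected breeds. Panel missing genotypes count as "not carrying"
(`absent`) by default; `unknown-excludes` drops records with any panel
missingness for conservative use. Multi-allelic records are kept intact
and tested per case-homozygous alternate allele; reference-homozygous
case genotypes are never candidates. Region intersection keeps records
whose left-anchored start lies inside the (1-based inclusive) interval.

## Consequence annotation

* Variants are left-aligned against the reference before projection; the
  VCF anchor base is excluded from the affected interval, so a 5-base REF
  / 1-base ALT record is the same event as "four bases removed". A
  homopolymer edit that shifts to position 1 stops there.
* For coding edits the spliced CDS is rebuilt (strand-aware) and
  translated with the standard nuclear code; class and protein fields
  come from comparing the two translations. Frame arithmetic:
  `net mod 3 ≠ 0` is a frameshift; `= 0` is in-frame.
* The first affected residue is the first codon whose **encoded residue**
  differs — not the first codon overlapping the indel — because a shifted
  frame can initially reproduce wild-type residues; this matches HGVS
  `fs` rules. `TerN` counts the new-frame stop with the first changed
  residue as 1, so the mutant stop is at `Pos + N − 1`; a frameshift with
  no downstream stop renders `fsTer?`, and one whose first changed
  residue is itself a stop collapses to the nonsense form `RefPosTer`.
  The reported `novel_peptide_length` is the number of novel residues
  preceding the new stop, i.e. `N − 1`.
* Indels straddling a CDS/exon boundary are classified `splice_region`,
  flagged `splice_region_unsupported`, and excluded from protein
  arithmetic; splice modelling is out of scope.
* Domain fates are coordinate arithmetic on a user-supplied domain table:
  under a truncating consequence, a domain entirely at/after the first
  affected residue is `lost`, spanning it `truncated`, before it
  `intact`. No domain-database lookup is performed.

The annotator is validated against an independent oracle that edits the
*genome*, shifts the transcript coordinates, re-extracts the CDS and
translates in full — a different code path from the spliced-CDS edit used
by the implementation.

## The simulator

### Pedigree builder

`build_aht_like_pedigree` emulates how a recessive trait is captured in a
young breed: one founder carrier; line-breeding (a mating uses a male
from within the pedigree with probability `backcross_rate`, default
0.75, otherwise a fresh unrelated founder); a per-generation preferred
stud reused with probability `popular_sire_rate` (default 0.25); litters
Poisson around 5; 4 matings per generation for 6 generations. Mate
selection prefers affected then carrier animals — an idealisation of a
breeder selecting for the trait (real breeders infer carrier status from
litters; the simulator reads it from the truth). The causal locus is
transmitted during construction (Mendelian sampling), so phenotype
(affected ⇔ dosage 2, full penetrance) and later haplotype drops are
mutually consistent. Construction is rejection-sampled to guarantee a
minimum number of affecteds; with the defaults rejection is rare, so the
conditioning has negligible effect on segregation ratios (verified by the
pooled carrier × carrier check).

### Gene drop

Founders receive labelled haplotypes; each meiosis draws a Poisson number
of crossovers with mean equal to the chromosome's map length (Haldane, no
interference), uniform positions, and a fair-coin starting homologue. The
constraint that a gamete carry (or not carry) the causal allele is
imposed by flipping the starting homologue when needed, which leaves the
crossover process unbiased because the coin is independent of it. Marker
genotypes are read off the transmitted mosaics as alternate-allele
dosages {0,1,2} with a distinct missing code; missingness is applied
independently per call.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| genome | 3 autosomes × 12 Mb | scaled-down autosomal genome; sex chromosomes excluded (the mapped signal is autosomal; avoids dosage complications) |
| markers | 480 per chromosome (~1 / 25 kb) | high-density chip spacing relative to expected segment sizes |
| genetic map | uniform 1 cM/Mb | simplest defensible map |
| causal locus | chr1 : 6,000,000 | mid-chromosome, inside the engineered transcript |
| founder haplotypes | all distinct | unrelated founders of an outbred predecessor breed; homozygosity then reflects identity by descent, not chance identity by state |
| marker allele frequencies | Uniform(0.2, 0.8) | chips ascertain common variants |
| missing calls | 0.2% | post-QC chip call rates |
| pedigree | 6 generations, litters ~5, ≥ 8 affecteds | enough meioses to shrink the shared segment to a few Mb while keeping it detectable |
| contrast panel | 89 genomes (`plant_private_frameshift` default); 20 in the demo for speed | the size of a realistic whole-genome control panel |

### The engineered transcript

The demo reference carries an 18-exon transcript with a 471-codon CDS
whose sequence is engineered so that deleting `TTAG` immediately after
the first base of codon 96 (which falls in exon 4) yields exactly
`Val96GlyfsTer50`: wild-type codon 96 is GTT (Val), the first mutant
residue is Gly, and the shifted frame is stop-free for 49 codons before a
planted TAA. Both reading frames are controlled during construction, so
the wild-type CDS translates cleanly and the mutant consequence is known
by construction rather than computed by the code under test. A decoy
transcript on another chromosome carries a private missense variant, so
the region-intersection step has real work to do. Background variants are
~80% shared with the panel and ~20% private; private synonymous and
intronic variants inside the mapped region exercise the protein-altering
filter.

### What the simulator does not model

Linkage disequilibrium among founder haplotypes (each is an independent
Bernoulli draw per marker), allele-frequency spectra ascertained from a
real chip, genotyping error beyond missingness, sex chromosomes,
selection and drift at population scale, and litter-size or
generation-count estimates of any real breed history. Passing tests
therefore demonstrate correctness of the algorithms under idealised
autozygosity, not robustness to array artefacts or population structure.

## Pipeline conventions

The region passed from scan to contrast is the rank-1 run's bp interval
(inclusive). An empty run set is a legitimate "no mappable region" result,
not an error. The report body contains no timestamps, so reruns on the
same inputs are byte-identical; provenance records the package version, a
config hash and input checksums. Final candidates are the region
survivors whose most severe consequence across overlapping transcripts is
protein-altering (missense, in-frame indel, frameshift, stop/start
events).

## Coat-rule defaults

Priority order: FOXI3 dup/dup → embryonic lethal (all else masked);
FOXI3 dup/wt → dominant ectodermal-dysplasia hairlessness; SGK3 del/del →
recessive hairlessness (hairless phenotypes mask length and curl);
otherwise furnishings iff ≥ 1 RSPO2 insertion allele (dominant), long
coat iff FGF5 long/long (recessive, the breed-typical configuration,
configurable per locus), curl iff ≥ 1 KRT71 curl allele *and* the coat is
long — short fur cannot curl, so curl is reported as masked, which is
also why the curly+short combination never appears in the enumerated
table. Shedding-associated loci and hairlessness modifier loci are
deliberately excluded: the evidence base is associative, not a
deterministic rule. Coat colour is out of scope.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` use: 1000 random instances
(≤ 200 markers × ≤ 12 samples) for run-finder/brute-force agreement; 500
random toy transcript/variant pairs (25–60 codons, 1–4 exons, both
strands) for annotator/oracle agreement; 100 gene-drop replicates at the
default conditions for causal-locus recovery (expected ≥ 95% rank-1
recovery); 100 pedigrees pooled for the Mendelian ratio (≈ 0.25 within 3
binomial SE); 5 variant fixtures for contrast soundness/completeness; and
3 fresh demo studies for end-to-end recovery. These sizes make the whole
acceptance run complete in well under a minute while keeping the binomial
error bars meaningful.

## Known limitations

* The run finder is exact interval logic, not a likelihood ROH caller; it
  has no tolerance for a single stray heterozygote inside a true segment
  (by design — the criterion is `He = 0`).
* Protein arithmetic assumes the transcript model is complete and correct;
  there is no NMD prediction and no multi-isoform prioritisation beyond
  "report the most severe across overlapping transcripts".
* The engineered frameshift site currently supports the TTAG/Val→Gly
  geometry; other deletion lengths fall back to a generic CDS placement
  whose truth is computed by translation at generation time.
* X-linked inheritance is unsupported throughout.
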