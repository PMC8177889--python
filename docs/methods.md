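# Methods

This note documents the model implemented by `hydroprofiler`, the default
parameters, the design of the synthetic-data generators, the numerical
choices, and the known limitations.

## 1. Problem setting

Molecular hydrogen is a central intermediate of anaerobic gut metabolism:
fermentative bacteria dispose of excess reductant by evolving H₂, while other
taxa (including some enteric pathogens) consume it as a respiratory electron
donor. The enzymes on both sides are hydrogenases, classified by active-site
metal content ([NiFe], [FeFe], [Fe]) and by predicted biochemical activity:
**uptake**, **evolving**, **bidirectional**, **bifurcating**, and **sensory**.

The package answers the question: *given shotgun metagenomic reads from two
groups of samples (for example, healthy versus inflamed gut communities), does
the relative abundance of any hydrogenase activity category differ between
the groups?* It also provides the statistics used to interpret companion
colonization-fitness experiments (competitive index, limit-of-detection
handling, comparative Ct).

## 2. Pipeline model

### 2.1 Reference database (`refdb`)

The reference is a protein FASTA plus a TSV metadata table in the style of
public hydrogenase catalogues: one row per entry with `entry_id`,
`metal_class`, `activity_category`, and a free-text `source_label`.
Metadata tokens are normalized (brackets stripped, case folded), so
`[NiFe]`/`nife` and `Uptake`/`uptake` parse identically. Classification is
taken from the metadata as-is; no sequence-based re-classification is done.
Curation marks entries as *excluded* rather than deleting them; search and
profiling only ever see the active subset.

### 2.2 Read QC and host decontamination (`search.quality_filter`, `search.filter_host_reads`)

A read pair is dropped when either mate is shorter than 50 nt or has mean
phred quality below 20 — an unreliable mate compromises the whole fragment.
Host decontamination removes pairs where either mate shares ≥ 10 exact
canonical (strand-minimum) 21-mers with the host genome. With 100 bp mates
this removes essentially every host read (a mate contains 80 21-mer windows,
so even several sequencing errors leave well over 10 intact windows) while a
random non-host 100-mer has a vanishing probability of sharing ten exact
21-mers with an unrelated genome.

### 2.3 Translated six-frame search (`search.search_reads`)

Each mate is searched independently and contributes at most one read-level
count (best-hit policy), emulating the read-level counting of a translated
aligner run with an e-value reporting cutoff:

1. The mate is translated in all six frames (stops render `*`, codons
   containing `N` render `X`; trailing partial codons are dropped).
2. Exact 4-residue seeds shared with any active reference entry are found
   through a precomputed seed index. Seeds may not contain `X` or `*`.
3. Each seed is extended without gaps in both directions under BLOSUM62
   (`*` scored at the matrix minimum, −4). By default extension runs to the
   query/subject bounds rather than stopping on an X-drop: queries are at
   most ~33 residues, so this is cheap, and it makes the reported raw score
   *exactly* the optimum over all ungapped local alignments that contain a
   seed — a property the test suite verifies against exhaustive enumeration.
   An explicit `xdrop` can be set for strict emulation of heuristic
   aligners.
4. Raw scores are converted to bit scores with the published ungapped
   BLOSUM62 Karlin–Altschul constants (λ = 0.318, K = 0.13):
   `bit = (λ·raw − ln K) / ln 2`. The e-value is
   `search_space · 2^(−bit)` with `search_space = total reference residues ×
   (mate length // 3)` unless given explicitly.
5. A mate reports a hit only when `evalue ≤ 0.001` (the conventional cutoff
   for short-read translated functional profiling). Ties on bit score break
   to the lowest e-value, then to the lexicographically smallest entry id.

The seed-and-extend core is JIT-compiled with numba (`cache=False`, so no
binary cache files are written into the repository).

### 2.4 Decoy-based reference curation (`curate`)

A reference entry is reliable only if reads recruit to it from
hydrogenase-containing sequence. The validation maps reads simulated from
wild-type genomes and from *knockout* genomes (every hydrogenase CDS
excised) against the reference and compares per-entry **relative**
recruitment — each entry's share of all hydrogenase-mapped reads within its
dataset, which makes the rule invariant to sequencing depth. An entry is
excluded when its knockout-dataset relative recruitment is **twofold or
greater** (inclusive boundary) than its wild-type relative recruitment.
Zero conventions: recruitment only from hydrogenase-free sequence is exactly
the targeted failure mode (ratio = ∞, excluded); no recruitment anywhere
means the entry is merely untested (ratio = 0, retained).

### 2.5 Category profiling and group comparison (`profile`)

Per-sample best-hit counts form a sample × entry table (structural zero
columns for never-hit active entries). Each sample's counts are normalized
by its total hydrogenase-mapped reads; entry fractions are summed into the
five activity categories.

The comparison unit is the *reference entry*: for each category, each entry
contributes one value per group — its average normalized abundance across
that group's samples. Averages exactly equal to zero are replaced by a
pseudo-value **after** averaging (presets 0.05 and 0.0005 for two analysis
styles; the pseudo-value only keeps zero entries on a log-style plot scale
and cannot create a spurious group difference because it is applied to both
groups symmetrically). The two groups' vectors of per-entry averages are
compared with a two-sided Mann–Whitney U test, Bonferroni-corrected across
the categories actually testable (categories with no entries in the table do
not count toward the correction factor).

**Mann–Whitney U implementation.** U is the rank-sum statistic of the first
sample (average ranks on ties). For pooled sizes ≤ 16 the p-value is exact:
all C(n+m, n) group labelings of the pooled values are enumerated, and the
two-sided p is the probability of a deviation of U from nm/2 at least as
large as observed (the permutation distribution of U is symmetric about
nm/2 even with ties). Larger samples use the normal approximation with tie
and continuity corrections. The implementation is cross-checked in the test
suite against independent full enumeration and against
`scipy.stats.mannwhitneyu` (the scipy routine is used only as a check, never
as the implementation).

### 2.6 Fitness statistics (`fitness`)

* **CFU/g** from serial-dilution plate counts:
  `colonies · 10^dilution / plated_volume · homogenate_volume / mass`.
* **Limit of detection**: values below 10 CFU/g (including zero counts) are
  set to 10 CFU/g, the plating detection floor, so log-scale statistics stay
  defined.
* **Competitive index**: `(wt_out/mut_out) / (wt_in/mut_in)` after LOD
  substitution; CI > 1 reads as a wild-type advantage.
* **Geometric mean ± 95% CI**: t-based interval on the natural-log scale,
  exponentiated.
* **Paired Student's t-test on log data**, two-sided, n − 1 degrees of
  freedom; constant log-differences within float rounding are treated as
  zero spread (identical samples give t = 0, p = 1; a constant non-zero
  ratio is flagged degenerate).
* **Comparative Ct**: ΔCt per sample, ΔΔCt against the control-group mean
  ΔCt, fold change 2^(−ΔΔCt).

## 3. Synthetic-data generators (`simulate`)

All generators are deterministic under a single integer seed; independent
sub-streams are derived through `numpy.random.SeedSequence`. Coordinates
are 0-based half-open throughout.

* **Reference proteins** are uniform random sequences over the 20 canonical
  amino acids (a per-entry length drawn from an inclusive range when a range
  is given). **Decoy proteins** additionally share no exact 8-residue
  substring with any entry, so any read recruitment they receive from
  hydrogenase-free sequence is genuine decoy signal, not residual homology.
* **Genomes** place each protein's reverse-translated CDS (uniform random
  synonymous codons) once, at a rejection-sampled non-overlapping position
  on a random strand, in uniform random nucleotide background.
  **Knockout genomes** excise every CDS with role `hydrogenase` and shift
  the kept features; the study pipeline verifies by exhaustive substring
  scan (both strands) that no excised CDS survives anywhere.
* **Reads**: abutting-mate fragments of length 2 × read length at uniform
  random positions; mate 2 is the reverse complement of the far half. The
  number of pairs for a coverage target is
  `round(fold · genome_length / (2 · read_length))`. Errors are
  substitution-only at a flat per-base rate with flat `I` quality strings —
  enough to exercise a translated homology search; indels, quality decay and
  GC bias are deliberately out of scope. Every pair carries ground truth
  (source genome, fragment start, overlapped entry if any).
* **Condition communities**: two groups of samples; each sample draws a
  binomial number of host-contamination pairs, then splits the remaining
  pairs across member genomes by that group's abundance vector
  (multinomial).

## 4. Validation studies (`pipelines`) and their fixture design

### 4.1 Decoy validation study

Five genomes carry 10 genuine entries (2 per category) and 3 decoy genes;
the decoys are also planted in the reference as if annotated. Reads at
50-fold coverage from wild-type and knockout genomes are searched and the
twofold rule applied. Expected outcome: in the knockout dataset only decoy
genes remain, so decoys take essentially the whole hydrogenase-mapped share
(relative ratio ≫ 2, excluded) while genuine entries recruit nothing
(ratio 0, retained).

### 4.2 Planted enrichment study

A two-group community with one carrier genome per category, a
hydrogenase-free background genome, and a host genome contributing 5% of
pairs. The planted (uptake) carrier moves from 3% abundance in the first
group to 12% in the second (4-fold); the other carriers stay at 15% and the
background absorbs the shift.

The fixture sizes were chosen *a priori* from power arithmetic, not tuned
against outcomes:

* With compositional (closure) normalization, boosting one category
  necessarily depresses all others; the background genome absorbs most of
  the shift so the non-planted depression is only ≈ 12% relative — far
  smaller than the ≈ 2.6× spread of per-entry abundances induced by the
  heterogeneous protein lengths (150–450 aa), so non-planted categories are
  not pushed to spurious significance.
* The planted per-entry shift is ≈ 3.5× — far larger than that spread — so
  with 8 entries per category the exact Mann–Whitney test on two groups of
  8 per-entry averages can reach p = 2/12870 ≈ 1.6 × 10⁻⁴, surviving a
  ×5 Bonferroni correction with a wide margin (with only 2 entries per
  category the minimum attainable p is 1/3, so significance would be
  mathematically impossible).

### 4.3 Search validation

On genomes with known CDS placements and error-free reads, every mate fully
contained in a hydrogenase CDS must be assigned to its source entry
(expected accuracy 1.0), and reads from knockout genomes give the spurious
floor: passing the 0.001 cutoff requires a raw score around 52–56 (≈ 14
high-identity residues beyond chance) after an exact 4-mer seed, which
random sequence only rarely achieves. The floor is *per-locus*, not
per-read: when a 100 kb fixture does contain a chance-homology locus (a
minority of seeds), every fragment covering that locus recruits, giving
either 0 or roughly 0.1% of pairs. Aggregated over seeds the pair-level
spurious rate stays well below 0.5%, the bound asserted by the acceptance
suite.

## 5. Numerical choices

* BLOSUM62 is loaded from Biopython's `substitution_matrices`; the 22-symbol
  internal alphabet is the 20 canonical residues plus `X` (matrix values)
  and `*` (matrix minimum, −4).
* The genetic code comes from Biopython's standard codon table; codons
  containing `N` translate to `X`.
* Seed lookup uses a rolling base-22 key over 22⁴ = 234 256 buckets in a CSR
  index; host k-mers use rolling 2-bit canonical keys in an int64 sorted
  array with `searchsorted` membership.
* Child seeds are always reduced modulo 2³¹ so they remain valid for any
  consumer.
* Exact Mann–Whitney enumeration uses a 1 × 10⁻⁹ tolerance when comparing
  deviations, guarding against float noise in average ranks.

## 6. Limitations

* The error model is substitution-only; indels would shift reading frames
  and are not handled by the ungapped search.
* Synthetic reference proteins are uniform random sequences; real
  hydrogenase families have conserved motifs and cross-family homology, so
  real-data specificity will differ from the synthetic floor measured here.
* The search is ungapped with a fixed substitution matrix and fixed
  Karlin–Altschul constants; it is designed for ≤ ~33-residue translated
  queries, not full-length proteins.
* The normal-approximation branch of the Mann–Whitney test is asymptotic;
  exact enumeration is limited to pooled sizes ≤ 16.
* Compositional normalization means category abundances are relative;
  absolute abundance shifts are not identifiable from these data alone.
* The expected-category-fraction truth summary ignores window overlap
  between nearby same-category features (features are placed sparsely).
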