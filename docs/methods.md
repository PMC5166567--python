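# Methods

`mupquant` implements proteoform-specific, label-free quantification for
protein families whose members are too similar to distinguish by
antibodies, genetics or intact-mass approaches. The model system is the
major urinary protein (MUP) family of house mice: ~20–34 lipocalin
proteoforms encoded by a single gene cluster, with central members
exceeding 97% sequence identity and peripheral members at 82–94%. The
package covers the full analysis chain — proteotypic-peptide inference,
MS1/MS2 intensity roll-up, normalization, paired differential testing,
detection-frequency classification and relative composition — together
with a ground-truthed synthetic-data generator that stands in for raw
mass-spectrometry data.

## Proteotypic peptides and database context

All identification and quantification rests on *proteotypic* peptides:
tryptic peptides whose sequence occurs in exactly one proteoform within
a given database context. Uniqueness is therefore **relative to the
database**: a peptide unique among the family members alone
(`family_only` context) may recur in an unrelated background protein
once the whole proteome is searched (`comprehensive` context). Growing
the database can only remove proteotypic peptides, never add them; this
monotonicity is enforced as a property test and measured in the
acceptance script. `compare_contexts` reports, per proteoform, how many
proteotypic peptides survive in each context and which proteoforms lose
all of them (becoming unidentifiable).

Digestion follows the standard tryptic rule — cleavage C-terminal to
K or R, suppressed when the next residue is proline — with up to
`max_missed` (default 2) missed cleavages. The rule is authored here
and validated against an independent brute-force substring oracle
rather than delegated, because uniqueness decisions depend on its exact
semantics. Peptide admissibility applies three filters:

* length 6–30 residues (configurable; typical search-engine bounds),
* monoisotopic m/z inside the acquisition window 250–1500 (the
  instrument range used for this family, chosen wide enough to keep
  short unique peptides), computed as (M + z·1.00728)/z over charge
  states 2–4, with z = 1 also considered for peptides of ≤ 7 residues
  that would otherwise fall below the window,
* fixed carbamidomethylation of cysteine (+57.021464 Da); no variable
  modifications.

Isoleucine and leucine are isobaric and indistinguishable by mass
spectrometry, so I/L are treated as equivalent when deciding uniqueness
(`il_equivalent=True` by default, toggleable). Redundancy clearing on
FASTA input collapses records with identical sequences — optionally
after trimming an annotated signal peptide, since precursor and mature
forms of the same proteoform otherwise masquerade as two entries.

Putative long proteoforms (cDNA-derived entries carrying a C-terminal
extension) are screened by collecting peptides unique to the long form;
the verdict is "supported" when an extension-unique peptide was
observed, "not supported at protein level" when none was, and
"undecidable" when the extension yields no admissible tryptic peptide
at all.

Pairwise identity uses Biopython global alignment with BLOSUM62 and
affine gaps (open 10, extend 0.5); identity = identical columns /
alignment length × 100, gap columns included. These parameters are a
conventional choice — the exact alignment settings behind published
identity figures for this family are not recorded anywhere we could
follow, so small deviations from published percentages are expected.

## Quantification model

The ion library holds every proteotypic peptide of the active context
that was observed in at least one identification run, each mapped to
its single parent. Proteoform intensity per sample is the **sum**
(default; mean available for sensitivity analysis) of the proteoform's
library-peptide areas. MS2 (SWATH-style) quantification first sums each
peptide's fragment rows to a peptide area, then rolls up identically.
The aggregation choice is not dictated by the vendor tools this
emulates (their internal behavior is undocumented), hence both options.

Missing detections are kept as missing (NaN), never zero, so that an
individual lacking a proteoform drops out of that proteoform's paired
comparison instead of dragging means toward zero. Zero-imputation is
available as a flag for workflows whose extraction software reports
baseline areas.

## Normalization

Three strategies, applied per sample:

1. **none** — raw areas; retains concentration changes on the MS level.
2. **TAS (total area sums)** — each sample is rescaled so its summed
   intensity equals the across-sample mean total. Idempotent by
   construction.
3. **manual** — division by an externally measured scale factor, here
   the total urinary protein concentration (µg/µL, Bradford-style).

The choice matters precisely because the quantification targets
dominate the sample: when family members rise, the total protein
concentration rises with them, so raw or TAS-normalized data show
apparent regulation that concentration normalization removes. The
package demonstrates this with a synthetic scenario in which all family
members share one true fold and the family is the entire signal: raw
fold estimates sit near the true shared fold while manual-normalized
folds return to ~1 and nothing passes the significance filter.

## Statistics

Differential expression between the paired time points uses two-sided
paired t-tests on the normalized areas (raw scale by default; an
optional log2 transform is provided since the emulated software's
internal scale is unreported). Fold change is the ratio of group means
mean(t2)/mean(t1) over paired values. Proteoforms with fewer than
`min_pairs` (default 3) complete pairs are excluded with a log entry;
zero-variance differences yield an undefined p and are flagged rather
than silently passed.

Multiple testing uses Bonferroni–Dunn control: the adjusted threshold
is α/k with k the number of proteoforms actually quantified, so the
threshold depends on the database context (e.g. α = 0.05 gives 0.005 at
k = 10 and 0.0033 at k = 15). A result is significant only if it also
clears the two-fold rule (fold > 2, or < 0.5 for downregulation — the
reciprocal rule is our symmetric extension, as only upregulation is
discussed in the source material).

Detection frequencies (individuals expressing a proteoform / total
individuals, rounded to integer percent) are binned exactly as the
field reports them: ubiquitous = 100%, common = 50–70%, uncommon =
30–49%, rare < 10%. The printed bins leave gaps (10–29%, 71–99%);
values there are reported as "unclassified" with a warning instead of
guessing intent.

MS1/MS2 concordance is the Pearson correlation of log2 fold changes
over shared proteoforms (≥ 3 required), with proteoforms whose folds
disagree by more than a configurable ratio (default 2) listed as
discordant.

## Relative composition

The 100% method assumes equal ionization efficiency across the family's
peptides — defensible because of the high homology, and explicitly an
assumption: unequal efficiencies bias shares proportionally and are not
corrected. Per proteoform, score = (summed unique-peptide areas across
samples) / (number of unique peptides in the active library); scores
are normalized to 100%, and proteoforms below 5% (configurable) are
pooled into "Others". Unique-peptide counts come from the active ion
library, so composition, like uniqueness, is context-dependent. The
family's share of total intensity sums *all* family-derived peptides —
unique and shared within the family — over the total of everything
quantified, reported pooled and as a per-sample mean ± SD.

## Synthetic data generator

The generator emulates the statistical structure of a paired
two-time-point urinary-proteome study with a dominant homologous
family; its defaults are the study conditions the analysis is designed
for:

* **Family**: one random 157-residue base ("consensus") built from
  tryptic segments of 6–12 residues; 14 central proteoforms with ≤ 2
  point substitutions each (≥ 97% identity to the base) and 5
  peripheral proteoforms with 10–28 substitutions (82–94%). Identity
  bands are defined **versus the base**, not over all pairs: two
  peripherals at 88% to the consensus are necessarily less than 82%
  identical to each other, so an all-pairs band would be
  self-contradictory. Substitution positions are unique per proteoform,
  placed only inside admissible fully-cleaved peptides, never touch K/R
  (preserving the digest pattern), and never introduce P or swap I/L;
  the result is audited with the real proteotypic mapper and re-drawn
  until every member keeps ≥ 1 proteotypic peptide.
* **Background**: random non-homologous proteins (80–250 residues)
  sharing no tryptic peptide with the family (collisions re-drawn),
  expressed constantly across time points.
* **Design**: 13 individuals × {t1, t2} (26 samples). Detection is
  Bernoulli per (proteoform, individual) — a proteoform absent for an
  individual contributes nothing at either time point, mimicking
  genotype-like presence/absence. Default detection probabilities
  follow the published survey ladder (100, 100, 70, …, 2%), assigned by
  decreasing abundance so abundant members are also ubiquitous.
* **Abundance**: proteoform baseline × per-individual effect
  (lognormal, CV 0.30) × true fold at t2 × biological noise (lognormal,
  CV 0.25) averaged over pooled replicate draws (2 at t1, 3 at t2,
  mirroring urine pooling). All noise is multiplicative lognormal with
  unit mean; a CV of zero yields exactly 1, so noise-free runs are
  bit-exact.
* **Signals**: peptide MS1 area = summed detected-parent abundance ×
  per-peptide ionization factor (lognormal, CV 0.8, drawn once and
  shared across samples) × technical noise (CV 0.10). The MS2 matrix
  distributes each peptide area over 6 fragment rows with per-peptide
  Dirichlet(5) weights via exact telescoping, so fragments sum exactly
  to the MS1 area when fragment noise (CV 0.05) is off.
* **Concentration**: proportional to the true total protein amount,
  anchored so the t1 average equals 1.4 µg/µL, with 5% measurement
  noise. When no upregulation map is given, the most abundant family
  members are upregulated at fold 3 — with a partial fold on the last
  member so the expected family-driven rise lands exactly on the stated
  1.4 → 2.6 µg/µL averages (family intensity share 0.85 at t1).

The source study reports no technical CV (its pilot data are not
available), so the noise defaults above are assumed values typical for
label-free intensities and are documented here rather than fitted.

What the generator does **not** model: retention time, chromatographic
peak shape, raw spectra, interference/co-elution, missed-cleavage
variability between samples (matrices contain fully cleaved peptides;
missed-cleavage handling lives in the uniqueness logic), search-engine
scoring and FDR. Passing tests therefore demonstrate correctness of the
quantification arithmetic and statistics under the stated noise model —
not robustness to chromatographic artifacts or identification errors in
real data.

## Numerical and design choices

* Fold change = ratio of group means (matching group-comparison
  software); a per-pair-ratio alternative is not provided.
* t-tests on the raw area scale by default; `log2=True` available.
* TAS idempotence holds to < 1e-12 relative; shares + Others sum to
  100 within 1e-9 (retained shares are rescaled after binning so the
  total is exact).
* NaN handling: sums use min-count-1 semantics (all-absent → absent);
  means skip NaN.
* Seeds: one `numpy` Generator per simulation; identical seed + spec
  reproduce bit-identical matrices.
* Degenerate inputs raise informative errors rather than warn: empty
  sequences, non-standard residues (with position), non-positive
  masses/factors, empty ion libraries (listing unidentifiable
  proteoforms), zero total intensities, k = 0 tests.

## Problem sizes used in the shipped checks

The statistical acceptance checks use a 9-member family (6 central, 3
peripheral) with 8 background proteins; error control and power are
each measured over 200 simulations at n = 13 pairs, the study's sample
size. The full-pipeline demonstration uses the 19-proteoform default
family with 20 background proteins. These sizes were chosen so the
whole suite re-runs comfortably on a laptop while keeping n at the
design value where it matters (the paired tests).

## Known limitations

* Composition shares inherit any true ionization-efficiency inequality
  (assumption of the 100% method); the generator can quantify this bias
  but the method does not correct it.
* Real pairwise-identity figures depend on alignment parameters that
  are not standardized; expect ±few percent against published numbers.
* The detection model is binary per individual; partial detectability
  (abundance-dependent dropout) is not modeled.
* `k` (number of tests) is taken as the number of proteoforms passing
  `min_pairs`, a proxy for the emulated software's undocumented notion
  of "quantifiable".
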