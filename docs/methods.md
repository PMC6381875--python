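# Methods

## Data model and coordinates

An observation is one phosphopeptide identification in one sample and gel
fraction: protein accession, gene symbol, peptide sequence, the 1-based
protein position of the residue immediately preceding the peptide, 1-based
phospho-site offsets within the peptide, phospho count, Met-oxidation
count, gel fraction, MS1 peak area (≥ 0), and a site-localization
confidence in [0, 1]. The global protein position of a site is
`preceding_position + offset`, and validation checks both that the peptide
occurs at the stated position and that every site's global residue is
S/T/Y.

The analyte identity (`PeptideKey`) is (sequence, phospho count, localized
offsets). Mono- and multi-phosphorylated forms of one sequence are distinct
analytes. Observations whose localization confidence falls below the
configurable threshold (default 0.95) keep their phospho count but lose
their offsets: they are detected and quantified as a separate
non-localized analyte but contribute no motif windows. This convention is
ours; search engines differ in how they key non-localized sites.

## Differential detection

Detection collapses gel fractions and Met-oxidation variants: an analyte is
detected in a sample iff at least one observation exists. For a two-group
contrast, analytes detected in ≥ `min_detect` (default 3) replicates of one
group and zero of the other are called, scored with the pooled
two-proportion z statistic and the one-sided upper-tail normal probability
computed in closed form from the complementary error function — no
continuity correction, no table interpolation. The one-sided orientation
matches the worked reference values (3/8 vs 0/8 → z = 1.92, p = 0.027;
2/8 vs 0/8 → z = 1.51, p = 0.066); a flag doubles the p-value for a
two-sided reading. When the pooled proportion is 0 or 1 the statistic is
undefined and the function raises; in reporting contexts such analytes
carry no evidence either way. No multiple-testing correction is applied by
default (an optional Benjamini–Hochberg flag exists for the quantitative
tests). QC summaries report detection-frequency curves per replicate group
and pairwise repeatability (overlap / min of the two detected sets, × 100;
a Jaccard denominator is available — the choice is not standardized in the
field).

## Label-free quantification

Per (analyte, sample): areas are summed over gel fractions and
Met-oxidation variants, then divided by the sample's lysate protein
concentration. A peptide sequence shared by homologous proteins is a single
peptide-level row attributed to all matching accessions for protein-level
rollups. Zero total area cannot be log-transformed and is stored as
missing; missing cells are never imputed (absence is the detection
analysis's job).

Group comparisons use two-tailed Student's t-tests (pooled variance;
Welch by flag) on natural-log areas for analytes with ≥ `min_per_group`
(default 3) present cells per side. Whether the original workflow tested
raw or log areas is not documented; we default to log because the
classification and plotting conventions are all ln-ratio-based, and the
generator's multiplicative noise makes ln areas exactly normal. Heat-map
bias scores are `ln(group mean / grand mean)` with the grand mean taken
over all samples' present cells; the identity
`score_A − score_B = ln(mean_A) − ln(mean_B)` holds algebraically and is
tested numerically. The scatter classification flags analytes with
|ln(KO/WT)| or |ln(F/M)| ≥ 1 (an e-fold, ≈ 2.7×, change).

## Motif extraction

Each confidently localized site yields a 13-mer window (width 6 per side)
read from the protein sequence — flanks extend beyond peptide boundaries
and protein termini are padded with 'X', which never matches and is
excluded from numerator and denominator counts at its offset. The extractor
is the iterative greedy binomial procedure: at each step, for every unfixed
(offset, residue), compute the exact binomial tail P(X ≥ k) with
k = foreground matches, n = foreground size at that offset, q = background
frequency; fix the minimum-p position if p ≤ significance (default 4×10⁻⁶)
and k ≥ min_occurrences (default 5); restrict both sets and repeat; emit
the accumulated pattern, remove its windows, restart. Candidates with zero
background frequency are skipped (no finite model); ties on p are broken by
larger fold enrichment, then smaller |offset|, then alphabetical residue,
so output is deterministic. The binomial tail is an exact log-space
summation (stable to n ≈ 10⁵) and is verified against exhaustive outcome
enumeration for n ≤ 12.

The default background is all same-centered windows of the supplied FASTA.
In the pipeline, extraction runs per contrast direction on the windows of
the differential analyte set (exclusives plus significant quantitative
calls); on synthetic data the whole-dataset foreground is
indistinguishable from the proteome background by construction, so the
differential set is the meaningful foreground. The proline-directed class
(P at +1, the CDK/MAPK/GSK-3 signature) is compared between genotypes as a
per-sample proportion of site windows with a two-tailed paired t-test
across matched KO/WT pairs.

## Gene-set enrichment and count comparisons

Enrichment is protein-level: k distinct annotated genes among n tested
genes versus a K-gene candidate set in an N-gene universe (default
20,000), using the identical pooled two-proportion z (asserted to be the
same implementation). Matching is case-insensitive; peptide multiplicity
does not inflate k. Direction-count comparisons (e.g. more female- than
male-biased analytes) pool exclusive and quantitative calls, de-duplicated
by analyte, and report the pooled z on the two counts. A generic Pearson
chi-square (hand formula Σ(O−E)²/E, upper chi-square tail, no Yates
correction by default) covers r×c cross-group count tables.

## Synthetic data generator

The generator emulates the study conditions end to end: 4 replicates per
genotype × sex cell (16 samples), matched KO/WT pairs within sex, lysate
concentrations ~N(3.0, 0.1) mg/ml, 215 proteins × 10 tryptic-style peptides
(length 10–17, C-terminal K/R, one site per peptide at S:T:Y ≈
0.78:0.20:0.02, ~10 % of null peptides di-phosphorylated). Planted
effects: 50 group-exclusive analytes per contrast (detection probability
0.9 in the favored group, 0 in the other; half per direction), 50
fold-change analytes (×4 on the favored genotype's mean), 2,000 null
peptides at baseline detection 0.7, and a +1-proline bias: WT-favored
genotype-biased peptides get central residue S and P at +1 (fraction 1.0 by
default), giving both a clean motif-extraction target and a WT > KO
proline-class asymmetry. The candidate-gene list contains 30 % of the
sex-biased genes plus a 5 % background draw, so the expected annotation
overlap is known exactly.

Intensities: each peptide has one base abundance exp(N(13, 1.5²));
per-sample values multiply it by the planted fold factor and exp(N(0,
0.1²)) measurement noise, split across 3 gel fractions by a Dirichlet
draw, with a 60/40 Met-ox variant split for ~10 % of M-containing
detections. Baseline detection 0.7 reproduces the observed replicate
structure of such experiments (~65 % of a group's analytes in >2 of 4
samples, ~24 % in all 4). Randomness uses one integer-derived stream per
sample — (seed, CRC32(sample id)) — so adding samples never perturbs
existing ones, plus a master stream for study-level structure; all outputs
are byte-reproducible given the seed.

What the generator does **not** emulate: retention-time structure, missed
cleavages, intensity-dependent detection (detection and abundance are
independent except for planted effects), correlated peptides within a
protein, isotope interference, and search-engine scoring artifacts.
Passing recovery tests therefore demonstrates the statistical logic is
correct under the stated model, not that real acquisitions meet the
model's assumptions.

## Numerical and design notes

- `two_proportion_z` validates 0 ≤ xᵢ ≤ nᵢ and raises on pooled
  proportion 0 or 1.
- Degenerate quantitative tests (zero variance both sides): p = 1 when
  means are equal, p = 0 with a `degenerate` flag otherwise.
- Output ordering is always (p, key) lexicographic, so reports are
  reproducible byte-for-byte; two identical runs differ only in the
  manifest's echo of the output directory.
- Problem sizes in the test suite: the full default study (2,150 peptides
  × 16 samples) runs once per session; unit tests use a 150-peptide
  study. These sizes give planted-effect recovery margins far from the
  pass thresholds (e.g. exclusive recovery probability per analyte
  ≈ 1 − 2×10⁻⁵) while keeping the suite under a minute.

## Known limitations

- The detection and quantification analyses treat replicates as unpaired
  even though the design is pair-matched; only the motif-class comparison
  uses the pairing. This mirrors the reference workflow but discards some
  power.
- Enrichment assumes gene symbols are unique identifiers; paralog
  ambiguity is not modeled.
- Motif extraction reports the binomial p of the last fixed position per
  motif step, not a multiple-testing-adjusted motif score; the stringent
  default significance (4×10⁻⁶) is the guard against the implicit
  12 × 20 candidate scan.
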