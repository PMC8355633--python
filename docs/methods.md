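# Methods

## The test

For one SNP–probe pair with GWAS summary statistics (β_G, SE_G) and eQTL
summary statistics (β_E, SE_E), let Z_G = β_G/SE_G and Z_E = β_E/SE_E. The
statistic

T_SMR = Z_G² Z_E² / (Z_G² + Z_E²)

is compared against a χ² distribution with one degree of freedom;
P_SMR = P(χ²₁ > T_SMR). Algebraically T_SMR is half the harmonic mean of
Z_G² and Z_E², hence 0 ≤ T_SMR ≤ min(Z_G², Z_E²), symmetric in its
arguments and invariant to the sign of either Z. When both Z's are zero the
limit along any ray is 0, which we adopt as the convention. The statistic
is an approximation to the Wald-ratio test of b_xy = β_G/β_E: with a strong
instrument (|Z_E| ≫ |Z_G|) it approaches Z_G², and it is never larger, so
the test is slightly conservative — visible in the Monte-Carlo type-I error
sitting just below the nominal level (≈0.045 at α = 0.05 with |Z_E| ≈ 14).

Significance is controlled family-wise per dataset at threshold
α / n_probes with α = 0.05, where n_probes is the probe count of the
*source* expression panel, not the number of pairs actually tested after
merging. The two choices differ in general; the source-panel denominator
matches how panel-wide thresholds are quoted for the four real panels we
mirror (28 522, 33 323, 7 350, 5 829 probes → 1.8×10⁻⁶, 1.5×10⁻⁶,
6.8×10⁻⁶, 8.6×10⁻⁶ at two significant figures). It is configurable
(`n_probes="infer"` counts probes in the file instead).

Every harmonized SNP–probe pair is tested by default (`all_pairs`), so one
gene may be supported by several significant SNPs; the canonical
one-top-cis-eQTL-per-probe selection (`top_per_probe`, eligibility
p ≤ 5×10⁻⁸, ties by |Z_E| then rsID) is available as an option. No
heterogeneity (HEIDI-style) filtering or LD pruning is applied.

P-values are carried internally as log tail probabilities. For df = 1,
log sf(t) = log 2 + log Φ̄(√t), which stays finite far beyond the point
where the linear-scale sf underflows (t ≳ 1 400); significance is decided
in log space so extreme associations serialize and compare correctly.

## Harmonization

Studies are matched on rsID alone — build-agnostic, at the cost of ignoring
chrom:pos confirmation. The eQTL effect allele is the reference: a GWAS
effect reported on the other allele is sign-flipped, after optionally
complementing the GWAS alleles to resolve strand. Pairs whose alleles are
irreconcilable are dropped and counted. Palindromic SNPs (A/T, C/G) cannot
be strand-resolved from labels; the default `strict` policy drops them,
`lenient` trusts the labels. Because T_SMR squares both Z's it is
insensitive to flips; the sign of b_xy is not, which is why alignment
matters. Alignment is idempotent and preserves |Z|.

eQTL duplicate (snp, probe) rows collapse to the smallest-p row —
deterministic and favouring the strongest signal. Rows violating basic
invariants (SE ≤ 0, p outside (0, 1], identical alleles, unparseable
numerics) are dropped with per-reason counts; a missing p-value column is
tolerated and recomputed as 2Φ̄(|β/SE|), since the method itself only needs
β and SE.

## The generative model

The simulator emulates the two-sample design the pipeline consumes: two
disjoint cohorts genotyped at a shared panel of m cis SNPs.

- **Genotypes.** Per-SNP effect-allele frequencies f_j ~ U(maf_range),
  drawn once per configuration and shared by both cohorts. Each haplotype
  is a latent AR(1) standard Gaussian across SNPs (lag-one correlation
  ld_rho) thresholded at Φ⁻¹(f_j); summing two haplotypes gives
  Hardy–Weinberg dosages with tunable neighbour LD. Defaults: m = 50,
  maf_range = (0.05, 0.5), ld_rho = 0.5 — a modest cis-region LD level.
- **Expression.** One causal probe: x = b_zx·g_causal + ε, ε ~ N(0,1),
  with b_zx = 0.5 per allele in expression-SD units (a strong cis eQTL:
  |Z_E| ≈ 15–25 at n = 5 000). Nine further probes are pure noise, and the
  emulated panel size used for thresholding is n_probes_total = 1 000 —
  small enough for seconds-scale experiments, large enough that the
  Bonferroni threshold (5×10⁻⁵) is meaningfully strict.
- **Trait.** In the independent GWAS cohort only the *genetic* component
  of expression propagates: y = b_xy·b_zx·g_causal + ε. This is the clean
  causal model — no environmental-expression confounding path. A
  `pleiotropy_beta` toggle adds a direct SNP→trait effect; T_SMR cannot
  distinguish that from mediation (a documented limitation, not an
  asserted property — distinguishing them is what heterogeneity tests are
  for, and those are out of scope).
- **Summary reduction.** Each study reports per-SNP simple least-squares
  β, SE and the t-test p (df n−2), exactly the marginal-regression output
  real deposits contain. The trait is simulated quantitative even though
  disease GWAS are typically case–control: the method operates purely on
  β/SE, whose Z-score behaviour is the same on either scale.
- **Panel identity.** rsIDs, positions and allele labels form a fixed
  reference panel shared by every simulation (frequencies and cohorts
  remain per-configuration), so independently parameterized GWAS and eQTL
  tables still intersect and harmonize — mirroring how real studies share
  dbSNP identifiers. A configurable fraction of SNPs (default 0.5) is
  reported by the GWAS on the opposite allele with β negated, exercising
  the alignment step; a `palindromic_fraction` lets tests exercise the
  strict-policy drop path.

What the model does **not** emulate: realistic LD from reference panels,
allele-frequency differences between cohorts, case–control ascertainment,
multiple causal variants per gene, trans effects, and sample overlap
between studies. Passing calibration/power tests therefore demonstrates
the statistic and pipeline are implemented correctly under the stated
model, not that the method is robust to those real-data complications.

## Experiment sizes and numerical choices

- Type-I error: 2 000 replicates of a single-SNP, n = 1 000-per-cohort
  null simulation with b_zx = 0.7 (median |Z_E| ≈ 14, minimum ≈ 7 across
  frequency draws), rejecting at nominal α = 0.05. The binomial 95% band
  around 0.05 at 2 000 replicates is (0.040, 0.060).
- Power: 1 000 replicates per b_xy ∈ {0, 0.1, 0.2, 0.4} under the default
  50-SNP model at n = 5 000 per cohort, calling success when the causal
  gene is Bonferroni-significant at 0.05/1 000. Wald-ratio recovery:
  median of 500 replicates at b_xy = 0.3; causal-probe ranking: 200
  replicates. These sizes put Monte-Carlo error well inside the margins
  being checked while keeping the whole suite at minutes scale.
- Replicate seeds derive from one base seed via `SeedSequence`; identical
  configuration + seed reproduces byte-identical tables, result files and
  manifests (floats serialized at 15 significant digits, which round-trips
  IEEE doubles to ≤1e-12 relative).
- Monomorphic SNPs in a finite cohort have no estimable slope; their rows
  are emitted with missing SE and dropped by the readers, counted.
- Degenerate inputs: empty SNP intersections and datasets where nothing
  passes the threshold are valid outcomes (warned, never raised); an
  overlap rate between two empty gene sets is defined as 0 with a warning.

## Overlap reports

Dataset-level gene sets (exact symbol match, no aliasing) are compared
pairwise. The default rate is `min_fraction` = |A∩B|/min(|A|,|B|) — the
fraction of the smaller gene list that is shared — with Jaccard
(|A∩B|/|A∪B|) selectable; Jaccard never exceeds min_fraction. Outputs are
a symmetric rate matrix (TSV) and an annotated heatmap (PNG).

## Design choices where the design was open

- `all_pairs` instrument selection as the default (rather than the
  canonical top-cis-eQTL rule) because panel-wide thresholding combined
  with per-pair testing is what lets one gene accumulate several
  significant supporting SNPs; both modes ship.
- The Bonferroni denominator follows the source panel (see above);
  exposed as configuration.
- Strict palindrome dropping by default: without allele frequencies a
  palindromic SNP's strand is genuinely ambiguous, and frequency-based
  rescue is out of scope.
- The pipeline's demo grid (2 GWAS × 4 eQTL panels of 1 000/800/500/400
  probes, n = 4 000 per cohort) is sized so each combination finishes in
  seconds yet the causal gene is reliably discovered.
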