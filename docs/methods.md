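# Methods

## Data model

A survey is a tidy table of non-negative concentrations (mg/g dry weight)
keyed by site, compartment (`soil` or `biota`), element symbol and
replicate index. Element symbols are normalized at ingest (`"AL"` → `"Al"`)
because they are the join key between the concentration table and the
background table; every (site, compartment) group must cover the same
ordered element panel. Units are treated as opaque labels: the source
tables print mg/g dry weight (unusually high for soils — µg/g is more
plausible physically) and the package performs no unit conversion.

Replicate-level data for the original survey were never published, so the
packaged fixture stores each printed group mean as a single `replicate=1`
record and the printed standard errors as side metadata
(`fixtures.table2_se()`). Indices are always computed from group means, so
single-record groups and replicated groups flow through the same path.

## Indices

- CF = C_metal / C_background, per site and element, on soil means.
  The published band definitions use strict inequalities on both ends
  ("1 < CF < 3"), which leaves boundary values unassigned; classification
  here uses half-open intervals closed on the left — [0,1) low, [1,3)
  moderate, [3,6) considerable, [6,∞) very high — so it is total and
  deterministic. A coarse two-way split (`classify_cf_two_way`, CF ≥ 3 =
  "high") is derived on demand for presentation.
- PLI = geometric mean of a site's CFs, computed in log space for overflow
  safety; any CF = 0 gives PLI = 0 (the geometric-mean limit, not an
  error). PLI = 0 → perfection, (0,1] → baseline, >1 → deteriorated.
- DC = Σ CF with bands proportional to the element count n; the bands are
  taken at face value, so DC = n classifies as moderate ("n ≤ DC < 2n").
- BCF = biota mean / soil mean per site and element; the bioaccumulation
  rule is inclusive (BCF ≥ 1), the one boundary the source states
  explicitly.
- Between-site ratio = biota mean at site 1 / biota mean at site 2.

Elements missing from the background table are skipped for CF with a
warning collected on the report (and logged); the site's PLI/DC then
aggregate over the covered elements only, with `n_elements` recording the
count actually used. Zero soil or denominator means likewise produce
warnings rather than exceptions in the whole-panel report; the scalar
functions raise `DomainError` for out-of-domain arguments.

Background concentrations are mandatory user input: the original survey
never published its reference values, and its printed CF/PLI/DC table
cannot be reproduced from the printed concentrations under any single
background table. The repository ships an all-ones `unit_background.csv`,
clearly labelled, so the machinery is runnable; the printed CF/PLI/DC
table is packaged as a display fixture only.

## Statistics

One-way ANOVA is computed across all (site, compartment) groups of an
element (scipy `f_oneway`), with pairwise comparisons by Tukey's HSD
(scipy `tukey_hsd`) at α = 0.05. The source tables never name their
post-hoc procedure; Tukey HSD is the package's reading of "different
superscripts differ significantly". Letters are assigned by descending
mean using interval-based compact-letter merging: every maximal run of
consecutively ranked groups that are pairwise non-significant receives one
letter, so the highest-mean group always carries "a" and significantly
different groups never share a letter. Degenerate variance structures are
resolved explicitly: all values equal → F = 0, p = 1 (one shared letter);
zero within-group variance with distinct means → F = ∞, p = 0 (any mean
difference significant).

Pearson correlation matrices pair observations by replicate index within a
(site, compartment) scope; p-values use the exact t transform with n − 2
degrees of freedom. Pairs with fewer than 3 complete observations or an
element with zero variance are reported as undefined (NaN, flag `na`),
never fabricated. Flags mirror the two-level reporting convention
(p ≤ 0.05, p ≤ 0.01) with no multiple-testing correction by default,
matching how such matrices are usually printed; a Bonferroni option
(`correction="bonferroni"`, p multiplied by the number of off-diagonal
pairs) is available as opt-in rigor. The printed correlation matrices of
the original survey are not reproducible — the pairing unit and n behind
them were never published — so they serve as layout references only.

## Synthetic data

`generate_panel` draws value = soil_median·site_effect·enrichment^[biota]·exp(z)
with z multivariate normal, covariance diag(σ)·R·diag(σ). The lognormal
multiplicative model is the simplest one under which every survey
statistic is well defined: concentrations stay positive, the configured
`enrichment` is the true BCF, the per-site factor cancels out of BCF and
of the enrichment estimator, and R is the log-scale correlation the
Pearson screening should recover. One correlation structure is shared by
both compartments.

Defaults (`fixtures.study_config()`) emulate the surveyed conditions: the
16-element panel, soil medians set to the printed Site I soil means,
enrichment factors set to the printed Site I BCF column, a Site II effect
equal to the geometric mean of the printed soil Site II/Site I ratios,
σ = 0.3 (the middle of the printed SE/mean range at three replicates per
group) and n = 3 replicates, the package's reading of the survey's
analytical replication. `recover_parameters` closes the loop: enrichment
as the biota/soil ratio of geometric means and dispersion as the pooled
within-group standard deviation of log values.

What the generator does **not** emulate: detection-limit censoring,
between-colony (as opposed to analytical) variance components,
caste-specific accumulation, spatial soil structure, and per-compartment
correlation differences. Tests passing on synthetic panels therefore
validate the arithmetic and the statistical machinery under a clean
lognormal world, not the field realism of any particular survey.

## Pipeline and numerical conventions

`RunConfig`/`run_pipeline` tie ingest → indices → stats into one run that
emits the concentration summary (mean ± SE with compact letters when every
group has ≥ 2 replicates), the CF/PLI/DC table, the BCF/ratio table,
per-scope correlation matrices (skipped with a warning below 3
replicates), and a JSON summary. CSV floats are printed at 4 decimals to
mirror the source tables' precision; the JSON keeps full precision. Every
output carries a 12-hex-digit SHA-256 hash of the analytical configuration
(output directory and log level excluded) plus the seed, and re-running an
identical configuration is byte-stable. Exit codes: 0 ok, 1 input error,
2 internal error.

Problem sizes used by the test suite were chosen to make sampling checks
sharp but cheap: n = 200–500 replicates for parameter-recovery and
correlation-recovery checks, 1000 random CF vectors for the geometric-mean
oracle, 2000 replicates for the ANOVA null calibration.

## Sequence summary

`summarize_fasta` reports length (all residues) and GC fraction
(G+C)/(A+C+G+T) with U counted as T and N/ambiguity codes excluded from
both numerator and denominator, insensitive to case and line wrapping. The
barcode fixture used in tests, `fixtures.synthetic_reference_standin()`,
is a synthetic stand-in matching only the deposited 12S rRNA fragment's
printed summary statistics (407 bases, GC ≈ 34.2%); it carries no
biological signal and real accession FASTA should be used whenever
sequence content matters.

## Known limitations

- Six of the sixteen printed BCF/ratio rows (Al, Cd, Co, Fe, Mn, Mo) are
  arithmetically inconsistent with the printed concentration means
  (apparent transcription errors such as a soil Co mean of 0.519 where
  ~0.05 would be consistent); `fixtures.CONSISTENT_RATIO_ELEMENTS` and
  `CONSISTENT_BCF_CELLS` list the cells that do recompute, and only those
  are asserted against.
- The printed CF/PLI/DC table lists PLI and DC per metal although both are
  defined as per-site aggregates; those per-metal values cannot be
  reconciled with the definitions and are not recomputed.
- The printed significance superscripts and correlation coefficients
  depend on unpublished replicate-level data; the package reproduces the
  procedures, validated by oracle and calibration tests, not those printed
  values.
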