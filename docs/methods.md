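# Methods

## Data model

A clonotype is identified by the pair (chain, CDR3 amino-acid sequence).
V/J gene calls and the nucleotide sequence are carried through but ignored
for matching: repertoires assembled from bulk RNA-seq are compared at the
CDR3 level, and keeping the chain in the key prevents collisions between
loci. A `pool_chains` switch collapses the key to the CDR3 sequence alone
for sensitivity analyses. CDR3 strings containing stop codons (`*`) or
ambiguous residues (`X`) are dropped at read time with a logged count —
non-productive or ambiguous assemblies cannot be meaningfully matched across
samples — and sequences shorter than 6 amino acids are removed before any
analysis. TRUST-style fractional read estimates are rounded half-up at
ingest so that all downstream contingency tables are integer-valued.

## Diversity

CPK (clonotypes per kilo-read) = unique clonotypes / total TCR reads × 1000.
Shannon entropy is computed in nats on read-count proportions and the
Simpson index as Gini–Simpson (1 − Σp²); both are reported alongside CPK but
are known to track sequencing depth strongly in variable-depth bulk data,
which is why CPK is the primary metric. Depth dependence of any metric is
quantified as a linear mixed-model association of the metric with total
reads, with a patient random intercept.

The immune metagene score is the mean per-gene z-score (across samples) over
a supplied gene set; zero-variance genes are dropped with a log line. This
is a deliberate simplification — the score stands in for module scores
derived in upstream co-expression work whose exact construction is not
re-derived here — and it is exactly what the synthetic generator emits, so
the association machinery is exercised end to end.

Association of CPK with the metagene score uses a linear mixed model
(`cpk ~ score + (1 | patient)`), fitted by maximum likelihood with the slope
tested by a likelihood-ratio test against the intercept-only model.
A singular or non-converging fit falls back to patient-demeaned ordinary
regression, flagged in the result's `method` field. The LRT was fixed as the
contract (rather than a Wald test) because it is well defined in the
fallback-free case and invariant to parameterization. The outcome comparison
(regressive vs progressive/persistent CPK within the proliferative subtype)
is a two-sided Mann–Whitney U test without patient adjustment, because
repeated measures are not available for every patient in that subset; both
group means and medians are reported since a single location summary would
be ambiguous.

## Sharing

For each unordered pair of biopsies the 2×2 table is
[shared, unique-to-A; unique-to-B, remainder of the clonotype universe],
where the universe is the distinct clonotype set of the *whole* cohort —
biopsies and brushes when brushes are loaded — so the background matches the
cohort-wide count while pairing stays biopsy-only. Fisher's exact test uses
the standard two-sided convention (sum of hypergeometric probabilities of
tables at most as probable as the observed one). The reported odds ratio is
the sample OR with the Haldane–Anscombe 0.5 correction applied only when a
cell is zero; group summaries report both the mean OR and the mean log2 OR,
because raw mean ORs are dominated by a few extreme pairs while the log2
scale is what the group comparison (ANOVA + Tukey HSD) operates on. BH-FDR
is computed once, jointly across all pairs (including cross-patient pairs),
and a pair is "enriched" when FDR < 0.01 and OR > 1. Group labels are
mutually exclusive: different patient; same patient only (different location
and time); same patient + same location (different time); same patient +
same timepoint (different location). Same patient + same location + same
time would be a single sample and cannot form a pair. Pairs involving an
empty repertoire are excluded with a log line.

## Clonal expansion

Within each sample, counts are normalized to counts per thousand reads
(CPT); per-sample CPT sums to 1000 exactly. Samples with fewer than 250
total TCR reads are removed first — low totals inflate CPT and create a
spurious depth–expansion association, and the built-in check (Pearson
correlation of expanded-clone count with depth on retained samples, PASS
when p > 0.05) verifies the filter did its job. The expansion cutoff is
mean + 3 SD of the *pooled* set of all (clonotype, sample) CPT observations
across retained samples. Pooling (rather than per-clonotype moments) is the
reading consistent with normalizing "all TCRs" together; a
`per_clonotype=True` variant exposes the alternative, falling back to the
pooled cutoff for clonotypes observed once. Clones absent from a sample
contribute no structural zeros to the moments — the observation universe is
what was detected, and padding with zeros would make the threshold depend on
the cohort universe size. Chains are pooled when computing the threshold.

Recurrent expansion counts distinct (patient, location, clonotype) triples
expanded at ≥ 2 timepoints. The permutation null shuffles expanded /
not-expanded labels uniformly across all observations of retained samples,
preserving the total number of expanded labels in each of the (default
1000) draws; the p-value uses the add-one rule
p = (1 + #{draws ≥ observed}) / (1 + B), which is never zero and at 1000
draws bottoms out at 1/1001 ≈ 0.001 — reported as p < 0.001.

## Public vs private

A clonotype is public when observed in ≥ 2 patients — brushes count here,
since they sharpen the patient tally — or when it is a β-chain sequence
present in an external healthy-donor CDR3 list (the α/γ/δ chains get no
reference rescue). Database matching is exact on the CDR3 sequence,
chain-aware when the database row declares a chain. The expansion–publicness
table is reported for biopsy-observed clonotypes (primary) and for all
clonotypes (secondary, in `extra`), since which comparison set underlies the
published figure is ambiguous. When a cohort has no public (or no private)
clonotypes the 2×2 loses a column and the odds ratio is uninformative; the
result is flagged `degenerate_public_classes` rather than forced to a
number. A sensitivity hook re-runs sharing, the CPK–metagene association and
the outcome comparison on the private-only cohort and reports both runs side
by side.

## Synthetic cohort generator

The generator emulates the screening-cohort structure: `n_patients = 50`
patients, 3 procedures, 2 biopsied lesions per patient plus one brush per
procedure (450 samples). Per-sample TCR read depth is log-normal
(log-mean 4.87, log-SD 1.0 → median ≈ 130 reads, ~26% of biopsies at
≥ 250 reads, matching a regime where only a minority of biopsies clear the
expansion filter). Clonotypes live in a shared public pool (800 clones,
75% β-chain) and disjoint patient-private pools (400 clones each); CDR3
strings are random valid amino-acid strings of length 8–20 framed by C…F,
with no sequence-level realism beyond the alphabet.

Each sample draws `round(0.55 · depth^0.85)` distinct clones (capped by the
pool) with weights: public clones scaled so the aggregate public mass is
`p_public_draw = 0.2`; clones the patient used before get ×3; clones used at
the same procedure ×2.5 extra; clones used at the same location ×1.6 extra.
The multiplicative ordering (time boost > location boost) is what produces
the observed ordering of pair-sharing enrichment. Abundances are
Dirichlet-multinomial (concentration 8 per clone), giving moderate
overdispersion without a heavy natural tail that would masquerade as
expansion.

60 expansion slots are assigned to read-filter-passing biopsies; each slot
multiplies one clone's Dirichlet weight by 50. The expanded clone is chosen
among the sample's clones with preference ×8 for clones the patient used
before and ×3 for public clones — realizing the enrichment of expansion
among shared and public TCRs — and recurs at the same lesion's
next-timepoint biopsy with probability 0.6 when that biopsy also passes the
read filter (so planted truth stays observable). Regressive lesions draw
from an effectively smaller clone pool (unique-rate × 0.6), lowering their
CPK; the per-sample metagene score is −(realized CPK/100) + N(0, 0.5²), so
the negative CPK–module association holds by construction. Ground truth
(clonotype origin and publicness, planted expansions, recurrences, outcome,
true scores) is emitted as separate tables, never embedded in the AIRR
file.

Two frozen companions support the test suite. `scaled_config` (12 patients,
smaller pools) keeps multi-seed replicate suites fast; `null_config`
disables every effect — boosts 1, one shared pool (`p_public_draw = 1`) so
patient identity is uninformative, outcome effect off, planting preferences
off, recurrence probability 0 — while keeping planted expansions (randomly
placed) and high depth over a small pool, so the expansion caller and the
recurrence count retain resolution and type-I calibration checks are not
vacuous. All lesions are labelled proliferative under the null so the
outcome comparison always has two groups.

What the generator does **not** emulate: V(D)J recombination statistics and
generation probabilities, sequence-similarity structure, HLA restriction,
realistic clone-size power laws, or batch effects. Passing tests therefore
demonstrate that the statistical machinery recovers the planted structure
under the stated sampling model — not that the biological effect sizes in
real airway data are reproduced.

## Numerical and design choices

- Fisher p-values agree with exact hypergeometric enumeration to 1e-10
  (verified on random tables with N ≤ 40 and on small-cohort pair tables).
- Mann–Whitney uses exact enumeration for pooled n ≤ 12 without ties,
  otherwise the normal approximation with tie and continuity corrections.
- ANOVA/Tukey on groups that are all one constant returns p = 1 rather than
  0/0.
- Degenerate correlations (constant expansion counts across samples) return
  p = 1 with a flagged method rather than raising mid-pipeline.
- One master seed drives everything; the CLI derives per-stage streams from
  it, and reruns are byte-identical.
- Replicate suites run at reduced scale (12-patient cohorts for orderings
  and associations; 6-patient null cohorts, 200 replicates, 199 permutations
  per replicate for calibration), sizes chosen to keep the default test run
  fast while leaving the binomial calibration bands meaningful.

## Known limitations

- The mixed-model fallback (patient-demeaned OLS) tests a within-patient
  slope only; its p-value is not exchangeable with the LRT p.
- The pooled mean+3SD expansion rule is depth-sensitive in principle; it is
  only validated here in combination with the 250-read filter.
- Exact CDR3 matching understates database concordance relative to fuzzy or
  motif-based matching.
- The sample odds ratio with Haldane correction is biased for sparse tables;
  the conditional-MLE odds ratio is reported alongside it in `extra`.
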