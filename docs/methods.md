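# Methods

`promopop` analyses an aligned sample of promoter-region sequences drawn
from hierarchically structured natural populations (groups of populations
of accessions). This note records the models and procedures implemented,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
open.

## Haplotype model and gap conventions

Accessions are collapsed to haplotypes by exact sequence identity over the
alphabet `{A, C, G, T, -, N}` with the gap treated as a **fifth character
state**: two accessions differing only at a gap column carry different
haplotypes. `N` is missing data; it equals only itself for collapsing
(conservative and deterministic — an `N` never silently merges two
haplotypes) and never creates a polymorphic site.

A **tandem gap** — a maximal run of gap columns carried by exactly the
same set of accessions — is one insertion/deletion event and is counted
as a single unit of variation. Adjacent gap runs with different carrier
sets are separate events. Substitution sites are single columns with at
least two non-gap, non-`N` states. A site is flagged **rare** when its
minor state is carried by 1–2 accessions *and* that count is below 2% of
the sample.

Internal coordinates are 0-based half-open; all report tables are 1-based
inclusive.

The consensus is the column-wise most frequent state (gap eligible), with
ties broken by the fixed order `A < C < G < T < -`. It can be weighted by
accession (default — every sequenced individual counts) or computed
unweighted over the distinct haplotypes; both are exposed because either
convention is defensible when a sample is dominated by one haplotype.
Per-haplotype difference profiles count variation *units* (tandem gaps
merged) between haplotype and consensus.

## Diversity and neutrality statistics

- **Haplotype diversity** uses Nei's unbiased estimator
  `Hd = n (1 − Σ p_i²) / (n − 1)`.
- **Mean pairwise differences** `k` average the per-pair difference count
  over all `n(n−1)/2` accession pairs (haplotype multiplicities
  respected); **nucleotide diversity** `π = k / L_eff`.
- **Gap modes.** `complete` (default): every column containing a gap or
  `N` in any included sequence is excluded and `L_eff` is the number of
  remaining columns — the conventional behaviour of diversity software.
  `fifth-state`: gaps are a state, tandem-gap events count once, and
  `L_eff` is the alignment length. Reports name the mode used.
- **Tajima's D** follows the standard 1989 formulation,
  `D = (k − S/a₁)/√(e₁S + e₂S(S−1))`, with the usual coefficient chain
  (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ depending only on n). Undefined (reported
  missing) when `S = 0`.
- **Fu & Li's F\*** (no outgroup) is
  `F* = (k − η_s (n−1)/n) / √(u_F η + v_F η²)` with the corrected variance
  coefficients (the Simonsen–Churchill–Aquadro form used by standard
  software). η counts mutations (a site with m states contributes m−1);
  η_s counts mutations private to a single sequence. The coefficients are
  validated in the test suite against an independent exact-rational
  transcription of the same published formulas.
- **Significance.** Where the original workflow delegated significance to
  desktop software, we use an explicit null: Kingman n-coalescent
  genealogies with exactly `S` infinite-sites mutations dropped on
  branches with probability proportional to branch length; the statistic
  is recomputed per replicate and the two-tailed empirical p uses a +1
  pseudo-count, `p = (1 + #{|sim| ≥ |obs|})/(1 + reps)`. The same null
  underlies the mean-D calibration test (n = 20 conditioned on S = 20,
  2000 genealogies).

## AMOVA

Two-level hierarchy (groups / populations within groups / within
populations). Sums of squares follow the Excoffier convention,
`SS_unit = (1/M) Σ_{i<j} δ²`, computed block-wise over haplotypes so the
accession × accession matrix is never materialised. The default distance
is **identity** (δ² = 1 between different haplotypes) — the
"haplotype-frequency" AMOVA, which admits the closed form
`SS = (M² − Σ c_k²)/(2M)` and reproduces the published variance table
exactly from the published count table. A **differences** mode (squared
fifth-state event counts between haplotype sequences) is provided for
sequence-aware AMOVA.

Variance components use the standard unequal-sample-size coefficients
(n′, n″, n‴); Φ statistics are `Φ_CT = Va/V`, `Φ_SC = Vb/(Vb+Vc)`,
`Φ_ST = (Va+Vb)/V`. Negative components are reported and flagged, never
truncated; rounding (3 d.p., matching the published table) happens only
at report time. Permutation significance permutes accessions among
populations (Φ_ST), accessions among populations within groups (Φ_SC),
and whole populations among groups (Φ_CT), each with the +1 correction.
The permutation loop uses a numpy-only re-implementation of the component
algebra that is cross-checked against the full path in the test suite.

## Motif (TFBS) scanning and enrichment

Motif libraries are user-supplied TSVs of IUPAC consensus patterns
(≥ 4 bases) with transcription-factor names and functional categories;
the package ships a small plausible monocot promoter library as the
simulation default. Scanning is exhaustive over the ungapped haplotype
sequence, overlapping matches all reported, and each hit carries both
ungapped and alignment coordinates. The default is forward-strand only
(promoters are directional); `both` scans the reverse strand by matching
the reverse-complemented pattern, keeping forward coordinates.

Hits of a motif whose alignment intervals overlap form a **locus**; a
locus is **conserved** iff every haplotype has a hit there.

Enrichment uses sequence reshuffling: the observed count of a motif (or a
pooled category — both units are exposed, since either reading of
"abundant binding signals" is defensible) on a sequence is compared with
counts on `reps` reshuffles, `p = (1 + #{null ≥ obs})/(1 + reps)`. The
default shuffle preserves mononucleotide composition; an
Altschul–Erickson Euler-path shuffle preserving exact dinucleotide counts
is available because motif nulls are sensitive to dinucleotide content.
No multiple-testing correction is applied by default (matching the
original single-test reporting); Benjamini–Hochberg can be applied by the
caller on the returned table.

## Synthetic cohort generator

The generator emulates the study design so every stage is testable
without the archived sequences:

- 2000 bp founder, i.i.d. bases at GC 0.44 (typical Pooideae promoter
  composition).
- The published 22-haplotype × 5-population count table (112 accessions;
  populations of 19–26), groups southern = {P1, P2}, northern =
  {P3, P4, P5}.
- Per-haplotype mutation recipes drawn from the seed: 2–30 substitutions
  (the published range of consensus differences), positions drawn without
  replacement uniformly over non-indel columns (infinite-sites-like, so
  oracle counting stays exact); six tandem indels of 2–8 bp assigned to
  the divergent southern-cluster haplotypes; 21 extra private
  substitutions on haplotypes carried by 1–2 accessions, realising the
  published count of rare polymorphisms.
- Indels are alignment columns shared by all records (gap in carriers),
  so output is already aligned — the pipeline consumes pre-aligned input.
- Optional motif planting writes concrete IUPAC instances at random
  gap-free, non-overlapping loci of target haplotypes for enrichment
  power tests.

All randomness flows from one integer seed through a single generator;
reruns are byte-identical.

**What it does not emulate:** coalescent/recombination genealogy,
selection, sequencing error, alignment uncertainty, or real promoter
sequence composition beyond GC content. Passing tests therefore
demonstrate that the *procedures* are correct on data with the assumed
structure, not that the archived sequences would yield any particular
π, D, F\* or TFBS value — those are accession-dependent. Quantities that
depend only on the count table (Hd row, frequency-based AMOVA) are exact
reproductions.

## Numerical and design choices

- Statistics are computed in double precision and rounded only in report
  tables (3 d.p.).
- `Hd`, `D`, `F*` are undefined (reported missing / raising a typed
  error) for n < 2, n < 4, or S = η = 0 rather than returning 0.
- Permutation and simulation p-values never return 0: the +1 pseudo-count
  bounds them below by 1/(reps+1).
- Zero total variance in AMOVA raises an explicit undefined-percentages
  error rather than emitting NaNs.
- Pipeline stage seeds are derived from the root seed by hashing the
  stage name (SHA-256, reduced below 2³¹), so stages are reproducible
  standalone.
- The motif stage is failure-isolated: a malformed library cannot corrupt
  the population-genetic outputs.

## Problem sizes used in the shipped analyses and tests

The analysis drivers default to the full 112-accession cohort with 10 000
enrichment permutations. The test suite uses the same cohort but smaller
Monte-Carlo sizes chosen to keep sampling error well inside the asserted
tolerances: 2000 genealogies for the mean-D check, 500 replicate datasets
× 999 shuffles for enrichment calibration (300 bp sequences — calibration
is length-invariant), 200 datasets × 199 genealogies for neutrality
p-value calibration, and 99–199 permutations where only determinism or an
extreme-case floor is asserted.

## Known limitations

- AMOVA supports at most the three-level hierarchy (no locus-by-locus
  mode).
- Fu & Li's D\*/F with an outgroup are not implemented (no outgroup in
  scope).
- The identity-distance AMOVA ignores how different two haplotypes are;
  use the differences mode when that matters.
- The coalescent null assumes a panmictic constant-size population within
  the tested scope; for structured scopes the p-values are approximate in
  the usual way.
- IUPAC scanning is consensus matching, not PWM scoring; degenerate
  patterns weight all compatible bases equally.
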