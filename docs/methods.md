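# Methods

## The comparative model

The unit of analysis is a **codon-aligned orthologous segment pair**: two
coding sequences, one per species, aligned at the protein level and
back-translated so that every residue column is a codon column. Columns are
classified once and consumed by every statistic:

* *indel* — a gap in either species; excluded from all counts;
* *invalid* — an in-frame stop codon or a non-ACGT symbol in either codon;
  such a column disqualifies the whole pair (pair-level purge, matching the
  filter chain's semantics) rather than being silently skipped;
* otherwise *codon-identical*, *synonymous* (same amino acid, different
  codon) or *non-synonymous*, plus an *nt12-conserved* flag (first and
  second bases identical).

Synonymy is defined purely by identical translation. Serine's two codon
families (TCN and AGY) therefore form one synonymous class, but a
cross-family serine pair can never be nt12-conserved, so the conditioned
GC3 statistic excludes it by construction.

**Non-synonymous side.** Over exchanged columns we accumulate the 20×20
count matrix `C[i][j]` (residue *i* in species A, *j* in species B;
diagonal = conserved columns), the antisymmetric imbalance
`D = C − Cᵀ`, and net usage `net(i) = Σⱼ D[i][j]`. Antisymmetry forces
`Σᵢ net(i) = 0` exactly, and relabeling the species transposes `C` and
negates `D` and all nets — both identities are enforced and tested. The
ERK statistic counts E, R and K residues per segment among exchanged
positions only; the per-pair differences `erk_A − erk_B` enter a two-sided
paired Wilcoxon signed-rank test (zeros dropped — Wilcoxon's original
rule; exact null for effective n ≤ 25 without ties, otherwise the normal
approximation with tie and continuity correction). A `fraction` variant
divides by the number of exchanged positions.

**Synonymous side.** Only synonymous, nt12-conserved columns enter the GC3
ledger: `gc3_to_at3` counts columns where species A's third base is A/T
while B's is G/C, `at3_to_gc3` the reverse, and
`net_gc3_loss_A = gc3_to_at3 − at3_to_gc3` (positive when lineage A has
drifted toward A/T wobble bases relative to B). Per-codon usage is
tabulated over the **59 informative codons** (61 sense codons minus ATG and
TGG, whose one-codon families carry no synonymous signal) at
amino-acid-conserved positions; frequencies are normalized per species over
those 59, so the shifts `f_A − f_B` sum to zero. The 2×2 contingency
{AT3, GC3} × {shift > 0, shift < 0} is tested with Fisher's exact test
(two-sided by the point-probability rule; exact ties in shift are tallied
separately and excluded).

**Within-family correspondence analysis (WCA).** Rows are (segment ×
species) codon-count vectors. Each row's counts are converted to
within-family frequencies (codon count / that row's family total; rows
missing a family fall back to the pooled family shares, a zero-information
profile there), centered against the row-weighted mean profile, scaled by
the chi-square metric (√ of the weighted mean frequency), weighted by row
mass and decomposed by SVD. This removes amino-acid composition from the
analysis, leaving purely synonymous structure; the row-weighted mean
coordinate is zero on every axis by construction. Because CA axes have
arbitrary sign, axis 1 is oriented so that the mean coordinate of
AT3-ending codons is positive. Per-species row clouds are summarized by
mean and 2×2 covariance; ellipses default to 1.5 SD (configurable).

**Pairing.** Candidate pairs are all cross-species sequence pairs sharing
an orthology group. The in-repo aligner is an exact affine-gap
Smith–Waterman under BLOSUM62 with BLAST-style gap cost
`open + L·extend` (defaults 11/1, so a length-1 gap costs 12).
The traceback is deterministic: it starts at the maximum cell (row-major
first on ties) and prefers diagonal, then up, then left; gap states close
into the match state on ties. `X` scores 0 against everything; `*` carries
a −10⁶ score so no local alignment can cross a stop. Percent identity
follows the BLAST `pident` convention (identical pairs / alignment length,
gaps in the denominator). Per group the single best alignment is kept
(score, then identity, then lexicographically smallest id pair); pairs then
need identity ≥ 80 % (boundary inclusive; a strict flag exists) and either
e-value ≤ 10⁻⁹ (when hits come from an external table) or raw score ≥ 50
(internally aligned pairs — the in-repo aligner has no database context,
so Karlin–Altschul e-values are out of scope). Identity is measured over
the aligned (HSP) region. A sequence may be best in more than one group;
it is retained but flagged in the report.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the study conditions:

| parameter | default | meaning / why |
| --- | --- | --- |
| `n_pairs` | 4155 | ortholog pairs at study scale |
| `codon_length` | 100 | codons per ancestor (~100 aligned codon pairs/segment) |
| `p_syn` | 0.10 | per-codon synonymous substitution probability per lineage |
| `p_nonsyn` | 0.02 | per-codon non-synonymous probability per lineage; with the `syn-first` cascade this yields ~96 % translated identity: conserved ≈ (1 − 0.9·0.02)² ≈ 0.964 |
| `delta_at3` | 0.05 | lineage-A wobble A/T preference; synonymous resampling weights are `1 ± delta·[AT3]` (+ for A, − for B). Chosen so the expected net GC3 shift is a fraction of a percent of the synonymous nt12-conserved columns (≈ 2·p_syn·δ/4 ≈ 0.25 %), the magnitude regime of the real comparison |
| `p_indel` | 0.02 | whole-codon indel probability (frame always preserved — frameshifts would test nothing in scope) |
| `n_decoys` | 100 | partner-less sequences per species |
| `p_misassign` | 0.01 | fraction of orthology rows pointed at a wrong group |

Ancestors draw amino acids from a fixed vertebrate-like frequency vector
and codons uniformly within each family; they are stop-free by
construction. Per codon the event cascade is: synonymous resampling with
probability `p_syn`, else non-synonymous replacement with `p_nonsyn`, else
indel — one event per codon per lineage, no explicit branch lengths, since
the downstream analysis is count-based, not rate-based. Non-synonymous
targets are drawn from **per-lineage** row-stochastic 20×20 preference
matrices (uniform off-diagonal by default). One root seed feeds per-pair
child seeds derived by counter, so generation is order-independent and
byte-identical across platforms.

**Why per-lineage preference matrices.** A single shared matrix can never
inject a detectable imbalance: both lineages would replace residues
identically and `D` would be mean-zero by symmetry. Presets therefore set
lineage A's matrix only.

**Why the `E2D_excess` preset also suppresses E as a target.** A
row-stochastic conditional-target matrix conserves each source residue's
total replacement rate: boosting `P(target = D | source = E)` retargets E's
replacements without changing E's net balance, so `net(E)` stays ~0 while
`net(D)` rises. The biologically meaningful signature — a lineage that
*loses* glutamic acid and uses aspartic acid instead — requires both a
boosted E→D outflow (0.8) and a suppressed inflow into E (factor 0.05 on
the E column, rows renormalized). Preset strengths were set by a power
calculation (effect/SD ≥ 2.6 per component at 200 pairs × 150 codons), so
sign recovery succeeds in ≥95 % of replicates as the recovery tests require.

## Numerical and design choices

* Coordinates are 0-based half-open codon indices everywhere; input
  sequences are canonicalized to upper case; any codon containing a
  non-ACGT symbol translates to `X`, stops to `*` (the purge keys on them).
* Counting and classification run on integer codon indices
  (`16·b₁ + 4·b₂ + b₃`), fully vectorized; string-level rescans exist only
  as independent test oracles.
* Fisher's two-sided p uses the point-probability rule (sum of tables with
  probability ≤ observed), the dominant convention; the Wilcoxon test
  follows the exact/approximate switching rule above.
* Degenerate inputs: an all-identical WCA table is an error (no
  synonymous-usage variance); all-zero ERK differences give p = 1 with a
  warning; zero codon totals are errors.
* `mean_gc` reports the unweighted mean of per-segment GC (headline) and
  the pooled, length-weighted value, since either convention is defensible.
* The imbalance matrix is additionally rendered in the conventional printed
  lower-triangular layout (rows C..Y × columns A..W). A polar/unpolar
  aggregation utility takes a user-supplied partition; no particular
  partition is endorsed.

## What passing tests do and do not show

The generator reproduces the *counting structure* of real data (paired
columns, family-constrained synonymous choices, indels, decoys, assignment
noise). It does **not** emulate: between-gene heterogeneity of GC3 and of
substitution rates, codon-usage selection beyond the single wobble
preference, within-gene rate variation, alignment error against deep
orthology profiles, or expression-level effects (libraries are treated as
presence/diversity profiles). Consequences worth knowing:

* With the homogeneous default bias, the WCA species separation at study
  scale is weak and axis 1 is not guaranteed to carry it (real
  transcriptomes have large between-gene GC3 variance that pins axis 1 to
  the GC3 gradient; the constructed-gradient tests cover that regime).
* **The codon-level Fisher test is mildly anti-conservative on paired
  data.** A synonymous substitution shifts one codon up in species A and
  its family partner up in species B, so per-codon shifts are negatively
  dependent within synonymous families — the 59 codons are not independent
  units. Measured at 200 pairs × 150 codons under the null: rejection rate
  ≈ 0.08 at nominal α = 0.05 (vs ≈ 0.04 when the two libraries are made
  independent). The aggregate contingency test on paired ortholog sets —
  here and in comparable published analyses — should therefore be read
  with this caveat; the test suite asserts the stated ≤ 0.07 calibration
  bound and documents this known failure rather than hiding it.
* Midrank Spearman correlation against a *binary* indicator is bounded
  below 1 (≈ √3/2 for a balanced split): the WCA axis-1/AT3 agreement
  checks normalize by the exact tie-bound maximum, so "≥ 0.9" means 90 %
  of perfect rank separation.

## Limitations

No e-value calibration for the internal aligner (score threshold instead);
no codon-model likelihoods (GY94-style), dN/dS, ENC/CAI, or tRNA-adaptation
measures; no multiple-HSP chaining; protein alignments are authoritative
(no codon-aware realignment). Functional profiling assumes term→category
maps are provided; it never runs profile searches itself.
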