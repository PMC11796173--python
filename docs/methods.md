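# Methods

## Scope and model

The package reimplements, as a tested pipeline, the curation analysis
behind the ARMC5 mutational landscape in PBMAH: variant nomenclature
parsing, evidence assignment under the ACMG-AMP framework with the
gene-specific conventions appropriate to a two-hit tumor suppressor,
five-class combination, and cohort-level aggregation. Coordinates are
1-based and inclusive on the canonical transcript (c. numbering,
NM_001105247.1) and the 935-residue protein; no genomic (g.) coordinates
are modelled because the curated tables provide none, and no reference
sequence is consulted (printed ref bases are taken on faith).

## HGVS layer

A tolerant lexer ingests the tables verbatim: typeset whitespace is
stripped (`c.407 T>C`), redundant explicit bases on duplications are
dropped from the normalized form (`c.2697dupG` → `c.2697dup`), the
misplaced-asterisk frameshift form `fs44*` is read as `fs*44`, and the
parenthesized alias form `c.170del (= c.165del)` resolves to the primary
description with the alias retained. Unsupported constructs (inversions,
extensions) raise rather than misparse. Formatting a parsed change
reproduces its normalized string, and parse→format→parse is the identity
over every string in the packaged tables (tested).

Consequence inference: an intron offset of magnitude ≤ 2 on either span
endpoint is a canonical splice change; structural events map to
large-deletion; otherwise the protein-level kind decides, with the three
in-frame subkinds collapsed to one category. A printed impact from a
curated table is ground truth: contradictions are logged at warning level
and the printed impact retained. One table variant (`c.1371-3C>A`) is
splice only by its printed impact — the −3 offset is non-canonical and
inference alone would not call it.

## Evidence assignment

Assignment rules follow the table's legend, with two deliberate
gene-specific choices:

* **PS3 from a somatic second hit.** For a proven two-hit tumor
  suppressor, a second somatic event in tumor DNA is treated as
  functional evidence of a damaging effect and fires PS3; the criterion
  carries a provenance tag (`functional_assay` vs `somatic_second_hit`).
  A functional result showing *no* damaging effect fires BS3 instead and
  suppresses second-hit PS3, so the pair is never co-emitted.
* **PVS1 strength split at the NMD-escape boundary.** Truncating point
  variants whose new termination codon (the altered residue for a
  nonsense change; start + fs offset − 1 for a frameshift) lies at or
  beyond `nmd_escape_codon` carry PVS1 at strong (`PVS1_S`). The default
  668 is derived from the curated table (full PVS1 through the
  654-residue stop, `PVS1_S` from residue 683 on), not from transcript
  annotation, and is configurable. Splice and large-deletion variants
  keep full PVS1 (no single termination codon).

MAF tiers (all configurable): PM2 when the variant is absent from
population databases or below 1e-5 (absence is distinct from an observed
zero); BS1 at ≥ 0.001; BA1 at ≥ 0.05; a polymorphism flag at > 0.02 that
the as-curated combiner turns into class benign. Codes with no occurrence
in the curated tables (PS2, PS4, PM3, PM6, PP2, BS4, BP2, BP5, BP7) are
representable but have no assignment rule.

## Combining policies

`strict` restates the published combining table rule by rule; evaluation
is over effective strengths (a modified PVS1 counts as strong), any
benign-side/pathogenic-side conflict or an empty rule set yields VUS. The
implementation is verified against an independent brute-force evaluator
over the exhaustive enumeration of bounded criteria multisets (2160
cases), plus randomized monotonicity and permutation-invariance checks.

`as_curated` reproduces the printed table's precedence, in fixed order:
polymorphism override → benign rules → relaxed likely-benign (a single
strong-benign code with no supporting-benign suffices) → pathogenic rules
→ VUS. Every precedence application is logged at warning level so
curation quirks stay auditable. Over the transcribed table this policy
reproduces 142/145 printed classes; the three mismatches are
pre-registered irreducible quirks (an in-frame duplication printed VUS
although its criteria satisfy a likely-pathogenic combination, and two
variants printed likely benign on a single supporting-benign code, which
no combining rule reaches). The strict policy's mismatches are a
superset (139/145), confined to benign-side and in-frame entries.

## Transcribed tables and their known discrepancies

The packaged TSVs transcribe the published germline and somatic tables;
SHA-256 checksums are recorded and verified on load. The available source
text of the germline table carries 145 variants (plus the three frequent
polymorphisms), one in-frame indel short of the prose totals (146
variants, 6 in-frame, 48 indel, 36 novel); the missing row was evidently
lost in text extraction of the original table and is not reconstructed.
`consistency_report` flags this, together with the genuine internal
inconsistencies of the source: the somatic SNV sub-counts (27+23+2) that
contradict the printed 51, two protein annotations inconsistent with
their cDNA codon (somatic `c.1851del p.(His518Thrfs*12)`, codon 617; and
germline `c.2149C>A p.(Ser730*)`, codon 717), and a 13th protein-level
germline/somatic match (`p.(Ala106Argfs*31)`, encoded by different cDNA
events) that the published 12-variant intersection omits.

Counting conventions chosen to reproduce the published totals:

* The germline total counts distinct cDNA descriptions, so the two
  dual-encoded protein changes (`Ile58Asnfs*45` from c.170dup/c.172dup;
  `Trp386*` from c.1157G>A/c.1158G>A) count twice each. Index-case counts
  for the 34 recurrent protein variants come from the source's
  recurrence enumeration; the per-cDNA apportionment of dual-encoded
  totals (4 → 2+2, 2 → 1+1) is editorial. All other variants default to 1.
* The somatic total counts distinct events keyed at protein level (the
  two encodings of `Cys353*` merge), with cnLOH as one event class and
  the partial deletion as one event — 104 over the transcribed table.
* Germline∩somatic overlap matches on normalized cDNA descriptions by
  default, reproducing the published 12; protein-level matching is
  available and yields the superset of 13.
* Percentages round half-up to integers; "truncating" pools nonsense and
  frameshift.

## Domain map

The armadillo-repeat region (default residues 8–383) and the C-terminal
BTB/POZ domain (default 703–930) are configurable approximations — the
tables print no coordinates — and affect only hotspot-domain annotation
(PM1) and the lollipop model, never the landscape counts.

## Synthetic cohorts

The generator emulates: the observed consequence mix (46% missense,
truncating split 42:24 frameshift:nonsense, 3% splice, 4% in-frame, 2%
large deletions); a truncated-geometric recurrence distribution
(p = 0.75, max 10 — mostly private variants, occasional strong
recurrence); a five-class latent mix defaulting to the pathogenic-heavy
composition of reported cohorts (0.02/0.12/0.26/0.25/0.35); and second
hits attached to class-4/5 variants with probability 0.4, split
cnLOH/point 50:50. Frameshift stop offsets are drawn uniformly from
1–110, the range seen in the curated tables. Criteria profiles are
sampled from per-class template pools verified unambiguous under the
strict combiner at import time, so latent-class recovery is exactly 100%
by construction — the recovery test is a pipeline integrity check, not a
statistical claim. Variants are distinct at both cDNA and protein level
via rejection sampling; an overfull spec raises an infeasibility error.

What the generator does **not** emulate: real mutational hotspots or
sequence context (positions are uniform over residues 2–815), codon-level
consistency between the synthesized ref/alt amino acids and actual codon
changes, clinical phenotypes, penetrance, or the curation quirks above.
Passing synthetic tests therefore demonstrates pipeline correctness and
statistical calibration of the generator itself, not performance on real
cohorts; the transcribed tables serve the latter role.

## Numerical and degenerate-input choices

Percentages use decimal half-up rounding (never banker's rounding).
Summaries of empty inputs return zeros; `combine` of an empty criteria
set is VUS; recurrence and overlap of empty lists are empty. Duplicate
evidence codes collapse silently when strengths agree and raise when they
conflict. All summaries are invariant under row permutation (tested).
Problem sizes in the test suite (synthetic cohorts of 30–10,000 variants,
five 30-record subsamples for the brute-force cross-checks) keep the full
suite in the single-digit seconds while exercising every code path.
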