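# armc5curate

ACMG-AMP variant curation and mutational-landscape statistics for
**ARMC5**, the tumor-suppressor gene whose germline inactivating variants
cause 20–25% of Primary Bilateral Macronodular Adrenal Hyperplasia
(PBMAH). The package is for clinical geneticists and curators who need to
classify newly observed ARMC5 variants against the published landscape,
and for method developers who need a tested, scriptable reimplementation
of the curation rules behind that landscape.

## What it does

* **HGVS parsing** of cDNA (`c.`, transcript NM_001105247.1) and protein
  (`p.`, 935 residues) descriptions, tolerant of the typesetting quirks in
  published tables (stray whitespace, `c.2697dupG`-style redundant bases,
  `fs44*` for `fs*44`), plus consequence inference (missense, nonsense,
  frameshift, splice, in-frame indel, large deletion).
* **ACMG-AMP engine**: evidence codes PVS1–BP7 with strength levels,
  assignment from structured annotations with the gene-specific
  conventions used for ARMC5 —
  * a somatic second hit in tumor DNA fires **PS3** (two-hit
    tumor-suppressor evidence);
  * **PVS1 is downgraded to strong** (`PVS1_S`) for truncating variants
    whose new termination codon falls at or beyond the NMD-escape
    boundary (default residue 668);
  * MAF tiers: PM2 below 1e-5 (or absent), BS1 at ≥ 0.001, BA1 at ≥ 5%,
    with a polymorphism override at > 0.02;
  and combination into the five classes (benign … pathogenic) under a
  `strict` policy (published guideline; conflicts → VUS) or an
  `as_curated` policy that reproduces the published table's precedence
  (benign evidence first, single strong-benign code suffices for likely
  benign).
* **Landscape statistics** over the packaged, checksum-verified
  transcription of the published germline (148 rows: 145 variants + 3
  polymorphisms) and somatic (106 rows, 104 distinct events) tables:
  consequence spectra, SNV/indel split, protein-level recurrence,
  multi-hit residues, germline∩somatic overlap, domain annotation and a
  JSON lollipop-plot model.
* **Synthetic cohorts** with the same statistical structure (consequence
  mix, truncated-geometric recurrence, latent five-class truth with
  rule-consistent criteria profiles, Knudson-style second hits) for
  pipeline testing without the curated tables.

## Worked example

```
$ curator summarize --out report.json
{
  "n_germline": 145,
  "n_somatic": 104,
  "n_shared": 12,
  "n_total_distinct": 237,
  "concordance": "142/145"
}
```

145 distinct germline variants load from the packaged table (one
in-frame row of the published 146 is absent from the available source
text; `curator validate` flags every such discrepancy), 104 distinct
somatic events, 12 variants seen both germline and somatic, and the
as-curated combiner reproduces 142/145 printed classifications — the
three exceptions are irreducible table quirks, listed by
`curator concordance`.

```
$ curator classify --criteria "PVS1PM2PP4"
PVS1;PM2;PP4 -> class 5 (Pathogenic)
$ curator classify --criteria "BS2BP6PS3" --policy as_curated
BS2;BP6;PS3 -> class 2 (Likely benign)
```

The first is the standard truncating-variant profile (very strong + one
moderate + one supporting). The second shows benign-side precedence
under the as-curated policy: strong-benign plus supporting-benign
evidence outweighs the PS3 second-hit evidence.

Library use mirrors the CLI:

```python
from armc5curate import (load_packaged_germline, load_packaged_somatic,
                         summarize_germline, germline_somatic_overlap)

germline = [r for r in load_packaged_germline() if not r.polymorphism]
somatic = load_packaged_somatic()
summary = summarize_germline(germline)
summary.counts_by_consequence   # {'missense': 67, 'frameshift': 42, ...}
len(germline_somatic_overlap(germline, somatic))  # 12
```

## Layout

* `src/armc5curate/hgvs.py` — HGVS parsing, consequence inference
* `src/armc5curate/acmg.py` — evidence codes, assignment, five-class combination
* `src/armc5curate/landscape.py` — spectra, recurrence, overlap, lollipop model
* `src/armc5curate/io_tables.py` — TSV schemas, checksums, JSON reports, config
* `src/armc5curate/synthetic.py` — seeded synthetic cohort generator
* `src/armc5curate/data/` — transcribed germline/somatic tables (TSV + checksums)
* `docs/methods.md` — model, parameters, conventions and limitations
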