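"""Synthetic germline/somatic cohort generation.

The generator emulates the statistical structure of a curated
tumor-suppressor variant cohort: a consequence-category mix matching the
observed germline spectrum, a heavy-tailed (truncated-geometric)
recurrence distribution dominated by private variants, latent five-class
truth with criteria profiles sampled conditionally on the class, and
Knudson-style somatic second hits (copy-neutral LOH or point events)
attached to pathogenic/likely-pathogenic germline variants.

Criteria profiles are drawn from per-class template pools that are
unambiguous under the strict combining policy, so the latent class is
exactly recoverable from the emitted criteria — any recovery miss is a
bug, not noise. The generator deliberately never reproduces the
irreducible curation quirks of the real table (e.g. a likely-benign call
from a single supporting-benign code).
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .hgvs import (
    AA3, CdnaChange, Consequence, ProteinChange, StructuralEvent,
    StructuralKind, parse_cdna, parse_protein, PROTEIN_LENGTH,
)
from .acmg import (
    Classification, CriteriaSet, EngineConfig, combine, parse_criteria_string,
)
from .landscape import SomaticEvent, VariantRecord

# germline consequence mix observed in the curated spectrum: 46% missense,
# 45% truncating split 42:24 frameshift:nonsense, 3% splice, 4% in-frame,
# 2% large deletions
DEFAULT_CONSEQUENCE_MIX: Dict[Consequence, float] = {
    Consequence.MISSENSE: 0.46,
    Consequence.FRAMESHIFT: 0.45 * 42 / 66,
    Consequence.NONSENSE: 0.45 * 24 / 66,
    Consequence.SPLICE: 0.03,
    Consequence.INFRAME_INDEL: 0.04,
    Consequence.LARGE_DELETION: 0.02,
}

# five-class mix loosely following the curated table (pathogenic-heavy,
# benign classes rare among reported variants)
DEFAULT_CLASS_MIX: Dict[Classification, float] = {
    Classification.BENIGN: 0.02,
    Classification.LIKELY_BENIGN: 0.12,
    Classification.VUS: 0.26,
    Classification.LIKELY_PATHOGENIC: 0.25,
    Classification.PATHOGENIC: 0.35,
}

TRUNCATING_CONSEQUENCES = {Consequence.NONSENSE, Consequence.FRAMESHIFT,
                           Consequence.SPLICE, Consequence.LARGE_DELETION}

# criteria-profile templates per (class, truncating?); every template is
# verified unambiguous under combine(strict) at import time
_TEMPLATES: Dict[Tuple[Classification, bool], List[str]] = {
    (Classification.PATHOGENIC, True): [
        "PVS1;PM2;PP4", "PVS1;PS3;PM2", "PVS1;PM2;PP4;PP5", "PVS1;PS3;PM2;PP4"],
    (Classification.PATHOGENIC, False): [
        "PS3;PM2;PM5;PP3;PP4", "PS3;PS1;PM2", "PS3;PM1;PM2;PP3;PP5"],
    (Classification.LIKELY_PATHOGENIC, True): [
        "PVS1;PM2", "PVS1_S;PM2;PP4"],
    (Classification.LIKELY_PATHOGENIC, False): [
        "PS3;PM2;PP4", "PM2;PM5;PP3;PP4", "PM1;PM2;PP3;PP4", "PS3;PP3;PP4"],
    (Classification.VUS, True): [
        "PM2"],
    (Classification.VUS, False): [
        "PM2", "PM2;PP4", "PM2;PP3;PP4", "PP4"],
    (Classification.LIKELY_BENIGN, True): [
        "BP4;BP6"],
    (Classification.LIKELY_BENIGN, False): [
        "BP4;BP6", "BS1;BP4", "BP1;BP3;BP4"],
    (Classification.BENIGN, True): [
        "BA1"],
    (Classification.BENIGN, False): [
        "BA1", "BS1;BS2", "BA1;BP4;BP6"],
}


def _check_templates() -> None:
    cfg = EngineConfig(conflict_policy="strict")
    for (cls, _), pool in _TEMPLATES.items():
        for tpl in pool:
            got = combine(parse_criteria_string(tpl), cfg)
            if got is not cls:
                raise AssertionError(
                    f"template {tpl!r} combines to {got.name}, expected {cls.name}")


_check_templates()


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``recurrence_p`` is the success parameter of a geometric recurrence
    distribution truncated at ``recurrence_max`` (most variants private,
    occasional strong recurrence); ``second_hit_prob`` is the probability
    that a pathogenic/likely-pathogenic germline variant has a somatic
    second hit, split cnLOH vs point event by ``loh_fraction``.
    """

    n_variants: int = 100
    consequence_mix: Dict[Consequence, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX))
    latent_class_mix: Dict[Classification, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    recurrence_p: float = 0.75
    recurrence_max: int = 10
    second_hit_prob: float = 0.4
    loh_fraction: float = 0.5
    n_shared_keys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("consequence_mix", self.consequence_mix),
                          ("latent_class_mix", self.latent_class_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} sums to {total}, expected 1")
        if not 0 < self.recurrence_p <= 1:
            raise ValueError("recurrence_p must be in (0, 1]")
        if self.n_shared_keys > self.n_variants:
            raise ValueError("cannot plant more shared keys than variants")


@dataclass
class SyntheticCohort:
    germline: List[VariantRecord]
    somatic: List[SomaticEvent]
    truth: Dict[str, Classification]  # cDNA/event key -> latent class


_BASES = "ACGT"
_AA_LIST = sorted(AA3)


def _truncated_geometric(rng: random.Random, p: float, max_k: int) -> int:
    k = 1
    while k < max_k and rng.random() > p:
        k += 1
    return k


def _sample_mix(rng: random.Random, mix: Dict) -> object:
    keys = list(mix)
    return rng.choices(keys, weights=[mix[k] for k in keys], k=1)[0]


def _random_missense_like(rng: random.Random, residue: int, stop: bool) -> Tuple[str, str]:
    """Random substitution HGVS pair within a codon (bases 3*codon-2 .. 3*codon)."""
    ref, alt = rng.sample(_AA_LIST, 2)
    pos = 3 * residue - 2 + rng.randint(0, 2)
    b1, b2 = rng.sample(_BASES, 2)
    cdna = f"c.{pos}{b1}>{b2}"
    protein = f"p.({ref}{residue}*)" if stop else f"p.({ref}{residue}{alt})"
    return cdna, protein


def _synthesize_variant(
    rng: random.Random, consequence: Consequence, serial: int = 0,
) -> Tuple[object, Optional[ProteinChange]]:
    """One syntactically valid HGVS pair (or structural event) per category."""
    if consequence is Consequence.LARGE_DELETION:
        lo = rng.randint(1, 4)
        hi = rng.randint(lo, 6)
        # serial keeps synthetic deletion descriptions distinct as grouping keys
        return (StructuralEvent(StructuralKind.PARTIAL_DELETION,
                                description=f"exons {lo}-{hi} deletion [{serial}]"),
                None)
    residue = rng.randint(2, PROTEIN_LENGTH - 120)
    pos = 3 * residue - 2  # first base of the codon
    if consequence is Consequence.SPLICE:
        off = rng.choice([1, 2])
        sign = rng.choice("+-")
        b1, b2 = rng.sample(_BASES, 2)
        return parse_cdna(f"c.{pos}{sign}{off}{b1}>{b2}"), None
    if consequence in (Consequence.MISSENSE, Consequence.NONSENSE):
        cdna, prot = _random_missense_like(
            rng, residue, stop=consequence is Consequence.NONSENSE)
        return parse_cdna(cdna), parse_protein(prot)
    if consequence is Consequence.FRAMESHIFT:
        ref, alt = rng.sample(_AA_LIST, 2)
        n = rng.randint(1, 110)  # fs*N offsets observed in curated tables
        kind = rng.choice(["del", "dup"])
        return (parse_cdna(f"c.{pos + rng.randint(0, 2)}{kind}"),
                parse_protein(f"p.({ref}{residue}{alt}fs*{n})"))
    # in-frame single-residue deletion
    ref = rng.choice(_AA_LIST)
    return (parse_cdna(f"c.{pos}_{pos + 2}del"),
            parse_protein(f"p.({ref}{residue}del)"))


_MAX_DRAWS = 200


def _draw_distinct(rng: random.Random, consequence: Consequence, serial: int,
                   used_keys: set) -> Tuple[object, Optional[ProteinChange]]:
    """Rejection-sample until the cDNA/event key and protein key are fresh.

    Distinctness is required at both levels so synthetic cohorts, like the
    curated tables, contain *different* variants; the combined key space
    (positions x base pairs x edit kinds) is far larger than any plausible
    cohort, so a failure to draw a fresh variant marks an infeasible spec.
    """
    for _ in range(_MAX_DRAWS):
        event, protein = _synthesize_variant(rng, consequence, serial)
        keys = {event.key if isinstance(event, StructuralEvent) else event.hgvs()}
        if protein is not None:
            keys.add(protein.key)
        if not (keys & used_keys):
            used_keys.update(keys)
            return event, protein
    raise ValueError(
        f"infeasible spec: cannot draw a fresh {consequence.value} variant "
        f"after {_MAX_DRAWS} attempts")


def _profile_for(rng: random.Random, cls: Classification,
                 consequence: Consequence) -> CriteriaSet:
    truncating = consequence in TRUNCATING_CONSEQUENCES
    pool = _TEMPLATES[(cls, truncating)]
    return parse_criteria_string(rng.choice(pool))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort from a seed.

    Germline variants receive syntactically valid HGVS strings at random
    residues, criteria profiles sampled conditionally on the latent class
    (unambiguous under the strict combiner), and recurrence counts from the
    truncated-geometric distribution. Somatic second hits (cnLOH or point
    truncating events) attach to pathogenic/likely-pathogenic variants with
    probability ``second_hit_prob``; the first ``n_shared_keys`` germline
    point variants are additionally replayed as somatic events to plant a
    known germline/somatic overlap.
    """
    rng = random.Random(spec.seed)
    germline: List[VariantRecord] = []
    somatic: List[SomaticEvent] = []
    truth: Dict[str, Classification] = {}
    used_keys: set = set()

    for serial in range(spec.n_variants):
        consequence = _sample_mix(rng, spec.consequence_mix)
        cls = _sample_mix(rng, spec.latent_class_mix)
        event, protein = _draw_distinct(rng, consequence, serial, used_keys)
        criteria = _profile_for(rng, cls, consequence)
        rec = VariantRecord(
            cdna=event,
            protein=protein,
            consequence=consequence,
            printed_criteria=criteria,
            printed_class=cls,
            second_hit_reported="unknown",
            functional_reported="unknown",
            context="pbmah",
            novel=rng.random() < 0.25,
            n_index_cases=_truncated_geometric(
                rng, spec.recurrence_p, spec.recurrence_max),
            polymorphism=False,
        )
        germline.append(rec)
        truth[rec.cdna_key or rec.protein_key] = cls

        if (cls >= Classification.LIKELY_PATHOGENIC
                and rng.random() < spec.second_hit_prob):
            if rng.random() < spec.loh_fraction:
                somatic.append(SomaticEvent(
                    event=StructuralEvent(StructuralKind.CNLOH),
                    protein=None, category="cnLOH",
                    associated_germline=(rec.protein_key,)))
            else:
                s_event, s_protein = _draw_distinct(
                    rng, Consequence.FRAMESHIFT, serial, used_keys)
                somatic.append(SomaticEvent(
                    event=s_event, protein=s_protein, category="frameshift",
                    associated_germline=(rec.protein_key,)))

    planted = 0
    for rec in germline:
        if planted >= spec.n_shared_keys:
            break
        if rec.structural or rec.protein is None:
            continue
        somatic.append(SomaticEvent(
            event=rec.cdna, protein=rec.protein,
            category=rec.consequence.value.replace("inframe_indel", "inframe"),
            associated_germline=()))
        planted += 1
    if planted < spec.n_shared_keys:
        raise ValueError(
            f"could not plant {spec.n_shared_keys} shared keys: only "
            f"{planted} point germline variants available")
    return SyntheticCohort(germline=germline, somatic=somatic, truth=truth)


@dataclass
class RecoveryReport:
    n_total: int
    n_recovered: int
    misses: List[Tuple[str, Classification, Classification]]

    @property
    def recovery_rate(self) -> float:
        return 1.0 if self.n_total == 0 else self.n_recovered / self.n_total


def recover_classes(cohort: SyntheticCohort,
                    cfg: Optional[EngineConfig] = None) -> RecoveryReport:
    """Re-derive each latent class from the emitted criteria via combine(strict).

    Cohorts generated with unambiguous profiles recover at exactly 100%;
    any miss indicates a combiner or generator defect.
    """
    cfg = cfg or EngineConfig(conflict_policy="strict")
    misses = []
    n_rec = 0
    for rec in cohort.germline:
        key = rec.cdna_key or rec.protein_key
        want = cohort.truth[key]
        got = combine(rec.printed_criteria, cfg, polymorphism=rec.polymorphism)
        if got is want:
            n_rec += 1
        else:
            misses.append((key, want, got))
    return RecoveryReport(n_total=len(cohort.germline), n_recovered=n_rec,
                          misses=misses)


def cohort_to_tables(cohort: SyntheticCohort) -> Tuple["pd.DataFrame", "pd.DataFrame"]:
    """Render a cohort in the germline/somatic TSV schemas (pipeline closure)."""
    import pandas as pd

    IMPACT_LABEL = {
        Consequence.MISSENSE: "Missense", Consequence.NONSENSE: "Nonsense",
        Consequence.FRAMESHIFT: "Frameshift", Consequence.SPLICE: "Splice",
        Consequence.INFRAME_INDEL: "In frame deletion",
        Consequence.LARGE_DELETION: "Large deletion",
        Consequence.SYNONYMOUS: "Synonymous",
    }
    g_rows = []
    for r in cohort.germline:
        g_rows.append({
            "cdna": r.cdna.hgvs() if not r.structural else r.cdna.description,
            "protein": r.protein.hgvs() if r.protein else "NA",
            "impact": IMPACT_LABEL[r.consequence],
            "classification": r.printed_class.label,
            "criteria": r.printed_criteria.serialize(),
            "second_hit": "NA", "functional": "NA", "context": r.context,
            "novel": "1" if r.novel else "0",
            "n_index_cases": str(r.n_index_cases),
            "polymorphism": "1" if r.polymorphism else "0",
            "refs": ",".join(r.refs),
        })
    s_rows = []
    S_LABEL = {"missense": "Missense", "nonsense": "Nonsense",
               "frameshift": "Frameshift", "splice": "Splice",
               "inframe": "In frame", "large_deletion": "Deletion",
               "cnLOH": "Deletion"}
    for e in cohort.somatic:
        s_rows.append({
            "cdna": ("cnLOH" if isinstance(e.event, StructuralEvent)
                     and e.event.kind is StructuralKind.CNLOH
                     else e.event.hgvs() if not e.structural
                     else e.event.description),
            "protein": e.protein.hgvs() if e.protein else "NA",
            "impact": S_LABEL[e.category],
            "associated_germline": ";".join(e.associated_germline) or "none",
            "context": e.context,
            "refs": ",".join(e.refs),
        })
    g_cols = ["cdna", "protein", "impact", "classification", "criteria",
              "second_hit", "functional", "context", "novel", "n_index_cases",
              "polymorphism", "refs"]
    s_cols = ["cdna", "protein", "impact", "associated_germline", "context", "refs"]
    return (pd.DataFrame(g_rows, columns=g_cols),
            pd.DataFrame(s_rows, columns=s_cols))


def write_cohort(cohort: SyntheticCohort, out_dir) -> Tuple[str, str]:
    """Write a cohort as germline/somatic TSVs; returns the two paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g_df, s_df = cohort_to_tables(cohort)
    g_path, s_path = out / "germline.tsv", out / "somatic.tsv"
    g_df.to_csv(g_path, sep="\t", index=False)
    s_df.to_csv(s_path, sep="\t", index=False)
    return str(g_path), str(s_path)
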