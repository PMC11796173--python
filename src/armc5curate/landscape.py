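"""Mutational-landscape statistics over curated germline and somatic
ARMC5 variant tables: consequence spectra, protein-level recurrence,
multi-hit residues, germline/somatic overlap, domain annotation and a
serializable lollipop-plot model.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .hgvs import (
    CdnaChange, Consequence, ProteinChange, StructuralEvent, StructuralKind,
    is_snv, PROTEIN_LENGTH,
)
from .acmg import Classification, CriteriaSet


@dataclass(frozen=True)
class VariantRecord:
    """One curated germline variant (a row of the germline table)."""

    cdna: Union[CdnaChange, StructuralEvent]
    protein: Optional[ProteinChange]
    consequence: Consequence
    printed_criteria: CriteriaSet
    printed_class: Classification
    second_hit_reported: str = "unknown"  # yes | no | unknown
    functional_reported: str = "unknown"
    context: str = "pbmah"
    novel: bool = False
    n_index_cases: int = 1
    polymorphism: bool = False
    refs: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_index_cases < 1:
            raise ValueError("n_index_cases must be >= 1")

    @property
    def structural(self) -> bool:
        return isinstance(self.cdna, StructuralEvent)

    @property
    def protein_key(self) -> str:
        """Grouping key: normalized protein change, else the event itself."""
        if self.protein is not None:
            return self.protein.key
        return self.cdna.key

    @property
    def cdna_key(self) -> Optional[str]:
        return None if self.structural else self.cdna.key


@dataclass(frozen=True)
class SomaticEvent:
    """One somatic tumoral alteration (a row of the somatic table)."""

    event: Union[CdnaChange, StructuralEvent]
    protein: Optional[ProteinChange]
    category: str  # missense|nonsense|frameshift|splice|inframe|large_deletion|cnLOH
    associated_germline: Tuple[str, ...] = ()
    context: str = "pbmah"
    refs: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.event, StructuralEvent):
            if self.event.kind is StructuralKind.CNLOH and self.protein is not None:
                raise ValueError("cnLOH events carry no HGVS fields")

    @property
    def structural(self) -> bool:
        return isinstance(self.event, StructuralEvent)

    @property
    def key(self) -> str:
        """Distinct-event key: protein change when present, else the event."""
        if self.protein is not None:
            return self.protein.key
        return self.event.key

    @property
    def cdna_key(self) -> Optional[str]:
        return None if self.structural else self.event.key


# Approximate domain bounds on the 935-residue protein. The armadillo-repeat
# region occupies the N-terminal/central part of the protein and the BTB/POZ
# protein-interaction domain sits in the C-terminus; exact coordinates are
# not part of the curated tables, so these are configurable defaults used
# only for annotation and plotting.
DEFAULT_DOMAINS = (("Armadillo repeats", 8, 383), ("BTB/POZ", 703, 930))


@dataclass(frozen=True)
class DomainMap:
    protein_length: int = PROTEIN_LENGTH
    domains: Tuple[Tuple[str, int, int], ...] = DEFAULT_DOMAINS

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in sorted(self.domains, key=lambda d: d[1]):
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"domain {name} out of protein bounds")
            if start <= prev_end:
                raise ValueError(f"domain {name} overlaps the previous one")
            prev_end = end

    def containing(self, residue: int) -> Optional[str]:
        for name, start, end in self.domains:
            if start <= residue <= end:
                return name
        return None


def _pct(numer: int, denom: int) -> int:
    """Integer percentage, rounded half-up."""
    if denom == 0:
        return 0
    return int((Decimal(100) * numer / denom).quantize(0, rounding=ROUND_HALF_UP))


@dataclass
class LandscapeSummary:
    n_variants: int = 0
    counts_by_consequence: Dict[str, int] = field(default_factory=dict)
    pct_by_consequence: Dict[str, int] = field(default_factory=dict)
    n_snv: int = 0
    n_indel: int = 0
    n_structural: int = 0
    n_novel: int = 0
    recurrent_protein_variants: List[Tuple[str, int]] = field(default_factory=list)
    multi_hit_residues: List[int] = field(default_factory=list)
    n_somatic: int = 0
    somatic_counts: Dict[str, int] = field(default_factory=dict)
    n_shared: int = 0
    shared_keys: List[str] = field(default_factory=list)
    n_total_distinct: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_germline(records: Sequence[VariantRecord],
                       include_polymorphisms: bool = False) -> LandscapeSummary:
    """Tally the germline spectrum: consequence counts and rounded percentages,
    SNV/indel/structural split and novelty count.

    Frequent-polymorphism rows are excluded by default, matching the
    convention that the germline variant total counts disease-relevant
    variants only. The "truncating" percentage pools nonsense and
    frameshift.
    """
    recs = [r for r in records if include_polymorphisms or not r.polymorphism]
    counts = Counter(r.consequence.value for r in recs)
    n = len(recs)
    pct = {k: _pct(v, n) for k, v in counts.items()}
    pct["truncating"] = _pct(
        counts.get("nonsense", 0) + counts.get("frameshift", 0), n)
    n_structural = sum(1 for r in recs if r.structural)
    n_snv = sum(1 for r in recs if not r.structural and is_snv(r.cdna))
    return LandscapeSummary(
        n_variants=n,
        counts_by_consequence=dict(counts),
        pct_by_consequence=pct,
        n_snv=n_snv,
        n_indel=n - n_structural - n_snv,
        n_structural=n_structural,
        n_novel=sum(1 for r in recs if r.novel),
        recurrent_protein_variants=[
            (k, t) for k, _, t in recurrence_table(recs) if t >= 2],
        multi_hit_residues=sorted(multi_hit_residues(recs)),
    )


def recurrence_table(records: Sequence[VariantRecord]) -> List[Tuple[str, int, int]]:
    """Protein-level recurrence: (protein key, #distinct cDNA encodings,
    total index cases), sorted by descending total then key.

    Distinct cDNA changes that encode the same protein change (the
    dual-encoded events) collapse into one row whose total pools the
    per-encoding index-case counts.
    """
    cdnas: Dict[str, Set[str]] = defaultdict(set)
    totals: Dict[str, int] = Counter()
    for r in records:
        key = r.protein_key
        cdnas[key].add(r.cdna_key or key)
        totals[key] += r.n_index_cases
    rows = [(k, len(cdnas[k]), totals[k]) for k in totals]
    rows.sort(key=lambda row: (-row[2], row[0]))
    return rows


def multi_hit_residues(records: Sequence[VariantRecord],
                       kinds: Optional[Set[str]] = None) -> Dict[int, Set[str]]:
    """Residues hit by >= 2 distinct protein changes, with the change kinds.

    ``kinds`` restricts the census (e.g. {"missense"} for substitution-only
    multi-hit positions). Structural events and records without protein
    annotation are ignored. The result maps residue -> set of protein-kind
    names and iterates as a set of residues.
    """
    hits: Dict[int, Set[str]] = defaultdict(set)
    kinds_at: Dict[int, Set[str]] = defaultdict(set)
    for r in records:
        if r.protein is None:
            continue
        if kinds is not None and r.protein.kind.value not in kinds:
            continue
        hits[r.protein.start_res].add(r.protein.key)
        kinds_at[r.protein.start_res].add(r.protein.kind.value)
    return {res: kinds_at[res] for res, keys in hits.items() if len(keys) >= 2}


def germline_somatic_overlap(
    germline: Sequence[VariantRecord],
    somatic: Sequence[SomaticEvent],
    on: str = "cdna",
) -> Set[str]:
    """Shared germline/somatic variants, as a set of normalized protein keys.

    ``on="cdna"`` (default) requires the same normalized cDNA description,
    which reproduces the published intersection; ``on="protein"`` matches on
    protein keys alone and may also capture events encoded by different
    cDNA changes. Structural and cnLOH events never match point variants.
    """
    if on not in ("cdna", "protein"):
        raise ValueError("on must be 'cdna' or 'protein'")
    if on == "cdna":
        germ = {r.cdna_key for r in germline if r.cdna_key}
        return {e.key for e in somatic if e.cdna_key and e.cdna_key in germ}
    germ = {r.protein_key for r in germline if not r.structural}
    return {e.key for e in somatic
            if not e.structural and e.protein is not None and e.key in germ}


SOMATIC_CATEGORIES = ("missense", "nonsense", "frameshift", "splice",
                      "inframe", "large_deletion", "cnLOH")


def summarize_somatic(events: Sequence[SomaticEvent]) -> Dict[str, int]:
    """Somatic spectrum over distinct events.

    Distinctness is at event-key level: a protein change encoded by two
    different cDNA edits counts once, cnLOH counts once as an event class
    (the table may list it on several germline backgrounds), and each
    structural deletion counts once per description.
    """
    by_key: Dict[str, str] = {}
    for e in events:
        by_key.setdefault(e.key, e.category)
    counts = Counter(by_key.values())
    out = {cat: counts.get(cat, 0) for cat in SOMATIC_CATEGORIES}
    out["total"] = len(by_key)
    return out


def lollipop_export(records: Sequence[VariantRecord],
                    dmap: DomainMap = DomainMap()) -> List[dict]:
    """Serializable lollipop-plot model: one entry per protein key.

    Recurrence (index-case total) gives the lollipop tail size; class 4/5
    variants form the colored group and class 2/3 the grey group, following
    the usual landscape-figure convention. Structural events have no
    residue and are excluded.
    """
    by_key: Dict[str, dict] = {}
    for r in records:
        if r.protein is None:
            continue
        entry = by_key.setdefault(r.protein_key, {
            "protein_key": r.protein_key,
            "residue": r.protein.start_res,
            "category": r.consequence.value,
            "recurrence": 0,
            "color_group": "pathogenic" if r.printed_class >= Classification.LIKELY_PATHOGENIC
                           else "grey",
            "domain": dmap.containing(r.protein.start_res),
        })
        entry["recurrence"] += r.n_index_cases
    return sorted(by_key.values(), key=lambda d: d["residue"])


# Spectrum totals printed in the source publication, used by
# consistency_report to cross-check a transcribed table against the prose.
PUBLISHED_GERMLINE = {
    "n_variants": 146, "missense": 67, "frameshift": 42, "nonsense": 24,
    "splice": 4, "inframe_indel": 6, "large_deletion": 3,
    "n_snv": 95, "n_indel": 48, "n_novel": 36,
}
PUBLISHED_SOMATIC = {
    "total": 104, "missense": 27, "nonsense": 23, "splice": 2,
    "frameshift": 49, "inframe": 2, "large_deletion": 1, "snv_total": 51,
}
PUBLISHED_SHARED = 12
PUBLISHED_TOTAL_DISTINCT = 238


def _codon_window(c: CdnaChange) -> Tuple[int, int]:
    start_codon = (c.start + 2) // 3
    end_codon = ((c.end or c.start) + 2) // 3
    return start_codon - 1, end_codon + 2


def consistency_report(
    germline: Sequence[VariantRecord],
    somatic: Sequence[SomaticEvent],
    published: bool = True,
) -> List[str]:
    """Cross-check internal identities and (optionally) the published totals.

    Always checked: the conservation identity on distinct-alteration counts,
    cDNA-vs-protein codon consistency of point variants, and duplicate
    protein keys arising from distinct cDNA encodings. With
    ``published=True`` the recomputed spectra are also compared against the
    totals printed in the source prose, flagging every discrepancy
    (including the source's own internally inconsistent somatic SNV
    sub-counts). Returns a list of human-readable flags; an empty list
    means a fully self-consistent cohort.
    """
    flags: List[str] = []
    summary = summarize_germline(germline)
    som = summarize_somatic(somatic)
    shared = germline_somatic_overlap(germline, somatic)
    n_total = summary.n_variants + som["total"] - len(shared)

    # conservation identity recomputed from independent set cardinalities
    germ_keys = {r.cdna_key or r.protein_key for r in germline if not r.polymorphism}
    som_keys = {e.key for e in somatic}
    if len(germ_keys) != summary.n_variants:
        flags.append("duplicate germline cDNA descriptions detected")

    # codon consistency of protein annotation vs cDNA position
    for coll, label in ((germline, "germline"), (somatic, "somatic")):
        for item in coll:
            c = item.cdna if isinstance(item, VariantRecord) else item.event
            p = item.protein
            if not isinstance(c, CdnaChange) or p is None or c.intron_offset:
                continue
            lo, hi = _codon_window(c)
            if not (lo <= p.start_res <= hi):
                flags.append(
                    f"{label} {c.raw_text} {p.raw_text}: protein residue "
                    f"{p.start_res} inconsistent with cDNA codon range {lo}-{hi}")

    # dual-encoded protein changes (same protein key, distinct cDNA)
    enc: Dict[str, Set[str]] = defaultdict(set)
    for r in germline:
        if r.cdna_key:
            enc[r.protein_key].add(r.cdna_key)
    dual = sorted(k for k, v in enc.items() if len(v) > 1)
    if dual:
        flags.append(f"germline dual-encoded protein changes: {', '.join(dual)}")
    prot_shared = germline_somatic_overlap(germline, somatic, on="protein")
    extra = sorted(prot_shared - shared)
    if extra:
        flags.append(
            "protein-level germline/somatic matches with distinct cDNA "
            f"(not in the published intersection): {', '.join(extra)}")

    if published:
        g = PUBLISHED_GERMLINE
        checks = [
            ("germline variant total", summary.n_variants, g["n_variants"]),
            ("germline SNV count", summary.n_snv, g["n_snv"]),
            ("germline indel count", summary.n_indel, g["n_indel"]),
            ("germline novel count", summary.n_novel, g["n_novel"]),
        ]
        for cat in ("missense", "frameshift", "nonsense", "splice",
                    "inframe_indel", "large_deletion"):
            checks.append((f"germline {cat} count",
                           summary.counts_by_consequence.get(cat, 0), g[cat]))
        s = PUBLISHED_SOMATIC
        for cat in ("missense", "nonsense", "splice", "frameshift",
                    "inframe", "large_deletion"):
            checks.append((f"somatic {cat} count", som[cat], s[cat]))
        checks += [
            ("somatic event total", som["total"], s["total"]),
            ("germline/somatic shared count", len(shared), PUBLISHED_SHARED),
            ("total distinct alterations", n_total, PUBLISHED_TOTAL_DISTINCT),
        ]
        for label, got, want in checks:
            if got != want:
                flags.append(f"{label}: recomputed {got} != published {want}")
        snv_sub = s["missense"] + s["nonsense"] + s["splice"]
        if snv_sub != s["snv_total"]:
            flags.append(
                f"published somatic SNV sub-counts sum to {snv_sub}, "
                f"not the printed {s['snv_total']}")
    return flags
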