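"""ACMG-AMP evidence codes, gene-specific assignment rules and the
five-class combining logic used for ARMC5 variant curation.

Evidence codes carry a strength level (stand-alone, very strong, strong,
moderate, supporting). A code may be applied at a non-default strength —
the one modification used here is PVS1 downgraded to strong ("PVS1_S")
for truncating variants whose new termination codon falls late enough in
the last coding stretch to escape nonsense-mediated decay.

Two combining policies are provided. ``strict`` implements the published
guideline: the pathogenic and benign rule sets are evaluated
independently and any conflict (or no rule firing) yields a VUS.
``as_curated`` reproduces the precedence order used in the curated ARMC5
table: a population-polymorphism flag forces benign; benign-side rules
are evaluated first and take precedence over pathogenic evidence; a
single strong-benign code with no supporting-benign code suffices for
likely benign; remaining cases fall through to the pathogenic rules.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .hgvs import Consequence

logger = logging.getLogger(__name__)


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


PATHOGENIC_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
ALL_CODES = PATHOGENIC_CODES + BENIGN_CODES

_PREFIX_STRENGTH = {
    "PVS": Strength.VERY_STRONG, "PS": Strength.STRONG, "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING, "BA": Strength.STAND_ALONE, "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

_STRENGTH_SUFFIX = {
    Strength.VERY_STRONG: "VS", Strength.STRONG: "S",
    Strength.MODERATE: "M", Strength.SUPPORTING: "P",
}
_SUFFIX_STRENGTH = {v: k for k, v in _STRENGTH_SUFFIX.items()}


def default_strength(code: str) -> Strength:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _PREFIX_STRENGTH[prefix]
    raise ValueError(f"unknown ACMG code {code!r}")


@dataclass(frozen=True)
class AcmgCriterion:
    """One ACMG-AMP evidence code applied at an (optionally modified) strength."""

    code: str
    strength: Strength
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown ACMG code {self.code!r}")

    @classmethod
    def of(cls, code: str, strength: Optional[Strength] = None, provenance: str = "") -> "AcmgCriterion":
        return cls(code, strength or default_strength(code), provenance)

    @property
    def modified(self) -> bool:
        return self.strength is not default_strength(self.code)

    @property
    def benign_side(self) -> bool:
        return self.code.startswith("B")

    def serialize(self) -> str:
        if self.modified:
            return f"{self.code}_{_STRENGTH_SUFFIX[self.strength]}"
        return self.code


class CriteriaSet:
    """A set of ACMG criteria; each code appears at most once."""

    def __init__(self, criteria: Iterable[AcmgCriterion] = ()) -> None:
        self._by_code: Dict[str, AcmgCriterion] = {}
        for c in criteria:
            self.add(c)

    def add(self, criterion: AcmgCriterion) -> None:
        prior = self._by_code.get(criterion.code)
        if prior is not None and prior.strength is not criterion.strength:
            raise ValueError(
                f"{criterion.code} given twice at different strengths "
                f"({prior.strength.value} vs {criterion.strength.value})"
            )
        self._by_code.setdefault(criterion.code, criterion)

    def __iter__(self) -> Iterator[AcmgCriterion]:
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> AcmgCriterion:
        return self._by_code[code]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CriteriaSet):
            return NotImplemented
        return {c.code: c.strength for c in self} == {c.code: c.strength for c in other}

    def __repr__(self) -> str:
        return f"CriteriaSet({self.serialize()!r})"

    def serialize(self) -> str:
        """Semicolon-joined codes, e.g. "PVS1_S;PM2;PP4"."""
        return ";".join(c.serialize() for c in self)

    def codes(self) -> List[str]:
        return list(self._by_code)


_TOKEN = re.compile(
    "(" + "|".join(sorted(ALL_CODES, key=len, reverse=True))
    + r")(?:_(VS|S|M|P))?"
)


def parse_criteria_string(text: str) -> CriteriaSet:
    """Tokenize a criteria string, concatenated ("PVS1PM2PP4") or delimited.

    Greedy longest-match tokenization; a strength suffix ("PVS1_S") marks a
    modified criterion. An untokenizable residue raises, naming the fragment.
    """
    cs = CriteriaSet()
    pos = 0
    text = text.strip()
    while pos < len(text):
        if text[pos] in " ;,":
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if not m:
            raise ValueError(f"cannot tokenize criteria string at {text[pos:]!r}")
        code, suffix = m.group(1), m.group(2)
        strength = _SUFFIX_STRENGTH[suffix] if suffix else default_strength(code)
        cs.add(AcmgCriterion(code, strength))
        pos = m.end()
    return cs


class Classification(IntEnum):
    """Five-class pathogenicity scale (class 1 benign ... class 5 pathogenic)."""

    BENIGN = 1
    LIKELY_BENIGN = 2
    VUS = 3
    LIKELY_PATHOGENIC = 4
    PATHOGENIC = 5

    @classmethod
    def from_label(cls, label: str) -> "Classification":
        key = label.strip().lower().replace("_", " ")
        table = {
            "benign": cls.BENIGN, "likely benign": cls.LIKELY_BENIGN,
            "vus": cls.VUS, "uncertain significance": cls.VUS,
            "variant of uncertain significance": cls.VUS,
            "likely pathogenic": cls.LIKELY_PATHOGENIC, "pathogenic": cls.PATHOGENIC,
        }
        if key not in table:
            raise ValueError(f"unknown classification label {label!r}")
        return table[key]

    @property
    def label(self) -> str:
        return {1: "Benign", 2: "Likely benign", 3: "VUS",
                4: "Likely pathogenic", 5: "Pathogenic"}[int(self)]


@dataclass(frozen=True)
class EngineConfig:
    """Thresholds and policy knobs of the classification engine.

    All frequencies are allele fractions in the general population.
    ``nmd_escape_codon`` is the first residue from which a new termination
    codon is assumed to escape nonsense-mediated decay (PVS1 downgraded to
    strong); the default is derived from the curated ARMC5 table, not from
    transcript annotation.
    """

    ba1_threshold: float = 0.05
    bs1_threshold: float = 0.001
    pm2_max_maf: float = 1e-5
    polymorphism_maf: float = 0.02
    nmd_escape_codon: int = 668
    conflict_policy: str = "strict"  # or "as_curated"

    def __post_init__(self) -> None:
        if not (self.pm2_max_maf < self.bs1_threshold < self.polymorphism_maf < self.ba1_threshold):
            raise ValueError("MAF tiers must be ordered pm2 < bs1 < polymorphism < ba1")
        if self.conflict_policy not in ("strict", "as_curated"):
            raise ValueError(f"unknown conflict policy {self.conflict_policy!r}")


@dataclass(frozen=True)
class EvidenceProfile:
    """Structured annotations from which evidence codes are assigned.

    ``maf=None`` means the variant is absent from population databases,
    which is distinct from an observed frequency of zero.
    """

    maf: Optional[float] = None
    insilico: str = "absent"  # deleterious | benign | conflicting | absent
    segregation: bool = False
    phenotype_specific: bool = False
    somatic_second_hit: bool = False
    functional_damaging: str = "untested"  # yes | no | untested
    reputable_source: str = "none"  # pathogenic_report | benign_report | none
    same_aa_known_pathogenic: bool = False
    other_missense_at_residue_pathogenic: bool = False
    in_hotspot_domain: bool = False
    inframe_in_repeat: bool = False
    missense_in_truncating_gene: bool = False
    healthy_adult_carrier: bool = False


TRUNCATING = {Consequence.NONSENSE, Consequence.FRAMESHIFT,
              Consequence.SPLICE, Consequence.LARGE_DELETION}


def assign_criteria(
    consequence: Consequence,
    position: Optional[int],
    ev: EvidenceProfile,
    cfg: EngineConfig = EngineConfig(),
) -> CriteriaSet:
    """Assign ACMG evidence codes from structured annotations.

    Gene-specific conventions: a somatic second hit in tumor DNA fires PS3
    (tumor-suppressor two-hit evidence, treated as functional evidence of a
    damaging effect), and PVS1 is downgraded to strong when the termination
    codon of a nonsense/frameshift variant lies at or beyond the
    NMD-escape boundary. ``position`` is the termination-codon residue for
    truncating point variants and is required for them.
    """
    cs = CriteriaSet()
    if consequence in TRUNCATING:
        if consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
            if position is None:
                raise ValueError("truncating variant requires a termination-codon position")
            escapes_nmd = position >= cfg.nmd_escape_codon
        else:
            # splice and large deletions: no single termination codon; keep
            # the default very-strong weight
            escapes_nmd = False
        cs.add(AcmgCriterion("PVS1",
                             Strength.STRONG if escapes_nmd else Strength.VERY_STRONG))

    if ev.same_aa_known_pathogenic:
        cs.add(AcmgCriterion.of("PS1"))
    if ev.functional_damaging == "yes":
        cs.add(AcmgCriterion.of("PS3", provenance="functional_assay"))
    elif ev.somatic_second_hit and ev.functional_damaging != "no":
        cs.add(AcmgCriterion.of("PS3", provenance="somatic_second_hit"))

    if ev.in_hotspot_domain:
        cs.add(AcmgCriterion.of("PM1"))
    if ev.maf is None or ev.maf < cfg.pm2_max_maf:
        cs.add(AcmgCriterion.of("PM2"))
    if consequence is Consequence.INFRAME_INDEL:
        cs.add(AcmgCriterion.of("BP3" if ev.inframe_in_repeat else "PM4"))
    if ev.other_missense_at_residue_pathogenic:
        cs.add(AcmgCriterion.of("PM5"))

    if ev.segregation:
        cs.add(AcmgCriterion.of("PP1"))
    if ev.insilico == "deleterious":
        cs.add(AcmgCriterion.of("PP3"))
    elif ev.insilico == "benign":
        cs.add(AcmgCriterion.of("BP4"))
    if ev.phenotype_specific:
        cs.add(AcmgCriterion.of("PP4"))
    if ev.reputable_source == "pathogenic_report":
        cs.add(AcmgCriterion.of("PP5"))
    elif ev.reputable_source == "benign_report":
        cs.add(AcmgCriterion.of("BP6"))

    if ev.maf is not None:
        if ev.maf >= cfg.ba1_threshold:
            cs.add(AcmgCriterion.of("BA1"))
        elif ev.maf >= cfg.bs1_threshold:
            cs.add(AcmgCriterion.of("BS1"))
    if ev.healthy_adult_carrier:
        cs.add(AcmgCriterion.of("BS2"))
    if ev.functional_damaging == "no":
        cs.add(AcmgCriterion.of("BS3"))
    if ev.missense_in_truncating_gene and consequence is Consequence.MISSENSE:
        cs.add(AcmgCriterion.of("BP1"))
    return cs


def _effective_counts(cs: CriteriaSet) -> Dict[str, int]:
    n = dict(pvs=0, strong_p=0, moderate=0, supporting=0, ba1=0, bs=0, bp=0)
    for c in cs:
        if c.code == "BA1":
            n["ba1"] += 1
        elif c.benign_side:
            if c.strength is Strength.STRONG:
                n["bs"] += 1
            else:
                n["bp"] += 1
        elif c.strength is Strength.VERY_STRONG:
            n["pvs"] += 1
        elif c.strength is Strength.STRONG:
            n["strong_p"] += 1
        elif c.strength is Strength.MODERATE:
            n["moderate"] += 1
        else:
            n["supporting"] += 1
    return n


def _pathogenic_fires(n: Dict[str, int]) -> bool:
    pvs, s, m, p = n["pvs"], n["strong_p"], n["moderate"], n["supporting"]
    return (
        (pvs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )


def _likely_pathogenic_fires(n: Dict[str, int]) -> bool:
    pvs, s, m, p = n["pvs"], n["strong_p"], n["moderate"], n["supporting"]
    return (
        (pvs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )


def _benign_fires(n: Dict[str, int]) -> bool:
    return n["ba1"] >= 1 or n["bs"] >= 2


def _likely_benign_fires(n: Dict[str, int]) -> bool:
    return (n["bs"] >= 1 and n["bp"] >= 1) or n["bp"] >= 2


def combine(
    cs: CriteriaSet,
    cfg: EngineConfig = EngineConfig(),
    polymorphism: bool = False,
) -> Classification:
    """Combine evidence codes into one of the five classes.

    ``polymorphism`` marks a variant whose population frequency exceeds the
    polymorphism threshold; under the ``as_curated`` policy it forces class
    benign regardless of other evidence. The function is total: any
    unresolved or conflicting evidence yields VUS.
    """
    n = _effective_counts(cs)
    path = _pathogenic_fires(n)
    lpath = _likely_pathogenic_fires(n)
    ben = _benign_fires(n)
    lben = _likely_benign_fires(n)

    if cfg.conflict_policy == "strict":
        if (path or lpath) and (ben or lben):
            return Classification.VUS
        if path:
            return Classification.PATHOGENIC
        if lpath:
            return Classification.LIKELY_PATHOGENIC
        if ben:
            return Classification.BENIGN
        if lben:
            return Classification.LIKELY_BENIGN
        return Classification.VUS

    # as_curated: polymorphism override > benign rules > pathogenic rules > VUS
    if polymorphism:
        if not (ben or lben or n["bs"] >= 1):
            logger.warning("polymorphism override applied without benign-side evidence")
        return Classification.BENIGN
    if ben:
        return Classification.BENIGN
    if lben or n["bs"] >= 1:
        if (path or lpath):
            logger.warning("benign-side precedence over pathogenic evidence (%s)", cs.serialize())
        return Classification.LIKELY_BENIGN
    if path:
        return Classification.PATHOGENIC
    if lpath:
        return Classification.LIKELY_PATHOGENIC
    return Classification.VUS


@dataclass
class ConcordanceReport:
    n_match: int
    mismatches: List[Tuple[object, Classification, Classification]]

    @property
    def n_total(self) -> int:
        return self.n_match + len(self.mismatches)


def concordance(records: Sequence, cfg: EngineConfig = EngineConfig()) -> ConcordanceReport:
    """Re-combine each record's printed criteria and compare with its printed class."""
    n_match = 0
    mismatches = []
    for rec in records:
        computed = combine(rec.printed_criteria, cfg, polymorphism=rec.polymorphism)
        if computed is rec.printed_class:
            n_match += 1
        else:
            mismatches.append((rec, rec.printed_class, computed))
    return ConcordanceReport(n_match=n_match, mismatches=mismatches)
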