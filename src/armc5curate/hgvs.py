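"""HGVS parsing and consequence inference for ARMC5 coding variants.

Variants are described at cDNA level (``c.`` numbering on the canonical
ARMC5 transcript NM_001105247.1) and at protein level (``p.`` notation on
the 935-residue protein). The lexer is deliberately tolerant of the
typesetting artifacts found in published variant tables: stray whitespace
inside descriptions ("c.407 T>C"), redundant explicit bases on
duplications ("c.2697dupG"), parentheses placed around the whole protein
description ("(p.Ala110Asp)") and frameshift stop offsets written with a
misplaced asterisk ("fs44*" for "fs*44"). Unsupported HGVS constructs
(inversions, extensions) raise instead of mis-parsing.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

logger = logging.getLogger(__name__)

PROTEIN_LENGTH = 935

AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}


class HgvsParseError(ValueError):
    """Raised when an HGVS description cannot be tokenized."""


class UnsupportedHgvsError(HgvsParseError):
    """Raised for syntactically valid but unmodelled edit kinds (inv, ext...)."""


class EditKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


class ProteinKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_DEL = "inframe_del"
    INFRAME_DUP = "inframe_dup"
    INFRAME_DELINS = "inframe_delins"
    SYNONYMOUS = "synonymous"
    NO_PROTEIN = "no_protein"


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    LARGE_DELETION = "large_deletion"


class StructuralKind(str, Enum):
    WHOLE_GENE_DELETION = "whole_gene_deletion"
    PARTIAL_DELETION = "partial_deletion"
    CNLOH = "cnLOH"


@dataclass(frozen=True)
class StructuralEvent:
    """A non-HGVS event: whole/partial gene deletion or copy-neutral LOH."""

    kind: StructuralKind
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind is StructuralKind.PARTIAL_DELETION and not self.description:
            raise ValueError("partial deletion requires a description")

    @property
    def key(self) -> str:
        if self.kind is StructuralKind.CNLOH:
            return "cnLOH"
        return self.description or self.kind.value


@dataclass(frozen=True)
class CdnaChange:
    """A parsed cDNA-level edit in c. coordinates (1-based, inclusive)."""

    raw_text: str
    start: int
    edit_kind: EditKind
    end: Optional[int] = None
    ref_bases: Optional[str] = None
    alt_bases: Optional[str] = None
    intron_offset: Optional[int] = None
    end_intron_offset: Optional[int] = None
    alias_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end is not None:
            if (self.end, self.end_intron_offset or 0) < (self.start, self.intron_offset or 0):
                raise HgvsParseError(f"span end before start in {self.raw_text!r}")
        if self.edit_kind is EditKind.SUBSTITUTION:
            if self.end is not None or len(self.ref_bases or "") != 1 or len(self.alt_bases or "") != 1:
                raise HgvsParseError(
                    f"substitution must have a single position and single ref/alt base: {self.raw_text!r}"
                )

    @property
    def span_length(self) -> int:
        return (self.end - self.start + 1) if self.end is not None else 1

    def hgvs(self) -> str:
        """Normalized HGVS string (whitespace-free, redundant bases dropped)."""
        def pos(base: int, off: Optional[int]) -> str:
            return f"{base}{off:+d}" if off else str(base)

        s = "c." + pos(self.start, self.intron_offset)
        if self.end is not None:
            s += "_" + pos(self.end, self.end_intron_offset)
        if self.edit_kind is EditKind.SUBSTITUTION:
            s += f"{self.ref_bases}>{self.alt_bases}"
        elif self.edit_kind is EditKind.DELETION:
            s += "del"
        elif self.edit_kind is EditKind.DUPLICATION:
            s += "dup"
        elif self.edit_kind is EditKind.INSERTION:
            s += "ins" + (self.alt_bases or "")
        else:
            s += "delins" + (self.alt_bases or "")
        return s

    @property
    def key(self) -> str:
        return self.hgvs()


@dataclass(frozen=True)
class ProteinChange:
    """A parsed protein-level edit (3-letter amino-acid codes)."""

    raw_text: str
    start_res: int
    kind: ProteinKind
    ref_aa: str = ""
    alt_aa: Optional[str] = None
    end_res: Optional[int] = None
    end_ref_aa: Optional[str] = None
    fs_stop_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start_res < 1:
            raise HgvsParseError(f"residue number must be >= 1: {self.raw_text!r}")
        if self.start_res > PROTEIN_LENGTH:
            logger.warning("residue %d beyond protein length %d in %r",
                           self.start_res, PROTEIN_LENGTH, self.raw_text)
        if self.end_res is not None and self.end_res < self.start_res:
            raise HgvsParseError(f"residue span end before start: {self.raw_text!r}")

    @property
    def key(self) -> str:
        """Normalized protein-change key: parens stripped, fs offset retained.

        Two differently typeset descriptions of the same protein event
        (e.g. "p.(Pro109Serfs28*)" and "p.(Pro109Serfs*28)") share a key.
        """
        head = f"{self.ref_aa}{self.start_res}"
        if self.end_res is not None:
            head += f"_{self.end_ref_aa}{self.end_res}"
        if self.kind is ProteinKind.FRAMESHIFT:
            tail = f"{self.alt_aa or ''}fs"
            if self.fs_stop_offset is not None:
                tail += f"*{self.fs_stop_offset}"
            return head + tail
        if self.kind is ProteinKind.NONSENSE:
            return head + "*"
        if self.kind is ProteinKind.INFRAME_DEL:
            return head + "del"
        if self.kind is ProteinKind.INFRAME_DUP:
            return head + "dup"
        if self.kind is ProteinKind.INFRAME_DELINS:
            return head + "delins" + (self.alt_aa or "")
        return head + (self.alt_aa or "")

    def hgvs(self) -> str:
        return f"p.({self.key})"

    @property
    def termination_residue(self) -> Optional[int]:
        """Residue of the (new) termination codon for truncating changes.

        For a nonsense change this is the altered residue itself; for a
        frameshift written fs*N the stop sits N codons into the shifted
        frame, the first altered residue counting as 1.
        """
        if self.kind is ProteinKind.NONSENSE:
            return self.start_res
        if self.kind is ProteinKind.FRAMESHIFT and self.fs_stop_offset is not None:
            return self.start_res + self.fs_stop_offset - 1
        return None


_WS = re.compile(r"[\s    ]+")
_ALIAS = re.compile(r"^(?P<primary>.*?)\s*\(\s*=\s*(?P<alias>c\.[^)]+?)\s*\)\s*$")
_CDNA = re.compile(
    r"^c\.(?P<start>\d+)(?P<soff>[+-]\d+)?(?:_(?P<end>\d+)(?P<eoff>[+-]\d+)?)?(?P<edit>.+)$"
)
_UNSUPPORTED_EDIT = re.compile(r"^(inv|ext|=|\[)")


def _squash(text: str) -> str:
    return _WS.sub("", text.replace("−", "-").replace("–", "-"))


def parse_cdna(text: str) -> CdnaChange:
    """Parse an HGVS cDNA description, tolerating typesetting whitespace.

    The parenthesized alias form "c.170del (= c.165del)" resolves to the
    primary description with ``alias_of`` set to the alternate one.
    """
    raw = text.strip()
    alias = None
    m = _ALIAS.match(raw)
    body = raw
    if m:
        body, alias = m.group("primary"), _squash(m.group("alias"))
    body = _squash(body)
    if not body.startswith("c."):
        raise HgvsParseError(f"not a cDNA description: {text!r}")
    m = _CDNA.match(body)
    if not m:
        raise HgvsParseError(f"cannot parse cDNA position in {text!r}")
    start, end = int(m.group("start")), m.group("end")
    soff = int(m.group("soff")) if m.group("soff") else None
    eoff = int(m.group("eoff")) if m.group("eoff") else None
    edit = m.group("edit")

    kw = dict(raw_text=raw, start=start, end=int(end) if end else None,
              intron_offset=soff, end_intron_offset=eoff, alias_of=alias)
    if _UNSUPPORTED_EDIT.match(edit):
        raise UnsupportedHgvsError(f"unsupported edit kind {edit!r} in {text!r}")
    m2 = re.fullmatch(r"(?P<ref>[ACGT])>(?P<alt>[ACGT])", edit)
    if m2:
        return CdnaChange(edit_kind=EditKind.SUBSTITUTION,
                          ref_bases=m2.group("ref"), alt_bases=m2.group("alt"), **kw)
    m2 = re.fullmatch(r"delins(?P<alt>[ACGT]+)", edit)
    if m2:
        return CdnaChange(edit_kind=EditKind.DELINS, alt_bases=m2.group("alt"), **kw)
    m2 = re.fullmatch(r"del(?P<ref>[ACGT]*)", edit)
    if m2:
        return CdnaChange(edit_kind=EditKind.DELETION, ref_bases=m2.group("ref") or None, **kw)
    m2 = re.fullmatch(r"dup(?P<ref>[ACGT]*)", edit)
    if m2:
        return CdnaChange(edit_kind=EditKind.DUPLICATION, ref_bases=m2.group("ref") or None, **kw)
    m2 = re.fullmatch(r"ins(?P<alt>[ACGT]+)", edit)
    if m2:
        return CdnaChange(edit_kind=EditKind.INSERTION, alt_bases=m2.group("alt"), **kw)
    raise HgvsParseError(f"cannot parse edit {edit!r} in {text!r}")


def _check_aa(code: str, text: str) -> str:
    if code not in AA3:
        raise HgvsParseError(f"unknown amino-acid code {code!r} in {text!r}")
    return code


_FS = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2})?fs(?:\*(?P<n1>\d+)|(?P<n2>\d+)\*)?$"
)
_SPAN = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?:_(?P<eref>[A-Z][a-z]{2})(?P<epos>\d+))?"
    r"(?P<op>delins|del|dup)(?P<alt>(?:[A-Z][a-z]{2})*)$"
)
_SUB = re.compile(r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>\*|Ter|[A-Z][a-z]{2})$")


def parse_protein(text: str) -> ProteinChange:
    """Parse an HGVS protein description ("p.(...)", "p...." or "(p....)")."""
    raw = text.strip()
    body = _squash(raw)
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if not body.startswith("p."):
        raise HgvsParseError(f"not a protein description: {text!r}")
    body = body[2:]
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if body in ("?", "0"):
        return ProteinChange(raw_text=raw, start_res=1, kind=ProteinKind.NO_PROTEIN, ref_aa="")

    m = _FS.match(body)
    if m:
        n = m.group("n1") or m.group("n2")
        return ProteinChange(
            raw_text=raw, start_res=int(m.group("pos")), kind=ProteinKind.FRAMESHIFT,
            ref_aa=_check_aa(m.group("ref"), text),
            alt_aa=_check_aa(m.group("alt"), text) if m.group("alt") else None,
            fs_stop_offset=int(n) if n else None)
    m = _SPAN.match(body)
    if m:
        op = {"del": ProteinKind.INFRAME_DEL, "dup": ProteinKind.INFRAME_DUP,
              "delins": ProteinKind.INFRAME_DELINS}[m.group("op")]
        alt = m.group("alt") or None
        if alt:
            for i in range(0, len(alt), 3):
                _check_aa(alt[i:i + 3], text)
        return ProteinChange(
            raw_text=raw, start_res=int(m.group("pos")), kind=op,
            ref_aa=_check_aa(m.group("ref"), text),
            end_res=int(m.group("epos")) if m.group("epos") else None,
            end_ref_aa=_check_aa(m.group("eref"), text) if m.group("eref") else None,
            alt_aa=alt)
    m = _SUB.match(body)
    if m:
        ref = _check_aa(m.group("ref"), text)
        alt = m.group("alt")
        if alt in ("*", "Ter"):
            return ProteinChange(raw_text=raw, start_res=int(m.group("pos")),
                                 kind=ProteinKind.NONSENSE, ref_aa=ref, alt_aa="*")
        _check_aa(alt, text)
        kind = ProteinKind.SYNONYMOUS if alt == ref else ProteinKind.MISSENSE
        return ProteinChange(raw_text=raw, start_res=int(m.group("pos")),
                             kind=kind, ref_aa=ref, alt_aa=alt)
    raise HgvsParseError(f"cannot parse protein change {body!r} in {text!r}")


CANONICAL_SPLICE_OFFSET = 2

_PROTEIN_TO_CONSEQUENCE = {
    ProteinKind.MISSENSE: Consequence.MISSENSE,
    ProteinKind.NONSENSE: Consequence.NONSENSE,
    ProteinKind.FRAMESHIFT: Consequence.FRAMESHIFT,
    ProteinKind.INFRAME_DEL: Consequence.INFRAME_INDEL,
    ProteinKind.INFRAME_DUP: Consequence.INFRAME_INDEL,
    ProteinKind.INFRAME_DELINS: Consequence.INFRAME_INDEL,
    ProteinKind.SYNONYMOUS: Consequence.SYNONYMOUS,
}

PRINTED_IMPACTS = {
    "missense": Consequence.MISSENSE,
    "nonsense": Consequence.NONSENSE,
    "frameshift": Consequence.FRAMESHIFT,
    "splice": Consequence.SPLICE,
    "in frame deletion": Consequence.INFRAME_INDEL,
    "in frame insertion": Consequence.INFRAME_INDEL,
    "in frame indel": Consequence.INFRAME_INDEL,
    "in frame": Consequence.INFRAME_INDEL,
    "large deletion": Consequence.LARGE_DELETION,
    "deletion": Consequence.LARGE_DELETION,
    "synonymous": Consequence.SYNONYMOUS,
}


def infer_consequence(
    cdna: Union[CdnaChange, StructuralEvent, None],
    protein: Optional[ProteinChange] = None,
    printed_impact: Optional[str] = None,
) -> Consequence:
    """Infer the consequence category of a variant.

    Canonical splice-site changes (intron offset of magnitude <= 2 on either
    span endpoint) and structural events are decided at cDNA level; all
    other variants are decided by the protein-level kind, with the in-frame
    subkinds collapsing to a single in-frame indel category. A printed
    impact from a curated table acts as ground truth: a contradiction with
    the inferred category is logged at warning level and the printed impact
    is retained.
    """
    if cdna is None and protein is None:
        raise ValueError("need a cDNA change, a structural event or a protein change")

    inferred: Optional[Consequence] = None
    if isinstance(cdna, StructuralEvent):
        inferred = Consequence.LARGE_DELETION
    elif cdna is not None:
        offsets = [o for o in (cdna.intron_offset, cdna.end_intron_offset) if o]
        if offsets and min(abs(o) for o in offsets) <= CANONICAL_SPLICE_OFFSET:
            inferred = Consequence.SPLICE
    if inferred is None and protein is not None and protein.kind is not ProteinKind.NO_PROTEIN:
        inferred = _PROTEIN_TO_CONSEQUENCE.get(protein.kind)
    if inferred is None and cdna is not None and not isinstance(cdna, StructuralEvent):
        if cdna.intron_offset or cdna.end_intron_offset:
            inferred = Consequence.SPLICE  # intronic but non-canonical; best guess

    if printed_impact:
        printed = PRINTED_IMPACTS.get(printed_impact.strip().lower())
        if printed is None:
            raise ValueError(f"unknown printed impact {printed_impact!r}")
        if inferred is not None and printed is not inferred:
            logger.warning(
                "printed impact %s contradicts inferred %s for %s; printed retained",
                printed.value, inferred.value,
                (cdna.raw_text if isinstance(cdna, CdnaChange) else cdna) if cdna else protein,
            )
        return printed
    if inferred is None:
        raise ValueError("could not infer a consequence")
    return inferred


def is_snv(cdna: CdnaChange) -> bool:
    """True iff the edit is a single-nucleotide substitution.

    Single-base duplications and deletions count as indels, matching the
    SNV/indel split used in variant-table summaries.
    """
    return cdna.edit_kind is EditKind.SUBSTITUTION
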