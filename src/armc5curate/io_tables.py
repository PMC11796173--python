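"""Reading and writing the curation tables and reports.

The curated tables travel as UTF-8 TSV with a header row and "NA" for
absent values. Criteria strings are accepted both in the run-together
dialect of the printed table ("PVS1PM2PP4") and semicolon-delimited.
Packaged fixtures (transcribed from the published germline and somatic
tables) ship with recorded SHA-256 checksums that are verified on load.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .hgvs import (
    CdnaChange, HgvsParseError, ProteinChange, StructuralEvent, StructuralKind,
    infer_consequence, parse_cdna, parse_protein,
)
from .acmg import Classification, CriteriaSet, EngineConfig, parse_criteria_string
from .landscape import DomainMap, LandscapeSummary, SomaticEvent, VariantRecord

logger = logging.getLogger(__name__)

NA_VALUES = ("", "NA")


class TableValidationError(ValueError):
    """Raised when a variant table violates its schema; carries row context."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("table validation failed:\n" + "\n".join(problems))


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: Tuple[Tuple[str, str, bool], ...]  # (name, semantic type, required)
    version: str = "1"

    def required(self) -> List[str]:
        return [c for c, _, req in self.columns if req]


GERMLINE_SCHEMA = TableSchema(
    name="germline_variants",
    columns=(
        ("cdna", "hgvs_cdna_or_structural", True),
        ("protein", "hgvs_protein", False),
        ("impact", "printed_impact", True),
        ("classification", "five_class_label", True),
        ("criteria", "acmg_criteria", True),
        ("second_hit", "tri_state", False),
        ("functional", "tri_state", False),
        ("context", "free_text", False),
        ("novel", "bool01", False),
        ("n_index_cases", "positive_int", False),
        ("polymorphism", "bool01", False),
        ("refs", "comma_list", False),
    ),
)

SOMATIC_SCHEMA = TableSchema(
    name="somatic_variants",
    columns=(
        ("cdna", "hgvs_cdna_or_structural", True),
        ("protein", "hgvs_protein", False),
        ("impact", "printed_impact", True),
        ("associated_germline", "semicolon_list", False),
        ("context", "free_text", False),
        ("refs", "comma_list", False),
    ),
)


def _read_tsv(path: Union[str, Path], schema: TableSchema) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema.required() if c not in df.columns]
    if missing:
        raise TableValidationError(
            [f"{schema.name}: missing required column(s) {', '.join(missing)}"])
    return df


def _parse_structural(text: str) -> StructuralEvent:
    low = text.lower()
    if "cnloh" in low:
        return StructuralEvent(StructuralKind.CNLOH)
    if "complete deletion" in low:
        return StructuralEvent(StructuralKind.WHOLE_GENE_DELETION, description=text)
    if "deletion" in low:
        return StructuralEvent(StructuralKind.PARTIAL_DELETION, description=text)
    raise HgvsParseError(f"unrecognized structural event {text!r}")


def _parse_event(text: str) -> Union[CdnaChange, StructuralEvent]:
    stripped = text.strip()
    if stripped.startswith("c."):
        return parse_cdna(stripped)
    return _parse_structural(stripped)


def load_germline_table(path: Union[str, Path]) -> List[VariantRecord]:
    """Load a germline variant table; every row must parse fully.

    Rows that fail HGVS, criteria or classification parsing are collected
    and reported together with their row number and printed text; nothing
    is silently dropped.
    """
    df = _read_tsv(path, GERMLINE_SCHEMA)
    records: List[VariantRecord] = []
    problems: List[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        try:
            cdna = _parse_event(row["cdna"])
            prot_text = row.get("protein", "")
            protein = parse_protein(prot_text) if prot_text not in NA_VALUES else None
            consequence = infer_consequence(
                cdna, protein, printed_impact=row["impact"])
            records.append(VariantRecord(
                cdna=cdna,
                protein=protein,
                consequence=consequence,
                printed_criteria=parse_criteria_string(row["criteria"]),
                printed_class=Classification.from_label(row["classification"]),
                second_hit_reported=row.get("second_hit", "NA").replace("NA", "unknown") or "unknown",
                functional_reported=row.get("functional", "NA").replace("NA", "unknown") or "unknown",
                context=row.get("context", "") or "pbmah",
                novel=row.get("novel", "0") == "1",
                n_index_cases=int(row.get("n_index_cases", "1") or 1),
                polymorphism=row.get("polymorphism", "0") == "1",
                refs=tuple(r for r in (row.get("refs", "") or "").split(",") if r),
            ))
        except (HgvsParseError, ValueError) as exc:
            problems.append(f"row {rowno} ({row['cdna']!r}): {exc}")
    if problems:
        raise TableValidationError(problems)
    return records


_SOMATIC_CATEGORY = {
    "missense": "missense", "nonsense": "nonsense", "frameshift": "frameshift",
    "splice": "splice", "in frame": "inframe", "deletion": "large_deletion",
}


def load_somatic_table(path: Union[str, Path]) -> List[SomaticEvent]:
    """Load a somatic event table (point variants, structural events, cnLOH)."""
    df = _read_tsv(path, SOMATIC_SCHEMA)
    events: List[SomaticEvent] = []
    problems: List[str] = []
    for i, row in df.iterrows():
        rowno = i + 2
        try:
            event = _parse_event(row["cdna"])
            prot_text = row.get("protein", "")
            protein = parse_protein(prot_text) if prot_text not in NA_VALUES else None
            if isinstance(event, StructuralEvent):
                category = ("cnLOH" if event.kind is StructuralKind.CNLOH
                            else "large_deletion")
            else:
                category = _SOMATIC_CATEGORY[row["impact"].strip().lower()]
            assoc = tuple(a.strip() for a in
                          (row.get("associated_germline", "") or "").split(";")
                          if a.strip() and a.strip().lower() != "none")
            events.append(SomaticEvent(
                event=event,
                protein=protein,
                category=category,
                associated_germline=assoc,
                context=row.get("context", "") or "pbmah",
                refs=tuple(r for r in (row.get("refs", "") or "").split(",") if r),
            ))
        except (HgvsParseError, ValueError, KeyError) as exc:
            problems.append(f"row {rowno} ({row['cdna']!r}): {exc}")
    if problems:
        raise TableValidationError(problems)
    return events


# ---------------------------------------------------------------- fixtures

_DATA_PACKAGE = "armc5curate.data"
FIXTURE_PROVENANCE = "transcribed from published Tables 1-2"


def _data_path(name: str) -> Path:
    return Path(resources.files(_DATA_PACKAGE) / name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fixture_checksums() -> Dict[str, str]:
    with (resources.files(_DATA_PACKAGE) / "checksums.json").open() as fh:
        return json.load(fh)


def _verified_path(name: str) -> Path:
    path = _data_path(name)
    recorded = fixture_checksums().get(name)
    actual = _sha256(path)
    if recorded != actual:
        raise TableValidationError(
            [f"fixture {name}: checksum {actual} does not match recorded {recorded}"])
    logger.info("fixture %s verified (%s)", name, FIXTURE_PROVENANCE)
    return path


def load_packaged_germline() -> List[VariantRecord]:
    """The packaged germline table, checksum-verified."""
    return load_germline_table(_verified_path("germline_variants.tsv"))


def load_packaged_somatic() -> List[SomaticEvent]:
    """The packaged somatic table, checksum-verified."""
    return load_somatic_table(_verified_path("somatic_variants.tsv"))


# ---------------------------------------------------------------- reports

REPORT_KEYS = ("germline", "somatic", "overlap", "concordance", "anomalies",
               "config", "fixtures")


def validate_report_structure(report: dict) -> None:
    """Minimal structural validation of a summary report."""
    problems = [k for k in REPORT_KEYS if k not in report]
    if problems:
        raise ValueError(f"report missing sections: {', '.join(problems)}")
    if not isinstance(report["germline"].get("n_variants"), int):
        raise ValueError("report germline.n_variants must be an integer")


def write_report(
    summary: LandscapeSummary,
    concordance_report,
    anomalies: Sequence[str],
    path: Union[str, Path],
    config: EngineConfig = EngineConfig(),
    fixture_info: Optional[Dict[str, str]] = None,
) -> dict:
    """Serialize a full landscape report as deterministic JSON."""
    d = summary.to_dict()
    # JSON has no tuples; normalize so the returned dict round-trips exactly
    d["recurrent_protein_variants"] = [list(x) for x in d["recurrent_protein_variants"]]
    report = {
        "germline": {k: d[k] for k in (
            "n_variants", "counts_by_consequence", "pct_by_consequence",
            "n_snv", "n_indel", "n_structural", "n_novel",
            "recurrent_protein_variants", "multi_hit_residues")},
        "somatic": {"n_somatic": d["n_somatic"], "counts": d["somatic_counts"]},
        "overlap": {"n_shared": d["n_shared"], "shared_keys": d["shared_keys"],
                    "n_total_distinct": d["n_total_distinct"]},
        "concordance": {
            "n_match": concordance_report.n_match,
            "n_total": concordance_report.n_total,
            "mismatches": [
                {"variant": rec.protein_key if hasattr(rec, "protein_key") else str(rec),
                 "printed": printed.label, "computed": computed.label}
                for rec, printed, computed in concordance_report.mismatches],
        } if concordance_report is not None else None,
        "anomalies": list(anomalies),
        "config": {k: getattr(config, k) for k in (
            "ba1_threshold", "bs1_threshold", "pm2_max_maf", "polymorphism_maf",
            "nmd_escape_codon", "conflict_policy")},
        "fixtures": fixture_info or {},
    }
    validate_report_structure(report)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def read_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Engine + domain configuration, round-trippable through YAML/JSON."""

    engine: EngineConfig = field(default_factory=EngineConfig)
    domain_map: DomainMap = field(default_factory=DomainMap)
    seed: int = 0
    log_level: str = "WARNING"

    def to_dict(self) -> dict:
        return {
            "engine": {k: getattr(self.engine, k) for k in (
                "ba1_threshold", "bs1_threshold", "pm2_max_maf",
                "polymorphism_maf", "nmd_escape_codon", "conflict_policy")},
            "domain_map": {
                "protein_length": self.domain_map.protein_length,
                "domains": [list(d) for d in self.domain_map.domains]},
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        dm = d.get("domain_map", {})
        return cls(
            engine=EngineConfig(**d.get("engine", {})),
            domain_map=DomainMap(
                protein_length=dm.get("protein_length", 935),
                domains=tuple(tuple(x) for x in dm["domains"]))
            if "domains" in dm else DomainMap(),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "WARNING"),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def dump(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
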