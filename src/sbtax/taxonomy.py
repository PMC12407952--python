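"""Seven-rank lineages, genome/sample metadata records, and quality tiers.

Lineages are 7-slot tuples (kingdom..species) serialized in the common
metagenomics dialect ``k__...|p__...|c__...|o__...|f__...|g__...|s__...``.
A slot holds either a known taxon name or an unknown-cluster label of the
form ``MSBT<integer>`` allocated from the database's monotonic counter.
Slots are filled top-down with no gaps: missing trailing ranks are absent.

Metadata records follow the bundled JSON schema documents (one per record
kind, versioned, under ``sbtax/schemas/``); validation returns violations
as data rather than raising, and unrecognized attributes are preserved
verbatim for forward compatibility.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Optional

import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = dict(zip(RANK_PREFIXES, RANKS))

UNKNOWN_LABEL_RE = re.compile(r"^MSBT\d+$")


class LineageError(ValueError):
    """Malformed lineage string or rank structure."""


@dataclass(frozen=True, order=True)
class Lineage:
    """Ordered labels from kingdom down to species; trailing ranks may be absent."""

    labels: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != 7:
            raise LineageError("a lineage has exactly 7 slots")
        seen_gap = False
        for label in self.labels:
            if label is None:
                seen_gap = True
            elif seen_gap:
                raise LineageError("lineage filled with a gap (missing ancestor rank)")
            elif label == "":
                raise LineageError("empty label; absent ranks must be omitted")

    @classmethod
    def of(cls, *labels: str) -> "Lineage":
        return cls(tuple(labels) + (None,) * (7 - len(labels)))

    def __getitem__(self, rank: str) -> Optional[str]:
        return self.labels[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        return sum(1 for x in self.labels if x is not None)

    @property
    def deepest_rank(self) -> Optional[str]:
        return RANKS[self.depth - 1] if self.depth else None

    def prefix(self, depth: int) -> "Lineage":
        return Lineage(self.labels[:depth] + (None,) * (7 - depth))

    def with_rank(self, rank: str, label: str) -> "Lineage":
        i = RANKS.index(rank)
        labels = list(self.labels)
        labels[i] = label
        return Lineage(tuple(labels))

    def is_full(self) -> bool:
        return self.depth == 7

    def is_known_at(self, rank: str) -> bool:
        label = self[rank]
        return label is not None and not UNKNOWN_LABEL_RE.match(label)

    def serialize(self) -> str:
        parts = [
            p + label
            for p, label in zip(RANK_PREFIXES, self.labels)
            if label is not None
        ]
        return "|".join(parts)

    def __str__(self) -> str:
        return self.serialize()


def parse_lineage(text: str) -> Lineage:
    """Parse a pipe-separated prefixed lineage string.

    Segments must appear in rank order starting at the kingdom, each with
    its ``k__``/``p__``/... prefix; missing trailing ranks are absent.
    """
    if not text or not text.strip():
        raise LineageError("empty lineage string")
    segments = text.strip().split("|")
    if len(segments) > 7:
        raise LineageError(f"more than 7 segments in {text!r}")
    labels: list[Optional[str]] = []
    for i, seg in enumerate(segments):
        prefix, expected = seg[:3], RANK_PREFIXES[i]
        if prefix not in _PREFIX_TO_RANK:
            raise LineageError(f"malformed prefix in segment {seg!r}")
        if prefix != expected:
            raise LineageError(
                f"out-of-order rank: segment {seg!r} at position {i + 1}, "
                f"expected prefix {expected!r}"
            )
        label = seg[3:]
        if not label:
            raise LineageError(f"empty label in segment {seg!r}")
        labels.append(label)
    return Lineage(tuple(labels) + (None,) * (7 - len(labels)))


# ---------------------------------------------------------------------------
# quality tiers

TIERS = ("high", "medium", "low", "fail")


def quality_tier(completeness: float, contamination: float) -> str:
    """Genome quality tier from completeness/contamination percentages.

    high: completeness >90 and contamination <=5; medium: completeness >=50
    and contamination <=10 (not high); low: completeness <50 and
    contamination <=10; contamination >10 is 'fail'.
    """
    for name, value in (("completeness", completeness), ("contamination", contamination)):
        if not 0 <= value <= 100:
            raise ValueError(f"{name} out of range [0,100]: {value}")
    if contamination > 10:
        return "fail"
    if completeness > 90 and contamination <= 5:
        return "high"
    if completeness >= 50:
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# metadata records

GENOME_TYPES = ("reference", "MAG")


@dataclass
class GenomeRecord:
    metasbt_id: str
    genome_id: str
    genome_type: str
    taxonomy: Optional[Lineage] = None
    sample_id: Optional[str] = None
    dataset_id: Optional[str] = None
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    strain_heterogeneity: Optional[float] = None
    extra: dict[str, Any] = field(default_factory=dict)

    def to_document(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "metasbt_id": self.metasbt_id,
            "genome_id": self.genome_id,
            "genome_type": self.genome_type,
        }
        if self.taxonomy is not None:
            doc["taxonomy"] = self.taxonomy.serialize()
        for key in ("sample_id", "dataset_id", "completeness", "contamination",
                    "strain_heterogeneity"):
            value = getattr(self, key)
            if value is not None:
                doc[key] = value
        doc.update(self.extra)
        return doc

    @classmethod
    def from_document(cls, doc: dict[str, Any]) -> "GenomeRecord":
        known = {"metasbt_id", "genome_id", "genome_type", "taxonomy", "sample_id",
                 "dataset_id", "completeness", "contamination", "strain_heterogeneity"}
        tax = doc.get("taxonomy")
        return cls(
            metasbt_id=doc.get("metasbt_id", ""),
            genome_id=doc.get("genome_id", ""),
            genome_type=doc.get("genome_type", ""),
            taxonomy=parse_lineage(tax) if tax else None,
            sample_id=doc.get("sample_id"),
            dataset_id=doc.get("dataset_id"),
            completeness=doc.get("completeness"),
            contamination=doc.get("contamination"),
            strain_heterogeneity=doc.get("strain_heterogeneity"),
            extra={k: v for k, v in doc.items() if k not in known},
        )


@dataclass
class SampleRecord:
    sample_id: str
    attributes: dict[str, Any] = field(default_factory=dict)

    def to_document(self) -> dict[str, Any]:
        return {"sample_id": self.sample_id, **self.attributes}

    @classmethod
    def from_document(cls, doc: dict[str, Any]) -> "SampleRecord":
        return cls(sample_id=doc.get("sample_id", ""),
                   attributes={k: v for k, v in doc.items() if k != "sample_id"})


# ---------------------------------------------------------------------------
# schema-driven validation (subset of JSON Schema: required/type/enum/range)

def load_schema(kind: str) -> dict[str, Any]:
    """Load a bundled, versioned record schema ('genome' or 'sample')."""
    ref = resources.files("sbtax").joinpath(f"schemas/{kind}.schema.json")
    return json.loads(ref.read_text())


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"{self.field}: {self.rule} — {self.message}"


_TYPES = {"string": str, "number": (int, float), "integer": int}


def validate_record(document: dict[str, Any], schema: dict[str, Any]) -> list[Violation]:
    """Check a record document against a schema; violations are data, not errors.

    Unrecognized attributes are allowed and preserved (forward compatibility).
    """
    out: list[Violation] = []
    props = schema.get("properties", {})
    for name in schema.get("required", []):
        if name not in document or document[name] in (None, ""):
            out.append(Violation(name, "required", "missing required field"))
    for name, rules in props.items():
        if name not in document or document[name] is None:
            continue
        value = document[name]
        expected = rules.get("type")
        if expected and (isinstance(value, bool) or not isinstance(value, _TYPES[expected])):
            out.append(Violation(name, "type", f"expected {expected}, got {type(value).__name__}"))
            continue
        if "enum" in rules and value not in rules["enum"]:
            out.append(Violation(name, "enum", f"{value!r} not one of {rules['enum']}"))
        if "minimum" in rules and value < rules["minimum"]:
            out.append(Violation(name, "range", f"{value} < minimum {rules['minimum']}"))
        if "maximum" in rules and value > rules["maximum"]:
            out.append(Violation(name, "range", f"{value} > maximum {rules['maximum']}"))
        if rules.get("format") == "lineage":
            try:
                parse_lineage(str(value))
            except LineageError as exc:
                out.append(Violation(name, "format", str(exc)))
    return out


# ---------------------------------------------------------------------------
# TSV interfaces

def read_taxonomy_table(path: str | Path) -> dict[str, Lineage]:
    """Taxonomy table TSV: columns genome_id, lineage (canonical string)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "lineage"} <= set(df.columns):
        raise ValueError("taxonomy table needs columns genome_id, lineage")
    return {row.genome_id: parse_lineage(row.lineage) for row in df.itertuples()}


def write_taxonomy_table(taxa: dict[str, Lineage], path: str | Path) -> None:
    rows = [{"genome_id": gid, "lineage": lin.serialize()}
            for gid, lin in sorted(taxa.items())]
    pd.DataFrame(rows, columns=["genome_id", "lineage"]).to_csv(path, sep="\t", index=False)


def records_to_tsv(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Flatten genome records to one TSV row per record (bulk I/O form)."""
    docs = [r.to_document() for r in records]
    base = ["metasbt_id", "genome_id", "genome_type", "taxonomy", "sample_id",
            "dataset_id", "completeness", "contamination", "strain_heterogeneity"]
    extra = sorted({k for d in docs for k in d} - set(base))
    pd.DataFrame(docs, columns=base + extra).to_csv(path, sep="\t", index=False)


def records_from_tsv(path: str | Path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"metasbt_id": str, "genome_id": str})
    records = []
    for doc in df.to_dict(orient="records"):
        clean = {k: v for k, v in doc.items() if not pd.isna(v)}
        records.append(GenomeRecord.from_document(clean))
    return records
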