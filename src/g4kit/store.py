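"""Flat-file store of curated G-quadruplex / protein interaction records.

Each record describes one experimentally characterised interaction between a
protein and a nucleic acid that folds into a G-quadruplex: identifiers
(interaction ID, UniProt accession and entry name, gene name and synonyms,
PDB entries, PMID), the target quadruplex (name and sequence), binding
parameters (change in melting temperature on binding, association constant
Ka in 1/M, dissociation constant Kd in M), the detection technique and the
reporting authors.  Records are categorised by whether the target quadruplex
is DNA or RNA.

Persistence is TSV (header row mandatory, list fields joined on ";") or JSON
(array of snake_case objects).  Search mirrors a curated-database front end:
``quick_search`` matches one query string against every searchable text
field, ``advanced_search`` takes a conjunction of per-field criteria over the
ten supported criterion fields.  All matching is case-insensitive substring.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import StoreValidationError

_DNA_TARGET = frozenset("ACGTN")
_RNA_TARGET = frozenset("ACGUN")

COLUMNS = [
    "interaction_id", "category", "protein_name", "protein_synonyms",
    "uniprot_id", "uniprot_entry_name", "organism", "gene_name",
    "gene_synonyms", "protein_fasta", "target_name", "target_sequence",
    "delta_tm", "ka", "kd", "pdb_ids", "interacting_residues",
    "technique", "pmid", "authors",
]
LIST_FIELDS = frozenset(
    {"protein_synonyms", "gene_synonyms", "pdb_ids", "interacting_residues", "authors"}
)
NUMERIC_FIELDS = frozenset({"delta_tm", "ka", "kd"})

#: The ten criterion fields accepted by advanced_search.
ADVANCED_FIELDS = (
    "interaction_id", "target_name", "target_sequence", "protein_name",
    "uniprot_id", "uniprot_entry_name", "gene_name", "gene_synonyms",
    "pmid", "author",
)


@dataclass
class InteractionRecord:
    interaction_id: str
    category: str  # "DNA" or "RNA": which kind of quadruplex the protein binds
    protein_name: str = ""
    protein_synonyms: list[str] = field(default_factory=list)
    uniprot_id: str = ""
    uniprot_entry_name: str = ""
    organism: str = ""
    gene_name: str = ""
    gene_synonyms: list[str] = field(default_factory=list)
    protein_fasta: str = ""
    target_name: str = ""
    target_sequence: str = ""
    delta_tm: float | None = None  # change in melting temperature, deg C
    ka: float | None = None        # association constant, 1/M
    kd: float | None = None        # dissociation constant, M
    pdb_ids: list[str] = field(default_factory=list)
    interacting_residues: list[str] = field(default_factory=list)
    technique: str = ""
    pmid: str = ""
    authors: list[str] = field(default_factory=list)


def validate_record(r: InteractionRecord) -> list[str]:
    """Return one named violation per failed invariant (empty list iff valid)."""
    violations = []
    if not r.interaction_id:
        violations.append("interaction_id: empty")
    if r.category not in ("DNA", "RNA"):
        violations.append(f"category: must be DNA or RNA, got {r.category!r}")
    else:
        allowed = _DNA_TARGET if r.category == "DNA" else _RNA_TARGET
        if r.target_sequence and not set(r.target_sequence.upper()) <= allowed:
            violations.append("target_sequence: alphabet/category mismatch")
    if r.kd is not None and not r.kd > 0:
        violations.append(f"kd: must be > 0, got {r.kd}")
    if r.ka is not None and not r.ka > 0:
        violations.append(f"ka: must be > 0, got {r.ka}")
    if r.pmid and not r.pmid.isdigit():
        violations.append("pmid: non-digit characters")
    return violations


def _check_unique_ids(records: Sequence[InteractionRecord]) -> None:
    seen: dict[str, int] = {}
    for r in records:
        seen[r.interaction_id] = seen.get(r.interaction_id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise StoreValidationError(f"duplicate interaction_id(s): {', '.join(dups)}")


def _validate_all(records: Sequence[InteractionRecord]) -> None:
    _check_unique_ids(records)
    problems = []
    for r in records:
        for v in validate_record(r):
            problems.append(f"record {r.interaction_id!r}: {v}")
    if problems:
        raise StoreValidationError("; ".join(problems))


def _record_from_strings(row: Mapping[str, str], where: str) -> InteractionRecord:
    kwargs: dict = {}
    for col in COLUMNS:
        raw = (row.get(col) or "").strip()
        if col in LIST_FIELDS:
            kwargs[col] = [x.strip() for x in raw.split(";") if x.strip()]
        elif col in NUMERIC_FIELDS:
            if raw == "":
                kwargs[col] = None
            else:
                try:
                    kwargs[col] = float(raw)
                except ValueError:
                    raise StoreValidationError(
                        f"{where}: field {col!r}: not a number: {raw!r}"
                    ) from None
        else:
            kwargs[col] = raw
    return InteractionRecord(**kwargs)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.upper()
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "JSON"
    if suffix in (".tsv", ".txt", ".tab"):
        return "TSV"
    raise StoreValidationError(f"cannot infer record format from {path.name!r}; pass format=")


def load_records(
    path: str | Path, fmt: str | None = None, strict: bool = True
) -> list[InteractionRecord]:
    """Load interaction records from a TSV or JSON file.

    With ``strict=True`` (default) every record must pass
    :func:`validate_record` and interaction IDs must be unique; violations
    raise :class:`StoreValidationError` naming the record and field.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records: list[InteractionRecord] = []
    if fmt == "TSV":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise StoreValidationError(f"{path}: empty file (header row mandatory)")
            missing = [c for c in COLUMNS if c not in reader.fieldnames]
            if missing:
                raise StoreValidationError(f"{path}: missing column(s): {', '.join(missing)}")
            for i, row in enumerate(reader, start=2):
                records.append(_record_from_strings(row, f"{path}: line {i}"))
    elif fmt == "JSON":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise StoreValidationError(f"{path}: expected a JSON array of records")
        for obj in data:
            kwargs = {}
            for col in COLUMNS:
                v = obj.get(col)
                if col in LIST_FIELDS:
                    kwargs[col] = [str(x) for x in (v or [])]
                elif col in NUMERIC_FIELDS:
                    kwargs[col] = None if v is None else float(v)
                else:
                    kwargs[col] = "" if v is None else str(v)
            records.append(InteractionRecord(**kwargs))
    else:
        raise StoreValidationError(f"unknown record format: {fmt}")
    if strict:
        _validate_all(records)
    return records


def save_records(
    path: str | Path, records: Sequence[InteractionRecord], fmt: str | None = None
) -> None:
    """Write records as TSV (";"-joined lists) or JSON (array of objects)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "TSV":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(COLUMNS)
            for r in records:
                row = []
                for col in COLUMNS:
                    v = getattr(r, col)
                    if col in LIST_FIELDS:
                        row.append(";".join(v))
                    elif v is None:
                        row.append("")
                    else:
                        row.append(str(v))
                writer.writerow(row)
    elif fmt == "JSON":
        path.write_text(json.dumps([asdict(r) for r in records], indent=1) + "\n")
    else:
        raise StoreValidationError(f"unknown record format: {fmt}")


def browse_by_category(
    records: Iterable[InteractionRecord], category: str
) -> list[InteractionRecord]:
    """Records whose target quadruplex is DNA or RNA, sorted by interaction ID."""
    if category not in ("DNA", "RNA"):
        raise ValueError(f"category must be DNA or RNA, got {category!r}")
    return sorted(
        (r for r in records if r.category == category), key=lambda r: r.interaction_id
    )


def _searchable_texts(r: InteractionRecord) -> list[str]:
    texts = [
        r.interaction_id, r.protein_name, r.target_name, r.target_sequence,
        r.protein_fasta, r.uniprot_id, r.uniprot_entry_name, r.gene_name,
        r.technique, r.pmid,
    ]
    texts.extend(r.protein_synonyms)
    texts.extend(r.gene_synonyms)
    texts.extend(r.authors)
    return [t for t in texts if t]


def quick_search(
    records: Iterable[InteractionRecord], query: str
) -> list[InteractionRecord]:
    """Case-insensitive substring search of one query across all text fields.

    An empty query is an error, to distinguish it from "match everything".
    """
    if not query:
        raise ValueError("quick_search query must be non-empty")
    q = query.lower()
    matches = [
        r for r in records if any(q in t.lower() for t in _searchable_texts(r))
    ]
    return sorted(matches, key=lambda r: r.interaction_id)


def _field_texts(r: InteractionRecord, criterion: str) -> list[str]:
    if criterion == "gene_synonyms":
        return r.gene_synonyms
    if criterion == "author":
        return r.authors
    return [getattr(r, criterion)]


def advanced_search(
    records: Iterable[InteractionRecord], criteria: Mapping[str, str]
) -> list[InteractionRecord]:
    """Conjunctive (AND) per-field search over the ten criterion fields.

    Each criterion is a case-insensitive substring match against its own
    field; a record matches only if every criterion matches.
    """
    if not criteria:
        raise ValueError("advanced_search needs at least one criterion")
    unknown = sorted(set(criteria) - set(ADVANCED_FIELDS))
    if unknown:
        raise ValueError(
            f"unknown search field(s) {', '.join(unknown)}; "
            f"valid fields: {', '.join(ADVANCED_FIELDS)}"
        )
    for name, value in criteria.items():
        if not value:
            raise ValueError(f"criterion {name!r} has an empty query")
    matches = []
    for r in records:
        ok = all(
            any(crit.lower() in t.lower() for t in _field_texts(r, name) if t)
            for name, crit in criteria.items()
        )
        if ok:
            matches.append(r)
    return sorted(matches, key=lambda r: r.interaction_id)
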