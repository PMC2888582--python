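"""Readers and writers for every external format the pipeline touches.

Formats handled: FASTA protein databases (via Biopython), the tab-separated
PSM dialect shared with the synthetic generator, OBO 1.2 ontologies, GAF 2.x
annotation files, GMT gene-set files and the agonist/antagonist regulation
table.  Also constructs reversed-sequence decoy databases.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from gvprotcomm.ontology import AnnotationSet, OntologyGraph

DECOY_PREFIX = "DECOY_"

#: canonical column order of the PSM TSV dialect
PSM_COLUMNS = (
    "sample",
    "replicate",
    "fraction",
    "peptide",
    "charge",
    "xcorr",
    "deltacn",
    "rsp",
    "accession",
    "is_decoy",
)

VALID_CHARGES = (1, 2, 3)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclasses.dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``accessions`` holds every parent protein of the matched peptide; shared
    peptides therefore carry more than one accession.  ``is_decoy`` marks
    matches against the reversed database.
    """

    sample: str
    replicate: int
    fraction: int
    peptide: str
    charge: int
    xcorr: float
    deltacn: float
    rsp: int
    accessions: tuple[str, ...]
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.charge not in VALID_CHARGES:
            raise ValueError(f"charge must be one of {VALID_CHARGES}, got {self.charge}")
        if self.xcorr < 0:
            raise ValueError(f"xcorr must be >= 0, got {self.xcorr}")
        if not 0.0 <= self.deltacn <= 1.0:
            raise ValueError(f"deltacn must be in [0, 1], got {self.deltacn}")
        if self.rsp < 1:
            raise ValueError(f"rsp must be >= 1, got {self.rsp}")
        if not self.accessions:
            raise ValueError("a PSM needs at least one protein accession")


@dataclasses.dataclass
class ProteinDatabase:
    """Protein sequences keyed by accession, with per-entry decoy flags."""

    sequences: dict[str, str]
    decoy_flags: dict[str, bool] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc in self.sequences:
            self.decoy_flags.setdefault(acc, acc.startswith(DECOY_PREFIX))

    @property
    def target_accessions(self) -> list[str]:
        return [a for a in self.sequences if not self.decoy_flags[a]]

    @property
    def decoy_accessions(self) -> list[str]:
        return [a for a in self.sequences if self.decoy_flags[a]]

    def __len__(self) -> int:
        return len(self.sequences)


def build_decoy_database(db: ProteinDatabase) -> ProteinDatabase:
    """Append one reversed-sequence decoy per target entry.

    Reversal keeps the amino-acid multiset (and hence composition and search
    space characteristics) of each source sequence.  Palindromic sequences
    yield a decoy identical to the target; this is permitted and simply
    flagged through the ``DECOY_`` accession prefix.
    """
    if not db.sequences:
        raise ValueError("cannot build decoys for an empty database")
    if db.decoy_accessions:
        raise ValueError("database already contains decoy entries")
    combined = dict(db.sequences)
    flags = dict(db.decoy_flags)
    for acc, seq in db.sequences.items():
        decoy_acc = DECOY_PREFIX + acc
        if decoy_acc in combined:
            raise ValueError(f"duplicate accession after prefixing: {decoy_acc}")
        combined[decoy_acc] = seq[::-1]
        flags[decoy_acc] = True
    return ProteinDatabase(sequences=combined, decoy_flags=flags)


def read_fasta(path: str | Path) -> ProteinDatabase:
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate accession in FASTA: {rec.id}")
        sequences[rec.id] = str(rec.seq)
    return ProteinDatabase(sequences=sequences)


def write_fasta(db: ProteinDatabase, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in db.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSM TSV dialect
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[PsmRecord]) -> pd.DataFrame:
    """Tabulate PSM records; multi-parent accessions are ';'-joined."""
    rows = [
        (
            r.sample,
            r.replicate,
            r.fraction,
            r.peptide,
            r.charge,
            r.xcorr,
            r.deltacn,
            r.rsp,
            ";".join(r.accessions),
            r.is_decoy,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(PSM_COLUMNS)).astype(
        {
            "replicate": "int64",
            "fraction": "int64",
            "charge": "int64",
            "xcorr": "float64",
            "deltacn": "float64",
            "rsp": "int64",
            "is_decoy": "bool",
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[PsmRecord]:
    return [
        PsmRecord(
            sample=str(row.sample),
            replicate=int(row.replicate),
            fraction=int(row.fraction),
            peptide=str(row.peptide),
            charge=int(row.charge),
            xcorr=float(row.xcorr),
            deltacn=float(row.deltacn),
            rsp=int(row.rsp),
            accessions=tuple(str(row.accession).split(";")),
            is_decoy=bool(row.is_decoy),
        )
        for row in frame.itertuples(index=False)
    ]


def validate_psm_frame(frame: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    """Validate dtypes and value ranges; report offenders with line numbers.

    Line numbers refer to the data file: header is line 1, first record line 2.
    """
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    frame = frame[list(PSM_COLUMNS)].copy()
    problems: list[str] = []
    for col in ("replicate", "fraction", "charge", "rsp"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            problems.append(f"line {line}: non-numeric {col!r}")
        frame[col] = coerced
    for col in ("xcorr", "deltacn"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            problems.append(f"line {line}: non-numeric {col!r}")
        frame[col] = coerced
    if problems:
        raise FormatError(f"{source}: " + "; ".join(problems))
    checks = [
        (~frame["charge"].isin(VALID_CHARGES), "unknown charge"),
        (frame["xcorr"] < 0, "negative xcorr"),
        (~frame["deltacn"].between(0.0, 1.0), "deltacn outside [0, 1]"),
        (frame["rsp"] < 1, "rsp < 1"),
    ]
    for bad, message in checks:
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise FormatError(f"{source}: line {line}: {message}")
    frame["is_decoy"] = frame["is_decoy"].map(_parse_bool)
    return frame.astype(
        {
            "replicate": "int64",
            "fraction": "int64",
            "charge": "int64",
            "rsp": "int64",
            "is_decoy": "bool",
        }
    )


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise FormatError(f"unparseable boolean: {value!r}")


def read_psm_table(path: str | Path, as_records: bool = False):
    """Read the PSM TSV dialect.

    Returns a validated :class:`pandas.DataFrame` by default, or a list of
    :class:`PsmRecord` when ``as_records`` is true.  Malformed lines raise
    :class:`FormatError` naming the offending line.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = validate_psm_frame(frame, source=str(path))
    return frame_to_records(frame) if as_records else frame


def write_psm_table(psms: pd.DataFrame | Sequence[PsmRecord], path: str | Path) -> None:
    frame = psms if isinstance(psms, pd.DataFrame) else records_to_frame(psms)
    out = frame[list(PSM_COLUMNS)].copy()
    out["is_decoy"] = out["is_decoy"].map(lambda v: "true" if v else "false")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# OBO 1.2
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> OntologyGraph:
    """Parse the OBO 1.2 subset the pipeline needs.

    Honoured tags: id, name, namespace, is_a, relationship: part_of,
    is_obsolete.  Other stanza types and tags are skipped.  Obsolete terms are
    kept in the graph but flagged and excluded from ancestry.
    """
    terms: dict[str, dict] = {}
    edges: list[tuple[str, str, str]] = []
    current: dict | None = None
    in_term = False
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                current = {"obsolete": False} if in_term else None
                continue
            if not in_term or current is None or not line or line.startswith("!"):
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            key = key.strip()
            if key == "id":
                current["id"] = value
                terms[value] = current
            elif key == "name":
                current["name"] = value
            elif key == "namespace":
                current["namespace"] = value
            elif key == "is_a":
                edges.append((current["id"], value, "is_a"))
            elif key == "relationship":
                rel, _, target = value.partition(" ")
                if rel == "part_of":
                    edges.append((current["id"], target.strip(), "part_of"))
            elif key == "is_obsolete" and value.lower() == "true":
                current["obsolete"] = True
    graph = OntologyGraph()
    for term_id, info in terms.items():
        graph.add_term(
            term_id,
            name=info.get("name", term_id),
            namespace=info.get("namespace", "biological_process"),
            obsolete=info["obsolete"],
        )
    for child, parent, rel in edges:
        if parent not in terms:
            raise FormatError(f"OBO edge references unknown term: {child} -> {parent}")
        graph.add_edge(child, parent, rel)
    return graph


# ---------------------------------------------------------------------------
# GAF 2.x
# ---------------------------------------------------------------------------

def read_gaf(path: str | Path) -> AnnotationSet:
    """Read GAF 2.x annotations into an :class:`AnnotationSet`.

    Comment lines (``!``) are skipped.  Any annotation whose qualifier field
    contains ``NOT`` is excluded from the positive annotation set;
    ``colocalizes_with`` / ``contributes_to`` qualifiers are retained.
    """
    annotations: dict[str, set[tuple[str, str]]] = {}
    aspects: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: expected >=9 GAF columns")
            protein = fields[1]
            qualifier = fields[3]
            term = fields[4]
            evidence = fields[6]
            aspect = fields[8]
            if "NOT" in qualifier.split("|"):
                continue
            annotations.setdefault(protein, set()).add((term, evidence))
            aspects[(protein, term)] = aspect
    return AnnotationSet(annotations=annotations, aspects=aspects)


def write_gaf(annotation_rows: Iterable[tuple], path: str | Path) -> None:
    """Write GAF 2.2 rows (db, protein, symbol, qualifier, term, evidence, aspect)."""
    with open(path, "w") as handle:
        handle.write("!gaf-version: 2.2\n")
        for db, protein, symbol, qualifier, term, evidence, aspect in annotation_rows:
            fields = [
                db, protein, symbol, qualifier, term, "GV_REF:0000001",
                evidence, "", aspect, "", "", "protein", "taxon:9913",
                "20100101", "GVC", "", "",
            ]
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GMT and regulation TSV
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> member..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs name, description and >=1 member")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate gene set {name!r}")
            sets[name] = {m for m in fields[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, "synthetic gene set", *sorted(members)]) + "\n")


def read_regulation(path: str | Path) -> pd.DataFrame:
    """Read the regulation TSV: accession, process_term, direction.

    Direction must be ``agonist`` or ``antagonist``; contradictory duplicate
    assertions (the same accession/process pair in both directions) raise.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["accession", "process_term", "direction"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = ~frame["direction"].isin(["agonist", "antagonist"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: line {line}: direction must be agonist|antagonist")
    dirs_per_pair = frame.groupby(["accession", "process_term"])["direction"].nunique()
    conflicts = dirs_per_pair[dirs_per_pair > 1]
    if not conflicts.empty:
        acc, proc = conflicts.index[0]
        raise FormatError(f"{path}: contradictory directions for ({acc!r}, {proc!r})")
    return frame.drop_duplicates(subset=["accession", "process_term"]).reset_index(drop=True)


def write_regulation(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["accession", "process_term", "direction"]].to_csv(path, sep="\t", index=False)
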