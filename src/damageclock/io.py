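"""Readers and writers for the plain-text formats the toolkit consumes.

FASTA sequences (DNA only), TSV count tables (``p<TAB>n``), TSV
prevalence series (``time<TAB>cumulative``), TSV mutation lists
(``position<TAB>ref<TAB>alt[<TAB>label]``), PED-like pedigree tables and
JSON/TSV/HTML reports.  User-facing coordinates are 1-based inclusive
everywhere; BED export (see :mod:`damageclock.hotspots`) is the single
0-based surface.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distributions import EventDistribution
from .hotspots import VALID_BASES, AnnotatedSequence, MutationRecord
from .pedigree import Member, Pedigree
from .prevalence import PrevalenceSeries

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_series_table",
    "read_mutations",
    "read_pedigree",
    "write_pedigree",
    "write_report",
    "REPORT_SCHEMA",
]

REPORT_SCHEMA = "damageclock-report/1"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, coord_offset: int = 1) -> list[AnnotatedSequence]:
    """Read a (multi-record) FASTA file of DNA sequences, uppercased.

    ``U`` and any other non-ACGT character are rejected with the
    offending record named (DNA only).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)} (DNA A/C/G/T only)"
            )
        out.append(AnnotatedSequence(id=rec.id, sequence=seq, coord_offset=coord_offset))
    return out


def write_fasta(seqs: list[AnnotatedSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, zero_included: bool = True, label: str = "") -> EventDistribution:
    """Read a ``p<TAB>n`` count table; duplicate ``p`` rows are summed."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty count table") from None
    if not {"p", "n"} <= set(df.columns):
        raise ParseError(f"{path}: expected header columns 'p' and 'n', got {list(df.columns)}")
    if df.empty:
        raise ParseError(f"{path}: count table has no rows")
    if (df["n"] < 0).any():
        raise ParseError(f"{path}: negative person counts")
    counts = df.groupby("p")["n"].sum().to_dict()
    return EventDistribution(counts, zero_included=zero_included, label=label or path.stem)


def write_count_table(dist: EventDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {"p": list(dist.counts), "n": list(dist.counts.values())}
    ).to_csv(Path(path), sep="\t", index=False)


def read_series_table(
    path: str | Path,
    time_kind: str = "age-at-diagnosis",
    at_risk: float | None = None,
    label: str = "",
) -> PrevalenceSeries:
    """Read a ``time<TAB>cumulative`` prevalence series."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty series table") from None
    if not {"time", "cumulative"} <= set(df.columns):
        raise ParseError(f"{path}: expected header columns 'time' and 'cumulative'")
    return PrevalenceSeries(
        df["time"].to_numpy(float),
        df["cumulative"].to_numpy(float),
        time_kind=time_kind,
        at_risk=at_risk,
        label=label or path.stem,
    )


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a ``position<TAB>ref<TAB>alt[<TAB>label]`` mutation table."""
    path = Path(path)
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("position"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected position<TAB>ref<TAB>alt[<TAB>label]")
        try:
            out.append(
                MutationRecord(
                    position=int(fields[0]),
                    ref=fields[1].upper(),
                    alt=fields[2].upper(),
                    label=fields[3] if len(fields) > 3 else "",
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not out:
        raise ParseError(f"{path}: no mutation records")
    return out


# ---------------------------------------------------------------------------
# PED-like pedigree tables
# ---------------------------------------------------------------------------

_PED_HEADER = ["id", "father", "mother", "generation", "at_risk", "founder_carrier", "married_in"]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-like TSV (``0`` or ``.`` for a missing parent)."""
    path = Path(path)
    members, carriers, married = [], [], []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty pedigree file")
    start = 1 if lines[0].split("\t")[0] == "id" else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        f = line.split("\t")
        if len(f) != len(_PED_HEADER):
            raise ParseError(f"{path}:{lineno}: expected {len(_PED_HEADER)} columns, got {len(f)}")
        father = None if f[1] in ("0", ".") else f[1]
        mother = None if f[2] in ("0", ".") else f[2]
        members.append(
            Member(id=f[0], father=father, mother=mother, generation=int(f[3]), at_risk=f[4] == "1")
        )
        if f[5] == "1":
            carriers.append(f[0])
        if f[6] == "1":
            married.append(f[0])
    return Pedigree(members, founder_carriers=carriers, married_in=married)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    lines = ["\t".join(_PED_HEADER)]
    for m in ped.members.values():
        lines.append(
            "\t".join(
                [
                    m.id,
                    m.father or "0",
                    m.mother or "0",
                    str(m.generation),
                    "1" if m.at_risk else "0",
                    "1" if m.id in ped.founder_carriers else "0",
                    "1" if m.id in ped.married_in else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialise a results object (anything with ``to_dict``) or plain dict.

    JSON reports are schema-versioned; TSV flattens scalar fields; HTML
    embeds pre-rendered hotspot HTML when the payload carries it under
    the key ``"html"``.
    """
    path = Path(path)
    payload = results.to_dict() if hasattr(results, "to_dict") else dict(results or {})
    if format == "json":
        doc = {"schema": REPORT_SCHEMA, "results": payload}
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        rows = [(k, v) for k, v in payload.items() if not isinstance(v, (dict, list))]
        path.write_text("".join(f"{k}\t{v}\n" for k, v in rows))
    elif format == "html":
        body = payload.pop("html", "")
        items = "".join(
            f"<tr><td>{k}</td><td>{v}</td></tr>"
            for k, v in payload.items()
            if not isinstance(v, (dict, list))
        )
        path.write_text(
            "<!DOCTYPE html>\n<html><body>"
            f"<table>{items}</table>{body}</body></html>\n"
        )
    else:
        raise ValueError(f"unknown report format {format!r}")
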