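"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* Coordinates are 0-based half-open internally and 1-based inclusive in every
  user-facing table (each table header says so).
* FASTA headers follow the dialect ``id|taxon|clade``; a plain id leaves
  taxon/clade empty.
* ``X`` is a valid residue everywhere and is treated as missing data
  downstream.

All readers reject malformed input explicitly rather than coercing it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import AlignIO, SeqIO

from .msa import MultipleAlignment
from .tree import PhyloTree, parse_newick, parse_newick_list

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

PathOrStream = Union[str, Path, TextIO]


@dataclass
class ProteinRecord:
    """A protein sequence with its taxon and clade labels."""

    id: str
    sequence: str
    taxon: str = ""
    clade: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def header(self) -> str:
        if self.taxon or self.clade:
            return f"{self.id}|{self.taxon}|{self.clade}"
        return self.id


def _as_handle(source: PathOrStream, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_fasta(source: PathOrStream) -> list[ProteinRecord]:
    """Read unaligned FASTA into ProteinRecords (header dialect id|taxon|clade)."""
    handle, close = _as_handle(source)
    try:
        seen: set[str] = set()
        records: list[ProteinRecord] = []
        for rec in SeqIO.parse(handle, "fasta"):
            parts = rec.description.split("|")
            rid = parts[0].split()[0] if parts[0].split() else ""
            taxon = parts[1].strip() if len(parts) > 1 else ""
            clade = parts[2].strip() if len(parts) > 2 else ""
            seq = str(rec.seq)
            if "-" in seq or "." in seq:
                pos = 1 + min(
                    [k for k in (seq.find("-"), seq.find(".")) if k >= 0]
                )
                raise ValueError(
                    f"record {rid!r}: illegal character (gap) at position {pos}; "
                    "plain FASTA must be unaligned"
                )
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r}")
            seen.add(rid)
            records.append(ProteinRecord(id=rid, sequence=seq, taxon=taxon, clade=clade))
        if not records:
            raise ValueError("no records found in FASTA input")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[ProteinRecord], dest: PathOrStream) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for rec in records:
            handle.write(f">{rec.header}\n{rec.sequence}\n")
    finally:
        if close:
            handle.close()


def read_alignment(source: PathOrStream, format: str = "fasta") -> MultipleAlignment:
    """Read an alignment from aligned FASTA or Stockholm (``format`` in
    {"fasta", "stockholm"}). Stockholm annotation (``#=GC`` etc.) is ignored."""
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    handle, close = _as_handle(source)
    try:
        if format == "fasta":
            # parse as plain records first so ragged input gets our error
            ids, rows = [], []
            for rec in SeqIO.parse(handle, "fasta"):
                ids.append(rec.description.split()[0])
                rows.append(str(rec.seq).replace(".", "-"))
            if not ids:
                raise ValueError("no records found in alignment input")
            return MultipleAlignment(ids=ids, rows=rows)
        aln = AlignIO.read(handle, "stockholm")
        return MultipleAlignment(
            ids=[r.id for r in aln], rows=[str(r.seq).replace(".", "-") for r in aln]
        )
    finally:
        if close:
            handle.close()


def write_alignment(msa: MultipleAlignment, dest: PathOrStream) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        handle.write(msa.to_fasta())
    finally:
        if close:
            handle.close()


def read_newick(source: PathOrStream) -> PhyloTree:
    handle, close = _as_handle(source)
    try:
        return parse_newick(handle.read())
    finally:
        if close:
            handle.close()


def read_tree_sample(source: PathOrStream) -> list[PhyloTree]:
    """Read a multi-tree Newick file (one tree per line)."""
    handle, close = _as_handle(source)
    try:
        return parse_newick_list(handle.read())
    finally:
        if close:
            handle.close()


def write_newick(tree: PhyloTree, dest: PathOrStream | None = None, **kw) -> str:
    text = tree.to_newick(**kw)
    if dest is not None:
        handle, close = _as_handle(dest, "w")
        try:
            handle.write(text + "\n")
        finally:
            if close:
                handle.close()
    return text


TSV_COORD_NOTE = "# coordinates: 1-based inclusive"


def write_tsv(df, dest: PathOrStream, coordinate_note: bool = False) -> None:
    """Write a pandas DataFrame as UTF-8 TSV with a header row."""
    handle, close = _as_handle(dest, "w")
    try:
        if coordinate_note:
            handle.write(TSV_COORD_NOTE + "\n")
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()
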