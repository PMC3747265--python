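"""Readers and writers: gapped FASTA, Newick, taxonomy/primer TSV, run config.

FASTA parsing uses Bio.SeqIO; Newick goes through :mod:`primereval.tree`
(dendropy-backed). All tabular outputs are plain TSV.
"""

from __future__ import annotations

import configparser
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .tree import PhyloTree

__all__ = [
    "RANKS", "SequenceRecord", "SequenceLibrary",
    "read_fasta", "write_fasta", "read_newick", "write_newick",
    "read_taxonomy_tsv", "write_taxonomy_tsv", "read_config", "get_logger",
]

#: Fixed rank order for semicolon-separated taxonomy strings.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_VALID = set("ACGTUN-.") | set("RYSWKMBDHV")


def get_logger(name: str = "primereval") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


log = get_logger()


@dataclass
class SequenceRecord:
    """One aligned sequence with optional ranked taxonomy."""

    id: str
    aligned_seq: str
    taxonomy: Optional[list[tuple[str, str]]] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.aligned_seq.upper().replace("U", "T").replace(".", "-")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in {self.id!r}")
        if not seq.replace("-", ""):
            raise ValueError(f"record {self.id!r} has zero ungapped length")
        self.aligned_seq = seq

    @property
    def ungapped(self) -> str:
        return self.aligned_seq.replace("-", "")

    def rank_label(self, rank: str) -> Optional[str]:
        if not self.taxonomy:
            return None
        for r, label in self.taxonomy:
            if r == rank:
                return label
        return None


class SequenceLibrary:
    """An aligned set of sequences sharing one column space."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("library must contain at least one record")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        lengths = {len(r.aligned_seq) for r in records}
        if len(lengths) != 1:
            raise ValueError(
                f"records have unequal alignment lengths: {sorted(lengths)}")
        self.records = records
        self._by_id = {r.id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].aligned_seq)

    def subset(self, ids: Iterable[str]) -> "SequenceLibrary":
        return SequenceLibrary([self._by_id[i] for i in ids])


def read_fasta(path) -> SequenceLibrary:
    """Read an aligned, gapped FASTA file into a library.

    'U' is normalized to 'T' and '.' to '-'; unequal record lengths or
    duplicate ids raise ValueError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [SequenceRecord(rec.id, str(rec.seq))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceLibrary(records)


def write_fasta(library: SequenceLibrary, path) -> None:
    with open(path, "w") as fh:
        for rec in library:
            fh.write(f">{rec.id}\n{rec.aligned_seq}\n")


def read_newick(path, support_dialect: str = "auto") -> PhyloTree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return PhyloTree.from_newick(path.read_text(), support_dialect)


def write_newick(tree: PhyloTree, path,
                 support_dialect: str = "internal-node-label") -> None:
    Path(path).write_text(tree.to_newick(support_dialect) + "\n")


def parse_taxonomy_string(text: str) -> list[tuple[str, str]]:
    """Split 'Bacteria;Proteobacteria;...' into (rank, label) pairs."""
    labels = [t.strip() for t in text.strip().rstrip(";").split(";")]
    if len(labels) > len(RANKS):
        raise ValueError(f"more than {len(RANKS)} taxonomy ranks: {text!r}")
    return [(rank, label) for rank, label in zip(RANKS, labels) if label]


def format_taxonomy(taxonomy: list[tuple[str, str]]) -> str:
    return ";".join(label for _, label in taxonomy)


def read_taxonomy_tsv(path) -> dict[str, list[tuple[str, str]]]:
    """Read 'id<TAB>domain;phylum;...;genus' lines."""
    out: dict[str, list[tuple[str, str]]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            seq_id, tax = line.split("\t")[:2]
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: expected two columns") from exc
        out[seq_id] = parse_taxonomy_string(tax)
    return out


def write_taxonomy_tsv(library: SequenceLibrary, path) -> None:
    with open(path, "w") as fh:
        for rec in library:
            if rec.taxonomy:
                fh.write(f"{rec.id}\t{format_taxonomy(rec.taxonomy)}\n")


def attach_taxonomy(library: SequenceLibrary,
                    taxonomy: dict[str, list[tuple[str, str]]]) -> None:
    missing = [i for i in library.ids if i not in taxonomy]
    if missing:
        log.warning("no taxonomy for %d sequences (e.g. %s)",
                    len(missing), missing[0])
    for rec in library:
        if rec.id in taxonomy:
            rec.taxonomy = taxonomy[rec.id]


@dataclass
class RunSettings:
    """INI-style run configuration (section [primereval])."""

    values: dict = field(default_factory=dict)

    def get(self, key, default=None, cast=str):
        if key not in self.values:
            return default
        return cast(self.values[key])


def read_config(path) -> RunSettings:
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(path)
    section = "primereval" if parser.has_section("primereval") else \
        parser.sections()[0] if parser.sections() else None
    values = dict(parser[section]) if section else dict(parser.defaults())
    return RunSettings(values=values)
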