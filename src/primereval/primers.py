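"""Degenerate-primer matching, coverage tables, and in-silico amplicons.

Matching semantics: a primer IUPAC code matches a target base iff the base
is in the code's set; a target N (or any ambiguity code in the target)
matches nothing and counts toward the mismatch budget. Primers are matched
on both strands — a '-' strand hit means the primer's reverse complement
matched the reference strand at that position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import SequenceLibrary, SequenceRecord, get_logger

__all__ = [
    "PrimerSpec", "DEFAULT_PRIMERS", "iupac_match", "coverage",
    "extract_amplicons", "reverse_complement", "read_primer_tsv",
    "write_primer_tsv",
]

log = get_logger(__name__)

# A=1 C=2 G=4 T=8; a primer code's mask is the union of its bases.
IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
IUPAC_SETS = {
    code: frozenset(b for b in "ACGT" if IUPAC_MASK[code] & IUPAC_MASK[b])
    for code in IUPAC_MASK
}
_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

# target bases: plain A/C/G/T carry their bit, everything else matches nothing
_TARGET_BITS = np.zeros(256, dtype=np.uint8)
for _b, _m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _TARGET_BITS[ord(_b)] = _m


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerSpec:
    """A named IUPAC-degenerate primer, written 5'->3'."""

    name: str
    iupac_seq: str
    direction: str  # "forward" | "reverse"
    reference_position: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("primer name must be non-empty")
        seq = self.iupac_seq
        if not seq:
            raise ValueError("primer sequence must be non-empty")
        if seq != seq.upper():
            raise ValueError(f"primer sequence must be uppercase: {seq!r}")
        bad = set(seq) - set(IUPAC_MASK)
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)} in {seq!r}")
        if self.direction not in {"forward", "reverse"}:
            raise ValueError(f"direction must be forward/reverse, "
                             f"got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.iupac_seq)

    @property
    def mask(self) -> np.ndarray:
        return np.array([IUPAC_MASK[c] for c in self.iupac_seq],
                        dtype=np.uint8)

    @property
    def revcomp_mask(self) -> np.ndarray:
        return np.array(
            [IUPAC_MASK[c] for c in reverse_complement(self.iupac_seq)],
            dtype=np.uint8)


# The ten primer/direction combinations evaluated, five loci on two strands.
# Coordinates are 1-based E. coli 16S positions of the locus.
DEFAULT_PRIMERS: tuple[PrimerSpec, ...] = (
    PrimerSpec("338f", "ACTCCTACGGGAGGCAGC", "forward", (338, 355)),
    PrimerSpec("338r", "GCTGCCTCCCGTAGGAGT", "reverse", (338, 355)),
    PrimerSpec("518f", "CCAGCAGCCGCGGTAAT", "forward", (526, 542)),
    PrimerSpec("518r", "ATTACCGCGGCTGCTGG", "reverse", (526, 542)),
    PrimerSpec("799f", "AACMGGATTAGATACCCKG", "forward", (781, 799)),
    PrimerSpec("799r", "CMGGGTATCTAATCCKGTT", "reverse", (781, 799)),
    PrimerSpec("926f", "AACTCAAAGGAATTGACGG", "forward", (908, 926)),
    PrimerSpec("926r", "CCGTCAATTCCTTTGAGTT", "reverse", (908, 926)),
    PrimerSpec("1062f", "GTCAGCTCGTGYYGTGAG", "forward", (1064, 1081)),
    PrimerSpec("1062r", "CTCACRRCACGAGCTGAC", "reverse", (1064, 1081)),
)


def _mismatch_counts(mask: np.ndarray, target_bits: np.ndarray) -> np.ndarray:
    """Mismatches of the primer mask at every offset of the target."""
    L = len(mask)
    if len(target_bits) < L:
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(target_bits, L)
    return L - ((windows & mask) != 0).sum(axis=1)


def iupac_match(primer: PrimerSpec, seq: str,
                max_mismatches: int = 0) -> list[tuple[int, str]]:
    """All (start, strand) hits of the primer on an ungapped sequence.

    Positions are 0-based starts on the reference strand; strand '-' means
    the primer's reverse complement matched there.
    """
    if "-" in seq or "." in seq:
        raise ValueError("iupac_match expects an ungapped sequence")
    if not 0 <= max_mismatches < len(primer):
        raise ValueError("max_mismatches must be in [0, primer length)")
    bits = _TARGET_BITS[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    hits = []
    for mask, strand in ((primer.mask, "+"), (primer.revcomp_mask, "-")):
        mm = _mismatch_counts(mask, bits)
        for pos in np.nonzero(mm <= max_mismatches)[0]:
            hits.append((int(pos), strand, int(mm[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [(p, s) for p, s, _ in hits]


def _best_hit(primer: PrimerSpec, seq: str,
              max_mismatches: int) -> Optional[tuple[int, int]]:
    """(start, mismatches) of the best strand-appropriate anchor, or None.

    Forward primers anchor on '+', reverse primers on '-' (their reverse
    complement read on the reference strand). Ties resolve leftmost.
    """
    bits = _TARGET_BITS[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    mask = primer.mask if primer.direction == "forward" else \
        primer.revcomp_mask
    mm = _mismatch_counts(mask, bits)
    if mm.size == 0 or mm.min() > max_mismatches:
        return None
    best = int(mm.min())
    return int(np.argmax(mm == best)), best


# --------------------------------------------------------------------------
# coverage
# --------------------------------------------------------------------------

class CoverageTable:
    """Per (primer, taxon group): covered/total counts and percentages."""

    COLUMNS = ["primer", "group", "covered", "total",
               "coverage_pct", "noncoverage_pct"]

    def __init__(self, rows: list[dict]):
        self.frame = pd.DataFrame(rows, columns=self.COLUMNS)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def pct(self, primer: str, group: str = "all") -> float:
        sel = self.frame[(self.frame.primer == primer)
                         & (self.frame.group == group)]
        return float(sel.coverage_pct.iloc[0])


def coverage(primers, library: SequenceLibrary,
             group_rank: str = "all") -> CoverageTable:
    """Exact-match (0 mismatch, either strand) coverage per taxon group.

    A sequence is covered iff the degenerate primer has at least one
    zero-mismatch hit on its degapped sequence, on either strand.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    if group_rank != "all":
        from .io import RANKS
        if group_rank not in RANKS:
            raise ValueError(f"unknown rank {group_rank!r}")
    rows = []
    groups: dict[str, list[SequenceRecord]] = {}
    for rec in library:
        if group_rank == "all":
            continue
        label = rec.rank_label(group_rank) or "unclassified"
        groups.setdefault(label, []).append(rec)
    for primer in primers:
        covered_ids = set()
        for rec in library:
            if iupac_match(primer, rec.ungapped, 0):
                covered_ids.add(rec.id)

        def row(group, recs):
            total = len(recs)
            cov = sum(1 for r in recs if r.id in covered_ids)
            pct = 100.0 * cov / total
            return dict(primer=primer.name, group=group, covered=cov,
                        total=total, coverage_pct=pct,
                        noncoverage_pct=100.0 - pct)

        for label in sorted(groups):
            rows.append(row(label, groups[label]))
        rows.append(row("all", library.records))
    return CoverageTable(rows)


# --------------------------------------------------------------------------
# amplicon extraction
# --------------------------------------------------------------------------

def _window_ungapped(primer: PrimerSpec, start: int, read_length: int,
                     seq_len: int) -> tuple[int, int, bool]:
    """Retained ungapped [s, e) after removing the primer; flags truncation.

    The read window spans ``read_length`` ungapped bases measured from the
    primer's 5' start (forward) or ending at its 3'-most reference position
    (reverse); the primer-covered bases are then removed.
    """
    plen = len(primer)
    if primer.direction == "forward":
        s, e = start + plen, start + read_length
    else:
        site_end = start + plen  # reference-strand site is [start, site_end)
        s, e = site_end - read_length, start
    truncated = s < 0 or e > seq_len
    return max(s, 0), min(e, seq_len), truncated


def extract_amplicons(
    library: SequenceLibrary,
    primer: PrimerSpec,
    read_length: int = 280,
    anchor_mismatches: int = 2,
    on_missing: str = "exclude",
) -> SequenceLibrary:
    """Cut per-sequence short reads at the primer site, primer removed.

    Output reads stay in reference orientation as an alignment over the
    union of retained columns; positions outside a sequence's window are
    gap-filled. Sequences with no anchor are excluded (default) or trimmed
    at the library-majority window (``on_missing="majority-column"``).
    """
    if read_length <= len(primer):
        raise ValueError("read_length must exceed primer length")
    if on_missing not in {"exclude", "majority-column"}:
        raise ValueError(f"unknown on_missing {on_missing!r}")

    col_ranges: dict[str, tuple[int, int]] = {}  # id -> alignment [s, e)
    missing: list[str] = []
    n_trunc = 0
    for rec in library:
        ungapped = rec.ungapped
        hit = _best_hit(primer, ungapped, anchor_mismatches)
        if hit is None:
            missing.append(rec.id)
            continue
        s, e, truncated = _window_ungapped(
            primer, hit[0], read_length, len(ungapped))
        n_trunc += truncated
        # map ungapped range to alignment columns
        cols = np.nonzero(np.frombuffer(rec.aligned_seq.encode(),
                                        dtype="S1") != b"-")[0]
        col_ranges[rec.id] = (int(cols[s]), int(cols[e - 1]) + 1) \
            if e > s else (0, 0)
    if n_trunc:
        log.warning("%s: %d reads truncated at sequence ends",
                    primer.name, n_trunc)
    if missing:
        if on_missing == "exclude" or not col_ranges:
            log.info("%s: excluded %d sequences with no primer anchor",
                     primer.name, len(missing))
        else:
            starts = pd.Series([r[0] for r in col_ranges.values()])
            ends = pd.Series([r[1] for r in col_ranges.values()])
            majority = (int(starts.mode().iloc[0]), int(ends.mode().iloc[0]))
            log.info("%s: trimming %d anchorless sequences at majority "
                     "columns %s", primer.name, len(missing), majority)
            for seq_id in missing:
                col_ranges[seq_id] = majority
    if not col_ranges:
        raise ValueError(f"no sequence carries an anchor for {primer.name}")

    keep_cols = sorted({c for s, e in col_ranges.values()
                        for c in range(s, e)})
    col_pos = {c: k for k, c in enumerate(keep_cols)}
    out = []
    for rec in library:
        if rec.id not in col_ranges:
            continue
        s, e = col_ranges[rec.id]
        chars = ["-"] * len(keep_cols)
        for c in range(s, e):
            chars[col_pos[c]] = rec.aligned_seq[c]
        out.append(SequenceRecord(rec.id, "".join(chars), rec.taxonomy))
    return SequenceLibrary(out)


# --------------------------------------------------------------------------
# primer tables
# --------------------------------------------------------------------------

def read_primer_tsv(path) -> list[PrimerSpec]:
    """TSV columns: name, sequence, direction (header optional)."""
    primers = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name":
                continue
            if len(parts) < 3:
                raise ValueError(f"primer row needs 3 columns: {line!r}")
            primers.append(PrimerSpec(parts[0], parts[1].upper(), parts[2]))
    if not primers:
        raise ValueError(f"no primers in {path}")
    names = [p.name for p in primers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate primer names")
    return primers


def write_primer_tsv(primers, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\tdirection\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.iupac_seq}\t{p.direction}\n")
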