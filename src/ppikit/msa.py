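"""Alignment handling for two-chain complex prediction.

Structure predictors for protein complexes consume a single multiple
sequence alignment (MSA) spanning both chains.  This module builds such
alignments from two per-chain a3m files: an organism-*paired* MSA that
concatenates the best hit from each species (exposing inter-chain
coevolution), a *block-diagonalized* MSA that stacks the two per-chain
alignments with gap padding on the partner's columns, and fusions of
several such alignments over a shared concatenated query.  It also
estimates alignment depth as Neff, the number of sequence clusters at
62% identity.

a3m is the FASTA-like format written by HHblits: uppercase letters and
``-`` occupy query columns, lowercase letters mark insertions relative
to the query and are deleted when the file is loaded, so every row of a
parsed :class:`MSA` has exactly the query length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "AlignedRow",
    "MSA",
    "PairedMSA",
    "NeffResult",
    "MSAFormatError",
    "read_a3m",
    "write_a3m",
    "filter_gapped_rows",
    "pair_by_organism",
    "block_diagonalize",
    "fuse_msas",
    "compute_neff",
]

_OX_RE = re.compile(r"\bOX=(\d+)")
# lowercase letters and '.' are insertion states in a3m
_INSERTION_TABLE = str.maketrans("", "", "abcdefghijklmnopqrstuvwxyz.")


class MSAFormatError(ValueError):
    """Raised when an alignment file violates the a3m/FASTA contract."""


@dataclass(frozen=True)
class AlignedRow:
    """One aligned sequence: header, normalized row and source rank.

    ``rank`` is the 0-based position in the source file (0 = query);
    HHblits writes hits in E-value order, so a lower rank means a better
    hit.  ``organism_id`` is the NCBI taxon parsed from a UniProt-style
    ``OX=<digits>`` header token, or ``None`` when the header has none.
    """

    header: str
    sequence: str
    rank: int
    organism_id: int | None = None

    @property
    def gap_fraction(self) -> float:
        return self.sequence.count("-") / len(self.sequence)

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


@dataclass
class MSA:
    """An ordered alignment whose row 0 is the (gap-free) query."""

    rows: list[AlignedRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MSAFormatError("an MSA must contain at least the query row")
        width = len(self.rows[0].sequence)
        for row in self.rows:
            if len(row.sequence) != width:
                raise MSAFormatError(
                    f"row {row.rank} ({row.header!r}) has length "
                    f"{len(row.sequence)}, expected {width}"
                )

    @property
    def query(self) -> AlignedRow:
        return self.rows[0]

    @property
    def query_length(self) -> int:
        return len(self.rows[0].sequence)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass
class PairedMSA(MSA):
    """Concatenated two-chain MSA with per-row pairing provenance.

    ``provenance[i]`` records ``(organism_id, rank_a, rank_b)`` for
    ``rows[i + 1]`` (the query pair row carries no provenance).
    """

    provenance: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class NeffResult:
    """Cluster count (the Neff value) plus the row → cluster map."""

    n_clusters: int
    cluster_assignment: dict[int, int]


def _parse_organism(header: str) -> int | None:
    m = _OX_RE.search(header)
    return int(m.group(1)) if m else None


def read_a3m(path: str | Path) -> MSA:
    """Read an a3m/FASTA alignment, dropping insertion columns.

    Lowercase letters (and ``.``) are removed from every row, after
    which all rows must share the query length; a mismatch raises
    :class:`MSAFormatError` naming the offending record.  ``OX=<digits>``
    header tokens are parsed into ``organism_id``.
    """
    path = Path(path)
    with open(path) as handle:
        records = list(SimpleFastaParser(handle))
    if not records:
        raise MSAFormatError(f"{path}: empty alignment file")
    rows = [
        AlignedRow(
            header=header,
            sequence=seq.translate(_INSERTION_TABLE),
            rank=i,
            organism_id=_parse_organism(header),
        )
        for i, (header, seq) in enumerate(records)
    ]
    try:
        return MSA(rows)
    except MSAFormatError as exc:
        raise MSAFormatError(f"{path}: {exc}") from None


def write_a3m(msa: MSA, path: str | Path) -> None:
    """Write an MSA as single-line-per-sequence a3m (round-trips reads)."""
    lines = []
    for row in msa.rows:
        lines.append(f">{row.header}")
        lines.append(row.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def filter_gapped_rows(msa: MSA, max_gap_fraction: float = 0.9) -> MSA:
    """Drop hits whose gap fraction strictly exceeds ``max_gap_fraction``.

    The default removes hits with more than 90% gaps.  The query row is
    always retained (it defines the coordinate system), and relative
    order is preserved, so the operation is idempotent.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    kept = [msa.rows[0]]
    kept.extend(
        row for row in msa.rows[1:] if row.gap_fraction <= max_gap_fraction
    )
    out = MSA(kept)
    if isinstance(msa, PairedMSA):
        keep_idx = {id(r) for r in kept}
        prov = [
            p
            for r, p in zip(msa.rows[1:], msa.provenance)
            if id(r) in keep_idx
        ]
        out = PairedMSA(kept, provenance=prov)
    return out


def _best_hit_per_organism(msa: MSA) -> dict[int, AlignedRow]:
    """Lowest-rank (best) hit for every organism with an OX token."""
    best: dict[int, AlignedRow] = {}
    for row in msa.rows[1:]:
        if row.organism_id is None:
            continue
        if row.organism_id not in best:
            best[row.organism_id] = row
    return best


def pair_by_organism(msa_a: MSA, msa_b: MSA) -> PairedMSA:
    """Pair two per-chain MSAs species-by-species.

    For every organism present in both alignments, the highest-ranked
    hit of chain A is concatenated with the highest-ranked hit of chain
    B; organisms seen in only one alignment, and hits without an
    ``OX=`` token, contribute nothing.  Row 0 is the concatenated query
    pair.  Output hit rows follow chain A rank order.
    """
    best_a = _best_hit_per_organism(msa_a)
    best_b = _best_hit_per_organism(msa_b)
    shared = [org for org in best_a if org in best_b]

    qa, qb = msa_a.query, msa_b.query
    rows = [
        AlignedRow(
            header=f"{qa.header} & {qb.header}",
            sequence=qa.sequence + qb.sequence,
            rank=0,
        )
    ]
    provenance: list[tuple[int, int, int]] = []
    for out_rank, org in enumerate(shared, start=1):
        ra, rb = best_a[org], best_b[org]
        rows.append(
            AlignedRow(
                header=f"{ra.header} & {rb.header}",
                sequence=ra.sequence + rb.sequence,
                rank=out_rank,
                organism_id=org,
            )
        )
        provenance.append((org, ra.rank, rb.rank))
    return PairedMSA(rows, provenance=provenance)


def block_diagonalize(msa_a: MSA, msa_b: MSA) -> MSA:
    """Stack two per-chain MSAs into one concatenated alignment.

    Row 0 is the concatenated query pair.  Every non-query row of chain
    A is elongated with gaps on the right (the partner's columns) and
    every non-query row of chain B with gaps on the left, yielding a
    block-diagonal alignment of width ``L_A + L_B`` with
    ``1 + (|A|-1) + (|B|-1)`` rows.
    """
    la, lb = msa_a.query_length, msa_b.query_length
    rows = [
        AlignedRow(
            header=f"{msa_a.query.header} & {msa_b.query.header}",
            sequence=msa_a.query.sequence + msa_b.query.sequence,
            rank=0,
        )
    ]
    rank = 1
    for row in msa_a.rows[1:]:
        rows.append(replace(row, sequence=row.sequence + "-" * lb, rank=rank))
        rank += 1
    for row in msa_b.rows[1:]:
        rows.append(replace(row, sequence="-" * la + row.sequence, rank=rank))
        rank += 1
    return MSA(rows)


def fuse_msas(parts: Sequence[MSA]) -> MSA:
    """Concatenate several MSAs sharing the same query into one.

    The shared query row appears once, followed by the non-query rows of
    each part in order.  Parts with differing query strings raise
    ``ValueError``.
    """
    if not parts:
        raise ValueError("fuse_msas requires at least one MSA")
    query_seq = parts[0].query.sequence
    for i, part in enumerate(parts[1:], start=2):
        if part.query.sequence != query_seq:
            raise ValueError(
                f"part {i} query does not match part 1 query; "
                "all fused MSAs must share the concatenated query"
            )
    rows = [replace(parts[0].query, rank=0)]
    rank = 1
    for part in parts:
        for row in part.rows[1:]:
            rows.append(replace(row, rank=rank))
            rank += 1
    return MSA(rows)


def _row_array(row: AlignedRow) -> np.ndarray:
    return np.frombuffer(row.sequence.encode("ascii"), dtype="S1")


def compute_neff(
    msa: MSA,
    identity_threshold: float = 0.62,
    coverage_threshold: float = 0.9,
) -> NeffResult:
    """Effective sequence count by greedy clustering at 62% identity.

    Rows are sorted by ungapped length (descending, stable) and each row
    joins the first existing cluster whose representative it matches at
    ``>= identity_threshold`` identity over mutually aligned columns,
    with those columns covering ``>= coverage_threshold`` of the shorter
    sequence; otherwise it founds a new cluster.  The cluster count is
    the Neff value.

    Identity is computed directly on the aligned rows (columns where
    both sequences are non-gap); no realignment is performed.
    """
    n = len(msa.rows)
    arrays = [_row_array(r) for r in msa.rows]
    gap = np.frombuffer(b"-", dtype="S1")[0]
    nongap = [a != gap for a in arrays]
    ungapped = [int(m.sum()) for m in nongap]

    order = sorted(range(n), key=lambda i: -ungapped[i])
    reps: list[int] = []  # row index of each cluster representative
    assignment: dict[int, int] = {}
    for i in order:
        placed = False
        for ci, rep in enumerate(reps):
            both = nongap[i] & nongap[rep]
            shared = int(both.sum())
            if shared == 0:
                continue
            shorter = min(ungapped[i], ungapped[rep])
            if shorter == 0 or shared / shorter < coverage_threshold:
                continue
            matches = int((arrays[i] == arrays[rep])[both].sum())
            if matches / shared >= identity_threshold:
                assignment[i] = ci
                placed = True
                break
        if not placed:
            assignment[i] = len(reps)
            reps.append(i)
    return NeffResult(n_clusters=len(reps), cluster_assignment=assignment)
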