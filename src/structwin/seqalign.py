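"""Sequence-to-structure correspondence.

This module builds the three-way map

    structure residue  ↔  reference protein position  ↔  alignment column(s)

that lets the window engine pull, for any spatial set of residues, the
alignment columns that carry their data. Nucleotide alignments are mapped
codon-wise (three columns per residue) with automatic reading-frame and
strand detection, including reverse-sense coding sequences; protein
alignments map one column per residue; numeric tables are indexed directly
by reference position.

All coordinates — reference positions and alignment columns — are 1-based
and inclusive, in files and in the API.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .errors import InputError, LowIdentityError, MappingFailureError
from .structures import ResidueId

_DNA_CHARS = set("ACGTN-")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
_STOPS = set(_CODON_TABLE.stop_codons)

Alphabet = Literal["dna", "protein"]
Strand = Literal["forward", "reverse"]
GapPolicy = Literal["complete-deletion", "pairwise"]


@dataclass
class AlignmentData:
    """An equal-length multiple sequence alignment (nucleotide or protein)."""

    names: list[str]
    rows: list[str]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise InputError("names and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        if self.alphabet == "dna":
            bad = set("".join(self.rows)) - _DNA_CHARS
            if bad:
                raise InputError(f"non-nucleotide characters in dna alignment: {sorted(bad)}")
        elif self.alphabet != "protein":
            raise InputError(f"alphabet must be 'dna' or 'protein', got {self.alphabet!r}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        """Column ``i`` (1-based) as a string of states, one per row."""
        return "".join(row[i - 1] for row in self.rows)

    def take_columns(self, columns: Sequence[int]) -> "AlignmentData":
        """New alignment restricted to the given 1-based columns, in order."""
        rows = ["".join(row[c - 1] for c in columns) for row in self.rows]
        return AlignmentData(names=list(self.names), rows=rows, alphabet=self.alphabet)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike, alphabet: str = "auto") -> "AlignmentData":
        records = list(SeqIO.parse(os.fspath(path), "fasta"))
        if not records:
            raise InputError(f"no sequences in {path}")
        names = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
        if alphabet == "auto":
            chars = set("".join(rows))
            alphabet = "dna" if chars <= _DNA_CHARS else "protein"
        return cls(names=names, rows=rows, alphabet=alphabet)  # type: ignore[arg-type]


@dataclass
class ReferenceSeq:
    """Ungapped reference protein sequence; positions are 1-based."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise InputError("reference sequence is empty")
        if "-" in self.residues:
            raise InputError("reference sequence must not contain gaps")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceSeq":
        records = list(SeqIO.parse(os.fspath(path), "fasta"))
        if not records:
            raise InputError(f"no sequences in {path}")
        return cls(id=records[0].id, residues=str(records[0].seq))


@dataclass
class NumericTable:
    """Per-reference-position numeric data (1-based positions)."""

    values: dict[int, float]

    def __post_init__(self) -> None:
        for pos in self.values:
            if pos < 1:
                raise InputError(f"positions are 1-based; got {pos}")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "NumericTable":
        """Read a two-column (position, value) TSV, with or without a header."""
        df = pd.read_csv(os.fspath(path), sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise InputError(f"{path}: need two tab-separated columns (position, value)")
        try:
            int(df.iloc[0, 0])
        except (ValueError, TypeError):
            df = df.iloc[1:]  # header row
        try:
            values = {int(p): float(v) for p, v in zip(df.iloc[:, 0], df.iloc[:, 1])}
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}: non-numeric entry in table: {exc}") from exc
        return cls(values=values)


@dataclass
class ResidueDataMap:
    """structure residue → reference position → alignment column(s).

    ``residue_to_ref`` and ``ref_to_columns`` are both partial; the composed
    residue → columns map is defined exactly where both are. For nucleotide
    data every mapped reference position owns exactly three strictly
    increasing columns (the codon; for reverse-strand data the triplet is
    stored in ascending column order but is read 3'→5').
    """

    residue_to_ref: dict[ResidueId, int]
    ref_to_columns: dict[int, tuple[int, ...]]
    strand: Strand | None = None

    def __post_init__(self) -> None:
        # injective within each chain; homo-oligomer protomers may share
        # reference positions across chains by design
        by_chain: dict[str, list[int]] = {}
        for rid, pos in self.residue_to_ref.items():
            by_chain.setdefault(rid.chain, []).append(pos)
        for chain, refs in by_chain.items():
            if len(refs) != len(set(refs)):
                raise InputError(f"residue_to_ref not injective within chain {chain}")
        for pos, cols in self.ref_to_columns.items():
            if list(cols) != sorted(set(cols)):
                raise InputError(f"columns for reference position {pos} not strictly increasing")

    def columns_for(self, rid: ResidueId) -> tuple[int, ...] | None:
        pos = self.residue_to_ref.get(rid)
        if pos is None:
            return None
        return self.ref_to_columns.get(pos)

    def mapped_residues(self) -> list[ResidueId]:
        return [rid for rid in self.residue_to_ref if self.columns_for(rid) is not None]


# ---------------------------------------------------------------------------
# pairwise protein alignment (global, affine gaps, BLOSUM62)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style affine gaps (open 11, extend 1): a length-L gap costs 11 + L
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_BLOSUM_ALPHABET = set(str(substitution_matrices.load("BLOSUM62").alphabet))


def _sanitize(seq: str) -> str:
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq.upper())


def _align_pair(a: str, b: str) -> tuple[float, list[tuple[int, int]], float]:
    """Globally align ``a`` to ``b``.

    Returns (score, aligned 0-based position pairs, identity over aligned
    pairs). The first optimal alignment reported by the aligner is used, so
    results are deterministic.
    """
    aligner = _make_aligner()
    alignment = aligner.align(_sanitize(a), _sanitize(b))[0]
    pairs: list[tuple[int, int]] = []
    blocks_a, blocks_b = alignment.aligned
    for (sa, ea), (sb, _) in zip(blocks_a, blocks_b):
        for k in range(int(ea) - int(sa)):
            pairs.append((int(sa) + k, int(sb) + k))
    matches = sum(1 for i, j in pairs if a[i].upper() == b[j].upper())
    identity = matches / len(pairs) if pairs else 0.0
    return float(alignment.score), pairs, identity


def align_protein_to_reference(
    structure_seq: str,
    index: Sequence[ResidueId],
    ref: ReferenceSeq,
    min_identity: float = 0.30,
) -> dict[ResidueId, int]:
    """Map structure residues to reference positions by global alignment.

    Mismatched aligned pairs still map (the reference drives the data, the
    structure drives space); residues aligned to gaps are absent from the
    map. Raises :class:`LowIdentityError` below ``min_identity``.
    """
    if not structure_seq:
        raise InputError("structure sequence is empty")
    if len(structure_seq) != len(index):
        raise InputError("structure sequence and residue index differ in length")
    _, pairs, identity = _align_pair(structure_seq, ref.residues)
    if identity < min_identity:
        raise LowIdentityError(
            f"structure/reference alignment identity {identity:.1%} is below the "
            f"{min_identity:.0%} floor; check that the reference matches the structure"
        )
    return {index[i]: j + 1 for i, j in pairs}


# ---------------------------------------------------------------------------
# translation and codon mapping


def reverse_complement(dna: str) -> str:
    return dna.upper().translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0, strand: Strand = "forward") -> str:
    """Translate an ungapped coding sequence with the standard genetic code.

    ``frame`` ∈ {0, 1, 2} skips that many leading bases; ``strand='reverse'``
    reverse-complements first (reverse-sense translation). Codons containing
    N translate to 'X'; stops to '*'; a trailing partial codon is dropped.
    """
    seq = dna.upper()
    for pos, c in enumerate(seq, start=1):
        if c not in "ACGTN":
            raise InputError(f"invalid nucleotide {c!r} at position {pos}")
    if frame not in (0, 1, 2):
        raise InputError(f"frame must be 0, 1 or 2, got {frame}")
    if strand == "reverse":
        seq = reverse_complement(seq)
    elif strand != "forward":
        raise InputError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    seq = seq[frame:]
    out: list[str] = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append(_CODON_TABLE.forward_table[codon])
    return "".join(out)


def map_codons(
    ref: ReferenceSeq,
    aln: AlignmentData,
    representative: int = 0,
    min_identity: float = 0.30,
) -> tuple[dict[int, tuple[int, int, int]], Strand]:
    """Locate each reference residue's codon among the alignment columns.

    The representative row (default: first), stripped of gaps, is translated
    in all six frame/strand combinations; each translation is aligned to the
    reference and the best-scoring combination wins (ties prefer forward
    strand, then the lowest frame). Each mapped reference position receives
    the three alignment columns holding that codon's bases in the
    representative row (ascending column order; read 3'→5' when the strand is
    reverse).
    """
    if aln.alphabet != "dna":
        raise InputError("map_codons requires a nucleotide alignment")
    if not 0 <= representative < aln.n:
        raise InputError(f"representative row {representative} out of range (n={aln.n})")
    rep = aln.rows[representative]
    nongap_cols = [i + 1 for i, c in enumerate(rep) if c != "-"]
    ungapped = rep.replace("-", "")
    if len(ungapped) < 3:
        raise MappingFailureError("representative row has fewer than 3 bases")

    candidates: list[tuple[float, int, int, list[tuple[int, int]], float, Strand]] = []
    diagnostics: list[str] = []
    for strand_rank, strand in enumerate(("forward", "reverse")):
        for frame in (0, 1, 2):
            peptide = translate(ungapped, frame=frame, strand=strand)  # type: ignore[arg-type]
            if not peptide:
                continue
            score, pairs, identity = _align_pair(peptide, ref.residues)
            diagnostics.append(f"{strand}/frame{frame}: identity {identity:.1%}")
            candidates.append((score, strand_rank, frame, pairs, identity, strand))  # type: ignore[arg-type]
    qualifying = [c for c in candidates if c[4] >= min_identity]
    if not qualifying:
        raise MappingFailureError(
            "no frame/strand combination reaches the "
            f"{min_identity:.0%} identity floor ({'; '.join(diagnostics)})"
        )
    score, _, frame, pairs, _, strand = min(
        qualifying, key=lambda c: (-c[0], c[1], c[2])
    )

    n_bases = len(ungapped)
    ref_to_columns: dict[int, tuple[int, int, int]] = {}
    for pep_i, ref_j in pairs:  # 0-based peptide/reference indices
        cols = []
        for k in range(3):
            reading_pos = frame + 3 * pep_i + k
            u = reading_pos if strand == "forward" else n_bases - 1 - reading_pos
            cols.append(nongap_cols[u])
        ref_to_columns[ref_j + 1] = tuple(sorted(cols))  # type: ignore[assignment]
    return ref_to_columns, strand  # type: ignore[return-value]


def map_protein_columns(
    ref: ReferenceSeq,
    aln: AlignmentData,
    representative: int = 0,
    min_identity: float = 0.30,
) -> dict[int, tuple[int]]:
    """Protein-alignment analogue of :func:`map_codons`: one column per position."""
    if aln.alphabet != "protein":
        raise InputError("map_protein_columns requires a protein alignment")
    if not 0 <= representative < aln.n:
        raise InputError(f"representative row {representative} out of range (n={aln.n})")
    rep = aln.rows[representative]
    nongap_cols = [i + 1 for i, c in enumerate(rep) if c != "-"]
    ungapped = rep.replace("-", "")
    if not ungapped:
        raise MappingFailureError("representative row is all gaps")
    _, pairs, identity = _align_pair(ungapped, ref.residues)
    if identity < min_identity:
        raise MappingFailureError(
            f"representative/reference identity {identity:.1%} below the "
            f"{min_identity:.0%} floor"
        )
    return {ref_j + 1: (nongap_cols[rep_i],) for rep_i, ref_j in pairs}


def compose_map(
    residue_to_ref: Mapping[ResidueId, int],
    ref_to_columns: Mapping[int, tuple[int, ...]],
    strand: Strand | None = None,
) -> ResidueDataMap:
    """Bundle the two partial maps; composition is defined where both are."""
    return ResidueDataMap(
        residue_to_ref=dict(residue_to_ref),
        ref_to_columns={p: tuple(c) for p, c in ref_to_columns.items()},
        strand=strand,
    )


# ---------------------------------------------------------------------------
# window sub-alignments


def _ambiguity_chars(alphabet: Alphabet) -> set[str]:
    return {"-", "N"} if alphabet == "dna" else {"-", "X"}


def filter_columns(aln: AlignmentData, drop: Iterable[str]) -> AlignmentData:
    """Remove every column containing any character in ``drop``."""
    drop = set(drop)
    keep = [
        c for c in range(1, aln.length + 1) if not (set(aln.column(c)) & drop)
    ]
    return aln.take_columns(keep)


def window_subalignment(
    aln: AlignmentData,
    rmap: ResidueDataMap,
    window: Iterable[ResidueId],
    gap_policy: GapPolicy = "complete-deletion",
) -> AlignmentData:
    """Columns of the alignment carried by the mapped residues of a window.

    Residues are visited in id order; unmapped residues contribute nothing
    (an all-unmapped window yields a zero-column alignment). Under
    ``complete-deletion`` every column containing a gap — or an ambiguity
    character ('N' for nucleotide, 'X' for protein) — is removed.
    """
    window = sorted(window)
    if not window:
        raise InputError("window is empty")
    columns: list[int] = []
    for rid in window:
        cols = rmap.columns_for(rid)
        if cols is not None:
            columns.extend(cols)
    sub = aln.take_columns(columns)
    if gap_policy == "complete-deletion":
        sub = filter_columns(sub, _ambiguity_chars(aln.alphabet))
    elif gap_policy != "pairwise":
        raise InputError(f"unknown gap_policy {gap_policy!r}")
    return sub
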