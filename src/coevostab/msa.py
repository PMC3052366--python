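"""Alignment container, FASTA I/O, reference mapping and redundancy filtering.

The package works on protein multiple sequence alignments (MSAs) over the
20 canonical amino acids plus the gap symbol ``-``.  The amino-acid order
used everywhere (column frequencies, energy matrices) is the fixed order
``G A L V I P R T S C M K E Q D N W Y F H``, so that frequency vectors and
per-position mutational stability vectors line up without reindexing.

Ambiguous residues (``X``) are treated as gaps: the downstream statistics
(column entropies, mutual information, stability lookups) are defined on
the 20-letter alphabet only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Fixed amino-acid order shared with energy matrices.
AA_ORDER = "GALVIPRTSCMKEQDNWYFH"
GAP = "-"
#: Integer code used for the gap state in encoded alignments.
GAP_CODE = 20

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _aa, _i in _AA_INDEX.items():
    _ENCODE_TABLE[ord(_aa)] = _i
_ENCODE_TABLE[ord(GAP)] = GAP_CODE


class AlignmentFormatError(ValueError):
    """Rows of unequal length or otherwise malformed alignment input."""


class AlphabetError(ValueError):
    """A symbol outside the 20 canonical amino acids, 'X' and the gap."""


@dataclass
class Alignment:
    """An aligned set of protein sequences.

    Parameters
    ----------
    ids
        One identifier per row.
    rows
        Equal-length strings over the alphabet ``AA_ORDER`` plus ``-``.
    labels
        Optional per-sequence subfamily tags (e.g. ``"C23"`` / ``"N23"``).
    ref_index
        Optional row index of the designated reference sequence.
    positions
        1-based position labels carried from the reference numbering; when
        unset, columns are labelled 1..L.
    """

    ids: list[str]
    rows: list[str]
    labels: list[str] | None = None
    ref_index: int | None = None
    positions: list[int] | None = None
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows must have the same length")
        if self.rows:
            L = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != L:
                    raise AlignmentFormatError(
                        f"row {rid!r} has length {len(row)}, expected {L}"
                    )
        if self.labels is not None and len(self.labels) != len(self.rows):
            raise AlignmentFormatError("labels must match the number of rows")
        if self.positions is None:
            self.positions = list(range(1, self.length + 1))
        elif len(self.positions) != self.length:
            raise AlignmentFormatError("positions must match the alignment length")
        self.encoded()  # validates the alphabet eagerly

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_seqs, L); gap encodes as 20."""
        if self._encoded is None:
            if not self.rows:
                self._encoded = np.empty((0, 0), dtype=np.int8)
                return self._encoded
            raw = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
            codes = _ENCODE_TABLE[raw]
            if (codes < 0).any():
                bad = sorted({chr(c) for c in raw[codes < 0]})
                raise AlphabetError(f"unexpected symbols in alignment: {bad}")
            self._encoded = codes.reshape(self.n_seqs, self.length)
        return self._encoded

    def column(self, position: int) -> np.ndarray:
        """Encoded column at a 1-based position label."""
        return self.encoded()[:, self._column_index(position)]

    def _column_index(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise IndexError(f"position {position} not in alignment") from None

    def subset_rows(self, indices: list[int]) -> "Alignment":
        return replace(
            self,
            ids=[self.ids[k] for k in indices],
            rows=[self.rows[k] for k in indices],
            labels=None if self.labels is None else [self.labels[k] for k in indices],
            ref_index=None,
            _encoded=None,
        )

    def subfamily(self, label: str) -> "Alignment":
        """Rows whose subfamily tag equals ``label``."""
        if self.labels is None:
            raise ValueError("alignment carries no subfamily labels")
        return self.subset_rows([k for k, lb in enumerate(self.labels) if lb == label])


@dataclass
class ColumnFrequencies:
    """Amino-acid counts and relative frequencies of one alignment column.

    ``counts`` and ``freqs`` follow ``AA_ORDER``; gap rows do not contribute.
    For an all-gap column ``n_ungapped`` is 0, ``freqs`` is all-NaN and the
    ``all_gap`` flag is set.
    """

    position: int
    counts: np.ndarray
    freqs: np.ndarray
    n_ungapped: int

    @property
    def all_gap(self) -> bool:
        return self.n_ungapped == 0


def _normalize_row(seq: str) -> str:
    s = seq.upper().replace(".", GAP)
    if "X" in s:
        logger.warning("ambiguous residue 'X' treated as gap")
        s = s.replace("X", GAP)
    return s


def read_fasta_msa(path) -> Alignment:
    """Read an aligned multi-FASTA file.

    Rows are upper-cased, ``.`` is normalised to ``-`` and ``X`` is treated
    as a gap (with a logged warning).  Records of unequal length raise
    :class:`AlignmentFormatError`; any other non-canonical symbol raises
    :class:`AlphabetError`.
    """
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize_row(str(rec.seq)))
    if not ids:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentFormatError(f"unequal record lengths {sorted(lengths)} in {path}")
    return Alignment(ids=ids, rows=rows)


def write_fasta_msa(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labels_tsv(path) -> dict[str, str]:
    """Read a 2-column TSV of (sequence id, subfamily label)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentFormatError(f"expected 2 tab-separated fields: {line!r}")
            out[parts[0]] = parts[1]
    return out


def attach_labels(
    aln: Alignment,
    mapping: dict[str, str] | None = None,
    id_regex: str | None = None,
) -> Alignment:
    """Attach subfamily labels from an id->label mapping or an id regex.

    With ``id_regex``, the first capture group of the match against each id
    becomes the label.
    """
    if (mapping is None) == (id_regex is None):
        raise ValueError("provide exactly one of mapping or id_regex")
    if mapping is not None:
        labels = [mapping.get(rid) for rid in aln.ids]
        missing = [rid for rid, lb in zip(aln.ids, labels) if lb is None]
        if missing:
            raise KeyError(f"no label for ids: {missing[:5]}")
    else:
        pat = re.compile(id_regex)
        labels = []
        for rid in aln.ids:
            m = pat.search(rid)
            if m is None:
                raise KeyError(f"id {rid!r} does not match label regex")
            labels.append(m.group(1))
    return replace(aln, labels=list(labels), _encoded=None)


def map_to_reference(aln: Alignment, ref_id: str) -> Alignment:
    """Keep only columns where the reference row has a residue.

    Positions are renumbered 1..L_ref following the reference residue order
    (so downstream results use the reference sequence numbering).  The
    operation is idempotent: mapping an already-mapped alignment on the same
    reference changes nothing.
    """
    try:
        ref_index = aln.ids.index(ref_id)
    except ValueError:
        raise KeyError(f"reference id {ref_id!r} not in alignment") from None
    keep = [k for k, c in enumerate(aln.rows[ref_index]) if c != GAP]
    rows = ["".join(row[k] for k in keep) for row in aln.rows]
    return Alignment(
        ids=list(aln.ids),
        rows=rows,
        labels=None if aln.labels is None else list(aln.labels),
        ref_index=ref_index,
        positions=list(range(1, len(keep) + 1)),
    )


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over mutually ungapped columns.

    Returns 0.0 when the two rows share no ungapped column.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = _ENCODE_TABLE[np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)]
    b = _ENCODE_TABLE[np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)]
    if (a < 0).any() or (b < 0).any():
        raise AlphabetError("unexpected symbols in row")
    shared = (a != GAP_CODE) & (b != GAP_CODE)
    n = int(shared.sum())
    if n == 0:
        return 0.0
    return float((a[shared] == b[shared]).sum() / n)


def filter_redundancy(aln: Alignment, max_identity: float) -> Alignment:
    """Greedy redundancy reduction at an identity ceiling.

    Single pass in input order: a row is kept iff its identity to every
    previously kept row is <= ``max_identity``.  Deterministic and
    order-stable; no kept pair exceeds the ceiling.
    """
    if not (0.0 < max_identity <= 1.0):
        raise ValueError("max_identity must be in (0, 1]")
    if aln.n_seqs == 0:
        return aln
    enc = aln.encoded()
    ungapped = enc != GAP_CODE
    kept: list[int] = []
    for k in range(aln.n_seqs):
        ok = True
        for j in kept:
            shared = ungapped[k] & ungapped[j]
            n = int(shared.sum())
            ident = 0.0 if n == 0 else float((enc[k, shared] == enc[j, shared]).sum() / n)
            if ident > max_identity:
                ok = False
                break
        if ok:
            kept.append(k)
    out = aln.subset_rows(kept)
    return replace(out, positions=list(aln.positions))


def column_frequencies(aln: Alignment, position: int) -> ColumnFrequencies:
    """Amino-acid counts/frequencies of one column (gap rows excluded)."""
    col = aln.column(position)
    counts = np.bincount(col[col != GAP_CODE], minlength=20).astype(np.int64)
    n = int(counts.sum())
    freqs = counts / n if n > 0 else np.full(20, np.nan)
    return ColumnFrequencies(position=position, counts=counts, freqs=freqs, n_ungapped=n)


def frequency_matrix(aln: Alignment) -> np.ndarray:
    """L x 20 matrix of per-column relative frequencies (NaN rows = all-gap).

    Vectorised convenience over :func:`column_frequencies`; row order follows
    ``aln.positions``.
    """
    enc = aln.encoded()
    L = aln.length
    counts = np.zeros((L, 21), dtype=np.int64)
    for j in range(L):
        counts[j] = np.bincount(enc[:, j], minlength=21)
    aa_counts = counts[:, :20].astype(float)
    totals = aa_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = aa_counts / totals
    freqs[totals[:, 0] == 0] = np.nan
    return freqs
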