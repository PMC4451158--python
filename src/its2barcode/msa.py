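"""Progressive multiple sequence alignment and the gapped-matrix container.

The MSA is the coordinate system for everything downstream: variable-site
classification, diagnostic sites, K2P distances and the column bootstrap
all address 1-based alignment columns of this object.

Alignment strategy: identical sequences are grouped first (they align
trivially), a neighbor-joining guide tree is built from pairwise K2P
distances between the unique sequences, and profiles are merged postorder
by affine-gap global alignment of profile columns ("once a gap, always a
gap"). All tie-breaking is lexicographic in sample ids, so the output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .alignment import AlignmentParams, global_align, gotoh_ops
from .distance import DistanceMatrix, count_site_patterns, k2p_distance
from .errors import SaturatedDistanceError, ValidationError
from .records import SeqRecord, check_unique_ids
from .seqio import HeaderSchema

GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """Gapped rows over 1-based alignment columns.

    ``rows`` maps sample_id -> gapped string (insertion order is row
    order); ``labels`` maps sample_id -> species.
    """

    rows: dict[str, str]
    labels: dict[str, str]

    def __post_init__(self):
        if not self.rows:
            raise ValidationError("alignment has no rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValidationError("rows must all have the same length")
        n = lengths.pop()
        if n == 0:
            raise ValidationError("alignment has zero columns")
        missing = [i for i in self.rows if i not in self.labels]
        if missing:
            raise ValidationError(f"rows without species label: {missing[:5]}")
        for col in range(n):
            if all(r[col] == GAP for r in self.rows.values()):
                raise ValidationError(f"all-gap column at site {col + 1}")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def degapped(self, sample_id: str) -> str:
        return self.rows[sample_id].replace(GAP, "")

    def species_of(self, sample_id: str) -> str:
        return self.labels[sample_id]


def column(msa: MultipleAlignment, site: int) -> dict[str, str]:
    """Vertical slice at a 1-based site; raises IndexError out of range."""
    if not 1 <= site <= msa.n_cols:
        raise IndexError(f"site {site} outside [1, {msa.n_cols}]")
    return {i: row[site - 1] for i, row in msa.rows.items()}


# ---------------------------------------------------------------------------
# Profiles


class _Profile:
    """Rows plus a per-column symbol-frequency matrix over a shared alphabet."""

    def __init__(self, ids: list[str], rows: list[str], alphabet: str):
        self.ids = ids
        self.rows = rows
        self.alphabet = alphabet
        idx = {c: k for k, c in enumerate(alphabet)}
        mat = np.zeros((len(rows[0]), len(alphabet)))
        for row in rows:
            for col, ch in enumerate(row):
                mat[col, idx[ch]] += 1.0
        self.freq = mat / len(rows)


def _score_matrix(alphabet: str, params: AlignmentParams) -> np.ndarray:
    k = len(alphabet)
    S = np.full((k, k), params.mismatch)
    for i, c in enumerate(alphabet):
        S[i, i] = params.match
    g = alphabet.index(GAP)
    S[g, :] = 0.0
    S[:, g] = 0.0
    return S


def _merge(pa: _Profile, pb: _Profile, params: AlignmentParams, S: np.ndarray) -> _Profile:
    sub = pa.freq @ S @ pb.freq.T
    _, ops = gotoh_ops(sub, params.gap_open, params.gap_extend)
    rows_a = [[] for _ in pa.rows]
    rows_b = [[] for _ in pb.rows]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for out, row in zip(rows_a, pa.rows):
                out.append(row[ia])
            ia += 1
        else:
            for out in rows_a:
                out.append(GAP)
        if op in ("D", "L"):
            for out, row in zip(rows_b, pb.rows):
                out.append(row[ib])
            ib += 1
        else:
            for out in rows_b:
                out.append(GAP)
    merged_rows = ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b]
    return _Profile(pa.ids + pb.ids, merged_rows, pa.alphabet)


def _guide_distance(a: str, b: str, params: AlignmentParams) -> float:
    aln = global_align(a, b, params)
    try:
        return k2p_distance(count_site_patterns(aln.row_a, aln.row_b))
    except SaturatedDistanceError:
        # guide tree only: fall back to the uncorrected p-distance
        counts = count_site_patterns(aln.row_a, aln.row_b)
        return counts.P + counts.Q


def progressive_msa(
    records: list[SeqRecord], params: AlignmentParams = AlignmentParams()
) -> MultipleAlignment:
    """Progressive MSA over an NJ guide tree; row order follows the input."""
    if len(records) < 2:
        raise ValidationError("need at least 2 records to align")
    check_unique_ids(records)

    groups: dict[str, list[str]] = {}
    for r in records:
        groups.setdefault(r.sequence, []).append(r.sample_id)
    uniq = sorted(((min(ids), seq) for seq, ids in groups.items()))
    alphabet = "".join(sorted(set("".join(s for _, s in uniq)))) + GAP

    if len(uniq) == 1:
        aligned = {uniq[0][0]: uniq[0][1]}
    elif len(uniq) == 2:
        aln = global_align(uniq[0][1], uniq[1][1], params)
        aligned = {uniq[0][0]: aln.row_a, uniq[1][0]: aln.row_b}
    else:
        from .phylo import neighbor_joining  # deferred: phylo imports distance only

        ids = [rid for rid, _ in uniq]
        seqs = {rid: seq for rid, seq in uniq}
        k = len(ids)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d[i, j] = d[j, i] = _guide_distance(seqs[ids[i]], seqs[ids[j]], params)
        guide = neighbor_joining(DistanceMatrix(tuple(ids), d))
        S = _score_matrix(alphabet, params)

        def min_leaf(node) -> str:
            if node.is_leaf:
                return node.name
            return min(min_leaf(c) for c in node.children)

        def build(node) -> _Profile:
            if node.is_leaf:
                return _Profile([node.name], [seqs[node.name]], alphabet)
            children = sorted(node.children, key=min_leaf)
            prof = build(children[0])
            for child in children[1:]:
                prof = _merge(prof, build(child), params, S)
            return prof

        final = build(guide.root)
        aligned = dict(zip(final.ids, final.rows))

    seq_to_row = {}
    for rid, seq in uniq:
        seq_to_row[seq] = aligned[rid]
    rows = {r.sample_id: seq_to_row[r.sequence] for r in records}
    labels = {r.sample_id: r.species for r in records}
    return MultipleAlignment(rows, labels)


# ---------------------------------------------------------------------------
# Aligned FASTA / PHYLIP I/O

_ALIGNED_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")


def read_aligned_fasta(
    path: str | Path, schema: HeaderSchema = HeaderSchema()
) -> MultipleAlignment:
    rows: dict[str, str] = {}
    labels: dict[str, str] = {}
    for bio in SeqIO.parse(str(path), "fasta"):
        sample_id, species = schema.parse(bio.description)
        seq = str(bio.seq).upper()
        bad = set(seq) - _ALIGNED_ALPHABET
        if bad:
            raise ValidationError(f"{sample_id}: bad symbols in alignment: {sorted(bad)}")
        if sample_id in rows:
            raise ValidationError(f"duplicate sample_id: {sample_id}")
        rows[sample_id] = seq
        labels[sample_id] = species
    return MultipleAlignment(rows, labels)


def write_aligned_fasta(
    msa: MultipleAlignment, path: str | Path, schema: HeaderSchema = HeaderSchema()
) -> None:
    recs = [
        BioSeqRecord(
            Seq(row),
            id=schema.delimiter.join([i, msa.labels[i]])
            if schema.sample_field == 0
            else schema.delimiter.join([msa.labels[i], i]),
            description="",
        )
        for i, row in msa.rows.items()
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(recs)


def write_phylip(msa: MultipleAlignment, path: str | Path) -> None:
    """Relaxed (long-name) sequential PHYLIP."""
    with open(path, "w") as fh:
        fh.write(f"{len(msa.rows)} {msa.n_cols}\n")
        for i, row in msa.rows.items():
            fh.write(f"{i}  {row}\n")
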