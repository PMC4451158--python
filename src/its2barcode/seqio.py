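"""FASTA I/O, primer trimming and rDNA sub-region annotation.

The amplicon analysed by this pipeline spans a partial 5.8S gene, the ITS2
spacer proper, and a partial 28S gene. Across the target taxa the flanking
gene fragments are length-constant (84 bp of 5.8S, 141 bp of 28S), so the
default annotation backend is a fixed-flank rule; ``annotate_regions`` is
the interface point where a profile-HMM backend could be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from Bio.Seq import Seq

from .errors import (
    FastaParseError,
    PrimerGeometryError,
    PrimerNotFoundError,
    TooShortError,
    UndefinedGCError,
    ValidationError,
)
from .records import BASES, SeqRecord, Source, check_unique_ids, revcomp

log = logging.getLogger(__name__)

#: Universal ITS2 amplification primers (forward given 5'->3', reverse as
#: printed 3'->5' on the protocol sheet; see ``trim_primers``).
DEFAULT_FWD_PRIMER = "ATTCACACCAAGTATCGCAT"
DEFAULT_REV_PRIMER = "ATTGTAGTCTGGAGAAGCGTC"

#: Fixed flank lengths (bp) of the partial rDNA genes around ITS2.
P58S_LEN = 84
P28S_LEN = 141
MIN_ITS2_LEN = 226
MIN_AMPLICON_LEN = P58S_LEN + P28S_LEN + MIN_ITS2_LEN  # 451


@dataclass(frozen=True)
class HeaderSchema:
    """How a FASTA header encodes the labels, e.g. ``S1|Ferula_sinkiangensis``."""

    delimiter: str = "|"
    sample_field: int = 0
    species_field: int = 1

    def parse(self, header: str) -> tuple[str, str]:
        parts = header.split(self.delimiter)
        need = max(self.sample_field, self.species_field) + 1
        if len(parts) < need:
            raise ValidationError(
                f"header {header!r} has {len(parts)} field(s); "
                f"schema needs {need} (delimiter {self.delimiter!r})"
            )
        return parts[self.sample_field].strip(), parts[self.species_field].strip()

    def format(self, record: SeqRecord) -> str:
        fields = ["", ""]
        fields[self.sample_field] = record.sample_id
        fields[self.species_field] = record.species
        return self.delimiter.join(fields)


class Region(str, Enum):
    FULL = "FULL"
    P58S = "P58S"
    ITS2 = "ITS2"
    P28S = "P28S"


@dataclass(frozen=True)
class RegionAnnotation:
    """Partition of an amplicon into partial 5.8S / ITS2 / partial 28S.

    Intervals are 1-based, half-open ``[start, end)`` and tile ``[1, full_len]``.
    """

    full_len: int
    p58s: tuple[int, int]
    its2: tuple[int, int]
    p28s: tuple[int, int]

    def __post_init__(self):
        a, b, c = self.p58s, self.its2, self.p28s
        if not (a[0] == 1 and a[1] == b[0] and b[1] == c[0] and c[1] == self.full_len + 1):
            raise ValidationError(f"region intervals do not tile [1,{self.full_len}]")
        if b[1] <= b[0]:
            raise ValidationError("empty ITS2 interval")

    def interval(self, region: Region) -> tuple[int, int]:
        if region is Region.FULL:
            return (1, self.full_len + 1)
        return {Region.P58S: self.p58s, Region.ITS2: self.its2, Region.P28S: self.p28s}[region]

    def extract(self, sequence: str, region: Region) -> str:
        s, e = self.interval(region)
        return sequence[s - 1 : e - 1]


@dataclass(frozen=True)
class RegionStats:
    region: Region
    length_bp: int
    gc_percent: float


# ---------------------------------------------------------------------------
# FASTA I/O


def _prevalidate_fasta(path: Path) -> None:
    """Cheap structural scan so parse errors can carry a line number."""
    with open(path) as fh:
        seen_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError("empty FASTA header", line=lineno)
                seen_header = True
            elif not seen_header:
                raise FastaParseError(
                    "sequence data before first '>' header", line=lineno
                )


def read_fasta(
    path: str | Path,
    schema: HeaderSchema = HeaderSchema(),
    source: Source = Source.SAMPLED,
) -> list[SeqRecord]:
    """Read labeled records from FASTA; order preserved, sequences uppercased.

    Raises
    ------
    FastaParseError : structurally malformed file (with line number).
    ValidationError : unparseable header, bad alphabet, or duplicate sample_id.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    _prevalidate_fasta(path)
    out: list[SeqRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        sample_id, species = schema.parse(bio.description)
        out.append(SeqRecord(sample_id, species, str(bio.seq).upper(), source))
    check_unique_ids(out)
    return out


def write_fasta(
    records: Iterable[SeqRecord],
    path: str | Path,
    schema: HeaderSchema = HeaderSchema(),
    wrap: int = 70,
) -> None:
    """Write records as FASTA, wrapped at *wrap* columns."""
    bio_records = [
        BioSeqRecord(Seq(r.sequence), id=schema.format(r), description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(bio_records)


# ---------------------------------------------------------------------------
# Primer trimming


def _best_hamming_match(seq: str, probe: str, prefer: str) -> tuple[int, int]:
    """Minimum-Hamming sliding-window match of *probe* in *seq*.

    Returns ``(start, mismatches)``; ties resolved to the leftmost
    (``prefer='left'``) or rightmost (``prefer='right'``) window.
    """
    k = len(probe)
    if k > len(seq):
        return (-1, k + 1)
    best_start, best_mm = -1, k + 1
    positions = range(len(seq) - k + 1)
    for start in positions:
        mm = sum(1 for a, b in zip(seq[start : start + k], probe) if a != b)
        if mm < best_mm or (mm == best_mm and prefer == "right"):
            best_start, best_mm = start, mm
    return best_start, best_mm


def trim_primers(
    record: SeqRecord,
    fwd: str = DEFAULT_FWD_PRIMER,
    rev: str = DEFAULT_REV_PRIMER,
    max_mismatch: int = 0,
) -> SeqRecord:
    """Excise the amplicon strictly between the primer binding sites.

    The forward primer is matched as written on the sense strand. The
    reverse primer is conventionally written on the protocol sheet either
    5'->3' on the antisense strand or 3'->5' on the sense strand; both
    conventions are tried — the sense strand is searched for
    ``revcomp(rev)`` and for ``revcomp(reversed(rev))`` (= the plain
    complement) — and the better-scoring interpretation wins. Which one
    fired is logged.
    """
    if not fwd or not rev:
        raise ValidationError("primers must be non-empty")
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    seq = record.sequence

    f_start, f_mm = _best_hamming_match(seq, fwd.upper(), prefer="left")
    if f_mm > max_mismatch:
        raise PrimerNotFoundError("forward", max_mismatch)

    candidates = {
        "antisense 5'->3'": revcomp(rev.upper()),
        "sense 3'->5'": revcomp(rev.upper()[::-1]),
    }
    r_start, r_mm, r_probe, r_which = -1, len(rev) + 1, "", ""
    for which, probe in candidates.items():
        start, mm = _best_hamming_match(seq, probe, prefer="right")
        if mm < r_mm:
            r_start, r_mm, r_probe, r_which = start, mm, probe, which
    if r_mm > max_mismatch:
        raise PrimerNotFoundError("reverse", max_mismatch)
    log.debug(
        "%s: reverse primer matched under the %s interpretation (%d mismatches)",
        record.sample_id, r_which, r_mm,
    )

    f_end = f_start + len(fwd)
    if r_start < f_end:
        raise PrimerGeometryError(
            f"{record.sample_id}: primer matches overlap or are out of order "
            f"(forward ends at {f_end}, reverse starts at {r_start})"
        )
    inner = seq[f_end:r_start]
    if not inner:
        raise PrimerGeometryError(f"{record.sample_id}: nothing between primers")
    return record.with_sequence(inner)


# ---------------------------------------------------------------------------
# Region annotation and statistics


def annotate_regions(record: SeqRecord) -> RegionAnnotation:
    """Fixed-flank annotation: first 84 bp = partial 5.8S, last 141 bp = partial 28S.

    Raises ``TooShortError`` for amplicons below 451 bp (84 + 226 + 141).
    """
    n = len(record.sequence)
    if n < MIN_AMPLICON_LEN:
        raise TooShortError(
            f"{record.sample_id}: amplicon {n} bp < minimum {MIN_AMPLICON_LEN} bp"
        )
    return RegionAnnotation(
        full_len=n,
        p58s=(1, 1 + P58S_LEN),
        its2=(1 + P58S_LEN, n - P28S_LEN + 1),
        p28s=(n - P28S_LEN + 1, n + 1),
    )


def gc_percent(seq: str) -> float:
    """GC content in percent over unambiguous bases only.

    Ambiguity codes and gaps are excluded from numerator and denominator,
    so the value is invariant to ambiguous base calls.
    """
    counts = {b: seq.count(b) for b in BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedGCError("no unambiguous A/C/G/T base in region")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def region_stats(record: SeqRecord, ann: RegionAnnotation) -> list[RegionStats]:
    """Per-region length and GC% for FULL, P58S, ITS2 and P28S."""
    if ann.full_len != len(record.sequence):
        raise ValidationError("annotation does not match record length")
    out = []
    for region in (Region.FULL, Region.P58S, Region.ITS2, Region.P28S):
        sub = ann.extract(record.sequence, region)
        out.append(RegionStats(region, len(sub), gc_percent(sub)))
    return out


def write_region_stats_tsv(
    rows: Sequence[tuple[SeqRecord, list[RegionStats]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\tregion\tlength_bp\tgc_percent\n")
        for record, stats in rows:
            for st in stats:
                fh.write(
                    f"{record.sample_id}\t{record.species}\t{st.region.value}"
                    f"\t{st.length_bp}\t{st.gc_percent:.1f}\n"
                )
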