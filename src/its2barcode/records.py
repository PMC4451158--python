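"""Labeled barcode sequence records.

A record couples a DNA string with the two labels the whole pipeline keys
on: a unique sample (voucher) identifier and a species binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from Bio.Seq import Seq

from .errors import ValidationError

#: Unambiguous bases.
BASES = "ACGT"

#: IUPAC DNA alphabet accepted in records (gaps are alignment-only).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Purines / pyrimidines — a change within a set is a transition.
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class Source(str, Enum):
    SAMPLED = "sampled"
    GENBANK = "genbank"
    SIMULATED = "simulated"


@dataclass(frozen=True)
class SeqRecord:
    """One barcode amplicon with its sample and species labels.

    Parameters
    ----------
    sample_id : unique identifier of the sample/voucher within a dataset.
    species : binomial species label, e.g. ``Ferula_sinkiangensis``.
    sequence : uppercase DNA over the IUPAC alphabet, gap-free.
    source : provenance of the sequence.
    """

    sample_id: str
    species: str
    sequence: str
    source: Source = Source.SAMPLED

    def __post_init__(self):
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.species:
            raise ValidationError("species label must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.sample_id}: sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"{self.sample_id}: non-IUPAC symbols in sequence: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "SeqRecord":
        return replace(self, sequence=sequence)


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware, via Biopython)."""
    return str(Seq(seq).reverse_complement())


def is_transition(a: str, b: str) -> bool:
    """True iff *a* -> *b* is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and (
        (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
    )


def check_unique_ids(records) -> None:
    seen = set()
    for r in records:
        if r.sample_id in seen:
            raise ValidationError(f"duplicate sample_id: {r.sample_id}")
        seen.add(r.sample_id)
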