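"""Alignment-column variation analysis and diagnostic-site detection.

Columns are classified disjointly: any column containing a gap is an
*indel* column (even if its bases also vary), columns with >= 2 distinct
bases and no gap are *substitution* columns, and everything else is
monomorphic — so monomorphic + substitution + indel = n_cols and the
variable-site arithmetic adds up. A site is *diagnostic* for a species
when every sample of that species carries one identical symbol there (a
gap counts as a symbol) and no sample of any other species carries it:
one such character is enough to authenticate the species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .errors import ValidationError
from .msa import GAP, MultipleAlignment

_BASES = frozenset("ACGT")


class SiteKind(str, Enum):
    MONOMORPHIC = "monomorphic"
    SUBSTITUTION = "substitution"
    INDEL = "indel"


@dataclass(frozen=True)
class SiteClass:
    site: int  # 1-based alignment column
    kind: SiteKind
    states: tuple[str, ...]  # sorted distinct symbols at the column
    has_ambiguity: bool = False


@dataclass(frozen=True)
class DiagnosticSite:
    species: str
    site: int
    state: str
    background: frozenset[str]

    def __post_init__(self):
        if self.state in self.background:
            raise ValidationError("diagnostic state present in background")


@dataclass(frozen=True)
class Haplotype:
    sequence: str  # aligned (gaps included)
    members: tuple[str, ...]


def classify_sites(msa: MultipleAlignment) -> list[SiteClass]:
    """Classify every column as monomorphic, substitution or indel."""
    out = []
    rows = list(msa.rows.values())
    for col in range(msa.n_cols):
        syms = {row[col] for row in rows}
        states = tuple(sorted(syms))
        ambiguous = any(s not in _BASES and s != GAP for s in syms)
        if GAP in syms:
            kind = SiteKind.INDEL
        elif len(syms) >= 2:
            kind = SiteKind.SUBSTITUTION
        else:
            kind = SiteKind.MONOMORPHIC
        out.append(SiteClass(col + 1, kind, states, ambiguous))
    return out


def variable_sites(sites: Iterable[SiteClass]) -> list[SiteClass]:
    return [s for s in sites if s.kind is not SiteKind.MONOMORPHIC]


def tally_substitutions(sites: Iterable[SiteClass]) -> dict[frozenset[str], int]:
    """Histogram of substitution columns by their unordered base set,
    e.g. {C,T} -> 26; non-substitution sites are filtered out."""
    tally: Counter = Counter()
    for s in sites:
        if s.kind is SiteKind.SUBSTITUTION:
            tally[frozenset(s.states)] += 1
    return dict(tally)


def collapse_haplotypes(msa: MultipleAlignment) -> dict[str, list[Haplotype]]:
    """Group each species' rows by exact aligned-string identity."""
    by_species: dict[str, dict[str, list[str]]] = {}
    for sample_id, row in msa.rows.items():
        sp = msa.labels[sample_id]
        by_species.setdefault(sp, {}).setdefault(row, []).append(sample_id)
    return {
        sp: [Haplotype(seq, tuple(members)) for seq, members in haps.items()]
        for sp, haps in by_species.items()
    }


def find_diagnostic_sites(msa: MultipleAlignment) -> list[DiagnosticSite]:
    """All (species, site) pairs where the species is fixed for a symbol
    absent from every other species; sorted by site then species."""
    species = sorted(set(msa.labels.values()))
    if len(species) < 2:
        raise ValidationError("diagnostic sites need >= 2 species")
    rows_by_species = {
        sp: [row for i, row in msa.rows.items() if msa.labels[i] == sp] for sp in species
    }
    out: list[DiagnosticSite] = []
    for col in range(msa.n_cols):
        col_syms = {sp: {row[col] for row in rows} for sp, rows in rows_by_species.items()}
        for sp in species:
            own = col_syms[sp]
            if len(own) != 1:
                continue
            state = next(iter(own))
            background = frozenset().union(*(col_syms[o] for o in species if o != sp))
            if state not in background:
                out.append(DiagnosticSite(sp, col + 1, state, background))
    out.sort(key=lambda d: (d.site, d.species))
    return out


@dataclass(frozen=True)
class IndelEventSpan:
    """A maximal run of adjacent indel columns sharing one gap pattern."""

    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    gapped_samples: frozenset[str]


def indel_events(msa: MultipleAlignment) -> list[IndelEventSpan]:
    """Event-based view of indels: adjacent indel columns with an identical
    set of gapped samples merge into one event. The default site-based
    counting treats every indel column separately; this is the optional
    merged view."""
    sites = classify_sites(msa)
    events: list[IndelEventSpan] = []
    current: IndelEventSpan | None = None
    for s in sites:
        if s.kind is not SiteKind.INDEL:
            current = None
            continue
        pattern = frozenset(i for i, row in msa.rows.items() if row[s.site - 1] == GAP)
        if current is not None and current.end == s.site - 1 and current.gapped_samples == pattern:
            current = IndelEventSpan(current.start, s.site, pattern)
            events[-1] = current
        else:
            current = IndelEventSpan(s.site, s.site, pattern)
            events.append(current)
    return events


def min_haplotype_separation(msa: MultipleAlignment) -> dict[str, int]:
    """For each species, the minimum number of *substitution-visible*
    differing columns (both symbols unambiguous bases) between one of its
    rows and any row of another species.

    This is the character support available to distance-based clade
    inference: gap columns are excluded because pairwise deletion makes
    them invisible to K2P distances. A species separated from its nearest
    neighbor by k such columns loses its clade in roughly e^-k of column
    bootstrap replicates (all k columns unsampled), so splits with k < 3
    cannot reach high support under any correct implementation."""
    haps = collapse_haplotypes(msa)
    out: dict[str, int] = {}
    for sp, hlist in haps.items():
        best = None
        for other_sp, other_list in haps.items():
            if other_sp == sp:
                continue
            for h in hlist:
                for o in other_list:
                    diff = sum(
                        1
                        for x, y in zip(h.sequence, o.sequence)
                        if x != y and x in _BASES and y in _BASES
                    )
                    best = diff if best is None or diff < best else best
        out[sp] = best if best is not None else 0
    return out


# ---------------------------------------------------------------------------
# Writers


def write_variable_sites_tsv(msa: MultipleAlignment, path: str | Path) -> None:
    """Variable-site matrix: one row per haplotype, one column per variable
    site, headed by the 1-based site positions."""
    var = variable_sites(classify_sites(msa))
    positions = [s.site for s in var]
    haps = collapse_haplotypes(msa)
    with open(path, "w") as fh:
        fh.write("species\thaplotype\tn_members\t" + "\t".join(map(str, positions)) + "\n")
        for sp in sorted(haps):
            for k, hap in enumerate(haps[sp], start=1):
                states = "\t".join(hap.sequence[p - 1] for p in positions)
                fh.write(f"{sp}\thap{k}\t{len(hap.members)}\t{states}\n")


def write_diagnostic_sites_tsv(sites: Iterable[DiagnosticSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tsite\tstate\tbackground\n")
        for d in sites:
            fh.write(f"{d.species}\t{d.site}\t{d.state}\t{''.join(sorted(d.background))}\n")
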