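"""Kimura 2-parameter distances and per-species divergence summaries.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P of
compared sites) from transversions (proportion Q) and corrects for
multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are excluded
pair by pair (pairwise deletion), the convention of the standard barcoding
toolchain; indels contribute nothing to the distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ComputationError,
    NoOverlapError,
    SaturatedDistanceError,
    ValidationError,
)

# A=0 C=1 G=2 T=3, gap=4, anything else (ambiguity codes) = 5.
_ENC = np.full(256, 5, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_ENC[ord("-")] = 4


def encode_row(seq: str) -> np.ndarray:
    """Encode a (possibly gapped) sequence for vectorized site counting."""
    return _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Compared-site tally for one sequence pair after pairwise deletion."""

    n: int
    s: int  # transitions
    v: int  # transversions

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError("no compared sites")
        if self.s + self.v > self.n:
            raise ValidationError("s + v cannot exceed n")

    @property
    def P(self) -> float:
        return self.s / self.n

    @property
    def Q(self) -> float:
        return self.v / self.n


def count_site_patterns(row_a: str, row_b: str) -> PairwiseSiteCounts:
    """Count compared sites, transitions and transversions for two aligned rows."""
    if len(row_a) != len(row_b):
        raise ValidationError("aligned rows must have equal length")
    return _count_encoded(encode_row(row_a), encode_row(row_b))


def _count_encoded(ea: np.ndarray, eb: np.ndarray) -> PairwiseSiteCounts:
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        raise NoOverlapError("no comparable site left after pairwise deletion")
    diff = valid & (ea != eb)
    # XOR of the base encoding is 2 exactly for A<->G and C<->T.
    s = int((diff & ((ea ^ eb) == 2)).sum())
    v = int(diff.sum()) - s
    return PairwiseSiteCounts(n=n, s=s, v=v)


def k2p_distance(counts: PairwiseSiteCounts) -> float:
    """K2P distance in substitutions/site; raises on saturation."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(P, Q)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_between(row_a: str, row_b: str) -> float:
    return k2p_distance(count_site_patterns(row_a, row_b))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by sample ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValidationError("matrix must be symmetric")
        if np.any(self.d[np.isfinite(self.d)] < 0):
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "ids", tuple(self.ids))

    def index(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown id: {sample_id}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def __len__(self) -> int:
        return len(self.ids)


class SaturatedPairsError(ComputationError):
    """One or more sequence pairs exceeded the K2P correction range."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        shown = ", ".join(f"{a}~{b}" for a, b in pairs[:5])
        more = "" if len(pairs) <= 5 else f" (+{len(pairs) - 5} more)"
        super().__init__(f"saturated K2P distance for pair(s): {shown}{more}")


def distance_matrix(msa, on_saturation: str = "error") -> DistanceMatrix:
    """All-pairs K2P distances over the rows of a multiple alignment.

    Identical rows are grouped before computation, so datasets with few
    haplotypes cost only one distance per haplotype pair.

    Parameters
    ----------
    on_saturation : ``"error"`` raises :class:`SaturatedPairsError`;
        ``"inf"`` flags the affected entries with ``+inf`` instead.
    """
    ids = list(msa.rows)
    if len(ids) < 2:
        raise ValidationError("need at least 2 rows")
    if on_saturation not in ("error", "inf"):
        raise ValidationError("on_saturation must be 'error' or 'inf'")
    rows = [msa.rows[i] for i in ids]
    group_of: dict[str, int] = {}
    members: list[list[int]] = []
    for idx, row in enumerate(rows):
        g = group_of.setdefault(row, len(members))
        if g == len(members):
            members.append([])
        members[g].append(idx)
    uniq = [encode_row(row) for row in group_of]
    k = len(uniq)
    du = np.zeros((k, k))
    bad: list[tuple[str, str]] = []
    for a in range(k):
        for b in range(a + 1, k):
            try:
                du[a, b] = du[b, a] = k2p_distance(_count_encoded(uniq[a], uniq[b]))
            except SaturatedDistanceError:
                du[a, b] = du[b, a] = np.inf
                bad.append((ids[members[a][0]], ids[members[b][0]]))
    if bad and on_saturation == "error":
        raise SaturatedPairsError(bad)
    rep = np.empty(len(rows), dtype=int)
    for g, mem in enumerate(members):
        rep[mem] = g
    full = du[np.ix_(rep, rep)]
    np.fill_diagonal(full, 0.0)
    return DistanceMatrix(tuple(ids), full)


@dataclass(frozen=True)
class DistanceStats:
    min: float
    max: float
    mean: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("require min <= mean <= max")


@dataclass(frozen=True)
class SpeciesDistanceSummary:
    """Per-species intra/interspecific distance statistics.

    ``intra`` is ``None`` for species with fewer than two samples (there is
    no within-species pair, which is different from a distance of zero).
    """

    species: str
    n_samples: int
    intra: DistanceStats | None
    inter: DistanceStats


def _stats(values: Sequence[float]) -> DistanceStats:
    arr = np.asarray(values, dtype=float)
    return DistanceStats(float(arr.min()), float(arr.max()), float(arr.mean()))


def species_summaries(
    dm: DistanceMatrix, labels: Mapping[str, str]
) -> list[SpeciesDistanceSummary]:
    """Table of within- and between-species distance ranges and means.

    Means are unweighted arithmetic means over sample pairs. For species X
    the interspecific pool is every pair (x, y) with x in X and y outside X.
    """
    missing = [i for i in dm.ids if i not in labels]
    if missing:
        raise ValidationError(f"unlabeled ids: {missing[:5]}")
    species_order: list[str] = []
    for i in dm.ids:
        if labels[i] not in species_order:
            species_order.append(labels[i])
    idx_by_species = {
        sp: [k for k, i in enumerate(dm.ids) if labels[i] == sp] for sp in species_order
    }
    out = []
    for sp in species_order:
        own = idx_by_species[sp]
        others = [k for k in range(len(dm.ids)) if k not in own]
        intra = None
        if len(own) >= 2:
            vals = [dm.d[a, b] for x, a in enumerate(own) for b in own[x + 1 :]]
            intra = _stats(vals)
        if not others:
            raise ValidationError(f"species {sp} has no interspecific pair")
        inter = _stats([dm.d[a, b] for a in own for b in others])
        out.append(SpeciesDistanceSummary(sp, len(own), intra, inter))
    return out


# ---------------------------------------------------------------------------
# Writers


def write_square_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, sid in enumerate(dm.ids):
            fh.write(sid + "\t" + "\t".join(f"{x:.6f}" for x in dm.d[i]) + "\n")


def write_phylip_lower(dm: DistanceMatrix, path: str | Path) -> None:
    """Lower-triangle PHYLIP-style matrix (relaxed names)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(f"{dm.d[i, j]:.6f}" for j in range(i))
            fh.write(sid + ("\t" + row if row else "") + "\n")


def write_species_summary_tsv(
    summaries: Iterable[SpeciesDistanceSummary],
    path: str | Path,
    extra: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Species summary table; *extra* may add per-species columns
    (e.g. GC%, sequence length, diagnostic-site counts)."""
    extra = extra or {}
    extra_cols = sorted({c for cols in extra.values() for c in cols})
    with open(path, "w") as fh:
        header = ["species", "n_samples"] + extra_cols + [
            "intra_min", "intra_max", "intra_mean",
            "inter_min", "inter_max", "inter_mean", "inter_range_mean",
        ]
        fh.write("\t".join(header) + "\n")
        for s in summaries:
            row = [s.species, str(s.n_samples)]
            row += [str(extra.get(s.species, {}).get(c, "")) for c in extra_cols]
            if s.intra is None:
                row += ["", "", ""]
            else:
                row += [f"{s.intra.min:.3f}", f"{s.intra.max:.3f}", f"{s.intra.mean:.3f}"]
            row += [
                f"{s.inter.min:.3f}", f"{s.inter.max:.3f}", f"{s.inter.mean:.3f}",
                f"{s.inter.min:.3f}-{s.inter.max:.3f} ({s.inter.mean:.3f})",
            ]
            fh.write("\t".join(row) + "\n")
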