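"""Species-structured barcode dataset simulator with full ground truth.

The generator emulates the structure of a multi-species barcoding survey
of closely related plants: ~10 species sampled 2-14 times each, one shared
haplotype per species (zero intraspecific variation), interspecific
divergences of a few percent with a transition-biased substitution
process, short (1-4 bp) indels between species, and at least one private
("diagnostic") substitution per species. Every stochastic choice flows
from a single seeded generator and is recorded as an event, so replaying
the ground truth reproduces the emitted sequences byte for byte.

Construction, in order:

1. random ancestral sequence at the target GC content;
2. a Kingman-coalescent species tree whose branch lengths are rescaled so
   that the expected pairwise distance (tree path + the planted diagnostic
   substitutions) equals ``target_inter_mean``;
3. a continuous-time K2P substitution process (transition/transversion
   rate ratio ``kappa``) simulated per site down each branch via Poisson
   event counts;
4. one private transition planted per species (per
   ``planted_diagnostics_per_species``) at sites still monomorphic across
   all species;
5. at most one short indel per terminal branch;
6. each sample is an exact copy of its species haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .msa import MultipleAlignment
from .phylo import PhyloTree, TreeNode, write_newick
from .records import SeqRecord, Source

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Default per-species sample counts for a 10-species survey
#: (74 vouchers, the shape typical of a regional medicinal-plant study).
DEFAULT_SAMPLE_COUNTS = (13, 6, 14, 6, 11, 5, 10, 4, 3, 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs of the generator (see module docstring)."""

    n_species: int = 10
    samples_per_species: tuple[int, ...] | None = None
    root_length: int = 453
    target_inter_mean: float = 0.03
    kappa: float = 4.0
    gc_target: float = 0.55
    indel_prob_per_branch: float = 0.3
    indel_len_range: tuple[int, int] = (1, 4)
    planted_diagnostics_per_species: int = 1
    intraspecific_mutations: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ConfigError("need at least 2 species")
        if self.samples_per_species is not None and len(self.samples_per_species) != self.n_species:
            raise ConfigError("samples_per_species length must equal n_species")
        if self.samples_per_species is not None and min(self.samples_per_species) < 1:
            raise ConfigError("every species needs >= 1 sample")
        if self.root_length < 10:
            raise ConfigError("root_length too short")
        if not 0 < self.target_inter_mean < 0.3:
            raise ConfigError("target_inter_mean must be in (0, 0.3)")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if not 0 < self.gc_target < 1:
            raise ConfigError("gc_target must be in (0, 1)")
        if not 0 <= self.indel_prob_per_branch <= 1:
            raise ConfigError("indel_prob_per_branch must be a probability")
        lo, hi = self.indel_len_range
        if not 1 <= lo <= hi:
            raise ConfigError("indel lengths must satisfy 1 <= lo <= hi")
        if self.planted_diagnostics_per_species < 0:
            raise ConfigError("planted_diagnostics_per_species must be >= 0")


@dataclass(frozen=True)
class SubEvent:
    site: int  # 0-based position in the sequence current at that branch
    old: str
    new: str


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # "ins" | "del"
    pos: int  # 0-based start, in pre-indel haplotype coordinates
    length: int
    inserted: str = ""  # for insertions


@dataclass(frozen=True)
class PlantedDiagnostic:
    species: str
    site_root: int  # 0-based, pre-indel coordinates (shared by all species)
    site_in_haplotype: int  # 0-based, in the species' emitted sequence
    old: str
    new: str


@dataclass
class GroundTruth:
    """Everything needed to reproduce and verify a simulated dataset."""

    config: SimulationConfig
    root_sequence: str
    species_tree: PhyloTree
    branch_events: dict[str, tuple[SubEvent, ...]]  # child-node name -> events
    diagnostics: tuple[PlantedDiagnostic, ...]
    indels: dict[str, tuple[IndelEvent, ...]]  # species -> events
    haplotypes: dict[str, str]

    def substitution_event_counts(self) -> tuple[int, int]:
        """(transitions, transversions) across all recorded branch events."""
        s = v = 0
        for events in self.branch_events.values():
            for e in events:
                if _TRANSITION[e.old] == e.new:
                    s += 1
                else:
                    v += 1
        return s, v

    def replay(self) -> dict[str, str]:
        """Re-derive every species haplotype from the recorded events."""
        seqs: dict[str, str] = {}

        def walk(node: TreeNode, seq: list[str]):
            my = seq
            if node.name in self.branch_events:
                my = seq.copy()
                for e in self.branch_events[node.name]:
                    assert my[e.site] == e.old, "event log inconsistent"
                    my[e.site] = e.new
            if node.is_leaf:
                seqs[node.name] = "".join(my)
            for child in node.children:
                walk(child, my)

        walk(self.species_tree.root, list(self.root_sequence))
        for d in self.diagnostics:
            s = list(seqs[d.species])
            assert s[d.site_root] == d.old
            s[d.site_root] = d.new
            seqs[d.species] = "".join(s)
        for sp, events in self.indels.items():
            s = seqs[sp]
            for e in events:
                if e.kind == "del":
                    s = s[: e.pos] + s[e.pos + e.length :]
                else:
                    s = s[: e.pos] + e.inserted + s[e.pos :]
            seqs[sp] = s
        return seqs


def _coalescent_tree(names: list[str], rng: np.random.Generator) -> tuple[TreeNode, float]:
    """Random Kingman coalescent topology; returns (root, mean pairwise path)."""
    lineages: list[tuple[TreeNode, float, int]] = [  # (node, height, n_leaves)
        (TreeNode(name=nm), 0.0, 1) for nm in names
    ]
    t = 0.0
    anc = 0
    pair_sum = 0.0
    n_total = len(names)
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha, ca), (nb, hb, cb) = lineages[i], lineages[j]
        na.length = t - ha
        nb.length = t - hb
        anc += 1
        parent = TreeNode(name=f"anc{anc}", children=[na, nb])
        pair_sum += 2.0 * t * ca * cb
        del lineages[j], lineages[i]
        lineages.append((parent, t, ca + cb))
    root = lineages[0][0]
    n_pairs = n_total * (n_total - 1) / 2
    return root, pair_sum / n_pairs


def _scale_branches(node: TreeNode, factor: float) -> None:
    if node.length is not None:
        node.length *= factor
    for c in node.children:
        _scale_branches(c, factor)


def _evolve_branch(
    seq: list[str], branch_len: float, kappa: float, rng: np.random.Generator
) -> tuple[list[str], tuple[SubEvent, ...]]:
    """K2P substitution process: per-site Poisson event counts, each event a
    transition with probability kappa/(kappa+2), else one of the two
    transversions."""
    out = seq.copy()
    events: list[SubEvent] = []
    counts = rng.poisson(max(branch_len, 0.0), size=len(seq))
    p_ti = kappa / (kappa + 2.0)
    for site in np.nonzero(counts)[0]:
        for _ in range(counts[site]):
            old = out[site]
            if rng.random() < p_ti:
                new = _TRANSITION[old]
            else:
                options = [b for b in "ACGT" if b != old and b != _TRANSITION[old]]
                new = options[rng.integers(0, 2)]
            out[site] = new
            events.append(SubEvent(int(site), old, new))
    return out, tuple(events)


def simulate_dataset(cfg: SimulationConfig = SimulationConfig()) -> tuple[list[SeqRecord], GroundTruth]:
    """Generate a labeled dataset plus its ground truth (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    names = [f"Species_{i + 1:02d}" for i in range(cfg.n_species)]
    if cfg.samples_per_species is not None:
        samples = tuple(cfg.samples_per_species)
    elif cfg.n_species == len(DEFAULT_SAMPLE_COUNTS):
        samples = DEFAULT_SAMPLE_COUNTS
    else:
        samples = tuple(int(x) for x in rng.integers(2, 15, size=cfg.n_species))

    L = cfg.root_length
    gc = cfg.gc_target
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root_seq = "".join(_BASES[rng.choice(4, size=L, p=base_probs)])

    # Species tree, rescaled so expected pairwise distance (tree path plus
    # the planted diagnostics' contribution of 2k/L per pair) hits target.
    root, mean_path = _coalescent_tree(names, rng)
    diag_part = 2.0 * cfg.planted_diagnostics_per_species / L
    tree_target = cfg.target_inter_mean - diag_part
    if tree_target <= 0:
        raise ConfigError(
            "planted diagnostics alone exceed target_inter_mean "
            f"({diag_part:.4f} >= {cfg.target_inter_mean:.4f})"
        )
    _scale_branches(root, tree_target / mean_path)
    tree = PhyloTree(root)

    # Substitutions down every branch.
    branch_events: dict[str, tuple[SubEvent, ...]] = {}
    haplotypes: dict[str, str] = {}

    def walk(node: TreeNode, seq: list[str]):
        my = seq
        if node.length is not None:
            my, events = _evolve_branch(seq, node.length, cfg.kappa, rng)
            if events:
                branch_events[node.name] = events
        if node.is_leaf:
            haplotypes[node.name] = "".join(my)
        for child in node.children:
            walk(child, my)

    walk(root, list(root_seq))

    # Planted diagnostics at sites still monomorphic across all species.
    hap_arr = {sp: list(h) for sp, h in haplotypes.items()}
    mono = [
        i
        for i in range(L)
        if len({hap_arr[sp][i] for sp in names}) == 1
    ]
    need = cfg.planted_diagnostics_per_species * cfg.n_species
    if need > len(mono):
        raise ConfigError(
            f"cannot plant {need} diagnostics: only {len(mono)} monomorphic sites"
        )
    diagnostics: list[PlantedDiagnostic] = []
    if need:
        chosen = rng.choice(np.array(mono), size=need, replace=False)
        for k, site in enumerate(chosen):
            sp = names[k % cfg.n_species]
            old = hap_arr[sp][site]
            new = _TRANSITION[old]  # transition keeps the process bias
            hap_arr[sp][site] = new
            diagnostics.append(PlantedDiagnostic(sp, int(site), int(site), old, new))
    haplotypes = {sp: "".join(hap_arr[sp]) for sp in names}

    # At most one short indel per terminal branch, never destroying the
    # species' own diagnostic sites.
    indels: dict[str, tuple[IndelEvent, ...]] = {}
    lo, hi = cfg.indel_len_range
    for sp in names:
        if rng.random() >= cfg.indel_prob_per_branch:
            continue
        length = int(rng.integers(lo, hi + 1))
        own_sites = {d.site_root for d in diagnostics if d.species == sp}
        seq = haplotypes[sp]
        if rng.random() < 0.5 and len(seq) > length:  # deletion
            candidates = [
                s
                for s in range(len(seq) - length + 1)
                if not own_sites & set(range(s, s + length))
            ]
            if not candidates:
                continue
            pos = int(candidates[rng.integers(0, len(candidates))])
            event = IndelEvent("del", pos, length)
            haplotypes[sp] = seq[:pos] + seq[pos + length :]
        else:  # insertion
            pos = int(rng.integers(0, len(seq) + 1))
            ins = "".join(_BASES[rng.choice(4, size=length, p=base_probs)])
            event = IndelEvent("ins", pos, length, ins)
            haplotypes[sp] = seq[:pos] + ins + seq[pos:]
        indels[sp] = (event,)

    # Shift diagnostic haplotype coordinates past any deletion/insertion.
    shifted: list[PlantedDiagnostic] = []
    for d in diagnostics:
        pos = d.site_root
        for e in indels.get(d.species, ()):
            if e.kind == "del" and e.pos <= pos:
                pos -= e.length
            elif e.kind == "ins" and e.pos <= pos:
                pos += e.length
        shifted.append(replace(d, site_in_haplotype=pos))
    diagnostics = shifted

    # Samples: exact copies of the species haplotype (plus optional
    # within-species noise when the barcoding-gap failure knob is on).
    records: list[SeqRecord] = []
    for sp, n_samples in zip(names, samples):
        for s in range(1, n_samples + 1):
            seq = haplotypes[sp]
            if cfg.intraspecific_mutations > 0 and s > 1:
                arr = list(seq)
                for site in rng.choice(len(arr), size=cfg.intraspecific_mutations, replace=False):
                    arr[site] = _TRANSITION[arr[site]]
                seq = "".join(arr)
            records.append(SeqRecord(f"{sp}_s{s:02d}", sp, seq, Source.SIMULATED))

    gt = GroundTruth(
        config=cfg,
        root_sequence=root_seq,
        species_tree=tree,
        branch_events=branch_events,
        diagnostics=tuple(diagnostics),
        indels=indels,
        haplotypes=dict(haplotypes),
    )
    return records, gt


def write_dataset(records: list[SeqRecord], gt: GroundTruth, outdir: str | Path) -> dict[str, str]:
    """Emit FASTA plus ground-truth sidecar files; returns artifact paths."""
    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "simulated.fasta"),
        "species_tree": str(outdir / "species_tree.nwk"),
        "diagnostics": str(outdir / "planted_diagnostics.tsv"),
        "events": str(outdir / "event_log.tsv"),
    }
    write_fasta(records, paths["fasta"])
    write_newick(gt.species_tree, paths["species_tree"])
    with open(paths["diagnostics"], "w") as fh:
        fh.write("species\tsite_root_0based\tsite_in_haplotype_0based\told\tnew\n")
        for d in gt.diagnostics:
            fh.write(f"{d.species}\t{d.site_root}\t{d.site_in_haplotype}\t{d.old}\t{d.new}\n")
    with open(paths["events"], "w") as fh:
        fh.write("branch\tkind\tsite\told\tnew\tlength\tinserted\n")
        for branch, events in sorted(gt.branch_events.items()):
            for e in events:
                fh.write(f"{branch}\tsub\t{e.site}\t{e.old}\t{e.new}\t\t\n")
        for sp, events in sorted(gt.indels.items()):
            for e in events:
                fh.write(f"{sp}\t{e.kind}\t{e.pos}\t\t\t{e.length}\t{e.inserted}\n")
    return paths


# ---------------------------------------------------------------------------
# Hand-checkable worked fixture


def make_worked_alignment() -> MultipleAlignment:
    """A fixed 40-column, 10-row alignment (2 species x 5 samples) with
    hand-verifiable ground truth:

    * variable sites: 8 = 6 substitution + 2 indel columns;
    * substitution state-sets: {C,T} x3 (sites 5, 12, 18), {A,G} x1
      (site 22), {A,C} x1 (site 26), {A,C,T} x1 (site 30);
    * indel columns: sites 34 and 37;
    * diagnostic sites: exactly 2 (sites 5 and 22), each fixed for a
      different state in both species, hence 4 (species, site) records;
    * every other column is constant across all rows.
    """
    n_cols = 40
    baseline = [("ACGT")[(i % 4)] for i in range(n_cols)]  # col i (0-based)
    a_rows = [baseline.copy() for _ in range(5)]
    b_rows = [baseline.copy() for _ in range(5)]

    def set_col(col_1based, a_syms, b_syms):
        for r, s in zip(a_rows, a_syms):
            r[col_1based - 1] = s
        for r, s in zip(b_rows, b_syms):
            r[col_1based - 1] = s

    set_col(5, "CCCCC", "TTTTT")  # diagnostic for both species, {C,T}
    set_col(12, "CCCTT", "CCCCC")  # {C,T}
    set_col(18, "TTCCC", "TTTTT")  # {C,T}
    set_col(22, "AAAAA", "GGGGG")  # diagnostic for both species, {A,G}
    set_col(26, "AAAAC", "AAAAA")  # {A,C}
    set_col(30, "CTCTC", "ACCCC")  # {A,C,T}
    set_col(34, "--AAA", "AAAAA")  # indel
    set_col(37, "GGGGG", "GG-GG")  # indel

    rows = {}
    labels = {}
    for k, row in enumerate(a_rows, start=1):
        rows[f"A{k}"] = "".join(row)
        labels[f"A{k}"] = "Alpha_sp"
    for k, row in enumerate(b_rows, start=1):
        rows[f"B{k}"] = "".join(row)
        labels[f"B{k}"] = "Beta_sp"
    return MultipleAlignment(rows, labels)
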