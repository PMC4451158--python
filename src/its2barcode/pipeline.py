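"""End-to-end barcoding pipeline: trim/annotate -> align -> distances ->
variation -> classification -> NJ tree, with a manifest of every artifact.

All tabular outputs are TSV with a single header row; metadata lines are
prefixed with ``#`` so the files stay diff-friendly. Files are written via
a temporary name and atomically renamed, and the run manifest is written
last, so a manifest implies a complete artifact set.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .alignment import AlignmentParams
from .classify import Method, leave_one_out_eval, write_results_tsv
from .distance import (
    distance_matrix,
    species_summaries,
    write_phylip_lower,
    write_species_summary_tsv,
    write_square_tsv,
)
from .errors import BarcodeError, TooShortError
from .msa import progressive_msa, write_aligned_fasta
from .phylo import (
    BootstrapConfig,
    bootstrap_support,
    is_monophyletic,
    neighbor_joining,
    write_newick,
)
from .records import SeqRecord
from .seqio import (
    HeaderSchema,
    annotate_regions,
    read_fasta,
    region_stats,
    trim_primers,
    write_region_stats_tsv,
)
from .variation import (
    classify_sites,
    find_diagnostic_sites,
    variable_sites,
    write_diagnostic_sites_tsv,
    write_variable_sites_tsv,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    input_fasta: str | Path | None = None
    records: tuple[SeqRecord, ...] | None = None  # alternative to a path
    out_dir: str | Path = "its2barcode_out"
    header_schema: HeaderSchema = HeaderSchema()
    align_params: AlignmentParams = AlignmentParams()
    bootstrap: BootstrapConfig = BootstrapConfig()
    methods: tuple[str, ...] = (Method.NEAREST_DISTANCE.value, Method.BLAST1.value)
    trim: bool = False
    fwd_primer: str | None = None
    rev_primer: str | None = None
    max_primer_mismatch: int = 1
    seed: int = 0


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    notices: list[str] = []

    def stage(name):
        log.info("stage: %s", name)

    # --- input -------------------------------------------------------
    stage("read")
    if cfg.records is not None:
        records = list(cfg.records)
    elif cfg.input_fasta is not None:
        records = read_fasta(cfg.input_fasta, cfg.header_schema)
    else:
        raise BarcodeError("pipeline needs input_fasta or records")
    if not records:
        raise BarcodeError("no input records")

    if cfg.trim:
        stage("trim")
        records = [
            trim_primers(
                r,
                cfg.fwd_primer or _default_primer("fwd"),
                cfg.rev_primer or _default_primer("rev"),
                cfg.max_primer_mismatch,
            )
            for r in records
        ]

    # --- region stats ------------------------------------------------
    stage("region stats")
    stat_rows = []
    too_short: list[str] = []
    for r in records:
        try:
            stat_rows.append((r, region_stats(r, annotate_regions(r))))
        except TooShortError:
            too_short.append(r.sample_id)
    if too_short:
        notices.append(
            f"region annotation skipped for {len(too_short)} record(s) "
            f"shorter than the annotatable minimum: {', '.join(too_short[:6])}"
            + ("..." if len(too_short) > 6 else "")
        )
    p = out / "region_stats.tsv"
    _atomic_write(p, lambda t: write_region_stats_tsv(stat_rows, t))
    artifacts["region_stats"] = p.name

    # --- alignment ---------------------------------------------------
    n_species = len({r.species for r in records})
    if len(records) < 2:
        notices.append("fewer than 2 records: alignment and downstream stages skipped")
        msa = None
    else:
        stage("align")
        msa = progressive_msa(records, cfg.align_params)
        p = out / "aligned.fasta"
        _atomic_write(p, lambda t: write_aligned_fasta(msa, t, cfg.header_schema))
        artifacts["aligned_fasta"] = p.name

    if msa is not None:
        # --- distances ---------------------------------------------------
        stage("distances")
        dm = distance_matrix(msa)
        p = out / "distances_square.tsv"
        _atomic_write(p, lambda t: write_square_tsv(dm, t))
        artifacts["distances_square"] = p.name
        p = out / "distances_lower.phy"
        _atomic_write(p, lambda t: write_phylip_lower(dm, t))
        artifacts["distances_phylip"] = p.name

        if n_species >= 2:
            summaries = species_summaries(dm, msa.labels)
            sites = classify_sites(msa)
            diag = find_diagnostic_sites(msa)
            extra = {
                s.species: {
                    "diagnostic_sites": sum(1 for d in diag if d.species == s.species)
                }
                for s in summaries
            }
            p = out / "species_summary.tsv"
            _atomic_write(p, lambda t: write_species_summary_tsv(summaries, t, extra))
            artifacts["species_summary"] = p.name

            # --- variation ---------------------------------------------
            stage("variation")
            p = out / "variable_sites.tsv"
            _atomic_write(p, lambda t: write_variable_sites_tsv(msa, t))
            artifacts["variable_sites"] = p.name
            p = out / "diagnostic_sites.tsv"
            _atomic_write(p, lambda t: write_diagnostic_sites_tsv(diag, t))
            artifacts["diagnostic_sites"] = p.name

            # --- classification ----------------------------------------
            for method in cfg.methods:
                stage(f"classification ({method})")
                report = leave_one_out_eval(
                    records, method, cfg.align_params, msa=msa
                )
                p = out / f"classification_{Method(method).value}.tsv"
                _atomic_write(p, lambda t, rep=report: write_results_tsv(rep, t))
                artifacts[f"classification_{Method(method).value}"] = p.name

        # --- tree --------------------------------------------------------
        if len(records) >= 4:
            stage("tree")
            tree = bootstrap_support(msa, cfg.bootstrap)
        elif len(records) == 3:
            stage("tree (no bootstrap: too few taxa)")
            tree = neighbor_joining(distance_matrix(msa))
        else:
            tree = None
            notices.append("fewer than 3 taxa: tree stage skipped")
        if tree is not None:
            p = out / "tree.nwk"
            _atomic_write(p, lambda t: write_newick(tree, t))
            artifacts["tree_newick"] = p.name
            mono = {
                sp: is_monophyletic(tree, msa.labels, sp)
                for sp in sorted(set(msa.labels.values()))
            }
        else:
            mono = {}
    else:
        mono = {}

    manifest = {
        "tool": "its2barcode",
        "version": __version__,
        "inputs": {
            "input_fasta": str(cfg.input_fasta) if cfg.input_fasta else None,
            "n_records": len(records),
            "n_species": n_species,
        },
        "parameters": {
            "align_params": vars(cfg.align_params).copy()
            if hasattr(cfg.align_params, "__dict__")
            else {
                "match": cfg.align_params.match,
                "mismatch": cfg.align_params.mismatch,
                "gap_open": cfg.align_params.gap_open,
                "gap_extend": cfg.align_params.gap_extend,
            },
            "bootstrap_replicates": cfg.bootstrap.replicates,
            "bootstrap_seed": cfg.bootstrap.seed,
            "methods": list(cfg.methods),
            "seed": cfg.seed,
        },
        "monophyly": mono,
        "notices": notices,
        "artifacts": artifacts,
        # isolated so everything above is byte-stable across reruns
        "timestamp_unix": int(time.time()),
    }
    p = out / "manifest.json"
    _atomic_write(
        p, lambda t: Path(t).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    )
    return manifest


def _default_primer(which: str) -> str:
    from .seqio import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER

    return DEFAULT_FWD_PRIMER if which == "fwd" else DEFAULT_REV_PRIMER
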