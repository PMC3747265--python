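"""End-to-end evaluation: NFL library (simulated or loaded) -> coverage ->
per-primer short-read libraries -> replicate trees -> branch-length,
topology, OTU and taxonomy reports.

Child seeds for every stochastic stage are derived by stable hashing of the
stage name with the master seed, so a run is fully reproducible (and
byte-identical) given one seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_library, score_assignments, train
from .compare import (binned_profile, compare_trees, normalize_max1,
                      pair_distances, pearson, slope_through_origin,
                      sliding_window_placement)
from .io import (SequenceLibrary, get_logger, read_fasta, read_taxonomy_tsv,
                 attach_taxonomy, write_fasta, write_newick,
                 write_taxonomy_tsv)
from .otu import DEFAULT_CUTOFFS, richness_ratio
from .phylo import bootstrap_supports, neighbor_joining, \
    pairwise_seq_distance, patristic_matrix
from .primers import DEFAULT_PRIMERS, PrimerSpec, coverage, extract_amplicons
from .simulate import SimulationConfig, simulate_library
from .tree import PhyloTree

__all__ = ["RunConfig", "run_evaluation", "derive_seed"]

log = get_logger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunConfig:
    """Defaults follow the evaluated protocol: 280 bp reads, five replicate
    trees per SR library and three for NFL, 500 bootstrap replicates,
    0.01 profile bins, OTU cutoffs 0.01/0.02/0.03, classifier k=8 with 100
    bootstrap rounds and an 80% cutoff."""

    mode: str = "simulate"                  # "simulate" | "load"
    fasta_path: Optional[str] = None        # load mode
    taxonomy_path: Optional[str] = None
    primers: tuple[PrimerSpec, ...] = DEFAULT_PRIMERS
    n_taxa: int = 40                        # simulate mode
    read_length: int = 280
    anchor_mismatches: int = 2
    on_missing: str = "exclude"
    n_sr_replicates: int = 5
    n_nfl_replicates: int = 3
    bootstrap_replicates: int = 500
    bin_width: float = 0.01
    otu_cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    classifier_k: int = 8
    classifier_bootstrap: int = 100
    classifier_cutoff: float = 80.0
    window_step: int = 100
    mds_dims: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in {"simulate", "load"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            if not self.fasta_path:
                raise ValueError("load mode requires fasta_path")
            if not Path(self.fasta_path).exists():
                raise ValueError(f"missing input FASTA: {self.fasta_path}")

    def to_jsonable(self) -> dict:
        d = dict(self.__dict__)
        d["primers"] = [dict(name=p.name, seq=p.iupac_seq,
                             direction=p.direction) for p in self.primers]
        d["otu_cutoffs"] = list(self.otu_cutoffs)
        return d


def _replicate_trees(library: SequenceLibrary, n: int, n_boot: int,
                     master_seed: int, stage: str) -> list[PhyloTree]:
    """Replicate NJ trees, each from a column-resampled alignment copy,
    each with its own bootstrap supports."""
    from .phylo import _default_builder, _resample_columns
    trees = []
    for rep in range(n):
        seed = derive_seed(master_seed, f"{stage}:rep{rep}")
        rng = np.random.default_rng(seed)
        resampled = _resample_columns(library, rng)
        tree = bootstrap_supports(
            resampled, n_replicates=n_boot,
            seed=derive_seed(master_seed, f"{stage}:rep{rep}:boot"))
        trees.append(tree)
    return trees


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_evaluation(config: RunConfig, outdir) -> Path:
    """Run every stage and write the report TSVs; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # ------------------------------------------------ input library
        stage = "input"
        if config.mode == "simulate":
            sim_cfg = SimulationConfig(
                n_taxa=config.n_taxa,
                seed=derive_seed(config.seed, "simulate"))
            true_tree, nfl = simulate_library(sim_cfg)
            write_newick(true_tree, outdir / "true_tree.nwk")
            write_fasta(nfl, outdir / "nfl_library.fasta")
            write_taxonomy_tsv(nfl, outdir / "nfl_taxonomy.tsv")
            written += [outdir / "true_tree.nwk",
                        outdir / "nfl_library.fasta",
                        outdir / "nfl_taxonomy.tsv"]
        else:
            nfl = read_fasta(config.fasta_path)
            if config.taxonomy_path:
                attach_taxonomy(nfl, read_taxonomy_tsv(config.taxonomy_path))

        # ---------------------------------------------------- coverage
        stage = "coverage"
        cov = coverage(config.primers, nfl, group_rank="phylum"
                       if nfl.records[0].taxonomy else "all")
        cov.to_tsv(outdir / "coverage.tsv")
        written.append(outdir / "coverage.tsv")

        # ------------------------------------------------- SR libraries
        stage = "extract"
        sr_libs: dict[str, SequenceLibrary] = {}
        for primer in config.primers:
            sr_libs[primer.name] = extract_amplicons(
                nfl, primer, read_length=config.read_length,
                anchor_mismatches=config.anchor_mismatches,
                on_missing=config.on_missing)
            write_fasta(sr_libs[primer.name],
                        outdir / f"sr_{primer.name}.fasta")
            written.append(outdir / f"sr_{primer.name}.fasta")

        # -------------------------------------------------- tree sets
        stage = "trees"
        trees: dict[str, list[PhyloTree]] = {}
        trees["NFL"] = _replicate_trees(
            nfl, config.n_nfl_replicates, config.bootstrap_replicates,
            config.seed, "trees:NFL")
        for name, lib in sr_libs.items():
            trees[name] = _replicate_trees(
                lib, config.n_sr_replicates, config.bootstrap_replicates,
                config.seed, f"trees:{name}")
        for name, ts in trees.items():
            for k, t in enumerate(ts):
                write_newick(t, outdir / f"tree_{name}_{k + 1}.nwk")
                written.append(outdir / f"tree_{name}_{k + 1}.nwk")

        # -------------------------------------- within-library table
        stage = "within-library comparison"
        rows = []
        for name in ["NFL"] + [p.name for p in config.primers]:
            ts = trees[name]
            pair_rows = []
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    rep = compare_trees(ts[i], ts[j], dims=config.mds_dims)
                    pair_rows.append(dict(
                        library=name, rep_i=str(i + 1), rep_j=str(j + 1),
                        **rep.as_dict()))
            rows.extend(pair_rows)
            mean_row = dict(library=name, rep_i="mean", rep_j="mean")
            for key in ("pearson_r", "slope", "wrmsd", "rf", "wrf1", "wrf2"):
                mean_row[key] = float(np.mean([r[key] for r in pair_rows]))
            rows.append(mean_row)
        _fmt(pd.DataFrame(rows), outdir / "tree_comparison_within.tsv")
        written.append(outdir / "tree_comparison_within.tsv")

        # ------------------------------------------ SR-vs-NFL table
        stage = "SR-vs-NFL comparison"
        rows = []
        profile_dir = outdir / "binned_profiles"
        profile_dir.mkdir(exist_ok=True)
        nfl_dm_seq = normalize_max1(pairwise_seq_distance(
            nfl, model="p"))
        for primer in config.primers:
            name = primer.name
            pair_rows = []
            for i, t_sr in enumerate(trees[name]):
                for j, t_nfl in enumerate(trees["NFL"]):
                    rep = compare_trees(t_nfl, t_sr, dims=config.mds_dims)
                    pair_rows.append(dict(
                        library=name, sr_rep=str(i + 1), nfl_rep=str(j + 1),
                        **rep.as_dict()))
            rows.extend(pair_rows)
            # pairwise-sequence-distance comparison on shared ids
            sr_dm_seq = normalize_max1(pairwise_seq_distance(
                sr_libs[name], model="p"))
            paired_seq = pair_distances(nfl_dm_seq, sr_dm_seq)
            mean_row = dict(library=name, sr_rep="mean", nfl_rep="mean")
            for key in ("pearson_r", "slope", "wrmsd", "rf", "wrf1", "wrf2"):
                mean_row[key] = float(np.mean([r[key] for r in pair_rows]))
            mean_row["pearson_pairwise"] = pearson(paired_seq)
            mean_row["slope_pairwise"] = slope_through_origin(paired_seq)
            rows.append(mean_row)
            # binned profiles (rep 1 trees, and sequence distances)
            pm_nfl = normalize_max1(patristic_matrix(trees["NFL"][0]))
            pm_sr = normalize_max1(patristic_matrix(trees[name][0]))
            prof = binned_profile(pair_distances(pm_nfl, pm_sr),
                                  width=config.bin_width)
            _fmt(prof, profile_dir / f"{name}_patristic.tsv")
            prof2 = binned_profile(paired_seq, width=config.bin_width)
            _fmt(prof2, profile_dir / f"{name}_pairwise.tsv")
            written += [profile_dir / f"{name}_patristic.tsv",
                        profile_dir / f"{name}_pairwise.tsv"]
        _fmt(pd.DataFrame(rows), outdir / "tree_comparison_vs_nfl.tsv")
        written.append(outdir / "tree_comparison_vs_nfl.tsv")

        # ------------------------------------------------ OTU richness
        stage = "otu"
        rows = []
        for primer in config.primers:
            rep = richness_ratio(sr_libs[primer.name], nfl,
                                 cutoffs=config.otu_cutoffs)
            rep.insert(0, "library", primer.name)
            rows.append(rep)
        _fmt(pd.concat(rows, ignore_index=True),
             outdir / "otu_richness.tsv")
        written.append(outdir / "otu_richness.tsv")

        # -------------------------------------------------- taxonomy
        stage = "taxonomy"
        if nfl.records[0].taxonomy:
            model = train(nfl, k=config.classifier_k)
            nfl_results = classify_library(
                model, nfl, n_bootstrap=config.classifier_bootstrap,
                cutoff=config.classifier_cutoff,
                seed=derive_seed(config.seed, "classify:NFL"))
            rows = []
            for primer in config.primers:
                sr_results = classify_library(
                    model, sr_libs[primer.name],
                    n_bootstrap=config.classifier_bootstrap,
                    cutoff=config.classifier_cutoff,
                    seed=derive_seed(config.seed,
                                     f"classify:{primer.name}"))
                shared = set(sr_results) & set(nfl_results)
                for rank in ("phylum", "genus"):
                    row = score_assignments(
                        {k: sr_results[k] for k in shared},
                        {k: nfl_results[k] for k in shared}, rank)
                    rows.append(dict(library=primer.name, **row))
            _fmt(pd.DataFrame(rows), outdir / "taxonomy_performance.tsv")
            written.append(outdir / "taxonomy_performance.tsv")
        else:
            log.warning("no taxonomy: skipping classifier stage")

        # --------------------------------------------- sliding window
        stage = "sliding window"
        profile = sliding_window_placement(
            nfl, trees["NFL"][0], window=config.read_length,
            step=config.window_step)
        _fmt(profile, outdir / "window_profile.tsv")
        written.append(outdir / "window_profile.tsv")

        # ---------------------------------------------------- manifest
        stage = "manifest"
        manifest = dict(version=__version__, seed=config.seed,
                        config=config.to_jsonable(),
                        outputs=sorted(str(p.relative_to(outdir))
                                       for p in written))
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
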