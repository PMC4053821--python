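"""Config-driven end-to-end runs.

One YAML config drives simulate -> D statistics -> tree analytics ->
genome scans, with a single global seed from which each stage's seed is
derived deterministically, stderr+file logging, and a JSON manifest of
parameters, seeds and output checksums.  Identical config + seed gives
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .admixture import admixture_fraction, dstat_all, polarize, results_table
from .genomescan import divergence_track, kendall_tau, rf_track
from .gtree import TreeSet
from .simulate import simulate_genome
from .sptree import AdmixturePulse, SimulationConfig, SpeciesTreeModel, default_panel
from .trees import clade_frequencies, consensus_tree, star_species_tree

__all__ = ["PipelineConfig", "run_pipeline", "default_config", "stage_seed"]

log = logging.getLogger("coalscan.pipeline")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PulseConfig(_Strict):
    donor: str
    recipient: str
    time: float
    proportion: float


class SimulateStage(_Strict):
    enabled: bool = True
    newick: Optional[str] = None      # None -> bundled demo panel
    ne: float = 1.0e5
    mu: float = 1.0e-9
    outgroup: str = "WAR"
    pulses: list[PulseConfig] = Field(default_factory=list)
    n_windows: int = 2000
    window_length: int = 5000
    ploidy: str = "haploid"
    subwindow_recombination: bool = False


class DstatStage(_Strict):
    enabled: bool = True
    mode: str = "pseudohaploid"       # or "freq"
    alpha: float = 0.01
    blocks: Optional[int] = None      # block size in bp; None -> simulation windows


class TreesStage(_Strict):
    enabled: bool = True
    consensus: bool = True
    star: bool = True
    max_trees: Optional[int] = None   # subsample cap for the analytics


class ScanStage(_Strict):
    enabled: bool = True
    window: int = 1_000_000


class PipelineConfig(_Strict):
    """Schema-validated before any stage runs; unknown keys rejected."""

    seed: int = 1
    simulate: SimulateStage = Field(default_factory=SimulateStage)
    dstat: DstatStage = Field(default_factory=DstatStage)
    trees: TreesStage = Field(default_factory=TreesStage)
    scan: ScanStage = Field(default_factory=ScanStage)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def default_config() -> PipelineConfig:
    """The bundled demo: the 10-ingroup-taxa panel with one gamma = 0.1
    pulse from the Javan warty-pig lineage into the Sumatran boar."""
    return PipelineConfig(
        seed=1,
        simulate=SimulateStage(
            pulses=[PulseConfig(donor="VER", recipient="SUM",
                                time=5.0e4, proportion=0.1)],
            n_windows=2000,
        ),
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: one global knob, independent streams."""
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order and write a run
    manifest.  A stage failure aborts with the failing stage named;
    outputs written so far are renamed with a ``.partial`` marker."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s [%(name)s] %(message)s", "%Y-%m-%dT%H:%M:%S"))
    log.addHandler(handler)
    stderr = logging.StreamHandler(sys.stderr)
    log.addHandler(stderr)
    log.setLevel(logging.INFO)

    outputs: list[Path] = []
    manifest = {
        "tool": "coalscan",
        "version": __version__,
        "config": config.model_dump(),
        "seeds": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    current_stage = "simulate"
    try:
        # -- simulate ------------------------------------------------------
        sim_cfg = config.simulate
        model = (default_panel(ne=sim_cfg.ne, mu=sim_cfg.mu)
                 if sim_cfg.newick is None else
                 SpeciesTreeModel.from_newick(sim_cfg.newick, ne=sim_cfg.ne,
                                              mu=sim_cfg.mu,
                                              outgroup=sim_cfg.outgroup))
        seed = stage_seed(config.seed, "simulate")
        manifest["seeds"]["simulate"] = seed
        sim = simulate_genome(SimulationConfig(
            model,
            [AdmixturePulse(p.donor, p.recipient, p.time, p.proportion)
             for p in sim_cfg.pulses],
            n_windows=sim_cfg.n_windows,
            window_length=sim_cfg.window_length,
            seed=seed,
            ploidy=sim_cfg.ploidy,
            subwindow_recombination=sim_cfg.subwindow_recombination,
        ))
        log.info("simulate: %d windows, %d variant sites",
                 sim_cfg.n_windows, sim.matrix.n_sites)
        sim.matrix.to_vcf(outdir / "genotypes.vcf")
        sim.matrix.to_tsv(outdir / "genotypes.tsv")
        sim.windows.to_bed(outdir / "windows.bed")
        outputs += [outdir / "genotypes.vcf", outdir / "genotypes.tsv",
                    outdir / "windows.bed"]
        if sim.trees is not None:
            sim.trees.to_newick_file(outdir / "gene_trees.nwk")
            outputs.append(outdir / "gene_trees.nwk")
        if sim.recomb_rate is not None:
            sim.windows.to_bed(outdir / "recombination.bed",
                               values=sim.recomb_rate)
            outputs.append(outdir / "recombination.bed")

        # -- D statistics ---------------------------------------------------
        if config.dstat.enabled:
            current_stage = "dstat"
            seed = stage_seed(config.seed, "dstat")
            manifest["seeds"]["dstat"] = seed
            derived = polarize(sim.matrix, model.outgroup,
                               mode=config.dstat.mode, seed=seed)
            results = dstat_all(derived, model.outgroup,
                                blocks=config.dstat.blocks,
                                alpha=config.dstat.alpha)
            table = results_table(results)
            table.to_csv(outdir / "dstat.tsv", sep="\t", index=False,
                         float_format="%.6g")
            outputs.append(outdir / "dstat.tsv")
            n_sig = int(table["p_bonf"].lt(config.dstat.alpha).sum())
            log.info("dstat: %d quartets, %d significant at adjusted p < %g",
                     len(table), n_sig, config.dstat.alpha)
            for p in sim_cfg.pulses:
                others = [t for t in model.labels
                          if t not in (p.recipient, p.donor, model.outgroup)]
                if others and sim_cfg.ploidy == "diploid":
                    frac = admixture_fraction(
                        sim.matrix, others[0], p.recipient, p.donor,
                        model.outgroup, seed=seed)
                    log.info("admixture fraction %s->%s: f=%.4f (SE %.4f)",
                             p.donor, p.recipient, frac.f_hat, frac.se_f)

        # -- tree analytics --------------------------------------------------
        if config.trees.enabled and sim.trees is not None:
            current_stage = "trees"
            trees = sim.trees
            if config.trees.max_trees and len(trees) > config.trees.max_trees:
                trees = TreeSet(trees.trees[:config.trees.max_trees],
                                taxa=trees.taxa)
            freqs = clade_frequencies(trees, rooted=False)
            with open(outdir / "clade_frequencies.tsv", "w") as fh:
                fh.write("clade\tfrequency\n")
                for members, f in sorted(freqs.items(),
                                         key=lambda kv: -kv[1]):
                    fh.write(",".join(sorted(members)) + f"\t{f:.6g}\n")
            outputs.append(outdir / "clade_frequencies.tsv")
            if config.trees.consensus:
                cons = consensus_tree(trees)
                (outdir / "consensus.nwk").write_text(cons.to_newick() + "\n")
                outputs.append(outdir / "consensus.nwk")
            if config.trees.star:
                og = (model.outgroup if sim_cfg.ploidy == "haploid"
                      else f"{model.outgroup}.1")
                star = star_species_tree(trees, og)
                (outdir / "star.nwk").write_text(star.to_newick() + "\n")
                outputs.append(outdir / "star.nwk")
            log.info("trees: %d gene trees analysed", len(trees))

        # -- scans -----------------------------------------------------------
        if config.scan.enabled:
            current_stage = "scan"
            div = divergence_track(sim.matrix, model.outgroup,
                                   window=config.scan.window)
            div.to_bedgraph(outdir / "divergence.bedgraph")
            outputs.append(outdir / "divergence.bedgraph")
            rows = []
            if sim.trees is not None:
                rf = rf_track(sim.trees, window=config.scan.window)
                rf.to_bedgraph(outdir / "mean_rf.bedgraph")
                outputs.append(outdir / "mean_rf.bedgraph")
                if sim.recomb_rate is not None:
                    from .genomescan import WindowTrack
                    rec = WindowTrack(sim.windows, np.asarray(sim.recomb_rate),
                                      np.ones(len(sim.windows), dtype=np.int64),
                                      np.zeros(len(sim.windows), dtype=bool),
                                      name="recombination")
                    # align tilings when scan window == simulation window
                    if len(rec.values) == len(rf.values):
                        cr = kendall_tau(rec, rf)
                        rows.append(("recombination", "mean_rf",
                                     cr.tau, cr.p, cr.n))
            with open(outdir / "correlations.tsv", "w") as fh:
                fh.write("track_x\ttrack_y\ttau\tp\tn\n")
                for r in rows:
                    fh.write("\t".join(str(v) for v in r) + "\n")
            outputs.append(outdir / "correlations.tsv")
            log.info("scan: %d windows", len(div.values))

    except Exception:
        for f in outputs:
            if f.exists():
                f.rename(f.with_suffix(f.suffix + ".partial"))
        log.exception("stage %r failed; partial outputs marked", current_stage)
        raise
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr)
        handler.close()

    manifest["outputs"] = {f.name: _sha256(f) for f in outputs}
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
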