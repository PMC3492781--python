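"""End-to-end pipeline: simulate -> stats -> cluster -> assign -> bottleneck
-> matrix tests, with a run manifest for traceability.

A run is driven by a YAML config (see :func:`default_config` for the
packaged demo) and a single seed; every stage draws its randomness from a
named substream of that seed and writes plain delimited-text reports into
the output directory. The manifest records the config snapshot, seed,
output paths with digests, package version, and timestamps, and is
rewritten at every stage boundary so a failed run still documents what
completed.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assign import assign_all, migration_matrix
from .bottleneck import bottleneck_test
from .cluster import evanno_select, gibbs_cluster
from .io import read_genepop, write_genepop
from .mantel import correlation_table
from .matrix import SquareMatrix
from .popgen import allele_counts, diversity_summary, pairwise_fst, private_alleles
from . import experiments

log = logging.getLogger(__name__)

STAGES = ("simulate", "stats", "cluster", "assign", "bottleneck", "mantel")


def default_config() -> dict:
    """The packaged demo configuration (desk-scale, minutes on one CPU)."""
    return {
        "scenario": "vector_outlier",
        "seed": 1,
        "cluster": {
            "k_min": 1, "k_max": 4, "replicates": 2,
            "burn_in": 200, "iters": 800,
        },
        "bottleneck": {"n_sims": 150},
        "mantel": {"n_perm": 999, "tail": "greater"},
        "exclude_cluster": experiments.OUTLIER,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    out_dir: str
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: dict = field(default_factory=dict)  # stage -> {status, outputs}

    def record(self, stage: str, status: str, outputs: list[Path] | None = None):
        entry = {"status": status, "timestamp": _dt.datetime.now().isoformat()}
        if outputs:
            entry["outputs"] = {
                str(p.name): _sha256(p) for p in outputs if p.exists()
            }
        self.stages[stage] = entry
        self.write()

    def write(self) -> None:
        path = Path(self.out_dir) / "manifest.json"
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "stages": self.stages,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _stage_seed(seed: int, stage: str) -> int:
    tag = STAGES.index(stage)
    return int(
        np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31)
    )


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute the full analysis chain; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    manifest = RunManifest(config=config, seed=seed, out_dir=str(out))
    manifest.started = _dt.datetime.now().isoformat()
    manifest.write()
    stage = "simulate"
    try:
        # ----------------------------------------------------------- simulate
        manifest.record(stage, "started")
        scenario = config.get("scenario", "vector_outlier")
        if "genotypes" in config:  # pre-existing data: load instead of simulate
            panel = read_genepop(config["genotypes"])
            if "site_to_cluster" in config:
                panel = panel.with_cluster_map(config["site_to_cluster"])
            shipping = SquareMatrix.read(config["shipping_matrix"])
            distance = SquareMatrix.read(config["distance_matrix"])
        else:
            sim_seed = _stage_seed(seed, "simulate")
            sim = experiments.simulate_study(sim_seed, scenario=scenario)
            panel = sim["panel"]
            shipping = sim["shipping"]
            distance = sim["distance"]
            sim["migration_network"].write(out / "migration_network.tsv")
        write_genepop(panel, out / "genotypes.gen")
        shipping.write(out / "shipping.tsv")
        distance.write(out / "distance.tsv")
        manifest.record(stage, "done", [out / "genotypes.gen", out / "shipping.tsv",
                                        out / "distance.tsv"])

        # -------------------------------------------------------------- stats
        stage = "stats"
        manifest.record(stage, "started")
        site_summary = diversity_summary(panel, by="site", rarefaction_copies=36)
        cluster_summary = diversity_summary(panel, by="cluster", rarefaction_copies=36)
        counts = allele_counts(panel, by="cluster")
        props, private_detail = private_alleles(counts)
        cluster_summary["private"] = props
        fst = pairwise_fst(panel, by="cluster")
        site_summary.to_csv(out / "diversity_sites.tsv", sep="\t", float_format="%.4f")
        cluster_summary.to_csv(out / "diversity_clusters.tsv", sep="\t",
                               float_format="%.4f")
        private_detail.to_csv(out / "private_alleles.tsv", sep="\t", index=False,
                              float_format="%.4f")
        fst.write(out / "fst.tsv", float_format="%.4f")
        manifest.record(stage, "done", [out / "diversity_sites.tsv",
                                        out / "diversity_clusters.tsv",
                                        out / "fst.tsv"])

        # ------------------------------------------------------------ cluster
        stage = "cluster"
        manifest.record(stage, "started")
        ccfg = config.get("cluster", {})
        k_min, k_max = int(ccfg.get("k_min", 1)), int(ccfg.get("k_max", 4))
        reps = int(ccfg.get("replicates", 2))
        burn, iters = int(ccfg.get("burn_in", 200)), int(ccfg.get("iters", 800))
        base = _stage_seed(seed, "cluster")
        runs_by_K = {}
        si = 0
        for K in range(k_min, k_max + 1):
            runs_by_K[K] = []
            for _ in range(reps):
                runs_by_K[K].append(
                    gibbs_cluster(panel, K, burn_in=burn, iters=iters,
                                  seed=base + si)
                )
                si += 1
        ev = evanno_select(runs_by_K)
        ev.table.to_csv(out / "evanno.tsv", sep="\t", float_format="%.4f")
        if ev.selected_K is not None:
            best = max(runs_by_K[ev.selected_K], key=lambda m: m.L)
            best.membership_frame().to_csv(out / "memberships.tsv", sep="\t",
                                           float_format="%.4f")
        manifest.record(stage, "done", [out / "evanno.tsv"])

        # ------------------------------------------------------------- assign
        stage = "assign"
        manifest.record(stage, "started")
        res = assign_all(panel, by="cluster", leave_one_out=True)
        M = migration_matrix(res)
        res.to_frame().to_csv(out / "assignments.tsv", sep="\t",
                              float_format="%.3f")
        M.write(out / "migration.tsv", float_format="%.4f")
        manifest.record(stage, "done", [out / "assignments.tsv",
                                        out / "migration.tsv"])

        # --------------------------------------------------------- bottleneck
        stage = "bottleneck"
        manifest.record(stage, "started")
        bcfg = config.get("bottleneck", {})
        n_sims = int(bcfg.get("n_sims", 150))
        b_seed = _stage_seed(seed, "bottleneck")
        lines = ["cluster\tp_excess\tp_deficit\tp_two_sided\tmode_shift"]
        for g in panel.group_names("cluster"):
            try:
                br = bottleneck_test(counts, g, n_sims=n_sims, seed=b_seed)
            except (ValueError, RuntimeError) as exc:
                log.warning("bottleneck test skipped for %s: %s", g, exc)
                continue
            lines.append(
                f"{g}\t{br.p_excess:.4f}\t{br.p_deficit:.4f}"
                f"\t{br.p_two_sided:.4f}\t{br.mode_shift}"
            )
            br.per_locus.to_csv(out / f"bottleneck_{g}.tsv", sep="\t",
                                index=False, float_format="%.4f")
        (out / "bottleneck_summary.tsv").write_text("\n".join(lines) + "\n")
        manifest.record(stage, "done", [out / "bottleneck_summary.tsv"])

        # ------------------------------------------------------------- mantel
        stage = "mantel"
        manifest.record(stage, "started")
        mcfg = config.get("mantel", {})
        n_perm = int(mcfg.get("n_perm", 9999))
        tail = mcfg.get("tail", "greater")
        m_seed = _stage_seed(seed, "mantel")
        matrices = {
            "F_ST": fst,
            "Distance": distance,
            "Migration": M,
            "Shipping": shipping,
        }
        full = correlation_table(matrices, n_perm=n_perm, tail=tail, seed=m_seed)
        full.to_frame().to_csv(out / "mantel_full.tsv", sep="\t",
                               float_format="%.4f")
        outputs = [out / "mantel_full.tsv"]
        excl = config.get("exclude_cluster")
        if excl:
            excluded = correlation_table(
                matrices, n_perm=n_perm, tail=tail, seed=m_seed + 1,
                exclude=[excl],
            )
            excluded.to_frame().to_csv(out / "mantel_excluded.tsv", sep="\t",
                                       float_format="%.4f")
            outputs.append(out / "mantel_excluded.tsv")
        manifest.record(stage, "done", outputs)
    except Exception:
        manifest.record(stage, "failed")
        manifest.finished = _dt.datetime.now().isoformat()
        manifest.write()
        log.error("pipeline aborted at stage %r", stage)
        raise
    manifest.finished = _dt.datetime.now().isoformat()
    manifest.write()
    return manifest
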