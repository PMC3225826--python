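"""End-to-end orchestration: wire the analysis stages together with
explicit seeds, write per-stage TSV outputs and a run manifest.

Stage order: simulate (or load) -> modules -> coherence -> significance ->
scan -> network -> motifs -> knockdown -> hostgenes.  Identical config and
seeds produce byte-identical outputs; the manifest records seeds, input
digests and per-stage row counts so accidental overwrites are detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import (
    downstream,
    io_formats,
    knockdown_model,
    modules_builder,
    network as network_mod,
    pwm_scan,
    significance,
    synthetic_data,
)
from .coherence import CoherenceEngine
from .containers import KnockdownDataset

log = logging.getLogger("coregnet")

ALL_STAGES = (
    "simulate",
    "modules",
    "coherence",
    "significance",
    "scan",
    "network",
    "motifs",
    "knockdown",
    "hostgenes",
)


@dataclass
class RunConfig:
    input_dir: str = "inputs"
    out_dir: str = "results"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    min_module_size: int = 2
    background_kind: str = significance.BG1_CRM_POOL
    n_reps: int = 100
    quantile: float = 0.9999
    calibration_length: int = 1_000_000
    cluster_window: int = 200
    n_random_networks: int = 100
    swaps_per_edge: int = 10
    prescreen_alpha: float = 0.05
    verbose: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in raw and isinstance(raw["stages"], str):
            raw["stages"] = tuple(raw["stages"].split(","))
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _line_count(path: Path) -> int:
    return sum(1 for _ in open(path))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return (and write) the run manifest."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="[%(name)s] %(message)s",
    )
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    manifest: dict = {
        "config": {**asdict(config), "stages": list(config.stages)},
        "stages": {},
    }
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(ALL_STAGES, seed_seq.spawn(len(ALL_STAGES)))
    }

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "done",
            "seed": stage_seeds[stage],
            "outputs": {
                p.name: {"sha256": _sha256(p), "rows": _line_count(p)}
                for p in outputs
            },
        }
        log.info("stage %s done (%d outputs)", stage, len(outputs))

    def skip(stage: str) -> None:
        manifest["stages"][stage] = {"status": "skipped"}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # -- simulate ----------------------------------------------------------
    if "simulate" in stages:
        try:
            synthetic_data.generate_fixture(indir, seed=stage_seeds["simulate"])
        except Exception as exc:
            fail("simulate", exc)
        record("simulate", sorted(indir.iterdir()))
    else:
        skip("simulate")

    crm_targets = mirna_targets = None
    if stages - {"simulate"}:
        crm_targets = io_formats.read_target_map(indir / "crm_targets.tsv", "CRM")
        mirna_targets = io_formats.read_target_map(
            indir / "mirna_targets.tsv", "MIRNA"
        )

    # -- modules -----------------------------------------------------------
    modules = None
    if "modules" in stages:
        try:
            modules = modules_builder.build_modules(
                crm_targets, mirna_targets, min_size=config.min_module_size
            )
            io_formats.write_modules_table(modules, outdir / "modules.tsv")
        except Exception as exc:
            fail("modules", exc)
        record("modules", [outdir / "modules.tsv"])
    else:
        skip("modules")

    engine = None

    def get_engine() -> CoherenceEngine:
        nonlocal engine
        if engine is None:
            expr = io_formats.read_expression_matrix(
                indir / "expression.tsv", indir / "gene_map.tsv"
            )
            engine = CoherenceEngine(expr)
        return engine

    # -- coherence ---------------------------------------------------------
    if "coherence" in stages:
        try:
            if modules is None:
                modules = io_formats.read_modules_table(outdir / "modules.tsv")
            eng = get_engine()
            for mod in modules:
                value = eng.coherence(mod.genes)
                mod.coherence = None if np.isnan(value) else value
            io_formats.write_modules_table(
                modules, outdir / "modules_coherence.tsv"
            )
        except Exception as exc:
            fail("coherence", exc)
        record("coherence", [outdir / "modules_coherence.tsv"])
    else:
        skip("coherence")

    # -- significance ------------------------------------------------------
    if "significance" in stages:
        try:
            if modules is None:
                modules = io_formats.read_modules_table(outdir / "modules.tsv")
            spec = significance.BackgroundSpec(
                kind=config.background_kind,
                n_reps=config.n_reps,
                seed=stage_seeds["significance"],
            )
            scored = significance.score_modules(
                get_engine(), modules, spec, crm_targets, mirna_targets
            )
            io_formats.write_modules_table(scored, outdir / "modules_scored.tsv")
        except Exception as exc:
            fail("significance", exc)
        record("significance", [outdir / "modules_scored.tsv"])
    else:
        skip("significance")

    # -- scan --------------------------------------------------------------
    c2m_edges = None
    if "scan" in stages:
        try:
            pwms = io_formats.read_pwms(indir / "pwms.txt")
            crms = io_formats.read_crm_definitions(indir / "crm_definitions.tsv")
            upstream = io_formats.read_fasta(indir / "upstream.fasta")
            scan_cfg = pwm_scan.ScanConfig(
                quantile=config.quantile,
                calibration_length=config.calibration_length,
                cluster_window=config.cluster_window,
            )
            rng = np.random.default_rng(stage_seeds["scan"])
            needed = sorted({m for crm in crms for m in crm.motif_ids})
            pwm_by_id = {p.motif_id: p for p in pwms}
            cutoffs = pwm_scan.compute_cutoffs(
                [pwm_by_id[m] for m in needed], scan_cfg, rng
            )
            with open(outdir / "hits.tsv", "w") as handle:
                handle.write("motif_id\tseq_id\tstart\tstrand\tscore\n")
                for motif in needed:
                    for seq_id in sorted(upstream):
                        for hit in pwm_scan.scan_sequence(
                            pwm_by_id[motif],
                            upstream[seq_id],
                            cutoffs[motif],
                            scan_cfg,
                            seq_id,
                        ):
                            handle.write(
                                f"{hit.motif_id}\t{hit.seq_id}\t{hit.start + 1}"
                                f"\t{hit.strand}\t{hit.score!r}\n"
                            )
            c2m_edges = pwm_scan.predict_crm_mirna_edges(
                crms, upstream, pwms, scan_cfg, rng, cutoffs=cutoffs
            )
            with open(outdir / "c2m_edges.tsv", "w") as handle:
                handle.write("crm_id\tmirna_id\n")
                for crm_id, mirna_id in c2m_edges:
                    handle.write(f"{crm_id}\t{mirna_id}\n")
        except Exception as exc:
            fail("scan", exc)
        record("scan", [outdir / "hits.tsv", outdir / "c2m_edges.tsv"])
    else:
        skip("scan")

    def load_c2m() -> list[tuple[str, str]]:
        edges = []
        with open(outdir / "c2m_edges.tsv") as handle:
            next(handle)
            for line in handle:
                crm_id, mirna_id = line.rstrip("\n").split("\t")
                edges.append((crm_id, mirna_id))
        return edges

    # -- network -----------------------------------------------------------
    net = None
    if "network" in stages:
        try:
            if c2m_edges is None:
                c2m_edges = load_c2m()
            crms = io_formats.read_crm_definitions(indir / "crm_definitions.tsv")
            pwm_gene_map = io_formats.read_gene_map(indir / "pwm_gene_map.tsv")
            m2c_edges = network_mod.derive_mirna_crm_edges(
                mirna_targets, crms, pwm_gene_map
            )
            net = network_mod.build_network(
                crm_targets, mirna_targets, c2m_edges, m2c_edges
            )
            io_formats.write_edge_list(net, outdir / "network_edges.tsv")
        except Exception as exc:
            fail("network", exc)
        record("network", [outdir / "network_edges.tsv"])
    else:
        skip("network")

    # -- motifs ------------------------------------------------------------
    if "motifs" in stages:
        try:
            if net is None:
                net = io_formats.read_edge_list(outdir / "network_edges.tsv")
            catalog = network_mod.generate_pattern_catalog()
            stats = network_mod.pattern_zscores(
                net,
                catalog,
                n_random=config.n_random_networks,
                rng=np.random.default_rng(stage_seeds["motifs"]),
                swaps_per_edge=config.swaps_per_edge,
            )
            network_mod.write_pattern_stats(
                stats, catalog, outdir / "pattern_stats.tsv"
            )
        except Exception as exc:
            fail("motifs", exc)
        record("motifs", [outdir / "pattern_stats.tsv"])
    else:
        skip("motifs")

    # -- knockdown ---------------------------------------------------------
    if "knockdown" in stages:
        try:
            logratios = io_formats.read_logratio_vector(indir / "knockdown.tsv")
            tf_map = io_formats.read_target_map(indir / "tf_targets.tsv", "MODULE")
            tf_targets = set().union(*tf_map.entries.values())
            genes = sorted(logratios)
            mirna_ids = sorted(mirna_targets.entries)
            b_mir = np.zeros((len(genes), len(mirna_ids)))
            gene_index = {g: i for i, g in enumerate(genes)}
            for j, mirna_id in enumerate(mirna_ids):
                for g in mirna_targets.entries[mirna_id]:
                    if g in gene_index:
                        b_mir[gene_index[g], j] = 1.0
            data = KnockdownDataset(
                gene_ids=genes,
                g=np.array([logratios[g] for g in genes]),
                b_tf=np.array([1.0 if g in tf_targets else 0.0 for g in genes]),
                b_mir=b_mir,
                mirna_ids=mirna_ids,
            )
            result = knockdown_model.stepwise_select(
                data, mirna_ids, prescreen_alpha=config.prescreen_alpha
            )
            knockdown_model.write_fit_result(result, outdir / "knockdown_fit.tsv")
        except Exception as exc:
            fail("knockdown", exc)
        record("knockdown", [outdir / "knockdown_fit.tsv"])
    else:
        skip("knockdown")

    # -- hostgenes ---------------------------------------------------------
    if "hostgenes" in stages:
        try:
            host_map = io_formats.read_host_map(indir / "host_genes.tsv")
            if c2m_edges is None:
                c2m_edges = load_c2m()
            records = downstream.shared_crm_hostgenes(
                host_map, c2m_edges, crm_targets
            )
            with open(outdir / "hostgenes.tsv", "w") as handle:
                handle.write("mirna_id\thost_gene\tshared_crms\n")
                for rec in records:
                    handle.write(
                        f"{rec.mirna_id}\t{rec.host_gene_id}\t"
                        f"{','.join(sorted(rec.shared_crms)) or 'NA'}\n"
                    )
        except Exception as exc:
            fail("hostgenes", exc)
        record("hostgenes", [outdir / "hostgenes.tsv"])
    else:
        skip("hostgenes")

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return manifest
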