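"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic given its seed and returns, alongside the
data, a :class:`~coregnet.containers.SyntheticTruth` recording what was
planted, so downstream recovery can be scored exactly.

The generators emulate:

* block-correlated expression (equicorrelated Gaussian blocks — the
  minimal structure the pipeline's pairwise-Pearson view can see);
* heavy-tailed regulator out-degrees (discretized power law for miRNAs);
* upstream sequences with motif sites planted inside a co-occurrence
  window, sampled from the PWM so scores vary around the cutoff;
* tripartite networks with planted feed-forward loops;
* knockdown log-ratios drawn from the linear co-regulation model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import io_formats
from .containers import (
    BASES,
    CRMDefinition,
    ExpressionMatrix,
    KnockdownDataset,
    PWM,
    RegulatoryNetwork,
    SyntheticTruth,
    TargetMap,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Expression


def gen_expression(
    n_genes: int,
    n_samples: int,
    blocks: Sequence[tuple[int, float]] = (),
    noise_sd: float = 0.5,
    seed: int = 0,
    extra_probesets: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Equicorrelated-Gaussian block expression.

    Genes inside a block share a latent factor so their pairwise Pearson
    correlation is ``rho``; all other genes are independent standard
    normals.  Each gene gets one clean probeset; ``extra_probesets`` adds
    that many noisy probesets per gene (profile + N(0, noise_sd)), to
    exercise the max-over-probesets rule.
    """
    sizes = [s for s, _ in blocks]
    if sum(sizes) > n_genes:
        raise ValueError("block sizes exceed n_genes")
    for _, rho in blocks:
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"block rho must lie in [0, 1), got {rho}")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    profiles = rng.standard_normal((n_genes, n_samples))

    truth = SyntheticTruth()
    cursor = 0
    for size, rho in blocks:
        member_idx = range(cursor, cursor + size)
        shared = rng.standard_normal(n_samples)
        for i in member_idx:
            profiles[i] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * profiles[i]
        truth.planted_blocks.append(
            (frozenset(genes[i] for i in member_idx), rho)
        )
        cursor += size

    probeset_ids: list[str] = []
    rows: list[np.ndarray] = []
    probeset_to_gene: dict[str, str] = {}
    for i, gene in enumerate(genes):
        for k in range(1 + extra_probesets):
            pid = f"{gene}_ps{k + 1}"
            probeset_ids.append(pid)
            probeset_to_gene[pid] = gene
            row = profiles[i]
            if k > 0:
                row = row + noise_sd * rng.standard_normal(n_samples)
            rows.append(row)

    expr = ExpressionMatrix(
        probeset_ids=probeset_ids,
        sample_ids=[f"S{j + 1:03d}" for j in range(n_samples)],
        values=np.array(rows),
        probeset_to_gene=probeset_to_gene,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Target maps


def _draw_degree(law: tuple, rng: np.random.Generator, max_degree: int) -> int:
    kind = law[0]
    if kind == "fixed":
        k = int(law[1])
    elif kind == "uniform":
        k = int(rng.integers(law[1], law[2] + 1))
    elif kind == "powerlaw":
        # discretized Pareto on [kmin, kmax] with exponent alpha
        _, alpha, kmin, kmax = law
        u = rng.random()
        a = 1.0 - alpha
        # inverse-CDF of the continuous power law, then floor
        lo, hi = float(kmin), float(kmax) + 1.0
        k = int(np.floor((lo**a + u * (hi**a - lo**a)) ** (1.0 / a)))
        k = min(max(k, int(kmin)), int(kmax))
    else:
        raise ValueError(f"unknown degree law {law!r}")
    if k <= 0 or k > max_degree:
        raise ValueError(f"degree {k} outside (0, {max_degree}]")
    return k


def gen_target_maps(
    n_crms: int,
    n_mirnas: int,
    gene_universe: Sequence[str],
    crm_degree_range: tuple[int, int] = (20, 60),
    mirna_degree_law: tuple = ("powerlaw", 2.0, 10, 80),
    overlap_spec: Sequence[tuple[str, str, Iterable[str]]] = (),
    seed: int = 0,
) -> tuple[TargetMap, TargetMap, SyntheticTruth]:
    """Random CRM and miRNA target maps over a gene universe.

    CRM out-degrees are uniform over ``crm_degree_range``; miRNA
    out-degrees follow ``mirna_degree_law`` (a discretized power law by
    default).  ``overlap_spec`` entries ``(crm_id, mirna_id, genes)`` force
    the listed genes into both regulators' target sets, so that pair's
    module contains a chosen (typically co-expressed) block.  CRM IDs are
    ``CRM001``..; miRNA IDs are ``MIR001``..
    """
    universe = sorted(gene_universe)
    if not universe:
        raise ValueError("empty gene universe")
    lo, hi = crm_degree_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid crm_degree_range")
    if hi > len(universe):
        raise ValueError("CRM degree exceeds universe size")
    rng = np.random.default_rng(seed)

    crm_entries: dict[str, set[str]] = {}
    for i in range(1, n_crms + 1):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=k, replace=False)
        crm_entries[f"CRM{i:03d}"] = {universe[j] for j in idx}

    mirna_entries: dict[str, set[str]] = {}
    for i in range(1, n_mirnas + 1):
        k = _draw_degree(mirna_degree_law, rng, len(universe))
        idx = rng.choice(len(universe), size=k, replace=False)
        mirna_entries[f"MIR{i:03d}"] = {universe[j] for j in idx}

    truth = SyntheticTruth()
    for crm_id, mirna_id, genes in overlap_spec:
        genes = frozenset(genes)
        if crm_id not in crm_entries or mirna_id not in mirna_entries:
            raise ValueError(f"overlap_spec names unknown pair ({crm_id},{mirna_id})")
        if not genes <= set(universe):
            raise ValueError("overlap genes outside the universe")
        crm_entries[crm_id] |= genes
        mirna_entries[mirna_id] |= genes
        truth.planted_overlaps.append((crm_id, mirna_id, genes))

    return (
        TargetMap("CRM", crm_entries),
        TargetMap("MIRNA", mirna_entries),
        truth,
    )


# ---------------------------------------------------------------------------
# Upstream sequences


def _sample_site(pwm: PWM, rng: np.random.Generator, consensus: bool) -> str:
    if consensus:
        return pwm.consensus()
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.length)]
    return "".join(BASES[c] for c in cols)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gen_upstream_sequences(
    pwms: Sequence[PWM],
    n_seqs: int,
    length: int = 5000,
    planting: Sequence[tuple[str, Iterable[str], int]] = (),
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    consensus: bool = False,
) -> tuple[dict[str, str], SyntheticTruth]:
    """I.i.d. background sequences with clustered motif sites planted.

    Each planting directive ``(seq_id, motif_ids, cluster_width)`` places
    one site per motif, all inside one window of ``cluster_width`` bases,
    at non-overlapping positions and on random strands.  Sequence IDs are
    ``MIR001``..``MIRnnn``.  Truth records (seq_id, motif_id, start, strand).
    """
    pwm_by_id = {p.motif_id: p for p in pwms}
    rng = np.random.default_rng(seed)
    seq_ids = [f"MIR{i:03d}" for i in range(1, n_seqs + 1)]
    q = np.asarray(background_freqs, dtype=float)
    if q.shape != (4,) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background_freqs must be 4 values summing to 1")

    arrays = {
        sid: rng.choice(list(BASES), size=length, p=q) for sid in seq_ids
    }
    truth = SyntheticTruth()
    for seq_id, motif_ids, cluster_width in planting:
        if seq_id not in arrays:
            raise ValueError(f"planting names unknown sequence {seq_id!r}")
        motifs = [pwm_by_id[m] for m in motif_ids]
        if sum(p.length for p in motifs) > cluster_width:
            raise ValueError("motifs cannot fit in the cluster window")
        if cluster_width > length:
            raise ValueError("cluster window longer than the sequence")
        win_start = int(rng.integers(0, length - cluster_width + 1))
        placed: list[tuple[int, int]] = []
        for pwm in motifs:
            for _ in range(1000):
                start = win_start + int(
                    rng.integers(0, cluster_width - pwm.length + 1)
                )
                span = (start, start + pwm.length)
                if all(span[1] <= a or span[0] >= b for a, b in placed):
                    break
            else:
                raise ValueError("could not place non-overlapping sites")
            placed.append(span)
            site = _sample_site(pwm, rng, consensus)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else reverse_complement(site)
            arrays[seq_id][span[0] : span[1]] = list(inserted)
            truth.planted_sites.append((seq_id, pwm.motif_id, start, strand))

    seqs = {sid: "".join(arrays[sid]) for sid in seq_ids}
    return seqs, truth


def gen_pwms(
    n_pwms: int, length: int = 12, sharpness: float = 0.95, seed: int = 0
) -> list[PWM]:
    """Random informative PWMs: one dominant base per position.

    The residual probability mass is split unevenly (Dirichlet) over the
    three minor bases so window scores are continuous-valued rather than
    falling on a small discrete grid — matching real matrices and keeping
    empirical quantile cutoffs well behaved.
    """
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(1, n_pwms + 1):
        probs = np.empty((4, length))
        for j in range(length):
            dominant = rng.integers(0, 4)
            minors = rng.dirichlet(np.ones(3)) * (1.0 - sharpness)
            col = np.empty(4)
            col[dominant] = sharpness
            col[[b for b in range(4) if b != dominant]] = minors
            probs[:, j] = col
        pwms.append(PWM(f"M{i:03d}", probs))
    return pwms


# ---------------------------------------------------------------------------
# Knockdown log-ratios


def gen_knockdown(
    tf_targets: Iterable[str],
    mirna_targets: TargetMap,
    a_tf: float,
    a_mir: Mapping[str, float],
    c: float = 0.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    gene_universe: Sequence[str] | None = None,
) -> tuple[KnockdownDataset, SyntheticTruth]:
    """Knockdown log-ratios from the linear co-regulation model:
    g = c + a_TF*b_TF + sum_i a_mir_i*b_mir_i + N(0, noise_sd)."""
    for mirna_id in a_mir:
        if mirna_id not in mirna_targets.entries:
            raise ValueError(f"miRNA {mirna_id!r} absent from target map")
    tf_targets = set(tf_targets)
    if gene_universe is None:
        genes = sorted(mirna_targets.gene_universe() | tf_targets)
    else:
        genes = sorted(set(gene_universe))
    mirna_ids = sorted(mirna_targets.entries)
    gene_index = {g: i for i, g in enumerate(genes)}

    b_tf = np.array([1.0 if g in tf_targets else 0.0 for g in genes])
    b_mir = np.zeros((len(genes), len(mirna_ids)))
    for j, mirna_id in enumerate(mirna_ids):
        for g in mirna_targets.entries[mirna_id]:
            if g in gene_index:
                b_mir[gene_index[g], j] = 1.0

    coeff = np.array([a_mir.get(m, 0.0) for m in mirna_ids])
    rng = np.random.default_rng(seed)
    g_vec = c + a_tf * b_tf + b_mir @ coeff
    if noise_sd > 0:
        g_vec = g_vec + noise_sd * rng.standard_normal(len(genes))

    data = KnockdownDataset(genes, g_vec, b_tf, b_mir, mirna_ids)
    truth = SyntheticTruth(
        active_mirnas={m for m, a in a_mir.items() if a != 0.0},
        coefficients={"intercept": c, "tf": a_tf, **dict(a_mir)},
    )
    return data, truth


# ---------------------------------------------------------------------------
# Networks


def gen_network(
    n_crms: int,
    n_mirnas: int,
    n_genes: int,
    edge_probs: Mapping[str, float] | None = None,
    planted_ffl_count: int = 0,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, SyntheticTruth]:
    """Random typed tripartite network plus planted feed-forward loops.

    Each allowed edge (per-type probability from ``edge_probs``) is sampled
    independently; every planted FFL adds a fresh (CRM, miRNA, gene) triple
    with edges C2M, C2G and M2G.
    """
    probs = {"C2G": 0.0, "M2G": 0.0, "C2M": 0.0, "M2C": 0.0}
    if edge_probs:
        unknown = set(edge_probs) - set(probs)
        if unknown:
            raise ValueError(f"unknown edge types {sorted(unknown)}")
        probs.update(edge_probs)
    rng = np.random.default_rng(seed)

    crms = [f"CRM{i:03d}" for i in range(1, n_crms + 1)]
    mirnas = [f"MIR{i:03d}" for i in range(1, n_mirnas + 1)]
    genes = _gene_ids(n_genes)
    nodes = (
        {c: "CRM" for c in crms}
        | {m: "MIRNA" for m in mirnas}
        | {g: "GENE" for g in genes}
    )

    edges: set[tuple[str, str, str]] = set()

    def sample(sources: list[str], targets: list[str], etype: str) -> None:
        p = probs[etype]
        if p <= 0 or not sources or not targets:
            return
        mask = rng.random((len(sources), len(targets))) < p
        for i, j in zip(*np.nonzero(mask)):
            edges.add((sources[i], targets[j], etype))

    sample(crms, genes, "C2G")
    sample(mirnas, genes, "M2G")
    sample(crms, mirnas, "C2M")
    sample(mirnas, crms, "M2C")

    truth = SyntheticTruth()
    for i in range(1, planted_ffl_count + 1):
        c, m, g = f"FFLC{i:03d}", f"FFLM{i:03d}", f"FFLG{i:03d}"
        nodes[c], nodes[m], nodes[g] = "CRM", "MIRNA", "GENE"
        edges |= {(c, m, "C2M"), (c, g, "C2G"), (m, g, "M2G")}
        truth.planted_ffls.append((c, m, g))

    return RegulatoryNetwork(nodes, edges), truth


# ---------------------------------------------------------------------------
# Complete fixture directory


def generate_fixture(outdir: str | Path, seed: int = 0) -> dict:
    """Write a complete, internally consistent input directory.

    The fixture couples the generators: two co-expressed gene blocks are
    planted as the shared targets of (CRM001, MIR001) and (CRM002, MIR002);
    those CRMs' motifs are planted within a 150 bp window upstream of the
    matching miRNAs; the PWM->TF-gene map lets MIR003 repress CRM001; the
    knockdown log-ratios are generated from the linear model with MIR001
    and MIR002 active.  Returns a manifest of what was written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]

    n_genes, n_samples = 120, 30
    blocks = [(8, 0.9), (8, 0.85)]
    expr, expr_truth = gen_expression(
        n_genes, n_samples, blocks, noise_sd=0.5, seed=seeds[0], extra_probesets=1
    )
    block1, block2 = (sorted(b) for b, _ in expr_truth.planted_blocks)

    genes = _gene_ids(n_genes)
    crm_targets, mirna_targets, map_truth = gen_target_maps(
        n_crms=3,
        n_mirnas=6,
        gene_universe=genes,
        crm_degree_range=(25, 40),
        mirna_degree_law=("uniform", 15, 50),
        overlap_spec=[
            ("CRM001", "MIR001", block1),
            ("CRM002", "MIR002", block2),
        ],
        seed=seeds[1],
    )

    pwms = gen_pwms(4, seed=seeds[2])
    crms = [
        CRMDefinition("CRM001", frozenset({"M001", "M002"})),
        CRMDefinition("CRM002", frozenset({"M003", "M004"})),
        CRMDefinition("CRM003", frozenset({"M001", "M003"})),
    ]
    upstream, site_truth = gen_upstream_sequences(
        pwms,
        n_seqs=6,
        length=2000,
        planting=[
            ("MIR001", ["M001", "M002"], 150),
            ("MIR002", ["M003", "M004"], 150),
        ],
        seed=seeds[3],
    )

    # each motif's TF gene; MIR003 is made to target CRM001's TF gene
    tf_genes = {"M001": "G0001", "M002": "G0002", "M003": "G0003", "M004": "G0004"}
    mirna_targets.entries["MIR003"].add("G0001")

    host_map = {
        "MIR001": sorted(crm_targets.entries["CRM001"])[0],
        "MIR004": "G0119",
    }

    rng_tf = np.random.default_rng(seeds[4])
    tf_targets = {genes[i] for i in rng_tf.choice(n_genes, size=40, replace=False)}
    knockdown, kd_truth = gen_knockdown(
        tf_targets,
        mirna_targets,
        a_tf=-1.0,
        a_mir={"MIR001": -0.8, "MIR002": 0.6},
        c=0.1,
        noise_sd=0.3,
        seed=seeds[5],
        gene_universe=genes,
    )

    io_formats.write_expression_matrix(
        expr, outdir / "expression.tsv", outdir / "gene_map.tsv"
    )
    io_formats.write_target_map(crm_targets, outdir / "crm_targets.tsv")
    io_formats.write_target_map(mirna_targets, outdir / "mirna_targets.tsv")
    io_formats.write_pwms(pwms, outdir / "pwms.txt")
    io_formats.write_crm_definitions(crms, outdir / "crm_definitions.tsv")
    io_formats.write_fasta(upstream, outdir / "upstream.fasta")
    with open(outdir / "pwm_gene_map.tsv", "w") as handle:
        for motif in sorted(tf_genes):
            handle.write(f"{motif}\t{tf_genes[motif]}\n")
    with open(outdir / "host_genes.tsv", "w") as handle:
        for mirna in sorted(host_map):
            handle.write(f"{mirna}\t{host_map[mirna]}\n")
    with open(outdir / "tf_targets.tsv", "w") as handle:
        for gene in sorted(tf_targets):
            handle.write(f"TF\t{gene}\n")
    io_formats.write_logratio_vector(
        dict(zip(knockdown.gene_ids, knockdown.g)), outdir / "knockdown.tsv"
    )

    truth = expr_truth.merge(map_truth).merge(site_truth).merge(kd_truth)
    truth_json = {
        "planted_blocks": [
            {"genes": sorted(g), "rho": rho} for g, rho in truth.planted_blocks
        ],
        "planted_sites": [
            {"seq": s, "motif": m, "start": p, "strand": st}
            for s, m, p, st in truth.planted_sites
        ],
        "planted_overlaps": [
            {"crm": c, "mirna": m, "genes": sorted(g)}
            for c, m, g in truth.planted_overlaps
        ],
        "active_mirnas": sorted(truth.active_mirnas),
        "coefficients": truth.coefficients,
        "seed": seed,
    }
    with open(outdir / "truth.json", "w") as handle:
        json.dump(truth_json, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return truth_json
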