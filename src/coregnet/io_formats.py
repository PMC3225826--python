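"""Readers and writers for every external format the pipeline touches.

Everything is plain text: TSV tables, FASTA sequences and TRANSFAC-style
matrix blocks.  Parsers are strict — malformed input raises
:class:`~coregnet.containers.FormatError` naming the offending line rather
than silently truncating.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .containers import (
    CRMDefinition,
    CRMiRNAModule,
    ExpressionMatrix,
    FormatError,
    PWM,
    RegulatoryNetwork,
    TargetMap,
    ValidationError,
)

_VALID_BASES = set("ACGTN")


def _tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-empty, non-comment lines."""
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            yield lineno, row


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_matrix(
    matrix_path: str | Path, gene_map_path: str | Path
) -> ExpressionMatrix:
    """Read a series-matrix-style TSV plus a two-column probeset->gene map.

    The matrix header row carries a label cell followed by sample IDs; each
    data row is a probeset ID followed by one value per sample.  Probesets
    absent from the gene map are retained unmapped.
    """
    rows = list(_tsv_rows(matrix_path))
    if not rows:
        raise FormatError(f"{matrix_path}: empty expression matrix")
    header_lineno, header = rows[0]
    if len(header) < 2:
        raise FormatError(
            f"{matrix_path}:{header_lineno}: header needs a label plus >=1 sample"
        )
    sample_ids = header[1:]
    n_samples = len(sample_ids)

    probeset_ids: list[str] = []
    values: list[list[float]] = []
    for lineno, row in rows[1:]:
        if len(row) != n_samples + 1:
            raise FormatError(
                f"{matrix_path}:{lineno}: expected {n_samples + 1} fields, "
                f"got {len(row)}"
            )
        probeset_ids.append(row[0])
        try:
            values.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{matrix_path}:{lineno}: non-numeric value ({exc})")
    if not probeset_ids:
        raise FormatError(f"{matrix_path}: no data rows")

    probeset_to_gene: dict[str, str] = {}
    known = set(probeset_ids)
    for lineno, row in _tsv_rows(gene_map_path):
        if len(row) < 2:
            raise FormatError(
                f"{gene_map_path}:{lineno}: expected 2 columns, got {len(row)}"
            )
        if row[0] in known:
            probeset_to_gene[row[0]] = row[1]

    return ExpressionMatrix(
        probeset_ids=probeset_ids,
        sample_ids=sample_ids,
        values=np.array(values, dtype=float),
        probeset_to_gene=probeset_to_gene,
    )


def write_expression_matrix(
    expr: ExpressionMatrix, matrix_path: str | Path, gene_map_path: str | Path
) -> None:
    with open(matrix_path, "w") as handle:
        handle.write("ID_REF\t" + "\t".join(expr.sample_ids) + "\n")
        for probeset, row in zip(expr.probeset_ids, expr.values):
            handle.write(
                probeset + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )
    with open(gene_map_path, "w") as handle:
        for probeset in expr.probeset_ids:
            gene = expr.probeset_to_gene.get(probeset)
            if gene is not None:
                handle.write(f"{probeset}\t{gene}\n")


# ---------------------------------------------------------------------------
# PWMs (TRANSFAC-style matrix text)


def read_pwms(path: str | Path) -> list[PWM]:
    """Parse TRANSFAC-style matrix blocks into normalized PWMs.

    A block is an ``ID`` line, a ``P0  A C G T`` header, numbered position
    rows of four counts or frequencies, and a ``//`` terminator.  Counts are
    normalized per position; pseudocounts are applied downstream at scan
    time, not here.
    """
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    saw_header = False

    def finish(lineno: int) -> None:
        nonlocal motif_id, rows, saw_header
        if motif_id is None and not rows:
            return
        if motif_id is None:
            raise FormatError(f"{path}:{lineno}: matrix block without an ID line")
        if not rows:
            raise FormatError(f"{path}:{lineno}: matrix {motif_id} has no rows")
        counts = np.array(rows, dtype=float).T  # 4 x L
        try:
            pwms.append(PWM.from_counts(motif_id, counts))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}")
        motif_id, rows, saw_header = None, [], False

    lineno = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            tag = fields[0]
            if tag == "//":
                finish(lineno)
            elif tag == "ID":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: ID line without identifier")
                motif_id = fields[1]
            elif tag == "P0":
                saw_header = True
            elif tag[0].isdigit():
                if not saw_header:
                    raise FormatError(
                        f"{path}:{lineno}: position row before 'P0' header"
                    )
                if len(fields) < 5:
                    raise FormatError(
                        f"{path}:{lineno}: position row needs 4 base counts"
                    )
                try:
                    rows.append([float(x) for x in fields[1:5]])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric count")
            # other TRANSFAC tags (NA, DE, XX, ...) are ignored
    finish(lineno)
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs as TRANSFAC-style frequency blocks (lossless to ~1e-17)."""
    with open(path, "w") as handle:
        for pwm in pwms:
            handle.write(f"ID {pwm.motif_id}\nP0 A C G T\n")
            for j in range(pwm.length):
                cells = " ".join(repr(float(v)) for v in pwm.probs[:, j])
                handle.write(f"{j + 1:02d} {cells}\n")
            handle.write("//\n")


# ---------------------------------------------------------------------------
# Target maps and other two-column tables


def read_target_map(path: str | Path, regulator_class: str) -> TargetMap:
    """Read a two-column (regulator, gene) TSV; duplicates collapse to sets."""
    entries: dict[str, set[str]] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        entries.setdefault(row[0], set()).add(row[1])
    return TargetMap(regulator_class=regulator_class, entries=entries)


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    with open(path, "w") as handle:
        for regulator in sorted(tmap.entries):
            for gene in sorted(tmap.entries[regulator]):
                handle.write(f"{regulator}\t{gene}\n")


def read_gene_map(path: str | Path) -> dict[str, set[str]]:
    """Generic two-column key->set map (e.g. PWM motif -> TF gene IDs)."""
    out: dict[str, set[str]] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        out.setdefault(row[0], set()).add(row[1])
    return out


def read_host_map(path: str | Path) -> dict[str, str]:
    """miRNA -> host gene, one host per miRNA (later lines win is an error)."""
    out: dict[str, str] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        if row[0] in out and out[row[0]] != row[1]:
            raise FormatError(f"{path}:{lineno}: conflicting host for {row[0]!r}")
        out[row[0]] = row[1]
    return out


def read_crm_definitions(path: str | Path) -> list[CRMDefinition]:
    """Read CRM definitions as (crm_id, motif_id) pairs."""
    motifs: dict[str, set[str]] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        motifs.setdefault(row[0], set()).add(row[1])
    return [CRMDefinition(crm, frozenset(ms)) for crm, ms in sorted(motifs.items())]


def write_crm_definitions(crms: Sequence[CRMDefinition], path: str | Path) -> None:
    with open(path, "w") as handle:
        for crm in sorted(crms, key=lambda c: c.crm_id):
            for motif in sorted(crm.motif_ids):
                handle.write(f"{crm.crm_id}\t{motif}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {sequence ID: uppercased sequence over A,C,G,T,N}."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"{path}: sequence {record.id!r} contains non-IUPAC-DNA "
                f"characters {sorted(bad)}"
            )
        if record.id in out:
            raise ValidationError(f"{path}: duplicate sequence ID {record.id!r}")
        out[record.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for seq_id in seqs:
            handle.write(f">{seq_id}\n")
            seq = seqs[seq_id]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Networks and result tables


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    """Write typed edges as a (source, target, edge_type) TSV."""
    with open(path, "w") as handle:
        handle.write("source\ttarget\tedge_type\n")
        for src, tgt, etype in sorted(network.edges):
            handle.write(f"{src}\t{tgt}\t{etype}\n")


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    edges = []
    for lineno, row in _tsv_rows(path):
        if row == ["source", "target", "edge_type"]:
            continue
        if len(row) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
        edges.append((row[0], row[1], row[2]))
    return RegulatoryNetwork.from_edges(edges)


def _fmt(x: float | None) -> str:
    return "NA" if x is None else repr(float(x))


def write_modules_table(modules: Sequence[CRMiRNAModule], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "crm_id\tmirna_id\tn_genes\tcoherence\tp_value\tq_value\tgene_ids\n"
        )
        for mod in modules:
            handle.write(
                "\t".join(
                    [
                        mod.crm_id,
                        mod.mirna_id,
                        str(len(mod.genes)),
                        _fmt(mod.coherence),
                        _fmt(mod.p_value),
                        _fmt(mod.q_value),
                        ",".join(sorted(mod.genes)),
                    ]
                )
                + "\n"
            )


def read_modules_table(path: str | Path) -> list[CRMiRNAModule]:
    modules: list[CRMiRNAModule] = []
    for lineno, row in _tsv_rows(path):
        if row[0] == "crm_id":
            continue
        if len(row) < 7:
            raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(row)}")
        parse = lambda x: None if x == "NA" else float(x)
        modules.append(
            CRMiRNAModule(
                crm_id=row[0],
                mirna_id=row[1],
                genes=frozenset(row[6].split(",")),
                coherence=parse(row[3]),
                p_value=parse(row[4]),
                q_value=parse(row[5]),
            )
        )
    return modules


def read_logratio_vector(path: str | Path) -> dict[str, float]:
    """Read per-gene knockdown log-ratios from a two-column TSV."""
    out: dict[str, float] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
        if row[0] == "gene_id":
            continue
        try:
            out[row[0]] = float(row[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric log-ratio {row[1]!r}")
    return out


def write_logratio_vector(values: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tlog_ratio\n")
        for gene in values:
            handle.write(f"{gene}\t{repr(float(values[gene]))}\n")
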