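"""PWM log-likelihood-ratio scanning of pri-miRNA upstream sequences.

Sites are scored as sum over positions of ``log(p'_j(base)/q(base))`` in
natural-log units, where ``p'`` is the PWM column blended with the
background by a pseudocount weight and ``q`` is the background base
distribution; ``N`` bases contribute zero.  Per-motif cutoffs are the
empirical 99.99% quantile of the window scores of a long random sequence
drawn from the background, and a window scoring strictly above the cutoff
is a predicted binding site.  A CRM is linked to a miRNA when every motif
of the CRM has a predicted site in the miRNA's upstream sequence and the
chosen sites all fit inside one 200 bp span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import BASE_INDEX, CRMDefinition, PWM


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    seq_id: str
    start: int  # 0-based leftmost base on the forward strand
    strand: str  # "+" or "-"
    score: float


@dataclass
class ScanConfig:
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount_weight: float = 0.01
    quantile: float = 0.9999
    calibration_length: int = 1_000_000
    both_strands: bool = True
    pooled_strand_calibration: bool = True
    upstream_length: int = 5000
    cluster_window: int = 200
    strict: bool = True

    def __post_init__(self) -> None:
        q = np.asarray(self.background_freqs, dtype=float)
        if q.shape != (4,) or np.any(q <= 0) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("background_freqs must be 4 positive values summing to 1")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if self.pseudocount_weight < 0:
            raise ValueError("pseudocount_weight must be >= 0")


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T,N to 0..4 (int8)."""
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence")


def log_odds_matrix(pwm: PWM, config: ScanConfig) -> np.ndarray:
    """5 x L natural-log odds matrix; row 4 (N) is all zeros."""
    q = np.asarray(config.background_freqs, dtype=float)
    w = config.pseudocount_weight
    blended = (1.0 - w) * pwm.probs + w * q[:, None]
    with np.errstate(divide="ignore"):
        lom = np.log(blended / q[:, None])
    return np.vstack([lom, np.zeros((1, pwm.length))])


def _revcomp_matrix(lom: np.ndarray) -> np.ndarray:
    """Log-odds matrix scoring the reverse-complement strand in forward
    coordinates: complement the base rows and reverse the positions."""
    out = np.empty_like(lom)
    out[:4] = lom[3::-1, ::-1]
    out[4] = lom[4, ::-1]
    return out


def score_site(pwm: PWM, window: str, config: ScanConfig) -> float:
    """Log-likelihood-ratio score of one window on the forward strand."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != PWM length {pwm.length}"
        )
    enc = encode_sequence(window)
    lom = log_odds_matrix(pwm, config)
    return float(lom[enc, np.arange(pwm.length)].sum())


def window_scores(lom: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Scores of every window of an encoded sequence under a 5 x L matrix."""
    L = lom.shape[1]
    n_win = len(encoded) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lom[encoded[j : j + n_win], j]
    return scores


def compute_cutoff(
    pwm: PWM, config: ScanConfig, rng: np.random.Generator
) -> float:
    """Empirical score quantile on a random background sequence."""
    seq = rng.choice(4, size=config.calibration_length, p=config.background_freqs)
    return _cutoff_from_calibration(pwm, seq.astype(np.int8), config)


def _cutoff_from_calibration(
    pwm: PWM, encoded: np.ndarray, config: ScanConfig
) -> float:
    needed = 100.0 / (1.0 - config.quantile)
    if len(encoded) < needed - 0.5:
        msg = (
            f"calibration length {len(encoded)} too short for quantile "
            f"{config.quantile} (need >= {needed:.0f} bases)"
        )
        warnings.warn(msg)
        if config.strict:
            raise ValueError(msg)
    lom = log_odds_matrix(pwm, config)
    scores = window_scores(lom, encoded)
    if config.both_strands and config.pooled_strand_calibration:
        scores = np.concatenate([scores, window_scores(_revcomp_matrix(lom), encoded)])
    return float(np.quantile(scores, config.quantile))  # linear interpolation


def compute_cutoffs(
    pwms: Sequence[PWM], config: ScanConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Per-motif cutoffs from one shared calibration sequence."""
    seq = rng.choice(4, size=config.calibration_length, p=config.background_freqs)
    seq = seq.astype(np.int8)
    return {pwm.motif_id: _cutoff_from_calibration(pwm, seq, config) for pwm in pwms}


def scan_sequence(
    pwm: PWM, seq: str, cutoff: float, config: ScanConfig, seq_id: str = ""
) -> list[MotifHit]:
    """All windows scoring strictly above the cutoff, both strands if
    configured; reverse-strand hits are reported in forward coordinates
    (start = leftmost forward base)."""
    encoded = encode_sequence(seq)
    lom = log_odds_matrix(pwm, config)
    hits: list[MotifHit] = []
    strands = [("+", lom)]
    if config.both_strands:
        strands.append(("-", _revcomp_matrix(lom)))
    for strand, matrix in strands:
        scores = window_scores(matrix, encoded)
        for start in np.nonzero(scores > cutoff)[0]:
            hits.append(
                MotifHit(pwm.motif_id, seq_id, int(start), strand, float(scores[start]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _clustered_cover(
    hits_by_motif: Mapping[str, list[tuple[int, int]]], window: int
) -> bool:
    """True iff one hit per motif can be chosen with all chosen intervals
    inside a single span of ``window`` bases (max end - min start <= window)."""
    if any(not hits for hits in hits_by_motif.values()):
        return False
    anchors = sorted({start for hits in hits_by_motif.values() for start, _ in hits})
    for x in anchors:
        if all(
            any(start >= x and end <= x + window for start, end in hits)
            for hits in hits_by_motif.values()
        ):
            return True
    return False


def predict_crm_mirna_edges(
    crms: Sequence[CRMDefinition],
    upstream: Mapping[str, str],
    pwms: Sequence[PWM],
    config: ScanConfig,
    rng: np.random.Generator,
    cutoffs: Mapping[str, float] | None = None,
) -> list[tuple[str, str]]:
    """CRM -> miRNA edges: every CRM motif has a site in the miRNA's
    upstream sequence, and the sites co-occur within the cluster window."""
    pwm_by_id = {p.motif_id: p for p in pwms}
    needed = sorted({m for crm in crms for m in crm.motif_ids})
    missing = [m for m in needed if m not in pwm_by_id]
    if missing:
        raise KeyError(f"CRM motifs without a PWM: {missing}")
    if cutoffs is None:
        cutoffs = compute_cutoffs([pwm_by_id[m] for m in needed], config, rng)

    # hits[seq_id][motif_id] -> list of (start, end) intervals
    hits: dict[str, dict[str, list[tuple[int, int]]]] = {
        seq_id: {} for seq_id in upstream
    }
    for motif_id in needed:
        pwm = pwm_by_id[motif_id]
        for seq_id, seq in upstream.items():
            found = scan_sequence(pwm, seq, cutoffs[motif_id], config, seq_id)
            hits[seq_id][motif_id] = [(h.start, h.start + pwm.length) for h in found]

    edges: list[tuple[str, str]] = []
    for crm in sorted(crms, key=lambda c: c.crm_id):
        for seq_id in sorted(upstream):
            per_motif = {m: hits[seq_id].get(m, []) for m in crm.motif_ids}
            if _clustered_cover(per_motif, config.cluster_window):
                edges.append((crm.crm_id, seq_id))
    return edges
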