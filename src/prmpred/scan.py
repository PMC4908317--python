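"""Proteome scanning: slide PWMs over protein sequences and keep windows
whose score p-value passes a threshold.

Coordinates are 1-based inclusive throughout, matching protein residue
numbering.  Windows containing residues outside the model alphabet (X, U,
B, ...) are skipped and counted, never scored.  Overlapping hits from the
same PWM are all reported; candidate binding sites are counted
individually downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainMismatch, DuplicateId, EmptyInput, EmptySignificantSet
from .pwm import Pwm, ScoreDistribution, pvalue_of_score, significant_positions

DEFAULT_PVALUE_THRESHOLD = 1e-5


@dataclass(frozen=True)
class PeptideHit:
    """One candidate binding site: a scanned window passing the p-value cut.

    ``significant_protein_positions`` are the 1-based residue coordinates
    (within [start, end]) of the motif's significant columns; the
    peptide-level evidence scores average over exactly these residues.
    """

    protein_id: str
    pwm_id: str
    domain_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    window_seq: str
    score: float
    pvalue: float
    significant_protein_positions: tuple = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ScanLog:
    """Counts accumulated during a scan (windows skipped, evaluated)."""

    windows_evaluated: int = 0
    windows_skipped_ambiguous: int = 0
    sequences_too_short: int = 0
    messages: list = field(default_factory=list)


def scan_sequence(
    pwm: Pwm,
    dist: ScoreDistribution,
    protein_id: str,
    sequence: str,
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
    *,
    ic_cutoff: float = 1.0,
    log: ScanLog | None = None,
):
    """Score every window of ``sequence`` and return hits with p-value <=
    threshold, sorted by start coordinate.

    All windows are evaluated (no heuristic skipping).  A sequence shorter
    than the motif yields an empty list.  Windows containing non-alphabet
    residues are skipped and counted in ``log``.
    """
    if not (0 < pvalue_threshold <= 1):
        raise ValueError("pvalue_threshold must be in (0, 1]")
    log = log if log is not None else ScanLog()
    n = pwm.n
    if len(sequence) < n:
        log.sequences_too_short += 1
        return []
    try:
        sig_cols = significant_positions(pwm, ic_cutoff)
    except EmptySignificantSet:
        # hits still reported; peptide feature scores will be undefined
        sig_cols = []
        log.messages.append(
            f"pwm {pwm.id}: no significant column at IC cutoff {ic_cutoff}"
        )
    rows = [pwm._index.get(ch) for ch in sequence]
    weights = pwm.weights
    hits = []
    for start0 in range(len(sequence) - n + 1):
        window_rows = rows[start0 : start0 + n]
        if any(r is None for r in window_rows):
            log.windows_skipped_ambiguous += 1
            continue
        log.windows_evaluated += 1
        score = 0.0
        for j, r in enumerate(window_rows):
            score += weights[r, j]
        pv = pvalue_of_score(dist, score)
        if pv <= pvalue_threshold:
            hits.append(
                PeptideHit(
                    protein_id=protein_id,
                    pwm_id=pwm.id,
                    domain_id=pwm.domain_id,
                    start=start0 + 1,
                    end=start0 + n,
                    window_seq=sequence[start0 : start0 + n],
                    score=float(score),
                    pvalue=pv,
                    significant_protein_positions=tuple(
                        start0 + 1 + c for c in sig_cols
                    ),
                )
            )
    return hits


def scan_proteome(
    pwms,
    dists,
    proteome,
    pvalue_threshold: float = DEFAULT_PVALUE_THRESHOLD,
    *,
    ic_cutoff: float = 1.0,
    log: ScanLog | None = None,
):
    """Scan every (PWM, protein) pair.

    Parameters
    ----------
    pwms : sequence of Pwm
    dists : mapping pwm_id -> ScoreDistribution
    proteome : sequence of (protein_id, sequence) pairs

    Returns hits ordered by (pwm_id, protein_id, start).  Duplicate
    protein ids raise :class:`DuplicateId`; an empty proteome raises
    :class:`EmptyInput`.
    """
    proteome = list(proteome)
    if not proteome:
        raise EmptyInput("empty proteome")
    seen = set()
    for pid, _ in proteome:
        if pid in seen:
            raise DuplicateId(f"duplicate protein id {pid!r}")
        seen.add(pid)
    log = log if log is not None else ScanLog()
    hits = []
    for pwm in sorted(pwms, key=lambda p: p.id):
        dist = dists[pwm.id]
        for pid, seq in sorted(proteome, key=lambda t: t[0]):
            hits.extend(
                scan_sequence(
                    pwm, dist, pid, seq, pvalue_threshold,
                    ic_cutoff=ic_cutoff, log=log,
                )
            )
    return hits


def overlap_fraction(hit_a: PeptideHit, hit_b: PeptideHit) -> float:
    """Overlap of two hit intervals on the same protein, as a fraction of
    the shorter hit's length (the denominator is the shorter hit so that a
    site fully contained in a longer one counts as a full overlap).
    """
    if hit_a.protein_id != hit_b.protein_id:
        raise DomainMismatch(
            f"hits on different proteins: {hit_a.protein_id} vs {hit_b.protein_id}"
        )
    inter = min(hit_a.end, hit_b.end) - max(hit_a.start, hit_b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(hit_a.length, hit_b.length)
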