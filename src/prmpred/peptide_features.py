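"""Peptide-level evidence scores for candidate binding sites.

Four scores, each in [0, 1], are computed per hit over the significant
motif residues only:

* disordered region (DR) — fraction of significant residues in a
  predicted disordered region, since SH3 binding sites concentrate in
  intrinsically disordered segments;
* surface accessibility (SA) — fraction of significant residues with
  relative solvent accessibility at or above an exposure cutoff
  (default 25%);
* peptide conservation (PC) — mean per-residue conservation score from a
  multiple alignment of orthologous sequences (unweighted sum-of-pairs);
* structural contact (SC) — agreement with known domain-peptide
  co-complex contact maps, transferred by global alignment of the query
  domain and peptide onto each base model.

DR/SA/PC read per-residue tracks produced by upstream predictors (or by
:mod:`prmpred.synthetic` for testing); SC aligns query sequences to a
small library of contact base models with Needleman-Wunsch/BLOSUM62.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    DegenerateModel,
    EmptyInput,
    EmptySignificantSet,
    MissingReference,
    TrackMismatch,
)
from .scan import PeptideHit

DEFAULT_RSA_CUTOFF = 0.25
DEFAULT_DISORDER_BINARIZE = 0.5
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue values for one protein: disorder probability (or 0/1
    call), relative solvent accessibility fraction, or conservation."""

    protein_id: str
    kind: str  # disorder | rsa | conservation
    values: tuple

    def __post_init__(self):
        if self.kind not in ("disorder", "rsa", "conservation"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.kind in ("disorder", "rsa"):
            for v in self.values:
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"{self.kind} value {v} outside [0, 1] "
                        f"for {self.protein_id}"
                    )

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class ContactModel:
    """One domain-peptide co-complex reduced to aligned residue-pair
    contacts with areas normalized to the model's largest contact."""

    model_id: str
    domain_seq: str
    peptide_seq: str
    contacts: tuple  # of (domain_index, peptide_index, normalized_area)

    def __post_init__(self):
        if not self.contacts:
            raise DegenerateModel(f"{self.model_id}: no contact pairs")
        for di, pi, c in self.contacts:
            if not (0 <= di < len(self.domain_seq)):
                raise ValueError(f"{self.model_id}: domain index {di} out of range")
            if not (0 <= pi < len(self.peptide_seq)):
                raise ValueError(f"{self.model_id}: peptide index {pi} out of range")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"{self.model_id}: contact area {c} outside [0, 1]")


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment with its residue-to-residue mapping."""

    aligned_a: str
    aligned_b: str
    score: float
    mapping: tuple  # of (index_a, index_b) for aligned residue pairs


def _sig_values(hit: PeptideHit, track: ResidueTrack):
    if not hit.significant_protein_positions:
        raise EmptySignificantSet(
            f"hit {hit.protein_id}:{hit.start}-{hit.end} has no significant positions"
        )
    if len(track) < hit.end:
        raise TrackMismatch(
            f"{track.kind} track for {track.protein_id} has {len(track)} "
            f"values, hit ends at {hit.end}"
        )
    return [track.values[p - 1] for p in hit.significant_protein_positions]


def disorder_score(
    hit: PeptideHit,
    track: ResidueTrack,
    binarize_at: float = DEFAULT_DISORDER_BINARIZE,
) -> float:
    """DR: fraction of significant residues called disordered.

    Probabilistic tracks are binarized at ``binarize_at`` (inclusive);
    tracks already holding 0/1 calls pass through unchanged.
    """
    vals = _sig_values(hit, track)
    calls = [1.0 if v >= binarize_at else 0.0 for v in vals]
    return float(np.mean(calls))


def accessibility_score(
    hit: PeptideHit,
    track: ResidueTrack,
    rsa_cutoff: float = DEFAULT_RSA_CUTOFF,
) -> float:
    """SA: fraction of significant residues exposed (RSA >= cutoff,
    boundary inclusive)."""
    vals = _sig_values(hit, track)
    calls = [1.0 if v >= rsa_cutoff else 0.0 for v in vals]
    return float(np.mean(calls))


def conservation_score(hit: PeptideHit, track: ResidueTrack) -> float:
    """PC: mean conservation value over the significant residues."""
    return float(np.mean(_sig_values(hit, track)))


def conservation_from_msa(
    rows,
    reference_id: str,
    substitution_matrix=None,
    *,
    normalize: bool = True,
) -> ResidueTrack:
    """Per-residue conservation of a reference sequence from a multiple
    alignment, by the unweighted sum-of-pairs rule.

    Each column's raw score is the mean substitution score over all
    unordered row pairs; a pair involving a gap scores 0.  Columns where
    the reference row has a gap are dropped, so the track maps one-to-one
    onto the reference residues.  With ``normalize`` the column scores are
    z-normalized across the reference columns (constant columns map to 0).

    Parameters
    ----------
    rows : sequence of (row_id, gapped_sequence), all the same length
    reference_id : id of the row the track coordinates follow
    substitution_matrix : optional mapping (a, b) -> score; the default is
        the identity matrix (match 1, mismatch 0)
    """
    rows = list(rows)
    if len(rows) < 2:
        raise EmptyInput("need >= 2 alignment rows")
    length = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != length:
            raise ValueError(f"row {rid!r} length {len(seq)} != {length}")
    ref = dict(rows).get(reference_id)
    if ref is None:
        raise MissingReference(f"reference row {reference_id!r} absent")

    def subs(a, b):
        if substitution_matrix is None:
            return 1.0 if a == b else 0.0
        return float(substitution_matrix[a, b])

    k = len(rows)
    npairs = k * (k - 1) // 2
    raw = []
    for col in range(length):
        if ref[col] == "-":
            continue
        letters = [seq[col] for _, seq in rows]
        total = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                if letters[i] == "-" or letters[j] == "-":
                    continue
                total += subs(letters[i], letters[j])
        raw.append(total / npairs)
    raw = np.asarray(raw)
    if normalize:
        sd = raw.std()
        raw = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return ResidueTrack(
        protein_id=reference_id, kind="conservation", values=tuple(float(x) for x in raw)
    )


def _make_aligner(substitution_matrix, gap_open, gap_extend):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrix
    # first gap residue costs `gap_open`, each further residue `gap_extend`
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    seq_a: str,
    seq_b: str,
    substitution_matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment under an affine gap
    scheme; BLOSUM62 by default.  Among co-optimal alignments the first in
    the aligner's deterministic enumeration is returned, so repeated calls
    give identical tracebacks.
    """
    if not seq_a or not seq_b:
        raise EmptyInput("cannot align an empty sequence")
    if substitution_matrix is None:
        substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    mapping = []
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        mapping.extend((a0 + k, b0 + k) for k in range(a1 - a0))
    aligned_a, aligned_b = _gapped_strings(seq_a, seq_b, mapping)
    return Alignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        mapping=tuple(mapping),
    )


def _gapped_strings(seq_a, seq_b, mapping):
    """Rebuild gapped strings from a monotone residue mapping (unaligned
    stretches are placed sequentially, a-side first)."""
    out_a, out_b = [], []
    ia = ib = 0
    for a, b in mapping:
        while ia < a:
            out_a.append(seq_a[ia]); out_b.append("-"); ia += 1
        while ib < b:
            out_a.append("-"); out_b.append(seq_b[ib]); ib += 1
        out_a.append(seq_a[ia]); out_b.append(seq_b[ib]); ia += 1; ib += 1
    while ia < len(seq_a):
        out_a.append(seq_a[ia]); out_b.append("-"); ia += 1
    while ib < len(seq_b):
        out_a.append("-"); out_b.append(seq_b[ib]); ib += 1
    return "".join(out_a), "".join(out_b)


def contact_model_from_map(
    pairs, domain_seq: str, peptide_seq: str, model_id: str = "model"
) -> ContactModel:
    """Build a :class:`ContactModel` from raw residue-pair contact areas
    (e.g. in A^2): areas are divided by the model's maximum pair area, so
    the largest contact maps to 1.0.  Order of input pairs is irrelevant.
    """
    pairs = list(pairs)
    if not pairs:
        raise DegenerateModel(f"{model_id}: no contact pairs")
    max_area = max(a for _, _, a in pairs)
    if max_area <= 0:
        raise DegenerateModel(f"{model_id}: all contact areas are zero")
    contacts = tuple(
        sorted((di, pi, a / max_area) for di, pi, a in pairs)
    )
    return ContactModel(
        model_id=model_id,
        domain_seq=domain_seq,
        peptide_seq=peptide_seq,
        contacts=contacts,
    )


def structural_contact_score(
    domain_seq: str,
    peptide_seq: str,
    base_models,
    substitution_matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    *,
    log_messages: list | None = None,
):
    """SC: best mean transferred contact area over the base models.

    For each base model the query domain is aligned to the model domain
    and the query peptide to the model peptide (independent alignments —
    the contacts are defined between the two chains of the co-complex).
    A model contact pair contributes its normalized area only when both of
    its residues are aligned to query residues; the denominator is always
    the model's total number of contact pairs, so a gap at a contact
    residue lowers the average in proportion to that contact's area.

    Returns ``(sc, best_model_id)`` with ``sc`` in [0, 1].  When no
    contact of any model is alignable the score is 0.0 and a warning is
    recorded in ``log_messages``.
    """
    if not base_models:
        raise EmptyInput("need at least one contact base model")
    best = 0.0
    best_id = None
    any_aligned = False
    for model in base_models:
        dom_map = dict(
            align_global(model.domain_seq, domain_seq, substitution_matrix,
                         gap_open, gap_extend).mapping
        )
        pep_map = dict(
            align_global(model.peptide_seq, peptide_seq, substitution_matrix,
                         gap_open, gap_extend).mapping
        )
        total = 0.0
        aligned_here = 0
        for di, pi, c in model.contacts:
            if di in dom_map and pi in pep_map:
                total += c
                aligned_here += 1
        score = total / len(model.contacts)
        any_aligned = any_aligned or aligned_here > 0
        if best_id is None or score > best:
            best, best_id = score, model.model_id
    if not any_aligned and log_messages is not None:
        log_messages.append(
            "structural contact: no contact residue alignable in any base model"
        )
    return float(best), best_id
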