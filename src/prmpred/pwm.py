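"""Position weight matrices for short linear motifs.

A PWM is built from the fixed-length binding peptides reported for one
peptide-recognition domain (e.g. an SH3 domain screened by phage display).
Columns hold per-position residue counts; weights are log2 odds against a
background residue distribution.  Window scores are therefore additive in
bits, and the exact null distribution of the score of a background-random
window is obtained by a column-wise convolution with scores rounded to a
fixed granularity.  Tail probabilities of that distribution convert window
scores into p-values, and the per-column relative entropy (information
content) identifies the significant motif positions that carry the
specificity and enter the peptide-level evidence scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlphabetError,
    EmptySignificantSet,
    InsufficientData,
    LengthMismatch,
    UnattainableThreshold,
)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Log-odds floor (bits) for zero-frequency cells (pseudocount 0).
LOG_ODDS_FLOOR: float = -30.0

#: Default score discretization step (bits) for the null distribution.
DEFAULT_GRANULARITY: float = 1e-3

#: Default per-cell pseudocount scale: total added mass per column is
#: ``m * pseudocount`` distributed proportionally to the background, so the
#: default adds one virtual observation per column for a 20-letter alphabet.
DEFAULT_PSEUDOCOUNT: float = 0.05


def _round_to_grid(x: float, granularity: float) -> int:
    """Round a score to an integer number of grid steps (half away from zero)."""
    return int(np.floor(x / granularity + 0.5))


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix over a fixed alphabet.

    Attributes
    ----------
    id, domain_id : str
        Identifiers of the matrix and of the domain it models.
    alphabet : str
        Ordered residue alphabet (rows).
    counts : ndarray of shape (m, n)
        Residue counts per motif column, including pseudocount mass.
    weights : ndarray of shape (m, n)
        Log2 odds of the column frequency against the background, floored
        at :data:`LOG_ODDS_FLOOR` for zero-frequency cells.
    background : ndarray of shape (m,)
        Background residue probabilities (sum to 1, all positive).
    pseudocount : float
        Per-cell pseudocount scale used during construction.
    """

    id: str
    domain_id: str
    alphabet: str
    counts: np.ndarray
    weights: np.ndarray
    background: np.ndarray
    pseudocount: float
    _index: dict = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {a: i for i, a in enumerate(self.alphabet)}
        )

    @property
    def n(self) -> int:
        """Motif length (number of columns)."""
        return self.counts.shape[1]

    @property
    def m(self) -> int:
        """Alphabet size (number of rows)."""
        return self.counts.shape[0]

    def row(self, residue: str) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise AlphabetError(f"residue {residue!r} not in alphabet") from None

    @property
    def frequencies(self) -> np.ndarray:
        """Column-normalized (pseudocounted) residue frequencies."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    @property
    def max_score(self) -> float:
        """Score of the per-column best residue (the consensus score)."""
        return float(self.weights.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        """Highest-weight residue at each column (ties: first in alphabet)."""
        return "".join(self.alphabet[i] for i in self.weights.argmax(axis=0))


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of PWM window scores on a score grid.

    ``support`` holds the attainable (rounded) scores in ascending order,
    ``probs`` their probabilities under the background model, and
    ``tail_prob[k] = P(score >= support[k])``.
    """

    pwm_id: str
    granularity: float
    support: np.ndarray      # ascending floats (integer multiples of granularity)
    probs: np.ndarray
    tail_prob: np.ndarray
    _support_int: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        ints = np.round(self.support / self.granularity).astype(np.int64)
        object.__setattr__(self, "_support_int", ints)


def _resolve_background(background, alphabet: str) -> np.ndarray:
    m = len(alphabet)
    if isinstance(background, str):
        if background == "uniform":
            return np.full(m, 1.0 / m)
        raise ValueError(
            "background must be 'uniform' or an explicit probability vector; "
            "use proteome_background() for a proteome-derived one"
        )
    bg = np.asarray(background, dtype=float)
    if bg.shape != (m,):
        raise ValueError(f"background must have length {m}")
    if not np.all(bg > 0):
        raise ValueError("background entries must all be > 0")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    return bg


def proteome_background(sequences, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    """Residue frequencies of a set of sequences (one added count per letter).

    Residues outside the alphabet are ignored.  The add-one regularization
    keeps every background probability positive even for letters absent
    from the proteome.
    """
    index = {a: i for i, a in enumerate(alphabet)}
    counts = np.ones(len(alphabet))
    for seq in sequences:
        for ch in seq:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def build_pwm(
    peptides,
    background="uniform",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    *,
    alphabet: str = AMINO_ACIDS,
    id: str = "pwm",
    domain_id: str = "",
) -> Pwm:
    """Build a PWM from equal-length binding peptides.

    Pseudocount mass ``m * pseudocount * background[a]`` is added to every
    cell, i.e. the total virtual mass per column is ``m * pseudocount``
    distributed proportionally to the background.  With a uniform
    background this reduces to a flat per-cell pseudocount.

    Raises
    ------
    InsufficientData, LengthMismatch, AlphabetError
    """
    peptides = list(peptides)
    if len(peptides) < 2:
        raise InsufficientData(f"need >= 2 peptides, got {len(peptides)}")
    n = len(peptides[0])
    for p in peptides:
        if len(p) != n:
            raise LengthMismatch(
                f"peptide {p!r} has length {len(p)}, expected {n}"
            )
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    m = len(alphabet)
    bg = _resolve_background(background, alphabet)
    index = {a: i for i, a in enumerate(alphabet)}
    raw = np.zeros((m, n))
    for p in peptides:
        for j, ch in enumerate(p):
            i = index.get(ch)
            if i is None:
                raise AlphabetError(f"residue {ch!r} in peptide {p!r}")
            raw[i, j] += 1
    counts = raw + m * pseudocount * bg[:, None]
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):
        weights = np.log2(freqs / bg[:, None])
    weights = np.maximum(weights, LOG_ODDS_FLOOR)
    return Pwm(
        id=id, domain_id=domain_id, alphabet=alphabet,
        counts=counts, weights=weights, background=bg, pseudocount=pseudocount,
    )


def score_window(pwm: Pwm, window: str) -> float:
    """Sum of per-column log-odds weights (bits) for one window."""
    if len(window) != pwm.n:
        raise LengthMismatch(
            f"window length {len(window)} != motif length {pwm.n}"
        )
    return float(sum(pwm.weights[pwm.row(ch), j] for j, ch in enumerate(window)))


def score_distribution(
    pwm: Pwm, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact null score distribution by column-wise convolution.

    Per-column weights are rounded to integer multiples of ``granularity``
    and the distribution of their sum under the background model is built
    one column at a time, so the result is exact up to the rounding: the
    tail probability at any window's score differs from the unrounded one
    by at most the mass within ``n * granularity / 2`` of the score.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    key = np.vectorize(lambda w: _round_to_grid(w, granularity))(pwm.weights)
    key = key.astype(np.int64)
    # dense array over the attainable integer score range, column by column
    lo, hi = 0, 0
    probs = np.ones(1)
    for j in range(pwm.n):
        col = key[:, j]
        new_lo = lo + int(col.min())
        new_hi = hi + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for a in range(pwm.m):
            off = lo + int(col[a]) - new_lo
            new[off : off + probs.size] += pwm.background[a] * probs
        probs, lo, hi = new, new_lo, new_hi
    nz = np.nonzero(probs)[0]
    support_int = nz + lo
    p = probs[nz]
    tail = np.cumsum(p[::-1])[::-1]
    tail = np.minimum(tail, 1.0)  # guard accumulated round-off
    return ScoreDistribution(
        pwm_id=pwm.id,
        granularity=granularity,
        support=support_int * granularity,
        probs=p,
        tail_prob=tail,
    )


def pvalue_of_score(dist: ScoreDistribution, score: float) -> float:
    """P(background window score >= ``score``).

    The query score is rounded to the distribution's grid with the same
    rule used when building it; scores below the minimum support return
    1.0 and scores above the maximum return 0.0.
    """
    snap = _round_to_grid(score, dist.granularity)
    idx = int(np.searchsorted(dist._support_int, snap, side="left"))
    if idx >= dist.support.size:
        return 0.0
    return float(dist.tail_prob[idx])


def threshold_for_pvalue(dist: ScoreDistribution, pvalue: float) -> float:
    """Minimal support score whose tail probability is <= ``pvalue``.

    Satisfies ``pvalue_of_score(dist, threshold) <= pvalue``.  Raises
    :class:`UnattainableThreshold` when even the maximum attainable score
    has tail probability above ``pvalue``.
    """
    if not (0 < pvalue <= 1):
        raise ValueError("pvalue must be in (0, 1]")
    # tail_prob is non-increasing; find first index with tail <= pvalue
    idx = int(np.searchsorted(-dist.tail_prob, -pvalue, side="left"))
    if idx >= dist.support.size:
        raise UnattainableThreshold(
            f"smallest attainable tail probability is {dist.tail_prob[-1]:.3g} "
            f"> requested {pvalue:.3g}"
        )
    return float(dist.support[idx])


def position_information_content(pwm: Pwm) -> np.ndarray:
    """Per-column relative entropy (bits) of the pseudocounted frequencies
    against the background; 0 for a background-matching column, up to
    log2(m) for a point mass on the rarest residue of a uniform background.
    """
    f = pwm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log2(f / pwm.background[:, None])
    terms = np.where(f > 0, terms, 0.0)
    ic = terms.sum(axis=0)
    return np.maximum(ic, 0.0)


def significant_positions(pwm: Pwm, ic_cutoff: float = 1.0):
    """0-based indices of columns with information content >= ``ic_cutoff``.

    These columns carry the motif's specificity; the per-residue evidence
    scores average over them only.  Raises :class:`EmptySignificantSet`
    when no column qualifies.
    """
    if ic_cutoff < 0:
        raise ValueError("ic_cutoff must be >= 0")
    ic = position_information_content(pwm)
    cols = [j for j in range(pwm.n) if ic[j] >= ic_cutoff]
    if not cols:
        raise EmptySignificantSet(
            f"no column with information content >= {ic_cutoff} "
            f"(max is {ic.max():.3f})"
        )
    return cols


# --- serialization -------------------------------------------------------

def pwm_to_text(pwm: Pwm) -> str:
    """Tab-separated matrix of counts with a ``#``-prefixed metadata block."""
    buf = io.StringIO()
    buf.write(f"# id\t{pwm.id}\n")
    buf.write(f"# domain_id\t{pwm.domain_id}\n")
    buf.write(f"# pseudocount\t{pwm.pseudocount!r}\n")
    buf.write("# background\t" + "\t".join(repr(float(b)) for b in pwm.background) + "\n")
    buf.write("residue\t" + "\t".join(str(j + 1) for j in range(pwm.n)) + "\n")
    for i, a in enumerate(pwm.alphabet):
        buf.write(a + "\t" + "\t".join(repr(float(c)) for c in pwm.counts[i]) + "\n")
    return buf.getvalue()


def pwm_from_text(text: str) -> Pwm:
    """Inverse of :func:`pwm_to_text` (weights are recomputed from counts)."""
    meta = {}
    rows = []
    letters = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            meta[parts[0]] = parts[1:]
            continue
        parts = line.split("\t")
        if parts[0] == "residue":
            continue
        letters.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    alphabet = "".join(letters)
    counts = np.array(rows)
    bg = np.array([float(x) for x in meta["background"]])
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore"):
        weights = np.log2(freqs / bg[:, None])
    weights = np.maximum(weights, LOG_ODDS_FLOOR)
    return Pwm(
        id=meta["id"][0],
        domain_id=meta["domain_id"][0] if meta.get("domain_id") else "",
        alphabet=alphabet,
        counts=counts,
        weights=weights,
        background=bg,
        pseudocount=float(meta["pseudocount"][0]),
    )
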