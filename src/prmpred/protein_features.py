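"""Protein-pair evidence: co-expression across profile panels and
co-occurring sequence-signature information content.

Co-expression (EX): the Pearson correlation of a gene pair is computed in
every expression profile where both genes are measured, the per-profile
correlations are Fisher z-transformed, averaged in z-space and mapped
back with tanh.  Averaging in z-space rather than on raw correlations is
the standard way to combine correlation estimates of unequal reliability
from many experiments.

Sequence signature (SS): domain/motif identifiers (InterPro-style) carried
by each protein side of a reference set of known interactions define
co-occurrence probabilities p_ij and marginals p_i; the score of a new
pair sums log2(p_ij / (p_i p_j)) over the cross pairs of its signatures,
i.e. the pointwise mutual information of seeing the two signatures on the
two sides of an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientData,
    NoExpressionEvidence,
    NoSignatureEvidence,
)

R_CLIP = 0.999999  # |r| clipped here before atanh
MIN_SHARED_CONDITIONS = 3


@dataclass
class ExpressionPanel:
    """A set of expression profiles, each a genes x conditions matrix."""

    profiles: list  # of (profile_id, pandas.DataFrame with gene index)

    def __post_init__(self):
        for pid, df in self.profiles:
            if df.shape[1] < MIN_SHARED_CONDITIONS:
                raise ValueError(
                    f"profile {pid} has {df.shape[1]} conditions, need >= "
                    f"{MIN_SHARED_CONDITIONS}"
                )


def profile_correlations(gene_a, gene_b, panel: ExpressionPanel,
                         *, log_messages: list | None = None):
    """Pearson correlation of a gene pair in every qualifying profile.

    A profile qualifies when both genes are present with at least three
    shared non-missing conditions and both have positive variance; other
    profiles are skipped with a log record.  Raises
    :class:`NoExpressionEvidence` when no profile qualifies — callers
    treat that as a missing feature, never as correlation 0.
    """
    rs = []
    for pid, df in panel.profiles:
        if gene_a not in df.index or gene_b not in df.index:
            _log(log_messages, f"profile {pid}: gene absent, skipped")
            continue
        xa = df.loc[gene_a].to_numpy(dtype=float)
        xb = df.loc[gene_b].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xb))
        if ok.sum() < MIN_SHARED_CONDITIONS:
            _log(log_messages, f"profile {pid}: <{MIN_SHARED_CONDITIONS} shared conditions")
            continue
        xa, xb = xa[ok], xb[ok]
        if xa.std() == 0 or xb.std() == 0:
            _log(log_messages, f"profile {pid}: zero variance, skipped")
            continue
        rs.append(float(np.corrcoef(xa, xb)[0, 1]))
    if not rs:
        raise NoExpressionEvidence(f"no qualifying profile for ({gene_a}, {gene_b})")
    return rs


def combine_expression(correlations, *, log_messages: list | None = None) -> float:
    """Fisher-z combination: EX = tanh(mean of atanh(r_i)).

    Correlations at +-1 are clipped to +-``R_CLIP`` (with a warning) so
    the transform stays finite.
    """
    rs = np.asarray(list(correlations), dtype=float)
    if rs.size == 0:
        raise NoExpressionEvidence("empty correlation list")
    if np.any(np.abs(rs) >= 1):
        _log(log_messages, "correlation at +-1 clipped before Fisher transform")
        rs = np.clip(rs, -R_CLIP, R_CLIP)
    zbar = np.arctanh(rs).mean()
    return float(np.tanh(zbar))


def _log(messages, text):
    if messages is not None:
        messages.append(text)


@dataclass
class SignatureModel:
    """Signature co-occurrence statistics estimated from reference PPIs.

    ``p_pair[(i, j)]`` (unordered, stored with i <= j) is the smoothed
    probability of seeing signatures i and j on the two sides of a
    reference interaction; ``p_sig[i]`` the smoothed marginal of seeing i
    on one side.
    """

    p_sig: dict
    p_pair: dict
    n_reference_pairs: int
    pseudocount: float = 0.5

    def pair_probability(self, i, j) -> float:
        key = (i, j) if i <= j else (j, i)
        p = self.p_pair.get(key)
        if p is None:
            # unseen pair: pseudocount mass only
            p = self.pseudocount / self._pair_norm
        return p

    # populated by fit_signature_model
    _pair_norm: float = field(default=1.0, repr=False)


def fit_signature_model(
    reference_ppis,
    signatures,
    pseudocount: float = 0.5,
) -> SignatureModel:
    """Estimate signature co-occurrence probabilities from reference PPIs.

    For each reference interaction (A, B), every signature on A crossed
    with every signature on B contributes one observation to the
    unordered pair count; each side's signatures contribute to the
    marginals.  Jeffreys-style pseudocount keeps all probabilities
    positive so the log-ratio score is defined for unseen pairs.

    Raises :class:`InsufficientData` when no reference pair has
    signatures on both sides.
    """
    pair_counts = {}
    sig_counts = {}
    n_pair_obs = 0
    n_sig_obs = 0
    usable = 0
    for a, b in reference_ppis:
        sa = set(signatures.get(a, ()))
        sb = set(signatures.get(b, ()))
        if not sa or not sb:
            continue
        usable += 1
        for i in sa:
            for j in sb:
                key = (i, j) if i <= j else (j, i)
                pair_counts[key] = pair_counts.get(key, 0) + 1
                n_pair_obs += 1
        for s in list(sa) + list(sb):
            sig_counts[s] = sig_counts.get(s, 0) + 1
            n_sig_obs += 1
    if usable == 0:
        raise InsufficientData(
            "no reference pair with signatures on both sides"
        )
    vocab = sorted(sig_counts)
    n_vocab = len(vocab)
    sig_norm = n_sig_obs + pseudocount * n_vocab
    p_sig = {s: (sig_counts[s] + pseudocount) / sig_norm for s in vocab}
    n_pair_types = n_vocab * (n_vocab + 1) // 2
    pair_norm = n_pair_obs + pseudocount * n_pair_types
    p_pair = {k: (c + pseudocount) / pair_norm for k, c in pair_counts.items()}
    model = SignatureModel(
        p_sig=p_sig,
        p_pair=p_pair,
        n_reference_pairs=usable,
        pseudocount=pseudocount,
    )
    model._pair_norm = pair_norm
    return model


def signature_score(a_signatures, b_signatures, model: SignatureModel,
                    sign: int = +1) -> float:
    """SS = sum over cross signature pairs of log2(p_ij / (p_i p_j)).

    Signatures unknown to the model are skipped; if either protein has
    none known, :class:`NoSignatureEvidence` is raised.  ``sign=-1``
    negates the sum for compatibility with conventions that report the
    negated log-ratio.
    """
    sa = [s for s in set(a_signatures) if s in model.p_sig]
    sb = [s for s in set(b_signatures) if s in model.p_sig]
    if not sa or not sb:
        raise NoSignatureEvidence("no signature known to the model")
    total = 0.0
    for i in sa:
        for j in sb:
            pij = model.pair_probability(i, j)
            total += np.log2(pij / (model.p_sig[i] * model.p_sig[j]))
    return float(sign * total)
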