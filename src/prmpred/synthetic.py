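"""Synthetic data with planted ground truth for every pipeline input.

The generator emulates the shape of the real inputs — a proteome with
motif instances planted at known coordinates, per-residue disorder / RSA /
conservation tracks, domain-peptide contact base models, an ontology DAG
with annotations, a panel of expression profiles, signature assignments
with a reference interaction list, and labeled feature vectors — so the
whole pipeline can be exercised end to end with a known answer key.
Everything is a pure function of (spec, seed): the same
:class:`FixtureSpec` always produces byte-identical outputs.

Class-conditional feature distributions are Beta for bounded features and
Gaussian for unbounded ones.  The default parameters encode the
qualitative picture seen in real SH3 interaction data: disorder and
surface accessibility separate positives from negatives strongly, peptide
conservation only weakly (most yeast peptides are conserved whether or
not they bind), and among protein features the ontology-based and
signature scores are stronger than expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .ontology import AnnotationSet, GoDag
from .peptide_features import ContactModel
from .protein_features import ExpressionPanel
from .pwm import AMINO_ACIDS

# (alpha, beta) for Beta-distributed bounded features and (mu, sd) for
# Gaussian unbounded ones, per class.
DEFAULT_FEATURE_PARAMS = {
    "DR": {"dist": "beta", "pos": (6.0, 2.0), "neg": (2.0, 5.0)},
    "SA": {"dist": "beta", "pos": (6.0, 2.0), "neg": (2.0, 5.0)},
    "PC": {"dist": "gauss", "pos": (0.6, 1.0), "neg": (0.0, 1.0)},
    "SC": {"dist": "beta", "pos": (5.0, 2.0), "neg": (2.0, 3.0)},
    "CC": {"dist": "beta", "pos": (5.0, 2.0), "neg": (2.0, 5.0)},
    "BP": {"dist": "beta", "pos": (5.0, 2.0), "neg": (2.0, 5.0)},
    "MF": {"dist": "beta", "pos": (3.0, 2.0), "neg": (2.0, 3.0)},
    "EX": {"dist": "tanh-gauss", "pos": (0.8, 0.6), "neg": (0.0, 0.6)},
    "SS": {"dist": "gauss", "pos": (3.0, 2.0), "neg": (0.0, 2.0)},
}


@dataclass(frozen=True)
class MotifSpec:
    """One planted motif: consensus sequence plus per-position noise (the
    probability that a peptide letter deviates from the consensus)."""

    pwm_id: str
    domain_id: str
    consensus: str
    noise: float = 0.15
    n_peptides: int = 30


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic universe.  All sampling is driven by
    ``seed`` through independent child streams per component."""

    seed: int = 0
    # proteome
    n_proteins: int = 60
    protein_length: tuple = (120, 220)
    motifs: tuple = (
        MotifSpec("pwm_classI", "dom1", "RKLPPLPKR"),
        MotifSpec("pwm_classII", "dom2", "PAMPARPSV"),
    )
    planted_per_motif: int = 6
    # residue tracks: Beta parameters inside planted sites vs background
    disorder_site: tuple = (6.0, 2.0)
    disorder_background: tuple = (2.0, 5.0)
    rsa_site: tuple = (6.0, 2.0)
    rsa_background: tuple = (2.0, 5.0)
    conservation_site: tuple = (0.8, 0.6)   # Gaussian (mu, sd)
    conservation_background: tuple = (0.0, 1.0)
    # ontology
    go_depth: int = 3
    go_branching: int = 3
    # expression
    n_profiles: int = 6
    n_conditions: int = 12
    r_positive: float = 0.7
    r_negative: float = 0.0
    # signatures
    n_signatures: int = 24
    signatures_per_protein: tuple = (1, 3)
    favored_pair_fraction: float = 0.8
    # labeled feature vectors
    feature_params: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_PARAMS))
    # protein pairs for the protein-feature generators
    n_positive_pairs: int = 12
    n_negative_pairs: int = 12


def _child_rng(spec: FixtureSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, index]))


_STREAMS = {
    "peptides": 1, "proteome": 2, "tracks": 3, "ontology": 4,
    "expression": 5, "signatures": 6, "labeled": 7, "contacts": 8,
    "pairs": 9,
}


def _stream(spec: FixtureSpec, name: str) -> np.random.Generator:
    return _child_rng(spec, _STREAMS[name])


def _sample_motif_window(rng, motif: MotifSpec) -> str:
    out = []
    for ch in motif.consensus:
        if motif.noise > 0 and rng.random() < motif.noise:
            out.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
        else:
            out.append(ch)
    return "".join(out)


def generate_binding_peptides(spec: FixtureSpec):
    """Phage-display-like peptide lists: per motif, ``n_peptides`` noisy
    copies of the consensus."""
    rng = _stream(spec, "peptides")
    return {
        m.pwm_id: [_sample_motif_window(rng, m) for _ in range(m.n_peptides)]
        for m in spec.motifs
    }


def generate_proteome_with_motifs(spec: FixtureSpec):
    """Random background proteome with motif instances planted at
    recorded coordinates.

    Returns ``(proteome, truth)`` where ``proteome`` is a list of
    (protein_id, sequence) and ``truth`` a DataFrame with one row per
    planted site (protein_id, pwm_id, domain_id, start, end, window),
    1-based inclusive coordinates.
    """
    rng = _stream(spec, "proteome")
    lo, hi = spec.protein_length
    seqs = {}
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seqs[f"prot{i:03d}"] = list(
            AMINO_ACIDS[k] for k in rng.integers(0, len(AMINO_ACIDS), length)
        )
    occupied = {pid: [] for pid in seqs}
    truth_rows = []
    ids = sorted(seqs)
    for motif in spec.motifs:
        n = len(motif.consensus)
        if n > min(len(s) for s in seqs.values()):
            raise SpecError(
                f"motif {motif.pwm_id} longer than the shortest protein"
            )
        planted = 0
        attempts = 0
        while planted < spec.planted_per_motif:
            attempts += 1
            if attempts > 1000 * spec.planted_per_motif:
                raise SpecError("cannot place planted motifs without overlap")
            pid = ids[rng.integers(len(ids))]
            seq = seqs[pid]
            start0 = int(rng.integers(0, len(seq) - n + 1))
            span = (start0, start0 + n - 1)
            if any(not (span[1] < s or span[0] > e) for s, e in occupied[pid]):
                continue
            window = _sample_motif_window(rng, motif)
            seq[start0 : start0 + n] = list(window)
            occupied[pid].append(span)
            truth_rows.append(
                dict(protein_id=pid, pwm_id=motif.pwm_id,
                     domain_id=motif.domain_id, start=start0 + 1,
                     end=start0 + n, window=window)
            )
            planted += 1
    proteome = [(pid, "".join(seqs[pid])) for pid in ids]
    truth = pd.DataFrame(truth_rows).sort_values(
        ["pwm_id", "protein_id", "start"]
    ).reset_index(drop=True)
    return proteome, truth


def generate_residue_tracks(spec: FixtureSpec, proteome, truth: pd.DataFrame):
    """Disorder / RSA / conservation tracks covering every protein.

    Residues inside planted sites draw from the site distributions
    (high disorder, high exposure, high conservation); everything else
    from the background distributions.
    """
    rng = _stream(spec, "tracks")
    in_site = {pid: set() for pid, _ in proteome}
    for row in truth.itertuples():
        in_site[row.protein_id].update(range(row.start, row.end + 1))
    tracks = {"disorder": {}, "rsa": {}, "conservation": {}}
    for pid, seq in proteome:
        L = len(seq)
        site_mask = np.array([(i + 1) in in_site[pid] for i in range(L)])
        for kind, site_par, bg_par in (
            ("disorder", spec.disorder_site, spec.disorder_background),
            ("rsa", spec.rsa_site, spec.rsa_background),
        ):
            vals = rng.beta(bg_par[0], bg_par[1], L)
            if site_mask.any():
                vals[site_mask] = rng.beta(site_par[0], site_par[1],
                                           int(site_mask.sum()))
            tracks[kind][pid] = vals
        mu_s, sd_s = spec.conservation_site
        mu_b, sd_b = spec.conservation_background
        cons = rng.normal(mu_b, sd_b, L)
        if site_mask.any():
            cons[site_mask] = rng.normal(mu_s, sd_s, int(site_mask.sum()))
        tracks["conservation"][pid] = cons
    return tracks


def generate_contact_models(spec: FixtureSpec, peptides=None):
    """Toy co-complex base models: one per motif, with the motif
    consensus as the peptide chain, a random ~60-residue domain chain and
    random contact pairs concentrated on the peptide positions."""
    rng = _stream(spec, "contacts")
    models = []
    for k, motif in enumerate(spec.motifs):
        dom = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), 60)
        )
        pep = motif.consensus
        n_contacts = int(rng.integers(6, 12))
        pairs = set()
        while len(pairs) < n_contacts:
            pairs.add((int(rng.integers(0, 60)), int(rng.integers(0, len(pep)))))
        contacts = tuple(
            sorted((di, pi, float(rng.uniform(0.2, 1.0))) for di, pi in pairs)
        )
        # renormalize so the max is exactly 1
        mx = max(c for _, _, c in contacts)
        contacts = tuple((di, pi, c / mx) for di, pi, c in contacts)
        models.append(
            ContactModel(model_id=f"model_{motif.domain_id}",
                         domain_seq=dom, peptide_seq=pep, contacts=contacts)
        )
    return models


def generate_protein_pairs(spec: FixtureSpec, proteome=None):
    """Disjoint positive and negative protein pairs over the proteome ids
    (generated ids are used if no proteome is given)."""
    rng = _stream(spec, "pairs")
    if proteome is None:
        ids = [f"prot{i:03d}" for i in range(spec.n_proteins)]
    else:
        ids = [pid for pid, _ in proteome]
    need = 2 * (spec.n_positive_pairs + spec.n_negative_pairs)
    if need > len(ids):
        raise SpecError(
            f"{need} distinct proteins needed for the requested pairs, "
            f"proteome has {len(ids)}"
        )
    order = list(rng.permutation(ids))
    pos, neg = [], []
    for _ in range(spec.n_positive_pairs):
        pos.append((order.pop(), order.pop()))
    for _ in range(spec.n_negative_pairs):
        neg.append((order.pop(), order.pop()))
    return pos, neg


def generate_go_dag_and_annotations(spec: FixtureSpec, positive_pairs,
                                    negative_pairs):
    """Random rooted DAG per namespace plus annotations that place
    interacting pairs on the same leaf's vicinity and non-interacting
    pairs under different top-level branches."""
    rng = _stream(spec, "ontology")
    namespaces = ("cellular_component", "biological_process",
                  "molecular_function")
    terms, edges, ns_of = [], [], {}
    leaves = {ns: [] for ns in namespaces}
    for ns in namespaces:
        prefix = ns.split("_")[0][:2].upper()
        root = f"{prefix}:0"
        terms.append(root)
        ns_of[root] = ns
        frontier = [root]
        counter = 1
        for depth in range(spec.go_depth):
            nxt = []
            for parent in frontier:
                for _ in range(spec.go_branching):
                    t = f"{prefix}:{counter}"
                    counter += 1
                    terms.append(t)
                    ns_of[t] = ns
                    edges.append((t, parent))
                    nxt.append(t)
            frontier = nxt
        leaves[ns] = frontier
    dag = GoDag.from_edges(terms, edges, ns_of)

    annotations = AnnotationSet()
    for ns in namespaces:
        lv = leaves[ns]
        for a, b in positive_pairs:
            leaf = lv[rng.integers(len(lv))]
            annotations.add(a, leaf)
            annotations.add(b, leaf)
        # negatives: leaves under different children of the root
        for a, b in negative_pairs:
            i, j = rng.choice(len(lv), size=2, replace=False)
            per_branch = max(1, len(lv) // spec.go_branching)
            if i // per_branch == j // per_branch:
                j = (i + per_branch) % len(lv)
            annotations.add(a, lv[int(i)])
            annotations.add(b, lv[int(j)])
    return dag, annotations


def generate_expression_panel(spec: FixtureSpec, positive_pairs,
                              negative_pairs):
    """Profiles in which each positive pair shares a latent factor with
    loading sqrt(r+), inducing expected correlation ``r_positive``;
    negative-pair genes are independent noise (plus ``r_negative`` if
    nonzero)."""
    rng = _stream(spec, "expression")
    genes = sorted({g for p in positive_pairs + negative_pairs for g in p})
    factors_of = {}
    for k, (a, b) in enumerate(positive_pairs):
        factors_of.setdefault(a, []).append(k)
        factors_of.setdefault(b, []).append(k)
    load = np.sqrt(max(spec.r_positive, 0.0))
    profiles = []
    for p in range(spec.n_profiles):
        factors = rng.normal(size=(max(len(positive_pairs), 1), spec.n_conditions))
        rows = {}
        for g in genes:
            noise = rng.normal(size=spec.n_conditions)
            ks = factors_of.get(g)
            if ks:
                shared = factors[ks].sum(axis=0) / np.sqrt(len(ks))
                rows[g] = load * shared + np.sqrt(1 - load**2) * noise
            else:
                rows[g] = noise
        profiles.append(
            (f"profile{p:02d}",
             pd.DataFrame(rows, index=[f"cond{c}" for c in range(spec.n_conditions)]).T)
        )
    return ExpressionPanel(profiles=profiles)


def generate_signature_data(spec: FixtureSpec, positive_pairs,
                            negative_pairs):
    """Signature assignments plus a reference interaction list in which a
    few favored signature pairs are strongly enriched on interacting
    pairs.

    Returns ``(signatures, reference_ppis)`` where ``signatures`` maps
    protein -> set of signature ids and ``reference_ppis`` is the
    positive pair list (the training interactions for the signature
    model).
    """
    rng = _stream(spec, "signatures")
    vocab = [f"sig{i:03d}" for i in range(spec.n_signatures)]
    n_favored = max(2, spec.n_signatures // 6)
    favored = [(vocab[2 * i], vocab[2 * i + 1]) for i in range(n_favored)]
    signatures = {}

    def base_signatures(protein):
        lo, hi = spec.signatures_per_protein
        k = int(rng.integers(lo, hi + 1))
        return {vocab[int(i)] for i in rng.choice(len(vocab), size=k, replace=False)}

    for a, b in positive_pairs:
        sa, sb = base_signatures(a), base_signatures(b)
        if rng.random() < spec.favored_pair_fraction:
            fi, fj = favored[int(rng.integers(n_favored))]
            sa.add(fi)
            sb.add(fj)
        signatures.setdefault(a, set()).update(sa)
        signatures.setdefault(b, set()).update(sb)
    for a, b in negative_pairs:
        for g in (a, b):
            signatures.setdefault(g, set()).update(base_signatures(g))
    return signatures, list(positive_pairs)


def _draw_feature(rng, params, cls: str, size: int) -> np.ndarray:
    kind = params["dist"]
    a, b = params[cls]
    if kind == "beta":
        return rng.beta(a, b, size)
    if kind == "gauss":
        return rng.normal(a, b, size)
    if kind == "tanh-gauss":
        return np.tanh(rng.normal(a, b, size))
    raise SpecError(f"unknown feature distribution {kind!r}")


def generate_labeled_pairs(spec: FixtureSpec, n_per_class: int = 200,
                           missingness: float = 0.0) -> pd.DataFrame:
    """Labeled feature vectors drawn from the class-conditional
    distributions, balanced classes, with a uniform missingness mask.

    ``missingness`` 0 is the fully observed ("filtered") regime; a
    positive rate hides each feature value independently with that
    probability ("unfiltered" regime).
    """
    if not (0 <= missingness < 1):
        raise SpecError("missingness must be in [0, 1)")
    rng = _stream(spec, "labeled")
    names = list(spec.feature_params)
    cols = {}
    for name in names:
        params = spec.feature_params[name]
        pos = _draw_feature(rng, params, "pos", n_per_class)
        neg = _draw_feature(rng, params, "neg", n_per_class)
        cols[name] = np.concatenate([pos, neg])
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=int), np.zeros(n_per_class, dtype=int)]
    )
    df = pd.DataFrame(cols)
    df.insert(0, "pair_id", [f"pair{i:05d}" for i in range(len(df))])
    df["label"] = labels
    if missingness > 0:
        mask = rng.random((len(df), len(names))) < missingness
        vals = df[names].to_numpy()
        vals[mask] = np.nan
        df[names] = vals
    return df
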