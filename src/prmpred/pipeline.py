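"""Top-level pipeline: scan -> peptide features -> protein features ->
posteriors -> Bayes combination.

``run_predict_pipeline`` takes a loaded :class:`~prmpred.io.DatasetBundle`
and returns per-site prediction records plus a run report counting what
happened at every stage (windows scanned, hits, candidates with missing
features, predictions above the decision threshold).  Candidates whose
features are all missing in one scope fall back to the other classifier's
posterior; candidates with no evidence in either scope are excluded and
counted.
"""

from __future__ import annotations

import numpy as np

from . import bayes, io
from .bayes import (
    PEPTIDE_FEATURES,
    PROTEIN_FEATURES,
    PredictionRecord,
    class_posterior,
    combine_posteriors,
    fit_naive_bayes,
)
from .errors import (
    EmptyInput,
    EmptySignificantSet,
    MissingAnnotation,
    NoEvidence,
    NoExpressionEvidence,
    NoSignatureEvidence,
    PrmPredError,
    TrackMismatch,
)
from .ontology import TcssScorer
from .peptide_features import (
    accessibility_score,
    conservation_score,
    disorder_score,
    structural_contact_score,
)
from .protein_features import (
    combine_expression,
    fit_signature_model,
    profile_correlations,
    signature_score,
)
from .pwm import score_distribution
from .scan import ScanLog, scan_proteome

_NAMESPACE_FEATURES = (
    ("CC", "cellular_component"),
    ("BP", "biological_process"),
    ("MF", "molecular_function"),
)


def train_models(bundle: io.DatasetBundle):
    """Fit the peptide and protein classifiers from the bundle's labeled
    feature tables."""
    cfg = bundle.config
    if bundle.labeled_pep is None or bundle.labeled_pro is None:
        raise EmptyInput("bundle has no labeled training tables")
    models = {}
    for scope, table, names in (
        ("pep", bundle.labeled_pep, PEPTIDE_FEATURES),
        ("pro", bundle.labeled_pro, PROTEIN_FEATURES),
    ):
        X = table[list(names)].to_numpy(dtype=float)
        y = table["label"].to_numpy(dtype=int)
        models[scope] = fit_naive_bayes(
            X, y, scope, n_bins=cfg.n_bins, smoothing=cfg.smoothing,
            prior=cfg.prior,
        )
    return models["pep"], models["pro"]


def compute_peptide_features(hit, bundle: io.DatasetBundle, report):
    """DR / SA / PC / SC for one hit; unavailable values become NaN."""
    cfg = bundle.config
    feats = dict.fromkeys(PEPTIDE_FEATURES, np.nan)
    trackset = bundle.tracks
    for name, kind, func, kwargs in (
        ("DR", "disorder", disorder_score, {"binarize_at": cfg.disorder_binarize}),
        ("SA", "rsa", accessibility_score, {"rsa_cutoff": cfg.rsa_cutoff}),
        ("PC", "conservation", conservation_score, {}),
    ):
        track = trackset.get(kind, {}).get(hit.protein_id)
        if track is None:
            report.count(f"missing_track_{kind}")
            continue
        try:
            feats[name] = func(hit, track, **kwargs)
        except (EmptySignificantSet, TrackMismatch) as exc:
            report.count(f"feature_error_{name}")
            report.log(f"{name} {hit.protein_id}:{hit.start}: {exc}")
    domain = bundle.domains.get(hit.domain_id)
    if domain is not None and bundle.contact_models:
        _, domain_seq = domain
        sc, _model = structural_contact_score(
            domain_seq, hit.window_seq, bundle.contact_models,
            log_messages=report.messages,
        )
        feats["SC"] = sc
    else:
        report.count("missing_domain_seq")
    return feats


class _ProteinFeatureCache:
    """Per-run cache of protein-pair features (many hits share a pair)."""

    def __init__(self, bundle: io.DatasetBundle, report):
        self.bundle = bundle
        self.report = report
        cfg = bundle.config
        self.scorers = {}
        for feat, ns in _NAMESPACE_FEATURES:
            try:
                self.scorers[feat] = TcssScorer(
                    bundle.dag, bundle.annotations, ns,
                    cfg.tcss_cutoffs[ns], cfg.aggregate,
                )
            except PrmPredError as exc:
                report.log(f"semantic similarity unavailable for {ns}: {exc}")
        self.signature_model = None
        if bundle.reference_ppis and bundle.signatures:
            try:
                self.signature_model = fit_signature_model(
                    bundle.reference_ppis, bundle.signatures
                )
            except PrmPredError as exc:
                report.log(f"signature model unavailable: {exc}")
        self._cache = {}

    def features(self, a, b):
        key = (a, b)
        if key in self._cache:
            return self._cache[key]
        cfg = self.bundle.config
        feats = dict.fromkeys(PROTEIN_FEATURES, np.nan)
        for feat, _ns in _NAMESPACE_FEATURES:
            scorer = self.scorers.get(feat)
            if scorer is None:
                continue
            try:
                feats[feat] = scorer.similarity(a, b)
            except MissingAnnotation:
                self.report.count(f"missing_annotation_{feat}")
        try:
            rs = profile_correlations(a, b, self.bundle.panel,
                                      log_messages=self.report.messages)
            feats["EX"] = combine_expression(rs)
        except NoExpressionEvidence:
            self.report.count("missing_expression")
        if self.signature_model is not None:
            try:
                feats["SS"] = signature_score(
                    self.bundle.signatures.get(a, ()),
                    self.bundle.signatures.get(b, ()),
                    self.signature_model, sign=cfg.signature_sign,
                )
            except NoSignatureEvidence:
                self.report.count("missing_signature")
        self._cache[key] = feats
        return feats


class RunReport:
    """Structured per-stage counts and messages for one pipeline run."""

    def __init__(self):
        self.counts = {}
        self.messages = []

    def count(self, key, by=1):
        self.counts[key] = self.counts.get(key, 0) + by

    def log(self, msg):
        self.messages.append(msg)

    def as_text(self):
        lines = ["# run report"]
        for k in sorted(self.counts):
            lines.append(f"{k}\t{self.counts[k]}")
        for m in self.messages:
            lines.append("# " + m)
        return "\n".join(lines) + "\n"


def run_predict_pipeline(bundle: io.DatasetBundle, pep_model=None,
                         pro_model=None):
    """Execute the full prediction workflow on a loaded bundle.

    Returns ``(records, pair_scores, report)``: per-site
    :class:`PredictionRecord` objects ordered deterministically, the
    per-protein-pair aggregated scores, and the run report.
    """
    cfg = bundle.config
    report = RunReport()
    if pep_model is None or pro_model is None:
        pep_model, pro_model = train_models(bundle)

    dists = {p.id: score_distribution(p, cfg.granularity) for p in bundle.pwms}
    scan_log = ScanLog()
    hits = scan_proteome(
        bundle.pwms, dists, bundle.proteome, cfg.pvalue_threshold,
        ic_cutoff=cfg.ic_cutoff, log=scan_log,
    )
    report.count("windows_evaluated", scan_log.windows_evaluated)
    report.count("windows_skipped_ambiguous", scan_log.windows_skipped_ambiguous)
    report.count("hits", len(hits))
    for m in scan_log.messages:
        report.log(m)

    pro_cache = _ProteinFeatureCache(bundle, report)
    records = []
    for hit in hits:
        bait = bundle.domains.get(hit.domain_id, (hit.domain_id, ""))[0]
        pep_feats = compute_peptide_features(hit, bundle, report)
        pro_feats = pro_cache.features(bait, hit.protein_id)
        cand_id = f"{bait}|{hit.protein_id}|{hit.pwm_id}:{hit.start}-{hit.end}"
        x_pep = np.array([pep_feats[f] for f in PEPTIDE_FEATURES])
        x_pro = np.array([pro_feats[f] for f in PROTEIN_FEATURES])
        p_pep = p_pro = None
        try:
            p_pep = class_posterior(pep_model, x_pep)
        except NoEvidence:
            report.count("no_peptide_evidence")
        try:
            p_pro = class_posterior(pro_model, x_pro)
        except NoEvidence:
            report.count("no_protein_evidence")
        if p_pep is None and p_pro is None:
            report.count("excluded_no_evidence")
            report.log(f"candidate {cand_id} excluded: no evidence in either scope")
            continue
        if p_pep is None:
            combined = p_pro
        elif p_pro is None:
            combined = p_pep
        else:
            combined = combine_posteriors(p_pep, p_pro, cfg.prior)
        features = {**pep_feats, **pro_feats}
        records.append(
            PredictionRecord(
                candidate_id=cand_id, p_pep=p_pep, p_pro=p_pro,
                combined=combined, features=features,
                decision=combined >= cfg.decision_threshold,
            )
        )
    records.sort(key=lambda r: (-r.combined, r.candidate_id))
    report.count("candidates_scored", len(records))
    report.count("missing_any_feature",
                 sum(any(np.isnan(v) for v in r.features.values())
                     for r in records))
    report.count("predictions_above_threshold",
                 sum(r.decision for r in records))
    pair_scores = bayes.aggregate_pairs(records, how="max")
    report.count("unique_pairs", len(pair_scores))
    report.count("pairs_above_threshold",
                 sum(v >= cfg.decision_threshold for v in pair_scores.values()))
    return records, pair_scores, report


PREDICTION_COLUMNS = (
    ("candidate_id",) + PEPTIDE_FEATURES + PROTEIN_FEATURES
    + ("p_pep", "p_pro", "combined", "decision")
)


def write_prediction_table(records, path):
    """Stable tab-separated output: header, floats at 6 decimals, sorted
    by combined probability descending with id as tie-break."""
    ordered = sorted(records, key=lambda r: (-r.combined, r.candidate_id))

    def fmt(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "NA"
        return f"{v:.6f}"

    with open(path, "w") as fh:
        fh.write("# " + "\t".join(PREDICTION_COLUMNS) + "\n")
        for r in ordered:
            cells = [r.candidate_id]
            cells += [fmt(r.features.get(f)) for f in PEPTIDE_FEATURES]
            cells += [fmt(r.features.get(f)) for f in PROTEIN_FEATURES]
            cells += [fmt(r.p_pep), fmt(r.p_pro), fmt(r.combined),
                      "1" if r.decision else "0"]
            fh.write("\t".join(cells) + "\n")
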