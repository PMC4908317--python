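"""Readers and writers for the pipeline's file formats.

All tabular files are tab-separated with ``#``-prefixed header/metadata
lines.  Sequence data is FASTA (via Biopython), the ontology is a minimal
OBO subset (via ``obonet``), expression profiles are genes x conditions
matrices with a manifest, and trained classifiers serialize to JSON.
Parse errors name the offending file and line.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .bayes import BinnedNaiveBayes
from .errors import ConfigError, DuplicateId, ParseError
from .ontology import AnnotationSet, GoDag
from .peptide_features import ResidueTrack, contact_model_from_map
from .protein_features import ExpressionPanel
from .pwm import Pwm, pwm_from_text, pwm_to_text
from .scan import PeptideHit

DEFAULT_EXCLUDED_EVIDENCE = ("IEA",)


# --- sequences -----------------------------------------------------------

def read_fasta(path):
    """FASTA -> list of (id, sequence); duplicate ids are an error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateId(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records, path):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_peptide_list(path):
    """Binding peptides: FASTA or one peptide per line (``#`` comments)."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith(">"):
        return [seq for _, seq in read_fasta(path)]
    peptides = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not line.isalpha():
            raise ParseError(f"{path}:{ln}: invalid peptide {line!r}")
        peptides.append(line.upper())
    return peptides


def write_pwm(pwm: Pwm, path):
    with open(path, "w") as fh:
        fh.write(pwm_to_text(pwm))


def read_pwm(path) -> Pwm:
    with open(path) as fh:
        return pwm_from_text(fh.read())


# --- residue tracks ------------------------------------------------------

def write_tracks(tracks: dict, path):
    """``tracks``: kind -> protein_id -> array of per-residue values.
    Combined format with a kind column."""
    with open(path, "w") as fh:
        fh.write("# kind\tprotein_id\tposition\tvalue\n")
        for kind in sorted(tracks):
            for pid in sorted(tracks[kind]):
                for pos, v in enumerate(tracks[kind][pid], start=1):
                    fh.write(f"{kind}\t{pid}\t{pos}\t{v:.6f}\n")


def read_tracks(path):
    """Returns kind -> protein_id -> ResidueTrack."""
    raw = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            kind, pid, pos, val = parts
            try:
                pos, val = int(pos), float(val)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
            raw.setdefault(kind, {}).setdefault(pid, {})[pos] = val
    out = {}
    for kind, per_protein in raw.items():
        out[kind] = {}
        for pid, vals in per_protein.items():
            length = max(vals)
            if sorted(vals) != list(range(1, length + 1)):
                raise ParseError(
                    f"{path}: track {kind}/{pid} has gaps in positions"
                )
            out[kind][pid] = ResidueTrack(
                protein_id=pid, kind=kind,
                values=tuple(vals[p] for p in range(1, length + 1)),
            )
    return out


# --- contact models ------------------------------------------------------

def write_contact_models(models, tsv_path, fasta_path):
    chains = []
    with open(tsv_path, "w") as fh:
        fh.write("# model_id\tdomain_index\tpeptide_index\tarea\n")
        for m in models:
            for di, pi, c in m.contacts:
                fh.write(f"{m.model_id}\t{di}\t{pi}\t{c:.6f}\n")
            chains.append((f"{m.model_id}|domain", m.domain_seq))
            chains.append((f"{m.model_id}|peptide", m.peptide_seq))
    write_fasta(chains, fasta_path)


def read_contact_models(tsv_path, fasta_path):
    seqs = dict(read_fasta(fasta_path))
    raw = {}
    with open(tsv_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{tsv_path}:{ln}: expected 4 columns")
            mid, di, pi, area = parts
            try:
                raw.setdefault(mid, []).append((int(di), int(pi), float(area)))
            except ValueError as exc:
                raise ParseError(f"{tsv_path}:{ln}: {exc}") from None
    models = []
    for mid in sorted(raw):
        dom = seqs.get(f"{mid}|domain")
        pep = seqs.get(f"{mid}|peptide")
        if dom is None or pep is None:
            raise ParseError(f"{fasta_path}: missing chains for model {mid}")
        # stored areas are already normalized; renormalization is a no-op
        # when the maximum is 1 but repairs un-normalized inputs
        models.append(contact_model_from_map(raw[mid], dom, pep, model_id=mid))
    return models


# --- ontology and annotations -------------------------------------------

def write_obo(dag: GoDag, path):
    """Minimal OBO subset: id, name, namespace, is_a."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic-fixture\n")
        for term in sorted(dag.graph.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {dag.namespace[term]}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {parent}\n")


def read_obo(path) -> GoDag:
    import obonet

    g = obonet.read_obo(str(path))
    terms = list(g.nodes)
    ns = {t: g.nodes[t].get("namespace", "unknown") for t in terms}
    edges = []
    for child, parent, key in g.edges(keys=True):
        if key in ("is_a", "part_of"):
            edges.append((child, parent))
    return GoDag.from_edges(terms, edges, ns)


def write_annotations(annotations: AnnotationSet, dag: GoDag, path,
                      evidence_code: str = "EXP"):
    with open(path, "w") as fh:
        fh.write("# protein_id\tterm_id\tevidence_code\tnamespace\n")
        for protein in sorted(annotations.by_protein):
            for term in sorted(annotations.by_protein[protein]):
                fh.write(
                    f"{protein}\t{term}\t{evidence_code}\t{dag.namespace[term]}\n"
                )


def read_annotations(path, exclude_evidence=DEFAULT_EXCLUDED_EVIDENCE) -> AnnotationSet:
    """GAF-like annotations; evidence codes in ``exclude_evidence``
    (default: computationally inferred, IEA) are dropped."""
    out = AnnotationSet()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 columns")
            protein, term, evidence = parts[0], parts[1], parts[2]
            if evidence in exclude_evidence:
                continue
            out.add(protein, term)
    return out


# --- expression ----------------------------------------------------------

def write_expression_panel(panel: ExpressionPanel, out_dir, manifest_path):
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.dirname(os.path.abspath(manifest_path))
    with open(manifest_path, "w") as fh:
        fh.write("# profile_id\tpath\n")
        for pid, df in panel.profiles:
            fpath = os.path.join(out_dir, f"{pid}.tsv")
            df.to_csv(fpath, sep="\t", index_label="gene")
            fh.write(f"{pid}\t{os.path.relpath(fpath, base)}\n")


def read_expression_panel(manifest_path) -> ExpressionPanel:
    base = os.path.dirname(os.path.abspath(manifest_path))
    profiles = []
    with open(manifest_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{manifest_path}:{ln}: expected 2 columns")
            pid, rel = parts
            fpath = os.path.join(base, rel)
            if not os.path.exists(fpath):
                raise FileNotFoundError(f"{manifest_path}:{ln}: {fpath} missing")
            df = pd.read_csv(fpath, sep="\t", index_col=0)
            profiles.append((pid, df))
    return ExpressionPanel(profiles=profiles)


# --- signatures and reference interactions -------------------------------

def write_signatures(signatures: dict, path):
    with open(path, "w") as fh:
        fh.write("# protein_id\tsignature_id\n")
        for protein in sorted(signatures):
            for sig in sorted(signatures[protein]):
                fh.write(f"{protein}\t{sig}\n")


def read_signatures(path) -> dict:
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_pairs(pairs, path):
    with open(path, "w") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_pairs(path):
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            out.append((parts[0], parts[1]))
    return out


# --- hit and prediction tables ------------------------------------------

HIT_COLUMNS = ("protein_id", "pwm_id", "domain_id", "start", "end",
               "window_seq", "score", "pvalue", "significant_positions")


def write_hit_table(hits, path):
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            sig = ",".join(str(p) for p in h.significant_protein_positions)
            fh.write(
                f"{h.protein_id}\t{h.pwm_id}\t{h.domain_id}\t{h.start}\t"
                f"{h.end}\t{h.window_seq}\t{h.score:.6f}\t{h.pvalue:.6g}\t{sig}\n"
            )


def read_hit_table(path):
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(HIT_COLUMNS):
                raise ParseError(f"{path}:{ln}: expected {len(HIT_COLUMNS)} columns")
            sig = tuple(int(x) for x in parts[8].split(",")) if parts[8] else ()
            hits.append(
                PeptideHit(
                    protein_id=parts[0], pwm_id=parts[1], domain_id=parts[2],
                    start=int(parts[3]), end=int(parts[4]), window_seq=parts[5],
                    score=float(parts[6]), pvalue=float(parts[7]),
                    significant_protein_positions=sig,
                )
            )
    return hits


# --- classifier serialization -------------------------------------------

def save_model(model: BinnedNaiveBayes, path):
    payload = {
        "format": "prmpred-nb/1",
        "scope": getattr(model, "scope_", None),
        "feature_names": list(getattr(model, "feature_names_", [])),
        "n_bins": model.n_bins,
        "smoothing": model.smoothing,
        "prior": model.prior_,
        "bin_edges": [list(map(float, e)) for e in model.bin_edges_],
        "likelihoods": model.likelihoods_.tolist(),
        "counts": model.counts_.tolist(),
        "feature_bounds": [
            list(b) if b is not None else None
            for b in (model.feature_bounds or [])
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> BinnedNaiveBayes:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "prmpred-nb/1":
        raise ParseError(f"{path}: unknown model format")
    bounds = [tuple(b) if b is not None else None
              for b in payload["feature_bounds"]] or None
    model = BinnedNaiveBayes(
        n_bins=payload["n_bins"], smoothing=payload["smoothing"],
        prior=payload["prior"], feature_bounds=bounds,
    )
    model.n_features_in_ = len(payload["bin_edges"])
    model.classes_ = np.array([0, 1])
    model.bin_edges_ = [np.asarray(e) for e in payload["bin_edges"]]
    model.likelihoods_ = np.asarray(payload["likelihoods"])
    model.counts_ = np.asarray(payload["counts"])
    model.prior_ = float(payload["prior"])
    model.scope_ = payload.get("scope")
    model.feature_names_ = tuple(payload.get("feature_names", ()))
    return model


# --- configuration / bundle ---------------------------------------------

@dataclass
class RunConfig:
    """Thresholds and cutoffs governing a pipeline run, with the
    defaults used throughout: scan p-value 1e-5, RSA exposure cutoff
    0.25, per-namespace similarity cutoffs 2.4 / 3.5 / 3.3, decision
    threshold 0.9."""

    pvalue_threshold: float = 1e-5
    rsa_cutoff: float = 0.25
    disorder_binarize: float = 0.5
    ic_cutoff: float = 1.0
    tcss_cutoffs: dict = field(default_factory=lambda: {
        "cellular_component": 2.4,
        "biological_process": 3.5,
        "molecular_function": 3.3,
    })
    decision_threshold: float = 0.9
    prior: float = 0.5
    n_bins: int = 10
    smoothing: float = 1.0
    pseudocount: float = 0.05
    granularity: float = 1e-3
    signature_sign: int = 1
    aggregate: str = "max"
    seed: int = 0

    def validate(self):
        if not (0 < self.pvalue_threshold <= 1):
            raise ConfigError("pvalue_threshold must be in (0, 1]")
        if not (0 < self.decision_threshold < 1):
            raise ConfigError("decision_threshold must be in (0, 1)")
        if not (0 < self.prior < 1):
            raise ConfigError("prior must be in (0, 1)")
        for ns, c in self.tcss_cutoffs.items():
            if c <= 0:
                raise ConfigError(f"tcss cutoff for {ns} must be > 0")
        if not (0 <= self.rsa_cutoff <= 1):
            raise ConfigError("rsa_cutoff must be in [0, 1]")
        if self.signature_sign not in (1, -1):
            raise ConfigError("signature_sign must be +1 or -1")
        return self


@dataclass
class DatasetBundle:
    """All inputs of one pipeline run, loaded and validated."""

    proteome: list                  # (protein_id, sequence)
    pwms: list                      # Pwm
    domains: dict                   # domain_id -> (protein_id, domain_seq)
    tracks: dict                    # kind -> protein_id -> ResidueTrack
    contact_models: list
    dag: GoDag
    annotations: AnnotationSet
    panel: ExpressionPanel
    signatures: dict
    reference_ppis: list
    labeled_pep: pd.DataFrame | None
    labeled_pro: pd.DataFrame | None
    config: RunConfig


def read_domains(path):
    """Domain table: domain_id, parent protein_id, domain sequence."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 columns")
            out[parts[0]] = (parts[1], parts[2])
    return out


def write_domains(domains: dict, path):
    with open(path, "w") as fh:
        fh.write("# domain_id\tprotein_id\tdomain_seq\n")
        for did in sorted(domains):
            pid, seq = domains[did]
            fh.write(f"{did}\t{pid}\t{seq}\n")


def load_dataset_bundle(config_path) -> DatasetBundle:
    """Load a YAML config naming every input file (paths relative to the
    config's directory) and parse them all, reporting missing files with
    their paths and malformed records with line numbers."""
    base = os.path.dirname(os.path.abspath(config_path))
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "inputs" not in raw:
        raise ConfigError(f"{config_path}: missing 'inputs' section")
    inputs = raw["inputs"]

    def path_of(key, required=True):
        rel = inputs.get(key)
        if rel is None:
            if required:
                raise ConfigError(f"{config_path}: missing input '{key}'")
            return None
        p = os.path.join(base, rel)
        if not os.path.exists(p):
            raise FileNotFoundError(f"{config_path}: input '{key}' -> {p}")
        return p

    cfg = RunConfig(**raw.get("run", {})).validate()
    proteome = read_fasta(path_of("proteome"))
    pwm_dir = path_of("pwm_dir")
    pwms = [read_pwm(os.path.join(pwm_dir, f))
            for f in sorted(os.listdir(pwm_dir)) if f.endswith(".pwm")]
    bundle = DatasetBundle(
        proteome=proteome,
        pwms=pwms,
        domains=read_domains(path_of("domains")),
        tracks=read_tracks(path_of("tracks")),
        contact_models=read_contact_models(
            path_of("contact_map"), path_of("contact_chains")
        ),
        dag=read_obo(path_of("ontology")),
        annotations=read_annotations(path_of("annotations")),
        panel=read_expression_panel(path_of("expression_manifest")),
        signatures=read_signatures(path_of("signatures")),
        reference_ppis=read_pairs(path_of("reference_ppis")),
        labeled_pep=_maybe_table(path_of("labeled_pep", required=False)),
        labeled_pro=_maybe_table(path_of("labeled_pro", required=False)),
        config=cfg,
    )
    return bundle


def _maybe_table(path):
    if path is None:
        return None
    return pd.read_csv(path, sep="\t", comment=None)


# --- fixture bundle ------------------------------------------------------

def write_fixture_bundle(spec, out_dir, missingness: float = 0.0,
                         n_labeled_per_class: int = 400) -> str:
    """Write a complete synthetic input bundle (all pipeline inputs plus
    planted-truth tables) and return the path of its config file.

    The positive protein pairs used for the protein-feature inputs are
    the (domain-carrier, target) pairs implied by the planted sites, so
    the planted interactions look interacting on every evidence channel;
    an equal number of unplanted (carrier, target) pairs serve as
    negatives.
    """
    from . import synthetic
    from .pwm import build_pwm

    os.makedirs(out_dir, exist_ok=True)
    proteome, truth = synthetic.generate_proteome_with_motifs(spec)
    write_fasta(proteome, os.path.join(out_dir, "proteome.fasta"))
    truth.to_csv(os.path.join(out_dir, "planted_truth.tsv"), sep="\t", index=False)

    peptides = synthetic.generate_binding_peptides(spec)
    pwm_dir = os.path.join(out_dir, "pwms")
    os.makedirs(pwm_dir, exist_ok=True)
    domain_of = {m.pwm_id: m.domain_id for m in spec.motifs}
    for pwm_id, peps in peptides.items():
        with open(os.path.join(pwm_dir, f"{pwm_id}.peptides.txt"), "w") as fh:
            fh.write("\n".join(peps) + "\n")
        pwm = build_pwm(peps, "uniform", id=pwm_id, domain_id=domain_of[pwm_id])
        write_pwm(pwm, os.path.join(pwm_dir, f"{pwm_id}.pwm"))

    tracks = synthetic.generate_residue_tracks(spec, proteome, truth)
    write_tracks(tracks, os.path.join(out_dir, "tracks.tsv"))

    models = synthetic.generate_contact_models(spec)
    write_contact_models(
        models,
        os.path.join(out_dir, "contact_map.tsv"),
        os.path.join(out_dir, "contact_chains.fasta"),
    )

    # interaction universe implied by the planted sites
    bait_of = {m.domain_id: f"bait_{m.domain_id}" for m in spec.motifs}
    pos_pairs = sorted(
        {(bait_of[row.domain_id], row.protein_id) for row in truth.itertuples()}
    )
    planted_targets = {d: {b for a, b in pos_pairs if a == bait_of[d]}
                       for d in bait_of}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 99]))
    neg_pairs = []
    all_targets = [pid for pid, _ in proteome]
    domains_cycle = sorted(bait_of)
    while len(neg_pairs) < len(pos_pairs):
        d = domains_cycle[len(neg_pairs) % len(domains_cycle)]
        t = all_targets[int(rng.integers(len(all_targets)))]
        if t in planted_targets[d] or (bait_of[d], t) in neg_pairs:
            continue
        neg_pairs.append((bait_of[d], t))

    dag, annotations = synthetic.generate_go_dag_and_annotations(
        spec, pos_pairs, neg_pairs
    )
    write_obo(dag, os.path.join(out_dir, "ontology.obo"))
    write_annotations(annotations, dag, os.path.join(out_dir, "annotations.tsv"))

    panel = synthetic.generate_expression_panel(spec, pos_pairs, neg_pairs)
    expr_dir = os.path.join(out_dir, "expression")
    write_expression_panel(panel, expr_dir,
                           os.path.join(out_dir, "expression_manifest.tsv"))

    signatures, reference = synthetic.generate_signature_data(
        spec, pos_pairs, neg_pairs
    )
    write_signatures(signatures, os.path.join(out_dir, "signatures.tsv"))
    write_pairs(reference, os.path.join(out_dir, "reference_ppis.tsv"))

    domains = {
        m.domain_id: (bait_of[m.domain_id], models[i].domain_seq)
        for i, m in enumerate(spec.motifs)
    }
    write_domains(domains, os.path.join(out_dir, "domains.tsv"))

    labeled = synthetic.generate_labeled_pairs(
        spec, n_per_class=n_labeled_per_class, missingness=missingness
    )
    pep_cols = ["pair_id", "DR", "SA", "PC", "SC", "label"]
    pro_cols = ["pair_id", "CC", "BP", "MF", "EX", "SS", "label"]
    labeled[pep_cols].to_csv(os.path.join(out_dir, "labeled_pep.tsv"),
                             sep="\t", index=False)
    labeled[pro_cols].to_csv(os.path.join(out_dir, "labeled_pro.tsv"),
                             sep="\t", index=False)

    config = {
        "inputs": {
            "proteome": "proteome.fasta",
            "pwm_dir": "pwms",
            "domains": "domains.tsv",
            "tracks": "tracks.tsv",
            "contact_map": "contact_map.tsv",
            "contact_chains": "contact_chains.fasta",
            "ontology": "ontology.obo",
            "annotations": "annotations.tsv",
            "expression_manifest": "expression_manifest.tsv",
            "signatures": "signatures.tsv",
            "reference_ppis": "reference_ppis.tsv",
            "labeled_pep": "labeled_pep.tsv",
            "labeled_pro": "labeled_pro.tsv",
        },
        "run": {"seed": spec.seed},
    }
    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
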