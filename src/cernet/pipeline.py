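"""End-to-end orchestration: expression matrices in, ceRNA network out.

Stage order mirrors the analysis chain: RNA differential expression ->
co-expression network -> miRNA differential expression -> target scanning
+ interaction map -> ceRNA triplet inference -> enrichment.  Every
intermediate is written as TSV next to a serialized copy of the effective
configuration and a JSON run log with the node/edge/feature counts of each
stage.  A fixed seed makes the whole bundle byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .coexpr import (adjacency, build_lncrna_pcg_network, correlation_matrix,
                     extract_subnetwork, network_to_frame, pick_soft_power)
from .cerna import (build_cerna_network, cerna_network_to_frame,
                    extract_anchor_motifs, infer_triplets)
from .datatypes import triplets_to_frame
from .diffexpr import de_test_counts, de_test_tpm, filter_low_expression, size_factors
from .enrich import gsea_preranked, hypergeom_enrich
from .errors import CernetError, ParseError, StageError
from .synthdata import counts_to_tpm
from .targets import ScanParams, build_interaction_map, scan_many


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one pipeline run."""

    rna_counts: str = "counts_rna.tsv"
    mirna_counts: str = "counts_mirna.tsv"
    biotypes: str = "biotypes.tsv"
    groups: str = "groups.tsv"
    lncrna_fasta: str = "lncrna.fa"
    utr3_fasta: str = "utr3.fa"
    mirna_fasta: str = "mirna.fa"
    whitelist: str = "whitelist.tsv"
    gmt: str = "gene_sets.gmt"
    out_dir: str = "results"

    alpha: float = 0.05
    lfc_min: float = 2.0
    min_mean: float = 1.0
    adjacency_threshold: float = 0.02
    soft_power: int | str = "auto"   # integer or "auto"
    scan_min_score: float = 140.0
    require_whitelist: bool = True
    alpha_corr: float = 0.05
    anchors: list = field(default_factory=list)
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def for_fixture(cls, fixture_dir, out_dir, **overrides) -> "PipelineConfig":
        """Config pointing at a :func:`cernet.synthdata.write_fixture` layout."""
        from .synthdata import FIXTURE_FILES
        d = Path(fixture_dir)
        paths = {k: str(d / v) for k, v in FIXTURE_FILES.items()
                 if k in {f.name for f in dataclasses.fields(cls)}}
        return cls(out_dir=str(out_dir), **paths, **overrides)

    def validate(self) -> None:
        for name in ("alpha", "alpha_corr"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.lfc_min < 0 or self.min_mean < 0 or self.scan_min_score < 0:
            raise ValueError("lfc_min, min_mean and scan_min_score must be >= 0")
        if self.adjacency_threshold < 0:
            raise ValueError("adjacency_threshold must be >= 0")
        if self.soft_power != "auto" and int(self.soft_power) < 1:
            raise ValueError("soft_power must be 'auto' or an integer >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    out_dir: Path
    log: dict
    de_rna: pd.DataFrame
    de_mirna: pd.DataFrame
    triplets: list
    files: dict


def _require_file(path, stage: str, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage, writing all intermediates under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict = {}
    logd: dict = {"version": __version__, "seed": config.seed,
                  "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                                 if not isinstance(v, str) or k == "soft_power"},
                  "stages": {}}

    def _write(name, frame: pd.DataFrame, index=False):
        path = out / name
        frame.to_csv(path, sep="\t", index=index)
        files[name] = path
        return path

    # ---- stage: load RNA inputs ------------------------------------------
    stage = "load_rna"
    try:
        counts = cio.read_expression_tsv(
            _require_file(config.rna_counts, stage, "RNA count matrix"))
        biotypes = cio.read_series_tsv(
            _require_file(config.biotypes, stage, "biotype table"), "biotype")
        groups = cio.read_series_tsv(
            _require_file(config.groups, stage, "group table"), "group")
    except (ParseError, StageError):
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: RNA differential expression ------------------------------
    stage = "rna_de"
    try:
        filtered = filter_low_expression(counts, config.min_mean)
        sf = size_factors(filtered)
        de_rna = de_test_counts(filtered, groups, config.alpha, config.lfc_min)
        de_set = de_rna.loc[de_rna["is_de"], "feature_id"]
        bt = biotypes.reindex(filtered.index)
        de_lnc = set(de_set[bt.loc[de_set] == "lncRNA"])
        de_pcg = set(de_set[bt.loc[de_set] == "mRNA"])
        _write("de_rna.tsv", de_rna)
        logd["stages"][stage] = {
            "n_features_in": int(counts.shape[0]),
            "n_after_filter": int(filtered.shape[0]),
            "n_de_mrna": len(de_pcg), "n_de_lncrna": len(de_lnc)}
    except CernetError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: co-expression network ------------------------------------
    stage = "coexpr"
    try:
        log_norm = np.log2(filtered / sf + 1.0)
        _write("rna_log_norm.tsv", log_norm.rename_axis("feature_id"), index=True)
        corr = correlation_matrix(log_norm)
        power = (pick_soft_power(corr) if config.soft_power == "auto"
                 else int(config.soft_power))
        adj = adjacency(corr, power)
        net = build_lncrna_pcg_network(adj, biotypes,
                                       config.adjacency_threshold, corr)
        _write("coexpr_edges.tsv", network_to_frame(net))
        sub = (extract_subnetwork(net, de_lnc) if de_lnc
               else net.__class__())
        _write("subnet_edges.tsv", network_to_frame(sub))
        logd["stages"][stage] = {
            "soft_power": int(power),
            "n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges(),
            "subnet_nodes": sub.number_of_nodes(),
            "subnet_edges": sub.number_of_edges()}
    except CernetError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: miRNA differential expression ----------------------------
    stage = "mirna_de"
    try:
        mir_counts = cio.read_expression_tsv(
            _require_file(config.mirna_counts, stage,
                          "miRNA count matrix (required for the target/ceRNA "
                          "stages)"))
        tpm = counts_to_tpm(mir_counts)
        _write("tpm_mirna.tsv", tpm.rename_axis("feature_id"), index=True)
        de_mirna = de_test_tpm(tpm, groups, config.alpha, config.lfc_min)
        de_mir = set(de_mirna.loc[de_mirna["is_de"], "feature_id"])
        _write("de_mirna.tsv", de_mirna)
        logd["stages"][stage] = {"n_mirna": int(tpm.shape[0]),
                                 "n_de_mirna": len(de_mir)}
    except CernetError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: target scanning + interaction map ------------------------
    stage = "targets"
    try:
        mir_seqs = cio.read_fasta(_require_file(config.mirna_fasta, stage,
                                                "mature miRNA FASTA"))
        lnc_seqs = cio.read_fasta(_require_file(config.lncrna_fasta, stage,
                                                "lncRNA FASTA"))
        utr_seqs = cio.read_fasta(_require_file(config.utr3_fasta, stage,
                                                "3'UTR FASTA"))
        # scanning is restricted to the DE universe the ceRNA stage uses
        mir_sel = {m: s for m, s in mir_seqs.items() if m in de_mir}
        tx_sel = {t: s for t, s in lnc_seqs.items() if t in de_lnc}
        tx_sel.update({t: s for t, s in utr_seqs.items() if t in de_pcg})
        params = ScanParams(min_score=config.scan_min_score)
        hits = scan_many(mir_sel, tx_sel, params)
        hits_frame = pd.DataFrame(
            [{"mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
              "start": h.start, "end": h.end, "score": h.score,
              "seed_class": h.seed_class} for h in hits],
            columns=["mirna_id", "transcript_id", "start", "end",
                     "score", "seed_class"])
        _write("target_hits.tsv", hits_frame)
        wl = cio.read_whitelist(_require_file(config.whitelist, stage,
                                              "interaction whitelist"))
        known = set(mir_seqs) | set(lnc_seqs) | set(utr_seqs)
        imap = build_interaction_map(hits, wl, config.require_whitelist,
                                     known_ids=known)
        map_frame = pd.DataFrame(
            [{"mirna_id": m, "target_id": t, "evidence": tag}
             for (m, t), tag in sorted(imap.pairs().items())],
            columns=["mirna_id", "target_id", "evidence"])
        _write("interaction_map.tsv", map_frame)
        logd["stages"][stage] = {"n_hits": len(hits), "n_map_pairs": len(imap)}
    except CernetError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: ceRNA network --------------------------------------------
    stage = "cerna"
    try:
        if list(tpm.columns) != list(filtered.columns):
            raise StageError(stage, "RNA and miRNA matrices must share the "
                                    "same sample columns in the same order")
        expr_all = pd.concat([log_norm, np.log2(tpm + 1.0)])
        triplets = infer_triplets(imap, expr_all, de_lnc, de_pcg, de_mir,
                                  alpha_corr=config.alpha_corr,
                                  log_transform=False)
        _write("triplets.tsv", triplets_to_frame(triplets))
        cnet = build_cerna_network(triplets)
        _write("cerna_edges.tsv", cerna_network_to_frame(cnet))
        for anchor in config.anchors:
            motifs = extract_anchor_motifs(cnet, anchor, triplets=triplets)
            _write(f"motifs_{anchor}.tsv", triplets_to_frame(motifs))
        logd["stages"][stage] = {
            "n_triplets": len(triplets),
            "n_lncrna": sum(1 for _, d in cnet.nodes(data=True)
                            if d["role"] == "lncRNA"),
            "n_mirna": sum(1 for _, d in cnet.nodes(data=True)
                           if d["role"] == "miRNA"),
            "n_mrna": sum(1 for _, d in cnet.nodes(data=True)
                          if d["role"] == "mRNA"),
            "n_edges": cnet.number_of_edges()}
    except CernetError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: enrichment ------------------------------------------------
    stage = "enrich"
    try:
        gmt = cio.read_gmt(_require_file(config.gmt, stage, "GMT gene sets"))
        bt = biotypes.reindex(filtered.index)
        pcg_universe = set(filtered.index[bt == "mRNA"])
        hyper = hypergeom_enrich(de_pcg & pcg_universe, pcg_universe, gmt)
        _write("enrich_hyper.tsv", hyper)
        ranked = de_rna.loc[sorted(pcg_universe), "log2fc"]
        gsea = gsea_preranked(ranked, gmt, n_perm=config.n_perm,
                              seed=config.seed)
        _write("enrich_gsea.tsv", gsea)
        logd["stages"][stage] = {"n_sets": len(gmt),
                                 "n_hyper_rows": int(hyper.shape[0]),
                                 "n_gsea_rows": int(gsea.shape[0])}
    except CernetError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    config.to_yaml(out / "config.yaml")
    files["config.yaml"] = out / "config.yaml"
    with open(out / "run_log.json", "w") as fh:
        json.dump(logd, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files["run_log.json"] = out / "run_log.json"
    return PipelineResult(out, logd, de_rna, de_mirna, triplets, files)
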