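"""End-to-end orchestration of the fertility-transcriptome analysis.

The pipeline mirrors the study design: per-station detection filtering and
two-engine NB differential expression with permutation eFDR, per-station
top-scoring-pair scans with permutation significance, clustering of the
top pair ratios with bootstrap support and hypergeometric enrichment, a
combined analysis of all samples (AI-pregnant vs the rest, on genes
detected at both stations), and optional qPCR validation statistics.

Every stage reads its inputs from, and writes its outputs to, a single run
directory as tab-separated files, so stages are independently re-runnable
and idempotent. All stochastic stages require an explicit seed in the
configuration; missing seeds fail validation before any compute.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .cluster import bootstrap_support, cluster_enrichment, main_split_clusters
from .containers import CountMatrix
from .diffexpr import de_table, consensus_deg, efdr
from .normalize import detection_filter, fpkm, tmm_factors, venn_partition
from .qpcr import concordance, delta_ct, group_ttest_dct, reference_stability_check
from .simulate import SimConfig, simulate_counts, simulate_qpcr
from .tsp import ratio_features, tsp_scan, tsp_permutation_p


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    output_dir: str
    seeds: dict
    alpha: float = 0.01
    cpm_threshold: float = 1.0
    min_detect_samples: int = 6
    efdr_permutations: int = 10_000
    tsp_permutations: int = 5000
    top_k: int = 20
    bootstrap: int = 5000
    epsilon: float = 1.0
    positive_label: str = "AI_PREGNANT"
    simulate: list | None = None
    inputs: dict | None = None
    qpcr_reference: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seeds, dict):
            raise ConfigError("seeds must be a mapping of stage -> integer")
        required = {"efdr", "tsp", "bootstrap"}
        if self.simulate is not None:
            required |= {"simulate", "qpcr"}
        missing = required - set(self.seeds)
        if missing:
            raise ConfigError(f"missing seeds for stochastic stages: {sorted(missing)}")
        for k, v in self.seeds.items():
            if not isinstance(v, int):
                raise ConfigError(f"seed {k!r} must be an integer, got {v!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        for name in ("efdr_permutations", "tsp_permutations", "top_k", "bootstrap"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.simulate is None and self.inputs is None:
            raise ConfigError("either a 'simulate' section or an 'inputs' section is required")
        if self.simulate is not None:
            n_genes = {s.get("n_genes", 2000) for s in self.simulate}
            if len(n_genes) > 1:
                raise ConfigError("all simulated stations must share n_genes")
        if self.inputs is not None:
            for key in ("counts_dir", "sample_table", "gene_lengths"):
                if key not in self.inputs:
                    raise ConfigError(f"inputs section missing {key!r}")
            for key, value in self.inputs.items():
                if key in ("counts_dir", "sample_table", "gene_lengths", "qpcr_table"):
                    if not Path(value).exists():
                        raise ConfigError(f"input path does not exist: {value}")

    @property
    def out(self) -> Path:
        return Path(self.output_dir)


class _Log:
    def __init__(self, path: Path):
        self.path = path

    def __call__(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        with open(self.path, "a") as fh:
            fh.write(f"[{stamp}] {msg}\n")


def _read_run_data(cfg: PipelineConfig):
    """Load counts/samples/lengths from the run directory's cached copies."""
    out = cfg.out
    samples = hio.read_sample_table(out / "samples.tsv")
    paths = [out / "counts" / f"{sid}.counts.tsv" for sid in samples["sample_id"]]
    matrix = hio.read_htseq_counts(paths, list(samples["sample_id"]))
    lengths = hio.read_gene_lengths(out / "gene_lengths.tsv")
    return matrix, samples, lengths


def stage_simulate(cfg: PipelineConfig, log=None) -> None:
    """Generate the synthetic dataset (or copy provided inputs) into the run dir."""
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    log = log or _Log(out / "run.log")
    if cfg.simulate is not None:
        frames, tables, truths = [], [], {}
        lengths = None
        for k, block in enumerate(cfg.simulate):
            conf = SimConfig(**{**block, "seed": cfg.seeds["simulate"] + k})
            conf.group_labels = tuple(conf.group_labels)
            conf.group_sizes = tuple(conf.group_sizes)
            conf.library_size_range = tuple(conf.library_size_range)
            matrix, samp, lens, truth = simulate_counts(conf)
            frames.append(matrix.counts)
            tables.append(samp)
            truths[conf.station] = truth
            if lengths is None:
                lengths = lens
            log(f"simulate: station {conf.station}, seed {conf.seed}, "
                f"{conf.n_genes} genes, groups {conf.group_sizes}")
        counts = pd.concat(frames, axis=1)
        samples = pd.concat(tables, ignore_index=True)
        matrix = CountMatrix(counts)
        hio.write_counts(matrix, out / "counts")
        hio.write_sample_table(samples, out / "samples.tsv")
        hio.write_gene_lengths(lengths, out / "gene_lengths.tsv")
        de_rows = [
            {"station": st, "gene_id": g, "true_log2fc": f}
            for st, tr in truths.items()
            for g, f in tr.de_genes.items()
        ]
        pd.DataFrame(de_rows, columns=["station", "gene_id", "true_log2fc"]).to_csv(
            out / "truth_de.tsv", sep="\t", index=False
        )
        pair_rows = [
            {"station": st, "gene_i": a, "gene_j": b}
            for st, tr in truths.items()
            for a, b in tr.reversal_pairs
        ]
        pd.DataFrame(pair_rows, columns=["station", "gene_i", "gene_j"]).to_csv(
            out / "truth_pairs.tsv", sep="\t", index=False
        )
        # qPCR table from the first station's truth: strongest planted genes
        first = cfg.simulate[0]["station"] if "station" in cfg.simulate[0] else "A"
        truth = truths[first]
        samp = samples[samples["station"] == first]
        targets = sorted(truth.de_genes, key=lambda g: -abs(truth.de_genes[g]))[:6]
        nulls = [
            g
            for g in truth.group_means.index
            if g not in truth.de_genes
            and g not in {x for p in truth.reversal_pairs for x in p}
        ]
        reference = nulls[0]
        qtab = simulate_qpcr(
            truth, samp, targets, reference, seed=cfg.seeds["qpcr"]
        )
        hio.write_qpcr_table(qtab, out / "qpcr.tsv")
        (out / "qpcr_reference.txt").write_text(reference + "\n")
        log(f"simulate: qPCR table for station {first}, reference {reference}, "
            f"targets {targets}")
    else:
        samples = hio.read_sample_table(cfg.inputs["sample_table"])
        paths = [
            Path(cfg.inputs["counts_dir"]) / f"{sid}.counts.tsv"
            for sid in samples["sample_id"]
        ]
        matrix = hio.read_htseq_counts(paths, list(samples["sample_id"]))
        hio.write_counts(matrix, out / "counts")
        hio.write_sample_table(samples, out / "samples.tsv")
        hio.write_gene_lengths(
            hio.read_gene_lengths(cfg.inputs["gene_lengths"]), out / "gene_lengths.tsv"
        )
        if "qpcr_table" in cfg.inputs:
            hio.write_qpcr_table(
                hio.read_qpcr_table(cfg.inputs["qpcr_table"]), out / "qpcr.tsv"
            )
            (out / "qpcr_reference.txt").write_text(
                (cfg.qpcr_reference or "") + "\n"
            )
        log("inputs copied into run directory")


def _station_contrast(samples: pd.DataFrame, station: str, positive: str):
    sub = samples[samples["station"] == station]
    outcomes = list(dict.fromkeys(sub["outcome"]))
    if len(outcomes) != 2:
        raise ValueError(f"station {station}: expected two outcomes, got {outcomes}")
    order = (positive, [o for o in outcomes if o != positive][0]) if positive in outcomes else tuple(outcomes)
    return sub, order


def stage_filter(cfg: PipelineConfig, log=None) -> dict:
    """Per-station detection filter and the station-set (Venn) partition."""
    out = cfg.out
    log = log or _Log(out / "run.log")
    matrix, samples, _ = _read_run_data(cfg)
    stations = list(dict.fromkeys(samples["station"]))
    detected = {}
    for st in stations:
        sids = samples.loc[samples["station"] == st, "sample_id"]
        sub = matrix.subset_samples(list(sids))
        min_samples = min(cfg.min_detect_samples, sub.n_samples)
        genes = detection_filter(sub, cfg.cpm_threshold, min_samples)
        detected[st] = genes
        pd.Series(sorted(genes)).to_csv(
            out / f"detected_{st}.tsv", sep="\t", index=False, header=["gene_id"]
        )
        log(f"filter: station {st}: {len(genes)} genes with CPM > "
            f"{cfg.cpm_threshold} in >= {min_samples} samples")
    venn = {}
    if len(stations) == 2:
        shared, only_a, only_b = venn_partition(*(detected[s] for s in stations))
        venn = {
            "stations": stations,
            "shared": len(shared),
            f"only_{stations[0]}": len(only_a),
            f"only_{stations[1]}": len(only_b),
            "union": len(shared) + len(only_a) + len(only_b),
        }
        (out / "venn.json").write_text(json.dumps(venn, indent=2))
        log(f"filter: venn partition {venn}")
    return {"detected": {k: len(v) for k, v in detected.items()}, "venn": venn}


def _load_detected(cfg: PipelineConfig, station: str) -> list:
    path = cfg.out / f"detected_{station}.tsv"
    return pd.read_csv(path, sep="\t")["gene_id"].tolist()


def stage_de(cfg: PipelineConfig, log=None) -> dict:
    """Two-engine consensus differential expression per station."""
    out = cfg.out
    log = log or _Log(out / "run.log")
    matrix, samples, _ = _read_run_data(cfg)
    summary = {}
    for st in list(dict.fromkeys(samples["station"])):
        sub_samples, order = _station_contrast(samples, st, cfg.positive_label)
        sub = matrix.subset_samples(list(sub_samples["sample_id"])).subset_genes(
            _load_detected(cfg, st)
        )
        res = de_table(sub, sub_samples["outcome"].to_numpy(), cfg.alpha, group_order=order)
        res.to_csv(out / f"de_{st}.tsv", sep="\t", index_label="gene_id")
        degs = consensus_deg(res, cfg.alpha)
        summary[st] = {
            "contrast": list(order),
            "n_genes_tested": int(res.shape[0]),
            "n_consensus_degs": len(degs),
            "degs": sorted(degs),
        }
        log(f"de: station {st}: {len(degs)} consensus DEGs at nominal p <= {cfg.alpha} "
            f"(both engines), contrast {order}")
    return summary


def stage_efdr(cfg: PipelineConfig, log=None) -> dict:
    """Label-permutation empirical FDR of the consensus rule per station."""
    out = cfg.out
    log = log or _Log(out / "run.log")
    matrix, samples, _ = _read_run_data(cfg)
    summary = {}
    for k, st in enumerate(list(dict.fromkeys(samples["station"]))):
        sub_samples, order = _station_contrast(samples, st, cfg.positive_label)
        sub = matrix.subset_samples(list(sub_samples["sample_id"])).subset_genes(
            _load_detected(cfg, st)
        )
        est = efdr(
            sub,
            sub_samples["outcome"].to_numpy(),
            alpha=cfg.alpha,
            n_perm=cfg.efdr_permutations,
            seed=cfg.seeds["efdr"] + k,
            group_order=order,
        )
        rec = {
            "alpha": est.alpha,
            "n_observed": est.n_observed,
            "mean_null_discoveries": est.mean_null_discoveries,
            "efdr": est.efdr,
            "undefined": est.undefined,
            "n_permutations": est.n_permutations,
            "seed": est.seed,
        }
        (out / f"efdr_{st}.json").write_text(json.dumps(rec, indent=2))
        summary[st] = rec
        log(f"efdr: station {st}: {rec}")
    return summary


def _station_fpkm(cfg, matrix, samples, station, genes):
    lengths = hio.read_gene_lengths(cfg.out / "gene_lengths.tsv")
    sids = samples.loc[samples["station"] == station, "sample_id"]
    sub = matrix.subset_samples(list(sids)).subset_genes(genes)
    return fpkm(sub, lengths, tmm_factors(sub))


def stage_tsp(cfg: PipelineConfig, log=None) -> dict:
    """Per-station and combined top-scoring-pair analyses on FPKM."""
    out = cfg.out
    log = log or _Log(out / "run.log")
    matrix, samples, lengths = _read_run_data(cfg)
    stations = list(dict.fromkeys(samples["station"]))
    summary = {}
    for k, st in enumerate(stations):
        sub_samples, order = _station_contrast(samples, st, cfg.positive_label)
        genes = _load_detected(cfg, st)
        expr = _station_fpkm(cfg, matrix, samples, st, genes)
        labels = sub_samples["outcome"].to_numpy()
        scan = tsp_scan(expr, labels, top_k=cfg.top_k, positive=order[0])
        scan.permutation_p = tsp_permutation_p(
            expr, labels, n_perm=cfg.tsp_permutations, seed=cfg.seeds["tsp"] + k,
            positive=order[0],
        )
        scan.n_permutations = cfg.tsp_permutations
        scan.seed = cfg.seeds["tsp"] + k
        scan.to_frame().to_csv(out / f"tsp_{st}.tsv", sep="\t", index=False)
        feats = ratio_features(expr, scan.pairs, cfg.epsilon)
        feats.to_csv(out / f"features_{st}.tsv", sep="\t", index_label="pair")
        summary[st] = _scan_summary(scan)
        log(f"tsp: station {st}: {summary[st]}")
    # combined analysis: all samples, AI-pregnant vs the rest, shared genes
    if len(stations) == 2:
        shared = sorted(
            set(_load_detected(cfg, stations[0])) & set(_load_detected(cfg, stations[1]))
        )
        sub = matrix.subset_genes(shared)
        expr = fpkm(sub, lengths, tmm_factors(sub))
        labels = np.where(
            samples["outcome"].to_numpy() == cfg.positive_label,
            cfg.positive_label,
            "REST",
        )
        scan = tsp_scan(expr, labels, top_k=cfg.top_k, positive=cfg.positive_label)
        scan.permutation_p = tsp_permutation_p(
            expr, labels, n_perm=cfg.tsp_permutations,
            seed=cfg.seeds["tsp"] + len(stations), positive=cfg.positive_label,
        )
        scan.n_permutations = cfg.tsp_permutations
        scan.to_frame().to_csv(out / "tsp_combined.tsv", sep="\t", index=False)
        feats = ratio_features(expr, scan.pairs, cfg.epsilon)
        feats.to_csv(out / "features_combined.tsv", sep="\t", index_label="pair")
        summary["combined"] = _scan_summary(scan)
        log(f"tsp: combined: {summary['combined']}")
    return summary


def _scan_summary(scan) -> dict:
    return {
        "n_genes": scan.n_genes,
        "n_pairs_evaluated": scan.n_pairs_evaluated,
        "max_delta": scan.max_delta,
        "n_pairs_at_max": scan.n_pairs_at_max,
        "permutation_p": scan.permutation_p,
        "top_pairs": [
            [p.gene_i, p.gene_j, p.delta, p.gamma] for p in scan.pairs[:5]
        ],
    }


def stage_cluster(cfg: PipelineConfig, log=None) -> dict:
    """Bootstrap-supported clustering of pair-ratio features + enrichment."""
    out = cfg.out
    log = log or _Log(out / "run.log")
    samples = hio.read_sample_table(out / "samples.tsv")
    summary = {}
    blocks = [f for f in ("A", "B", "combined") if (out / f"features_{f}.tsv").exists()]
    blocks = blocks or [
        p.stem.replace("features_", "") for p in out.glob("features_*.tsv")
    ]
    for k, name in enumerate(blocks):
        feats = pd.read_csv(out / f"features_{name}.tsv", sep="\t", index_col="pair")
        dend = bootstrap_support(
            feats, n_boot=cfg.bootstrap, seed=cfg.seeds["bootstrap"] + k
        )
        (out / f"dendrogram_{name}.nwk").write_text(dend.to_newick())
        positives = set(
            samples.loc[samples["outcome"] == cfg.positive_label, "sample_id"]
        ) & set(feats.columns)
        n_total = feats.shape[1]
        main_split = main_split_clusters(dend)
        rows = []
        for c in main_split:
            rows.append(
                {
                    "cluster": "|".join(sorted(c)),
                    "size": len(c),
                    "n_positive": len(c & positives),
                    "bp": dend.bootstrap_proportion.get(c),
                    "enrichment_p": cluster_enrichment(c, positives, n_total),
                }
            )
        enr = pd.DataFrame(rows)
        enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        best = min(rows, key=lambda r: r["enrichment_p"]) if rows else None
        summary[name] = {
            "main_split": [sorted(c) for c in main_split],
            "bp": [r["bp"] for r in rows],
            "enrichment_p": best["enrichment_p"] if best else None,
        }
        log(f"cluster: {name}: {summary[name]}")
    return summary


def stage_qpcr(cfg: PipelineConfig, log=None) -> dict:
    """qPCR validation: reference stability, dCT t-tests, RNA-seq concordance."""
    out = cfg.out
    log = log or _Log(out / "run.log")
    if not (out / "qpcr.tsv").exists():
        return {"skipped": True}
    table = hio.read_qpcr_table(out / "qpcr.tsv")
    reference = (out / "qpcr_reference.txt").read_text().strip() or cfg.qpcr_reference
    samples = hio.read_sample_table(out / "samples.tsv")
    sample_ids = sorted(set(table["sample_id"]))
    meta = samples.set_index("sample_id").loc[sample_ids]
    station = meta["station"].iloc[0]
    _, order = _station_contrast(samples, station, cfg.positive_label)
    dct = delta_ct(table, reference)
    dct = dct[sample_ids]
    groups = meta.loc[dct.columns, "outcome"].to_numpy()
    ref_p, ref_ok = reference_stability_check(table, reference, meta["outcome"])
    res = group_ttest_dct(dct, groups, alpha=0.1, group_order=order)
    res.to_csv(out / "qpcr_results.tsv", sep="\t", index_label="gene_id")
    rho = p_rho = None
    de_path = out / f"de_{station}.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t", index_col="gene_id")
        shared = res.index.intersection(de.index)
        if len(shared) >= 3:
            rho, p_rho = concordance(
                res.loc[shared, "fold_change"], 2.0 ** de.loc[shared, "log2fc"]
            )
    summary = {
        "reference_gene": reference,
        "reference_p": ref_p,
        "reference_stable": ref_ok,
        "n_genes": int(res.shape[0]),
        "n_significant": int(res["significant"].sum()),
        "spearman_rho": rho,
        "spearman_p": p_rho,
    }
    log(f"qpcr: {summary}")
    return summary


_STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "de": stage_de,
    "efdr": stage_efdr,
    "tsp": stage_tsp,
    "cluster": stage_cluster,
    "qpcr": stage_qpcr,
}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order; write summary.json and a reproducibility log."""
    cfg.validate()
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    log(
        "run_all: alpha=%s, cpm_threshold=%s (strict >), min_detect_samples=%s, "
        "efdr_permutations=%s, tsp_permutations=%s, top_k=%s, bootstrap=%s, seeds=%s"
        % (
            cfg.alpha,
            cfg.cpm_threshold,
            cfg.min_detect_samples,
            cfg.efdr_permutations,
            cfg.tsp_permutations,
            cfg.top_k,
            cfg.bootstrap,
            cfg.seeds,
        )
    )
    summary: dict = {"config": {"alpha": cfg.alpha, "seeds": cfg.seeds}}
    for name in ("simulate", "filter", "de", "efdr", "tsp", "cluster", "qpcr"):
        try:
            result = _STAGES[name](cfg, log)
        except Exception as exc:  # noqa: BLE001 - stage name must reach the CLI
            raise StageError(name, exc) from exc
        if result is not None:
            summary[name] = result
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log("run_all: complete")
    return summary
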