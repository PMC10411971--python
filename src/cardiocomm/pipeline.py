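"""End-to-end orchestration: simulate -> QC -> pseudobulk -> DE ->
composition -> crosstalk, from a single config, with a manifest of
hashed outputs so identical (config, seed) runs are verifiable as
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import crosstalk as ct
from . import mdnoise, pseudobulk, simulate
from .io_qc import (QCThresholds, apply_qc_filter, compute_cell_qc,
                    CountMatrix, read_10x, write_10x)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

MAC_CLUSTERS = ("Mac1", "Mac2", "Mac3", "Mac4", "Mac5", "Mac6", "Mac7",
                "Mac8", "Mac9")
NEU_CLUSTERS = ("Neu1", "Neu2")


@dataclass
class DEParams:
    k: float = 0.5
    pnr: float = 0.2
    nss: int = 5
    nv: float = 0.02
    q_threshold: float = 0.8     # pseudobulk condition-enrichment screens
    min_cells: int = 20
    pool: str = "injured"


@dataclass
class CompositionParams:
    cond_a: str = "PBS"
    cond_b: str = "CL"
    pool: str = "injured"
    pseudocount: float = 0.5


@dataclass
class CrosstalkParams:
    quantile: float = 0.75
    timepoints: tuple[int, ...] = (3, 7)
    mac_clusters: tuple[str, ...] = MAC_CLUSTERS
    neu_clusters: tuple[str, ...] = NEU_CLUSTERS


@dataclass
class PipelineConfig:
    """Everything one run needs; either synthetic (``sim``) or on-disk input.

    ``sim`` holds keyword arguments for :func:`simulate.default_config`
    (n_genes, n_cells, datasets...).  Alternatively ``input_dirs`` maps
    dataset id -> 10x directory and ``annotation`` points to a TSV with
    barcode, cluster, condition, timepoint, dataset columns.
    """

    seed: int = 0
    outdir: str = "cardiocomm_out"
    sim: dict | None = field(default_factory=dict)
    input_dirs: dict | None = None
    annotation: str | None = None
    mito_prefix: str = "mt-"
    qc: QCThresholds = field(default_factory=QCThresholds)
    de: DEParams = field(default_factory=DEParams)
    composition: CompositionParams = field(default_factory=CompositionParams)
    crosstalk: CrosstalkParams = field(default_factory=CrosstalkParams)
    lr_pairs: str | None = None     # human pair TSV; None -> bundled demo
    orthologs: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["crosstalk"]["timepoints"] = list(self.crosstalk.timepoints)
        d["crosstalk"]["mac_clusters"] = list(self.crosstalk.mac_clusters)
        d["crosstalk"]["neu_clusters"] = list(self.crosstalk.neu_clusters)
        return d


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "qc" in raw:
        kwargs["qc"] = QCThresholds(**raw["qc"])
    if "de" in raw:
        kwargs["de"] = DEParams(**raw["de"])
    if "composition" in raw:
        kwargs["composition"] = CompositionParams(**raw["composition"])
    if "crosstalk" in raw:
        c = dict(raw["crosstalk"])
        for key in ("timepoints", "mac_clusters", "neu_clusters"):
            if key in c:
                c[key] = tuple(c[key])
        kwargs["crosstalk"] = CrosstalkParams(**c)
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str, extra: str = "") -> int:
    return (seed ^ zlib.crc32(f"{stage}:{extra}".encode())) & 0x7FFFFFFF


def _flat_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.columns = ["|".join(map(str, c)) for c in df.columns]
    return out


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.data = {"config": config.to_dict(), "seed": config.seed,
                     "stages": {}}

    def add(self, stage: str, paths, params: dict | None = None) -> None:
        entry = self.data["stages"].setdefault(stage, {"outputs": {},
                                                       "params": params or {}})
        for p in paths:
            p = Path(p)
            entry["outputs"][str(p.relative_to(self.outdir))] = _sha256(p)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        sim_cfg = simulate.default_config(seed=config.seed, **config.sim)
        matrices, ann, truth = simulate.generate_all(sim_cfg)
        return matrices, ann, truth
    if not config.input_dirs or not config.annotation:
        raise ValueError("config needs either `sim` or `input_dirs` + `annotation`")
    matrices = {ds: read_10x(path, dataset=ds)
                for ds, path in config.input_dirs.items()}
    ann = pd.read_csv(config.annotation, sep="\t", index_col=0)
    return matrices, ann, None


def _concat_matrices(matrices: dict[str, CountMatrix]) -> CountMatrix:
    from scipy import sparse
    keys = list(matrices)
    genes = matrices[keys[0]].genes
    for ds in keys[1:]:
        if not matrices[ds].genes.equals(genes):
            raise ValueError("datasets must share the gene universe")
    counts = sparse.hstack([matrices[ds].counts for ds in keys], format="csr")
    barcodes = pd.Index(np.concatenate([matrices[ds].barcodes for ds in keys]))
    return CountMatrix(genes, barcodes, counts, dataset="combined")


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts with the failing stage named; outputs of
    completed stages remain on disk and are listed in the exception.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("pseudobulk", _stage_pseudobulk),
        ("de", _stage_de),
        ("composition", _stage_composition),
        ("crosstalk", _stage_crosstalk),
        ("evaluation", _stage_evaluation),
    ]
    for name, fn in stages:
        try:
            fn(config, outdir, manifest, state)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        log.info("stage %s complete", name)
    manifest.write()
    return manifest.data


def _stage_simulate(config, outdir, manifest, state) -> None:
    matrices, ann, truth = _load_inputs(config)
    state.update(matrices=matrices, ann=ann, truth=truth)
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(exist_ok=True)
    paths = []
    if config.sim is not None:
        for ds, m in matrices.items():
            d = write_10x(m, stage_dir / ds)
            paths += [d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"]
        ann_path = stage_dir / "annotation.tsv"
        ann.rename_axis("barcode").to_csv(ann_path, sep="\t")
        paths.append(ann_path)
        paths += simulate.write_truth(truth, stage_dir / "truth").values()
    manifest.add("simulate", paths, params={"sim": config.sim,
                                            "seed": config.seed})


def _stage_qc(config, outdir, manifest, state) -> None:
    stage_dir = outdir / "qc"
    stage_dir.mkdir(exist_ok=True)
    reports, metrics_frames, kept = {}, [], {}
    for ds, m in state["matrices"].items():
        metrics = compute_cell_qc(m, mito_prefix=config.mito_prefix)
        retained, report = apply_qc_filter(metrics, config.qc)
        reports[ds] = report.to_dict()
        metrics["retained"] = metrics.index.isin(retained)
        metrics["dataset"] = ds
        metrics_frames.append(metrics)
        kept[ds] = m.subset_barcodes(retained)
    metrics_all = pd.concat(metrics_frames)
    metrics_path = stage_dir / "cell_qc_metrics.tsv"
    metrics_all.rename_axis("barcode").to_csv(metrics_path, sep="\t",
                                              float_format="%.6g")
    report_path = stage_dir / "qc_report.json"
    report_path.write_text(json.dumps(reports, indent=2, sort_keys=True) + "\n")

    retained_barcodes = pd.Index(np.concatenate(
        [m.barcodes for m in kept.values()]))
    state["matrices_qc"] = kept
    state["ann_qc"] = state["ann"].loc[retained_barcodes]
    manifest.add("qc", [metrics_path, report_path],
                 params=reports[next(iter(reports))]["thresholds"])


def _stage_pseudobulk(config, outdir, manifest, state) -> None:
    stage_dir = outdir / "pseudobulk"
    stage_dir.mkdir(exist_ok=True)
    combined = _concat_matrices(state["matrices_qc"])
    pb = pseudobulk.aggregate_pseudobulk(combined, state["ann_qc"])
    pb = pseudobulk.normalize_pseudobulk(pb)
    state["combined"] = combined
    state["pb"] = pb
    paths = []
    for layer in ("raw_mean", "raw_sum", "norm"):
        p = stage_dir / f"{layer}.tsv"
        _flat_cols(getattr(pb, layer)).rename_axis("gene").to_csv(
            p, sep="\t", float_format="%.6g")
        paths.append(p)
    meta = pd.DataFrame({"n_cells": pb.n_cells, "total_counts": pb.total_counts})
    meta.index = ["|".join(map(str, c)) for c in meta.index]
    meta_path = stage_dir / "group_sizes.tsv"
    meta.rename_axis("group").to_csv(meta_path, sep="\t")
    manifest.add("pseudobulk", paths + [meta_path])


def _pooled_counts(pb, ann, cluster: str, condition: str, pool: str):
    """Summed raw counts + cell count for a cluster under one condition."""
    if pool == "injured":
        tps = set(comp.INJURED_TIMEPOINTS)
    else:
        tps = set(ann["timepoint"].unique())
    datasets = ann.loc[(ann["condition"] == condition)
                       & ann["timepoint"].isin(tps), "dataset"].unique()
    cols = [(cluster, ds) for ds in datasets if (cluster, ds) in pb.raw_sum.columns]
    if not cols:
        return None, 0
    x = pb.raw_sum[cols].sum(axis=1).to_numpy()
    n = int(pb.n_cells[cols].sum())
    return x, n


def _stage_de(config, outdir, manifest, state) -> None:
    stage_dir = outdir / "de"
    stage_dir.mkdir(exist_ok=True)
    pb, ann = state["pb"], state["ann_qc"]
    p = config.de
    frames = []
    clusters = sorted(ann["cluster"].unique())
    for cluster in clusters:
        x_a, n_a = _pooled_counts(pb, ann, cluster, config.composition.cond_a, p.pool)
        x_b, n_b = _pooled_counts(pb, ann, cluster, config.composition.cond_b, p.pool)
        if x_a is None or x_b is None or min(n_a, n_b) < p.min_cells:
            continue
        rng = np.random.default_rng(_stage_seed(config.seed, "de", cluster))
        degs = mdnoise.noiseq_sim(x_a, x_b, genes=pb.genes, pnr=p.pnr,
                                  nss=p.nss, nv=p.nv, k=p.k,
                                  q_threshold=p.q_threshold, rng=rng)
        degs.insert(0, "cluster", cluster)
        frames.append(degs)
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["cluster", "gene", "M", "D", "q", "call"]))
    path = stage_dir / "condition_degs.tsv"
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    state["degs"] = table
    manifest.add("de", [path], params=dataclasses.asdict(p))


def _stage_composition(config, outdir, manifest, state) -> None:
    stage_dir = outdir / "composition"
    stage_dir.mkdir(exist_ok=True)
    ann = state["ann_qc"]
    p = config.composition
    props = comp.cluster_proportions(ann)
    ratios = comp.log2_condition_ratio(ann, cond_a=p.cond_a, cond_b=p.cond_b,
                                       pool=p.pool, pseudocount=p.pseudocount)
    timecourse = comp.composition_timecourse(props)
    paths = []
    for name, df, kw in (
        ("proportions", props, {"index": False}),
        ("log2_condition_ratio", ratios, {"index": False}),
        ("timecourse_percent", timecourse.rename_axis("cluster"), {}),
    ):
        path = stage_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", float_format="%.6g", **kw)
        paths.append(path)
    state["ratios"] = ratios
    manifest.add("composition", paths, params=dataclasses.asdict(p))


def _lr_database(config):
    if config.lr_pairs is None:
        return ct.load_demo_database()
    pairs = pd.read_csv(config.lr_pairs, sep="\t")
    orth = pd.read_csv(config.orthologs, sep="\t")
    ortho_map = (orth.groupby("human_gene")["zebrafish_gene"]
                 .apply(lambda s: sorted(set(s))).to_dict())
    return ct.build_lr_database(pairs, ortho_map)


def _stage_crosstalk(config, outdir, manifest, state) -> None:
    stage_dir = outdir / "crosstalk"
    stage_dir.mkdir(exist_ok=True)
    pb, ann = state["pb"], state["ann_qc"]
    p = config.crosstalk
    db, db_report = _lr_database(config)
    # restrict the database to genes present in the matrix
    genes = set(pb.genes)
    db = db[db["ligand"].isin(genes) & db["receptor"].isin(genes)].reset_index(drop=True)

    ds_by_cond_tp = {}
    for ds in ann["dataset"].unique():
        cond, tp = simulate.parse_dataset_id(ds)
        ds_by_cond_tp[(cond, tp)] = ds

    paths, specific_edges = [], []
    directions = {
        "mac_to_neu": (p.mac_clusters, p.neu_clusters),
        "neu_to_mac": (p.neu_clusters, p.mac_clusters),
    }
    cond_a, cond_b = config.composition.cond_a, config.composition.cond_b
    for tp in p.timepoints:
        key_a, key_b = (cond_a, tp), (cond_b, tp)
        if key_a not in ds_by_cond_tp or key_b not in ds_by_cond_tp:
            continue
        expressed = {}
        for cond, tp_ in (key_a, key_b):
            ds = ds_by_cond_tp[(cond, tp_)]
            expr = {}
            for cluster in set(p.mac_clusters) | set(p.neu_clusters):
                if (cluster, ds) in pb.norm.columns:
                    expr[cluster] = ct.expressed_genes(pb, (cluster, ds),
                                                       quantile=p.quantile)
            expressed[cond] = (ds, expr)
        for dname, (senders, receivers) in directions.items():
            labeled = {}
            for cond in (cond_a, cond_b):
                ds, expr = expressed[cond]
                avail = set(expr)
                labeled[cond] = ct.enumerate_interactions(
                    db, expr, [s for s in senders if s in avail],
                    [r for r in receivers if r in avail], ds)
            spec = ct.condition_specific_pairs(labeled[cond_a], labeled[cond_b],
                                               label_a=cond_a, label_b=cond_b)
            spec.insert(0, "timepoint", tp)
            spec.insert(0, "direction", dname)
            specific_edges.append(spec)
            base = stage_dir / f"{dname}_{tp}dpci"
            spec.to_csv(base.with_suffix(".csv"), index=False)
            union = pd.concat([labeled[cond_a], labeled[cond_b]])
            ct.write_sif(union.drop_duplicates(ct.EDGE_KEY), base.with_suffix(".sif"))
            ct.write_graphml(union, base.with_suffix(".graphml"))
            counts = ct.summarize_network(union)
            counts.rename_axis("sender").to_csv(
                base.parent / f"{base.name}_counts.tsv", sep="\t")
            paths += [base.with_suffix(".csv"), base.with_suffix(".sif"),
                      base.with_suffix(".graphml"),
                      base.parent / f"{base.name}_counts.tsv"]
    state["crosstalk_specific"] = (pd.concat(specific_edges, ignore_index=True)
                                   if specific_edges else pd.DataFrame())
    report_path = stage_dir / "lr_database_report.json"
    report_path.write_text(json.dumps(db_report, indent=2, sort_keys=True) + "\n")
    paths.append(report_path)
    manifest.add("crosstalk", paths,
                 params={"quantile": p.quantile,
                         "timepoints": list(p.timepoints)})


def _stage_evaluation(config, outdir, manifest, state) -> None:
    """Compare results with planted truth (synthetic runs only)."""
    truth = state.get("truth")
    if truth is None:
        return
    stage_dir = outdir / "evaluation"
    stage_dir.mkdir(exist_ok=True)
    metrics: dict = {}

    ann, ann_qc = state["ann"], state["ann_qc"]
    metrics["qc_retained_fraction"] = round(len(ann_qc) / len(ann), 6)

    # --- differential expression recovery (M>0 means cond_a-enriched)
    degs = state["degs"]
    cond_a = config.composition.cond_a
    expected = set()
    for row in truth.deg_table.itertuples():
        expected.add((row.cluster, row.gene,
                      1 if row.condition == cond_a else -1))
    for row in truth.lr_table.itertuples():
        sign = 1 if row.condition == cond_a else -1
        expected.add((row.sender, row.ligand, sign))
        expected.add((row.receiver, row.receptor, sign))
    tested_clusters = set(degs["cluster"].unique())
    expected = {e for e in expected if e[0] in tested_clusters}
    calls = degs[degs["call"]]
    called = {(r.cluster, r.gene, 1 if r.M > 0 else -1)
              for r in calls.itertuples()}
    tp = len(expected & called)
    metrics["de_n_calls"] = int(len(called))
    metrics["de_sensitivity"] = round(tp / len(expected), 6) if expected else None
    metrics["de_precision"] = round(tp / len(called), 6) if called else None

    # --- composition: planted-proportion ratio vs estimate
    ratios = state["ratios"].set_index("cluster")["log2_ratio"]
    sim_cfg_kwargs = config.sim or {}
    datasets = sim_cfg_kwargs.get("datasets", simulate.DEFAULT_DATASETS)
    pc = config.composition.pseudocount

    def pooled_planted(cond):
        tot, per = 0.0, {}
        for ds in datasets:
            c, t = simulate.parse_dataset_id(ds)
            if c == cond and t in comp.INJURED_TIMEPOINTS:
                for cl, frac in simulate._PROPORTIONS[ds].items():
                    per[cl] = per.get(cl, 0.0) + frac
                tot += 1
        return {cl: v / tot for cl, v in per.items()} if tot else {}

    pa, pb_ = pooled_planted(config.composition.cond_a), \
        pooled_planted(config.composition.cond_b)
    if pa and pb_:
        planted_ratio = {cl: float(np.log2(pa[cl] / pb_[cl])) for cl in pa}
        common = [cl for cl in planted_ratio if cl in ratios.index]
        err = [abs(ratios[cl] - planted_ratio[cl]) for cl in common]
        metrics["composition_mean_abs_error_log2"] = round(float(np.mean(err)), 6)
        metrics["composition_max_abs_error_log2"] = round(float(np.max(err)), 6)

    # --- crosstalk condition-specific recovery
    spec = state["crosstalk_specific"]
    if len(spec):
        detected = set()
        for r in spec.itertuples():
            if r.specificity.endswith("-only"):
                cond = r.specificity[:-len("-only")]
                detected.add((r.ligand, r.receptor, r.sender, r.receiver, cond))
        planted = {(r.ligand, r.receptor, r.sender, r.receiver, r.condition)
                   for r in truth.lr_table.itertuples()}
        hit = len(detected & planted)
        metrics["crosstalk_n_specific"] = int(len(detected))
        metrics["crosstalk_recall"] = round(hit / len(planted), 6) if planted else None
        metrics["crosstalk_precision"] = round(hit / len(detected), 6) if detected else None

    path = stage_dir / "evaluation.json"
    path.write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
    state["evaluation"] = metrics
    manifest.add("evaluation", [path])
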