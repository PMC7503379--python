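"""End-to-end orchestration: counts in, integrated tables out.

A :class:`RunConfig` names the inputs (per-sample cytosine reports, a
gene x sample expression count matrix, GFF3 gene models, optional
term annotation and flagged-gene list) and every stage parameter.
:func:`run_pipeline` then runs coverage filtering, per-comparison
DMC/DMR calling, exact-test DE calling, DEM classification,
correlation, clustering, enrichment and the co-expression network,
writing one TSV per stage plus a manifest with parameters, input
checksums and per-stage row counts.  The pipeline is a pure function
of (inputs, config): rerunning it reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import (
    enrichment_network as en,
    expression_diff as ed,
    genome_features as gf,
    integration as ig,
    methylation_diff as md,
)

log = logging.getLogger("methylinta")


@dataclass
class RunConfig:
    methyl_paths: dict[str, str]
    counts_path: str
    gff3_path: str
    annotation_path: str | None = None
    flagged_genes_path: str | None = None
    contig_lengths: dict[str, int] | None = None
    samples: list[str] | None = None
    comparisons: list[tuple[str, str]] | None = None
    outdir: str | None = None
    seed: int = 0
    # methylation
    min_reads: int = md.DEFAULT_MIN_READS
    window_bp: int = md.DEFAULT_WINDOW_BP
    alpha_dmc: float = md.DEFAULT_ALPHA
    min_abs_diff: float = 0.0
    min_dmc: int = 3
    min_span_bp: int = 50
    max_gap_bp: int = 100
    # expression
    bcv: float = ed.DEFAULT_BCV
    alpha_deg: float = ed.DEFAULT_ALPHA
    normalization: str = "tmm"
    # integration / network
    min_cluster: int = ig.DEFAULT_MIN_CLUSTER
    cluster_metric: str = "euclidean"
    rho_threshold: float = en.DEFAULT_RHO

    def __post_init__(self):
        if self.samples is None:
            self.samples = list(self.methyl_paths)
        if self.comparisons is None:
            self.comparisons = md.enumerate_comparisons(self.samples)
        known = set(self.samples)
        for a, b in self.comparisons:
            if a not in known or b not in known:
                raise ValueError(f"comparison ({a}, {b}) names unknown sample")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "comparisons" in d and d["comparisons"] is not None:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a dict of result tables (and writes
    them under ``config.outdir`` when set)."""
    out: dict = {}
    warnings: list[str] = []

    log.info("reading %d cytosine reports", len(config.methyl_paths))
    table = md.read_cytosine_report(config.methyl_paths)
    covered = md.filter_coverage(table, config.min_reads)
    log.info("coverage filter: %d -> %d sites", table.n_sites, covered.n_sites)

    with open(config.gff3_path) as fh:
        max_end: dict[str, int] = {}
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) > 4:
                max_end[parts[0]] = max(
                    max_end.get(parts[0], 0), int(parts[4])
                )
    contig_lengths = config.contig_lengths or {
        c: e + gf.FLANK_BP for c, e in max_end.items()
    }
    for c in covered.sites["chrom"].unique():
        contig_lengths.setdefault(
            c, int(covered.sites.loc[covered.sites["chrom"] == c, "pos"].max())
            + gf.FLANK_BP,
        )
    models = gf.build_gene_models(config.gff3_path, contig_lengths)
    index = gf.FeatureIndex(models)
    sites_annot = gf.annotate_sites(covered.sites, index)
    out["covered_sites"] = sites_annot

    counts = ed.read_count_matrix(config.counts_path)

    dmc_frames, dmr_frames, deg_frames, dem_frames = [], [], [], []
    for a, b in config.comparisons:
        dmcs = md.call_dmcs(
            covered, a, b,
            alpha=config.alpha_dmc,
            min_abs_diff=config.min_abs_diff,
            window_bp=config.window_bp,
        )
        dmcs = ig.assign_records(dmcs, index, by="point")
        dmrs = md.call_dmrs(
            dmcs, config.min_dmc, config.min_span_bp, config.max_gap_bp
        )
        dmrs = ig.assign_records(dmrs, index, by="interval")
        degs = ed.call_degs(
            counts, a, b,
            bcv=config.bcv, alpha=config.alpha_deg,
            normalization=config.normalization,
        )
        dem = ig.classify_dem(degs, dmcs, dmrs, index, alpha=config.alpha_deg)
        log.info(
            "%s vs %s: %d DMCs, %d DMRs, %d DEGs",
            a, b, len(dmcs), len(dmrs), int(degs["is_de"].sum()),
        )
        dmc_frames.append(dmcs)
        dmr_frames.append(dmrs)
        deg_frames.append(degs)
        dem_frames.append(dem)
    out["dmcs"] = pd.concat(dmc_frames, ignore_index=True)
    out["dmrs"] = pd.concat(dmr_frames, ignore_index=True)
    out["degs"] = pd.concat(deg_frames, ignore_index=True)
    out["dem"] = pd.concat(dem_frames, ignore_index=True)

    out["corr_dmc"] = ig.correlate_expression_methylation(
        out["dem"], out["dmcs"], level="DMC"
    )
    out["corr_dmr"] = ig.correlate_expression_methylation(
        out["dem"], out["dmrs"], level="DMR"
    )

    mat = ig.profile_matrix(out["dem"])
    out["clusters"] = ig.cluster_dem_profiles(
        mat, config.min_cluster, config.cluster_metric
    ).rename("cluster").rename_axis("gene_id").reset_index()

    out["quadrants"] = pd.concat(
        [ig.quadrant_profile(out["dem"], s) for s in config.samples],
        ignore_index=True,
    )

    out["tally"] = pd.concat(
        [
            md.tally_hypo_hyper(out["dmcs"], kind="DMC"),
            md.tally_hypo_hyper(out["dmrs"], kind="DMR"),
        ],
        ignore_index=True,
    )

    if config.annotation_path:
        annotation = en.read_annotation(config.annotation_path)
        universe = [str(g) for g in counts.index]
        enr = []
        for k, grp in out["clusters"].groupby("cluster"):
            query = [g for g in grp["gene_id"] if g in set(universe)]
            if not query:
                continue
            e = en.hypergeom_enrich(query, universe, annotation)
            e.insert(0, "cluster", k)
            enr.append(e)
        out["enrichment"] = (
            pd.concat(enr, ignore_index=True) if enr else pd.DataFrame()
        )

    dem_genes = sorted(
        set(out["dem"].loc[out["dem"]["class"] == "DEM", "gene_id"].dropna())
    )
    flagged = []
    if config.flagged_genes_path:
        with open(config.flagged_genes_path) as fh:
            flagged = [x.strip() for x in fh if x.strip()]
    net_genes = sorted(set(dem_genes) | set(flagged))
    net_genes = [g for g in net_genes if g in counts.index]
    if len(net_genes) >= 2 and counts.shape[1] >= 4:
        expr = en.cpm_log2(counts)
        G, dropped = en.build_network(
            expr, net_genes, rho_threshold=config.rho_threshold
        )
        part, Q = en.detect_communities(G)
        if flagged:
            part = en.filter_flagged_communities(part, flagged)
        out["network_edges"] = pd.DataFrame(
            [
                {"gene_a": u, "gene_b": v, "rho": d["weight"]}
                for u, v, d in G.edges(data=True)
            ],
            columns=["gene_a", "gene_b", "rho"],
        )
        out["communities"] = pd.DataFrame(
            [
                {"community": i + 1, "gene_id": g}
                for i, c in enumerate(part)
                for g in sorted(c)
            ],
            columns=["community", "gene_id"],
        )
        out["network_dropped"] = pd.DataFrame({"gene_id": dropped})
        out["modularity"] = Q

    manifest = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not k.endswith("_paths") and k not in ("outdir",)
        },
        "inputs": {
            **{f"methyl_{s}": _sha256(p) for s, p in config.methyl_paths.items()},
            "counts": _sha256(config.counts_path),
            "gff3": _sha256(config.gff3_path),
        },
        "row_counts": {
            k: int(len(v)) for k, v in out.items() if isinstance(v, pd.DataFrame)
        },
        "warnings": warnings,
    }
    out["manifest"] = manifest

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        for name, obj in out.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(
                    os.path.join(config.outdir, f"{name}.tsv"),
                    sep="\t", index=False,
                )
        md.write_dmr_bed(
            out["dmrs"], os.path.join(config.outdir, "dmrs.bed.tsv")
        )
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out


def summarize_run(out: dict) -> dict[str, pd.DataFrame]:
    """Report tables: per-comparison DMC/DMR counts stratified by
    context x feature, DEM/DM/DEG class tallies, hypo/hyper tallies."""
    tables = {}
    for kind in ("dmcs", "dmrs"):
        df = out[kind]
        if df.empty:
            tables[f"{kind}_by_stratum"] = pd.DataFrame()
            continue
        d = df.copy()
        d["comparison"] = d["sample_a"] + "_vs_" + d["sample_b"]
        tables[f"{kind}_by_stratum"] = (
            d.groupby(["comparison", "context", "feature"], dropna=False)
            .size()
            .rename("count")
            .reset_index()
        )
    dem = out["dem"].copy()
    dem["comparison"] = dem["sample_a"] + "_vs_" + dem["sample_b"]
    tables["class_tally"] = (
        dem.groupby(["comparison", "class"]).size().rename("count").reset_index()
    )
    tables["hypo_hyper"] = out["tally"]
    return tables
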