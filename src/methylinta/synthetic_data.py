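"""Synthetic genomes, methylomes, expression and annotations.

The generator emulates the structure of the study design every other
module targets: nine samples with one WGBS library each (no
replicates), beta-binomial methylation counts whose mean levels are
ordered by context (CG 0.70 > CHG 0.45 > CHH 0.08), methylation
depletion in both UTRs, planted DMRs in chosen contexts and gene
features, negative-binomial expression counts at BCV 0.2, and planted
DEM genes whose methylation difference and expression log-fold-change
are coupled with a chosen sign (negative coupling: hypermethylation
goes with down-regulation).

Everything is a deterministic function of the config seed; truth
tables record every planted interval and effect so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome_features as gf
from .methylation_diff import MethylTable

STUDY_SAMPLES = [
    "Root", "Flow", "Yleaf", "Mleaf", "Aroot",
    "Basal", "Distal", "Mleafcat", "Yleafcat",
]

DEFAULT_METHYL_MEANS = {"CG": 0.70, "CHG": 0.45, "CHH": 0.08}


@dataclass
class PlantedDmr:
    """One or more DMRs to plant: mean shift ``delta`` over a
    ``width_bp`` window of ``context`` sites inside the given gene
    feature, applied in ``affected_samples``."""

    context: str
    feature: str
    delta: float
    width_bp: int = 200
    affected_samples: tuple[str, ...] = ()
    n: int = 1


@dataclass
class PlantedDem:
    """A block of genes with coupled methylation and expression
    effects.  ``sign_coupling`` = -1 forces the expression
    log-fold-change sign opposite to the methylation delta
    (hypermethylated -> repressed)."""

    n_genes: int
    logfc: float
    methyl_delta: float
    context: str = "CG"
    feature: str = "exon"
    sign_coupling: int = -1
    width_bp: int = 200
    affected_samples: tuple[str, ...] = ()
    #: lognormal sd of a per-sample expression profile shared by the
    #: block (0 = none); >0 makes the block strongly co-expressed, the
    #: way a co-regulated pathway behaves across tissues
    coexpression_sdlog: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 120_000
    n_genes: int = 12
    gc_fraction: float = 0.40
    n_samples: int = 9
    sample_names: tuple[str, ...] = tuple(STUDY_SAMPLES)
    coverage_mean: float = 30.0
    methyl_means: dict = field(
        default_factory=lambda: dict(DEFAULT_METHYL_MEANS)
    )
    utr_depletion_factor: float = 0.3
    site_dispersion: float = 0.01
    planted_dmrs: list = field(default_factory=list)
    planted_dem: list = field(default_factory=list)
    bcv: float = 0.2
    expression_meanlog: float = 4.0
    expression_sdlog: float = 1.0
    libsize_sdlog: float = 0.1
    n_terms: int = 40
    terms_per_gene: float = 2.0
    min_sites_per_dmr: int = 5

    def __post_init__(self):
        self.sample_names = tuple(self.sample_names[: self.n_samples])
        if len(self.sample_names) != self.n_samples:
            self.sample_names = tuple(
                f"S{i + 1}" for i in range(self.n_samples)
            )
        for ctx, mu in self.methyl_means.items():
            if not 0 <= mu <= 1:
                raise ValueError(f"methylation mean for {ctx} outside [0,1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


# ---------------------------------------------------------------------------
# genome + annotation


def simulate_genome(config: SimConfig):
    """Random genome plus gene models.

    Returns (sequences: dict chrom -> str, models: list[GeneModel],
    truth: DataFrame of feature intervals).  Genes are placed with
    >= 12 kb spacing so 5 kb flanks never overlap; each gene has 2-6
    exons and annotated UTRs at both ends.
    """
    rng = _rng(config, 0)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for c in range(config.n_chroms):
        letters = rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8),
            size=config.chrom_length_bp,
            p=probs,
        )
        seqs[f"chr{c + 1}"] = letters.tobytes().decode()

    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    models = []
    g = 0
    for chrom, seq in seqs.items():
        cursor = 6_000
        for _ in range(per_chrom):
            if g >= config.n_genes:
                break
            n_ex = int(rng.integers(2, 7))
            ex_lens = rng.integers(150, 401, size=n_ex)
            in_lens = rng.integers(100, 801, size=n_ex - 1)
            glen = int(ex_lens.sum() + in_lens.sum())
            start = cursor
            end = start + glen - 1
            if end + 6_000 > len(seq):
                break
            exons = []
            p = start
            for i in range(n_ex):
                exons.append((p, p + int(ex_lens[i]) - 1))
                p += int(ex_lens[i])
                if i < n_ex - 1:
                    p += int(in_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            u5 = int(rng.integers(80, min(200, ex_lens[0]) + 1))
            u3 = int(rng.integers(80, min(200, ex_lens[-1]) + 1))
            first, last = exons[0], exons[-1]
            left_utr = (first[0], first[0] + u5 - 1)
            right_utr = (last[1] - u3 + 1, last[1])
            if strand == "+":
                utr5, utr3 = [left_utr], [right_utr]
            else:
                utr5, utr3 = [right_utr], [left_utr]
            gid = f"gene{g + 1:04d}"
            models.append(
                gf.assemble_gene_model(
                    gid, chrom, strand, start, end, exons, utr5, utr3,
                    len(seq),
                )
            )
            g += 1
            cursor = end + 12_000
    if g < config.n_genes:
        need = per_chrom * (5_000 + 12_000 + 6_000)
        raise ValueError(
            f"only {g}/{config.n_genes} genes fit; increase chrom_length_bp "
            f"to roughly {need} or reduce n_genes"
        )
    truth = pd.DataFrame(
        [
            (m.gene_id, m.chrom, m.strand, feat, st, en)
            for m in models
            for feat, st, en in m.features
        ],
        columns=["gene_id", "chrom", "strand", "feature", "start", "end"],
    )
    return seqs, models, truth


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.chrom}\tsim\t"
            tail = f"\t.\t{m.strand}\t.\t"
            fh.write(
                f"{base}gene\t{m.start}\t{m.end}{tail}ID={m.gene_id}\n"
                f"{base}mRNA\t{m.start}\t{m.end}{tail}"
                f"ID={m.gene_id}.1;Parent={m.gene_id}\n"
            )
            # exon records include their UTR portions (GFF3 convention)
            utrs = sorted(
                (st, en, f)
                for f, st, en in m.features
                if f in ("five_prime_utr", "three_prime_utr")
            )
            exon_parts = sorted(
                [(st, en) for f, st, en in m.features if f == "exon"]
                + [(st, en) for st, en, _ in utrs]
            )
            merged = []
            for st, en in exon_parts:
                if merged and st <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], en)
                else:
                    merged.append([st, en])
            for i, (st, en) in enumerate(merged):
                fh.write(
                    f"{base}exon\t{st}\t{en}{tail}"
                    f"ID={m.gene_id}.1.exon{i + 1};Parent={m.gene_id}.1\n"
                )
            for st, en, f in utrs:
                kind = (
                    "five_prime_UTR" if f == "five_prime_utr"
                    else "three_prime_UTR"
                )
                fh.write(
                    f"{base}{kind}\t{st}\t{en}{tail}"
                    f"ID={m.gene_id}.1.{kind};Parent={m.gene_id}.1\n"
                )


# ---------------------------------------------------------------------------
# methylomes


def _truncated_poisson(rng, lam, size):
    n = rng.poisson(lam, size=size)
    while True:
        z = n == 0
        if not z.any():
            return n
        n[z] = rng.poisson(lam, size=int(z.sum()))
        # a mean-30 Poisson essentially never needs a second pass


def _beta_draw(rng, mean, phi):
    """Beta draws with the given means and variance mean(1-mean)*phi."""
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    s = 1.0 / phi - 1.0
    return rng.beta(mean * s, (1.0 - mean) * s)


def simulate_methylomes(config: SimConfig, seqs, models):
    """Per-sample cytosine counts plus planted-DMR and DEM-gene truth.

    Returns (table: MethylTable, dmr_truth: DataFrame, dem_truth:
    DataFrame).  Baseline means are set by context, multiplied by the
    UTR depletion factor inside UTRs; planted intervals shift the mean
    by delta (clipped to [0.02, 0.98]) in their affected samples.
    """
    rng = _rng(config, 1)
    sites = gf.context_table(seqs.items())
    index = gf.FeatureIndex(models)
    sites = gf.annotate_sites(sites, index)
    ns = len(sites)
    mu = sites["context"].map(config.methyl_means).to_numpy(dtype=float)
    in_utr = sites["feature"].isin(
        ["five_prime_utr", "three_prime_utr"]
    ).to_numpy()
    mu = np.where(in_utr, mu * config.utr_depletion_factor, mu)

    samples = list(config.sample_names)
    mu_by_sample = np.tile(mu[:, None], (1, len(samples)))

    dmr_rows = []
    dem_rows = []
    used_genes: set[str] = set()
    gene_ids = [m.gene_id for m in models]

    def plant(context, feature, delta, width_bp, affected, gene=None,
              min_sites=config.min_sites_per_dmr):
        mask = (sites["context"] == context) & (sites["feature"] == feature)
        if gene is not None:
            mask &= sites["gene_id"] == gene
        cand = np.asarray(sites.index[mask])
        for _ in range(100):
            if cand.size == 0:
                break
            i = int(rng.choice(cand))
            chrom = sites.at[i, "chrom"]
            start = int(sites.at[i, "pos"])
            end = start + width_bp - 1
            inwin = (
                (sites["chrom"] == chrom)
                & (sites["context"] == context)
                & (sites["pos"] >= start)
                & (sites["pos"] <= end)
            ).to_numpy()
            if inwin.sum() < min_sites:
                continue
            overlap = any(
                r["chrom"] == chrom and r["start"] <= end and r["end"] >= start
                for r in dmr_rows
            )
            if overlap:
                continue
            cols = [samples.index(s) for s in affected]
            mu_by_sample[np.ix_(inwin, cols)] = np.clip(
                mu_by_sample[np.ix_(inwin, cols)] + delta, 0.02, 0.98
            )
            gid = sites.at[i, "gene_id"]
            dmr_rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "context": context, "feature": feature, "delta": delta,
                    "gene_id": gid,
                    "affected_samples": ",".join(affected),
                    "n_sites": int(inwin.sum()),
                }
            )
            return gid
        raise RuntimeError(
            f"could not place a {context}/{feature} DMR with >= "
            f"{min_sites} sites after 100 tries"
        )

    for spec in config.planted_dmrs:
        affected = tuple(spec.affected_samples) or (samples[0],)
        for _ in range(spec.n):
            plant(spec.context, spec.feature, spec.delta, spec.width_bp,
                  affected)

    for block_i, spec in enumerate(config.planted_dem):
        affected = tuple(spec.affected_samples) or (samples[0],)
        # only genes that actually expose sites of the target
        # context/feature can carry a planted methylation effect
        eligible = set(
            sites.loc[
                (sites["context"] == spec.context)
                & (sites["feature"] == spec.feature),
                "gene_id",
            ].dropna()
        )
        free = [
            x for x in gene_ids if x not in used_genes and x in eligible
        ]
        if len(free) < spec.n_genes:
            raise ValueError(
                f"only {len(free)} eligible genes for a planted DEM block "
                f"of {spec.n_genes} ({spec.context}/{spec.feature})"
            )
        chosen = list(rng.choice(free, size=spec.n_genes, replace=False))
        logfc = spec.logfc
        if spec.sign_coupling < 0:
            logfc = -np.sign(spec.methyl_delta) * abs(spec.logfc)
        for gid in chosen:
            used_genes.add(gid)
            plant(spec.context, spec.feature, spec.methyl_delta,
                  spec.width_bp, affected, gene=gid)
            dem_rows.append(
                {
                    "gene_id": gid, "block": f"B{block_i + 1}",
                    "logFC": float(logfc),
                    "methyl_delta": spec.methyl_delta,
                    "context": spec.context, "feature": spec.feature,
                    "affected_samples": ",".join(affected),
                }
            )

    meth = np.zeros((ns, len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for j in range(len(samples)):
        p = _beta_draw(rng, mu_by_sample[:, j], config.site_dispersion)
        n = _truncated_poisson(rng, config.coverage_mean, ns)
        m = rng.binomial(n, p)
        meth[:, j], total[:, j] = m, n
    table = MethylTable(
        sites[["chrom", "pos", "strand", "context"]].copy(), samples,
        meth, total,
    )
    dmr_truth = pd.DataFrame(
        dmr_rows,
        columns=["chrom", "start", "end", "context", "feature", "delta",
                 "gene_id", "affected_samples", "n_sites"],
    )
    dem_truth = pd.DataFrame(
        dem_rows,
        columns=["gene_id", "block", "logFC", "methyl_delta", "context",
                 "feature", "affected_samples"],
    )
    return table, dmr_truth, dem_truth


# ---------------------------------------------------------------------------
# expression and annotation


def simulate_expression(config: SimConfig, models, dem_truth: pd.DataFrame):
    """Gene x sample NB counts at dispersion bcv^2, with planted DEM
    log-fold-changes applied in the affected samples."""
    rng = _rng(config, 2)
    samples = list(config.sample_names)
    gene_ids = [m.gene_id for m in models]
    base = rng.lognormal(
        config.expression_meanlog, config.expression_sdlog, len(gene_ids)
    )
    libfac = (
        rng.lognormal(0.0, config.libsize_sdlog, len(samples))
        if config.libsize_sdlog > 0
        else np.ones(len(samples))
    )
    mu = np.outer(base, libfac)
    for _, row in dem_truth.iterrows():
        gi = gene_ids.index(row["gene_id"])
        for s in str(row["affected_samples"]).split(","):
            mu[gi, samples.index(s)] *= 2.0 ** row["logFC"]
    # shared within-block expression profiles (co-regulated pathways)
    for block_i, spec in enumerate(config.planted_dem):
        if getattr(spec, "coexpression_sdlog", 0.0) <= 0:
            continue
        profile = rng.lognormal(0.0, spec.coexpression_sdlog, len(samples))
        members = dem_truth.loc[
            dem_truth["block"] == f"B{block_i + 1}", "gene_id"
        ]
        for g in members:
            mu[gene_ids.index(g)] *= profile
    phi = config.bcv**2
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=gene_ids, columns=samples)


def simulate_annotation(config: SimConfig, models, dem_truth: pd.DataFrame):
    """Random flat term annotation plus one planted term per DEM block
    (the block's genes exactly), giving a known enriched term."""
    rng = _rng(config, 3)
    gene_ids = [m.gene_id for m in models]
    rows = []
    terms = [f"TERM{i + 1:04d}" for i in range(config.n_terms)]
    for g in gene_ids:
        k = rng.poisson(config.terms_per_gene)
        for t in rng.choice(terms, size=min(k, len(terms)), replace=False):
            rows.append({"gene_id": g, "term": t})
    if not dem_truth.empty:
        for block, grp in dem_truth.groupby("block"):
            for g in grp["gene_id"]:
                rows.append({"gene_id": g, "term": f"PLANTED_{block}"})
    return pd.DataFrame(rows, columns=["gene_id", "term"]).drop_duplicates()


# ---------------------------------------------------------------------------
# focused helpers for calibration / recovery runs


def simulate_null_pair(
    n_sites: int = 10_000,
    coverage_mean: float = 30.0,
    methyl_mean: float = 0.7,
    site_dispersion: float = 0.01,
    mean_spacing_bp: int = 30,
    seed: int = 0,
) -> MethylTable:
    """Two samples drawn from identical beta-binomial parameters: a
    null methylome for type-I-error calibration.  CG sites are laid
    out with realistic spacing so smoothing windows hold several
    pseudo-replicates."""
    rng = np.random.default_rng(seed)
    gaps = rng.integers(10, 2 * mean_spacing_bp - 9, size=n_sites)
    pos = np.cumsum(gaps) + 1
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "strand": "+", "context": "CG"}
    )
    meth = np.zeros((n_sites, 2), dtype=np.int64)
    total = np.zeros_like(meth)
    for j in range(2):
        p = _beta_draw(rng, np.full(n_sites, methyl_mean), site_dispersion)
        n = _truncated_poisson(rng, coverage_mean, n_sites)
        meth[:, j] = rng.binomial(n, p)
        total[:, j] = n
    return MethylTable(sites, ["A", "B"], meth, total)


def simulate_planted_dmr_pair(
    n_dmrs: int = 200,
    delta: float = 0.4,
    width_bp: int = 200,
    min_sites: int = 10,
    baseline: float = 0.3,
    coverage_mean: float = 30.0,
    site_dispersion: float = 0.01,
    mean_spacing_bp: int = 15,
    flank_bp: int = 2_000,
    seed: int = 0,
):
    """Two samples where sample B carries ``n_dmrs`` planted CG DMRs of
    mean shift ``delta`` over ``width_bp`` windows, separated by long
    null flanks.  Returns (MethylTable, truth DataFrame of spans)."""
    rng = np.random.default_rng(seed)
    pos_list, mu_a, mu_b, truth = [], [], [], []
    cursor = 1_000
    for _ in range(n_dmrs):
        # null flank
        p = cursor
        while p < cursor + flank_bp:
            pos_list.append(p)
            mu_a.append(baseline)
            mu_b.append(baseline)
            p += int(rng.integers(5, 2 * mean_spacing_bp - 4))
        # planted window (dense enough to guarantee min_sites)
        start = p
        k = 0
        last = p
        while p < start + width_bp or k < min_sites:
            pos_list.append(p)
            mu_a.append(baseline)
            mu_b.append(min(baseline + delta, 0.98))
            last = p
            p += int(rng.integers(5, 2 * mean_spacing_bp - 4))
            k += 1
        truth.append({"chrom": "chr1", "start": start, "end": last})
        cursor = p + flank_bp
    n_sites = len(pos_list)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": pos_list, "strand": "+", "context": "CG"}
    )
    meth = np.zeros((n_sites, 2), dtype=np.int64)
    total = np.zeros_like(meth)
    for j, mu in enumerate([np.array(mu_a), np.array(mu_b)]):
        pvals = _beta_draw(rng, mu, site_dispersion)
        n = _truncated_poisson(rng, coverage_mean, n_sites)
        meth[:, j] = rng.binomial(n, pvals)
        total[:, j] = n
    return (
        MethylTable(sites, ["A", "B"], meth, total),
        pd.DataFrame(truth),
    )


# ---------------------------------------------------------------------------
# one-call dataset emission


def simulate_all(config: SimConfig, outdir: str) -> dict[str, str]:
    """Emit a complete dataset directory: genome.fa, genes.gff3,
    methyl_<sample>.tsv per sample, counts.tsv, terms.tsv, truth/*.tsv
    and config.json.  Byte-identical for identical configs."""
    from .methylation_diff import write_cytosine_report

    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
    seqs, models, feat_truth = simulate_genome(config)
    table, dmr_truth, dem_truth = simulate_methylomes(config, seqs, models)
    counts = simulate_expression(config, models, dem_truth)
    terms = simulate_annotation(config, models, dem_truth)
    paths = {}
    paths["genome"] = os.path.join(outdir, "genome.fa")
    write_fasta(seqs, paths["genome"])
    paths["gff3"] = os.path.join(outdir, "genes.gff3")
    write_gff3(models, paths["gff3"])
    for s in table.samples:
        p = os.path.join(outdir, f"methyl_{s}.tsv")
        write_cytosine_report(table, s, p)
        paths[f"methyl_{s}"] = p
    paths["counts"] = os.path.join(outdir, "counts.tsv")
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    paths["terms"] = os.path.join(outdir, "terms.tsv")
    terms.to_csv(paths["terms"], sep="\t", index=False)
    for name, df in [
        ("features", feat_truth), ("dmrs", dmr_truth), ("dem", dem_truth),
    ]:
        p = os.path.join(outdir, "truth", f"{name}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    paths["config"] = os.path.join(outdir, "config.json")
    with open(paths["config"], "w") as fh:
        fh.write(config.to_json())
    return paths
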