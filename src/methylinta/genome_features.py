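"""Cytosine context annotation and gene-model feature partitioning.

Plant methylomes are read in three sequence contexts -- CG, CHG and CHH
(H = A, T or C) -- defined by the two bases immediately downstream of a
cytosine on its own strand.  Downstream analyses stratify every site by
context and by its position relative to gene models: a 5 kb upstream
flank, 5'UTR, exon, intron, 3'UTR, a 5 kb downstream flank, or
intergenic space.

All external coordinates are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CONTEXTS = ("CG", "CHG", "CHH")

FEATURES = (
    "upstream",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "downstream",
)

#: precedence when a position falls in several features of one gene
#: (UTRs are sub-intervals of exons in GFF3 but are tallied separately)
_FEATURE_RANK = {
    "five_prime_utr": 0,
    "three_prime_utr": 0,
    "exon": 1,
    "intron": 2,
    "upstream": 3,
    "downstream": 3,
}

FLANK_BP = 5_000

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class CytosineSite:
    """A genomic cytosine with strand and trinucleotide context class."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    context: str  # CG | CHG | CHH


@dataclass
class GeneModel:
    """A gene locus partitioned into the six feature classes.

    ``features`` holds (feature_class, start, end) with 1-based inclusive
    coordinates.  Flanks span :data:`FLANK_BP` on each side, oriented by
    gene strand (upstream = 5') and clipped at contig ends.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    features: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def _validate_alphabet(seq: np.ndarray, name: str) -> None:
    bad = ~np.isin(seq, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"non-nucleotide character {chr(seq[i])!r} at position {i + 1} in {name}"
        )


def call_contexts(genome: Iterable[tuple[str, str]]) -> Iterator[CytosineSite]:
    """Yield every cytosine on both strands with its resolved context.

    ``genome`` iterates (name, sequence) pairs over {A,C,G,T,N}.  A site's
    context depends on the two bases downstream on its own strand; CG is
    determinable from the first downstream base alone.  Sites whose context
    cannot be resolved (N or contig end in a deciding position) are skipped.
    """
    for name, seq in genome:
        s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        if s.size == 0:
            continue
        _validate_alphabet(s, name)
        for pos, strand, ctx in _contexts_one_seq(s):
            yield CytosineSite(name, pos, strand, ctx)


def _contexts_one_seq(s: np.ndarray) -> Iterator[tuple[int, str, str]]:
    """Contexts for one sequence (uint8 array), positions 1-based, sorted."""
    L = s.size
    A, C, G, T, N = (ord(c) for c in "ACGTN")

    def classify(b1: int | None, b2: int | None) -> str | None:
        # b1, b2 = first and second downstream base on the site's strand
        if b1 == G:
            return "CG"
        if b1 is None or b1 == N:
            return None
        # b1 is H (A/T/C)
        if b2 == G:
            return "CHG"
        if b2 is None or b2 == N:
            return None
        return "CHH"

    fwd = np.flatnonzero(s == C)
    rev = np.flatnonzero(s == G)
    comp = {A: T, T: A, C: G, G: C, N: N}
    # merge the two strands in position order
    fi = ri = 0
    while fi < fwd.size or ri < rev.size:
        take_fwd = ri >= rev.size or (fi < fwd.size and fwd[fi] <= rev[ri])
        if take_fwd:
            i = int(fwd[fi])
            fi += 1
            b1 = int(s[i + 1]) if i + 1 < L else None
            b2 = int(s[i + 2]) if i + 2 < L else None
            ctx = classify(b1, b2)
            if ctx is not None:
                yield i + 1, "+", ctx
        else:
            i = int(rev[ri])
            ri += 1
            b1 = comp[int(s[i - 1])] if i - 1 >= 0 else None
            b2 = comp[int(s[i - 2])] if i - 2 >= 0 else None
            ctx = classify(b1, b2)
            if ctx is not None:
                yield i + 1, "-", ctx


def context_table(genome: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Vectorized equivalent of :func:`call_contexts`: DataFrame with
    chrom, pos, strand, context, sorted by (chrom, pos, strand)."""
    A, C, G, T, N = (ord(c) for c in "ACGTN")
    frames = []
    for name, seq in genome:
        s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        if s.size == 0:
            continue
        _validate_alphabet(s, name)
        L = s.size
        pad = np.concatenate([s, [N, N]])

        def classify(b1, b2):
            # returns int codes: 0 CG, 1 CHG, 2 CHH, -1 unresolved
            is_h1 = (b1 == A) | (b1 == T) | (b1 == C)
            out = np.full(b1.shape, -1, dtype=np.int8)
            out[b1 == G] = 0
            out[is_h1 & (b2 == G)] = 1
            out[is_h1 & ((b2 == A) | (b2 == T) | (b2 == C))] = 2
            return out

        fwd = np.flatnonzero(s == C)
        cf = classify(pad[fwd + 1], pad[fwd + 2])
        comp = np.zeros(256, dtype=np.uint8)
        for x, y in ((A, T), (T, A), (C, G), (G, C), (N, N)):
            comp[x] = y
        rpad = np.concatenate([[N, N], s])
        rev = np.flatnonzero(s == G)
        cr = classify(comp[rpad[rev + 1]], comp[rpad[rev]])
        ctx_names = np.array(["CG", "CHG", "CHH"])
        for idx, codes, strand in ((fwd, cf, "+"), (rev, cr, "-")):
            ok = codes >= 0
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "pos": idx[ok] + 1,
                        "strand": strand,
                        "context": ctx_names[codes[ok]],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["chrom", "pos", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def call_contexts_fasta(fasta_path: str) -> Iterator[CytosineSite]:
    """:func:`call_contexts` over a FASTA file (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    yield from call_contexts((name, str(fa[name][:])) for name in fa.keys())


def sites_to_frame(sites: Iterable[CytosineSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(x.chrom, x.pos, x.strand, x.context) for x in sites],
        columns=["chrom", "pos", "strand", "context"],
    )


# ---------------------------------------------------------------------------
# gene models


def build_gene_models(
    gff3_path: str, contig_lengths: dict[str, int]
) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/UTR records into :class:`GeneModel` objects.

    Exons of all transcripts of a gene are unioned; introns are the gaps
    between merged exons; UTR records, when present, take precedence over
    the exon intervals they overlap.  Flanks of :data:`FLANK_BP` are added
    on each side, oriented by strand and clipped to [1, contig length].
    """
    import gffutils

    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.id} lacks a strand")
        exons = [
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        ]
        utr5 = [
            (f.start, f.end)
            for f in db.children(gene, featuretype="five_prime_UTR")
        ]
        utr3 = [
            (f.start, f.end)
            for f in db.children(gene, featuretype="three_prime_UTR")
        ]
        for st, en in exons:
            if st < gene.start or en > gene.end:
                raise ValueError(
                    f"exon {st}-{en} outside span of gene {gene.id}"
                )
        models.append(
            assemble_gene_model(
                gene.id,
                gene.seqid,
                gene.strand,
                gene.start,
                gene.end,
                exons or [(gene.start, gene.end)],
                utr5,
                utr3,
                contig_lengths[gene.seqid],
            )
        )
    return models


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for st, en in sorted(ivs):
        if out and st <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], en)
        else:
            out.append([st, en])
    return [(a, b) for a, b in out]


def _subtract(iv: tuple[int, int], cuts: list[tuple[int, int]]):
    """Parts of ``iv`` not covered by any of ``cuts`` (all 1-based incl.)."""
    segs = [iv]
    for cst, cen in cuts:
        nxt = []
        for st, en in segs:
            if cen < st or cst > en:
                nxt.append((st, en))
                continue
            if st < cst:
                nxt.append((st, cst - 1))
            if en > cen:
                nxt.append((cen + 1, en))
        segs = nxt
    return segs


def assemble_gene_model(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    exons: list[tuple[int, int]],
    utr5: list[tuple[int, int]],
    utr3: list[tuple[int, int]],
    contig_length: int,
) -> GeneModel:
    """Build the feature partition of one gene from its raw intervals."""
    exons = _merge_intervals(exons)
    utrs = _merge_intervals(utr5 + utr3)
    feats: list[tuple[str, int, int]] = []
    for st, en in _merge_intervals(utr5):
        feats.append(("five_prime_utr", st, en))
    for st, en in _merge_intervals(utr3):
        feats.append(("three_prime_utr", st, en))
    for ex in exons:
        for st, en in _subtract(ex, utrs):
            feats.append(("exon", st, en))
    for (_, e1), (s2, _) in itertools.pairwise(exons):
        if s2 > e1 + 1:
            feats.append(("intron", e1 + 1, s2 - 1))
    left = (max(1, start - FLANK_BP), start - 1)
    right = (end + 1, min(contig_length, end + FLANK_BP))
    if strand == "+":
        flanks = [("upstream", *left), ("downstream", *right)]
    else:
        flanks = [("upstream", *right), ("downstream", *left)]
    for name, st, en in flanks:
        if st <= en:
            feats.append((name, st, en))
    feats.sort(key=lambda f: (f[1], f[2]))
    return GeneModel(gene_id, chrom, strand, start, end, feats)


# ---------------------------------------------------------------------------
# feature assignment


class FeatureIndex:
    """Interval index over gene-model features for point/DMR labeling.

    Assignment is a total, deterministic function.  When a position falls
    in features of several genes (overlapping loci or adjacent flanks),
    the gene with the nearest TSS wins; remaining ties go to the
    lexicographically smaller gene id.  Within a gene, UTR beats exon
    beats intron beats flank.  Positions hitting no model are intergenic.
    """

    def __init__(self, models: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self._models = {m.gene_id: m for m in models}
        for m in self._models.values():
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            for feat, st, en in m.features:
                tree.addi(st, en + 1, (m.gene_id, feat))

    def assign(self, chrom: str, pos: int) -> tuple[str | None, str]:
        tree = self._trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return None, "intergenic"
        best = min(
            hits,
            key=lambda iv: (
                abs(pos - self._models[iv.data[0]].tss),
                iv.data[0],
                _FEATURE_RANK[iv.data[1]],
            ),
        )
        gene = best.data[0]
        # within the winning gene, pick the highest-precedence feature
        feat = min(
            (iv.data[1] for iv in hits if iv.data[0] == gene),
            key=lambda f: _FEATURE_RANK[f],
        )
        return gene, feat

    def assign_interval(self, chrom: str, start: int, end: int):
        """Label an interval (e.g. a DMR) by its midpoint."""
        return self.assign(chrom, (start + end) // 2)

    def assign_many(self, chrom: np.ndarray, pos: np.ndarray):
        """Vectorized :meth:`assign` for large site tables.

        Sweeps the sorted feature intervals once per chromosome:
        positions between consecutive interval boundaries share the
        same covering set, which is resolved once per segment when a
        single gene covers it and per position otherwise.
        """
        genes = np.full(len(pos), None, dtype=object)
        feats = np.full(len(pos), "intergenic", dtype=object)
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        for c in pd.unique(chrom):
            tree = self._trees.get(c)
            sel = np.flatnonzero(chrom == c)
            if tree is None or sel.size == 0:
                continue
            p = pos[sel]
            order = np.argsort(p, kind="mergesort")
            ps = p[order]
            bounds = sorted(
                {iv.begin for iv in tree} | {iv.end for iv in tree}
            )
            seg_lo = np.searchsorted(ps, bounds, side="left")
            prev_b = None
            for b, lo in zip(bounds + [None], list(seg_lo) + [len(ps)]):
                if prev_b is not None and lo > prev_lo:
                    qs = ps[prev_lo:lo]
                    hits = tree[int(prev_b)] if qs.size else ()
                    if hits:
                        gene_set = {iv.data[0] for iv in hits}
                        if len(gene_set) == 1:
                            g = next(iter(gene_set))
                            f = min(
                                (iv.data[1] for iv in hits),
                                key=lambda x: _FEATURE_RANK[x],
                            )
                            genes[sel[order[prev_lo:lo]]] = g
                            feats[sel[order[prev_lo:lo]]] = f
                        else:  # overlapping genes: resolve per position
                            for k in range(prev_lo, lo):
                                g, f = self.assign(c, int(ps[k]))
                                genes[sel[order[k]]] = g
                                feats[sel[order[k]]] = f
                prev_b, prev_lo = b, lo
        return genes, feats


def annotate_sites(
    sites: pd.DataFrame, index: FeatureIndex
) -> pd.DataFrame:
    """Add gene_id / feature columns to a site table (chrom, pos, ...)."""
    genes, feats = index.assign_many(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy()
    )
    out = sites.copy()
    out["gene_id"] = genes
    out["feature"] = feats
    return out
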