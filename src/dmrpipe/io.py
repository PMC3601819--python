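"""Per-cytosine methylation call I/O, context classification and feature extraction.

The on-disk call format is a tab-separated table with one row per cytosine::

    chrom  pos(1-based)  strand  context  n_meth  n_total

with optional ``#`` comment lines and transparent gzip. Internally everything is
0-based half-open; BED output follows BED conventions.

Methylation of a site (or of any pooled set of sites) is the fraction of
bisulfite reads calling it methylated, ``#C / (#C + #T)``; a site with no
coverage has *undefined* methylation (NaN), which is distinct from zero.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "CONTEXTS",
    "FEATURE_CLASSES",
    "CytosineCall",
    "MethylomeSample",
    "GeneModel",
    "CallFileParseError",
    "read_cytosine_calls",
    "write_cytosine_calls",
    "fractional_methylation",
    "classify_context",
    "cytosine_sites",
    "extract_features",
    "read_fasta",
    "write_fasta",
    "read_gene_models_gff3",
    "write_gene_models_gff3",
    "read_feature_bed",
    "write_feature_bed",
]

CONTEXTS = ("CG", "CHG", "CHH")
FEATURE_CLASSES = ("gene_body", "promoter", "downstream3p", "CDS", "intron", "TE_gene")

#: canonical column order of a calls table
CALL_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")


class CallFileParseError(ValueError):
    """Raised when a call file contains malformed lines; carries line numbers."""

    def __init__(self, path, problems: list[tuple[int, str]]):
        self.path = str(path)
        self.problems = problems
        head = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:5])
        more = "" if len(problems) <= 5 else f" (+{len(problems) - 5} more)"
        super().__init__(f"{path}: {head}{more}")


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine site with its bisulfite read counts (#C and #C + #T)."""

    chrom: str
    pos: int  # 0-based, forward-strand coordinate
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError("need 0 <= n_meth <= n_total")

    @property
    def fraction(self) -> float:
        return fractional_methylation(self.n_meth, self.n_total)


@dataclass
class MethylomeSample:
    """A sample's per-cytosine calls plus its unmethylated organelle controls.

    ``calls`` is a DataFrame with columns ``chrom, pos, strand, context,
    n_meth, n_total`` (one row per (chrom, pos, strand)); ``organelle_chroms``
    names chromosomes (chloroplast) that are biologically unmethylated and
    therefore usable for non-conversion error estimation.
    """

    sample_id: str
    calls: pd.DataFrame
    organelle_chroms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"calls table missing columns {missing}")
        self.organelle_chroms = frozenset(self.organelle_chroms)

    def nuclear_calls(self) -> pd.DataFrame:
        if not self.organelle_chroms:
            return self.calls
        return self.calls[~self.calls["chrom"].isin(self.organelle_chroms)]

    def organelle_calls(self) -> pd.DataFrame:
        return self.calls[self.calls["chrom"].isin(self.organelle_chroms)]


class PooledMethylation:
    """Pooled #C/(#C+#T) over arbitrary intervals via per-chromosome prefix sums."""

    def __init__(self, calls: pd.DataFrame, context: str | None = None) -> None:
        if context is not None:
            calls = calls[calls["context"] == context]
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in calls.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy(np.int64)
            order = np.argsort(pos, kind="stable")
            self._by_chrom[str(chrom)] = (
                pos[order],
                np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy(np.int64)[order])]),
                np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy(np.int64)[order])]),
            )

    def counts(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        if chrom not in self._by_chrom:
            return 0, 0
        pos, meth, total = self._by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(meth[hi] - meth[lo]), int(total[hi] - total[lo])

    def level(self, chrom: str, start: int, end: int) -> float:
        return fractional_methylation(*self.counts(chrom, start, end))


def fractional_methylation(n_meth: float, n_total: float) -> float:
    """#C / (#C + #T); NaN (undefined, not zero) when there is no coverage."""
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if n_total == 0:
        return math.nan
    return n_meth / n_total


# ---------------------------------------------------------------------------
# call-file I/O
# ---------------------------------------------------------------------------


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_calls(
    path,
    min_total: int = 0,
    sample_id: str | None = None,
    organelle_chroms: Iterable[str] = (),
) -> MethylomeSample:
    """Read a 6-column call file into a :class:`MethylomeSample`.

    Rows with ``n_total < min_total`` are dropped. Malformed lines (wrong
    column count, non-numeric counts, ``n_meth > n_total``, bad strand or
    context, pos < 1) raise :class:`CallFileParseError` naming the offending
    line numbers.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    problems: list[tuple[int, str]] = []
    chroms: list[str] = []
    rows: list[tuple[int, str, str, int, int]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                problems.append((lineno, f"expected 6 columns, got {len(fields)}"))
                continue
            chrom, pos_s, strand, context, nm_s, nt_s = fields
            try:
                pos = int(pos_s)
                n_meth = int(nm_s)
                n_total = int(nt_s)
            except ValueError:
                problems.append((lineno, "non-integer pos/counts"))
                continue
            if pos < 1:
                problems.append((lineno, f"pos must be >= 1 (got {pos})"))
                continue
            if strand not in ("+", "-"):
                problems.append((lineno, f"bad strand {strand!r}"))
                continue
            if context not in CONTEXTS:
                problems.append((lineno, f"bad context {context!r}"))
                continue
            if n_meth < 0 or n_total < 0 or n_meth > n_total:
                problems.append((lineno, f"invalid counts n_meth={n_meth} n_total={n_total}"))
                continue
            chroms.append(chrom)
            rows.append((pos - 1, strand, context, n_meth, n_total))
    if problems:
        raise CallFileParseError(path, problems)

    calls = pd.DataFrame(rows, columns=["pos", "strand", "context", "n_meth", "n_total"])
    calls.insert(0, "chrom", pd.Series(chroms, dtype=object))
    if len(calls):
        dup = calls.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise CallFileParseError(
                path, [(-1, f"{int(dup.sum())} duplicate (chrom, pos, strand) records")]
            )
        calls = calls[calls["n_total"] >= min_total].reset_index(drop=True)
    name = sample_id if sample_id is not None else path.name.split(".")[0]
    return MethylomeSample(name, calls, frozenset(organelle_chroms))


def write_cytosine_calls(sample: MethylomeSample, path) -> None:
    """Write the documented 6-column tab format (1-based positions)."""
    out = sample.calls.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    with _open_text(path, "wt") as handle:
        handle.write("#chrom\tpos\tstrand\tcontext\tn_meth\tn_total\n")
        out.to_csv(handle, sep="\t", header=False, index=False, columns=list(CALL_COLUMNS))


# ---------------------------------------------------------------------------
# sequence context
# ---------------------------------------------------------------------------


def classify_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at (chrom, pos, strand): CG, CHG, CHH or not_cytosine.

    On the forward strand the two bases 3' of the C decide the context (H = A,
    T or C). On the reverse strand the same rule applies to the reverse
    complement, i.e. a forward-strand G whose upstream neighbours are read
    complemented. Cytosines within 2 bp of the chromosome end that lack a full
    trinucleotide fall back to CHH; any N involved yields ``not_cytosine``.
    """
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"pos {pos} outside {chrom} (length {len(seq)})")
    if strand == "+":
        if seq[pos] != "C":
            return "not_cytosine"
        nxt = seq[pos + 1] if pos + 1 < len(seq) else None
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else None
        if nxt == "G":
            return "CG"
        if nxt is None:
            return "CHH"  # chromosome-end fallback
        if nxt not in "ACT":
            return "not_cytosine"  # N or other ambiguity code
        if nxt2 == "G":
            return "CHG"
        if nxt2 is None:
            return "CHH"
        if nxt2 not in "ACT":
            return "not_cytosine"
        return "CHH"
    if strand == "-":
        # cytosine on the minus strand is a forward-strand G; its 3' neighbours
        # on the minus strand are forward positions pos-1, pos-2 complemented.
        if seq[pos] != "G":
            return "not_cytosine"
        nxt = seq[pos - 1] if pos - 1 >= 0 else None
        nxt2 = seq[pos - 2] if pos - 2 >= 0 else None
        if nxt == "C":  # complement G
            return "CG"
        if nxt is None:
            return "CHH"
        if nxt not in "AGT":  # complement of H = {T, C, A} -> forward {A, G, T}
            return "not_cytosine"
        if nxt2 == "C":
            return "CHG"
        if nxt2 is None:
            return "CHH"
        if nxt2 not in "AGT":
            return "not_cytosine"
        return "CHH"
    raise ValueError(f"bad strand {strand!r}")


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i


_EDGE = np.int8(-2)  # past a chromosome end (distinct from N = -1)


def _contexts_from_neighbours(nxt: np.ndarray, nxt2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map (first, second) 3' neighbour codes to contexts; returns (keep, ctx)."""
    A, C, G, T = 0, 1, 2, 3
    h1 = (nxt == A) | (nxt == C) | (nxt == T)
    h2 = (nxt2 == A) | (nxt2 == C) | (nxt2 == T)
    cg = nxt == G
    chg = h1 & (nxt2 == G)
    # missing trinucleotide at a chromosome end falls back to CHH; N does not
    chh = (h1 & h2) | (nxt == _EDGE) | (h1 & (nxt2 == _EDGE))
    ctx = np.empty(nxt.shape, dtype=object)
    ctx[cg] = "CG"
    ctx[chg] = "CHG"
    ctx[chh & ~cg & ~chg] = "CHH"
    keep = cg | chg | chh
    return keep, ctx


def cytosine_sites(seq: str) -> pd.DataFrame:
    """All cytosines of a chromosome on both strands, with contexts, vectorized.

    Returns a DataFrame with columns ``pos, strand, context`` sorted by
    (pos, strand); sites whose context involves an ambiguity code are dropped.
    """
    code = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    n = code.size
    A, C, G, T = 0, 1, 2, 3

    def neighbours(pos: np.ndarray, offset1: int, offset2: int) -> tuple[np.ndarray, np.ndarray]:
        nxt = np.full(pos.size, _EDGE, dtype=np.int8)
        nxt2 = np.full(pos.size, _EDGE, dtype=np.int8)
        m1 = (pos + offset1 >= 0) & (pos + offset1 < n)
        nxt[m1] = code[pos[m1] + offset1]
        m2 = (pos + offset2 >= 0) & (pos + offset2 < n)
        nxt2[m2] = code[pos[m2] + offset2]
        return nxt, nxt2

    # forward strand: cytosine is C; neighbours at +1, +2
    fpos = np.flatnonzero(code == C)
    keep_f, ctx_f = _contexts_from_neighbours(*neighbours(fpos, 1, 2))

    # reverse strand: cytosine is a forward G; neighbours at -1, -2, complemented
    rpos = np.flatnonzero(code == G)
    nxt, nxt2 = neighbours(rpos, -1, -2)
    comp = np.array([T, G, C, A], dtype=np.int8)

    def comp_code(x: np.ndarray) -> np.ndarray:
        out = x.copy()
        ok = x >= 0
        out[ok] = comp[x[ok]]
        return out

    keep_r, ctx_r = _contexts_from_neighbours(comp_code(nxt), comp_code(nxt2))

    pos_all = np.concatenate([fpos[keep_f], rpos[keep_r]])
    strand_all = np.concatenate(
        [
            np.full(int(keep_f.sum()), "+", dtype=object),
            np.full(int(keep_r.sum()), "-", dtype=object),
        ]
    )
    ctx_all = np.concatenate([ctx_f[keep_f], ctx_r[keep_r]])
    # '+' < '-' is false in ASCII; order by (pos, + first) via the strand flag
    minus = strand_all == "-"
    order = np.lexsort((minus, pos_all))
    return pd.DataFrame(
        {"pos": pos_all[order], "strand": strand_all[order], "context": ctx_all[order]}
    )


# ---------------------------------------------------------------------------
# gene models and feature extraction
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene's transcribed span with exon structure.

    ``start``/``end`` bound the transcribed region genomically (0-based
    half-open). The TSS is the boundary coordinate at the 5' end in
    transcription orientation: ``start`` for + genes, ``end`` for - genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    is_te: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: TSS/TTS inverted or empty span")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


def extract_features(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> pd.DataFrame:
    """Derive classed intervals from gene models (the "FeatureSet").

    Protein-coding genes yield ``gene_body`` (the transcribed region),
    ``promoter`` (2 kb upstream of the TSS, strand-aware, truncated at
    chromosome edges), ``downstream3p`` (2 kb past the TTS), ``CDS`` (exons)
    and ``intron`` (gaps between exons). TE-classed genes yield ``TE_gene``
    intervals only.
    """
    records: list[tuple[str, int, int, str, str, str]] = []

    def add(chrom, start, end, cls, strand, gid):
        size = chrom_sizes[chrom]
        start, end = max(0, start), min(size, end)
        if start < end:
            records.append((chrom, start, end, cls, strand, gid))

    for gene in genes:
        if gene.chrom not in chrom_sizes:
            raise KeyError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom}")
        if gene.end > chrom_sizes[gene.chrom]:
            raise ValueError(f"gene {gene.gene_id} extends past chromosome end")
        if gene.is_te:
            add(gene.chrom, gene.start, gene.end, "TE_gene", gene.strand, gene.gene_id)
            continue
        add(gene.chrom, gene.start, gene.end, "gene_body", gene.strand, gene.gene_id)
        if gene.strand == "+":
            add(gene.chrom, gene.tss - promoter_bp, gene.tss, "promoter", "+", gene.gene_id)
            add(gene.chrom, gene.tts, gene.tts + downstream_bp, "downstream3p", "+", gene.gene_id)
        else:
            add(gene.chrom, gene.tss, gene.tss + promoter_bp, "promoter", "-", gene.gene_id)
            add(gene.chrom, gene.tts - downstream_bp, gene.tts, "downstream3p", "-", gene.gene_id)
        for exon_start, exon_end in gene.exons:
            add(gene.chrom, exon_start, exon_end, "CDS", gene.strand, gene.gene_id)
        prev_end = None
        for exon_start, exon_end in gene.exons:
            if prev_end is not None and exon_start > prev_end:
                add(gene.chrom, prev_end, exon_start, "intron", gene.strand, gene.gene_id)
            prev_end = exon_end
    frame = pd.DataFrame(
        records, columns=["chrom", "start", "end", "feature_class", "strand", "gene_id"]
    )
    return frame.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# FASTA / GFF3 / BED
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gene_models_gff3(genes: Sequence[GeneModel], path) -> None:
    """GFF3 with gene + exon rows; TE genes carry ``biotype=transposable_element``."""
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            biotype = "transposable_element" if gene.is_te else "protein_coding"
            attrs = f"ID={gene.gene_id};biotype={biotype}"
            handle.write(
                f"{gene.chrom}\tdmrpipe\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for i, (exon_start, exon_end) in enumerate(gene.exons, start=1):
                handle.write(
                    f"{gene.chrom}\tdmrpipe\texon\t{exon_start + 1}\t{exon_end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


def read_gene_models_gff3(path, te_attribute: str = "biotype", te_value: str = "transposable_element") -> list[GeneModel]:
    """Read gene models from GFF3 (gene + exon rows).

    TE genes are recognised by ``te_attribute=te_value`` on the gene row; the
    attribute name is configurable to cope with annotation dialects.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon", order_by="start")]
        is_te = te_value in g.attributes.get(te_attribute, [])
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons or [(g.start - 1, g.end)],
                is_te=is_te,
            )
        )
    return genes


def read_feature_bed(path) -> pd.DataFrame:
    """6-column BED with ``feature_class:gene_id`` in the name field."""
    rows = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            cls, _, gid = name.partition(":")
            rows.append((chrom, int(start), int(end), cls, strand, gid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_class", "strand", "gene_id"])


def write_feature_bed(features: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as handle:
        for row in features.itertuples(index=False):
            handle.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_class}:{row.gene_id}\t0\t{row.strand}\n"
            )
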