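"""Synthetic multi-sample methylomes with a truth ledger for recovery testing.

The generator emulates the data structure of a tissue-culture methylation
study in a plant genome: several wild-type plants, regenerants sampled at
successive selfed generations (T2/T4/T6), and callus, all sequenced at ~15x
with a realistic non-conversion error and an unmethylated chloroplast that
serves as the error-rate control.

True methylation is assigned per cytosine by locus class: intergenic/TE
background is methylated at high CG / mid CHG / low CHH levels; gene bodies
carry a CG-only gradient; promoters are mostly unmethylated except a
methylated subset whose CHH runs at an RdDM-island level — those methylated
loci are where hypomethylation can be planted. Each regenerant loses
methylation at each susceptible (planted) region independently with a shared
probability, so losses are partially shared across plants; the T4/T6
descendants of the first regenerant inherit its losses except for a small
recovering fraction. Callus gains CHH methylation at a distinct promoter
subset and regenerants do not inherit those gains.

Observed counts are Poisson coverage with binomial methylated calls at
``p_true * 1 + (1 - p_true) * error_rate`` — non-conversion only inflates
apparent methylation of unmethylated cytosines, which is exactly what
chloroplast-based error estimation measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, MethylomeSample, cytosine_sites

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_methylomes",
    "draw_counts",
    "simulate_smrna",
    "simulate_mrna",
    "write_truth",
    "read_truth",
]

ORGANELLE_CHROM = "chrC"

_STAGE_GENOME = 0
_STAGE_METH = 1
_STAGE_SMRNA = 2
_STAGE_MRNA = 3


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    chloroplast_length_bp: int = 20_000
    gc_content: float = 0.43
    n_genes: int = 100
    n_te_genes: int = 30

    # true methylation levels at methylated loci, by context
    baseline_meth: dict = field(default_factory=lambda: {"CG": 0.85, "CHG": 0.55, "CHH": 0.07})
    #: CHH level at RdDM-like islands (methylated promoters, TE genes); CHH
    #: hypo-DMRs are planted there because the genomic CHH background is far
    #: below the caller's 0.1 difference threshold
    chh_island_level: float = 0.25
    gene_body_cg_range: tuple = (0.3, 0.7)  # x CG baseline, 5'->3' gradient
    promoter_meth_fraction: float = 0.3  # promoters carrying methylation

    coverage_mean: float = 15.0
    error_rate: float = 0.012

    n_planted_dmrs: dict = field(default_factory=lambda: {"CG": 50, "CHG": 50, "CHH": 50})
    dmr_delta: dict = field(default_factory=lambda: {"CG": 0.8, "CHG": 0.6, "CHH": 0.15})
    dmr_length_bp: dict = field(default_factory=lambda: {"CG": 400, "CHG": 500, "CHH": 500})
    promoter_enrichment_fraction: float = 0.5
    shared_site_fraction: float = 0.5
    recovery_t4: float = 0.10
    recovery_t6_only: float = 0.044
    recovery_transient: float = 0.02

    n_regenerants: int = 3  # independent T2 plants; the first has T4/T6 descendants
    n_wildtypes: int = 2
    callus_chh_hyper: bool = True
    n_callus_hyper: int = 40
    callus_hyper_gain: float = 0.2

    de_fold: float = 4.0
    responsiveness: float = 0.3
    mrna_mean: float = 200.0
    mrna_dispersion: float = 0.05
    mrna_library_size: float | None = None  # None -> per-sample column sums
    smrna_window_bp: int = 50
    smrna_scale_24nt: float = 4.0  # expected 24-nt reads per window at full CHH methylation
    smrna_background_21nt: float = 0.2  # expected 21-nt reads per window

    def validate(self) -> None:
        probs = [
            self.gc_content,
            self.promoter_meth_fraction,
            self.promoter_enrichment_fraction,
            self.shared_site_fraction,
            self.recovery_t4,
            self.recovery_t6_only,
            self.recovery_transient,
            self.responsiveness,
            self.error_rate,
            *self.baseline_meth.values(),
            self.chh_island_level,
        ]
        if any(not 0 <= x <= 1 for x in probs):
            raise ValueError("all probabilities/levels must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.recovery_t4 + self.recovery_t6_only + self.recovery_transient > 1:
            raise ValueError("recovery probabilities exceed 1")
        # a dmr_delta above the planting level is permitted: the multiplicative
        # loss floors at 0 and the realised difference equals the level itself

    def _planting_level(self, context: str) -> float:
        """True methylation at loci where hypo-DMRs of `context` are planted."""
        return self.chh_island_level if context == "CHH" else self.baseline_meth[context]

    def sample_ids(self) -> list[str]:
        ids = [f"WT{i + 1}" for i in range(self.n_wildtypes)]
        for r in range(1, self.n_regenerants + 1):
            ids.append(f"R{r}_T2")
        if self.n_regenerants >= 1:
            ids += ["R1_T4", "R1_T6"]
        if self.callus_chh_hyper:
            ids.append("Callus")
        return ids


@dataclass
class SimTruth:
    """Everything the generator knows: the acceptance oracle."""

    config: SimConfig
    site_table: pd.DataFrame  # chrom, pos, strand, context, organelle(bool)
    p_true: dict  # sample_id -> float32 array aligned to site_table
    planted: pd.DataFrame  # dmr_id, chrom, start, end, context, level, delta
    loss: pd.DataFrame  # bool; index dmr_id, columns regenerant/generation samples
    stability: pd.Series  # category per dmr_id lost in R1_T2, else NA
    callus_hyper: pd.DataFrame  # chrom, start, end
    responsive_genes: frozenset = frozenset()
    de_genes: dict = field(default_factory=dict)  # sample_id -> frozenset of gene ids

    def planted_of_context(self, context: str) -> pd.DataFrame:
        return self.planted[self.planted["context"] == context].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig):
    """Random genome, gene/TE annotation and a chloroplast control chromosome.

    Returns ``(genome, genes, chrom_sizes, organelle_chroms)``. Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_GENOME])
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def random_seq(length: int) -> str:
        return bases[rng.choice(4, size=length, p=base_p)].tobytes().decode("ascii")

    genome: dict[str, str] = {}
    chrom_sizes: dict[str, int] = {}
    for i in range(config.n_chroms):
        name = f"chr{i + 1}"
        genome[name] = random_seq(config.chrom_length_bp)
        chrom_sizes[name] = config.chrom_length_bp
    genome[ORGANELLE_CHROM] = random_seq(config.chloroplast_length_bp)
    chrom_sizes[ORGANELLE_CHROM] = config.chloroplast_length_bp

    genes = _place_genes(config, rng)
    return genome, genes, chrom_sizes, frozenset({ORGANELLE_CHROM})


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    total = config.n_genes + config.n_te_genes
    if total == 0:
        return []
    margin = 2500  # room for the 2 kb promoter/downstream plus spacing
    per_chrom = [total // config.n_chroms] * config.n_chroms
    for i in range(total - sum(per_chrom)):
        per_chrom[i] += 1
    te_flags = np.zeros(total, dtype=bool)
    te_flags[: config.n_te_genes] = True
    rng.shuffle(te_flags)

    genes: list[GeneModel] = []
    k = 0
    for ci, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        chrom = f"chr{ci + 1}"
        slot = config.chrom_length_bp // n_here
        if slot < 2 * margin + 1000:
            raise ValueError(
                f"genome too short: {n_here} genes on a {config.chrom_length_bp} bp "
                "chromosome leave no room for gene models"
            )
        for j in range(n_here):
            lo = j * slot + margin
            hi = (j + 1) * slot - margin
            if te_flags[k]:
                length = int(rng.integers(1000, 3001))
                exons = None
            else:
                n_exons = int(rng.integers(1, 5))
                exon_lens = rng.integers(200, 601, size=n_exons)
                intron_lens = rng.integers(100, 401, size=max(0, n_exons - 1))
                length = int(exon_lens.sum() + intron_lens.sum())
            length = min(length, hi - lo - 1)
            start = int(rng.integers(lo, hi - length))
            strand = "+" if rng.random() < 0.5 else "-"
            if te_flags[k]:
                exons = [(start, start + length)]
            else:
                exons = []
                cursor = start
                for e in range(n_exons):
                    exon_end = min(cursor + int(exon_lens[e]), start + length)
                    if exon_end > cursor:
                        exons.append((cursor, exon_end))
                    cursor = exon_end
                    if e < n_exons - 1:
                        cursor += int(intron_lens[e])
                    if cursor >= start + length:
                        break
                exons[-1] = (exons[-1][0], start + length)
            genes.append(
                GeneModel(
                    gene_id=f"{'te' if te_flags[k] else 'g'}{k + 1:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=start + length,
                    exons=exons,
                    is_te=bool(te_flags[k]),
                )
            )
            k += 1
    return genes


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def _build_site_table(genome: Mapping[str, str], organelle: frozenset) -> pd.DataFrame:
    frames = []
    for chrom in genome:
        sites = cytosine_sites(genome[chrom])
        sites.insert(0, "chrom", chrom)
        sites["organelle"] = chrom in organelle
        frames.append(sites)
    return pd.concat(frames, ignore_index=True)


class _SiteIndex:
    """Row-range lookup into a site table sorted by (chrom block, pos)."""

    def __init__(self, site_table: pd.DataFrame) -> None:
        chroms = site_table["chrom"].to_numpy()
        self.pos = site_table["pos"].to_numpy(np.int64)
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(chroms)]])
        self.blocks = {
            str(chroms[bounds[i]]): (int(bounds[i]), int(bounds[i + 1]))
            for i in range(len(bounds) - 1)
        }

    def rows(self, chrom: str, start: int, end: int) -> slice:
        lo, hi = self.blocks[chrom]
        i0 = lo + int(np.searchsorted(self.pos[lo:hi], start, side="left"))
        i1 = lo + int(np.searchsorted(self.pos[lo:hi], end, side="left"))
        return slice(i0, i1)


def _assign_base_p(
    site_table: pd.DataFrame, genes: Sequence[GeneModel], config: SimConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Wild-type per-site methylation probability plus the promoter registry."""
    p = np.zeros(len(site_table), dtype=np.float32)
    ctx = site_table["context"].to_numpy()
    organelle = site_table["organelle"].to_numpy()
    for context, level in config.baseline_meth.items():
        p[(ctx == context) & ~organelle] = level

    pos = site_table["pos"].to_numpy(np.int64)
    index = _SiteIndex(site_table)

    lo_frac, hi_frac = config.gene_body_cg_range
    cg_base = config.baseline_meth["CG"]
    promoter_rows = []
    rng = np.random.default_rng([config.seed, _STAGE_METH, 0])
    for gene in genes:
        if gene.is_te:
            body = index.rows(gene.chrom, gene.start, gene.end)
            block = p[body]
            block[ctx[body] == "CHH"] = config.chh_island_level
            continue
        body = index.rows(gene.chrom, gene.start, gene.end)
        block = p[body]
        bctx = ctx[body]
        # CG-only gene-body gradient rising 5'->3'
        sel = bctx == "CG"
        if sel.any():
            rel = (pos[body][sel] - gene.start) / max(1, gene.end - gene.start)
            if gene.strand == "-":
                rel = 1 - rel
            block[sel] = (lo_frac + (hi_frac - lo_frac) * rel) * cg_base
        block[~sel] = 0.0
        p[body] = block
        if gene.strand == "+":
            prom_start, prom_end = max(0, gene.tss - 2000), gene.tss
        else:
            prom_start, prom_end = gene.tss, gene.tss + 2000
        methylated = rng.random() < config.promoter_meth_fraction
        prom = index.rows(gene.chrom, prom_start, prom_end)
        block = p[prom]
        pctx = ctx[prom]
        if methylated:
            block[pctx == "CG"] = config.baseline_meth["CG"]
            block[pctx == "CHG"] = config.baseline_meth["CHG"]
            block[pctx == "CHH"] = config.chh_island_level
        else:
            block[:] = 0.0
        p[prom] = block
        promoter_rows.append((gene.chrom, prom_start, prom_end, gene.gene_id, methylated))
    promoters = pd.DataFrame(
        promoter_rows, columns=["chrom", "start", "end", "gene_id", "methylated"]
    )
    p[organelle] = 0.0
    return p, promoters


def _plant_dmrs(
    site_table: pd.DataFrame,
    promoters: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose susceptible regions per context, enriched in methylated promoters.

    Every planted region is required to contain at least one 100-bp bin with
    >= 10 cytosines of its context so the caller's informative filter can be
    satisfied at the configured coverage.
    """
    ctx = site_table["context"].to_numpy()
    pos = site_table["pos"].to_numpy(np.int64)
    index = _SiteIndex(site_table)

    meth_promoters = promoters[promoters["methylated"]].reset_index(drop=True)
    te_genes = [g for g in genes if g.is_te]
    nuclear = [c for c in chrom_sizes if c != ORGANELLE_CHROM]

    # intergenic = outside gene spans +/- 2.2 kb
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}
    for gene in genes:
        blocked[gene.chrom].append((max(0, gene.start - 2200), gene.end + 2200))
    intergenic: dict[str, list[tuple[int, int]]] = {}
    for chrom in nuclear:
        segs, cursor = [], 0
        for s, e in sorted(blocked[chrom]):
            if s > cursor:
                segs.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < chrom_sizes[chrom]:
            segs.append((cursor, chrom_sizes[chrom]))
        intergenic[chrom] = segs

    used: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}

    def free(chrom, start, end):
        return all(e <= start or s >= end for s, e in used[chrom])

    def dense_enough(chrom, start, end, context):
        # the region must hold >= 10 context cytosines overall AND one whole
        # 100-bp caller bin with >= 10, fully inside the region: an edge bin
        # mixes planted and unplanted sites, diluting its pooled difference
        rows = index.rows(chrom, start, end)
        sel = ctx[rows] == context
        if int(sel.sum()) < 10:
            return False
        site_pos = pos[rows][sel]
        first_full = -(-start // 100)  # ceil
        last_full = end // 100  # exclusive
        if last_full <= first_full:
            return False
        bins = site_pos // 100
        inside = (bins >= first_full) & (bins < last_full)
        if not inside.any():
            return False
        counts = np.bincount(bins[inside] - first_full, minlength=last_full - first_full)
        return int(counts.max()) >= 10

    rows = []
    dmr_id = 0
    for context in ("CG", "CHG", "CHH"):
        n_wanted = config.n_planted_dmrs.get(context, 0)
        length = config.dmr_length_bp[context]
        level = config._planting_level(context)
        delta = config.dmr_delta[context]
        n_promoter = int(round(n_wanted * config.promoter_enrichment_fraction))
        for i in range(n_wanted):
            in_promoter = i < n_promoter
            placed = False
            for _attempt in range(500):
                if in_promoter:
                    if meth_promoters.empty:
                        break
                    prom = meth_promoters.iloc[int(rng.integers(len(meth_promoters)))]
                    span_chrom, span_s, span_e = prom["chrom"], prom["start"], prom["end"]
                elif context == "CHH":
                    # CHH islands outside promoters live at TE genes
                    if not te_genes:
                        break
                    te = te_genes[int(rng.integers(len(te_genes)))]
                    span_chrom, span_s, span_e = te.chrom, te.start, te.end
                else:
                    segs = [
                        (chrom, s, e)
                        for chrom in nuclear
                        for s, e in intergenic[chrom]
                        if e - s >= length
                    ]
                    if not segs:
                        break
                    span_chrom, span_s, span_e = segs[int(rng.integers(len(segs)))]
                if span_e - span_s < length:
                    continue
                start = int(rng.integers(span_s, span_e - length + 1))
                end = start + length
                if not free(span_chrom, start, end):
                    continue
                if not dense_enough(span_chrom, start, end, context):
                    continue
                used[span_chrom].append((start, end))
                rows.append(
                    (f"dmr{dmr_id:05d}", span_chrom, start, end, context, level, delta,
                     bool(in_promoter))
                )
                dmr_id += 1
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place planted {context} DMR #{i}: genome too small or "
                    "too few methylated loci"
                )
    return pd.DataFrame(
        rows,
        columns=["dmr_id", "chrom", "start", "end", "context", "level", "delta", "in_promoter"],
    )


def draw_counts(
    truth: SimTruth,
    sample_id: str,
    seed,
    coverage_mean: float | None = None,
    contexts: Iterable[str] | None = None,
) -> MethylomeSample:
    """Draw an observed methylome for `sample_id` from its true probabilities.

    Coverage is Poisson; methylated calls are binomial at
    ``p + (1 - p) * error_rate``. Zero-coverage sites are dropped. A fresh
    `seed` gives an independent technical replicate of the same truth.
    Restricting ``contexts`` draws only those sites (cheaper replicates when
    one context is analysed).
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    sites = truth.site_table
    p = truth.p_true[sample_id].astype(np.float64)
    if contexts is not None:
        sel = sites["context"].isin(list(contexts)).to_numpy()
        sites = sites[sel]
        p = p[sel]
    cov = coverage_mean if coverage_mean is not None else config.coverage_mean
    n_total = rng.poisson(cov, size=p.size)
    p_obs = p + (1 - p) * config.error_rate
    n_meth = rng.binomial(n_total, p_obs)
    keep = n_total > 0
    if keep.all():
        keep = slice(None)
    calls = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[keep],
            "pos": sites["pos"].to_numpy()[keep],
            "strand": sites["strand"].to_numpy()[keep],
            "context": sites["context"].to_numpy()[keep],
            "n_meth": n_meth[keep],
            "n_total": n_total[keep],
        }
    )
    return MethylomeSample(sample_id, calls, frozenset({ORGANELLE_CHROM}))


def simulate_methylomes(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    config: SimConfig,
):
    """Simulate all samples' methylomes; returns (samples dict, SimTruth)."""
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_METH, 1])
    site_table = _build_site_table(genome, frozenset({ORGANELLE_CHROM}))
    p_base, promoters = _assign_base_p(site_table, genes, config)
    planted = _plant_dmrs(site_table, promoters, genes, chrom_sizes, config, rng)

    ctx = site_table["context"].to_numpy()
    index = _SiteIndex(site_table)

    def region_rows(chrom, start, end, context) -> np.ndarray:
        rows = index.rows(chrom, start, end)
        return np.arange(rows.start, rows.stop)[ctx[rows] == context]

    region_idx = {
        row.dmr_id: region_rows(row.chrom, row.start, row.end, row.context)
        for row in planted.itertuples(index=False)
    }

    sample_ids = config.sample_ids()
    t2_regenerants = [s for s in sample_ids if s.endswith("_T2")]

    # per-regenerant stochastic loss at susceptible regions
    loss_cols: dict[str, np.ndarray] = {}
    for sid in t2_regenerants:
        loss_cols[sid] = rng.random(len(planted)) < config.shared_site_fraction

    # inheritance with per-region recovery for the R1 lineage
    categories = np.array(["stable_loss", "recovered_T4", "recovered_T6_only", "transient_T4"])
    probs = np.array(
        [
            1 - config.recovery_t4 - config.recovery_t6_only - config.recovery_transient,
            config.recovery_t4,
            config.recovery_t6_only,
            config.recovery_transient,
        ]
    )
    stability = pd.Series(pd.NA, index=planted["dmr_id"], dtype=object)
    if "R1_T2" in loss_cols:
        lost_t2 = loss_cols["R1_T2"]
        drawn = categories[rng.choice(4, size=len(planted), p=probs)]
        stability[:] = np.where(lost_t2, drawn, None)
        lost_t4 = lost_t2 & np.isin(drawn, ["stable_loss", "recovered_T6_only"])
        lost_t6 = lost_t2 & np.isin(drawn, ["stable_loss", "transient_T4"])
        loss_cols["R1_T4"] = lost_t4
        loss_cols["R1_T6"] = lost_t6
    loss = pd.DataFrame(loss_cols, index=planted["dmr_id"])

    # callus CHH hypermethylation at a distinct, unmethylated promoter subset
    callus_rows = []
    if config.callus_chh_hyper:
        free_promoters = promoters[~promoters["methylated"]].reset_index(drop=True)
        n_pick = min(config.n_callus_hyper, len(free_promoters))
        picks = rng.choice(len(free_promoters), size=n_pick, replace=False)
        for idx in np.sort(picks):
            row = free_promoters.iloc[int(idx)]
            callus_rows.append((row["chrom"], int(row["start"]), int(row["end"])))
    callus_hyper = pd.DataFrame(callus_rows, columns=["chrom", "start", "end"])

    # assemble per-sample true probabilities
    p_true: dict[str, np.ndarray] = {}
    for sid in sample_ids:
        p = p_base.copy()
        if sid in loss.columns:
            for row in planted.itertuples(index=False):
                if loss.at[row.dmr_id, sid]:
                    factor = max(0.0, 1.0 - row.delta / row.level)
                    idx = region_idx[row.dmr_id]
                    p[idx] = p[idx] * factor
        if sid == "Callus":
            for crow in callus_hyper.itertuples(index=False):
                idx = region_rows(crow.chrom, crow.start, crow.end, "CHH")
                p[idx] = np.minimum(1.0, p[idx] + config.callus_hyper_gain)
        p_true[sid] = p

    truth = SimTruth(
        config=config,
        site_table=site_table,
        p_true=p_true,
        planted=planted,
        loss=loss,
        stability=stability,
        callus_hyper=callus_hyper,
    )
    samples = {
        sid: draw_counts(truth, sid, [config.seed, _STAGE_METH, 2, i])
        for i, sid in enumerate(sample_ids)
    }
    return samples, truth


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------


def simulate_smrna(
    truth: SimTruth, config: SimConfig | None = None, sample_ids: Iterable[str] | None = None
) -> dict[str, pd.DataFrame]:
    """24-nt siRNA counts tracking true CHH methylation, plus 21-nt background.

    Windows of ``smrna_window_bp`` tile the nuclear genome; the 24-nt count in
    a window is Poisson with rate proportional to the sample's mean true CHH
    methylation there, so a regenerant that lost a CHH region also loses its
    24-nt reads. The 21-nt background is methylation-independent.
    """
    config = config or truth.config
    if sample_ids is None:
        sample_ids = list(truth.p_true)
    rng = np.random.default_rng([config.seed, _STAGE_SMRNA])
    sites = truth.site_table
    nuclear = ~sites["organelle"].to_numpy()
    chh = nuclear & (sites["context"].to_numpy() == "CHH")
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy(np.int64)

    out: dict[str, pd.DataFrame] = {}
    for sid in sample_ids:
        p = truth.p_true[sid]
        rows = []
        for chrom in pd.unique(chroms[nuclear]):
            sel = chh & (chroms == chrom)
            if not sel.any():
                continue
            size = int(pos[chroms == chrom].max()) + 1
            n_windows = size // config.smrna_window_bp + 1
            win = pos[sel] // config.smrna_window_bp
            sum_p = np.bincount(win, weights=p[sel], minlength=n_windows)
            n_sites = np.bincount(win, minlength=n_windows)
            mean_chh = np.divide(
                sum_p, n_sites, out=np.zeros_like(sum_p), where=n_sites > 0
            )
            c24 = rng.poisson(config.smrna_scale_24nt * mean_chh)
            c21 = rng.poisson(config.smrna_background_21nt, size=n_windows)
            starts = np.arange(n_windows) * config.smrna_window_bp
            for length, counts in ((24, c24), (21, c21)):
                nz = counts > 0
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "start": starts[nz],
                            "length": length,
                            "count": counts[nz],
                        }
                    )
                )
        out[sid] = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["chrom", "start", "length", "count"])
        )
    return out


# ---------------------------------------------------------------------------
# mRNA
# ---------------------------------------------------------------------------


def simulate_mrna(
    truth: SimTruth,
    genes: Sequence[GeneModel],
    config: SimConfig | None = None,
    sample_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene negative-binomial counts; promoter hypomethylation upregulates.

    A gene is *responsive* with probability ``responsiveness`` (drawn once).
    In a sample where a responsive gene's promoter overlaps a lost planted
    DMR, its mean is multiplied by ``de_fold``. Returns (counts table, library
    sizes); fills ``truth.responsive_genes`` and ``truth.de_genes``.
    """
    config = config or truth.config
    if sample_ids is None:
        sample_ids = list(truth.p_true)
    sample_ids = list(sample_ids)
    rng = np.random.default_rng([config.seed, _STAGE_MRNA])
    coding = [g for g in genes if not g.is_te]
    responsive = np.array([rng.random() < config.responsiveness for _ in coding])
    truth.responsive_genes = frozenset(
        g.gene_id for g, r in zip(coding, responsive) if r
    )

    def promoter(gene: GeneModel) -> tuple[str, int, int]:
        if gene.strand == "+":
            return gene.chrom, max(0, gene.tss - 2000), gene.tss
        return gene.chrom, gene.tss, gene.tss + 2000

    planted = truth.planted
    counts = {}
    disp = config.mrna_dispersion
    for sid in sample_ids:
        lost_ids = (
            set(truth.loss.index[truth.loss[sid]]) if sid in truth.loss.columns else set()
        )
        lost = planted[planted["dmr_id"].isin(lost_ids)]
        de_here = set()
        mu = np.full(len(coding), config.mrna_mean)
        for gi, gene in enumerate(coding):
            chrom, s, e = promoter(gene)
            hit = (
                (lost["chrom"] == chrom) & (lost["start"] < e) & (lost["end"] > s)
            ).any()
            if hit and responsive[gi]:
                mu[gi] *= config.de_fold
                de_here.add(gene.gene_id)
        truth.de_genes[sid] = frozenset(de_here)
        if disp > 0:
            n = 1.0 / disp
            counts[sid] = rng.negative_binomial(n, n / (n + mu))
        else:
            counts[sid] = rng.poisson(mu)
    table = pd.DataFrame(counts, index=[g.gene_id for g in coding])
    table.index.name = "gene_id"
    if config.mrna_library_size is not None:
        libsizes = pd.Series(float(config.mrna_library_size), index=table.columns)
    else:
        libsizes = table.sum(axis=0).astype(float)
    libsizes.name = "library_size"
    return table, libsizes


# ---------------------------------------------------------------------------
# truth ledger I/O (tab-separated, versioned header)
# ---------------------------------------------------------------------------

_TRUTH_VERSION = "dmrpipe-truth\tv1"


def write_truth(truth: SimTruth, path) -> None:
    """Persist the recoverable parts of the truth (not per-site arrays)."""
    with open(path, "wt") as fh:
        fh.write(f"#{_TRUTH_VERSION}\n")
        fh.write("##planted\n")
        planted = truth.planted.copy()
        planted["stability"] = truth.stability.reindex(planted["dmr_id"]).to_numpy()
        for sid in truth.loss.columns:
            planted[f"lost_{sid}"] = truth.loss[sid].reindex(planted["dmr_id"]).to_numpy()
        planted.to_csv(fh, sep="\t", index=False)
        fh.write("##callus_hyper\n")
        truth.callus_hyper.to_csv(fh, sep="\t", index=False)
        fh.write("##de_genes\n")
        fh.write("sample_id\tgene_id\n")
        for sid, gids in truth.de_genes.items():
            for gid in sorted(gids):
                fh.write(f"{sid}\t{gid}\n")


def read_truth(path) -> dict:
    """Read the truth ledger back as plain DataFrames keyed by section."""
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        first = fh.readline()
        if _TRUTH_VERSION not in first:
            raise ValueError(f"{path}: not a dmrpipe truth ledger")
        for line in fh:
            if line.startswith("##"):
                current = line[2:].strip()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    import io as _io

    return {
        name: pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
        for name, lines in sections.items()
        if lines
    }
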