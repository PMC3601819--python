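"""End-to-end orchestration: simulate, call, compare, enrich, integrate.

The pipeline config is a YAML file (or :class:`PipelineConfig`); every output
is listed in a tab-separated manifest with SHA-256 checksums so a rerun with
the same seed can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare, enrichment, expression, metaprofile, simulate
from .dmr import DMRCallingParams, call_dmrs, dmrs_to_frame, estimate_error_rate, write_dmr_bed
from .intervals import GenomicInterval
from .io import (
    CONTEXTS,
    extract_features,
    write_cytosine_calls,
    write_fasta,
    write_feature_bed,
    write_gene_models_gff3,
)

logger = logging.getLogger("dmrpipe")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_to_disk", "PRESETS"]

PRESETS = {
    "small": simulate.SimConfig(
        n_chroms=2,
        chrom_length_bp=400_000,
        n_genes=40,
        n_te_genes=12,
        n_planted_dmrs={"CG": 12, "CHG": 8, "CHH": 8},
        n_callus_hyper=10,
    ),
    "default": simulate.SimConfig(),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    outdir: str = "dmrpipe_out"
    seed: int = 0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    params: DMRCallingParams = field(default_factory=DMRCallingParams)
    control_id: str = "WT1"
    de_control_id: str = "WT2"
    n_random_sets: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simulate.SimConfig(**raw.pop("sim", {}))
        params_raw = raw.pop("params", {})
        params = DMRCallingParams(**params_raw)
        config = cls(sim=sim, params=params, **raw)
        return config

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["sim"] = dataclasses.asdict(self.sim)
        raw["params"] = dataclasses.asdict(self.params)
        raw["params"]["min_abs_diff"] = dict(self.params.min_abs_diff)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def simulate_to_disk(config: simulate.SimConfig, outdir) -> dict:
    """Run the generator and write every input file the analysis consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, chrom_sizes, organelle = simulate.simulate_genome(config)
    samples, truth = simulate.simulate_methylomes(genome, genes, chrom_sizes, config)
    smrna = simulate.simulate_smrna(truth)
    mrna, libsizes = simulate.simulate_mrna(truth, genes)

    write_fasta(genome, outdir / "genome.fa")
    write_gene_models_gff3(genes, outdir / "annotation.gff3")
    features = extract_features(genes, chrom_sizes)
    write_feature_bed(features, outdir / "features.bed")
    for sid, sample in samples.items():
        write_cytosine_calls(sample, outdir / f"{sid}.calls.tsv")
    for sid, table in smrna.items():
        expression.write_smrna_table(table, outdir / f"{sid}.smrna.tsv")
    mrna.to_csv(outdir / "mrna_counts.tsv", sep="\t")
    libsizes.to_csv(outdir / "mrna_libsizes.tsv", sep="\t", header=True)
    simulate.write_truth(truth, outdir / "truth.tsv")
    return {
        "genome": genome,
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "organelle": organelle,
        "samples": samples,
        "truth": truth,
        "smrna": smrna,
        "mrna": mrna,
        "libsizes": libsizes,
        "features": features,
    }


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute every stage on a simulated dataset; returns the manifest.

    Stages: simulation -> error rates -> per-context DMR calling per sample ->
    comparative analyses (overlap matrix, common DMRs, clustering, stability)
    -> feature enrichment -> differential expression + siRNA -> metaprofiles.
    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    written so far are listed in ``MANIFEST.partial``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    outputs: list[Path] = []
    stage = "simulate"
    try:
        data = simulate_to_disk(sim, outdir / "inputs")
        outputs += sorted((outdir / "inputs").iterdir())
        samples = data["samples"]
        truth = data["truth"]
        chrom_sizes = data["chrom_sizes"]
        nuclear = {c: s for c, s in chrom_sizes.items() if c != simulate.ORGANELLE_CHROM}
        genome_size = sum(nuclear.values())
        features = data["features"]
        control = samples[config.control_id]

        stage = "error_rate"
        rows = [
            (sid, ctx, estimate_error_rate(s, ctx))
            for sid, s in samples.items()
            for ctx in CONTEXTS
        ]
        err = pd.DataFrame(rows, columns=["sample_id", "context", "error_rate"])
        err.to_csv(outdir / "error_rates.tsv", sep="\t", index=False)
        outputs.append(outdir / "error_rates.tsv")

        stage = "call_dmrs"
        dmr_sets: dict[str, dict[str, list]] = {}
        for sid, sample in samples.items():
            if sid == config.control_id:
                continue
            dmr_sets[sid] = {}
            for ctx in CONTEXTS:
                dmrs = call_dmrs(sample, control, config.params, ctx, nuclear)
                dmr_sets[sid][ctx] = dmrs
                path = outdir / f"dmrs.{sid}.{ctx}.bed"
                write_dmr_bed(dmrs, path)
                outputs.append(path)
        logger.info("called DMRs for %d samples", len(dmr_sets))

        stage = "comparative"
        cg_hypo = {
            sid: [d for d in sets["CG"] if d.direction == "hypo"]
            for sid, sets in dmr_sets.items()
        }
        ov = compare.overlap_matrix(cg_hypo)
        ov.to_csv(outdir / "overlap_matrix.tsv", sep="\t")
        outputs.append(outdir / "overlap_matrix.tsv")
        regen = [sid for sid in cg_hypo if sid.startswith("R") and cg_hypo[sid]]
        if len(regen) >= 2:
            common = compare.common_dmrs([cg_hypo[sid] for sid in regen])
            pd.DataFrame(
                [(c.chrom, c.start, c.end) for c in common],
                columns=["chrom", "start", "end"],
            ).to_csv(outdir / "common_dmrs.tsv", sep="\t", index=False)
            outputs.append(outdir / "common_dmrs.tsv")
        else:
            common = []
        union: list[GenomicInterval] = []
        seen: set[tuple] = set()
        for sid in regen:
            for d in cg_hypo[sid]:
                key = (d.chrom, d.start, d.end)
                if key not in seen and all(
                    not d.interval.overlaps(u) for u in union
                ):
                    seen.add(key)
                    union.append(d.interval)
        if union:
            matrix, flagged = compare.methylation_matrix(
                union, list(samples.values()), "CG"
            )
            matrix.to_csv(outdir / "methylation_matrix.tsv", sep="\t")
            outputs.append(outdir / "methylation_matrix.tsv")
            clean = matrix[~flagged]
            if len(clean) >= 2:
                order, linkage = compare.hierarchical_cluster(clean)
                newick = compare.linkage_to_newick(linkage, list(clean.index))
                (outdir / "dmr_dendrogram.nwk").write_text(newick + "\n")
                outputs.append(outdir / "dmr_dendrogram.nwk")

        stage = "stability"
        lineage = {"R1_T2", "R1_T4", "R1_T6"}
        if lineage <= set(samples):
            t2_hypo = cg_hypo.get("R1_T2", [])
            calls, unclassifiable = compare.classify_stability_many(
                t2_hypo, control, samples["R1_T2"], samples["R1_T4"], samples["R1_T6"]
            )
            frame = compare.stability_calls_to_frame(calls)
            frame.to_csv(outdir / "stability.tsv", sep="\t", index=False)
            outputs.append(outdir / "stability.tsv")

        stage = "enrichment"
        pooled_hypo = [d for sid in regen for d in cg_hypo[sid]]
        if pooled_hypo:
            table = enrichment.enrichment_table(
                pooled_hypo,
                features,
                list(dict.fromkeys(features["feature_class"])),
                nuclear,
                n_sets=config.n_random_sets,
                seed=[config.seed, 101],
            )
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            outputs.append(outdir / "enrichment.tsv")

        stage = "expression"
        mrna, libsizes = data["mrna"], data["libsizes"]
        de_frames = []
        for sid in regen:
            if sid not in mrna.columns or config.de_control_id not in mrna.columns:
                continue
            de = expression.call_de(
                mrna[sid], mrna[config.de_control_id],
                float(libsizes[sid]), float(libsizes[config.de_control_id]),
            )
            de.insert(0, "sample_id", sid)
            de_frames.append(de)
        if de_frames:
            pd.concat(de_frames).to_csv(outdir / "de_calls.tsv", sep="\t")
            outputs.append(outdir / "de_calls.tsv")

        stage = "metaprofile"
        if regen and cg_hypo[regen[0]]:
            regions = [d.interval for d in cg_hypo[regen[0]]]
            wt_signal = metaprofile.MethylationSignal(control, "CG")
            rg_signal = metaprofile.MethylationSignal(samples[regen[0]], "CG")
            prof_wt = metaprofile.scaled_profile(regions, wt_signal, chrom_sizes=nuclear)
            prof_rg = metaprofile.scaled_profile(regions, rg_signal, chrom_sizes=nuclear)
            prof = prof_wt.to_frame().rename(columns={"value": "wildtype"})
            prof["regenerant"] = prof_rg.to_frame()["value"]
            prof.to_csv(outdir / "metaprofile_cg.tsv", sep="\t", index=False)
            outputs.append(outdir / "metaprofile_cg.tsv")

        stage = "manifest"
        manifest = pd.DataFrame(
            [(str(p.relative_to(outdir)), _sha256(p)) for p in outputs if p.is_file()],
            columns=["path", "sha256"],
        )
        manifest.to_csv(outdir / "MANIFEST.tsv", sep="\t", index=False)
        return manifest
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        partial = pd.DataFrame(
            [(str(p), "") for p in outputs], columns=["path", "sha256"]
        )
        try:
            partial.to_csv(outdir / "MANIFEST.partial", sep="\t", index=False)
        except OSError:
            pass
        raise PipelineError(stage, exc) from exc
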