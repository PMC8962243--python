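"""End-to-end orchestration: read -> harmonize -> condFDR -> clump -> tables.

The pipeline consumes two summary-statistics files and a pairwise LD
table, and writes publication-shaped outputs into an output directory:

* ``condfdr.tsv``    — per-variant FDR columns (SNP, FDR1|2, FDR2|1, CONJFDR)
* ``qq_curves.tsv``  — conditional Q-Q curve points per stratum
* ``qq_enrichment.tsv`` — per-stratum enrichment summaries
* ``manhattan.tsv``  — CHR, POS, NEGLOG10_CONJFDR (capped at 300), lead flag
* ``loci.tsv``       — Table-shaped locus records (one row per locus x gene)
* ``run.log``        — parameters, seeds, and drop counts

Every stage is a library call; the pipeline only wires them together,
so any step can be rerun interactively from Python.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import condfdr as cf
from . import ldops, sumstats

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_conjfdr_pipeline",
    "write_locus_table",
    "parse_locus_table",
    "read_gene_map",
]

DEFAULT_COLUMN_MAP = {
    "snp": "SNP", "chrom": "CHR", "pos": "BP",
    "a1": "A1", "a2": "A2", "z": "Z", "p": "P",
}


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_conjfdr_pipeline`.

    Paths may be None when the corresponding stage is skipped.  Column
    maps default to the SNP/CHR/BP/A1/A2/Z/P convention the synthetic
    generator writes.
    """

    sumstats1: str | None = None
    sumstats2: str | None = None
    ld_table: str | None = None
    gene_map: str | None = None
    output_dir: str = "crosstrait_out"
    column_map1: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    column_map2: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    conjfdr_threshold: float = 0.01
    r2_threshold: float = 0.1
    strata_thresholds: tuple = (1.0, 2.0, 3.0)
    pruning_iterations: int = 100
    min_stratum_size: int = 100
    exclude_mhc: bool = False
    gc_correction: bool = False
    drop_ambiguous: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.conjfdr_threshold < 1:
            raise ValueError("conjfdr_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides):
        """Load a YAML config; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    paired: sumstats.PairedSumstats
    blocks: ldops.LdBlockSet
    qq: "cf.QQCurves"
    fdr: "cf.CondFdrResult"
    loci: list
    outputs: dict = field(default_factory=dict)


def _stage(name):
    logger.info("stage: %s", name)


def run_conjfdr_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full shared-locus discovery pipeline.

    Stages: read both traits -> harmonize (optional MHC exclusion /
    genomic-control correction) -> LD blocks -> conditional Q-Q ->
    condFDR both directions (pruning-averaged CDF lookup) -> conjFDR ->
    strict thresholding -> clumping -> locus table.  All randomness
    derives from ``config.seed``; identical configs give byte-identical
    outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("crosstrait")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("config: %s", dataclasses.asdict(config))
        _stage("read")
        s1 = sumstats.read_sumstats(config.sumstats1, config.column_map1)
        s2 = sumstats.read_sumstats(config.sumstats2, config.column_map2)

        _stage("harmonize")
        paired = sumstats.harmonize_pair(s1, s2, drop_ambiguous=config.drop_ambiguous)
        if config.exclude_mhc:
            paired = sumstats.exclude_mhc(paired)
        if config.gc_correction:
            f = paired.frame
            z1c, lam1 = sumstats.gc_correct(f["z1"].to_numpy())
            z2c, lam2 = sumstats.gc_correct(f["z2"].to_numpy())
            logger.info("genomic inflation: lambda1=%.4f lambda2=%.4f", lam1, lam2)
            f = f.assign(z1=z1c, p1=sumstats.p_from_z(z1c),
                         z2=z2c, p2=sumstats.p_from_z(z2c))
            paired = sumstats.PairedSumstats(frame=f, meta=dict(paired.meta, lam1=lam1, lam2=lam2))

        _stage("ld blocks")
        pairs = ldops.read_ld_table(config.ld_table) if config.ld_table else []
        blocks = ldops.ld_blocks(pairs, paired.frame["snp"], config.r2_threshold)

        qcfg = cf.QQConfig(
            strata_thresholds=config.strata_thresholds,
            pruning_iterations=config.pruning_iterations,
            r2_threshold=config.r2_threshold,
            seed=config.seed,
            min_stratum_size=config.min_stratum_size,
        )
        _stage("conditional qq")
        qq = cf.conditional_qq(paired, blocks, qcfg)

        _stage("condfdr")
        fdr = cf.compute_condfdr_result(paired, blocks, qcfg)

        _stage("select + clump")
        merged = paired.frame.merge(fdr.frame, on="snp")
        sig = cf.select_significant(merged, config.conjfdr_threshold)
        loci = ldops.clump_loci(sig, blocks=blocks, r2_threshold=config.r2_threshold)
        logger.info("%d variants below conjFDR %.3g in %d loci",
                    len(sig), config.conjfdr_threshold, len(loci))

        _stage("write outputs")
        outputs = {}

        fdr_out = fdr.frame.rename(
            columns={"snp": "SNP", "fdr_1_given_2": "FDR1|2",
                     "fdr_2_given_1": "FDR2|1", "conj_fdr": "CONJFDR"}
        )[["SNP", "FDR1|2", "FDR2|1", "CONJFDR"]]
        outputs["condfdr"] = out_dir / "condfdr.tsv"
        fdr_out.to_csv(outputs["condfdr"], sep="\t", index=False, float_format="%.6g")

        outputs["qq_curves"] = out_dir / "qq_curves.tsv"
        qq.curves.to_csv(outputs["qq_curves"], sep="\t", index=False, float_format="%.6g")
        outputs["qq_enrichment"] = out_dir / "qq_enrichment.tsv"
        pd.DataFrame(
            {"stratum": list(qq.enrichment), "enrichment": list(qq.enrichment.values()),
             "median_size": [qq.stratum_sizes.get(t, 0.0) for t in qq.enrichment]}
        ).to_csv(outputs["qq_enrichment"], sep="\t", index=False, float_format="%.6g")

        lead_snps = {L.lead_snp for L in loci}
        man = merged[["chrom", "pos", "snp", "conj_fdr"]].copy()
        man["NEGLOG10_CONJFDR"] = np.minimum(
            -np.log10(np.maximum(man.pop("conj_fdr"), 1e-300)), 300.0
        )
        man["LEAD"] = man["snp"].isin(lead_snps)
        man = man.rename(columns={"chrom": "CHR", "pos": "POS", "snp": "SNP"})
        outputs["manhattan"] = out_dir / "manhattan.tsv"
        man.to_csv(outputs["manhattan"], sep="\t", index=False, float_format="%.6g")

        gene_map = read_gene_map(config.gene_map) if config.gene_map else None
        outputs["loci"] = out_dir / "loci.tsv"
        write_locus_table(loci, gene_map, outputs["loci"])

        return PipelineResult(paired=paired, blocks=blocks, qq=qq, fdr=fdr,
                              loci=loci, outputs=outputs)
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        handler.close()
        root.removeHandler(handler)


def read_gene_map(path):
    """SNP -> gene(s) TSV (columns SNP, GENE; repeated SNPs allowed)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.upper(): c for c in df.columns}
    if "SNP" not in cols or "GENE" not in cols:
        raise ValueError("gene map needs SNP and GENE columns")
    out: dict = {}
    for snp, gene in zip(df[cols["SNP"]], df[cols["GENE"]]):
        out.setdefault(str(snp), []).append(str(gene))
    return out


LOCUS_COLUMNS = ["Locus_No", "SNP", "Gene", "Chr:Pos", "A1/A2",
                 "Z1", "Z2", "ConjFDR", "P1", "P2"]


def write_locus_table(loci, gene_map=None, path=None):
    """Write the shared-locus table (one row per locus x mapped gene).

    A lead SNP mapped to several genes is written once per gene with
    identical statistics columns, mirroring the conventional published
    layout; unmapped leads get an empty Gene field.  Returns the frame.
    """
    rows = []
    for L in loci:
        genes = (gene_map or {}).get(L.lead_snp, L.genes or [""]) or [""]
        for g in genes:
            rows.append(
                {
                    "Locus_No": L.locus_no,
                    "SNP": L.lead_snp,
                    "Gene": g,
                    "Chr:Pos": f"{L.chrom}:{L.pos}",
                    "A1/A2": f"{L.a1}/{L.a2}",
                    "Z1": f"{L.z1:.2f}",
                    "Z2": f"{L.z2:.2f}",
                    "ConjFDR": f"{L.conj_fdr:.2g}",
                    "P1": f"{L.p1:.3g}",
                    "P2": f"{L.p2:.3g}",
                }
            )
    frame = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def parse_locus_table(path):
    """Parse a locus-table TSV back into :class:`~.ldops.SharedLocus` records.

    Tolerates extra columns.  Rows sharing a Locus_No (multi-gene loci)
    collapse into one record with the genes collected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locus table lacks columns: {sorted(missing)}")
    loci = []
    for locus_no, grp in df.groupby("Locus_No", sort=False):
        r = grp.iloc[0]
        chrom, pos = r["Chr:Pos"].split(":")
        a1, a2 = r["A1/A2"].split("/")
        loci.append(
            ldops.SharedLocus(
                locus_no=int(locus_no),
                lead_snp=r["SNP"],
                chrom=chrom,
                pos=int(pos.replace(",", "")),
                a1=a1,
                a2=a2,
                z1=float(r["Z1"]),
                z2=float(r["Z2"]),
                p1=float(r["P1"]),
                p2=float(r["P2"]),
                conj_fdr=float(r["ConjFDR"]),
                members=[r["SNP"]],
                genes=[g for g in grp["Gene"].fillna("").tolist() if g],
            )
        )
    loci.sort(key=lambda L: L.locus_no)
    return loci
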