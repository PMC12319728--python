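"""End-to-end gene x modality testing from summary-statistics files.

Ties the I/O, Stage-1 and testing modules into the analysis a user
runs on real data: harmonize every IDP GWAS table to the disease GWAS,
window each gene, build per-modality weight matrices (clumping +
screening), run the modality-level score test with the chosen
adjustment flags, and emit one tidy row per gene x modality with both
global and modality-specific Bonferroni calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stage1, sumstats_io
from .modality_test import modality_test
from .stage1 import Stage1Config
from .sumstats_io import GeneRegion, GwasTable, InputError, LDMatrix, ModalityMap

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id", "chrom", "modality", "n_snps", "K1", "T", "p_value",
    "p_method", "adjust_other", "adjust_direct", "status",
    "sig_global", "sig_modality", "thr_global", "thr_modality",
]


@dataclass(frozen=True)
class TestConfig:
    """Flags and thresholds of the file-based testing workflow."""

    adjust_other_modalities: bool = True
    adjust_direct: bool = True
    alpha: float = 0.05
    stage1: Stage1Config = field(default_factory=Stage1Config)
    p_method: str = "auto"
    mc_draws: int = 1_000_000
    seed: int = 0


def run_gene_modality_tests(
    disease: GwasTable,
    idp_tables: Mapping[str, GwasTable],
    ld: LDMatrix,
    genes: Sequence[GeneRegion],
    modality_map: ModalityMap,
    config: TestConfig = TestConfig(),
) -> pd.DataFrame:
    """Run the modality-level test for every gene x modality pair.

    All GWAS tables are harmonized to the disease table's allele
    coding; SNPs must be present in the LD matrix.  Pairs for which no
    IDP survives screening are reported with ``status='no_test'``.
    Bonferroni significance is reported at both the global level
    (``alpha`` / number of performed tests) and the modality-specific
    level (``alpha`` / tests within that modality).
    """
    harmonized = {
        idp: sumstats_io.harmonize_alleles(tab, disease)
        for idp, tab in idp_tables.items()
    }
    rows = []
    rng = np.random.default_rng(config.seed)
    for gene in genes:
        dis_win = sumstats_io.extract_gene_window(disease, gene)
        in_ld = [s for s in dis_win.snp_ids if s in set(ld.snp_ids)]
        if not in_ld:
            logger.info("gene %s: no windowed SNPs in LD matrix; skipped", gene.gene_id)
            continue
        dis_win = dis_win.subset(in_ld)
        gene_idp = {}
        for idp, tab in harmonized.items():
            win = sumstats_io.extract_gene_window(tab, gene)
            shared = [s for s in win.snp_ids if s in set(in_ld)]
            if shared:
                gene_idp[idp] = win.subset(shared)
        if not gene_idp:
            logger.info("gene %s: no IDP has windowed SNPs; skipped", gene.gene_id)
            continue
        weights = stage1.build_weight_matrix(
            gene_idp, ld, modality_map, gene, config.stage1
        )
        snp_list = next(iter(weights.values())).snp_ids
        dis_sub = dis_win.subset([s for s in snp_list])
        z_disease = dis_sub.df["z"].to_numpy(dtype=float)
        sub_ld = ld.subset(snp_list)
        for modality in modality_map.modalities():
            res = modality_test(
                gene.gene_id, modality, weights, z_disease, sub_ld,
                adjust_other_modalities=config.adjust_other_modalities,
                adjust_direct=config.adjust_direct,
                p_method=config.p_method, mc_draws=config.mc_draws,
                seed=rng,
            )
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "chrom": gene.chrom,
                    "modality": modality,
                    "n_snps": res.n_snps,
                    "K1": res.K1,
                    "T": res.T,
                    "p_value": res.p_value,
                    "p_method": res.p_method,
                    "adjust_other": config.adjust_other_modalities,
                    "adjust_direct": config.adjust_direct,
                    "status": "no_test" if res.no_test else "ok",
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise InputError("no gene x modality test could be performed")
    tested = out["status"] == "ok"
    m_global = max(int(tested.sum()), 1)
    out["thr_global"] = config.alpha / m_global
    out["sig_global"] = tested & (out["p_value"] < out["thr_global"])
    out["thr_modality"] = np.nan
    out["sig_modality"] = False
    for modality, grp in out.groupby("modality"):
        m_mod = max(int((grp["status"] == "ok").sum()), 1)
        thr = config.alpha / m_mod
        idx = grp.index
        out.loc[idx, "thr_modality"] = thr
        out.loc[idx, "sig_modality"] = (out.loc[idx, "status"] == "ok") & (
            out.loc[idx, "p_value"] < thr
        )
    return out[RESULT_COLUMNS]
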