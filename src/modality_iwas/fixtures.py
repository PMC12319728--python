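"""Self-contained toy input files for demonstrations and tests.

Writes a miniature but fully consistent study to a directory: per-IDP
GWAS summary tables, a disease GWAS table, a reference-panel dosage
matrix (from which the LD matrix can be computed), a BED gene
annotation and a modality map.  Everything is derived from the
package's own generative model, so the files exercise the whole
file-based pipeline without any download.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .simulation import SimParams, dataset_to_tables, simulate_dataset, snp_metadata
from .sumstats_io import GWAS_COLUMNS


def write_fixture_set(
    out_dir,
    seed: int = 0,
    n: int = 500,
    J: int = 12,
    K: int = 3,
    n_genes: int = 2,
) -> dict[str, object]:
    """Generate and write the toy dataset; returns the written paths.

    Each gene gets its own independently simulated SNP block; the
    blocks are concatenated into genome-wide-looking tables.  Gene
    windows are sized so the two blocks never overlap.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gene_starts = [1_000_000 + g * 40_000_000 for g in range(n_genes)]
    idp_frames: dict[str, list[pd.DataFrame]] = {}
    disease_frames: list[pd.DataFrame] = []
    panel_blocks: list[pd.DataFrame] = []
    bed_rows = []

    for g, start in enumerate(gene_starts):
        # common alleles so a 400-sample panel estimates LD well, and a
        # strong SNP->IDP signal so the toy genes survive the F-screen
        params = SimParams(n=n, J=J, K=K, scenario="null", tau=0.0,
                           trait_type="continuous", maf=0.2, sd_alpha=1.0)
        ds = simulate_dataset(params, rng)
        idp_tables, disease, _ = dataset_to_tables(ds)

        def relocate(tab):
            df = tab.df.copy()
            df["snp_id"] = [f"g{g + 1}_{s}" for s in df["snp_id"]]
            df["pos"] = df["pos"] - 2_000_000 + start
            return df

        for idp, tab in idp_tables.items():
            idp_frames.setdefault(idp, []).append(relocate(tab))
        disease_frames.append(relocate(disease))
        # a small independent panel for LD estimation
        panel_params = replace(params, n=400)
        panel = simulate_dataset(panel_params, rng).G_raw
        panel_blocks.append(
            pd.DataFrame(panel, columns=[f"g{g + 1}_rs{j + 1:06d}" for j in range(J)])
        )
        span = (J - 1) * 5_000
        bed_rows.append((16, start - 1, start + span, f"GENE{g + 1}"))

    paths: dict[str, object] = {}
    idp_dir = out / "idp_gwas"
    idp_dir.mkdir(exist_ok=True)
    header = {"snp_id": "SNP", "chrom": "CHR", "pos": "POS",
              "effect_allele": "A1", "other_allele": "A2", "z": "Z", "n": "N"}
    for idp, frames in idp_frames.items():
        df = pd.concat(frames, ignore_index=True)[GWAS_COLUMNS].rename(columns=header)
        p = idp_dir / f"{idp}.tsv"
        df.to_csv(p, sep="\t", index=False)
    paths["idp_gwas_dir"] = idp_dir

    dis = pd.concat(disease_frames, ignore_index=True)[GWAS_COLUMNS].rename(columns=header)
    paths["disease_gwas"] = out / "disease_gwas.tsv"
    dis.to_csv(paths["disease_gwas"], sep="\t", index=False)

    panel_df = pd.concat(panel_blocks, axis=1)
    paths["panel"] = out / "panel.tsv"
    panel_df.to_csv(paths["panel"], sep="\t", index=False)

    paths["genes"] = out / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for chrom, s, e, gid in bed_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{gid}\n")

    paths["modality_map"] = out / "modality_map.tsv"
    with open(paths["modality_map"], "w") as fh:
        fh.write("idp_id\tmodality\n")
        for idp in idp_frames:
            modality = "sMRI" if idp.startswith("mod1") else "dMRI"
            fh.write(f"{idp}\t{modality}\n")
    return paths
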