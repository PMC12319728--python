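"""The full file-based pipeline on generated toy inputs.

Writes a self-contained toy study (GWAS tables, reference panel, gene
annotation, modality map) to a temporary directory, then runs the same
code path as `modality-iwas test`: read files, estimate LD from the
panel, harmonize alleles, window genes, build weights, test every
gene x modality pair.
"""

import tempfile
from pathlib import Path

from modality_iwas import TestConfig, run_gene_modality_tests
from modality_iwas.fixtures import write_fixture_set
from modality_iwas.sumstats_io import (
    ld_from_panel,
    read_gene_bed,
    read_gwas_table,
    read_modality_map,
    read_panel,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture_set(Path(tmp) / "toy", seed=3)

    disease = read_gwas_table(paths["disease_gwas"], trait_id="disease")
    idp_tables = {
        p.stem: read_gwas_table(p, trait_id=p.stem)
        for p in sorted(paths["idp_gwas_dir"].glob("*.tsv"))
    }
    dosages, snp_ids = read_panel(paths["panel"])
    ld = ld_from_panel(dosages, snp_ids)
    genes = read_gene_bed(paths["genes"])
    modality_map = read_modality_map(paths["modality_map"])

    table = run_gene_modality_tests(
        disease, idp_tables, ld, genes, modality_map, TestConfig(seed=5)
    )
    print(table.to_string(index=False))
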