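"""Reading, harmonizing, and windowing GWAS summary-statistics inputs.

This module owns the file-facing side of the package: per-trait GWAS
tables (one row per SNP), SNP-by-SNP linkage-disequilibrium (LD)
correlation matrices given directly or computed from a reference-panel
dosage matrix, BED-like gene annotations, and the map that assigns each
imaging-derived phenotype (IDP) to an MRI modality.

Conventions
-----------
* Coordinates are 1-based; gene windows are inclusive at both ends.
  BED input (0-based, half-open) is converted on read.
* GWAS tables are whitespace- or tab-delimited text with a header.
  Canonical column names are ``SNP CHR POS A1 A2 Z N`` where ``A1`` is
  the effect allele; a ``column_map`` may rename them.
* Strand-ambiguous SNPs (A/T and C/G pairs) are dropped during allele
  harmonization because no allele frequencies are guaranteed in input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
#: Strand-ambiguous allele pairs: complement equals the other allele.
AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "z", "n"]

#: Default header names in GWAS text files, mapped to internal names.
DEFAULT_COLUMN_MAP = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "Z": "z",
    "N": "n",
}


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (e.g. missing mandatory columns)."""


@dataclass(frozen=True)
class GeneRegion:
    """A gene locus with a symmetric flanking window for SNP collection.

    ``start``/``end`` are 1-based inclusive base pairs.  ``window_bp``
    (default 1 Mb) extends the region on both sides when collecting
    SNPs, so the effective interval is
    ``[start - window_bp, end + window_bp]`` inclusive.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.window_bp < 0:
            raise InputError(f"gene {self.gene_id}: negative window_bp")

    @property
    def window_start(self) -> int:
        return self.start - self.window_bp

    @property
    def window_end(self) -> int:
        return self.end + self.window_bp


@dataclass
class GwasTable:
    """Per-SNP association summaries for a single trait.

    Wraps a DataFrame with columns ``snp_id, chrom, pos, effect_allele,
    other_allele, z, n``.  SNP ids are unique; ``z`` is the GWAS
    z-score and ``n`` the per-SNP sample size.
    """

    df: pd.DataFrame
    trait_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"GWAS table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate snp_id in GWAS table: {sorted(set(dup))}")
        if (self.df["pos"] < 1).any():
            raise InputError("GWAS table contains pos < 1")
        if (self.df["n"] < 3).any():
            raise InputError("GWAS table contains n < 3 (z-to-beta transform needs n >= 3)")
        bad = self.df["effect_allele"] == self.df["other_allele"]
        if bad.any():
            raise InputError(
                f"effect allele equals other allele for: {list(self.df.loc[bad, 'snp_id'])}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["snp_id"])

    def subset(self, snp_ids: Sequence[str]) -> "GwasTable":
        """Rows restricted to ``snp_ids``, in the given order."""
        sub = self.df.set_index("snp_id").loc[list(snp_ids)].reset_index()
        return GwasTable(sub[GWAS_COLUMNS], trait_id=self.trait_id)

    def to_file(self, path) -> None:
        out = self.df[GWAS_COLUMNS].rename(
            columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()}
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """SNP-by-SNP Pearson correlation matrix ``R`` with its id order."""

    snp_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        J = len(self.snp_ids)
        if self.R.shape != (J, J):
            raise InputError(f"LD matrix shape {self.R.shape} != ({J}, {J})")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise InputError("LD matrix is not symmetric (tolerance 1e-10)")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise InputError("LD matrix diagonal is not 1")
        if np.abs(self.R).max() > 1 + 1e-8:
            raise InputError("LD matrix has entries outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            idx = [index[s] for s in snp_ids]
        except KeyError as exc:
            raise InputError(f"SNP {exc.args[0]} not in LD matrix") from exc
        return LDMatrix(list(snp_ids), self.R[np.ix_(idx, idx)])

    def to_file(self, path) -> None:
        pd.DataFrame(self.R, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="SNP"
        )


@dataclass
class ModalityMap:
    """Assignment of each IDP id to exactly one modality label."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, idp_id: str) -> str:
        return self.mapping[idp_id]

    def modalities(self) -> list[str]:
        """Distinct modality labels in first-appearance order."""
        seen: dict[str, None] = {}
        for label in self.mapping.values():
            seen.setdefault(label)
        return list(seen)

    def idps_for(self, modality: str) -> list[str]:
        return [i for i, m in self.mapping.items() if m == modality]


def read_gwas_table(path, column_map: Mapping[str, str] | None = None,
                    trait_id: str = "") -> GwasTable:
    """Read a delimited GWAS summary table.

    ``column_map`` maps file header names to the internal names
    ``snp_id, chrom, pos, effect_allele, other_allele, z, n``; it
    defaults to the canonical ``SNP/CHR/POS/A1/A2/Z/N`` header.  Rows
    whose ``z`` or ``n`` cannot be parsed as numbers are dropped and
    counted in the log.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [src for src in cmap if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing}; found {list(raw.columns)}"
        )
    df = raw.rename(columns=cmap)[GWAS_COLUMNS].copy()
    df["z"] = pd.to_numeric(df["z"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    ok = df["z"].notna() & df["n"].notna() & df["pos"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) with unparseable z/n/pos", path, n_dropped)
    df = df[ok].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(float)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    return GwasTable(df, trait_id=trait_id or str(path))


def harmonize_alleles(target: GwasTable, reference: GwasTable) -> GwasTable:
    """Align ``target`` to the allele coding and SNP order of ``reference``.

    SNPs are restricted to the intersection.  Where target effect/other
    alleles are swapped relative to the reference, ``z`` is negated and
    the alleles flipped.  Strand-ambiguous SNPs (A/T, C/G) and allele
    pairs irreconcilable even after a swap are dropped.  The output
    follows the reference order.
    """
    tgt = target.df.set_index("snp_id")
    out_rows = []
    n_ambiguous = n_mismatch = 0
    for _, ref in reference.df.iterrows():
        sid = ref["snp_id"]
        if sid not in tgt.index:
            continue
        row = tgt.loc[sid]
        pair = frozenset((row["effect_allele"], row["other_allele"]))
        if pair in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        if (row["effect_allele"], row["other_allele"]) == (
            ref["effect_allele"], ref["other_allele"]
        ):
            z = row["z"]
        elif (row["effect_allele"], row["other_allele"]) == (
            ref["other_allele"], ref["effect_allele"]
        ):
            z = -row["z"]
        else:
            n_mismatch += 1
            continue
        out_rows.append(
            {
                "snp_id": sid,
                "chrom": row["chrom"],
                "pos": row["pos"],
                "effect_allele": ref["effect_allele"],
                "other_allele": ref["other_allele"],
                "z": z,
                "n": row["n"],
            }
        )
    if n_ambiguous or n_mismatch:
        logger.info(
            "harmonize_alleles(%s): dropped %d strand-ambiguous, %d irreconcilable",
            target.trait_id, n_ambiguous, n_mismatch,
        )
    if not out_rows:
        raise InputError(
            f"no SNPs shared between '{target.trait_id}' and '{reference.trait_id}' "
            "after harmonization"
        )
    return GwasTable(pd.DataFrame(out_rows, columns=GWAS_COLUMNS),
                     trait_id=target.trait_id)


def ld_from_panel(genotypes: np.ndarray, snp_ids: Sequence[str]) -> LDMatrix:
    """Pearson correlation LD matrix from an ``n_panel x J`` dosage matrix."""
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(snp_ids):
        raise InputError("panel shape does not match snp_ids")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [snp_ids[i] for i in zero]
        raise InputError(f"zero-variance panel column(s): {names}")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(list(snp_ids), R)


def read_ld_matrix(path) -> LDMatrix:
    """Read a square LD matrix with a leading row/column of SNP ids."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: LD matrix row ids differ from column ids")
    return LDMatrix([str(s) for s in df.index], df.to_numpy(dtype=float))


def extract_gene_window(table: GwasTable, region: GeneRegion) -> GwasTable:
    """SNPs on the gene's chromosome inside its flanked window (inclusive)."""
    df = table.df
    keep = (
        (df["chrom"].astype(str) == str(region.chrom))
        & (df["pos"] >= region.window_start)
        & (df["pos"] <= region.window_end)
    )
    out = df[keep].reset_index(drop=True)
    if out.empty:
        logger.info("gene %s: no SNPs in window for trait '%s'",
                    region.gene_id, table.trait_id)
    return GwasTable(out, trait_id=table.trait_id)


def filter_missingness(
    genotypes: np.ndarray,
    snp_ids: Sequence[str],
    max_missing: float = 0.01,
) -> tuple[np.ndarray, list[str]]:
    """Drop high-missingness SNPs and median-impute the rest.

    Missing entries are NaN.  SNPs whose missing fraction exceeds
    ``max_missing`` (or that are entirely missing) are removed; the
    remaining NaNs are replaced with the per-SNP median of observed
    values.
    """
    X = np.asarray(genotypes, dtype=float)
    miss = np.isnan(X).mean(axis=0)
    keep = miss <= max_missing
    all_missing = miss == 1.0
    keep &= ~all_missing
    n_drop = int((~keep).sum())
    if n_drop:
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        logger.info("filter_missingness: dropped %d SNP(s): %s", n_drop, dropped)
    X = X[:, keep].copy()
    kept_ids = [s for s, k in zip(snp_ids, keep) if k]
    for j in range(X.shape[1]):
        col = X[:, j]
        nan = np.isnan(col)
        if nan.any():
            col[nan] = np.median(col[~nan])
    return X, kept_ids


def read_panel(path) -> tuple[np.ndarray, list[str]]:
    """Read a reference-panel dosage matrix (header of SNP ids, one row
    per individual); missing entries may be 'NA' and become NaN."""
    df = pd.read_csv(path, sep=r"\s+")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def read_gene_bed(path) -> list[GeneRegion]:
    """Read a BED-like annotation (chrom, start, end, gene_id, ...).

    BED starts are 0-based half-open and are converted to 1-based
    inclusive coordinates.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ConfigurationError(f"{path}: gene BED needs >= 4 columns")
    regions = []
    for _, row in df.iterrows():
        regions.append(
            GeneRegion(
                gene_id=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]) + 1,
                end=int(row[2]),
            )
        )
    return regions


def read_modality_map(path) -> ModalityMap:
    """Read a two-column (idp_id, modality) delimited file with header."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: modality map needs 2 columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise InputError(f"{path}: IDP mapped to more than one modality")
    return ModalityMap(dict(zip(ids, df.iloc[:, 1].astype(str))))
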