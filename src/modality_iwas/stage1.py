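"""Stage-1 weight construction: SNP -> genetically imputed IDP coefficients.

The two-stage design first expresses each imaging-derived phenotype
(IDP) as a linear function of the SNPs in a gene.  Working purely from
summary statistics, the per-IDP weight vector is obtained by

1. converting each marginal GWAS z-score to a standardized marginal
   regression coefficient, ``beta = z / sqrt(n - 2 + z^2)`` (the sample
   correlation between SNP and IDP);
2. solving the LD system ``R w = beta`` so that ``w`` approximates the
   joint (multiple-regression) coefficients.

Around this core sit the SNP-selection steps used in practice: greedy
LD clumping per IDP, merging of per-IDP clump sets into one SNP set per
gene, and an F-test screen that discards gene-IDP pairs with no
detectable genetic signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .sumstats_io import (
    GeneRegion,
    GwasTable,
    InputError,
    LDMatrix,
    ModalityMap,
)

logger = logging.getLogger(__name__)


class ConditioningError(np.linalg.LinAlgError):
    """A linear system is numerically singular; a ridge is required."""


@dataclass(frozen=True)
class Stage1Config:
    """Tuning knobs of the weight-building pipeline.

    Defaults follow common practice for gene-level instrumental-variable
    analyses: a 1 Mb clumping radius with an r^2 cutoff of 0.5, an
    F-test screen at 5e-5, and a small automatic ridge whenever the LD
    matrix is ill-conditioned.
    """

    clump_radius_bp: int = 1_000_000
    clump_r2: float = 0.5
    screen_p: float = 5e-5
    do_clump: bool = True
    do_screen: bool = True
    ridge_cond_threshold: float = 1e8
    ridge_scale: float = 0.001


@dataclass
class ScreenResult:
    """Outcome of the gene-IDP F-test screen."""

    keep: bool
    p_value: float
    f_stat: float
    r2: float


@dataclass
class WeightMatrix:
    """Joint SNP-to-IDP coefficients for one modality.

    ``W`` is J x K_q: row order follows ``snp_ids``, column order
    ``idp_ids``.  SNPs absent from an IDP's clump set carry weight 0 in
    that column.
    """

    snp_ids: list[str]
    idp_ids: list[str]
    W: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.shape != (len(self.snp_ids), len(self.idp_ids)):
            raise InputError(
                f"weight matrix shape {self.W.shape} != "
                f"({len(self.snp_ids)}, {len(self.idp_ids)})"
            )
        if not np.isfinite(self.W).all():
            raise InputError("weight matrix contains non-finite entries")

    @property
    def n_idps(self) -> int:
        return len(self.idp_ids)


def z_to_marginal_beta(z, n):
    """Standardized marginal regression coefficient from a GWAS z-score.

    ``beta = z / sqrt(n - 2 + z^2)``, the sample correlation implied by
    the z statistic of a simple regression on a standardized SNP.
    Accepts scalars or arrays; requires ``n >= 3``.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise InputError("z_to_marginal_beta requires n >= 3")
    return z / np.sqrt(n - 2.0 + z**2)


def default_ridge(R: np.ndarray, config: Stage1Config = Stage1Config()) -> float:
    """Automatic ridge: ``ridge_scale * mean(diag(R))`` when the
    condition number of ``R`` exceeds ``ridge_cond_threshold``, else 0."""
    if np.linalg.cond(R) > config.ridge_cond_threshold:
        return config.ridge_scale * float(np.mean(np.diag(R)))
    return 0.0


def joint_weights(beta: np.ndarray, ld: LDMatrix | np.ndarray,
                  ridge_eps: float = 0.0) -> np.ndarray:
    """Solve ``(R + ridge_eps I) w = beta`` for the joint weights.

    ``beta`` may be a vector or a J x K matrix of stacked marginal
    coefficient vectors.  With ``ridge_eps=0`` this is ``R^{-1} beta``;
    a numerically singular ``R`` then raises :class:`ConditioningError`.
    """
    R = ld.R if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    b = np.asarray(beta, dtype=float)
    if b.shape[0] != R.shape[0]:
        raise InputError(
            f"dimension mismatch: beta has {b.shape[0]} rows, R is {R.shape[0]}x{R.shape[0]}"
        )
    A = R + ridge_eps * np.eye(R.shape[0]) if ridge_eps else R
    # reject numerically singular systems instead of returning garbage
    if np.linalg.cond(A) > 1 / np.finfo(float).eps:
        raise ConditioningError(
            "LD matrix is numerically singular; pass a positive ridge_eps "
            "(e.g. default_ridge(R))"
        )
    return np.linalg.solve(A, b)


def ld_clump(
    table: GwasTable,
    ld: LDMatrix,
    radius_bp: int = 1_000_000,
    r2_cutoff: float = 0.5,
) -> list[str]:
    """Greedy LD clumping; returns kept SNP ids in genomic order.

    Repeatedly takes the not-yet-clumped SNP with the smallest
    two-sided p-value (from ``z``), keeps it, and removes every
    remaining SNP within ``radius_bp`` whose squared correlation with
    it exceeds ``r2_cutoff``.  Ties on p are broken by smaller genomic
    position for determinism.
    """
    df = table.df
    ids = list(df["snp_id"])
    sub = ld.subset(ids)
    pos = df["pos"].to_numpy()
    p = 2.0 * stats.norm.sf(np.abs(df["z"].to_numpy()))
    order = np.lexsort((pos, p))  # primary: p ascending; tie-break: position
    r2 = sub.R**2
    available = np.ones(len(ids), dtype=bool)
    kept = np.zeros(len(ids), dtype=bool)
    for i in order:
        if not available[i]:
            continue
        kept[i] = True
        available[i] = False
        within = np.abs(pos - pos[i]) <= radius_bp
        available &= ~(within & (r2[i] > r2_cutoff))
    keep_idx = np.flatnonzero(kept)
    keep_idx = keep_idx[np.argsort(pos[keep_idx], kind="stable")]
    return [ids[i] for i in keep_idx]


def merge_clump_sets(
    per_idp_keeps: Iterable[Sequence[str]],
    positions: Mapping[str, int],
) -> list[str]:
    """Union of per-IDP clump SNP sets, ordered by genomic position."""
    merged = set()
    for keep in per_idp_keeps:
        merged.update(keep)
    return sorted(merged, key=lambda s: (positions[s], s))


def gene_idp_screen(
    beta: np.ndarray,
    ld: LDMatrix | np.ndarray,
    n: float,
    p_threshold: float = 5e-5,
    ridge_eps: float = 0.0,
) -> ScreenResult:
    """Summary-level F-test screen of a gene-IDP pair.

    Reconstructs the multiple-regression fit from marginal coefficients:
    ``R^2 = beta' R^{-1} beta`` (clipped to [0, 1)), then
    ``F = (R^2/J) / ((1-R^2)/(n-J-1))`` against an F(J, n-J-1) upper
    tail.  The pair is kept when ``p < p_threshold``.
    """
    R = ld.R if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    b = np.asarray(beta, dtype=float).ravel()
    J = b.size
    if J >= n - 1:
        raise InputError(f"F screen needs J < n - 1 (J={J}, n={n})")
    r2 = float(b @ joint_weights(b, R, ridge_eps))
    r2 = min(max(r2, 0.0), 1.0 - 1e-6)
    f = (r2 / J) / ((1.0 - r2) / (n - J - 1.0))
    p = float(stats.f.sf(f, J, n - J - 1.0))
    return ScreenResult(keep=p < p_threshold, p_value=p, f_stat=f, r2=r2)


def build_weight_matrix(
    idp_tables: Mapping[str, GwasTable],
    ld: LDMatrix,
    modality_map: ModalityMap,
    gene: GeneRegion,
    config: Stage1Config = Stage1Config(),
) -> dict[str, WeightMatrix]:
    """Stage-1 weight matrices for one gene, per modality.

    Per IDP: clump its GWAS table against the LD matrix (optional),
    then on the merged (union) SNP set of the gene transform z-scores
    to marginal betas, solve the joint weights, and apply the F-test
    screen (optional).  IDPs failing the screen contribute no column.
    SNPs outside an IDP's clump set receive weight 0 in its column.

    All tables must already be harmonized to one allele coding and
    restricted to the gene window.  Returns one :class:`WeightMatrix`
    per modality; a modality whose IDPs are all screened out yields a
    zero-column matrix (an empty-result signal, not an exception).
    """
    positions: dict[str, int] = {}
    per_idp_keep: dict[str, list[str]] = {}
    for idp_id, table in idp_tables.items():
        positions.update(zip(table.df["snp_id"], table.df["pos"]))
        if config.do_clump:
            per_idp_keep[idp_id] = ld_clump(
                table, ld, config.clump_radius_bp, config.clump_r2
            )
        else:
            per_idp_keep[idp_id] = list(table.df["snp_id"])

    merged = merge_clump_sets(per_idp_keep.values(), positions)
    if not merged:
        raise InputError(f"gene {gene.gene_id}: no SNPs after clumping")
    sub_ld = ld.subset(merged)
    ridge = default_ridge(sub_ld.R, config)
    snp_index = {s: i for i, s in enumerate(merged)}

    columns: dict[str, dict[str, np.ndarray]] = {m: {} for m in modality_map.modalities()}
    n_screened_out = 0
    for idp_id, table in idp_tables.items():
        tab = table.df.set_index("snp_id")
        # zero-filled marginal betas on the merged set; the IDP's own
        # clumped SNPs carry its transformed z-scores
        b = np.zeros(len(merged))
        own = [s for s in per_idp_keep[idp_id] if s in snp_index]
        if not own:
            continue
        z = tab.loc[own, "z"].to_numpy(dtype=float)
        n = tab.loc[own, "n"].to_numpy(dtype=float)
        b[[snp_index[s] for s in own]] = z_to_marginal_beta(z, n)
        if config.do_screen:
            n_med = float(np.median(n))
            screen = gene_idp_screen(b, sub_ld, n_med, config.screen_p, ridge)
            if not screen.keep:
                n_screened_out += 1
                logger.info(
                    "gene %s: IDP %s screened out (F p=%.3g >= %.3g)",
                    gene.gene_id, idp_id, screen.p_value, config.screen_p,
                )
                continue
        w = joint_weights(b, sub_ld, ridge)
        columns[modality_map[idp_id]][idp_id] = w

    out: dict[str, WeightMatrix] = {}
    for modality in modality_map.modalities():
        cols = columns[modality]
        W = (
            np.column_stack(list(cols.values()))
            if cols
            else np.empty((len(merged), 0))
        )
        out[modality] = WeightMatrix(
            snp_ids=list(merged), idp_ids=list(cols), W=W, modality=modality
        )
        if not cols:
            logger.info(
                "gene %s: no IDP of modality %s survived screening",
                gene.gene_id, modality,
            )
    if n_screened_out:
        logger.info("gene %s: %d IDP(s) screened out in total",
                    gene.gene_id, n_screened_out)
    return out
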