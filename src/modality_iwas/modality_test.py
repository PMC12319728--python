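"""Modality-level variance-component score test from summary statistics.

The central quantity is the score vector of the genetically imputed
IDPs of the tested modality against the disease GWAS z-scores, after
projecting out the adjusted columns (imputed IDPs of the other
modalities and, optionally, a burden column of ones absorbing residual
direct genetic effects):

    S      = A1' z  -  A1' R A2 (A2' R A2)^{-1} A2' z
    Cov(S) = A1' R A1 - A1' R A2 (A2' R A2)^{-1} A2' R A1

where ``A1`` (J x K1) holds the tested modality's weights, ``A2``
(J x K2) the adjustment weights, ``z`` the disease GWAS z-scores and
``R`` the SNP LD correlation matrix.  The test statistic ``T = S'S``
follows, under the null of no modality effect, a mixture of 1-df
chi-square distributions weighted by the eigenvalues of ``Cov(S)`` —
the same null law as SKAT-style variance-component tests.  Testing all
IDPs of a modality jointly through this quadratic form is powerful when
each IDP contributes a small effect of possibly inconsistent sign.

p-values for the mixture are computed by characteristic-function
inversion (Imhof/Davies-type numerical integration), by Liu et al.'s
moment-matching noncentral chi-square approximation as a fallback, or
by Monte Carlo sampling of the mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats

from .stage1 import WeightMatrix
from .sumstats_io import ConfigurationError, InputError, LDMatrix

logger = logging.getLogger(__name__)

#: Relative cutoff below which eigenvalues are treated as numerical noise.
EIGENVALUE_RTOL = 1e-12


class DegenerateTestError(ValueError):
    """All eigenvalues are zero: the null distribution is degenerate."""


@dataclass
class AdjustmentSet:
    """Columns projected out of the score: other-modality imputed IDPs
    and, when ``adjust_direct`` is on, a burden column of ones that
    absorbs residual direct genetic effects (the Egger-style intercept
    device carried over to the score test)."""

    A2: np.ndarray  # J x K2, possibly zero columns
    labels: list[str] = field(default_factory=list)
    adjust_other_modalities: bool = True
    adjust_direct: bool = True

    def __post_init__(self) -> None:
        self.A2 = np.atleast_2d(np.asarray(self.A2, dtype=float))
        if self.A2.shape[1] != len(self.labels):
            raise InputError("AdjustmentSet labels do not match column count")

    @property
    def n_columns(self) -> int:
        return self.A2.shape[1]


@dataclass
class ScoreResult:
    """Score vector, its null covariance, and the covariance spectrum."""

    S: np.ndarray
    cov_S: np.ndarray
    eigenvalues: np.ndarray
    dropped_adjustment: list[str] = field(default_factory=list)


@dataclass
class ModalityTestResult:
    """Outcome of one gene x modality test."""

    gene_id: str
    modality: str
    T: float
    p_value: float
    K1: int
    n_snps: int
    p_method: str
    mc_draws: int | None = None
    tested_idps: list[str] = field(default_factory=list)
    adjusted_labels: list[str] = field(default_factory=list)
    no_test: bool = False


def build_adjustment(
    weights: Mapping[str, WeightMatrix],
    tested_modality: str,
    adjust_other_modalities: bool = True,
    adjust_direct: bool = True,
) -> AdjustmentSet:
    """Assemble the adjustment columns for a tested modality.

    Takes the weight matrices of every *other* modality (when
    ``adjust_other_modalities``) plus the all-ones burden column (when
    ``adjust_direct``).  All weight matrices must share one SNP list.
    """
    snp_ids = weights[tested_modality].snp_ids
    blocks, labels = [], []
    if adjust_other_modalities:
        for modality, wm in weights.items():
            if modality == tested_modality:
                continue
            if wm.snp_ids != snp_ids:
                raise InputError(
                    f"weight matrices for {modality} and {tested_modality} "
                    "are on different SNP lists"
                )
            if wm.n_idps:
                blocks.append(wm.W)
                labels.extend(wm.idp_ids)
    if adjust_direct:
        blocks.append(np.ones((len(snp_ids), 1)))
        labels.append("__direct__")
    A2 = np.column_stack(blocks) if blocks else np.empty((len(snp_ids), 0))
    return AdjustmentSet(A2, labels, adjust_other_modalities, adjust_direct)


def _drop_collinear(A2: np.ndarray, R: np.ndarray,
                    labels: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Reduce ``A2`` to full rank under the R inner product.

    Uses rank-revealing (pivoted) QR of ``R^{1/2} A2``; dependent
    columns are dropped and reported.
    """
    from scipy.linalg import qr

    if A2.shape[1] == 0:
        return A2, list(labels), []
    w, V = np.linalg.eigh((R + R.T) / 2)
    Rhalf = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    B = Rhalf @ A2
    _, Rq, piv = qr(B, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    tol = diag.max() * max(B.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [labels[i] for i in sorted(piv[rank:])]
    if dropped:
        logger.info("dropped collinear adjustment column(s): %s", dropped)
    return A2[:, keep], [labels[i] for i in keep], dropped


def _projection_terms(A1, A2, R, z):
    """Shared pieces of score and covariance after the A2 projection."""
    RA2 = R @ A2
    M = A2.T @ RA2
    A1RA2 = A1.T @ RA2
    sol_z = np.linalg.solve(M, A2.T @ z) if z is not None else None
    sol_RA1 = np.linalg.solve(M, RA2.T @ A1)
    return A1RA2, sol_z, sol_RA1


def score_vector(
    A1: WeightMatrix | np.ndarray,
    adj: AdjustmentSet | None,
    ld: LDMatrix | np.ndarray,
    z_disease: np.ndarray,
) -> np.ndarray:
    """Score vector ``S = A1'z - A1' R A2 (A2' R A2)^{-1} A2' z``.

    With no adjustment columns this reduces to ``A1'z``.
    """
    A1m = A1.W if isinstance(A1, WeightMatrix) else np.atleast_2d(np.asarray(A1, float))
    R = ld.R if isinstance(ld, LDMatrix) else np.asarray(ld, float)
    z = np.asarray(z_disease, dtype=float)
    if A1m.shape[0] != R.shape[0] or z.shape[0] != R.shape[0]:
        raise InputError("A1, LD matrix and z must share one SNP list")
    if adj is None or adj.n_columns == 0:
        return A1m.T @ z
    A2, labels, _ = _drop_collinear(adj.A2, R, adj.labels)
    A1RA2, sol_z, _ = _projection_terms(A1m, A2, R, z)
    return A1m.T @ z - A1RA2 @ sol_z


def cov_score(
    A1: WeightMatrix | np.ndarray,
    adj: AdjustmentSet | None,
    ld: LDMatrix | np.ndarray,
) -> np.ndarray:
    """Null covariance ``A1'RA1 - A1'RA2 (A2'RA2)^{-1} A2'RA1`` (PSD)."""
    A1m = A1.W if isinstance(A1, WeightMatrix) else np.atleast_2d(np.asarray(A1, float))
    R = ld.R if isinstance(ld, LDMatrix) else np.asarray(ld, float)
    if adj is None or adj.n_columns == 0:
        C = A1m.T @ R @ A1m
    else:
        A2, _, _ = _drop_collinear(adj.A2, R, adj.labels)
        A1RA2, _, sol_RA1 = _projection_terms(A1m, A2, R, None)
        C = A1m.T @ R @ A1m - A1RA2 @ sol_RA1
    return (C + C.T) / 2.0


def score_result(A1, adj, ld, z_disease) -> ScoreResult:
    """Score vector, covariance and its clipped eigenvalue spectrum."""
    S = score_vector(A1, adj, ld, z_disease)
    C = cov_score(A1, adj, ld)
    lam = np.linalg.eigvalsh(C)[::-1]
    if lam.size and lam[0] > 0 and lam.min() < -1e-8 * lam[0]:
        # happens when R itself is numerically singular (e.g. duplicated
        # rare SNPs); the test is not computable for this input
        raise DegenerateTestError("cov_score is not PSD beyond numerical tolerance")
    lam = np.clip(lam, 0.0, None)
    return ScoreResult(S=S, cov_S=C, eigenvalues=lam)


def test_statistic(S: np.ndarray) -> float:
    """Quadratic-form statistic ``T = S'S``."""
    S = np.asarray(S, dtype=float)
    return float(S @ S)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


def _imhof_trig_tails(a: float, w: float, m: float, U: float, depth: int = 4):
    """Asymptotic tails ``S_m = int_U^inf sin(a - w u) u^-m du`` and the
    cosine analogue by repeated integration by parts (error O((m/wU)^depth))."""
    if depth == 0:
        return 0.0, 0.0
    S_next, C_next = _imhof_trig_tails(a, w, m + 1.0, U, depth - 1)
    S = -np.cos(a - w * U) * U**-m / w + (m / w) * C_next
    C = np.sin(a - w * U) * U**-m / w - (m / w) * S_next
    return S, C


def _imhof_pvalue(T: float, lam: np.ndarray) -> float:
    """Upper-tail probability of a positively weighted chi-square mixture
    by numerical inversion of the characteristic function.

    Imhof's integral ``p = 1/2 + (1/pi) int_0^inf sin(theta(u))/(u rho(u)) du``
    with ``theta(u) = (1/2) sum arctan(lam u) - T u / 2`` and
    ``rho(u) = prod (1 + lam^2 u^2)^{1/4}`` is evaluated by composite
    Gauss-Legendre quadrature on segments no longer than half an
    oscillation period, plus a closed-form asymptotic tail obtained by
    integration by parts once every ``arctan`` has saturated.
    """
    lam = np.asarray(lam, dtype=float)
    K = lam.size
    if T <= 0:
        return 1.0
    w = T / 2.0
    s = float(np.sum(1.0 / lam))
    m = K / 2.0 + 1.0
    # past U the arctan transients are over and the tail formula is accurate
    U = max(30.0 / lam.min(), 10.0 * m / w, 10.0 * s, 1.0)
    # resolve both the near-zero transient and the asymptotic oscillation
    seg = np.pi / (0.5 * float(lam.sum()) + w)
    n_seg = int(np.ceil(U / seg))
    max_nodes = 2_000_000
    if n_seg * _GL_NODES.size > max_nodes:
        n_seg = max_nodes // _GL_NODES.size
    edges = np.linspace(0.0, U, n_seg + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    total = 0.0
    chunk = 4096
    for lo in range(0, n_seg, chunk):
        h = half[lo:lo + chunk, None]
        u = mid[lo:lo + chunk, None] + h * _GL_NODES[None, :]
        theta = 0.5 * np.arctan(u[..., None] * lam).sum(axis=-1) - w * u
        log_rho = 0.25 * np.log1p((u[..., None] * lam) ** 2).sum(axis=-1)
        vals = np.sin(theta) * np.exp(-log_rho) / u
        total += float((vals @ _GL_WEIGHTS * h[:, 0]).sum())
    # tail: integrand ~ sin(K pi/4 - w u - s/(2u)) / (P u^m)
    P = float(np.exp(0.5 * np.sum(np.log(lam))))
    a = K * np.pi / 4.0
    b = s / 2.0
    S_m, _ = _imhof_trig_tails(a, w, m, U)
    _, C_m1 = _imhof_trig_tails(a, w, m + 1.0, U)
    S_m2, _ = _imhof_trig_tails(a, w, m + 2.0, U)
    tail = (S_m - b * C_m1 - 0.5 * b**2 * S_m2) / P
    return 0.5 + (total + tail) / np.pi


def _liu_pvalue(T: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching noncentral chi-square approximation."""
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = c2**3 / c3**2
    t_star = (T - c1) / np.sqrt(2.0 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta))


def _monte_carlo_pvalue(T: float, lam: np.ndarray, mc_draws: int,
                        rng: np.random.Generator) -> float:
    """(1 + hits) / (1 + draws) estimator of the mixture upper tail."""
    hits = 0
    chunk = 200_000
    done = 0
    while done < mc_draws:
        m = min(chunk, mc_draws - done)
        draws = rng.chisquare(1.0, size=(m, lam.size)) @ lam
        hits += int(np.count_nonzero(draws >= T))
        done += m
    return (1.0 + hits) / (1.0 + mc_draws)


def mixture_chisq_pvalue(
    T: float,
    eigenvalues: np.ndarray,
    method: str = "auto",
    mc_draws: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, str]:
    """p-value ``Pr(sum_k lam_k chi^2_1 > T)`` for the mixture null.

    Policy for ``method="auto"``: when all retained eigenvalues are
    equal (including the single-eigenvalue case) the mixture *is* a
    scaled K-df chi-square and the survival function is evaluated in
    closed form; otherwise Davies-type numerical inversion of the
    characteristic function is used when K > 5 and Monte Carlo sampling
    (``mc_draws`` mixture draws, never returning exactly 0) when
    K <= 5.  Liu's moment-matching approximation backs up the inversion
    whenever it fails to produce a p in (0, 1].

    Eigenvalues below ``1e-12 * max(eigenvalue)`` are discarded as
    numerical noise before any computation.

    Returns ``(p, method_used)``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-8 * max(lam.max(initial=0.0), 1.0)):
        raise InputError("negative eigenvalue passed to mixture_chisq_pvalue")
    lam = lam[lam > EIGENVALUE_RTOL * lam.max(initial=0.0)]
    if lam.size == 0:
        raise DegenerateTestError("all eigenvalues are zero; no test is defined")
    if T < 0:
        raise InputError("test statistic must be nonnegative")
    K = lam.size

    equal = np.allclose(lam, lam[0], rtol=1e-12, atol=0.0)
    if method == "auto":
        if equal:
            method = "chisq_exact"
        elif K > 5:
            method = "davies"
        else:
            method = "monte_carlo"

    if method == "chisq_exact":
        return float(stats.chi2.sf(T / lam[0], K)), "chisq_exact"
    if method == "davies":
        p = _imhof_pvalue(T, lam)
        if not (0.0 < p <= 1.0):
            logger.info("numerical inversion failed (p=%.3g); using Liu fallback", p)
            return _liu_pvalue(T, lam), "liu"
        return float(p), "davies"
    if method == "liu":
        return _liu_pvalue(T, lam), "liu"
    if method == "monte_carlo":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        return _monte_carlo_pvalue(T, lam, int(mc_draws), rng), "monte_carlo"
    raise ConfigurationError(f"unknown p-value method: {method}")


def modality_test(
    gene_id: str,
    tested_modality: str,
    idp_weights: Mapping[str, WeightMatrix],
    z_disease: np.ndarray,
    ld: LDMatrix | np.ndarray,
    adjust_other_modalities: bool = True,
    adjust_direct: bool = True,
    p_method: str = "auto",
    mc_draws: int = 1_000_000,
    seed: int | np.random.Generator | None = None,
) -> ModalityTestResult:
    """Test whether a whole modality carries a genetic pathway to the trait.

    Assembles ``A1`` from the tested modality's weight matrix and the
    adjustment set from the flags, computes the score vector, its null
    covariance and eigenvalues, the statistic ``T = S'S`` and the
    mixture chi-square p-value.  A modality with zero surviving IDP
    columns yields a no-test result rather than an exception.
    """
    A1 = idp_weights[tested_modality]
    n_snps = len(A1.snp_ids)
    if A1.n_idps == 0:
        logger.info("gene %s, modality %s: no surviving IDPs; no test",
                    gene_id, tested_modality)
        return ModalityTestResult(
            gene_id=gene_id, modality=tested_modality, T=np.nan, p_value=np.nan,
            K1=0, n_snps=n_snps, p_method="none", no_test=True,
        )
    adj = build_adjustment(idp_weights, tested_modality,
                           adjust_other_modalities, adjust_direct)
    sr = score_result(A1, adj, ld, z_disease)
    T = test_statistic(sr.S)
    try:
        p, used = mixture_chisq_pvalue(T, sr.eigenvalues, p_method, mc_draws, seed)
    except DegenerateTestError:
        logger.info("gene %s, modality %s: degenerate covariance; no test",
                    gene_id, tested_modality)
        return ModalityTestResult(
            gene_id=gene_id, modality=tested_modality, T=T, p_value=np.nan,
            K1=A1.n_idps, n_snps=n_snps, p_method="none", no_test=True,
        )
    return ModalityTestResult(
        gene_id=gene_id, modality=tested_modality, T=T, p_value=p,
        K1=A1.n_idps, n_snps=n_snps, p_method=used,
        mc_draws=mc_draws if used == "monte_carlo" else None,
        tested_idps=list(A1.idp_ids), adjusted_labels=list(adj.labels),
    )


def idp_specific_test(
    gene_id: str,
    idp_id: str,
    tested_modality: str,
    idp_weights: Mapping[str, WeightMatrix],
    z_disease: np.ndarray,
    ld: LDMatrix | np.ndarray,
    adjust_other_modalities: bool = True,
    adjust_direct: bool = True,
    **kwargs,
) -> ModalityTestResult:
    """Single-IDP variant of the modality test.

    With adjustment on this is the per-IDP comparator (each feature of
    the tested modality examined separately while other modalities and
    the direct-effect column are projected out); with both adjustment
    flags off it is the classical univariate two-stage test.
    """
    wm = idp_weights[tested_modality]
    if idp_id not in wm.idp_ids:
        return ModalityTestResult(
            gene_id=gene_id, modality=tested_modality, T=np.nan, p_value=np.nan,
            K1=0, n_snps=len(wm.snp_ids), p_method="none", no_test=True,
        )
    k = wm.idp_ids.index(idp_id)
    single = WeightMatrix(wm.snp_ids, [idp_id], wm.W[:, [k]], wm.modality)
    weights = dict(idp_weights)
    weights[tested_modality] = single
    res = modality_test(
        gene_id, tested_modality, weights, z_disease, ld,
        adjust_other_modalities, adjust_direct, **kwargs,
    )
    res.tested_idps = [idp_id]
    return res


def bonferroni_adjust(
    p_values: Sequence[float],
    alpha: float = 0.05,
    m: int | None = None,
) -> tuple[np.ndarray, float]:
    """Bonferroni familywise control: flag ``p < alpha/m`` (strict).

    ``m`` defaults to the number of p-values.  Returns the significance
    flags and the threshold used.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else int(m)
    if m < 1:
        raise InputError("bonferroni_adjust needs m >= 1")
    threshold = alpha / m
    return p < threshold, threshold
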