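"""Deterministic-vs-stochastic assembly machinery.

Three complementary diagnostics of community assembly:

* :func:`fit_ncm` — Sloan's neutral community model. The occurrence
  frequency of a taxon with mean relative abundance p is predicted as
  1 − I_d(N·m·p, N·m·(1−p)), where I is the regularised incomplete beta
  function, N the community size (reads per sample), m the migration
  probability, and d = 1/N the detection limit. Nm is fitted by non-linear
  least squares over taxa; goodness of fit R² = 1 − SS_res/SS_tot
  (Östman). A high R² means occupancy is explained by neutral dispersal.
* :func:`levins_niche_breadth` — Levins' B_j = 1/Σ_i P_ij² with P_ij the
  proportion of taxon j's total abundance found in sample i; B ranges from
  1 (confined to one sample) to N (spread evenly over N samples). Bcom is
  the mean B over taxa present in a sample.
* :func:`ses_c_score` — Stone & Roberts' checkerboard score against a
  fixed-marginal null sampled by sequential 2×2 swaps;
  SES = (C_obs − mean C_null)/sd C_null, with |SES| > 2 flagging
  non-random co-occurrence (positive = segregation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .otu_table import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "NcmFit",
    "NicheBreadthResult",
    "CScoreResult",
    "fit_ncm",
    "levins_niche_breadth",
    "c_score",
    "sequential_swap",
    "ses_c_score",
]


# ---------------------------------------------------------------------------
# Neutral community model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NcmFit:
    """Fitted Sloan neutral model.

    ``per_otu`` columns: p (mean relative abundance), freq (observed
    occurrence frequency), predicted, lower, upper (95% Wilson envelope),
    partition ('above' | 'within' | 'below').
    """

    Nm: float
    m: float
    N: int
    r_squared: float
    detection_limit: float
    per_otu: pd.DataFrame
    boundary: bool = False

    @property
    def partition_counts(self) -> dict[str, int]:
        return self.per_otu["partition"].value_counts().to_dict()

    def summary(self) -> dict:
        return {
            "Nm": self.Nm,
            "m": self.m,
            "N": self.N,
            "r_squared": self.r_squared,
            "detection_limit": self.detection_limit,
            "n_otus": int(len(self.per_otu)),
            "partition_counts": self.partition_counts,
            "boundary": self.boundary,
        }


def ncm_predicted_frequency(p: np.ndarray, Nm: float, d: float) -> np.ndarray:
    """Sloan predicted occurrence frequency 1 − I_d(Nm·p, Nm·(1−p))."""
    p = np.asarray(p, dtype=float)
    a = np.maximum(Nm * p, 1e-12)
    b = np.maximum(Nm * (1.0 - p), 1e-12)
    return 1.0 - betainc(a, b, d)


_LOG_NM_BOUNDS = (-3.0, 9.0)  # log10(Nm) search window


def fit_ncm(table: OtuTable, N: int | None = None) -> NcmFit:
    """Fit the neutral community model to an OTU table.

    N defaults to the median sample depth (exact when samples are rarefied
    to equal depth; a warning is logged otherwise). OTUs absent everywhere
    are dropped; at least 10 must remain.
    """
    totals = table.sample_totals
    if N is None:
        N = int(np.median(totals))
    if N < 1:
        raise ValueError("community size N must be >= 1")
    if len(np.unique(totals)) > 1:
        logger.warning("fit_ncm: unequal sample depths; using N=%d (median)", N)
    present = table.occupancy() > 0
    if present.sum() < 10:
        raise ValueError("need at least 10 OTUs present to fit the neutral model")
    rel = table.relative_abundance()[:, present]
    otu_ids = [o for o, k in zip(table.otu_ids, present) if k]
    p = rel.mean(axis=0)
    freq = (rel > 0).mean(axis=0)
    d = 1.0 / N
    if d >= p.max():
        raise ValueError(
            f"degenerate fit: detection limit {d:g} >= max mean abundance {p.max():g}"
        )

    def sse(log_nm: float) -> float:
        pred = ncm_predicted_frequency(p, 10.0**log_nm, d)
        return float(((freq - pred) ** 2).sum())

    res = minimize_scalar(sse, bounds=_LOG_NM_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(
            f"NCM fit did not converge: last log10(Nm)={res.x:.4f}, "
            f"residual={res.fun:.6g}"
        )
    log_nm = float(res.x)
    boundary = (
        log_nm <= _LOG_NM_BOUNDS[0] + 1e-3 or log_nm >= _LOG_NM_BOUNDS[1] - 1e-3
    )
    if boundary:
        logger.warning("fit_ncm: Nm estimate at search boundary (log10 Nm=%.2f)", log_nm)
    Nm = 10.0**log_nm
    pred = ncm_predicted_frequency(p, Nm, d)
    ss_res = float(((freq - pred) ** 2).sum())
    ss_tot = float(((freq - freq.mean()) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        # no occupancy variation (e.g. every OTU in every sample): the SSE is
        # flat in Nm beyond some point and the estimate is not identified
        r2 = np.nan
        boundary = True
        logger.warning("fit_ncm: occurrence frequencies have zero variance; "
                       "Nm not identified")
    n_samp = table.n_samples
    lower, upper = proportion_confint(pred * n_samp, n_samp, alpha=0.05, method="wilson")
    partition = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))
    per_otu = pd.DataFrame(
        {
            "p": p,
            "freq": freq,
            "predicted": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    return NcmFit(Nm=float(Nm), m=float(Nm / N), N=int(N), r_squared=float(r2),
                  detection_limit=d, per_otu=per_otu, boundary=boundary)


# ---------------------------------------------------------------------------
# Levins' niche breadth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NicheBreadthResult:
    """Per-OTU Levins B and per-sample community mean Bcom."""

    b: pd.Series  # index otu_id
    bcom: pd.Series  # index sample_id

    @property
    def mean_b(self) -> float:
        return float(self.b.mean())


def levins_niche_breadth(table: OtuTable) -> NicheBreadthResult:
    """Levins' B per OTU and community-level Bcom per sample.

    P_ij is taxon j's count in sample i divided by its total count over all
    samples; B_j = 1/Σ_i P_ij² ∈ [1, n_samples]. Bcom for a sample is the
    unweighted mean of B over taxa present there. OTUs absent everywhere
    are excluded with a warning.
    """
    tot = table.otu_totals
    present = tot > 0
    if not present.all():
        absent = [o for o, k in zip(table.otu_ids, present) if not k]
        warnings.warn(f"levins_niche_breadth: excluding {len(absent)} OTU(s) absent everywhere")
    counts = table.counts[:, present].astype(float)
    otu_ids = [o for o, k in zip(table.otu_ids, present) if k]
    P = counts / counts.sum(axis=0)
    b = 1.0 / (P**2).sum(axis=0)
    b_series = pd.Series(b, index=pd.Index(otu_ids, name="otu_id"), name="B")
    presence = counts > 0
    bcom = np.full(table.n_samples, np.nan)
    for i in range(table.n_samples):
        mask = presence[i]
        if mask.any():
            bcom[i] = b[mask].mean()
    bcom_series = pd.Series(bcom, index=pd.Index(table.sample_ids, name="sample_id"),
                            name="Bcom")
    return NicheBreadthResult(b_series, bcom_series)


# ---------------------------------------------------------------------------
# C-score and sequential-swap null model
# ---------------------------------------------------------------------------

def _as_binary(matrix: OtuTable | np.ndarray) -> np.ndarray:
    if isinstance(matrix, OtuTable):
        return matrix.presence_absence()
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("binary matrix must be 2-D")
    return (m > 0).astype(np.uint8)


def c_score(binary_matrix: OtuTable | np.ndarray) -> float:
    """Stone–Roberts checkerboard score, species as rows.

    C = mean over species pairs of (R_i − S_ij)(R_j − S_ij), with R row
    totals and S the number of shared sites.
    """
    A = _as_binary(binary_matrix).astype(np.int64)
    n_rows = A.shape[0]
    if n_rows < 2:
        raise ValueError("need at least 2 species rows")
    R = A.sum(axis=1)
    S = A @ A.T
    units = (R[:, None] - S) * (R[None, :] - S)
    iu = np.triu_indices(n_rows, k=1)
    return float(units[iu].mean())


def _has_checkerboard(A: np.ndarray) -> bool:
    n = A.shape[0]
    for i in range(n - 1):
        gt = A[i] > A[i + 1:]
        lt = A[i] < A[i + 1:]
        if (gt.any(axis=1) & lt.any(axis=1)).any():
            return True
    return False


class _SwapChain:
    """Markov chain over binary matrices with fixed row/column sums.

    Each step proposes a uniformly random 2×2 submatrix and swaps it iff it
    is a checkerboard ([[1,0],[0,1]] or its complement). The proposal is
    symmetric, so the stationary distribution is uniform over all matrices
    sharing the marginals. The pairwise shared-site matrix S and the total
    checkerboard-unit sum are maintained incrementally (O(n_rows) per
    accepted swap) so C-score sampling is cheap.
    """

    def __init__(self, A: np.ndarray, rng: np.random.Generator):
        self.A = A.astype(np.int64).copy()
        self.rng = rng
        self.n_rows, self.n_cols = self.A.shape
        self.R = self.A.sum(axis=1)
        self.S = self.A @ self.A.T
        units = (self.R[:, None] - self.S) * (self.R[None, :] - self.S)
        iu = np.triu_indices(self.n_rows, k=1)
        self.total = float(units[iu].sum())
        self.n_pairs = len(iu[0])

    def _pair_sum(self, r: int) -> float:
        u = (self.R[r] - self.S[r]) * (self.R - self.S[r])
        return float(u.sum() - u[r])

    def step(self) -> bool:
        rng = self.rng
        r1 = rng.integers(self.n_rows)
        r2 = rng.integers(self.n_rows - 1)
        if r2 >= r1:
            r2 += 1
        c1 = rng.integers(self.n_cols)
        c2 = rng.integers(self.n_cols - 1)
        if c2 >= c1:
            c2 += 1
        A = self.A
        a = A[r1, c1]
        b = A[r1, c2]
        if a == b or A[r2, c1] != b or A[r2, c2] != a:
            return False
        old = self._pair_sum(r1) + self._pair_sum(r2) \
            - (self.R[r1] - self.S[r1, r2]) * (self.R[r2] - self.S[r1, r2])
        x = A[:, c1].copy()
        y = A[:, c2].copy()
        # flip the four cells
        A[r1, c1], A[r1, c2] = b, a
        A[r2, c1], A[r2, c2] = a, b
        sgn = int(b) - int(a)
        delta = sgn * (x - y)
        delta[r1] = 0
        delta[r2] = 0
        self.S[r1, :] += delta
        self.S[:, r1] += delta
        self.S[r2, :] -= delta
        self.S[:, r2] -= delta
        new = self._pair_sum(r1) + self._pair_sum(r2) \
            - (self.R[r1] - self.S[r1, r2]) * (self.R[r2] - self.S[r1, r2])
        self.total += new - old
        return True

    @property
    def c(self) -> float:
        return self.total / self.n_pairs


def sequential_swap(
    binary_matrix: OtuTable | np.ndarray,
    n_burn: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Randomise a binary matrix by ``n_burn`` attempted checkerboard swaps.

    Row and column sums are preserved exactly. If the matrix contains no
    swappable 2×2 submatrix it is returned unchanged with a warning.
    """
    A = _as_binary(binary_matrix)
    if not _has_checkerboard(A):
        warnings.warn("sequential_swap: no swappable checkerboard submatrix; matrix unchanged")
        return A.copy()
    chain = _SwapChain(A, np.random.default_rng(seed))
    for _ in range(n_burn):
        chain.step()
    return chain.A.astype(np.uint8)


@dataclass(frozen=True)
class CScoreResult:
    c_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p_upper: float
    p_lower: float
    p_normal: float
    n_sim: int
    seed: int

    @property
    def verdict(self) -> str:
        """'segregation' (SES > 2), 'aggregation' (SES < −2), else 'random'."""
        if self.ses > 2:
            return "segregation"
        if self.ses < -2:
            return "aggregation"
        return "random"


def ses_c_score(
    matrix: OtuTable | np.ndarray,
    n_sim: int = 30000,
    thin: int = 1,
    burn_in: int | None = None,
    seed: int = 0,
) -> CScoreResult:
    """Standardised effect size of the C-score under the fixed-marginal null.

    The null is sampled by a sequential-swap chain: ``burn_in`` attempted
    swaps (default 5× the matrix fill), then one C-score recorded every
    ``thin`` attempts, ``n_sim`` times. SES = (C_obs − mean_null)/sd_null;
    empirical upper/lower tail probabilities carry the +1 correction.
    """
    if n_sim < 10:
        raise ValueError("n_sim must be >= 10 for a stable null standard deviation")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    A = _as_binary(matrix)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 species rows")
    if not _has_checkerboard(A):
        raise ValueError("degenerate null: matrix has no swappable submatrix")
    rng = np.random.default_rng(seed)
    fill = int(A.sum())
    if burn_in is None:
        burn_in = 5 * fill
    chain = _SwapChain(A, rng)
    c_obs = chain.c
    for _ in range(burn_in):
        chain.step()
    null = np.empty(n_sim)
    for k in range(n_sim):
        for _ in range(thin):
            chain.step()
        null[k] = chain.c
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        raise ValueError("degenerate null: zero variance across swap samples")
    ses = (c_obs - null_mean) / null_sd
    p_upper = (float((null >= c_obs).sum()) + 1) / (n_sim + 1)
    p_lower = (float((null <= c_obs).sum()) + 1) / (n_sim + 1)
    p_normal = float(2 * norm.sf(abs(ses)))
    return CScoreResult(
        c_obs=float(c_obs), null_mean=null_mean, null_sd=null_sd, ses=float(ses),
        p_upper=p_upper, p_lower=p_lower, p_normal=p_normal, n_sim=n_sim, seed=seed,
    )
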