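"""Alpha diversity, Bray–Curtis distances, and permutation statistics.

Alpha indices follow the vegan conventions the field uses: Shannon in nats,
Simpson as the Gini–Simpson complement 1 − Σp² (larger = more diverse),
Chao1 = S_obs + F1²/(2F2) (bias-corrected only when F2 = 0), ACE with rare
threshold 10, Pielou J = H / ln(S_obs).
ANOSIM, Mantel and partial Mantel are permutation tests with seeded
generators; the partial Mantel permutes the community matrix (Legendre).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date
from itertools import permutations as _permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from skbio.diversity import alpha as _skalpha

from .otu_table import OtuTable, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "AlphaDiversity",
    "PermutationTestResult",
    "alpha_diversity",
    "bray_curtis",
    "anosim",
    "mantel",
    "partial_mantel",
    "time_lag_analysis",
    "multi_nutrient_cycling_index",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with ordered labels."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.d, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    richness: int
    ace: float
    chao1: float
    shannon: float
    simpson: float
    pielou: float


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int
    method: str = ""


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: OtuTable, ace_rare_threshold: int = 10) -> list[AlphaDiversity]:
    """Per-sample richness, ACE, Chao1, Shannon (nats), Gini–Simpson, Pielou.

    Empty samples yield NaN indices and richness 0.
    """
    out = []
    for sid, row in zip(table.sample_ids, table.counts):
        counts = row[row > 0]
        s_obs = int(len(counts))
        if s_obs == 0:
            out.append(AlphaDiversity(sid, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        h = float(_skalpha.shannon(counts, base=np.e))
        simp = float(1.0 - np.sum((counts / counts.sum()) ** 2))
        # classic Chao1 = S_obs + F1^2/(2 F2); skbio falls back to the
        # bias-corrected form automatically when F2 = 0
        chao = float(_skalpha.chao1(counts, bias_corrected=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ace_v = float(_skalpha.ace(counts, rare_threshold=ace_rare_threshold))
            except (ZeroDivisionError, ValueError):
                ace_v = float(s_obs)
        if not np.isfinite(ace_v):
            ace_v = float(s_obs)
        pielou = h / np.log(s_obs) if s_obs > 1 else (np.nan if s_obs == 0 else 0.0)
        out.append(AlphaDiversity(sid, s_obs, ace_v, chao, h, simp, float(pielou)))
    return out


def alpha_diversity_frame(table: OtuTable) -> pd.DataFrame:
    rows = alpha_diversity(table)
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")


# ---------------------------------------------------------------------------
# Bray–Curtis
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable, transform: str = "relative") -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, d = Σ|x−y| / Σ(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.sample_totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, table.sample_totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad[:5]}")
    if transform == "relative":
        x = table.relative_abundance()
    elif transform == "counts":
        x = table.counts.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    rw = ranks[within_mask].mean()
    rb = ranks[~within_mask].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Clarke's analysis of similarities with label-permutation p-value."""
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValueError("groups length must match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    n = d.n
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.d[iu])
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, same, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g = groups[perm]
        same_p = g[iu[0]] == g[iu[1]]
        if _anosim_r(ranks, same_p, n) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(r_obs, n_perm, p, seed, "anosim")


def _check_ids(*mats: DistanceMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("distance matrices have mismatching ids")


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _prep(mat: DistanceMatrix, method: str) -> np.ndarray:
    """Full matrix, rank-transformed off-diagonal for spearman."""
    m = mat.d.copy()
    if method == "spearman":
        n = m.shape[0]
        off = ~np.eye(n, dtype=bool)
        m[off] = rankdata(m[off])
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    return m


def mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    Statistic: correlation of the off-diagonal entries; p-value by
    simultaneous row/column permutation of the second matrix, one-sided
    (r_perm >= r_obs), with the +1 correction.
    """
    _check_ids(dA, dB)
    n = dA.n
    iu = np.triu_indices(n, k=1)
    A = _prep(dA, method)
    B = _prep(dB, method)
    a = A[iu]
    r_obs = _corr(a, B[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        if _corr(a, Bp[iu]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(r_obs, n_perm, p, seed, f"mantel-{method}")


def mantel_exact(dA: DistanceMatrix, dB: DistanceMatrix, method: str = "pearson") -> PermutationTestResult:
    """Mantel p by complete enumeration of all n! permutations (n <= 8)."""
    _check_ids(dA, dB)
    n = dA.n
    if n > 8:
        raise ValueError("exact enumeration only for n <= 8")
    iu = np.triu_indices(n, k=1)
    A = _prep(dA, method)
    B = _prep(dB, method)
    a = A[iu]
    r_obs = _corr(a, B[iu])
    count = 0
    total = 0
    for perm in _permutations(range(n)):
        perm = np.array(perm)
        Bp = B[np.ix_(perm, perm)]
        if _corr(a, Bp[iu]) >= r_obs - 1e-12:
            count += 1
        total += 1
    return PermutationTestResult(r_obs, total, count / total, 0, f"mantel-exact-{method}")


def partial_mantel(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    dC: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Partial Mantel r of A and B controlling for C.

    r_AB·C = (r_AB − r_AC·r_BC) / sqrt((1−r_AC²)(1−r_BC²)); the p-value
    permutes the rows/columns of dA (community matrix) and recomputes the
    partial statistic with B and C fixed.
    """
    _check_ids(dA, dB, dC)
    n = dA.n
    iu = np.triu_indices(n, k=1)
    A = _prep(dA, method)
    b = _prep(dB, method)[iu]
    c = _prep(dC, method)[iu]
    r_bc = _corr(b, c)
    if abs(r_bc) >= 1 - 1e-12:
        raise ValueError("degenerate: |r_BC| = 1, partial correlation undefined")

    def partial_r(avec: np.ndarray) -> float:
        r_ab = _corr(avec, b)
        r_ac = _corr(avec, c)
        denom = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        if denom <= 1e-12:
            raise ValueError("degenerate: |r_AC| = 1, partial correlation undefined")
        return (r_ab - r_ac * r_bc) / denom

    r_obs = partial_r(A[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Ap = A[np.ix_(perm, perm)]
        try:
            if partial_r(Ap[iu]) >= r_obs:
                count += 1
        except ValueError:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(float(r_obs), n_perm, p, seed, f"partial-mantel-{method}")


# ---------------------------------------------------------------------------
# Time-lag regression
# ---------------------------------------------------------------------------

_DAYS_PER_MONTH = 30.44


def time_lag_analysis(
    d: DistanceMatrix,
    dates: Sequence[_date],
    mode: str = "absolute",
) -> tuple[pd.DataFrame, float]:
    """Pairwise dissimilarity against time lag.

    ``absolute`` lags are |Δt| in days. ``annual`` lags wrap around the
    annual cycle: day differences are mapped to fractional months
    (Δdays / 30.44) and folded so January vs December is 1 month, January
    vs July 6. Returns the pair table (lag, dissimilarity) and the Spearman
    rank correlation of lag vs dissimilarity.
    """
    if len(dates) != d.n:
        raise ValueError("dates length must match distance matrix")
    if mode not in ("absolute", "annual"):
        raise ValueError(f"unknown mode {mode!r}")
    ordinals = np.array([dt.toordinal() for dt in dates], dtype=float)
    iu = np.triu_indices(d.n, k=1)
    delta_days = np.abs(ordinals[iu[0]] - ordinals[iu[1]])
    if mode == "absolute":
        lags = delta_days
    else:
        months = delta_days / _DAYS_PER_MONTH
        wrapped = np.mod(months, 12.0)
        lags = np.minimum(wrapped, 12.0 - wrapped)
    diss = d.d[iu]
    frame = pd.DataFrame({
        "sample_a": [d.ids[i] for i in iu[0]],
        "sample_b": [d.ids[j] for j in iu[1]],
        "lag": lags,
        "dissimilarity": diss,
    })
    if len(frame) > 1 and np.ptp(lags) > 0:
        rho = float(spearmanr(lags, diss).statistic)
    else:
        rho = np.nan
    return frame, rho


# ---------------------------------------------------------------------------
# Multi-nutrient cycling index
# ---------------------------------------------------------------------------

DEFAULT_NUTRIENT_VARIABLES = (
    "TC", "TOC", "TN", "NH4-N", "NO3-N", "NO2-N", "TP", "PO4-P",
)


def multi_nutrient_cycling_index(
    metadata: Sequence[SampleMetadata],
    variables: Sequence[str] = DEFAULT_NUTRIENT_VARIABLES,
) -> pd.Series:
    """Averaging multifunctionality index: mean per-variable z-score.

    Variables missing from the metadata or with zero variance are excluded
    with a warning. Unit changes (affine per-variable rescaling) leave the
    index unchanged.
    """
    present = [v for v in variables if any(v in m.env for m in metadata)]
    if len(present) < 2:
        raise ValueError("need at least 2 nutrient variables with data")
    cols = {}
    for v in present:
        vals = np.array([m.env.get(v, np.nan) for m in metadata], dtype=float)
        sd = np.nanstd(vals)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"multi_nutrient_cycling_index: excluding constant variable {v!r}")
            continue
        cols[v] = (vals - np.nanmean(vals)) / sd
    if len(cols) < 2:
        raise ValueError("fewer than 2 variables with nonzero variance")
    z = np.vstack(list(cols.values()))
    idx = np.nanmean(z, axis=0)
    return pd.Series(idx, index=[m.sample_id for m in metadata], name="mnc_index")
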