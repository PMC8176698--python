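"""Synthetic OTU tables with known assembly structure.

Every downstream stage of the package (neutral-model fitting, niche breadth,
null models, SparCC networks) is exercised against data generated here, where
the ground truth is known by construction:

* ``simulate_neutral_series`` draws per-taxon relative abundances from the
  Sloan neutral model's stationary Beta marginal, Beta(N·m·p_j, N·m·(1−p_j)),
  then multinomial reads — exactly the distribution the NCM fitter assumes,
  so fitted m can be compared against the generating m.
* ``simulate_selection_series`` adds salinity-driven selection by Gaussian
  niche filtering of the source pool; strength 0 reduces exactly to the
  neutral path.
* ``implant_correlations`` injects known pairwise basis correlations on a
  latent log-normal scale for SparCC recovery tests.
* ``simulate_metadata`` emulates a twice-weekly 13-month sampling campaign
  with a seasonal salinity profile anti-correlated with precipitation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import date as _date, timedelta
from typing import Sequence

import numpy as np

from .otu_table import OtuTable, SampleMetadata

__all__ = [
    "SourcePool",
    "NeutralSimConfig",
    "SelectionConfig",
    "make_source_pool",
    "simulate_neutral_series",
    "simulate_selection_series",
    "implant_correlations",
    "simulate_metadata",
]


@dataclass(frozen=True)
class SourcePool:
    """Source (regional) community relative abundances, summing to 1."""

    otu_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if (p <= 0).any():
            raise ValueError("source pool abundances must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("source pool abundances must sum to 1")
        if len(p) != len(self.otu_ids):
            raise ValueError("otu_ids and p length mismatch")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class NeutralSimConfig:
    """Parameters of a neutral-assembly simulation.

    S taxa, N reads per sample, migration probability m in (0, 1],
    n_samples local communities.
    """

    S: int
    N: int
    m: float
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.m <= 1:
            raise ValueError("m must be in (0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class SelectionConfig:
    """Gaussian salinity niches: per-taxon optimum (permil), shared width
    sigma (permil), and a selection strength (0 = neutral)."""

    optima: np.ndarray
    sigma: float = 1.0
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        object.__setattr__(self, "optima", np.asarray(self.optima, dtype=float))


def make_source_pool(S: int, lognormal_sigma: float = 1.0, seed: int = 0) -> SourcePool:
    """Log-normal species-abundance distribution, normalised to sum 1.

    ``lognormal_sigma = 0`` degenerates to a uniform pool.
    """
    if S < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=S)) if lognormal_sigma > 0 \
        else np.ones(S)
    p = raw / raw.sum()
    ids = tuple(f"OTU_{i + 1}" for i in range(S))
    return SourcePool(ids, p)


def _draw_sample(rng: np.random.Generator, p_eff: np.ndarray, N: int, m: float) -> np.ndarray:
    """One local community: Sloan stationary Beta marginals then N reads."""
    a = N * m * p_eff
    b = N * m * (1.0 - p_eff)
    rel = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
    total = rel.sum()
    if total <= 0:  # pragma: no cover - vanishing probability
        rel = p_eff
        total = rel.sum()
    return rng.multinomial(N, rel / total)


def simulate_neutral_series(pool: SourcePool, cfg: NeutralSimConfig) -> OtuTable:
    """Neutral assembly: every sample drawn from the same source pool."""
    if cfg.S != len(pool.p):
        raise ValueError("cfg.S does not match pool size")
    sel = SelectionConfig(optima=np.zeros(cfg.S), sigma=1.0, strength=0.0)
    return simulate_selection_series(pool, cfg, sel, salinity=np.zeros(cfg.n_samples))


def simulate_selection_series(
    pool: SourcePool,
    cfg: NeutralSimConfig,
    sel: SelectionConfig,
    salinity: Sequence[float],
) -> OtuTable:
    """Salinity-filtered assembly.

    The effective source pool of sample i is
    p'_j ∝ p_j · exp(−strength · (salinity_i − optimum_j)² / (2 σ²));
    sampling then follows the neutral path. strength = 0 reproduces
    ``simulate_neutral_series`` draw-for-draw under the same seed.
    """
    salinity = np.asarray(salinity, dtype=float)
    if len(salinity) != cfg.n_samples:
        raise ValueError("salinity length must equal cfg.n_samples")
    if sel.strength > 0 and len(sel.optima) != cfg.S:
        raise ValueError("optima length must equal cfg.S")
    rng = np.random.default_rng(cfg.seed)
    counts = np.empty((cfg.n_samples, cfg.S), dtype=np.int64)
    for i, s in enumerate(salinity):
        if sel.strength > 0:
            w = np.exp(-sel.strength * (s - sel.optima) ** 2 / (2.0 * sel.sigma**2))
            p_eff = pool.p * np.maximum(w, 1e-300)
            p_eff = p_eff / p_eff.sum()
        else:
            p_eff = pool.p
        counts[i] = _draw_sample(rng, p_eff, cfg.N, cfg.m)
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(cfg.n_samples))
    return OtuTable(sample_ids, pool.otu_ids, counts)


def implant_correlations(
    table: OtuTable,
    pairs: Sequence[tuple[str, str, int]],
    rho: float,
    seed: int = 0,
    log_sigma: float = 1.0,
) -> OtuTable:
    """Re-draw the named OTU pairs from shared latent log-normal factors.

    Each pair (u, v, sign) gets per-sample latent log-abundances sharing a
    common factor scaled so that the basis (log-scale) correlation is
    ±|rho|; the latent fractions are centred on each OTU's observed mean
    relative abundance. Rows are then redrawn multinomially at their
    original depth, preserving every untouched OTU's expected proportion
    and the exact sample totals.
    """
    if not 0 < abs(rho) <= 1:
        raise ValueError("rho must satisfy 0 < |rho| <= 1")
    o_index = {o: j for j, o in enumerate(table.otu_ids)}
    seen: set[str] = set()
    for u, v, sign in pairs:
        for o in (u, v):
            if o not in o_index:
                raise KeyError(f"unknown OTU id {o!r}")
            if o in seen:
                raise ValueError(f"OTU {o!r} appears in more than one pair")
            seen.add(o)
        if sign not in (-1, 1):
            raise ValueError("pair sign must be -1 or +1")
    rng = np.random.default_rng(seed)
    fracs = table.relative_abundance().copy()
    mean_frac = fracs.mean(axis=0)
    lam = np.sqrt(abs(rho)) * log_sigma
    eps_sd = np.sqrt(max(log_sigma**2 - lam**2, 0.0))
    n = table.n_samples
    for u, v, sign in pairs:
        g = rng.normal(0.0, 1.0, size=n)
        for otu, flip in ((u, 1.0), (v, float(sign))):
            j = o_index[otu]
            base = max(mean_frac[j], 1.0 / max(table.sample_totals.max(), 1))
            z = flip * lam * g + rng.normal(0.0, eps_sd, size=n)
            fracs[:, j] = base * np.exp(z - log_sigma**2 / 2.0)
    totals = table.sample_totals
    new_counts = np.empty_like(table.counts)
    for i in range(n):
        pvec = fracs[i]
        ssum = pvec.sum()
        if ssum <= 0:
            new_counts[i] = table.counts[i]
            continue
        new_counts[i] = rng.multinomial(int(totals[i]), pvec / ssum)
    return OtuTable(table.sample_ids, table.otu_ids, new_counts, table.taxonomy)


def simulate_metadata(
    n_samples: int,
    date_start: _date = _date(2016, 9, 23),
    cadence: float = 3.5,
    salinity_profile: str = "seasonal",
    salinity_range: tuple[float, float] = (0.0, 6.1),
    seed: int = 0,
) -> list[SampleMetadata]:
    """Sampling-campaign metadata with a salinity covariate.

    Profiles: ``seasonal`` (annual sinusoid plus noise, anti-correlated with
    a generated precipitation series — dry season is salty), ``step`` (three
    equal blocks at low/medium/high salinity), ``constant`` (midpoint).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = salinity_range
    if not hi > lo >= 0:
        raise ValueError("salinity range must satisfy 0 <= lo < hi")
    rng = np.random.default_rng(seed)
    days = np.arange(n_samples) * cadence
    dates = [date_start + timedelta(days=float(d)) for d in days]
    phase = 2.0 * np.pi * days / 365.25
    if salinity_profile == "seasonal":
        # wetness in [0, 1]: high wetness = rain season = fresh water
        wetness = 0.5 + 0.4 * np.sin(phase) + rng.normal(0, 0.08, n_samples)
        wetness = np.clip(wetness, 0.0, 1.0)
        sal = lo + (hi - lo) * (1.0 - wetness) ** 2
        precip = 5.0 + 180.0 * wetness + rng.gamma(1.5, 5.0, n_samples)
    elif salinity_profile == "step":
        block = np.minimum(np.arange(n_samples) * 3 // n_samples, 2)
        levels = np.array([lo + 0.1 * (hi - lo), lo + 0.25 * (hi - lo), lo + 0.7 * (hi - lo)])
        sal = levels[block] + rng.normal(0, 0.01 * (hi - lo), n_samples)
        precip = rng.gamma(2.0, 20.0, n_samples)
    elif salinity_profile == "constant":
        sal = np.full(n_samples, (lo + hi) / 2.0)
        precip = rng.gamma(2.0, 20.0, n_samples)
    else:
        raise ValueError(f"unknown salinity_profile {salinity_profile!r}")
    sal = np.clip(sal, lo, hi)
    wind = rng.gamma(4.0, 0.8, n_samples)
    temp = 20.0 + 8.0 * np.sin(phase - 0.3) + rng.normal(0, 1.0, n_samples)
    out = []
    for i in range(n_samples):
        env = {
            "WT": float(temp[i]),
            "pH": float(7.8 + rng.normal(0, 0.2)),
            "TN": float(1.5 + 0.2 * sal[i] + rng.normal(0, 0.2)),
            "TP": float(0.08 + rng.normal(0, 0.01)),
        }
        out.append(
            SampleMetadata(
                sample_id=f"S{i + 1:03d}",
                date=dates[i],
                station="G",
                salinity=float(sal[i]),
                env=env,
                precipitation=float(precip[i]),
                wind=float(wind[i]),
            )
        )
    return out


def stable_stage_seed(root_seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a root seed and a label."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
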