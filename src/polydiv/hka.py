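"""Maximum-likelihood multilocus HKA test.

The HKA framework compares polymorphism-to-divergence ratios across loci.
Each locus i contributes two independent Poisson cells, the silent
segregating-site count S_i and the silent divergence count D_i:

    E[S_i] = k_i · θ_i · L_i · a(n_i)
    E[D_i] = θ_i · L_i · (T + (1 + k_i) / 2)

where a(n) is the harmonic number Σ 1/j, θ_i the per-site neutral diversity
of locus i, T the species divergence time in 2N-generation units (the
(1+k)/2 term carries ancestral polymorphism), and k_i a locus-specific
selection parameter: k = 1 is neutral, k < 1 directional selection, k > 1
balancing selection. The null model fixes k_i = 1 everywhere; the
alternative frees k_i for a designated candidate set and is compared by a
χ² likelihood-ratio test with df = number of candidates.

θ_i is profiled in closed form given (T, k); T and the candidate k's are
optimised numerically in log space with multi-start restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .errors import FitError
from .mk import chi_square_upper_tail
from .popstats import harmonic
from .seqdata import LocusAlignment, SiteClassTable, classify_sites
from . import popstats


@dataclass
class HKALocusCounts:
    """Silent polymorphism/divergence counts for one locus."""

    locus_id: str
    S: int
    D: int
    L: float
    n: int
    theta_multiplier: float = 1.0  # hook for e.g. X-linked scaling; default no correction

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise ValueError(f"{self.locus_id}: negative count")
        if self.L <= 0:
            raise ValueError(f"{self.locus_id}: L must be positive")
        if self.n < 2:
            raise ValueError(f"{self.locus_id}: n must be >= 2")


def hka_counts_from_alignment(
    aln: LocusAlignment, table: SiteClassTable | None = None, site_set: str = "silent"
) -> HKALocusCounts:
    """Silent S and divergence counts for the HKA test from one alignment.

    Divergence is the number of differing silent columns between the first
    ingroup allele and the outgroup (single-sequence convention).
    """
    table = table or classify_sites(aln)
    matrix = aln.ingroup_matrix()
    mask = popstats.site_mask(table, site_set)
    _, S = popstats._pair_diff_stats(matrix, mask)
    out_row = np.asarray(
        [popstats.MISSING if b not in "ACGT" else "ACGT".index(b) for b in aln.outgroup_seq],
        dtype=np.uint8,
    )
    D = int((matrix[0, mask] != out_row[mask]).sum())
    return HKALocusCounts(
        locus_id=aln.locus_id, S=S, D=D, L=popstats.site_count(table, site_set), n=aln.n
    )


@dataclass
class HKAFit:
    """Maximum-likelihood HKA fit (null when ``candidates`` is empty)."""

    theta: dict[str, float]  # per-locus θ̂ (per site)
    T: float
    k: dict[str, float]  # candidate loci only; all others fixed at 1
    logL: float
    candidates: tuple[str, ...] = ()
    converged: bool = True


def _hka_loglik(T: float, kvec: np.ndarray, data: dict) -> float:
    """Log-likelihood with per-locus θ profiled analytically."""
    a = data["a"]
    L = data["L"] * data["mult"]
    S, D = data["S"], data["D"]
    div_coef = T + (1.0 + kvec) / 2.0
    denom = L * (kvec * a + div_coef)
    theta = (S + D) / np.maximum(denom, 1e-300)
    muS = np.maximum(kvec * theta * L * a, 1e-300)
    muD = np.maximum(theta * L * div_coef, 1e-300)
    ll = np.sum(S * np.log(muS) - muS - gammaln(S + 1.0))
    ll += np.sum(D * np.log(muD) - muD - gammaln(D + 1.0))
    return float(ll)


def fit_hka(
    counts: list[HKALocusCounts],
    candidates: set[str] | list[str] | tuple[str, ...] = (),
    n_restarts: int = 5,
    seed: int = 0,
) -> HKAFit:
    """Fit the multilocus HKA model by maximum likelihood.

    ``candidates`` names the loci given a free selection parameter k; an
    empty set is the null (all-neutral) fit.
    """
    if len(counts) < 2:
        raise ValueError("HKA requires at least 2 loci")
    ids = [c.locus_id for c in counts]
    cand = tuple(sorted(set(candidates)))
    unknown = set(cand) - set(ids)
    if unknown:
        raise ValueError(f"unknown candidate loci: {sorted(unknown)}")
    if cand and len(cand) >= len(counts):
        raise ValueError("candidates must be a strict subset of loci")
    data = {
        "S": np.asarray([c.S for c in counts], dtype=float),
        "D": np.asarray([c.D for c in counts], dtype=float),
        "L": np.asarray([c.L for c in counts], dtype=float),
        "a": np.asarray([harmonic(c.n) for c in counts]),
        "mult": np.asarray([c.theta_multiplier for c in counts]),
    }
    cand_idx = [ids.index(c) for c in cand]

    def negll(x: np.ndarray) -> float:
        T = math.exp(x[0])
        kvec = np.ones(len(counts))
        for j, i in enumerate(cand_idx):
            kvec[i] = math.exp(x[1 + j])
        return -_hka_loglik(T, kvec, data)

    # moment start for T: pooled D/S ratio => T ≈ a · ΣD/ΣS − 1
    t0 = max(np.mean(data["a"]) * data["D"].sum() / max(data["S"].sum(), 1.0) - 1.0, 0.1)
    x0 = np.array([math.log(t0)] + [0.0] * len(cand))
    rng = np.random.default_rng(seed)
    best = None
    for kres in range(max(n_restarts, 1)):
        start = x0 if kres == 0 else x0 + rng.normal(0, 0.7, size=len(x0))
        res = optimize.minimize(
            negll, start, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("HKA fit failed to converge")
    T = math.exp(best.x[0])
    kvec = np.ones(len(counts))
    for j, i in enumerate(cand_idx):
        kvec[i] = math.exp(best.x[1 + j])
    div_coef = T + (1.0 + kvec) / 2.0
    Lm = data["L"] * data["mult"]
    theta = (data["S"] + data["D"]) / (Lm * (kvec * data["a"] + div_coef))
    return HKAFit(
        theta={i: float(t) for i, t in zip(ids, theta)},
        T=T,
        k={c: float(kvec[ids.index(c)]) for c in cand},
        logL=-float(best.fun),
        candidates=cand,
        converged=bool(best.success),
    )


def hka_lrt(
    counts: list[HKALocusCounts],
    candidates: set[str] | list[str] | tuple[str, ...],
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[float, int, float, HKAFit, HKAFit]:
    """LRT of selection on the candidate loci vs the all-neutral null.

    Returns ``(stat, df, p, null_fit, alt_fit)`` with stat = 2Δlog(L)
    clipped at 0 and df = number of candidate loci.
    """
    cand = tuple(sorted(set(candidates)))
    if not cand:
        raise ValueError("candidate set must be non-empty for the LRT")
    null_fit = fit_hka(counts, (), n_restarts=n_restarts, seed=seed)
    alt_fit = fit_hka(counts, cand, n_restarts=n_restarts, seed=seed)
    stat = max(2.0 * (alt_fit.logL - null_fit.logL), 0.0)
    df = len(cand)
    return stat, df, chi_square_upper_tail(stat, df), null_fit, alt_fit


def sample_hka_counts(
    theta: np.ndarray | list[float],
    T: float,
    L: np.ndarray | list[float],
    n: np.ndarray | list[int],
    k: np.ndarray | list[float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[HKALocusCounts]:
    """Draw (S, D) counts directly from the HKA Poisson model (for calibration)."""
    rng = rng or np.random.default_rng()
    theta = np.asarray(theta, dtype=float)
    L = np.asarray(L, dtype=float)
    n = np.asarray(n, dtype=int)
    kvec = np.ones_like(theta) if k is None else np.asarray(k, dtype=float)
    a = np.asarray([harmonic(int(m)) for m in n])
    S = rng.poisson(kvec * theta * L * a)
    D = rng.poisson(theta * L * (T + (1.0 + kvec) / 2.0))
    return [
        HKALocusCounts(locus_id=f"L{i:03d}", S=int(s), D=int(d), L=float(l), n=int(m))
        for i, (s, d, l, m) in enumerate(zip(S, D, L, n))
    ]
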