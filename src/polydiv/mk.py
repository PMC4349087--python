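"""Single-locus MK tables and the multilocus Poisson-likelihood MK framework.

The McDonald-Kreitman test contrasts polymorphism and fixed differences at
synonymous and nonsynonymous sites. The multilocus framework models the four
count cells of each locus i as independent Poissons:

    E[Ps_i] = θ · L_syn_i            E[Pn_i] = θ · L_nonsyn_i · f_i
    E[Ds_i] = λ · L_syn_i            E[Dn_i] = λ · L_nonsyn_i · f_i / (1 − α_g(i))

with a single neutral diversity θ = 4Neµ and neutral divergence λ = µt
shared by all loci, a per-locus selective constraint f_i, and α the
proportion of nonsynonymous fixations driven by positive selection (negative
α reflects segregating deleterious variants inflating Pn). Three nested
models differ only in α: M0 fixes α = 0 everywhere, M1 shares one α across
loci, M2 estimates α separately for the immune and control groups. Model fit
is compared by likelihood-ratio tests and by AICc/Akaike weights.

Per-locus constraints are profiled analytically; the remaining parameters
(θ, λ, and the α's via β = 1 − α > 0 in log space) are optimised
numerically with seeded multi-start restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import FitError, UndefinedStatisticError
from .seqdata import LocusAlignment, SiteClassTable, classify_sites
from .codons import is_synonymous_change

MODELS = ("M0", "M1", "M2")


@dataclass
class MKCountTable:
    """Per-locus (Ps, Pn, Ds, Dn) with site opportunities."""

    locus_id: str
    Ps: int
    Pn: int
    Ds: int
    Dn: int
    L_syn: float
    L_nonsyn: float
    group: str = "control"

    def __post_init__(self) -> None:
        for name in ("Ps", "Pn", "Ds", "Dn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.locus_id}: negative count {name}")
        if self.L_syn <= 0 or self.L_nonsyn <= 0:
            raise ValueError(f"{self.locus_id}: site opportunities must be positive")


def build_mk_table(aln: LocusAlignment, table: SiteClassTable | None = None) -> MKCountTable:
    """MK count table from a locus alignment.

    A coding column segregating in the ingroup contributes each observed
    non-consensus state as one polymorphism (synonymous or nonsynonymous in
    the consensus-codon context); a column monomorphic in the ingroup but
    differing from the outgroup contributes one fixed difference, classified
    by substituting the outgroup base into the ingroup codon. A site that is
    both polymorphic and divergent counts as polymorphism only.
    """
    table = table or classify_sites(aln)
    matrix = aln.ingroup_matrix()
    Ps = Pn = Ds = Dn = 0
    for cols3, codon in zip(table.codon_columns, table.consensus_codons):
        for pos, col in enumerate(cols3):
            states = np.unique(matrix[:, col])
            bases = [b for b, c in zip("ACGT", range(4)) if c in states]
            ref = codon[pos]
            alts = [b for b in bases if b != ref]
            if len(bases) > 1:
                for alt in alts:
                    if is_synonymous_change(codon, pos, alt):
                        Ps += 1
                    else:
                        Pn += 1
            else:
                out_base = aln.outgroup_seq[col]
                if out_base in "ACGT" and out_base != bases[0]:
                    # monomorphic ingroup differing from outgroup: fixed difference
                    ctx = codon[:pos] + bases[0] + codon[pos + 1 :]
                    if is_synonymous_change(ctx, pos, out_base):
                        Ds += 1
                    else:
                        Dn += 1
    return MKCountTable(
        locus_id=aln.locus_id,
        Ps=Ps,
        Pn=Pn,
        Ds=Ds,
        Dn=Dn,
        L_syn=table.syn_sites,
        L_nonsyn=table.nonsyn_sites,
        group=aln.group_label,
    )


def alpha_point_estimate(t: MKCountTable) -> float:
    """Point estimate α = 1 − (Ds·Pn)/(Dn·Ps); undefined when Ps or Dn is zero."""
    if t.Ps == 0 or t.Dn == 0:
        raise UndefinedStatisticError(f"{t.locus_id}: alpha undefined (Ps or Dn is zero)")
    return 1.0 - (t.Ds * t.Pn) / (t.Dn * t.Ps)


@dataclass
class MKModelFit:
    """Maximum-likelihood fit of one multilocus MK model."""

    model_id: str
    theta: float
    lam: float
    alpha: dict[str, float]  # group -> α (constrained values included)
    constraint: dict[str, float]  # locus -> f_i
    logL: float
    n_params: int
    n_obs: int
    aicc: float
    converged: bool
    n_restarts: int
    akaike_weight: float | None = None


def _poisson_loglik(x: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(x * np.log(mu) - mu - gammaln(x + 1.0)))


def _group_alpha(model_id: str, groups: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Per-locus α vector from free parameters (β = 1 − α in log space)."""
    if model_id == "M0":
        return np.zeros(len(groups))
    if model_id == "M1":
        return np.full(len(groups), 1.0 - math.exp(params[0]))
    a_control = 1.0 - math.exp(params[0])
    a_immune = 1.0 - math.exp(params[1])
    return np.where(groups == "immune", a_immune, a_control)


def _neg_loglik(x: np.ndarray, model_id: str, data: dict) -> float:
    theta = math.exp(x[0])
    lam = math.exp(x[1])
    alpha = _group_alpha(model_id, data["groups"], x[2:])
    beta = 1.0 - alpha
    La, Ls = data["La"], data["Ls"]
    # profile f_i analytically: f̂ = (Pn+Dn) / (La·(θ + λ/β))
    rate = La * (theta + lam / beta)
    f = np.where(data["PnDn"] > 0, data["PnDn"] / np.maximum(rate, 1e-300), 0.0)
    ll = _poisson_loglik(data["Ps"], theta * Ls)
    ll += _poisson_loglik(data["Ds"], lam * Ls)
    ll += _poisson_loglik(data["Pn"], theta * La * f)
    ll += _poisson_loglik(data["Dn"], lam * La * f / beta)
    return -ll


def fit_multilocus_mk(
    tables: list[MKCountTable],
    model_id: str = "M1",
    n_restarts: int = 5,
    seed: int = 0,
) -> MKModelFit:
    """Fit one of the nested multilocus MK models (M0, M1 or M2) by ML.

    Per-locus constraints f_i are profiled in closed form; (θ, λ) and the α
    parameters are optimised by Nelder-Mead from ``n_restarts`` seeded
    starting points around moment estimates.
    """
    if model_id not in MODELS:
        raise ValueError(f"model_id must be one of {MODELS}")
    if len(tables) < 2:
        raise ValueError("multilocus MK requires at least 2 loci")
    groups = np.asarray([t.group for t in tables])
    if model_id == "M2" and len(set(groups)) < 2:
        raise ValueError("M2 requires both immune and control loci")
    data = {
        "Ps": np.asarray([t.Ps for t in tables], dtype=float),
        "Pn": np.asarray([t.Pn for t in tables], dtype=float),
        "Ds": np.asarray([t.Ds for t in tables], dtype=float),
        "Dn": np.asarray([t.Dn for t in tables], dtype=float),
        "Ls": np.asarray([t.L_syn for t in tables], dtype=float),
        "La": np.asarray([t.L_nonsyn for t in tables], dtype=float),
        "groups": groups,
    }
    data["PnDn"] = data["Pn"] + data["Dn"]
    theta0 = max(data["Ps"].sum() / data["Ls"].sum(), 1e-6)
    lam0 = max(data["Ds"].sum() / data["Ls"].sum(), 1e-6)
    n_alpha = {"M0": 0, "M1": 1, "M2": 2}[model_id]
    x0 = np.array([math.log(theta0), math.log(lam0)] + [0.0] * n_alpha)

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(n_restarts, 1)):
        start = x0 if k == 0 else x0 + rng.normal(0, 0.5, size=len(x0))
        res = optimize.minimize(
            _neg_loglik,
            start,
            args=(model_id, data),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"multilocus MK fit failed for {model_id}")

    theta = math.exp(best.x[0])
    lam = math.exp(best.x[1])
    alpha_vec = _group_alpha(model_id, groups, best.x[2:])
    beta = 1.0 - alpha_vec
    rate = data["La"] * (theta + lam / beta)
    f = np.where(data["PnDn"] > 0, data["PnDn"] / np.maximum(rate, 1e-300), 0.0)
    alpha_by_group: dict[str, float] = {}
    for g in sorted(set(groups)):
        alpha_by_group[g] = float(alpha_vec[groups == g][0])
    n_params = len(tables) + 2 + n_alpha
    n_obs = 4 * len(tables)
    logL = -float(best.fun)
    return MKModelFit(
        model_id=model_id,
        theta=theta,
        lam=lam,
        alpha=alpha_by_group,
        constraint={t.locus_id: float(fi) for t, fi in zip(tables, f)},
        logL=logL,
        n_params=n_params,
        n_obs=n_obs,
        aicc=aicc(logL, n_params, n_obs),
        converged=bool(best.success),
        n_restarts=max(n_restarts, 1),
    )


def likelihood_ratio(fit_null: "MKModelFit", fit_alt: "MKModelFit | float", df: int | None = None):
    """LRT statistic 2·(logL_alt − logL_null), clipped at 0, with χ² p-value.

    Accepts either two model fits (df from their parameter counts) or two
    log-likelihoods with an explicit ``df``. Returns ``(stat, df, p)``.
    """
    if isinstance(fit_null, MKModelFit) and isinstance(fit_alt, MKModelFit):
        ll0, ll1 = fit_null.logL, fit_alt.logL
        df = fit_alt.n_params - fit_null.n_params
    else:
        ll0, ll1 = float(fit_null), float(fit_alt)  # type: ignore[arg-type]
        if df is None:
            raise ValueError("df required when passing raw log-likelihoods")
    if df < 1:
        raise ValueError("models are not nested with df >= 1")
    stat = max(2.0 * (ll1 - ll0), 0.0)
    return stat, df, chi_square_upper_tail(stat, df)


def chi_square_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of the χ² distribution."""
    if x < 0 or df < 1:
        raise ValueError("require x >= 0 and df >= 1")
    return float(stats.chi2.sf(x, df))


def aicc(logL: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n_obs <= n_params + 1:
        raise ValueError("AICc requires n_obs > n_params + 1")
    p = n_params
    return -2.0 * logL + 2.0 * p + 2.0 * p * (p + 1) / (n_obs - p - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized relative model support from AICc values (sums to 1)."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def sample_mk_counts(
    theta: float,
    lam: float,
    f,
    alpha_by_group: dict[str, float],
    L_syn,
    L_nonsyn,
    groups,
    rng: np.random.Generator | None = None,
) -> list[MKCountTable]:
    """Draw count tables directly from the multilocus MK Poisson model
    (used for calibration and power studies)."""
    rng = rng or np.random.default_rng()
    f = np.asarray(f, dtype=float)
    L_syn = np.asarray(L_syn, dtype=float)
    L_nonsyn = np.asarray(L_nonsyn, dtype=float)
    groups = list(groups)
    alpha = np.asarray([alpha_by_group[g] for g in groups])
    Ps = rng.poisson(theta * L_syn)
    Pn = rng.poisson(theta * L_nonsyn * f)
    Ds = rng.poisson(lam * L_syn)
    Dn = rng.poisson(lam * L_nonsyn * f / (1.0 - alpha))
    return [
        MKCountTable(
            locus_id=f"L{i:03d}", Ps=int(ps), Pn=int(pn), Ds=int(ds), Dn=int(dn),
            L_syn=float(ls), L_nonsyn=float(la), group=g,
        )
        for i, (ps, pn, ds, dn, ls, la, g) in enumerate(
            zip(Ps, Pn, Ds, Dn, L_syn, L_nonsyn, groups)
        )
    ]


def compare_mk_models(
    tables: list[MKCountTable], n_restarts: int = 5, seed: int = 0
) -> tuple[dict[str, MKModelFit], pd.DataFrame]:
    """Fit M0/M1/M2 and build the model-comparison report table.

    Rows mirror the standard layout: parameter count, log(L), 2Δlog(L)
    against the previous nested model, χ² P, AICc, Akaike weight, and the
    per-group α estimates (constrained values in square brackets in the
    formatted report).
    """
    models = list(MODELS)
    groups = {t.group for t in tables}
    if len(groups) < 2:
        models = ["M0", "M1"]
    fits = {m: fit_multilocus_mk(tables, m, n_restarts=n_restarts, seed=seed) for m in models}
    weights = akaike_weights([fits[m].aicc for m in models])
    for m, w in zip(models, weights):
        fits[m].akaike_weight = float(w)
    rows = []
    prev = None
    for m in models:
        fit = fits[m]
        stat = p = None
        if prev is not None:
            stat, _, p = likelihood_ratio(fits[prev], fit)
        a_ctrl = fit.alpha.get("control", 0.0)
        a_imm = fit.alpha.get("immune", a_ctrl)
        rows.append(
            {
                "model": m,
                "n_params": fit.n_params,
                "logL": fit.logL,
                "lrt_stat": stat,
                "chi2_p": p,
                "AICc": fit.aicc,
                "akaike_weight": fit.akaike_weight,
                "alpha_control": a_ctrl,
                "alpha_immune": a_imm,
            }
        )
        prev = m
    return fits, pd.DataFrame(rows)
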