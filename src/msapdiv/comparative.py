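"""Restricted-vs-widespread comparison of the diversity table.

Each diversity index is modelled with ``Markers`` (AFLP, U-MSAP, M-MSAP),
``Distribution`` (restricted, widespread) and their interaction as fixed
effects, and random intercepts for species and for population nested within
species, the populations being the paired observational units.  Proportions
(PPOL, PPRIV) are binomial responses on the logit scale with
``successes = round(index * n_loci)`` out of ``n_loci`` trials; SI and RI
are Gaussian with case weights proportional to ``n_loci`` (normalized to
mean 1).

Inference:

* fixed terms are tested with likelihood-ratio tests between nested
  maximum-likelihood fits -- the interaction by full vs no-interaction,
  each main effect by dropping it from the no-interaction model;
* estimated marginal means per Markers x Distribution cell (REML for the
  Gaussian family) with back-transformation from the logit scale for the
  binomial family;
* within each distribution class, the three pairwise marker contrasts with
  a Tukey-style family-wise adjustment computed from the joint distribution
  of the contrast statistics;
* group-wise Pearson correlations between the genetic (AFLP) and each
  epigenetic (U-MSAP, M-MSAP) version of an index over population values,
  with two-sided p from the exact t transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .mixed_models import MixedFit, fit_binomial_mixed, fit_linear_mixed

__all__ = [
    "ModelResult",
    "CorrelationResult",
    "INDEX_FAMILIES",
    "fit_index_model",
    "emm_pairwise",
    "correlate_groups",
    "pearson_p_from_r",
]

MARKER_LEVELS = ("AFLP", "U_MSAP", "M_MSAP")
DIST_LEVELS = ("restricted", "widespread")

#: model family per index: proportions are binomial, means are Gaussian
INDEX_FAMILIES = {
    "PPOL": "binomial_mixed",
    "PPRIV": "binomial_mixed",
    "SI": "linear_mixed",
    "RI": "linear_mixed",
}


@dataclass
class ModelResult:
    index_name: str
    model_family: str
    lrt: list[dict]  # term, chi_square, df, p
    emms: list[dict]  # markers, distribution, estimate, ci_low, ci_high
    contrasts: list[dict]  # pair, distribution, estimate, statistic, p_adjusted
    converged: bool
    messages: list[str] = field(default_factory=list)
    # internal state reused by emm_pairwise
    _fit: MixedFit | None = None

    def to_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "model_family": self.model_family,
            "lrt": self.lrt,
            "emms": self.emms,
            "contrasts": self.contrasts,
            "converged": self.converged,
            "messages": self.messages,
        }


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _design_row(marker: str, dist: str, terms: tuple[str, ...]) -> np.ndarray:
    mu = 1.0 if marker == "U_MSAP" else 0.0
    mm = 1.0 if marker == "M_MSAP" else 0.0
    dw = 1.0 if dist == "widespread" else 0.0
    cols = {
        "intercept": 1.0,
        "markers_u": mu,
        "markers_m": mm,
        "dist_w": dw,
        "int_u": mu * dw,
        "int_m": mm * dw,
    }
    return np.array([cols[t] for t in terms])


_TERMSETS = {
    "full": ("intercept", "markers_u", "markers_m", "dist_w", "int_u", "int_m"),
    "no_interaction": ("intercept", "markers_u", "markers_m", "dist_w"),
    "markers_only": ("intercept", "markers_u", "markers_m"),
    "distribution_only": ("intercept", "dist_w"),
}


def _build_X(table: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    return np.vstack(
        [
            _design_row(r.marker_type, r.distribution, terms)
            for r in table.itertuples(index=False)
        ]
    )


def _embed(beta: np.ndarray, src: tuple[str, ...], dst: tuple[str, ...]) -> np.ndarray:
    out = np.zeros(len(dst))
    for i, t in enumerate(src):
        if t in dst:
            out[dst.index(t)] = beta[i]
    return out


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    need = {"species", "population", "distribution", "marker_type", "n_loci"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"diversity table missing columns: {sorted(missing)}")
    counts = table.groupby(["species", "population"])["marker_type"].nunique()
    if (counts != 3).any():
        bad = counts[counts != 3].index.tolist()
        raise ValueError(f"populations without complete 3-marker records: {bad}")
    per_dist = table.groupby("distribution")["species"].nunique()
    for d in DIST_LEVELS:
        if per_dist.get(d, 0) < 2:
            raise ValueError(f"need >= 2 species in distribution class '{d}'")
    return table


def _pop_key(table: pd.DataFrame) -> np.ndarray:
    return (table["species"] + "/" + table["population"]).to_numpy()


def fit_index_model(
    table: pd.DataFrame, index_name: str, emms: bool = True
) -> ModelResult:
    """Fit the mixed model for one index and run the full inference chain.

    ``emms=False`` skips marginal means and contrasts (useful when only the
    likelihood-ratio tests are needed, e.g. in simulation studies).
    """
    family = INDEX_FAMILIES.get(index_name)
    if family is None:
        raise ValueError(
            f"unknown index '{index_name}' (expected one of {sorted(INDEX_FAMILIES)})"
        )
    table = _check_table(table)
    y = table[index_name].to_numpy(dtype=float)
    species = table["species"].to_numpy()
    pops = _pop_key(table)
    n_loci = table["n_loci"].to_numpy(dtype=float)
    messages: list[str] = []

    if family == "binomial_mixed":
        if np.any((y < 0) | (y > 1)):
            raise ValueError(f"{index_name} values outside [0, 1]: not a proportion")
        successes = np.round(y * n_loci)
        fits: dict[str, MixedFit] = {}
        order = ["distribution_only", "markers_only", "no_interaction", "full"]
        prev: tuple[tuple[str, ...], MixedFit] | None = None
        for name in order:
            terms = _TERMSETS[name]
            X = _build_X(table, terms)
            start_theta = None
            if prev is not None:
                src_terms, src_fit = prev
                b = _embed(src_fit.beta, src_terms, terms)
                start_theta = np.concatenate(
                    [
                        b,
                        [
                            np.log(max(src_fit.sigma_species, 1e-4)),
                            np.log(max(src_fit.sigma_population, 1e-4)),
                        ],
                    ]
                )
            fits[name] = fit_binomial_mixed(
                successes, n_loci, X, species, pops, start_theta=start_theta
            )
            prev = (terms, fits[name])
        final = fits["full"]
    else:
        if index_name == "SI" and np.any((y < 0) | (y > np.log(2) + 1e-9)):
            raise ValueError("SI values outside [0, ln 2]")
        fits = {}
        for name in ("full", "no_interaction", "markers_only", "distribution_only"):
            X = _build_X(table, _TERMSETS[name])
            fits[name] = fit_linear_mixed(
                y, X, species, pops, weights=n_loci, reml=False
            )
        if emms:
            # REML refit of the full model for marginal means and intervals
            final = fit_linear_mixed(
                y, _build_X(table, _TERMSETS["full"]), species, pops,
                weights=n_loci, reml=True,
            )
        else:
            final = fits["full"]

    def lrt_row(term: str, big: str, small: str, df: int) -> dict:
        chi2 = max(0.0, 2.0 * (fits[big].loglik - fits[small].loglik))
        return {
            "term": term,
            "chi_square": chi2,
            "df": df,
            "p": float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0,
        }

    lrt = [
        lrt_row("Markers", "no_interaction", "distribution_only", 2),
        lrt_row("Distribution", "no_interaction", "markers_only", 1),
        lrt_row("Markers:Distribution", "full", "no_interaction", 2),
    ]
    converged = all(f.converged for f in fits.values()) and final.converged
    for f in list(fits.values()) + [final]:
        messages.extend(f.messages)

    result = ModelResult(
        index_name=index_name,
        model_family=family,
        lrt=lrt,
        emms=[],
        contrasts=[],
        converged=converged,
        messages=messages,
        _fit=final,
    )
    if emms:
        result.emms = _estimate_emms(result)
        result.contrasts = emm_pairwise(result)
    return result


# ---------------------------------------------------------------------------
# marginal means and Tukey-adjusted contrasts
# ---------------------------------------------------------------------------


def _cells() -> list[tuple[str, str]]:
    return [(m, d) for d in DIST_LEVELS for m in MARKER_LEVELS]


def _estimate_emms(model: ModelResult) -> list[dict]:
    fit = model._fit
    terms = _TERMSETS["full"]
    binom = model.model_family == "binomial_mixed"
    if binom:
        crit = stats.norm.ppf(0.975)
    else:
        df = max(fit.n_obs - len(terms), 1)
        crit = stats.t.ppf(0.975, df)
    out = []
    for marker, dist in _cells():
        x = _design_row(marker, dist, terms)
        eta = float(x @ fit.beta)
        se = float(np.sqrt(max(x @ fit.vcov_beta @ x, 0.0)))
        lo, hi = eta - crit * se, eta + crit * se
        if binom:
            eta, lo, hi = (float(special.expit(v)) for v in (eta, lo, hi))
        out.append(
            {
                "markers": marker,
                "distribution": dist,
                "estimate": eta,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return out


def _max_abs_tail(t_obs: float, R: np.ndarray, df: float | None, rng: np.random.Generator) -> float:
    """P(max_j |T_j| >= t_obs) for a joint normal/t vector with correlation R."""
    ndraw = 200_000
    L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
    Zs = rng.standard_normal((ndraw, R.shape[0])) @ L.T
    if df is not None:
        scale = np.sqrt(rng.chisquare(df, size=ndraw) / df)
        Zs = Zs / scale[:, None]
    return float((np.abs(Zs).max(axis=1) >= abs(t_obs)).mean())


def emm_pairwise(model: ModelResult) -> list[dict]:
    """Within-distribution pairwise marker contrasts, Tukey-adjusted.

    The adjustment family is the three marker contrasts inside one
    distribution level; adjusted p values come from the joint distribution
    of the contrast statistics (multivariate normal for the binomial
    family, multivariate t for the Gaussian one), evaluated by a fixed-seed
    quasi Monte-Carlo draw.  Adjusted p is floored at the unadjusted p.
    """
    fit = model._fit
    if fit is None:
        raise ValueError("model carries no fit (was it constructed by fit_index_model?)")
    terms = _TERMSETS["full"]
    binom = model.model_family == "binomial_mixed"
    df = None if binom else max(fit.n_obs - len(terms), 1)
    rng = np.random.default_rng(20231207)
    out = []
    pairs = [("AFLP", "U_MSAP"), ("AFLP", "M_MSAP"), ("U_MSAP", "M_MSAP")]
    for dist in DIST_LEVELS:
        C = []
        for a, b in pairs:
            xa = _design_row(a, dist, terms)
            xb = _design_row(b, dist, terms)
            C.append(xa - xb)
        C = np.vstack(C)
        cov = C @ fit.vcov_beta @ C.T
        se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        est = C @ fit.beta
        tstat = est / se
        R = cov / np.outer(se, se)
        for i, (a, b) in enumerate(pairs):
            if binom:
                p_un = 2.0 * stats.norm.sf(abs(tstat[i]))
            else:
                p_un = 2.0 * stats.t.sf(abs(tstat[i]), df)
            p_adj = max(_max_abs_tail(tstat[i], R, df, rng), p_un)
            out.append(
                {
                    "pair": f"{a} - {b}",
                    "distribution": dist,
                    "estimate": float(est[i]),
                    "statistic": float(tstat[i]),
                    "statistic_kind": "z" if binom else "t",
                    "p_unadjusted": float(min(p_un, 1.0)),
                    "p_adjusted": float(min(p_adj, 1.0)),
                }
            )
    return out


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    group: str
    index_name: str
    marker_pair: tuple[str, str]
    r: float
    n: int
    t_stat: float
    p: float
    flagged: str | None = None


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the exact t transform.

    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on ``n - 2`` degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_groups(table: pd.DataFrame) -> list[CorrelationResult]:
    """Pearson correlations between genetic and epigenetic index values.

    For each distribution class, index and epigenetic marker set, population
    values of the AFLP index are correlated with the same populations'
    U-MSAP or M-MSAP values.
    """
    _check_table(table)
    out = []
    for group in DIST_LEVELS:
        sub = table[table["distribution"] == group]
        for index_name in INDEX_FAMILIES:
            wide = sub.pivot_table(
                index=["species", "population"],
                columns="marker_type",
                values=index_name,
            )
            for epi in ("U_MSAP", "M_MSAP"):
                x = wide["AFLP"].to_numpy(dtype=float)
                y = wide[epi].to_numpy(dtype=float)
                n = len(x)
                if n < 3:
                    raise ValueError(
                        f"group '{group}' has only {n} populations (need >= 3)"
                    )
                if np.std(x) == 0.0 or np.std(y) == 0.0:
                    out.append(
                        CorrelationResult(
                            group, index_name, ("AFLP", epi),
                            r=float("nan"), n=n, t_stat=float("nan"),
                            p=float("nan"), flagged="zero variance",
                        )
                    )
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                p = pearson_p_from_r(r, n)
                t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, 1e-300))
                out.append(
                    CorrelationResult(group, index_name, ("AFLP", epi), r, n, float(t), p)
                )
    return out
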