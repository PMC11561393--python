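"""Marginal maximum likelihood item calibration via EM (Bock–Aitkin).

Ability is integrated out over a rectangular quadrature grid.  Each EM
cycle computes, per person, the posterior over the grid nodes given the
current item parameters (E-step), accumulates expected per-node response
counts per item, and re-maximizes each item's expected complete-data
log-likelihood — optionally penalized by parameter priors — over its free
parameters (M-step).  1PLM items share a single discrimination that is
maximized jointly with all their difficulties in one block.  Convergence is
declared when the maximum absolute change over all free item parameters
drops below ``Etol``.

Standard errors come from the empirical (cross-product) information matrix
of per-person marginal score vectors, restricted to the free parameters.
The reported log-likelihood, −2LL, AIC and BIC always exclude prior density
terms, so AIC = −2LL + 2p and BIC = −2LL + p·ln(N) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .latent import LatentDist, make_quadrature, update_empirical_histogram
from .metadata import build_item_meta, param_arrays, validate_item_meta
from .models import P_FLOOR, three_pl_prob

__all__ = [
    "PriorSpec",
    "EMControl",
    "CalibrationResult",
    "e_step",
    "m_step_item",
    "estimate_mmle_em",
    "standard_errors",
    "fit_indices",
    "extract",
]

# M-step box constraints; wide enough to be inert for well-behaved items,
# tight enough to keep the 3PLM stable on degenerate expected counts.
A_BOUNDS = (0.01, 10.0)
B_BOUNDS = (-10.0, 10.0)
G_BOUNDS = (1e-4, 0.5)


@dataclass(frozen=True)
class PriorSpec:
    """Prior on one item-parameter class.

    ``beta(alpha, beta)`` is allowed only on g (support [0, 1]);
    ``lognormal(meanlog, sdlog)`` on a; ``normal(mean, sd)`` on b or a.
    """

    dist: str
    params: tuple[float, float]
    target: str  # 'a' | 'b' | 'g'

    def __post_init__(self):
        if self.dist not in ("beta", "lognormal", "normal"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if self.target not in ("a", "b", "g"):
            raise ValueError(f"prior target must be a, b, or g; got {self.target!r}")
        if self.dist == "beta" and self.target != "g":
            raise ValueError("beta priors are only supported on g")
        if self.dist in ("beta", "lognormal") and not all(p > 0 for p in self.params):
            raise ValueError(f"{self.dist} prior parameters must be positive")

    def logpdf(self, x: float) -> float:
        p1, p2 = self.params
        if self.dist == "beta":
            return (p1 - 1.0) * np.log(x) + (p2 - 1.0) * np.log1p(-x)
        if self.dist == "lognormal":
            lx = np.log(x)
            return -lx - 0.5 * ((lx - p1) / p2) ** 2
        return -0.5 * ((x - p1) / p2) ** 2

    def dlogpdf(self, x: float) -> float:
        p1, p2 = self.params
        if self.dist == "beta":
            return (p1 - 1.0) / x - (p2 - 1.0) / (1.0 - x)
        if self.dist == "lognormal":
            return -(1.0 + (np.log(x) - p1) / p2**2) / x
        return -(x - p1) / p2**2

    def mode(self) -> float:
        p1, p2 = self.params
        if self.dist == "beta":
            if p1 + p2 > 2:
                return (p1 - 1.0) / (p1 + p2 - 2.0)
            return 0.2
        if self.dist == "lognormal":
            return float(np.exp(p1 - p2**2))
        return p1


@dataclass(frozen=True)
class EMControl:
    """Estimation controls (defaults: Etol 1e-4, MaxE 500, 49-point grid on [−6, 6])."""

    D: float = 1.0
    Etol: float = 1e-4
    MaxE: int = 500
    quad_points: int = 49
    quad_bound: float = 6.0
    emp_hist: bool = False
    fix_a_1pl: bool = False
    a_val_1pl: float = 1.0
    fix_g: bool = False
    g_val: float = 0.2
    missing_code: str = "NA"

    def __post_init__(self):
        if self.Etol <= 0:
            raise ValueError("Etol must be positive")
        if self.MaxE < 1:
            raise ValueError("MaxE must be at least 1")


@dataclass
class EStepResult:
    expected_correct: np.ndarray  # items x nodes
    expected_n: np.ndarray  # items x nodes
    loglik: float
    posterior: np.ndarray  # persons x nodes


@dataclass
class CalibrationResult:
    est_meta: pd.DataFrame
    se_meta: pd.DataFrame
    varcov: pd.DataFrame
    loglik: float
    neg2ll: float
    aic: float
    bic: float
    n_free_params: int
    group: pd.DataFrame  # rows: estimates, se; cols: mu, sigma2, sigma
    em_cycles: int
    max_change: float
    first_order_ok: bool
    second_order_ok: bool
    latent: LatentDist
    loglik_history: list = field(default_factory=list)
    D: float = 1.0
    n_persons: int = 0
    n_items: int = 0
    n_fixed_items: int = 0
    flagged_items: list = field(default_factory=list)
    control: EMControl | None = None

    def summary(self) -> str:
        from .report import calibration_summary

        return calibration_summary(self)


# ---------------------------------------------------------------------------
# data validation


def validate_response_matrix(data, n_items: int | None = None) -> np.ndarray:
    """Coerce responses to an N×J float array of {0, 1, NaN}."""
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy()
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("response data must be a 2-D persons × items matrix")
    finite = arr[np.isfinite(arr)]
    if not np.isin(finite, (0.0, 1.0)).all():
        bad = np.unique(finite[~np.isin(finite, (0.0, 1.0))])
        raise ValueError(f"responses must be 0/1/missing; found {bad.tolist()}")
    if n_items is not None and arr.shape[1] != n_items:
        raise ValueError(
            f"data has {arr.shape[1]} columns but metadata describes {n_items} items"
        )
    return arr


# ---------------------------------------------------------------------------
# E-step


def e_step(data, meta: pd.DataFrame, dist: LatentDist, D: float = 1.0) -> EStepResult:
    """Posterior expectations over the quadrature grid.

    Missing responses are skipped person-wise; a person with no observed
    responses keeps the prior weights as posterior.  ``loglik`` is the
    marginal log-likelihood Σ_i log Σ_k w_k L_ik (prior-free).
    """
    X = validate_response_matrix(data, n_items=len(meta))
    a, b, g = param_arrays(meta)
    nodes = dist.nodes
    P = three_pl_prob(nodes[None, :], a[:, None], b[:, None], g[:, None], D)
    P = np.clip(P, P_FLOOR, 1.0 - P_FLOOR)
    logP, logQ = np.log(P), np.log1p(-P)
    M = np.isfinite(X)
    X1 = np.where(M, X, 0.0)
    X0 = np.where(M, 1.0 - X, 0.0)
    ll_ik = X1 @ logP + X0 @ logQ  # persons x nodes
    lw = ll_ik + np.log(np.clip(dist.weights, 1e-300, None))[None, :]
    lse = logsumexp(lw, axis=1)
    post = np.exp(lw - lse[:, None])
    expected_n = M.T.astype(float) @ post
    expected_correct = X1.T @ post
    return EStepResult(expected_correct, expected_n, float(lse.sum()), post)


# ---------------------------------------------------------------------------
# M-step

_PRIOR_TARGETS = {"a": 0, "b": 1, "g": 2}


def _prior_map(priors) -> dict[str, PriorSpec]:
    if priors is None:
        return {}
    if isinstance(priors, PriorSpec):
        priors = [priors]
    if isinstance(priors, dict):
        priors = list(priors.values())
    out = {}
    for p in priors:
        out[p.target] = p
    return out


def _item_neg_objective(params, r, n, nodes, D, model, priors, fix_g, g_val):
    """Negative expected complete-data log-likelihood (+ priors) and gradient."""
    if model == "3PLM":
        if fix_g:
            a, b = params
            g = g_val
        else:
            a, b, g = params
    else:
        a, b = params
        g = 0.0
    z = D * a * (nodes - b)
    L = 1.0 / (1.0 + np.exp(-z))
    P = np.clip(g + (1.0 - g) * L, P_FLOOR, 1.0 - P_FLOOR)
    Q = 1.0 - P
    f = float(r @ np.log(P) + (n - r) @ np.log(Q))
    w = r / P - (n - r) / Q
    dLdz = L * (1.0 - L)
    da = float(w @ ((1.0 - g) * dLdz * D * (nodes - b)))
    db = float(w @ (-(1.0 - g) * dLdz * D * a))
    grad = [da, db]
    if model == "3PLM" and not fix_g:
        grad.append(float(w @ (1.0 - L)))
    for tgt, idx in (("a", 0), ("b", 1), ("g", 2)):
        pr = priors.get(tgt)
        if pr is None:
            continue
        if tgt == "g" and (model != "3PLM" or fix_g):
            continue
        x = (a, b, g)[idx]
        f += pr.logpdf(x)
        grad[idx] += pr.dlogpdf(x)
    return -f, -np.asarray(grad)


def m_step_item(
    expected_correct_j,
    expected_n_j,
    nodes,
    model: str,
    priors=None,
    D: float = 1.0,
    start=None,
    fix_g: bool = False,
    g_val: float = 0.2,
):
    """Maximize one item's expected (penalized) log-likelihood.

    Returns ``(a, b, g, converged)``; g is NaN for 2PLM and the fixed value
    when ``fix_g``.  On optimizer failure a retry from a neutral start is
    attempted; a still-unconverged or boundary solution is flagged through
    ``converged=False`` and estimation continues.
    """
    model = "3PLM" if model == "DRM" else model
    priors = _prior_map(priors)
    r = np.asarray(expected_correct_j, dtype=float)
    n = np.asarray(expected_n_j, dtype=float)
    if (n < r - 1e-9).any():
        raise ValueError("expected_n must dominate expected_correct elementwise")
    if model == "3PLM" and not fix_g:
        bounds = [A_BOUNDS, B_BOUNDS, G_BOUNDS]
        g0 = priors["g"].mode() if "g" in priors else 0.2
        default = [1.0, 0.0, np.clip(g0, *G_BOUNDS)]
    else:
        bounds = [A_BOUNDS, B_BOUNDS]
        default = [1.0, 0.0]
    x0 = np.asarray(start, dtype=float) if start is not None else np.asarray(default)
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    args = (r, n, nodes, D, model, priors, fix_g, g_val)
    res = minimize(
        _item_neg_objective, x0, args=args, jac=True, method="L-BFGS-B",
        bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        res2 = minimize(
            _item_neg_objective, np.asarray(default), args=args, jac=True,
            method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if res2.fun < res.fun:
            res = res2
    x = res.x
    at_bound = any(
        np.isclose(x[i], bounds[i][0]) or np.isclose(x[i], bounds[i][1])
        for i in range(len(x))
    )
    converged = bool(res.success) and not at_bound
    if model == "3PLM":
        if fix_g:
            return float(x[0]), float(x[1]), float(g_val), converged
        return float(x[0]), float(x[1]), float(x[2]), converged
    return float(x[0]), float(x[1]), np.nan, converged


def _onepl_block_neg(params, fix_a, a_val, rs, ns, nodes, D, priors):
    """Joint objective for the shared-discrimination 1PLM block."""
    if fix_a:
        a = a_val
        bs = params
    else:
        a = params[0]
        bs = params[1:]
    f = 0.0
    ga = 0.0
    gb = np.zeros_like(bs)
    for j, (r, n, b) in enumerate(zip(rs, ns, bs)):
        z = D * a * (nodes - b)
        L = 1.0 / (1.0 + np.exp(-z))
        P = np.clip(L, P_FLOOR, 1.0 - P_FLOOR)
        f += float(r @ np.log(P) + (n - r) @ np.log1p(-P))
        w = r / P - (n - r) / (1.0 - P)
        dLdz = L * (1.0 - L)
        ga += float(w @ (dLdz * D * (nodes - b)))
        gb[j] = float(w @ (-dLdz * D * a))
    pr_a, pr_b = priors.get("a"), priors.get("b")
    if pr_a is not None and not fix_a:
        f += pr_a.logpdf(a)
        ga += pr_a.dlogpdf(a)
    if pr_b is not None:
        for j, b in enumerate(bs):
            f += pr_b.logpdf(b)
            gb[j] += pr_b.dlogpdf(b)
    if fix_a:
        return -f, -gb
    return -f, -np.concatenate([[ga], gb])


def _m_step_onepl_block(rs, ns, nodes, D, priors, fix_a, a_val, start_a, start_b):
    m = len(rs)
    if fix_a:
        x0 = np.asarray(start_b, dtype=float)
        bounds = [B_BOUNDS] * m
    else:
        x0 = np.concatenate([[start_a], start_b])
        bounds = [A_BOUNDS] + [B_BOUNDS] * m
    res = minimize(
        _onepl_block_neg, x0, args=(fix_a, a_val, rs, ns, nodes, D, priors),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-8},
    )
    if fix_a:
        return float(a_val), res.x.copy(), bool(res.success)
    return float(res.x[0]), res.x[1:].copy(), bool(res.success)


# ---------------------------------------------------------------------------
# free-parameter bookkeeping


def free_param_layout(meta: pd.DataFrame, control: EMControl, fixed_items=()):
    """Ordered list of free parameters as (kind, item_index) entries.

    ``kind`` is 'a1pl' (the shared 1PLM slope; item_index is the list of
    1PLM item positions), or 'a'/'b'/'g' for a single item.  ``fixed_items``
    (0-based) are excluded entirely (FIPC).
    """
    fixed = set(fixed_items)
    layout: list[tuple[str, object]] = []
    onepl = [
        j for j in range(len(meta))
        if meta["model"].iat[j] == "1PLM" and j not in fixed
    ]
    if onepl and not control.fix_a_1pl:
        layout.append(("a1pl", onepl))
    for j in range(len(meta)):
        if j in fixed:
            continue
        model = meta["model"].iat[j]
        model = "3PLM" if model == "DRM" else model
        if model == "1PLM":
            layout.append(("b", j))
        elif model == "2PLM":
            layout.append(("a", j))
            layout.append(("b", j))
        else:
            layout.append(("a", j))
            layout.append(("b", j))
            if not control.fix_g:
                layout.append(("g", j))
    return layout


def _layout_labels(layout, meta):
    labels = []
    for kind, idx in layout:
        if kind == "a1pl":
            labels.append("a(1PLM shared)")
        else:
            labels.append(f"{kind}({meta['id'].iat[idx]})")
    return labels


def _param_vector(meta, layout):
    a, b, g = param_arrays(meta)
    vals = []
    for kind, idx in layout:
        if kind == "a1pl":
            vals.append(a[idx[0]])
        elif kind == "a":
            vals.append(a[idx])
        elif kind == "b":
            vals.append(b[idx])
        else:
            vals.append(g[idx])
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# starting values


def _start_meta(data, models, item_ids, control: EMControl, priors) -> pd.DataFrame:
    X = validate_response_matrix(data)
    n_items = X.shape[1]
    models = list(models) if not isinstance(models, str) else [models] * n_items
    if len(models) == 1:
        models = models * n_items
    if len(models) != n_items:
        raise ValueError("models must broadcast to the number of items")
    pmap = _prior_map(priors)
    M = np.isfinite(X)
    with np.errstate(invalid="ignore"):
        p = np.where(M, X, 0.0).sum(axis=0) / M.sum(axis=0)
    if np.isnan(p).any():
        bad = [i + 1 for i in np.flatnonzero(np.isnan(p))]
        raise ValueError(f"item column(s) {bad} contain no observed responses")
    p = np.clip(p, 0.01, 0.99)
    D = control.D
    a0 = np.ones(n_items)
    b0 = -np.log(p / (1.0 - p)) / (D * 1.0)  # PROX-style start from p-values
    g0 = np.full(n_items, np.nan)
    for j, m in enumerate(models):
        if m in ("3PLM", "DRM"):
            if control.fix_g:
                g0[j] = control.g_val
            elif "g" in pmap:
                g0[j] = np.clip(pmap["g"].mode(), *G_BOUNDS)
            else:
                g0[j] = 0.2
    if control.fix_a_1pl:
        for j, m in enumerate(models):
            if m == "1PLM":
                a0[j] = control.a_val_1pl
    return build_item_meta(a0, np.clip(b0, -4, 4), g0, item_ids, 2, models)


# ---------------------------------------------------------------------------
# EM driver

# Estimates outside this region signal the 3PLM's "all-guessing" degeneracy
# (a spurious local EM optimum for very hard items) rather than a credible
# item: operational pools keep |b| well inside the quadrature range.
_PLAUSIBLE_A = 3.0
_PLAUSIBLE_B = 3.0
_RESCUE_STARTS_A = (0.7, 1.2, 2.0)
_RESCUE_STARTS_B = (-1.9, -1.0, 0.0, 1.0, 1.9)


def _rescue_degenerate(X, meta, dist, control: EMControl, priors, candidates):
    """Multi-start M-step refit of items stuck at implausible estimates.

    For each candidate 3PLM/DRM item with a > 3 or |b| > 3, re-fit the
    item's M-step objective against the current posterior from a grid of
    dispersed starts and keep the best.  Returns (meta, changed_items).
    """
    pmap = _prior_map(priors)
    a, b, g = param_arrays(meta)
    suspects = [
        j for j in candidates
        if meta["model"].iat[j] in ("3PLM", "DRM")
        and (a[j] > _PLAUSIBLE_A or abs(b[j]) > _PLAUSIBLE_B)
    ]
    if not suspects:
        return meta, []
    es = e_step(X, meta, dist, control.D)
    new = meta.copy()
    changed = []
    for j in suspects:
        best_f, best_par = np.inf, None
        g0 = control.g_val if control.fix_g else (
            pmap["g"].mode() if "g" in pmap else 0.2
        )
        for a0 in _RESCUE_STARTS_A:
            for b0 in _RESCUE_STARTS_B:
                start = [a0, b0] if control.fix_g else [a0, b0, g0]
                aj, bj, gj, _ = m_step_item(
                    es.expected_correct[j], es.expected_n[j], dist.nodes, "3PLM",
                    priors=pmap, D=control.D, start=start,
                    fix_g=control.fix_g, g_val=control.g_val,
                )
                par = np.array([aj, bj] if control.fix_g else [aj, bj, gj])
                f, _ = _item_neg_objective(
                    par, es.expected_correct[j], es.expected_n[j], dist.nodes,
                    control.D, "3PLM", pmap, control.fix_g, control.g_val,
                )
                if f < best_f:
                    best_f, best_par = f, (aj, bj, gj)
        if best_par is not None and not np.allclose(
            best_par, (a[j], b[j], g[j]), atol=1e-6
        ):
            new.loc[j, ["par.1", "par.2", "par.3"]] = best_par
            changed.append(j)
    return new, changed


def _run_m_step(meta, es: EStepResult, nodes, control: EMControl, priors, skip=()):
    """One full M-step over all non-fixed items; returns (new_meta, flags)."""
    pmap = _prior_map(priors)
    skip = set(skip)
    a, b, g = param_arrays(meta)
    new = meta.copy()
    flags = []
    onepl = [
        j for j in range(len(meta))
        if meta["model"].iat[j] == "1PLM" and j not in skip
    ]
    if onepl:
        a_sh, bs, ok = _m_step_onepl_block(
            [es.expected_correct[j] for j in onepl],
            [es.expected_n[j] for j in onepl],
            nodes, control.D, pmap,
            control.fix_a_1pl, control.a_val_1pl,
            a[onepl[0]], b[onepl],
        )
        if not ok:
            flags.append("1PLM block")
        for j, bj in zip(onepl, bs):
            new.loc[j, "par.1"] = a_sh
            new.loc[j, "par.2"] = bj
    for j in range(len(meta)):
        model = meta["model"].iat[j]
        if model == "1PLM" or j in skip:
            continue
        model_eff = "3PLM" if model == "DRM" else model
        start = [a[j], b[j]] if model_eff == "2PLM" or control.fix_g else [a[j], b[j], g[j]]
        aj, bj, gj, ok = m_step_item(
            es.expected_correct[j], es.expected_n[j], nodes, model_eff,
            priors=pmap, D=control.D, start=start,
            fix_g=control.fix_g, g_val=control.g_val,
        )
        if not ok:
            flags.append(meta["id"].iat[j])
        new.loc[j, "par.1"] = aj
        new.loc[j, "par.2"] = bj
        if model_eff == "3PLM":
            new.loc[j, "par.3"] = gj
    return new, flags


def estimate_mmle_em(
    data,
    models,
    cats: int = 2,
    control: EMControl | None = None,
    priors=None,
    item_ids=None,
    start_meta: pd.DataFrame | None = None,
) -> CalibrationResult:
    """Calibrate item parameters by MMLE-EM.

    ``models`` broadcasts a single label to all items.  With EmpHist the
    latent weights are re-estimated each cycle and standardized to mean 0,
    variance 1 (scale identification); otherwise the latent distribution
    stays fixed at the N(0, 1) quadrature weights.
    """
    control = control or EMControl()
    X = validate_response_matrix(data)
    n_persons, n_items = X.shape
    meta = (
        validate_item_meta(start_meta)
        if start_meta is not None
        else _start_meta(X, models, item_ids, control, priors)
    )
    dist = make_quadrature(control.quad_points, control.quad_bound)
    layout = free_param_layout(meta, control)
    nodes = dist.nodes

    history: list[float] = []
    max_change = np.inf
    cycles = 0
    flags: list[str] = []
    for attempt in range(3):
        for cycle in range(cycles + 1, control.MaxE + 1):
            es = e_step(X, meta, dist, control.D)
            history.append(es.loglik)
            new_meta, flags = _run_m_step(meta, es, nodes, control, priors)
            if control.emp_hist:
                mass = es.posterior.sum(axis=0)
                dist = update_empirical_histogram(dist, mass, standardize=True)
                nodes = dist.nodes
            max_change = float(
                np.max(np.abs(_param_vector(new_meta, layout) - _param_vector(meta, layout)))
            ) if layout else 0.0
            meta = new_meta
            cycles = cycle
            if max_change < control.Etol:
                break
        # escape the 3PLM all-guessing degeneracy: refit implausible items
        # from dispersed starts and, if anything moved, resume EM
        meta, changed = _rescue_degenerate(
            X, meta, dist, control, priors, range(len(meta))
        )
        if not changed or cycles >= control.MaxE:
            break

    final = e_step(X, meta, dist, control.D)
    p = len(layout)
    neg2ll, aic, bic = fit_indices(final.loglik, p, n_persons)
    se_meta, varcov, second_ok = standard_errors(X, meta, dist, control, layout, priors)
    grad = _marginal_gradient(X, meta, dist, control, layout, priors)
    first_ok = (max_change < control.Etol) and (
        np.max(np.abs(grad)) / n_persons < 1e-3 if len(grad) else True
    )
    mu, s2, s = dist.mu, dist.sigma2, dist.sigma
    group = pd.DataFrame(
        {"mu": [mu, np.nan], "sigma2": [s2, np.nan], "sigma": [s, np.nan]},
        index=["estimates", "se"],
    )
    if not control.emp_hist:
        group.loc["estimates"] = [0.0, 1.0, 1.0]
    return CalibrationResult(
        est_meta=meta,
        se_meta=se_meta,
        varcov=varcov,
        loglik=final.loglik,
        neg2ll=neg2ll,
        aic=aic,
        bic=bic,
        n_free_params=p,
        group=group,
        em_cycles=cycles,
        max_change=max_change,
        first_order_ok=bool(first_ok),
        second_order_ok=second_ok,
        latent=dist,
        loglik_history=history,
        D=control.D,
        n_persons=n_persons,
        n_items=n_items,
        flagged_items=flags,
        control=control,
    )


# ---------------------------------------------------------------------------
# standard errors and diagnostics


def _person_scores(X, meta, dist, D, layout):
    """Per-person score matrix of the marginal log-likelihood (N × p)."""
    es = e_step(X, meta, dist, D)
    post = es.posterior
    a, b, g = param_arrays(meta)
    nodes = dist.nodes
    n_persons = X.shape[0]
    S = np.zeros((n_persons, len(layout)))
    cache: dict[int, tuple] = {}

    def item_scores(j):
        if j in cache:
            return cache[j]
        z = D * a[j] * (nodes - b[j])
        L = 1.0 / (1.0 + np.exp(-z))
        P = np.clip(g[j] + (1.0 - g[j]) * L, P_FLOOR, 1.0 - P_FLOOR)
        Q = 1.0 - P
        dLdz = L * (1.0 - L)
        dP = {
            "a": (1.0 - g[j]) * dLdz * D * (nodes - b[j]),
            "b": -(1.0 - g[j]) * dLdz * D * a[j],
            "g": 1.0 - L,
        }
        x = X[:, j]
        m = np.isfinite(x)
        x1 = np.where(m, x, 0.0)
        # weight w_ik = m_i * (x_i/P_k - (1-x_i)/Q_k), posterior-weighted
        W = post * (x1[:, None] / P[None, :] - (np.where(m, 1.0 - x, 0.0))[:, None] / Q[None, :])
        W[~m] = 0.0
        cache[j] = (W, dP)
        return cache[j]

    for col, (kind, idx) in enumerate(layout):
        if kind == "a1pl":
            for j in idx:
                W, dP = item_scores(j)
                S[:, col] += W @ dP["a"]
        else:
            W, dP = item_scores(idx)
            S[:, col] = W @ dP[kind]
    return S


def _marginal_gradient(X, meta, dist, control, layout, priors):
    if not layout:
        return np.zeros(0)
    S = _person_scores(X, meta, dist, control.D, layout)
    grad = S.sum(axis=0)
    pmap = _prior_map(priors)
    a, b, g = param_arrays(meta)
    for col, (kind, idx) in enumerate(layout):
        key = "a" if kind == "a1pl" else kind
        pr = pmap.get(key)
        if pr is None:
            continue
        val = {"a": a, "b": b, "g": g}[key][idx[0] if kind == "a1pl" else idx]
        grad[col] += pr.dlogpdf(val)
    return grad


def standard_errors(X, meta, dist, control, layout, priors=None):
    """Cross-product (empirical) information SEs restricted to free parameters.

    Returns ``(se_meta, varcov, second_order_ok)``.  The shared 1PLM slope's
    SE is reported on the first 1PLM row only; fixed or absent parameters
    get missing SEs, matching the metadata layout of the estimates.
    """
    se_meta = meta.copy()
    se_meta[["par.1", "par.2", "par.3"]] = np.nan
    labels = _layout_labels(layout, meta)
    if not layout:
        return se_meta, pd.DataFrame(index=labels, columns=labels, dtype=float), True
    S = _person_scores(np.asarray(X, dtype=float), meta, dist, control.D, layout)
    info = S.T @ S
    second_ok = True
    try:
        np.linalg.cholesky(info)
        vc = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        second_ok = False
        vc = np.full_like(info, np.nan)
    se = np.sqrt(np.clip(np.diag(vc), 0.0, None))
    for col, (kind, idx) in enumerate(layout):
        if kind == "a1pl":
            se_meta.loc[idx[0], "par.1"] = se[col]
        elif kind == "a":
            se_meta.loc[idx, "par.1"] = se[col]
        elif kind == "b":
            se_meta.loc[idx, "par.2"] = se[col]
        else:
            se_meta.loc[idx, "par.3"] = se[col]
    varcov = pd.DataFrame(vc, index=labels, columns=labels)
    return se_meta, varcov, second_ok


def fit_indices(loglik: float, n_free_params: int, n_persons: int):
    """(−2LL, AIC, BIC) from a marginal log-likelihood."""
    if n_persons < 1:
        raise ValueError("n_persons must be at least 1")
    neg2ll = -2.0 * loglik
    aic = neg2ll + 2.0 * n_free_params
    bic = neg2ll + n_free_params * np.log(n_persons)
    return float(neg2ll), float(aic), float(bic)


_EXTRACT_KEYS = (
    "par.est", "se.est", "weights", "varcov", "group.par", "loglik", "fit.indices",
)


def extract(result: CalibrationResult, what: str):
    """Pull a named component of a calibration result.

    Valid keys: ``par.est`` (estimates in metadata layout), ``se.est``,
    ``weights`` ((theta, weight) table), ``varcov``, ``group.par``,
    ``loglik``, ``fit.indices``.
    """
    if what == "par.est":
        return result.est_meta.copy()
    if what == "se.est":
        return result.se_meta.copy()
    if what == "weights":
        return result.latent.to_frame()
    if what == "varcov":
        return result.varcov.copy()
    if what == "group.par":
        return result.group.copy()
    if what == "loglik":
        return result.loglik
    if what == "fit.indices":
        return pd.Series(
            {"-2loglikelihood": result.neg2ll, "AIC": result.aic, "BIC": result.bic}
        )
    raise KeyError(f"unknown component {what!r}; valid keys: {list(_EXTRACT_KEYS)}")
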