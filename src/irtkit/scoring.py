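"""Person ability estimation from calibrated item parameters.

Supported estimators (``ScoreConfig.method``):

* ``ML`` — maximum likelihood on a bounded range; SE = 1/√TIF(θ̂).
* ``MLF`` — ML after appending two virtual high-slope "fence" items at the
  range bounds that pull perfect/zero patterns inward.
* ``WL`` — Warm's weighted likelihood: solves the bias-corrected score
  equation S(θ) + J(θ)/(2·I(θ)) = 0 with J(θ) = Σ_j P′_j·P″_j/(P_j·Q_j).
* ``MAP`` — posterior mode under a normal prior; SE = 1/√(TIF + 1/σ₀²).
* ``EAP`` — posterior mean over a discrete quadrature of the prior;
  SE = posterior SD.
* ``EAP.SUM`` — EAP conditioning only on the number-correct score, with the
  summed-score likelihood from the Lord–Wingersky recursion.
* ``INV.TCC`` — inverts the test characteristic curve at the observed
  summed score by bisection; sub-guessing scores clamp to the lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .metadata import param_arrays, validate_item_meta
from .models import P_FLOOR, three_pl_prob

__all__ = [
    "ScoreConfig",
    "ScoreResult",
    "est_score",
    "lord_wingersky",
    "eap_sum",
    "inv_tcc_score",
]

METHODS = ("ML", "MLF", "WL", "MAP", "EAP", "EAP.SUM", "INV.TCC")


@dataclass(frozen=True)
class ScoreConfig:
    method: str = "EAP"
    norm_prior: tuple[float, float] = (0.0, 1.0)
    nquad: int = 41
    range: tuple[float, float] = (-5.0, 5.0)
    D: float = 1.0
    fences: tuple[float, float] | None = None  # MLF fence difficulties (lo, hi)
    fence_a: float = 3.0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.range[0] >= self.range[1]:
            raise ValueError("range must satisfy lo < hi")
        if self.nquad < 3:
            raise ValueError("nquad must be at least 3")
        if self.norm_prior[1] <= 0:
            raise ValueError("prior sd must be positive")


@dataclass
class ScoreResult:
    frame: pd.DataFrame  # columns est.theta, se.theta
    flags: list = field(default_factory=list)

    @property
    def est_theta(self) -> np.ndarray:
        return self.frame["est.theta"].to_numpy()

    @property
    def se_theta(self) -> np.ndarray:
        return self.frame["se.theta"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, na_rep="NA")


def _clip_probs(P):
    return np.clip(P, P_FLOOR, 1.0 - P_FLOOR)


def _loglik(theta, x, a, b, g, D):
    P = _clip_probs(three_pl_prob(theta, a, b, g, D))
    return float(x @ np.log(P) + (1.0 - x) @ np.log1p(-P))


def _test_info(theta, a, b, g, D):
    P = _clip_probs(three_pl_prob(theta, a, b, g, D))
    Q = 1.0 - P
    return float(np.sum((D * a) ** 2 * (Q / P) * ((P - g) / (1.0 - g)) ** 2))


def _maximize_1d(fun, lo, hi, n_starts=5):
    """Multi-start bounded maximization (the 3PLM likelihood can be multimodal)."""
    grid = np.linspace(lo, hi, n_starts + 2)[1:-1]
    best_x, best_f = None, -np.inf
    edges = np.linspace(lo, hi, n_starts + 1)
    for k in range(n_starts):
        res = minimize_scalar(
            lambda t: -fun(t), bounds=(edges[k], edges[k + 1]), method="bounded",
            options={"xatol": 1e-9},
        )
        if -res.fun > best_f:
            best_f, best_x = -res.fun, float(res.x)
    for x in (lo, hi, *grid):
        f = fun(x)
        if f > best_f:
            best_f, best_x = f, float(x)
    return best_x, best_f


def _score_ml(x_row, obs, a, b, g, cfg: ScoreConfig, flags, i, fences=False):
    lo, hi = cfg.range
    aa, bb, gg = a[obs], b[obs], g[obs]
    xs = x_row[obs]
    if fences:
        aa = np.concatenate([aa, [cfg.fence_a, cfg.fence_a]])
        fb = cfg.fences if cfg.fences is not None else (lo, hi)
        bb = np.concatenate([bb, list(fb)])
        gg = np.concatenate([gg, [0.0, 0.0]])
        # virtual responses: correct at the lower fence, incorrect at the
        # upper fence — pulls all-correct/all-incorrect patterns inward
        xs = np.concatenate([xs, [1.0, 0.0]])
    th, _ = _maximize_1d(lambda t: _loglik(t, xs, aa, bb, gg, cfg.D), lo, hi)
    if not fences and (np.isclose(th, lo) or np.isclose(th, hi)):
        flags.append(i)
    info = _test_info(th, aa, bb, gg, cfg.D)
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    return th, se


def _warm_terms(theta, a, b, g, D):
    z = D * a * (theta - b)
    L = 1.0 / (1.0 + np.exp(-z))
    P = _clip_probs(g + (1.0 - g) * L)
    Q = 1.0 - P
    dP = (1.0 - g) * L * (1.0 - L) * D * a
    d2P = (1.0 - g) * L * (1.0 - L) * (1.0 - 2.0 * L) * (D * a) ** 2
    return P, Q, dP, d2P


def _score_wl(x_row, obs, a, b, g, cfg: ScoreConfig, flags, i):
    lo, hi = cfg.range
    aa, bb, gg = a[obs], b[obs], g[obs]
    xs = x_row[obs]

    def wl_equation(theta):
        P, Q, dP, d2P = _warm_terms(theta, aa, bb, gg, cfg.D)
        S = float(np.sum((xs - P) * dP / (P * Q)))
        info = float(np.sum(dP**2 / (P * Q)))
        J = float(np.sum(dP * d2P / (P * Q)))
        return S + J / (2.0 * max(info, 1e-12))

    grid = np.linspace(lo, hi, 201)
    vals = np.array([wl_equation(t) for t in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if len(sign_change):
        k = sign_change[np.argmin(np.abs(grid[sign_change]))]
        th = brentq(wl_equation, grid[k], grid[k + 1], xtol=1e-10)
    else:
        th = lo if vals.mean() < 0 else hi
        flags.append(i)
    info = _test_info(th, aa, bb, gg, cfg.D)
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    return float(th), se


def _score_map(x_row, obs, a, b, g, cfg: ScoreConfig):
    lo, hi = cfg.range
    m0, s0 = cfg.norm_prior
    aa, bb, gg = a[obs], b[obs], g[obs]
    xs = x_row[obs]

    def objective(t):
        return _loglik(t, xs, aa, bb, gg, cfg.D) - 0.5 * ((t - m0) / s0) ** 2

    th, _ = _maximize_1d(objective, lo, hi)
    info = _test_info(th, aa, bb, gg, cfg.D) + 1.0 / s0**2
    return th, 1.0 / np.sqrt(info)


def _eap_grid(cfg: ScoreConfig):
    m0, s0 = cfg.norm_prior
    nodes = np.linspace(m0 - 6.0 * s0, m0 + 6.0 * s0, cfg.nquad)
    w = np.exp(-0.5 * ((nodes - m0) / s0) ** 2)
    return nodes, w / w.sum()


def _score_eap(X, M, a, b, g, cfg: ScoreConfig):
    nodes, w = _eap_grid(cfg)
    P = _clip_probs(
        three_pl_prob(nodes[None, :], a[:, None], b[:, None], g[:, None], cfg.D)
    )
    logP, logQ = np.log(P), np.log1p(-P)
    X1 = np.where(M, X, 0.0)
    X0 = np.where(M, 1.0 - X, 0.0)
    ll = X1 @ logP + X0 @ logQ
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll) * w[None, :]
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ nodes
    sd = np.sqrt(np.maximum(post @ nodes**2 - mean**2, 0.0))
    return mean, sd


def est_score(meta: pd.DataFrame, data, config: ScoreConfig | None = None) -> ScoreResult:
    """Estimate each person's ability and standard error.

    Missing responses are skipped person-wise.  A person with no observed
    responses gets the prior moments under EAP/MAP and missing values under
    ML-type methods.  Persons whose ML estimate hits a range bound are
    listed in ``flags`` (0-based row indices).
    """
    cfg = config or ScoreConfig()
    meta = validate_item_meta(meta)
    from .calibrate import validate_response_matrix

    X = validate_response_matrix(data, n_items=len(meta))
    a, b, g = param_arrays(meta)
    M = np.isfinite(X)
    n = X.shape[0]
    flags: list[int] = []

    if cfg.method == "EAP":
        est, se = _score_eap(X, M, a, b, g, cfg)
        return ScoreResult(pd.DataFrame({"est.theta": est, "se.theta": se}), flags)
    if cfg.method == "EAP.SUM":
        scores = np.where(M, X, 0.0).sum(axis=1)
        res, _ = eap_sum(meta, scores.astype(int), cfg)
        return res
    if cfg.method == "INV.TCC":
        scores = np.where(M, X, 0.0).sum(axis=1)
        return inv_tcc_score(meta, scores, cfg)

    est = np.full(n, np.nan)
    se = np.full(n, np.nan)
    for i in range(n):
        obs = M[i]
        if not obs.any():
            if cfg.method == "MAP":
                est[i], se[i] = cfg.norm_prior
            continue
        if cfg.method in ("ML", "MLF"):
            est[i], se[i] = _score_ml(
                X[i], obs, a, b, g, cfg, flags, i, fences=(cfg.method == "MLF")
            )
        elif cfg.method == "WL":
            est[i], se[i] = _score_wl(X[i], obs, a, b, g, cfg, flags, i)
        elif cfg.method == "MAP":
            est[i], se[i] = _score_map(X[i], obs, a, b, g, cfg)
    return ScoreResult(pd.DataFrame({"est.theta": est, "se.theta": se}), flags)


def lord_wingersky(meta: pd.DataFrame, theta: float, D: float = 1.0) -> np.ndarray:
    """Summed-score distribution at ability theta (length J+1, sums to 1).

    Recursion over items: dist_j(s) = dist_{j−1}(s)·Q_j + dist_{j−1}(s−1)·P_j.
    """
    meta = validate_item_meta(meta)
    a, b, g = param_arrays(meta)
    P = np.atleast_1d(three_pl_prob(theta, a, b, g, D))
    dist = np.array([1.0])
    for p in P:
        new = np.empty(len(dist) + 1)
        new[0] = dist[0] * (1.0 - p)
        new[1:-1] = dist[1:] * (1.0 - p) + dist[:-1] * p
        new[-1] = dist[-1] * p
        dist = new
    return dist


def eap_sum(meta: pd.DataFrame, summed_scores, config: ScoreConfig | None = None):
    """EAP from number-correct scores via the Lord–Wingersky recursion.

    Returns ``(ScoreResult, table)`` where ``table`` maps every achievable
    summed score 0..J to its posterior mean and SD; identical summed scores
    map to identical ability estimates.
    """
    cfg = config or ScoreConfig(method="EAP.SUM")
    meta = validate_item_meta(meta)
    J = len(meta)
    s = np.asarray(summed_scores)
    if ((s < 0) | (s > J)).any() or not np.issubdtype(s.dtype, np.integer):
        s = s.astype(float)
        if ((s < 0) | (s > J) | (s != np.round(s))).any():
            raise ValueError(f"summed scores must be integers in 0..{J}")
        s = s.astype(int)
    nodes, w = _eap_grid(cfg)
    lw = np.stack([lord_wingersky(meta, t, cfg.D) for t in nodes])  # K x (J+1)
    post = w[:, None] * lw  # K x (J+1), column s = posterior mass profile
    norm = post.sum(axis=0)
    mean = (post * nodes[:, None]).sum(axis=0) / norm
    sd = np.sqrt(
        np.maximum((post * nodes[:, None] ** 2).sum(axis=0) / norm - mean**2, 0.0)
    )
    table = pd.DataFrame(
        {"sum.score": np.arange(J + 1), "est.theta": mean, "se.theta": sd}
    )
    frame = pd.DataFrame({"est.theta": mean[s], "se.theta": sd[s]})
    return ScoreResult(frame), table


def _tcc(theta, a, b, g, D):
    return float(np.sum(three_pl_prob(theta, a, b, g, D)))


def inv_tcc_score(meta: pd.DataFrame, summed_scores, config: ScoreConfig | None = None) -> ScoreResult:
    """Map summed scores to abilities through the inverse TCC (bisection).

    Scores at or below TCC(lo) — including sub-guessing scores below Σg —
    clamp to lo; scores at or above TCC(hi) clamp to hi.  SE = 1/√TIF(θ̂).
    """
    cfg = config or ScoreConfig(method="INV.TCC")
    meta = validate_item_meta(meta)
    a, b, g = param_arrays(meta)
    lo, hi = cfg.range
    grid = np.linspace(lo, hi, 401)
    tcc_grid = np.array([_tcc(t, a, b, g, cfg.D) for t in grid])
    diffs = np.diff(tcc_grid)
    if (diffs < -1e-10).any():
        k = int(np.argmin(diffs))
        raise ValueError(
            f"TCC is not increasing on [{grid[k]:.3f}, {grid[k + 1]:.3f}]; "
            "inverse-TCC scoring requires a strictly increasing TCC"
        )
    s = np.asarray(summed_scores, dtype=float)
    J = len(meta)
    if ((s < 0) | (s > J)).any():
        raise ValueError(f"summed scores must lie in 0..{J}")
    est = np.empty(len(s))
    se = np.empty(len(s))
    t_lo, t_hi = tcc_grid[0], tcc_grid[-1]
    cache: dict[float, tuple[float, float]] = {}
    for i, si in enumerate(s):
        if si in cache:
            est[i], se[i] = cache[si]
            continue
        if si <= t_lo:
            th = lo
        elif si >= t_hi:
            th = hi
        else:
            th = brentq(lambda t: _tcc(t, a, b, g, cfg.D) - si, lo, hi, xtol=1e-8)
        info = _test_info(th, a, b, g, cfg.D)
        sei = 1.0 / np.sqrt(info) if info > 0 else np.nan
        cache[si] = (float(th), sei)
        est[i], se[i] = cache[si]
    return ScoreResult(pd.DataFrame({"est.theta": est, "se.theta": se}))
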