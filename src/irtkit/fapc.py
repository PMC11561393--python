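"""Fixed-ability-parameter calibration (Stocking's Method A).

Each pretest item is calibrated independently by maximizing its response
log-likelihood over the item parameters, treating the supplied person
ability estimates as known constants.  Items are completely separable, so
permuting item order permutes the results exactly.  With the guessing
parameter fixed at truth this reduces, item by item, to a logistic
regression of the responses on θ̂ with slope D·a and intercept −D·a·b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .calibrate import (
    A_BOUNDS,
    B_BOUNDS,
    G_BOUNDS,
    EMControl,
    _item_neg_objective,
    _prior_map,
    validate_response_matrix,
)
from .metadata import build_item_meta

__all__ = ["FapcInput", "FapcResult", "estimate_fapc"]


@dataclass(frozen=True)
class FapcInput:
    """Scores, pretest responses and model assignments for Method A."""

    scores: np.ndarray
    data: np.ndarray
    model: object = "3PLM"
    cats: int = 2
    item_ids: tuple | None = None
    priors: object = None

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(scores).all():
            raise ValueError("ability scores must be finite")
        data = validate_response_matrix(self.data)
        if len(scores) != data.shape[0]:
            raise ValueError(
                f"{len(scores)} scores for {data.shape[0]} persons in the data"
            )
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "data", data)


@dataclass
class FapcResult:
    est_meta: pd.DataFrame
    se_meta: pd.DataFrame
    neg2ll: float
    n_responses: pd.Series
    n_excluded: int
    excluded_ids: list
    group: pd.Series  # descriptive mean/sd of the supplied scores
    all_converged: bool
    flagged_items: list = field(default_factory=list)
    D: float = 1.0

    def summary(self) -> str:
        from .report import fapc_summary

        return fapc_summary(self)


def _observed_info(params, args, step=1e-5):
    """Observed information via central differences of the analytic gradient."""
    p = np.asarray(params, dtype=float)
    k = len(p)
    H = np.zeros((k, k))
    for i in range(k):
        hi = step * max(1.0, abs(p[i]))
        up, dn = p.copy(), p.copy()
        up[i] += hi
        dn[i] -= hi
        _, g_up = _item_neg_objective(up, *args)
        _, g_dn = _item_neg_objective(dn, *args)
        H[i] = (g_up - g_dn) / (2.0 * hi)
    return 0.5 * (H + H.T)  # negative-loglik Hessian = observed information


def estimate_fapc(
    inputs: FapcInput,
    D: float = 1.0,
    control: EMControl | None = None,
) -> FapcResult:
    """Per-item maximum likelihood given fixed ability estimates.

    Missing responses are dropped per item; an item with zero observed
    responses is excluded and counted.  Priors (e.g. a beta prior on g)
    penalize the per-item objective but the reported −2LL excludes prior
    terms.  The group line is descriptive: the mean and SD of the scores.
    """
    control = control or EMControl(D=D)
    theta = inputs.scores
    X = inputs.data
    n_items = X.shape[1]
    models = (
        [inputs.model] * n_items if isinstance(inputs.model, str) else list(inputs.model)
    )
    if len(models) != n_items:
        raise ValueError("model must broadcast to the number of items")
    ids = (
        list(inputs.item_ids)
        if inputs.item_ids is not None
        else [f"V{i + 1}" for i in range(n_items)]
    )
    pmap = _prior_map(inputs.priors)

    est = np.full((n_items, 3), np.nan)
    ses = np.full((n_items, 3), np.nan)
    n_resp = np.zeros(n_items, dtype=int)
    excluded: list[str] = []
    flagged: list[str] = []
    total_ll = 0.0
    for j in range(n_items):
        model = "3PLM" if models[j] in ("3PLM", "DRM") else models[j]
        x = X[:, j]
        m = np.isfinite(x)
        n_resp[j] = int(m.sum())
        if n_resp[j] == 0:
            excluded.append(ids[j])
            continue
        th, xs = theta[m], x[m]
        # person-level likelihood is the grid likelihood with unit "counts"
        # at the observed abilities: reuse the expected-count objective
        r = xs
        n = np.ones_like(xs)
        fix_g = control.fix_g and model == "3PLM"
        if model == "3PLM" and not fix_g:
            bounds = [A_BOUNDS, B_BOUNDS, G_BOUNDS]
            g0 = pmap["g"].mode() if "g" in pmap else 0.2
            x0 = np.array([1.0, 0.0, np.clip(g0, *G_BOUNDS)])
        else:
            bounds = [A_BOUNDS, B_BOUNDS]
            x0 = np.array([1.0, 0.0])
        args = (r, n, th, D, model, pmap, fix_g, control.g_val)
        res = minimize(
            _item_neg_objective, x0, args=args, jac=True, method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success:
            flagged.append(ids[j])
        at_bound = any(
            np.isclose(res.x[i], bounds[i][0]) or np.isclose(res.x[i], bounds[i][1])
            for i in range(len(res.x))
        )
        if at_bound and ids[j] not in flagged:
            flagged.append(ids[j])
        p = res.x
        if model == "3PLM":
            est[j] = [p[0], p[1], control.g_val if fix_g else p[2]]
        else:
            est[j, :2] = p
        # prior-free log-likelihood at the solution
        f_plain, _ = _item_neg_objective(p, r, n, th, D, model, {}, fix_g, control.g_val)
        total_ll += -f_plain
        H = _observed_info(p, args)
        try:
            vc = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(vc), 0.0, None))
            ses[j, : len(se)] = se
        except np.linalg.LinAlgError:
            flagged.append(ids[j])

    g_col = est[:, 2]
    meta = build_item_meta(
        np.where(np.isnan(est[:, 0]), 1.0, est[:, 0]),
        np.where(np.isnan(est[:, 1]), 0.0, est[:, 1]),
        g_col,
        ids,
        2,
        models,
    )
    # re-mark excluded items' parameters as missing after validation
    for j, iid in enumerate(ids):
        if iid in excluded:
            meta.loc[j, ["par.1", "par.2", "par.3"]] = np.nan
    se_meta = meta.copy()
    se_meta["par.1"], se_meta["par.2"], se_meta["par.3"] = (
        ses[:, 0], ses[:, 1], ses[:, 2],
    )
    group = pd.Series(
        {"mu": float(np.mean(theta)), "sigma": float(np.std(theta, ddof=1))}
    )
    return FapcResult(
        est_meta=meta,
        se_meta=se_meta,
        neg2ll=float(-2.0 * total_ll),
        n_responses=pd.Series(n_resp, index=ids, name="n"),
        n_excluded=len(excluded),
        excluded_ids=excluded,
        group=group,
        all_converged=not flagged and not excluded,
        flagged_items=flagged,
        D=D,
    )
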