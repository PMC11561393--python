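"""Fixed-item-parameter calibration (FIPC) for pretest items.

Operational items keep their bank parameter values while the pretest items
and the latent ability distribution are estimated, so new estimates land
directly on the operational scale without post-hoc linking.  Two variants:

* **OEM** (no-weights-update, one EM cycle): a single E-step using the
  fixed items only, then a single M-step for the non-fixed items.
* **MEM** (multiple-weights-update, multiple EM cycles): the first cycle
  equals OEM; from the second cycle on, every E-step uses all items at
  their current values and the non-fixed item parameters and the latent
  distribution (scale, and with EmpHist also the weights) are updated
  concurrently.  The latent scale is deliberately NOT re-standardized —
  the fixed items identify the scale, so (mu, sigma2) are free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import (
    CalibrationResult,
    EMControl,
    EStepResult,
    _marginal_gradient,
    _person_scores,
    _rescue_degenerate,
    _run_m_step,
    _layout_labels,
    _param_vector,
    e_step,
    fit_indices,
    free_param_layout,
    validate_response_matrix,
)
from .latent import LatentDist, make_quadrature
from .metadata import validate_item_meta

__all__ = ["FipcSpec", "estimate_fipc", "update_group_scale"]


@dataclass(frozen=True)
class FipcSpec:
    """Which items are fixed (1-based positions) and how to iterate."""

    fix_locations: tuple
    method: str = "MEM"
    emp_hist: bool = False

    def __post_init__(self):
        locs = tuple(int(v) for v in self.fix_locations)
        if not locs:
            raise ValueError("fix_locations must be non-empty")
        if len(set(locs)) != len(locs):
            raise ValueError("fix_locations contains duplicates")
        if self.method not in ("OEM", "MEM"):
            raise ValueError("method must be 'OEM' or 'MEM'")
        object.__setattr__(self, "fix_locations", locs)


def update_group_scale(posterior_mass, nodes, emp_hist: bool) -> LatentDist:
    """Re-estimate the latent distribution from accumulated posterior mass.

    With ``emp_hist`` the weights become the normalized mass on the fixed
    node grid (empirical histogram).  Without it, a normal distribution is
    fitted by the mass's first two moments and the node weights are the
    N(mu, sigma2) density at the nodes, renormalized.
    """
    mass = np.asarray(posterior_mass, dtype=float)
    nodes = np.asarray(nodes, dtype=float)
    total = mass.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("posterior mass is degenerate")
    w = mass / total
    if emp_hist:
        return LatentDist(nodes, w)
    mu = float(w @ nodes)
    sigma2 = float(w @ (nodes - mu) ** 2)
    if sigma2 <= 0:
        raise ValueError("posterior mass has zero variance")
    dens = np.exp(-0.5 * (nodes - mu) ** 2 / sigma2)
    return LatentDist(nodes, dens)


def _counts_from_posterior(X, post):
    M = np.isfinite(X)
    X1 = np.where(M, X, 0.0)
    return X1.T @ post, M.T.astype(float) @ post


def _group_scores(post, dist: LatentDist):
    """Per-person scores w.r.t. (mu, sigma2) of a normal latent density."""
    nodes, w = dist.nodes, dist.weights
    mu, s2 = dist.mu, max(dist.sigma2, 1e-8)
    du_mu = (nodes - mu) / s2
    du_s2 = -0.5 / s2 + 0.5 * (nodes - mu) ** 2 / s2**2
    dlw_mu = du_mu - w @ du_mu
    dlw_s2 = du_s2 - w @ du_s2
    return np.column_stack([post @ dlw_mu, post @ dlw_s2])


def estimate_fipc(
    meta: pd.DataFrame,
    data,
    spec: FipcSpec,
    control: EMControl | None = None,
    priors=None,
) -> CalibrationResult:
    """Estimate non-fixed items and the latent distribution with FIPC.

    ``meta`` holds final parameter values on the fixed rows and start
    placeholders (e.g. a=1, b=0, g=0.2) on the rows to be estimated.
    Fixed rows are returned bit-identical; their SEs are missing.  The
    free-parameter count includes the two group parameters (mu, sigma2).
    """
    control = control or EMControl()
    meta = validate_item_meta(meta)
    X = validate_response_matrix(data, n_items=len(meta))
    n_persons = X.shape[0]
    n_items = len(meta)
    fixed = sorted(loc - 1 for loc in spec.fix_locations)
    if fixed and (fixed[0] < 0 or fixed[-1] >= n_items):
        raise ValueError("fix_locations out of item range (1-based positions)")
    fixed_set = set(fixed)
    est = [j for j in range(n_items) if j not in fixed_set]

    dist = make_quadrature(control.quad_points, control.quad_bound)
    layout = free_param_layout(meta, control, fixed_items=fixed)
    fixed_values = meta.iloc[fixed][["par.1", "par.2", "par.3"]].copy()

    history: list[float] = []
    max_change = np.inf
    cycles = 0
    flags: list[str] = []
    for attempt in range(3):
        for cycle in range(cycles + 1, control.MaxE + 1):
            es_full = e_step(X, meta, dist, control.D)
            history.append(es_full.loglik)
            if cycle == 1:
                # OEM E-step: posterior from the fixed items only
                es_fix = e_step(X[:, fixed], meta.iloc[fixed], dist, control.D)
                r, n = _counts_from_posterior(X, es_fix.posterior)
                es_use = EStepResult(r, n, es_fix.loglik, es_fix.posterior)
            else:
                es_use = es_full
            new_meta, flags = _run_m_step(
                meta, es_use, dist.nodes, control, priors, skip=fixed
            )
            if cycle >= 2:
                dist = update_group_scale(
                    es_use.posterior.sum(axis=0), dist.nodes, spec.emp_hist
                )
            max_change = float(
                np.max(np.abs(_param_vector(new_meta, layout) - _param_vector(meta, layout)))
            ) if layout else 0.0
            meta = new_meta
            cycles = cycle
            if spec.method == "OEM":
                break
            if cycle >= 2 and max_change < control.Etol:
                break
        # multi-start refit of non-fixed items stuck at implausible values
        meta, changed = _rescue_degenerate(X, meta, dist, control, priors, est)
        if spec.method == "OEM" or not changed or cycles >= control.MaxE:
            break

    # fixed rows must be bit-identical to the input
    meta.iloc[fixed, meta.columns.get_indexer(["par.1", "par.2", "par.3"])] = (
        fixed_values.to_numpy()
    )

    final = e_step(X, meta, dist, control.D)
    p = len(layout) + 2  # non-fixed item parameters + (mu, sigma2)
    neg2ll, aic, bic = fit_indices(final.loglik, p, n_persons)

    # standard errors: item block + group block from one joint empirical
    # information matrix (delta method for sigma)
    se_meta = meta.copy()
    se_meta[["par.1", "par.2", "par.3"]] = np.nan
    S_items = (
        _person_scores(X, meta, dist, control.D, layout)
        if layout
        else np.zeros((n_persons, 0))
    )
    if spec.method == "OEM":
        # NWU: the latent distribution was never updated; report the
        # posterior-mass moments descriptively for the group line.
        group_dist = update_group_scale(final.posterior.sum(axis=0), dist.nodes, False)
    else:
        group_dist = dist
    S_group = _group_scores(final.posterior, group_dist)
    S = np.hstack([S_items, S_group])
    labels = _layout_labels(layout, meta) + ["mu", "sigma2"]
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
        target = {"a": "par.1", "b": "par.2", "g": "par.3"}.get(kind)
        if kind == "a1pl":
            se_meta.loc[idx[0], "par.1"] = se[col]
        else:
            se_meta.loc[idx, target] = se[col]
    varcov = pd.DataFrame(vc, index=labels, columns=labels)

    mu, s2, s = group_dist.mu, group_dist.sigma2, group_dist.sigma
    se_mu, se_s2 = se[-2], se[-1]
    se_sigma = se_s2 / (2.0 * s) if s > 0 else np.nan
    group = pd.DataFrame(
        {"mu": [mu, se_mu], "sigma2": [s2, se_s2], "sigma": [s, se_sigma]},
        index=["estimates", "se"],
    )

    grad = _marginal_gradient(X, meta, dist, control, layout, priors)
    first_ok = (spec.method == "OEM") or (
        max_change < control.Etol
        and (np.max(np.abs(grad)) / n_persons < 1e-3 if len(grad) else True)
    )

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
        n_fixed_items=len(fixed),
        flagged_items=flags,
        control=control,
    )
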