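"""Plain-text summaries of calibration and scoring results."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _item_table(est: pd.DataFrame, se: pd.DataFrame) -> str:
    out = est.copy()
    out.insert(4, "se.1", se["par.1"])
    out.insert(6, "se.2", se["par.2"])
    out["se.3"] = se["par.3"]
    out.columns = ["id", "cats", "model", "par.1", "se.1", "par.2", "se.2", "par.3", "se.3"]
    with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
        return out.to_string(index=False, na_rep="NA")


def calibration_summary(result) -> str:
    c = result.control
    lines = [
        "Summary of the Data",
        f" Number of Items: {result.n_items}",
        f" Number of Cases: {result.n_persons}",
        "",
        "Summary of Estimation Process",
        f" Maximum number of EM cycles: {c.MaxE if c else 'NA'}",
        f" Convergence criterion of E-step: {c.Etol if c else 'NA'}",
        f" Number of rectangular quadrature points: {len(result.latent.nodes)}",
        f" Minimum & Maximum quadrature points: {result.latent.nodes[0]:g}, "
        f"{result.latent.nodes[-1]:g}",
        f" Number of free parameters: {result.n_free_params}",
        f" Number of fixed items: {result.n_fixed_items}",
        f" Number of E-step cycles completed: {result.em_cycles}",
        f" Maximum parameter change: {result.max_change:.6g}",
        "",
        "Convergence and Stability of Solution",
        " First-order test: "
        + (
            "Convergence criteria are satisfied."
            if result.first_order_ok
            else "Convergence criteria are NOT satisfied."
        ),
        " Second-order test: "
        + (
            "The solution is a possible local maximum."
            if result.second_order_ok
            else "The information matrix is not positive definite."
        ),
        "",
        "Summary of Estimation Results",
        f" -2loglikelihood: {result.neg2ll:.2f}",
        f" Akaike Information Criterion (AIC): {result.aic:.2f}",
        f" Bayesian Information Criterion (BIC): {result.bic:.2f}",
        " Item Parameters:",
        _item_table(result.est_meta, result.se_meta),
        " Group Parameters:",
        result.group.to_string(float_format=lambda v: f"{v:.4f}", na_rep="NA"),
    ]
    if result.flagged_items:
        lines.append(f" Flagged items (boundary/non-converged): {result.flagged_items}")
    return "\n".join(lines)


def fapc_summary(result) -> str:
    lines = [
        "Summary of the Data",
        f" Number of Items in Response Data: {len(result.est_meta)}",
        f" Number of Excluded Items: {result.n_excluded}",
        " Number of Responses for Each Item:",
        result.n_responses.to_string(),
        "",
        "Convergence of Solution",
        " All item parameters were successfully converged."
        if result.all_converged
        else f" Some items did not converge cleanly: {result.flagged_items}",
        "",
        "Summary of Estimation Results",
        f" -2loglikelihood: {result.neg2ll:.2f}",
        " Item Parameters:",
        _item_table(result.est_meta, result.se_meta),
        " Group Parameters:",
        result.group.to_string(float_format=lambda v: f"{v:.4f}"),
    ]
    return "\n".join(lines)
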