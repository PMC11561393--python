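"""Dichotomous response simulation and the two reference study designs.

Responses are Bernoulli draws from the 3PL response probability at each
person's true ability.  Two canned designs mirror the simulated datasets
used throughout the package's worked examples:

* a 30-item linear test answered by 2,000 examinees with abilities drawn
  from N(0, 1) (``fixture_simdat30``), and
* a 60-item design with 50 operational 3PLM items answered by everyone
  plus 10 pretest items of which each examinee is randomly assigned 5,
  leaving the rest missing (``fixture_simdat60``); each pretest item then
  receives roughly 1,000 responses.

The canned fixtures are statistically equivalent stand-ins for externally
distributed datasets of the same design (synthetic: dimensions, missing
structure and generating distributions match; the exact item parameter
draws and random seeds of the originals are not public).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metadata import build_item_meta, param_arrays, validate_item_meta
from .models import three_pl_prob

__all__ = [
    "SimDesign",
    "SimResult",
    "simulate_responses",
    "fixture_simdat30",
    "fixture_simdat60",
    "write_response_csv",
    "read_response_csv",
]


@dataclass(frozen=True)
class SimDesign:
    """A simulation recipe: persons, ability distribution, items, design."""

    n_persons: int
    meta: pd.DataFrame
    theta_dist: tuple[float, float] = (0.0, 1.0)
    theta: np.ndarray | None = None  # explicit abilities override theta_dist
    pretest_block: tuple[int, int, int] | None = None  # (n_oper, n_pretest, k_assigned)
    D: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "meta", validate_item_meta(self.meta))
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")
        if self.pretest_block is not None:
            n_op, n_pt, k = self.pretest_block
            if n_op + n_pt != len(self.meta):
                raise ValueError(
                    "n_operational + n_pretest must equal the number of items"
                )
            if not (0 < k <= n_pt):
                raise ValueError("k_assigned must be in 1..n_pretest")
        if self.theta is not None and len(self.theta) != self.n_persons:
            raise ValueError("explicit theta vector must have n_persons entries")


@dataclass
class SimResult:
    data: np.ndarray  # persons x items, {0, 1, NaN}
    meta: pd.DataFrame  # true generating parameters
    theta: np.ndarray  # true abilities
    design: SimDesign


def simulate_responses(design: SimDesign) -> SimResult:
    """Draw a response matrix (and true abilities) under the design.

    Uses numpy's PCG64 generator seeded from ``design.seed``; identical
    designs produce identical matrices.
    """
    rng = np.random.default_rng(np.random.PCG64(design.seed))
    n, meta = design.n_persons, design.meta
    if design.theta is not None:
        theta = np.asarray(design.theta, dtype=float)
    else:
        m, s = design.theta_dist
        theta = rng.normal(m, s, size=n)
    a, b, g = param_arrays(meta)
    P = three_pl_prob(theta[:, None], a[None, :], b[None, :], g[None, :], design.D)
    X = (rng.random(P.shape) < P).astype(float)
    if design.pretest_block is not None:
        n_op, n_pt, k = design.pretest_block
        for i in range(n):
            assigned = rng.choice(n_pt, size=k, replace=False)
            hide = np.setdiff1d(np.arange(n_pt), assigned)
            X[i, n_op + hide] = np.nan
    return SimResult(X, meta, theta, design)


# --- generating parameter ranges for the canned designs -------------------
# a: lognormal around 1.2 (moderate discrimination); b: standard normal
# clipped to ±1.75, the difficulty window of an operational linear-test
# pool (harder items leave almost no examinees on the item's informative
# range and make the 3PLM's "all-guessing" degeneracy reachable);
# g: beta(5, 16) (mean ≈ 0.24, same family used as calibration prior),
# redrawn above 0.35 — multiple-choice floors beyond that are unrealistic.
_A_LOGNORM = (0.2, 0.25)  # (meanlog, sdlog)
_B_CLIP = (-1.75, 1.75)
_G_BETA = (5.0, 16.0)
_G_MAX = 0.35


def _draw_item_params(rng, n_items, prefix="V", start=1):
    a = rng.lognormal(*_A_LOGNORM, size=n_items)
    b = np.clip(rng.normal(0.0, 1.0, size=n_items), *_B_CLIP)
    g = rng.beta(*_G_BETA, size=n_items)
    while (g > _G_MAX).any():  # truncate by redraw
        g[g > _G_MAX] = rng.beta(*_G_BETA, size=int((g > _G_MAX).sum()))
    ids = [f"{prefix}{i}" for i in range(start, start + n_items)]
    return build_item_meta(a, b, g, ids, 2, "3PLM")


def fixture_simdat30(
    seed: int = 0,
    n_persons: int = 2000,
    n_items: int = 30,
    theta_dist=(0.0, 1.0),
    D: float = 1.702,
) -> SimResult:
    """2,000 × 30 complete binary matrix under 3PLM with N(0, 1) abilities."""
    rng = np.random.default_rng(np.random.PCG64([seed, 30]))
    meta = _draw_item_params(rng, n_items)
    design = SimDesign(
        n_persons=n_persons, meta=meta, theta_dist=theta_dist, D=D, seed=seed
    )
    return simulate_responses(design)


def fixture_simdat60(
    seed: int = 0,
    n_persons: int = 2000,
    n_operational: int = 50,
    n_pretest: int = 10,
    k_assigned: int = 5,
    theta_dist=(0.0, 1.0),
    D: float = 1.702,
) -> SimResult:
    """50 operational + 10 pretest items; 5 random pretest items per person.

    Returns the response matrix with the pretest missingness pattern and
    the full true metadata (operational rows first, ids OP1..OPn then
    PT1..PTm).
    """
    rng = np.random.default_rng(np.random.PCG64([seed, 60]))
    op = _draw_item_params(rng, n_operational, prefix="OP")
    pt = _draw_item_params(rng, n_pretest, prefix="PT")
    meta = pd.concat([op, pt], ignore_index=True)
    design = SimDesign(
        n_persons=n_persons,
        meta=meta,
        theta_dist=theta_dist,
        pretest_block=(n_operational, n_pretest, k_assigned),
        D=D,
        seed=seed,
    )
    return simulate_responses(design)


def write_response_csv(data, path, missing: str = "NA") -> None:
    """Headerless response CSV; missing entries written as ``missing``."""
    arr = np.asarray(data, dtype=float)
    df = pd.DataFrame(arr)
    df = df.astype(object).where(np.isfinite(arr), missing)
    df = df.map(lambda v: int(v) if isinstance(v, float) else v)
    df.to_csv(path, index=False, header=False)


def read_response_csv(path, missing: str = "NA") -> np.ndarray:
    """Read a headerless response CSV into a {0, 1, NaN} matrix."""
    df = pd.read_csv(
        path, header=None, na_values=[missing, "NA", "NaN", ""],
        keep_default_na=True,
    )
    return df.to_numpy(dtype=float)


def write_design_sidecar(result: SimResult, path) -> None:
    """JSON sidecar recording the design, seed and true parameters."""
    d = result.design
    payload = {
        "n_persons": d.n_persons,
        "theta_dist": list(d.theta_dist),
        "pretest_block": list(d.pretest_block) if d.pretest_block else None,
        "D": d.D,
        "seed": d.seed,
        "items": result.meta.where(result.meta.notna(), None).to_dict("records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
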