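"""Item metadata: the tabular currency of every IRT analysis.

An item-metadata table is a :class:`pandas.DataFrame` with one row per item
and the fixed columns ``id, cats, model, par.1, par.2, par.3``:

* ``id`` — unique item identifier,
* ``cats`` — number of score categories (always 2 for dichotomous items),
* ``model`` — one of ``1PLM``, ``2PLM``, ``3PLM``, ``DRM``,
* ``par.1`` — discrimination *a* (logit slope, > 0),
* ``par.2`` — difficulty *b* (on the latent θ scale),
* ``par.3`` — guessing probability *g* in [0, 1); ``NaN`` for 1PLM/2PLM.

``DRM`` is an umbrella label for dichotomous models and is treated as 3PLM
in every computation downstream.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODELS = ("1PLM", "2PLM", "3PLM", "DRM")
COLUMNS = ("id", "cats", "model", "par.1", "par.2", "par.3")

__all__ = [
    "MODELS",
    "COLUMNS",
    "MetadataError",
    "build_item_meta",
    "validate_item_meta",
    "read_item_meta_csv",
    "write_item_meta_csv",
    "param_arrays",
]


class MetadataError(ValueError):
    """Raised when an item-metadata table violates its invariants."""


def _broadcast(value, n: int, name: str) -> list:
    if np.isscalar(value) or isinstance(value, str):
        return [value] * n
    out = list(value)
    if len(out) != n:
        raise MetadataError(f"{name} has length {len(out)}, expected {n}")
    return out


def build_item_meta(
    a: Sequence[float],
    b: Sequence[float],
    g: Sequence[float] | None = None,
    item_ids: Sequence[str] | None = None,
    cats: int | Sequence[int] = 2,
    model: str | Sequence[str] = "3PLM",
) -> pd.DataFrame:
    """Assemble and validate an item-metadata table.

    Scalars for ``cats`` and ``model`` broadcast to all items.  When
    ``item_ids`` is absent, ids ``V1..Vn`` are assigned automatically.
    ``g`` may be ``None`` (all missing) or contain NaN for 1PLM/2PLM rows.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    if len(b) != n:
        raise MetadataError(f"a and b differ in length ({n} vs {len(b)})")
    if g is None:
        g = np.full(n, np.nan)
    else:
        g = np.asarray(g, dtype=float)
        if len(g) != n:
            raise MetadataError(f"g has length {len(g)}, expected {n}")
    if item_ids is None:
        item_ids = [f"V{i + 1}" for i in range(n)]
    else:
        item_ids = [str(s) for s in _broadcast(item_ids, n, "item_ids")]
    cats = _broadcast(cats, n, "cats")
    model = _broadcast(model, n, "model")
    df = pd.DataFrame(
        {
            "id": item_ids,
            "cats": np.asarray(cats, dtype=int),
            "model": model,
            "par.1": a,
            "par.2": b,
            "par.3": g,
        }
    )
    return validate_item_meta(df)


def validate_item_meta(df: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of an item-metadata table.

    Returns a normalized copy (column order, dtypes, ``g`` coerced to NaN on
    1PLM/2PLM rows — with a warning if a value was present).
    """
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise MetadataError(f"metadata is missing columns {missing_cols}")
    df = df.loc[:, list(COLUMNS)].copy().reset_index(drop=True)
    df["id"] = df["id"].astype(str)
    df["cats"] = df["cats"].astype(int)
    df["model"] = df["model"].astype(str)
    for c in ("par.1", "par.2", "par.3"):
        df[c] = pd.to_numeric(df[c], errors="coerce" if c == "par.3" else "raise")

    bad_model = sorted(set(df["model"]) - set(MODELS))
    if bad_model:
        raise MetadataError(
            f"unknown model label(s) {bad_model}; allowed models are {list(MODELS)}"
        )
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise MetadataError(f"duplicate item ids: {dups}")
    if (df["cats"] != 2).any():
        raise MetadataError("cats must equal 2 for all dichotomous models")
    if (df["par.1"] <= 0).any():
        bad = df.loc[df["par.1"] <= 0, "id"].tolist()
        raise MetadataError(f"discrimination (par.1) must be > 0; offending items: {bad}")
    g = df["par.3"]
    bad_g = g.notna() & ((g < 0) | (g >= 1))
    if bad_g.any():
        raise MetadataError(
            f"guessing (par.3) must lie in [0, 1); offending items: "
            f"{df.loc[bad_g, 'id'].tolist()}"
        )
    no_g = df["model"].isin(("1PLM", "2PLM"))
    stray = no_g & g.notna()
    if stray.any():
        warnings.warn(
            "par.3 given for 1PLM/2PLM item(s) "
            f"{df.loc[stray, 'id'].tolist()}; coerced to missing",
            UserWarning,
            stacklevel=2,
        )
        df.loc[stray, "par.3"] = np.nan
    return df


def read_item_meta_csv(path) -> pd.DataFrame:
    """Read an item-metadata CSV (header ``id,cats,model,par.1,par.2,par.3``)."""
    df = pd.read_csv(path, na_values=["NA", "NaN", ""], keep_default_na=True)
    return validate_item_meta(df)


def write_item_meta_csv(meta: pd.DataFrame, path) -> None:
    """Write an item-metadata table; missing values are encoded as ``NA``."""
    validate_item_meta(meta).to_csv(path, index=False, na_rep="NA")


def param_arrays(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(a, b, g)`` arrays; missing ``g`` is 0 (1PLM/2PLM convention)."""
    a = meta["par.1"].to_numpy(dtype=float)
    b = meta["par.2"].to_numpy(dtype=float)
    g = np.nan_to_num(meta["par.3"].to_numpy(dtype=float), nan=0.0)
    return a, b, g
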