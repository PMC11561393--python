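"""Item/test characteristic curves and information functions on a θ grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metadata import param_arrays, validate_item_meta
from .models import three_pl_prob

__all__ = ["CurveSet", "traceline", "info", "render_curves"]


@dataclass
class CurveSet:
    """Curves evaluated on an ordered θ grid.

    ``icc``/``iif`` are items × grid; ``tcc``/``tif`` are their column sums
    (expected summed score and total Fisher information).  Only the fields
    filled by the producing function are non-None.
    """

    thetas: np.ndarray
    item_ids: list
    icc: np.ndarray | None = None
    tcc: np.ndarray | None = None
    iif: np.ndarray | None = None
    tif: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: (item_or_test, theta, value, kind)."""
        rows = []
        for kind, per_item, total in (
            ("icc", self.icc, self.tcc),
            ("iif", self.iif, self.tif),
        ):
            if per_item is None:
                continue
            for j, iid in enumerate(self.item_ids):
                rows.append(
                    pd.DataFrame(
                        {
                            "item_or_test": iid,
                            "theta": self.thetas,
                            "value": per_item[j],
                            "kind": kind,
                        }
                    )
                )
            rows.append(
                pd.DataFrame(
                    {
                        "item_or_test": "TEST",
                        "theta": self.thetas,
                        "value": total,
                        "kind": "tcc" if kind == "icc" else "tif",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _check_grid(thetas):
    t = np.asarray(thetas, dtype=float)
    if t.size == 0:
        raise ValueError("theta grid must be non-empty")
    if not np.isfinite(t).all():
        raise ValueError("theta grid must be finite")
    return t


def traceline(meta: pd.DataFrame, thetas, D: float = 1.0) -> CurveSet:
    """ICCs and the TCC (expected summed score) on the grid."""
    meta = validate_item_meta(meta)
    t = _check_grid(thetas)
    a, b, g = param_arrays(meta)
    icc = three_pl_prob(t[None, :], a[:, None], b[:, None], g[:, None], D)
    return CurveSet(t, meta["id"].tolist(), icc=icc, tcc=icc.sum(axis=0))


def info(meta: pd.DataFrame, thetas, D: float = 1.0) -> CurveSet:
    """IIFs and the TIF (total Fisher information) on the grid."""
    meta = validate_item_meta(meta)
    t = _check_grid(thetas)
    a, b, g = param_arrays(meta)
    P = three_pl_prob(t[None, :], a[:, None], b[:, None], g[:, None], D)
    P = np.clip(P, 1e-12, 1 - 1e-12)
    Q = 1.0 - P
    iif = (D * a[:, None]) ** 2 * (Q / P) * ((P - g[:, None]) / (1.0 - g[:, None])) ** 2
    return CurveSet(t, meta["id"].tolist(), iif=iif, tif=iif.sum(axis=0))


def render_curves(
    curveset: CurveSet,
    selection=None,
    overlap: bool = True,
    score_curve: bool = False,
    out=None,
    csv_out=None,
    title: str | None = None,
):
    """Plot selected item curves (or the whole-test TCC/TIF) and/or export CSV.

    ``selection`` is a list of 0-based item indices; ``None`` plots the
    test-level curve.  For dichotomous items an expected-score curve equals
    the ICC, so ``score_curve`` only changes labeling.  Returns the
    matplotlib figure (or None if only CSV export was requested).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_item = curveset.icc if curveset.icc is not None else curveset.iif
    total = curveset.tcc if curveset.tcc is not None else curveset.tif
    kind = "icc" if curveset.icc is not None else "iif"
    n_items = len(curveset.item_ids)
    if selection is not None:
        selection = list(selection)
        bad = [j for j in selection if j < 0 or j >= n_items]
        if bad:
            raise IndexError(f"item index out of range: {bad}")

    if csv_out is not None:
        frame = curveset.to_frame()
        if selection is not None:
            ids = [curveset.item_ids[j] for j in selection]
            frame = frame[frame["item_or_test"].isin(ids)]
        frame.to_csv(csv_out, index=False)

    if out is None and csv_out is not None:
        return None
    fig, ax = plt.subplots(figsize=(6, 4))
    if selection is None:
        label = "TCC" if kind == "icc" else "TIF"
        ax.plot(curveset.thetas, total, label=label)
        ax.set_ylabel("expected score" if kind == "icc" else "information")
    else:
        ylab = (
            "expected score" if (score_curve or kind == "iif") else "P(correct)"
        )
        if kind == "iif":
            ylab = "information"
        for j in selection:
            ax.plot(curveset.thetas, per_item[j], label=str(curveset.item_ids[j]))
        ax.set_ylabel(ylab)
    ax.set_xlabel("theta")
    ax.legend(loc="best", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
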