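"""Expression-dependent drop-out: logistic curve fit and seeded injection.

Drop-out probability decreases with expression (lowly expressed
transcripts are more likely to be missed). The relationship is modeled as
a four-parameter logistic in log-expression; the curve is fit empirically
from the per-gene zero fraction vs. mean non-zero expression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from bpa.bpa_core import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DropoutCurve:
    """Monotone-decreasing drop-out probability vs. log expression.

    p(x) = floor + (ceiling - floor) / (1 + exp(slope * (x - midpoint)))
    """

    midpoint: float
    slope: float
    ceiling: float = 1.0
    floor: float = 0.0
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be non-negative")
        if not (0.0 <= self.floor <= 1.0 and 0.0 <= self.ceiling <= 1.0):
            raise ValueError("floor and ceiling must be probabilities")
        if self.floor > self.ceiling:
            raise ValueError("floor must not exceed ceiling")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "DropoutCurve":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def dropout_probability(curve: DropoutCurve, x) -> np.ndarray | float:
    """Evaluate the drop-out probability at log-expression x (vectorized)."""
    x = np.asarray(x, dtype=float)
    p = curve.floor + (curve.ceiling - curve.floor) / (
        1.0 + np.exp(curve.slope * (x - curve.midpoint))
    )
    return float(p) if p.ndim == 0 else p


def _logistic(x, midpoint, slope, ceiling, floor):
    return floor + (ceiling - floor) / (1.0 + np.exp(slope * (x - midpoint)))


def fit_dropout_curve(
    sc_expr: ExpressionMatrix,
    n_bins: int = 20,
) -> DropoutCurve:
    """Fit the logistic drop-out curve from observed zero fractions.

    Per gene: (mean log expression over non-zero cells, fraction of cells at
    zero). Points are aggregated into >= ``n_bins`` equal-count bins and the
    four-parameter logistic is fit by least squares; goodness of fit lands
    in ``fit_info``. All-zero genes carry no non-zero mean and are excluded.
    """
    values = sc_expr.values
    n_cells = values.shape[1]
    nonzero = values > 0
    genes_with_signal = nonzero.any(axis=1)
    if not (values == 0).any():
        raise ValueError("matrix contains no zeros; nothing to fit")
    with np.errstate(invalid="ignore"):
        mean_nonzero = np.where(
            genes_with_signal,
            values.sum(axis=1) / np.maximum(nonzero.sum(axis=1), 1),
            np.nan,
        )
    zero_frac = 1.0 - nonzero.sum(axis=1) / n_cells
    x = mean_nonzero[genes_with_signal]
    y = zero_frac[genes_with_signal]

    order = np.argsort(x)
    x, y = x[order], y[order]
    n_points = x.shape[0]
    n_bins_eff = min(n_bins, n_points)
    if n_bins_eff < 4:
        raise ValueError(f"only {n_bins_eff} usable bins; need at least 4")
    edges = np.array_split(np.arange(n_points), n_bins_eff)
    bx = np.array([x[idx].mean() for idx in edges])
    by = np.array([y[idx].mean() for idx in edges])

    trend = linregress(bx, by)
    if np.ptp(by) < 1e-3 or trend.pvalue > 0.05:
        warnings.warn("drop-out fraction nearly constant across bins; slope ~ 0")
        level = float(np.clip(by.mean(), 0.0, 1.0))
        eps = 1e-6
        return DropoutCurve(
            midpoint=float(bx.mean()),
            slope=0.0,
            ceiling=min(level + eps, 1.0),
            floor=level,
            fit_info={"flat": True, "binned_x": bx.tolist(), "binned_y": by.tolist()},
        )

    p0 = [float(np.median(bx)), 1.0, float(by.max()), float(by.min())]
    bounds = ([bx.min() - 5.0, 0.0, 0.0, 0.0], [bx.max() + 5.0, 50.0, 1.0, 1.0])
    params, _ = curve_fit(_logistic, bx, by, p0=p0, bounds=bounds, maxfev=20000)
    midpoint, slope, ceiling, floor = (float(v) for v in params)
    if floor > ceiling:
        floor, ceiling = ceiling, floor
    resid = by - _logistic(bx, midpoint, slope, ceiling, floor)
    ss_res = float((resid**2).sum())
    ss_tot = float(((by - by.mean()) ** 2).sum())
    return DropoutCurve(
        midpoint=midpoint,
        slope=slope,
        ceiling=ceiling,
        floor=floor,
        fit_info={
            "n_genes_used": int(genes_with_signal.sum()),
            "n_bins": n_bins_eff,
            "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
            "binned_x": bx.tolist(),
            "binned_y": by.tolist(),
        },
    )


def simulate_dropout(
    expr: ExpressionMatrix,
    curve: DropoutCurve,
    seed: int,
) -> tuple[ExpressionMatrix, float]:
    """Inject drop-outs into a complete (bulk-like) expression matrix.

    Each non-zero entry is independently zeroed with probability
    ``dropout_probability(curve, value)`` — the entry's own value, not the
    gene mean, drives its drop-out chance. Entries already at zero stay
    zero. Returns the new matrix and the realized overall zero fraction.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    p = dropout_probability(curve, values)
    drop = (rng.random(values.shape) < p) & (values > 0)
    values[drop] = 0.0
    realized_rate = float((values == 0).mean())
    note = expr.log_base_note + f"; simulated drop-out (seed={seed})"
    out = ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        cell_ids=list(expr.cell_ids),
        values=values,
        log_base_note=note,
    )
    return out, realized_rate
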