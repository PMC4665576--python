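"""Coverage/length/failure study for the predictive-value intervals.

The study crosses prevalences {0.05, 0.25, 0.5}, sensitivities and
specificities {0.5, 0.75, 0.85, 0.9} (48 accuracy combinations), accuracy
study sizes n0 = n1 in {50, 100, 500} and prevalence study sizes m_g in
{100, 500, 1000} — 432 cells, 10,000 replicates each by default.  Per
replicate, binomial estimates of se, sp and pi are drawn, the plug-in
predictive value and its delta-method variance are computed, all six interval
variants are constructed from the same draws, and each is scored for covering
the true predictive value.  The fixed-prevalence ("mercaldo") variants use
the same estimated pi in the point estimate but omit its variance
contribution — the setting in which treating the prevalence as known is an
(incorrect) simplification.

Replicates whose interval is undefined (boundary point estimate, so the
logistic transform and the t degrees of freedom break down) are excluded
from that method's coverage/length denominator and tallied as failures.

Summary tables average per-cell results with one parameter held fixed
("marginal" rows) and over all cells ("Overall").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import summary_accuracy
from .datatypes import INTERVAL_METHODS, IntervalSet
from .io import read_prevalence
from .predictive import (
    _component_df,
    _grad,
    _pv,
    _satterthwaite,
    confidence_interval,
    pv_covariance,
)

__all__ = [
    "SimulationDesign",
    "SimulationTable",
    "run_coverage_study",
    "mercaldo_interval",
]

_MARGINAL_PARAMS = ("pi", "se", "sp", "mg", "n")


@dataclass
class SimulationDesign:
    """Fully-crossed design of the interval coverage study."""

    pi_grid: tuple = (0.05, 0.25, 0.5)
    se_grid: tuple = (0.5, 0.75, 0.85, 0.9)
    sp_grid: tuple = (0.5, 0.75, 0.85, 0.9)
    n_grid: tuple = (50, 100, 500)
    mg_grid: tuple = (100, 500, 1000)
    reps: int = 10_000
    alpha: float = 0.05
    seed: int | None = None
    sides: tuple = ("ppv", "npv")

    def __post_init__(self) -> None:
        for name in ("pi_grid", "se_grid", "sp_grid"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if np.any((vals <= 0) | (vals >= 1)):
                raise ValueError(f"{name} values must lie inside (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.sides = tuple(s.lower() for s in self.sides)
        if any(s not in ("ppv", "npv") for s in self.sides):
            raise ValueError("sides must be 'ppv' and/or 'npv'")

    def cells(self) -> list[tuple]:
        """Deterministic cell order: (pi, se, sp, n, mg) fully crossed."""
        return list(
            itertools.product(
                self.pi_grid, self.se_grid, self.sp_grid, self.n_grid, self.mg_grid
            )
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "SimulationDesign":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(cfg) - set(known)
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = {k: (tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in cfg.items()}
        return cls(**kwargs)


@dataclass
class SimulationTable:
    """Per-cell results of :func:`run_coverage_study` plus summaries."""

    cells: pd.DataFrame
    design: SimulationDesign = field(repr=False, default=None)  # type: ignore[assignment]

    def overall(self, metric: str, side: str = "ppv") -> pd.Series:
        """Mean of the per-cell metric over all cells, per method."""
        df = self.cells[self.cells["side"] == side]
        return df.groupby("method")[metric].mean()

    def marginal_table(self, metric: str, side: str = "ppv") -> pd.DataFrame:
        """One row per fixed parameter value plus Overall; columns = methods."""
        df = self.cells[self.cells["side"] == side]
        rows = []
        for param in _MARGINAL_PARAMS:
            for value in sorted(df[param].unique()):
                sub = df[df[param] == value]
                row = sub.groupby("method")[metric].mean()
                row.name = f"{param}={value:g}"
                rows.append(row)
        ov = self.overall(metric, side)
        ov.name = "Overall"
        rows.append(ov)
        out = pd.DataFrame(rows)
        out.index.name = "fixed_parameter"
        return out[list(INTERVAL_METHODS)]

    def to_csv(self, outdir, prefix: str = "coverage_study") -> list[str]:
        """Write the long per-cell table and the marginal summaries."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        p = outdir / f"{prefix}_cells.csv"
        self.cells.to_csv(p, index=False)
        written.append(str(p))
        for side in sorted(self.cells["side"].unique()):
            for metric in ("coverage", "length", "failure"):
                p = outdir / f"{prefix}_{side}_{metric}.csv"
                self.marginal_table(metric, side).to_csv(p)
                written.append(str(p))
        return written


def _score(p_true, lo, up, valid) -> tuple[float, float, float]:
    n_ok = int(valid.sum())
    if n_ok == 0:
        cover = np.nan
        length = np.nan
    else:
        cover = float(np.mean((lo[valid] <= p_true) & (p_true <= up[valid])))
        length = float(np.mean(up[valid] - lo[valid]))
    return cover, length, 1.0 - n_ok / valid.size


def _logit_interval(p, sd, q):
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = sd / (p * (1 - p))
        eta = np.log(p / (1 - p))
        lo = 1.0 / (1.0 + np.exp(-(eta - q * scale)))
        up = 1.0 / (1.0 + np.exp(-(eta + q * scale)))
    return lo, up


def _simulate_cell(rng, pi, se, sp, n, mg, reps, alpha, sides):
    z = stats.norm.ppf(1 - alpha / 2)
    se_hat = rng.binomial(n, se, reps) / n
    sp_hat = rng.binomial(n, sp, reps) / n
    pi_hat = rng.binomial(mg, pi, reps) / mg
    rows = []
    for side in sides:
        p_true = float(_pv(se, sp, pi, side))
        p = _pv(se_hat, sp_hat, pi_hat, side)
        dse, dsp, dpi = _grad(se_hat, sp_hat, pi_hat, side)
        c_se = dse**2 * se_hat * (1 - se_hat) / n
        c_sp = dsp**2 * sp_hat * (1 - sp_hat) / n
        c_pi = dpi**2 * pi_hat * (1 - pi_hat) / mg
        v = c_se + c_sp + c_pi
        v_fix = c_se + c_sp
        sd = np.sqrt(v)
        sd_fix = np.sqrt(v_fix)

        defined = np.isfinite(p)
        interior = defined & (p > 0) & (p < 1)
        ok_t = interior & (v > 0)
        nu = _satterthwaite(
            c_se,
            c_sp,
            c_pi,
            _component_df(se_hat, n),
            _component_df(sp_hat, n),
            _component_df(pi_hat, mg),
        )
        ok_t &= ~np.isnan(nu)
        tq = np.full(reps, np.nan)
        if ok_t.any():
            tq[ok_t] = stats.t.ppf(1 - alpha / 2, nu[ok_t])

        lo_ln, up_ln = _logit_interval(p, sd, z)
        lo_lt, up_lt = _logit_interval(p, sd, tq)
        lo_ml, up_ml = _logit_interval(p, sd_fix, z)
        per_method = {
            "additive-normal": (p - z * sd, p + z * sd, defined),
            "additive-t": (p - tq * sd, p + tq * sd, ok_t),
            "logistic-normal": (lo_ln, up_ln, interior),
            "logistic-t": (lo_lt, up_lt, ok_t),
            "mercaldo-additive": (p - z * sd_fix, p + z * sd_fix, defined),
            "mercaldo-logistic": (lo_ml, up_ml, interior),
        }
        for method, (lo, up, valid) in per_method.items():
            cover, length, failure = _score(p_true, lo, up, valid)
            rows.append(
                {
                    "pi": pi,
                    "se": se,
                    "sp": sp,
                    "n": n,
                    "mg": mg,
                    "side": side,
                    "method": method,
                    "p_true": p_true,
                    "coverage": cover,
                    "length": length,
                    "failure": failure,
                }
            )
    return rows


def run_coverage_study(design: SimulationDesign) -> SimulationTable:
    """Run the full crossed coverage study; seeded and vectorised.

    Each cell gets an independent child seed spawned from ``design.seed`` in
    the deterministic cell order, so results are reproducible regardless of
    any parallel scheduling of cells.
    """
    cells = design.cells()
    children = np.random.SeedSequence(design.seed).spawn(len(cells))
    rows = []
    for (pi, se, sp, n, mg), child in zip(cells, children):
        rng = np.random.default_rng(child)
        rows.extend(
            _simulate_cell(
                rng, pi, se, sp, int(n), int(mg), design.reps, design.alpha, design.sides
            )
        )
    return SimulationTable(cells=pd.DataFrame(rows), design=design)


def mercaldo_interval(
    se: float,
    sp: float,
    pi: float,
    n1: int,
    n0: int,
    method: str = "additive",
    alpha: float = 0.05,
    side: str = "ppv",
) -> IntervalSet:
    """Fixed-prevalence (known-pi) interval for a single modality.

    Identical to :func:`facpv.predictive.confidence_interval` with the
    prevalence supplied as a fixed constant, i.e. the prevalence variance
    contribution is zero.
    """
    mapping = {
        "additive": "mercaldo-additive",
        "logistic": "mercaldo-logistic",
        "mercaldo-additive": "mercaldo-additive",
        "mercaldo-logistic": "mercaldo-logistic",
    }
    if method not in mapping:
        raise ValueError(f"method must be 'additive' or 'logistic', got {method!r}")
    acc = summary_accuracy([se], [sp], n1, n0)
    prev = read_prevalence([("fixed", pi, True)])
    pv = pv_covariance(acc, prev, "fixed", side=side)
    return confidence_interval(pv, method=mapping[method], alpha=alpha)
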