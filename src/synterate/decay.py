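"""The saturating gene-order decay model and its statistics.

Gene order conservation between two genomes decays with their 16S
divergence x toward a floor:

    GOC(x) = f_i + (1 - f_i) * p**x

``f_i`` in [0, 1) is the saturation level — the portion of ortholog
pairs between which breakpoints are rarely introduced — and ``p`` in
(0, 1] governs the rate of gene-order loss per unit divergence (the
smaller p, the steeper the decline, the faster the rearrangement rate).

The module is organized statsmodels-style: :class:`GeneOrderDecay` is
built from a table of genome-pair points and its ``fit`` returns a
:class:`GeneOrderDecayResults` carrying the estimates, BCa bootstrap
confidence intervals, per-species genome-stability indices, the
category comparisons (R-R / R-N / N-N), and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .stats import bca_from_samples, fisher_pitman_test

__all__ = [
    "predict_goc",
    "DivergencePoint",
    "RateModelParams",
    "GeneOrderDecay",
    "GeneOrderDecayResults",
    "fit_goc_model",
    "fit_categories",
    "stability_indices",
    "residual_category_test",
]

POINT_COLUMNS = ["species_a", "species_b", "x", "goc", "category"]
CATEGORIES = ("RR", "RN", "NN")
_EPS = 1e-9


def predict_goc(f_i: float, p: float, x) -> np.ndarray | float:
    """Model-predicted GOC at divergence ``x``: f_i + (1-f_i)·p^x."""
    x = np.asarray(x, dtype=float)
    out = f_i + (1.0 - f_i) * np.power(p, x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DivergencePoint:
    """One genome pair: divergence x, GOC_250 and resistance category."""

    species_a: str
    species_b: str
    x: float
    goc: float
    category: str

    def __post_init__(self):
        if self.x < 0:
            raise ValueError("divergence must be nonnegative")
        if not 0 <= self.goc <= 1:
            raise ValueError("GOC must lie in [0, 1]")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")


@dataclass(frozen=True)
class RateModelParams:
    """Fitted decay parameters with optional confidence intervals."""

    f_i: float
    p: float
    sse: float
    fit_mode: str = "free"                      # "free" | "fixed_f_i"
    ci_f_i: Optional[tuple[float, float]] = None
    ci_p: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if not 0 <= self.f_i < 1:
            raise ValueError("f_i must be in [0, 1)")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.sse < 0:
            raise ValueError("sse must be nonnegative")

    def predict(self, x):
        return predict_goc(self.f_i, self.p, x)


# ---------------------------------------------------------------------------
# least-squares fitting (Nelder–Mead on transformed parameters)
# ---------------------------------------------------------------------------

def _sse(x: np.ndarray, y: np.ndarray, f_i: float, p: float) -> float:
    return float(np.sum((y - (f_i + (1.0 - f_i) * np.power(p, x))) ** 2))


def _fit_arrays(
    x: np.ndarray,
    y: np.ndarray,
    fixed_f_i: Optional[float] = None,
    start: Optional[tuple[float, float]] = None,
    fast: bool = False,
) -> tuple[float, float, float]:
    """Minimize the sum of squares over (f_i, p), or p alone.

    Optimization runs on unconstrained coordinates (logit f_i, logit p)
    with Nelder–Mead.  Multi-start grid: f_i0 ∈ {~0, min(goc)/2,
    min(goc)} × p0 ∈ {1e-4, 1e-2}; ``start`` (used by bootstrap refits)
    replaces the grid with a single warm start.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0:
        raise ValueError("no points to fit")
    if fixed_f_i is None and (x.size < 2 or np.ptp(x) == 0):
        raise ValueError("need >= 2 points with distinct x to fit both "
                         "parameters")

    opts = {"xatol": 1e-6 if fast else 1e-9,
            "fatol": 1e-10 if fast else 1e-14,
            "maxiter": 400 if fast else 4000}

    def clip01(v: float) -> float:
        return float(np.clip(v, 1e-6, 1 - 1e-6))

    if fixed_f_i is not None:
        fi = float(fixed_f_i)

        def obj1(theta):
            return _sse(x, y, fi, expit(theta[0]))

        starts = ([logit(clip01(start[1]))] if start is not None
                  else [logit(1e-4), logit(1e-2), logit(0.5)])
        best = None
        for s in starts:
            res = minimize(obj1, np.array([s]), method="Nelder-Mead",
                           options=opts)
            if best is None or res.fun < best.fun:
                best = res
        p = clip_p(expit(best.x[0]))
        return fi, p, _sse(x, y, fi, p)

    def obj(theta):
        return _sse(x, y, expit(theta[0]), expit(theta[1]))

    ymin = float(np.min(y))
    if start is not None:
        grid = [(clip01(start[0]), clip01(start[1]))]
    else:
        grid = [(clip01(f0), p0)
                for f0 in (1e-3, ymin / 2, ymin)
                for p0 in (1e-4, 1e-2)]
    best = None
    for f0, p0 in grid:
        res = minimize(obj, np.array([logit(f0), logit(clip01(p0))]),
                       method="Nelder-Mead", options=opts)
        if best is None or res.fun < best.fun:
            best = res
    fi = float(np.clip(expit(best.x[0]), 0.0, 1 - _EPS))
    p = clip_p(expit(best.x[1]))
    return fi, p, _sse(x, y, fi, p)


def clip_p(p: float) -> float:
    return float(np.clip(p, _EPS, 1.0))


def _profile_fit_batch(
    X: np.ndarray,
    Y: np.ndarray,
    fixed_f_i: Optional[float] = None,
    n_iter: int = 70,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares refits for many resampled point sets at once.

    Exploits that the model is linear in f_i at fixed p:
    GOC = p^x + f_i (1 - p^x), so the optimal f_i has a closed form
    (clipped to [0, 1)) and only p needs a search — a golden-section
    over log p, run vectorized across the rows of ``X`` / ``Y``.  Used
    by the bootstrap/jackknife, where refit cost dominates; the
    headline fit uses multi-start Nelder–Mead on the same objective.
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    lo = np.full(X.shape[0], np.log(_EPS))
    hi = np.zeros(X.shape[0])

    def sse_at(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = np.exp(u[:, None] * X)          # p^x per row
        one_w = 1.0 - w
        if fixed_f_i is None:
            denom = np.sum(one_w ** 2, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                fi = np.sum((Y - w) * one_w, axis=1) / denom
            fi = np.clip(np.nan_to_num(fi), 0.0, 1.0 - _EPS)
        else:
            fi = np.full(X.shape[0], fixed_f_i)
        resid = Y - (w + fi[:, None] * one_w)
        return np.sum(resid ** 2, axis=1), fi

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    for _ in range(n_iter):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, _ = sse_at(c)
        fd, _ = sse_at(d)
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    u = (a + b) / 2.0
    _, fi = sse_at(u)
    return fi, np.exp(u)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class GeneOrderDecay:
    """Decay model for a table of genome-pair points.

    Parameters
    ----------
    points :
        DataFrame with columns ``species_a, species_b, x, goc,
        category`` (category in {"RR", "RN", "NN"}), or a sequence of
        :class:`DivergencePoint`.
    """

    def __init__(self, points):
        if isinstance(points, pd.DataFrame):
            missing = set(POINT_COLUMNS) - set(points.columns)
            if missing:
                raise ValueError(f"points table missing columns {missing}")
            df = points[POINT_COLUMNS].reset_index(drop=True).copy()
        else:
            df = pd.DataFrame([vars(p) for p in points], columns=POINT_COLUMNS)
        if len(df) == 0:
            raise ValueError("no points")
        bad = ~df["category"].isin(CATEGORIES)
        if bad.any():
            raise ValueError(f"invalid categories: {df.loc[bad, 'category'].unique()}")
        if (df["x"] < 0).any() or (df["goc"] < 0).any() or (df["goc"] > 1).any():
            raise ValueError("x must be >= 0 and goc within [0, 1]")
        self.points = df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneOrderDecay":
        return cls(df)

    @property
    def x(self) -> np.ndarray:
        return self.points["x"].to_numpy(float)

    @property
    def goc(self) -> np.ndarray:
        return self.points["goc"].to_numpy(float)

    def fit(self, fixed_f_i: Optional[float] = None) -> "GeneOrderDecayResults":
        """Least-squares fit of (f_i, p) — or p alone when ``fixed_f_i``
        is given — by multi-start Nelder–Mead."""
        fi, p, sse = _fit_arrays(self.x, self.goc, fixed_f_i=fixed_f_i)
        params = RateModelParams(
            f_i=fi, p=p, sse=sse,
            fit_mode="free" if fixed_f_i is None else "fixed_f_i",
        )
        return GeneOrderDecayResults(self, params, fixed_f_i=fixed_f_i)

    def fit_categories(
        self, mode: str = "independent",
    ) -> dict[str, "GeneOrderDecayResults"]:
        """Per-category fits of the R-R / R-N / N-N point classes.

        ``independent`` fits (f_i, p) in every category (six free
        parameters); ``fixed_f_i`` first fits the pooled points, then
        refits only p per category with f_i pinned to the pooled
        estimate (the four-parameter scheme that makes the category
        rates directly comparable).
        """
        if mode not in ("independent", "fixed_f_i"):
            raise ValueError("mode must be 'independent' or 'fixed_f_i'")
        present = [c for c in CATEGORIES
                   if (self.points["category"] == c).any()]
        if not present:
            raise ValueError("all categories empty")
        pinned = None
        out: dict[str, GeneOrderDecayResults] = {}
        if mode == "fixed_f_i":
            pinned = self.fit().params.f_i
        for cat in present:
            sub = GeneOrderDecay(self.points[self.points["category"] == cat])
            out[cat] = sub.fit(fixed_f_i=pinned)
        return out


class GeneOrderDecayResults:
    """Fit results: parameters, residuals, intervals, and comparisons."""

    def __init__(self, model: GeneOrderDecay, params: RateModelParams,
                 fixed_f_i: Optional[float] = None):
        self.model = model
        self.params = params
        self._fixed_f_i = fixed_f_i

    # -- basic accessors ----------------------------------------------
    @property
    def f_i(self) -> float:
        return self.params.f_i

    @property
    def p(self) -> float:
        return self.params.p

    @property
    def sse(self) -> float:
        return self.params.sse

    def predict(self, x) -> np.ndarray | float:
        return self.params.predict(x)

    @property
    def resid(self) -> np.ndarray:
        """Observed − predicted GOC per point."""
        return self.model.goc - self.predict(self.model.x)

    # -- bootstrap -----------------------------------------------------
    def bootstrap_ci(
        self,
        n_boot: int = 10_000,
        alpha: float = 0.05,
        rng: np.random.Generator | int | None = None,
        max_failure_fraction: float = 0.05,
    ) -> "GeneOrderDecayResults":
        """Attach BCa confidence intervals from ``n_boot`` resamples.

        Points are resampled with replacement and the model refit on
        each resample (warm-started at the point estimate); one set of
        resamples feeds the intervals of both parameters.  Returns a new
        results object with ``ci_f_i`` / ``ci_p`` filled in.
        """
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        x, y = self.model.x, self.model.goc
        n = x.size
        if n < 3:
            raise ValueError("need at least 3 points to bootstrap")
        fixed = self._fixed_f_i

        idx = rng.integers(0, n, size=(n_boot, n))
        boot_fi, boot_p = _profile_fit_batch(x[idx], y[idx], fixed_f_i=fixed)
        boot = np.column_stack([boot_fi, boot_p])
        jk_idx = np.array([np.delete(np.arange(n), i) for i in range(n)])
        jack_fi, jack_p = _profile_fit_batch(x[jk_idx], y[jk_idx],
                                             fixed_f_i=fixed)
        jack = np.column_stack([jack_fi, jack_p])
        failed = np.isnan(boot[:, 1]).mean()
        if failed > max_failure_fraction:
            raise RuntimeError(f"{failed:.1%} of bootstrap refits failed")

        ci_f = bca_from_samples(self.f_i, boot[:, 0], jack[:, 0], alpha) \
            if fixed is None else (self.f_i, self.f_i)
        ci_p = bca_from_samples(self.p, boot[:, 1], jack[:, 1], alpha)
        params = RateModelParams(
            f_i=self.f_i, p=self.p, sse=self.sse,
            fit_mode=self.params.fit_mode, ci_f_i=ci_f, ci_p=ci_p,
        )
        return GeneOrderDecayResults(self.model, params, fixed_f_i=fixed)

    # -- stability indices ----------------------------------------------
    def stability_indices(self) -> pd.DataFrame:
        """Mean residual per species over the points it participates in.

        A positive index means the species' gene order is better
        conserved than the model predicts at its divergences (0.1 =
        10% of the expected breakpoints are instead preserved).
        """
        res = self.resid
        pts = self.model.points
        rows = {}
        for col in ("species_a", "species_b"):
            for sp, r in zip(pts[col], res):
                rows.setdefault(sp, []).append(r)
        return pd.DataFrame(
            [{"species": sp, "value": float(np.mean(v)), "n_pairs": len(v)}
             for sp, v in sorted(rows.items())]
        )

    def stability_comparison(
        self,
        labels: Mapping[str, str],
        rng: np.random.Generator | int | None = None,
    ) -> float:
        """Fisher–Pitman p-value comparing stability indices of
        resistant (R) vs nonresistant (N) species."""
        idx = self.stability_indices()
        r = idx.loc[idx["species"].map(labels) == "R", "value"].to_numpy()
        nn = idx.loc[idx["species"].map(labels) == "N", "value"].to_numpy()
        return fisher_pitman_test(r, nn, rng=rng)

    def residual_category_test(
        self,
        rng: np.random.Generator | int | None = None,
        mode: str = "auto",
    ) -> float:
        """Fisher–Pitman p-value comparing residuals of the pooled
        R-R + R-N points against the N-N points, relative to this fit."""
        cats = self.model.points["category"].to_numpy()
        res = self.resid
        with_r = res[(cats == "RR") | (cats == "RN")]
        without = res[cats == "NN"]
        if with_r.size == 0 or without.size == 0:
            raise ValueError("both point categories must be nonempty")
        return fisher_pitman_test(with_r, without, rng=rng, mode=mode)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        p = self.params
        lines = [
            "Gene-order decay model: GOC(x) = f_i + (1 - f_i) * p**x",
            f"  points:   {len(self.model.points)}",
            f"  fit mode: {p.fit_mode}",
            f"  f_i  = {p.f_i:.6f}"
            + (f"   95% CI [{p.ci_f_i[0]:.6f}, {p.ci_f_i[1]:.6f}]" if p.ci_f_i else ""),
            f"  p    = {p.p:.6g}"
            + (f"   95% CI [{p.ci_p[0]:.6g}, {p.ci_p[1]:.6g}]" if p.ci_p else ""),
            f"  SSE  = {p.sse:.6g}",
        ]
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot(self, ax=None, color="C0", label=None, show_points=True):
        """GOC vs divergence with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if show_points:
            ax.scatter(self.model.x, self.model.goc, s=12, alpha=0.6,
                       color=color)
        xs = np.linspace(0, max(self.model.x.max(), 1e-6), 200)
        ax.plot(xs, self.predict(xs), color=color, label=label)
        ax.set_xlabel("16S distance (substitutions/site)")
        ax.set_ylabel("GOC$_{250}$")
        ax.set_ylim(0, 1.02)
        if label:
            ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_goc_model(points, fixed_f_i: Optional[float] = None) -> RateModelParams:
    return GeneOrderDecay(points).fit(fixed_f_i=fixed_f_i).params


def fit_categories(points, mode: str = "independent") -> dict[str, RateModelParams]:
    fits = GeneOrderDecay(points).fit_categories(mode=mode)
    return {cat: r.params for cat, r in fits.items()}


def stability_indices(points, params: RateModelParams) -> pd.DataFrame:
    model = GeneOrderDecay(points)
    return GeneOrderDecayResults(model, params).stability_indices()


def residual_category_test(points, params: RateModelParams,
                           rng=None, mode: str = "auto") -> float:
    model = GeneOrderDecay(points)
    return GeneOrderDecayResults(model, params).residual_category_test(
        rng=rng, mode=mode)
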