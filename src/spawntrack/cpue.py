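"""Delta-lognormal (hurdle) CPUE standardization with KDE region classification.

Zero-inflated haul-seine catch rates are standardized in two parts: a binomial
(logit) sub-model for the probability a haul catches any adults, and a
lognormal sub-model for the mean catch of a successful haul, each selected by
forward stepwise AIC with year always retained. Year-specific marginal means
(balanced over the other included factor levels, on the link scales) are
combined by Monte Carlo: Student-t realizations around each sub-model's
marginal mean are back-transformed and multiplied, giving a distribution of
the standardized catch rate per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import special


def bin_covariate(values, width: float = 2.5) -> pd.Categorical:
    """Half-open bins [k*width, (k+1)*width) labelled by bin midpoints."""
    if width <= 0:
        raise ValueError("width must be positive")
    v = np.asarray(values, float)
    idx = np.floor(v / width).astype(int)
    mids = (idx + 0.5) * width
    cats = np.unique(mids)
    return pd.Categorical(mids, categories=cats, ordered=True)


def _isotropic_kde(points: np.ndarray, weights: np.ndarray, bandwidth: float):
    """Weighted 2-D Gaussian KDE with a fixed isotropic bandwidth.

    The bandwidth is an absolute length in the survey's coordinate units,
    which is what a grid-based contour classification needs; covariance-scaled
    bandwidths (as in scipy's estimator) would couple the smoothing scale to
    the survey footprint and fail on collinear point sets.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    w = weights / weights.sum()
    inv2h2 = 1.0 / (2.0 * bandwidth ** 2)
    norm = 1.0 / (2.0 * np.pi * bandwidth ** 2)

    def evaluate(query: np.ndarray) -> np.ndarray:
        out = np.empty(len(query))
        for i0 in range(0, len(query), 2048):  # chunked to bound memory
            q = query[i0:i0 + 2048]
            d2 = ((q[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
            out[i0:i0 + 2048] = norm * (np.exp(-d2 * inv2h2) @ w)
        return out

    return evaluate


@dataclass
class RegionClassification:
    labels: pd.Series  # grid_id -> bool (concentrated)
    kde_bandwidth: float
    contour_level: float
    threshold: float
    density: pd.DataFrame  # gridded density surface (x, y, density)

    def region_of(self, grid_ids) -> np.ndarray:
        return np.where(self.labels.reindex(grid_ids).fillna(False).to_numpy(),
                        "concentrated", "not")


def kde_region_classify(hauls: pd.DataFrame, bandwidth: float = 2.0,
                        contour_level: float = 0.5,
                        weighted: bool = True) -> RegionClassification:
    """Label survey grids concentrated/not via a CPUE-weighted Gaussian KDE.

    The 2-D KDE is taken over haul locations weighted by nominal CPUE (or over
    positive-catch locations only with ``weighted=False``); grids whose centers
    fall inside the density contour enclosing ``contour_level`` of the total
    mass are labelled concentrated. ``bandwidth`` is an absolute isotropic
    smoothing scale in the survey's coordinate units (default: two grid widths).
    """
    cpue = hauls["adult_count"].to_numpy(float)
    if not (cpue > 0).any():
        raise ValueError("all-zero CPUE: no positive hauls to locate")
    if weighted:
        pts = hauls[["x", "y"]].to_numpy(float)
        w = cpue
    else:
        pts = hauls.loc[cpue > 0, ["x", "y"]].to_numpy(float)
        w = np.ones(len(pts))
    kde = _isotropic_kde(pts, w, bandwidth)

    centers = hauls.groupby("grid_id")[["x", "y"]].first()
    pad = 2.0 * bandwidth
    xs = np.linspace(centers["x"].min() - pad, centers["x"].max() + pad, 80)
    ys = np.linspace(centers["y"].min() - pad, centers["y"].max() + pad, 80)
    gx, gy = np.meshgrid(xs, ys)
    dens = kde(np.column_stack([gx.ravel(), gy.ravel()]))
    order = np.sort(dens)[::-1]
    cum = np.cumsum(order) / order.sum()
    k = int(np.searchsorted(cum, min(contour_level, 1.0 - 1e-12)))
    threshold = order[min(k, len(order) - 1)]

    grid_dens = kde(centers.to_numpy(float))
    labels = pd.Series(grid_dens >= threshold, index=centers.index, name="concentrated")
    density = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(), "density": dens})
    return RegionClassification(labels=labels, kde_bandwidth=bandwidth,
                                contour_level=contour_level, threshold=float(threshold),
                                density=density)


# ---------------------------------------------------------------------------
# Hurdle model
# ---------------------------------------------------------------------------

#: candidate model terms in patsy form; month and season are aliased by
#: construction, so whichever enters first blocks the other.
CANDIDATE_TERMS = {
    "month": "C(month)",
    "region": "C(region)",
    "season": "C(season)",
    "region_x_season": "C(region):C(season)",
    "temp_bin": "C(temp_bin)",
    "sal_bin": "C(sal_bin)",
    "vegetation": "C(vegetation)",
}
_ALIASED = {"month": {"season"}, "season": {"month"}}
_HIERARCHY = {"region_x_season": {"region", "season"}}


class HurdleCPUEModel:
    """Two-part binomial / lognormal catch-rate model with forward-AIC selection.

    Parameters
    ----------
    hauls : DataFrame
        Survey table (from :func:`spawntrack.io.read_hauls` or the survey
        simulator) with a ``region`` column; :meth:`from_survey` attaches one
        from a KDE classification.
    candidates : sequence of str
        Candidate terms offered to forward selection (keys of
        ``CANDIDATE_TERMS``); year is always retained in both sub-models.
    """

    def __init__(self, hauls: pd.DataFrame, candidates=tuple(CANDIDATE_TERMS),
                 temp_width: float = 2.5, sal_width: float = 2.5):
        unknown = set(candidates) - set(CANDIDATE_TERMS)
        if unknown:
            raise ValueError(f"unknown candidate terms: {sorted(unknown)}")
        if hauls["year"].nunique() < 2:
            raise ValueError("need >= 2 years for an annual index")
        df = hauls.copy()
        df["present"] = (df["adult_count"] > 0).astype(int)
        if df["present"].min() == df["present"].max():
            raise ValueError("hauls must include both zero and positive catches")
        if "temp_bin" not in df.columns and "temperature_c" in df.columns:
            df["temp_bin"] = bin_covariate(df["temperature_c"], temp_width)
        if "sal_bin" not in df.columns and "salinity_ppt" in df.columns:
            df["sal_bin"] = bin_covariate(df["salinity_ppt"], sal_width)
        if "vegetation" not in df.columns and "bottom_vegetation" in df.columns:
            df["vegetation"] = df["bottom_vegetation"].astype(bool)
        self.data = df
        self.positives = df[df["present"] == 1].assign(
            log_count=lambda d: np.log(d["adult_count"].astype(float)))
        self.candidates = tuple(candidates)

    @classmethod
    def from_survey(cls, hauls: pd.DataFrame, bandwidth: float = 2.0,
                    contour_level: float = 0.5, **kwargs) -> "HurdleCPUEModel":
        region = kde_region_classify(hauls, bandwidth, contour_level)
        df = hauls.copy()
        df["region"] = region.region_of(df["grid_id"])
        model = cls(df, **kwargs)
        model.region_classification = region
        return model

    # -- forward selection ----------------------------------------------------

    def _fit_one(self, response: str, terms: list[str], data: pd.DataFrame,
                 binomial: bool):
        rhs = " + ".join(["C(year)"] + [CANDIDATE_TERMS[t] for t in terms])
        formula = f"{response} ~ {rhs}"
        if binomial:
            return smf.glm(formula, data=data, family=sm.families.Binomial()).fit()
        return smf.ols(formula, data=data).fit()

    def _forward(self, response: str, data: pd.DataFrame, binomial: bool):
        selected: list[str] = []
        current = self._fit_one(response, selected, data, binomial)
        remaining = list(self.candidates)
        trace = [("year", current.aic)]
        while remaining:
            trials = []
            for term in remaining:
                if not _HIERARCHY.get(term, set()) <= set(selected):
                    continue
                if _ALIASED.get(term, set()) & set(selected):
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cand = self._fit_one(response, selected + [term], data, binomial)
                except Exception as err:  # separation / singular design
                    warnings.warn(f"dropping candidate {term!r}: {err}")
                    remaining.remove(term)
                    continue
                if np.isfinite(cand.aic):
                    trials.append((cand.aic, term, cand))
            if not trials:
                break
            best_aic, best_term, best_fit = min(trials, key=lambda t: t[0])
            if best_aic < current.aic:
                selected.append(best_term)
                remaining.remove(best_term)
                current = best_fit
                trace.append((best_term, best_aic))
            else:
                break
        return current, selected, trace

    def fit(self) -> "HurdleCPUEResults":
        binom, binom_terms, binom_trace = self._forward("present", self.data, True)
        logn, logn_terms, logn_trace = self._forward("log_count", self.positives, False)
        return HurdleCPUEResults(self, binom, binom_terms, binom_trace,
                                 logn, logn_terms, logn_trace)


def marginal_means(result, by: str = "year") -> pd.DataFrame:
    """Per-level marginal means on the link scale over a balanced factor grid.

    For each level of ``by``, the linear predictor is averaged over the
    Cartesian product of the other included factors' observed levels with
    equal weight per combination; the SE comes from the coefficient
    covariance and df is the residual df of the sub-model.
    """
    design_info = result.model.data.design_info
    data = result.model.data.frame
    factors = []
    for name in design_info.term_names:
        if name == "Intercept":
            continue
        for tok in name.split(":"):
            col = tok[2:-1] if tok.startswith("C(") else tok
            if col != by and col not in [f for f, _ in factors]:
                factors.append((col, sorted(data[col].dropna().unique())))
    rows = []
    for level in sorted(data[by].dropna().unique()):
        combos = pd.DataFrame(
            [dict(zip([by] + [f for f, _ in factors], (level,) + combo))
             for combo in product(*(lv for _, lv in factors))]
        ) if factors else pd.DataFrame({by: [level]})
        (X,) = patsy.build_design_matrices([design_info], combos)
        c = np.asarray(X).mean(axis=0)
        est = float(c @ result.params)
        se = float(np.sqrt(c @ result.cov_params() @ c))
        rows.append({by: level, "estimate": est, "se": se,
                     "df": float(result.df_resid)})
    return pd.DataFrame(rows)


@dataclass
class StandardizedIndex:
    """Per-year Monte-Carlo distributions of the standardized catch rate."""

    draws: pd.DataFrame  # n_draws x years

    def summary(self) -> pd.DataFrame:
        q = self.draws.quantile([0.025, 0.5, 0.975])
        return pd.DataFrame({
            "mean": self.draws.mean(), "median": q.loc[0.5],
            "q2.5": q.loc[0.025], "q97.5": q.loc[0.975],
        })


def combine_monte_carlo(binomial_mm: pd.DataFrame, lognormal_mm: pd.DataFrame,
                        sigma2: float, n_draws: int = 10000, seed: int = 0,
                        bias_correct: bool = True, df_cap: float = 200.0,
                        by: str = "year") -> StandardizedIndex:
    """Monte-Carlo product of the back-transformed sub-model marginal means.

    Per year, ``n_draws`` Student-t realizations are drawn around each
    sub-model's marginal mean with its SE and residual df (capped at
    ``df_cap``); the presence draw is inverse-logit transformed, the positive
    draw exponentiated with the lognormal half-variance correction
    exp(t + sigma^2/2), and the index draw is their product.
    """
    by_b = set(binomial_mm[by])
    by_l = set(lognormal_mm[by])
    if by_b != by_l:
        raise ValueError(f"mismatched year sets: {sorted(by_b ^ by_l)}")
    rng = np.random.default_rng(seed)
    bm = binomial_mm.set_index(by).sort_index()
    lm = lognormal_mm.set_index(by).sort_index()
    out = {}
    for level in bm.index:
        df_b = min(bm.at[level, "df"], df_cap)
        df_l = min(lm.at[level, "df"], df_cap)
        tb = bm.at[level, "estimate"] + bm.at[level, "se"] * rng.standard_t(df_b, n_draws)
        tl = lm.at[level, "estimate"] + lm.at[level, "se"] * rng.standard_t(df_l, n_draws)
        corr = sigma2 / 2.0 if bias_correct else 0.0
        out[level] = special.expit(tb) * np.exp(tl + corr)
    return StandardizedIndex(draws=pd.DataFrame(out))


class HurdleCPUEResults:
    """Fitted hurdle model: selected sub-models, AIC traces, index construction."""

    def __init__(self, model: HurdleCPUEModel, binomial_res, binomial_terms,
                 binomial_trace, lognormal_res, lognormal_terms, lognormal_trace):
        self.model = model
        self.binomial = binomial_res
        self.lognormal = lognormal_res
        self.binomial_terms = ["year"] + binomial_terms
        self.lognormal_terms = ["year"] + lognormal_terms
        self.binomial_trace = binomial_trace
        self.lognormal_trace = lognormal_trace

    @property
    def sigma2(self) -> float:
        """Residual variance of the lognormal sub-model (log scale)."""
        return float(self.lognormal.scale)

    def marginal_means(self, submodel: str = "binomial", by: str = "year") -> pd.DataFrame:
        res = self.binomial if submodel == "binomial" else self.lognormal
        return marginal_means(res, by=by)

    def standardized_index(self, n_draws: int = 10000, seed: int = 0,
                           bias_correct: bool = True) -> StandardizedIndex:
        return combine_monte_carlo(self.marginal_means("binomial"),
                                   self.marginal_means("lognormal"),
                                   self.sigma2, n_draws=n_draws, seed=seed,
                                   bias_correct=bias_correct)

    def summary(self) -> str:
        lines = ["Two-part (delta-lognormal) CPUE standardization",
                 f"  hauls: {len(self.model.data)} "
                 f"({len(self.model.positives)} positive)"]
        for name, res, terms, trace in (
                ("presence (binomial, logit)", self.binomial, self.binomial_terms,
                 self.binomial_trace),
                ("positive catch (lognormal)", self.lognormal, self.lognormal_terms,
                 self.lognormal_trace)):
            lines.append(f"\n  {name}: AIC = {res.aic:.1f}")
            lines.append(f"    terms: {' + '.join(terms)}")
            lines.append("    selection: " + " -> ".join(
                f"{t} ({a:.1f})" for t, a in trace))
        return "\n".join(lines)
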