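"""Daily spawning-site presence records and a binomial additive mixed model.

The response is daily presence/absence of each tagged fish at the spawning
site (zones 2-3) during the afternoon-evening window associated with spawning
(1400-2000 h), within the April-September spawning season. The model is

    logit P(present) = sex + size-within-sex + f_doy(day of year)
                       + f_lunar(lunar phase) + u_fish

with f_doy and f_lunar cyclic cubic regression splines (periods 365.25 d and
360 deg) and u_fish ~ N(0, sigma^2) a per-fish random intercept. The fit
maximizes the Bernoulli log-likelihood penalized by the spline roughness
penalties and a ridge on the random intercepts; smoothing parameters and the
random-effect variance are selected by Laplace-approximate marginal
likelihood (LAML), the standard criterion for penalized GLMM smoothers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import SPAWNING_SEASON_MONTHS, SPAWNING_SITE_ZONES
from .splines import center_constraint, cyclic_basis

SYNODIC_MONTH_DAYS = 29.530588853
#: reference new moon, 2000-01-06 18:14 UTC expressed in fixed-offset EST
_REFERENCE_NEW_MOON_EST = pd.Timestamp("2000-01-06 13:14:00")
_EPHEMERIS_SPAN = (pd.Timestamp("1990-01-01"), pd.Timestamp("2050-12-31"))


def lunar_phase(when) -> float:
    """Lunar phase in degrees: new moon = 0/360, full moon = 180.

    Mean-synodic approximation: 360 x (days since the reference new moon,
    modulo one synodic month) / synodic month. Accurate to roughly +/- 15
    degrees against almanac lunations, which is ample for a 0-360 covariate.
    Timestamps are interpreted as local EST.
    """
    t = pd.Timestamp(when)
    if not _EPHEMERIS_SPAN[0] <= t <= _EPHEMERIS_SPAN[1]:
        raise ValueError(f"{t} outside supported span {_EPHEMERIS_SPAN}")
    if t == t.normalize():
        t = t + pd.Timedelta(hours=12)  # date-level input: use local noon
    days = (t - _REFERENCE_NEW_MOON_EST) / pd.Timedelta(days=1)
    return float(360.0 * ((days % SYNODIC_MONTH_DAYS) / SYNODIC_MONTH_DAYS))


def build_presence_records(daily: pd.DataFrame, positions: pd.DataFrame,
                           tags: pd.DataFrame,
                           window: tuple[int, int] = (14, 20),
                           zones=SPAWNING_SITE_ZONES,
                           season_months=SPAWNING_SEASON_MONTHS) -> pd.DataFrame:
    """One record per active, uncensored tag per spawning-season date.

    ``present`` is 1 iff the fish has at least one hourly position in the
    spawning-site zones whose bin starts within ``[window[0], window[1])``
    local hours on that date. Dates outside a tag's battery/duty-cycle window
    or after its censor date produce no record (absence is only meaningful
    while the tag could have been heard).
    """
    from .residence import _active_mask

    hit = positions[positions["zone"].isin(zones)
                    & positions["bin_start"].dt.hour.between(window[0], window[1] - 1)]
    hit_dates = set(zip(hit["tag_id"].astype(str), hit["bin_start"].dt.normalize()))

    lo = min(daily["date"].min(), positions["bin_start"].min().normalize())
    hi = max(daily["date"].max(), positions["bin_start"].max().normalize())
    dates = pd.date_range(lo, hi, freq="D")
    dates = dates[dates.month.isin(sorted(season_months))]
    active = _active_mask(tags, dates)

    meta = tags.set_index(tags["tag_id"].astype(str))
    rows = []
    for tag in tags["tag_id"].astype(str):
        on = dates[active[tag].to_numpy()]
        if len(on) == 0:
            continue
        rows.append(pd.DataFrame({
            "tag_id": tag,
            "date": on,
            "present": [int((tag, d) in hit_dates) for d in on],
            "sex": meta.at[tag, "sex"],
            "total_length_mm": meta.at[tag, "total_length_mm"],
        }))
    rec = pd.concat(rows, ignore_index=True)
    rec["doy"] = rec["date"].dt.dayofyear
    rec["lunar_deg"] = rec["date"].map(lunar_phase)
    rec["year"] = rec["date"].dt.year
    return rec


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class _TermBlock:
    name: str
    sl: slice
    penalty: np.ndarray | None  # None = unpenalized fixed effect
    rank: int = 0
    logdet: float = 0.0  # log|S| on the penalized space, lambda factored out


class SpawningPresenceModel:
    """Binomial additive mixed model for daily spawning-site presence.

    Parameters
    ----------
    records : DataFrame
        Presence records from :func:`build_presence_records` (columns
        ``present, sex, total_length_mm, doy, lunar_deg, tag_id``).
    knots_doy, knots_lunar : int
        Knot counts for the two cyclic smooths. Defaults (10, 8) give the
        smooths 8 and 6 free coefficients, generous for one seasonal peak and
        a semi-lunar cycle.
    include_sex, include_size : bool
        Fixed effects: a male-female contrast and, optionally, sex-specific
        linear slopes of (centered) body size.
    smooths : tuple
        Which cyclic smooths to include; subset of ``("doy", "lunar")``.
    doy_period : float
        365.25 keeps day-of-year phases aligned across years.
    """

    def __init__(self, records: pd.DataFrame, knots_doy: int = 10,
                 knots_lunar: int = 8, include_sex: bool = True,
                 include_size: bool = True, random_intercept: bool = True,
                 smooths: tuple = ("doy", "lunar"), doy_period: float = 365.25):
        rec = records.reset_index(drop=True)
        y = rec["present"].to_numpy(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("present must be coded 0/1")
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present")
        self.records = rec
        self.endog = y

        cols: list[np.ndarray] = [np.ones(len(rec))]
        names = ["intercept"]
        blocks: list[_TermBlock] = [_TermBlock("intercept", slice(0, 1), None)]
        pos = 1

        if include_sex:
            per_sex = rec.groupby("sex")["tag_id"].nunique()
            if set(per_sex.index) != {"F", "M"} or per_sex.min() < 2:
                raise ValueError("need >= 2 fish per sex to estimate a sex contrast")
            cols.append((rec["sex"] == "M").to_numpy(float))
            names.append("sex[M]")
            blocks.append(_TermBlock("sex", slice(pos, pos + 1), None))
            pos += 1
        if include_size:
            size_c = rec["total_length_mm"].to_numpy(float)
            size_c = size_c - size_c.mean()
            for s in ("F", "M"):
                cols.append(size_c * (rec["sex"] == s).to_numpy(float))
                names.append(f"size[{s}]")
            blocks.append(_TermBlock("size", slice(pos, pos + 2), None))
            pos += 2

        self._smooth_info: dict[str, dict] = {}
        for term, col, period, k in (("doy", "doy", doy_period, knots_doy),
                                     ("lunar", "lunar_deg", 360.0, knots_lunar)):
            if term not in smooths:
                continue
            Xs, Ss = cyclic_basis(rec[col].to_numpy(float), period, k)
            Xz, Sz, Z = center_constraint(Xs, Ss)
            m = Xz.shape[1]
            sgn, logdet = np.linalg.slogdet(Sz)
            cols.extend(Xz.T)
            names.extend(f"s({term}).{i}" for i in range(m))
            blocks.append(_TermBlock(f"s({term})", slice(pos, pos + m), Sz,
                                     rank=m, logdet=logdet))
            self._smooth_info[term] = {"period": period, "n_knots": k, "Z": Z,
                                       "column": col, "slice": slice(pos, pos + m)}
            pos += m

        self.tag_levels = None
        if random_intercept:
            levels, codes = np.unique(rec["tag_id"], return_inverse=True)
            Zr = np.zeros((len(rec), len(levels)))
            Zr[np.arange(len(rec)), codes] = 1.0
            cols.extend(Zr.T)
            names.extend(f"re[{t}]" for t in levels)
            blocks.append(_TermBlock("random_intercept", slice(pos, pos + len(levels)),
                                     np.eye(len(levels)), rank=len(levels), logdet=0.0))
            self.tag_levels = levels
            pos += len(levels)

        self.exog = np.column_stack(cols)
        self.param_names = names
        self.blocks = blocks
        self._penalized = [b for b in blocks if b.penalty is not None]

    # -- inner penalized IRLS ------------------------------------------------

    def _stotal(self, lam: np.ndarray) -> np.ndarray:
        p = self.exog.shape[1]
        S = np.zeros((p, p))
        for lj, b in zip(lam, self._penalized):
            S[b.sl, b.sl] += lj * b.penalty
        return S

    def _pirls(self, S: np.ndarray, beta0: np.ndarray | None = None,
               maxiter: int = 100, tol: float = 1e-9):
        X, y = self.exog, self.endog
        n, p = X.shape
        beta = np.zeros(p) if beta0 is None else beta0.copy()

        def pen_ll(b):
            eta = X @ b
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            return ll - 0.5 * b @ S @ b

        f = pen_ll(beta)
        for _ in range(maxiter):
            eta = X @ beta
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            g = X.T @ (y - mu) - S @ beta
            Xw = X * w[:, None]
            H = X.T @ Xw + S
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                H = H + 1e-8 * np.eye(p)
                step = np.linalg.solve(H, g)
            t = 1.0
            for _ in range(30):
                cand = beta + t * step
                fc = pen_ll(cand)
                if fc >= f - 1e-12:
                    break
                t /= 2.0
            beta, fnew = cand, fc
            if abs(fnew - f) < tol * (abs(f) + 1.0):
                f = fnew
                break
            f = fnew
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = X.T @ (X * w[:, None]) + S
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return beta, H, ll

    def _laml(self, rho: np.ndarray, beta0=None):
        """Negative Laplace-approximate marginal likelihood at log smoothing params."""
        lam = np.exp(rho)
        S = self._stotal(lam)
        beta, H, ll = self._pirls(S, beta0=beta0)
        pen = 0.5 * beta @ S @ beta
        logdet_S = sum(b.rank * r + b.logdet
                       for b, r in zip(self._penalized, rho))
        sgn, logdet_H = np.linalg.slogdet(H)
        if sgn <= 0:
            return np.inf, beta
        laml = (ll - pen) + 0.5 * logdet_S - 0.5 * logdet_H
        return -laml, beta

    def fit(self, lambdas=None, maxiter: int = 120) -> "SpawningPresenceResults":
        """Fit the model; select smoothing parameters by LAML unless given.

        ``lambdas`` fixes the penalties: a sequence of one value per penalized
        block in model order (smooths, then the random-intercept precision
        1/sigma^2).
        """
        k = len(self._penalized)
        if lambdas is not None:
            rho = np.log(np.asarray(lambdas, float))
            if len(rho) != k:
                raise ValueError(f"expected {k} smoothing parameters, got {len(rho)}")
        elif k == 0:
            rho = np.zeros(0)
        else:
            warm = {"beta": None}

            def objective(rho):
                val, beta = self._laml(np.asarray(rho), beta0=warm["beta"])
                if np.isfinite(val):
                    warm["beta"] = beta
                return val

            # a wide initial simplex lets the search reach the heavy-shrinkage
            # regime (log-lambda ~ 10) that null smooth terms require
            x0 = np.zeros(k)
            simplex = np.vstack([x0] + [x0 + 4.0 * e for e in np.eye(k)])
            res = optimize.minimize(objective, x0=x0, method="Nelder-Mead",
                                    options={"maxfev": maxiter, "xatol": 0.05,
                                             "fatol": 1e-4,
                                             "initial_simplex": simplex})
            if not np.isfinite(res.fun):
                raise RuntimeError(f"smoothing-parameter search failed: {res}")
            rho = res.x
        lam = np.exp(rho)
        S = self._stotal(lam)
        beta, H, ll = self._pirls(S, maxiter=200)
        Vb = np.linalg.inv(H)  # Bayesian posterior covariance
        XtWX = H - S
        F = Vb @ XtWX  # edf matrix
        neg_laml, _ = self._laml(rho, beta0=beta)
        return SpawningPresenceResults(self, beta, Vb, F, lam, ll, -neg_laml)


class SpawningPresenceResults:
    """Fit results: coefficients, Bayesian covariance, EDFs, Wald tests."""

    def __init__(self, model: SpawningPresenceModel, params, cov, edf_matrix,
                 lambdas, llf, laml):
        self.model = model
        self.params = pd.Series(params, index=model.param_names)
        self.cov = cov
        self.lambdas = dict(zip((b.name for b in model._penalized), lambdas))
        self.llf = llf
        self.laml = laml
        self._edf_diag = np.diag(edf_matrix)
        re_block = next((b for b in model.blocks if b.name == "random_intercept"), None)
        self.random_intercept_sd = (float(1.0 / np.sqrt(self.lambdas["random_intercept"]))
                                    if re_block is not None else None)
        # complete-separation heuristic on unpenalized coefficients
        unpen = [i for b in model.blocks if b.penalty is None
                 for i in range(b.sl.start, b.sl.stop)]
        self.separation_flag = bool(np.any(np.abs(params[unpen]) > 15.0))

    # -- summaries -----------------------------------------------------------

    def edf(self, term: str) -> float:
        b = next(b for b in self.model.blocks if b.name == term)
        return float(self._edf_diag[b.sl].sum())

    @property
    def term_tests(self) -> pd.DataFrame:
        """Approximate Wald tests per model term (chi-square on EDF-rounded df)."""
        rows = []
        for b in self.model.blocks:
            beta = self.params.iloc[b.sl].to_numpy()
            V = self.cov[b.sl, b.sl]
            if b.name in ("intercept", "random_intercept"):
                continue
            if b.penalty is None:
                T = float(beta @ np.linalg.solve(V, beta))
                df = len(beta)
            else:
                T = float(beta @ np.linalg.pinv(V) @ beta)
                df = max(1, int(round(self.edf(b.name))))
            rows.append({"term": b.name, "edf": self.edf(b.name),
                         "wald_chi2": T, "df": df,
                         "p_value": float(stats.chi2.sf(T, df))})
        return pd.DataFrame(rows)

    @property
    def fittedvalues(self) -> np.ndarray:
        return special.expit(self.model.exog @ self.params.to_numpy())

    def predict(self, records: pd.DataFrame, population: bool = True) -> np.ndarray:
        """Inverse-logit predictions for new covariates (random effect = 0)."""
        m = self.model
        eta = np.full(len(records), self.params["intercept"])
        if "sex" in (b.name for b in m.blocks):
            eta += self.params["sex[M]"] * (records["sex"] == "M").to_numpy(float)
        if "size" in (b.name for b in m.blocks):
            size_c = (records["total_length_mm"].to_numpy(float)
                      - m.records["total_length_mm"].mean())
            for s in ("F", "M"):
                eta += self.params[f"size[{s}]"] * size_c * (records["sex"] == s).to_numpy(float)
        for term, info in m._smooth_info.items():
            Xs, _ = cyclic_basis(records[info["column"]].to_numpy(float),
                                 info["period"], info["n_knots"])
            eta += (Xs @ info["Z"]) @ self.params.iloc[info["slice"]].to_numpy()
        if not population:
            re = pd.Series(0.0, index=records.index)
            if m.tag_levels is not None:
                u = self.params[[f"re[{t}]" for t in m.tag_levels]]
                u.index = m.tag_levels
                re = records["tag_id"].map(u).fillna(0.0)
            eta += re.to_numpy()
        return special.expit(eta)

    def smooth_curve(self, term: str, n: int = 200) -> pd.DataFrame:
        """Centered smooth f(x) with pointwise SE over one period."""
        info = self.model._smooth_info[term]
        x = np.linspace(0.0, info["period"], n, endpoint=False)
        Xs, _ = cyclic_basis(x, info["period"], info["n_knots"])
        Xz = Xs @ info["Z"]
        beta = self.params.iloc[info["slice"]].to_numpy()
        V = self.cov[info["slice"], info["slice"]]
        return pd.DataFrame({"x": x, "fit": Xz @ beta,
                             "se": np.sqrt(np.einsum("ij,jk,ik->i", Xz, V, Xz))})

    def plot_smooths(self, axes=None):
        import matplotlib.pyplot as plt

        terms = list(self.model._smooth_info)
        if axes is None:
            _, axes = plt.subplots(1, len(terms), figsize=(5 * len(terms), 3.5))
            axes = np.atleast_1d(axes)
        for ax, term in zip(axes, terms):
            c = self.smooth_curve(term)
            ax.plot(c["x"], c["fit"], color="k")
            ax.fill_between(c["x"], c["fit"] - 2 * c["se"], c["fit"] + 2 * c["se"],
                            alpha=0.25, color="steelblue")
            ax.set_xlabel(term)
            ax.set_ylabel(f"s({term}) [logit]")
        return axes

    def summary(self) -> str:
        lines = ["Binomial additive mixed model (logit link)",
                 f"  observations: {len(self.model.endog)}   "
                 f"log-likelihood: {self.llf:.2f}   LAML: {self.laml:.2f}"]
        if self.random_intercept_sd is not None:
            lines.append(f"  random intercept SD (per fish): {self.random_intercept_sd:.3f}")
        if self.separation_flag:
            lines.append("  WARNING: possible complete separation in fixed effects")
        lines.append("\nFixed effects:")
        for b in self.model.blocks:
            if b.penalty is not None:
                continue
            for i in range(b.sl.start, b.sl.stop):
                se = np.sqrt(self.cov[i, i])
                lines.append(f"  {self.model.param_names[i]:<12} "
                             f"{self.params.iloc[i]: .4f}  (SE {se:.4f})")
        tt = self.term_tests
        if len(tt):
            lines.append("\nTerm tests (approximate Wald):")
            for _, r in tt.iterrows():
                lines.append(f"  {r['term']:<10} edf={r['edf']:5.2f}  "
                             f"chi2={r['wald_chi2']:8.2f}  p={r['p_value']:.3g}")
        return "\n".join(lines)
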