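"""Crossed random-intercept linear mixed model for the trial outcomes.

Model, per outcome variable:

    y = X beta + Z_p u + Z_f w + eps,
    u ~ N(0, sigma_p^2 I),  w ~ N(0, sigma_f^2 I),  eps ~ N(0, sigma_e^2 I),

with participants and face identities as *crossed* random intercepts and the
emotion x condition factorial (sum-to-zero coding, Type-III-style marginal
tests) as fixed effects. Estimation maximizes the restricted likelihood
profiled over the two variance ratios gamma = (sigma_p^2, sigma_f^2) /
sigma_e^2; all linear algebra runs through the q x q (q = n_participants +
n_faces) capacitance matrix, so fits are cheap enough for simulation studies.

Inference follows the lmerTest / emmeans conventions: denominator degrees of
freedom for t and F statistics come from the Satterthwaite moment match
(numerical derivatives of the contrast variance with respect to the variance
components, asymptotic covariance from the numeric Hessian of the REML
deviance); estimated marginal means average the fixed-effect prediction over
factor levels with equal weights; all-pairwise contrasts are adjusted with
the studentized-range (Tukey) distribution. Effect sizes use the Edwards
semi-partial R^2 mapping of (F, df1, df2); exact Kenward-Roger covariance
inflation is not implemented and the df source is the Satterthwaite value.

Usage::

    model = CrossedLMM.from_dataframe(df, value_col="apa_amplitude_cm")
    res = model.fit()
    res.anova()                 # F, Satterthwaite df, p, semi-partial R2
    res.emmeans()               # cell means +/- SE
    res.pairwise("emotion", by="condition")   # Tukey-adjusted contrasts
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["CrossedLMM", "CrossedLMMResults", "semipartial_r2"]

_GAMMA_BOUNDARY = 1e-8  # variance ratios below this snap to the boundary
_DEFAULT_STARTS = ((0.3, 0.3), (1.0, 1.0), (0.03, 0.03), (1.0, 0.03), (0.03, 1.0))


def semipartial_r2(F: float, df_num: float, df_den: float) -> float:
    """Edwards semi-partial R^2 from an F statistic and its degrees of freedom."""
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    x = df_num * F / df_den
    return x / (1.0 + x)


def _sum_code(levels: list, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    k = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    out = np.zeros((len(values), k - 1))
    for r, v in enumerate(values):
        i = idx[v]
        if i < k - 1:
            out[r, i] = 1.0
        else:
            out[r, :] = -1.0
    return out


def _cell_row(emotion: str, condition: str, emotions: list, conditions: list) -> np.ndarray:
    """Fixed-effect design row for one factor cell under sum coding."""
    e = _sum_code(emotions, np.array([emotion], dtype=object))[0]
    c = _sum_code(conditions, np.array([condition], dtype=object))[0]
    return np.concatenate(([1.0], e, c, np.outer(e, c).ravel()))


class CrossedLMM:
    """Linear mixed model with two crossed random intercepts.

    Build with :meth:`from_dataframe` for the emotion x condition factorial,
    or directly from a design matrix plus integer group codes for the two
    random factors.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        part_codes: np.ndarray,
        face_codes: np.ndarray,
        xnames: list[str] | None = None,
        term_slices: dict[str, list[int]] | None = None,
        cell_grid: pd.DataFrame | None = None,
    ):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.N, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("rank-deficient fixed-effect design")
        self.part_codes = np.asarray(part_codes, int)
        self.face_codes = np.asarray(face_codes, int)
        self.qp = int(self.part_codes.max()) + 1
        self.qf = int(self.face_codes.max()) + 1
        if self.qp < 2 or self.qf < 2:
            raise ValueError("need at least 2 participants and 2 faces")
        self.q = self.qp + self.qf
        self.xnames = xnames or [f"x{i}" for i in range(self.p)]
        self.term_slices = term_slices or {}
        self.cell_grid = cell_grid

        # X-side cross-products are y-independent; cache for fast refits
        Zcodes = np.concatenate([self.part_codes, self.qp + self.face_codes])
        rows = np.concatenate([np.arange(self.N), np.arange(self.N)])
        Z = np.zeros((self.N, self.q))
        Z[rows, Zcodes] = 1.0
        self._Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ self.X
        self.XtX = self.X.T @ self.X
        self._set_y_products()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value_col: str,
        emotion_col: str = "emotion",
        condition_col: str = "condition",
        participant_col: str = "participant_id",
        face_col: str = "face_id",
    ) -> "CrossedLMM":
        """Model ``value ~ emotion * condition + (1|participant) + (1|face)``."""
        data = data.dropna(subset=[value_col])
        emotions = sorted(data[emotion_col].unique())
        conditions = sorted(data[condition_col].unique())
        cells = data.groupby([emotion_col, condition_col]).size()
        if len(cells) < len(emotions) * len(conditions):
            raise ValueError("empty emotion x condition cells in the data")
        E = _sum_code(emotions, data[emotion_col].to_numpy())
        C = _sum_code(conditions, data[condition_col].to_numpy())
        inter = np.einsum("ni,nj->nij", E, C).reshape(len(data), -1)
        X = np.column_stack([np.ones(len(data)), E, C, inter])
        ke, kc = len(emotions) - 1, len(conditions) - 1
        names = (
            ["(Intercept)"]
            + [f"{emotion_col}[{lv}]" for lv in emotions[:-1]]
            + [f"{condition_col}[{lv}]" for lv in conditions[:-1]]
            + [f"{emotion_col}[{e}]:{condition_col}[{c}]" for e in emotions[:-1] for c in conditions[:-1]]
        )
        term_slices = {
            emotion_col: list(range(1, 1 + ke)),
            condition_col: list(range(1 + ke, 1 + ke + kc)),
            f"{emotion_col}:{condition_col}": list(range(1 + ke + kc, 1 + ke + kc + ke * kc)),
        }
        grid = pd.DataFrame(
            [
                {"emotion": e, "condition": c, "row": _cell_row(e, c, emotions, conditions)}
                for e in emotions
                for c in conditions
            ]
        )
        part_codes = pd.Categorical(data[participant_col]).codes
        face_codes = pd.Categorical(data[face_col]).codes
        model = cls(
            data[value_col].to_numpy(),
            X,
            part_codes,
            face_codes,
            xnames=names,
            term_slices=term_slices,
            cell_grid=grid,
        )
        model._levels = {"emotion": emotions, "condition": conditions}
        return model

    # -- internals ----------------------------------------------------------

    def _set_y_products(self) -> None:
        self.Zty = self._Z.T @ self.y
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def set_response(self, y: np.ndarray) -> "CrossedLMM":
        """Swap the response in place (design unchanged); returns self.

        Re-uses every X-side cross-product, which is what makes simulation
        studies with hundreds of refits affordable.
        """
        y = np.asarray(y, float)
        if y.shape != (self.N,):
            raise ValueError("response length mismatch")
        self.y = y
        self._set_y_products()
        return self

    def _profile(self, gamma: tuple[float, float]) -> dict:
        """Profiled REML pieces at variance ratios gamma=(g_p, g_f)."""
        gp, gf = max(gamma[0], 0.0), max(gamma[1], 0.0)
        d = np.concatenate([np.full(self.qp, gp), np.full(self.qf, gf)])
        ds = np.sqrt(d)
        M = np.eye(self.q) + (ds[:, None] * self.ZtZ) * ds[None, :]
        cM = cho_factor(M, lower=True)
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
        U = ds[:, None] * self.ZtX
        u = ds * self.Zty
        MiU = cho_solve(cM, U)
        Miu = cho_solve(cM, u)
        A = self.XtX - U.T @ MiU
        b = self.Xty - U.T @ Miu
        c = self.yty - float(u @ Miu)
        cA = cho_factor(A, lower=True)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cA[0]))))
        beta = cho_solve(cA, b)
        rss = max(c - float(b @ beta), 0.0)
        return {
            "logdetM": logdetM,
            "logdetA": logdetA,
            "beta": beta,
            "rss": rss,
            "cA": cA,
            "gamma": (gp, gf),
        }

    def _criterion(self, gamma: tuple[float, float]) -> float:
        pr = self._profile(gamma)
        rss = max(pr["rss"], 1e-300)
        return pr["logdetM"] + pr["logdetA"] + (self.N - self.p) * np.log(rss)

    def reml_deviance(self, sigma2_p: float, sigma2_f: float, sigma2_e: float) -> float:
        """-2 restricted log-likelihood at the given variance components."""
        if sigma2_e <= 0:
            raise ValueError("residual variance must be positive")
        pr = self._profile((sigma2_p / sigma2_e, sigma2_f / sigma2_e))
        Np = self.N - self.p
        return (
            Np * np.log(2.0 * np.pi)
            + Np * np.log(sigma2_e)
            + pr["logdetM"]
            + pr["logdetA"]
            + pr["rss"] / sigma2_e
        )

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        vc_fixed: dict[str, float] | None = None,
        n_restarts: int = 5,
        tol: float = 1e-8,
        start: tuple[float, float] | None = None,
    ) -> "CrossedLMMResults":
        """REML fit; returns a :class:`CrossedLMMResults`.

        ``vc_fixed`` pins a random component at a value (only 0.0 supported),
        e.g. ``{"participant": 0.0, "face": 0.0}`` collapses the model to OLS.
        ``start`` warm-starts the variance-ratio search (useful when refitting
        simulated responses on a fixed design).
        """
        vc_fixed = vc_fixed or {}
        for k, v in vc_fixed.items():
            if k not in ("participant", "face") or v != 0.0:
                raise ValueError("vc_fixed supports participant/face pinned at 0.0 only")
        fix_p = "participant" in vc_fixed
        fix_f = "face" in vc_fixed

        def unpack(theta: np.ndarray) -> tuple[float, float]:
            vals = iter(theta**2)
            gp = 0.0 if fix_p else next(vals)
            gf = 0.0 if fix_f else next(vals)
            return gp, gf

        n_free = 2 - fix_p - fix_f
        if n_free == 0:
            gamma_hat = (0.0, 0.0)
            converged = True
        else:
            starts = [start] if start is not None else []
            starts += [s for s in _DEFAULT_STARTS[: max(1, n_restarts)]]
            best = None
            for s in starts:
                theta0 = np.sqrt([v for v, fixed in zip(s, (fix_p, fix_f)) if not fixed])
                res = optimize.minimize(
                    lambda th: self._criterion(unpack(th)),
                    theta0,
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": tol, "maxiter": 600},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
            gamma_hat = unpack(best.x)
            converged = bool(best.success)
            gamma_hat = tuple(0.0 if g < _GAMMA_BOUNDARY else g for g in gamma_hat)

        pr = self._profile(gamma_hat)
        Np = self.N - self.p
        sigma2_e = pr["rss"] / Np
        boundary = set()
        if sigma2_e <= 1e-12 * (1.0 + self.yty / self.N):
            boundary.add("residual")
            sigma2_e = max(sigma2_e, 1e-300)
        if gamma_hat[0] == 0.0:
            boundary.add("participant")
        if gamma_hat[1] == 0.0:
            boundary.add("face")
        cov = sigma2_e * cho_solve(pr["cA"], np.eye(self.p))
        cov = (cov + cov.T) / 2.0
        m2ll = (
            Np * np.log(2.0 * np.pi)
            + Np * np.log(max(sigma2_e, 1e-300))
            + pr["logdetM"]
            + pr["logdetA"]
            + Np
        )
        return CrossedLMMResults(
            model=self,
            params=pr["beta"],
            cov_params=cov,
            vcomp={
                "participant": gamma_hat[0] * sigma2_e,
                "face": gamma_hat[1] * sigma2_e,
                "residual": sigma2_e,
            },
            gamma=gamma_hat,
            reml_criterion=float(m2ll),
            converged=converged,
            boundary=boundary,
            vc_fixed=set(vc_fixed),
        )


@dataclass
class CrossedLMMResults:
    """REML estimates with Satterthwaite-based inference helpers."""

    model: CrossedLMM
    params: np.ndarray
    cov_params: np.ndarray
    vcomp: dict[str, float]
    gamma: tuple[float, float]
    reml_criterion: float
    converged: bool
    boundary: set[str]
    vc_fixed: set[str] = field(default_factory=set)
    _vpar_cov: tuple[list[str], np.ndarray] | None = None

    # -- variance-parameter covariance (for Satterthwaite) ------------------

    def _free_vpars(self) -> list[str]:
        free = []
        for name in ("participant", "face"):
            if name not in self.boundary and name not in self.vc_fixed:
                free.append(name)
        free.append("residual")
        return free

    def _vparam_cov(self) -> tuple[list[str], np.ndarray]:
        """Asymptotic covariance of the free variance components.

        2 * inverse Hessian of the REML deviance, Hessian by central
        differences at the estimate.
        """
        if self._vpar_cov is not None:
            return self._vpar_cov
        free = self._free_vpars()
        theta0 = np.array([self.vcomp[k] for k in free])
        full = {k: self.vcomp[k] for k in ("participant", "face", "residual")}

        def dev(theta: np.ndarray) -> float:
            vals = dict(full)
            for k, v in zip(free, theta):
                vals[k] = v
            return self.model.reml_deviance(vals["participant"], vals["face"], vals["residual"])

        h = np.maximum(1e-4 * np.abs(theta0), 1e-7)
        k = len(free)
        H = np.zeros((k, k))
        f0 = dev(theta0)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            H[i, i] = (dev(theta0 + ei) - 2.0 * f0 + dev(theta0 - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    dev(theta0 + ei + ej) - dev(theta0 + ei - ej)
                    - dev(theta0 - ei + ej) + dev(theta0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = 2.0 * np.linalg.pinv(H)
        self._vpar_cov = (free, cov)
        return self._vpar_cov

    def _contrast_var_fn(self, L: np.ndarray):
        """f(vartheta) = L C(vartheta) L' for a single contrast row L."""
        model = self.model

        def f(vals: dict[str, float]) -> float:
            s2e = vals["residual"]
            pr = model._profile((vals["participant"] / s2e, vals["face"] / s2e))
            v = cho_solve(pr["cA"], L)
            return s2e * float(L @ v)

        return f

    def contrast_df(self, L: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast L beta."""
        L = np.asarray(L, float)
        if self.gamma[0] == 0.0 and self.gamma[1] == 0.0:
            return float(self.model.N - self.model.p)  # OLS collapse, exact
        free, cov = self._vparam_cov()
        fn = self._contrast_var_fn(L)
        full = {k: self.vcomp[k] for k in ("participant", "face", "residual")}
        f0 = fn(full)
        h = np.maximum(1e-4 * np.array([full[k] for k in free]), 1e-7)
        g = np.zeros(len(free))
        for i, k in enumerate(free):
            up, dn = dict(full), dict(full)
            up[k] = full[k] + h[i]
            dn[k] = max(full[k] - h[i], full[k] * 1e-3 if k == "residual" else 0.0)
            g[i] = (fn(up) - fn(dn)) / (up[k] - dn[k])
        denom = float(g @ cov @ g)
        if denom <= 0:
            return float(self.model.N - self.model.p)
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, self.model.N - self.model.p))

    # -- tests and summaries -------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Type-III-style F table with Satterthwaite denominator df.

        Multi-df terms follow the lmerTest recipe: eigendecompose the
        contrast covariance into independent 1-df contrasts, Satterthwaite
        each, and pool the dfs through the expected-F matching formula.
        """
        rows = []
        for term, cols in self.model.term_slices.items():
            Lmat = np.zeros((len(cols), self.model.p))
            for r, c in enumerate(cols):
                Lmat[r, c] = 1.0
            rows.append(self._wald_satterthwaite(term, Lmat))
        return pd.DataFrame(rows).set_index("term")

    def _wald_satterthwaite(self, term: str, Lmat: np.ndarray) -> dict:
        qn = Lmat.shape[0]
        Mc = Lmat @ self.cov_params @ Lmat.T
        vals, vecs = np.linalg.eigh(Mc)
        keep = vals > max(vals.max(), 1.0) * 1e-12
        vals, vecs = vals[keep], vecs[:, keep]
        U = vecs.T @ Lmat  # independent 1-df contrasts
        est = U @ self.params
        t2 = est**2 / vals
        F = float(np.sum(t2) / qn)
        nus = np.array([self.contrast_df(u) for u in U])
        good = nus > 2.0
        if good.any():
            E = float(np.sum(nus[good] / (nus[good] - 2.0)))
            df_den = 2.0 * E / (E - qn) if E > qn else float(np.mean(nus))
        else:
            df_den = float(np.mean(nus))
        df_den = float(np.clip(df_den, 1.0, self.model.N - self.model.p))
        pval = float(stats.f.sf(F, qn, df_den))
        return {
            "term": term,
            "F": F,
            "df_num": qn,
            "df_den": df_den,
            "p": pval,
            "r2": semipartial_r2(F, qn, df_den),
        }

    def emmeans(self) -> pd.DataFrame:
        """Estimated marginal means per emotion x condition cell."""
        grid = self.model.cell_grid
        if grid is None:
            raise ValueError("model was not built from a factor dataframe")
        rows = []
        for _, g in grid.iterrows():
            x = g["row"]
            se = float(np.sqrt(x @ self.cov_params @ x))
            rows.append(
                {
                    "emotion": g["emotion"],
                    "condition": g["condition"],
                    "emmean": float(x @ self.params),
                    "se": se,
                    "df": self.contrast_df(x),
                }
            )
        return pd.DataFrame(rows)

    def _cell_rows(self) -> dict[tuple[str, str], np.ndarray]:
        return {
            (g["emotion"], g["condition"]): g["row"] for _, g in self.model.cell_grid.iterrows()
        }

    def pairwise(self, factor: str = "emotion", by: str | None = None, adjust: str = "tukey") -> pd.DataFrame:
        """All pairwise EMM contrasts for ``factor``; Tukey-adjusted p values.

        With ``by`` set, contrasts are computed within each level of the other
        factor; the Tukey family size is the number of levels of ``factor``.
        """
        levels = self.model._levels
        cells = self._cell_rows()
        fac_levels = levels[factor]
        other = "condition" if factor == "emotion" else "emotion"
        by_levels = levels[other] if by == other else [None]
        k = len(fac_levels)
        rows = []
        for b in by_levels:
            for i in range(k):
                for j in range(i + 1, k):
                    def avg_row(lv):
                        if b is None:
                            sel = [
                                cells[(lv, o) if factor == "emotion" else (o, lv)]
                                for o in levels[other]
                            ]
                            return np.mean(sel, axis=0)
                        return cells[(lv, b) if factor == "emotion" else (b, lv)]

                    L = avg_row(fac_levels[i]) - avg_row(fac_levels[j])
                    est = float(L @ self.params)
                    se = float(np.sqrt(L @ self.cov_params @ L))
                    df = self.contrast_df(L)
                    tstat = est / se
                    p_unadj = 2.0 * float(stats.t.sf(abs(tstat), df))
                    if adjust == "tukey" and k > 2:
                        p_adj = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, df))
                    else:
                        p_adj = p_unadj
                    rows.append(
                        {
                            "contrast": f"{fac_levels[i]} - {fac_levels[j]}",
                            by or "": b,
                            "estimate": est,
                            "se": se,
                            "df": df,
                            "t": tstat,
                            "p_unadjusted": p_unadj,
                            "p_adjusted": min(1.0, max(p_adj, p_unadj)),
                        }
                    )
        out = pd.DataFrame(rows)
        if by is None and "" in out.columns:
            out = out.drop(columns=[""])
        return out

    def summary(self) -> str:
        lines = [
            "Crossed random-intercept linear mixed model (REML)",
            f"  observations: {self.model.N}   fixed effects: {self.model.p}",
            f"  groups: participant ({self.model.qp}), face ({self.model.qf})",
            "",
            "Variance components:",
        ]
        for k in ("participant", "face", "residual"):
            flag = "  (boundary)" if k in self.boundary else ""
            lines.append(f"  {k:<12} {self.vcomp[k]:>12.6g}{flag}")
        lines += ["", "Fixed effects (sum-to-zero coding):"]
        ses = np.sqrt(np.diag(self.cov_params))
        for name, b, se in zip(self.model.xnames, self.params, ses):
            lines.append(f"  {name:<36} {b:>12.5g}  (se {se:.4g})")
        lines += ["", f"REML criterion (-2 log Lr): {self.reml_criterion:.4f}"]
        try:
            an = self.anova()
            lines += ["", "Type-III F tests (Satterthwaite df):", an.to_string()]
        except Exception:  # pragma: no cover - anova needs term slices
            pass
        return "\n".join(lines)
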