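"""Linear mixed model for staircase thresholds, written from first
principles.

Model: one threshold per staircase,

    y_icj = mu_c + b_i + s_ij + e_icj

with a full cell-means fixed effect mu_c over the 16 target x background
cells, a participant random intercept b_i ~ N(0, sigma2_p), a staircase-
within-participant intercept s_ij ~ N(0, sigma2_s), and residual e ~
N(0, sigma2_e).  Estimation is REML: the residual variance and the fixed
effects are profiled out analytically and the profiled criterion is
maximized over the variance ratios (sigma2_p/sigma2_e, sigma2_s/sigma2_e)
by bounded quasi-Newton on the log scale with multiple starts.  The
marginal covariance is block diagonal by participant, so every likelihood
evaluation works on small per-participant Cholesky factors.

With one threshold row per staircase the staircase effect is not separately
identifiable (its design matrix is the identity); the default "strict"
variant detects this, warns, and absorbs sigma2_s into the residual.  The
genuine three-component fit engages whenever staircases contribute more
than one row.

Contrast inference uses Satterthwaite degrees of freedom: the contrast
variance is differentiated numerically with respect to the variance
components and combined with the inverse REML information.  Bonferroni
correction is applied within each declared contrast family; the default
cell-level family is all 120 pairwise contrasts among the 16 cells.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .conditions import build_condition_grid
from .experiment import logmar_difference, logmar_to_letters

N_PAIRWISE_CELL_CONTRASTS = 120  # C(16, 2)


class MixedModelError(RuntimeError):
    pass


class IdentifiabilityWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MixedModelSpec:
    """Model variant switch.

    ``variant='strict'`` requests the nested staircase random effect and
    falls back (with a warning) to absorbing it into the residual when every
    staircase contributes a single row; ``variant='absorbed'`` omits the
    staircase component up front.
    """

    variant: str = "strict"

    def __post_init__(self) -> None:
        if self.variant not in ("strict", "absorbed"):
            raise ValueError("variant must be 'strict' or 'absorbed'")


@dataclass
class ContrastResult:
    label: str
    estimate_deg: float
    std_error: float
    t_value: float
    df: float
    p_raw: float
    p_bonferroni: float
    family_size: int


@dataclass
class MixedModelFit:
    cells: list[str]
    cell_means: pd.Series
    cov_cell_means: np.ndarray
    sigma2_participant: float
    sigma2_staircase: float
    sigma2_residual: float
    loglik_reml: float
    converged: bool
    grad_norm: float
    n_obs: int
    df_residual: int
    variant: str
    variant_effective: str
    warnings_: list[str]
    _design: dict = field(repr=False, default_factory=dict)
    _satterthwaite_cov: np.ndarray | None = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "cells": self.cells,
            "cell_means": {k: float(v) for k, v in self.cell_means.items()},
            "sigma2_participant": self.sigma2_participant,
            "sigma2_staircase": self.sigma2_staircase,
            "sigma2_residual": self.sigma2_residual,
            "loglik_reml": self.loglik_reml,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_obs": self.n_obs,
            "variant": self.variant,
            "variant_effective": self.variant_effective,
            "warnings": self.warnings_,
        }


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

def _build_design(table: pd.DataFrame) -> dict:
    df = table.copy()
    df["cell"] = df["target_state"].astype(str) + df["background_state"].astype(str)
    canonical = [c.label for c in build_condition_grid()]
    observed = [c for c in canonical if c in set(df["cell"])]
    extra = sorted(set(df["cell"]) - set(observed))
    cells = observed + extra

    df = df.sort_values(["participant_id", "staircase_id"], kind="mergesort")
    df = df.reset_index(drop=True)
    y = df["threshold_deg"].to_numpy(float)
    n = len(df)
    p = len(cells)
    cell_idx = pd.Categorical(df["cell"], categories=cells).codes
    X = np.zeros((n, p))
    X[np.arange(n), cell_idx] = 1.0

    blocks = []
    singleton = True
    for _, grp in df.groupby("participant_id", sort=True):
        idx = grp.index.to_numpy()
        sc_groups = []
        for _, sgrp in grp.groupby("staircase_id", sort=True):
            local = np.searchsorted(idx, sgrp.index.to_numpy())
            sc_groups.append(local)
            if len(local) > 1:
                singleton = False
        blocks.append({"rows": idx, "staircase_groups": sc_groups})
    return {
        "y": y,
        "X": X,
        "cells": cells,
        "blocks": blocks,
        "n": n,
        "p": p,
        "all_singleton_staircases": singleton,
        "table": df,
    }


def _block_w(block: dict, gamma_p: float, gamma_s: float) -> np.ndarray:
    m = len(block["rows"])
    W = np.eye(m) + gamma_p * np.ones((m, m))
    if gamma_s:
        for local in block["staircase_groups"]:
            W[np.ix_(local, local)] += gamma_s
    return W


def _profiled_quantities(design: dict, gamma_p: float, gamma_s: float):
    """GLS pieces for W = I + gamma_p Z_p Z_p' + gamma_s Z_s Z_s'."""
    y, X, p = design["y"], design["X"], design["p"]
    logdet_w = 0.0
    xtwix = np.zeros((p, p))
    xtwiy = np.zeros(p)
    ytwiy = 0.0
    for block in design["blocks"]:
        rows = block["rows"]
        W = _block_w(block, gamma_p, gamma_s)
        c, low = cho_factor(W, lower=True)
        logdet_w += 2.0 * float(np.sum(np.log(np.diag(c))))
        Xb = X[rows]
        yb = y[rows]
        LX = cho_solve((c, low), Xb)
        Ly = cho_solve((c, low), yb)
        xtwix += Xb.T @ LX
        xtwiy += Xb.T @ Ly
        ytwiy += float(yb @ Ly)
    try:
        beta = np.linalg.solve(xtwix, xtwiy)
    except np.linalg.LinAlgError as exc:
        raise MixedModelError(f"singular design: {exc}") from exc
    rss = max(ytwiy - float(xtwiy @ beta), 1e-300)
    sign, logdet_xtwix = np.linalg.slogdet(xtwix)
    if sign <= 0:
        raise MixedModelError("singular design (X'W^-1 X not positive definite)")
    return beta, rss, logdet_w, logdet_xtwix, xtwix


def _reml_criterion(design: dict, gamma_p: float, gamma_s: float) -> float:
    """-2 x profiled REML log-likelihood (up to an additive constant)."""
    n, p = design["n"], design["p"]
    _, rss, logdet_w, logdet_xtwix, _ = _profiled_quantities(design, gamma_p, gamma_s)
    return logdet_w + logdet_xtwix + (n - p) * math.log(rss)


def _reml_loglik_sigma(design: dict, sigmas: np.ndarray, with_staircase: bool) -> float:
    """REML log-likelihood as a function of the variance components."""
    if with_staircase:
        s2p, s2s, s2e = sigmas
    else:
        s2p, s2e = sigmas
        s2s = 0.0
    s2e = max(float(s2e), 1e-300)
    gamma_p = max(float(s2p), 0.0) / s2e
    gamma_s = max(float(s2s), 0.0) / s2e
    n, p = design["n"], design["p"]
    _, rss, logdet_w, logdet_xtwix, _ = _profiled_quantities(design, gamma_p, gamma_s)
    # log|V| = n log s2e + log|W|; log|X'V^-1 X| = log|X'W^-1X| - p log s2e
    return -0.5 * (
        n * math.log(s2e)
        + logdet_w
        + logdet_xtwix
        - p * math.log(s2e)
        + rss / s2e
    )


_MULTISTARTS_2D = ((-4.0, -4.0), (0.0, 0.0), (3.0, -1.0))
_MULTISTARTS_1D = ((-4.0,), (0.0,), (3.0,))
_LOG_GAMMA_BOUNDS = (-20.0, 15.0)


def fit_mixed_model(
    table: pd.DataFrame, spec: MixedModelSpec | str | None = None
) -> MixedModelFit:
    """REML fit of the nested mixed model to a tidy threshold table."""
    if isinstance(spec, str):
        spec = MixedModelSpec(spec)
    spec = spec or MixedModelSpec()
    design = _build_design(table)
    n, p = design["n"], design["p"]
    if n <= p:
        raise MixedModelError("not enough observations to estimate the model")
    if design["table"]["participant_id"].nunique() < 2:
        raise MixedModelError("at least 2 participants required")

    warn_msgs: list[str] = []
    with_staircase = spec.variant == "strict"
    variant_effective = spec.variant
    if with_staircase and design["all_singleton_staircases"]:
        msg = (
            "staircase-within-participant variance is not identifiable with one "
            "threshold per staircase; absorbing it into the residual"
        )
        warnings.warn(msg, IdentifiabilityWarning, stacklevel=2)
        warn_msgs.append(msg)
        with_staircase = False
        variant_effective = "absorbed"
    if spec.variant == "absorbed":
        with_staircase = False

    k = 2 if with_staircase else 1

    def objective(x: np.ndarray) -> float:
        gamma = np.exp(np.clip(x, *_LOG_GAMMA_BOUNDS))
        gp = gamma[0]
        gs = gamma[1] if k == 2 else 0.0
        return _reml_criterion(design, gp, gs)

    starts = _MULTISTARTS_2D if k == 2 else _MULTISTARTS_1D
    best = None
    for start in starts:
        res = optimize.minimize(
            objective,
            np.array(start, dtype=float),
            method="L-BFGS-B",
            bounds=[_LOG_GAMMA_BOUNDS] * k,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    converged = bool(best.success)
    grad_norm = float(np.max(np.abs(np.atleast_1d(best.jac))))
    if not converged:
        # L-BFGS-B can stop with an "abnormal line search" right at a flat
        # optimum; a derivative-free polish distinguishes that from a real
        # failure
        polish = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
        )
        if polish.fun <= best.fun + 1e-12:
            improvement = best.fun - polish.fun
            best = polish if polish.fun < best.fun else best
            if improvement < 1e-6:
                converged = True
    if not converged:
        warn_msgs.append(f"optimizer did not report convergence: {best.message}")

    gamma = np.exp(best.x)
    gamma_p = float(gamma[0])
    gamma_s = float(gamma[1]) if k == 2 else 0.0
    beta, rss, _, _, xtwix = _profiled_quantities(design, gamma_p, gamma_s)
    s2e = rss / (n - p)
    s2p = gamma_p * s2e
    s2s = gamma_s * s2e
    cov_beta = s2e * np.linalg.inv(xtwix)
    sigmas = (
        np.array([s2p, s2s, s2e]) if with_staircase else np.array([s2p, s2e])
    )
    loglik = _reml_loglik_sigma(design, sigmas, with_staircase)

    fit = MixedModelFit(
        cells=design["cells"],
        cell_means=pd.Series(beta, index=design["cells"], name="threshold_deg"),
        cov_cell_means=cov_beta,
        sigma2_participant=float(s2p),
        sigma2_staircase=float(s2s),
        sigma2_residual=float(s2e),
        loglik_reml=float(loglik),
        converged=converged,
        grad_norm=grad_norm,
        n_obs=n,
        df_residual=n - p,
        variant=spec.variant,
        variant_effective=variant_effective,
        warnings_=warn_msgs,
        _design=design,
    )
    fit._design["with_staircase"] = with_staircase
    fit._design["sigmas"] = sigmas
    return fit


# ----------------------------------------------------------------------
# Satterthwaite machinery
# ----------------------------------------------------------------------

def _cov_beta_at(design: dict, sigmas: np.ndarray, with_staircase: bool) -> np.ndarray:
    if with_staircase:
        s2p, s2s, s2e = sigmas
    else:
        s2p, s2e = sigmas
        s2s = 0.0
    s2e = max(float(s2e), 1e-300)
    _, _, _, _, xtwix = _profiled_quantities(
        design, max(s2p, 0.0) / s2e, max(s2s, 0.0) / s2e
    )
    return s2e * np.linalg.inv(xtwix)


def _satterthwaite_cov(fit: MixedModelFit) -> np.ndarray:
    """Asymptotic covariance of the variance components (inverse REML information)."""
    if fit._satterthwaite_cov is not None:
        return fit._satterthwaite_cov
    design = fit._design
    with_staircase = design["with_staircase"]
    sig = np.asarray(design["sigmas"], float)
    kk = len(sig)
    steps = np.maximum(1e-3 * np.abs(sig), 1e-9)
    steps = np.minimum(steps, np.maximum(sig / 2.0, 1e-12))

    def ll(s):
        return _reml_loglik_sigma(design, np.maximum(s, 1e-12), with_staircase)

    H = np.zeros((kk, kk))
    f0 = ll(sig)
    for i in range(kk):
        for j in range(i, kk):
            ei = np.zeros(kk); ei[i] = steps[i]
            ej = np.zeros(kk); ej[j] = steps[j]
            if i == j:
                val = (ll(sig + ei) - 2 * f0 + ll(sig - ei)) / steps[i] ** 2
            else:
                val = (
                    ll(sig + ei + ej)
                    - ll(sig + ei - ej)
                    - ll(sig - ei + ej)
                    + ll(sig - ei - ej)
                ) / (4 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    cov = np.linalg.pinv(-H)
    fit._satterthwaite_cov = cov
    return cov


def _satterthwaite_df(fit: MixedModelFit, c: np.ndarray) -> float:
    design = fit._design
    with_staircase = design["with_staircase"]
    sig = np.asarray(design["sigmas"], float)
    kk = len(sig)
    steps = np.maximum(1e-3 * np.abs(sig), 1e-9)
    steps = np.minimum(steps, np.maximum(sig / 2.0, 1e-12))

    def g(s):
        return float(c @ _cov_beta_at(design, s, with_staircase) @ c)

    grad = np.zeros(kk)
    for i in range(kk):
        ei = np.zeros(kk); ei[i] = steps[i]
        grad[i] = (g(sig + ei) - g(np.maximum(sig - ei, 1e-12))) / (
            (sig[i] + steps[i]) - max(sig[i] - steps[i], 1e-12)
        )
    cov = _satterthwaite_cov(fit)
    denom = float(grad @ cov @ grad)
    g0 = g(sig)
    if not np.isfinite(denom) or denom <= 0 or g0 <= 0:
        return float(fit.df_residual)
    df = 2.0 * g0**2 / denom
    return float(np.clip(df, 1.0, fit.df_residual))


# ----------------------------------------------------------------------
# contrasts
# ----------------------------------------------------------------------

def _contrast_vector(fit: MixedModelFit, weights: dict[str, float]) -> np.ndarray:
    c = np.zeros(len(fit.cells))
    for cell, w in weights.items():
        if cell not in fit.cells:
            raise MixedModelError(f"contrast references unobserved cell {cell!r}")
        c[fit.cells.index(cell)] = w
    return c


def pairwise_contrasts(
    fit: MixedModelFit,
    contrasts: list[tuple[str, dict[str, float]]],
    family_size: int | None = None,
) -> list[ContrastResult]:
    """Evaluate contrasts of cell means with Bonferroni correction.

    ``contrasts`` is a list of (label, {cell_label: weight}); the Bonferroni
    family defaults to the number of contrasts supplied.
    """
    if not fit.converged:
        warnings.warn(
            "contrasts computed on a fit flagged as non-converged", UserWarning,
            stacklevel=2,
        )
    fam = family_size if family_size is not None else len(contrasts)
    out = []
    beta = fit.cell_means.to_numpy()
    for label, weights in contrasts:
        c = _contrast_vector(fit, weights)
        est = float(c @ beta)
        var = float(c @ fit.cov_cell_means @ c)
        se = math.sqrt(max(var, 0.0))
        if se > 0:
            t = est / se
            df = _satterthwaite_df(fit, c)
            p_raw = 2.0 * float(stats.t.sf(abs(t), df))
        else:
            t, df, p_raw = 0.0, float(fit.df_residual), 1.0
        out.append(
            ContrastResult(
                label=label,
                estimate_deg=est,
                std_error=se,
                t_value=t,
                df=df,
                p_raw=p_raw,
                p_bonferroni=min(1.0, fam * p_raw),
                family_size=fam,
            )
        )
    return out


def all_pairwise_cell_contrasts(fit: MixedModelFit) -> list[tuple[str, dict[str, float]]]:
    return [
        (f"{a}-{b}", {a: 1.0, b: -1.0})
        for a, b in itertools.combinations(fit.cells, 2)
    ]


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "estimate_deg": r.estimate_deg,
                "std_error": r.std_error,
                "t_value": r.t_value,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "family_size": r.family_size,
            }
            for r in results
        ]
    )


# ----------------------------------------------------------------------
# the full analysis report
# ----------------------------------------------------------------------

def _mean_of(cells: list[str]) -> dict[str, float]:
    w = 1.0 / len(cells)
    return {c: w for c in cells}


def _diff(a: dict[str, float], b: dict[str, float]) -> dict[str, float]:
    out = dict(a)
    for cell, w in b.items():
        out[cell] = out.get(cell, 0.0) - w
    return out


#: the comparison families reported for this experiment, as
#: (family name, [(label, positive cells, negative cells)]) with single-cell
#: comparisons drawn from the 120-contrast pairwise family and pooled
#: (multi-cell) comparisons forming their own family.
REPORT_FAMILIES: dict[str, list[tuple[str, list[str], list[str]]]] = {
    "black_vs_white": [
        ("BU-WU", ["BU"], ["WU"]),
        ("BN-WN", ["BN"], ["WN"]),
        ("BH-WH", ["BH"], ["WH"]),
        ("BL-WL", ["BL"], ["WL"]),
    ],
    "cr_vs_static_on_uniform": [
        ("HU-BU", ["HU"], ["BU"]),
        ("LU-BU", ["LU"], ["BU"]),
        ("pooled CR(U)-BU", ["HU", "LU"], ["BU"]),
        ("HU-WU", ["HU"], ["WU"]),
        ("LU-WU", ["LU"], ["WU"]),
        ("pooled CR(U)-WU", ["HU", "LU"], ["WU"]),
    ],
    "cr_vs_static_on_noise": [
        ("HN-BN", ["HN"], ["BN"]),
        ("LN-BN", ["LN"], ["BN"]),
        ("pooled CR(N)-BN", ["HN", "LN"], ["BN"]),
        ("HN-WN", ["HN"], ["WN"]),
        ("LN-WN", ["LN"], ["WN"]),
        ("pooled CR(N)-WN", ["HN", "LN"], ["WN"]),
        ("pooled CR(N)-static(N)", ["HN", "LN"], ["BN", "WN"]),
    ],
    "background_reversal": [
        ("BH-BN", ["BH"], ["BN"]),
        ("WH-WN", ["WH"], ["WN"]),
        ("pooled revH-staticN", ["BH", "WH"], ["BN", "WN"]),
        ("BL-BN", ["BL"], ["BN"]),
        ("WL-WN", ["WL"], ["WN"]),
        ("pooled revL-staticN", ["BL", "WL"], ["BN", "WN"]),
    ],
    "synchrony": [
        ("LL-HH", ["LL"], ["HH"]),
        ("LH-HL", ["LH"], ["HL"]),
        ("LL-LH", ["LL"], ["LH"]),
        ("HL-LL", ["HL"], ["LL"]),
        ("HL-HH", ["HL"], ["HH"]),
        ("HH-LH", ["HH"], ["LH"]),
        ("pooled async-sync", ["HL", "LH"], ["HH", "LL"]),
    ],
}


def _is_pooled(pos: list[str], neg: list[str]) -> bool:
    return len(pos) > 1 or len(neg) > 1


@dataclass
class AnalysisReport:
    fit: MixedModelFit
    raw_means: pd.Series
    adjusted_means: pd.Series
    families: dict[str, list[ContrastResult]]
    worst_cell: str
    best_cell: str
    range_logmar: float
    range_letters: float

    def to_markdown(self) -> str:
        lines = ["# Threshold analysis", ""]
        lines.append(
            f"Model: {self.fit.variant_effective} nesting; "
            f"sigma2_p={self.fit.sigma2_participant:.3g}, "
            f"sigma2_s={self.fit.sigma2_staircase:.3g}, "
            f"sigma2_e={self.fit.sigma2_residual:.3g}; "
            f"converged={self.fit.converged}"
        )
        lines.append("")
        lines.append("## Cell means (deg)")
        lines.append("")
        lines.append("| cell | raw mean | model-adjusted mean |")
        lines.append("|---|---|---|")
        for cell in self.fit.cells:
            lines.append(
                f"| {cell} | {self.raw_means.get(cell, float('nan')):.4f} "
                f"| {self.adjusted_means[cell]:.4f} |"
            )
        lines.append("")
        lines.append(
            f"Worst-to-best range: {self.worst_cell} "
            f"({self.adjusted_means[self.worst_cell]:.3f} deg) to {self.best_cell} "
            f"({self.adjusted_means[self.best_cell]:.3f} deg) = "
            f"{self.range_logmar:.3f} logMAR "
            f"(~{logmar_to_letters(self.range_logmar, rounded=True):.0f} letters)"
        )
        for name, results in self.families.items():
            lines.append("")
            lines.append(f"## {name}")
            lines.append("")
            lines.append(
                "| contrast | estimate (deg) | SE | t | df | p (raw) | p (Bonferroni) | family |"
            )
            lines.append("|---|---|---|---|---|---|---|---|")
            for r in results:
                lines.append(
                    f"| {r.label} | {r.estimate_deg:.4f} | {r.std_error:.4f} | "
                    f"{r.t_value:.2f} | {r.df:.1f} | {r.p_raw:.3g} | "
                    f"{r.p_bonferroni:.3g} | {r.family_size} |"
                )
        return "\n".join(lines)


def analysis_report(
    table: pd.DataFrame, spec: MixedModelSpec | str | None = None
) -> AnalysisReport:
    """Fit the mixed model and evaluate the five reported contrast families.

    Raw (sample) and model-adjusted cell means are both reported, since with
    unbalanced staircase counts they need not agree.
    """
    fit = fit_mixed_model(table, spec)
    df = table.copy()
    df["cell"] = df["target_state"].astype(str) + df["background_state"].astype(str)
    raw_means = df.groupby("cell")["threshold_deg"].mean()

    n_pooled = sum(
        1
        for fam in REPORT_FAMILIES.values()
        for (_, pos, neg) in fam
        if _is_pooled(pos, neg)
    )
    families: dict[str, list[ContrastResult]] = {}
    for name, entries in REPORT_FAMILIES.items():
        specs, fams = [], []
        for label, pos, neg in entries:
            if not all(c in fit.cells for c in pos + neg):
                continue
            specs.append((label, _diff(_mean_of(pos), _mean_of(neg))))
            fams.append(
                n_pooled if _is_pooled(pos, neg) else N_PAIRWISE_CELL_CONTRASTS
            )
        results = []
        for (label, weights), fam in zip(specs, fams):
            results.extend(pairwise_contrasts(fit, [(label, weights)], family_size=fam))
        families[name] = results

    adjusted = fit.cell_means
    worst = str(adjusted.idxmax())
    best = str(adjusted.idxmin())
    rng_logmar = logmar_difference(float(adjusted[worst]), float(adjusted[best]))
    return AnalysisReport(
        fit=fit,
        raw_means=raw_means,
        adjusted_means=adjusted,
        families=families,
        worst_cell=worst,
        best_cell=best,
        range_logmar=rng_logmar,
        range_letters=logmar_to_letters(rng_logmar),
    )
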