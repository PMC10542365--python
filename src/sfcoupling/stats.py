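"""Inferential machinery: spin tests, Fisher combination, FDR, ANOVA with
Tamhane's T2, Breusch-Pagan, bootstrap standardized regression with VIF, and
mediation.

The spatial permutation ("spin") test compares an empirical two-tailed
Spearman correlation between two regional maps to a null distribution
obtained by rigidly rotating one map on the sphere — a uniformly random
SO(3) rotation for the left hemisphere and its mirror (x-flipped conjugate)
for the right, preserving both spatial autocorrelation and hemispheric
symmetry.  Independent per-subject p-values are combined with Fisher's
method, T = -2 sum ln p_i, referred to a chi-square with 2n degrees of
freedom.  Regression coefficients are standardized betas with percentile
bootstrap confidence intervals (resampling rows with replacement) and
two-tailed sign-crossing bootstrap p-values; collinearity is screened with
the variance inflation factor (flagged above 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._rng import substream

__all__ = [
    "SpinTestResult",
    "FisherResult",
    "BootstrapRegressionResult",
    "MediationResult",
    "spin_test",
    "fisher_combine",
    "bh_fdr",
    "anova_oneway",
    "tamhane_t2",
    "breusch_pagan",
    "center",
    "build_design",
    "bootstrap_ols",
    "vif",
    "mediate",
]

VIF_FLAG_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpinTestResult:
    r_emp: float
    null_r: np.ndarray
    p_spin: float
    n_rotations: int
    seed: int


@dataclass(frozen=True)
class FisherResult:
    T: float
    df: int
    p_fisher: float


@dataclass(frozen=True)
class BootstrapRegressionResult:
    names: tuple
    beta_stand: np.ndarray
    bci: np.ndarray  # (k, 2) percentile interval
    p_boot: np.ndarray
    vif: np.ndarray
    n_boot: int
    seed: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta_stand": self.beta_stand,
                "bci_low": self.bci[:, 0],
                "bci_high": self.bci[:, 1],
                "p_boot": self.p_boot,
                "vif": self.vif,
                "vif_flag": self.vif > VIF_FLAG_THRESHOLD,
            },
            index=list(self.names),
        )


@dataclass(frozen=True)
class MediationResult:
    total: float
    direct: float
    indirect: float
    indirect_bci: tuple
    proportion_mediated: float
    n_boot: int
    seed: int


# ---------------------------------------------------------------------------
# spin test
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation in SO(3) via QR with sign and determinant fix."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = _rank(a), _rank(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return np.nan
    return float((ra * rb).sum() / denom)


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def spin_test(
    map_a,
    map_b,
    regions,
    n_rotations: int = 10000,
    seed: int = 0,
) -> SpinTestResult:
    """Spatial permutation test between two regional maps.

    The empirical statistic is the two-tailed Spearman correlation over
    regions where both maps are defined.  Each null draw applies one
    uniform random rotation to the left hemisphere's coordinates and its
    mirrored rotation to the right, reassigns ``map_a`` by
    nearest-rotated-neighbour within hemisphere, and recomputes the
    correlation;
    ``p_spin = (1 + #{|null| >= |r_emp|}) / (n_rotations + 1)``.
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or len(a) != regions.n_regions:
        raise ValueError("maps must align with the region set")

    hemis = [regions.hemisphere == "left", regions.hemisphere == "right"]
    for hmask in hemis:
        if hmask.sum() < 10:
            raise ValueError("need at least 10 regions per hemisphere")

    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < 3:
        raise ValueError("maps have no usable overlapping regions")
    r_emp = _spearman(a[both], b[both])

    rng = substream(seed, "spin_test")
    coords = [regions.xyz[h] for h in hemis]
    vals = [a[h] for h in hemis]
    null_r = np.empty(n_rotations)
    null_a = np.empty_like(a)
    for it in range(n_rotations):
        rot = _random_rotation(rng)
        for h, (hmask, xyz, va) in enumerate(zip(hemis, coords, vals)):
            rh = rot if h == 0 else _MIRROR @ rot @ _MIRROR
            rotated = xyz @ rh.T
            # nearest rotated point to each original position (max cosine)
            nearest = np.argmax(xyz @ rotated.T, axis=1)
            null_a[hmask] = va[nearest]
        ok = np.isfinite(null_a) & np.isfinite(b)
        null_r[it] = _spearman(null_a[ok], b[ok]) if ok.sum() >= 3 else np.nan
    tail = np.sum(np.abs(null_r[np.isfinite(null_r)]) >= abs(r_emp))
    p_spin = (1.0 + tail) / (n_rotations + 1.0)
    return SpinTestResult(
        r_emp=r_emp, null_r=null_r, p_spin=float(p_spin),
        n_rotations=n_rotations, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Fisher's method, FDR
# ---------------------------------------------------------------------------


def fisher_combine(pvals) -> FisherResult:
    """Fisher meta-analytic combination: T = -2 sum ln p, chi2 with 2n df."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    t = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return FisherResult(T=t, df=df, p_fisher=float(sps.chi2.sf(t, df)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ANOVA and Tamhane's T2
# ---------------------------------------------------------------------------


def _groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keys = pd.unique(labels)
    groups = [values[labels == k] for k in keys]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, g in zip(keys, groups):
        if len(g) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    return keys, groups


def anova_oneway(values, group_labels) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within F and its p-value)."""
    _, groups = _groups(values, group_labels)
    if np.std(np.concatenate(groups)) == 0:
        raise ValueError("all observations identical; ANOVA undefined")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tamhane_t2(values, group_labels) -> pd.DataFrame:
    """Tamhane's T2 pairwise comparisons (equal variances not assumed).

    Welch t statistics with Satterthwaite degrees of freedom for every group
    pair, adjusted with the conservative Sidak bound over the number of
    pairs.  Returns a table with one row per pair.
    """
    keys, groups = _groups(values, group_labels)
    pairs = [(i, j) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        vi, vj = gi.var(ddof=1) / len(gi), gj.var(ddof=1) / len(gj)
        se = np.sqrt(vi + vj)
        if se == 0:
            t, df, p_raw = 0.0, len(gi) + len(gj) - 2.0, 1.0
        else:
            t = (gi.mean() - gj.mean()) / se
            df = (vi + vj) ** 2 / (vi**2 / (len(gi) - 1) + vj**2 / (len(gj) - 1))
            p_raw = 2.0 * sps.t.sf(abs(t), df)
        p_adj = min(1.0, 1.0 - (1.0 - min(p_raw, 1.0)) ** m)
        rows.append((keys[i], keys[j], t, df, p_raw, p_adj))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "t", "df", "p_raw", "p_adj"]
    )


# ---------------------------------------------------------------------------
# Breusch-Pagan
# ---------------------------------------------------------------------------


def _add_intercept(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(x)), x])


def _ols(y: np.ndarray, x_with_const: np.ndarray):
    beta, *_ = np.linalg.lstsq(x_with_const, y, rcond=None)
    resid = y - x_with_const @ beta
    return beta, resid


def breusch_pagan(y, X) -> tuple[float, float]:
    """Heteroscedasticity test via the squared-residual auxiliary regression.

    Fits OLS of y on X, squares the unstandardized residuals, regresses the
    squared residuals on X again, and reports that auxiliary regression's
    F statistic and p-value.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(X, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n <= k + 1:
        raise ValueError("need more observations than predictors + 1")
    xc = _add_intercept(x)
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        raise ValueError("design is rank deficient")
    _, resid = _ols(y, xc)
    e2 = resid**2
    if np.allclose(e2, 0):
        raise ValueError("residuals are degenerate (perfect fit)")
    beta_aux, resid_aux = _ols(e2, xc)
    fitted = xc @ beta_aux
    ess = np.sum((fitted - e2.mean()) ** 2)
    rss = np.sum(resid_aux**2)
    f = (ess / k) / (rss / (n - k - 1))
    p = float(sps.f.sf(f, k, n - k - 1))
    return float(f), p


# ---------------------------------------------------------------------------
# design construction and bootstrap OLS
# ---------------------------------------------------------------------------


def center(x) -> np.ndarray:
    """Subtract the mean: x_i - average(X)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    return x - x.mean()


def build_design(
    predictors,
    interaction: tuple | None = None,
    quadratic_terms: tuple = (),
    covariates=None,
) -> pd.DataFrame:
    """Assemble a regression design table.

    ``predictors`` is a mapping / DataFrame of named columns.  When
    ``interaction=(name_a, name_b)`` is given, both columns are replaced by
    centered versions and their product is appended as
    ``"{a}_x_{b}"``.  Names in ``quadratic_terms`` get a squared centered
    column ``"{name}_sq"``.  ``covariates`` are appended unmodified.  A
    constant column ``const`` is always included; name collisions raise.
    """
    df = pd.DataFrame(predictors).astype(float).copy()
    if covariates is not None:
        cov = pd.DataFrame(covariates).astype(float)
        for name in cov.columns:
            if name in df.columns:
                raise ValueError(f"duplicate column name {name!r}")
        df = pd.concat([df, cov], axis=1)

    if interaction is not None:
        a, b = interaction
        for name in (a, b):
            if name not in df.columns:
                raise ValueError(f"interaction names unknown column {name!r}")
            df[name] = center(df[name].to_numpy())
        iname = f"{a}_x_{b}"
        if iname in df.columns:
            raise ValueError(f"duplicate column name {iname!r}")
        df[iname] = df[a] * df[b]

    for name in quadratic_terms:
        if name not in df.columns:
            raise ValueError(f"quadratic term names unknown column {name!r}")
        qname = f"{name}_sq"
        if qname in df.columns:
            raise ValueError(f"duplicate column name {qname!r}")
        df[qname] = center(df[name].to_numpy()) ** 2

    if "const" in df.columns:
        raise ValueError("duplicate column name 'const'")
    df.insert(0, "const", 1.0)
    return df


def _standardize_columns(m: np.ndarray, is_const: np.ndarray) -> np.ndarray:
    out = m.astype(float).copy()
    for j in range(m.shape[1]):
        if is_const[j]:
            continue
        mu, sd = out[:, j].mean(), out[:, j].std()
        if sd == 0:
            raise ValueError(f"column {j} is constant within the sample")
        out[:, j] = (out[:, j] - mu) / sd
    return out


def vif(design) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) for each non-constant column."""
    df = pd.DataFrame(design).astype(float)
    cols = [c for c in df.columns if df[c].nunique() > 1]
    if len(cols) < 2:
        raise ValueError("need at least 2 non-constant columns")
    x = df[cols].to_numpy()
    out = {}
    for j, name in enumerate(cols):
        others = np.delete(x, j, axis=1)
        xc = _add_intercept(others)
        _, resid = _ols(x[:, j], xc)
        sst = np.sum((x[:, j] - x[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def bootstrap_ols(
    y, design, n_boot: int = 10000, seed: int = 0
) -> BootstrapRegressionResult:
    """Standardized OLS coefficients with nonparametric bootstrap inference.

    Fits OLS on z-scored y and z-scored non-constant design columns, then
    resamples rows with replacement ``n_boot`` times, re-standardizing and
    refitting within each resample.  Reports 95% percentile intervals and
    two-tailed sign-crossing p-values with +1 smoothing:
    ``p = 2 min[(1 + #{b* <= 0}) / (B + 1), (1 + #{b* >= 0}) / (B + 1)]``.
    """
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame(design).astype(float)
    n = len(y)
    if len(df) != n:
        raise ValueError("y and design must align")
    if n <= df.shape[1] + 1:
        raise ValueError("need more rows than design columns + 1")
    is_const = np.array([df[c].nunique() == 1 for c in df.columns])
    names = [c for c, k in zip(df.columns, is_const) if not k]
    m = df.to_numpy()
    if np.linalg.matrix_rank(_standardize_columns(m, is_const)) < m.shape[1]:
        raise ValueError(
            "design is rank deficient (perfect collinearity; check VIF)"
        )

    def fit(yy, mm):
        ys = (yy - yy.mean()) / yy.std()
        ms = _standardize_columns(mm, is_const)
        beta, *_ = np.linalg.lstsq(ms, ys, rcond=None)
        return beta[~is_const]

    beta_full = fit(y, m)
    rng = substream(seed, "bootstrap_ols")
    draws = np.empty((n_boot, len(names)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            draws[b] = fit(y[idx], m[idx])
        except ValueError:  # degenerate resample (constant column): redraw
            draws[b] = np.nan
    ok = np.all(np.isfinite(draws), axis=1)
    draws = draws[ok]
    b_eff = draws.shape[0]
    bci = np.percentile(draws, [2.5, 97.5], axis=0).T
    le = (1.0 + np.sum(draws <= 0, axis=0)) / (b_eff + 1.0)
    ge = (1.0 + np.sum(draws >= 0, axis=0)) / (b_eff + 1.0)
    p = np.minimum(1.0, 2.0 * np.minimum(le, ge))
    if len(names) >= 2:
        vifs = vif(df).reindex(names).to_numpy()
    else:  # a lone predictor cannot be inflated by the others
        vifs = np.ones(len(names))
    return BootstrapRegressionResult(
        names=tuple(names), beta_stand=beta_full, bci=bci, p_boot=p,
        vif=vifs, n_boot=n_boot, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _slope(y, *cols):
    x = _add_intercept(np.column_stack(cols))
    beta, _ = _ols(np.asarray(y, dtype=float), x)
    return beta[1:]


def mediate(x, m, y, n_boot: int = 10000, seed: int = 0) -> MediationResult:
    """Simple mediation x -> m -> y with a bootstrapped indirect effect.

    ``a`` is the slope of m ~ x; ``(direct, b)`` come from y ~ x + m;
    the indirect effect is ``a * b`` and the total effect (slope of y ~ x)
    equals direct + indirect exactly by the OLS identity.  The indirect
    effect's 95% percentile bootstrap interval resamples rows jointly; an
    interval excluding zero indicates significant mediation.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(m) == n and len(y) == n):
        raise ValueError("x, m, y must have equal length")
    if n <= 10:
        raise ValueError("need more than 10 observations")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise ValueError(f"variable {name} has zero variance")

    def effects(xx, mm, yy):
        a = _slope(mm, xx)[0]
        direct, b = _slope(yy, xx, mm)
        total = _slope(yy, xx)[0]
        return total, direct, a * b

    total, direct, indirect = effects(x, m, y)
    rng = substream(seed, "mediation")
    draws = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, mb, yb = x[idx], m[idx], y[idx]
        if xb.std() == 0 or mb.std() == 0:
            draws[i] = np.nan
            continue
        draws[i] = effects(xb, mb, yb)[2]
    draws = draws[np.isfinite(draws)]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    prop = indirect / total if total != 0 else np.nan
    return MediationResult(
        total=float(total), direct=float(direct), indirect=float(indirect),
        indirect_bci=(float(lo), float(hi)), proportion_mediated=float(prop),
        n_boot=n_boot, seed=int(seed),
    )
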