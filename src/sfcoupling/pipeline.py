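"""End-to-end cohort analysis.

Orchestrates the full study on one synthetic (or user-supplied) cohort:
functional connectomes (static and windowed), regional SFC and its temporal
variance, wavelet Hurst maps, spin tests of both coupling statistics against
the hierarchy gradient and the biological maps, class-wise ANOVA, whole-brain
and per-class bootstrap standardized regressions with FDR, the
myelin -> Hurst -> temporal-variance mediation model, window-wise SFC-Hurst
co-fluctuation, and cross-subject Fisher combination.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats as sps

from . import connectome as cn
from . import hurst as hu
from . import stats as st
from ._rng import substream
from .synthetic import (
    GroundTruth,
    RegionSet,
    TimeSeriesPanel,
    make_region_set,
    simulate_bold_panel,
    simulate_structural_connectome,
)

__all__ = [
    "CohortSpec",
    "AnalysisConfig",
    "Cohort",
    "CohortResult",
    "MultiSubjectResult",
    "CofluctuationResult",
    "generate_cohort",
    "run_atlas_analysis",
    "run_multisubject",
    "windowed_cofluctuation",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for one synthetic cortical cohort.

    The defaults encode the study conditions the analysis is meant to
    recover: 400 bilateral regions in 5 classes, 1200 timepoints per run,
    a Hurst exponent decreasing from ``hurst_high`` to ``hurst_low`` along
    the hierarchy gradient, a myelin proxy anti-correlated with the
    gradient, and a coupling level driven positively by (standardized)
    myelin and Hurst plus independent noise — so coupling also declines
    along the gradient, the pattern the empirical analyses report.
    """

    n_regions: int = 400
    k_classes: int = 5
    smoothness: float = 0.5
    myelin_slope: float = -0.3
    myelin_noise: float = 0.45
    sc_decay: float = 3.0
    sc_gradient_decay: float = 1.0
    sc_density: float = 0.35
    n_timepoints: int = 1200
    tr: float = 0.72
    hurst_low: float = 0.60
    hurst_high: float = 0.85
    hurst_noise: float = 0.12
    coupling_base: float = 0.5
    coupling_myelin: float = 0.3
    coupling_hurst: float = 0.3
    coupling_noise: float = 0.05


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings; every threshold is a configurable default."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    n_windows: int = 20
    sfc_method: str = "pearson"
    min_pairs: int = 3
    spin_rotations: int = 10000
    n_boot: int = 10000
    hurst_mode: str = "ml"
    variance_quadratic: bool = False
    outlier_sd: float | None = None
    run_cofluctuation: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        cohort = CohortSpec(**d.pop("cohort", {}))
        return cls(cohort=cohort, **d)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cohort:
    regions: RegionSet
    sc: cn.StructuralConnectome
    panel: TimeSeriesPanel
    truth: GroundTruth


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Generate one subject's regions, connectome and BOLD panel."""
    regions = make_region_set(
        spec.n_regions,
        k_classes=spec.k_classes,
        smoothness=spec.smoothness,
        seed=seed,
        myelin_slope=spec.myelin_slope,
        myelin_noise=spec.myelin_noise,
    )
    sc = simulate_structural_connectome(
        regions,
        decay=spec.sc_decay,
        density=spec.sc_density,
        seed=seed,
        gradient_decay=spec.sc_gradient_decay,
    )
    rng = substream(seed, "cohort_profiles")
    rank01 = sps.rankdata(regions.gradient) / regions.n_regions
    h_true = (
        spec.hurst_high
        - (spec.hurst_high - spec.hurst_low) * rank01
        + spec.hurst_noise * rng.standard_normal(regions.n_regions)
    )
    h_true = np.clip(h_true, 0.51, 0.97)
    drive = spec.coupling_myelin * _zscore(regions.myelin) + spec.coupling_hurst * _zscore(h_true)
    coupling = np.clip(
        spec.coupling_base + drive + spec.coupling_noise * rng.standard_normal(regions.n_regions),
        0.05,
        0.95,
    )
    panel, truth = simulate_bold_panel(
        regions, sc, h_true, coupling,
        n_timepoints=spec.n_timepoints, seed=seed, tr=spec.tr,
    )
    return Cohort(regions=regions, sc=sc, panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# single-subject analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CofluctuationResult:
    per_region_r: np.ndarray
    per_region_p: np.ndarray
    p_fdr: np.ndarray
    mean_r: float
    fisher: st.FisherResult


@dataclass(frozen=True)
class CohortResult:
    maps: pd.DataFrame
    spin_table: pd.DataFrame
    anova_table: pd.DataFrame
    posthoc: dict
    whole_brain: dict
    class_tables: dict
    mediation: st.MediationResult
    cofluctuation: CofluctuationResult | None
    outliers_excluded: np.ndarray
    metadata: dict


def _finite_mask(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return mask


def run_atlas_analysis(config: AnalysisConfig, cohort: Cohort | None = None) -> CohortResult:
    """Run the full single-subject analysis and assemble all result tables."""
    if config.sfc_method not in ("pearson", "spearman"):
        raise ValueError("sfc_method must be 'pearson' or 'spearman'")
    if config.n_windows < 2:
        raise ValueError("need at least 2 windows")
    if cohort is None:
        cohort = generate_cohort(config.cohort, config.seed)
    regions, sc, panel = cohort.regions, cohort.sc, cohort.panel

    fc = cn.compute_fc(panel)
    wfc = cn.window_fc(panel, n_windows=config.n_windows)
    sfc = cn.regional_sfc(sc, fc, method=config.sfc_method, min_pairs=config.min_pairs)
    var = cn.temporal_sfc_variance(
        sc, wfc, method=config.sfc_method, min_pairs=config.min_pairs
    )
    hmap = hu.estimate_hurst_map(panel, mode=config.hurst_mode)

    maps = pd.DataFrame(
        {
            "region_id": regions.region_id,
            "hemisphere": regions.hemisphere,
            "gradient": regions.gradient,
            "class_label": regions.class_label,
            "myelin": regions.myelin,
            "sfc": sfc.sfc,
            "var_sfc": var.var_sfc,
            "hurst": hmap.H,
        }
    )

    # optional exclusion of extreme temporal-variance regions
    outliers = np.zeros(regions.n_regions, dtype=bool)
    if config.outlier_sd is not None:
        v = maps["var_sfc"].to_numpy()
        ok = np.isfinite(v)
        mu, sd = v[ok].mean(), v[ok].std()
        outliers = ok & (np.abs(v - mu) > config.outlier_sd * sd)
    keep = ~outliers

    # spin tests of both coupling statistics vs gradient / myelin / Hurst
    spin_rows = []
    targets = {
        "gradient": maps["gradient"].to_numpy(),
        "myelin": maps["myelin"].to_numpy(),
        "hurst": maps["hurst"].to_numpy(),
    }
    for stat_name in ("sfc", "var_sfc"):
        stat = maps[stat_name].to_numpy().copy()
        stat[~keep] = np.nan
        for tgt_name, tgt in targets.items():
            if stat_name == tgt_name:
                continue
            res = st.spin_test(
                stat, tgt, regions,
                n_rotations=config.spin_rotations, seed=config.seed,
            )
            spin_rows.append((stat_name, tgt_name, res.r_emp, res.p_spin, res.n_rotations))
    spin_table = pd.DataFrame(
        spin_rows, columns=["map", "target", "r", "p_spin", "n_rotations"]
    )

    # ANOVA + Tamhane across classes
    anova_rows, posthoc = [], {}
    for stat_name in ("sfc", "var_sfc"):
        vals = maps[stat_name].to_numpy()
        ok = np.isfinite(vals) & keep
        f, p = st.anova_oneway(vals[ok], maps["class_label"].to_numpy()[ok])
        anova_rows.append((stat_name, f, p))
        posthoc[stat_name] = st.tamhane_t2(vals[ok], maps["class_label"].to_numpy()[ok])
    anova_table = pd.DataFrame(anova_rows, columns=["map", "F", "p"])

    # whole-brain bootstrap regressions
    whole_brain = {}
    for stat_name in ("sfc", "var_sfc"):
        y = maps[stat_name].to_numpy()
        ok = _finite_mask(y, maps["hurst"].to_numpy()) & keep
        quad = ("hurst",) if (stat_name == "var_sfc" and config.variance_quadratic) else ()
        design = st.build_design(
            {"myelin": maps["myelin"].to_numpy()[ok], "hurst": maps["hurst"].to_numpy()[ok]},
            interaction=("myelin", "hurst"),
            quadratic_terms=quad,
            covariates={"gradient": maps["gradient"].to_numpy()[ok]},
        )
        whole_brain[stat_name] = st.bootstrap_ols(
            y[ok], design, n_boot=config.n_boot, seed=config.seed
        )

    # per-class regressions with BH-FDR over classes
    class_tables = {}
    for stat_name in ("sfc", "var_sfc"):
        y_all = maps[stat_name].to_numpy()
        rows = {}
        for k in sorted(maps["class_label"].unique()):
            sel = (maps["class_label"].to_numpy() == k) & keep
            y = y_all[sel]
            ok = _finite_mask(y, maps["hurst"].to_numpy()[sel])
            quad = ("hurst",) if (stat_name == "var_sfc" and config.variance_quadratic) else ()
            design = st.build_design(
                {
                    "myelin": maps["myelin"].to_numpy()[sel][ok],
                    "hurst": maps["hurst"].to_numpy()[sel][ok],
                },
                quadratic_terms=quad,
            )
            rows[k] = st.bootstrap_ols(
                y[ok], design, n_boot=config.n_boot, seed=config.seed
            ).table()
        table = pd.concat(rows, names=["class_label", "predictor"])
        for pred in table.index.get_level_values("predictor").unique():
            idx = table.index.get_level_values("predictor") == pred
            table.loc[idx, "p_fdr"] = st.bh_fdr(table.loc[idx, "p_boot"].to_numpy())
        class_tables[stat_name] = table

    # mediation: myelin -> Hurst -> temporal SFC variance
    ok = _finite_mask(
        maps["myelin"].to_numpy(), maps["hurst"].to_numpy(), maps["var_sfc"].to_numpy()
    ) & keep
    mediation = st.mediate(
        maps["myelin"].to_numpy()[ok],
        maps["hurst"].to_numpy()[ok],
        maps["var_sfc"].to_numpy()[ok],
        n_boot=config.n_boot,
        seed=config.seed,
    )

    cofl = (
        windowed_cofluctuation(sc, wfc, panel, method="spearman")
        if config.run_cofluctuation and config.n_windows >= 5
        else None
    )

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_regions": regions.n_regions,
        "n_outliers_excluded": int(outliers.sum()),
        "p_adjustment": {
            "spin_table": "unadjusted permutation p",
            "class_tables": "BH-FDR over classes per predictor",
            "whole_brain": "unadjusted bootstrap p",
        },
    }
    return CohortResult(
        maps=maps,
        spin_table=spin_table,
        anova_table=anova_table,
        posthoc=posthoc,
        whole_brain=whole_brain,
        class_tables=class_tables,
        mediation=mediation,
        cofluctuation=cofl,
        outliers_excluded=outliers,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# windowed SFC-Hurst co-fluctuation
# ---------------------------------------------------------------------------


def windowed_cofluctuation(
    sc: cn.StructuralConnectome,
    wfc: cn.WindowedFC,
    panel: TimeSeriesPanel,
    method: str = "spearman",
    min_pairs: int = 3,
    hurst_mode: str = "ml",
) -> CofluctuationResult:
    """Per-region association between window-wise SFC and window-wise Hurst.

    Window series are short (e.g. 60 samples for 20 windows of a
    1200-volume run), so the per-window Hurst fit uses octaves 1 through
    ``floor(log2 L) - 1``.  The group summary is the mean correlation over
    defined regions with a Fisher combination of the per-region p-values;
    per-region p-values are also BH-FDR adjusted.
    """
    w = wfc.n_windows
    if w < 5:
        raise ValueError("need at least 5 windows for co-fluctuation")
    n = sc.n_regions
    sfc_w = np.full((w, n), np.nan)
    hurst_w = np.full((w, n), np.nan)
    for wi, (a, b) in enumerate(wfc.window_bounds):
        sfc_w[wi] = cn._sfc_from_matrices(sc.weights, wfc.stack[wi], method, min_pairs).sfc
        seg = panel.values[:, a:b]
        length = b - a
        j_max = min(
            int(np.floor(np.log2(length))) - 1,
            pywt.dwt_max_level(length, pywt.Wavelet("sym4").dec_len),
        )
        for i in range(n):
            try:
                hurst_w[wi, i] = hu.estimate_hurst(
                    seg[i], j_min=1, j_max=j_max, mode=hurst_mode
                ).h
            except ValueError:
                pass
    r = np.full(n, np.nan)
    p = np.full(n, np.nan)
    for i in range(n):
        ok = np.isfinite(sfc_w[:, i]) & np.isfinite(hurst_w[:, i])
        if ok.sum() < 5:
            continue
        res = sps.spearmanr(sfc_w[ok, i], hurst_w[ok, i])
        r[i], p[i] = res.statistic, res.pvalue
    defined = np.isfinite(r) & np.isfinite(p)
    if not np.any(defined):
        raise ValueError("co-fluctuation undefined for every region")
    p_fdr = np.full(n, np.nan)
    p_fdr[defined] = st.bh_fdr(p[defined])
    fisher = st.fisher_combine(np.clip(p[defined], 1e-300, 1.0))
    return CofluctuationResult(
        per_region_r=r,
        per_region_p=p,
        p_fdr=p_fdr,
        mean_r=float(np.nanmean(r)),
        fisher=fisher,
    )


# ---------------------------------------------------------------------------
# multi-subject analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiSubjectResult:
    spin_table: pd.DataFrame
    regression_table: pd.DataFrame
    n_subjects: int
    metadata: dict


def run_multisubject(config: AnalysisConfig, n_subjects: int) -> MultiSubjectResult:
    """Per-subject statistics summarized as mean, [min, max] range, and a
    Fisher-combined p-value — the multi-subject reporting convention."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    spin_rows, beta_rows = [], []
    for s in range(n_subjects):
        sub_seed = int(substream(config.seed, "subject", s).integers(2**31))
        sub_config = AnalysisConfig(**{**config.to_dict(), "cohort": config.cohort, "seed": sub_seed})
        try:
            res = run_atlas_analysis(sub_config)
        except Exception as exc:  # noqa: BLE001 - abort naming the subject
            raise RuntimeError(f"subject {s} failed: {exc}") from exc
        for _, row in res.spin_table.iterrows():
            spin_rows.append((s, row["map"], row["target"], row["r"], row["p_spin"]))
        for stat_name, reg in res.whole_brain.items():
            for name, beta, p in zip(reg.names, reg.beta_stand, reg.p_boot):
                beta_rows.append((s, stat_name, name, beta, p))

    spin_df = pd.DataFrame(spin_rows, columns=["subject", "map", "target", "r", "p"])
    spin_summary = (
        spin_df.groupby(["map", "target"])
        .apply(_summarize, include_groups=False)
        .reset_index()
    )
    beta_df = pd.DataFrame(beta_rows, columns=["subject", "map", "predictor", "r", "p"])
    beta_summary = (
        beta_df.groupby(["map", "predictor"])
        .apply(_summarize, include_groups=False)
        .reset_index()
    )
    return MultiSubjectResult(
        spin_table=spin_summary,
        regression_table=beta_summary,
        n_subjects=n_subjects,
        metadata={"seed": config.seed, "fisher_df": 2 * n_subjects},
    )


def _summarize(g: pd.DataFrame) -> pd.Series:
    fisher = st.fisher_combine(np.clip(g["p"].to_numpy(), 1e-300, 1.0))
    return pd.Series(
        {
            "mean": g["r"].mean(),
            "min": g["r"].min(),
            "max": g["r"].max(),
            "T_fisher": fisher.T,
            "df": fisher.df,
            "p_fisher": fisher.p_fisher,
        }
    )
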