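"""Scratch wound-healing assay: wound detection and closure kinetics.

The cell-free scratch is detected as the largest connected low-texture
region of a frame (local standard deviation below an Otsu cut on the
texture map), which works for both phase-contrast and fluorescence movies.
Per-series areas are normalised to the first frame
(``percent(t) = 100 * area(t) / area(0)``), and closure across groups is
modelled with a mixed-effects linear regression,

    percent ~ 1 + time + group + group:time  +  (1 | replicate),

fitted by REML.  The group-by-time interaction is the difference in
closure slope (%/h) between each group and the reference; its Wald test
uses a t reference with within-replicate degrees of freedom (Pinheiro &
Bates style), which is better calibrated than the normal reference at the
handful of replicates typical of these assays and matches lmerTest's
Satterthwaite df for balanced designs.  Bonferroni correction over the non-reference groups is
applied for the per-group contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage import filters, morphology

__all__ = [
    "WoundSeries",
    "ClosureModelFit",
    "detect_wound",
    "percent_closure",
    "fit_closure_model",
]


@dataclass
class WoundSeries:
    """One replicate's wound areas over time for one construct group."""

    group: str
    replicate_id: str | int
    times: np.ndarray              # hours, strictly increasing from 0
    areas: np.ndarray              # pixels per frame
    percent: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.areas = np.asarray(self.areas, float)
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must increase strictly from 0")
        if np.any(self.areas < 0):
            raise ValueError("areas must be >= 0")
        self.percent = percent_closure(self.areas)


def local_std(image: np.ndarray, window: int) -> np.ndarray:
    """Windowed standard deviation (uniform window, reflective borders)."""
    img = np.asarray(image, float)
    mean = ndi.uniform_filter(img, window, mode="reflect")
    sq = ndi.uniform_filter(img * img, window, mode="reflect")
    return np.sqrt(np.clip(sq - mean * mean, 0.0, None))


def detect_wound(frame: np.ndarray, texture_window: int = 15,
                 min_contrast: float = 0.3) -> tuple[np.ndarray, int]:
    """Segment the cell-free wound as the largest low-texture region.

    Returns ``(mask, area_px)``.  A wound is only accepted when the Otsu
    split of the texture map is a genuine split: the mean texture of the
    low class must be below ``min_contrast`` times that of the high class.
    Otherwise (fully confluent field, uniform texture) the area is 0 and a
    warning is emitted.
    """
    tex = local_std(frame, texture_window)
    if np.ptp(tex) == 0:
        warnings.warn("texture map is constant; no wound detected")
        return np.zeros(frame.shape, bool), 0
    low = tex < filters.threshold_otsu(tex)
    if not low.any() or low.all():
        warnings.warn("degenerate texture split; no wound detected")
        return np.zeros(frame.shape, bool), 0
    if tex[low].mean() > min_contrast * tex[~low].mean():
        warnings.warn("no textureless region distinct from the monolayer; "
                      "no wound detected")
        return np.zeros(frame.shape, bool), 0
    lab, n = ndi.label(low, structure=np.ones((3, 3), int))
    if n == 0:
        warnings.warn("no low-texture region; no wound detected")
        return np.zeros(frame.shape, bool), 0
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    wound = lab == (1 + int(np.argmax(sizes)))
    # the windowed std erodes the wound by ~window/2 on every side (pixels
    # whose window straddles the edge see cell texture); dilating by the
    # window half-width restores the boundary to first order
    half = max(1, (texture_window - 1) // 2)
    wound = ndi.binary_dilation(wound, structure=morphology.disk(half))
    return wound, int(wound.sum())


def percent_closure(series_areas: np.ndarray) -> np.ndarray:
    """Areas normalised to the first frame, in percent (first value 100)."""
    areas = np.asarray(series_areas, float)
    if areas[0] <= 0:
        raise ValueError("no initial wound: area(0) must be > 0")
    # divide first: a/a == 1.0 exactly in IEEE, so percent[0] is exactly 100
    return 100.0 * (areas / areas[0])


@dataclass
class ClosureModelFit:
    """REML fit of the random-intercept closure regression.

    ``params``/``bse`` hold the fixed effects (patsy-style names);
    ``sigma_u2`` and ``sigma_e2`` are the replicate-intercept and residual
    variances.  ``contrasts`` is one row per non-reference group with the
    interaction estimate (slope difference, %/h), its SE, 95% CI, raw
    Wald-t p-value and Bonferroni-adjusted p-value.
    """

    reference_group: str
    params: pd.Series
    bse: pd.Series
    sigma_u2: float
    sigma_e2: float
    df_resid: float
    contrasts: pd.DataFrame
    converged: bool

    @property
    def baseline_slope(self) -> float:
        """Closure slope of the reference group, %/h."""
        return float(self.params["time"])

    def slope_difference(self, group: str) -> float:
        return float(self.contrasts.loc[group, "estimate"])


def fit_closure_model(series, reference_group: str,
                      random_slopes: bool = False,
                      conf_level: float = 0.95) -> ClosureModelFit:
    """Fit percent-closure trajectories with a mixed-effects model.

    ``series`` is a list of :class:`WoundSeries` or an equivalent tidy
    DataFrame with columns ``group``, ``replicate``, ``time``, ``percent``
    (the form produced by batch CSV input, and convenient for model-level
    simulations).  Requires at least two groups, two replicates per group
    and three time points.  The random effect is a per-replicate intercept
    by default (``random_slopes=True`` adds a random time slope).  Group
    contrasts versus ``reference_group`` are Wald t tests on the
    group-by-time interaction, Bonferroni-corrected over groups.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if isinstance(series, pd.DataFrame):
        data = series[["group", "replicate", "time", "percent"]].copy()
    else:
        rows = []
        for s in series:
            for t, p in zip(s.times, s.percent):
                rows.append({"group": s.group,
                             "replicate": f"{s.group}/{s.replicate_id}",
                             "time": t, "percent": p})
        data = pd.DataFrame(rows)
    groups = sorted(data["group"].unique())
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if data["time"].nunique() < 3:
        raise ValueError("need at least three time points")
    per_group = data.groupby("group")["replicate"].nunique()
    if (per_group < 2).any():
        raise ValueError("need at least two replicates per group")

    formula = (f"percent ~ C(group, Treatment('{reference_group}')) * time")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # RE at boundary
        model = smf.mixedlm(formula, data, groups=data["replicate"],
                            re_formula="~time" if random_slopes else "1")
        fit = model.fit(reml=True)

    params, bse = fit.fe_params, fit.bse_fe
    # within-replicate (level-1) degrees of freedom for time-varying terms,
    # after Pinheiro & Bates: observations minus replicates minus the number
    # of fixed terms estimated from within-replicate variation
    n_rep = data["replicate"].nunique()
    n_within_terms = sum("time" in name for name in params.index)
    df_resid = float(len(data) - n_rep - n_within_terms)
    tcrit = sps.t.ppf(0.5 + conf_level / 2, df_resid)

    others = [g for g in groups if g != reference_group]
    recs = []
    for g in others:
        name = f"C(group, Treatment('{reference_group}'))[T.{g}]:time"
        est, se = float(params[name]), float(bse[name])
        tval = est / se
        p = 2 * sps.t.sf(abs(tval), df_resid)
        recs.append({"group": g, "estimate": est, "se": se,
                     "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
                     "t": tval, "p_raw": p,
                     "p_adj": min(1.0, len(others) * p)})
    contrasts = pd.DataFrame(recs).set_index("group")

    sigma_u2 = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    return ClosureModelFit(
        reference_group=reference_group,
        params=params,
        bse=bse,
        sigma_u2=sigma_u2,
        sigma_e2=float(fit.scale),
        df_resid=df_resid,
        contrasts=contrasts,
        converged=bool(fit.converged),
    )
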