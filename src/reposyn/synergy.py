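"""Median-effect dose-response fitting and Chou-Talalay combination indices.

The median-effect model fa/fu = (D/Dm)^m (fa = fraction affected,
fu = 1 - fa) is linear in log coordinates: log(fa/fu) = m*log(D) - m*log(Dm).
A series is fitted by ordinary least squares of log10(fa/fu) on log10(D);
the slope is m, the median-effect dose Dm = 10^(-intercept/m), and the
Pearson correlation r of the linearization gauges fit quality (fits with
r < 0.90 or fewer than 3 usable points are invalid and void downstream
indices rather than producing one).

For a combination point with doses (d1, d2) and observed combined effect
fa, the combination index is CI = d1/Dx1(fa) + d2/Dx2(fa) with
Dx_k(fa) = Dm_k*(fa/fu)^(1/m_k) from the single-agent fits (mutually
exclusive Loewe form, no product term). A pair is called synergistic when
its mean CI over tested concentrations is strictly below 0.8.

Also here: the shRNA-screen depletion binning used to grade sensitizer
hits (>30% strong, 20-30% moderate, 10-20% weak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, FitError, InputError
from .simulate import FA_EPSILON

R_MIN_DEFAULT = 0.90          # linear-fit validity floor
CI_SYNERGY_DEFAULT = 0.8      # mean CI strictly below this calls a pair synergistic


def viability_to_fa(viability_pct, epsilon: float = FA_EPSILON):
    """Fraction affected from percent viability: fa = clamp(1 - v/100, eps, 1-eps)."""
    v = np.asarray(viability_pct, dtype=float)
    if (v < 0).any():
        raise InputError("viability_pct must be non-negative")
    fa = np.clip(1.0 - v / 100.0, epsilon, 1.0 - epsilon)
    return float(fa) if np.isscalar(viability_pct) else fa


@dataclass
class MedianEffectFit:
    """Parameters of one median-effect fit.

    m: slope (sigmoidicity); dm: median-effect dose (IC50 under the model),
    in the dose units of the input; r: Pearson correlation of the
    linearized fit; n_points: doses used; n_clamped: boundary points
    excluded before fitting.
    """

    m: float
    dm: float
    r: float
    n_points: int
    n_clamped: int = 0
    r_min: float = R_MIN_DEFAULT
    log_dose: np.ndarray = field(default=None, repr=False)
    logit_fa: np.ndarray = field(default=None, repr=False)

    @property
    def valid(self) -> bool:
        return (self.n_points >= 3 and np.isfinite(self.m) and np.isfinite(self.dm)
                and self.m > 0 and self.dm > 0 and self.r >= self.r_min)


def fit_median_effect(doses, fa, r_min: float = R_MIN_DEFAULT,
                      epsilon: float = FA_EPSILON) -> MedianEffectFit:
    """OLS fit of the median-effect linearization to one dose-effect series.

    Points with fa at the clamp boundary are excluded (their logit is an
    artefact of clamping) and counted in ``n_clamped``. Fewer than 3 usable
    distinct doses raise :class:`FitError`.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise InputError("doses and fa must have the same length")
    if (doses <= 0).any():
        raise InputError("doses must be strictly positive")
    usable = (fa > epsilon) & (fa < 1.0 - epsilon)
    n_clamped = int((~usable).sum())
    doses, fa = doses[usable], fa[usable]
    if len(np.unique(doses)) < 3:
        raise FitError(f"median-effect fit needs >=3 distinct usable doses, "
                       f"got {len(np.unique(doses))} ({n_clamped} clamped points excluded)")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    # a perfectly collinear fit can return rvalue rounding above 1
    r = min(r, 1.0)
    dm = 10.0 ** (-res.intercept / m) if m != 0 else math.inf
    return MedianEffectFit(m, float(dm), r, int(doses.size), n_clamped, r_min, x, y)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing effect level fa: Dx = Dm*(fa/(1-fa))^(1/m)."""
    if not fit.valid:
        raise FitError("cannot compute Dx from an invalid median-effect fit")
    if not 0.0 < fa < 1.0:
        raise InputError(f"fa must be strictly inside (0, 1), got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def ic50(fit: MedianEffectFit) -> float | None:
    """IC50 under the median-effect model (= Dm); None for invalid fits."""
    return float(fit.dm) if fit.valid else None


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      d1: float, d2: float, fa_combo: float) -> float:
    """Chou-Talalay CI of one combination point: d1/Dx1(fa) + d2/Dx2(fa)."""
    if not (fit1.valid and fit2.valid):
        raise FitError("both single-agent fits must be valid to compute CI")
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise InputError("doses must be non-negative and not both zero")
    if not 0.0 < fa_combo < 1.0:
        raise InputError(f"fa_combo must be strictly inside (0, 1), got {fa_combo}")
    ci = 0.0
    if d1 > 0:
        ci += d1 / dose_for_effect(fit1, fa_combo)
    if d2 > 0:
        ci += d2 / dose_for_effect(fit2, fa_combo)
    return float(ci)


# ---------------------------------------------------------------------------
# Pair evaluation from dose-response tables
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Synergy assessment of one drug pair in one cell line.

    ``points`` columns: dose1, dose2, fa, ci, synergistic_point.
    ``synergistic`` is True when mean CI over valid points is strictly
    below the threshold; ``reason`` explains unevaluable pairs.
    """

    cell_line: str
    drug1: str
    drug2: str
    points: pd.DataFrame
    mean_ci: float | None
    synergistic: bool | None
    fit1: MedianEffectFit | None = None
    fit2: MedianEffectFit | None = None
    ci_threshold: float = CI_SYNERGY_DEFAULT
    evaluable: bool = True
    reason: str = ""

    @property
    def n_points(self) -> int:
        return 0 if self.points is None else len(self.points)


def _average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean viability over replicates per (dose1, dose2), on the viability scale."""
    return (table.groupby(["dose1", "dose2"], as_index=False)["viability_pct"]
            .mean())


def fit_series(table: pd.DataFrame, r_min: float = R_MIN_DEFAULT,
               average_replicates: bool = True) -> MedianEffectFit:
    """Fit the median-effect model to a single-agent dose-response table."""
    tbl = _average_replicates(table) if average_replicates else table
    doses = tbl["dose1"].to_numpy() + tbl["dose2"].to_numpy()
    fa = viability_to_fa(tbl["viability_pct"].to_numpy())
    return fit_median_effect(doses, fa, r_min=r_min)


def evaluate_pair(single1: pd.DataFrame, single2: pd.DataFrame,
                  combo: pd.DataFrame, ci_threshold: float = CI_SYNERGY_DEFAULT,
                  r_min: float = R_MIN_DEFAULT,
                  average_replicates: bool = True) -> ScreenResult:
    """CI screen of one drug pair from its three dose-response series.

    The single-agent series are fitted; each combination point (replicates
    averaged on the viability scale by default) contributes
    CI = d1/Dx1(fa) + d2/Dx2(fa) at its observed fa. The pair-level call
    is mean CI < ci_threshold (strict); per-point flags are retained.
    An invalid single-agent fit marks the pair unevaluable with the reason.
    """
    cell_lines = set(single1["cell_line"]) | set(single2["cell_line"]) | set(combo["cell_line"])
    if len(cell_lines) != 1:
        raise InputError(f"pair evaluation mixes cell lines: {sorted(cell_lines)}")
    cell_line = cell_lines.pop()
    drug1 = combo["drug1"].iloc[0]
    drug2 = combo["drug2"].iloc[0]

    fits, names = [], []
    for tbl, name in ((single1, drug1), (single2, drug2)):
        try:
            fit = fit_series(tbl, r_min=r_min, average_replicates=average_replicates)
        except FitError as exc:
            return ScreenResult(cell_line, drug1, drug2, pd.DataFrame(), None, None,
                                ci_threshold=ci_threshold, evaluable=False,
                                reason=f"single-agent fit failed for {name}: {exc}")
        fits.append(fit)
        names.append(name)
    fit1, fit2 = fits
    for fit, name in zip(fits, names):
        if not fit.valid:
            return ScreenResult(cell_line, drug1, drug2, pd.DataFrame(), None, None,
                                fit1, fit2, ci_threshold, evaluable=False,
                                reason=f"invalid median-effect fit for {name} "
                                       f"(m={fit.m:.3g}, r={fit.r:.3g})")

    pts = _average_replicates(combo) if average_replicates else combo
    rows = []
    for _, row in pts.iterrows():
        fa = viability_to_fa(row["viability_pct"])
        if not FA_EPSILON < fa < 1.0 - FA_EPSILON:
            rows.append((row["dose1"], row["dose2"], fa, np.nan, None))
            continue
        ci = combination_index(fit1, fit2, row["dose1"], row["dose2"], fa)
        rows.append((row["dose1"], row["dose2"], fa, ci, ci < ci_threshold))
    points = pd.DataFrame(rows, columns=["dose1", "dose2", "fa", "ci", "synergistic_point"])
    valid_ci = points["ci"].dropna()
    if valid_ci.empty:
        return ScreenResult(cell_line, drug1, drug2, points, None, None, fit1, fit2,
                            ci_threshold, evaluable=False,
                            reason="no combination point with usable fa")
    mean_ci = float(valid_ci.mean())
    return ScreenResult(cell_line, drug1, drug2, points, mean_ci,
                        mean_ci < ci_threshold, fit1, fit2, ci_threshold)


def screen_to_table(results) -> pd.DataFrame:
    """Summarize ScreenResults as one row per (cell_line, drug pair)."""
    rows = []
    for r in results:
        rows.append({
            "cell_line": r.cell_line, "drug1": r.drug1, "drug2": r.drug2,
            "n_points": r.n_points, "mean_ci": r.mean_ci,
            "synergistic": r.synergistic, "evaluable": r.evaluable,
            "reason": r.reason,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shRNA depletion classification
# ---------------------------------------------------------------------------

DEPLETION_STRONG, DEPLETION_MODERATE, DEPLETION_WEAK, DEPLETION_BELOW = \
    "strong", "moderate", "weak", "below"


def gene_level_depletion(screen: pd.DataFrame) -> pd.Series:
    """Relative depletion per gene: 1 - mean(treated)/mean(reference) over its shRNAs."""
    grouped = screen.groupby("gene")[["reference", "treated"]].mean()
    return (1.0 - grouped["treated"] / grouped["reference"]).rename("depletion")


def classify_depletion(depletion: float, unit: str = "fraction") -> str:
    """Bin a gene-level relative depletion: strong >30%, moderate (20,30]%,
    weak (10,20]%, below otherwise."""
    if unit == "percent":
        frac = depletion / 100.0
    elif unit == "fraction":
        frac = float(depletion)
    else:
        raise ConfigError(f"unit must be 'fraction' or 'percent', got {unit!r}")
    if frac > 1.0:
        raise InputError(f"depletion above 100% is impossible, got {frac:.3g}")
    if frac > 0.30:
        return DEPLETION_STRONG
    if frac > 0.20:
        return DEPLETION_MODERATE
    if frac > 0.10:
        return DEPLETION_WEAK
    return DEPLETION_BELOW
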