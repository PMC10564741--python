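"""Moderated two-group differential expression and consensus signatures.

Implements the empirical-Bayes moderated t framework for a two-group
design: per-gene ordinary statistics (log2 fold change, pooled variance),
hyperparameter estimation by fitting a scaled F distribution to the sample
variances (method of moments on log s2), variance shrinkage, moderated t
and p-values, and the B statistic (log posterior odds of differential
expression under a two-component normal hierarchy).

On top sit the consensus-signature rules used to define an oncogene
signature across several experimental systems: a gene is called in one
study when B > 0 and its linear fold change exceeds 1.5 (up) or falls
below 0.75 (down), and enters the consensus when called in the same
direction in at least two studies. A generic ratio/p filter for
proteomics-style tables (0.8/1.2 bands, p < 0.05) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import ConfigError, FitError, InputError
from .simulate import ExpressionStudy

CALL_UP, CALL_DOWN, CALL_NONE = "up", "down", "none"


# ---------------------------------------------------------------------------
# Per-gene two-group statistics
# ---------------------------------------------------------------------------

@dataclass
class GeneStats:
    """Per-gene statistics for one study.

    ``table`` columns before moderation: logFC, s2, df. After
    :func:`ebayes_moderation`: s2_post, t_mod, p, B as well.
    ``leverage`` is the design constant c with var(logFC) = c * sigma^2
    (1/n1 + 1/n2 for the two-group difference).
    """

    study_id: str
    table: pd.DataFrame
    df_residual: float
    leverage: float


def gene_stats(study: ExpressionStudy) -> GeneStats:
    """Ordinary two-group statistics: logFC, pooled variance, residual df."""
    cond = study.matrix.loc[:, (study.group == "condition").to_numpy()]
    ctrl = study.matrix.loc[:, (study.group == "control").to_numpy()]
    n1, n2 = cond.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError(f"{study.study_id}: each group needs >=2 samples (got {n1}, {n2})")
    logfc = cond.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((cond.sub(cond.mean(axis=1), axis=0)) ** 2).sum(axis=1) + \
         ((ctrl.sub(ctrl.mean(axis=1), axis=0)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    table = pd.DataFrame({"logFC": logfc, "s2": ss / df, "df": float(df)})
    return GeneStats(study.study_id, table, float(df), 1.0 / n1 + 1.0 / n2)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass
class EBayesParams:
    """Hyperparameters of the hierarchical variance/effect model.

    d0: prior degrees of freedom (may be +inf); s0_sq: prior variance;
    pi_de: assumed proportion of differentially expressed genes;
    v0_ratio: prior variance of a true effect relative to its sampling
    variance under the alternative (floored so B stays finite).
    """

    d0: float
    s0_sq: float
    pi_de: float = 0.01
    v0_ratio: float = float("nan")

    def __post_init__(self):
        if not (self.d0 >= 0):  # 0 = no-shrinkage limit, inf = full shrinkage
            raise ConfigError(f"d0 must be non-negative, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ConfigError(f"s0_sq must be positive, got {self.s0_sq}")
        if not 0 < self.pi_de < 1:
            raise ConfigError(f"pi_de must be in (0,1), got {self.pi_de}")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (d0, s0_sq) so that s2 ~ s0_sq * F(df, d0), by moments of log s2.

    Genes with s2 = 0 are excluded from estimation; at least 10 positive
    variances are required.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise FitError("all gene variances are zero: hyperparameters of the "
                       "variance prior cannot be estimated from constant data")
    if pos.size < 10:
        raise FitError(f"need >=10 genes with positive variance, got {pos.size}")
    e = np.log(pos) - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return float(d0), float(s0_sq)


def _estimate_v0_ratio(t_mod: np.ndarray, df_total: np.ndarray, pi_de: float,
                       floor: float = 0.1, ceiling: float = 1e4) -> float:
    """Prior effect-variance ratio v0/c from the most extreme |t| values.

    Target-quantile method: the top ceil(pi_de/2 * n) |t| statistics are
    matched to the quantiles they would occupy under the mixture with a
    fraction pi_de of true effects; each yields a variance-ratio estimate
    (t/q)^2 - 1, averaged after clipping to [floor, ceiling].
    """
    t = np.abs(np.asarray(t_mod, dtype=float))
    n = t.size
    ntarget = int(math.ceil(pi_de / 2.0 * n))
    if ntarget < 1:
        return floor
    p = max(ntarget / n, pi_de)
    order = np.argsort(-t)[:ntarget]
    ttarget = t[order]
    dft = np.asarray(df_total, dtype=float)[order]
    p0 = 2.0 * stats.t.sf(ttarget, dft)
    rank = np.arange(1, ntarget + 1)
    ptarget = ((rank - 0.5) / n - (1.0 - p) * p0) / p
    v0 = np.full(ntarget, floor)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.ppf(ptarget[pos] / 2.0, dft[pos])  # negative tail quantile
        v0[pos] = (ttarget[pos] / qtarget) ** 2 - 1.0
    return float(np.clip(v0, floor, ceiling).mean())


def ebayes_moderation(gstats: GeneStats, pi_de: float = 0.01,
                      d0_override: float | None = None) -> tuple[EBayesParams, GeneStats]:
    """Complete GeneStats with moderated t, p and B.

    Shrinks each gene's variance toward the prior:
    s2_post = (d0*s0_sq + df*s2)/(d0 + df); t_mod = logFC/sqrt(s2_post * c);
    p from a t distribution on df + d0 degrees of freedom (capped at the
    pooled df when d0 is infinite); B is the log posterior odds of
    differential expression. ``d0_override`` forces the prior df (0 gives
    the ordinary t; inf gives full shrinkage), mainly for limit checks.
    """
    tbl = gstats.table
    s2 = tbl["s2"].to_numpy()
    df = gstats.df_residual
    c = gstats.leverage
    n_genes = len(tbl)

    if d0_override is None:
        d0, s0_sq = fit_variance_prior(s2, df)
    else:
        d0 = float(d0_override)
        if d0 < 0:
            raise ConfigError("d0 must be non-negative")
        try:
            _, s0_sq = fit_variance_prior(s2, df)
        except FitError:
            if d0 == 0:
                s0_sq = float(np.mean(s2)) or 1.0  # unused when d0 = 0
            else:
                raise

    if math.isinf(d0):
        s2_post = np.full(n_genes, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

    with np.errstate(divide="ignore"):
        t_mod = tbl["logFC"].to_numpy() / np.sqrt(s2_post * c)
    # cap total df at the pooled residual df so d0 = inf keeps a proper reference
    df_pooled = df * n_genes
    df_total = np.full(n_genes, min(df + d0, df_pooled))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    v0_ratio = _estimate_v0_ratio(t_mod, df_total, pi_de)
    r = 1.0 + v0_ratio
    t2 = t_mod ** 2
    kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    b = math.log(pi_de / (1.0 - pi_de)) - 0.5 * math.log(r) + kernel

    out = tbl.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = p
    out["B"] = b
    params = EBayesParams(d0, s0_sq, pi_de, v0_ratio)
    return params, GeneStats(gstats.study_id, out, df, c)


# ---------------------------------------------------------------------------
# Signature calls and consensus
# ---------------------------------------------------------------------------

def call_study_signature(gstats: GeneStats, fc_up: float = 1.5, fc_down: float = 0.75,
                         b_min: float = 0.0) -> pd.Series:
    """Per-gene call in one study: up/down/none.

    Thresholds are linear fold-change ratios: up requires B > b_min and
    logFC > log2(fc_up); down requires B > b_min and logFC < log2(fc_down).
    (A down bound of 0.75 only denotes depletion on the ratio scale, hence
    the log2 interpretation.)
    """
    if fc_down >= fc_up:
        raise ConfigError(f"fc_down ({fc_down}) must be < fc_up ({fc_up})")
    tbl = gstats.table
    if "B" not in tbl.columns:
        raise InputError("GeneStats not moderated yet: run ebayes_moderation first")
    logfc = tbl["logFC"]
    b = tbl["B"]
    calls = pd.Series(CALL_NONE, index=tbl.index, name=gstats.study_id)
    calls[(b > b_min) & (logfc > math.log2(fc_up))] = CALL_UP
    calls[(b > b_min) & (logfc < math.log2(fc_down))] = CALL_DOWN
    return calls


@dataclass
class ConsensusSignature:
    """Consensus up/down gene sets with the per-study call matrix behind them."""

    up: set[str]
    down: set[str]
    calls: pd.DataFrame           # genes x studies, values in {up, down, none}
    min_studies: int = 2
    ambiguous: list[str] = field(default_factory=list)  # reached both quotas; excluded

    def __post_init__(self):
        if self.up & self.down:
            raise InputError("up and down sets overlap")


def consensus_signature(calls: pd.DataFrame | dict[str, pd.Series],
                        min_studies: int = 2) -> ConsensusSignature:
    """Assemble the consensus signature from per-study calls.

    A gene enters ``up`` when called up in at least ``min_studies`` studies
    (likewise ``down``); genes reaching both quotas are excluded and listed
    as ambiguous. When passed a dict of per-study Series the gene universe
    is their index intersection.
    """
    if isinstance(calls, dict):
        if len(calls) < 2:
            raise InputError("need calls from >=2 studies")
        common = None
        for s in calls.values():
            common = s.index if common is None else common.intersection(s.index)
        if len(common) == 0:
            raise InputError("empty gene intersection across studies")
        calls = pd.DataFrame({k: s.loc[common] for k, s in calls.items()})
    if calls.shape[1] < 2:
        raise InputError("need calls from >=2 studies")
    if calls.shape[0] == 0:
        raise InputError("empty gene intersection across studies")
    n_up = (calls == CALL_UP).sum(axis=1)
    n_down = (calls == CALL_DOWN).sum(axis=1)
    up = set(calls.index[n_up >= min_studies])
    down = set(calls.index[n_down >= min_studies])
    ambiguous = sorted(up & down)
    up -= set(ambiguous)
    down -= set(ambiguous)
    return ConsensusSignature(up, down, calls, min_studies, ambiguous)


def signature_from_studies(studies, fc_up: float = 1.5, fc_down: float = 0.75,
                           b_min: float = 0.0, min_studies: int = 2,
                           pi_de: float = 0.01) -> ConsensusSignature:
    """Convenience wrapper: gene_stats -> ebayes -> calls -> consensus."""
    calls = {}
    for study in studies:
        _, moderated = ebayes_moderation(gene_stats(study), pi_de=pi_de)
        calls[study.study_id] = call_study_signature(moderated, fc_up, fc_down, b_min)
    return consensus_signature(calls, min_studies)


# ---------------------------------------------------------------------------
# Generic ratio/p filter (proteomics-style)
# ---------------------------------------------------------------------------

def fc_p_filter(table: pd.DataFrame, low: float = 0.8, high: float = 1.2,
                p_max: float = 0.05) -> pd.Series:
    """Classify features as up/down/unchanged from a ratio and a p-value.

    up requires ratio > high and p < p_max; down requires ratio < low and
    p < p_max; boundaries are excluded (strict inequalities). ``table``
    needs columns 'ratio' and 'p'.
    """
    if low >= high:
        raise ConfigError(f"low ({low}) must be < high ({high})")
    for col in ("ratio", "p"):
        if col not in table.columns:
            raise InputError(f"table lacks required column {col!r}")
    ratio, p = table["ratio"], table["p"]
    if (ratio <= 0).any():
        raise InputError("ratios must be strictly positive")
    if ((p <= 0) | (p > 1)).any():
        raise InputError("p-values must be in (0, 1]")
    out = pd.Series("unchanged", index=table.index)
    out[(ratio > high) & (p < p_max)] = CALL_UP
    out[(ratio < low) & (p < p_max)] = CALL_DOWN
    return out
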