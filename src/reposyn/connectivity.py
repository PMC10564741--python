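"""Connectivity scoring of a query signature against a perturbagen compendium.

Each condition profile (one cell line / dose / time point of one
perturbagen) is ranked by differential z-score and scored against the
query's up and down gene sets with a weighted Kolmogorov-Smirnov running
sum (weight w = 1 by default; w = 0 gives the classic KS statistic). The
two enrichment scores combine into a signed connectivity score
WTCS = (ES_up - ES_down)/2 when the components have opposite signs and 0
otherwise; negative WTCS means the perturbagen reverses the query.

Per-perturbagen aggregation is the mean of within-cell-line mean WTCS
(so frequently assayed cell lines carry no extra weight), giving the
repurposing score RS. Candidate reversers are perturbagens measured in
strictly more than 10 conditions with RS strictly below -0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .simulate import SignatureCompendium

log = logging.getLogger(__name__)


@dataclass
class QuerySignature:
    """Up/down query gene sets (either may be empty, not both)."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.up, self.down = set(self.up), set(self.down)
        if not self.up and not self.down:
            raise InputError("query signature has no genes in either tail")
        if self.up & self.down:
            raise InputError(f"query up/down sets overlap: {sorted(self.up & self.down)[:5]}")

    def restrict(self, universe: pd.Index) -> tuple["QuerySignature", int]:
        """Drop members absent from the compendium; returns (query, n_dropped)."""
        uni = set(universe)
        up, down = self.up & uni, self.down & uni
        dropped = len(self.up) + len(self.down) - len(up) - len(down)
        if dropped:
            log.warning("%d query genes absent from compendium were dropped", dropped)
        if not up and not down:
            raise InputError("no query genes overlap the compendium gene universe")
        return QuerySignature(up, down), dropped


def rank_profile(profile: pd.Series) -> pd.Index:
    """Gene ids ordered by descending score; ties broken by ascending gene id."""
    if profile.isna().any():
        raise InputError("profile contains missing scores")
    order = np.lexsort((profile.index.to_numpy(dtype=object), -profile.to_numpy()))
    return profile.index[order]


def enrichment_score(ranked_scores: pd.Series, gene_set, w: float = 1.0) -> float:
    """Weighted-KS enrichment score of ``gene_set`` in a ranked profile.

    ``ranked_scores`` must already be ordered (descending score). Hits
    advance the running sum by |score|^w normalized to the set's total
    weight (w = 0: each hit counts 1/Nh); misses retreat it by 1/(N - Nh).
    ES is the running sum at its maximum absolute deviation, in [-1, 1].
    """
    n = len(ranked_scores)
    hit = ranked_scores.index.isin(set(gene_set))
    nh = int(hit.sum())
    if nh == 0:
        raise InputError("gene set has no members in the ranked list")
    if nh >= n:
        raise InputError("gene set covers the whole list; ES undefined")
    if w == 0:
        inc = hit / nh
    else:
        weights = np.abs(ranked_scores.to_numpy()) ** w
        total = weights[hit].sum()
        if total == 0:  # all hit scores exactly zero: fall back to equal weights
            inc = hit / nh
        else:
            inc = np.where(hit, weights, 0.0) / total
    dec = (~hit) / (n - nh)
    running = np.cumsum(inc - dec)
    i_star = int(np.argmax(np.abs(running)))
    return float(running[i_star])


def wtcs(es_up: float | None, es_down: float | None) -> float:
    """Two-sided connectivity score from tail enrichment scores.

    Opposite signs combine to (es_up - es_down)/2; same signs (including
    either being 0) give 0. One-tailed queries pass the single available
    ES through unchanged.
    """
    if es_up is None and es_down is None:
        raise InputError("at least one tail ES is required")
    if es_down is None:
        return float(es_up)
    if es_up is None:
        return float(-es_down)  # keep negative = reversal for a down-only query
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


@dataclass
class ConnectivityResult:
    """Per-condition scores plus per-perturbagen aggregates.

    ``conditions`` columns: perturbagen, cell_line, es_up, es_down, wtcs.
    ``perturbagens`` columns: rs, n_conditions, n_cell_lines.
    """

    conditions: pd.DataFrame
    perturbagens: pd.DataFrame
    dropped_query_genes: int = 0


def score_and_aggregate(query: QuerySignature, compendium: SignatureCompendium,
                        w: float = 1.0) -> ConnectivityResult:
    """Score every condition and aggregate to repurposing scores.

    RS(perturbagen) = mean over cell lines of the within-cell-line mean
    WTCS; n_conditions counts every scored condition of the perturbagen.
    """
    if compendium.profiles.shape[1] == 0:
        raise InputError("compendium contains no conditions")
    query, dropped = query.restrict(compendium.gene_ids)

    profiles = compendium.profiles
    genes = profiles.index
    # pre-sort genes ascending so a stable argsort on -score breaks ties by gene id
    gene_order = np.argsort(genes.to_numpy(dtype=object), kind="stable")
    sorted_genes = genes[gene_order]
    scores = profiles.to_numpy()[gene_order, :]
    up_mask = sorted_genes.isin(query.up)
    down_mask = sorted_genes.isin(query.down)

    n = len(sorted_genes)
    records = []
    for j, cid in enumerate(profiles.columns):
        col = scores[:, j]
        order = np.argsort(-col, kind="stable")
        ranked = col[order]
        es_up = _es_from_arrays(ranked, up_mask[order], w) if query.up else None
        es_down = _es_from_arrays(ranked, down_mask[order], w) if query.down else None
        records.append((cid, es_up, es_down, wtcs(es_up, es_down)))

    cond = pd.DataFrame(records, columns=["condition_id", "es_up", "es_down", "wtcs"]) \
        .set_index("condition_id")
    meta = compendium.metadata.loc[cond.index, ["perturbagen", "cell_line"]]
    cond = pd.concat([meta, cond], axis=1)

    by_cell = cond.groupby(["perturbagen", "cell_line"], sort=True)["wtcs"].mean()
    rs = by_cell.groupby(level="perturbagen").mean().rename("rs")
    counts = cond.groupby("perturbagen").agg(
        n_conditions=("wtcs", "size"), n_cell_lines=("cell_line", "nunique"))
    perts = pd.concat([rs, counts], axis=1)
    return ConnectivityResult(cond, perts, dropped)


def _es_from_arrays(ranked_scores: np.ndarray, hit: np.ndarray, w: float) -> float:
    """Running-sum ES on pre-ranked numpy arrays (hot path of score_and_aggregate)."""
    n = ranked_scores.size
    nh = int(hit.sum())
    if nh == 0:
        raise InputError("gene set has no members in the ranked list")
    if w == 0:
        inc = hit / nh
    else:
        weights = np.abs(ranked_scores) ** w
        total = weights[hit].sum()
        inc = np.where(hit, weights, 0.0) / total if total > 0 else hit / nh
    running = np.cumsum(inc - (~hit) / (n - nh))
    return float(running[int(np.argmax(np.abs(running)))])


REASON_SELECTED = "selected"
REASON_FEW_CONDITIONS = "too_few_conditions"
REASON_SCORE = "score_above_threshold"


def select_candidates(result: ConnectivityResult, min_conditions: int = 10,
                      rs_max: float = -0.3) -> pd.DataFrame:
    """Candidate repurposing table with selection flags and exclusion reasons.

    A perturbagen is selected when measured in strictly more than
    ``min_conditions`` conditions and RS strictly below ``rs_max``.
    Selected rows come first, ascending by RS; excluded rows follow with
    the reason(s).
    """
    tbl = result.perturbagens.copy()
    enough = tbl["n_conditions"] > min_conditions
    scored = tbl["rs"] < rs_max
    tbl["selected"] = enough & scored
    reasons = []
    for e, s in zip(enough, scored):
        if e and s:
            reasons.append(REASON_SELECTED)
        else:
            parts = [] if e else [REASON_FEW_CONDITIONS]
            if not s:
                parts.append(REASON_SCORE)
            reasons.append(";".join(parts))
    tbl["reason"] = reasons
    tbl = tbl.sort_values(["selected", "rs"], ascending=[False, True])
    tbl.index.name = "perturbagen"
    return tbl


def permutation_null(ranked_scores: pd.Series, set_size: int, es_obs: float,
                     w: float = 1.0, n_perm: int = 999, seed: int = 0) -> float:
    """Empirical two-sided p-value for an observed ES against random gene sets.

    p = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1); deterministic given
    the seed.
    """
    n = len(ranked_scores)
    if set_size >= n:
        raise InputError("set_size must be smaller than the ranked list")
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    scores = ranked_scores.to_numpy()
    hits = np.zeros(n, dtype=bool)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        hits[:] = False
        hits[idx] = True
        if abs(_es_from_arrays(scores, hits, w)) >= abs(es_obs):
            count += 1
    return (1 + count) / (n_perm + 1)
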