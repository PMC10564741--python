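"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: multi-system
two-group expression studies sharing a planted up/down gene core, a
perturbagen signature compendium containing planted signature reversers,
dose-response plates drawn from the median-effect model with a controllable
Loewe-interaction level, and an shRNA depletion screen.

Randomness discipline: each generator draws from its own stream, derived
from the master seed by a stable text label, so adding or reordering
generators never perturbs another generator's output. Identical seed and
configuration give bit-identical outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigError, InputError

log = logging.getLogger(__name__)

FA_EPSILON = 1e-6  # fraction-affected clamp; the median-effect linearization is undefined at 0/1

#: Baseline log2 expression level (mean, SD) for simulated arrays.
_BASELINE_MEAN = 7.0
_BASELINE_SD = 1.0


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for (seed, label); stable across code changes."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-truth simulation.

    Defaults define the benchmark conditions used throughout the test
    suite: three experimental systems of 5+5 samples over 1000 genes with a
    planted 50-up/50-down core at |log2FC| = 2 (per-observation noise SD
    0.5, 20% per-system core dropout), and a 200-perturbagen compendium
    with 12 conditions each across 3 cell lines, of which three perturbagens
    reverse the core at mean |z| = 2 against a unit-normal null.
    """

    seed: int = 0
    n_genes: int = 1000
    n_samples_per_group: int = 5
    n_systems: int = 3
    core_up_size: int = 50
    core_down_size: int = 50
    effect_logfc: float = 2.0
    dropout_prob: float = 0.2
    noise_sd: float = 0.5
    n_perturbagens: int = 200
    conditions_per_perturbagen: int = 12
    n_cell_lines: int = 3
    reverser_ids: tuple[str, ...] = ("CP0005", "CP0050", "CP0150")
    reverser_strength: float = 2.0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_systems": self.n_systems,
            "core_up_size": self.core_up_size,
            "core_down_size": self.core_down_size,
            "n_perturbagens": self.n_perturbagens,
            "conditions_per_perturbagen": self.conditions_per_perturbagen,
            "n_cell_lines": self.n_cell_lines,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.core_up_size + self.core_down_size > self.n_genes:
            raise ConfigError("core_up_size + core_down_size exceeds n_genes")
        if not 0 <= self.dropout_prob < 1:
            raise ConfigError(f"dropout_prob must be in [0, 1), got {self.dropout_prob}")
        if self.noise_sd < 0 or self.reverser_strength < 0:
            raise ConfigError("noise_sd and reverser_strength must be non-negative")
        unknown = set(self.reverser_ids) - set(self.perturbagen_ids())
        if unknown:
            raise ConfigError(f"reverser_ids not among perturbagen ids: {sorted(unknown)}")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def perturbagen_ids(self) -> list[str]:
        return [f"CP{i:04d}" for i in range(self.n_perturbagens)]

    def cell_line_ids(self) -> list[str]:
        return [f"CL{i + 1}" for i in range(self.n_cell_lines)]


def planted_core_genes(config: SimConfig) -> tuple[list[str], list[str]]:
    """Planted up-core and down-core gene ids (shared by all generators)."""
    rng = stream(config.seed, "core-genes")
    genes = np.asarray(config.gene_ids())
    picked = rng.choice(config.n_genes, size=config.core_up_size + config.core_down_size,
                        replace=False)
    up = sorted(genes[picked[: config.core_up_size]].tolist())
    down = sorted(genes[picked[config.core_up_size:]].tolist())
    return up, down


# ---------------------------------------------------------------------------
# Expression systems
# ---------------------------------------------------------------------------

@dataclass
class ExpressionStudy:
    """One experimental system: log2 expression matrix with two-group labels."""

    study_id: str
    matrix: pd.DataFrame        # genes x samples, log2 scale
    group: pd.Series            # sample -> {"condition", "control"}

    def __post_init__(self):
        if self.matrix.index.duplicated().any():
            raise InputError(f"{self.study_id}: duplicate gene ids")
        if self.matrix.isna().any().any():
            raise InputError(f"{self.study_id}: missing values in expression matrix")
        counts = self.group.value_counts()
        for grp in ("condition", "control"):
            if counts.get(grp, 0) < 2:
                raise InputError(f"{self.study_id}: group {grp!r} has <2 samples")


@dataclass
class SystemsTruth:
    """Planted ground truth for the simulated expression systems."""

    up_core: list[str]
    down_core: list[str]
    #: core genes x systems boolean: gene active (effect present) in that system
    active: pd.DataFrame

    def consensus_core(self, min_studies: int = 2) -> tuple[set[str], set[str]]:
        """Core genes active in >= min_studies systems, split by direction."""
        n_active = self.active.sum(axis=1)
        eligible = set(n_active.index[n_active >= min_studies])
        return eligible & set(self.up_core), eligible & set(self.down_core)


def simulate_kras_systems(config: SimConfig) -> tuple[list[ExpressionStudy], SystemsTruth]:
    """Simulate ``n_systems`` two-group expression studies sharing a planted core.

    Each core gene is active in a given system with probability
    ``1 - dropout_prob``; active up-core genes have a condition-minus-control
    mean difference of ``+effect_logfc`` (down-core ``-effect_logfc``),
    non-core genes zero. Per-observation Gaussian noise with SD ``noise_sd``
    is added on the log2 scale.
    """
    rng = stream(config.seed, "expression-systems")
    genes = config.gene_ids()
    up, down = planted_core_genes(config)
    core = up + down
    sign = pd.Series(0.0, index=genes)
    sign[up] = 1.0
    sign[down] = -1.0

    n = config.n_samples_per_group
    study_ids = [f"SYS{k + 1}" for k in range(config.n_systems)]
    active = pd.DataFrame(
        rng.random((len(core), config.n_systems)) >= config.dropout_prob,
        index=core, columns=study_ids)

    studies = []
    for sid in study_ids:
        baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=len(genes))
        active_full = pd.Series(1.0, index=genes)
        active_full.loc[core] = active[sid].to_numpy(dtype=float)
        effect = (sign * config.effect_logfc * active_full).to_numpy()
        cond = baseline[:, None] + effect[:, None] + rng.normal(
            0.0, config.noise_sd, size=(len(genes), n))
        ctrl = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
        cols = [f"{sid}_cond_{i + 1}" for i in range(n)] + \
               [f"{sid}_ctrl_{i + 1}" for i in range(n)]
        matrix = pd.DataFrame(np.hstack([cond, ctrl]), index=genes, columns=cols)
        group = pd.Series(["condition"] * n + ["control"] * n, index=cols)
        studies.append(ExpressionStudy(sid, matrix, group))
    return studies, SystemsTruth(up, down, active)


# ---------------------------------------------------------------------------
# Perturbagen compendium
# ---------------------------------------------------------------------------

@dataclass
class SignatureCompendium:
    """Per-condition perturbagen differential z-score profiles with metadata."""

    profiles: pd.DataFrame      # genes x conditions, differential z-scores
    metadata: pd.DataFrame      # indexed by condition_id: perturbagen, cell_line, dose, time

    def __post_init__(self):
        if self.profiles.shape[1] != len(self.metadata):
            raise InputError("profiles and metadata disagree on condition count")
        if not self.profiles.columns.equals(pd.Index(self.metadata.index)):
            raise InputError("profile columns do not match metadata condition ids")
        if self.profiles.isna().any().any():
            raise InputError("incomplete condition profiles (missing scores)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.profiles.index


def simulate_compendium(config: SimConfig,
                        reverser_ids: Sequence[str] | None = None) -> SignatureCompendium:
    """Simulate a perturbagen compendium with planted signature reversers.

    Reverser perturbagens get z-scores centred at ``-reverser_strength`` on
    the planted up-core genes and ``+reverser_strength`` on the down-core
    (unit Gaussian noise on top); all other scores are unit-normal null
    draws. Conditions cycle through cell lines, doses and time points. The
    last non-reverser perturbagen is generated with at most 10 conditions so
    the downstream robustness filter (strictly more than 10 conditions) has
    something to remove.
    """
    reverser_ids = tuple(reverser_ids if reverser_ids is not None else config.reverser_ids)
    pert_ids = config.perturbagen_ids()
    unknown = set(reverser_ids) - set(pert_ids)
    if unknown:
        raise ConfigError(f"unknown reverser ids: {sorted(unknown)}")

    rng = stream(config.seed, "compendium")
    genes = config.gene_ids()
    up, down = planted_core_genes(config)
    shift = np.zeros(len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    shift[[gene_pos[g] for g in up]] = -config.reverser_strength
    shift[[gene_pos[g] for g in down]] = config.reverser_strength

    cell_lines = config.cell_line_ids()
    doses = [0.1, 1.0, 10.0]
    times = [6, 24]
    non_reversers = [p for p in pert_ids if p not in reverser_ids]
    underassayed = non_reversers[-1] if non_reversers else None

    cols, meta_rows, blocks = [], [], []
    for pert in pert_ids:
        n_cond = config.conditions_per_perturbagen
        if pert == underassayed:
            n_cond = min(10, n_cond)
        z = rng.standard_normal((len(genes), n_cond))
        if pert in reverser_ids:
            z += shift[:, None]
        blocks.append(z)
        for j in range(n_cond):
            cid = f"{pert}_c{j + 1:02d}"
            cols.append(cid)
            meta_rows.append({
                "condition_id": cid,
                "perturbagen": pert,
                "cell_line": cell_lines[j % len(cell_lines)],
                "dose": doses[(j // len(cell_lines)) % len(doses)],
                "time": times[j % len(times)],
            })
    profiles = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    metadata = pd.DataFrame(meta_rows).set_index("condition_id", drop=False)
    return SignatureCompendium(profiles, metadata)


# ---------------------------------------------------------------------------
# Dose-response generators (median-effect model)
# ---------------------------------------------------------------------------

def median_effect_fa(dose, m: float, dm: float):
    """Fraction affected under the median-effect model: fa = 1/(1 + (Dm/D)^m)."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (dm / dose) ** m)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _clamp_fa(fa, epsilon: float = FA_EPSILON):
    return np.clip(fa, epsilon, 1.0 - epsilon)


def _fa_table(rows) -> pd.DataFrame:
    from .io import DOSE_RESPONSE_COLUMNS
    return pd.DataFrame(rows, columns=DOSE_RESPONSE_COLUMNS)


def simulate_single_agent_response(m: float, dm: float, dose_grid,
                                   n_replicates: int = 3,
                                   fa_noise_sd: float = 0.1,
                                   seed: int = 0,
                                   drug: str = "drugA",
                                   cell_line: str = "CL1") -> pd.DataFrame:
    """Simulate a single-agent viability series from the median-effect model.

    Noise is Gaussian on the logit(fa) scale; fa is clamped to
    (epsilon, 1-epsilon) before and after noising. Returns a dose-response
    table (viability_pct = 100*(1-fa)).
    """
    if m <= 0 or dm <= 0:
        raise InputError(f"median-effect parameters must be positive (m={m}, Dm={dm})")
    dose_grid = np.asarray(dose_grid, dtype=float)
    if (dose_grid <= 0).any():
        raise InputError("doses must be strictly positive")
    rng = stream(seed, f"single-agent:{drug}:{cell_line}")
    fa0 = _clamp_fa(median_effect_fa(dose_grid, m, dm))
    rows = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, fa_noise_sd, size=dose_grid.shape) if fa_noise_sd > 0 else 0.0
        fa = _clamp_fa(_expit(_logit(fa0) + noise))
        for d, f in zip(dose_grid, fa):
            rows.append((cell_line, drug, d, "", 0.0, rep, 100.0 * (1.0 - f)))
    return _fa_table(rows)


@dataclass(frozen=True)
class CombinationDesign:
    """Constant-ratio two-drug design with a planted Loewe interaction level.

    ``psi`` multiplies the Loewe sum: the noise-free fraction affected at
    total dose D (split d1 = w1*D, d2 = w2*D) solves
    d1/Dx1(fa) + d2/Dx2(fa) = psi, where Dxk(fa) = Dmk*(fa/(1-fa))^(1/mk).
    psi = 1 is Loewe-additive, psi < 1 synergistic, psi > 1 antagonistic;
    a downstream combination-index estimate recovers psi.
    """

    m1: float
    m2: float
    dm1: float
    dm2: float
    ratio_w1: float = 0.5
    ratio_w2: float = 0.5
    psi: float = 1.0
    dose_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    n_replicates: int = 3
    fa_noise_sd: float = 0.1

    def __post_init__(self):
        for name in ("m1", "m2", "dm1", "dm2", "psi"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        grid = np.asarray(self.dose_grid, dtype=float)
        if grid.size == 0 or (grid <= 0).any() or (np.diff(grid) <= 0).any():
            raise ConfigError("dose_grid must be strictly positive and strictly increasing")
        if not np.isclose(self.ratio_w1 + self.ratio_w2, 1.0):
            raise ConfigError("ratio weights must sum to 1")
        if min(self.ratio_w1, self.ratio_w2) < 0:
            raise ConfigError("ratio weights must be non-negative")


def loewe_fa(d1: float, d2: float, m1: float, dm1: float, m2: float, dm2: float,
             psi: float = 1.0, epsilon: float = FA_EPSILON) -> tuple[float, bool]:
    """Noise-free combination effect: solve d1/Dx1(fa) + d2/Dx2(fa) = psi for fa.

    The left side is strictly decreasing in fa, so the root is unique;
    bisection (Brent) to |residual| < 1e-10. Returns (fa, flagged); when the
    equation has no root inside (epsilon, 1-epsilon) the fa is clamped at
    the nearer boundary and flagged, with a warning logged.
    """
    def g(fa: float) -> float:
        dx1 = dm1 * (fa / (1.0 - fa)) ** (1.0 / m1)
        dx2 = dm2 * (fa / (1.0 - fa)) ** (1.0 / m2)
        return d1 / dx1 + d2 / dx2 - psi

    lo, hi = epsilon, 1.0 - epsilon
    g_lo, g_hi = g(lo), g(hi)
    if g_lo < 0.0:  # even a tiny effect over-satisfies the sum: dose below range
        log.warning("combination dose (%.4g, %.4g) too small for fa in range; clamped", d1, d2)
        return lo, True
    if g_hi > 0.0:
        log.warning("combination dose (%.4g, %.4g) too large for fa in range; clamped", d1, d2)
        return hi, True
    fa = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    assert abs(g(fa)) < 1e-10
    return float(fa), False


def simulate_combination_response(design: CombinationDesign, seed: int = 0,
                                  drug1: str = "drugA", drug2: str = "drugB",
                                  cell_line: str = "CL1") -> pd.DataFrame:
    """Simulate a constant-ratio combination series with planted interaction psi."""
    rng = stream(seed, f"combination:{drug1}+{drug2}:{cell_line}")
    rows = []
    grid = np.asarray(design.dose_grid, dtype=float)
    fa0 = np.empty_like(grid)
    for i, total in enumerate(grid):
        d1, d2 = design.ratio_w1 * total, design.ratio_w2 * total
        fa0[i], _ = loewe_fa(d1, d2, design.m1, design.dm1, design.m2, design.dm2,
                             design.psi)
    for rep in range(1, design.n_replicates + 1):
        noise = (rng.normal(0.0, design.fa_noise_sd, size=grid.shape)
                 if design.fa_noise_sd > 0 else 0.0)
        fa = _clamp_fa(_expit(_logit(_clamp_fa(fa0)) + noise))
        for total, f in zip(grid, fa):
            rows.append((cell_line, drug1, design.ratio_w1 * total,
                         drug2, design.ratio_w2 * total, rep, 100.0 * (1.0 - f)))
    return _fa_table(rows)


# ---------------------------------------------------------------------------
# shRNA depletion screen
# ---------------------------------------------------------------------------

def simulate_shrna_screen(genes: Sequence[str],
                          planted_depletion: Mapping[str, float],
                          shrnas_per_gene: int = 6,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate per-shRNA abundances in reference and treated arms.

    Treated mean abundance equals (1 - planted_depletion[gene]) times the
    reference; multiplicative noise (Gaussian on log2 abundance, SD
    ``noise_sd``) perturbs the treated arm. Genes absent from
    ``planted_depletion`` get depletion 0.
    """
    for g, d in planted_depletion.items():
        if not 0 <= d < 1:
            raise ConfigError(f"planted depletion for {g} must be in [0, 1), got {d}")
    rng = stream(seed, "shrna-screen")
    rows = []
    for gene in genes:
        depletion = float(planted_depletion.get(gene, 0.0))
        reference = 1000.0 * np.exp2(rng.normal(0.0, 1.0, size=shrnas_per_gene))
        factor = np.exp2(rng.normal(0.0, noise_sd, size=shrnas_per_gene)) if noise_sd > 0 else 1.0
        treated = reference * (1.0 - depletion) * factor
        for i, (ref, trt) in enumerate(zip(reference, treated)):
            rows.append((gene, f"{gene}_sh{i + 1}", ref, trt))
    return pd.DataFrame(rows, columns=["gene", "shrna", "reference", "treated"])
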