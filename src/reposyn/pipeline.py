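"""End-to-end orchestration: simulate -> signature -> connectivity -> synergy.

A run is a pure function of its configuration and master seed: every stage
derives its randomness from the seed by stable labels, the effective
configuration is echoed into the output directory, and rerunning with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .connectivity import QuerySignature, score_and_aggregate, select_candidates
from .diffexp import signature_from_studies
from .exceptions import ConfigError, InputError, StageError
from .simulate import (CombinationDesign, ExpressionStudy, SignatureCompendium,
                       SimConfig, simulate_combination_response,
                       simulate_compendium, simulate_kras_systems,
                       simulate_single_agent_response)
from .synergy import evaluate_pair, fit_series, screen_to_table

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "signature", "connect", "synergy")


@dataclass(frozen=True)
class PairSpec:
    """One drug pair of the simulated screen: single-agent parameters and
    the planted Loewe interaction level psi."""

    drug1: str
    drug2: str
    psi: float
    m1: float = 1.0
    m2: float = 1.0
    dm1: float = 1.0
    dm2: float = 1.0


#: Default simulated screen: one clearly synergistic pair, one additive,
#: one antagonistic, echoing the spread of interaction levels a pairwise
#: viability screen encounters.
DEFAULT_PAIRS = (
    PairSpec("MEKi-1", "PKCi-1", psi=0.5, m1=1.2, m2=0.9, dm1=0.5, dm2=2.0),
    PairSpec("MEKi-1", "WEE1i-1", psi=1.0, m1=1.2, m2=1.1, dm1=0.5, dm2=1.0),
    PairSpec("MEKi-1", "HDACi-1", psi=1.6, m1=1.2, m2=1.4, dm1=0.5, dm2=0.8),
)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration. Thresholds default to the decision
    rules the pipeline implements: fold-change bands 1.5/0.75 with B > 0 in
    >=2 studies for the signature; >10 conditions and RS < -0.3 for
    candidate selection; mean CI < 0.8 for the synergy call."""

    out_dir: str = "reposyn_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    # signature stage
    fc_up: float = 1.5
    fc_down: float = 0.75
    b_min: float = 0.0
    min_studies: int = 2
    pi_de: float = 0.01
    signature_gmt: str | None = None   # external query when signature stage is off
    # connectivity stage
    min_conditions: int = 10
    rs_max: float = -0.3
    es_weight: float = 1.0
    # synergy stage
    ci_synergy: float = 0.8
    r_min: float = 0.90
    pairs: tuple[PairSpec, ...] = DEFAULT_PAIRS
    screen_cell_lines: tuple[str, ...] = ("CL1", "CL2")
    screen_noise_sd: float = 0.1
    screen_replicates: int = 3
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.fc_down >= self.fc_up:
            raise ConfigError("fc_down must be < fc_up")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a plain mapping (YAML/JSON), rejecting unknown keys."""
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(data["sim"]) - sim_known
            if sim_unknown:
                raise ConfigError(f"unknown sim keys: {sorted(sim_unknown)}")
            sim = dict(data["sim"])
            if "reverser_ids" in sim:
                sim["reverser_ids"] = tuple(sim["reverser_ids"])
            data["sim"] = SimConfig(**sim)
        if "pairs" in data:
            data["pairs"] = tuple(
                p if isinstance(p, PairSpec) else PairSpec(**p) for p in data["pairs"])
        for key in ("stages", "screen_cell_lines"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["screen_cell_lines"] = list(self.screen_cell_lines)
        d["pairs"] = [asdict(p) for p in self.pairs]
        d["sim"] = asdict(self.sim)
        d["sim"]["reverser_ids"] = list(self.sim.reverser_ids)
        return d


def _dose_grid(dm: float) -> np.ndarray:
    """Six total doses log-spaced from Dm/4 to 4*Dm."""
    return np.geomspace(dm / 4.0, 4.0 * dm, 6)


def _simulate_screen(config: RunConfig) -> pd.DataFrame:
    """Single-agent and combination plates for every pair and cell line."""
    tables = []
    for cell in config.screen_cell_lines:
        singles_done = set()
        for pair in config.pairs:
            for drug, m, dm in ((pair.drug1, pair.m1, pair.dm1),
                                (pair.drug2, pair.m2, pair.dm2)):
                if (cell, drug) in singles_done:
                    continue
                singles_done.add((cell, drug))
                tables.append(simulate_single_agent_response(
                    m, dm, _dose_grid(dm), config.screen_replicates,
                    config.screen_noise_sd, config.seed, drug=drug, cell_line=cell))
            dm_mix = 0.5 * (pair.dm1 + pair.dm2)
            design = CombinationDesign(
                pair.m1, pair.m2, pair.dm1, pair.dm2, psi=pair.psi,
                dose_grid=tuple(_dose_grid(dm_mix)),
                n_replicates=config.screen_replicates,
                fa_noise_sd=config.screen_noise_sd)
            tables.append(simulate_combination_response(
                design, config.seed, drug1=pair.drug1, drug2=pair.drug2,
                cell_line=cell))
    return pd.concat(tables, ignore_index=True)


def _read_query_gmt(path: str | Path) -> QuerySignature:
    sets = rio.read_gmt(path)
    up = set().union(*[set(g) for n, g in sets.items() if n.upper().endswith("_UP")]) \
        if any(n.upper().endswith("_UP") for n in sets) else set()
    down = set().union(*[set(g) for n, g in sets.items() if n.upper().endswith(("_DN", "_DOWN"))]) \
        if any(n.upper().endswith(("_DN", "_DOWN")) for n in sets) else set()
    if not up and not down:
        raise InputError(f"{path}: no *_UP/*_DN records found")
    return QuerySignature(up, down)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write all outputs.

    Returns the run report (also written to report.json). A stage failure
    raises :class:`StageError` after leaving a FAILED marker naming the
    stage; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "config.yaml").open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    report: dict = {"seed": config.seed, "stages": list(config.stages), "counts": {}}
    from . import __version__
    report["version"] = __version__

    studies: list[ExpressionStudy] | None = None
    compendium: SignatureCompendium | None = None
    query: QuerySignature | None = None
    screen_table: pd.DataFrame | None = None
    truth = None

    stage = "simulate"
    try:
        if "simulate" in config.stages:
            studies, truth = simulate_kras_systems(config.sim)
            compendium = simulate_compendium(config.sim)
            screen_table = _simulate_screen(config)
            for study in studies:
                rio.write_gct(study.matrix, out / f"{study.study_id}.gct")
                pd.DataFrame({"sample_id": study.group.index,
                              "group": study.group.values}) \
                    .to_csv(out / f"{study.study_id}.samples.tsv", sep="\t", index=False)
            rio.write_gct(compendium.profiles, out / "compendium.gct")
            rio.write_condition_metadata(compendium.metadata, out / "compendium.meta.tsv")
            rio.write_dose_response(screen_table, out / "dose_response.tsv")
            ground_truth = {
                "up_core": truth.up_core,
                "down_core": truth.down_core,
                "active": {sid: truth.active[sid].astype(bool).to_dict()
                           for sid in truth.active.columns},
                "reverser_ids": list(config.sim.reverser_ids),
                "pair_psi": {f"{p.drug1}+{p.drug2}": p.psi for p in config.pairs},
            }
            with (out / "ground_truth.json").open("w") as fh:
                json.dump(ground_truth, fh, indent=1, sort_keys=True)
            report["counts"]["simulate"] = {
                "studies": len(studies),
                "genes": config.sim.n_genes,
                "conditions": int(compendium.profiles.shape[1]),
                "screen_rows": int(len(screen_table)),
            }

        stage = "signature"
        if "signature" in config.stages:
            if studies is None:
                raise StageError(stage, "no studies available (enable simulate or "
                                        "provide inputs programmatically)")
            signature = signature_from_studies(
                studies, config.fc_up, config.fc_down, config.b_min,
                config.min_studies, config.pi_de)
            rio.write_gmt({"SIG_UP": sorted(signature.up),
                           "SIG_DN": sorted(signature.down)}, out / "signature.gmt")
            calls_report = {
                "per_study_calls": {
                    sid: {"up": int((signature.calls[sid] == "up").sum()),
                          "down": int((signature.calls[sid] == "down").sum())}
                    for sid in signature.calls.columns},
                "up": sorted(signature.up),
                "down": sorted(signature.down),
                "ambiguous": signature.ambiguous,
                "min_studies": signature.min_studies,
            }
            with (out / "signature_calls.json").open("w") as fh:
                json.dump(calls_report, fh, indent=1, sort_keys=True)
            query = QuerySignature(signature.up, signature.down)
            report["counts"]["signature"] = {
                "up": len(signature.up), "down": len(signature.down),
                "ambiguous": len(signature.ambiguous),
                "per_study": calls_report["per_study_calls"],
            }
        elif config.signature_gmt:
            query = _read_query_gmt(config.signature_gmt)
            report["counts"]["signature"] = {
                "up": len(query.up), "down": len(query.down), "source": "provided_gmt"}

        stage = "connect"
        if "connect" in config.stages:
            if compendium is None:
                raise StageError(stage, "no compendium available (enable simulate)")
            if query is None:
                raise StageError(stage, "no query signature (enable signature stage "
                                        "or set signature_gmt)")
            result = score_and_aggregate(query, compendium, w=config.es_weight)
            candidates = select_candidates(result, config.min_conditions, config.rs_max)
            candidates.reset_index().to_csv(out / "candidates.tsv", sep="\t",
                                            index=False, float_format="%.10g")
            report["counts"]["connect"] = {
                "perturbagens_scored": int(len(candidates)),
                "conditions_scored": int(len(result.conditions)),
                "filtered_few_conditions": int(
                    (candidates["n_conditions"] <= config.min_conditions).sum()),
                "selected": int(candidates["selected"].sum()),
                "selected_ids": candidates.index[candidates["selected"]].tolist(),
                "dropped_query_genes": result.dropped_query_genes,
            }

        stage = "synergy"
        if "synergy" in config.stages:
            if screen_table is None:
                raise StageError(stage, "no dose-response data (enable simulate)")
            results = []
            combos = screen_table[screen_table["drug2"] != ""]
            singles = screen_table[screen_table["drug2"] == ""]
            for (cell, d1, d2), combo in combos.groupby(["cell_line", "drug1", "drug2"]):
                s1 = singles[(singles["cell_line"] == cell) & (singles["drug1"] == d1)]
                s2 = singles[(singles["cell_line"] == cell) & (singles["drug1"] == d2)]
                if s1.empty or s2.empty:
                    raise StageError(stage, f"missing single-agent series for "
                                            f"{d1}/{d2} in {cell}")
                results.append(evaluate_pair(s1, s2, combo, config.ci_synergy,
                                             config.r_min))
            table = screen_to_table(results)
            table.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.10g")
            detail = {
                f"{r.cell_line}:{r.drug1}+{r.drug2}": {
                    "mean_ci": r.mean_ci, "synergistic": r.synergistic,
                    "evaluable": r.evaluable, "reason": r.reason,
                    "fit1": None if r.fit1 is None else
                        {"m": r.fit1.m, "dm": r.fit1.dm, "r": r.fit1.r},
                    "fit2": None if r.fit2 is None else
                        {"m": r.fit2.m, "dm": r.fit2.dm, "r": r.fit2.r},
                    "points": None if r.points is None else
                        r.points[["dose1", "dose2", "fa", "ci"]].round(10)
                        .to_dict(orient="records"),
                }
                for r in results}
            with (out / "screen_detail.json").open("w") as fh:
                json.dump(detail, fh, indent=1, sort_keys=True)
            report["counts"]["synergy"] = {
                "pairs_evaluated": int(len(table)),
                "pairs_synergistic": int(table["synergistic"].fillna(False).sum()),
                "pairs_unevaluable": int((~table["evaluable"]).sum()),
            }
    except StageError:
        (out / "FAILED").write_text(stage + "\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(stage + "\n")
        raise StageError(stage, str(exc)) from exc

    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
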