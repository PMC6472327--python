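"""End-to-end orchestration: synth -> fit -> evaluate -> econ -> report.

Every stage writes its artifact to disk (panel CSV, fitted intensity
matrix JSON, protocol-comparison CSV, Table-2-style economics CSV) so
stages are independently runnable and testable; a run manifest records
the seed, the config hash and library versions, which suffices to
reproduce any bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    generate_panel_dataset,
    simulate_trajectories,
)
from .econ import EconParameters, protocol_economics, total_costs
from .markov import IntensityMatrix, StateSpace, default_policy_intensity, fit
from .screening import ScreeningProtocol, compare_protocols, default_protocol_grid

logger = logging.getLogger("cvdscreen")

__all__ = ["RunConfig", "run_pipeline", "report_table2"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Reproducible configuration of a full pipeline run."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    variant: str = "policy"  # "policy" or "descriptive"
    protocols: list[str] = field(default_factory=lambda: ["5-5-5", "10-5-2", "7-4-1"])
    reference: str = "5-5-5"
    use_default_grid: bool = False
    horizon: float = 20.0
    n_eval: int = 5000  # trajectories simulated from the fitted Q for evaluation
    refit: bool = True  # fit Q from the synthetic panel (else use the default Q)
    n_boot: int = 500
    econ: EconParameters = field(default_factory=EconParameters)

    def __post_init__(self):
        if self.variant not in ("policy", "descriptive"):
            raise ValueError("variant must be 'policy' or 'descriptive'")
        if self.reference not in self.protocols:
            self.protocols = [self.reference] + list(self.protocols)

    def protocol_objects(self) -> list[ScreeningProtocol]:
        protos = [ScreeningProtocol.from_label(l) for l in self.protocols]
        if self.use_default_grid:
            have = {p.label for p in protos}
            protos += [p for p in default_protocol_grid() if p.label not in have]
        return protos

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["smoker_prev"] = dict(d["cohort"]["smoker_prev"])
        d["econ"]["adverse_incidence"] = dict(d["econ"]["adverse_incidence"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.canonical_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "cohort" in payload:
            cohort = dict(payload["cohort"])
            cohort["age_range"] = tuple(cohort.get("age_range", (40.0, 64.0)))
            cohort["initial_distribution"] = tuple(
                cohort.get("initial_distribution", CohortConfig().initial_distribution)
            )
            payload["cohort"] = CohortConfig(**cohort)
        if "econ" in payload:
            payload["econ"] = EconParameters(**payload["econ"])
        return cls(**payload)


def report_table2(comparison: pd.DataFrame, params: EconParameters, reference: str) -> pd.DataFrame:
    """Comparison table in the published layout, one column per protocol.

    Rows: person-years unidentified in the high-risk category, the delta
    versus the reference, events prevented, the three statin adverse-event
    types, QALYs gained, health-check costs, statin savings, total costs
    and the total-cost delta (costs in thousand GBP).  Every economics row
    is recomputed from the person-year delta through the econ operations.
    """
    if reference not in comparison.index:
        raise ValueError(f"reference {reference!r} missing from comparison")
    cols = {}
    ref_total = None
    order = [reference] + [p for p in comparison.index if p != reference]
    for label in order:
        row = comparison.loc[label]
        econ = protocol_economics(
            max(0.0, row["statin_person_years_gained"]), row["screens"], params
        )
        col = {
            "n_people": row["n_people"],
            "unrecognised_person_years": row["unrecognised_py"],
            "delta_unrecognised_person_years": row["delta_unrecognised_py"],
            "events_prevented": econ.events_prevented,
            "adverse_diabetes": econ.adverse_events["diabetes"],
            "adverse_haemorrhagic_stroke": econ.adverse_events["haemorrhagic_stroke"],
            "adverse_myopathy": econ.adverse_events["myopathy"],
            "qalys_gained": econ.qalys_gained,
            "health_check_costs_kgbp": econ.health_check_costs / 1e3,
            "statin_savings_kgbp": econ.statin_savings / 1e3,
            "total_costs_kgbp": total_costs(econ.health_check_costs, econ.statin_savings) / 1e3,
        }
        cols[label] = col
    table = pd.DataFrame(cols)
    ref_total = table.loc["total_costs_kgbp", reference]
    table.loc["delta_total_costs_kgbp"] = table.loc["total_costs_kgbp"] - ref_total
    return table


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict of the in-memory artifacts (panel, fitted Q, comparison
    DataFrame, Table-2-style DataFrame, manifest).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    # --- synth -------------------------------------------------------
    logger.info("stage synth: generating panel (n=%d)", config.cohort.n_individuals)
    cohort_cfg = CohortConfig(**{**asdict(config.cohort), "seed": seeds[0],
                                 "smoker_prev": dict(config.cohort.smoker_prev),
                                 "antihypertensive_prev": dict(config.cohort.antihypertensive_prev)})
    true_Q = default_policy_intensity()
    try:
        panel, truth = generate_panel_dataset(cohort_cfg, intensity=true_Q)
    except Exception as exc:
        raise RuntimeError(f"[synth] stage failed: {exc}") from exc
    panel.to_csv(out / "panel.csv")
    true_Q.to_json(out / "true_q.json")

    # --- fit -----------------------------------------------------------
    space = StateSpace.policy() if config.variant == "policy" else StateSpace.descriptive()
    if config.refit:
        logger.info("stage fit: maximising panel likelihood")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_res = fit(panel, space, exact_death_times=True, compute_ci=False)
        except Exception as exc:
            raise RuntimeError(f"[fit] stage failed: {exc}") from exc
        Q_eval = fit_res.Q
        fitted_payload = {"log_likelihood": fit_res.log_likelihood,
                          "converged": bool(fit_res.converged)}
    else:
        Q_eval = true_Q
        fitted_payload = {"log_likelihood": None, "converged": None}
    Q_eval.to_json(out / "fitted_q.json")

    # --- evaluate ------------------------------------------------------
    logger.info("stage evaluate: %d protocols over %d trajectories",
                len(config.protocols), config.n_eval)
    protos = config.protocol_objects()
    if len(protos) == 1:
        logger.warning("empty protocol grid besides reference: reference-only report")
    try:
        trajectories = simulate_trajectories(
            Q_eval,
            config.n_eval,
            t_max=config.horizon,
            initial_distribution=config.cohort.initial_distribution,
            seed=seeds[1],
        )
        comparison = compare_protocols(
            trajectories,
            protos,
            reference=config.reference,
            horizon=config.horizon,
            n_boot=config.n_boot,
            seed=seeds[2],
        )
    except Exception as exc:
        raise RuntimeError(f"[evaluate] stage failed: {exc}") from exc
    comparison.to_csv(out / "comparison.csv", float_format=_FLOAT_FMT)

    # --- econ / report -------------------------------------------------
    try:
        table2 = report_table2(comparison, config.econ, config.reference)
    except Exception as exc:
        raise RuntimeError(f"[econ] stage failed: {exc}") from exc
    table2.to_csv(out / "table2.csv", float_format=_FLOAT_FMT)

    manifest = {
        "package": "cvdscreen",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    config.to_yaml(out / "config.yaml")
    return {
        "panel": panel,
        "Q": Q_eval,
        "fit": fitted_payload,
        "comparison": comparison,
        "table2": table2,
        "manifest": manifest,
    }
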