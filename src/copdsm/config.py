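"""YAML run configuration: one flat file describing simulation, model,
sampler, diagnostics and design blocks, materialised into the library's
dataclasses. Every stochastic stage takes an explicit seed."""

from __future__ import annotations

import yaml

from .dropout import DropoutFormula, DropoutSpec
from .families import Family, TransitionSpec
from .inference import ModelFormula, SamplerConfig
from .simulate import CovariateConfig, SimulationConfig

__all__ = ["load_config", "simulation_from_config", "formula_from_config",
           "sampler_from_config", "default_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return cfg


def _dropout_spec(block) -> DropoutSpec | None:
    if not block:
        return None
    return DropoutSpec(
        family=Family(block.get("family", "loglogistic")),
        theta0=float(block["theta0"]),
        alpha=(float(block["alpha"]) if block.get("alpha") is not None else None),
        beta={k: float(v) for k, v in (block.get("beta") or {}).items()},
        dropout_window_days=float(block.get("dropout_window", 30.0)),
    )


def simulation_from_config(cfg: dict, seed: int | None = None) -> SimulationConfig:
    sim = cfg.get("simulation", {})
    fam = Family(sim.get("family", "loglogistic"))
    fam21 = Family(sim.get("family_21", fam))

    def _spec(state_from, fam_):
        sfx = "1" if state_from == 1 else "2"
        return TransitionSpec(
            state_from=state_from,
            family=fam_,
            theta0=float(sim.get(f"theta{sfx}", 150.0 if state_from == 1 else 8.0)),
            alpha=(float(sim[f"alpha{sfx}"]) if sim.get(f"alpha{sfx}") is not None else None),
            beta={k: float(v) for k, v in (sim.get(f"beta_{sfx}") or {}).items()},
            sigma2=float(sim.get(f"sigma2_{sfx}", 0.1)),
        )

    arm = int(sim.get("n_per_arm", 150))
    arms = {0: arm, 1: arm} if sim.get("two_arm", True) else {0: arm}
    cov = CovariateConfig(**(sim.get("covariates") or {}))
    return SimulationConfig(
        spec_12=_spec(1, fam),
        spec_21=_spec(2, fam21),
        seed=int(seed if seed is not None else sim.get("seed", 0)),
        arm_sizes=arms,
        study_length_days=float(sim.get("study_length", 364.0)),
        covariates=cov,
        dropout=_dropout_spec(sim.get("dropout")),
        dropout_window_days=float(sim.get("dropout_window", 30.0)),
    )


def formula_from_config(cfg: dict) -> ModelFormula:
    m = cfg.get("model", {})
    dropout = None
    if m.get("dropout"):
        d = m["dropout"]
        dropout = DropoutFormula(
            family=Family(d.get("family", "loglogistic")),
            covariates=tuple(d.get("covariates", ["disease_stage"])),
            include_study_length=bool(d.get("include_study_length", False)),
        )
    return ModelFormula(
        family=Family(m.get("family", "loglogistic")),
        family_21=Family(m["family_21"]) if m.get("family_21") else None,
        covariates_12=tuple(m.get("covariates_12", [])),
        covariates_21=tuple(m.get("covariates_21", [])),
        frailty_12=bool(m.get("frailty_12", m.get("frailty", True))),
        frailty_21=bool(m.get("frailty_21", m.get("frailty", True))),
        include_study_length=bool(m.get("include_study_length", True)),
        dropout=dropout,
    )


def sampler_from_config(cfg: dict, seed: int | None = None) -> SamplerConfig:
    s = cfg.get("sampler", {})
    return SamplerConfig(
        chains=int(s.get("chains", 4)),
        warmup=int(s.get("warmup", 1000)),
        draws=int(s.get("draws", 1000)),
        seed=int(seed if seed is not None else s.get("seed", 0)),
    )


def default_config() -> dict:
    """The shipped reference scenario as a plain config mapping."""
    return {
        "simulation": {
            "family": "loglogistic",
            "n_per_arm": 150,
            "two_arm": True,
            "study_length": 364.0,
            "theta1": 150.0, "alpha1": 1.34, "sigma2_1": 0.1,
            "theta2": 8.0, "alpha2": 2.97, "sigma2_2": 0.1,
            "beta_1": {"treatment": 0.31},
            "dropout": None,
            "seed": 0,
        },
        "model": {
            "family": "loglogistic",
            "covariates_12": ["treatment"],
            "frailty": True,
        },
        "sampler": {"chains": 2, "warmup": 600, "draws": 600, "seed": 0},
        "diagnostics": {"replicates": 100, "k_max": 8},
    }


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
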