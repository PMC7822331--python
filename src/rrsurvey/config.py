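"""Pipeline configuration (YAML).

A config file has four optional blocks plus a seed::

    seed: 7
    cohort:            # CohortConfig fields; behaviour_model entries are
      n: 792           # {prevalence: float, coef: {term: beta}}
      arm_split: 0.5
    design:            # either a deck block or a probability triple
      deck: {total_cards: 40, forced_yes_cards: 8, forced_no_cards: 8, genuine_cards: 24}
      # or: probabilities: {forced_yes: 0.2, forced_no: 0.2, genuine: 0.6}
    analysis:
      level: 0.95
      behaviours: [theft, drugs, violence, speeding, arson]
      regression:
        outcomes: [theft, drugs, arson]
        terms: [method, education, marital_status, crime, conduct,
                age, sentence_months, oc_score]
        stepwise: true
    output:
      decimals: 4

Unspecified fields fall back to the package defaults (the study-shaped
cohort and the 40-card deck).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .cohort import BEHAVIOURS, BehaviourModel, CohortConfig
from .design import DeckSpec, RRDesign, STUDY_DESIGN, design_from_deck

__all__ = ["AnalysisConfig", "OutputConfig", "PipelineConfig", "load_config"]

DEFAULT_REGRESSION_TERMS = [
    "method",
    "education",
    "marital_status",
    "crime",
    "conduct",
    "age",
    "sentence_months",
    "oc_score",
]


@dataclass
class AnalysisConfig:
    level: float = 0.95
    behaviours: list = field(default_factory=lambda: list(BEHAVIOURS))
    regression_outcomes: list = field(default_factory=lambda: ["theft", "drugs", "arson"])
    regression_terms: list = field(default_factory=lambda: list(DEFAULT_REGRESSION_TERMS))
    stepwise: bool = True

    def validate(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")


@dataclass
class OutputConfig:
    decimals: int = 4

    def validate(self):
        if self.decimals < 1:
            raise ValueError("decimal places must be >= 1")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    design: RRDesign = STUDY_DESIGN
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    def validate(self):
        self.cohort.validate()
        self.analysis.validate()
        self.output.validate()


def _parse_design(block: dict) -> RRDesign:
    if "deck" in block:
        return design_from_deck(DeckSpec(**block["deck"]))
    if "probabilities" in block:
        p = block["probabilities"]
        return RRDesign(
            p_forced_yes=float(p["forced_yes"]),
            p_forced_no=float(p["forced_no"]),
            p_genuine=float(p["genuine"]),
        )
    raise ValueError("design block needs either 'deck' or 'probabilities'")


def _parse_cohort(block: dict) -> CohortConfig:
    block = dict(block)
    if "behaviour_model" in block:
        block["behaviour_model"] = {
            b: BehaviourModel(
                prevalence=float(spec["prevalence"]),
                coef=dict(spec.get("coef", {})),
            )
            for b, spec in block["behaviour_model"].items()
        }
    allowed = {f.name for f in dc_fields(CohortConfig)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown cohort config fields: {sorted(unknown)}")
    return CohortConfig(**block)


def _parse_analysis(block: dict) -> AnalysisConfig:
    cfg = AnalysisConfig()
    if "level" in block:
        cfg.level = float(block["level"])
    if "behaviours" in block:
        cfg.behaviours = list(block["behaviours"])
    reg = block.get("regression", {})
    if "outcomes" in reg:
        cfg.regression_outcomes = list(reg["outcomes"])
    if "terms" in reg:
        cfg.regression_terms = list(reg["terms"])
    if "stepwise" in reg:
        cfg.stepwise = bool(reg["stepwise"])
    return cfg


def load_config(path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    cfg = PipelineConfig()
    if "cohort" in raw:
        cfg.cohort = _parse_cohort(raw["cohort"])
    if "design" in raw:
        cfg.design = _parse_design(raw["design"])
    if "analysis" in raw:
        cfg.analysis = _parse_analysis(raw["analysis"])
    if "output" in raw:
        cfg.output = OutputConfig(**raw["output"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
        cfg.cohort.seed = cfg.seed
    cfg.validate()
    return cfg
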