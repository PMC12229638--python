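"""Run configuration: one YAML file drives every stage.

Every field has a default; a config file only needs the keys it overrides,
and CLI flags override file values.  Instrument acquisition settings may be
carried under ``instrument:`` as inert provenance metadata — they are stored
and echoed, never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chemmass import Formula, ProbeSpec, default_probe
from .classify import EvalConfig
from .screening import ScreenConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Toolkit-wide options with documented defaults.

    seed            : base seed for all stochastic stages (default 0)
    probe           : tag definition (Br-OTPP by default)
    screen          : screening tolerances (see :class:`ScreenConfig`)
    quant_weighting : calibration weighting, "none" (default) or "1/x"
    stats_variant   : "student" (default) or "welch"
    n_components    : PLS-DA components (default 3)
    classify        : repeated-split protocol (see :class:`EvalConfig`)
    log_level       : python logging level name (default "INFO")
    instrument      : opaque acquisition metadata, carried for provenance
    """

    seed: int = 0
    probe: ProbeSpec = field(default_factory=default_probe)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    quant_weighting: str = "none"
    stats_variant: str = "student"
    n_components: int = 3
    classify: EvalConfig = field(default_factory=EvalConfig)
    log_level: str = "INFO"
    instrument: dict = field(default_factory=dict)


def _probe_from_dict(d: dict) -> ProbeSpec:
    kwargs = {}
    if "cation_formula" in d:
        kwargs["cation_formula"] = Formula.parse(d["cation_formula"])
    if "leaving_group" in d:
        kwargs["leaving_group"] = Formula.parse(d["leaving_group"])
    if "diagnostic_fragment_formula" in d:
        v = d["diagnostic_fragment_formula"]
        kwargs["diagnostic_fragment_formula"] = Formula.parse(v) if v else None
    if "diagnostic_fragment_mz" in d:
        kwargs["diagnostic_fragment_mz"] = d["diagnostic_fragment_mz"]
    return ProbeSpec(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file (all keys optional)."""
    cfg = RunConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "probe" in data:
        cfg.probe = _probe_from_dict(data["probe"])
        cfg.screen.probe = cfg.probe
    screen = data.get("screen", {})
    for key in (
        "reporter_mz", "reporter_tol_ppm", "min_rel_intensity", "annot_tol_ppm",
        "rt_tol_min", "dedup_rt_min", "dedup_mz_ppm", "mode",
    ):
        if key in screen:
            setattr(cfg.screen, key, screen[key])
    for key in ("seed", "quant_weighting", "stats_variant", "n_components", "log_level"):
        if key in data:
            setattr(cfg, key, data[key])
    cls = data.get("classify", {})
    for key in ("model", "n_trials", "n_train", "n_test", "stratified", "seed",
                "rf_trees", "lr_penalty"):
        if key in cls:
            setattr(cfg.classify, key, cls[key])
    cfg.instrument = dict(data.get("instrument", {}))
    return cfg
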