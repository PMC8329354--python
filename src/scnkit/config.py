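"""Pipeline configuration: YAML schema, validation, config hashing.

Schema (all sections at top level of the YAML file)::

    seed: 20260925          # REQUIRED; master seed for every random draw
    q: 0.05                 # BH rate for the edge threshold, in (0, 1)
    q_nodal: 0.05           # BH rate across ROIs (default: q)
    permutations: 1000      # >= 100
    n_random: 100           # random references for small-world ratios
    conditions: [restricted, full]
    stratify: false         # additionally analyse each group separately
    input_table: null       # path to a thickness table; null -> synthetic
    synthetic:              # used when input_table is null
      n_young: 43
      n_old: 37
      base_mean_mm: 2.5
      base_sd_mm: 0.25
      subject_reliability: 0.5
      modules: default      # "default", or a list of {rois: [...], r: ...}
      thinning:             # optional mean shifts (mm, subtracted)
        - {roi: rh_lateraloccipital, condition: restricted, shift_mm: 0.1}
      covariance_boost:     # optional correlation increments
        - {rois: [lh_insula, ...], condition: restricted, delta_r: 0.3}
    metrics:
      global: [clustering, path_length, global_efficiency, local_efficiency]
      nodal: [degree, nodal_efficiency, betweenness]

ROIs may be given by atlas label or integer index. Validation errors carry
the dotted path of the offending field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .atlas import RoiAtlas, desikan_killiany
from .permutation import DEFAULT_GLOBAL, DEFAULT_NODAL, GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES
from .simulate import (
    CohortSpec,
    CovarianceEffect,
    CovarianceModule,
    ThinningEffect,
    default_modules,
)

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Configuration file is invalid; message names the field path."""


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {msg}")


def _roi_index(value, atlas: RoiAtlas, path: str) -> int:
    if isinstance(value, int):
        _require(0 <= value < atlas.n, path, f"ROI index {value} out of range")
        return value
    if isinstance(value, str):
        try:
            return atlas.index(value)
        except KeyError:
            raise ConfigError(f"{path}: unknown ROI label {value!r}") from None
    raise ConfigError(f"{path}: ROI must be a label or index")


@dataclass
class PipelineConfig:
    seed: int
    q: float = 0.05
    q_nodal: float | None = None
    permutations: int = 1000
    n_random: int = 100
    conditions: tuple[str, str] = ("restricted", "full")
    stratify: bool = False
    input_table: str | None = None
    cohort_spec: CohortSpec | None = None
    global_metrics: tuple[str, ...] = DEFAULT_GLOBAL
    nodal_metrics: tuple[str, ...] = DEFAULT_NODAL
    atlas: RoiAtlas = field(default_factory=desikan_killiany)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        """SHA-256 of the canonicalized raw configuration."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> PipelineConfig:
    _require(isinstance(raw, dict), "<root>", "config must be a mapping")
    known = {"seed", "q", "q_nodal", "permutations", "n_random", "conditions",
             "stratify", "input_table", "synthetic", "metrics"}
    unknown = set(raw) - known
    _require(not unknown, "<root>", f"unknown fields: {sorted(unknown)}")
    _require("seed" in raw and raw["seed"] is not None, "seed",
             "a master seed is mandatory; every random draw must be auditable")
    _require(isinstance(raw["seed"], int), "seed", "must be an integer")
    seed = raw["seed"]

    q = raw.get("q", 0.05)
    _require(isinstance(q, (int, float)) and 0 < q < 1, "q", "must be in (0, 1)")
    q_nodal = raw.get("q_nodal")
    if q_nodal is not None:
        _require(isinstance(q_nodal, (int, float)) and 0 < q_nodal < 1,
                 "q_nodal", "must be in (0, 1)")
    perms = raw.get("permutations", 1000)
    _require(isinstance(perms, int) and perms >= 100, "permutations", "must be an integer >= 100")
    n_random = raw.get("n_random", 100)
    _require(isinstance(n_random, int) and n_random >= 0, "n_random", "must be an integer >= 0")
    conditions = tuple(raw.get("conditions", ("restricted", "full")))
    _require(len(conditions) == 2 and len(set(conditions)) == 2,
             "conditions", "exactly two distinct labels required")
    stratify = bool(raw.get("stratify", False))
    input_table = raw.get("input_table")

    atlas = desikan_killiany()

    metrics = raw.get("metrics") or {}
    _require(isinstance(metrics, dict), "metrics", "must be a mapping")
    gsel = tuple(metrics.get("global", DEFAULT_GLOBAL))
    bad = set(gsel) - set(GLOBAL_METRIC_NAMES)
    _require(not bad, "metrics.global", f"unknown metrics {sorted(bad)}")
    nsel = tuple(metrics.get("nodal", DEFAULT_NODAL))
    bad = set(nsel) - set(NODAL_METRIC_NAMES)
    _require(not bad, "metrics.nodal", f"unknown metrics {sorted(bad)}")

    cohort_spec = None
    if input_table is None:
        syn = raw.get("synthetic") or {}
        _require(isinstance(syn, dict), "synthetic", "must be a mapping")
        mods_raw = syn.get("modules", "default")
        if mods_raw == "default":
            modules = default_modules(atlas)
        else:
            _require(isinstance(mods_raw, list), "synthetic.modules",
                     'must be "default" or a list')
            modules = tuple(
                CovarianceModule(
                    rois=tuple(
                        _roi_index(rv, atlas, f"synthetic.modules[{k}].rois")
                        for rv in m.get("rois", [])
                    ),
                    r=float(m.get("r", 0.0)),
                )
                for k, m in enumerate(mods_raw)
            )
        thinning = tuple(
            ThinningEffect(
                roi=_roi_index(t.get("roi"), atlas, f"synthetic.thinning[{k}].roi"),
                condition=str(t.get("condition")),
                shift_mm=float(t.get("shift_mm", 0.0)),
            )
            for k, t in enumerate(syn.get("thinning") or [])
        )
        boosts = tuple(
            CovarianceEffect(
                rois=tuple(
                    _roi_index(rv, atlas, f"synthetic.covariance_boost[{k}].rois")
                    for rv in b.get("rois", [])
                ),
                condition=str(b.get("condition")),
                delta_r=float(b.get("delta_r", 0.0)),
            )
            for k, b in enumerate(syn.get("covariance_boost") or [])
        )
        try:
            cohort_spec = CohortSpec(
                n_young=int(syn.get("n_young", 43)),
                n_old=int(syn.get("n_old", 37)),
                conditions=conditions,
                atlas=atlas,
                base_mean=float(syn.get("base_mean_mm", 2.5)),
                base_sd=float(syn.get("base_sd_mm", 0.25)),
                covariance_modules=modules,
                thinning_effects=thinning,
                covariance_effects=boosts,
                subject_reliability=float(syn.get("subject_reliability", 0.5)),
                seed=seed,
            )
        except ValueError as e:
            raise ConfigError(f"synthetic: {e}") from None

    return PipelineConfig(
        seed=seed, q=float(q),
        q_nodal=None if q_nodal is None else float(q_nodal),
        permutations=perms, n_random=n_random, conditions=conditions,
        stratify=stratify, input_table=input_table, cohort_spec=cohort_spec,
        global_metrics=gsel, nodal_metrics=nsel, atlas=atlas, raw=raw,
    )
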