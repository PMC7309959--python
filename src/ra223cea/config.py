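"""Parameter configuration: loading, validation, overrides.

The full model input set (survival-curve parameters, adverse-event rates,
utilities, resource-use frequencies, unit costs, discounting and horizon)
lives in one YAML document.  A scalar entry may be a bare number or a mapping
``{value: x, owsa: [lo, hi], calibrated: true}``; the loader flattens these
into plain values plus side tables of one-way-sensitivity ranges and
calibrated-assumption flags keyed by dotted parameter paths
(e.g. ``unit_costs.hospitalization_day``).

The packaged base case (``data/base_case.yaml``) makes the analysis runnable
with zero external inputs.
"""

from __future__ import annotations

import copy
import importlib.resources
import io
import json
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import yaml

from .survival import SurvivalCurve

ARM_RADIUM = "radium223"
ARM_BSC = "bsc"
ARMS = (ARM_RADIUM, ARM_BSC)
ENDPOINTS = ("OS", "PFS", "SSE")

#: health-state keys as used in the utilities section
STATE_KEYS = ("pf_no_sse", "pf_sse", "prog_no_sse", "prog_sse")

# top-level sections whose scalars are probabilities/utilities (beta-sampled
# in PSA); everything else with a range is gamma-sampled.
_BETA_SECTIONS = {
    "ae_weekly_rates",
    "ae_hospitalization_proportion",
    "utilities",
    "sse_type_distribution",
}

__all__ = [
    "ARM_RADIUM",
    "ARM_BSC",
    "ARMS",
    "ENDPOINTS",
    "STATE_KEYS",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "validate",
    "override",
]


class ConfigError(ValueError):
    """Raised for unparseable or invalid configuration documents."""


@dataclass(frozen=True)
class ParamSpec:
    """A registered scalar parameter: dotted path, base value, PSA metadata."""

    path: str
    value: float
    lower: float | None = None
    upper: float | None = None
    kind: str = "gamma"  # sampling family for PSA: "gamma" or "beta"

    @property
    def has_range(self) -> bool:
        return self.lower is not None and self.upper is not None


@dataclass(frozen=True)
class ModelConfig:
    """Validated, fully-resolved parameter set for one model evaluation."""

    values: Mapping[str, Any]
    owsa_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    calibrated: frozenset = field(default_factory=frozenset)

    # -- navigation ---------------------------------------------------------

    def get(self, path: str) -> Any:
        node: Any = self.values
        for part in path.split("."):
            try:
                node = node[part]
            except (KeyError, TypeError) as err:
                raise KeyError(f"no parameter at path {path!r}") from err
        return node

    def __getitem__(self, path: str) -> Any:
        return self.get(path)

    @property
    def horizon_weeks(self) -> int:
        return int(round(self.get("horizon_years") * 52))

    @property
    def cycle_weeks(self) -> float:
        return float(self.get("cycle_length_weeks"))

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_weeks / self.cycle_weeks))

    def curve(self, endpoint: str, arm: str) -> SurvivalCurve:
        spec = self.get(f"curves.{endpoint}.{arm}")
        return SurvivalCurve(
            family=spec["family"], scale=float(spec["scale"]), shape=float(spec["shape"])
        )

    # -- flat scalar registry ----------------------------------------------

    def iter_params(self) -> Iterator[ParamSpec]:
        """Yield every registered scalar parameter with its PSA metadata."""

        def walk(node: Any, path: str, section: str) -> Iterator[ParamSpec]:
            if isinstance(node, Mapping):
                for key, sub in node.items():
                    yield from walk(sub, f"{path}.{key}" if path else str(key), section or str(key))
            elif isinstance(node, (int, float)) and not isinstance(node, bool):
                is_beta = section in _BETA_SECTIONS or path.startswith(
                    "second_line.proportion"
                )
                kind = "beta" if is_beta else "gamma"
                lo_hi = self.owsa_ranges.get(path)
                yield ParamSpec(
                    path=path,
                    value=float(node),
                    lower=None if lo_hi is None else lo_hi[0],
                    upper=None if lo_hi is None else lo_hi[1],
                    kind=kind,
                )

        skip = {"arms", "curves", "owsa_structural"}
        for key, node in self.values.items():
            if key in skip:
                continue
            yield from walk(node, key, key)

    def param_ids(self) -> list[str]:
        return [p.path for p in self.iter_params()]

    # -- export -------------------------------------------------------------

    def to_dict(self) -> dict:
        return copy.deepcopy(dict(self.values))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        """Resolved parameter set plus provenance metadata, for export."""
        payload = {
            "parameters": self.to_dict(),
            "owsa_ranges": {k: list(v) for k, v in sorted(self.owsa_ranges.items())},
            "calibrated": sorted(self.calibrated),
        }
        return json.dumps(payload, indent=2, sort_keys=False)

    def digest(self) -> str:
        """Stable content hash of the resolved parameter set."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _resolve(node: Any, path: str, owsa: dict, calibrated: set) -> Any:
    """Collapse {value, owsa, calibrated} wrappers into plain values."""
    if isinstance(node, Mapping):
        if "value" in node:
            extra = set(node) - {"value", "owsa", "calibrated"}
            if extra:
                raise ConfigError(f"{path}: unexpected keys {sorted(extra)}")
            if node.get("calibrated"):
                calibrated.add(path)
            if "owsa" in node:
                rng = node["owsa"]
                if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
                    raise ConfigError(f"{path}: owsa must be [lower, upper]")
                owsa[path] = (float(rng[0]), float(rng[1]))
            return float(node["value"])
        return {
            key: _resolve(sub, f"{path}.{key}" if path else str(key), owsa, calibrated)
            for key, sub in node.items()
        }
    return node


def load_config(source) -> ModelConfig:
    """Load and validate a configuration.

    ``source`` may be a filesystem path, a YAML string, a file-like object, a
    mapping, or ``None`` for the packaged base case.  Raises
    :class:`ConfigError` with an aggregated violation list if invalid.
    """
    if source is None:
        text = (
            importlib.resources.files("ra223cea")
            .joinpath("data/base_case.yaml")
            .read_text()
        )
        doc = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        doc = copy.deepcopy(dict(source))
    elif isinstance(source, io.IOBase):
        doc = yaml.safe_load(source)
    else:
        import os

        text = str(source)
        if os.path.exists(text):
            with open(text) as fh:
                try:
                    doc = yaml.safe_load(fh)
                except yaml.YAMLError as err:
                    raise ConfigError(f"cannot parse {text}: {err}") from err
        else:
            try:
                doc = yaml.safe_load(text)
            except yaml.YAMLError as err:
                raise ConfigError(f"cannot parse configuration text: {err}") from err
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration document must be a mapping")

    owsa: dict[str, tuple[float, float]] = {}
    calibrated: set[str] = set()
    values = {
        key: _resolve(node, str(key), owsa, calibrated) for key, node in doc.items()
    }
    config = ModelConfig(
        values=values, owsa_ranges=owsa, calibrated=frozenset(calibrated)
    )
    violations = validate(config)
    if violations:
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    return config


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "arms",
    "horizon_years",
    "cycle_length_weeks",
    "discount_rate_annual",
    "mean_injections",
    "drug_price_per_injection",
    "administration_cost_per_injection",
    "curves",
    "ae_weekly_rates",
    "ae_hospitalization_proportion",
    "ae_outpatient_cost",
    "sse_type_distribution",
    "sse_type_unit_cost",
    "utilities",
    "management_frequencies",
    "management_unit_costs",
    "facility_use",
    "unit_costs",
    "second_line",
)

_PROBABILITY_SECTIONS = (
    "ae_weekly_rates",
    "ae_hospitalization_proportion",
    "utilities",
    "sse_type_distribution",
)


def validate(config: ModelConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    out: list[str] = []
    vals = config.values

    for key in _REQUIRED_KEYS:
        if key not in vals:
            out.append(f"missing required section {key!r}")
    if out:
        return out

    # probabilities / proportions / utilities in [0, 1]
    for spec in config.iter_params():
        section = spec.path.split(".", 1)[0]
        if section in _PROBABILITY_SECTIONS or spec.path.startswith(
            "second_line.proportion"
        ):
            if not 0.0 <= spec.value <= 1.0:
                out.append(
                    f"{spec.path}: value {spec.value} outside [0, 1]"
                )
        elif spec.path != "discount_rate_annual" and spec.value < 0:
            out.append(f"{spec.path}: value {spec.value} must be non-negative")
        if spec.has_range and not (spec.lower <= spec.value <= spec.upper):
            out.append(
                f"{spec.path}: OWSA range ({spec.lower}, {spec.upper}) does not "
                f"bracket base value {spec.value}"
            )

    # SSE type distribution sums to 1 per arm
    dist = vals["sse_type_distribution"]
    for arm in ARMS:
        total = sum(entry[arm] for entry in dist.values())
        if abs(total - 1.0) > 1e-6:
            out.append(
                f"sse_type_distribution[{arm}]: shares sum to {total:.6f}, expected 1"
            )

    # both arms carry all three endpoint curves, constructible
    for endpoint in ENDPOINTS:
        for arm in ARMS:
            try:
                config.curve(endpoint, arm)
            except (KeyError, ValueError) as err:
                out.append(f"curves.{endpoint}.{arm}: {err}")

    if vals["discount_rate_annual"] < 0:
        out.append("discount_rate_annual must be >= 0")
    if vals["horizon_years"] <= 0:
        out.append("horizon_years must be positive")
    if vals["cycle_length_weeks"] <= 0:
        out.append("cycle_length_weeks must be positive")

    # AE tables aligned on names
    names = set(vals["ae_weekly_rates"])
    for table in ("ae_hospitalization_proportion", "ae_outpatient_cost"):
        diff = names.symmetric_difference(vals[table])
        if diff:
            out.append(f"{table}: adverse-event names differ from rates: {sorted(diff)}")

    return out


# ---------------------------------------------------------------------------
# overrides
# ---------------------------------------------------------------------------


def override(config: ModelConfig, param_id: str, value: float) -> ModelConfig:
    """Return a new configuration with one scalar replaced.

    The original configuration is untouched.  ``param_id`` must be a
    registered dotted path (see :meth:`ModelConfig.param_ids`) or one of the
    structural scalars ``discount_rate_annual`` / ``horizon_years`` /
    ``cycle_length_weeks``.
    """
    structural = {"discount_rate_annual", "horizon_years", "cycle_length_weeks"}
    known = set(config.param_ids()) | structural
    if param_id not in known:
        sample = sorted(known)
        raise KeyError(
            f"unknown parameter id {param_id!r}; valid ids include e.g. "
            f"{sample[:5]} ... ({len(sample)} total)"
        )
    new_values = copy.deepcopy(dict(config.values))
    node = new_values
    *head, leaf = param_id.split(".")
    for part in head:
        node = node[part]
    node[leaf] = float(value)
    return ModelConfig(
        values=new_values,
        owsa_ranges=dict(config.owsa_ranges),
        calibrated=config.calibrated,
    )
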