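"""Report writers: cost-effectiveness tables, breakdowns, run manifests.

Machine-readable outputs carry unrounded values; rounding happens only in the
human-oriented table views (the published ICER is computed from unrounded
increments, and re-deriving it from rounded ones gives a visibly different
number — the reports preserve that distinction).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import ModelConfig
from .economics import CEAResult
from .sensitivity import PSASample, TornadoEntry

__all__ = [
    "cea_table",
    "breakdown_table",
    "tornado_table",
    "psa_table",
    "ceac_table",
    "write_manifest",
]


def cea_table(result: CEAResult) -> pd.DataFrame:
    """Per-arm and incremental life-years, QALYs, costs and ICER."""
    ref, comp = result.reference, result.comparator
    icer = result.icer
    return pd.DataFrame(
        [
            {
                "row": comp.arm,
                "life_years": comp.life_years,
                "qalys": comp.qalys,
                "cost": comp.total_cost,
                "icer": "",
            },
            {
                "row": ref.arm,
                "life_years": ref.life_years,
                "qalys": ref.qalys,
                "cost": ref.total_cost,
                "icer": "",
            },
            {
                "row": "incremental",
                "life_years": result.delta_life_years,
                "qalys": result.delta_qalys,
                "cost": result.delta_cost,
                "icer": icer,
            },
        ]
    )


def breakdown_table(result: CEAResult) -> pd.DataFrame:
    """Cost categories per arm plus the incremental column."""
    ref = result.reference.costs.as_dict()
    comp = result.comparator.costs.as_dict()
    rows = []
    for key in ref:
        rows.append(
            {
                "category": key,
                result.reference.arm: ref[key],
                result.comparator.arm: comp[key],
                "incremental": ref[key] - comp[key],
            }
        )
    return pd.DataFrame(rows)


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "param_id": e.param_id,
                "lower": e.lower,
                "upper": e.upper,
                "icer_at_lower": e.icer_at_lower,
                "icer_at_upper": e.icer_at_upper,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


def psa_table(samples: Sequence[PSASample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "draw": s.draw,
                "cost_reference": s.cost_reference,
                "qalys_reference": s.qalys_reference,
                "cost_comparator": s.cost_comparator,
                "qalys_comparator": s.qalys_comparator,
                "delta_cost": s.delta_cost,
                "delta_qalys": s.delta_qalys,
            }
            for s in samples
        ]
    )


def ceac_table(points: Sequence[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(points, columns=["wtp", "probability_cost_effective"])


def write_manifest(
    command: str,
    config: ModelConfig,
    out_dir: Path,
    outputs: Sequence[str],
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a JSON run manifest and return its path.

    The config digest is a SHA-256 of the key-sorted resolved parameter set,
    so it is stable under reordering of the source document.  All randomness
    in a run flows from the recorded seed through numpy's PCG64 generator.
    """
    from . import __version__

    manifest = {
        "command": command,
        "config_digest": config.digest(),
        "calibrated_parameters": sorted(config.calibrated),
        "seed": seed,
        "rng": "numpy.random.default_rng (PCG64)",
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
        "outputs": list(outputs),
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
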