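"""Named analysis scenarios over the packaged (or a user-supplied) network.

``full``         - the complete night-time network, G6P + acetate as carbon
                   sources, all six regulated enzymes.
``gap_variant``  - glycolysis and the pentose phosphate pathway removed,
                   GAP + acetate as carbon sources (tests the sensitivity
                   of the maximum yield to the model boundary).
``asl_nir_only`` - regulation restricted to the two enzymes with
                   experimentally confirmed CHLAMY1 binding (ASL, NiR).

Every run writes a summary table, the enumerated mode set, and a manifest
sufficient to reproduce the run byte for byte.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .efm import EfmSet, enumerate_efms
from .network import (
    MetabolicNetwork,
    load_core_model,
    load_core_regulation_sets,
    subnetwork,
)
from .yields import scenario_compare, summarise, yield_records

__all__ = ["ScenarioConfig", "ScenarioResult", "run_scenario", "sweep_downregulation"]

GAP_VARIANT_DROP = frozenset({"R_GPI", "R_PFK", "R_FBA", "R_G6PDH", "R_TKT"})


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "full"
    network: MetabolicNetwork | None = None  # None -> packaged core model
    regulated: frozenset[str] | None = None  # None -> scenario default
    targets: tuple[str, ...] = ()  # () -> model config targets
    schemes: tuple[str, ...] = ("all", "knockout", "weighted")
    w_affected: Fraction = Fraction(1, 10)
    output_dir: Path | None = None
    seed: int = 0  # recorded in the manifest; the pipeline itself is deterministic


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    network: MetabolicNetwork
    efms: EfmSet
    regulated: frozenset[str]
    summary: pd.DataFrame
    manifest: dict


def _prepare(config: ScenarioConfig) -> tuple[MetabolicNetwork, frozenset[str]]:
    net = config.network if config.network is not None else load_core_model()
    sets = load_core_regulation_sets() if config.network is None else {}
    if config.scenario == "full":
        regulated = config.regulated or sets.get(
            "chlamy1", net.config.regulated_reactions
        )
    elif config.scenario == "gap_variant":
        drop = GAP_VARIANT_DROP & set(net.reaction_ids)
        externals = (net.config.external - {"G6P"}) | {"GAP"}
        net = subnetwork(net, drop, externals_override=externals)
        net.config = net.config.__class__(
            external=net.config.external,
            regulated_reactions=net.config.regulated_reactions,
            carbon_sources=frozenset({"GAP", "Ac"}) & set(net.metabolite_ids),
            targets=net.config.targets,
        )
        regulated = (
            config.regulated
            or sets.get("chlamy1", net.config.regulated_reactions)
        ) & set(net.reaction_ids)
    elif config.scenario == "asl_nir_only":
        regulated = config.regulated or sets.get(
            "asl_nir_only", frozenset({"R_ASL", "R_NIR"})
        )
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    return net, frozenset(regulated)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Parse -> enumerate -> classify -> regulate -> summarise, with manifest."""
    t0 = time.perf_counter()
    net, regulated = _prepare(config)
    efms = enumerate_efms(net)
    targets = list(config.targets) or list(net.config.targets)
    summary = scenario_compare(
        efms, regulated, targets, config.schemes, config.w_affected
    )
    manifest = {
        "tool": "chlamyflux",
        "version": __version__,
        "python": platform.python_version(),
        "scenario": config.scenario,
        "network": net.name,
        "network_hash": efms.network_hash(),
        "n_reactions": len(net.reactions),
        "n_metabolites": len(net.metabolites),
        "n_modes": len(efms),
        "regulated_reactions": sorted(regulated),
        "targets": targets,
        "schemes": list(config.schemes),
        "w_affected": str(config.w_affected),
        "seed": config.seed,
        "wall_seconds": round(time.perf_counter() - t0, 3),
    }
    result = ScenarioResult(config, net, efms, regulated, summary, manifest)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        summary.to_json(out / "summary.json", orient="records", indent=2)
        efms.to_json(out / "efms.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def sweep_downregulation(
    config: ScenarioConfig, w_values: Sequence[Fraction | float]
) -> pd.DataFrame:
    """Weighted mean per (target, w); flags whether the shift direction
    relative to the unweighted mean is the same at every w."""
    ws = [Fraction(w).limit_denominator(10**6) for w in w_values]
    if any(not 0 < w <= 1 for w in ws):
        raise ValueError("w values must lie in (0, 1]")
    net, regulated = _prepare(config)
    efms = enumerate_efms(net)
    targets = list(config.targets) or list(net.config.targets)
    from .efm import classify_by_target

    rows = []
    for target in targets:
        sub = classify_by_target(efms, target)
        recs = yield_records(sub, target, regulated)
        if not recs:
            continue
        base = summarise(recs, "all", target=target)
        shifts = []
        for w in ws:
            s = summarise(recs, "weighted", w_affected=w, target=target)
            shift = s.weighted_mean - base.mean
            shifts.append(shift)
            rows.append(
                {
                    "target": target,
                    "w_affected": float(w),
                    "mean_all": base.mean,
                    "weighted_mean": s.weighted_mean,
                    "shift": shift,
                }
            )
        sign = {s > 0 for s in shifts}
        for r in rows[-len(ws):]:
            r["shift_sign_constant"] = len(sign) == 1
    return pd.DataFrame(rows)
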