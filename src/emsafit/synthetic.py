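"""Synthetic EMSA titrations with the statistical structure the fit assumes.

A :class:`Scenario` bundles true model parameters with the experimental
design: a geometric concentration ladder, a replicate count, and the SD of
additive Gaussian noise applied on the normalized-fraction scale (the scale
the fit and the bootstrap operate on).  Presets mirror the study design this
model was built for — a 4-fold titration ladder from 2.5 to 640 nM with a
cooperative wild-type condition (C = 5) on a sequence-paired-site probe and
non-cooperative conditions (C = 1) for the dimerization-deficient mutant and
for probes with two independent sites.  The preset Kd (40 nM, mid-ladder)
and f (0.85) are synthetic defaults chosen to be well identifiable from the
ladder, not measured values.

Noise is applied per lane and band, clipped at zero, and the lane is
renormalized, after which fractions are scaled by a constant per-lane total
intensity (10,000 arbitrary units) so raw and normalized representations
stay interconvertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding_model import ModelParams, mixture_occupancy, statistical_weight
from .gel_io import TitrationSeries

__all__ = [
    "LANE_TOTAL_INTENSITY",
    "DEFAULT_LADDER",
    "Scenario",
    "make_ladder",
    "simulate_series",
    "preset_scenarios",
    "scenario_from_dict",
    "load_scenario_file",
]

LANE_TOTAL_INTENSITY = 10_000.0

#: 4-fold titration ladder, 2.5 to 640 nM.
DEFAULT_LADDER = (2.5, 10.0, 40.0, 160.0, 640.0)


@dataclass(frozen=True)
class Scenario:
    """A fully specified synthetic titration experiment."""

    name: str
    params: ModelParams
    ladder: tuple[float, ...] = DEFAULT_LADDER
    n_reps: int = 3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        ladder = tuple(float(c) for c in self.ladder)
        if len(ladder) < 1 or any(c <= 0 for c in ladder):
            raise ValueError("ladder must be non-empty with positive concentrations")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ladder must be strictly increasing")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "ladder", ladder)

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=int(seed))


def make_ladder(start: float, fold: float, n: int) -> np.ndarray:
    """Geometric concentration ladder ``start * fold**i`` for i = 0..n-1 (nM)."""
    if start <= 0:
        raise ValueError(f"start must be > 0, got {start!r}")
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    return start * float(fold) ** np.arange(n)


def simulate_series(scenario: Scenario) -> TitrationSeries:
    """Simulate one titration series from a scenario, deterministically per seed.

    For each (concentration, replicate) the true mixture-occupancy fractions
    are perturbed by independent N(0, noise_sd) per band, clipped at 0,
    renormalized, and scaled to the constant lane total.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    p = scenario.params
    rows = []
    for conc in scenario.ladder:
        alpha = statistical_weight(conc, p.kd)
        truth = np.array(mixture_occupancy(alpha, p.C, p.f))
        for rep in range(1, scenario.n_reps + 1):
            frac = truth + rng.normal(0.0, scenario.noise_sd, size=3)
            frac = np.clip(frac, 0.0, None)
            total = frac.sum()
            if total <= 0:  # pathological draw at extreme noise; keep truth
                frac = truth.copy()
                total = frac.sum()
            frac = frac / total
            bands = frac * LANE_TOTAL_INTENSITY
            rows.append((conc, rep, *bands))
    lanes = pd.DataFrame(
        rows, columns=["conc_nM", "replicate", "band0", "band1", "band2"]
    )
    return TitrationSeries(scenario.name, lanes)


def preset_scenarios() -> dict[str, Scenario]:
    """Named scenarios mirroring the four experimental conditions.

    ``wt_sps``: cooperative binding (C = 5) of the wild-type complex to the
    sequence-paired-site probe.  ``ra_sps``: the dimer-interface mutant on the
    same probe, non-cooperative (C = 1).  ``wt_2xcsl`` / ``ra_2xcsl``: either
    complex on a probe with two independent sites, non-cooperative (C = 1).
    All share the 4-fold 2.5–640 nM ladder, Kd = 40 nM, f = 0.85.
    """
    base = dict(ladder=DEFAULT_LADDER, n_reps=3, noise_sd=0.02)
    return {
        "wt_sps": Scenario("wt_sps", ModelParams(kd=40.0, C=5.0, f=0.85), **base),
        "ra_sps": Scenario("ra_sps", ModelParams(kd=40.0, C=1.0, f=0.85), **base),
        "wt_2xcsl": Scenario("wt_2xcsl", ModelParams(kd=40.0, C=1.0, f=0.85), **base),
        "ra_2xcsl": Scenario("ra_2xcsl", ModelParams(kd=40.0, C=1.0, f=0.85), **base),
    }


def scenario_from_dict(d: dict) -> Scenario:
    """Build a Scenario from a plain mapping (as loaded from YAML/JSON)."""
    d = dict(d)
    params = d.pop("params")
    return Scenario(
        name=str(d.pop("name")),
        params=ModelParams(
            kd=float(params["kd"]), C=float(params["C"]), f=float(params["f"])
        ),
        ladder=tuple(float(c) for c in d.pop("ladder", DEFAULT_LADDER)),
        n_reps=int(d.pop("n_reps", 3)),
        noise_sd=float(d.pop("noise_sd", 0.02)),
        seed=int(d.pop("seed", 0)),
    )


def load_scenario_file(path: str | Path) -> Scenario:
    """Load a Scenario from a YAML or JSON file with the same field names."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scenario_from_dict(data)
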