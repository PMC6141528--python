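"""End-to-end convenience wrappers: model → simulate → refine → evaluate.

These are thin glue functions used by the command-line interface, the
test-suite and the reproduction script; the heavy lifting lives in
:mod:`~complexome.model`, :mod:`~complexome.simulator` and
:mod:`~complexome.refine`.

The default planted-recovery conditions pair a strongly binding, slowly
dissociating regime (kon = 10, koff = 0.01 per time unit) with a 16×16
grid and three replicate runs of 60 cycles (two samples each in the
second, post-burn-in half); under them the planted member sets are the
near-absorbing states of the dynamics.
"""

from __future__ import annotations

from dataclasses import replace

from .metrics import MetricsReport, composite_score
from .model import ModelConfig, ReactionModel
from .refine import RefinedComplex, RefinementConfig, refine_pipeline
from .simulator import SimulatedComplex, SpatialConfig, run_simulation
from .synthetic import PlantedScenario

__all__ = [
    "PLANTED_MODEL_CONFIG",
    "PLANTED_SPATIAL",
    "run_planted_pipeline",
    "evaluate_prediction",
]

PLANTED_MODEL_CONFIG = ModelConfig(kon_default=10.0, koff_default=0.01)
PLANTED_SPATIAL = SpatialConfig(rows=16, cols=16, sv_capacity=150, dt=1.0,
                                n_cycles=60, burn_in_fraction=0.5)


def run_planted_pipeline(
    scenario: PlantedScenario,
    spatial: SpatialConfig | None = None,
    model_config: ModelConfig | None = None,
    refinement: RefinementConfig | None = None,
    n_runs: int = 3,
    samples_per_run: int = 2,
    seed: int = 0,
) -> tuple[ReactionModel, list[SimulatedComplex], list[RefinedComplex]]:
    """Build the model of a synthetic scenario, simulate it and refine."""
    spatial = spatial if spatial is not None else replace(PLANTED_SPATIAL)
    model_config = model_config if model_config is not None else replace(PLANTED_MODEL_CONFIG)
    model = scenario.build_model(model_config)
    scs = run_simulation(model, spatial, n_runs=n_runs,
                         samples_per_run=samples_per_run, seed=seed)
    refinement = refinement or RefinementConfig()
    rcs = refine_pipeline(scs, refinement)
    return model, scs, rcs


def evaluate_prediction(rcs, reference, omega: float = 0.25) -> MetricsReport:
    """Composite-score report of refined complexes against a reference set."""
    return composite_score(
        [rc.members for rc in rcs],
        [r.members for r in reference],
        omega=omega,
        predicted_ids=[rc.id for rc in rcs],
        reference_ids=[r.id for r in reference],
    )
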