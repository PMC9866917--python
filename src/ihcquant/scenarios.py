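"""Preset four-image cases parameterized to satisfy each subtype rule system.

Each scenario fixes, per biomarker, the stained-area fraction and the stain
luma so that after the full pipeline (preprocessing with the published window
and gain tables, then band + watershed segmentation) the measured indicators
land on the correct side of every condition of exactly one rule system.

The Luminal A system needs a large ER area with bright in-band stain, which
is only reachable when segmenting the noise-filtered image (the brightness
gain saturates bright stains out of the band); the other three systems need
low-brightness intensity readings (KI = 1 or 2), which are only reachable
when segmenting the gain-amplified image with dark stains.  Each scenario
therefore carries its own :class:`PipelineConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ihcquant.config import PipelineConfig
from ihcquant.core_io import BiomarkerKind, Grade
from ihcquant.subtype_rules import Subtype
from ihcquant.synthetic import FixtureSpec, make_ihc_image


@dataclass(frozen=True)
class _MarkerPlan:
    fraction: float
    luma: float
    negatives: int = 0
    jitter: float = 2.0
    overlap: bool = False


@dataclass(frozen=True)
class SubtypeScenario:
    subtype: Subtype
    grade: Grade
    config: PipelineConfig
    plans: dict  # BiomarkerKind -> _MarkerPlan
    noise_density: float = 0.01


_FILTERED = PipelineConfig(segment_on="filtered")
_AMPLIFIED = PipelineConfig(segment_on="amplified")

SCENARIOS = {
    Subtype.LUMINAL_A: SubtypeScenario(
        subtype=Subtype.LUMINAL_A,
        grade=Grade.G1,
        config=_FILTERED,
        plans={
            BiomarkerKind.ER: _MarkerPlan(0.80, 195.0, negatives=0, overlap=True),
            BiomarkerKind.PR: _MarkerPlan(0.32, 170.0, negatives=6),
            BiomarkerKind.HER2: _MarkerPlan(0.04, 120.0, negatives=0),
            BiomarkerKind.KI67: _MarkerPlan(0.08, 170.0, negatives=6),
        },
    ),
    Subtype.LUMINAL_B: SubtypeScenario(
        subtype=Subtype.LUMINAL_B,
        grade=Grade.G3,
        config=_AMPLIFIED,
        plans={
            # alpha = 4 -> ER stain lands in (180, 210); original luma ~49 keeps ER KI = 3
            BiomarkerKind.ER: _MarkerPlan(0.15, 48.8, jitter=0.5),
            BiomarkerKind.PR: _MarkerPlan(0.04, 13.0, jitter=0.5),
            BiomarkerKind.HER2: _MarkerPlan(0.05, 13.0, jitter=0.5),
            # alpha = 6 -> Ki-67 stain lands in (160, 180); original luma ~28 gives KI = 2
            BiomarkerKind.KI67: _MarkerPlan(0.30, 28.3, jitter=0.5),
        },
    ),
    Subtype.HER2_AMPLIFIED: SubtypeScenario(
        subtype=Subtype.HER2_AMPLIFIED,
        grade=Grade.G3,
        config=_AMPLIFIED,
        plans={
            BiomarkerKind.ER: _MarkerPlan(0.03, 13.0, jitter=0.5),
            BiomarkerKind.PR: _MarkerPlan(0.03, 13.0, jitter=0.5),
            BiomarkerKind.HER2: _MarkerPlan(0.05, 13.0, jitter=0.5),
            BiomarkerKind.KI67: _MarkerPlan(0.05, 13.0, jitter=0.5),
        },
    ),
    Subtype.BASAL_LIKE: SubtypeScenario(
        subtype=Subtype.BASAL_LIKE,
        grade=Grade.G3,
        config=_AMPLIFIED,
        plans={
            BiomarkerKind.ER: _MarkerPlan(0.03, 13.0, jitter=0.5),
            BiomarkerKind.PR: _MarkerPlan(0.03, 13.0, jitter=0.5),
            # bright blue-range stain saturates out of every band under the gain
            BiomarkerKind.HER2: _MarkerPlan(0.05, 110.0, jitter=0.5),
            # alpha = 4 -> in Ki-67 band; original luma ~42 gives KI = 3
            BiomarkerKind.KI67: _MarkerPlan(0.10, 42.5, jitter=0.5),
        },
    ),
}


def make_subtype_case(
    subtype: Subtype,
    seed: int,
    height: int = 256,
    width: int = 256,
) -> tuple[dict, SubtypeScenario]:
    """Generate the four-image stack for a subtype scenario.

    Returns ``(stack, scenario)`` where ``stack`` maps biomarker kind to the
    rendered (noisy) image and ``scenario`` carries the pipeline config and
    the grade the case should be consistent with.
    """
    scenario = SCENARIOS[subtype]
    rng = np.random.default_rng(seed)
    stack = {}
    for kind in BiomarkerKind:
        plan = scenario.plans[kind]
        spec = FixtureSpec(
            height=height,
            width=width,
            positive_fraction=plan.fraction,
            positive_luma=plan.luma,
            negative_count=plan.negatives,
            nucleus_radius_px=(14.0, 3.0),
            impulse_noise_density=scenario.noise_density,
            seed=int(rng.integers(2**31)),
            allow_overlap=plan.overlap,
            luma_jitter=plan.jitter,
        )
        stack[kind] = make_ihc_image(spec)[0]
    return stack, scenario
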