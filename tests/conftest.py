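"""Shared fixtures: the bundled model and zero-noise synthetic trials.

Generation and analysis of the preset trials are session-scoped; several
test modules reuse them.
"""

import pytest

from kinerisk.model import default_model
from kinerisk.pipeline import RunConfig, run_analysis
from kinerisk.synthetic_data import PRESET_SKILLS, generate_motion, preset_script


@pytest.fixture(scope="session")
def model_muscles():
    return default_model()


@pytest.fixture(scope="session")
def trials(model_muscles):
    """skill -> (script, marker series, ground truth) at zero noise."""
    model, muscles = model_muscles
    out = {}
    for skill in PRESET_SKILLS:
        script = preset_script(skill)
        series, truth = generate_motion(script, model, muscles)
        out[skill] = (script, series, truth)
    return out


@pytest.fixture(scope="session")
def analyses(trials):
    """skill -> AnalysisResult, smoothing disabled (zero-noise input)."""
    out = {}
    for skill, (script, series, truth) in trials.items():
        config = RunConfig(
            series=series,
            smoothing=False,
            skill="pitch" if skill == "pitch" else None,
        )
        out[skill] = run_analysis(config)
    return out
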