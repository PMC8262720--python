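import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nciprof import AnalysisMode, ThresholdConfig, profile_structure
from nciprof.fixtures import standard_suite


@pytest.fixture(scope="session")
def cfg():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def suite():
    """The full planted fixture suite: list of (name, pdb_text, manifest)."""
    return standard_suite()


@pytest.fixture(scope="session")
def suite_results(suite):
    """Profiling results for every fixture, keyed by fixture name."""
    out = {}
    for name, text, man in suite:
        mode = AnalysisMode()
        for k, v in man.mode_flags.items():
            setattr(mode, k, v)
        out[name] = (profile_structure(text, mode=mode, input_name=name), man)
    return out


def mode_for(manifest):
    mode = AnalysisMode()
    for k, v in manifest.mode_flags.items():
        setattr(mode, k, v)
    return mode
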