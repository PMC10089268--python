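"""Bundled data files: the synthetic growth-reference fixture and the
default engine configuration.

The bundled LMS table (``lms_bmi_synthetic.csv``) is a SYNTHETIC stand-in
for a real BMI-for-age growth reference: smooth, monotone, order-of-magnitude
realistic L/M/S values covering 108-155 months for both sexes. It exists so
the package is fully self-contained and deterministic; any analysis of real
children must supply a real reference table via configuration.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .health import LMSTable

_PKG = "habitcoach.data_files"


def _resource(name: str):
    return resources.files(_PKG).joinpath(name)


@lru_cache(maxsize=1)
def load_default_lms() -> LMSTable:
    """The bundled synthetic BMI-for-age LMS table (ages 108-155 months)."""
    with resources.as_file(_resource("lms_bmi_synthetic.csv")) as path:
        return LMSTable.from_csv(path)


def default_config_text() -> str:
    """Raw YAML text of the default engine configuration."""
    return _resource("default_config.yaml").read_text()
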