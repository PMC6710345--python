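"""Metal reference profiles: background concentrations and toxic-response factors.

The Hakanson potential-ecological-risk framework weights each metal's
contamination factor by a dimensionless "toxic-response" factor Tr.  The
classical ordering is::

    Zn = 1 < Cr = 2 < Cu = Pb = Ni = 5 < As = 10 < Cd = 30

Background concentrations (mg/kg dry soil) default to the regional soil
background values shipped with the package; both are fully configurable
through a reference table so the module works for any metal panel.

Two named profiles ship with the package:

``"default"``
    The classical toxic-response factors above.
``"ni2-compat"``
    Identical except Tr(Ni) = 2.  The published per-site risk table of the
    copper-tailings survey that this package's worked examples reproduce is
    only arithmetically consistent with Tr(Ni) = 2, although the survey's
    text states Ni = 5; this profile reproduces that table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ConfigurationError, ValidationError

PROFILES = ("default", "ni2-compat")

_REQUIRED_COLUMNS = ("metal", "background_value", "toxic_response")


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("soilrisknet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def validate_reference(ref: pd.DataFrame) -> pd.DataFrame:
    """Check a reference table and return it indexed by metal.

    Raises
    ------
    ValidationError
        If columns are missing, metals repeat, or any background value or
        toxic-response factor is not strictly positive.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in ref.columns]
    if missing:
        raise ValidationError(f"reference table missing columns: {missing}")
    if ref["metal"].duplicated().any():
        dupes = sorted(ref.loc[ref["metal"].duplicated(), "metal"])
        raise ValidationError(f"duplicate metals in reference table: {dupes}")
    out = ref.set_index("metal")[["background_value", "toxic_response"]].astype(float)
    if (out["background_value"] <= 0).any():
        bad = sorted(out.index[out["background_value"] <= 0])
        raise ValidationError(f"non-positive background value for: {bad}")
    if (out["toxic_response"] <= 0).any():
        bad = sorted(out.index[out["toxic_response"] <= 0])
        raise ValidationError(f"non-positive toxic-response factor for: {bad}")
    return out


def reference_profile(name: str = "default") -> pd.DataFrame:
    """Return a named reference profile indexed by metal.

    Columns are ``background_value`` (mg/kg) and ``toxic_response``
    (dimensionless).
    """
    if name not in PROFILES:
        raise ConfigurationError(
            f"unknown reference profile {name!r}; available: {PROFILES}"
        )
    ref = validate_reference(_packaged_csv("metal_reference.csv"))
    if name == "ni2-compat":
        ref.loc["Ni", "toxic_response"] = 2.0
    return ref


def load_reference(path) -> pd.DataFrame:
    """Load and validate a user reference CSV (metal, background_value, toxic_response)."""
    return validate_reference(pd.read_csv(path))


def survey_site_means() -> pd.DataFrame:
    """Published per-site mean metal concentrations (mg/kg dry soil).

    Site-mean concentrations for the four sites (TD0 on the tailings dam,
    TD1-TD3 downstream along the seepage stream) of the copper-tailings
    survey used throughout the documentation, one row per site.  Useful as a
    small worked example: running the risk stage on these rows reproduces
    the survey's published per-site monomial risk factors.
    """
    df = _packaged_csv("site_mean_concentrations.csv")
    df.insert(0, "sample_id", df["site"])
    return df.set_index("sample_id")
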