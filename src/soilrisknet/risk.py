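"""Hakanson potential-ecological-risk scoring of multi-metal soil concentrations.

For metal *i* with measured concentration :math:`C_D^i` and background
reference :math:`C_R^i`:

.. math::

    C_f^i = C_D^i / C_R^i, \\qquad
    E_r^i = T_r^i \\; C_f^i, \\qquad
    RI = \\sum_i E_r^i

where :math:`C_f` is the contamination factor, :math:`T_r` the toxic-response
factor, :math:`E_r` the monomial potential ecological risk factor and *RI*
the integrated potential ecological risk index of a sample.  All quantities
are dimensionless and non-negative; *RI* is linear in each concentration.

Tables are plain :class:`pandas.DataFrame` objects: samples in rows
(indexed by sample id), one column per metal, plus a ``site`` column
grouping samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

SITE_COLUMN = "site"


def round_half_up(x, decimals: int = 2):
    """Round half away from zero at ``decimals`` places (display rounding).

    Report tables round 73.7995 to 73.80 the way a human editor would;
    bankers' rounding (the float default) would not.  Internal values are
    never rounded.
    """
    q = Decimal(1).scaleb(-decimals)

    def _one(v) -> float:
        v = float(v)
        if np.isnan(v):
            return v
        return float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP))

    if np.isscalar(x):
        return _one(x)
    if isinstance(x, pd.DataFrame):
        return x.map(_one)
    if isinstance(x, pd.Series):
        return x.map(_one)
    return np.vectorize(_one)(np.asarray(x))


def _metal_columns(conc: pd.DataFrame) -> list[str]:
    return [c for c in conc.columns if c != SITE_COLUMN]


def _check_concentrations(conc: pd.DataFrame, ref: pd.DataFrame) -> list[str]:
    metals = _metal_columns(conc)
    missing = [m for m in metals if m not in ref.index]
    if missing:
        raise ConfigurationError(
            f"no reference entry (background value / toxic response) for metals: {missing}"
        )
    values = conc[metals]
    if values.isna().any().any():
        bad = sorted(values.columns[values.isna().any()])
        raise ValidationError(f"missing concentration values in columns: {bad}")
    if (values < 0).any().any():
        bad = sorted(values.columns[(values < 0).any()])
        raise ValidationError(f"negative concentrations in columns: {bad}")
    return metals


def contamination_factor(conc: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-metal contamination factor Cf = C_D / C_R.

    Parameters
    ----------
    conc
        Samples x metals concentration table (mg/kg); may include a
        ``site`` column, which is passed through untouched.
    ref
        Reference table indexed by metal with a ``background_value`` column
        (see :func:`soilrisknet.references.reference_profile`).
    """
    metals = _check_concentrations(conc, ref)
    cf = conc[metals] / ref.loc[metals, "background_value"]
    if SITE_COLUMN in conc.columns:
        cf.insert(0, SITE_COLUMN, conc[SITE_COLUMN])
    return cf


def monomial_risk(cf: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Monomial potential ecological risk factor Er = Tr * Cf, per sample and metal."""
    metals = _metal_columns(cf)
    missing = [m for m in metals if m not in ref.index]
    if missing:
        raise ConfigurationError(f"no toxic-response factor for metals: {missing}")
    er = cf[metals] * ref.loc[metals, "toxic_response"]
    if SITE_COLUMN in cf.columns:
        er.insert(0, SITE_COLUMN, cf[SITE_COLUMN])
    return er


def risk_index(
    er: pd.DataFrame, *, expected_metals=None, allow_missing: bool = False
) -> pd.Series:
    """Integrated risk index RI = sum of Er over metals, per sample.

    ``expected_metals`` declares the configured panel; a sample missing one
    of them raises unless ``allow_missing`` is set, in which case the metal
    is excluded and the exclusion logged.
    """
    metals = _metal_columns(er)
    if expected_metals is not None:
        absent = [m for m in expected_metals if m not in metals]
        if absent:
            if not allow_missing:
                raise ValidationError(
                    f"Er values missing for configured metals: {absent} "
                    "(pass allow_missing=True to exclude them)"
                )
            logger.warning("risk_index: excluding metals with no Er values: %s", absent)
        metals = [m for m in expected_metals if m in metals]
    values = er[metals]
    if values.isna().any().any():
        if not allow_missing:
            bad = values.index[values.isna().any(axis=1)].tolist()
            raise ValidationError(f"samples with missing Er values: {bad}")
        logger.warning("risk_index: NaN Er values excluded from the sum")
    ri = values.sum(axis=1, skipna=allow_missing)
    ri.name = "RI"
    return ri


def site_summary(values: pd.Series, sites: pd.Series) -> pd.DataFrame:
    """Per-site mean +/- sample standard deviation (ddof=1) with n.

    A single-sample site has an undefined dispersion, reported as NaN.
    """
    if len(values) != len(sites):
        raise ValidationError("values and sites must align")
    if len(values) == 0:
        raise ValidationError("empty input")
    grouped = values.groupby(sites.values)
    out = grouped.agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
    out.index.name = SITE_COLUMN
    return out


def site_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site arithmetic means of every metal column (site x metal)."""
    return table.groupby(SITE_COLUMN)[_metal_columns(table)].mean()


def contribution_to_ri(
    site_er_means: pd.DataFrame,
    site_ri_means: pd.Series,
    *,
    site_weights: pd.Series | None = None,
) -> pd.Series:
    """Per-metal percent contribution to the overall risk index.

    Default is the unweighted ratio of across-site averages:
    ``100 * mean_over_sites(Er site means) / mean_over_sites(RI site means)``,
    each site counting once regardless of its sample size.  Pass
    ``site_weights`` (e.g. per-site n) for a sample-weighted variant.
    """
    if not site_er_means.index.equals(site_ri_means.index):
        if set(site_er_means.index) != set(site_ri_means.index):
            raise ValidationError("Er and RI summaries cover different sites")
        site_ri_means = site_ri_means.loc[site_er_means.index]
    if site_weights is None:
        er_avg = site_er_means.mean(axis=0)
        ri_avg = site_ri_means.mean()
    else:
        w = site_weights.loc[site_er_means.index].astype(float)
        er_avg = site_er_means.mul(w, axis=0).sum(axis=0) / w.sum()
        ri_avg = (site_ri_means * w).sum() / w.sum()
    if ri_avg == 0:
        raise ValidationError("mean RI is zero; contributions undefined")
    contrib = 100.0 * er_avg / ri_avg
    contrib.name = "contribution_pct"
    return contrib


@dataclass
class RiskResult:
    """Bundle of all risk-stage outputs for one concentration table."""

    cf: pd.DataFrame
    er: pd.DataFrame
    ri: pd.Series
    site_er: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    site_ri: pd.DataFrame | None = None
    contribution: pd.Series | None = None

    def per_sample_table(self) -> pd.DataFrame:
        """Tidy per-sample table: site, Cf-*, Er-* columns and RI."""
        metals = _metal_columns(self.er)
        out = pd.DataFrame(index=self.er.index)
        if SITE_COLUMN in self.er.columns:
            out[SITE_COLUMN] = self.er[SITE_COLUMN]
        for m in metals:
            out[f"Cf-{m}"] = self.cf[m]
        for m in metals:
            out[f"Er-{m}"] = self.er[m]
        out["RI"] = self.ri
        return out

    def site_table(self, decimals: int = 2) -> pd.DataFrame:
        """Per-site report: one 'Er-<metal>' row per metal plus an 'RI' row.

        Cells hold ``mean ± sd`` strings rounded half-up at ``decimals``;
        the last column is the percent contribution of each metal.
        """
        rows = {}
        for metal, summ in self.site_er.items():
            rows[f"Er-{metal}"] = {
                s: f"{round_half_up(r['mean'], decimals):.{decimals}f} ± "
                f"{round_half_up(r['sd'], decimals):.{decimals}f}"
                for s, r in summ.iterrows()
            }
            if self.contribution is not None:
                rows[f"Er-{metal}"]["contribution_pct"] = round_half_up(
                    self.contribution[metal], decimals
                )
        if self.site_ri is not None:
            rows["RI"] = {
                s: f"{round_half_up(r['mean'], decimals):.{decimals}f} ± "
                f"{round_half_up(r['sd'], decimals):.{decimals}f}"
                for s, r in self.site_ri.iterrows()
            }
        return pd.DataFrame(rows).T


def compute_risk(conc: pd.DataFrame, ref: pd.DataFrame) -> RiskResult:
    """Run the full risk stage: Cf, Er, RI, per-site summaries, contributions."""
    cf = contamination_factor(conc, ref)
    er = monomial_risk(cf, ref)
    metals = _metal_columns(er)
    ri = risk_index(er, expected_metals=metals)
    result = RiskResult(cf=cf, er=er, ri=ri)
    if SITE_COLUMN in conc.columns:
        sites = conc[SITE_COLUMN]
        result.site_er = {m: site_summary(er[m], sites) for m in metals}
        result.site_ri = site_summary(ri, sites)
        er_means = pd.DataFrame({m: s["mean"] for m, s in result.site_er.items()})
        result.contribution = contribution_to_ri(er_means, result.site_ri["mean"])
    return result
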