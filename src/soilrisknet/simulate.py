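"""Synthetic site-structured concentration and gene-abundance data.

The generator exists so that every pipeline stage can be exercised against
a known ground truth: the study design it emulates is a four-site
contamination gradient (3 samples on the tailings dam, 9 at each of three
downstream sites) with right-skewed, positive concentrations and copy
numbers, planted rank-correlation structure, and structural non-detects
(a gene absent from a whole site).

Model: a latent Gaussian copula.  Target Spearman correlations are planted
on the latent scale through the exact bivariate-normal conversion

    r_latent = 2 * sin(pi * rho_spearman / 6)

after which each variable is mapped through a per-site lognormal marginal
whose (mu, sigma) are moment-matched to the configured mean and sd.  Rank
correlations survive the (monotone) marginal transform, so the sample
Spearman of a planted pair converges to its target.  Gene copy numbers are
rounded to integers after correlation induction; structural zeros are
applied last and are exactly zero in every replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, validate_panel
from .errors import ConfigurationError, ValidationError
from .references import _packaged_csv

__all__ = [
    "CorrelationBlock",
    "SimConfig",
    "SimResult",
    "GroundTruth",
    "spearman_to_latent",
    "lognormal_params",
    "simulate",
    "default_study_fixture",
]


def spearman_to_latent(rho: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho`` under a normal copula.

    Exact for the bivariate normal: rho_s = (6/pi) * arcsin(r/2).
    """
    if not -1.0 < rho < 1.0:
        raise ConfigurationError(f"target Spearman rho must be in (-1, 1), got {rho}")
    return 2.0 * math.sin(math.pi * rho / 6.0)


def latent_to_spearman(r: float) -> float:
    """Inverse of :func:`spearman_to_latent`."""
    return 6.0 / math.pi * math.asin(r / 2.0)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError(f"lognormal moments must be positive, got {mean}, {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class CorrelationBlock:
    """A set of variables sharing a common pairwise target Spearman rho."""

    name: str
    variables: list[str]
    rho: float


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    ``metal_moments`` maps metal -> site -> (mean, sd) in mg/kg;
    ``gene_baselines`` maps gene -> baseline mean copies, scaled per site
    by ``gene_site_multipliers`` (default 1) with lognormal coefficient of
    variation ``gene_cv``.  ``structural_zeros`` is a list of (gene, site)
    pairs forced to non-detect in every sample of that site.
    """

    sites: list[tuple[str, int]]
    metal_moments: dict[str, dict[str, tuple[float, float]]]
    panel: pd.DataFrame
    gene_baselines: dict[str, float]
    gene_site_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_cv: float = 0.5
    blocks: list[CorrelationBlock] = field(default_factory=list)
    structural_zeros: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery experiments."""

    latent_corr: pd.DataFrame
    spearman_target: pd.DataFrame
    blocks: dict[str, list[str]]
    structural_zeros: list[tuple[str, str]]


@dataclass
class SimResult:
    concentrations: pd.DataFrame
    abundance: AbundanceTable
    panel: pd.DataFrame
    truth: GroundTruth


def _latent_correlation(variables: list[str], blocks: list[CorrelationBlock]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(variables)}
    r = np.eye(len(variables))
    for block in blocks:
        missing = [v for v in block.variables if v not in idx]
        if missing:
            raise ConfigurationError(
                f"correlation block {block.name!r} names unknown variables: {missing}"
            )
        rr = spearman_to_latent(block.rho)
        for i, a in enumerate(block.variables):
            for b in block.variables[i + 1:]:
                r[idx[a], idx[b]] = r[idx[b], idx[a]] = rr
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin <= 1e-10:
        raise ConfigurationError(
            "implied latent correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); reduce block overlap or project "
            "to the nearest positive-definite matrix (Higham) first"
        )
    return r


def simulate(config: SimConfig, seed: int | None = None) -> SimResult:
    """Draw one synthetic study from ``config``.

    Deterministic: the same config and seed give byte-identical tables.
    """
    panel = config.panel if config.panel.index.name == "gene" else validate_panel(config.panel)
    genes = list(panel.index)
    metals = list(config.metal_moments)
    site_labels = [s for s, _ in config.sites]
    for gene, site in config.structural_zeros:
        if panel.loc[gene, "class"] == "16S":
            raise ConfigurationError("cannot plant a structural zero on the 16S gene")
        if site not in site_labels:
            raise ConfigurationError(f"structural zero refers to unknown site {site!r}")
    for _, n in config.sites:
        if n < 1:
            raise ConfigurationError("every site needs n >= 1")

    variables = metals + genes
    r = _latent_correlation(variables, config.blocks)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chol = np.linalg.cholesky(r)

    rows_conc, rows_gene, sample_ids, sites_out = [], [], [], []
    for site, n in config.sites:
        z = rng.standard_normal((n, len(variables))) @ chol.T
        x = np.empty_like(z)
        for j, metal in enumerate(metals):
            mu, sigma = lognormal_params(*config.metal_moments[metal][site])
            x[:, j] = np.exp(mu + sigma * z[:, j])
        for j, gene in enumerate(genes, start=len(metals)):
            mult = config.gene_site_multipliers.get(gene, {}).get(site, 1.0)
            mean = config.gene_baselines[gene] * mult
            mu, sigma = lognormal_params(mean, config.gene_cv * mean)
            x[:, j] = np.rint(np.exp(mu + sigma * z[:, j]))
        rows_conc.append(x[:, : len(metals)])
        rows_gene.append(x[:, len(metals):])
        sample_ids.extend(f"{site}-{i + 1:02d}" for i in range(n))
        sites_out.extend([site] * n)

    conc = pd.DataFrame(np.vstack(rows_conc), columns=metals, index=sample_ids)
    conc.insert(0, "site", sites_out)
    conc.index.name = "sample_id"
    gene_df = pd.DataFrame(np.vstack(rows_gene), columns=genes, index=conc.index)
    for gene, site in config.structural_zeros:
        gene_df.loc[conc["site"] == site, gene] = 0.0
    data = gene_df.copy()
    data.insert(0, "site", conc["site"])
    abundance = AbundanceTable(data=data, detect=gene_df > 0)

    latent = pd.DataFrame(r, index=variables, columns=variables)
    spearman_target = latent.map(latent_to_spearman)
    np.fill_diagonal(spearman_target.values, 1.0)
    truth = GroundTruth(
        latent_corr=latent,
        spearman_target=spearman_target,
        blocks={b.name: list(b.variables) for b in config.blocks},
        structural_zeros=list(config.structural_zeros),
    )
    return SimResult(concentrations=conc, abundance=abundance, panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# Default study fixture
# ---------------------------------------------------------------------------

_MRG_SUBCLASS = {
    "copA": "copper", "copB": "copper", "pcoA": "copper",
    "czcA": "cadmium-zinc-cobalt", "czcC": "cadmium-zinc-cobalt",
    "czcD": "cadmium-zinc-cobalt",
    "arsB": "arsenic", "arsC": "arsenic",
    "pbrT": "lead", "chrB": "chromium",
}
_ARG_SUBCLASS = {
    "tetA": "tetracycline", "tetC": "tetracycline", "tetG": "tetracycline",
    "tetK": "tetracycline", "tetM": "tetracycline", "tetO": "tetracycline",
    "tetQ": "tetracycline", "tetS": "tetracycline", "tetW": "tetracycline",
    "tetX": "tetracycline", "tetA/P": "tetracycline", "tetB/P": "tetracycline",
    "sulII": "sulfonamide",
    "ereA": "macrolide", "mphA": "macrolide",
    "blaCTX-M": "beta-lactam", "blaSHV": "beta-lactam",
}
_MGE_SUBCLASS = {"intI1": "integron-integrase", "tnpA": "transposase"}

_BASELINES = {
    "arsC": 1.0e6, "arsB": 3.0e5, "pbrT": 2.0e5, "czcA": 2.0e5, "copA": 1.0e5,
    "pcoA": 5.0e4, "czcD": 2.0e4, "chrB": 2.0e4, "copB": 1.0e4, "czcC": 5.0e3,
    "ereA": 3.0e5, "tetC": 1.0e5, "tetG": 1.0e5, "tetA": 8.0e4, "tetS": 8.0e4,
    "tetX": 1.0e5, "sulII": 8.0e4, "tetK": 5.0e3, "tetM": 5.0e3, "tetO": 5.0e3,
    "tetQ": 5.0e3, "tetW": 5.0e3, "tetA/P": 5.0e3, "tetB/P": 5.0e3,
    "mphA": 1.0e4, "blaCTX-M": 3.0e3, "blaSHV": 3.0e3,
    "intI1": 1.0e4, "tnpA": 2.0e4, "16S": 1.0e8,
}

# site multipliers mirror the gradient the generator emulates: most
# resistance genes peak at the high-risk site just below the dam (TD1),
# copper-resistance genes and most ARGs increase downstream, and the dam
# top (TD0) is depleted in everything including total bacteria.
_SITE_PATTERNS = {
    "mrg": {"TD0": 0.2, "TD1": 1.5, "TD2": 0.8, "TD3": 1.0},
    "copper": {"TD0": 0.3, "TD1": 0.6, "TD2": 1.0, "TD3": 1.5},
    "arg": {"TD0": 0.3, "TD1": 0.8, "TD2": 1.0, "TD3": 1.5},
    "mge": {"TD0": 0.1, "TD1": 1.0, "TD2": 1.0, "TD3": 1.2},
    "16S": {"TD0": 0.3, "TD1": 1.2, "TD2": 1.0, "TD3": 1.0},
}

MRG_BLOCK = ["Cd", "arsB", "arsC", "pbrT", "czcA", "czcC", "czcD", "chrB", "sulII"]
ARG_BLOCK = ["copB", "tetC", "tetG", "tetX", "tetM", "tetQ", "mphA"]


def default_panel() -> pd.DataFrame:
    """The 10 MRG + 17 ARG + 2 MGE + 16S panel of the emulated survey."""
    rows = (
        [{"gene": g, "class": "MRG", "subclass": s} for g, s in _MRG_SUBCLASS.items()]
        + [{"gene": g, "class": "ARG", "subclass": s} for g, s in _ARG_SUBCLASS.items()]
        + [{"gene": g, "class": "MGE", "subclass": s} for g, s in _MGE_SUBCLASS.items()]
        + [{"gene": "16S", "class": "16S", "subclass": "ribosomal"}]
    )
    return pd.DataFrame(rows)


def default_config(seed: int = 0, n_per_site: dict[str, int] | None = None) -> SimConfig:
    """The default study configuration: 30 samples over TD0-TD3, 7 metals,
    a 30-gene panel, an MRG block co-varying with Cd (with sulII inside it),
    an ARG block containing copB, and intI1 structurally absent at TD0.
    """
    means = _packaged_csv("site_mean_concentrations.csv").set_index("site")
    sds = _packaged_csv("site_concentration_sd.csv").set_index("site")
    metal_moments = {
        m: {s: (float(means.loc[s, m]), float(sds.loc[s, m])) for s in means.index}
        for m in means.columns
    }
    sizes = {"TD0": 3, "TD1": 9, "TD2": 9, "TD3": 9}
    if n_per_site:
        sizes.update(n_per_site)
    panel = default_panel()
    multipliers: dict[str, dict[str, float]] = {}
    for _, row in panel.iterrows():
        g = row["gene"]
        if g == "16S":
            multipliers[g] = _SITE_PATTERNS["16S"]
        elif row["class"] == "MGE":
            multipliers[g] = _SITE_PATTERNS["mge"]
        elif row["class"] == "ARG":
            multipliers[g] = dict(_SITE_PATTERNS["mrg"] if g == "sulII" else _SITE_PATTERNS["arg"])
        elif row["subclass"] == "copper":
            multipliers[g] = _SITE_PATTERNS["copper"]
        else:
            multipliers[g] = _SITE_PATTERNS["mrg"]
    return SimConfig(
        sites=[(s, sizes[s]) for s in ("TD0", "TD1", "TD2", "TD3")],
        metal_moments=metal_moments,
        panel=panel,
        gene_baselines=dict(_BASELINES),
        gene_site_multipliers=multipliers,
        gene_cv=0.5,
        blocks=[
            CorrelationBlock("mrg-cd", list(MRG_BLOCK), 0.7),
            CorrelationBlock("arg-copb", list(ARG_BLOCK), 0.7),
        ],
        structural_zeros=[("intI1", "TD0")],
        seed=seed,
    )


def default_study_fixture(seed: int = 0, n_per_site: dict[str, int] | None = None) -> SimResult:
    """Simulate one full synthetic study under the default configuration."""
    return simulate(default_config(seed=seed, n_per_site=n_per_site))
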