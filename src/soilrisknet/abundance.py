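"""qPCR gene-abundance processing: quantification, replicate collapse,
16S normalization, variance-stabilizing transforms and class aggregation.

The central container is a wide abundance table: samples in rows (indexed
by sample id), a ``site`` column, and one column of absolute copy numbers
per gene, including the 16S rRNA gene.  Non-detects are stored as explicit
zeros together with a boolean detect mask, never as missing values, so that
downstream rank statistics stay computable.

Relative abundance divides every gene by the same sample's 16S copies — an
approximate fraction of bacteria carrying that gene — and is invariant
under any uniform rescaling of a sample's absolute values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

SITE_COLUMN = "site"
GENE_CLASSES = ("MRG", "ARG", "MGE", "16S")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene panel (gene, class, subclass) and index it by gene.

    Exactly one gene must carry class ``16S``; gene ids must be unique.
    """
    for col in ("gene", "class"):
        if col not in panel.columns:
            raise ValidationError(f"panel missing column {col!r}")
    if panel["gene"].duplicated().any():
        raise ValidationError("duplicate gene ids in panel")
    unknown = set(panel["class"]) - set(GENE_CLASSES)
    if unknown:
        raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
    n16 = (panel["class"] == "16S").sum()
    if n16 != 1:
        raise ValidationError(f"panel must contain exactly one 16S gene, found {n16}")
    return panel.set_index("gene")


def sixteen_s_gene(panel: pd.DataFrame) -> str:
    """Identifier of the panel's single 16S rRNA gene."""
    idx = panel.index if panel.index.name == "gene" else panel["gene"]
    return str(np.asarray(idx)[np.asarray(panel["class"]) == "16S"][0])


def standard_curve_quantify(ct, slope: float, intercept: float):
    """Convert qPCR Ct values to copy numbers via a standard curve.

    The curve is Ct = slope * log10(copies) + intercept with slope < 0, so
    ``copies = 10 ** ((ct - intercept) / slope)``.

    Returns the copy numbers; :func:`amplification_efficiency` reports the
    per-cycle efficiency implied by the slope.
    """
    if slope >= 0:
        raise ValidationError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** ((np.asarray(ct, dtype=float) - intercept) / slope)


def copies_to_ct(copies, slope: float, intercept: float):
    """Inverse of :func:`standard_curve_quantify` (used to simulate Ct data)."""
    if slope >= 0:
        raise ValidationError(f"standard-curve slope must be negative, got {slope}")
    return slope * np.log10(np.asarray(copies, dtype=float)) + intercept


def amplification_efficiency(slope: float) -> float:
    """Efficiency 10**(-1/slope) - 1; 1.0 means perfect doubling per cycle."""
    if slope >= 0:
        raise ValidationError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


@dataclass
class AbundanceTable:
    """Wide absolute-abundance table plus its detect mask.

    ``data`` holds the ``site`` column and one float column per gene (zeros
    at non-detects); ``detect`` is a boolean frame over the same gene
    columns.
    """

    data: pd.DataFrame
    detect: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c != SITE_COLUMN]

    def __post_init__(self):
        genes = self.genes
        if list(self.detect.columns) != genes or not self.detect.index.equals(
            self.data.index
        ):
            raise ValidationError("detect mask must align with the abundance table")
        if (self.data[genes] < 0).any().any():
            raise ValidationError("negative abundances")
        if ((self.data[genes] > 0) & ~self.detect).any().any():
            raise ValidationError("positive abundance flagged as non-detect")

    @classmethod
    def from_frame(cls, data: pd.DataFrame) -> "AbundanceTable":
        """Build from a plain wide table, inferring the mask as value > 0."""
        genes = [c for c in data.columns if c != SITE_COLUMN]
        return cls(data=data, detect=data[genes] > 0)

    def detected_at_site(self) -> pd.DataFrame:
        """Gene x site table: detected in at least one sample of the site."""
        return self.detect.groupby(self.data[SITE_COLUMN]).any().T


def collapse_replicates(
    measurements: pd.DataFrame,
    *,
    min_detect: int = 2,
    sites: pd.Series | None = None,
    average: str = "copies",
    slope: float | None = None,
    intercept: float | None = None,
) -> AbundanceTable:
    """Collapse triplicate qPCR measurements into one value per sample-gene.

    ``measurements`` is long-format with columns ``sample_id``, ``gene``,
    ``replicate``, ``value`` and boolean ``detected``.  ``value`` holds
    copies (``average="copies"``) or Ct (``average="ct"``, requiring the
    standard-curve ``slope``/``intercept`` to convert the averaged Ct).

    The collapsed value is the mean over detected replicates; a sample-gene
    with fewer than ``min_detect`` amplified replicates is a non-detect and
    contributes an explicit zero.  All-negative replicates are a valid
    non-detect, not an error.
    """
    required = {"sample_id", "gene", "replicate", "value", "detected"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
    counts = measurements.groupby(["sample_id", "gene"])["replicate"].nunique()
    if (counts > 3).any():
        raise ValidationError("more than 3 replicates for some sample-gene pairs")
    det = measurements[measurements["detected"].astype(bool)]
    if average == "ct" and (det["value"] <= 0).any():
        raise ValidationError("detected Ct values must be positive")
    n_det = (
        measurements.assign(d=measurements["detected"].astype(int))
        .groupby(["sample_id", "gene"])["d"]
        .sum()
    )
    mean_val = det.groupby(["sample_id", "gene"])["value"].mean()
    if average == "ct":
        if slope is None or intercept is None:
            raise ValidationError("average='ct' requires slope and intercept")
        mean_val = pd.Series(
            standard_curve_quantify(mean_val, slope, intercept), index=mean_val.index
        )
    elif average != "copies":
        raise ValidationError(f"unknown averaging mode {average!r}")
    detected = n_det >= min_detect
    values = mean_val.reindex(n_det.index).where(detected, 0.0).fillna(0.0)
    wide = values.unstack("gene").fillna(0.0)
    mask = detected.unstack("gene").fillna(False)
    wide.index.name = "sample_id"
    data = wide.copy()
    if sites is not None:
        data.insert(0, SITE_COLUMN, sites.reindex(wide.index))
    return AbundanceTable(data=data, detect=mask[wide.columns])


def normalize_to_16s(table: AbundanceTable, panel: pd.DataFrame) -> pd.DataFrame:
    """Relative abundance: each gene divided by the sample's 16S copies.

    The 16S column is removed from the output.  Raises if any sample has
    zero or missing 16S copies, naming the sample.
    """
    gene16 = sixteen_s_gene(panel)
    if gene16 not in table.data.columns:
        raise ValidationError(f"16S column {gene16!r} missing from abundance table")
    denom = table.data[gene16]
    bad = denom.index[(denom <= 0) | denom.isna()].tolist()
    if bad:
        raise ValidationError(f"16S copies missing or zero for samples: {bad}")
    genes = [g for g in table.genes if g != gene16]
    rel = table.data[genes].div(denom, axis=0)
    if SITE_COLUMN in table.data.columns:
        rel.insert(0, SITE_COLUMN, table.data[SITE_COLUMN])
    return rel


def transform(values, method: str = "log", pseudocount: float | None = None):
    """Square-root or natural-log transform to improve normality.

    For ``method="log"`` a pseudocount is added before taking logs when
    zeros are present; the default pseudocount is half the smallest nonzero
    value in the input (logged).  A log transform of all-zero input is an
    error.  Both transforms are strictly monotone, so rank statistics are
    unchanged.
    """
    df = isinstance(values, (pd.DataFrame, pd.Series))
    numeric = values.select_dtypes("number") if isinstance(values, pd.DataFrame) else values
    arr = np.asarray(numeric, dtype=float)
    if (arr < 0).any():
        raise ValidationError("transform requires non-negative input")
    if method == "sqrt":
        out = np.sqrt(arr)
    elif method == "log":
        if pseudocount is None:
            if (arr == 0).any():
                nz = arr[arr > 0]
                if nz.size == 0:
                    raise ValidationError("log transform of all-zero input")
                pseudocount = float(nz.min()) / 2.0
                logger.info("transform: using pseudocount %g (min nonzero / 2)", pseudocount)
            else:
                pseudocount = 0.0
        if ((arr + pseudocount) <= 0).any():
            raise ValidationError("log transform needs positive values after pseudocount")
        out = np.log(arr + pseudocount)
    else:
        raise ValidationError(f"unknown transform {method!r}; use 'sqrt' or 'log'")
    if df:
        if isinstance(values, pd.DataFrame):
            res = values.copy()
            res[numeric.columns] = out
            return res
        return pd.Series(out, index=values.index, name=values.name)
    return out


def aggregate_by_class(
    table: pd.DataFrame, panel: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample class totals and per-site gene composition within class.

    Parameters
    ----------
    table
        Wide abundance table (absolute or relative); a ``site`` column is
        required for the composition output.
    panel
        Validated gene panel indexed by gene.

    Returns
    -------
    totals
        Samples x classes sums (16S excluded from resistance totals but
        reported as its own class when present).
    composition
        Long table (site, class, gene, percent): each gene's percent of its
        class total at that site, computed from site-summed abundances;
        percentages within one site and class sum to 100 where the class
        total is nonzero.
    """
    if panel.index.name != "gene":
        panel = validate_panel(panel)
    genes = [c for c in table.columns if c != SITE_COLUMN]
    unclassified = [g for g in genes if g not in panel.index]
    if unclassified:
        raise ValidationError(f"genes missing from panel: {unclassified}")
    classes = panel.loc[genes, "class"]
    totals = table[genes].T.groupby(classes.values).sum().T
    if SITE_COLUMN not in table.columns:
        return totals, pd.DataFrame(columns=[SITE_COLUMN, "class", "gene", "percent"])
    site_sums = table.groupby(SITE_COLUMN)[genes].sum()
    records = []
    for cls in classes.unique():
        cls_genes = [g for g in genes if classes[g] == cls]
        cls_total = site_sums[cls_genes].sum(axis=1)
        for g in cls_genes:
            with np.errstate(invalid="ignore"):
                pct = 100.0 * site_sums[g] / cls_total
            for site, v in pct.items():
                records.append(
                    {SITE_COLUMN: site, "class": cls, "gene": g, "percent": v}
                )
    return totals, pd.DataFrame.from_records(records)
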