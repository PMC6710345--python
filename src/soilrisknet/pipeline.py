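"""End-to-end orchestration: simulate -> risk -> abundance -> stats -> network.

Each stage is an ordinary function over a :class:`RunConfig`; the command
line in :mod:`soilrisknet.cli` is a thin wrapper.  Stages read and write
plain CSV/TSV files so any stage can be run on its own against files
produced elsewhere.  ``run_all`` writes a manifest recording the package
version, the seed, a hash of the configuration and every file produced,
so a run is reproducible and auditable: re-running with the same config
and seed reproduces byte-identical outputs.

All randomness flows from the single config seed: stage *i* of the
ordered stage list uses ``SeedSequence([seed, i])``, so changing the seed
changes every stage coherently while stages stay independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, abundance as ab, network as net, references, risk, stats
from .errors import ValidationError
from .simulate import default_config, simulate

STAGES = ("simulate", "risk", "abundance", "stats", "network")


@dataclass
class RunConfig:
    """Run-wide configuration; mirrors the CLI flags and the YAML schema."""

    output_dir: str = "soilrisknet_out"
    concentrations: str | None = None  # CSV: sample_id, site, one column/metal
    abundance_table: str | None = None  # wide CSV: sample_id, site, genes
    qpcr: str | None = None  # long CSV: sample_id, gene, replicate, value, detected
    panel: str | None = None  # CSV: gene, class, subclass
    reference: str | None = None  # CSV: metal, background_value, toxic_response
    reference_profile: str = "default"
    transform: str = "log"
    alpha: float = 0.05
    rho_threshold: float = 0.6
    p_threshold: float = 0.05
    min_detect: int = 2
    seed: int = 0
    community_method: str = "louvain"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha out of range: {self.alpha}")
        if not 0 <= self.rho_threshold < 1:
            raise ValidationError(f"rho_threshold out of range: {self.rho_threshold}")
        if not 0 < self.p_threshold <= 1:
            raise ValidationError(f"p_threshold out of range: {self.p_threshold}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % 2**31)


@dataclass
class StageReport:
    stage: str
    outputs: list[str] = field(default_factory=list)
    rows: dict[str, int] = field(default_factory=dict)


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write(report: StageReport, df: pd.DataFrame, path: Path, **kwargs) -> None:
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, **kwargs)
    report.outputs.append(path.name)
    report.rows[path.name] = len(df)


def _reference(cfg: RunConfig) -> pd.DataFrame:
    if cfg.reference:
        return references.load_reference(cfg.reference)
    return references.reference_profile(cfg.reference_profile)


def run_simulate(cfg: RunConfig) -> StageReport:
    """Generate the default synthetic study and write its input files."""
    report = StageReport("simulate")
    out = _outdir(cfg)
    sim = simulate(default_config(seed=cfg.stage_seed("simulate")))
    _write(report, sim.concentrations, out / "concentrations.csv")
    _write(report, sim.abundance.data, out / "abundance.csv", index_label="sample_id")
    _write(report, sim.abundance.detect, out / "detect_mask.csv", index_label="sample_id")
    _write(report, sim.panel.reset_index(), out / "panel.csv", index=False)
    return report


def _load_concentrations(cfg: RunConfig, out: Path) -> pd.DataFrame:
    path = cfg.concentrations or out / "concentrations.csv"
    if not Path(path).exists():
        raise ValidationError(f"concentration table not found: {path}")
    return pd.read_csv(path, index_col=0)


def _load_panel(cfg: RunConfig, out: Path) -> pd.DataFrame:
    path = cfg.panel or out / "panel.csv"
    if not Path(path).exists():
        raise ValidationError(f"gene panel not found: {path}")
    return ab.validate_panel(pd.read_csv(path))


def _load_abundance(cfg: RunConfig, out: Path) -> ab.AbundanceTable:
    if cfg.qpcr:
        long = pd.read_csv(cfg.qpcr)
        sites = None
        if cfg.concentrations:
            conc = _load_concentrations(cfg, out)
            sites = conc["site"]
        return ab.collapse_replicates(long, min_detect=cfg.min_detect, sites=sites)
    path = cfg.abundance_table or out / "abundance.csv"
    if not Path(path).exists():
        raise ValidationError(f"abundance table not found: {path}")
    data = pd.read_csv(path, index_col=0)
    mask_path = out / "detect_mask.csv"
    if mask_path.exists() and cfg.abundance_table is None:
        mask = pd.read_csv(mask_path, index_col=0).astype(bool)
        return ab.AbundanceTable(data=data, detect=mask)
    return ab.AbundanceTable.from_frame(data)


def run_risk(cfg: RunConfig) -> StageReport:
    """Hakanson risk scoring of the concentration table."""
    report = StageReport("risk")
    out = _outdir(cfg)
    conc = _load_concentrations(cfg, out)
    result = risk.compute_risk(conc, _reference(cfg))
    _write(report, result.per_sample_table(), out / "per_sample_risk.csv",
           index_label="sample_id")
    _write(report, result.site_table(), out / "risk_site_summary.csv",
           index_label="quantity")
    return report


def run_abundance(cfg: RunConfig) -> StageReport:
    """Absolute and 16S-normalized abundances plus class composition."""
    report = StageReport("abundance")
    out = _outdir(cfg)
    panel = _load_panel(cfg, out)
    table = _load_abundance(cfg, out)
    rel = ab.normalize_to_16s(table, panel)
    totals, composition = ab.aggregate_by_class(table.data, panel)
    _write(report, table.data, out / "absolute_abundance.csv", index_label="sample_id")
    _write(report, rel, out / "relative_abundance.csv", index_label="sample_id")
    _write(report, totals, out / "class_totals.csv", index_label="sample_id")
    _write(report, composition, out / "composition.csv", index=False)
    return report


def _network_inputs(cfg: RunConfig, out: Path):
    conc = _load_concentrations(cfg, out)
    panel = _load_panel(cfg, out)
    table = _load_abundance(cfg, out)
    rel = ab.normalize_to_16s(table, panel)
    result = risk.compute_risk(conc, _reference(cfg))
    return assemble_network_table(rel, panel, result)


def assemble_network_table(
    rel: pd.DataFrame, panel: pd.DataFrame, risk_result: risk.RiskResult
) -> tuple[pd.DataFrame, dict]:
    """Join relative abundances with per-sample risk components.

    The risk side contributes one ``RI-<metal>`` column per metal (the
    per-sample monomial risk factors) plus the integrated ``RI``, all in
    category ``RI``; gene columns take their panel class.  Only samples
    present in both tables are kept.
    """
    genes = [c for c in rel.columns if c != "site"]
    er = risk_result.er
    metals = [c for c in er.columns if c != "site"]
    risk_cols = er[metals].rename(columns={m: f"RI-{m}" for m in metals})
    risk_cols["RI"] = risk_result.ri
    joined = rel[genes].join(risk_cols, how="inner")
    if joined.empty:
        raise ValidationError("no overlapping samples between abundance and risk tables")
    categories = {f"RI-{m}": "RI" for m in metals}
    categories["RI"] = "RI"
    categories.update({g: str(panel.loc[g, "class"]) for g in genes})
    return joined, categories


def run_stats(cfg: RunConfig) -> StageReport:
    """Site-difference tests (ANOVA + Duncan letters) and the correlation table."""
    report = StageReport("stats")
    out = _outdir(cfg)
    table, _ = _network_inputs(cfg, out)
    conc = _load_concentrations(cfg, out)
    sites = conc.loc[table.index, "site"]
    rows = []
    for var in table.columns:
        values = ab.transform(table[var], method=cfg.transform)
        if pd.Series(values).nunique() <= 1:
            continue
        anova = stats.one_way_anova(values, sites)
        duncan = stats.duncan_mrt(values, sites, alpha=cfg.alpha, anova=anova)
        summ = risk.site_summary(table[var], sites)
        for site, r in summ.iterrows():
            rows.append({
                "variable": var, "site": site, "n": int(r["n"]),
                "mean": r["mean"], "sd": r["sd"],
                "letters": duncan.letters[site],
                "anova_F": anova.f, "anova_p": anova.p,
            })
    _write(report, pd.DataFrame(rows), out / "site_comparison.csv", index=False)
    corr = stats.spearman_matrix(table)
    _write(report, corr, out / "correlations.csv", index=False)
    return report


def run_network(cfg: RunConfig) -> StageReport:
    """Build, modularize and export the co-occurrence network."""
    report = StageReport("network")
    out = _outdir(cfg)
    table, categories = _network_inputs(cfg, out)
    graph = net.build_network(
        table, categories,
        rho_threshold=cfg.rho_threshold, p_threshold=cfg.p_threshold,
    )
    net.detect_modules(graph, seed=cfg.stage_seed("network"), method=cfg.community_method)
    net.find_hubs(graph)
    net.export_network(graph, out / "network.graphml", "graphml")
    net.export_network(graph, out / "network.gexf", "gexf")
    report.outputs += ["network.graphml", "network.gexf"]
    report.rows["network.graphml"] = graph.number_of_nodes()
    _write(report, net.edge_table(graph), out / "edges.tsv", index=False)
    _write(report, net.node_table(graph), out / "nodes.tsv", index=False)
    return report


def run_report(cfg: RunConfig, reports: list[StageReport] | None = None) -> Path:
    """Write the run manifest (versions, seed, config hash, outputs, rows)."""
    out = _outdir(cfg)
    manifest = {
        "package": "soilrisknet",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "stages": [
            {"stage": r.stage, "outputs": r.outputs, "rows": r.rows}
            for r in (reports or [])
        ],
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_all(cfg: RunConfig) -> Path:
    """Run every stage in order and write the manifest.

    If no concentration/abundance inputs are configured, the synthetic
    default study is generated first so the pipeline is self-contained.
    """
    reports = []
    if cfg.concentrations is None and cfg.abundance_table is None and cfg.qpcr is None:
        reports.append(run_simulate(cfg))
    reports.append(run_risk(cfg))
    reports.append(run_abundance(cfg))
    reports.append(run_stats(cfg))
    reports.append(run_network(cfg))
    return run_report(cfg, reports)
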