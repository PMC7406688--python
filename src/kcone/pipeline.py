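"""End-to-end orchestration: metabolome statistics -> enrichment ->
k-cone differential activity -> cross-cell-line intersection.

The pipeline consumes a reaction-list network, per-cell-line concentration
tables for two conditions, and optionally a GMT pathway file and a
precomputed gene-level differential-expression table.  Every stage writes a
TSV with a commented header stating column semantics and the ratio
orientation (positive log2 fold change = higher enzyme activity in
condition B); a JSON manifest records thresholds, policies and a config
hash so identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .network import parse_reaction_file, split_reversible, validate_reconstruction
from .stats import (
    ConcentrationTable,
    diff_records_to_frame,
    differential_metabolites,
    enrichment_records_to_frame,
    intersect_enrichment,
    intersect_significant_metabolites,
    ora,
    read_gmt,
)
from .cone import (
    activity_records_to_frame,
    annotate_with_expression,
    differential_activity,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report"]

_RATIO_NOTE = (
    "# ratio orientation: log2_fc = log2(k_B/k_A) = log2(M_A/M_B); "
    "'up' = higher inferred enzyme activity in condition B\n"
)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class CellLineInput:
    name: str
    table_a: str
    table_b: str


@dataclass(frozen=True)
class PipelineConfig:
    network: str
    cell_lines: tuple[CellLineInput, ...]
    outdir: str
    gmt: str | None = None
    gene_de: str | None = None
    alpha: float = 0.05
    lfc_min: float = 1.0
    holm_alpha: float = 0.05
    fdr_alpha: float = 0.05
    pairing: str = "cross"
    unmeasured: str = "one"
    convention: str = "substrate"
    correction: str = "bh"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.alpha, self.holm_alpha, self.fdr_alpha):
            if not (0 < p <= 1):
                raise ConfigError(f"probability threshold {p} outside (0, 1]")
        if len(self.cell_lines) < 1:
            raise ConfigError("need at least one cell line")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            lines = tuple(
                CellLineInput(c["name"], c["table_a"], c["table_b"])
                for c in raw.pop("cell_lines")
            )
            return cls(cell_lines=lines, **raw)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad config file {path}: {exc}") from exc

    def digest(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in self.__dict__.items() if k != "cell_lines"},
             "cell_lines": [c.__dict__ for c in self.cell_lines]},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    diffmet: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    activity: dict[str, pd.DataFrame] = field(default_factory=dict)
    shared_metabolites: tuple[str, ...] = ()
    shared_pathways: tuple[str, ...] = ()
    pathway_regions: dict[tuple[str, ...], int] = field(default_factory=dict)
    shared_reactions: tuple[str, ...] = ()
    manifest: dict = field(default_factory=dict)

    @property
    def has_expression(self) -> bool:
        return any("concordant" in df.columns and df["concordant"].astype(str).str.len().gt(0).any()
                   for df in self.activity.values())


def _write_tsv(df: pd.DataFrame, path: Path, note: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if note:
            fh.write(note)
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order, writing TSVs + manifest to the run directory.

    Any stage failure removes partial outputs and raises :class:`StageError`
    naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(outdir=out)
    stage = "setup"
    try:
        stage = "network"
        net = split_reversible(parse_reaction_file(Path(config.network).read_text()))

        stage = "load-tables"
        tables: dict[str, tuple[ConcentrationTable, ConcentrationTable]] = {}
        for cl in config.cell_lines:
            tables[cl.name] = (
                ConcentrationTable.from_tsv(cl.table_a, condition=f"{cl.name}:A"),
                ConcentrationTable.from_tsv(cl.table_b, condition=f"{cl.name}:B"),
            )
        measured = set().union(*(set(t[0].metabolite_ids) for t in tables.values()))
        validation = validate_reconstruction(net, measured)
        (out / "validation.tsv").write_text(validation.to_tsv())

        stage = "differential-metabolites"
        diff_records = {}
        for name, (ta, tb) in tables.items():
            recs = differential_metabolites(ta, tb, alpha=config.alpha, lfc_min=config.lfc_min)
            diff_records[name] = recs
            df = diff_records_to_frame(recs)
            result.diffmet[name] = df
            _write_tsv(df, out / f"diffmet_{name}.tsv",
                       "# log2_fc = mean log2(B/A); Welch t-test on logs\n")

        stage = "enrichment"
        if config.gmt:
            sets = read_gmt(config.gmt)
            enriched_names = {}
            for name, (ta, _tb) in tables.items():
                selected = {r.metabolite_id for r in diff_records[name] if r.significant}
                background = set(ta.metabolite_ids)
                recs = ora(selected, background, sets,
                           holm_alpha=config.holm_alpha, fdr_alpha=config.fdr_alpha)
                df = enrichment_records_to_frame(recs)
                result.enrichment[name] = df
                _write_tsv(df, out / f"enrichment_{name}.tsv",
                           "# hypergeometric over-representation; enriched = Holm & FDR both pass\n")
                enriched_names[name] = [r.pathway for r in recs if r.enriched]
            if len(enriched_names) >= 2:
                shared, regions = intersect_enrichment(enriched_names)
                result.shared_pathways = shared
                result.pathway_regions = regions
                rows = [{"region": "&".join(k), "count": v} for k, v in regions.items()]
                _write_tsv(pd.DataFrame(rows).set_index("region"), out / "pathway_venn.tsv",
                           "# exact Venn regions over per-line enriched pathway sets\n")

        stage = "metabolite-intersection"
        if len(diff_records) >= 2:
            result.shared_metabolites = intersect_significant_metabolites(diff_records)
            pd.DataFrame({"metabolite": list(result.shared_metabolites)}).to_csv(
                out / "metabolites_shared.tsv", sep="\t", index=False)

        stage = "kcone-activity"
        gene_de = None
        if config.gene_de:
            gene_de = pd.read_csv(config.gene_de, sep="\t", comment="#")
        changed: dict[str, set[str]] = {}
        for name, (ta, tb) in tables.items():
            recs = differential_activity(
                net, ta, tb, alpha=config.alpha, pairing=config.pairing,
                unmeasured=config.unmeasured, convention=config.convention,
                correction=config.correction, lfc_fallback=config.lfc_min,
            )
            if gene_de is not None:
                recs = annotate_with_expression(recs, gene_de, alpha=config.alpha)
            df = activity_records_to_frame(recs)
            result.activity[name] = df
            _write_tsv(df, out / f"activity_{name}.tsv", _RATIO_NOTE)
            changed[name] = {r.step_id for r in recs if r.direction != "unchanged"}

        stage = "reaction-intersection"
        if len(changed) >= 2:
            result.shared_reactions = tuple(sorted(set.intersection(*changed.values())))
        elif changed:
            result.shared_reactions = tuple(sorted(next(iter(changed.values()))))
        pd.DataFrame({"reaction": list(result.shared_reactions)}).to_csv(
            out / "reactions_shared.tsv", sep="\t", index=False)

        stage = "manifest"
        result.manifest = {
            "tool": "kcone",
            "version": __version__,
            "config_digest": config.digest(),
            "alpha": config.alpha,
            "lfc_min": config.lfc_min,
            "holm_alpha": config.holm_alpha,
            "fdr_alpha": config.fdr_alpha,
            "pairing": config.pairing,
            "unmeasured": config.unmeasured,
            "convention": config.convention,
            "correction": config.correction,
            "seed": config.seed,
            "cell_lines": [c.name for c in config.cell_lines],
            "ratio_orientation": "log2(k_B/k_A); up = more active in condition B",
        }
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise StageError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return result


def report(result: PipelineResult, top: int = 10) -> str:
    """Deterministic markdown summary recomputable from the stage tables."""
    missing = [name for name in ("diffmet", "activity") if not getattr(result, name)]
    if missing:
        raise ValueError(f"incomplete result bundle; missing stages: {missing}")
    lines = ["# k-cone pipeline report", ""]
    lines.append("## Differential metabolites")
    for name, df in sorted(result.diffmet.items()):
        n_sig = int(df["significant"].sum())
        lines.append(f"- {name}: {n_sig} significant metabolites of {len(df)}")
    lines.append(f"- shared across lines: {len(result.shared_metabolites)} "
                 f"({', '.join(result.shared_metabolites) if result.shared_metabolites else 'none'})")
    if result.enrichment:
        lines.append("")
        lines.append("## Enriched pathways")
        for name, df in sorted(result.enrichment.items()):
            lines.append(f"- {name}: {int(df['enriched'].sum())} enriched pathways")
        lines.append(f"- shared across lines: {len(result.shared_pathways)} "
                     f"({', '.join(result.shared_pathways) if result.shared_pathways else 'none'})")
        if result.pathway_regions:
            lines.append("- Venn regions:")
            for combo, count in sorted(result.pathway_regions.items()):
                lines.append(f"    - {' & '.join(combo)}: {count}")
    lines.append("")
    lines.append("## Changed reactions (k-cone)")
    for name, df in sorted(result.activity.items()):
        n_changed = int((df["direction"] != "unchanged").sum())
        lines.append(f"- {name}: {n_changed} changed reactions")
        ranked = df.loc[~df["constant_term"]].reindex(
            df.loc[~df["constant_term"], "mean_log2_fc"].abs().sort_values(ascending=False).index
        )
        for step, row in ranked.head(top).iterrows():
            lines.append(
                f"    - {step}: log2 fc {row['mean_log2_fc']:+.3f} "
                f"(q={row['q_value']:.3g}, {row['direction']})"
            )
    lines.append(f"- shared across lines: {len(result.shared_reactions)} "
                 f"({', '.join(result.shared_reactions) if result.shared_reactions else 'none'})")
    if result.has_expression:
        lines.append("")
        lines.append("## Expression concordance")
        for name, df in sorted(result.activity.items()):
            concordant = int((df["concordant"] == "concordant").sum())
            lines.append(f"- {name}: {concordant} reactions concordant with transcript direction")
    return "\n".join(lines) + "\n"


def volcano_plot(diffmet: pd.DataFrame, path, alpha: float = 0.05, lfc_min: float = 1.0) -> None:
    """Basic volcano figure of a differential-metabolite table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(diffmet["p_value"].clip(lower=1e-300))
    colors = ["red" if s and f > 0 else "blue" if s else "grey"
              for s, f in zip(diffmet["significant"], diffmet["log2_fc"])]
    ax.scatter(diffmet["log2_fc"], logp, c=colors, s=14)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.6, c="k")
    for x in (-lfc_min, lfc_min):
        ax.axvline(x, ls="--", lw=0.6, c="k")
    ax.set_xlabel("log2 fold change (B/A)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
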