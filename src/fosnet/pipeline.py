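"""End-to-end analysis pipeline: ANOVA patterns → networks → group comparison.

``run_pipeline`` chains the stages on one sample table (read from CSV or
freshly simulated), writes every result as TSV/JSON plus a machine-readable
run manifest, and returns the in-memory bundle.  With
``collapse_phases=True`` (the default, matching the source methodology —
justified when no treatment × time interaction dominates, and doubling the
animals per network) connectivity is computed per treatment group; with it
off, per treatment × phase cell.  The optional within-phase centering flag
removes phase-driven mean differences per region before correlating, which
otherwise inflate correlations between regions sharing strong time
effects.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .anova import analyze_activation, posthoc_frame, results_frame
from .compare import bootstrap_compare
from .connectivity import correlation_matrix, edge_list, permutation_null, write_graphml
from .io import read_sample_table
from .sample_table import PHASES, TREATMENTS, region_columns, validate_sample_table
from .synthetic import GeneratorConfig, simulate_counts

logger = logging.getLogger(__name__)

#: Floor on resampling effort for analysis runs (overridable only explicitly).
MIN_RESAMPLES = 100


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be given.  ``seed``
    drives the permutation and bootstrap streams (the generator carries its
    own seed) and is recorded in the manifest and every result.
    """

    input_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    alpha: float = 0.05
    method: str = "pearson"
    n_perm: int = 10_000
    n_boot: int = 10_000
    seed: int = 0
    collapse_phases: bool = True
    center_within_phase: bool = False
    edge_threshold: float = 0.0
    outdir: str = "fosnet_results"
    write_graphml: bool = False
    unsafe_small_resamples: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        if not self.unsafe_small_resamples:
            if self.n_perm < MIN_RESAMPLES or self.n_boot < MIN_RESAMPLES:
                raise ValueError(
                    f"n_perm and n_boot must be >= {MIN_RESAMPLES} for analysis runs "
                    "(set unsafe_small_resamples=True only for testing)"
                )
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must lie in [0, 1]")


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML (or JSON) key-value file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"run config {path} must be a mapping of RunConfig fields")
    if "generator" in data and isinstance(data["generator"], dict):
        data["generator"] = GeneratorConfig(**data["generator"])
    return RunConfig(**data)


def _derive_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def _center_within_phase(group_table: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-phase region means within a group (correlation input only)."""
    out = group_table.copy()
    regions = region_columns(out)
    out[regions] = out[regions].astype(float) - out.groupby("phase", observed=True)[
        regions
    ].transform("mean")
    # shift back to nonnegative so the frame stays a valid sample table
    out[regions] -= out[regions].min().clip(upper=0)
    return out


def run_pipeline(config: RunConfig) -> Dict:
    """Execute every stage and write all outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.input_path is not None:
        table = read_sample_table(config.input_path)
        source = {"kind": "csv", "path": str(config.input_path)}
    else:
        table = validate_sample_table(simulate_counts(config.generator))
        source = {"kind": "generator", "generator_seed": config.generator.seed}
    logger.info("loaded table: %d animals, %d regions", len(table), len(region_columns(table)))

    # stage 1: per-region factorial ANOVA + pattern classification
    results, labels, posthocs = analyze_activation(table, alpha=config.alpha)
    anova_df = results_frame(results, labels)
    anova_df.to_csv(outdir / "anova_patterns.tsv", sep="\t", index=False)
    posthoc_df = posthoc_frame(posthocs)
    posthoc_df.to_csv(outdir / "posthoc.tsv", sep="\t", index=False)
    patterns = {lab.region: lab.pattern for lab in labels}
    (outdir / "patterns.json").write_text(json.dumps(patterns, indent=2, sort_keys=True))
    logger.info("ANOVA stage done (%.2fs)", time.perf_counter() - t0)

    # stage 2: group-wise networks with permutation Z
    if config.collapse_phases:
        groups = {t: table[table["treatment"] == t] for t in TREATMENTS}
    else:
        groups = {
            f"{t}_{p}": table[(table["treatment"] == t) & (table["phase"] == p)]
            for t in TREATMENTS
            for p in PHASES
        }
    seed_root = np.random.SeedSequence(config.seed)
    perm_seeds = {name: _derive_seed(s) for name, s in zip(groups, seed_root.spawn(len(groups)))}
    boot_seed = _derive_seed(seed_root.spawn(1)[0])

    networks = {}
    for name, sub in groups.items():
        work = _center_within_phase(sub) if (config.center_within_phase and config.collapse_phases) else sub
        corr = correlation_matrix(work, method=config.method)
        perm = permutation_null(
            work, n_perm=config.n_perm, method=config.method,
            seed=perm_seeds[name], group=name,
        )
        corr.values.to_csv(outdir / f"correlation_{name}.tsv", sep="\t")
        perm.to_frame().to_csv(outdir / f"connectivity_{name}.tsv", sep="\t")
        edges = edge_list(corr, config.edge_threshold)
        edges.to_csv(outdir / f"edges_{name}.tsv", sep="\t", index=False)
        if config.write_graphml:
            write_graphml(corr, outdir / f"network_{name}.graphml", config.edge_threshold)
        networks[name] = {"correlation": corr, "permutation": perm, "edges": edges}
    logger.info("connectivity stage done (%.2fs)", time.perf_counter() - t0)

    # stage 3: bootstrap comparison MA vs SAL (per phase if not collapsed)
    comparisons = {}
    if config.collapse_phases:
        compare_inputs = {"all": table}
    else:
        compare_inputs = {p: table[table["phase"] == p] for p in PHASES}
    for i, (name, sub) in enumerate(compare_inputs.items()):
        work = _center_within_phase(sub) if (config.center_within_phase and config.collapse_phases) else sub
        diff = bootstrap_compare(
            work, by="treatment", group_a="MA", group_b="SAL",
            n_boot=config.n_boot, seed=boot_seed + i, method=config.method,
        )
        suffix = "" if name == "all" else f"_{name}"
        diff.to_frame().to_csv(outdir / f"compare{suffix}.tsv", sep="\t")
        comparisons[name] = diff
    logger.info("comparison stage done (%.2fs)", time.perf_counter() - t0)

    manifest = {
        "package": "fosnet",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "source": source,
        "parameters": {
            "alpha": config.alpha,
            "method": config.method,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "permutation_seeds": perm_seeds,
            "bootstrap_seed": boot_seed,
            "collapse_phases": config.collapse_phases,
            "center_within_phase": config.center_within_phase,
            "edge_threshold": config.edge_threshold,
        },
        "n_animals": int(len(table)),
        "regions": region_columns(table),
        "group_sizes": {name: int(len(sub)) for name, sub in groups.items()},
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "table": table,
        "anova": anova_df,
        "posthoc": posthoc_df,
        "patterns": patterns,
        "networks": networks,
        "comparisons": comparisons,
        "manifest": manifest,
        "outdir": outdir,
    }
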