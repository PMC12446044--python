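"""End-to-end orchestration: score -> compare -> discover, with a manifest.

A run is driven by a single :class:`RunConfig` (usually loaded from YAML).
Outputs are deterministic for a fixed config: rerunning on the same inputs
produces byte-identical files. The manifest records every parameter, seed,
the package version and SHA-256 checksums of the inputs, so the manifest
alone suffices to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import compute_mpeai, write_activity
from .compare import (
    aggregate_module_tpm,
    anosim,
    bray_curtis,
    compare_features,
    comparison_table,
    shannon_per_sample,
    wilcoxon_rank_sum,
)
from .drivers import discover_drivers, driver_table
from .io import (
    METHANOGENESIS_MODULES,
    read_expression_table,
    read_module_annotation,
    read_taxon_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    expr_mg: str
    expr_mt: str
    modules: str
    taxa_mg: str
    taxa_mt: str
    out_dir: str
    module_ids: list[str] = field(
        default_factory=lambda: sorted(METHANOGENESIS_MODULES)
    )
    activity_layer: str = "MT"   # layer the index is scored on
    taxa_layer: str = "MT"       # abundance layer fed to RF/correlation
    tpm_threshold: float = 1.0
    sample_fraction: float = 0.10
    epsilon: float = 1e-6
    mtry: int = 3
    ntree: int = 10_000
    top_k: int = 30
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for key in ("expr_mg", "expr_mt", "modules", "taxa_mg", "taxa_mt"):
            p = Path(getattr(self, key))
            if not p.is_file():
                raise FileNotFoundError(f"config: {key} path does not exist: {p}")
        if not 0 <= self.sample_fraction <= 1:
            raise ValueError("config: sample_fraction must be in [0, 1]")
        for key in ("tpm_threshold", "epsilon", "alpha"):
            if getattr(self, key) <= 0 and key != "tpm_threshold":
                raise ValueError(f"config: {key} must be positive")
        for key in ("mtry", "ntree", "top_k", "n_permutations"):
            if getattr(self, key) < 1:
                raise ValueError(f"config: {key} must be >= 1")
        if self.activity_layer not in ("MG", "MT") or self.taxa_layer not in ("MG", "MT"):
            raise ValueError("config: layers must be 'MG' or 'MT'")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_frame(frame: pd.DataFrame, path) -> None:
    # repr floats for byte-stable, lossless output
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([frame.index.name or "id", *map(str, frame.columns)]) + "\n")
        for idx, row in frame.iterrows():
            cells = [
                repr(float(v)) if isinstance(v, (float, np.floating)) else str(v)
                for v in row
            ]
            fh.write("\t".join([str(idx), *cells]) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute score -> compare -> discover and write the report bundle.

    Writes ``activity.tsv`` (+ JSON sidecar), ``compare_modules.tsv``,
    ``compare_taxa.tsv``, ``diversity.tsv``, ``drivers.tsv``,
    ``manifest.json`` and ``summary.txt`` into ``config.out_dir``. Any
    stage error aborts the run naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    inputs = {
        "expr_mg": config.expr_mg,
        "expr_mt": config.expr_mt,
        "modules": config.modules,
        "taxa_mg": config.taxa_mg,
        "taxa_mt": config.taxa_mt,
    }

    expr_mg = stage("read", lambda: read_expression_table(config.expr_mg, "MG"))
    expr_mt = stage("read", lambda: read_expression_table(config.expr_mt, "MT"))
    catalog = stage("read", lambda: read_module_annotation(config.modules))
    taxa_mg = stage("read", lambda: read_taxon_table(config.taxa_mg, "MG"))
    taxa_mt = stage("read", lambda: read_taxon_table(config.taxa_mt, "MT"))

    # --- pathway activity ---------------------------------------------------
    expr_for_index = expr_mt if config.activity_layer == "MT" else expr_mg
    profile = stage(
        "mpeai",
        lambda: compute_mpeai(
            expr_for_index,
            catalog,
            modules=set(config.module_ids),
            tpm_threshold=config.tpm_threshold,
            sample_fraction=config.sample_fraction,
            epsilon=config.epsilon,
        ),
    )
    write_activity(profile, out / "activity.tsv", out / "activity.json")
    logger.info("mpeai: %d genes retained", profile.gene_count)

    # --- MG vs MT comparisons ----------------------------------------------
    def _compare_modules():
        rows = {}
        for m in config.module_ids:
            rows[m] = {
                "MT": aggregate_module_tpm(expr_mt, catalog, m),
                "MG": aggregate_module_tpm(expr_mg, catalog, m),
            }
        mt_frame = pd.DataFrame({m: v["MT"] for m, v in rows.items()}).T
        mg_frame = pd.DataFrame({m: v["MG"] for m, v in rows.items()}).T
        results = compare_features(mt_frame, mg_frame)
        table = comparison_table(results)
        return table.rename(columns={"mean_a": "mean_mt", "mean_b": "mean_mg"})

    module_table = stage("compare", _compare_modules)
    module_table.index.name = "module"
    _write_frame(module_table, out / "compare_modules.tsv")

    def _compare_taxa():
        results = compare_features(taxa_mt.to_frame(), taxa_mg.to_frame())
        table = comparison_table(results)
        return table.rename(columns={"mean_a": "mean_mt", "mean_b": "mean_mg"})

    taxa_table = stage("compare", _compare_taxa)
    taxa_table.index.name = "taxon"
    _write_frame(taxa_table, out / "compare_taxa.tsv")

    def _diversity():
        sh_mg = shannon_per_sample(taxa_mg)
        sh_mt = shannon_per_sample(taxa_mt)
        stat, p = wilcoxon_rank_sum(sh_mg.to_numpy(), sh_mt.to_numpy())
        combined = pd.concat(
            [taxa_mg.to_frame().add_suffix("|MG"), taxa_mt.to_frame().add_suffix("|MT")],
            axis=1,
        ).fillna(0.0)
        labels = ["MG"] * taxa_mg.n_samples + ["MT"] * taxa_mt.n_samples
        R, p_anosim = anosim(
            bray_curtis(combined),
            labels,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        frame = pd.DataFrame(
            {
                "shannon": pd.concat([sh_mg.add_suffix("|MG"), sh_mt.add_suffix("|MT")]),
            }
        )
        frame.index.name = "sample"
        stats_row = {
            "shannon_wilcoxon_statistic": stat,
            "shannon_wilcoxon_p": p,
            "anosim_R": R,
            "anosim_p": p_anosim,
        }
        return frame, stats_row

    diversity_frame, diversity_stats = stage("diversity", _diversity)
    _write_frame(diversity_frame, out / "diversity.tsv")

    # --- driver discovery ---------------------------------------------------
    taxa_for_rf = taxa_mt if config.taxa_layer == "MT" else taxa_mg
    pass1, pass2 = stage(
        "discover",
        lambda: discover_drivers(
            taxa_for_rf,
            profile,
            mtry=config.mtry,
            ntree=config.ntree,
            top_k=config.top_k,
            seed=config.seed,
            alpha=config.alpha,
        ),
    )
    drivers_frame = driver_table([pass1, pass2]).set_index("taxon")
    _write_frame(drivers_frame, out / "drivers.tsv")

    # --- manifest and summary ----------------------------------------------
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "gene_count": profile.gene_count,
        "dropped_zero_variance": profile.dropped_zero_variance,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    n_candidates = int(pass1.table["candidate"].sum())
    n_candidates2 = int(pass2.table["candidate"].sum())
    summary_lines = [
        f"mpeai: {profile.gene_count} pathway genes over {len(profile.sample_ids)} samples "
        f"(layer {config.activity_layer})",
        f"module MG-vs-MT contrasts: "
        f"{int((module_table['p_value'] <= config.alpha).sum())}/{len(module_table)} "
        f"significant at p <= {config.alpha}",
        f"diversity: shannon wilcoxon p = {diversity_stats['shannon_wilcoxon_p']:.4g}; "
        f"ANOSIM R = {diversity_stats['anosim_R']:.4f}, p = {diversity_stats['anosim_p']:.4g}",
        f"drivers: {n_candidates} mitigation candidates (all taxa), "
        f"{n_candidates2} (cultivated only)",
    ]
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n", encoding="utf-8")

    return {
        "activity": profile,
        "modules": module_table,
        "taxa": taxa_table,
        "diversity": diversity_frame,
        "diversity_stats": diversity_stats,
        "drivers": drivers_frame,
        "manifest": manifest,
    }
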