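"""Synthetic paired MG/MT rumen datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a 48-animal paired metagenome/metatranscriptome cohort:

* a latent per-sample pathway activity ``a_s ~ N(0, 1)``;
* methanogenesis-module genes whose MT expression responds to ``a_s``
  (log-linear coupling) while their MG abundance does not, with MT module
  totals exceeding MG by ~2.5x — the pathway-hyperactivity contrast;
* archaeal taxa whose MT activity is suppressed ~4x relative to their MG
  abundance — the abundance/activity decoupling;
* a minority of planted "driver" taxa whose abundance is negatively
  coupled to ``a_s`` (multiplicatively, before compositional closure);
* log-normal expression and abundance noise, with taxon tables closed to
  relative abundances.

All randomness flows from one seed through named substreams (activity,
genes, taxa, noise) so components can be varied independently and a fixed
seed reproduces the dataset bit-identically.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (
    ExpressionMatrix,
    ModuleCatalog,
    TaxonTable,
    write_expression_table,
    write_module_annotation,
    write_taxon_table,
)

_MODULES = ("M00356", "M00357", "M00563", "M00567")

_CULTIVATED_DRIVER_EPITHETS = (
    "succinifaciens", "bryantii", "porcinum", "pectinovorum",
    "rectale", "saccharophilum",
)
_NOISE_GENERA = (
    "Prevotella", "Fibrobacter", "Succiniclasticum", "Sodaliphilus",
    "Ruminococcus_E", "Butyrivibrio_A",
)
_EPITHET_PREFIX = ("rumino", "fibro", "lacti", "aceto", "butyro", "sacchari", "cellulo", "amylo")
_EPITHET_SUFFIX = ("philus", "vorans", "genes", "lyticus", "fermentans", "cola", "factor", "bium")


@dataclass
class SimulationParams:
    """Knobs of the paired-omics simulator.

    Defaults describe the emulated cohort: 48 paired samples, four
    methanogenesis modules of 25 genes each, 200 taxa of which 8 are
    planted negative drivers (log-scale effect gamma = 0.8) and 10 are
    archaea transcribed 4x below their genomic abundance; MT module totals
    exceed MG by a factor of 2.5; log-normal noise with sd 0.5.
    """

    n_samples: int = 48
    genes_per_module: int = 25
    n_background_genes: int = 400
    n_taxa: int = 200
    n_drivers: int = 8
    n_archaea: int = 10
    driver_effect: float = 0.8          # gamma: log-abundance units per sd of activity
    module_mt_fold: float = 2.5         # MT/MG module-total ratio
    archaeal_suppression: float = 4.0   # MG/MT abundance ratio for archaea
    activity_coupling: float = 0.3      # beta: log-TPM units per sd of activity
    noise_sd: float = 0.5               # log-scale noise sd
    uncultivated_fraction: float = 0.6  # share of noise taxa with placeholder names
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_drivers + self.n_archaea > self.n_taxa:
            raise ValueError("n_drivers + n_archaea must not exceed n_taxa")
        for name in ("module_mt_fold", "archaeal_suppression", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.driver_effect < 0:
            raise ValueError("driver_effect must be nonnegative")
        if not 0 <= self.uncultivated_fraction <= 1:
            raise ValueError("uncultivated_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    latent_activity: np.ndarray
    driver_taxa: list[str]
    archaeal_taxa: list[str]
    effect_sizes: np.ndarray

    def __post_init__(self) -> None:
        if set(self.driver_taxa) & set(self.archaeal_taxa):
            raise ValueError("driver and archaeal taxon sets must be disjoint")


@dataclass
class SyntheticDataset:
    expr_mg: ExpressionMatrix
    expr_mt: ExpressionMatrix
    catalog: ModuleCatalog
    taxa_mg: TaxonTable
    taxa_mt: TaxonTable
    truth: SyntheticTruth
    params: SimulationParams = field(default=None)  # type: ignore[assignment]


def _substream(seed: int, name: str) -> np.random.Generator:
    # named substreams off one master seed; crc32 keys are process-stable
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    )


def _taxon_names(params: SimulationParams, rng: np.random.Generator):
    """Deterministic GTDB-style names: archaea, drivers, then noise taxa.

    Drivers mix cultivated binomials (Treponema-like) with placeholder
    epithets; noise taxa get a placeholder name (accession epithet or
    placeholder genus) with probability ``uncultivated_fraction``.
    """
    names: list[str] = []
    archaea = [
        f"Methanobrevibacter{'' if i % 3 else '_A'} sp{900310000 + 7 * i:09d}"
        for i in range(params.n_archaea)
    ]
    n_cult = min(len(_CULTIVATED_DRIVER_EPITHETS), (params.n_drivers + 1) // 2)
    drivers = [
        f"Treponema_D {_CULTIVATED_DRIVER_EPITHETS[i]}" for i in range(n_cult)
    ] + [
        f"Treponema_D sp{4554000 + 13 * i:09d}"
        for i in range(params.n_drivers - n_cult)
    ]
    names.extend(archaea)
    names.extend(drivers)
    n_noise = params.n_taxa - len(names)
    used = set(names)
    i = 0
    while len(names) < params.n_taxa:
        if rng.random() < params.uncultivated_fraction:
            if rng.random() < 0.5:
                name = f"UBA{1000 + i} sp{2351000 + 11 * i:09d}"
            else:
                genus = _NOISE_GENERA[i % len(_NOISE_GENERA)]
                name = f"{genus} sp{900320000 + 17 * i:09d}"
        else:
            genus = _NOISE_GENERA[i % len(_NOISE_GENERA)]
            epithet = (
                _EPITHET_PREFIX[(i // len(_NOISE_GENERA)) % len(_EPITHET_PREFIX)]
                + _EPITHET_SUFFIX[(i // (len(_NOISE_GENERA) * len(_EPITHET_PREFIX))) % len(_EPITHET_SUFFIX)]
            )
            name = f"{genus} {epithet}"
            if name in used:
                name = f"{genus} {epithet}ii"
        if name in used:  # pragma: no cover - defensive
            i += 1
            continue
        used.add(name)
        names.append(name)
        i += 1
    assert n_noise == len(names) - params.n_archaea - params.n_drivers
    return archaea, drivers, names


def generate_paired_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Simulate paired MG/MT expression and taxon tables plus ground truth.

    Construction: (1) latent activity ``a_s`` i.i.d. standard normal;
    (2) module gene g: MT TPM ``= exp(b_g + beta a_s + noise)`` and MG TPM
    ``= exp(b_g + noise) / module_mt_fold`` (no activity dependence), so
    summed module TPM in MT exceeds MG by about the fold; (3) background
    genes i.i.d. log-normal in both layers; (4) taxon weights log-normal
    with a shared per-taxon baseline, drivers multiplied by
    ``exp(-gamma a_s)`` in both layers, archaeal MT weights divided by the
    suppression factor, then columns closed to relative abundances.
    """
    params = params or SimulationParams()
    params.validate()
    rng_act = _substream(params.seed, "activity")
    rng_genes = _substream(params.seed, "genes")
    rng_taxa = _substream(params.seed, "taxa")
    rng_noise = _substream(params.seed, "noise")

    S = params.n_samples
    a = rng_act.standard_normal(S)
    sample_ids = [f"S{i + 1:02d}" for i in range(S)]

    # --- expression matrices ------------------------------------------------
    G_mod = len(_MODULES) * params.genes_per_module
    gene_ids = [
        f"{m}_g{j + 1:03d}" for m in _MODULES for j in range(params.genes_per_module)
    ]
    b = rng_genes.normal(3.0, 0.7, size=G_mod)  # baseline log-TPM, median ~20
    eps_mt = rng_noise.normal(0.0, params.noise_sd, size=(G_mod, S))
    eps_mg = rng_noise.normal(0.0, params.noise_sd, size=(G_mod, S))
    mt_mod = np.exp(b[:, None] + params.activity_coupling * a[None, :] + eps_mt)
    mg_mod = np.exp(b[:, None] + eps_mg) / params.module_mt_fold

    bg_ids = [f"bg_g{j + 1:04d}" for j in range(params.n_background_genes)]
    b_bg = rng_genes.normal(2.0, 1.0, size=params.n_background_genes)
    bg_mt = np.exp(
        b_bg[:, None] + rng_noise.normal(0.0, params.noise_sd, size=(params.n_background_genes, S))
    )
    bg_mg = np.exp(
        b_bg[:, None] + rng_noise.normal(0.0, params.noise_sd, size=(params.n_background_genes, S))
    )

    all_gene_ids = gene_ids + bg_ids
    expr_mt = ExpressionMatrix(all_gene_ids, sample_ids, np.vstack([mt_mod, bg_mt]), "MT")
    expr_mg = ExpressionMatrix(all_gene_ids, sample_ids, np.vstack([mg_mod, bg_mg]), "MG")
    catalog = ModuleCatalog(
        {
            gid: frozenset({m})
            for m in _MODULES
            for gid in (f"{m}_g{j + 1:03d}" for j in range(params.genes_per_module))
        }
    )

    # --- taxon tables -------------------------------------------------------
    archaea, drivers, names = _taxon_names(params, rng_taxa)
    T = params.n_taxa
    base = rng_taxa.normal(0.0, 1.0, size=T)
    is_archaeon = np.isin(names, archaea)
    base[is_archaeon] += 0.5  # archaea genomically abundant in the rumen
    is_driver = np.isin(names, drivers)

    log_mg = base[:, None] + rng_noise.normal(0.0, params.noise_sd, size=(T, S))
    log_mt = base[:, None] + rng_noise.normal(0.0, params.noise_sd, size=(T, S))
    # drivers: abundance anti-coupled to latent activity (both layers)
    log_mg[is_driver] -= params.driver_effect * a[None, :]
    log_mt[is_driver] -= params.driver_effect * a[None, :]
    # archaea: transcription suppressed relative to genomic abundance
    log_mt[is_archaeon] -= np.log(params.archaeal_suppression)

    w_mg = np.exp(log_mg)
    w_mt = np.exp(log_mt)
    taxa_mg = TaxonTable(names, sample_ids, w_mg / w_mg.sum(axis=0), "MG")
    taxa_mt = TaxonTable(names, sample_ids, w_mt / w_mt.sum(axis=0), "MT")

    truth = SyntheticTruth(
        latent_activity=a,
        driver_taxa=drivers,
        archaeal_taxa=archaea,
        effect_sizes=np.full(params.n_drivers, params.driver_effect),
    )
    return SyntheticDataset(expr_mg, expr_mt, catalog, taxa_mg, taxa_mt, truth, params)


def emit_fixture(out_dir, dataset: SyntheticDataset) -> dict[str, Path]:
    """Write the five tables plus a truth JSON into ``out_dir``.

    Files are plain TSV/JSON with full-precision floats; regenerating with
    the same seed reproduces them byte-for-byte, and reading them back
    reproduces the in-memory objects exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_mg": out / "expr_mg.tsv",
        "expr_mt": out / "expr_mt.tsv",
        "modules": out / "modules.tsv",
        "taxa_mg": out / "taxa_mg.tsv",
        "taxa_mt": out / "taxa_mt.tsv",
        "truth": out / "truth.json",
    }
    write_expression_table(dataset.expr_mg, paths["expr_mg"])
    write_expression_table(dataset.expr_mt, paths["expr_mt"])
    write_module_annotation(dataset.catalog, paths["modules"])
    write_taxon_table(dataset.taxa_mg, paths["taxa_mg"])
    write_taxon_table(dataset.taxa_mt, paths["taxa_mt"])
    truth = {
        "latent_activity": [repr(float(v)) for v in dataset.truth.latent_activity],
        "driver_taxa": dataset.truth.driver_taxa,
        "archaeal_taxa": dataset.truth.archaeal_taxa,
        "effect_sizes": [repr(float(v)) for v in dataset.truth.effect_sizes],
        "params": asdict(dataset.params) if dataset.params else None,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_truth(path) -> SyntheticTruth:
    """Read a truth JSON written by :func:`emit_fixture`."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return SyntheticTruth(
        latent_activity=np.array([float(v) for v in raw["latent_activity"]]),
        driver_taxa=list(raw["driver_taxa"]),
        archaeal_taxa=list(raw["archaeal_taxa"]),
        effect_sizes=np.array([float(v) for v in raw["effect_sizes"]]),
    )
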