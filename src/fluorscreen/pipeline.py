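"""Configuration, dataset assembly and end-to-end orchestration.

The pipeline chains curate → split → train L1 → train L2 → screen →
chemspace on either user CSVs or the built-in synthetic library, emitting a
manifest with per-stage audits, derived seeds and output digests.  A single
global seed fans out to per-stage seeds (stable hash of the stage name) so
every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curation import (
    FLUORESCENT,
    curate,
    records_from_frame,
    records_to_frame,
    split_dataset,
)
from .dmpnn import (
    CLASSIFICATION,
    REGRESSION,
    EncoderConfig,
    Model,
    Sample,
    train_model,
)
from .errors import ConfigurationError, DataError
from .molgraph import WavelengthPair
from .screen import (
    build_l1_cache,
    build_l2_cache,
    chemspace_embed,
    fingerprint,
    scaffold_frequencies,
    screening_frame,
    two_step_screen,
)
from .synthdata import GeneratorSpec, generate_library


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ------------------------------------------------------ dataset assembly

def classification_samples(truth: pd.DataFrame, window) -> list:
    """Samples (molecule, wavelength query, planted label) from a truth table."""
    pair = WavelengthPair(window[0], window[1])
    return [
        Sample(row.smiles, pair, float(row.label))
        for row in truth.itertuples(index=False)
    ]


def regression_samples(records: pd.DataFrame, prop: str,
                       max_per_molecule: int | None = None) -> list:
    """Samples (molecule, solvent, measured value) for one property.

    ``max_per_molecule`` caps the number of solvent entries kept per molecule
    (first occurrences in table order), e.g. 1 for one-entry-per-molecule
    training sets.
    """
    sub = records[records["property"] == prop]
    if max_per_molecule is not None:
        sub = sub.groupby("smiles", sort=False).head(max_per_molecule)
    return [
        Sample(row.smiles, row.solvent_smiles, float(row.value))
        for row in sub.itertuples(index=False)
    ]


def samples_from_records(records, prop: str | None = None, window=None) -> list:
    """Samples from curated MoleculeRecords (classification or regression)."""
    out = []
    for rec in records:
        if prop is None:
            if rec.fluorescence_label is None:
                continue
            cond = rec.condition or (window[0], window[1])
            out.append(
                Sample(rec.canonical_smiles, WavelengthPair(cond[0], cond[1]),
                       1.0 if rec.fluorescence_label == FLUORESCENT else 0.0)
            )
        else:
            for m in rec.measurements:
                if m.property == prop:
                    out.append(
                        Sample(rec.canonical_smiles, m.solvent_smiles, float(m.value))
                    )
    return out


# ------------------------------------------------------------- config

@dataclass
class StageModelConfig:
    epochs: int = 30
    init_lr: float = 1e-4
    hidden: int = 300
    depth: int = 3
    batch_size: int = 64


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    library_csv: str | None = None       # if unset, the synthetic library is used
    synth_n: int = 1000
    synth_inconsistency_rate: float = 0.05
    label_threshold: float = 20.0
    split_ratios: tuple = (0.7, 0.1, 0.2)
    l1: StageModelConfig = field(default_factory=StageModelConfig)
    l2: StageModelConfig = field(default_factory=lambda: StageModelConfig(epochs=50, init_lr=1e-3))
    l2_properties: tuple = ("em_wavelength",)
    screen_abs_nm: float = 390.0
    screen_em_nm: float = 435.0
    screen_solvent: str = "O"
    screen_threshold: float = 0.5
    chemspace_perplexity: float = 30.0
    chemspace_top_scaffolds: int = 20


def _from_mapping(cls, data: dict, path="config"):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigurationError(f"unknown key {path}.{key}")
        ftype = fields[key].type
        if isinstance(value, dict) and ftype == "StageModelConfig":
            value = _from_mapping(StageModelConfig, value, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    return _from_mapping(PipelineConfig, raw)


def dump_config(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def write_csv_with_meta(df: pd.DataFrame, path, meta: dict):
    """CSV artifact with a reproducibility header (leading comment lines)."""
    header = "".join(
        f"# {k}: {v}\n" for k, v in {"tool": f"fluorscreen {__version__}", **meta}.items()
    )
    Path(path).write_text(header + df.to_csv(index=False))


def read_csv_with_meta(path) -> pd.DataFrame:
    """Read a CSV, skipping a leading ``#`` metadata block.

    Only *leading* lines are treated as comments — ``#`` is a legitimate
    character inside the data (triple bonds in SMILES).
    """
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
            else:
                break
    return pd.read_csv(path, skiprows=skip)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ------------------------------------------------------------- pipeline

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute curate → split → train L1 → train L2 → screen → chemspace.

    Returns a manifest (stages, seeds, audits, output digests); any stage
    error aborts with the failing stage named.
    """
    if cfg.library_csv is not None and not Path(cfg.library_csv).exists():
        raise ConfigurationError(f"input file not found: {cfg.library_csv}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(cfg), "seed": cfg.seed}
    manifest = {"tool": f"fluorscreen {__version__}", **meta, "stages": []}
    stage = "init"
    try:
        # ------------------------------------------------ curate
        stage = "curate"
        gen_spec = GeneratorSpec(
            n=cfg.synth_n,
            seed=derive_seed(cfg.seed, "synth"),
            inconsistency_rate=cfg.synth_inconsistency_rate,
        )
        if cfg.library_csv is None:
            raw_frame, truth = generate_library(gen_spec)
        else:
            raw_frame = read_csv_with_meta(cfg.library_csv)
            truth = None
        records = records_from_frame(raw_frame)
        curated, audits = curate(records, task="classification",
                                 threshold=cfg.label_threshold)
        curated_path = out / "curated.csv"
        write_csv_with_meta(records_to_frame(curated), curated_path, meta)
        manifest["stages"].append(
            {"name": stage, "audits": [a.as_dict() for a in audits],
             "output": _digest(curated_path)}
        )

        # ------------------------------------------------ split
        stage = "split"
        split_seed = derive_seed(cfg.seed, "split")
        train, val, test = split_dataset(curated, cfg.split_ratios, split_seed)
        manifest["stages"].append(
            {"name": stage, "seed": split_seed,
             "sizes": [len(train), len(val), len(test)]}
        )

        # ------------------------------------------------ train L1
        stage = "train_l1"
        window = (cfg.screen_abs_nm, cfg.screen_em_nm)
        l1_cfg = EncoderConfig(
            task=CLASSIFICATION, depth=cfg.l1.depth, hidden=cfg.l1.hidden,
            epochs=cfg.l1.epochs, init_lr=cfg.l1.init_lr,
            batch_size=cfg.l1.batch_size, seed=derive_seed(cfg.seed, "train_l1"),
        )
        l1_train = samples_from_records(train, window=window)
        l1_val = samples_from_records(val, window=window) or l1_train[:1]
        params, hist = train_model(l1_train, l1_val, l1_cfg)
        l1_model = Model(l1_cfg, params,
                         cache=build_l1_cache(l1_train, WavelengthPair(*window)))
        manifest["stages"].append(
            {"name": stage, "seed": l1_cfg.seed, "epochs": l1_cfg.epochs,
             "best_epoch": hist.best_epoch,
             "final_train_loss": hist.train_loss[-1]}
        )

        # ------------------------------------------------ train L2
        stage = "train_l2"
        l2_models = {}
        l2_info = []
        for prop in cfg.l2_properties:
            l2_cfg = EncoderConfig(
                task=REGRESSION, target_property=prop, depth=cfg.l2.depth,
                hidden=cfg.l2.hidden, epochs=cfg.l2.epochs,
                init_lr=cfg.l2.init_lr, batch_size=cfg.l2.batch_size,
                seed=derive_seed(cfg.seed, f"train_l2_{prop}"),
            )
            p_train = samples_from_records(train, prop=prop)
            p_val = samples_from_records(val, prop=prop) or p_train[:1]
            if not p_train:
                raise DataError(f"no training measurements for {prop}")
            params, hist = train_model(p_train, p_val, l2_cfg)
            l2_models[prop] = Model(l2_cfg, params,
                                    cache=build_l2_cache(p_train, prop))
            l2_info.append({"property": prop, "seed": l2_cfg.seed,
                            "best_epoch": hist.best_epoch})
        manifest["stages"].append({"name": stage, "models": l2_info})

        # ------------------------------------------------ screen
        stage = "screen"
        library = [(r.canonical_smiles, None) for r in test]
        hits = two_step_screen(
            library, l1_model, l2_models, WavelengthPair(*window),
            cfg.screen_solvent, cfg.screen_threshold,
        )
        hits_path = out / "hits.csv"
        write_csv_with_meta(screening_frame(hits), hits_path, meta)
        survivors = [h for h in hits if h.passed_l1]
        manifest["stages"].append(
            {"name": stage, "n_library": len(hits), "n_hits": len(survivors),
             "threshold": cfg.screen_threshold, "output": _digest(hits_path)}
        )

        # ------------------------------------------------ chemspace
        stage = "chemspace"
        hit_smiles = [h.canonical_smiles for h in survivors] or [
            h.canonical_smiles for h in hits
        ]
        scaffolds = scaffold_frequencies(hit_smiles, cfg.chemspace_top_scaffolds)
        fps = np.stack([fingerprint(s) for s in hit_smiles])
        coords = chemspace_embed(fps, cfg.chemspace_perplexity,
                                 derive_seed(cfg.seed, "chemspace") % (2**31))
        coords_df = pd.DataFrame(
            {"smiles": hit_smiles, "tsne1": coords[:, 0], "tsne2": coords[:, 1]}
        )
        coords_path = out / "chemspace.csv"
        scaff_path = out / "scaffolds.csv"
        write_csv_with_meta(coords_df, coords_path, meta)
        write_csv_with_meta(scaffolds, scaff_path, meta)
        manifest["stages"].append(
            {"name": stage, "outputs": [_digest(coords_path), _digest(scaff_path)]}
        )
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
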