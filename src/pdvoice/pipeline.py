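"""End-to-end orchestration: synthesis -> preprocessing -> features ->
spectrograms -> classifier tracks -> summary grid.

One ``PipelineConfig`` (and its single master seed) determines every
artifact; re-running with the same config reproduces the same summary.  The
summary grid mirrors the study's results table: nine feature tracks
(acoustic + mean/variance vectors of LPC, LAR, Cep, MFCC) crossed with the
logistic-regression and random-forest classifiers, plus the image
classifier on color and grayscale spectrograms — 20 cells of mean AUC.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import acoustic, audio, specgram, spectral, synth
from .cnn import CnnConfig, train_and_eval_images
from .evaluate import EvalProtocol, run_protocol
from .exceptions import PdVoiceError

log = logging.getLogger("pdvoice")

FEATURE_TRACKS = (
    "acoustic",
    "lpc_mean", "lpc_var",
    "lar_mean", "lar_var",
    "cep_mean", "cep_var",
    "mfcc_mean", "mfcc_var",
)
MODELS = ("lr", "rf")
CNN_MODES = ("color", "grayscale")


@dataclass
class PipelineConfig:
    """All pipeline constants in one place."""

    out_dir: Path = Path("pdvoice_run")
    n_hc: int = 41
    n_pd: int = 40
    rng_seed: int = 0
    fs: int = 8000
    preprocess: audio.PreprocessConfig = field(default_factory=audio.PreprocessConfig)
    protocol: EvalProtocol = field(default_factory=EvalProtocol)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    cnn_iterations: int = 10
    segment_s: float = specgram.SEGMENT_S
    skip: Tuple[str, ...] = ()
    write_wavs: bool = False
    write_images: bool = False
    #: forwarded to the random-forest track (e.g. {"n_trees": 100} for
    #: quick runs); empty dict keeps the study hyperparameters
    rf_kwargs: dict = field(default_factory=dict)


def cohort_feature_tables(
    cohort, cfg: Optional[PipelineConfig] = None
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray], List[specgram.Spectrogram]]:
    """Preprocess a cohort and compute every feature family.

    Returns the acoustic feature table (one row per kept recording, with
    metadata), a dict of pooled spectral matrices keyed by track name, and
    the per-recording 1.5 s spectrograms.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    spectral_rows: Dict[str, list] = {t: [] for t in FEATURE_TRACKS if t != "acoustic"}
    spectrograms = []
    for sample, record in cohort:
        processed, keep = audio.preprocess(sample, cfg.preprocess)
        if not keep:
            log.info("rejecting %s (too short or silent)", record.subject_id)
            continue
        fv = acoustic.extract_acoustic_features(processed, sex=record.sex)
        row = {
            "subject_id": record.subject_id,
            "group": record.group,
            "sex": record.sex,
            "age": record.age,
        }
        row.update(dict(zip(acoustic.FEATURE_NAMES, fv.to_array())))
        rows.append(row)

        summary = spectral.extract_spectral_summary(processed)
        for family in spectral.FAMILIES:
            spectral_rows[f"{family}_mean"].append(summary.vector(family, "mean"))
            spectral_rows[f"{family}_var"].append(summary.vector(family, "var"))

        segment = audio.truncate_to(processed, cfg.segment_s)
        spectrograms.append(specgram.compute_spectrogram(segment))
    if not rows:
        raise PdVoiceError("every recording was rejected by preprocessing")
    table = pd.DataFrame(rows)
    matrices = {k: np.vstack(v) for k, v in spectral_rows.items()}
    return table, matrices, spectrograms


def evaluate_tracks(
    table: pd.DataFrame,
    matrices: Dict[str, np.ndarray],
    protocol: EvalProtocol,
    rf_kwargs: Optional[dict] = None,
) -> Dict[str, Dict[str, float]]:
    """Run LR and RF over all nine feature tracks; returns mean AUC grid."""
    y = (table["group"] == "PD").astype(int).to_numpy()
    grid: Dict[str, Dict[str, float]] = {}
    for track in FEATURE_TRACKS:
        if track == "acoustic":
            X = table[list(acoustic.FEATURE_NAMES)].to_numpy()
            names = list(acoustic.FEATURE_NAMES)
        else:
            X = matrices[track]
            names = [f"{track}_{k+1}" for k in range(X.shape[1])]
        grid[track] = {}
        for model in MODELS:
            kwargs = {"rf_kwargs": rf_kwargs} if (model == "rf" and rf_kwargs) else {}
            result = run_protocol(X, y, model, protocol, feature_names=names, **kwargs)
            grid[track][model] = result.mean_auc
            log.info("track %-10s %-2s mean AUC %.3f", track, model, result.mean_auc)
    return grid


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute all stages and write features, results and a manifest.

    Returns the machine-readable summary that is also written to
    ``summary.json`` in the run directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("generating cohort: %d HC + %d PD, seed %d", cfg.n_hc, cfg.n_pd, cfg.rng_seed)
    cohort = synth.generate_cohort(cfg.n_hc, cfg.n_pd, cfg.rng_seed, fs=cfg.fs)

    if cfg.write_wavs:
        wav_dir = out / "wav"
        meta = []
        for sample, record in cohort:
            audio.write_wav(sample, wav_dir / f"{record.subject_id}.wav")
            meta.append(
                {
                    "subject_id": record.subject_id,
                    "group": record.group,
                    "sex": record.sex,
                    "age": round(record.age, 1),
                }
            )
        pd.DataFrame(meta).to_csv(out / "metadata.tsv", sep="\t", index=False)

    table, matrices, spectrograms = cohort_feature_tables(cohort, cfg)
    table.to_csv(out / "acoustic_features.tsv", sep="\t", index=False)

    summary: Dict = {"seed": cfg.rng_seed, "n_subjects": int(len(table)), "tracks": {}}
    if "statistical" not in cfg.skip:
        summary["tracks"] = evaluate_tracks(table, matrices, cfg.protocol, cfg.rf_kwargs)

    if "cnn" not in cfg.skip:
        y = (table["group"] == "PD").astype(int).to_numpy()
        cnn_protocol = EvalProtocol(
            n_iterations=cfg.cnn_iterations,
            train_fraction=cfg.protocol.train_fraction,
            cv_folds=cfg.protocol.cv_folds,
            rng_seed=cfg.protocol.rng_seed,
        )
        summary["cnn"] = {}
        for mode in CNN_MODES:
            images = []
            for i, spec in enumerate(spectrograms):
                img = specgram.render_image(
                    spec,
                    mode=mode,
                    size=cfg.cnn.input_size,
                    out_path=(
                        out / "spectrograms" / f"{table.subject_id.iloc[i]}_{mode}.png"
                        if cfg.write_images
                        else None
                    ),
                )
                images.append(img.pixels)
            result = train_and_eval_images(images, y, cfg.cnn, cnn_protocol)
            summary["cnn"][mode] = result.mean_auc
            log.info("cnn %-9s mean AUC %.3f", mode, result.mean_auc)

    payload = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(payload)
    manifest = {
        "summary.json": hashlib.sha256(payload.encode()).hexdigest(),
        "acoustic_features.tsv": hashlib.sha256(
            (out / "acoustic_features.tsv").read_bytes()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
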