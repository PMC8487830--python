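"""End-to-end orchestration: simulate -> preprocess -> extract -> compress -> evaluate.

Runs the full fatigue-detection chain for one or more measurement
conditions (learned low-coherence pair, seeded Gaussian matrix, or no
compression at all) and emits a comparison table of cross-validated
accuracies, one row per condition x feature kind. Every stochastic step
derives its seed deterministically from the global seed, so a rerun with
the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from functools import partial
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, fractal, icsca, preprocess, synthetic

logger = logging.getLogger("voxfatigue")

CONDITIONS = ("icsca", "gaussian", "uncompressed")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    seed: int = 0
    # corpus
    n_per_class: int = 412
    hurst_normal: float = 0.8
    hurst_fatigued: float = 0.3
    duration_s: float = 0.25
    rate: int = 16000
    snr_db: float | None = 20.0
    # preprocessing
    mu: float = 0.95
    frame_len: int = 256
    stride: int = 64
    window: str = "hamming"
    # features
    feature_kinds: tuple = ("swff",)
    feature_dim: int = 256
    wavelet: str = fractal.DEFAULT_WAVELET
    levels: int = 4
    k_max: int = 10
    # compression
    conditions: tuple = CONDITIONS
    compressed_dim: int = 32
    icsca_beta: float = 0.001
    icsca_gamma: float = 0.4
    icsca_max_outer: int = 12
    icsca_max_inner: int = 300
    # classifier
    n_rules: int = 2
    penalty_c: float = 9.7656e-4
    kernel_gamma: float = 0.5
    folds: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("feature_kinds", "conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("feature_kinds", "conditions"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunReport:
    """Comparison table plus per-stage artifacts of one pipeline run."""

    table: pd.DataFrame
    cv_reports: dict
    sensing_pair: icsca.SensingPair | None
    config: RunConfig
    mu_t_trace: list = field(default_factory=list)


def _subseed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stable across processes)."""
    tag = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def extract_features(
    signals, config: RunConfig, feature_kind: str = "swff"
) -> np.ndarray:
    """Stack per-utterance feature vectors for a list of AudioSignals."""
    pconf = preprocess.PreprocessConfig(
        mu=config.mu, frame_len=config.frame_len, stride=config.stride, window=config.window
    )
    rows = []
    for sig in signals:
        frames = preprocess.preprocess_signal(sig, pconf)
        rows.append(
            fractal.utterance_feature_vector(
                frames,
                feature_kind,
                target_dim=config.feature_dim,
                wavelet_name=config.wavelet,
                levels=config.levels,
                k_max=config.k_max,
            )
        )
    return np.stack(rows)


def run_pipeline(config: RunConfig | None = None, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full chain for every requested condition x feature kind.

    Conditions: "icsca" (learned pair, features compressed to
    config.compressed_dim), "gaussian" (seeded random matrix baseline at the
    same dimension), "uncompressed" (classifier sees the raw feature_dim
    vectors). Fails loudly with the stage name on any stage error.
    """
    if config is None:
        config = RunConfig()
    t_start = time.time()

    stage = "simulate"
    try:
        spec = synthetic.SyntheticCorpusSpec(
            n_per_class=config.n_per_class,
            hurst_by_class={"normal": config.hurst_normal, "fatigued": config.hurst_fatigued},
            duration_s=config.duration_s,
            rate=config.rate,
            snr_db=config.snr_db,
            seed=_subseed(config.seed, "simulate"),
        )
        corpus = synthetic.generate_corpus(spec)
        y = corpus.labels
        logger.info("simulate: %d signals of %d samples", len(corpus.signals), int(config.duration_s * config.rate))

        stage = "extract"
        features = {}
        for kind in config.feature_kinds:
            features[kind] = extract_features(corpus.signals, config, kind)
            logger.info("extract[%s]: %s", kind, features[kind].shape)

        stage = "learn-matrix"
        pair = None
        mu_trace: list = []
        if "icsca" in config.conditions:
            icfg = icsca.ICSCAConfig(
                beta=config.icsca_beta,
                gamma=config.icsca_gamma,
                max_outer=config.icsca_max_outer,
                max_inner=config.icsca_max_inner,
                seed=_subseed(config.seed, "icsca"),
            )
            pair, icsca_report = icsca.icsca_learn(config.feature_dim, config.compressed_dim, icfg)
            mu_trace = icsca_report.mu_t
            logger.info(
                "learn-matrix: mu_t %.3f -> %.4f over %d rounds",
                icsca_report.mu_init, mu_trace[-1], len(mu_trace),
            )
        gauss = icsca.gaussian_measurement_matrix(
            config.compressed_dim, config.feature_dim, _subseed(config.seed, "gaussian")
        )

        stage = "train/evaluate"
        trainer = partial(
            classifier.wls_svm_train,
            C_rules=config.n_rules,
            penalty_c=config.penalty_c,
            kernel_gamma=config.kernel_gamma,
            seed=_subseed(config.seed, "train"),
        )
        rows = []
        cv_reports = {}
        for kind in config.feature_kinds:
            X = features[kind]
            for cond in config.conditions:
                if cond == "icsca":
                    Z = icsca.compress(pair.phi, X)
                elif cond == "gaussian":
                    Z = icsca.compress(gauss, X)
                elif cond == "uncompressed":
                    Z = X
                else:
                    raise ValueError(f"unknown condition {cond!r}")
                t0 = time.time()
                rep = classifier.kfold_cv(
                    Z, y, K=config.folds, trainer=trainer, seed=_subseed(config.seed, "folds")
                )
                cv_reports[(kind, cond)] = rep
                rows.append(
                    {
                        "feature": kind,
                        "condition": cond,
                        "dim": Z.shape[1],
                        "mean_accuracy": rep.mean_accuracy,
                        "wall_s": time.time() - t0,
                    }
                )
                logger.info(
                    "evaluate[%s/%s]: accuracy %.4f", kind, cond, rep.mean_accuracy
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    table = pd.DataFrame(rows)
    report = RunReport(
        table=table, cv_reports=cv_reports, sensing_pair=pair, config=config, mu_t_trace=mu_trace
    )
    logger.info("pipeline complete in %.1f s", time.time() - t_start)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yml")
        table.to_csv(out_dir / "report.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(
                {
                    f"{kind}/{cond}": {
                        "mean_accuracy": rep.mean_accuracy,
                        "fold_accuracies": rep.fold_accuracies,
                        "fold_sizes": rep.fold_sizes,
                    }
                    for (kind, cond), rep in cv_reports.items()
                },
                fh,
                indent=2,
            )
        if pair is not None:
            save_sensing_pair(out_dir / "sensing_pair.npz", pair, config)
    return report


def save_sensing_pair(path: str | Path, pair: icsca.SensingPair, config: RunConfig | None = None) -> None:
    """Serialize a sensing pair with its shape metadata."""
    meta = {"m": pair.m, "n": pair.n}
    if config is not None:
        meta["seed"] = config.seed
    np.savez(path, phi=pair.phi, psi=pair.psi, meta=json.dumps(meta))


def load_sensing_pair(path: str | Path) -> icsca.SensingPair:
    data = np.load(path, allow_pickle=False)
    return icsca.SensingPair(phi=data["phi"], psi=data["psi"])
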