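"""End-to-end orchestration: simulate/load -> deconvolve -> band registry ->
features -> per-organ PLS-DA fingerprints, with one global seed, a run log
and the effective configuration serialised next to the outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import bands as bands_mod
from . import deconv, features, pls, synth
from .io import ORGANS, manifest_frame, read_manifest, read_spectrum, write_table

logger = logging.getLogger("zframan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serialisable to/from YAML.

    Unknown keys in a config file are rejected fail-fast.
    """

    input_dir: str = "."
    manifest: str = "manifest.csv"
    output_dir: str = "out"
    simulate: bool = False
    seed: int = 0
    organs: list[str] = field(default_factory=lambda: list(ORGANS))
    # deconvolution
    background_kind: str = "polynomial"
    background_degree: int = 3
    prominence_k: float = 5.0
    max_bands: int = 40
    min_amplitude: float = 1e-6
    merge_cm1: float = 5.0
    restarts: int = 3
    # band registry
    delta: float = 10.0
    threshold: float = 0.60
    window_size: int = 1
    # features / PLS
    collapse: str = "max_area"
    pls_mode: str = "plsda"
    q2_gain: float = 0.01
    projection: str = "covariance"
    module_definition: str = "norm"
    normalise_modules: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def fit_config(self) -> deconv.FitConfig:
        return deconv.FitConfig(
            background_kind=self.background_kind,
            background_degree=self.background_degree,
            prominence_k=self.prominence_k,
            max_bands=self.max_bands,
            min_amplitude=self.min_amplitude,
            merge_cm1=self.merge_cm1,
            restarts=self.restarts,
            seed=self.seed,
        )


def _setup_log(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the per-organ outputs under ``output_dir``.

    Writes fit_report.csv, registry.csv, presence.csv, retained.csv,
    annotations.csv, then per organ features_<organ>.csv,
    pls_report_<organ>.csv and fingerprint_<organ>.csv, plus run.log and the
    effective config.  A failure leaves partial outputs and a FAILED marker
    naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out)
    config.to_yaml(out / "config_used.yaml")
    stage = "setup"
    t0 = time.time()
    try:
        stage = "load"
        if config.simulate:
            logger.info("simulating default dataset (seed=%d)", config.seed)
            ds = synth.simulate_dataset(seed=config.seed, organs=tuple(config.organs))
            spectra = ds.spectra
            manifest = ds.manifest
            ds.write(Path(config.input_dir))
        else:
            meta_map = read_manifest(Path(config.manifest))
            manifest = manifest_frame(meta_map)
            spectra = []
            for fname, meta in meta_map.items():
                if meta.organ not in config.organs:
                    continue
                fpath = Path(config.input_dir) / fname
                if not fpath.exists():
                    fpath2 = Path(config.input_dir) / "spectra" / fname
                    if fpath2.exists():
                        fpath = fpath2
                    else:
                        raise PipelineError(
                            f"stage load: manifest references missing file {fname}"
                        )
                spectra.append(read_spectrum(fpath, meta))
            manifest = manifest[manifest["organ"].isin(config.organs)]
        logger.info("loaded %d spectra", len(spectra))

        stage = "fit"
        comp = deconv.fit_dataset(spectra, config.fit_config())
        write_table(comp, out / "fit_report.csv")
        logger.info(
            "deconvolution: %d components over %d spectra (%.1f s)",
            int(comp["F"].notna().sum()), len(spectra), time.time() - t0,
        )

        stage = "registry"
        registry, labelled = bands_mod.cluster_band_frequencies(comp, config.delta)
        write_table(bands_mod.registry_frame(registry), out / "registry.csv")
        presence = bands_mod.presence_table(labelled, manifest)
        write_table(presence, out / "presence.csv")
        retained = bands_mod.retain_bands(presence, config.threshold, config.window_size)
        write_table(bands_mod.retained_frame(retained), out / "retained.csv")
        all_retained = sorted(
            {b for bs in retained.values() for b in bs}, key=float
        )
        write_table(bands_mod.annotation_frame(all_retained), out / "annotations.csv")
        logger.info(
            "registry: %d bands, %d retained overall", len(registry), len(all_retained)
        )

        for organ in config.organs:
            if organ not in retained or not retained[organ]:
                logger.warning("no retained bands for %s; skipping", organ)
                continue
            stage = f"features[{organ}]"
            mat = features.build_features(
                labelled, retained, organ, manifest, collapse=config.collapse
            )
            write_table(mat, out / f"features_{organ}.csv")

            stage = f"fingerprint[{organ}]"
            X, y, groups = features.split_features(mat)
            est = pls.PLSFingerprint(
                q2_gain=config.q2_gain,
                projection=config.projection,
                module=config.module_definition,
                normalise_modules=config.normalise_modules,
                mode=config.pls_mode,
            ).fit(X, y, groups)
            table = est.fingerprint_table(organ)
            write_table(table.to_frame(), out / f"fingerprint_{organ}.csv")
            report = pd.DataFrame(
                {
                    "component": range(1, len(est.r2_) + 1),
                    "r2_cum": est.r2_,
                    "q2": est.q2_,
                }
            )
            report["selected_components"] = est.n_components_
            write_table(report, out / f"pls_report_{organ}.csv")
            logger.info(
                "%s: A*=%d, R2=%.3f, Q2=%.3f, top descriptor %s",
                organ, est.n_components_,
                est.r2_[est.n_components_ - 1] if len(est.r2_) else float("nan"),
                est.q2_[est.n_components_ - 1] if len(est.q2_) else float("nan"),
                est.modules_.index[0],
            )
        logger.info("pipeline done in %.1f s", time.time() - t0)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
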