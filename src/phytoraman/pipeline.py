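"""End-to-end monitoring workflow: simulate/read -> preprocess -> QC ->
band kinetics -> PCA -> Kruskal-Wallis, with all artifacts written as
delimiter-separated text plus a JSON run manifest.

Identical configuration and seed produce byte-identical numeric tables.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .bands import kinetic_series
from .chemometrics import kruskal_wallis, pairwise_rank_comparison, pca
from .preprocess import PreprocessParams, preprocess
from .qc import correlation_map, repeatability, similarity_to_reference
from .simulate import SimulationConfig, default_config, simulate
from .spectra import SpectraSet

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenario: str | None = "pilot"
    simulation: SimulationConfig | None = None   # overrides scenario if given
    input_path: str | None = None                # read spectra instead of simulating
    preprocess_params: PreprocessParams = field(default_factory=PreprocessParams)
    reference_day: int = 0
    pool_sessions: bool = True
    band_quantities: tuple[str, ...] = (
        "carotenoid_1524",
        "lipid_1660",
        "unsaturation_index",
        "carotenoid_ratio",
    )
    half_window: float = 8.0
    pca_components: int = 3
    kw_alpha: float = 0.05
    kw_pairs: str = "adjacent"
    seed: int = 0
    out_dir: str = "phytoraman_run"

    def resolve_simulation(self) -> SimulationConfig | None:
        if self.input_path is not None:
            return None
        if self.simulation is not None:
            return self.simulation
        return default_config(self.scenario or "pilot", seed=self.seed)


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    lines = [f"# {k}={v}" for k, v in provenance.items()]
    lines.append(df.to_csv(index=False, float_format=_FLOAT_FMT).rstrip("\n"))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write every artifact under ``out_dir``.

    Returns a bundle dict with the in-memory results and the manifest.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed}
    bundle: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is None:
                    logger.info("stage %s done in %.2fs", name, timings[name])
                else:
                    logger.error("stage %s failed: %s", name, exc)

        return _Timer()

    sim_config = config.resolve_simulation()
    if sim_config is not None:
        sim_dict = pio.config_to_dict(sim_config)
        provenance = {"seed": sim_config.seed, "config": pio.config_hash(sim_dict)}
        manifest["simulation"] = {
            "scenario": config.scenario,
            "config_hash": provenance["config"],
            "n_spectra": sim_config.n_spectra,
        }
        with stage("simulate"):
            raw = simulate(sim_config)
        pio.write_config(sim_config, out_dir / "simulation_config.yaml")
    else:
        provenance = {"seed": config.seed, "input": config.input_path}
        with stage("read"):
            raw = pio.read_spectra(config.input_path)
        manifest["input"] = {"path": config.input_path, "n_spectra": raw.n_spectra}
    manifest["n_spectra"] = raw.n_spectra
    pio.write_spectra(raw, out_dir / "spectra_raw.csv", provenance)
    bundle["raw"] = raw

    with stage("preprocess"):
        pre = preprocess(raw, config.preprocess_params)
    pio.write_spectra(pre, out_dir / "spectra_preprocessed.csv", provenance)
    bundle["preprocessed"] = pre

    with stage("qc"):
        cm = correlation_map(pre)
        rep = repeatability(pre, pool_sessions=config.pool_sessions)
        sim_series = similarity_to_reference(
            pre, reference_day=config.reference_day, pool_sessions=config.pool_sessions
        )
    np.savetxt(
        out_dir / "qc_correlation_map.csv",
        cm.matrix,
        fmt=_FLOAT_FMT,
        delimiter=",",
        header=",".join(cm.ids),
        comments="# ",
    )
    _write_table(rep, out_dir / "qc_repeatability.csv", provenance)
    _write_table(sim_series, out_dir / "qc_similarity.csv", provenance)
    bundle["correlation_map"] = cm
    bundle["repeatability"] = rep
    bundle["similarity"] = sim_series

    with stage("bands"):
        kinetics = {
            q: kinetic_series(pre, q, half_window=config.half_window)
            for q in config.band_quantities
        }
    for q, table in kinetics.items():
        _write_table(table, out_dir / f"band_kinetics_{q}.csv", provenance)
    bundle["kinetics"] = kinetics

    with stage("pca"):
        pca_result = pca(pre, k=config.pca_components)
    _write_table(pca_result.scores_table(), out_dir / "pca_scores.csv", provenance)
    loadings = pd.DataFrame(
        pca_result.loadings.T,
        columns=[f"PC{j + 1}" for j in range(pca_result.loadings.shape[0])],
    )
    loadings.insert(0, "wavenumber", pre.axis)
    _write_table(loadings, out_dir / "pca_loadings.csv", provenance)
    variance = pd.DataFrame(
        {
            "component": [f"PC{j + 1}" for j in range(pca_result.explained_fraction.size)],
            "explained_fraction": pca_result.explained_fraction,
        }
    )
    _write_table(variance, out_dir / "pca_variance.csv", provenance)
    bundle["pca"] = pca_result

    with stage("kruskal_wallis"):
        kw = kruskal_wallis(pca_result.scores[:, 0], pre.meta["day"].to_numpy())
        pairwise = pairwise_rank_comparison(kw, alpha=config.kw_alpha, pairs=config.kw_pairs)
    _write_table(kw.group_stats, out_dir / "kw_groups.csv", provenance)
    _write_table(pairwise, out_dir / "kw_pairwise.csv", provenance)
    bundle["kw"] = kw
    bundle["kw_pairwise"] = pairwise

    manifest["kw"] = {"H": kw.H, "p_value": kw.p_value}
    manifest["explained_fraction"] = [float(v) for v in pca_result.explained_fraction]
    manifest["stage_timings_s"] = timings
    manifest["versions"] = _versions()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    bundle["manifest"] = manifest
    return bundle


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "phytoraman": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
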