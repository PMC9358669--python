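"""End-to-end screen orchestration.

``run_screen`` wires the stages together: read the native and metabolomics
runs, deconvolve the native scans into neutral-mass traces, detect
features on both sides, match complexes to ligands by delta-mass and
retention time, build the combined molecular/binding network, and write a
reproducible artifact bundle (feature tables, match table, GraphML
network, QC report).  The pipeline is a pure function of its inputs and
configuration; repeated runs produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from nativemet import deconvolution as deconv
from nativemet import features as feat
from nativemet import io as msio
from nativemet import matching as cmatch
from nativemet import networking as net

logger = logging.getLogger("nativemet")

__all__ = ["PipelineConfig", "PipelineError", "run_screen"]


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    """All knobs of one screen, with the screening defaults."""

    native_mzml: str = ""
    metabolomics_mzml: str = ""
    output_dir: str = "nativemet_out"
    apo_mass: float | None = None  # None -> autodetect

    # deconvolution
    charge_range: tuple[int, int] = (5, 25)
    peak_tol_ppm: float = 10.0
    min_charge_support: int = 3
    trace_window: float = 5.0
    trace_min_scans: int = 3

    # feature finding
    min_height_native: float = 0.0
    min_height_metabolomics: float = 0.0
    min_width: float = 0.05
    smoothing: int = 5
    mz_tol_ppm: float = 10.0

    # matching
    mass_tol: float = 4.0
    rt_tol: float = 0.2
    max_stoichiometry: int = 2

    # networking
    score_threshold: float = 0.7
    min_matched: int = 6
    top_k: int = 10
    frag_tol: float = 0.02

    seed: int = 0
    log_level: str = "INFO"
    qc_plot: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.charge_range, list):
            cfg.charge_range = tuple(cfg.charge_range)
        return cfg

    def validate(self) -> None:
        if self.mass_tol <= 0 or self.rt_tol <= 0:
            raise PipelineError("config: tolerances must be positive")
        for name in ("native_mzml", "metabolomics_mzml"):
            p = getattr(self, name)
            if not p:
                raise PipelineError(f"config: {name} not set")
            if not Path(p).exists():
                raise PipelineError(f"config: {name} path does not exist: {p}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - name the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("deconvolution")
def _native_side(config: PipelineConfig, run: msio.Run):
    species = deconv.deconvolve_run(
        run,
        charge_range=config.charge_range,
        peak_tol=config.peak_tol_ppm,
        min_charge_support=config.min_charge_support,
    )
    traces = deconv.build_mass_traces(
        run,
        window=config.trace_window,
        min_scans=config.trace_min_scans,
        species_per_scan=species,
    )
    protein_features = feat.build_protein_features(
        traces,
        min_height=config.min_height_native,
        min_width=config.min_width,
        smoothing=config.smoothing,
    )
    return species, traces, protein_features


@_stage("feature_finding")
def _metabolite_side(config: PipelineConfig, run: msio.Run):
    return feat.build_metabolite_features(
        run,
        mz_tol=config.mz_tol_ppm,
        min_height=config.min_height_metabolomics,
        min_width=config.min_width,
        smoothing=config.smoothing,
    )


@_stage("matching")
def _match_stage(config, protein_features, metabolite_features, apo_mass):
    return cmatch.match(
        protein_features,
        metabolite_features,
        apo_mass=apo_mass,
        mass_tol=config.mass_tol,
        rt_tol=config.rt_tol,
        max_stoichiometry=config.max_stoichiometry,
    )


@_stage("networking")
def _network_stage(config, metabolite_features, spectra, matches, apo_mass):
    return net.build_network(
        metabolite_features,
        spectra,
        matches=matches,
        score_threshold=config.score_threshold,
        min_matched=config.min_matched,
        top_k=config.top_k,
        frag_tol=config.frag_tol,
        apo_mass=apo_mass,
    )


def run_screen(config: PipelineConfig) -> dict:
    """Run the full screen; returns a dict of output paths and summaries."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    native_run = msio.read_mzml(config.native_mzml)
    metab_run = msio.read_mzml(config.metabolomics_mzml)

    species, traces, protein_features = _native_side(config, native_run)
    metabolite_features, ms2_spectra = _metabolite_side(config, metab_run)

    if config.apo_mass is not None:
        apo_mass = config.apo_mass
    else:
        apo_mass = cmatch.apo_autodetect(protein_features)
        logger.info("autodetected apo mass: %.2f Da", apo_mass)

    matches = _match_stage(config, protein_features, metabolite_features, apo_mass)
    network = _network_stage(
        config, metabolite_features, ms2_spectra, matches, apo_mass
    )

    # --- artifact bundle
    prot_csv = outdir / "protein_features.csv"
    met_csv = outdir / "metabolite_features.csv"
    match_csv = outdir / "matches.csv"
    graphml = outdir / "network.graphml"
    msio.write_feature_csv(feat.features_to_table(protein_features), prot_csv)
    msio.write_feature_csv(feat.features_to_table(metabolite_features), met_csv)
    cmatch.matches_to_table(matches).to_csv(
        match_csv, index=False, float_format="%.6f"
    )
    msio.write_graphml(network, graphml)

    rt, apo_xic = deconv.extract_xic(
        native_run, apo_mass, config.trace_window, species_per_scan=species
    )
    depletion = deconv.detect_apo_depletion(rt, apo_xic)
    xic_csv = outdir / "apo_xic.csv"
    np.savetxt(
        xic_csv,
        np.column_stack([rt, apo_xic]),
        delimiter=",",
        header="rt_min,intensity",
        comments="",
        fmt="%.6f",
    )

    components = network.components()
    qc = {
        "apo_mass": float(apo_mass),
        "n_native_scans": len(native_run.ms1()),
        "n_mass_traces": len(traces),
        "n_protein_features": len(protein_features),
        "n_metabolite_features": len(metabolite_features),
        "n_matches": len(matches),
        "n_unique_bound_ligands": len({m.metabolite_feature_id for m in matches}),
        "n_depletion_events": len(depletion),
        "depletion_events": [
            {"rt_min": rt_, "depth_frac": d_} for rt_, d_ in depletion
        ],
        "network_components": sorted(
            (len(c) for c in components), reverse=True
        ),
        "n_msms_edges": len(network.edges_of_type("msms")),
        "n_binding_edges": len(network.edges_of_type("binding")),
    }
    qc_json = outdir / "qc_report.json"
    qc_json.write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n")

    if config.qc_plot:
        _qc_plot(rt, apo_xic, depletion, outdir / "apo_xic.png")

    return {
        "protein_features": str(prot_csv),
        "metabolite_features": str(met_csv),
        "matches": str(match_csv),
        "network": str(graphml),
        "apo_xic": str(xic_csv),
        "qc_report": str(qc_json),
        "qc": qc,
    }


def _qc_plot(rt, xic, depletion, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(rt, xic, lw=0.8, color="k", label="apo XIC")
    for rt_, depth in depletion:
        ax.axvline(rt_, color="r", ls="--", alpha=0.5)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("deconvoluted intensity")
    ax.set_title("Apo-protein XIC with depletion calls")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
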