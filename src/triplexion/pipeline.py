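"""End-to-end orchestration: configuration, staged execution, reporting.

``run_pipeline`` executes scan -> TFO design -> affinity (Tm and EMSA
routes) -> kinetics rates/modulation -> helix geometry -> strain-peak
fit on whatever inputs are available (simulated from the scenario seed
by default), skipping stages without inputs with a logged warning, and
``write_report`` emits a deterministic file set of TSV tables plus the
peak-fit JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import affinity_analysis as aff
from . import kinetics_modulation as kin
from . import sequence_screen as seq
from . import synthetic_data as syn
from . import triplex_geometry as geo

logger = logging.getLogger("triplexion")

STRAIN_METRICS = ("L1", "L2", "dL", "L3")


@dataclass
class RunConfig:
    """Flat run configuration; CLI flags override these, these override
    defaults.  Unknown keys in a config file are rejected."""

    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "triplexion_out"
    simulate: bool = True
    keep_going: bool = False
    # scan
    min_length: int = 15
    max_pyrimidine_fraction: float = 0.10
    max_consecutive_interruptions: int = 1
    proximity_margin: int = 20
    # affinity
    window: int = 9
    polyorder: int = 2
    min_prominence: float = 0.05
    # kinetics
    mode: str = "transcription"
    window_start: float | None = None
    # geometry / strain fit
    atom: str = "C1'"
    pairs: str = "all"
    metric: str = "L1"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def echo(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.echo().encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    tts: list = field(default_factory=list)            # TTSCandidate
    tfos: list = field(default_factory=list)           # TFODesign
    kd_tm: dict = field(default_factory=dict)          # label -> KdEstimate
    kd_emsa: dict = field(default_factory=dict)
    modulation: list = field(default_factory=list)     # (template, tfo, ModulationResult)
    geometry: dict = field(default_factory=dict)       # id -> GeometryMetrics
    strain_fits: dict = field(default_factory=dict)    # metric -> PeakFit
    warnings: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, scenario: syn.SyntheticScenario | None = None) -> RunReport:
    """Run all stages on a synthetic scenario (or default scenario).

    Stage failures abort unless ``config.keep_going`` is set, in which
    case the stage is recorded as skipped and downstream stages run on
    whatever inputs remain.
    """
    if scenario is None:
        scenario = syn.SyntheticScenario(seed=config.seed)
    report = RunReport(config_hash=config.digest())

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            if not config.keep_going:
                raise
            msg = f"stage {name} skipped: {exc}"
            logger.warning(msg)
            report.skipped.append(name)
            report.warnings.append(msg)
        finally:
            report.timings[name] = time.perf_counter() - t0

    def do_scan():
        params = seq.ScanParams(
            min_length=config.min_length,
            max_pyrimidine_fraction=config.max_pyrimidine_fraction,
            max_consecutive_interruptions=config.max_consecutive_interruptions,
            proximity_margin=config.proximity_margin,
        )
        promoter = syn.gen_promoter(scenario.promoter, scenario.seed)
        report.tts = seq.scan_tts(promoter, params)
        for tts in report.tts:
            for motif in ("purine", "pyrimidine"):
                report.tfos.append(seq.design_tfo(tts, motif))

    def do_affinity():
        curves = syn.gen_melt_titration(scenario.melt, scenario.seed)
        try:
            report.kd_tm["synthetic"] = aff.estimate_kd_tm(
                curves, window=config.window, polyorder=config.polyorder,
                min_prominence_frac=config.min_prominence,
            )
        except aff.NoStableTriplexError as exc:
            report.warnings.append(f"melt titration: no stable triplex ({exc})")
        lanes = syn.gen_gel_lanes(scenario.gel, scenario.seed)
        try:
            report.kd_emsa["synthetic"] = aff.estimate_kd_emsa(lanes)
        except aff.NoStableTriplexError as exc:
            report.warnings.append(f"EMSA titration: no stable triplex ({exc})")

    def do_kinetics():
        ref = syn.gen_kinetic_traces(
            dataclasses.replace(scenario.kinetics, modulation_multiplier=1.0),
            scenario.seed, condition="no_tfo_reference")
        sample = syn.gen_kinetic_traces(scenario.kinetics, scenario.seed + 1)
        def rates(traces):
            out = []
            for tr in traces:
                w = kin.select_window(tr, config.mode, config.window_start)
                out.append(kin.fit_rate(tr, w))
            return out
        report.modulation = [
            ("synthetic", "purine", kin.modulation(rates(sample), rates(ref)))
        ]

    def do_geometry():
        structure = syn.gen_helix(scenario.helix, scenario.seed)
        report.geometry["synthetic"] = geo.compute_metrics(
            structure, atom_selection=config.atom, pairs=config.pairs)

    def do_strain():
        points = syn.gen_strain_points(scenario.strain, scenario.seed)
        try:
            report.strain_fits[config.metric] = geo.fit_strain_modulation(points)
        except geo.NoPeakError as exc:
            report.warnings.append(f"strain fit: no peak ({exc})")

    stage("scan", do_scan)
    stage("affinity", do_affinity)
    stage("kinetics", do_kinetics)
    stage("geometry", do_geometry)
    stage("strain_fit", do_strain)
    return report


def fit_strain_all_metrics(
    metrics: dict[str, geo.GeometryMetrics],
    modulations: dict[str, float],
) -> dict[str, geo.PeakFit]:
    """Fit the strain-peak model for every distance metric that yields a
    proper interior peak; metrics with monotone fits are omitted."""
    fits: dict[str, geo.PeakFit] = {}
    for metric in STRAIN_METRICS:
        points = geo.assemble_strain_points(metrics, modulations, metric=metric)
        try:
            fits[metric] = geo.fit_strain_modulation(points)
        except geo.NoPeakError:
            continue
    return fits


def best_strain_fit(fits: dict[str, geo.PeakFit]) -> tuple[str, geo.PeakFit]:
    """Best-fitting metric by residual sum of squares."""
    if not fits:
        raise geo.NoPeakError("no metric produced an interior peak")
    metric = min(sorted(fits), key=lambda m: fits[m].rss)
    return metric, fits[metric]


def write_report(report: RunReport, out_dir: str | Path, config: RunConfig | None = None) -> list[Path]:
    """Write the deterministic report file set; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "tts.tsv"
    seq.write_tts_tsv(report.tts, p)
    written.append(p)

    p = out / "tfo.fasta"
    seq.write_tfo_fasta(report.tfos, p)
    written.append(p)

    for name, table in (("kd_tm.tsv", report.kd_tm), ("kd_emsa.tsv", report.kd_emsa)):
        p = out / name
        with open(p, "w") as fh:
            fh.write("label\tkd_uM\tstderr_uM\tmethod\thill\n")
            for label in sorted(table):
                e = table[label]
                fh.write(f"{label}\t{e.kd:.4g}\t{e.stderr:.3g}\t{e.method}\t{e.fit.hill:.3g}\n")
        written.append(p)

    p = out / "modulation.tsv"
    kin.write_modulation_tsv(report.modulation, p)
    written.append(p)

    p = out / "geometry.tsv"
    geo.write_metrics_tsv(report.geometry, p)
    written.append(p)

    p = out / "strain_fit.json"
    payload = {m: geo.peak_fit_report(f) for m, f in sorted(report.strain_fits.items())}
    payload["warnings"] = sorted(report.warnings)
    p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(p)

    if config is not None:
        p = out / "config.echo"
        p.write_text(config.echo())
        written.append(p)
    return written


def setup_logging(level: str, out_dir: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True,
    )
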