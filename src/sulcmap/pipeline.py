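"""End-to-end orchestration: simulate a two-species cohort, run the
delineation/magnification/summary stages per hemisphere, aggregate group
tables and species x hemisphere ANOVAs, and write a deterministic,
manifest-indexed report bundle.

All randomness derives from the config seed; per-hemisphere seeds are
spawned deterministically, so the same config always yields byte-identical
result files (hash equality of manifests).  Failure of one subject is
isolated: the remaining subjects complete and the failure is recorded in
the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .delineate import delineate_v1
from .errors import ParameterError, SulcmapError
from .magnify import collect_samples, fit_cmf
from .metrics import summaries_frame, summarize_sulcus
from .stats import two_way_anova
from .synth import PRESETS, add_measurement_noise, generate_v1_patch

log = logging.getLogger(__name__)

SULCI = ("rCaS", "eCaS")


@dataclass
class NoiseConfig:
    angle_sd: float = 3.0
    log_ecc_sd: float = 0.10
    dropout_rate: float = 0.05


@dataclass
class CohortConfig:
    species: str
    n_subjects: int
    preset_overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Single document controlling a full pipeline run."""

    cohorts: list[CohortConfig] = field(default_factory=lambda: [
        CohortConfig("human", 4), CohortConfig("macaque", 3)])
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    resolution: float = 1.2
    tol_deg: float = 10.0
    foveal_quantile: float = 0.05
    fit_init: tuple[float, float] = (1.0, 0.05)
    histogram_fractions: tuple[float, ...] = (0.99, 0.75, 0.50, 0.25)
    measures: tuple[str, ...] = ("mean_ecc", "pct_of_v1")
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "cohorts" in doc:
            doc["cohorts"] = [CohortConfig(**c) for c in doc["cohorts"]]
        if "noise" in doc:
            doc["noise"] = NoiseConfig(**doc["noise"])
        for key in ("fit_init", "histogram_fractions", "measures"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> list[str]:
        """Collect every violation at once; empty list means valid."""
        problems = []
        if not self.cohorts:
            problems.append("config lists no cohorts")
        for c in self.cohorts:
            if c.species not in PRESETS:
                problems.append(f"unknown species {c.species!r}")
            if c.n_subjects < 1:
                problems.append(f"cohort {c.species!r}: n_subjects must be >= 1")
        if not (0 <= self.noise.dropout_rate < 1):
            problems.append("noise.dropout_rate must lie in [0, 1)")
        if self.noise.angle_sd < 0 or self.noise.log_ecc_sd < 0:
            problems.append("noise standard deviations must be >= 0")
        if self.resolution <= 0:
            problems.append("resolution must be positive")
        if not (0 <= self.seed < 2 ** 31):
            problems.append("seed must lie in [0, 2^31)")
        return problems


def subject_seed(base_seed: int, species: str, subject: int, hemi: str) -> int:
    """Deterministic per-hemisphere seed below 2^31."""
    key = f"{base_seed}:{species}:{subject}:{hemi}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


@dataclass
class HemisphereResult:
    subject_id: str
    species: str
    hemisphere: str
    fit: "object"
    summaries: list
    n_v1: int


def analyze_hemisphere(config: RunConfig, species: str, subject: int,
                       hemi: str) -> HemisphereResult:
    """Simulate one hemisphere and run it through the full analysis chain."""
    cohort = next(c for c in config.cohorts if c.species == species)
    preset = PRESETS[species](**cohort.preset_overrides)
    seed = subject_seed(config.seed, species, subject, hemi)
    subject_id = f"{species}{subject:03d}"
    pial, white, truth = generate_v1_patch(
        preset, resolution=config.resolution, seed=seed,
        hemisphere=hemi, subject_id=subject_id)
    rmap = add_measurement_noise(
        truth, angle_sd=config.noise.angle_sd,
        log_ecc_sd=config.noise.log_ecc_sd,
        dropout_rate=config.noise.dropout_rate, seed=seed)
    delineation = delineate_v1(rmap, pial, tol_deg=config.tol_deg,
                               foveal_quantile=config.foveal_quantile,
                               ecc_max=preset.stimulus_radius)
    samples = collect_samples(rmap, delineation, truth.labels, sulcus_names=SULCI)
    fit = fit_cmf(samples["d_hat"], samples["ecc"], init=config.fit_init)
    summaries = [summarize_sulcus(rmap, pial, white, truth.labels, delineation, s)
                 for s in SULCI if s in truth.labels]
    return HemisphereResult(subject_id=subject_id, species=species,
                            hemisphere=hemi, fit=fit, summaries=summaries,
                            n_v1=len(delineation.v1_vertices))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full cohort pipeline and write the report bundle.

    Returns the report dict (also written as JSON).  The bundle contains
    per-hemisphere fit records, the tidy summary table, group mean/SEM
    tables, one ANOVA per measure x sulcus, a failure list, and a manifest
    with a content hash for every artifact.
    """
    problems = config.validate()
    if problems:
        raise ParameterError("invalid config:\n- " + "\n- ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fits = []
    all_summaries = []
    failures = []
    for cohort in config.cohorts:
        for subject in range(cohort.n_subjects):
            for hemi in ("left", "right"):
                try:
                    res = analyze_hemisphere(config, cohort.species, subject, hemi)
                except SulcmapError as exc:
                    failures.append({"species": cohort.species, "subject": subject,
                                     "hemisphere": hemi, "error": str(exc)})
                    log.warning("subject %s/%d/%s failed: %s",
                                cohort.species, subject, hemi, exc)
                    continue
                fits.append({
                    "subject_id": res.subject_id, "species": res.species,
                    "hemisphere": res.hemisphere, "a": res.fit.a, "b": res.fit.b,
                    "r_squared": res.fit.r_squared, "sse": res.fit.sse,
                    "converged": res.fit.converged, "n_samples": res.fit.n_samples,
                    "n_v1": res.n_v1,
                })
                all_summaries.extend(res.summaries)

    summary_df = summaries_frame(all_summaries) if all_summaries else pd.DataFrame()
    summary_path = out / "sulcal_summaries.csv"
    summary_df.to_csv(summary_path, index=False)
    fits_path = out / "cmf_fits.json"
    fits_path.write_text(json.dumps(fits, indent=1, sort_keys=True))

    group_tables = {}
    anovas = {}
    if not summary_df.empty:
        from .stats import group_table
        for measure in config.measures:
            group_tables[measure] = group_table(summary_df, measure)
            for sulcus in SULCI:
                sub = summary_df[summary_df["sulcus"] == sulcus].dropna(
                    subset=[measure])
                key = f"{measure}:{sulcus}"
                try:
                    res = two_way_anova(sub[measure], sub["species"],
                                        sub["hemisphere"])
                except (ParameterError, KeyError) as exc:
                    anovas[key] = {"error": str(exc)}
                    continue
                anovas[key] = {
                    eff: dataclasses.asdict(res[eff])
                    for eff in ("species", "hemisphere", "interaction")
                }
                anovas[key]["grand_n"] = res.grand_n
                anovas[key]["ss_type"] = res.ss_type
        for measure, table in group_tables.items():
            table.to_csv(out / f"group_{measure}.csv", index=False)
    anova_path = out / "anova.json"
    anova_path.write_text(json.dumps(anovas, indent=1, sort_keys=True))

    report = {
        "config": _config_doc(config),
        "n_hemispheres": len(fits),
        "failures": failures,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    manifest = {"seed": config.seed, "files": {}}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report["manifest"] = manifest
    report["anovas"] = anovas
    report["summaries"] = summary_df
    report["fits"] = fits
    return report


def _config_doc(config: RunConfig) -> dict:
    doc = dataclasses.asdict(config)
    return json.loads(json.dumps(doc, default=list, sort_keys=True))


def write_subject_bundle(out_dir, pial, white, truth, rmap=None,
                         timeseries=None) -> list[str]:
    """Write one synthetic subject to disk (surfaces, overlays, labels,
    optional time series, and a generator-parameter sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(name, fn):
        fn(out / name)
        written.append(name)

    _w("pial.surf.gii", lambda p: sio.write_surface(pial, p, format="gifti"))
    _w("white.surf.gii", lambda p: sio.write_surface(white, p, format="gifti"))
    _w("true_polar_angle.csv",
       lambda p: sio.write_overlay(truth.true_map.polar_angle, p, format="csv"))
    _w("true_eccentricity.csv",
       lambda p: sio.write_overlay(truth.true_map.eccentricity, p, format="csv"))
    if rmap is not None:
        _w("polar_angle.csv", lambda p: sio.write_overlay(rmap.polar_angle, p,
                                                          format="csv"))
        _w("eccentricity.csv", lambda p: sio.write_overlay(rmap.eccentricity, p,
                                                           format="csv"))
    _w("labels.json", lambda p: sio.write_labels(truth.labels, p, format="json"))
    if timeseries is not None:
        _w("timeseries.csv",
           lambda p: pd.DataFrame(timeseries).to_csv(p, index=False, header=False))
    params = json.loads(json.dumps(truth.generator_params, default=list))
    _w("generator_params.json",
       lambda p: p.write_text(json.dumps(params, indent=1, sort_keys=True)))
    return written
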