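"""End-to-end cohort analysis.

For each animal: activity trace -> Long/Mid/Short classification ->
high/low-motility split -> residence-time extraction per period ->
power-law fit and MF-DFA spectrum per state x period -> cohort summary
tables (power-law exponents a, b and spectrum h_peak/width, mean +/- sd per
class/period/state with pairwise t-tests).  One animal's degenerate data
(e.g. a continuously swimming mutant-like trace) is recorded as a
per-animal error and does not abort the cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .activity import ActivityTimeSeries, classify_animal, split_motility_periods
from .errors import InputError, MFKineticsError
from .mfdfa import MFDFAConfig, analyze_residence_series
from .residence import extract_residence_times
from .scalefree import (ACTIVE_FIT_RANGE, INACTIVE_FIT_RANGE, fit_powerlaw,
                        residence_npd, summarize_groups)

logger = logging.getLogger("mfkinetics.pipeline")


@dataclass
class PipelineConfig:
    """Declarative configuration echoed verbatim into every output artifact."""

    dt: float = 0.05
    intensity_threshold: int = 12
    activity_threshold: float = 12.0
    aa_threshold: float = 0.75
    ratio_threshold: float = 0.01
    ratio_mode: str = "late_over_early"
    fit_range_active: tuple[float, float] = ACTIVE_FIT_RANGE
    fit_range_inactive: tuple[float, float] = INACTIVE_FIT_RANGE
    binning: str = "logarithmic"
    n_bins: int = 40
    boundary_policy: str = "drop_edges"
    q_min: float = -10.0
    q_max: float = 10.0
    n_q: int = 41
    s_min: int = 16
    n_scales: int = 20
    min_durations_mfdfa: int = 100
    high_motility_fraction_override: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.dt, self.activity_threshold, self.aa_threshold) <= 0:
            raise InputError("thresholds and dt must be positive")

    def mfdfa_config(self) -> MFDFAConfig:
        return MFDFAConfig(q_min=self.q_min, q_max=self.q_max, n_q=self.n_q,
                           s_min=self.s_min, n_scales=self.n_scales)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fit_range_active", "fit_range_inactive"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnimalResult:
    animal_id: str
    label: dict
    fits: dict = field(default_factory=dict)       # (period, state) -> fit dict
    spectra: dict = field(default_factory=dict)    # (period, state) -> spectrum dict
    error: Optional[str] = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        key = lambda k: f"{k[0]}/{k[1]}"
        return {"animal_id": self.animal_id, "label": self.label,
                "fits": {key(k): v for k, v in self.fits.items()},
                "spectra": {key(k): v for k, v in self.spectra.items()},
                "error": self.error, "notes": self.notes}


@dataclass
class ResultBundle:
    per_animal: dict
    summary_powerlaw: "object"         # pandas DataFrame
    comparisons_powerlaw: "object"
    summary_spectrum: "object"
    comparisons_spectrum: "object"
    config: PipelineConfig
    provenance: dict

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.per_animal.values() if r.error is not None)


def _analyze_animal(animal_id: str, series: ActivityTimeSeries,
                    config: PipelineConfig) -> AnimalResult:
    label = classify_animal(series, aa_threshold=config.aa_threshold,
                            ratio_threshold=config.ratio_threshold,
                            ratio_mode=config.ratio_mode)
    result = AnimalResult(animal_id=animal_id, label=dataclasses.asdict(label))
    high, low = split_motility_periods(
        series, label, fraction_override=config.high_motility_fraction_override)
    fit_ranges = {"active": config.fit_range_active,
                  "inactive": config.fit_range_inactive}
    for period, segment in (("high-motility", high), ("low-motility", low)):
        res = extract_residence_times(segment,
                                      activity_threshold=config.activity_threshold,
                                      boundary_policy=config.boundary_policy)
        for state in ("active", "inactive"):
            durations = res.active_durations if state == "active" \
                else res.inactive_durations
            tag = (period, state)
            try:
                npd = residence_npd(durations, binning=config.binning,
                                    n_bins=config.n_bins)
                fit = fit_powerlaw(npd, fit_range=fit_ranges[state])
                result.fits[tag] = dataclasses.asdict(fit)
            except MFKineticsError as exc:
                result.notes.append(f"{period}/{state}: power-law fit skipped ({exc})")
            if durations.size >= config.min_durations_mfdfa:
                try:
                    spec = analyze_residence_series(durations,
                                                    config=config.mfdfa_config())
                    result.spectra[tag] = spec.to_dict()
                except MFKineticsError as exc:
                    result.notes.append(f"{period}/{state}: MF-DFA skipped ({exc})")
            else:
                result.notes.append(
                    f"{period}/{state}: MF-DFA skipped "
                    f"({durations.size} < {config.min_durations_mfdfa} durations)")
    return result


def run_pipeline(inputs: Sequence[tuple[str, ActivityTimeSeries]],
                 config: Optional[PipelineConfig] = None,
                 out_dir=None) -> ResultBundle:
    """Run the full analysis for a cohort of (animal_id, activity) pairs.

    ``inputs`` may also contain (animal_id, path) pairs; CSV/HDF5 files are
    loaded via :mod:`mfkinetics.io`.  When ``out_dir`` is given, per-animal
    JSON, cohort CSV tables and a manifest are written there.
    """
    config = config or PipelineConfig()
    config.validate()
    if len(inputs) == 0:
        raise InputError("empty cohort")

    per_animal: dict[str, AnimalResult] = {}
    for animal_id, item in inputs:
        try:
            series = _coerce_series(item)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_animal[animal_id] = _analyze_animal(animal_id, series, config)
            logger.info("animal %s analyzed", animal_id)
        except (MFKineticsError, OSError) as exc:
            logger.warning("animal %s failed: %s", animal_id, exc)
            per_animal[animal_id] = AnimalResult(animal_id=animal_id, label={},
                                                 error=str(exc))
    if all(r.error is not None for r in per_animal.values()):
        raise InputError("every animal in the cohort failed")

    groups_fit: dict[str, list] = {}
    groups_spec: dict[str, list] = {}
    for r in per_animal.values():
        if r.error is not None:
            continue
        cls = r.label.get("activity_class", "?")
        for (period, state), fit in r.fits.items():
            groups_fit.setdefault(f"{cls}/{period}/{state}", []).append(
                {"a": fit["a"], "b": fit["b"]})
        for (period, state), spec in r.spectra.items():
            groups_spec.setdefault(f"{cls}/{period}/{state}", []).append(
                {"h_peak": spec["h_peak"], "width": spec["width"]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sum_fit, cmp_fit = summarize_groups(groups_fit) if groups_fit \
            else (None, None)
        sum_spec, cmp_spec = summarize_groups(groups_spec) if groups_spec \
            else (None, None)

    bundle = ResultBundle(per_animal=per_animal,
                          summary_powerlaw=sum_fit, comparisons_powerlaw=cmp_fit,
                          summary_spectrum=sum_spec, comparisons_spectrum=cmp_spec,
                          config=config,
                          provenance={"config_hash": config.hash(),
                                      "package_version": __version__,
                                      "n_animals": len(per_animal)})
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _coerce_series(item) -> ActivityTimeSeries:
    if isinstance(item, ActivityTimeSeries):
        return item
    path = Path(item)
    from . import io as mfio
    if path.suffix in (".h5", ".hdf5"):
        return mfio.read_activity_hdf5(path)
    if path.suffix == ".csv":
        return mfio.read_activity_csv(path)
    raise InputError(f"unreadable input: {item!r}")


def _write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    import time
    out_dir.mkdir(parents=True, exist_ok=True)
    for animal_id, res in bundle.per_animal.items():
        path = out_dir / f"animal_{animal_id}.json"
        path.write_text(json.dumps(res.to_dict(), indent=1, sort_keys=True))
    for name, table in (("powerlaw_summary", bundle.summary_powerlaw),
                        ("powerlaw_comparisons", bundle.comparisons_powerlaw),
                        ("spectrum_summary", bundle.summary_spectrum),
                        ("spectrum_comparisons", bundle.comparisons_spectrum)):
        if table is not None and len(table):
            table.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {"provenance": bundle.provenance,
                "config": bundle.config.to_dict(),
                "animals": sorted(bundle.per_animal),
                "created": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=list))
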