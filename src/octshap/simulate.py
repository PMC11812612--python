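"""Synthetic bilateral posterior-pole cohorts with planted group effects.

Real posterior-pole OCT case-control datasets of this kind are typically
not publicly deposited, so the pipeline is exercised on simulated cohorts
that carry the statistical structure the analysis assumes:

* a per-layer baseline thickness shared by both eyes of a subject,
* a between-subject bilateral random offset (global biological variability),
* per-zone bilateral random offsets (topographic variability: subjects
  differ locally, not only in overall thickness, so contrasts between
  zones of the same layer do not cancel subject variability exactly),
* zone-localised thinning in patients (the planted group effect),
* a signed inter-eye offset split +/- between the two eyes (asymmetry,
  larger in patients so inter-eye difference features carry signal),
* i.i.d. per-cell measurement noise.

All generative distributions are Gaussian -- the simplest model carrying
that structure.  Only the three directly segmented layers are simulated;
the inner retinal complex (mIRL) is always derived downstream as their
cellwise sum, never simulated independently.

The default configuration emulates a cohort of 79 patients and 69 controls
with thinning concentrated in the ganglion-cell and nerve-fibre layers of
the papillomacular bundle and supero-temporal quadrant.  Baseline and
effect magnitudes are package conventions chosen to be anatomically
plausible; they are not estimates of any clinical population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .zones import (
    BASE_LAYERS,
    EYES,
    GRID_SHAPE,
    GridScan,
    ZoneMap,
    ZONES,
    default_zone_map,
    mirror_zone_map,
)

GROUPS = ("patient", "control")


class ConfigError(ValueError):
    """A cohort configuration field violates its constraints."""


class CohortParseError(ValueError):
    """A cohort CSV is malformed or incomplete."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Thicknesses and all standard deviations are in micrometres.
    ``effect_um[(layer, zone)]`` is the thinning subtracted from every cell
    of that zone in patients' grids of that layer.
    """

    n_patients: int = 79
    n_controls: int = 69
    baseline_um: dict[str, float] = field(
        default_factory=lambda: {"mRNFL": 30.0, "mGCL": 42.0, "mIPL": 36.0}
    )
    effect_um: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("mGCL", 2): 4.0,
            ("mGCL", 6): 3.0,
            ("mRNFL", 2): 3.0,
            ("mRNFL", 6): 2.0,
            ("mIPL", 2): 1.5,
        }
    )
    subject_sd_um: float = 6.0
    local_sd_um: float = 3.0
    asym_sd_um: dict[str, float] = field(
        default_factory=lambda: {"patient": 2.0, "control": 1.0}
    )
    noise_sd_um: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.n_controls < 1:
            raise ConfigError("n_controls must be >= 1")
        if set(self.baseline_um) != set(BASE_LAYERS):
            raise ConfigError(f"baseline_um must cover exactly {BASE_LAYERS}")
        for layer, value in self.baseline_um.items():
            if not value > 0:
                raise ConfigError(f"baseline_um[{layer}] must be > 0")
        for (layer, zone), value in self.effect_um.items():
            if layer not in BASE_LAYERS:
                raise ConfigError(f"effect_um layer {layer!r} not in {BASE_LAYERS}")
            if zone not in ZONES:
                raise ConfigError(f"effect_um zone {zone} not in {ZONES}")
            if value < 0:
                raise ConfigError(f"effect_um[{layer}, {zone}] must be >= 0")
            if value >= self.baseline_um[layer]:
                raise ConfigError(
                    f"effect_um[{layer}, {zone}] must stay below the "
                    f"{layer} baseline so expected thickness remains positive"
                )
        if self.subject_sd_um < 0:
            raise ConfigError("subject_sd_um must be >= 0")
        if self.local_sd_um < 0:
            raise ConfigError("local_sd_um must be >= 0")
        if self.noise_sd_um < 0:
            raise ConfigError("noise_sd_um must be >= 0")
        if set(self.asym_sd_um) != set(GROUPS):
            raise ConfigError(f"asym_sd_um must cover exactly {GROUPS}")
        for group, value in self.asym_sd_um.items():
            if value < 0:
                raise ConfigError(f"asym_sd_um[{group}] must be >= 0")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's six base-layer grids (2 eyes x 3 layers) plus label."""

    subject_id: str
    group: str
    scans: dict[tuple[str, str], GridScan]  # (eye, layer) -> grid

    def __post_init__(self) -> None:
        expected = {(e, l) for e in EYES for l in BASE_LAYERS}
        if set(self.scans) != expected:
            missing = sorted(expected - set(self.scans))
            raise CohortParseError(
                f"subject {self.subject_id}: missing grids {missing}"
            )
        if self.group not in GROUPS:
            raise CohortParseError(
                f"subject {self.subject_id}: group must be one of {GROUPS}"
            )


def generate_cohort(
    config: CohortConfig, zone_map: ZoneMap | None = None
) -> list[SubjectRecord]:
    """Draw a synthetic cohort; fully determined by ``config`` (incl. seed).

    Patients come first (P0001..), then controls (C0001..).  For each
    subject and layer the bilateral latent field is baseline + a shared
    subject offset + a per-zone offset field; patient zones lose
    ``effect_um`` (zone membership via the right-eye zone map, mirrored
    for the left eye); each eye then adds half of a signed inter-eye
    offset (OD +d/2, OS -d/2) and independent cell noise.
    """
    zone_map = zone_map or default_zone_map()
    zone_map_by_eye = {"OD": zone_map, "OS": mirror_zone_map(zone_map)}
    rng = np.random.default_rng(config.seed)

    effect_field = {}  # (layer, eye) -> 8x8 thinning field for patients
    for layer in BASE_LAYERS:
        od = np.zeros(GRID_SHAPE)
        for (eff_layer, zone), magnitude in sorted(config.effect_um.items()):
            if eff_layer == layer:
                od[zone_map.members(zone)] -= magnitude
        effect_field[(layer, "OD")] = od
        effect_field[(layer, "OS")] = od[:, ::-1]

    records = []
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    counters = {"patient": 0, "control": 0}
    for group in groups:
        counters[group] += 1
        subject_id = f"{'P' if group == 'patient' else 'C'}{counters[group]:04d}"
        scans = {}
        for layer in BASE_LAYERS:
            shared = config.baseline_um[layer] + rng.normal(0.0, config.subject_sd_um)
            zone_offsets = rng.normal(0.0, config.local_sd_um, size=len(ZONES))
            local_od = np.zeros(GRID_SHAPE)
            for z, offset in zip(ZONES, zone_offsets):
                local_od[zone_map.members(z)] += offset
            local = {"OD": local_od, "OS": local_od[:, ::-1]}
            asym = rng.normal(0.0, config.asym_sd_um[group])
            for eye, half in (("OD", +0.5), ("OS", -0.5)):
                cells = np.full(GRID_SHAPE, shared) + local[eye]
                if group == "patient":
                    cells = cells + effect_field[(layer, eye)]
                cells = cells + half * asym
                cells = cells + rng.normal(0.0, config.noise_sd_um, size=GRID_SHAPE)
                scans[(eye, layer)] = GridScan(subject_id, eye, layer, cells)
        records.append(SubjectRecord(subject_id, group, scans))
    return records


# ---------------------------------------------------------------------------
# long-format cohort CSV I/O
# columns: subject_id, group, eye, layer, row, col, thickness_um (row/col 1-based)

def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for eye in EYES:
            for layer in BASE_LAYERS:
                cells = rec.scans[(eye, layer)].cells
                for r in range(8):
                    for c in range(8):
                        rows.append(
                            (rec.subject_id, rec.group, eye, layer, r + 1, c + 1, cells[r, c])
                        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "eye", "layer", "row", "col", "thickness_um"],
    )


def write_cohort(records: list[SubjectRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Parse a long-format cohort CSV, validating completeness.

    Raises :class:`CohortParseError` naming the first missing or duplicated
    (subject, eye, layer, row, col) cell.
    """
    frame = pd.read_csv(path)
    required = {"subject_id", "group", "eye", "layer", "row", "col", "thickness_um"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise CohortParseError(f"cohort CSV missing columns {sorted(missing_cols)}")
    return cohort_from_frame(frame)


def cohort_from_frame(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for subject_id, sub in frame.groupby("subject_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise CohortParseError(f"subject {subject_id}: conflicting group labels")
        scans = {}
        for eye in EYES:
            for layer in BASE_LAYERS:
                cells = np.full(GRID_SHAPE, np.nan)
                sel = sub[(sub["eye"] == eye) & (sub["layer"] == layer)]
                for _, row in sel.iterrows():
                    r, c = int(row["row"]) - 1, int(row["col"]) - 1
                    if not (0 <= r < 8 and 0 <= c < 8):
                        raise CohortParseError(
                            f"{subject_id}/{eye}/{layer}: cell "
                            f"({row['row']}, {row['col']}) outside the 8x8 grid"
                        )
                    if not np.isnan(cells[r, c]):
                        raise CohortParseError(
                            f"{subject_id}/{eye}/{layer}: duplicate cell ({r + 1}, {c + 1})"
                        )
                    cells[r, c] = row["thickness_um"]
                holes = np.argwhere(np.isnan(cells))
                if len(holes):
                    r, c = holes[0]
                    raise CohortParseError(
                        f"{subject_id}/{eye}/{layer}: missing cell ({r + 1}, {c + 1})"
                    )
                scans[(eye, layer)] = GridScan(subject_id, eye, layer, cells)
        records.append(SubjectRecord(subject_id, str(groups[0]), scans))
    return records


# ---------------------------------------------------------------------------
# config file I/O (YAML/JSON with the CohortConfig fields)

def load_config(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML (or JSON, a YAML subset).

    ``effect_um`` is given as a nested mapping ``layer -> zone -> um``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    kwargs = dict(raw)
    if "effect_um" in kwargs:
        effect = {}
        for layer, zones in kwargs["effect_um"].items():
            for zone, value in zones.items():
                effect[(str(layer), int(zone))] = float(value)
        kwargs["effect_um"] = effect
    try:
        return CohortConfig(**kwargs)
    except TypeError as exc:  # unknown field
        raise ConfigError(str(exc)) from None


# ---------------------------------------------------------------------------
# direct feature-space generator (for selection-behaviour studies)

def planted_feature_table(
    n_patients: int = 75,
    n_controls: int = 75,
    informative: tuple[str, ...] = (
        "AVG_mGCL_2",
        "AVG_mGCL_6",
        "AVG_mRNFL_2",
        "AVG_mRNFL_6",
        "AVG_mIPL_2",
        "DIFF_mGCL_2",
    ),
    shift_sd: float = 1.0,
    seed: int = 0,
):
    """A feature table with unit-variance noise features and a planted shift.

    All 48 canonical features are i.i.d. standard normal; in patients, the
    ``informative`` features are shifted by ``-shift_sd`` standard
    deviations (thinning).  Used to study whether the selection pipeline
    recovers a known informative subset from pure noise, independent of the
    grid-level generative model.
    """
    from .features import FeatureTable, canonical_feature_names

    names = canonical_feature_names()
    unknown = set(informative) - set(names)
    if unknown:
        raise ConfigError(f"unknown informative features {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = n_patients + n_controls
    X = rng.normal(size=(n, len(names)))
    X[:n_patients, [names.index(f) for f in informative]] -= shift_sd
    subjects = [f"P{i + 1:04d}" for i in range(n_patients)] + [
        f"C{i + 1:04d}" for i in range(n_controls)
    ]
    frame = pd.DataFrame(X, index=pd.Index(subjects, name="subject_id"), columns=names)
    labels = pd.Series(
        ["patient"] * n_patients + ["control"] * n_controls,
        index=frame.index,
        name="group",
    )
    return FeatureTable(frame, labels)
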