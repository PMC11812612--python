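"""Bilateral AVG/DIFF feature construction from zoned thickness grids.

Each subject contributes 48 features: for every structure (mRNFL, mGCL,
mIPL and the derived mIRL complex) and every analysis zone (1-6), the
average of the two eyes' zone-mean thicknesses (AVG) and the inter-eye
difference (DIFF, signed OD - OS by default).  Feature names follow
``{AVG|DIFF}_{layer}_{zone}``, e.g. ``AVG_mGCL_2``.

Canonical feature order: all AVG features before all DIFF features,
layers in the order mRNFL, mGCL, mIPL, mIRL, zones 1-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simulate import GROUPS, SubjectRecord
from .zones import ALL_LAYERS, ZONES, GridScan, ZoneMap, derive_irl, mirror_zone_map, zone_means

MEASUREMENTS = ("AVG", "DIFF")


class FeatureError(ValueError):
    """A subject or table cannot yield a valid feature vector."""


def canonical_feature_names() -> list[str]:
    """The 48 feature names in canonical order (2 x 4 x 6)."""
    return [
        f"{meas}_{layer}_{zone}"
        for meas in MEASUREMENTS
        for layer in ALL_LAYERS
        for zone in ZONES
    ]


def parse_feature_name(name: str) -> tuple[str, str, int]:
    """Split ``AVG_mGCL_2`` into (measurement, structure, zone)."""
    parts = name.split("_")
    if len(parts) != 3 or parts[0] not in MEASUREMENTS or parts[1] not in ALL_LAYERS:
        raise FeatureError(f"unparseable feature name {name!r}")
    try:
        zone = int(parts[2])
    except ValueError:
        raise FeatureError(f"unparseable feature name {name!r}") from None
    if zone not in ZONES:
        raise FeatureError(f"unparseable feature name {name!r}")
    return parts[0], parts[1], zone


def build_features(
    subject: SubjectRecord,
    zone_map: ZoneMap,
    signed_diff: bool = True,
) -> pd.Series:
    """The 48-entry feature vector (um) for one subject.

    ``zone_map`` is given in right-eye orientation and mirrored internally
    for the left eye.  With ``signed_diff=False``, DIFF features are
    absolute inter-eye differences instead of signed OD - OS.
    """
    scans: dict[tuple[str, str], GridScan] = dict(subject.scans)
    for eye in ("OD", "OS"):
        scans[(eye, "mIRL")] = derive_irl(scans, subject.subject_id, eye)
    maps = {"OD": zone_map, "OS": mirror_zone_map(zone_map)}
    per_eye = {
        (eye, layer): zone_means(scans[(eye, layer)], maps[eye])
        for eye in ("OD", "OS")
        for layer in ALL_LAYERS
    }
    values = {}
    for layer in ALL_LAYERS:
        for zone in ZONES:
            od = per_eye[("OD", layer)][zone]
            os_ = per_eye[("OS", layer)][zone]
            values[f"AVG_{layer}_{zone}"] = (od + os_) / 2.0
            diff = od - os_
            values[f"DIFF_{layer}_{zone}"] = diff if signed_diff else abs(diff)
    return pd.Series(values, name=subject.subject_id).reindex(canonical_feature_names())


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x features matrix plus binary group labels.

    ``X`` is indexed by subject_id with one column per feature;
    ``y`` holds ``"patient"`` / ``"control"`` on the same index.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) == 0:
            raise FeatureError("feature table must contain at least one subject")
        if not self.X.index.equals(self.y.index):
            raise FeatureError("features and labels must share the subject index")
        if self.X.isna().any().any():
            raise FeatureError("feature table contains missing values")
        bad = set(self.y.unique()) - set(GROUPS)
        if bad:
            raise FeatureError(f"labels must be in {GROUPS}, found {sorted(bad)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def select(self, features: list[str]) -> "FeatureTable":
        """Restrict to a feature subset (order preserved as given)."""
        missing = [f for f in features if f not in self.X.columns]
        if missing:
            raise FeatureError(f"unknown features {missing}")
        return FeatureTable(self.X[list(features)], self.y)


def build_feature_table(
    cohort: list[SubjectRecord],
    zone_map: ZoneMap,
    signed_diff: bool = True,
) -> FeatureTable:
    """One canonical 48-feature row per subject, with group labels."""
    if not cohort:
        raise FeatureError("cannot build a feature table from an empty cohort")
    rows = [build_features(subject, zone_map, signed_diff=signed_diff) for subject in cohort]
    X = pd.DataFrame(rows)
    X.index.name = "subject_id"
    y = pd.Series([s.group for s in cohort], index=X.index, name="group")
    return FeatureTable(X, y)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with header = feature names + ``group``, indexed by subject_id."""
    out = table.X.copy()
    out["group"] = table.y
    out.to_csv(path)


def read_feature_table(path: str | Path) -> FeatureTable:
    frame = pd.read_csv(path, index_col=0)
    if "group" not in frame.columns:
        raise FeatureError("feature table CSV must contain a 'group' column")
    y = frame.pop("group")
    return FeatureTable(frame, y)
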