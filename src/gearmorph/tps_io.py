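"""I/O for 2-D landmark data and cohort tables.

Reads and writes tpsDig2-style TPS landmark files, slider tables (which
semi-landmarks slide between which neighbours), per-fish covariate tables
and per-fish-per-trial outcome tables, and validates that the pieces of a
cohort are mutually consistent.

Conventions
-----------
* Landmark indices are 1-based in every file and in every error message
  (the TPS / tpsUtil convention).  Internally arrays are 0-based.
* Coordinates are stored as digitised (image convention, y increasing
  downward); nothing flips the y axis except plotting code.
* ``SCALE=`` factors are applied on read, so in-memory coordinates are in
  millimetres whenever a scale was recorded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "SliderTable",
    "CovariateTable",
    "ValidationReport",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_sliders",
    "write_sliders",
    "read_covariates",
    "read_trials",
    "validate_dataset",
]

SEXES = ("F", "M")
GEARS = ("trawl", "trap")


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 2 landmark coordinates (mm after scale)."""

    points: np.ndarray
    specimen_id: str
    scale: float | None = None
    image_ref: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be k x 2, got {self.points.shape}")
        if self.points.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.points.shape == other.points.shape
            and np.allclose(self.points, other.points, atol=1e-12)
        )


@dataclass
class LandmarkDataset:
    """An ordered cohort of configurations sharing one landmark template.

    ``landmark_roles`` flags each landmark index as ``"fixed"`` or
    ``"semi"``; ``curve_memberships`` maps each semi landmark (0-based
    index) to a curve id so sliding knows which neighbours it has.
    """

    configurations: list[LandmarkConfiguration]
    landmark_roles: Sequence[str] | None = None
    curve_memberships: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset must contain at least one configuration")
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts across records: {sorted(ks)}")
        if self.landmark_roles is not None:
            self.landmark_roles = list(self.landmark_roles)
            if len(self.landmark_roles) != self.k:
                raise ValueError("landmark_roles length must equal k")
            bad = set(self.landmark_roles) - {"fixed", "semi"}
            if bad:
                raise ValueError(f"unknown landmark roles: {sorted(bad)}")
            for idx in self.curve_memberships:
                if self.landmark_roles[idx] != "semi":
                    raise ValueError(
                        f"landmark {idx + 1} has a curve but is not flagged semi"
                    )

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords(self) -> np.ndarray:
        """Stack configurations into an n x k x 2 array."""
        return np.stack([c.points for c in self.configurations])

    def semi_indices(self) -> np.ndarray:
        if self.landmark_roles is None:
            return np.array([], dtype=int)
        return np.flatnonzero(np.asarray(self.landmark_roles) == "semi")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkDataset):
            return NotImplemented
        return (
            self.configurations == other.configurations
            and (self.landmark_roles or None) == (other.landmark_roles or None)
        )


@dataclass
class SliderTable:
    """Rows of (before, slide, after) 1-based landmark indices."""

    rows: np.ndarray  # m x 3, int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, 3)
        if self.rows.ndim != 2 or self.rows.shape[1] != 3:
            raise ValueError("slider table must be m x 3")
        for before, slide, after in self.rows:
            if slide == before or slide == after:
                raise ValueError(
                    f"slider row ({before},{slide},{after}): slide index equals a neighbour"
                )
        if len(set(map(int, self.rows[:, 1]))) != len(self.rows):
            raise ValueError("a landmark appears as the sliding point in two rows")

    @property
    def m(self) -> int:
        return len(self.rows)

    def validate_against(self, dataset: LandmarkDataset) -> None:
        k = dataset.k
        if self.rows.size and (self.rows.min() < 1 or self.rows.max() > k):
            raise ValueError(f"slider index outside 1..{k}")
        if dataset.landmark_roles is not None:
            roles = list(dataset.landmark_roles)
            for _, slide, _ in self.rows:
                if roles[slide - 1] != "semi":
                    raise ValueError(f"slider landmark {slide} is flagged fixed")


class CovariateTable:
    """Per-fish covariates: mass (g), standard length (mm), sex, gear, tank,
    optional caudal-fin height (mm) and area (mm^2).

    Thin validation wrapper around a pandas DataFrame indexed by fish id.
    """

    REQUIRED = ["id", "mass", "standard_length", "sex", "gear", "tank"]
    OPTIONAL = ["caudal_height", "caudal_area"]

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
            raise ValueError(f"duplicate fish ids: {dupes}")
        if (df["mass"] <= 0).any() or (df["standard_length"] <= 0).any():
            raise ValueError("mass and standard_length must be positive")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex codes: {sorted(bad_sex)} (expected {SEXES})")
        bad_gear = set(df["gear"]) - set(GEARS)
        if bad_gear:
            raise ValueError(f"unknown gear codes: {sorted(bad_gear)} (expected {GEARS})")
        self.frame = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, ids: Iterable[str]) -> "CovariateTable":
        wanted = list(ids)
        sub = self.frame.set_index("id").loc[wanted].reset_index()
        return CovariateTable(sub)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Dataset/covariate consistency report; passes iff no entries."""

    missing_landmarks: list[str] = field(default_factory=list)
    missing_covariates: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    k_mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.missing_landmarks
            or self.missing_covariates
            or self.duplicate_ids
            or self.k_mismatches
        )

    def entries(self) -> list[str]:
        out = []
        out += [f"missing landmarks for id {i}" for i in self.missing_landmarks]
        out += [f"missing covariates for id {i}" for i in self.missing_covariates]
        out += [f"duplicate specimen id {i}" for i in self.duplicate_ids]
        out += self.k_mismatches
        return out


# ---------------------------------------------------------------------------
# TPS reading / writing
# ---------------------------------------------------------------------------

def _parse_tps_records(text: str, source: str) -> list[LandmarkConfiguration]:
    lines = [ln.strip() for ln in text.splitlines()]
    records: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    record_no = 0
    while i < n_lines:
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{source}: expected LM= at line {i + 1}, got {line!r}")
        record_no += 1
        try:
            lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{source}: bad LM count in record {record_no}") from exc
        i += 1
        pts = []
        while i < n_lines and len(pts) < lm:
            ln = lines[i]
            if not ln:
                i += 1
                continue
            if "=" in ln and not _looks_numeric(ln):
                break  # keyword line before enough coordinates
            parts = ln.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{source}: record {record_no}: bad coordinate line {ln!r}"
                )
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"{source}: record {record_no}: bad coordinate line {ln!r}"
                ) from exc
            i += 1
        if len(pts) != lm:
            raise TPSParseError(
                f"{source}: record {record_no} declares LM={lm} but has "
                f"{len(pts)} coordinate lines"
            )
        image_ref = None
        spec_id = None
        scale = None
        while i < n_lines:
            ln = lines[i]
            if not ln:
                i += 1
                continue
            up = ln.upper()
            if up.startswith("LM="):
                break
            if up.startswith("IMAGE="):
                image_ref = ln.split("=", 1)[1].strip() or None
            elif up.startswith("ID="):
                spec_id = ln.split("=", 1)[1].strip()
            elif up.startswith("SCALE="):
                try:
                    scale = float(ln.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSParseError(
                        f"{source}: record {record_no}: bad SCALE line {ln!r}"
                    ) from exc
            else:
                raise TPSParseError(
                    f"{source}: record {record_no}: unrecognised line {ln!r}"
                )
            i += 1
        points = np.asarray(pts, dtype=float)
        if scale is not None:
            points = points * scale
        records.append(
            LandmarkConfiguration(
                points=points,
                specimen_id=spec_id if spec_id is not None else str(record_no - 1),
                scale=scale,
                image_ref=image_ref,
            )
        )
    return records


def _looks_numeric(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
        return True
    except ValueError:
        return False


def read_tps(
    path: str | Path,
    landmark_roles: Sequence[str] | None = None,
    curve_memberships: dict[int, str] | None = None,
) -> LandmarkDataset:
    """Read a tpsDig2 TPS file into a :class:`LandmarkDataset`.

    ``SCALE=`` factors are applied so coordinates come out in mm; record
    order is preserved.  Raises :class:`TPSParseError` on malformed records
    and ``ValueError`` if records disagree on the landmark count.
    """
    text = Path(path).read_text()
    records = _parse_tps_records(text, str(path))
    if not records:
        raise TPSParseError(f"{path}: no TPS records found")
    return LandmarkDataset(
        configurations=records,
        landmark_roles=landmark_roles,
        curve_memberships=dict(curve_memberships or {}),
    )


def write_tps(dataset: LandmarkDataset, path: str | Path, precision: int = 6) -> Path:
    """Write a dataset as a TPS file (one LM= block per specimen).

    Coordinates are written post-scale (mm); no SCALE= line is emitted so a
    round-trip through :func:`read_tps` reproduces the same coordinates.
    """
    buf = io.StringIO()
    for cfg in dataset.configurations:
        buf.write(f"LM={cfg.k}\n")
        for x, y in cfg.points:
            buf.write(f"{x:.{precision}f} {y:.{precision}f}\n")
        if cfg.image_ref:
            buf.write(f"IMAGE={cfg.image_ref}\n")
        buf.write(f"ID={cfg.specimen_id}\n")
    out = Path(path)
    out.write_text(buf.getvalue())
    return out


def read_sliders(path: str | Path, dataset: LandmarkDataset | None = None) -> SliderTable:
    """Read a 3-column slider CSV (header: before, slide, after; 1-based)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    try:
        idx = [cols.index(c) for c in ("before", "slide", "after")]
    except ValueError as exc:
        raise ValueError(
            f"{path}: slider table needs columns before, slide, after"
        ) from exc
    table = SliderTable(df.iloc[:, idx].to_numpy(dtype=int))
    if dataset is not None:
        table.validate_against(dataset)
    return table


def write_sliders(table: SliderTable, path: str | Path) -> Path:
    pd.DataFrame(table.rows, columns=["before", "slide", "after"]).to_csv(
        path, index=False
    )
    return Path(path)


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path))


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV (fish_id, gear, trial_index, outcome, capture_time_s,
    captured) with blank fields left as NaN."""
    df = pd.read_csv(path)
    if "fish_id" not in df.columns or "gear" not in df.columns:
        raise ValueError(f"{path}: trial table needs fish_id and gear columns")
    df["fish_id"] = df["fish_id"].astype(str)
    return df


def validate_dataset(
    dataset: LandmarkDataset, covariates: CovariateTable
) -> ValidationReport:
    """Cross-check landmark records against the covariate table.

    Report-based: never raises; the report passes iff it has no entries.
    Idempotent and side-effect-free.
    """
    report = ValidationReport()
    lm_ids = dataset.ids
    seen: set[str] = set()
    for i in lm_ids:
        if i in seen:
            report.duplicate_ids.append(i)
        seen.add(i)
    cov_ids = set(covariates.ids)
    report.missing_landmarks = sorted(cov_ids - set(lm_ids))
    report.missing_covariates = sorted(set(lm_ids) - cov_ids)
    ks = {c.k for c in dataset.configurations}
    if len(ks) > 1:  # unreachable through the constructor, kept for raw lists
        report.k_mismatches.append(f"multiple landmark counts: {sorted(ks)}")
    return report
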