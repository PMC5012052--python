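"""Reading and writing labelled 3D ROI point sets and the validation table.

The on-disk formats replace the spreadsheet export step of the original
workflow, where ROI points placed in a DICOM viewer are exported with their
scanner-space coordinates.  Two dialects are supported: ``delimited``
(comma-separated with header ``case,vertebra,site,role,x,y,z``) and
``structured`` (JSON with the same fields).  Coordinates are millimetres in
a right-handed patient coordinate system (DICOM patient space); the
convention tag travels with the dataset and is never converted silently.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, asdict
from importlib import resources

from .frames import AnatomicalLandmarks

__all__ = [
    "ParseError",
    "DuplicatePointError",
    "ValidationError",
    "IncompleteTableError",
    "ROLES",
    "LabeledPoint",
    "ROIDataset",
    "MeasurementRecord",
    "AngleReportRow",
    "read_roi_points",
    "write_roi_points",
    "load_validation_table",
    "write_angles_report",
    "read_angles_report",
]


class ParseError(ValueError):
    """Malformed input row; the message names the offending line."""


class DuplicatePointError(ValueError):
    """Two points share the same (case, vertebra, site, role) key."""


class ValidationError(ValueError):
    """Dataset violates a structural invariant (non-finite, unpaired, ...)."""


class IncompleteTableError(ValueError):
    """Validation table is missing a source row for some implant."""


ROLES = frozenset({
    "landmark_O", "landmark_A", "landmark_B",
    "insertion", "exit",
    "safety_1", "safety_2", "safety_3", "safety_4",
    "shape_vertex",
})

VERTEBRAE = frozenset({"C1", "C2"})

#: Fixed coordinate-convention tag of datasets this package reads/writes.
COORDINATE_CONVENTION = "RAS-mm"


@dataclass(frozen=True)
class LabeledPoint:
    """One labelled ROI point in scanner (world) millimetres."""

    case_id: str
    vertebra: str
    site_label: str
    role: str
    x: float
    y: float
    z: float

    def __post_init__(self):
        if self.vertebra not in VERTEBRAE:
            raise ValidationError(f"unknown vertebra {self.vertebra!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        for c in (self.x, self.y, self.z):
            if not (isinstance(c, (int, float)) and math.isfinite(c)):
                raise ValidationError(
                    f"non-finite coordinate in point {self.key}")

    @property
    def key(self):
        return (self.case_id, self.vertebra, self.site_label, self.role)

    @property
    def xyz(self):
        return (self.x, self.y, self.z)


class ROIDataset:
    """A collection of labelled ROI points with unique keys.

    Provides the lookups the downstream geometry needs: the O/A/B landmark
    triplet per (case, vertebra), and insertion/exit/safety points per
    (case, implant site).
    """

    units = "mm"

    def __init__(self, points=(), coordinate_convention: str = COORDINATE_CONVENTION):
        self.coordinate_convention = coordinate_convention
        self._points: dict[tuple, LabeledPoint] = {}
        for p in points:
            self.add(p)
        self._check_pairing()

    def add(self, point: LabeledPoint) -> None:
        if point.key in self._points:
            raise DuplicatePointError(f"duplicate ROI point key {point.key}")
        self._points[point.key] = point

    @property
    def points(self) -> list[LabeledPoint]:
        return list(self._points.values())

    def __len__(self):
        return len(self._points)

    def __iter__(self):
        return iter(self._points.values())

    def _check_pairing(self):
        sites = {}
        for p in self:
            if p.role in ("insertion", "exit"):
                sites.setdefault((p.case_id, p.site_label), set()).add(p.role)
        for key, roles in sites.items():
            if roles != {"insertion", "exit"}:
                raise ValidationError(
                    f"implant site {key} must have exactly one insertion and "
                    f"one exit point, found roles {sorted(roles)}")

    def cases(self) -> list[str]:
        return sorted({p.case_id for p in self})

    def implant_sites(self, case_id: str) -> list[str]:
        return sorted({p.site_label for p in self
                       if p.case_id == case_id and p.role == "insertion"})

    def _one(self, case_id, role, site_label=None, vertebra=None) -> LabeledPoint:
        hits = [p for p in self
                if p.case_id == case_id and p.role == role
                and (site_label is None or p.site_label == site_label)
                and (vertebra is None or p.vertebra == vertebra)]
        if len(hits) != 1:
            raise ValidationError(
                f"expected exactly one point (case={case_id}, role={role}, "
                f"site={site_label}, vertebra={vertebra}), found {len(hits)}")
        return hits[0]

    def landmarks(self, case_id: str, vertebra: str) -> AnatomicalLandmarks:
        """The O/A/B landmark triplet of one vertebra of one case."""
        O = self._one(case_id, "landmark_O", vertebra=vertebra)
        A = self._one(case_id, "landmark_A", vertebra=vertebra)
        B = self._one(case_id, "landmark_B", vertebra=vertebra)
        return AnatomicalLandmarks(O=O.xyz, A=A.xyz, B=B.xyz, vertebra=vertebra)

    def implant_points(self, case_id: str, site_label: str):
        """(insertion, exit) coordinate tuples of one implant site."""
        I = self._one(case_id, "insertion", site_label=site_label)
        E = self._one(case_id, "exit", site_label=site_label)
        return I.xyz, E.xyz

    def safety_points(self, case_id: str, site_label: str):
        """The four safety-margin points of one implant site, in order."""
        return tuple(
            self._one(case_id, f"safety_{i}", site_label=site_label).xyz
            for i in (1, 2, 3, 4))

    def has_safety_points(self, case_id: str, site_label: str) -> bool:
        roles = {p.role for p in self
                 if p.case_id == case_id and p.site_label == site_label}
        return {"safety_1", "safety_2", "safety_3", "safety_4"} <= roles


_CSV_HEADER = ["case", "vertebra", "site", "role", "x", "y", "z"]


def read_roi_points(source, dialect: str = "delimited") -> ROIDataset:
    """Read an ROI point file (``delimited`` CSV or ``structured`` JSON).

    ``source`` is a path or an open text stream.  Rejects duplicate keys,
    malformed rows (naming the line) and non-finite coordinates.
    """
    close, stream = _open(source, "r")
    try:
        if dialect == "delimited":
            return _read_csv(stream)
        if dialect == "structured":
            return _read_json(stream)
        raise ValueError(f"unknown dialect {dialect!r}")
    finally:
        if close:
            stream.close()


def _open(source, mode):
    if hasattr(source, "read") or hasattr(source, "write"):
        return False, source
    return True, open(source, mode, newline="" if "r" in mode else "")


def _read_csv(stream) -> ROIDataset:
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty file: missing header") from None
    if [h.strip() for h in header] != _CSV_HEADER:
        raise ParseError(f"line 1: expected header {','.join(_CSV_HEADER)}")
    ds = ROIDataset()
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 7:
            raise ParseError(f"line {lineno}: expected 7 fields, got {len(row)}")
        try:
            x, y, z = (float(row[i]) for i in (4, 5, 6))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad coordinate ({exc})") from None
        try:
            ds.add(LabeledPoint(case_id=row[0].strip(), vertebra=row[1].strip(),
                                site_label=row[2].strip(), role=row[3].strip(),
                                x=x, y=y, z=z))
        except ValidationError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    ds._check_pairing()
    return ds


def _read_json(stream) -> ROIDataset:
    doc = json.load(stream)
    ds = ROIDataset(
        coordinate_convention=doc.get("coordinate_convention",
                                      COORDINATE_CONVENTION))
    for i, rec in enumerate(doc.get("points", [])):
        try:
            ds.add(LabeledPoint(case_id=rec["case"], vertebra=rec["vertebra"],
                                site_label=rec["site"], role=rec["role"],
                                x=float(rec["x"]), y=float(rec["y"]),
                                z=float(rec["z"])))
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, DuplicatePointError):
                raise
            raise ParseError(f"point record {i}: {exc}") from None
    ds._check_pairing()
    return ds


def write_roi_points(dataset: ROIDataset, destination,
                     dialect: str = "delimited") -> None:
    """Write an ROI dataset; coordinates keep full float precision."""
    close, stream = _open(destination, "w")
    try:
        if dialect == "delimited":
            w = csv.writer(stream, lineterminator="\n")
            w.writerow(_CSV_HEADER)
            for p in dataset:
                w.writerow([p.case_id, p.vertebra, p.site_label, p.role,
                            repr(p.x), repr(p.y), repr(p.z)])
        elif dialect == "structured":
            json.dump({"coordinate_convention": dataset.coordinate_convention,
                       "units": "mm",
                       "points": [{"case": p.case_id, "vertebra": p.vertebra,
                                   "site": p.site_label, "role": p.role,
                                   "x": p.x, "y": p.y, "z": p.z}
                                  for p in dataset]},
                      stream, indent=1)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    finally:
        if close:
            stream.close()


# --------------------------------------------------------------------------
# validation table (gold-standard vs manual angle measurements)

SOURCES = ("gold_standard", "observer1_rep1", "observer1_rep2",
           "observer2_rep1", "observer2_rep2")


@dataclass(frozen=True)
class MeasurementRecord:
    """One row of the validation table: six angles from one source.

    A record carries the two projected angles and four safety angles of one
    implant, either mathematically calculated (``gold_standard``) or
    measured manually on screen by one observer in one repeat.
    """

    case_id: str
    implant_id: int
    source: str
    proj_a1: float
    proj_a2: float
    saf_a1: float
    saf_a2: float
    saf_a3: float
    saf_a4: float

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if not 0 <= self.implant_id <= 9:
            raise ValidationError(f"implant_id must be 0-9, got {self.implant_id}")
        for v in self.angles:
            if not math.isfinite(v):
                raise ValidationError("non-finite angle value")

    @property
    def is_gold(self) -> bool:
        return self.source == "gold_standard"

    @property
    def proj_angles(self) -> tuple:
        return (self.proj_a1, self.proj_a2)

    @property
    def saf_angles(self) -> tuple:
        return (self.saf_a1, self.saf_a2, self.saf_a3, self.saf_a4)

    @property
    def angles(self) -> tuple:
        return self.proj_angles + self.saf_angles

    @property
    def observer(self) -> int | None:
        return None if self.is_gold else int(self.source[8])

    @property
    def repeat(self) -> int | None:
        return None if self.is_gold else int(self.source[-1])


def load_validation_table(source=None) -> list[MeasurementRecord]:
    """Load the packaged validation-table transcription (or a CSV stream).

    Returns exactly 60 records — 12 implants, each with its calculated
    gold-standard row and 2 observers x 2 repeats of manual measurements.
    """
    if source is None:
        text = resources.files("osic.data").joinpath("table1.csv").read_text()
        stream = io.StringIO(text)
        close = False
    else:
        close, stream = _open(source, "r")
    try:
        reader = csv.DictReader(stream)
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(MeasurementRecord(
                    case_id=row["case_id"].strip(),
                    implant_id=int(row["implant_id"]),
                    source=row["source"].strip(),
                    **{k: float(row[k]) for k in
                       ("proj_a1", "proj_a2", "saf_a1", "saf_a2",
                        "saf_a3", "saf_a4")}))
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    finally:
        if close:
            stream.close()
    by_implant = {}
    for r in records:
        by_implant.setdefault((r.case_id, r.implant_id), set()).add(r.source)
    for key, sources in sorted(by_implant.items()):
        missing = set(SOURCES) - sources
        if missing:
            raise IncompleteTableError(
                f"implant {key} is missing sources {sorted(missing)}")
    if len(records) != 5 * len(by_implant):
        raise IncompleteTableError("duplicate source rows present")
    return records


# --------------------------------------------------------------------------
# angle reports

@dataclass(frozen=True)
class AngleReportRow:
    """Computed per-implant results: 2 ProjA, 4 SafA, 2 widths, length."""

    case_id: str
    site_label: str
    proj_a1: float
    proj_a2: float
    saf_a1: float
    saf_a2: float
    saf_a3: float
    saf_a4: float
    width_plane1: float
    width_plane2: float
    implant_length: float


_REPORT_FIELDS = ["case", "site", "proj_a1", "proj_a2",
                  "saf_a1", "saf_a2", "saf_a3", "saf_a4",
                  "width_plane1", "width_plane2", "implant_length"]


def write_angles_report(results, destination, format: str = "delimited") -> None:
    """Write computed angle rows (degrees/mm, 6 decimal places).

    Column order is fixed; an empty result collection is an error.
    """
    results = list(results)
    if not results:
        raise ValueError("nothing to report: empty result collection")
    close, stream = _open(destination, "w")
    try:
        if format == "delimited":
            w = csv.writer(stream, lineterminator="\n")
            w.writerow(_REPORT_FIELDS)
            for r in results:
                w.writerow([r.case_id, r.site_label] +
                           [f"{v:.6f}" for v in (
                               r.proj_a1, r.proj_a2, r.saf_a1, r.saf_a2,
                               r.saf_a3, r.saf_a4, r.width_plane1,
                               r.width_plane2, r.implant_length)])
        elif format == "structured":
            json.dump([asdict(r) for r in results], stream, indent=1)
        else:
            raise ValueError(f"unknown report format {format!r}")
    finally:
        if close:
            stream.close()


def read_angles_report(source, format: str = "delimited") -> list[AngleReportRow]:
    """Read back an angle report written by :func:`write_angles_report`."""
    close, stream = _open(source, "r")
    try:
        if format == "delimited":
            reader = csv.DictReader(stream)
            return [AngleReportRow(
                case_id=row["case"], site_label=row["site"],
                **{k: float(row[k]) for k in _REPORT_FIELDS[2:]})
                for row in reader]
        if format == "structured":
            return [AngleReportRow(**rec) for rec in json.load(stream)]
        raise ValueError(f"unknown report format {format!r}")
    finally:
        if close:
            stream.close()
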