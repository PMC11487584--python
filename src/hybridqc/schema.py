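"""Tissue-composition grammar, ROI records and the long-format dataset table.

The tissue below each probe position is described outer-to-inner as a
``+``-separated list of layers; a layer holding two intermixed components is
written with ``/`` (e.g. ``SST+CB+CSF/NB``).  Component codes:

=====  =============================
ST     subcutaneous tissue
SST    swollen subcutaneous tissue
CB     cranial bone
NB     normal brain
A      air
CSF    cerebrospinal fluid
SAH    subarachnoid hemorrhage
EH     extracerebral hematoma
ICH    intracerebral hematoma
IT     ischemic tissue
BC     brain contusion
=====  =============================

The dataset long table holds one row per (ROI, wavelength): two rows per
ROI, one for each TRS wavelength, with StO2 and BFI repeated across the
pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from hybridqc.errors import DomainError, SchemaError

#: Recognized tissue component codes.
TISSUE_CODES = frozenset(
    {"ST", "SST", "CB", "NB", "A", "CSF", "SAH", "EH", "ICH", "IT", "BC"}
)

#: Fixed column order of the long-format dataset table.
TABLE_COLUMNS = [
    "measurement_id",
    "wavelength",
    "mua",
    "musp",
    "sto2",
    "bfi",
    "tissue_composition",
    "injury",
    "craniectomy",
    "sedation",
    "hematoma",
    "gender",
    "bone",
    "age",
]

#: Optional columns tolerated (and used by summaries when present).
OPTIONAL_COLUMNS = ["subject_id", "cohort"]


@dataclass(frozen=True)
class TissueComposition:
    """Ordered outer-to-inner tissue layers.

    ``layers`` is a tuple of layers; each layer is a tuple of 1 or 2
    component codes (2 codes = intermixed layer, printed with ``/``).
    """

    layers: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise SchemaError("composition must have at least one layer")
        for layer in self.layers:
            if not (1 <= len(layer) <= 2):
                raise SchemaError(f"a layer must hold 1 or 2 codes, got {layer}")
            for code in layer:
                if code not in TISSUE_CODES:
                    raise SchemaError(f"unknown tissue code {code!r}")

    @property
    def raw(self) -> str:
        """Canonical string form, e.g. ``'SST+CB+CSF/NB'``."""
        return "+".join("/".join(layer) for layer in self.layers)

    @property
    def codes(self) -> frozenset[str]:
        """Set of all component codes present."""
        return frozenset(c for layer in self.layers for c in layer)

    def __str__(self) -> str:
        return self.raw


def parse_composition(text: str) -> TissueComposition:
    """Parse a composition string like ``'ST+CB+CSF/NB'``.

    Whitespace around separators is normalized away; a trailing ``*`` (the
    printed no-cranial-bone marker) is not part of the grammar and rejected.
    Round trip: ``parse_composition(s).raw == s`` for normalized ``s``.
    """
    if not isinstance(text, str) or not text.strip():
        raise SchemaError("composition string must be non-empty")
    layers: list[tuple[str, ...]] = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise SchemaError(f"empty layer in composition {text!r}")
        codes = tuple(c.strip() for c in chunk.split("/"))
        if any(not c for c in codes):
            raise SchemaError(f"empty component in layer {chunk!r}")
        for c in codes:
            if c not in TISSUE_CODES:
                raise SchemaError(f"unknown tissue code {c!r} in composition {text!r}")
        if len(codes) > 2:
            raise SchemaError(f"mixed layer {chunk!r} must contain exactly 2 codes")
        layers.append(codes)
    return TissueComposition(layers=tuple(layers))


def roi_area(radius: float = 15.0) -> float:
    """Area (mm^2) of the circular region of interest under the probe.

    The default 15-mm radius (~700 mm^2) matches the depth most probed at a
    30-mm interfiber distance.
    """
    if radius < 0:
        raise DomainError(f"radius must be >= 0, got {radius}")
    return math.pi * radius**2


@dataclass
class ROIRecord:
    """One probed region of interest with its clinical annotations."""

    measurement_id: str
    subject_id: str
    cohort: Literal["MCA", "TBI", "SAH"]
    composition: TissueComposition | None
    radial_distance: float | None = None
    angle: float | None = None
    skull_present: bool = True
    surgery: bool = False
    sedation: bool = False
    hematoma: bool = False
    injury: bool = True
    gender: str = "M"
    age: float = 40.0
    roi_radius: float = 15.0

    def __post_init__(self) -> None:
        if self.cohort not in ("MCA", "TBI", "SAH"):
            raise SchemaError(f"unknown cohort {self.cohort!r}")
        if not (self.age > 0):
            raise DomainError(f"age must be > 0, got {self.age}")
        if self.angle is not None and not (0 <= self.angle <= 180):
            raise DomainError(f"angle must be within [0, 180] degrees, got {self.angle}")
        if not (self.roi_radius > 0):
            raise DomainError(f"roi_radius must be > 0, got {self.roi_radius}")


@dataclass
class ROIResult:
    """Per-ROI analysis outcome feeding the long table.

    ``mua`` and ``musp`` map wavelength (nm) to the fitted coefficient, or
    None for a failed fit; ``sto2`` (%) and ``bfi`` (cm^2/s) are shared
    across the ROI's two rows.
    """

    roi: ROIRecord
    mua: Mapping[float, float | None]
    musp: Mapping[float, float | None]
    sto2: float | None = None
    bfi: float | None = None


@dataclass
class DatasetTable:
    """Long-format dataset: one row per (ROI, wavelength)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"dataset table missing columns: {missing}")
        counts = self.df.groupby("measurement_id", sort=False)["wavelength"].count()
        if not (counts == 2).all():
            bad = counts[counts != 2].index.tolist()
            raise SchemaError(f"each ROI must have exactly 2 rows (687 and 830 nm); bad: {bad}")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetTable":
        return cls(df=pd.read_csv(path))


def to_long_table(results: Sequence[ROIResult]) -> DatasetTable:
    """Assemble the long table: 2 rows per ROI, deterministic order.

    Rows are sorted by measurement id then wavelength ascending; StO2 and
    BFI repeat across a ROI's two rows; failed fits leave nulls.
    """
    ids = [r.roi.measurement_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate measurement ids: {dupes}")
    rows = []
    for r in results:
        roi = r.roi
        for lam in (687.0, 830.0):
            rows.append(
                {
                    "measurement_id": roi.measurement_id,
                    "subject_id": roi.subject_id,
                    "cohort": roi.cohort,
                    "wavelength": lam,
                    "mua": r.mua.get(lam),
                    "musp": r.musp.get(lam),
                    "sto2": r.sto2,
                    "bfi": r.bfi,
                    "tissue_composition": roi.composition.raw if roi.composition else None,
                    "injury": roi.injury,
                    "craniectomy": roi.surgery,
                    "sedation": roi.sedation,
                    "hematoma": roi.hematoma,
                    "gender": roi.gender,
                    "bone": roi.skull_present,
                    "age": roi.age,
                }
            )
    df = pd.DataFrame(rows).sort_values(["measurement_id", "wavelength"], kind="stable")
    df = df[["subject_id", "cohort"] + TABLE_COLUMNS].reset_index(drop=True)
    return DatasetTable(df=df)


def _pct(k: int, n: int) -> int:
    """Integer percent, rounded half away from zero."""
    return int(math.floor(100.0 * k / n + 0.5))


def summarize(table: DatasetTable) -> dict:
    """Cohort summary statistics over distinct ROIs.

    Percentages are computed over distinct ROIs (not rows) and rounded half
    away from zero to integer percent.  Ages and gender are summarized per
    subject when a ``subject_id`` column is present, else per ROI.
    """
    df = table.df
    if df.empty:
        raise DomainError("cannot summarize an empty table")
    rois = df.drop_duplicates("measurement_id")
    n = len(rois)
    out: dict = {"n_rois": n, "n_rows": len(df)}

    for col, key in (("craniectomy", "surgery"), ("bone", "skull"),
                     ("sedation", "sedation"), ("hematoma", "hematoma"),
                     ("injury", "injury")):
        if col in rois.columns:
            yes = int(rois[col].astype(bool).sum())
            out[key] = {"yes": yes, "no": n - yes, "pct": _pct(yes, n)}

    if "subject_id" in rois.columns:
        subjects = rois.drop_duplicates("subject_id")
        out["n_subjects"] = len(subjects)
    else:
        subjects = rois
    if "cohort" in subjects.columns:
        out["cohort"] = subjects["cohort"].value_counts().to_dict()
    if "gender" in subjects.columns:
        g = subjects["gender"].value_counts().to_dict()
        out["gender"] = {"M": int(g.get("M", 0)), "F": int(g.get("F", 0))}
    ages = subjects["age"].dropna()
    out["age"] = {"mean": float(ages.mean()), "sd": float(ages.std(ddof=1))}

    comp = rois["tissue_composition"].dropna()
    out["composition_counts"] = {str(k): int(v) for k, v in comp.value_counts().items()}
    return out
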