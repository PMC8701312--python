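"""Domain containers and file I/O.

Per-vertex maps travel as :class:`VertexMap` (values + unit tag + mesh
binding), cohorts as :class:`SubjectRecord` collections, gene lists as
:class:`GeneSet`.  Readers/writers cover FreeSurfer binary morphometry
("curv") files, GIFTI shape files, delimited text, and GMT/plain gene-set
lists.  Every writer emits a sidecar JSON next to the file carrying the unit
tag, mesh id, and provenance (stage, parameters, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import SurfaceMesh

log = logging.getLogger(__name__)

#: Allowed unit tags for a VertexMap.
UNITS = ("mm", "percent-per-year", "t", "dimensionless", "integer-label")

N_RBSR_ITEMS = 43
#: RBS-R items are ordinal 0..3; anything outside is a corrupt sentinel.
RBSR_ITEM_MAX = 3
DEFAULT_MAX_MISSING_ITEMS = 3


class FormatError(ValueError):
    """File does not parse under the named dialect."""


class SchemaError(ValueError):
    """Tabular input is missing required structure."""


class UnitError(ValueError):
    """Arithmetic attempted between maps with mismatched unit tags."""


# ---------------------------------------------------------------------------
# VertexMap


@dataclass
class VertexMap:
    """One scalar per mesh vertex with a mandatory unit tag.

    ``valid`` marks vertices carrying meaningful data; ingestion never
    leaves NaN in ``values`` (missing values are zeroed and masked).
    """

    values: np.ndarray
    unit: str
    mesh_id: str = "mesh"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if self.valid is None:
            self.valid = ~np.isnan(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).ravel()
            if self.valid.shape != self.values.shape:
                raise ValueError("validity mask length mismatch")
            self.valid = self.valid & ~np.isnan(self.values)
        if np.any(~self.valid):
            self.values = np.where(self.valid, self.values, 0.0)

    def __len__(self) -> int:
        return self.values.shape[0]

    def _check_compatible(self, other: "VertexMap") -> None:
        if self.unit != other.unit:
            raise UnitError(f"unit mismatch: {self.unit!r} vs {other.unit!r}")
        if len(self) != len(other):
            raise ValueError("vertex count mismatch")

    def __add__(self, other: "VertexMap") -> "VertexMap":
        self._check_compatible(other)
        return VertexMap(self.values + other.values, self.unit, self.mesh_id,
                         self.valid & other.valid)

    def __sub__(self, other: "VertexMap") -> "VertexMap":
        self._check_compatible(other)
        return VertexMap(self.values - other.values, self.unit, self.mesh_id,
                         self.valid & other.valid)

    def bind_check(self, mesh: SurfaceMesh) -> None:
        if len(self) != mesh.n_vertices:
            raise FormatError(
                f"map has {len(self)} vertices but mesh {mesh.mesh_id!r} "
                f"has {mesh.n_vertices}"
            )


# ---------------------------------------------------------------------------
# Subjects


@dataclass
class SubjectRecord:
    """Demographics, covariates, and RBS-R item responses for one subject."""

    subject_id: str
    group: str              # "ASD" | "TD"
    sex: str                # "male" | "female"
    age_t1: float           # years
    isi: float              # interscan interval, years
    fsiq: float
    handedness: str = "right"   # "right" | "left"
    rbsr_items_t1: np.ndarray | None = None  # 43 ordinal responses, NaN = missing
    rbsr_items_t2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.group = _parse_categorical(self.group, {"asd": "ASD", "td": "TD"}, "group")
        self.sex = _parse_categorical(
            self.sex, {"male": "male", "m": "male", "female": "female", "f": "female"}, "sex")
        self.handedness = _parse_categorical(
            self.handedness,
            {"right": "right", "r": "right", "left": "left", "l": "left"},
            "handedness")
        if not self.isi > 0:
            raise SchemaError(f"subject {self.subject_id}: isi must be > 0, got {self.isi}")
        if not self.age_t1 > 0:
            raise SchemaError(f"subject {self.subject_id}: age_t1 must be > 0")
        for name in ("rbsr_items_t1", "rbsr_items_t2"):
            items = getattr(self, name)
            if items is not None:
                items = np.asarray(items, dtype=np.float64).ravel()
                obs = items[~np.isnan(items)]
                if obs.size and (np.any(obs < 0) or np.any(obs > RBSR_ITEM_MAX)
                                 or np.any(obs != np.round(obs))):
                    raise SchemaError(
                        f"subject {self.subject_id}: {name} values must be "
                        f"integers in 0..{RBSR_ITEM_MAX} (numeric sentinels rejected)")
                setattr(self, name, items)

    def n_missing(self, timepoint: int) -> int:
        items = self.rbsr_items_t1 if timepoint == 1 else self.rbsr_items_t2
        return 0 if items is None else int(np.isnan(items).sum())


@dataclass
class Cohort:
    """An ordered collection of subjects sharing one surface template."""

    subjects: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "age_t1": [s.age_t1 for s in self.subjects],
                "isi": [s.isi for s in self.subjects],
                "fsiq": [s.fsiq for s in self.subjects],
                "handedness": [s.handedness for s in self.subjects],
            }
        )

    def rbsr_matrix(self, timepoint: int) -> np.ndarray:
        """(n_subjects, 43) item matrix with NaN for missing."""
        attr = "rbsr_items_t1" if timepoint == 1 else "rbsr_items_t2"
        rows = []
        for s in self.subjects:
            items = getattr(s, attr)
            rows.append(np.full(N_RBSR_ITEMS, np.nan) if items is None else items)
        return np.vstack(rows)


def _parse_categorical(value: str, mapping: Mapping[str, str], name: str) -> str:
    key = str(value).strip().lower()
    if key not in mapping:
        raise SchemaError(f"cannot parse {name} value {value!r}")
    return mapping[key]


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSet:
    """A named gene list with free-text annotation (e.g. 'down-regulated')."""

    name: str
    members: tuple[str, ...]
    annotation: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        dupes = []
        for m in self.members:
            if m in seen:
                dupes.append(m)
            seen[m] = None
        if dupes:
            log.warning("gene set %s: collapsed duplicate symbols %s", self.name, dupes)
            warnings.warn(f"gene set {self.name}: duplicate symbols collapsed", stacklevel=2)
        self.members = tuple(seen)
        if not self.members:
            raise SchemaError(f"gene set {self.name} is empty")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Sidecar provenance


def write_sidecar(path: str | Path, *, unit: str | None = None, mesh_id: str | None = None,
                  stage: str = "", parameters: Mapping | None = None,
                  seed: int | None = None) -> Path:
    side = Path(str(path) + ".json")
    payload = {
        "unit": unit,
        "mesh_id": mesh_id,
        "provenance": {"stage": stage, "parameters": dict(parameters or {}), "seed": seed},
    }
    side.write_text(json.dumps(payload, indent=1, default=str))
    return side


def read_sidecar(path: str | Path) -> dict | None:
    side = Path(str(path) + ".json")
    if not side.exists():
        return None
    return json.loads(side.read_text())


# ---------------------------------------------------------------------------
# Vertex-map readers / writers


def write_vertex_map(vmap: VertexMap, path: str | Path, format: str | None = None,
                     **provenance) -> Path:
    """Write a map as curv / GIFTI shape / CSV, inferring format from suffix."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "curv":
        # curv needs a face count; it is informational only in new-style files
        nib.freesurfer.io.write_morph_data(str(path), vmap.values.astype(np.float32))
    elif fmt == "gifti-shape":
        darr = nib.gifti.GiftiDataArray(
            vmap.values.astype(np.float32), intent="NIFTI_INTENT_SHAPE")
        nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
    elif fmt == "csv":
        pd.DataFrame({"vertex": np.arange(len(vmap)),
                      "value": [f"{v:.9g}" for v in vmap.values]}).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown vertex-map format {fmt!r}")
    write_sidecar(path, unit=vmap.unit, mesh_id=vmap.mesh_id, **provenance)
    return path


def read_vertex_map(path: str | Path, format: str | None = None,
                    unit: str | None = None, mesh: SurfaceMesh | None = None) -> VertexMap:
    """Read a per-vertex map; dialect from ``format`` or the file suffix.

    The unit tag comes from the sidecar JSON when present, else ``unit``
    (required).  Supplying ``mesh`` enforces the vertex-count contract.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "curv":
        try:
            values = np.asarray(nib.freesurfer.io.read_morph_data(str(path)), dtype=np.float64)
        except Exception as exc:  # unknown magic bytes etc.
            raise FormatError(f"{path} is not a readable curv file: {exc}") from exc
    elif fmt == "gifti-shape":
        img = nib.load(str(path))
        if not isinstance(img, nib.gifti.GiftiImage) or not img.darrays:
            raise FormatError(f"{path} is not a GIFTI shape file")
        values = np.asarray(img.darrays[0].data, dtype=np.float64)
    elif fmt == "csv":
        frame = pd.read_csv(path)
        if "value" not in frame.columns:
            raise SchemaError(f"{path}: CSV map needs a 'value' column")
        if "vertex" in frame.columns:
            idx = frame["vertex"].to_numpy()
            if not np.array_equal(idx, np.arange(len(frame))):
                raise SchemaError(f"{path}: vertex index column must be 0-based and contiguous")
        values = frame["value"].to_numpy(dtype=np.float64)
    else:
        raise FormatError(f"unknown vertex-map format {fmt!r}")

    side = read_sidecar(path)
    side_unit = side.get("unit") if side else None
    mesh_id = (side or {}).get("mesh_id") or (mesh.mesh_id if mesh else "mesh")
    tag = side_unit or unit
    if tag is None:
        raise UnitError(f"{path}: no unit tag in sidecar and none supplied")
    vmap = VertexMap(values, tag, mesh_id)
    if mesh is not None:
        vmap.bind_check(mesh)
    return vmap


def _infer_format(path: Path) -> str:
    s = path.suffix.lower()
    if s in {".curv", ".thickness", ".sulc"} or path.name.endswith((".curv", ".thickness")):
        return "curv"
    if s == ".gii":
        return "gifti-shape"
    if s in {".csv", ".tsv"}:
        return "csv"
    return "curv"


# ---------------------------------------------------------------------------
# Surface I/O (FreeSurfer binary geometry + CSV fallback)


def write_surface(mesh: SurfaceMesh, path: str | Path, **provenance) -> Path:
    path = Path(path)
    nib.freesurfer.io.write_geometry(str(path), mesh.vertices, mesh.faces)
    write_sidecar(path, mesh_id=mesh.mesh_id, **provenance)
    return path


def read_surface(path: str | Path, mesh_id: str | None = None) -> SurfaceMesh:
    path = Path(path)
    coords, faces = nib.freesurfer.io.read_geometry(str(path))
    side = read_sidecar(path)
    return SurfaceMesh(coords, faces, mesh_id or (side or {}).get("mesh_id") or path.stem)


# ---------------------------------------------------------------------------
# Cohort table


_REQUIRED_COLUMNS = ("subject_id", "group", "sex", "age_t1", "isi", "fsiq", "handedness")


def read_cohort_table(path: str | Path,
                      max_missing_items: int = DEFAULT_MAX_MISSING_ITEMS) -> Cohort:
    """Read a delimited cohort table into SubjectRecords.

    RBS-R item columns are ``rbsr_t1_1`` .. ``rbsr_t1_43`` (and ``_t2_``);
    missing items are empty fields or ``NA``.  Rows exceeding
    ``max_missing_items`` missing items at either timepoint are rejected.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    frame = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=False)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")

    item_cols = {tp: [f"rbsr_t{tp}_{i}" for i in range(1, N_RBSR_ITEMS + 1)] for tp in (1, 2)}
    have_items = {tp: all(c in frame.columns for c in cols) for tp, cols in item_cols.items()}

    subjects = []
    for _, row in frame.iterrows():
        kwargs = {}
        for tp in (1, 2):
            if have_items[tp]:
                items = row[item_cols[tp]].to_numpy(dtype=np.float64)
                n_miss = int(np.isnan(items).sum())
                if n_miss > max_missing_items:
                    raise SchemaError(
                        f"subject {row['subject_id']}: {n_miss} missing RBS-R items at "
                        f"T{tp} exceeds the cap of {max_missing_items}")
                kwargs[f"rbsr_items_t{tp}"] = items
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=row["group"], sex=row["sex"],
            age_t1=float(row["age_t1"]), isi=float(row["isi"]), fsiq=float(row["fsiq"]),
            handedness=row["handedness"], **kwargs))
    return Cohort(subjects)


def write_cohort_table(cohort: Cohort, path: str | Path, **provenance) -> Path:
    path = Path(path)
    frame = cohort.to_frame()
    for tp in (1, 2):
        items = cohort.rbsr_matrix(tp)
        for i in range(N_RBSR_ITEMS):
            col = pd.Series(items[:, i]).astype("Int64")
            frame[f"rbsr_t{tp}_{i + 1}"] = col
    frame.to_csv(path, index=False, na_rep="NA")
    write_sidecar(path, **provenance)
    return path


# ---------------------------------------------------------------------------
# Gene sets


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT lines (name, annotation, members...) or a one-symbol-per-line list."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise SchemaError(f"{path} is empty")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if any("\t" in ln for ln in lines):
        sets = []
        for ln in lines:
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}: GMT line needs name, annotation, >=1 member: {ln!r}")
            sets.append(GeneSet(fields[0], tuple(f for f in fields[2:] if f), fields[1]))
        return sets
    return [GeneSet(path.stem, tuple(lines))]


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.annotation, *gs.members]) + "\n")
    return path
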