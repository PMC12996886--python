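"""File I/O: NIfTI volumes, phenotype tables, gene networks/sets, predictions.

Formats: volumes as .nii/.nii.gz (nibabel); phenotypes and predictions as
CSV; networks as TSV edge lists with a source/target header; gene sets as
GMT.  All reader errors carry the offending file (and line where it applies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("brainacn")

REAL_DATA_SHAPE = (121, 145, 121)  # preprocessed real-scale grid, 1.5 mm isotropic


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass
class Volume:
    """A 3D image: voxel grid plus spacing in millimetres."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.voxels.ndim} axes (shape {self.voxels.shape})")
        n_bad = int(np.sum(~np.isfinite(self.voxels)))
        if n_bad:
            raise FormatError(f"volume contains {n_bad} non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")


@dataclass(frozen=True)
class SubjectRecord:
    """One phenotype row: id, chronological age, gender, site, optional diagnosis."""

    subject_id: str
    age: float
    gender: str
    site: str
    diagnosis: Optional[str] = None


@dataclass(frozen=True)
class PredictionRecord:
    """Per-subject brain-age output; bag = predicted_age - chronological_age."""

    subject_id: str
    chronological_age: Optional[float]
    predicted_age: float
    bag: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.chronological_age is not None:
            expected = self.predicted_age - self.chronological_age
            if self.bag is None:
                object.__setattr__(self, "bag", expected)
            elif abs(self.bag - expected) > 1e-5:  # CSVs carry 6 decimals
                raise ValueError(
                    f"bag must equal predicted_age - chronological_age ({expected}), got {self.bag}"
                )


# --------------------------------------------------------------------- volumes

def normalize_intensity(x: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Per-volume intensity normalisation.

    ``minmax`` rescales each volume to [0, 1]; ``zscore`` standardises each
    volume to zero mean / unit variance (this cancels any global multiplicative
    intensity factor, e.g. a scanner/site gain); ``none`` is the identity.
    Accepts a single 3D volume or a batch with the subject axis first.
    """
    x = np.asarray(x, dtype=np.float64)
    axes = tuple(range(x.ndim - 3, x.ndim))
    if method == "none":
        return x
    if method == "minmax":
        lo = x.min(axis=axes, keepdims=True)
        hi = x.max(axis=axes, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (x - lo) / span
    if method == "zscore":
        mu = x.mean(axis=axes, keepdims=True)
        sd = x.std(axis=axes, keepdims=True)
        return (x - mu) / np.where(sd > 0, sd, 1.0)
    raise ValueError(f"unknown normalisation method {method!r}")


def read_volume(path: str | Path, normalize: Union[str, bool] = "minmax",
                shape_check: bool = False) -> Volume:
    """Load a NIfTI volume.

    ``normalize`` selects the load-time voxel-value normalisation: "minmax"
    (default), "zscore", or "none"/False.  With ``shape_check`` the real-data
    grid 121x145x121 is enforced.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim} axes (shape {data.shape})")
    n_bad = int(np.sum(~np.isfinite(data)))
    if n_bad:
        raise FormatError(f"{path}: {n_bad} NaN/inf voxels")
    if shape_check and data.shape != REAL_DATA_SHAPE:
        raise FormatError(f"{path}: real-data mode expects shape {REAL_DATA_SHAPE}, got {data.shape}")
    if normalize is True:
        normalize = "minmax"
    if normalize not in (False, None, "none"):
        data = normalize_intensity(data, method=normalize)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(voxels=data, spacing=spacing, subject_id=path.name.split(".")[0])


def write_volume(volume: Volume, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


# ------------------------------------------------------------------ phenotypes

def read_phenotypes(path: str | Path) -> List[SubjectRecord]:
    """Read a phenotype CSV with columns subject_id,age,gender,site[,diagnosis]."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "gender": str, "site": str})
    required = {"subject_id", "age", "gender", "site"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate subject_ids {sorted(set(dup))}")
    if df["age"].isna().any() or (df["age"] < 0).any():
        bad = df.loc[df["age"].isna() | (df["age"] < 0), "subject_id"].tolist()
        raise FormatError(f"{path}: non-finite or negative ages for subjects {bad}")
    has_dx = "diagnosis" in df.columns
    return [
        SubjectRecord(
            subject_id=row.subject_id,
            age=float(row.age),
            gender=row.gender,
            site=row.site,
            diagnosis=(None if not has_dx or pd.isna(row.diagnosis) else str(row.diagnosis)),
        )
        for row in df.itertuples()
    ]


def write_phenotypes(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "age": r.age,
            "gender": r.gender,
            "site": r.site,
            **({"diagnosis": r.diagnosis} if r.diagnosis is not None else {}),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------- predictions

def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "chronological_age": [r.chronological_age for r in records],
            "predicted_age": [round(r.predicted_age, 6) for r in records],
            "bag": [None if r.bag is None else round(r.bag, 6) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_predictions(path: str | Path) -> List[PredictionRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    out = []
    for row in df.itertuples():
        chron = None if pd.isna(row.chronological_age) else float(row.chronological_age)
        bag = None if pd.isna(row.bag) else float(row.bag)
        out.append(
            PredictionRecord(
                subject_id=row.subject_id,
                chronological_age=chron,
                predicted_age=float(row.predicted_age),
                bag=bag,
            )
        )
    return out


# -------------------------------------------------------------------- networks

def read_network(path: str | Path, directed: bool, kind: str = "", uppercase: bool = False):
    """Read a TSV edge list (header ``source<TAB>target``) into a GeneNetwork.

    Duplicate undirected edges (including reversed pairs) are collapsed with a
    logged count; self-loops are rejected.
    """
    from .netpleio import GeneNetwork  # local import: netpleio owns the type

    path = Path(path)
    edges: List[Tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0].lower() != "source" or header[1].lower() != "target":
            raise FormatError(f"{path}:1: expected header 'source\\ttarget', got {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields, got {len(fields)}")
            u, v = fields[0].strip(), fields[1].strip()
            if uppercase:
                u, v = u.upper(), v.upper()
            if u == v:
                raise FormatError(f"{path}:{ln}: self-loop {u!r} not allowed")
            edges.append((u, v))
    net, n_dupes = GeneNetwork.from_edges(edges, directed=directed, kind=kind or path.stem,
                                          return_duplicate_count=True)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dupes)
    return net


def write_network(network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


# ------------------------------------------------------------------- gene sets

def read_gene_sets(path: str | Path, uppercase: bool = False):
    """Read a GMT file: one gene set per line, name<TAB>description<TAB>genes..."""
    from .netpleio import GeneSet

    path = Path(path)
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT line needs >= 3 tab-separated fields (name, description, genes), got {len(fields)}"
                )
            members = {f.strip().upper() if uppercase else f.strip() for f in fields[2:] if f.strip()}
            sets.append(GeneSet(name=fields[0], members=frozenset(members)))
    return sets


def write_gene_sets(sets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na"] + sorted(gs.members)) + "\n")
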