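"""Reading, validating, mirroring and writing landmark datasets.

Supported text formats
----------------------
TPS
    3D points as ``LM3=k`` blocks followed by ``k`` whitespace-separated
    ``x y z`` lines, an ``ID=`` record, and an optional non-standard
    ``COMMENT=`` line carrying group/side/covariate metadata (ignored by
    other software).
NTS
    Rectangular matrix: header ``1 {n}L {3k} 0 dim=3``, one label line,
    then one row of 3k values per specimen.  Carries no group metadata.
CSV
    Wide form: one specimen per row with ``specimen_id``, ``group``,
    ``side`` columns, ``{label}_x/_y/_z`` coordinate columns, and any
    remaining numeric columns treated as covariates.

Coordinates are in millimetres, right-handed axes; right-side anatomy is
the canonical orientation.  Left-side specimens are mirror-imaged at load
time (``mirror_left=True``) so that all configurations are comparable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Curve",
    "LandmarkProtocol",
    "LandmarkConfiguration",
    "LandmarkDataset",
    "ValidationIssue",
    "read_landmarks",
    "write_landmarks",
    "mirror_configuration",
    "validate_against_protocol",
    "load_protocol",
    "humerus_protocol",
    "glenoid_protocol",
]

_AXES = {"x": 0, "y": 1, "z": 2}
_SIDES = {"left", "right", "unknown"}


class LandmarkFormatError(ValueError):
    """Raised on malformed landmark files (names the offending record)."""


@dataclass(frozen=True)
class Curve:
    """An anchored slideable curve: anchor, semilandmarks..., anchor."""

    anchor_start: str
    semilandmarks: tuple[str, ...]
    anchor_end: str

    @property
    def points(self) -> tuple[str, ...]:
        return (self.anchor_start, *self.semilandmarks, self.anchor_end)


@dataclass(frozen=True)
class LandmarkProtocol:
    """Declaration of landmark names, types and slideable curves.

    ``landmarks`` is an ordered tuple of ``(label, type)`` pairs where type
    is ``"II"`` (homologous type-II landmark) or ``"SL"`` (semilandmark).
    """

    name: str
    landmarks: tuple[tuple[str, str], ...]
    curves: tuple[Curve, ...] = ()
    slide_by_default: bool = False

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.landmarks]
        if len(set(labels)) != len(labels):
            raise ValueError(f"protocol {self.name!r}: duplicate landmark labels")
        sl = {lab for lab, t in self.landmarks if t == "SL"}
        on_curves: list[str] = []
        for c in self.curves:
            on_curves.extend(c.semilandmarks)
            for anchor in (c.anchor_start, c.anchor_end):
                if anchor in sl:
                    raise ValueError(
                        f"protocol {self.name!r}: curve anchor {anchor!r} is a semilandmark"
                    )
                if anchor not in labels:
                    raise ValueError(f"protocol {self.name!r}: unknown anchor {anchor!r}")
        if sorted(on_curves) != sorted(set(on_curves)) or set(on_curves) != sl:
            raise ValueError(
                f"protocol {self.name!r}: every semilandmark must lie on exactly one curve"
            )

    @property
    def expected_k(self) -> int:
        return len(self.landmarks)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.landmarks)

    @property
    def semilandmark_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, t in self.landmarks if t == "SL")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class LandmarkConfiguration:
    """One specimen's named 3D points plus metadata; the atomic observation."""

    specimen_id: str
    group: str
    coords: np.ndarray  # (k, 3) float64, millimetres
    side: str = "unknown"
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be (k, 3), got {self.coords.shape}"
            )
        if self.side not in _SIDES:
            raise ValueError(f"specimen {self.specimen_id!r}: invalid side {self.side!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def is_fossil(self) -> bool:
        return self.group.startswith("fossil:")


@dataclass
class LandmarkDataset:
    """A protocol plus the specimens observed under it."""

    protocol: LandmarkProtocol
    specimens: list[LandmarkConfiguration]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    def __len__(self) -> int:
        return len(self.specimens)

    @property
    def extant(self) -> list[LandmarkConfiguration]:
        return [s for s in self.specimens if not s.is_fossil]

    @property
    def fossils(self) -> list[LandmarkConfiguration]:
        return [s for s in self.specimens if s.is_fossil]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.extant:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def coords_array(self) -> np.ndarray:
        """Stack all specimens into an (n, k, 3) array (order preserved)."""
        return np.stack([s.coords for s in self.specimens])


# ---------------------------------------------------------------------------
# protocols

def load_protocol(source: str | Path) -> LandmarkProtocol:
    """Load a protocol from YAML: a bundled name or a filesystem path."""
    path = Path(source)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        text = path.read_text()
    else:
        res = importlib.resources.files("shouldergm").joinpath(f"protocols/{source}.yaml")
        try:
            text = res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(f"no bundled protocol or YAML file named {source!r}") from None
    doc = yaml.safe_load(text)
    curves = tuple(
        Curve(anchor_start=c[0], semilandmarks=tuple(c[1:-1]), anchor_end=c[-1])
        for c in doc.get("curves", [])
    )
    return LandmarkProtocol(
        name=doc["name"],
        landmarks=tuple((str(lab), str(t)) for lab, t in doc["landmarks"]),
        curves=curves,
        slide_by_default=bool(doc.get("slide_by_default", False)),
    )


def humerus_protocol() -> LandmarkProtocol:
    """Proximal humerus: 21 type-II landmarks + 4 articular-arc semilandmarks."""
    return load_protocol("humerus")


def glenoid_protocol() -> LandmarkProtocol:
    """Glenoid cavity: 5 type-II landmarks + 8 surface semilandmarks."""
    return load_protocol("glenoid")


# ---------------------------------------------------------------------------
# mirroring and validation

def mirror_configuration(
    config: LandmarkConfiguration, plane_normal_axis: str = "x"
) -> LandmarkConfiguration:
    """Reflect a configuration across a coordinate plane and flip its side flag.

    Mirroring negates one coordinate axis for every point; it preserves
    centroid size and all inter-point distances exactly, and is an
    involution.
    """
    try:
        ax = _AXES[plane_normal_axis]
    except KeyError:
        raise ValueError(f"invalid axis {plane_normal_axis!r}; expected one of x, y, z") from None
    coords = config.coords.copy()
    coords[:, ax] = -coords[:, ax]
    side = {"left": "right", "right": "left"}.get(config.side, "unknown")
    return replace(config, coords=coords, side=side, covariates=dict(config.covariates))


def mirror_left_specimens(dataset: LandmarkDataset) -> LandmarkDataset:
    """Return a dataset with every left-side specimen mirrored to canonical right."""
    return LandmarkDataset(
        protocol=dataset.protocol,
        specimens=[
            mirror_configuration(s) if s.side == "left" else s
            for s in dataset.specimens
        ],
        provenance=dataset.provenance,
    )


@dataclass(frozen=True)
class ValidationIssue:
    specimen_id: str
    message: str


def validate_against_protocol(dataset: LandmarkDataset) -> list[ValidationIssue]:
    """Report per-specimen protocol violations; an empty list means valid."""
    k = dataset.protocol.expected_k
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for s in dataset.specimens:
        if s.specimen_id in seen:
            issues.append(ValidationIssue(s.specimen_id, "duplicate specimen id"))
        seen.add(s.specimen_id)
        if s.k != k:
            issues.append(
                ValidationIssue(s.specimen_id, f"expected {k} points, found {s.k}")
            )
        if not np.all(np.isfinite(s.coords)):
            bad = np.argwhere(~np.isfinite(s.coords))[0]
            issues.append(
                ValidationIssue(
                    s.specimen_id,
                    f"non-finite coordinate at point {bad[0]} axis {'xyz'[bad[1]]}",
                )
            )
    return issues


# ---------------------------------------------------------------------------
# readers / writers

def read_landmarks(
    path: str | Path,
    protocol: LandmarkProtocol,
    fmt: str | None = None,
    mirror_left: bool = True,
) -> LandmarkDataset:
    """Read a landmark dataset, auto-detecting the format from the extension.

    With ``mirror_left`` (the default), left-side specimens are reflected
    across the y-z plane at load time so right-side anatomy is canonical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        specimens = _read_tps(path)
    elif fmt == "nts":
        specimens = _read_nts(path)
    elif fmt == "csv":
        specimens = _read_csv(path, protocol)
    else:
        raise ValueError(f"unknown landmark format {fmt!r} (expected tps, nts or csv)")
    if mirror_left:
        specimens = [
            mirror_configuration(s) if s.side == "left" else s for s in specimens
        ]
    ds = LandmarkDataset(protocol=protocol, specimens=specimens, provenance=str(path))
    bad = [i for i in validate_against_protocol(ds) if "points" in i.message]
    if bad:
        raise LandmarkFormatError(
            f"{path}: specimen {bad[0].specimen_id!r}: {bad[0].message}"
        )
    return ds


def write_landmarks(dataset: LandmarkDataset, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        _write_tps(dataset, path)
    elif fmt == "nts":
        _write_nts(dataset, path)
    elif fmt == "csv":
        _write_csv(dataset, path)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")


_FLOAT_FMT = "%.12g"


def _read_tps(path: Path) -> list[LandmarkConfiguration]:
    specimens: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    meta: dict[str, str] = {}
    expect = 0

    def flush(lineno: int) -> None:
        nonlocal coords, meta, expect
        if expect == 0 and not coords:
            return
        if len(coords) != expect:
            raise LandmarkFormatError(
                f"{path}:{lineno}: expected {expect} points, found {len(coords)}"
            )
        cov = {}
        group = meta.get("group", "unknown")
        side = meta.get("side", "unknown")
        for key, val in meta.items():
            if key not in {"group", "side", "id"}:
                cov[key] = float(val)
        specimens.append(
            LandmarkConfiguration(
                specimen_id=meta.get("id", f"specimen_{len(specimens) + 1}"),
                group=group,
                side=side,
                coords=np.array(coords),
                covariates=cov,
            )
        )
        coords, meta, expect = [], {}, 0

    with open(path) as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(lineno)
                expect = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                meta["id"] = line.split("=", 1)[1].strip()
            elif upper.startswith("COMMENT="):
                for item in line.split("=", 1)[1].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k.strip()] = v.strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                continue  # IMAGE=, SCALE=, ... ignored
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: expected 'x y z', got {line!r}"
                    )
                try:
                    coords.append([float(p) for p in parts])
                except ValueError:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from None
        flush(lineno + 1)
    return specimens


def _write_tps(dataset: LandmarkDataset, path: Path) -> None:
    with open(path, "w") as fh:
        for s in dataset.specimens:
            fh.write(f"LM3={s.k}\n")
            for row in s.coords:
                fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")
            comment = f"group={s.group};side={s.side}"
            for key, val in s.covariates.items():
                comment += f";{key}={_FLOAT_FMT % val}"
            fh.write(f"COMMENT={comment}\n")
            fh.write(f"ID={s.specimen_id}\n")


def _read_nts(path: Path) -> list[LandmarkConfiguration]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith('"')]
    header = lines[0].split()
    if len(header) < 4:
        raise LandmarkFormatError(f"{path}:1: malformed NTS header {lines[0]!r}")
    n_field = header[1]
    labelled = n_field.upper().endswith("L")
    n = int(n_field.rstrip("Ll"))
    ncols = int(header[2])
    dim = 3
    for tok in header[4:]:
        if tok.lower().startswith("dim="):
            dim = int(tok.split("=")[1])
    if dim != 3 or ncols % 3:
        raise LandmarkFormatError(f"{path}: only 3D NTS matrices are supported")
    k = ncols // 3
    body = lines[1:]
    if labelled:
        labels: list[str] = []
        while len(labels) < n and body:
            labels.extend(body.pop(0).split())
        if len(labels) != n:
            raise LandmarkFormatError(f"{path}: expected {n} specimen labels")
    else:
        labels = [f"specimen_{i + 1}" for i in range(n)]
    values: list[float] = []
    for i, line in enumerate(body):
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise LandmarkFormatError(
                    f"{path}: non-numeric value {tok!r} in matrix row {i + 1}"
                ) from None
    if len(values) != n * ncols:
        raise LandmarkFormatError(
            f"{path}: expected {n * ncols} matrix values, found {len(values)}"
        )
    arr = np.array(values).reshape(n, k, 3)
    return [
        LandmarkConfiguration(specimen_id=labels[i], group="unknown", coords=arr[i])
        for i in range(n)
    ]


def _write_nts(dataset: LandmarkDataset, path: Path) -> None:
    n = len(dataset.specimens)
    k = dataset.protocol.expected_k
    with open(path, "w") as fh:
        fh.write(f"1 {n}L {3 * k} 0 dim=3\n")
        fh.write(" ".join(s.specimen_id for s in dataset.specimens) + "\n")
        for s in dataset.specimens:
            fh.write(" ".join(_FLOAT_FMT % v for v in s.coords.ravel()) + "\n")


_RESERVED_COLS = {"specimen_id", "group", "side"}


def _read_csv(path: Path, protocol: LandmarkProtocol) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise LandmarkFormatError(f"{path}: missing required column 'specimen_id'")
    coord_cols = [f"{lab}_{ax}" for lab in protocol.labels for ax in "xyz"]
    missing = [c for c in coord_cols if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: missing coordinate columns {missing[:4]}...")
    cov_cols = [
        c for c in df.columns if c not in _RESERVED_COLS and c not in coord_cols
    ]
    specimens = []
    for idx, row in df.iterrows():
        vals = row[coord_cols]
        bad = vals.astype(object).apply(lambda v: _try_float(v) is None)
        if bad.any():
            col = bad.idxmax()
            raise LandmarkFormatError(
                f"{path}: row {idx + 2}, column {col!r}: non-numeric coordinate {row[col]!r}"
            )
        coords = np.array([float(v) for v in vals], dtype=float).reshape(-1, 3)
        cov = {
            c: float(row[c])
            for c in cov_cols
            if pd.notna(row[c]) and _try_float(row[c]) is not None
        }
        specimens.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                group=str(row["group"]) if "group" in df.columns else "unknown",
                side=str(row["side"]) if "side" in df.columns else "unknown",
                coords=coords,
                covariates=cov,
            )
        )
    return specimens


def _try_float(v: object) -> float | None:
    try:
        return float(v)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None


def _write_csv(dataset: LandmarkDataset, path: Path) -> None:
    labels = dataset.protocol.labels
    cov_names = sorted({name for s in dataset.specimens for name in s.covariates})
    rows = []
    for s in dataset.specimens:
        row: dict[str, object] = {
            "specimen_id": s.specimen_id,
            "group": s.group,
            "side": s.side,
        }
        for name in cov_names:
            row[name] = s.covariates.get(name, np.nan)
        for lab, (x, y, z) in zip(labels, s.coords):
            row[f"{lab}_x"], row[f"{lab}_y"], row[f"{lab}_z"] = x, y, z
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
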