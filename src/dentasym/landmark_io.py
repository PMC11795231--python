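"""Reading, writing and structural organisation of 2D landmark data.

A *configuration* is one replicate digitization of one tooth side: an ordered
set of fixed anatomical landmarks followed by outline semilandmarks. Two
schemes are built in: the maxillary first molar (UM1, 8 fixed landmarks) and
the mandibular first molar (LM1, 10 fixed landmarks), each with 20 occlusal
outline semilandmarks.

Two file dialects are supported:

* ``delimited`` — a lossless long-format table, one row per point, with
  columns (individual, site, tooth_class, side, replicate, point_index,
  point_type, x, y). Round-trips bit-exactly.
* ``tps`` — the community TPS format: ``LM=n`` blocks of whitespace-separated
  coordinates with metadata packed into the ``ID=`` line as
  ``individual:site:tooth_class:side:replicate``.

Antimere handling: left and right teeth are mirror images, so before they can
share one shape space one side must be reflected. This package reflects the
*right* side (x negated about the configuration centroid), preserving landmark
order — landmarks are defined anatomically, not by image left/right.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LandmarkFormatError, SchemeMismatchError, ValidationError

SITES = ("BG", "SS", "WS", "YB")
TOOTH_CLASSES = ("UM1", "LM1")
SIDES = ("L", "R")

_UM1_LANDMARKS = (
    "mesial fovea centre (mesial end of sagittal fissure)",
    "sagittal x buccal fissure intersection",
    "sagittal x lingual fissure intersection",
    "distal fovea centre (distal end of sagittal fissure)",
    "paracone apex",
    "metacone apex",
    "protocone apex",
    "hypocone apex",
)
_LM1_LANDMARKS = (
    "mesial fovea centre (mesial end of longitudinal fissure)",
    "longitudinal x mesiobuccal fissure intersection",
    "longitudinal x lingual fissure intersection",
    "longitudinal x distobuccal fissure intersection",
    "distal fovea (distal end of longitudinal fissure)",
    "protoconid apex",
    "hypoconid apex",
    "metaconid apex",
    "entoconid apex",
    "hypoconulid apex",
)


@dataclass(frozen=True)
class LandmarkScheme:
    """Fixed-landmark + semilandmark layout for one tooth class.

    Points are ordered: ``n_fixed`` anatomical landmarks first, then
    ``n_semi`` outline semilandmarks. ``closed_outline`` declares whether the
    semilandmark chain wraps (a full occlusal outline) — it controls neighbour
    chords during sliding.
    """

    tooth_class: str
    n_fixed: int
    n_semi: int = 20
    landmark_defs: tuple[str, ...] = ()
    closed_outline: bool = True

    def __post_init__(self) -> None:
        if self.tooth_class not in TOOTH_CLASSES:
            raise ValidationError(f"unknown tooth class {self.tooth_class!r}")
        expected = {"UM1": 8, "LM1": 10}[self.tooth_class]
        if self.n_fixed != expected:
            raise ValidationError(
                f"{self.tooth_class} scheme requires {expected} fixed landmarks, "
                f"got {self.n_fixed}"
            )
        if self.n_semi != 20:
            raise ValidationError("schemes use 20 outline semilandmarks")

    @property
    def n_points(self) -> int:
        return self.n_fixed + self.n_semi

    @property
    def semi_indices(self) -> np.ndarray:
        """Row indices of the semilandmarks within a configuration."""
        return np.arange(self.n_fixed, self.n_points)

    @classmethod
    def for_tooth(cls, tooth_class: str) -> "LandmarkScheme":
        if tooth_class == "UM1":
            return cls("UM1", 8, 20, _UM1_LANDMARKS)
        if tooth_class == "LM1":
            return cls("LM1", 10, 20, _LM1_LANDMARKS)
        raise ValidationError(f"unknown tooth class {tooth_class!r}")


@dataclass
class DigitizedConfiguration:
    """One replicate digitization of one tooth side, in raw image units."""

    individual_id: str
    site: str
    tooth_class: str
    side: str
    replicate: int
    coords: np.ndarray  # (n_points, 2)
    reflected: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"non-finite coordinates in {self.individual_id} "
                f"{self.tooth_class} {self.side} rep {self.replicate}"
            )
        if self.side not in SIDES:
            raise ValidationError(f"side must be L or R, got {self.side!r}")
        if not 1 <= int(self.replicate) <= 3:
            raise ValidationError(f"replicate must be in 1..3, got {self.replicate}")
        self.replicate = int(self.replicate)

    @property
    def label(self) -> str:
        return f"{self.individual_id}:{self.tooth_class}:{self.side}:{self.replicate}"


@dataclass
class ConfigurationSet:
    """A validated collection of configurations sharing one scheme."""

    scheme: LandmarkScheme
    configurations: list[DigitizedConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cfg in self.configurations:
            self._check(cfg)

    def _check(self, cfg: DigitizedConfiguration) -> None:
        if cfg.tooth_class != self.scheme.tooth_class:
            raise SchemeMismatchError(
                f"configuration {cfg.label} is {cfg.tooth_class}, "
                f"set scheme is {self.scheme.tooth_class}"
            )
        if cfg.coords.shape[0] != self.scheme.n_points:
            raise SchemeMismatchError(
                f"configuration {cfg.label} has {cfg.coords.shape[0]} points; "
                f"scheme {self.scheme.tooth_class} requires {self.scheme.n_points}"
            )

    def add(self, cfg: DigitizedConfiguration) -> None:
        self._check(cfg)
        self.configurations.append(cfg)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for cfg in self.configurations:
            seen.setdefault(cfg.individual_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n_fixed = self.scheme.n_fixed
        for cfg in self.configurations:
            for j, (x, y) in enumerate(cfg.coords):
                rows.append(
                    {
                        "individual": cfg.individual_id,
                        "site": cfg.site,
                        "tooth_class": cfg.tooth_class,
                        "side": cfg.side,
                        "replicate": cfg.replicate,
                        "point_index": j,
                        "point_type": "fixed" if j < n_fixed else "semi",
                        "x": x,
                        "y": y,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class AntimerePair:
    """All replicates of one individual's left and right teeth."""

    individual_id: str
    left: list[DigitizedConfiguration]
    right: list[DigitizedConfiguration]


def reflect_configuration(config: DigitizedConfiguration) -> DigitizedConfiguration:
    """Mirror a configuration about the vertical (y) axis.

    x-coordinates are negated — an exact floating-point operation, so
    applying the reflection twice returns the original coordinates
    bit-exactly. Centroid size and the y-centroid are preserved exactly; the
    x-centroid changes sign, which is immaterial because alignment removes
    translation. Landmark order is unchanged.
    """
    coords = config.coords.copy()
    coords[:, 0] = -coords[:, 0]
    return replace(config, coords=coords, reflected=not config.reflected)


def pair_antimeres(
    config_set: ConfigurationSet,
) -> tuple[list[AntimerePair], list[str]]:
    """Group configurations into complete left/right antimere pairs.

    Returns ``(pairs, excluded)`` where *excluded* lists individuals missing
    one side or with unequal replicate counts. Order follows first appearance.
    """
    if len(config_set) == 0:
        raise ValidationError("cannot pair antimeres of an empty configuration set")
    by_ind: dict[str, dict[str, list[DigitizedConfiguration]]] = {}
    for cfg in config_set:
        by_ind.setdefault(cfg.individual_id, {"L": [], "R": []})[cfg.side].append(cfg)
    pairs: list[AntimerePair] = []
    excluded: list[str] = []
    for ind, sides in by_ind.items():
        left = sorted(sides["L"], key=lambda c: c.replicate)
        right = sorted(sides["R"], key=lambda c: c.replicate)
        if left and right and len(left) == len(right):
            pairs.append(AntimerePair(ind, left, right))
        else:
            excluded.append(ind)
    return pairs, excluded


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

_DELIM_COLUMNS = [
    "individual",
    "site",
    "tooth_class",
    "side",
    "replicate",
    "point_index",
    "point_type",
    "x",
    "y",
]


def _frame_to_set(frame: pd.DataFrame, scheme: LandmarkScheme) -> ConfigurationSet:
    out = ConfigurationSet(scheme)
    keys = ["individual", "site", "tooth_class", "side", "replicate"]
    for (ind, site, tc, side, rep), grp in frame.groupby(keys, sort=False):
        grp = grp.sort_values("point_index")
        coords = grp[["x", "y"]].to_numpy(dtype=float)
        if coords.shape[0] != scheme.n_points:
            raise SchemeMismatchError(
                f"record {ind}:{tc}:{side}:{rep} has {coords.shape[0]} points; "
                f"scheme {scheme.tooth_class} requires {scheme.n_points}"
            )
        out.add(
            DigitizedConfiguration(
                individual_id=str(ind),
                site=str(site),
                tooth_class=str(tc),
                side=str(side),
                replicate=int(rep),
                coords=coords,
            )
        )
    return out


def _read_delimited(path: Path, scheme: LandmarkScheme) -> ConfigurationSet:
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # malformed CSV: report as a parse error
        raise LandmarkFormatError(f"{path}: {exc}") from exc
    missing = [c for c in _DELIM_COLUMNS if c not in frame.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {missing}")
    return _frame_to_set(frame, scheme)


def _write_delimited(config_set: ConfigurationSet, path: Path) -> None:
    frame = config_set.to_frame()
    # repr-round-trip float formatting keeps the delimited dialect lossless
    frame.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def _read_tps(path: Path, scheme: LandmarkScheme) -> ConfigurationSet:
    out = ConfigurationSet(scheme)
    coords: list[tuple[float, float]] = []
    meta: str | None = None
    expected: int | None = None

    def flush(lineno: int) -> None:
        nonlocal coords, meta, expected
        if expected is None:
            return
        if meta is None:
            raise LandmarkFormatError(f"{path}:{lineno}: record without an ID= line")
        if len(coords) != expected:
            raise LandmarkFormatError(
                f"{path}:{lineno}: LM={expected} but {len(coords)} coordinate rows"
            )
        parts = meta.split(":")
        if len(parts) != 5:
            raise LandmarkFormatError(
                f"{path}:{lineno}: ID must be individual:site:tooth:side:replicate, "
                f"got {meta!r}"
            )
        ind, site, tc, side, rep = parts
        arr = np.array(coords, dtype=float)
        if arr.shape[0] != scheme.n_points:
            raise SchemeMismatchError(
                f"{path}:{lineno}: record {meta} has {arr.shape[0]} points; "
                f"scheme requires {scheme.n_points}"
            )
        out.add(DigitizedConfiguration(ind, site, tc, side, int(rep), arr))
        coords, meta, expected = [], None, None

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(lineno)
                try:
                    expected = int(line[3:])
                except ValueError as exc:
                    raise LandmarkFormatError(f"{path}:{lineno}: bad LM= line") from exc
            elif upper.startswith("ID="):
                meta = line[3:]
            elif upper.startswith(("CURVES=", "POINTS=", "IMAGE=", "SCALE=")):
                continue
            else:
                bits = line.split()
                if len(bits) != 2:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: expected 'x y', got {line!r}"
                    )
                try:
                    coords.append((float(bits[0]), float(bits[1])))
                except ValueError as exc:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: non-numeric coordinate {line!r}"
                    ) from exc
        flush(lineno)
    return out


def _write_tps(config_set: ConfigurationSet, path: Path) -> None:
    scheme = config_set.scheme
    with open(path, "w") as fh:
        for cfg in config_set:
            fh.write(f"LM={scheme.n_points}\n")
            for x, y in cfg.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(
                f"ID={cfg.individual_id}:{cfg.site}:{cfg.tooth_class}:"
                f"{cfg.side}:{cfg.replicate}\n"
            )


def read_landmark_table(
    path: str | Path, scheme: LandmarkScheme, dialect: str = "delimited"
) -> ConfigurationSet:
    """Read a landmark file into a validated :class:`ConfigurationSet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "delimited":
        return _read_delimited(path, scheme)
    if dialect == "tps":
        return _read_tps(path, scheme)
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_landmark_table(
    config_set: ConfigurationSet, path: str | Path, dialect: str = "delimited"
) -> None:
    """Write a configuration set in the requested dialect."""
    path = Path(path)
    if dialect == "delimited":
        _write_delimited(config_set, path)
    elif dialect == "tps":
        _write_tps(config_set, path)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
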