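"""Depth profiles and their canonical TSV serialisation.

A :class:`DepthProfile` is the common currency of the package: an ordered
series of (depth, value) pairs with a declared quantity kind.  Depth is in mm,
zero at the mat–atmosphere interface and positive downward.

The on-disk dialect is tab-separated text with ``# key=value`` comment header
lines carrying metadata (units, kind, generator parameters), then a header row
``depth_mm<TAB>value``, then numeric rows.  Formatting is deterministic
(repr-roundtrip floats, LF endings) so two writes of the same profile are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger("oxymat")

#: recognised profile kinds and their default units
PROFILE_KINDS = {
    "o2_concentration": "umol/L",
    "par": "uE/m2/s",
    "organic_carbon": "wt%",
    "net_rate": "nmol/L/s",
}

_NONNEG_KINDS = {"o2_concentration", "par", "organic_carbon"}


class ProfileError(ValueError):
    """Raised for malformed or invariant-violating profiles."""


@dataclass
class DepthProfile:
    """Ordered (depth, value) series with a declared quantity kind.

    Parameters
    ----------
    depths : array-like
        Depths in mm, strictly increasing, 0 at the mat–atmosphere interface.
    values : array-like
        Measured or simulated quantity at each depth.
    kind : str
        One of ``o2_concentration``, ``par``, ``organic_carbon``, ``net_rate``.
    metadata : dict
        Free-form key-value metadata (time of day, generator parameters, ...).
    """

    depths: np.ndarray
    values: np.ndarray
    kind: str = "o2_concentration"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.values.ndim != 1:
            raise ProfileError("depths and values must be one-dimensional")
        if self.depths.size != self.values.size:
            raise ProfileError(
                f"length mismatch: {self.depths.size} depths vs "
                f"{self.values.size} values"
            )
        if self.depths.size == 0:
            raise ProfileError("empty profile")
        if not np.all(np.isfinite(self.depths)) or not np.all(
            np.isfinite(self.values)
        ):
            raise ProfileError("profile contains non-finite entries")
        if self.depths.size > 1 and not np.all(np.diff(self.depths) > 0):
            raise ProfileError("depths must be strictly increasing")
        if self.kind not in PROFILE_KINDS:
            raise ProfileError(
                f"unknown profile kind {self.kind!r}; expected one of "
                f"{sorted(PROFILE_KINDS)}"
            )
        if self.kind in _NONNEG_KINDS and np.any(self.values < 0):
            raise ProfileError(f"{self.kind} values must be non-negative")

    def __len__(self) -> int:
        return int(self.depths.size)

    @property
    def units(self) -> str:
        return self.metadata.get("units", PROFILE_KINDS[self.kind])

    def resample(self, new_depths) -> "DepthProfile":
        """Linear interpolation onto ``new_depths`` (constant extrapolation)."""
        new_depths = np.asarray(new_depths, dtype=float)
        vals = np.interp(new_depths, self.depths, self.values)
        return DepthProfile(new_depths, vals, kind=self.kind,
                            metadata=dict(self.metadata))


def write_profile(profile: DepthProfile, path) -> None:
    """Write a profile in the canonical TSV dialect (deterministic bytes)."""
    path = Path(path)
    lines = [f"# kind={profile.kind}"]
    if "units" not in profile.metadata:
        lines.append(f"# units={PROFILE_KINDS[profile.kind]}")
    for key in sorted(profile.metadata):
        lines.append(f"# {key}={profile.metadata[key]}")
    lines.append("depth_mm\tvalue")
    for d, v in zip(profile.depths, profile.values):
        lines.append(f"{float(d)!r}\t{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", newline="\n")


def read_profile(path, kind: str | None = None) -> DepthProfile:
    """Read a profile written by :func:`write_profile`.

    ``kind`` overrides the metadata declaration; if neither is present the
    default ``o2_concentration`` is applied with a logged warning.
    """
    path = Path(path)
    metadata: dict = {}
    depths: list[float] = []
    values: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                metadata[key.strip()] = val.strip()
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols[:2] != ["depth_mm", "value"]:
                raise ProfileError(
                    f"{path}:{lineno}: expected header 'depth_mm\\tvalue', "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ProfileError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        try:
            depths.append(float(cols[0]))
            values.append(float(cols[1]))
        except ValueError as exc:
            raise ProfileError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    file_kind = metadata.pop("kind", None)
    if kind is None:
        kind = file_kind
    if kind is None:
        kind = "o2_concentration"
        logger.warning("%s: no kind metadata; defaulting to %s", path, kind)
    if "units" not in metadata:
        metadata["units"] = PROFILE_KINDS.get(kind, "")
        logger.warning("%s: no units metadata; defaulting to %s", path,
                       metadata["units"])
    return DepthProfile(np.array(depths), np.array(values), kind=kind,
                        metadata=metadata)
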