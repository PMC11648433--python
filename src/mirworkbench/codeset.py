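"""Data model for nCounter-style count data.

An nCounter run produces, per lane (one sample's position on the cartridge),
a vector of counts over the probes of a fixed codeset.  Besides endogenous
target probes the codeset carries control probes -- positive controls spiked
at a known concentration titration, negative controls against sequences absent
from any sample, ligation controls, exogenous spike-ins and housekeeping mRNA
probes -- and every downstream computation keys on the probe class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "Stage",
    "ProbeDefinition",
    "LaneMetadata",
    "CountMatrix",
    "ValidationError",
    "ParseError",
    "EmptySelectionError",
]


class ValidationError(ValueError):
    """Input violates a data-model invariant (coordinates in the message)."""


class ParseError(ValueError):
    """A file could not be interpreted as the expected dialect."""


class EmptySelectionError(ValidationError):
    """A probe-class subset or normaliser selection came back empty."""


class ProbeClass(str, enum.Enum):
    """The six probe classes of an nCounter miRNA codeset."""

    ENDOGENOUS = "endogenous"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    LIGATION = "ligation"
    SPIKEIN = "spikein"
    HOUSEKEEPING = "housekeeping"

    @classmethod
    def parse(cls, text: str) -> "ProbeClass":
        key = str(text).strip().lower()
        aliases = {
            "endogenous": cls.ENDOGENOUS,
            "endogenous1": cls.ENDOGENOUS,
            "positive": cls.POSITIVE,
            "negative": cls.NEGATIVE,
            "ligation": cls.LIGATION,
            "spikein": cls.SPIKEIN,
            "spikeincontrol": cls.SPIKEIN,
            "spike_in": cls.SPIKEIN,
            "housekeeping": cls.HOUSEKEEPING,
        }
        if key not in aliases:
            raise ValidationError(f"unknown probe class {text!r}")
        return aliases[key]


class Stage(str, enum.Enum):
    """Processing stage of a count matrix.

    Workflows advance a matrix through these stages in a workflow-specific
    order; the stage tag records the last transform applied.
    """

    RAW = "raw"
    BACKGROUND_CORRECTED = "background_corrected"
    POSITIVE_NORMALISED = "positive_normalised"
    CONTENT_NORMALISED = "content_normalised"


@dataclass(frozen=True)
class ProbeDefinition:
    """One probe of the codeset.

    ``concentration_fM`` is the spiked concentration of a positive-control
    probe and must be present exactly for positive probes.
    """

    probe_id: str
    probe_class: ProbeClass
    concentration_fM: Optional[float] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.probe_class is ProbeClass.POSITIVE:
            if self.concentration_fM is None:
                raise ValidationError(
                    f"positive probe {self.probe_id!r} needs concentration_fM"
                )
            if self.concentration_fM < 0:
                raise ValidationError(
                    f"probe {self.probe_id!r}: negative concentration"
                )
        elif self.concentration_fM is not None:
            raise ValidationError(
                f"probe {self.probe_id!r} ({self.probe_class.value}): "
                "concentration_fM is reserved for positive controls"
            )


@dataclass(frozen=True)
class LaneMetadata:
    """Scanner metadata for one lane.

    ``fov_counted``/``fov_attempted`` are fields of view successfully imaged
    over those attempted; ``binding_density`` is the scanner's image-saturation
    readout.  Absent scanner attributes are ``None`` (marked missing), never 0.
    """

    lane_id: str
    group: Optional[str] = None
    fov_counted: Optional[int] = None
    fov_attempted: Optional[int] = None
    binding_density: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fov_attempted is not None and self.fov_attempted <= 0:
            raise ValidationError(f"lane {self.lane_id!r}: fov_attempted must be > 0")
        if (
            self.fov_counted is not None
            and self.fov_attempted is not None
            and self.fov_counted > self.fov_attempted
        ):
            raise ValidationError(
                f"lane {self.lane_id!r}: fov_counted > fov_attempted"
            )
        if self.fov_counted is not None and self.fov_counted < 0:
            raise ValidationError(f"lane {self.lane_id!r}: negative fov_counted")
        if self.binding_density is not None and self.binding_density < 0:
            raise ValidationError(f"lane {self.lane_id!r}: negative binding density")


@dataclass
class CountMatrix:
    """Lanes x probes count grid with probe and lane annotation.

    ``values`` is a pandas DataFrame indexed by lane_id with one column per
    probe_id, in stable lane/probe order.  Counts live on the linear scale at
    every stage; log transforms happen inside consuming operations.
    """

    lanes: Sequence[LaneMetadata]
    probes: Sequence[ProbeDefinition]
    values: pd.DataFrame
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.lanes = list(self.lanes)
        self.probes = list(self.probes)
        if not isinstance(self.stage, Stage):
            self.stage = Stage(self.stage)
        lane_ids = [ln.lane_id for ln in self.lanes]
        probe_ids = [p.probe_id for p in self.probes]
        if len(set(lane_ids)) != len(lane_ids):
            raise ValidationError("duplicate lane_id")
        if len(set(probe_ids)) != len(probe_ids):
            dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
            raise ValidationError(f"duplicate probe_id: {dupes}")
        vals = pd.DataFrame(self.values)
        if list(vals.index) != lane_ids or list(vals.columns) != probe_ids:
            try:
                vals = vals.loc[lane_ids, probe_ids]
            except KeyError as exc:
                raise ValidationError(f"values grid does not cover annotation: {exc}")
        if vals.isna().any().any():
            cell = next(
                (ln, pr)
                for ln in vals.index
                for pr in vals.columns
                if pd.isna(vals.at[ln, pr])
            )
            raise ValidationError(f"missing count at lane {cell[0]!r}, probe {cell[1]!r}")
        arr = vals.to_numpy(dtype=float)
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at lane {vals.index[i]!r}, probe {vals.columns[j]!r}"
            )
        if self.stage is Stage.RAW and not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"raw-stage count is not an integer at lane {vals.index[i]!r}, "
                f"probe {vals.columns[j]!r}"
            )
        self.values = vals.astype(int) if self.stage is Stage.RAW else vals.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def lane_ids(self) -> list[str]:
        return [ln.lane_id for ln in self.lanes]

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def n_lanes(self) -> int:
        return len(self.lanes)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def groups(self) -> pd.Series:
        """Per-lane group labels as a Series indexed by lane_id."""
        return pd.Series(
            {ln.lane_id: ln.group for ln in self.lanes}, name="group"
        )

    def lane(self, lane_id: str) -> LaneMetadata:
        for ln in self.lanes:
            if ln.lane_id == lane_id:
                return ln
        raise KeyError(lane_id)

    def probe(self, probe_id: str) -> ProbeDefinition:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def classes_present(self) -> set[ProbeClass]:
        return {p.probe_class for p in self.probes}

    def subset_by_class(self, probe_class: ProbeClass | str) -> "CountMatrix":
        """Restrict to probes of one class, lane order preserved.

        Raises :class:`EmptySelectionError` when the class does not occur in
        the codeset at all (as opposed to an empty result of a value filter).
        """
        probe_class = (
            probe_class
            if isinstance(probe_class, ProbeClass)
            else ProbeClass.parse(probe_class)
        )
        keep = [p for p in self.probes if p.probe_class is probe_class]
        if not keep:
            raise EmptySelectionError(
                f"codeset has no probes of class {probe_class.value!r}"
            )
        return self.subset_by_probes([p.probe_id for p in keep])

    def subset_by_probes(self, probe_ids: Iterable[str]) -> "CountMatrix":
        wanted = list(probe_ids)
        missing = [p for p in wanted if p not in self.values.columns]
        if missing:
            raise ValidationError(f"probes not in codeset: {missing}")
        order = [p for p in self.probe_ids if p in set(wanted)]
        probes = [p for p in self.probes if p.probe_id in set(wanted)]
        return CountMatrix(
            lanes=list(self.lanes),
            probes=probes,
            values=self.values[order].copy(),
            stage=self.stage,
        )

    def with_values(self, values: pd.DataFrame, stage: Stage) -> "CountMatrix":
        """Same annotation, new value grid and stage."""
        return CountMatrix(
            lanes=list(self.lanes), probes=list(self.probes), values=values, stage=stage
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            lanes=list(self.lanes),
            probes=list(self.probes),
            values=self.values.copy(),
            stage=self.stage,
        )

    def equals(self, other: "CountMatrix", rel_tol: float = 0.0) -> bool:
        if self.lane_ids != other.lane_ids or self.probe_ids != other.probe_ids:
            return False
        if self.stage is not other.stage:
            return False
        a = self.values.to_numpy(dtype=float)
        b = other.values.to_numpy(dtype=float)
        if rel_tol == 0.0:
            return bool(np.array_equal(a, b))
        return bool(np.allclose(a, b, rtol=rel_tol, atol=0.0))
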