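"""Study dataset containers: dose events and timed concentration observations."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CovariateRecord
from .pkmodel import DoseEvent, IndividualParams


@dataclass(frozen=True)
class Observation:
    """A timed concentration measurement.

    ``bql`` marks values below the assay's lower limit of quantification
    (0.2 mg/L); such rows are retained in the data but excluded from
    fitting by default.
    """

    time_h: float
    dv_mg_L: float
    bql: bool = False


@dataclass
class Subject:
    id: str
    covariates: CovariateRecord
    doses: list[DoseEvent]
    observations: list[Observation]

    def validate(self) -> None:
        if not self.doses:
            raise ValueError(f"subject {self.id}: at least one dose required")
        first = min(d.start_h for d in self.doses)
        for i, obs in enumerate(self.observations):
            if obs.time_h < first:
                raise ValueError(
                    f"subject {self.id}, observation {i}: time {obs.time_h} "
                    f"precedes first dose at {first}"
                )
            if not obs.bql and not obs.dv_mg_L > 0:
                raise ValueError(
                    f"subject {self.id}, observation {i}: non-BQL DV must be "
                    f"positive, got {obs.dv_mg_L}"
                )


@dataclass
class SimTruth:
    """Ground truth stored by the simulator for recovery tests."""

    etas: dict[str, tuple[float, float]]
    params: dict[str, IndividualParams]


@dataclass
class StudyDataset:
    subjects: list[Subject]
    truth: SimTruth | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset must contain at least one subject")

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.subjects:
            if s.id in seen:
                raise ValueError(f"duplicate subject id {s.id!r}")
            seen.add(s.id)
            s.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        """All observation rows, including BQL-flagged ones."""
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_quantifiable(self) -> int:
        return sum(1 for s in self.subjects for o in s.observations if not o.bql)

    def covariate_median(self, name: str) -> float:
        return float(np.median([getattr(s.covariates, name) for s in self.subjects]))
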