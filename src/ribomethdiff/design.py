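"""Study design: donors x growth states x technical replicates.

The reference design is three primary fibroblast donors (HDF76, HDF85,
HDF161), each profiled in three growth states — proliferating (P),
contact-inhibited quiescent (Q) and peroxide-induced senescent (SIPS) —
with two technical sequencing replicates per biological sample, i.e.
18 libraries over 9 biological samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["Sample", "StudyDesign", "STATES", "DEFAULT_DONORS", "default_design"]

STATES = ("P", "Q", "SIPS")
DEFAULT_DONORS = ("HDF76", "HDF85", "HDF161")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    donor: str
    state: str
    tech_rep: int = 1

    @property
    def biological_id(self) -> str:
        return f"{self.donor}.{self.state}"


@dataclass(frozen=True)
class StudyDesign:
    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        keys = [(s.donor, s.state, s.tech_rep) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (donor, state, tech_rep) in design")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in design")
        for s in self.samples:
            if s.state not in STATES:
                raise ValueError(f"unknown state {s.state!r} for sample {s.sample_id}")

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def donors(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.samples:
            if s.donor not in out:
                out.append(s.donor)
        return tuple(out)

    @property
    def states(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.samples:
            if s.state not in out:
                out.append(s.state)
        return tuple(out)

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"sample {sample_id!r} not in design")

    def biological_samples(self) -> list[tuple[str, str, str]]:
        """Unique biological samples as (id, donor, state), design order.

        The id is the shared ``biological_id`` when a biological sample has
        multiple technical replicates, else the library's own sample_id.
        """
        groups: dict[str, list[Sample]] = {}
        for s in self.samples:
            groups.setdefault(s.biological_id, []).append(s)
        return [
            (
                (members[0].sample_id if len(members) == 1 else bid),
                members[0].donor,
                members[0].state,
            )
            for bid, members in groups.items()
        ]

    def biological_design(self) -> "StudyDesign":
        """Collapse technical replicates to one entry per biological sample.

        A biological sample with several libraries is renamed to its
        ``biological_id`` (matching merged count profiles); one with a single
        library keeps its own sample_id, so replicate-free designs pass
        through unchanged.
        """
        return StudyDesign(
            tuple(
                Sample(bid, donor, state)
                for bid, donor, state in self.biological_samples()
            )
        )

    def is_complete_crossing(self) -> bool:
        cells = {(d, st) for _, d, st in self.biological_samples()}
        return cells == {(d, st) for d in self.donors for st in self.states}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "donor": [s.donor for s in self.samples],
                "state": [s.state for s in self.samples],
                "tech_rep": [s.tech_rep for s in self.samples],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDesign":
        required = {"sample_id", "donor", "state"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table missing column(s): {sorted(missing)}")
        reps = df["tech_rep"] if "tech_rep" in df.columns else [1] * len(df)
        return cls(
            tuple(
                Sample(str(r), str(d), str(st), int(t))
                for r, d, st, t in zip(df["sample_id"], df["donor"], df["state"], reps)
            )
        )

    @classmethod
    def read(cls, path: str | Path) -> "StudyDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_design(
    donors: Iterable[str] = DEFAULT_DONORS,
    states: Iterable[str] = STATES,
    tech_reps: int = 2,
) -> StudyDesign:
    """3 donors x 3 states x 2 technical replicates = 18 libraries."""
    samples = [
        Sample(f"{d}.{st}.r{r}", d, st, r)
        for d in donors
        for st in states
        for r in range(1, tech_reps + 1)
    ]
    return StudyDesign(tuple(samples))
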