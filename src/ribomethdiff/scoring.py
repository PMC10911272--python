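"""RMS scoring: fragment end counts -> per-site methylation scores.

A 2'-O-methyl group protects the phosphodiester bond 3' of the modified
ribose from alkaline hydrolysis, so fragment ends are depleted at that
bond relative to its neighbours.  The score for a site at position ``p``
(bond ``p``, between positions ``p`` and ``p+1``) is the flank-normalised
protection

    score = clip(1 - n_site / mean(flank counts), 0, 1)

with flanks taken ``w`` bonds to each side, skipping bonds that belong to
other catalogued sites (their counts are themselves depleted and would
deflate the local cleavage baseline).  A score of 1 means full
methylation, 0 means none.  Sites whose flank coverage falls below
``min_flank_mean`` are masked as missing rather than reported noisily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import SiteCatalog
from .design import StudyDesign

__all__ = [
    "EndCountProfile",
    "ScoreParams",
    "RMSScoreTable",
    "read_end_counts",
    "write_end_counts",
    "merge_technical_replicates",
    "compute_rms_scores",
    "score_validity_summary",
]

END_CONVENTIONS = ("five_prime", "three_prime", "both")


@dataclass
class EndCountProfile:
    """Per-bond fragment end counts for one library.

    ``counts[subunit][i]`` is the end count attributed to bond ``i+1`` (the
    bond 3' of position ``i+1``); a subunit of length L has L-1 bonds.
    """

    sample_id: str
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for su, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"{self.sample_id}/{su}: counts must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{self.sample_id}/{su}: negative counts")
            self.counts[su] = arr

    @property
    def library_size(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


@dataclass(frozen=True)
class ScoreParams:
    """Scoring knobs: flank window (bonds per side), coverage threshold,
    and which fragment end carries the cleavage evidence."""

    window: int = 2
    min_flank_mean: float = 10.0
    end_convention: str = "five_prime"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_flank_mean < 0:
            raise ValueError("min_flank_mean must be >= 0")
        if self.end_convention not in END_CONVENTIONS:
            raise ValueError(f"end_convention must be one of {END_CONVENTIONS}")


@dataclass
class RMSScoreTable:
    """Sites x samples matrix of methylation scores in [0, 1]; NaN = masked."""

    scores: pd.DataFrame  # index: site labels, columns: sample ids

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("scores outside [0, 1]")

    @property
    def valid_mask(self) -> pd.DataFrame:
        return self.scores.notna()

    def write(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="site", float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path) -> "RMSScoreTable":
        df = pd.read_csv(path, sep="\t", index_col="site")
        return cls(df)


def read_end_counts(
    path: str | Path,
    reference_lengths: Mapping[str, int],
    sample_id: str | None = None,
) -> EndCountProfile:
    """Read a bedGraph-like TSV (subunit, position, count) into a profile.

    The position column indexes the bond (1..L-1).  Positions absent from
    the file get count 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    count_col = next((c for c in df.columns if c.startswith("count")), None)
    if count_col is None or not {"subunit", "position"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns subunit, position, count*")
    counts: dict[str, np.ndarray] = {}
    for su, length in reference_lengths.items():
        arr = np.zeros(length - 1, dtype=np.int64)
        sub = df[df["subunit"] == su]
        pos = sub["position"].to_numpy(dtype=int)
        if len(pos) and (pos.min() < 1 or pos.max() > length - 1):
            raise ValueError(f"{path}: {su} bond index outside 1..{length - 1}")
        arr[pos - 1] = sub[count_col].to_numpy(dtype=np.int64)
        counts[su] = arr
    return EndCountProfile(sample_id=sample_id or path.stem, counts=counts)


def write_end_counts(profile: EndCountProfile, path: str | Path) -> None:
    rows = ["subunit\tposition\tcount5p"]
    for su, arr in profile.counts.items():
        nz = np.nonzero(arr)[0]
        rows.extend(f"{su}\t{i + 1}\t{arr[i]}" for i in nz)
    Path(path).write_text("\n".join(rows) + "\n")


def merge_technical_replicates(
    profiles: Sequence[EndCountProfile], design: StudyDesign
) -> list[EndCountProfile]:
    """Sum counts position-wise across technical replicates of each biological sample."""
    n_reps: dict[str, int] = {}
    for s in design:
        n_reps[s.biological_id] = n_reps.get(s.biological_id, 0) + 1
    by_bio: dict[str, EndCountProfile] = {}
    order: list[str] = []
    for prof in profiles:
        sample = design.sample(prof.sample_id)  # KeyError if unknown
        bio = sample.biological_id
        if bio not in by_bio:
            # single-replicate samples keep their own id (matches the design)
            name = prof.sample_id if n_reps[bio] == 1 else bio
            merged = EndCountProfile(
                sample_id=name, counts={su: arr.copy() for su, arr in prof.counts.items()}
            )
            by_bio[bio] = merged
            order.append(bio)
        else:
            merged = by_bio[bio]
            if set(merged.counts) != set(prof.counts):
                raise ValueError(f"replicates of {bio} cover different subunits")
            for su, arr in prof.counts.items():
                if merged.counts[su].shape != arr.shape:
                    raise ValueError(
                        f"replicates of {bio} disagree on {su} length: "
                        f"{merged.counts[su].shape[0]} vs {arr.shape[0]}"
                    )
                merged.counts[su] = merged.counts[su] + arr
    return [by_bio[b] for b in order]


def _site_bond_indices(catalog: SiteCatalog) -> dict[str, set[int]]:
    """0-based bond array indices of catalogued site bonds, per subunit."""
    out: dict[str, set[int]] = {}
    for s in catalog:
        out.setdefault(s.subunit, set()).add(s.position - 1)
    return out


def compute_rms_scores(
    profiles: Sequence[EndCountProfile],
    catalog: SiteCatalog,
    params: ScoreParams = ScoreParams(),
) -> RMSScoreTable:
    """Score every catalogued site in every profile.

    Sites too close to a reference end to have any flank, or whose flank
    mean is below ``params.min_flank_mean``, are masked (NaN), never an
    exception.
    """
    site_bonds = _site_bond_indices(catalog)
    labels = catalog.labels
    data = np.full((len(labels), len(profiles)), np.nan)
    w = params.window
    for j, prof in enumerate(profiles):
        for i, site in enumerate(catalog):
            arr = prof.counts.get(site.subunit)
            if arr is None:
                continue
            nbonds = catalog.reference_lengths[site.subunit] - 1
            if arr.shape[0] != nbonds:
                raise ValueError(
                    f"{prof.sample_id}/{site.subunit}: expected {nbonds} bonds, "
                    f"got {arr.shape[0]}"
                )
            b = site.position - 1  # 0-based bond index
            if b >= nbonds:
                continue  # terminal position has no 3' bond: masked
            flank_ix = [
                k
                for k in range(b - w, b + w + 1)
                if k != b and 0 <= k < nbonds and k not in site_bonds[site.subunit]
            ]
            if not flank_ix:
                continue
            flank_mean = float(arr[flank_ix].mean())
            if flank_mean < params.min_flank_mean:
                continue
            data[i, j] = min(max(1.0 - arr[b] / flank_mean, 0.0), 1.0)
    return RMSScoreTable(
        pd.DataFrame(data, index=labels, columns=[p.sample_id for p in profiles])
    )


def score_validity_summary(table: RMSScoreTable) -> dict:
    """Counts of valid (unmasked) scores per sample and per site, plus overall fraction."""
    mask = table.valid_mask
    n_cells = mask.size
    return {
        "per_sample": mask.sum(axis=0),
        "per_site": mask.sum(axis=1),
        "n_valid": int(mask.to_numpy().sum()),
        "n_cells": int(n_cells),
        "fraction_valid": float(mask.to_numpy().sum() / n_cells) if n_cells else float("nan"),
    }
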