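"""Substrate residency statistics from distance trajectories.

The occupancy statistic used throughout: a substrate is *bound* in a
frame when its distance to a reference atom (by default the Calpha of
the pocket-edge glycine at the end of TM3) falls inside a distance
window, 3.5-8.0 Angstrom by default, both edges inclusive.  Per-replicate
bound fractions are combined as a plain mean with a sample (n-1)
standard deviation.  A narrower 6-8 Angstrom window flags frames where a
chloride ion overlaps the sulfate site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Structure

__all__ = [
    "TrajectoryTrace",
    "BindingWindow",
    "BindingStatistic",
    "DEFAULT_WINDOW",
    "SITE_INTERSECTION_WINDOW",
    "extract_distance_trace",
    "bound_mask",
    "bound_fraction",
    "aggregate_replicates",
    "site_intersection_fraction",
    "read_trace",
    "write_trace",
]


@dataclass
class TrajectoryTrace:
    """Per-frame substrate-to-reference distances for one replicate."""

    replicate_id: str
    distances: np.ndarray
    source: str = "file"  # synthetic | file | coordinates
    seed: int | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1 or self.distances.size < 1:
            raise ValueError("a trace needs at least one frame")
        if not np.all(np.isfinite(self.distances)) or np.any(self.distances < 0):
            raise ValueError("distances must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class BindingWindow:
    """Closed distance interval defining the bound state."""

    lower: float = 3.5
    upper: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError(f"need 0 <= lower < upper, got [{self.lower}, {self.upper}]")

    def contains(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, float)
        return (d >= self.lower) & (d <= self.upper)


DEFAULT_WINDOW = BindingWindow(3.5, 8.0)
#: window in which a bound chloride overlaps the sulfate binding site
SITE_INTERSECTION_WINDOW = BindingWindow(6.0, 8.0)


@dataclass
class BindingStatistic:
    """Replicate-aggregated bound fraction: mean with sample sd."""

    per_replicate_fractions: list[float]
    mean: float
    sd: float
    n_replicates: int
    single_replicate: bool = False

    def as_percent(self) -> str:
        """Rounded percentage report in the usual '82 +/- 4%' style."""
        return f"{round(self.mean * 100):.0f} +/- {round(self.sd * 100):.0f}%"


def extract_distance_trace(
    frames: Sequence[Structure],
    ligand_selection: dict,
    reference: dict,
    replicate_id: str = "rep",
) -> TrajectoryTrace:
    """Per-frame distance between a ligand (centroid if multi-atom) and a
    reference atom.

    *ligand_selection* and *reference* are keyword dicts passed to
    :meth:`Structure.select`; the reference must resolve to exactly one
    atom per frame (default choice in practice: ``names="CA"`` of the
    reference residue).
    """
    distances = []
    for i, frame in enumerate(frames):
        lig = frame.select(**ligand_selection)
        if not lig:
            raise KeyError(f"ligand selection resolves to no atoms in frame {i}")
        ref = frame.select(**reference)
        if len(ref) != 1:
            raise KeyError(
                f"reference selection resolves to {len(ref)} atoms in frame {i}; need 1")
        centroid = np.mean([a.position for a in lig], axis=0)
        distances.append(float(np.linalg.norm(centroid - ref[0].position)))
    return TrajectoryTrace(replicate_id=replicate_id,
                           distances=np.array(distances), source="coordinates")


def bound_mask(trace: TrajectoryTrace, window: BindingWindow = DEFAULT_WINDOW) -> np.ndarray:
    """Boolean per-frame mask: lower <= d <= upper (closed interval)."""
    return window.contains(trace.distances)


def bound_fraction(trace: TrajectoryTrace, window: BindingWindow = DEFAULT_WINDOW) -> float:
    """Fraction of frames with the substrate inside the binding window."""
    mask = bound_mask(trace, window)
    return float(np.count_nonzero(mask)) / trace.n_frames


def aggregate_replicates(
    traces: Sequence[TrajectoryTrace],
    window: BindingWindow = DEFAULT_WINDOW,
) -> BindingStatistic:
    """Mean and sample sd (ddof=1) of per-replicate bound fractions.

    With a single replicate the sd is reported as 0 and flagged.
    """
    if not traces:
        raise ValueError("need at least one trace")
    fractions = [bound_fraction(t, window) for t in traces]
    mean = float(np.mean(fractions))
    if len(fractions) == 1:
        return BindingStatistic(fractions, mean, 0.0, 1, single_replicate=True)
    sd = float(np.std(fractions, ddof=1))
    return BindingStatistic(fractions, mean, sd, len(fractions))


def site_intersection_fraction(
    trace: TrajectoryTrace,
    window: BindingWindow = SITE_INTERSECTION_WINDOW,
) -> float:
    """Fraction of frames in the 6-8 Angstrom band where the chloride
    intersects the sulfate site."""
    return bound_fraction(trace, window)


# ---------------------------------------------------------------------------
# trace TSV I/O: '# replicate=<id> source=<src>' header then frame<TAB>distance


def write_trace(trace: TrajectoryTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# replicate={trace.replicate_id} source={trace.source}")
        if trace.seed is not None:
            fh.write(f" seed={trace.seed}")
        fh.write("\nframe\tdistance_A\n")
        for i, d in enumerate(trace.distances):
            fh.write(f"{i}\t{d:.6f}\n")


def read_trace(path: str | Path) -> TrajectoryTrace:
    replicate_id = Path(path).stem
    meta: dict[str, str] = {}
    distances = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if line.startswith("frame"):
                continue
            _, d = line.split("\t")
            distances.append(float(d))
    return TrajectoryTrace(
        replicate_id=meta.get("replicate", replicate_id),
        distances=np.array(distances),
        source=meta.get("source", "file"),
        seed=int(meta["seed"]) if "seed" in meta else None,
    )
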