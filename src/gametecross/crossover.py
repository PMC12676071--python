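"""Window aggregation and crossover calling on haplotype-origin tracks.

Origin labels are aggregated into non-overlapping windows of 10% relative
chromosome length by majority vote (ties and empty windows are missing).
Crossovers are counted as label changes between consecutive informative
windows; a change whose flanking window midpoints are separated by more than
the maximum gap (default 30% relative length) is discarded as unresolvable.
Each event's position is the midpoint of the two flanking informative window
midpoints, and its resolution is the number of intervening missing windows.

Crossovers outside the outermost window midpoints, and double crossovers
within one window, are undetectable by construction at this resolution; the
synthetic-data module quantifies that censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import ORIGIN_A, ORIGIN_B, ORIGIN_MISSING
from .phasing import HaplotypeTrack

__all__ = [
    "CrossoverConfig",
    "WindowTrack",
    "CrossoverEvent",
    "aggregate_windows",
    "call_crossovers",
    "events_to_frame",
    "crossover_summary",
]


@dataclass(frozen=True)
class CrossoverConfig:
    """Window size, gap rule and gap-boundary convention for crossover calling."""

    window_fraction: float = 0.10
    max_gap_rel: float = 0.30
    inclusive_gap: bool = True  # whether a separation of exactly max_gap_rel is kept

    def __post_init__(self):
        n = 1.0 / self.window_fraction
        if abs(n - round(n)) > 1e-9:
            raise ValueError("1/window_fraction must be an integer")
        if self.max_gap_rel < 2 * self.window_fraction - 1e-12:
            raise ValueError("max_gap_rel must be >= 2 * window_fraction")

    @property
    def n_windows(self) -> int:
        return int(round(1.0 / self.window_fraction))

    def midpoint(self, window_index) -> float:
        return (np.asarray(window_index) + 0.5) * self.window_fraction


@dataclass
class WindowTrack:
    """Per-chromosome window labels of one gamete (A/B/missing per window)."""

    nucleus_id: str
    labels: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (n_windows,) int8


@dataclass(frozen=True)
class CrossoverEvent:
    individual_id: str
    nucleus_id: str
    chromosome: str
    position_rel: float
    resolution: int  # intervening missing windows (0 = adjacent informative windows)
    left_window: int
    right_window: int


def _window_labels(origins: np.ndarray, rel: np.ndarray, cfg: CrossoverConfig) -> np.ndarray:
    if ((rel < 0) | (rel > 1)).any():
        raise ValueError("relative marker positions outside [0, 1]")
    n = cfg.n_windows
    idx = np.minimum((rel / cfg.window_fraction).astype(int), n - 1)
    count_a = np.bincount(idx[origins == ORIGIN_A], minlength=n)
    count_b = np.bincount(idx[origins == ORIGIN_B], minlength=n)
    labels = np.full(n, ORIGIN_MISSING, dtype=np.int8)
    labels[count_a > count_b] = ORIGIN_A
    labels[count_b > count_a] = ORIGIN_B
    return labels


def aggregate_windows(track: HaplotypeTrack, cfg: CrossoverConfig | None = None) -> WindowTrack:
    """Majority-vote origin labels into relative windows, per chromosome."""
    cfg = cfg or CrossoverConfig()
    wt = WindowTrack(nucleus_id=track.nucleus_id)
    for chrom, origins in track.origins.items():
        wt.labels[chrom] = _window_labels(origins, track.rel_positions[chrom], cfg)
    return wt


def _call_chrom(labels: np.ndarray, cfg: CrossoverConfig) -> list[tuple[float, int, int, int]]:
    informative = np.flatnonzero(labels >= 0)
    if len(informative) < 2:
        return []
    out = []
    left, right = informative[:-1], informative[1:]
    change = labels[left] != labels[right]
    sep = (right - left) * cfg.window_fraction
    tol = 1e-9
    keep = sep <= cfg.max_gap_rel + tol if cfg.inclusive_gap else sep < cfg.max_gap_rel - tol
    for lw, rw in zip(left[change & keep], right[change & keep]):
        pos = 0.5 * (cfg.midpoint(lw) + cfg.midpoint(rw))
        out.append((float(pos), int(rw - lw - 1), int(lw), int(rw)))
    return out


def call_crossovers(
    wt: WindowTrack, individual_id: str, cfg: CrossoverConfig | None = None
) -> list[CrossoverEvent]:
    """Call crossovers on an aggregated window track.

    Chromosomes with fewer than two informative windows yield no events.
    """
    cfg = cfg or CrossoverConfig()
    events = []
    for chrom, labels in wt.labels.items():
        for pos, res, lw, rw in _call_chrom(labels, cfg):
            events.append(
                CrossoverEvent(
                    individual_id=individual_id,
                    nucleus_id=wt.nucleus_id,
                    chromosome=chrom,
                    position_rel=pos,
                    resolution=res,
                    left_window=lw,
                    right_window=rw,
                )
            )
    return events


_EVENT_COLUMNS = [
    "individual_id",
    "nucleus_id",
    "chromosome",
    "position_rel",
    "resolution",
    "left_window",
    "right_window",
]


def events_to_frame(events: list[CrossoverEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    return pd.DataFrame([e.__dict__ for e in events])[_EVENT_COLUMNS]


def crossover_summary(
    events: pd.DataFrame,
    nuclei: pd.DataFrame,
    n_chromosomes: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-nucleus and per-individual crossover counts.

    ``nuclei`` must list every retained nucleus (columns individual_id,
    nucleus_id) so that zero-event nuclei are counted. Returns the per-nucleus
    table (total count and crossovers per chromatid = total / n chromosomes),
    the per-individual table (means over nuclei), and resolution statistics
    (fraction of events resolved with at most one intervening missing window).
    """
    per_nuc = nuclei[["individual_id", "nucleus_id"]].copy()
    if len(events):
        counts = events.groupby("nucleus_id").size()
        per_nuc["n_crossovers"] = per_nuc["nucleus_id"].map(counts).fillna(0).astype(int)
    else:
        per_nuc["n_crossovers"] = 0
    per_nuc["cc_per_chromatid"] = per_nuc["n_crossovers"] / n_chromosomes
    per_ind = (
        per_nuc.groupby("individual_id", sort=True)
        .agg(n_nuclei=("nucleus_id", "size"), mean_co_per_nucleus=("n_crossovers", "mean"),
             cc_per_chromatid=("cc_per_chromatid", "mean"))
        .reset_index()
    )
    if len(events):
        res = events["resolution"].to_numpy()
        res_stats = {
            "n_events": int(len(events)),
            "fraction_resolution_le_1": float((res <= 1).mean()),
            "histogram": {int(k): int(v) for k, v in zip(*np.unique(res, return_counts=True))},
        }
    else:
        res_stats = {"n_events": 0, "fraction_resolution_le_1": float("nan"), "histogram": {}}
    return per_nuc, per_ind, res_stats
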